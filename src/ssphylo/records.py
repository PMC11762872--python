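"""Core value types: nucleotide records and sequence-structure pairs.

All coordinates in this package are 0-based, half-open intervals ``[start, end)``.
Sequences are RNA: ``T`` is normalized to ``U`` on input, alphabet ``{A,C,G,U,N}``.
Secondary structures use dot-bracket notation over ``{(, ), .}`` with nested
(pseudoknot-free) pairs only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NUCLEOTIDES = "ACGU"
SEQ_ALPHABET = frozenset("ACGUN")
STRUCT_ALPHABET = frozenset("().")

#: Canonical Watson-Crick pairs plus the GU wobble, both orientations.
ALLOWED_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


class RecordError(ValueError):
    """Raised when a sequence record violates its invariants."""


class StructureError(ValueError):
    """Raised for malformed dot-bracket strings; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


def normalize_seq(raw: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return raw.upper().replace("T", "U")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence.

    ``taxon_name`` holds the organism name used by the species-name filter;
    when built from FASTA it defaults to the first two whitespace-separated
    words of the description (or the id with underscores read as spaces).
    """

    id: str
    seq: str
    description: str = ""
    taxon_name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise RecordError("sequence record id must be non-empty")
        if not self.seq:
            raise RecordError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - SEQ_ALPHABET
        if bad:
            raise RecordError(
                f"record {self.id!r}: invalid characters {sorted(bad)} "
                "(expected A/C/G/U/N after normalization)"
            )

    def __len__(self) -> int:
        return len(self.seq)


def parse_dotbracket(structure: str, entry_id: str = "?") -> tuple[tuple[int, int], ...]:
    """Return the base pairs (i, j), i < j, of a dot-bracket string.

    Validates balance and nesting with an explicit stack; the error names the
    entry and the 0-based position of the first offending bracket.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(structure):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(
                    f"entry {entry_id!r}: unmatched ')' at position {pos}", pos
                )
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(
                f"entry {entry_id!r}: invalid structure character {ch!r} at position {pos}",
                pos,
            )
    if stack:
        raise StructureError(
            f"entry {entry_id!r}: unmatched '(' at position {stack[-1]}", stack[-1]
        )
    return tuple(sorted(pairs))


@dataclass(frozen=True)
class SequenceStructurePair:
    """A nucleotide sequence with a same-length dot-bracket structure."""

    record: SequenceRecord
    structure: str
    pairs: tuple[tuple[int, int], ...] = field(init=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.record.seq):
            raise StructureError(
                f"entry {self.record.id!r}: structure length {len(self.structure)} "
                f"!= sequence length {len(self.record.seq)}"
            )
        object.__setattr__(
            self, "pairs", parse_dotbracket(self.structure, self.record.id)
        )

    @property
    def seq(self) -> str:
        return self.record.seq

    @property
    def id(self) -> str:
        return self.record.id

    def __len__(self) -> int:
        return len(self.record.seq)


def pairing_states(structure: str) -> str:
    """Alias: the structure string itself is the per-position pairing state."""
    return structure
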