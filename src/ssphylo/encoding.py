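"""The 12-letter sequence-structure alphabet.

Each position of an RNA carries one of four nucleotides and one of three
pairing states (unpaired, paired left = the 5' partner, paired right = the
3' partner), giving 12 combined states.  A :class:`TranslationTable` is a
bijection between (nucleotide, state) and a 12-letter alphabet; the concrete
letters are arbitrary but fixed and versioned, and all downstream scores,
distances and likelihoods are invariant under relabeling.

``N`` is allowed only at unpaired positions and is encoded as a 13th wildcard
symbol that distance and likelihood computations treat as missing data.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import NUCLEOTIDES, SequenceRecord, SequenceStructurePair, StructureError

UNPAIRED, PAIRED_LEFT, PAIRED_RIGHT = ".", "(", ")"
STATES = (UNPAIRED, PAIRED_LEFT, PAIRED_RIGHT)

#: Wildcard symbol for an unpaired N.
WILDCARD = "N"
#: Gap character used in alignments of encoded sequences.
GAP = "-"


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class TranslationTable:
    """Bijection (nucleotide, pairing state) <-> 12-letter alphabet."""

    forward: dict
    version: str = "ssphylo-1"

    def __post_init__(self) -> None:
        keys = {(n, s) for n in NUCLEOTIDES for s in STATES}
        if set(self.forward) != keys:
            raise EncodingError("translation table must cover all 12 (nucleotide, state) keys")
        letters = list(self.forward.values())
        if len(set(letters)) != 12:
            raise EncodingError("translation table letters must be 12 distinct symbols")
        if WILDCARD in letters or GAP in letters:
            raise EncodingError(f"letters {WILDCARD!r} and {GAP!r} are reserved")

    @property
    def alphabet(self) -> str:
        """The 12 letters, in (state-major, nucleotide-minor) order."""
        return "".join(self.forward[(n, s)] for s in STATES for n in NUCLEOTIDES)

    @property
    def inverse(self) -> dict:
        return {v: k for k, v in self.forward.items()}

    def encode_symbol(self, nuc: str, state: str) -> str:
        if nuc == "N":
            if state != UNPAIRED:
                raise EncodingError("N at a paired position cannot be encoded")
            return WILDCARD
        try:
            return self.forward[(nuc, state)]
        except KeyError:
            raise EncodingError(f"cannot encode ({nuc!r}, {state!r})") from None

    def decode_symbol(self, symbol: str) -> tuple[str, str]:
        if symbol == WILDCARD:
            return "N", UNPAIRED
        try:
            return self.inverse[symbol]
        except KeyError:
            raise EncodingError(f"symbol {symbol!r} not in alphabet") from None

    def to_tsv(self) -> str:
        lines = ["nucleotide\tstate\tletter"]
        for s in STATES:
            for n in NUCLEOTIDES:
                lines.append(f"{n}\t{s}\t{self.forward[(n, s)]}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, version: str = "custom") -> "TranslationTable":
        forward = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("nucleotide"):
                continue
            nuc, state, letter = line.split("\t")
            forward[(nuc, state)] = letter
        return cls(forward=forward, version=version)


def _default_forward() -> dict:
    by_state = {UNPAIRED: "ACGU", PAIRED_LEFT: "BDHV", PAIRED_RIGHT: "EFIW"}
    return {
        (nuc, state): letters[i]
        for state, letters in by_state.items()
        for i, nuc in enumerate(NUCLEOTIDES)
    }


#: Default table: unpaired A,C,G,U -> A,C,G,U; paired-left -> B,D,H,V;
#: paired-right -> E,F,I,W.
DEFAULT_TABLE = TranslationTable(forward=_default_forward())


@dataclass(frozen=True)
class EncodedSequence:
    """A sequence over the 12-letter alphabet (plus the N wildcard)."""

    id: str
    symbols: str
    alphabet_version: str = DEFAULT_TABLE.version

    def __len__(self) -> int:
        return len(self.symbols)


def encode(pair: SequenceStructurePair, table: TranslationTable = DEFAULT_TABLE) -> EncodedSequence:
    """Translate a sequence-structure pair into 12-letter symbols."""
    symbols = []
    for pos, (nuc, state) in enumerate(zip(pair.seq, pair.structure)):
        if nuc == "N" and state != UNPAIRED:
            raise EncodingError(f"entry {pair.id!r}: N at paired position {pos}")
        symbols.append(table.encode_symbol(nuc, state))
    return EncodedSequence(id=pair.id, symbols="".join(symbols), alphabet_version=table.version)


def decode(enc: EncodedSequence, table: TranslationTable = DEFAULT_TABLE) -> SequenceStructurePair:
    """Invert :func:`encode`; validates that the implied brackets balance."""
    seq_chars, struct_chars = [], []
    for symbol in enc.symbols:
        nuc, state = table.decode_symbol(symbol)
        seq_chars.append(nuc)
        struct_chars.append(state)
    structure = "".join(struct_chars)
    record = SequenceRecord(id=enc.id, seq="".join(seq_chars)) if seq_chars else None
    if record is None:
        raise EncodingError("cannot decode an empty encoded sequence into a record")
    try:
        return SequenceStructurePair(record=record, structure=structure)
    except StructureError as exc:
        raise EncodingError(f"entry {enc.id!r}: decoded brackets unbalanced: {exc}") from exc
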