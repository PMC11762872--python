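"""On-disk formats: FASTA, xfasta, 1-letter-encoded FASTA, constraint files.

The xfasta dialect carried here: per entry one ``>`` header line, then a
sequence block, then a dot-bracket structure block of the same total length.
Both blocks may span multiple lines; a line consisting only of ``(``, ``)``
and ``.`` is a structure line, anything else is sequence.  Newick trees are
handled in :mod:`ssphylo.trees`.

All readers accept Unix or Windows line endings and UTF-8 text.
"""

from __future__ import annotations

import os
import re
from typing import Iterable, Sequence

from Bio import SeqIO

from .encoding import GAP, WILDCARD, DEFAULT_TABLE, EncodedSequence, TranslationTable
from .records import (
    SEQ_ALPHABET,
    STRUCT_ALPHABET,
    SequenceRecord,
    SequenceStructurePair,
    normalize_seq,
)


class ParseError(ValueError):
    pass


def _derive_taxon_name(rec_id: str, description: str) -> str:
    # description from Bio.SeqIO includes the id as the first token
    words = description.split()
    if words and words[0] == rec_id:
        words = words[1:]
    if len(words) >= 2:
        return " ".join(words[:2])
    if words:
        return words[0]
    return rec_id.replace("_", " ")


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read nucleotide FASTA; T is normalized to U and case folded to upper.

    Raises :class:`ParseError` naming the offending record on duplicate ids,
    empty sequences or out-of-alphabet characters.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = normalize_seq(str(rec.seq))
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - SEQ_ALPHABET
        if bad:
            raise ParseError(
                f"{path}: record {rec.id!r} contains invalid characters {sorted(bad)}"
            )
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=seq,
                description=rec.description,
                taxon_name=_derive_taxon_name(rec.id, rec.description),
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description and rec.description != rec.id:
                desc = rec.description
                if desc.startswith(rec.id):
                    desc = desc[len(rec.id):].strip()
                if desc:
                    header += f" {desc}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


_STRUCT_LINE = re.compile(r"^[().]+$")


def read_xfasta(path: str | os.PathLike) -> list[SequenceStructurePair]:
    """Read sequence + dot-bracket entries; validates lengths and bracket balance."""
    pairs: list[SequenceStructurePair] = []
    seen: set[str] = set()
    with open(path) as fh:
        header: str | None = None
        seq_parts: list[str] = []
        struct_parts: list[str] = []

        def flush() -> None:
            if header is None:
                return
            rec_id = header.split()[0]
            if rec_id in seen:
                raise ParseError(f"{path}: duplicate entry id {rec_id!r}")
            seen.add(rec_id)
            seq = normalize_seq("".join(seq_parts))
            structure = "".join(struct_parts)
            if not seq:
                raise ParseError(f"{path}: entry {rec_id!r} has no sequence block")
            if len(structure) != len(seq):
                raise ParseError(
                    f"{path}: entry {rec_id!r}: structure length {len(structure)} "
                    f"!= sequence length {len(seq)}"
                )
            record = SequenceRecord(
                id=rec_id,
                seq=seq,
                description=header,
                taxon_name=_derive_taxon_name(rec_id, header),
            )
            pairs.append(SequenceStructurePair(record=record, structure=structure))

        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                seq_parts, struct_parts = [], []
            elif _STRUCT_LINE.match(line):
                struct_parts.append(line)
            else:
                if struct_parts:
                    raise ParseError(
                        f"{path}: entry {header!r}: sequence line after structure block"
                    )
                seq_parts.append(line)
        flush()
    return pairs


def write_xfasta(pairs: Iterable[SequenceStructurePair], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for pair in pairs:
            fh.write(f">{pair.id}\n")
            for i in range(0, len(pair.seq), width):
                fh.write(pair.seq[i : i + width] + "\n")
            for i in range(0, len(pair.structure), width):
                fh.write(pair.structure[i : i + width] + "\n")


def read_encoded_fasta(
    path: str | os.PathLike, table: TranslationTable = DEFAULT_TABLE
) -> list[EncodedSequence]:
    """Read 1-letter-encoded FASTA; gap characters are preserved (alignments)."""
    allowed = set(table.alphabet) | {WILDCARD, GAP}
    out: list[EncodedSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        symbols = str(rec.seq)
        bad = set(symbols) - allowed
        if bad:
            raise ParseError(
                f"{path}: record {rec.id!r} has symbols outside the 12-letter "
                f"alphabet: {sorted(bad)}"
            )
        out.append(EncodedSequence(id=rec.id, symbols=symbols, alphabet_version=table.version))
    return out


def write_encoded_fasta(
    encoded: Iterable[EncodedSequence],
    path: str | os.PathLike,
    table: TranslationTable = DEFAULT_TABLE,
    width: int = 70,
) -> None:
    allowed = set(table.alphabet) | {WILDCARD, GAP}
    with open(path, "w") as fh:
        for enc in encoded:
            bad = set(enc.symbols) - allowed
            if bad:
                raise ParseError(
                    f"record {enc.id!r} has symbols outside the alphabet: {sorted(bad)}"
                )
            fh.write(f">{enc.id}\n")
            for i in range(0, len(enc.symbols), width):
                fh.write(enc.symbols[i : i + width] + "\n")


def read_constraints(path: str | os.PathLike, seq_length: int | None = None) -> frozenset[int]:
    """Read positions forbidden to pair: one 0-based position or half-open
    ``start-end`` range per line; ``#`` starts a comment."""
    forbidden: set[int] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                if "-" in line:
                    start_s, end_s = line.split("-", 1)
                    start, end = int(start_s), int(end_s)
                    if end < start:
                        raise ValueError
                    forbidden.update(range(start, end))
                else:
                    forbidden.add(int(line))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: cannot parse constraint {line!r}") from None
    if seq_length is not None:
        out_of_range = [p for p in forbidden if p < 0 or p >= seq_length]
        if out_of_range:
            raise ParseError(
                f"{path}: constraint positions out of range for length {seq_length}: "
                f"{sorted(out_of_range)[:5]}"
            )
    return frozenset(forbidden)


def write_constraints(forbidden: Sequence[int] | frozenset[int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# positions forbidden to pair (0-based)\n")
        for pos in sorted(forbidden):
            fh.write(f"{pos}\n")
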