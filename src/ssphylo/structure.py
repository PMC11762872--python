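"""Secondary-structure prediction for ITS2 sequences.

Two routes, mirroring common practice for this spacer:

* **Homology modeling** — base pairs of a curated template structure are
  transferred onto a target through a global nucleotide alignment; the
  fraction of template pairs that survive (both partners aligned, target
  nucleotides able to pair) is the *structure transfer percentage* used by
  the >= 50% homology filter.
* **Constrained folding** — a weighted base-pair-maximization fold (Nussinov
  recursion, GC=3 / AU=2 / GU=1 weights, minimum hairpin loop of 3) with a
  set of positions forbidden to pair.  Forbidding the central ring of the
  ITS2 steers the fold toward the four homologous core helices.

The helix-core report counts helices emanating from the exterior (central)
loop; pairs of internal sub-helices count toward their exterior helix, so a
four-helix ITS2 reports ``n_helices == 4`` with the third helix the longest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alignment import gotoh_align
from .records import (
    ALLOWED_PAIRS,
    SequenceRecord,
    SequenceStructurePair,
)

#: Stacking-free pair weights for the folding objective.
PAIR_WEIGHTS = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "U"): 2.0, ("U", "A"): 2.0,
    ("G", "U"): 1.0, ("U", "G"): 1.0,
}


class StructurePredictionError(ValueError):
    pass


@dataclass(frozen=True)
class TemplateRecord:
    """A sequence-structure pair used as a homology-modeling template."""

    pair: SequenceStructurePair
    name: str

    def __post_init__(self) -> None:
        if not self.pair.pairs:
            raise StructurePredictionError(
                f"template {self.name!r} has no base pairs"
            )


@dataclass(frozen=True)
class TransferResult:
    """Homology-modeled structure plus the structure transfer percentage."""

    modeled: SequenceStructurePair
    transfer_percent: float
    template_name: str


def transfer_structure(
    target: SequenceRecord,
    template: TemplateRecord,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    denominator: str = "template",
) -> TransferResult:
    """Transfer the template's base pairs onto ``target`` via global alignment.

    A template pair (p, q) transfers to target positions (i, j) iff both p
    and q align to non-gap target columns and target[i], target[j] form a
    canonical or GU wobble pair.  ``transfer_percent`` divides the number of
    transferred pairs by the template's pair count (``denominator='template'``,
    the default) or by half the target positions receiving structure
    (``denominator='target'``).
    """
    tmpl_seq = template.pair.seq

    def score(x: str, y: str) -> float:
        return match if x == y else mismatch

    gt, gm, _ = gotoh_align(target.seq, tmpl_seq, score, gap_open, gap_extend)
    # map template position -> target position (or None)
    tmpl_to_target: dict[int, int | None] = {}
    ti = mi = 0
    for x, y in zip(gt, gm):
        if y is not None:
            tmpl_to_target[mi] = ti if x is not None else None
            mi += 1
        if x is not None:
            ti += 1

    structure = ["."] * len(target.seq)
    transferred = 0
    for p, q in template.pair.pairs:
        i, j = tmpl_to_target[p], tmpl_to_target[q]
        if i is None or j is None:
            continue
        if (target.seq[i], target.seq[j]) not in ALLOWED_PAIRS:
            continue
        structure[i], structure[j] = "(", ")"
        transferred += 1
    n_template_pairs = len(template.pair.pairs)
    if denominator == "template":
        pct = 100.0 * transferred / n_template_pairs
    elif denominator == "target":
        pct = 100.0 * (2 * transferred) / len(target.seq)
    else:
        raise StructurePredictionError(f"unknown denominator {denominator!r}")
    modeled = SequenceStructurePair(record=target, structure="".join(structure))
    return TransferResult(modeled=modeled, transfer_percent=pct, template_name=template.name)


def select_best_template(
    target: SequenceRecord, templates: Sequence[TemplateRecord], **kwargs
) -> TransferResult:
    """Best transfer over a template set; ties keep the earlier template."""
    if not templates:
        raise StructurePredictionError("empty template list")
    best: TransferResult | None = None
    for tmpl in templates:
        res = transfer_structure(target, tmpl, **kwargs)
        if best is None or res.transfer_percent > best.transfer_percent:
            best = res
    return best


def filter_by_homology(
    results: Sequence[TransferResult], threshold_percent: float = 50.0
) -> tuple[list[TransferResult], list[tuple[TransferResult, str]]]:
    """Keep results with transfer_percent >= threshold (inclusive)."""
    kept, discarded = [], []
    for res in results:
        if res.transfer_percent >= threshold_percent:
            kept.append(res)
        else:
            discarded.append((res, "low_structural_homology"))
    return kept, discarded


def constrained_fold(
    seq: SequenceRecord | str,
    forbidden: Iterable[int] = (),
    min_loop: int = 3,
    exterior: Iterable[int] = (),
) -> SequenceStructurePair:
    """Weighted base-pair-maximization fold with unpaired-position constraints.

    Maximizes the sum of pair weights (GC=3, AU=2, GU=1) over nested
    structures in which no forbidden position pairs, every pair (i, j) holds
    at least ``min_loop`` unpaired-or-paired nucleotides between partners
    (``j - i - 1 >= min_loop``), and N never pairs.  ``exterior`` positions
    must stay on the exterior loop: they neither pair nor sit inside any
    pair, the semantics used for the ITS2 central ring (so the fold cannot
    bridge two core helices with one enclosing pair).  Deterministic
    traceback: leaving i unpaired is preferred at ties, then the smallest
    partner j for i, then the leftmost split.
    """
    record = seq if isinstance(seq, SequenceRecord) else SequenceRecord(id="seq", seq=seq)
    if min_loop < 0:
        raise StructurePredictionError("min_loop must be >= 0")
    s = record.seq
    n = len(s)
    ext = set(exterior)
    forb = set(forbidden) | ext
    bad = [p for p in forb if p < 0 or p >= n]
    if bad:
        raise StructurePredictionError(f"forbidden positions out of range: {sorted(bad)[:5]}")
    # ext_before[p] = number of exterior positions < p
    ext_before = [0] * (n + 1)
    for p in range(n):
        ext_before[p + 1] = ext_before[p] + (1 if p in ext else 0)

    def weight(i: int, j: int) -> float | None:
        if i in forb or j in forb:
            return None
        if j - i - 1 < min_loop:
            return None
        if ext_before[j] - ext_before[i + 1] > 0:  # would enclose the ring
            return None
        return PAIR_WEIGHTS.get((s[i], s[j]))

    # pair-weight matrix with -inf at disallowed pairs, for the vector fill
    NEG = float("-inf")
    nuc_idx = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
    wtab = np.full((5, 5), NEG)
    for (x, y), w in PAIR_WEIGHTS.items():
        wtab[nuc_idx[x], nuc_idx[y]] = w
    codes = np.array([nuc_idx[c] for c in s], dtype=int) if n else np.zeros(0, dtype=int)
    wmat = wtab[np.ix_(codes, codes)] if n else np.zeros((0, 0))
    if forb:
        fb = sorted(forb)
        wmat[fb, :] = NEG
        wmat[:, fb] = NEG
    ii, jj = np.indices(wmat.shape) if n else (None, None)
    if n:
        wmat[jj - ii - 1 < min_loop] = NEG
        if ext:
            eb = np.array(ext_before)
            inside = eb[jj] - eb[np.minimum(ii + 1, n)]
            wmat[inside > 0] = NEG

    # W[i, j] = best score on s[i..j]; the extra row keeps W[k+1, j] = 0
    # for k == j, and the untouched lower triangle supplies empty intervals.
    W = np.zeros((n + 1, max(n, 1)))
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            cand = wmat[i, i + 1 : j + 1] + W[i + 1, i:j] + W[i + 2 : j + 2, j]
            W[i, j] = max(W[i + 1, j], float(cand.max()))

    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i <= j:
            if i == j:
                return
            target = W[i][j]
            if abs((W[i + 1][j] if i + 1 <= j else 0.0) - target) < 1e-9:
                i += 1
                continue
            for k in range(i + 1, j + 1):
                w = weight(i, k)
                if w is None:
                    continue
                inner = W[i + 1][k - 1] if i + 1 <= k - 1 else 0.0
                right = W[k + 1][j] if k + 1 <= j else 0.0
                if abs(w + inner + right - target) < 1e-9:
                    structure[i], structure[k] = "(", ")"
                    traceback(i + 1, k - 1)
                    i, j = k + 1, j
                    break
            else:  # pragma: no cover - DP guarantees a branch matches
                raise StructurePredictionError("traceback failed")

    if n:
        traceback(0, n - 1)
    return SequenceStructurePair(record=record, structure="".join(structure))


@dataclass(frozen=True)
class HelixCoreReport:
    """Exterior-helix architecture of a secondary structure."""

    n_helices: int
    helix_lengths: tuple[int, ...]
    longest_index: int | None  # 1-based, ties -> smallest index

    @property
    def fits_four_helix_core(self) -> bool:
        """True for the canonical eukaryote ITS2 core: four helices, third longest."""
        return self.n_helices == 4 and self.longest_index == 3


def analyze_core(pair: SequenceStructurePair) -> HelixCoreReport:
    """Count helices emanating from the exterior (central) loop.

    An exterior helix is rooted at a pair enclosed by no other pair; all
    pairs nested inside it (including sub-helices past multibranch points)
    count toward its length.  Helices are reported in 5'->3' order of their
    opening position.
    """
    pairs = pair.pairs
    if not pairs:
        return HelixCoreReport(n_helices=0, helix_lengths=(), longest_index=None)
    lengths: list[int] = []
    current_end = -1
    for i, j in pairs:  # sorted by opening position; nested, so intervals don't cross
        if i > current_end:
            lengths.append(1)
            current_end = j
        else:
            lengths[-1] += 1
    longest = max(lengths)
    return HelixCoreReport(
        n_helices=len(lengths),
        helix_lengths=tuple(lengths),
        longest_index=lengths.index(longest) + 1,
    )


def transfer_report_tsv(results: Iterable[TransferResult]) -> str:
    """TSV: id, template, transfer_percent, n_helices, longest_index."""
    lines = ["id\ttemplate\ttransfer_percent\tn_helices\tlongest_index"]
    for res in results:
        rep = analyze_core(res.modeled)
        lines.append(
            f"{res.modeled.id}\t{res.template_name}\t{res.transfer_percent:.2f}"
            f"\t{rep.n_helices}\t{rep.longest_index if rep.longest_index else 'NA'}"
        )
    return "\n".join(lines) + "\n"
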