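"""ITS2 annotation inside a 5.8S-ITS2-28S fragment.

The ITS2 spacer is delimited by locating, with profile hidden Markov models,
the conserved end of the 5.8S gene and the conserved start of the 28S gene.
The region strictly between the two hits is the ITS2.  Following the proximal
stem convention, the annotated region is then extended by up to ``L`` (default
25) nucleotides into each flanking gene: those nucleotides form the stem that
closes the ITS2.  A sequence is "annotatable by the full proximal stem" only
when both extensions have the full length ``L``.

The profile HMMs are small plan-7-style models (match/insert/delete per
column) trained from an ungapped motif alignment with maximum-likelihood
emissions and pseudocount 1.  Scoring is Viterbi in log-odds space against a
uniform background; the scan is local in the sequence (flanking residues are
free) and local in the model (entry and exit at any column, each paying a
uniform -log(length) penalty), so a flank truncated mid-motif is still
recognized from its surviving columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .records import NUCLEOTIDES, SequenceRecord

_NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}
_LOG_BG = math.log(0.25)


class HmmError(ValueError):
    pass


@dataclass(frozen=True)
class ProfileHMM:
    """Profile HMM over {A,C,G,U} with per-column match emissions.

    ``match_emissions`` has shape (length, 4).  Transition probabilities are
    shared across columns: ``delta`` is the match->insert and match->delete
    probability, ``epsilon`` the insert->insert and delete->delete
    self-transition.
    """

    match_emissions: np.ndarray
    delta: float = 0.02
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.match_emissions.ndim != 2 or self.match_emissions.shape[1] != 4:
            raise HmmError("match_emissions must have shape (length, 4)")
        if self.length < 1:
            raise HmmError("profile HMM needs at least one match state")
        sums = self.match_emissions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise HmmError("each match emission distribution must sum to 1")
        if not (0 < self.delta < 0.5 and 0 < self.epsilon < 1):
            raise HmmError("invalid transition parameters")

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def log_transitions(self) -> dict[str, float]:
        d, e = self.delta, self.epsilon
        return {
            "mm": math.log(1 - 2 * d),
            "mi": math.log(d),
            "md": math.log(d),
            "ii": math.log(e),
            "im": math.log(1 - e),
            "dd": math.log(e),
            "dm": math.log(1 - e),
        }


def build_profile_hmm(
    motif_records: Sequence[SequenceRecord] | Sequence[str],
    pseudocount: float = 1.0,
    delta: float = 0.02,
    epsilon: float = 0.1,
) -> ProfileHMM:
    """Train a profile HMM from an ungapped motif alignment.

    Emissions are maximum-likelihood column frequencies with ``pseudocount``
    added to every nucleotide count; all rows must have equal length.
    """
    seqs = [r.seq if isinstance(r, SequenceRecord) else str(r) for r in motif_records]
    if not seqs:
        raise HmmError("need at least one motif sequence")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise HmmError("motif alignment rows must have equal length (ungapped)")
    counts = np.full((length, 4), pseudocount, dtype=float)
    for s in seqs:
        for k, ch in enumerate(s):
            if ch in _NUC_INDEX:
                counts[k, _NUC_INDEX[ch]] += 1.0
    emissions = counts / counts.sum(axis=1, keepdims=True)
    return ProfileHMM(match_emissions=emissions, delta=delta, epsilon=epsilon)


def viterbi_scan(seq: str, hmm: ProfileHMM) -> tuple[int, int, float]:
    """Best-scoring occurrence of the profile in ``seq``.

    Returns ``(start, end, log_odds)`` with a 0-based half-open interval.
    The alignment is local in both the sequence and the model: a path enters
    at any match column a and leaves at any column b >= a, paying a uniform
    entry and exit penalty of ``-log(length)`` each (so a truncated motif can
    still be recognized from its surviving columns, while isolated lucky
    matches are penalized).  Interior columns may be deleted and insert
    states may add sequence between columns.  Emissions are scored as
    log-odds against a uniform background, so unmatched sequence flanks
    contribute zero and never change the optimum.
    """
    n, L = len(seq), hmm.length
    if n < 1:
        raise HmmError("empty sequence")
    t = hmm.log_transitions
    NEG = -math.inf
    entry = -math.log(L)  # uniform choice of entry column; same for exit

    # log-odds emission per (column, position); N scores as background
    lo = np.empty((L, n))
    log_e = np.log(hmm.match_emissions)
    for i, ch in enumerate(seq):
        if ch in _NUC_INDEX:
            lo[:, i] = log_e[:, _NUC_INDEX[ch]] - _LOG_BG
        else:
            lo[:, i] = 0.0

    best_score, best_start, best_end = NEG, 0, 1

    def consider(M: np.ndarray, Ms: np.ndarray) -> None:
        nonlocal best_score, best_start, best_end
        i = int(np.argmax(M))
        score = float(M[i]) + entry  # exit penalty
        if score > best_score:
            best_score, best_start, best_end = score, int(Ms[i]), i + 1

    # M/I/D score arrays for the previous model column, plus the sequence
    # start index of the best path reaching each cell.
    prevM = lo[0] + entry
    prevMs = np.arange(n, dtype=int)
    prevI = np.full(n, NEG); prevIs = np.zeros(n, dtype=int)
    prevD = np.full(n, NEG); prevDs = np.zeros(n, dtype=int)
    for i in range(1, n):
        cand = ((prevM[i - 1] + t["mi"], prevMs[i - 1]),
                (prevI[i - 1] + t["ii"], prevIs[i - 1]))
        prevI[i], prevIs[i] = max(cand, key=lambda c: c[0])
    consider(prevM, prevMs)

    for k in range(1, L):
        M = np.full(n, NEG); Ms = np.zeros(n, dtype=int)
        I = np.full(n, NEG); Is = np.zeros(n, dtype=int)
        D = np.full(n, NEG); Ds = np.zeros(n, dtype=int)
        for i in range(n):
            # delete consumes no sequence, so it reads the previous column at i
            cand = ((prevM[i] + t["md"], prevMs[i]),
                    (prevD[i] + t["dd"], prevDs[i]))
            D[i], Ds[i] = max(cand, key=lambda c: c[0])
            # match: transitions from the previous column, or a fresh entry
            cand = [(entry, i)]
            if i > 0:
                cand.extend(((prevM[i - 1] + t["mm"], prevMs[i - 1]),
                             (prevI[i - 1] + t["im"], prevIs[i - 1]),
                             (prevD[i - 1] + t["dm"], prevDs[i - 1])))
            best, start = max(cand, key=lambda c: c[0])
            M[i] = best + lo[k, i]
            Ms[i] = start
            if i > 0:
                cand = ((M[i - 1] + t["mi"], Ms[i - 1]),
                        (I[i - 1] + t["ii"], Is[i - 1]))
                I[i], Is[i] = max(cand, key=lambda c: c[0])
        consider(M, Ms)
        prevM, prevMs, prevI, prevIs, prevD, prevDs = M, Ms, I, Is, D, Ds

    if best_score == NEG:
        raise HmmError("no Viterbi path found")
    return best_start, best_end, best_score


@dataclass(frozen=True)
class Its2Annotation:
    """ITS2 delimitation plus the proximal-stem extension.

    Intervals are 0-based half-open on the input sequence.  The proximal
    interval extends the ITS2 by up to ``L`` nucleotides into the 5.8S (left)
    and 28S (right); ``full_proximal_stem`` is true only when neither
    extension was truncated at a sequence boundary.
    """

    its2_start: int
    its2_end: int
    proximal_start: int
    proximal_end: int
    full_proximal_stem: bool
    log_odds: float

    @property
    def its2_interval(self) -> tuple[int, int]:
        return (self.its2_start, self.its2_end)

    @property
    def proximal_interval(self) -> tuple[int, int]:
        return (self.proximal_start, self.proximal_end)


def viterbi_annotate(
    seq: SequenceRecord,
    hmm5: ProfileHMM,
    hmm3: ProfileHMM,
    L: int = 25,
    min_log_odds: float = 0.0,
) -> Optional[Its2Annotation]:
    """Delimit the ITS2 between the 5.8S-end and 28S-start profile hits.

    Returns ``None`` (an annotation failure, to be filtered downstream) when
    either flank scores below ``min_log_odds`` or the hits do not leave a
    non-empty spacer between them.
    """
    n = len(seq.seq)
    if n < hmm5.length + hmm3.length:
        return None
    _, e5, score5 = viterbi_scan(seq.seq, hmm5)
    if score5 < min_log_odds:
        return None
    tail = seq.seq[e5:]
    if not tail:
        return None
    s3_rel, _, score3 = viterbi_scan(tail, hmm3)
    if score3 < min_log_odds:
        return None
    s3 = e5 + s3_rel
    if s3 <= e5:
        return None
    proximal_start = max(0, e5 - L)
    proximal_end = min(n, s3 + L)
    full = (e5 - L >= 0) and (s3 + L <= n)
    return Its2Annotation(
        its2_start=e5,
        its2_end=s3,
        proximal_start=proximal_start,
        proximal_end=proximal_end,
        full_proximal_stem=full,
        log_odds=score5 + score3,
    )


def filter_annotatable(
    records: Sequence[SequenceRecord],
    annotations: Sequence[Optional[Its2Annotation]],
) -> tuple[list[tuple[SequenceRecord, Its2Annotation]], list[tuple[SequenceRecord, str]]]:
    """Keep records annotated by the full proximal stem.

    Returns ``(kept, discarded)``; each discarded record carries a
    machine-readable reason: ``annotation_failed`` or
    ``truncated_proximal_stem``.
    """
    kept: list[tuple[SequenceRecord, Its2Annotation]] = []
    discarded: list[tuple[SequenceRecord, str]] = []
    for rec, ann in zip(records, annotations, strict=True):
        if ann is None:
            discarded.append((rec, "annotation_failed"))
        elif not ann.full_proximal_stem:
            discarded.append((rec, "truncated_proximal_stem"))
        else:
            kept.append((rec, ann))
    return kept, discarded


def annotations_to_tsv(
    items: Iterable[tuple[SequenceRecord, Optional[Its2Annotation]]]
) -> str:
    """TSV report: id, start, end, proximal bounds, stem flag, score."""
    lines = ["id\tstart\tend\tproximal_start\tproximal_end\tfull_proximal_stem\tscore"]
    for rec, ann in items:
        if ann is None:
            lines.append(f"{rec.id}\tNA\tNA\tNA\tNA\tfalse\tNA")
        else:
            lines.append(
                f"{rec.id}\t{ann.its2_start}\t{ann.its2_end}\t{ann.proximal_start}"
                f"\t{ann.proximal_end}\t{str(ann.full_proximal_stem).lower()}"
                f"\t{ann.log_odds:.4f}"
            )
    return "\n".join(lines) + "\n"
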