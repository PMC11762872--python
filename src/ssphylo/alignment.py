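"""Pairwise and progressive alignment of 12-letter sequence-structure strings.

Alignment of encoded sequences uses a symmetric 12x12 substitution matrix
with affine gap costs (a gap of length k costs ``gap_open + k * gap_extend``;
terminal gaps are penalized like internal ones by default, ClustalW-style).
The default matrix separates the two information channels the encoding fuses:

    score(x, y) = +2 if same nucleotide, -1 otherwise
                  +2 if same pairing state, -2 otherwise

so identical symbols score +4 and a symbol differing in both channels -3.
Multiple alignment is progressive: a neighbor-joining guide tree on
pairwise-identity distances, then profile-profile Gotoh merges in postorder
("once a gap, always a gap").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .encoding import GAP, WILDCARD, DEFAULT_TABLE, EncodedSequence, TranslationTable

# traceback states, in tie-break priority order: match > deletion > insertion
_M, _X, _Y = 0, 1, 2
_NEG = float("-inf")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringModel12:
    """Symmetric 12x12 score matrix over the encoded alphabet + gap costs."""

    scores: dict
    gap_open: float = -8.0
    gap_extend: float = -2.0
    alphabet: str = ""

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise AlignmentError("gap penalties must be <= 0")
        for (x, y), s in self.scores.items():
            if abs(self.scores.get((y, x), s) - s) > 1e-12:
                raise AlignmentError(f"score matrix not symmetric at ({x},{y})")

    def score(self, x: str, y: str) -> float:
        if WILDCARD in (x, y):
            return 0.0
        try:
            return self.scores[(x, y)]
        except KeyError:
            raise AlignmentError(f"symbol pair ({x!r},{y!r}) outside the alphabet") from None

    def to_tsv(self) -> str:
        letters = sorted({x for x, _ in self.scores})
        lines = ["\t" + "\t".join(letters)]
        for x in letters:
            lines.append(x + "\t" + "\t".join(f"{self.scores[(x, y)]:g}" for y in letters))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, gap_open: float = -8.0, gap_extend: float = -2.0) -> "ScoringModel12":
        lines = [l for l in text.splitlines() if l.strip()]
        letters = lines[0].split("\t")[1:]
        scores = {}
        for line in lines[1:]:
            parts = line.split("\t")
            x = parts[0]
            for y, v in zip(letters, parts[1:]):
                scores[(x, y)] = float(v)
        return cls(scores=scores, gap_open=gap_open, gap_extend=gap_extend,
                   alphabet="".join(letters))


def default_model(
    table: TranslationTable = DEFAULT_TABLE,
    gap_open: float = -8.0,
    gap_extend: float = -2.0,
) -> ScoringModel12:
    """Build the default channel-separating 12x12 model for ``table``."""
    inv = table.inverse
    scores = {}
    for x, (nx, sx) in inv.items():
        for y, (ny, sy) in inv.items():
            s = (2.0 if nx == ny else -1.0) + (2.0 if sx == sy else -2.0)
            scores[(x, y)] = s
    return ScoringModel12(
        scores=scores, gap_open=gap_open, gap_extend=gap_extend, alphabet=table.alphabet
    )


def _pair_score_matrix(
    a: Sequence, b: Sequence, score: Callable[[object, object], float]
) -> np.ndarray:
    S = np.empty((len(a), len(b)))
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            S[i, j] = score(x, y)
    return S


def _gotoh_fill(S: np.ndarray, gap_open: float, gap_extend: float):
    """Vectorized three-matrix Gotoh fill given the (la, lb) pair-score matrix.

    Row i of the horizontal-gap matrix Y satisfies a prefix-maximum recurrence
    (Y[i,j] = extend*j + max_{k<j}(max(M,X)[i,k] + open - extend*k)), so each
    row is filled with numpy accumulate operations instead of a j-loop.
    """
    la, lb = S.shape
    go, ge = gap_open, gap_extend
    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)  # gap in b, consumes a
    Y = np.full((la + 1, lb + 1), _NEG)  # gap in a, consumes b
    M[0, 0] = 0.0
    cols = np.arange(lb + 1, dtype=float)
    Y[0, 1:] = go + ge * cols[1:]
    for i in range(1, la + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = best_prev[:-1] + S[i - 1]
        X[i] = np.maximum(
            np.maximum(M[i - 1] + go + ge, X[i - 1] + ge), Y[i - 1] + go + ge
        )
        base = np.maximum(M[i], X[i]) + go - ge * cols
        acc = np.maximum.accumulate(base)
        Y[i, 1:] = acc[:-1] + ge * cols[1:]
    return M, X, Y


def gotoh_align(
    a: Sequence,
    b: Sequence,
    score: Callable[[object, object], float],
    gap_open: float,
    gap_extend: float,
    pair_scores: np.ndarray | None = None,
) -> tuple[list, list, float]:
    """Global affine-gap alignment (three-matrix Gotoh) of two symbol sequences.

    Returns gapped copies of ``a`` and ``b`` (``None`` marks a gap) and the
    optimal score.  A gap run of length k costs ``gap_open + k*gap_extend``.
    Deterministic traceback: diagonal (match) preferred over deletion (gap in
    ``b``) over insertion (gap in ``a``).  ``pair_scores`` may carry the
    precomputed (la, lb) score matrix; otherwise ``score`` is evaluated on
    every symbol pair.
    """
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        raise AlignmentError("cannot align empty sequences")
    S = pair_scores if pair_scores is not None else _pair_score_matrix(a, b, score)
    M, X, Y = _gotoh_fill(S, gap_open, gap_extend)

    # traceback from the best final state, preferring M > X > Y throughout
    i, j = la, lb
    finals = ((M[i, j], _M), (X[i, j], _X), (Y[i, j], _Y))
    best = max(f[0] for f in finals)
    state = next(st for sc, st in finals if sc == best)
    out_a: list = []
    out_b: list = []
    while i > 0 or j > 0:
        if state == _M:
            prev = M[i, j] - S[i - 1, j - 1]
            out_a.append(a[i - 1]); out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            for cand_state, cand in ((_M, M[i, j]), (_X, X[i, j]), (_Y, Y[i, j])):
                if abs(cand - prev) < 1e-9:
                    state = cand_state
                    break
        elif state == _X:
            val = X[i, j]
            out_a.append(a[i - 1]); out_b.append(None)
            i -= 1
            if i == 0 and j == 0:
                break
            opts = ((_M, M[i, j] + gap_open + gap_extend),
                    (_X, X[i, j] + gap_extend),
                    (_Y, Y[i, j] + gap_open + gap_extend))
            for cand_state, cand in opts:
                if abs(cand - val) < 1e-9:
                    state = cand_state
                    break
        else:
            val = Y[i, j]
            out_a.append(None); out_b.append(b[j - 1])
            j -= 1
            if i == 0 and j == 0:
                break
            opts = ((_M, M[i, j] + gap_open + gap_extend),
                    (_Y, Y[i, j] + gap_extend),
                    (_X, X[i, j] + gap_open + gap_extend))
            for cand_state, cand in opts:
                if abs(cand - val) < 1e-9:
                    state = cand_state
                    break
    out_a.reverse(); out_b.reverse()
    return out_a, out_b, float(best)


def _model_tables(model: ScoringModel12):
    """Dense score matrix over (alphabet + wildcard) and a symbol index map."""
    letters = sorted({x for x, _ in model.scores}) + [WILDCARD]
    index = {c: i for i, c in enumerate(letters)}
    k = len(letters)
    S = np.zeros((k, k))
    for (x, y), s in model.scores.items():
        S[index[x], index[y]] = s
    return index, S


def pairwise_align(
    a: EncodedSequence, b: EncodedSequence, model: ScoringModel12 | None = None
) -> tuple[str, str, float]:
    """Globally align two encoded sequences; gaps rendered as ``-``."""
    if model is None:
        model = default_model()
    index, table = _model_tables(model)
    try:
        ia = np.array([index[c] for c in a.symbols])
        ib = np.array([index[c] for c in b.symbols])
    except KeyError as exc:
        raise AlignmentError(f"symbol {exc.args[0]!r} outside the alphabet") from exc
    pair_scores = table[np.ix_(ia, ib)]
    ga, gb, sc = gotoh_align(
        a.symbols, b.symbols, model.score, model.gap_open, model.gap_extend,
        pair_scores=pair_scores,
    )
    to_str = lambda row: "".join(GAP if s is None else s for s in row)
    return to_str(ga), to_str(gb), sc


def fractional_identity(gapped_a: str, gapped_b: str) -> float:
    """Identical symbols / columns aligned without a gap in either row."""
    both = [(x, y) for x, y in zip(gapped_a, gapped_b) if x != GAP and y != GAP]
    if not both:
        return 0.0
    return sum(1 for x, y in both if x == y) / len(both)


@dataclass
class MultipleAlignment:
    """Rows of equal-length gapped symbol strings."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows must be parallel")
        if len(self.rows) >= 1:
            ncol = len(self.rows[0])
            if any(len(r) != ncol for r in self.rows):
                raise AlignmentError("alignment rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("alignment row ids must be unique")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def to_encoded(self) -> list[EncodedSequence]:
        return [EncodedSequence(id=i, symbols=r) for i, r in zip(self.ids, self.rows)]

    def subsample_columns(self, columns: Sequence[int]) -> "MultipleAlignment":
        rows = ["".join(r[c] for c in columns) for r in self.rows]
        return MultipleAlignment(ids=list(self.ids), rows=rows)


def guide_tree(encoded: Sequence[EncodedSequence], model: ScoringModel12 | None = None):
    """NJ guide tree from pairwise-alignment fractional-identity distances."""
    from . import phylogeny  # local import to avoid a cycle

    if len(encoded) < 2:
        raise AlignmentError("need at least two sequences")
    if model is None:
        model = default_model()
    n = len(encoded)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ga, gb, _ = pairwise_align(encoded[i], encoded[j], model)
            D[i, j] = D[j, i] = 1.0 - fractional_identity(ga, gb)
    labels = [e.id for e in encoded]
    return phylogeny.neighbor_joining(labels, D)


def _profile_columns(rows: list[str]) -> list[tuple[str, ...]]:
    return [tuple(r[c] for r in rows) for c in range(len(rows[0]))]


def _column_score(model: ScoringModel12):
    cache: dict = {}

    def score(u: tuple, v: tuple) -> float:
        key = (u, v)
        if key in cache:
            return cache[key]
        total, count = 0.0, 0
        for x in u:
            if x == GAP:
                continue
            for y in v:
                if y == GAP:
                    continue
                total += model.score(x, y)
                count += 1
        val = total / count if count else 0.0
        cache[key] = val
        return val

    return score


def _profile_counts(rows: list[str], index: dict) -> np.ndarray:
    """(n_cols, n_symbols) non-gap symbol counts per alignment column."""
    counts = np.zeros((len(rows[0]), len(index)))
    for row in rows:
        for c, ch in enumerate(row):
            if ch != GAP:
                counts[c, index[ch]] += 1.0
    return counts


def _merge(rows_a: list[str], ids_a: list[str], rows_b: list[str], ids_b: list[str],
           model: ScoringModel12) -> tuple[list[str], list[str]]:
    cols_a = _profile_columns(rows_a)
    cols_b = _profile_columns(rows_b)
    # profile-profile column score: mean pairwise S over non-gap symbols,
    # computed as a count bilinear form (equivalent to _column_score)
    index, table = _model_tables(model)
    Ca = _profile_counts(rows_a, index)
    Cb = _profile_counts(rows_b, index)
    na = Ca.sum(axis=1)
    nb = Cb.sum(axis=1)
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        pair_scores = np.where(denom > 0, (Ca @ table @ Cb.T) / np.where(denom > 0, denom, 1.0), 0.0)
    ga, gb, _ = gotoh_align(cols_a, cols_b, _column_score(model),
                            model.gap_open, model.gap_extend,
                            pair_scores=pair_scores)
    na, nb = len(rows_a), len(rows_b)
    out_rows = []
    for r in range(na):
        out_rows.append("".join(GAP if c is None else c[r] for c in ga))
    for r in range(nb):
        out_rows.append("".join(GAP if c is None else c[r] for c in gb))
    return out_rows, ids_a + ids_b


def progressive_align(
    encoded: Sequence[EncodedSequence], model: ScoringModel12 | None = None
) -> MultipleAlignment:
    """Progressive multiple alignment along the NJ guide tree (postorder)."""
    if model is None:
        model = default_model()
    if len(encoded) < 2:
        raise AlignmentError("need at least two sequences")
    by_id = {e.id: e for e in encoded}
    if len(encoded) == 2:
        ga, gb, _ = pairwise_align(encoded[0], encoded[1], model)
        return MultipleAlignment(ids=[encoded[0].id, encoded[1].id], rows=[ga, gb])
    tree = guide_tree(encoded, model)
    profiles: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            e = by_id[node.taxon.label]
            profiles[node] = ([e.symbols], [e.id])
        else:
            children = node.child_nodes()
            rows, ids = profiles.pop(children[0])
            for child in children[1:]:
                rows_b, ids_b = profiles.pop(child)
                rows, ids = _merge(rows, ids, rows_b, ids_b, model)
            profiles[node] = (rows, ids)
    rows, ids = profiles[tree.seed_node]
    msa = MultipleAlignment(ids=ids, rows=rows)
    # degap invariant: every row reproduces its input exactly
    for rid, enc in by_id.items():
        assert msa.row(rid).replace(GAP, "") == enc.symbols
    return msa
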