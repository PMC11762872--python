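"""Tree inference over the 12-letter sequence-structure alphabet.

Distances (p-distance with a 12-state Jukes-Cantor-type correction),
Saitou-Nei neighbor joining, Fitch parsimony, maximum likelihood by
Felsenstein pruning under 12x12 substitution models, nonparametric bootstrap
with bipartition support mapping, and outgroup rooting (re-exported from
:mod:`ssphylo.trees`).

Gap and wildcard symbols are treated as missing data throughout: excluded
pairwise in distances, a full state set in parsimony, a vector of ones in
likelihood.  All stochastic steps take an explicit seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar

from .alignment import MultipleAlignment
from .encoding import GAP, WILDCARD, DEFAULT_TABLE, TranslationTable
from .trees import root_with_outgroup, map_support, rf_distance  # noqa: F401 (public API)

K = 12  # alphabet size


class PhylogenyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# distances

def p_distance(msa: MultipleAlignment, i: int, j: int) -> float:
    """Proportion of differing symbols over columns comparable in both rows.

    Columns with a gap or wildcard in either row are excluded from both the
    numerator and the denominator.
    """
    skip = {GAP, WILDCARD}
    ri, rj = msa.rows[i], msa.rows[j]
    comparable = diff = 0
    for x, y in zip(ri, rj):
        if x in skip or y in skip:
            continue
        comparable += 1
        if x != y:
            diff += 1
    if comparable == 0:
        raise PhylogenyError(f"rows {i} and {j} share no comparable columns")
    return diff / comparable


def jc12_distance(p: float) -> float:
    """12-state Jukes-Cantor-type correction d = -(11/12) ln(1 - (12/11) p)."""
    if not 0 <= p < 11 / 12:
        raise PhylogenyError(f"p-distance {p:.4f} is saturated (>= 11/12)")
    return -(11 / 12) * math.log(1 - (12 / 11) * p)


def distance_matrix(
    msa: MultipleAlignment, correction: str = "jc12"
) -> tuple[list[str], np.ndarray]:
    """All-pairs distances from an alignment; correction in {'p', 'jc12'}.

    Vectorized equivalent of calling :func:`p_distance` on every row pair
    (the scalar function is kept as the reference implementation).
    """
    _, mat = _state_codes(msa, DEFAULT_TABLE)
    n = msa.n_rows
    D = np.zeros((n, n))
    valid = mat >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise PhylogenyError(f"rows {i} and {j} share no comparable columns")
            p = float(((mat[i] != mat[j]) & both).sum()) / comparable
            d = p if correction == "p" else jc12_distance(p)
            D[i, j] = D[j, i] = d
    return list(msa.ids), D


def distance_matrix_phylip(labels: Sequence[str], D: np.ndarray) -> str:
    """PHYLIP square-format serialization of a distance matrix."""
    lines = [f"{len(labels)}"]
    for lab, row in zip(labels, D):
        name = lab.replace(" ", "_")[:10].ljust(10)
        lines.append(name + "  " + "  ".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(labels: Sequence[str], D: np.ndarray) -> dendropy.Tree:
    """Saitou-Nei NJ with the Studier-Keppler criterion.

    Returns an unrooted tree (trifurcating seed node for n >= 3).  Negative
    branch-length estimates are clamped to zero with the deficit moved to the
    sister edge.  Ties in the Q criterion pick the smallest (label, label)
    pair lexicographically.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise PhylogenyError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-9):
        raise PhylogenyError("distance matrix is not symmetric")
    if n < 2:
        raise PhylogenyError("need at least two taxa")

    taxa = dendropy.TaxonNamespace([str(l) for l in labels])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    node_labels: list[str] = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(str(lab)))
        nodes.append(node)
        node_labels.append(str(lab))
    dist = {(a, b): D[a, b] for a in range(n) for b in range(n)}
    active = list(range(n))
    next_id = n

    def d(a: int, b: int) -> float:
        return 0.0 if a == b else dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    lengths: dict[int, float] = {}
    children: dict[int, list[int]] = {}
    label_of = dict(enumerate(node_labels))
    node_of = dict(enumerate(nodes))

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (m - 2) * d(a, b) - r[a] - r[b]
            key = tuple(sorted((label_of[a], label_of[b])))
            cand = (q, key, a, b)
            if best is None or cand[:2] < best[:2]:
                best = cand
        _, _, a, b = best
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        lb = d(a, b) - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        u = next_id
        next_id += 1
        node_of[u] = dendropy.Node()
        label_of[u] = min(label_of[a], label_of[b])
        children[u] = [a, b]
        lengths[a], lengths[b] = la, lb
        for c in active:
            if c in (a, b):
                continue
            dist[(u, c)] = dist[(c, u)] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        active = [c for c in active if c not in (a, b)] + [u]

    root = dendropy.Node()
    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
        lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
        lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        for x, lx in ((a, la), (b, lb), (c, lc)):
            lengths[x] = max(lx, 0.0)
            root.add_child(node_of[x])
    elif len(active) == 2:
        a, b = active
        lengths[a] = d(a, b) / 2
        lengths[b] = d(a, b) / 2
        root.add_child(node_of[a])
        root.add_child(node_of[b])

    # assemble topology
    def attach(idx: int) -> None:
        for child in children.get(idx, []):
            node_of[idx].add_child(node_of[child])
            attach(child)

    for idx in active:
        attach(idx)
    for idx, length in lengths.items():
        node_of[idx].edge.length = float(length)
    tree.seed_node = root
    tree.is_rooted = False
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.support = None
    return tree


def nj_tree(msa: MultipleAlignment, correction: str = "jc12") -> dendropy.Tree:
    """NJ tree straight from an alignment (distance + neighbor_joining)."""
    labels, D = distance_matrix(msa, correction=correction)
    return neighbor_joining(labels, D)


# ---------------------------------------------------------------------------
# parsimony

def _state_codes(
    msa: MultipleAlignment, table: TranslationTable
) -> tuple[dict[str, int], np.ndarray]:
    alpha = table.alphabet
    code = {c: i for i, c in enumerate(alpha)}
    mat = np.empty((msa.n_rows, msa.n_cols), dtype=np.int8)
    for r, row in enumerate(msa.rows):
        for c, ch in enumerate(row):
            mat[r, c] = code.get(ch, -1)  # -1 = missing (gap/wildcard)
    return code, mat


def _fitch_leaf_masks(
    msa: MultipleAlignment, table: TranslationTable
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-leaf state bitmasks over compressed site patterns, plus counts."""
    _, mat = _state_codes(msa, table)
    patterns, counts = _compress_patterns(mat)
    full = (1 << K) - 1
    masks: dict[str, np.ndarray] = {}
    for r, rid in enumerate(msa.ids):
        states = patterns[r]
        m = np.where(states < 0, full, 1 << states.astype(np.int64))
        masks[rid] = m.astype(np.int64)
    return masks, counts


def _fitch_combine(a, b, cost: np.ndarray):
    inter = a & b
    empty = inter == 0
    cost += empty
    return np.where(empty, a | b, inter)


def fitch_parsimony(
    msa: MultipleAlignment, tree: dendropy.Tree, table: TranslationTable = DEFAULT_TABLE
) -> int:
    """Fitch set-intersection parsimony score over the 12-state alphabet.

    Gaps and wildcards are missing data (full state set).  Polytomies are
    scored by folding children pairwise, which on the trifurcating root of an
    unrooted binary tree equals the score of any binary rooting.
    """
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    if leaf_labels != set(msa.ids):
        raise PhylogenyError("tree leaves do not match alignment rows")
    masks, counts = _fitch_leaf_masks(msa, table)
    n_pat = counts.shape[0]
    cost = np.zeros(n_pat, dtype=np.int64)
    sets: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = masks[node.taxon.label]
        else:
            acc = None
            for child in node.child_nodes():
                cs = sets.pop(child)
                acc = cs if acc is None else _fitch_combine(acc, cs, cost)
            sets[node] = acc
    return int(cost @ counts)


def _enumerate_rooted(leaves: Sequence[str]):
    """All rooted binary tree shapes over ``leaves`` as nested tuples."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for sub in _enumerate_rooted(rest):
        for placed in _insert_everywhere(sub, first):
            yield placed


def _insert_everywhere(tree, leaf):
    yield (leaf, tree)
    if isinstance(tree, tuple):
        left, right = tree
        for t in _insert_everywhere(left, leaf):
            yield (t, right)
        for t in _insert_everywhere(right, leaf):
            yield (left, t)


def _nested_to_dendropy(first_leaf: str, nested, taxa: dendropy.TaxonNamespace) -> dendropy.Tree:
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(sub) -> dendropy.Node:
        if isinstance(sub, tuple):
            node = dendropy.Node()
            node.add_child(build(sub[0]))
            node.add_child(build(sub[1]))
        else:
            node = dendropy.Node(taxon=taxa.require_taxon(sub))
        node.edge.length = 1.0
        return node

    root = dendropy.Node()
    root.add_child(build(first_leaf))
    if isinstance(nested, tuple):
        root.add_child(build(nested[0]))
        root.add_child(build(nested[1]))
    else:
        root.add_child(build(nested))
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def enumerate_topologies(labels: Sequence[str]):
    """All unrooted binary topologies on ``labels`` (deterministic order)."""
    if len(labels) < 3:
        raise PhylogenyError("need at least three taxa")
    taxa = dendropy.TaxonNamespace(list(labels))
    for nested in _enumerate_rooted(list(labels[1:])):
        yield _nested_to_dendropy(labels[0], nested, taxa)


def _nni_neighbors(tree: dendropy.Tree):
    """Yield the NNI rearrangements of every internal edge (clones)."""
    internal_edges = []
    for idx, node in enumerate(tree.preorder_node_iter()):
        if node is tree.seed_node or node.is_leaf():
            continue
        internal_edges.append(idx)
    for edge_idx in internal_edges:
        for which in (0, 1):
            clone = tree.clone(depth=1)
            v = list(clone.preorder_node_iter())[edge_idx]
            u = v.parent_node
            siblings = [c for c in u.child_nodes() if c is not v]
            if not siblings:
                continue
            s = siblings[0]
            a = v.child_nodes()[which]
            # swap subtree a with subtree s across edge (u, v)
            u.remove_child(s)
            v.remove_child(a)
            u.add_child(a)
            v.add_child(s)
            yield clone


def mp_search(
    msa: MultipleAlignment,
    table: TranslationTable = DEFAULT_TABLE,
    exhaustive_max_taxa: int = 8,
) -> dendropy.Tree:
    """Most-parsimonious tree: exhaustive for small taxon sets, else NNI
    hill-climbing (first improvement, deterministic order) from the NJ tree."""
    n = msa.n_rows
    if n <= exhaustive_max_taxa:
        masks, counts = _fitch_leaf_masks(msa, table)

        def score_nested(sub, cost: np.ndarray) -> np.ndarray:
            if isinstance(sub, tuple):
                return _fitch_combine(
                    score_nested(sub[0], cost), score_nested(sub[1], cost), cost
                )
            return masks[sub]

        first = msa.ids[0]
        best_nested, best_score = None, None
        for nested in _enumerate_rooted(list(msa.ids[1:])):
            cost = np.zeros(counts.shape[0], dtype=np.int64)
            _fitch_combine(masks[first], score_nested(nested, cost), cost)
            score = int(cost @ counts)
            if best_score is None or score < best_score:
                best_nested, best_score = nested, score
        taxa = dendropy.TaxonNamespace(list(msa.ids))
        return _nested_to_dendropy(first, best_nested, taxa)
    current = nj_tree(msa)
    current_score = fitch_parsimony(msa, current, table)
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbors(current):
            score = fitch_parsimony(msa, cand, table)
            if score < current_score:
                current, current_score = cand, score
                improved = True
                break
    return current


# ---------------------------------------------------------------------------
# likelihood

@dataclass(frozen=True)
class SubstitutionModel12:
    """Reversible 12x12 rate matrix Q with stationary distribution pi.

    Q is normalized to one expected substitution per site per unit branch
    length.  ``name`` distinguishes the presets; the JC12 preset uses a
    closed-form transition matrix.
    """

    Q: np.ndarray
    pi: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.Q.shape != (K, K) or self.pi.shape != (K,):
            raise PhylogenyError("model dimensions must be 12x12 / 12")
        if not math.isclose(self.pi.sum(), 1.0, abs_tol=1e-9):
            raise PhylogenyError("stationary distribution must sum to 1")
        off = self.Q - np.diag(np.diag(self.Q))
        if (off < -1e-12).any():
            raise PhylogenyError("off-diagonal rates must be non-negative")
        if not np.allclose(self.Q.sum(axis=1), 0.0, atol=1e-9):
            raise PhylogenyError("rate matrix rows must sum to zero")

    @classmethod
    def jc12(cls) -> "SubstitutionModel12":
        pi = np.full(K, 1 / K)
        Q = np.full((K, K), 1 / (K - 1))
        np.fill_diagonal(Q, -1.0)
        return cls(Q=Q, pi=pi, name="jc12")

    @classmethod
    def gtr12(cls, exchangeabilities: np.ndarray, pi: np.ndarray) -> "SubstitutionModel12":
        """GTR: Q_ij = s_ij * pi_j, normalized to 1 expected sub/site."""
        R = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(pi, dtype=float)
        if not np.allclose(R, R.T, atol=1e-9):
            raise PhylogenyError("exchangeability matrix must be symmetric")
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -(pi * np.diag(Q)).sum()
        if rate <= 0:
            raise PhylogenyError("degenerate rate matrix")
        return cls(Q=Q / rate, pi=pi, name="gtr12")

    def P(self, t: float) -> np.ndarray:
        """Transition probabilities P(t) = exp(Qt); row-stochastic."""
        if t < 0:
            raise PhylogenyError("branch length must be non-negative")
        if self.name == "jc12":
            e = math.exp(-K / (K - 1) * t)
            same = 1 / K + (K - 1) / K * e
            diff = 1 / K - 1 / K * e
            P = np.full((K, K), diff)
            np.fill_diagonal(P, same)
            return P
        return expm(self.Q * t)


def _compress_patterns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cols = [tuple(mat[:, c]) for c in range(mat.shape[1])]
    uniq: dict[tuple, int] = {}
    counts: list[int] = []
    order: list[tuple] = []
    for col in cols:
        if col in uniq:
            counts[uniq[col]] += 1
        else:
            uniq[col] = len(order)
            order.append(col)
            counts.append(1)
    return np.array(order, dtype=np.int8).T.copy(), np.array(counts, dtype=float)


def log_likelihood(
    msa: MultipleAlignment,
    tree: dendropy.Tree,
    model: SubstitutionModel12,
    table: TranslationTable = DEFAULT_TABLE,
) -> float:
    """Felsenstein pruning log-likelihood; gaps/wildcards are missing data.

    For reversible models the value is invariant under the placement of the
    (possibly trifurcating) root.
    """
    leaf_set = {l.taxon.label for l in tree.leaf_node_iter()}
    if leaf_set != set(msa.ids):
        raise PhylogenyError("tree leaves do not match alignment rows")
    _, mat = _state_codes(msa, table)
    patterns, counts = _compress_patterns(mat)
    n_pat = patterns.shape[1]
    row_of = {rid: r for r, rid in enumerate(msa.ids)}

    P_cache: dict[float, np.ndarray] = {}

    def P_of(length: float | None) -> np.ndarray:
        t = 0.0 if length is None else float(length)
        if t not in P_cache:
            P_cache[t] = model.P(t)
        return P_cache[t]

    partials: dict[dendropy.Node, np.ndarray] = {}
    scale_log = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            states = patterns[row_of[node.taxon.label]]
            L = np.zeros((n_pat, K))
            missing = states < 0
            L[missing, :] = 1.0
            obs = ~missing
            L[np.arange(n_pat)[obs], states[obs].astype(int)] = 1.0
        else:
            L = np.ones((n_pat, K))
            for child in node.child_nodes():
                Lc = partials.pop(child)
                L = L * (Lc @ P_of(child.edge.length).T)
            # rescale to avoid underflow
            mx = L.max(axis=1, keepdims=True)
            mx[mx == 0] = 1.0
            L = L / mx
            scale_log += float(counts @ np.log(mx[:, 0]))
        partials[node] = L
    root_L = partials[tree.seed_node]
    site = root_L @ model.pi
    if (site <= 0).any():
        return float("-inf")
    return float(counts @ np.log(site)) + scale_log


def optimize_branch_lengths(
    msa: MultipleAlignment,
    tree: dendropy.Tree,
    model: SubstitutionModel12,
    table: TranslationTable = DEFAULT_TABLE,
    tol: float = 1e-6,
    max_rounds: int = 5,
    min_length: float = 1e-8,
    max_length: float = 10.0,
) -> tuple[dendropy.Tree, float]:
    """Coordinate-wise Brent optimization of every edge length."""
    tree = tree.clone(depth=1)
    edges = [n for n in tree.preorder_node_iter() if n is not tree.seed_node]
    for node in edges:
        if node.edge.length is None or node.edge.length < min_length:
            node.edge.length = max(min_length, 0.05)
    current = log_likelihood(msa, tree, model, table)
    for _ in range(max_rounds):
        previous = current
        for node in edges:
            def neg(t: float) -> float:
                node.edge.length = t
                return -log_likelihood(msa, tree, model, table)

            res = minimize_scalar(
                neg, bounds=(min_length, max_length), method="bounded",
                options={"xatol": tol},
            )
            node.edge.length = float(res.x)
        current = log_likelihood(msa, tree, model, table)
        if current - previous < 1e-4:
            break
    return tree, current


def ml_search(
    msa: MultipleAlignment,
    model: SubstitutionModel12 | None = None,
    table: TranslationTable = DEFAULT_TABLE,
    branch_tol: float = 1e-6,
) -> dendropy.Tree:
    """ML tree: NNI hill-climb from the NJ start, branch lengths by Brent."""
    if model is None:
        model = SubstitutionModel12.jc12()
    current = nj_tree(msa)
    current, current_ll = optimize_branch_lengths(msa, current, model, table, tol=branch_tol)
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbors(current):
            cand_opt, cand_ll = optimize_branch_lengths(
                msa, cand, model, table, tol=branch_tol, max_rounds=2
            )
            if cand_ll > current_ll + 1e-6:
                current, current_ll = cand_opt, cand_ll
                improved = True
                break
    return current


def estimate_gtr12(
    msa: MultipleAlignment,
    tree: dendropy.Tree,
    table: TranslationTable = DEFAULT_TABLE,
    maxiter: int = 60,
) -> SubstitutionModel12:
    """Estimate GTR12 exchangeabilities by direct likelihood maximization.

    Stationary frequencies are fixed at the empirical symbol frequencies
    (with a pseudocount); exchangeabilities are optimized in log space with
    L-BFGS-B on the given tree.
    """
    alpha = table.alphabet
    counts = np.ones(K)
    for row in msa.rows:
        for ch in row:
            if ch in alpha:
                counts[alpha.index(ch)] += 1
    pi = counts / counts.sum()
    n_ex = K * (K - 1) // 2
    iu = np.triu_indices(K, 1)

    def model_from(theta: np.ndarray) -> SubstitutionModel12:
        R = np.zeros((K, K))
        R[iu] = np.exp(theta)
        R = R + R.T
        return SubstitutionModel12.gtr12(R, pi)

    def neg(theta: np.ndarray) -> float:
        try:
            return -log_likelihood(msa, tree, model_from(theta), table)
        except PhylogenyError:
            return 1e12

    res = minimize(neg, np.zeros(n_ex), method="L-BFGS-B", options={"maxiter": maxiter})
    return model_from(res.x)


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap(
    msa: MultipleAlignment,
    builder: Callable[[MultipleAlignment], dendropy.Tree],
    B: int = 100,
    seed: int = 42,
) -> list[dendropy.Tree]:
    """B pseudo-replicates: resample alignment columns with replacement and
    rebuild a tree from each (the encoded columns carry sequence and
    structure jointly, so both are resampled together)."""
    if B < 1:
        raise PhylogenyError("bootstrap requires B >= 1")
    rng = np.random.default_rng(seed)
    ncol = msa.n_cols
    replicates = []
    for _ in range(B):
        cols = rng.integers(0, ncol, size=ncol)
        replicates.append(builder(msa.subsample_columns(list(cols))))
    return replicates


def bootstrap_support(
    msa: MultipleAlignment,
    reference: dendropy.Tree,
    builder: Callable[[MultipleAlignment], dendropy.Tree],
    B: int = 100,
    seed: int = 42,
) -> dendropy.Tree:
    """Convenience: run the bootstrap and map supports onto ``reference``."""
    return map_support(reference, bootstrap(msa, builder, B=B, seed=seed))
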