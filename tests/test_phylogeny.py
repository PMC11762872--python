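"""Distances, NJ, parsimony, likelihood, bootstrap: oracles and properties."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from ssphylo.alignment import MultipleAlignment
from ssphylo.encoding import DEFAULT_TABLE
from ssphylo.phylogeny import (
    PhylogenyError,
    SubstitutionModel12,
    bootstrap,
    distance_matrix,
    distance_matrix_phylip,
    enumerate_topologies,
    estimate_gtr12,
    fitch_parsimony,
    jc12_distance,
    log_likelihood,
    ml_search,
    mp_search,
    neighbor_joining,
    nj_tree,
    optimize_branch_lengths,
    p_distance,
)
from ssphylo.trees import (
    TreeError,
    bipartitions,
    map_support,
    parse_newick,
    rf_distance,
    root_with_outgroup,
    to_newick,
)

ALPHA = DEFAULT_TABLE.alphabet


# ---------------------------------------------------------------------------
# distances

class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["BDHV", "BDHV"])
        assert p_distance(msa, 0, 1) == 0.0

    def test_one_difference_in_ten(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["B" * 10, "B" * 9 + "D"])
        assert p_distance(msa, 0, 1) == pytest.approx(0.1)

    def test_gap_and_wildcard_columns_excluded(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["BD-NV", "BDD-V"])
        # comparable columns: 0, 1, 4 -> no differences
        assert p_distance(msa, 0, 1) == 0.0

    def test_all_gapped_row_pair_is_an_error(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["--", "BD"])
        with pytest.raises(PhylogenyError):
            p_distance(msa, 0, 1)

    def test_jc12_closed_form(self):
        assert jc12_distance(0.0) == 0.0
        # independent numeric evaluation of -(11/12) ln(1 - (12/11) p) at p=0.1
        assert jc12_distance(0.1) == pytest.approx(0.105885, abs=1e-5)

    def test_jc12_saturation(self):
        with pytest.raises(PhylogenyError):
            jc12_distance(0.95)

    def test_matrix_matches_scalar_reference(self, rng):
        rows = ["".join(ALPHA[k] for k in rng.integers(0, 12, 60)) for _ in range(4)]
        msa = MultipleAlignment(ids=list("abcd"), rows=rows)
        labels, D = distance_matrix(msa, correction="p")
        for i in range(4):
            for j in range(4):
                expected = 0.0 if i == j else p_distance(msa, i, j)
                assert D[i, j] == pytest.approx(expected)
        assert labels == list("abcd")

    def test_phylip_serialization_has_header_and_rows(self):
        labels, D = ["a", "b"], np.array([[0.0, 0.5], [0.5, 0.0]])
        text = distance_matrix_phylip(labels, D)
        lines = text.strip().split("\n")
        assert lines[0] == "2" and len(lines) == 3


# ---------------------------------------------------------------------------
# neighbor joining

def random_additive_tree(rng: np.random.Generator, n: int) -> dendropy.Tree:
    """Random binary unrooted tree with positive branch lengths."""
    labels = [f"x{i}" for i in range(n)]
    taxa = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(l)) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for k in (j, i):  # pop larger index first
            child = nodes.pop(k)
            parent.add_child(child)
        nodes.append(parent)
    root = dendropy.Node()
    for node in nodes:
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            node.edge.length = float(rng.uniform(0.1, 2.0))
    return tree


def path_distance_matrix(tree: dendropy.Tree):
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return labels, D


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        """Additive distances from ((A:1,B:2):1,(C:2,D:3):2): NJ returns the
        AB|CD split with exact branch lengths."""
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 3, 6, 7], [3, 0, 7, 8], [6, 7, 0, 5], [7, 8, 5, 0]], dtype=float
        )
        tree = neighbor_joining(labels, D)
        assert frozenset({"A", "B"}) in bipartitions(tree) or frozenset(
            {"C", "D"}
        ) in bipartitions(tree)
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 2.0, "D": 3.0})

    def test_three_taxa_resolved_exactly(self):
        D = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = neighbor_joining(["a", "b", "c"], D)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 1.0, "c": 2.0})

    def test_ultrametric_tie_is_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        labels = list("abcd")
        t1 = to_newick(neighbor_joining(labels, D))
        t2 = to_newick(neighbor_joining(labels, D))
        assert t1 == t2

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(PhylogenyError):
            neighbor_joining(["a", "b"], D)

    @pytest.mark.parametrize("trial", range(100))
    def test_additive_matrices_recovered_exactly(self, trial):
        """NJ is exact on additive distances: topology (RF=0) and branch
        lengths (path metric reproduced) for random trees, n <= 10."""
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 11))
        true = random_additive_tree(rng, n)
        labels, D = path_distance_matrix(true)
        est = neighbor_joining(labels, D)
        assert rf_distance(true, est) == 0
        _, D2 = path_distance_matrix(est)
        assert np.allclose(D, D2, atol=1e-9)


# ---------------------------------------------------------------------------
# parsimony

def brute_force_parsimony(msa: MultipleAlignment, tree: dendropy.Tree) -> int:
    """Minimize substitutions over all internal-node assignments.

    Optimal assignments only need states observed at the leaves (uniform
    substitution cost), so the enumeration is restricted to those.
    """
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    total = 0
    for c in range(msa.n_cols):
        observed = sorted(
            {msa.row(l)[c] for l in leaves} - {"-", "N"}
        )
        if not observed:
            continue
        best = math.inf
        for assign in itertools.product(observed, repeat=len(internal)):
            states = dict(zip(internal, assign))
            cost = 0
            for node in tree.preorder_node_iter():
                if node is tree.seed_node:
                    continue
                child_state = (
                    msa.row(node.taxon.label)[c] if node.is_leaf() else states[node]
                )
                if child_state in ("-", "N"):
                    continue  # missing data: free
                parent_state = states[node.parent_node]
                if child_state != parent_state:
                    cost += 1
            best = min(best, cost)
        total += int(best)
    return total


class TestParsimony:
    def test_identical_rows_score_zero(self):
        msa = MultipleAlignment(ids=list("abc"), rows=["BDHV"] * 3)
        tree = parse_newick("(a,b,c);")
        assert fitch_parsimony(msa, tree) == 0

    def test_single_variable_site_xxy(self):
        msa = MultipleAlignment(ids=list("abc"), rows=["B", "B", "D"])
        tree = parse_newick("(a,b,c);")
        assert fitch_parsimony(msa, tree) == 1

    def test_xxyy_pattern_distinguishes_topologies(self):
        msa = MultipleAlignment(ids=list("abcd"), rows=["B", "B", "D", "D"])
        matching = parse_newick("((a,b),(c,d));")
        conflicting = parse_newick("((a,c),(b,d));")
        assert fitch_parsimony(msa, matching) == 1
        assert fitch_parsimony(msa, conflicting) == 2

    def test_label_mismatch_rejected(self):
        msa = MultipleAlignment(ids=list("ab"), rows=["B", "B"])
        with pytest.raises(PhylogenyError):
            fitch_parsimony(msa, parse_newick("(a,x,y);"))

    @pytest.mark.parametrize("trial", range(20))
    def test_fitch_matches_brute_force(self, trial):
        """Fitch DP equals minimization over all internal assignments."""
        rng = np.random.default_rng(trial)
        n = int(rng.integers(3, 7))
        labels = [f"x{i}" for i in range(n)]
        symbols = ALPHA[:4] + "-"
        rows = [
            "".join(symbols[k] for k in rng.integers(0, len(symbols), 5))
            .ljust(5, ALPHA[0])
            for _ in range(n)
        ]
        # ensure at least one comparable symbol per row
        rows = [r if set(r) != {"-"} else ALPHA[0] * 5 for r in rows]
        msa = MultipleAlignment(ids=labels, rows=rows)
        tree = next(enumerate_topologies(labels))
        assert fitch_parsimony(msa, tree) == brute_force_parsimony(msa, tree)

    def test_mp_search_prefers_compatible_topology(self):
        msa = MultipleAlignment(
            ids=list("abcd"), rows=["BBBB", "BBBD", "DDDB", "DDDD"]
        )
        best = mp_search(msa)
        assert frozenset({"a", "b"}) in bipartitions(best) or frozenset(
            {"c", "d"}
        ) in bipartitions(best)


# ---------------------------------------------------------------------------
# likelihood

def direct_likelihood(msa: MultipleAlignment, tree: dendropy.Tree,
                      model: SubstitutionModel12) -> float:
    """Sum over all internal-node state assignments (oracle, <= 5 taxa)."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    code = {c: i for i, c in enumerate(ALPHA)}
    total_ll = 0.0
    P = {n: model.P(n.edge.length or 0.0) for n in tree.preorder_node_iter()
         if n is not tree.seed_node}
    for c in range(msa.n_cols):
        site = 0.0
        for assign in itertools.product(range(12), repeat=len(internal)):
            states = dict(zip(internal, assign))
            prob = model.pi[states[tree.seed_node]]
            for node in tree.preorder_node_iter():
                if node is tree.seed_node:
                    continue
                parent_state = states[node.parent_node]
                if node.is_leaf():
                    ch = msa.row(node.taxon.label)[c]
                    if ch in ("-", "N"):
                        continue  # marginalized: sum over child states = 1
                    prob *= P[node][parent_state, code[ch]]
                else:
                    prob *= P[node][parent_state, states[node]]
            site += prob
        total_ll += math.log(site)
    return total_ll


class TestLikelihood:
    def test_two_taxon_single_site_closed_form(self):
        """Same symbol at both tips: L = (1/12)(1/12 + (11/12) e^{-(12/11)t})."""
        msa = MultipleAlignment(ids=["a", "b"], rows=["B", "B"])
        for t in (0.05, 0.3, 1.0):
            tree = parse_newick(f"(a:{t/2},b:{t/2});")
            expected = (1 / 12) * (1 / 12 + (11 / 12) * math.exp(-(12 / 11) * t))
            got = log_likelihood(msa, tree, SubstitutionModel12.jc12())
            assert got == pytest.approx(math.log(expected), abs=1e-9)

    def test_long_branch_limit_is_stationary(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["B", "D"])
        tree = parse_newick("(a:40,b:40);")
        got = log_likelihood(msa, tree, SubstitutionModel12.jc12())
        assert got == pytest.approx(math.log((1 / 12) * (1 / 12)), abs=1e-6)

    def test_invariant_under_rerooting(self, rng):
        rows = ["".join(ALPHA[k] for k in rng.integers(0, 12, 8)) for _ in range(4)]
        msa = MultipleAlignment(ids=list("abcd"), rows=rows)
        model = SubstitutionModel12.jc12()
        tree = parse_newick("((a:0.1,b:0.2):0.15,(c:0.3,d:0.25):0.05);")
        base = log_likelihood(msa, tree, model)
        rerooted = root_with_outgroup(tree, ["a"])
        assert log_likelihood(msa, rerooted, model) == pytest.approx(base, abs=1e-8)

    def test_zero_length_branches_keep_likelihood_finite(self):
        msa = MultipleAlignment(ids=list("abc"), rows=["BD", "BD", "DD"])
        tree = parse_newick("(a:0.0,b:0.0,c:0.1);")
        assert math.isfinite(log_likelihood(msa, tree, SubstitutionModel12.jc12()))

    @pytest.mark.parametrize("trial", range(6))
    def test_pruning_matches_direct_summation(self, trial):
        """Felsenstein pruning equals the sum over all internal states."""
        rng = np.random.default_rng(trial)
        n = int(rng.integers(3, 6))
        labels = [f"x{i}" for i in range(n)]
        symbols = ALPHA + "-"
        rows = ["".join(symbols[k] for k in rng.integers(0, 13, 3)) for _ in range(n)]
        rows = [r if set(r) != {"-"} else ALPHA[0] * 3 for r in rows]
        msa = MultipleAlignment(ids=labels, rows=rows)
        tree = next(enumerate_topologies(labels))
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node:
                node.edge.length = float(rng.uniform(0.05, 0.8))
        model = SubstitutionModel12.jc12()
        assert log_likelihood(msa, tree, model) == pytest.approx(
            direct_likelihood(msa, tree, model), abs=1e-9
        )

    def test_branch_length_optimization_improves_likelihood(self, rng):
        rows = ["".join(ALPHA[k] for k in rng.integers(0, 12, 40)) for _ in range(4)]
        rows[1] = rows[0][:35] + rows[1][35:]
        msa = MultipleAlignment(ids=list("abcd"), rows=rows)
        model = SubstitutionModel12.jc12()
        tree = parse_newick("((a:0.5,b:0.5):0.5,(c:0.5,d:0.5):0.5);")
        before = log_likelihood(msa, tree, model)
        opt, after = optimize_branch_lengths(msa, tree, model)
        assert after >= before - 1e-9

    def test_ml_search_recovers_clear_split(self):
        msa = MultipleAlignment(
            ids=list("abcd"),
            rows=[
                "B" * 20,
                "B" * 18 + "D" * 2,
                "B" * 10 + "V" * 10,
                "B" * 10 + "V" * 8 + "E" * 2,
            ],
        )
        tree = ml_search(msa)
        assert frozenset({"a", "b"}) in bipartitions(tree) or frozenset(
            {"c", "d"}
        ) in bipartitions(tree)

    def test_gtr12_estimation_returns_valid_model(self, rng):
        rows = ["".join(ALPHA[k] for k in rng.integers(0, 12, 30)) for _ in range(3)]
        msa = MultipleAlignment(ids=list("abc"), rows=rows)
        tree = parse_newick("(a:0.2,b:0.2,c:0.2);")
        model = estimate_gtr12(msa, tree, maxiter=5)
        assert model.name == "gtr12"
        P = model.P(0.3)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-8)
        assert (P >= -1e-12).all()


# ---------------------------------------------------------------------------
# bootstrap, support, rooting, RF

class TestBootstrap:
    def test_unanimous_columns_give_full_support(self):
        msa = MultipleAlignment(
            ids=list("abcd"), rows=["B" * 12, "B" * 12, "D" * 12, "D" * 12]
        )
        ref = nj_tree(msa, correction="p")
        reps = bootstrap(msa, lambda m: nj_tree(m, correction="p"), B=20, seed=1)
        annotated = map_support(ref, reps)
        supports = [
            n.support for n in annotated.preorder_node_iter()
            if getattr(n, "support", None) is not None
        ]
        assert supports == [100]

    def test_single_replicate_support_binary(self, small_dataset):
        msa = small_dataset.true_alignment
        ref = nj_tree(msa)
        reps = bootstrap(msa, nj_tree, B=1, seed=3)
        annotated = map_support(ref, reps)
        for node in annotated.preorder_node_iter():
            if getattr(node, "support", None) is not None:
                assert node.support in (0, 100)

    def test_fixed_seed_reproducible(self, small_dataset):
        msa = small_dataset.true_alignment
        reps1 = bootstrap(msa, nj_tree, B=5, seed=7)
        reps2 = bootstrap(msa, nj_tree, B=5, seed=7)
        assert [to_newick(t) for t in reps1] == [to_newick(t) for t in reps2]

    def test_b_below_one_rejected(self, small_dataset):
        with pytest.raises(PhylogenyError):
            bootstrap(small_dataset.true_alignment, nj_tree, B=0, seed=1)


class TestRooting:
    def test_single_leaf_outgroup(self):
        tree = parse_newick("((a:1,b:1):1,(c:1,o:1):1);")
        rooted = root_with_outgroup(tree, ["o"])
        children = rooted.seed_node.child_nodes()
        sides = [sorted(l.taxon.label for l in ch.leaf_iter()) for ch in children]
        assert ["o"] in sides

    def test_two_leaf_monophyletic_outgroup(self):
        tree = parse_newick("((a:1,b:1):1,(o1:1,o2:1):2);")
        rooted = root_with_outgroup(tree, ["o1", "o2"])
        sides = [
            sorted(l.taxon.label for l in ch.leaf_iter())
            for ch in rooted.seed_node.child_nodes()
        ]
        assert ["o1", "o2"] in sides

    def test_split_outgroup_rejected(self):
        tree = parse_newick("((o1:1,a:1):1,(o2:1,b:1):1);")
        with pytest.raises(TreeError, match="monophyletic"):
            root_with_outgroup(tree, ["o1", "o2"])


class TestRobinsonFoulds:
    def test_identical_trees_distance_zero(self):
        t = parse_newick("((a,b),(c,d));")
        assert rf_distance(t, parse_newick("((a,b),(c,d));")) == 0

    def test_conflicting_quartets_distance_two(self):
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,c),(b,d));")
        assert rf_distance(t1, t2) == 2

    def test_star_vs_resolved(self):
        star = parse_newick("(a,b,c,d,e);")
        resolved = parse_newick("(((a,b),c),(d,e));")
        assert rf_distance(star, resolved) == len(bipartitions(resolved))

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(TreeError):
            rf_distance(parse_newick("(a,b,c);"), parse_newick("(a,b,x);"))

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_dendropy_treecompare(self, trial):
        """Dual route: our bipartition RF equals dendropy's symmetric difference."""
        from dendropy.calculate import treecompare

        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 9))
        t1 = random_additive_tree(rng, n)
        t2 = random_additive_tree(rng, n)
        ours = rf_distance(t1, t2)
        taxa = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=to_newick(t1), schema="newick", taxon_namespace=taxa)
        d2 = dendropy.Tree.get(data=to_newick(t2), schema="newick", taxon_namespace=taxa)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        assert ours == treecompare.symmetric_difference(d1, d2)
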