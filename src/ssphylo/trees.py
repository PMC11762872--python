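"""Phylogenetic tree plumbing on top of dendropy.

Trees throughout the package are :class:`dendropy.Tree` objects.  Bootstrap
support is stored exactly, as an integer percent in ``node.support`` /
``node.label`` on internal nodes; the conventional display rule of hiding
values <= 50 is applied only at write time when requested.

Newick output is produced by a deterministic writer (fixed child order as
stored, branch lengths formatted with 6 decimals) so that identical runs
give byte-identical files.
"""

from __future__ import annotations

import os

import dendropy


class TreeError(ValueError):
    pass


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; integer internal labels become support values."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises various error types
        raise TreeError(f"cannot parse Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise TreeError("leaf labels are not unique")
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.label is not None:
            try:
                node.support = int(round(float(node.label)))
            except ValueError:
                node.support = None
        else:
            node.support = None
    return tree


def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def _format_node(node: dendropy.Node, hide_support_below: int | None) -> str:
    if node.is_leaf():
        out = node.taxon.label.replace(" ", "_")
    else:
        parts = [_format_node(c, hide_support_below) for c in node.child_nodes()]
        out = "(" + ",".join(parts) + ")"
        support = getattr(node, "support", None)
        if support is not None and (
            hide_support_below is None or support > hide_support_below
        ):
            out += str(int(support))
    if node.edge.length is not None:
        out += f":{node.edge.length + 0.0:.6f}"  # + 0.0 normalizes -0.0
    return out


def to_newick(tree: dendropy.Tree, hide_support_below: int | None = None) -> str:
    """Deterministic Newick serialization (support as internal labels)."""
    return _format_node(tree.seed_node, hide_support_below) + ";"


def write_newick(
    tree: dendropy.Tree, path: str | os.PathLike, hide_support_below: int | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree, hide_support_below) + "\n")


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf-label sets.

    Each internal edge splits the leaves in two; the set not containing the
    lexicographically smallest leaf represents the split, so the encoding is
    rooting-invariant.
    """
    all_leaves = frozenset(leaf_labels(tree))
    ref = min(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(below) <= 1 or len(below) >= len(all_leaves) - 1:
            continue
        side = below if ref not in below else all_leaves - below
        splits.add(side)
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds symmetric bipartition distance."""
    l1, l2 = set(leaf_labels(t1)), set(leaf_labels(t2))
    if l1 != l2:
        raise TreeError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    return len(bipartitions(t1) ^ bipartitions(t2))


def root_with_outgroup(tree: dendropy.Tree, outgroup_labels) -> dendropy.Tree:
    """Root on the edge separating the outgroup from the ingroup (midpoint).

    The outgroup must induce a single edge in the unrooted tree; otherwise a
    :class:`TreeError` names the conflicting split.
    """
    outgroup = frozenset(outgroup_labels)
    all_leaves = frozenset(leaf_labels(tree))
    missing = outgroup - all_leaves
    if missing:
        raise TreeError(f"outgroup labels not in tree: {sorted(missing)}")
    if not outgroup or outgroup == all_leaves:
        raise TreeError("outgroup must be a proper non-empty subset of the leaves")
    tree = tree.clone(depth=1)
    target = None
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if below == outgroup or below == all_leaves - outgroup:
            target = node
            break
    if target is None:
        raise TreeError(
            f"outgroup {sorted(outgroup)} is not monophyletic in the unrooted tree"
        )
    length = target.edge.length
    if length is None:
        tree.reroot_at_edge(target.edge, update_bipartitions=False)
    else:
        tree.reroot_at_edge(
            target.edge, length1=length / 2.0, length2=length / 2.0,
            update_bipartitions=False,
        )
    tree.seed_node.support = None
    tree.is_rooted = True
    return tree


def map_support(reference: dendropy.Tree, replicates) -> dendropy.Tree:
    """Annotate internal nodes of ``reference`` with bootstrap percentages.

    Support of an edge = percentage of replicate trees containing the same
    bipartition.  All values are stored; hiding values <= 50 is left to the
    Newick writer.
    """
    replicates = list(replicates)
    if not replicates:
        raise TreeError("need at least one replicate tree")
    counts: dict[frozenset[str], int] = {}
    for rep in replicates:
        for split in bipartitions(rep):
            counts[split] = counts.get(split, 0) + 1
    tree = reference.clone(depth=1)
    all_leaves = frozenset(leaf_labels(tree))
    ref_leaf = min(all_leaves)
    n_rep = len(replicates)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node is tree.seed_node:
            node.support = None
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(below) <= 1 or len(below) >= len(all_leaves) - 1:
            node.support = None
            continue
        side = below if ref_leaf not in below else all_leaves - below
        node.support = int(round(100.0 * counts.get(side, 0) / n_rep))
    return tree


def build_tree(newick: str) -> dendropy.Tree:
    """Convenience alias used in tests and examples."""
    return parse_newick(newick)
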