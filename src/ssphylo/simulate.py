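"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the structure of real ITS2 data sets: a root
sequence-structure pair with four helices emanating from a central ring (the
third helix the longest, as in the eukaryote core), character evolution along
a known tree in which paired positions co-substitute so that an allowed base
pair is maintained (compensatory substitution), optional deletions confined
to unpaired positions, template sets at controlled divergences, and full
5.8S-ITS2-28S cistrons with planted annotation boundaries.

Every operation takes an explicit seed and a fixed seed gives byte-identical
output.  Ground truth (true tree, true alignment, true structures and
intervals) is returned alongside the data so every downstream stage can be
scored without re-derivation.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .annotation import Its2Annotation
from .encoding import GAP, DEFAULT_TABLE, TranslationTable, encode
from .alignment import MultipleAlignment
from .records import ALLOWED_PAIRS, NUCLEOTIDES, SequenceRecord, SequenceStructurePair
from .structure import TemplateRecord

#: Fixed conserved flank motifs (25 nt each): the 5.8S gene end and the 28S
#: gene start used when planting cistron boundaries.  Arbitrary but frozen so
#: annotation models and generated data agree by construction.
FLANK5_MOTIF = "GAACGCAGCGAAAUGCGAUACGUAG"
FLANK3_MOTIF = "UUGACCUCAAAUCAGGUAGGACUAC"

_PARTNERS = {
    "A": ("U",),
    "C": ("G",),
    "G": ("C", "U"),
    "U": ("A", "G"),
}


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the generator.

    ``helix_spec`` lists base pairs per exterior helix; the default
    ``[6, 8, 14, 5]`` encodes the four-helix core with the third helix
    longest.  ``site_count`` (optional) pads the central ring with unpaired
    spacer so the root reaches the requested length; it must be at least the
    structural footprint.  ``indel_rate`` is a per-site, per-unit-branch
    deletion rate applied to unpaired positions only.
    """

    n_taxa: int = 8
    tree: dendropy.Tree | None = None
    birth_rate: float = 1.0
    site_count: int | None = None
    helix_spec: Sequence[int] = (6, 8, 14, 5)
    loop_len: int = 4
    spacer_len: int = 5
    flank_len: int = 25
    indel_rate: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if any(h < 2 for h in self.helix_spec):
            raise SimulationError("helix_spec lengths must be >= 2")
        if self.site_count is not None and self.site_count < self.footprint:
            raise SimulationError(
                f"site_count {self.site_count} below structural footprint {self.footprint}"
            )

    @property
    def footprint(self) -> int:
        helices = sum(2 * h + self.loop_len for h in self.helix_spec)
        return helices + self.spacer_len * (len(self.helix_spec) + 1)


def simulate_tree(n: int, birth_rate: float = 1.0, seed: int = 42) -> dendropy.Tree:
    """Yule (pure-birth) tree with n extant leaves labeled t1..tn."""
    if n < 3:
        raise SimulationError("need at least three taxa")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n, rng=rng
    )
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i}"
    tree.seed_node.edge.length = None
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.support = None
    return tree


def _root_structure(config: SimConfig) -> str:
    spacer = "." * config.spacer_len
    parts = [spacer]
    for h in config.helix_spec:
        parts.append("(" * h + "." * config.loop_len + ")" * h)
        parts.append(spacer)
    structure = "".join(parts)
    if config.site_count is not None and config.site_count > len(structure):
        structure += "." * (config.site_count - len(structure))
    return structure


def _root_pair(config: SimConfig, rng: np.random.Generator) -> SequenceStructurePair:
    structure = _root_structure(config)
    seq = [""] * len(structure)
    pair_map: dict[int, int] = {}
    pairs = SequenceStructurePair(
        record=SequenceRecord(id="root", seq="A" * len(structure)), structure=structure
    ).pairs
    for i, j in pairs:
        pair_map[i], pair_map[j] = j, i
    for pos in range(len(structure)):
        if seq[pos]:
            continue
        nuc = NUCLEOTIDES[rng.integers(4)]
        seq[pos] = nuc
        if pos in pair_map:
            partner_options = _PARTNERS[nuc]
            seq[pair_map[pos]] = partner_options[rng.integers(len(partner_options))]
    return SequenceStructurePair(
        record=SequenceRecord(id="root", seq="".join(seq)), structure=structure
    )


@dataclass
class SimulatedDataset:
    """Generator output plus the ground truth needed to score every stage."""

    tree: dendropy.Tree
    root: SequenceStructurePair
    pairs: list[SequenceStructurePair]
    true_alignment: MultipleAlignment  # encoded symbols in root coordinates
    substitution_events: dict[str, int] = field(default_factory=dict)

    @property
    def leaf_ids(self) -> list[str]:
        return [p.id for p in self.pairs]

    def ground_truth_json(self) -> str:
        from .trees import to_newick

        return json.dumps(
            {
                "tree": to_newick(self.tree),
                "root_structure": self.root.structure,
                "alignment": dict(zip(self.true_alignment.ids, self.true_alignment.rows)),
                "substitution_events": self.substitution_events,
            },
            indent=1,
            sort_keys=True,
        )


def evolve_pairs(
    tree: dendropy.Tree | None = None, config: SimConfig | None = None
) -> SimulatedDataset:
    """Evolve a sequence-structure pair along a tree with compensatory pairing.

    Substitution events arrive per site as a Poisson process at one event per
    site per unit branch length; an event replaces the nucleotide uniformly
    by one of the other three, and if the position is paired and the new pair
    is not allowed, the partner is redrawn from the allowed partners (the
    compensatory co-substitution that keeps structure conserved while the
    sequence diverges).  Deletions (rate ``config.indel_rate``) hit unpaired
    positions only, so true structures stay well-defined under the true
    alignment, which is kept in root coordinates.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    if tree is None:
        tree = config.tree or simulate_tree(config.n_taxa, config.birth_rate, config.seed)
    root = _root_pair(config, rng)
    structure = root.structure
    pair_map: dict[int, int] = {}
    for i, j in root.pairs:
        pair_map[i], pair_map[j] = j, i
    n_sites = len(root)
    unpaired = [p for p in range(n_sites) if p not in pair_map]

    leaves: list[tuple[str, list[str], set[int]]] = []
    events: dict[str, int] = {}

    def walk(node: dendropy.Node, seq: list[str], deleted: set[int], n_events: int) -> None:
        t = node.edge.length or 0.0
        seq = seq.copy()
        deleted = set(deleted)
        if t > 0:
            counts = rng.poisson(t, size=n_sites)
            for pos in range(n_sites):
                for _ in range(int(counts[pos])):
                    if pos in deleted:
                        continue
                    old = seq[pos]
                    choices = [n for n in NUCLEOTIDES if n != old]
                    new = choices[rng.integers(3)]
                    seq[pos] = new
                    n_events += 1
                    partner = pair_map.get(pos)
                    if partner is not None and (new, seq[partner]) not in ALLOWED_PAIRS:
                        opts = _PARTNERS[new]
                        seq[partner] = opts[rng.integers(len(opts))]
            if config.indel_rate > 0:
                p_del = 1.0 - np.exp(-config.indel_rate * t)
                for pos in unpaired:
                    if pos not in deleted and rng.random() < p_del:
                        deleted.add(pos)
        if node.is_leaf():
            leaves.append((node.taxon.label, seq, deleted))
            events[node.taxon.label] = n_events
        else:
            for child in node.child_nodes():
                walk(child, seq, deleted, n_events)

    walk(tree.seed_node, list(root.seq), set(), 0)

    pairs_out: list[SequenceStructurePair] = []
    rows: list[str] = []
    ids: list[str] = []
    table = DEFAULT_TABLE
    for label, seq, deleted in leaves:
        kept = [p for p in range(n_sites) if p not in deleted]
        leaf_seq = "".join(seq[p] for p in kept)
        leaf_struct = "".join(structure[p] for p in kept)
        pair = SequenceStructurePair(
            record=SequenceRecord(id=label, seq=leaf_seq), structure=leaf_struct
        )
        pairs_out.append(pair)
        enc = encode(pair, table).symbols
        row = []
        k = 0
        for p in range(n_sites):
            if p in deleted:
                row.append(GAP)
            else:
                row.append(enc[k])
                k += 1
        rows.append("".join(row))
        ids.append(label)
    truth = MultipleAlignment(ids=ids, rows=rows)
    return SimulatedDataset(
        tree=tree, root=root, pairs=pairs_out, true_alignment=truth,
        substitution_events=events,
    )


def make_cistron(
    pair: SequenceStructurePair,
    flank5_motif: str = FLANK5_MOTIF,
    flank3_motif: str = FLANK3_MOTIF,
    extra5: int = 30,
    extra3: int = 30,
    seed: int = 42,
) -> tuple[SequenceRecord, Its2Annotation]:
    """Plant the pair as the ITS2 of a 5.8S-ITS2-28S cistron fragment.

    Layout: ``[extra5 random nt][flank5_motif][ITS2][flank3_motif][extra3
    random nt]``.  The returned annotation is the planted truth: the ITS2
    interval and its proximal extension by 25 nt (``min(25, len(motif))``)
    into each flank.
    """
    if not flank5_motif or not flank3_motif:
        raise SimulationError("flank motifs must be non-empty")
    rng = np.random.default_rng(seed)
    rand = lambda k: "".join(NUCLEOTIDES[rng.integers(4)] for _ in range(k))
    left = rand(extra5) + flank5_motif
    right = flank3_motif + rand(extra3)
    seq = left + pair.seq + right
    its2_start = len(left)
    its2_end = its2_start + len(pair)
    L = 25
    record = SequenceRecord(
        id=f"{pair.id}_cistron", seq=seq, description=f"{pair.id}_cistron",
        taxon_name=pair.record.taxon_name,
    )
    truth = Its2Annotation(
        its2_start=its2_start,
        its2_end=its2_end,
        proximal_start=max(0, its2_start - L),
        proximal_end=min(len(seq), its2_end + L),
        full_proximal_stem=its2_start >= L and its2_end + L <= len(seq),
        log_odds=float("nan"),
    )
    return record, truth


def make_template_set(
    pairs: Sequence[SequenceStructurePair],
    k: int = 4,
    divergence_levels: Sequence[float] = (0.0, 0.1, 0.3, 0.7),
    seed: int = 42,
) -> list[TemplateRecord]:
    """Templates at controlled divergences from the given pairs.

    Each template keeps its source structure while the sequence is mutated
    position-wise with the given probability (compensatory at paired
    positions), so expected transfer percentages decrease with divergence and
    straddle the 50% homology filter.
    """
    if k < 1:
        raise SimulationError("need k >= 1 templates")
    rng = np.random.default_rng(seed)
    templates: list[TemplateRecord] = []
    for idx in range(k):
        src = pairs[idx % len(pairs)]
        div = divergence_levels[idx % len(divergence_levels)]
        pair_map: dict[int, int] = {}
        for i, j in src.pairs:
            pair_map[i], pair_map[j] = j, i
        seq = list(src.seq)
        for pos in range(len(seq)):
            if rng.random() < div:
                choices = [n for n in NUCLEOTIDES if n != seq[pos]]
                seq[pos] = choices[rng.integers(3)]
                partner = pair_map.get(pos)
                if partner is not None and (seq[pos], seq[partner]) not in ALLOWED_PAIRS:
                    opts = _PARTNERS[seq[pos]]
                    seq[partner] = opts[rng.integers(len(opts))]
        name = f"template_{idx + 1}_div{div:g}"
        rec = SequenceRecord(id=name, seq="".join(seq))
        templates.append(
            TemplateRecord(pair=SequenceStructurePair(record=rec, structure=src.structure), name=name)
        )
    return templates
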