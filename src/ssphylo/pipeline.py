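"""End-to-end ITS2 sequence-structure pipeline.

Stage order follows the analysis workflow this package automates:

    annotate -> species/annotation filters -> structure prediction ->
    homology filter -> 12-letter encoding -> multiple alignment ->
    NJ/MP/ML trees -> bootstrap support -> outgroup rooting -> report

Every input record is tracked in a manifest (kept/discarded with a reason
from a closed vocabulary: ``not_binomial``, ``annotation_failed``,
``truncated_proximal_stem``, ``low_structural_homology``,
``user_excluded``), and kept + discarded equals the input count at every
stage.  Identical configuration and seed give byte-identical artifacts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import io as ssio
from .alignment import MultipleAlignment, default_model, progressive_align
from .annotation import (
    Its2Annotation,
    annotations_to_tsv,
    build_profile_hmm,
    filter_annotatable,
    viterbi_annotate,
)
from .encoding import DEFAULT_TABLE, encode
from .phylogeny import bootstrap, map_support, ml_search, mp_search, nj_tree
from .records import SequenceRecord, SequenceStructurePair
from .structure import (
    TemplateRecord,
    analyze_core,
    constrained_fold,
    filter_by_homology,
    select_best_template,
)
from .trees import root_with_outgroup, to_newick, write_newick

logger = logging.getLogger("ssphylo")

_BINOMIAL = re.compile(r"^[A-Z][a-z-]+ [a-z][a-z-]+$")
_EPITHET_BLOCKLIST = {"sp", "sp.", "cf.", "aff.", "uncultured", "environmental"}


class PipelineError(RuntimeError):
    pass


def filter_species_named(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Keep records whose taxon name is a proper binomial species name."""
    kept, discarded = [], []
    for rec in records:
        name = rec.taxon_name.strip()
        words = name.split()
        ok = (
            bool(_BINOMIAL.match(name))
            and len(words) == 2
            and words[1] not in _EPITHET_BLOCKLIST
        )
        if ok:
            kept.append(rec)
        else:
            discarded.append((rec, "not_binomial"))
    return kept, discarded


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_fasta: str
    out_dir: str
    templates_xfasta: Optional[str] = None
    motif5_fasta: Optional[str] = None
    motif3_fasta: Optional[str] = None
    constraints_file: Optional[str] = None
    require_binomial_species: bool = True
    require_full_proximal_stem: bool = True
    min_transfer_percent: float = 50.0
    structure_mode: str = "homology"  # homology | constrained_fold | homology_then_fold
    proximal_length: int = 25
    gap_open: float = -8.0
    gap_extend: float = -2.0
    tree_methods: tuple[str, ...] = ("nj",)
    bootstrap_replicates: int = 100
    outgroup: tuple[str, ...] = ()
    exclude_ids: tuple[str, ...] = ()
    seed: int = 42

    def __post_init__(self) -> None:
        if not self.tree_methods:
            raise PipelineError("at least one tree method is required")
        bad = set(self.tree_methods) - {"nj", "mp", "ml"}
        if bad:
            raise PipelineError(f"unknown tree methods: {sorted(bad)}")
        if not 0 <= self.min_transfer_percent <= 100:
            raise PipelineError("min_transfer_percent must be in [0, 100]")
        if self.structure_mode not in {"homology", "constrained_fold", "homology_then_fold"}:
            raise PipelineError(f"unknown structure mode {self.structure_mode!r}")
        if self.structure_mode != "constrained_fold" and self.templates_xfasta is None:
            raise PipelineError("homology modes require a template file")

    @classmethod
    def overview_preset(cls, **kwargs) -> "RunConfig":
        """Large-scale overview setting: NJ only, no bootstrap."""
        kwargs.setdefault("tree_methods", ("nj",))
        kwargs.setdefault("bootstrap_replicates", 0)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("tree_methods", "outgroup", "exclude_ids"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunResult:
    manifest: pd.DataFrame
    alignment: Optional[MultipleAlignment]
    trees: dict
    out_dir: Path


def _central_ring_positions(pair: SequenceStructurePair) -> frozenset[int]:
    """Exterior-loop (central ring) positions: unpaired and under no pair."""
    inside = [False] * len(pair)
    for i, j in pair.pairs:
        for p in range(i, j + 1):
            inside[p] = True
    return frozenset(p for p in range(len(pair)) if not inside[p])


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline; artifacts land under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "trees").mkdir(exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    records = ssio.read_fasta(config.input_fasta)
    log(f"input: {len(records)} records")
    ledger: dict[str, dict] = {
        rec.id: {"id": rec.id, "taxon_name": rec.taxon_name, "status": "kept",
                 "stage": "", "reason": "", "its2_start": "", "its2_end": "",
                 "full_proximal_stem": "", "template": "", "transfer_percent": ""}
        for rec in records
    }

    def discard(rec_id: str, stage: str, reason: str) -> None:
        ledger[rec_id].update(status="discarded", stage=stage, reason=reason)

    current = list(records)
    for rec in current:
        if rec.id in config.exclude_ids:
            discard(rec.id, "user_filter", "user_excluded")
    current = [r for r in current if ledger[r.id]["status"] == "kept"]

    if config.require_binomial_species:
        kept, dropped = filter_species_named(current)
        for rec, reason in dropped:
            discard(rec.id, "species_filter", reason)
        current = kept
        log(f"species filter: {len(current)} kept, {len(dropped)} discarded")

    # annotation
    if config.motif5_fasta and config.motif3_fasta:
        motif5 = [r.seq for r in ssio.read_fasta(config.motif5_fasta)]
        motif3 = [r.seq for r in ssio.read_fasta(config.motif3_fasta)]
    else:
        from .simulate import FLANK3_MOTIF, FLANK5_MOTIF

        motif5, motif3 = [FLANK5_MOTIF], [FLANK3_MOTIF]
    hmm5 = build_profile_hmm(motif5)
    hmm3 = build_profile_hmm(motif3)
    annotations = [
        viterbi_annotate(rec, hmm5, hmm3, L=config.proximal_length) for rec in current
    ]
    for rec, ann in zip(current, annotations):
        if ann is not None:
            ledger[rec.id].update(
                its2_start=ann.its2_start, its2_end=ann.its2_end,
                full_proximal_stem=str(ann.full_proximal_stem).lower(),
            )
    if config.require_full_proximal_stem:
        kept_ann, dropped = filter_annotatable(current, annotations)
        for rec, reason in dropped:
            discard(rec.id, "annotation_filter", reason)
    else:
        kept_ann = [(r, a) for r, a in zip(current, annotations) if a is not None]
        for rec, ann in zip(current, annotations):
            if ann is None:
                discard(rec.id, "annotation_filter", "annotation_failed")
    log(f"annotation: {len(kept_ann)} kept, {len(current) - len(kept_ann)} discarded")
    (out / "annotations.tsv").write_text(
        annotations_to_tsv(list(zip(current, annotations)))
    )

    # extract the proximal region (ITS2 plus proximal stem flanks): the
    # modeled structures include the stem, as curated templates do.
    extracted: list[SequenceRecord] = []
    for rec, ann in kept_ann:
        sub = rec.seq[ann.proximal_start : ann.proximal_end]
        extracted.append(
            SequenceRecord(id=rec.id, seq=sub, description=rec.description,
                           taxon_name=rec.taxon_name)
        )

    # structure prediction
    structures: list[SequenceStructurePair] = []
    if config.structure_mode in {"homology", "homology_then_fold"}:
        templates = [
            TemplateRecord(pair=p, name=p.id)
            for p in ssio.read_xfasta(config.templates_xfasta)
        ]
        results = [select_best_template(rec, templates) for rec in extracted]
        for rec, res in zip(extracted, results):
            ledger[rec.id].update(
                template=res.template_name, transfer_percent=f"{res.transfer_percent:.2f}"
            )
        kept_res, dropped_res = filter_by_homology(results, config.min_transfer_percent)
        for res, reason in dropped_res:
            discard(res.modeled.id, "homology_filter", reason)
        log(f"homology filter: {len(kept_res)} kept, {len(dropped_res)} discarded")
        if config.structure_mode == "homology":
            structures = [res.modeled for res in kept_res]
        else:
            for res in kept_res:
                ring = _central_ring_positions(res.modeled)
                structures.append(constrained_fold(res.modeled.record, exterior=ring))
    else:
        constraints = (
            ssio.read_constraints(config.constraints_file)
            if config.constraints_file
            else frozenset()
        )
        for rec in extracted:
            forb = frozenset(p for p in constraints if p < len(rec.seq))
            structures.append(constrained_fold(rec, forbidden=forb))

    survivors = [s for s in structures]
    n_kept = len(survivors)
    manifest = pd.DataFrame([ledger[rec.id] for rec in records])
    manifest_path = out / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    if n_kept < 4:
        log(f"aborting: only {n_kept} records survived the filters (need >= 4)")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise PipelineError(
            f"only {n_kept} records survive the filters; tree building needs >= 4 "
            f"(manifest written to {manifest_path})"
        )

    ssio.write_xfasta(survivors, out / "structures.xfasta")
    core = [analyze_core(p) for p in survivors]
    log(
        "core architecture: "
        + ", ".join(f"{p.id}:{c.n_helices}h" for p, c in zip(survivors, core))
    )

    # encoding + alignment
    encoded = [encode(p, DEFAULT_TABLE) for p in survivors]
    model = default_model(DEFAULT_TABLE, config.gap_open, config.gap_extend)
    msa = progressive_align(encoded, model)
    ssio.write_encoded_fasta(msa.to_encoded(), out / "alignment.enc.fasta")
    log(f"alignment: {msa.n_rows} rows x {msa.n_cols} columns")

    # trees
    builders = {
        "nj": lambda m: nj_tree(m),
        "mp": lambda m: mp_search(m),
        "ml": lambda m: ml_search(m),
    }
    trees: dict = {}
    for method in config.tree_methods:
        build = builders[method]
        tree = build(msa)
        if config.bootstrap_replicates > 0:
            reps = bootstrap(msa, build, B=config.bootstrap_replicates, seed=config.seed)
            tree = map_support(tree, reps)
        if config.outgroup:
            tree = root_with_outgroup(tree, config.outgroup)
        trees[method] = tree
        write_newick(tree, out / "trees" / f"{method}.nwk")
        log(f"{method} tree: {to_newick(tree)}")

    summary = [
        f"records_in\t{len(records)}",
        f"records_kept\t{n_kept}",
        f"alignment_columns\t{msa.n_cols}",
        f"bootstrap_replicates\t{config.bootstrap_replicates}",
        f"tree_methods\t{','.join(config.tree_methods)}",
    ]
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return RunResult(manifest=manifest, alignment=msa, trees=trees, out_dir=out)
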