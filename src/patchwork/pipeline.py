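"""End-to-end orchestration: simulate -> segment -> rip -> hic -> link.

A single YAML config (or :class:`RunConfig`) drives the stages; every
output file is listed in a manifest with its SHA-256 checksum and the
resolved parameters, so identical config + seed reproduce identical
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import hic as hic_mod
from . import io_formats as iof
from . import linkage, rip, segmentation, synthetic

log = logging.getLogger("patchwork")

DEFAULT_PARAMS = {
    "bin_size": 5_000,
    "mapq_min": 30,
    "read_length": 80,
    "rip_threshold": 0.9,
    "segment_window": 1_000,
    "min_block_len": 2_000,
    "tad_window_bins": 5,
    "tad_min_bins": 5,
    "proximity_max_dist": 5_000,
    "mite_window": 2_000,
    "modqv_min": 20,
}

ALL_STAGES = ("simulate", "segment", "rip", "hic", "link")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "patchwork_out"
    stages: tuple[str, ...] = ALL_STAGES
    simulate: dict = field(default_factory=dict)
    hic: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    paths: dict = field(default_factory=dict)  # external inputs when not simulating

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = dict(DEFAULT_PARAMS)
        params.update(raw.pop("params", {}))
        cfg = cls(**{**raw, "params": params})
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages:
            if "segment" in self.stages and "fasta" not in self.paths:
                raise ValueError("segment stage enabled but no 'fasta' path configured")
            if "hic" in self.stages and "pairs" not in self.paths:
                raise ValueError("hic stage enabled but no 'pairs' path configured")
            if "link" in self.stages and "expression" not in self.paths:
                raise ValueError("link stage enabled but no 'expression' path configured")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "params": dict(config.params),
        "stages": list(config.stages),
        "outputs": [],
    }
    outputs: list[tuple[str, Path]] = []

    def emit(stage: str, path: Path):
        outputs.append((stage, path))

    state: dict = {}
    try:
        if "simulate" in config.stages:
            _stage_simulate(config, outdir, state, emit)
        if "segment" in config.stages:
            _stage_segment(config, outdir, state, emit)
        if "rip" in config.stages:
            _stage_rip(config, outdir, state, emit)
        if "hic" in config.stages:
            _stage_hic(config, outdir, state, emit)
        if "link" in config.stages:
            _stage_link(config, outdir, state, emit)
    except Exception:
        _write_manifest(manifest, outputs, outdir)
        raise
    _write_manifest(manifest, outputs, outdir)
    return manifest


def _write_manifest(manifest: dict, outputs: list, outdir: Path) -> None:
    manifest["outputs"] = [
        {"stage": stage, "path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
        for stage, p in outputs
        if p.exists()
    ]
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _stage_simulate(config, outdir, state, emit):
    log.info("stage simulate")
    sim = dict(config.simulate)
    plan = synthetic.default_block_plan(
        n_chromosomes=sim.get("n_chromosomes", 7),
        genome_size=sim.get("genome_size", 35_000_000),
        seed=config.seed,
    )
    res = synthetic.generate_blocky_genome(
        plan, seed=config.seed, mite_near_gene_rate=sim.get("mite_near_gene_rate", 0.07)
    )
    state["genome"], state["blocks_true"] = res.genome, res.blocks
    state["repeats"], state["genes"] = res.repeats, res.genes
    state["centromeres"] = res.centromeres
    iof.write_fasta(res.genome, outdir / "genome.fa")
    emit("simulate", outdir / "genome.fa")
    iof.write_intervals(
        res.blocks.assign(name=res.blocks["kind"], score=0, strand="+"),
        outdir / "blocks_true.bed", "BED",
    )
    emit("simulate", outdir / "blocks_true.bed")
    rep = res.repeats.rename(
        columns={"family": "Family", "copy_id": "CopyID",
                 "fragment_index": "FragmentIndex", "repeat_class": "Class"}
    ).assign(type="dispersed_repeat")
    iof.write_intervals(
        rep, outdir / "repeats.gff3", "GFF3",
        attribute_cols=["Family", "CopyID", "FragmentIndex", "Class"],
    )
    emit("simulate", outdir / "repeats.gff3")
    iof.write_intervals(
        res.genes.assign(name=res.genes["gene_id"], score=0),
        outdir / "genes.bed", "BED",
    )
    emit("simulate", outdir / "genes.bed")

    hp = dict(config.hic)
    params = synthetic.HiCSimParams(
        n_pairs=hp.get("n_pairs", 1_000_000),
        alpha_within_AT=hp.get("alpha_within_AT", -0.55),
        alpha_within_GC=hp.get("alpha_within_GC", -1.29),
        same_type_affinity=hp.get("same_type_affinity", 3.0),
        trans_fraction=hp.get("trans_fraction", 0.15),
        centromere_boost=hp.get("centromere_boost", 40.0),
        seed=config.seed,
    )
    pairs = synthetic.simulate_hic_pairs(
        res.blocks, res.genome, params, centromeres=res.centromeres
    )
    state["pairs"] = pairs
    iof.write_pairs(pairs, outdir / "pairs.tsv")
    emit("simulate", outdir / "pairs.tsv")
    state["mod_calls"] = synthetic.simulate_mod_calls(
        res.genome, res.blocks, seed=config.seed
    )
    iof.write_mod_calls(state["mod_calls"], outdir / "mod_calls.tsv")
    emit("simulate", outdir / "mod_calls.tsv")


def _stage_segment(config, outdir, state, emit):
    log.info("stage segment")
    if "genome" not in state:
        state["genome"] = iof.read_fasta(config.paths["fasta"])
    track = segmentation.gc_track(state["genome"], config.params["segment_window"])
    seg = segmentation.segment_at_rich(track, config.params["min_block_len"])
    state["blocks"] = seg.blocks
    state["segmentation"] = seg
    iof.write_intervals(
        seg.blocks.assign(name=seg.blocks["kind"], score=0, strand="+"),
        outdir / "blocks.bed", "BED",
    )
    emit("segment", outdir / "blocks.bed")
    summary = segmentation.composition_summary(
        seg.blocks, state.get("repeats"), state.get("genes")
    )
    summary.to_csv(outdir / "composition.tsv", sep="\t", index=False)
    emit("segment", outdir / "composition.tsv")


def _stage_rip(config, outdir, state, emit):
    log.info("stage rip")
    blocks = state.get("blocks", state.get("blocks_true"))
    repeats = state.get("repeats")
    if repeats is None and "repeats" in config.paths:
        gff = iof.read_intervals(config.paths["repeats"], "GFF3")
        repeats = gff.rename(
            columns={"Family": "family", "CopyID": "copy_id",
                     "FragmentIndex": "fragment_index", "Class": "repeat_class"}
        )
        state["repeats"] = repeats
    profile = rip.rip_profile(repeats, state["genome"], blocks)
    profile.to_csv(outdir / "rip.tsv", sep="\t", index=False)
    emit("rip", outdir / "rip.tsv")
    edges = rip.nesting_interruptions(repeats)
    edges.to_csv(outdir / "interruptions.tsv", sep="\t", index=False)
    emit("rip", outdir / "interruptions.tsv")
    refs = (
        repeats.groupby("family")
        .agg(repeat_class=("repeat_class", "first"))
        .reset_index()
    )
    # reference length proxy: longest single-fragment annotation per family
    frag_len = (repeats["end"] - repeats["start"]).groupby(repeats["family"]).max()
    refs["ref_len"] = refs["family"].map(frag_len)
    stats = rip.repeat_family_stats(repeats, blocks, refs)
    stats.to_csv(outdir / "repeat_families.tsv", sep="\t", index=False)
    emit("rip", outdir / "repeat_families.tsv")
    state["rip_profile"] = profile


def _stage_hic(config, outdir, state, emit):
    log.info("stage hic")
    pairs = state.get("pairs")
    if pairs is None:
        pairs = iof.read_pairs(config.paths["pairs"])
    matrix = hic_mod.build_contact_matrix(
        pairs, state["genome"], bin_size=config.params["bin_size"],
        mapq_min=config.params["mapq_min"],
    )
    balanced = hic_mod.ice_normalize(matrix)
    state["matrix"], state["balanced"] = matrix, balanced
    iof.write_contact_matrix(matrix, outdir / "matrix")
    emit("hic", outdir / "matrix.bins.tsv")
    emit("hic", outdir / "matrix.coo.tsv")
    blocks = state.get("blocks", state.get("blocks_true"))
    scores = hic_mod.compartment_pca(balanced, blocks)
    scores.to_csv(outdir / "compartments.tsv", sep="\t", index=False)
    emit("hic", outdir / "compartments.tsv")
    tads = hic_mod.call_tads(
        balanced, config.params["tad_window_bins"], config.params["tad_min_bins"]
    )
    state["tads"] = tads
    iof.write_intervals(
        tads.assign(name=tads["tad_id"].where(tads["label"] == "TAD", "gap"), score=0, strand="+"),
        outdir / "tads.bed", "BED",
    )
    emit("hic", outdir / "tads.bed")
    fits = []
    for kind in ("AT", "GC"):
        try:
            fit = hic_mod.fit_distance_decay(
                matrix, blocks[blocks["kind"] == kind], label=kind
            )
            fits.append({"label": kind, "alpha": fit.alpha, "r_squared": fit.r_squared})
        except ValueError as exc:
            log.warning("decay fit for %s skipped: %s", kind, exc)
    pd.DataFrame(fits).to_csv(outdir / "decay.tsv", sep="\t", index=False)
    emit("hic", outdir / "decay.tsv")
    cents = hic_mod.detect_centromeres(matrix, seed=config.seed)
    cents.to_csv(outdir / "centromeres.tsv", sep="\t", index=False)
    emit("hic", outdir / "centromeres.tsv")
    state["centromere_calls"] = cents


def _stage_link(config, outdir, state, emit):
    log.info("stage link")
    expr = state.get("expression")
    if expr is None and "expression" in config.paths:
        expr = iof.read_expression(config.paths["expression"])
    if expr is None:
        ep = dict(config.expression)
        params = synthetic.ExpressionSimParams(
            tad_effect_sd=ep.get("tad_effect_sd", 0.6),
            residual_sd=ep.get("residual_sd", 1.0),
            n_de_fraction=ep.get("n_de_fraction", 0.2),
            mite_fold=ep.get("mite_fold", 3.0),
            seed=config.seed,
        )
        mites = state["repeats"][state["repeats"]["repeat_class"] == "MITE"]
        sim = synthetic.simulate_expression(state["genes"], state.get("tads"), mites, params)
        expr = sim.table
        iof.write_expression(expr, outdir / "expression.tsv")
        emit("link", outdir / "expression.tsv")
    state["expression"] = expr
    blocks = state.get("blocks", state.get("blocks_true"))
    model = linkage.tad_coregulation_model(expr, state.get("tads"), state.get("repeats"), state.get("genome"))
    model.table.to_csv(outdir / "tad_model.tsv", sep="\t", index=False)
    emit("link", outdir / "tad_model.tsv")
    state["tad_model"] = model
    if "matrix" in state:
        enr = linkage.gene_set_contact_enrichment(
            state["matrix"], state["genes"], expr, which="top", seed=config.seed
        )
        enr.table.to_csv(outdir / "enrichment_top.tsv", sep="\t", index=False)
        emit("link", outdir / "enrichment_top.tsv")
        mantel = linkage.mantel_repeat_contacts(
            blocks, state["matrix"], state["repeats"], n_perm=999, seed=config.seed
        )
        pd.DataFrame([dataclasses.asdict(mantel)]).to_csv(
            outdir / "mantel.tsv", sep="\t", index=False
        )
        emit("link", outdir / "mantel.tsv")
    mites = state["repeats"][state["repeats"]["repeat_class"] == "MITE"]
    me = linkage.mite_enrichment(
        mites, state["genes"], expr, window=config.params["mite_window"]
    )
    me.family_table.to_csv(outdir / "mite_families.tsv", sep="\t", index=False)
    emit("link", outdir / "mite_families.tsv")
    state["mite_enrichment"] = me
    if "mod_calls" in state:
        summary = linkage.methylation_summary(
            state["mod_calls"], blocks, state.get("genes"), state["genome"],
            modqv_min=config.params["modqv_min"],
        )
        with open(outdir / "m6a.json", "w") as fh:
            json.dump(
                {
                    "fraction_modified": summary["fraction_modified"],
                    "n_calls_passing": summary["n_calls_passing"],
                    "n_adenines": summary["n_adenines"],
                },
                fh, indent=2, sort_keys=True,
            )
        emit("link", outdir / "m6a.json")
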