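"""End-to-end orchestration from a single structured config.

A run either consumes real inputs (peak BEDs, coverage bedGraphs, gene
models, DE tables, FISH counts) or generates a synthetic bundle first,
then executes: peak merging -> all-of-N co-binding call -> gene
assignment -> promoter/gene-body scoring -> change significance ->
top-fraction call -> target classification -> overlap-enrichment battery
-> concordance -> metagene profiles -> FISH ratios.  Every stage writes a
plain-text artifact and a count into the run manifest; no output carries
a timestamp, so reruns of the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import RegionSpec, read_chrom_sizes, read_gene_models
from .errors import ConfigError, DataError
from .peaks import (
    assign_to_genes,
    bound_gene_sets,
    call_all_of_n,
    merge_factor_peaks,
    read_peak_bed,
    write_assignments_tsv,
    write_regions_bed,
)
from .scoring import (
    change_significance,
    score_genes,
    top_fraction,
    write_scores_tsv,
)
from .signal import average_profile, kmeans_rows, profile_matrix, read_track, zscore
from .simulate import FACTORS, SimConfig, generate_bundle
from .stats import (
    annotate_direction,
    classify_targets,
    concordance,
    enrichment_battery,
    fish_ratio_table,
    read_de_table,
    read_fish_counts,
)

log = logging.getLogger(__name__)


@dataclass
class Params:
    """Analysis thresholds; defaults are the study's stated windows."""

    promoter_upstream: int = 500
    promoter_downstream: int = 200
    genebody_offset: int = 500
    downstream_bp: int = 500
    top_fraction: float = 0.05
    top_on: str = "wt"
    de_alpha: float = 0.05
    null_draws: int = 10_000
    min_coverage_fraction: float = 0.5
    profile_upstream: int = 1000
    profile_downstream: int = 2000
    profile_bin_size: int = 10
    kmeans_k: int = 3
    min_overlap_bp: int = 1
    require_factors: Optional[list] = None


@dataclass
class RunConfig:
    """Either a ``simulate`` block or real-input paths, plus parameters."""

    seed: int = 0
    simulate: Optional[SimConfig] = None
    inputs: Optional[dict] = None
    params: Params = field(default_factory=Params)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError(
                "config must contain exactly one of 'simulate' or 'inputs'"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.get("simulate")
        if sim is not None:
            sim = dict(sim)
            sim.setdefault("seed", d.get("seed", 0))
            sim = SimConfig.from_dict(sim)
        params = Params(**d.get("params", {}))
        return cls(
            seed=int(d.get("seed", 0)),
            simulate=sim,
            inputs=d.get("inputs"),
            params=params,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            payload = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse config {path}: {e}") from e
        if not isinstance(payload, dict):
            raise ConfigError(f"config {path} must be a mapping")
        return cls.from_dict(payload)

    def canonical(self) -> str:
        d = {
            "seed": self.seed,
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "inputs": self.inputs,
            "params": self.params.__dict__,
        }
        return yaml.safe_dump(d, sort_keys=True)


_REQUIRED_INPUTS = ("genes", "track_wt", "track_mut", "de_primary")


def _resolve_inputs(cfg: RunConfig, outdir: Path) -> dict:
    if cfg.simulate is not None:
        paths = generate_bundle(cfg.simulate, outdir / "inputs")
        return {
            "genes": paths["genes"],
            "chrom_sizes": paths["chrom_sizes"],
            "peaks": {f: paths[f"peaks_{f}"] for f in FACTORS},
            "track_wt": paths["track_wt"],
            "track_mut": paths["track_mut"],
            "de_primary": paths["de_lin35"],
            "de_second": paths["de_htz1"],
            "fish": paths["fish"],
            "tss_table": None,
        }
    inputs = dict(cfg.inputs)
    missing = [k for k in _REQUIRED_INPUTS if not inputs.get(k)]
    if missing:
        raise ConfigError(f"inputs block missing required keys: {missing}")
    if not isinstance(inputs.get("peaks"), dict) or not inputs["peaks"]:
        raise ConfigError("inputs.peaks must map factor name -> BED path")
    for key in _REQUIRED_INPUTS:
        if not Path(inputs[key]).exists():
            raise DataError(f"input file not found: {inputs[key]}")
    inputs.setdefault("chrom_sizes", None)
    inputs.setdefault("de_second", None)
    inputs.setdefault("fish", None)
    inputs.setdefault("tss_table", None)
    return inputs


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = cfg.params
    counts: dict = {}

    inputs = _resolve_inputs(cfg, outdir)
    chrom_sizes = (
        read_chrom_sizes(inputs["chrom_sizes"]) if inputs["chrom_sizes"] else None
    )
    genes = read_gene_models(inputs["genes"], inputs.get("tss_table"))
    counts["genes"] = len(genes)

    log.info("stage=merge_peaks n_factors=%d seed=%d", len(inputs["peaks"]),
             cfg.seed)
    peak_sets = [
        read_peak_bed(path, factor=factor)
        for factor, path in sorted(inputs["peaks"].items())
    ]
    merged = merge_factor_peaks(peak_sets, min_overlap_bp=p.min_overlap_bp)
    counts["merged_regions"] = len(merged)
    required = p.require_factors or sorted(inputs["peaks"])
    cobound = call_all_of_n(merged, required)
    counts["cobound_regions"] = len(cobound)
    write_regions_bed(cobound, outdir / "dream8_regions.bed")

    promoter_spec = RegionSpec(
        "tss", upstream_bp=p.promoter_upstream,
        downstream_bp=p.promoter_downstream,
    )
    assignments = assign_to_genes(
        merged, genes, promoter_spec, downstream_bp=p.downstream_bp
    )
    write_assignments_tsv(assignments, outdir / "region_gene_assignments.tsv")
    bound_all, bound_any = bound_gene_sets(assignments, required)
    counts["bound_by_all"] = len(bound_all)
    counts["bound_by_any"] = len(bound_any)

    log.info("stage=score n_genes=%d seed=%d", len(genes), cfg.seed)
    track_wt = read_track(inputs["track_wt"])
    track_mut = read_track(inputs["track_mut"])
    scores = score_genes(
        track_wt, genes, track_mut,
        promoter_spec=promoter_spec,
        body_offset=p.genebody_offset,
        min_coverage_fraction=p.min_coverage_fraction,
    )
    scores["p_change"] = change_significance(
        genes, track_wt, track_mut, scores,
        null_draws=p.null_draws, seed=cfg.seed,
        body_offset=p.genebody_offset,
        min_coverage_fraction=p.min_coverage_fraction,
    )
    write_scores_tsv(scores, outdir / "gene_scores.tsv")
    scored_universe = set(scores.index[scores["genebody_score"].notna()])
    counts["scored_genes"] = len(scored_universe)

    top = top_fraction(scores, p.top_fraction, on=p.top_on)
    (outdir / "top_fraction.txt").write_text(
        "".join(f"{g}\n" for g in sorted(top.member_gene_ids))
    )
    _dump_json(
        {
            "fraction": top.fraction,
            "threshold_score": top.threshold_score,
            "n_members": top.n_members,
            "n_scored": top.n_scored,
            "ranked_on": p.top_on,
        },
        outdir / "top_fraction.json",
    )
    counts["top_fraction_members"] = top.n_members

    de1 = read_de_table(inputs["de_primary"], alpha=p.de_alpha)
    labels = classify_targets(
        de1, bound_all, bound_any, universe=scored_universe, alpha=p.de_alpha
    )
    labels.rename("label").to_frame().rename_axis("gene_id").to_csv(
        outdir / "target_classification.tsv", sep="\t"
    )
    counts["direct_targets"] = int((labels == "direct").sum())
    counts["indirect_targets"] = int((labels == "indirect").sum())

    direct = set(labels.index[labels == "direct"])
    up1 = set(de1.index[de1["direction"] == "up"]) & scored_universe
    topset = set(top.member_gene_ids) & scored_universe
    tests = [
        ("direct_vs_top_genebody", direct, topset),
        ("bound_any_vs_top_genebody", bound_any & scored_universe, topset),
        ("bound_any_up_vs_top_genebody", bound_any & up1, topset),
        (
            "bound_all_unregulated_vs_top_genebody",
            (bound_all & scored_universe) - up1
            - set(de1.index[de1["direction"] == "down"]),
            topset,
        ),
    ]
    de2 = None
    if inputs.get("de_second"):
        de2 = read_de_table(inputs["de_second"], alpha=p.de_alpha)
        up2 = set(de2.index[de2["direction"] == "up"]) & scored_universe
        tests.append(("up_primary_vs_up_second", up1, up2))
    battery = enrichment_battery(tests, scored_universe)
    _dump_json(battery.to_dict(orient="records"), outdir / "enrichments.json")
    battery.to_csv(outdir / "enrichments.tsv", sep="\t", index=False,
                   float_format="%.6g")
    counts["enrichment_tests"] = len(battery)

    if de2 is not None:
        conc = concordance(de1, de2, alpha=p.de_alpha)
        _dump_json(
            {
                "shared_misexpressed": conc.shared_misexpressed,
                "concordant_fraction": conc.concordant_fraction,
                "alpha": p.de_alpha,
            },
            outdir / "concordance.json",
        )
        counts["shared_misexpressed"] = conc.shared_misexpressed

    # metagene profiles on Z-scored tracks
    prof_dir = outdir / "profiles"
    prof_dir.mkdir(exist_ok=True)
    prof_spec = RegionSpec(
        "tss", upstream_bp=p.profile_upstream,
        downstream_bp=p.profile_downstream,
    )
    z_wt = zscore(track_wt)
    z_mut = zscore(track_mut)
    by_id = {g.gene_id: g for g in genes}
    gene_sets = {
        "direct": direct,
        "indirect": set(labels.index[labels == "indirect"]),
        "all": set(labels.index),
    }
    n_profiles = 0
    for set_name, gids in gene_sets.items():
        members = [by_id[g] for g in sorted(gids) if g in by_id]
        if not members:
            continue
        for track_name, tr in (("wt", z_wt), ("mut", z_mut)):
            pm = profile_matrix(
                tr, members, prof_spec, bin_size=p.profile_bin_size,
                min_coverage_fraction=p.min_coverage_fraction,
            )
            if pm.data.shape[0] == 0:
                continue
            avg = average_profile(pm)
            avg.to_csv(
                prof_dir / f"avg_{set_name}_{track_name}.tsv", sep="\t",
                float_format="%.6g",
            )
            n_profiles += 1
            if set_name == "all" and track_name == "wt":
                pm.to_tsv(prof_dir / "matrix_all_wt.tsv")
                km = kmeans_rows(pm, k=p.kmeans_k, seed=cfg.seed)
                km.to_frame().rename_axis("gene_id").to_csv(
                    prof_dir / "kmeans_clusters.tsv", sep="\t"
                )
    counts["profiles"] = n_profiles

    if inputs.get("fish"):
        foci = read_fish_counts(inputs["fish"])
        ftab = fish_ratio_table(foci, mutant="mut", wildtype="wt")
        ftab.to_csv(outdir / "fish_ratios.tsv", sep="\t", index=False,
                    float_format="%.6g")
        counts["fish_probes"] = int(ftab["probe"].nunique()) if len(ftab) else 0

    manifest = {
        "tool": "dreamchip",
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(
            cfg.canonical().encode()
        ).hexdigest(),
        "stage_counts": counts,
    }
    _dump_json(manifest, outdir / "run_manifest.json")
    return manifest
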