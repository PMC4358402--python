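"""Synthetic input bundles with recorded ground truth.

The generator emulates the statistical structure the analysis assumes in
a repressive-complex / histone-variant study:

* a single chromosome of non-overlapping genes on both strands, some
  shorter than the gene-body minimum so exclusion rules are exercised;
* promoter-localized histone-variant (H2A.Z-like) peaks on broadly
  expressed genes, present in both genotypes;
* additional gene-body signal plateaus on a planted subset of co-bound
  genes ("direct targets"), attenuated in the mutant track while the
  promoter signal is retained;
* eight per-factor peak sets co-occurring at the planted promoter sites
  plus factor-specific decoy peaks at deliberately unequal rates;
* differential-expression tables with planted up-regulation of the
  direct targets and a second mutant sharing misexpressed genes at a
  planted direction-concordance;
* an H3-like control track identical in construction between genotypes;
* RNA-FISH focus counts with a planted mutant/wild-type ratio for
  target probes and ratio 1 for the control probe.

Every component draws from its own seeded substream, so regenerating any
piece is bit-reproducible given the config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import GeneModel, GenomicInterval, write_bed12
from .errors import ConfigError, DataError
from .peaks import PeakSet, write_regions_bed
from .signal import SignalTrack, write_bedgraph

#: the eight-subunit complex profiled by the co-binding analysis
FACTORS = (
    "lin-35", "efl-1", "dpl-1", "lin-9",
    "lin-37", "lin-52", "lin-54", "lin-53",
)

FISH_TARGET_PROBES = ("hcp-6", "lin-9", "polh-1")
FISH_CONTROL_PROBE = "sqv-1"


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults that mirror the
    study conditions the analysis is meant to recover."""

    seed: int
    n_genes: int = 2000
    chrom_name: str = "chrI"
    chrom_length: int = 8_000_000
    gene_length_min: int = 300
    gene_length_max: int = 5000
    intergenic_min: int = 400
    intergenic_max: int = 1500
    fraction_broadly_expressed: float = 0.6
    fraction_bound: float = 0.05
    fraction_direct_given_bound: float = 0.7
    min_bound_gene_length: int = 800
    # planted co-binding site: promoter window around the TSS
    site_upstream: int = 150
    site_downstream: int = 50
    promoter_peak_height: float = 4.0
    body_enrichment_fold: float = 4.0
    mutant_attenuation_fold: float = 2.0
    noise_sd: float = 0.2  # sd of multiplicative log-normal noise
    track_bin: int = 25
    peak_width: int = 400
    peak_jitter: int = 100
    decoy_width: int = 300
    decoy_rate_base: float = 30.0  # factor i gets Poisson(base * (1 + i/4))
    de_effect_log2fc: float = 1.5
    de_effect_sd: float = 0.3
    de_detect_prob: float = 0.95
    de_alpha: float = 0.05
    background_misexpression_rate: float = 0.02
    second_mutant_shared_rate: float = 0.8
    concordance_target: float = 0.97
    fish_target_ratio: float = 2.0
    fish_wt_mean_soma: float = 25.0
    fish_wt_mean_germline: float = 40.0
    fish_planes: int = 8

    def __post_init__(self) -> None:
        for name in (
            "fraction_broadly_expressed", "fraction_bound",
            "fraction_direct_given_bound", "de_detect_prob",
            "background_misexpression_rate", "second_mutant_shared_rate",
            "concordance_target",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "body_enrichment_fold", "mutant_attenuation_fold",
            "fish_target_ratio",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.seed is None:
            raise ConfigError("seed is mandatory")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent substream per generator component."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


# substream ids
_S_GENOME, _S_TRUTH, _S_PEAKS, _S_TRACKS, _S_DE, _S_FISH = range(6)


@dataclass
class Truth:
    """Planted ground truth: per-gene flags/effects and co-binding sites."""

    table: pd.DataFrame  # index gene_id
    sites: list  # list[GenomicInterval], one per bound gene
    config: SimConfig

    @property
    def bound_gene_ids(self) -> set:
        return set(self.table.index[self.table["is_dream8_bound"]])

    @property
    def direct_gene_ids(self) -> set:
        return set(self.table.index[self.table["is_direct_target"]])

    def to_json(self, path) -> None:
        payload = {
            "genes": {
                gid: {
                    k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v))
                    for k, v in row.items()
                }
                for gid, row in self.table.to_dict(orient="index").items()
            },
            "sites": [[s.chrom, int(s.start), int(s.end)] for s in self.sites],
            "config": self.config.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "Truth":
        payload = json.loads(Path(path).read_text())
        table = pd.DataFrame.from_dict(payload["genes"], orient="index")
        table.index.name = "gene_id"
        sites = [GenomicInterval(c, s, e) for c, s, e in payload["sites"]]
        return cls(table=table.sort_index(), sites=sites,
                   config=SimConfig.from_dict(payload["config"]))


def generate_genome(cfg: SimConfig) -> list[GeneModel]:
    """Place non-overlapping genes of mixed strand along one chromosome."""
    if cfg.n_genes < 10:
        raise ConfigError("n_genes must be >= 10")
    rng = cfg.rng(_S_GENOME)
    lengths = rng.integers(cfg.gene_length_min, cfg.gene_length_max + 1,
                           size=cfg.n_genes)
    gaps = rng.integers(cfg.intergenic_min, cfg.intergenic_max + 1,
                        size=cfg.n_genes)
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    genes = []
    pos = 1000
    width = len(str(cfg.n_genes))
    for i in range(cfg.n_genes):
        start = pos + int(gaps[i])
        end = start + int(lengths[i])
        if end > cfg.chrom_length - 1000:
            raise DataError(
                f"genes do not fit: need > {end + 1000} bp on "
                f"{cfg.chrom_name} of length {cfg.chrom_length}"
            )
        genes.append(
            GeneModel(
                gene_id=f"g{i:0{width}d}",
                chrom=cfg.chrom_name,
                start=start,
                end=end,
                strand=str(strands[i]),
            )
        )
        pos = end
    return genes


def generate_truth(genes: Sequence[GeneModel], cfg: SimConfig) -> Truth:
    """Sample which genes are broadly expressed, co-bound, and direct."""
    rng = cfg.rng(_S_TRUTH)
    gids = [g.gene_id for g in genes]
    n = len(gids)
    broad = np.zeros(n, dtype=bool)
    broad[rng.random(n) < cfg.fraction_broadly_expressed] = True
    eligible = [
        i for i in range(n)
        if broad[i] and genes[i].length >= cfg.min_bound_gene_length
    ]
    n_bound = round(n * cfg.fraction_bound)
    if n_bound > len(eligible):
        raise ConfigError(
            "not enough broadly expressed genes of sufficient length to bind"
        )
    bound_idx = rng.choice(eligible, size=n_bound, replace=False)
    bound = np.zeros(n, dtype=bool)
    bound[bound_idx] = True
    n_direct = round(n_bound * cfg.fraction_direct_given_bound)
    direct_idx = rng.choice(bound_idx, size=n_direct, replace=False)
    direct = np.zeros(n, dtype=bool)
    direct[direct_idx] = True

    table = pd.DataFrame(
        {
            "is_broadly_expressed": broad,
            "is_dream8_bound": bound,
            "is_direct_target": direct,
            "planted_body_enrichment": np.where(
                direct, cfg.body_enrichment_fold, 1.0
            ),
            "planted_mutant_attenuation": np.where(
                direct, cfg.mutant_attenuation_fold, 1.0
            ),
            "planted_de_log2fc": np.where(direct, cfg.de_effect_log2fc, 0.0),
        },
        index=pd.Index(gids, name="gene_id"),
    )
    sites = []
    for i in sorted(bound_idx):
        g = genes[i]
        if g.strand == "+":
            s, e = g.tss - cfg.site_upstream, g.tss + cfg.site_downstream
        else:
            s, e = g.tss - cfg.site_downstream, g.tss + cfg.site_upstream
        sites.append(GenomicInterval(g.chrom, max(s, 0), e))
    return Truth(table=table, sites=sites, config=cfg)


def generate_peaks(
    genes: Sequence[GeneModel], truth: Truth, cfg: SimConfig
) -> list[PeakSet]:
    """Eight factor peak sets: co-occurring planted peaks plus decoys."""
    rng = cfg.rng(_S_PEAKS)
    sites = truth.sites
    half = cfg.peak_width // 2
    peak_sets = []
    for i, factor in enumerate(FACTORS):
        ivs = []
        for site in sites:
            jitter = int(rng.integers(-cfg.peak_jitter, cfg.peak_jitter + 1))
            center = site.midpoint + jitter
            ivs.append(
                GenomicInterval(
                    site.chrom, max(center - half, 0), center + half
                )
            )
        lam = cfg.decoy_rate_base * (1 + i / 4)  # deliberately unequal
        n_decoy = int(rng.poisson(lam))
        placed = 0
        while placed < n_decoy:
            s = int(rng.integers(0, cfg.chrom_length - cfg.decoy_width))
            iv = GenomicInterval(cfg.chrom_name, s, s + cfg.decoy_width)
            if any(iv.overlaps(site) for site in sites):
                continue  # decoys avoid planted promoter sites
            ivs.append(iv)
            placed += 1
        peak_sets.append(PeakSet(factor=factor, peaks=ivs, stage="sim"))
    return peak_sets


def _apply_to_bins(arr: np.ndarray, start: int, end: int, bin_size: int,
                   fn) -> None:
    lo = max(start // bin_size, 0)
    hi = min(-(-end // bin_size), len(arr))
    if hi > lo:
        arr[lo:hi] = fn(arr[lo:hi])


def generate_tracks(
    genes: Sequence[GeneModel], truth: Truth, cfg: SimConfig
) -> tuple[SignalTrack, SignalTrack, SignalTrack]:
    """(wt, mut, h3_control) signal/input tracks at track_bin resolution.

    Baseline 1.0 everywhere; broadly expressed genes gain an additive
    promoter bump over TSS-150..+50; direct targets gain a multiplicative
    gene-body plateau, divided by the attenuation fold in the mutant
    while the promoter bump is unchanged.  The H3 control is flat and
    shared between genotypes.
    """
    rng = cfg.rng(_S_TRACKS)
    nb = -(-cfg.chrom_length // cfg.track_bin)
    wt = np.ones(nb)
    mut = np.ones(nb)
    tbl = truth.table
    by_id = {g.gene_id: g for g in genes}
    for gid, row in tbl.iterrows():
        g = by_id[gid]
        if row["is_direct_target"]:
            fold = row["planted_body_enrichment"]
            att = row["planted_mutant_attenuation"]
            _apply_to_bins(wt, g.start, g.end, cfg.track_bin,
                           lambda v: v * fold)
            _apply_to_bins(mut, g.start, g.end, cfg.track_bin,
                           lambda v: v * (fold / att))
        if row["is_broadly_expressed"]:
            if g.strand == "+":
                s, e = g.tss - 150, g.tss + 50
            else:
                s, e = g.tss - 50, g.tss + 150
            h = cfg.promoter_peak_height
            _apply_to_bins(wt, s, e, cfg.track_bin, lambda v: v + h)
            _apply_to_bins(mut, s, e, cfg.track_bin, lambda v: v + h)
    h3 = np.ones(nb)
    if cfg.noise_sd > 0:
        wt = wt * np.exp(rng.normal(0, cfg.noise_sd, nb))
        mut = mut * np.exp(rng.normal(0, cfg.noise_sd, nb))
        h3 = h3 * np.exp(rng.normal(0, cfg.noise_sd, nb))
    starts = np.arange(nb, dtype=np.int64) * cfg.track_bin
    ends = np.minimum(starts + cfg.track_bin, cfg.chrom_length)

    def mk(vals):
        return SignalTrack({cfg.chrom_name: (starts, ends, vals)})

    return mk(wt), mk(mut), mk(h3)


def _fill_null_de(rng, n, alpha):
    lfc = rng.normal(0, 0.2, n)
    padj = rng.uniform(alpha, 1.0, n)
    return lfc, padj


def _sig_padj(rng, n, alpha, lo_exp=-8.0):
    return 10 ** rng.uniform(lo_exp, np.log10(alpha), n)


def generate_de_tables(
    genes: Sequence[GeneModel], truth: Truth, cfg: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(primary-mutant, second-mutant) differential-expression tables.

    Direct targets get the planted positive log2FC and a significant
    adjusted p with probability ``de_detect_prob``; background genes
    misexpress in either direction at a low false-positive rate.  The
    second mutant re-misexpresses a subset of the primary mutant's
    misexpressed genes, flipping the direction of exactly
    ``round((1 - concordance_target) * shared)`` of them so the realized
    concordance matches the target up to rounding, plus its own
    background misexpression.
    """
    rng = cfg.rng(_S_DE)
    gids = np.array([g.gene_id for g in genes])
    n = len(gids)
    tbl = truth.table.loc[gids]
    direct = tbl["is_direct_target"].to_numpy()
    broad = tbl["is_broadly_expressed"].to_numpy()

    lfc, padj = _fill_null_de(rng, n, cfg.de_alpha)
    # background misexpression (false positives of the upstream DE model)
    bg = (~direct) & (rng.random(n) < cfg.background_misexpression_rate)
    n_bg = int(bg.sum())
    lfc[bg] = rng.choice([-1.0, 1.0], n_bg) * rng.uniform(0.5, 2.5, n_bg)
    padj[bg] = _sig_padj(rng, n_bg, cfg.de_alpha, lo_exp=-6.0)
    # planted derepression of direct targets
    detected = direct & (rng.random(n) < cfg.de_detect_prob)
    n_det = int(detected.sum())
    lfc[detected] = cfg.de_effect_log2fc + rng.normal(0, cfg.de_effect_sd, n_det)
    padj[detected] = _sig_padj(rng, n_det, cfg.de_alpha)
    rpkm = rng.lognormal(np.where(broad, 3.0, 1.0), 1.0, n)
    de_primary = pd.DataFrame(
        {"log2fc": lfc, "padj": padj, "rpkm": rpkm},
        index=pd.Index(gids, name="gene_id"),
    )

    lfc2, padj2 = _fill_null_de(rng, n, cfg.de_alpha)
    mis1 = padj <= cfg.de_alpha
    shared = mis1 & (rng.random(n) < cfg.second_mutant_shared_rate)
    shared_idx = np.nonzero(shared)[0]
    m = len(shared_idx)
    n_flip = round((1 - cfg.concordance_target) * m)
    flip_idx = (
        rng.choice(shared_idx, size=n_flip, replace=False)
        if n_flip
        else np.array([], dtype=int)
    )
    sign2 = np.sign(lfc)
    sign2[flip_idx] *= -1
    mags = rng.uniform(0.6, 2.0, m)
    lfc2[shared_idx] = sign2[shared_idx] * mags
    padj2[shared_idx] = _sig_padj(rng, m, cfg.de_alpha)
    # second mutant's private misexpression
    bg2 = (~mis1) & (rng.random(n) < cfg.background_misexpression_rate)
    n_bg2 = int(bg2.sum())
    lfc2[bg2] = rng.choice([-1.0, 1.0], n_bg2) * rng.uniform(0.5, 2.5, n_bg2)
    padj2[bg2] = _sig_padj(rng, n_bg2, cfg.de_alpha, lo_exp=-6.0)
    rpkm2 = rng.lognormal(np.where(broad, 3.0, 1.0), 1.0, n)
    de_second = pd.DataFrame(
        {"log2fc": lfc2, "padj": padj2, "rpkm": rpkm2},
        index=pd.Index(gids, name="gene_id"),
    )
    return de_primary, de_second


def generate_fish_counts(truth: Truth, cfg: SimConfig) -> pd.DataFrame:
    """Per-plane Poisson focus counts for target and control probes."""
    rng = cfg.rng(_S_FISH)
    rows = []
    for probe in (*FISH_TARGET_PROBES, FISH_CONTROL_PROBE):
        ratio = cfg.fish_target_ratio if probe in FISH_TARGET_PROBES else 1.0
        for compartment, wt_mean in (
            ("soma", cfg.fish_wt_mean_soma),
            ("germline", cfg.fish_wt_mean_germline),
        ):
            for genotype, mean in (("wt", wt_mean), ("mut", wt_mean * ratio)):
                counts = rng.poisson(mean, cfg.fish_planes)
                for plane, c in enumerate(counts, start=1):
                    rows.append(
                        {
                            "probe": probe,
                            "genotype": genotype,
                            "compartment": compartment,
                            "plane": plane,
                            "count": int(c),
                        }
                    )
    return pd.DataFrame(rows)


def generate_bundle(cfg: SimConfig, outdir) -> dict:
    """Write a complete input bundle in on-disk formats plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = generate_genome(cfg)
    truth = generate_truth(genes, cfg)
    peak_sets = generate_peaks(genes, truth, cfg)
    wt, mut, h3 = generate_tracks(genes, truth, cfg)
    de1, de2 = generate_de_tables(genes, truth, cfg)
    fish = generate_fish_counts(truth, cfg)

    paths = {"genes": outdir / "genes.bed"}
    write_bed12(genes, paths["genes"])
    (outdir / "chrom.sizes").write_text(
        f"{cfg.chrom_name}\t{cfg.chrom_length}\n"
    )
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    peaks_dir = outdir / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    for ps in peak_sets:
        p = peaks_dir / f"{ps.factor}.bed"
        with open(p, "w") as fh:
            for iv in ps.peaks:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ps.factor}\n")
        paths[f"peaks_{ps.factor}"] = p
    for name, tr in (("track_wt", wt), ("track_mut", mut), ("track_h3", h3)):
        p = outdir / f"{name}.bedgraph"
        write_bedgraph(tr, p)
        paths[name] = p
    for name, de in (("de_lin35", de1), ("de_htz1", de2)):
        p = outdir / f"{name}.tsv"
        out = de.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths[name] = p
    paths["fish"] = outdir / "fish_counts.tsv"
    fish.to_csv(paths["fish"], sep="\t", index=False)
    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
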