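"""Per-gene promoter and gene-body signal scores and mutant change tests.

The gene-body score is the coverage-aware mean signal from 500 bp
downstream of the gene 5' end to the gene 3' end; genes shorter than the
offset are excluded.  The promoter score covers TSS-500..+200.  Both
windows are strand-relative and configurable.

Wild-type vs mutant change per gene is summarized as
``log2((mut + eps) / (wt + eps))`` with a small pseudocount, and its
significance is an empirical two-sided p-value against length-matched
random genomic regions scored on both tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import GeneModel, GenomicInterval, RegionSpec, anchored_region
from .errors import ConfigError, DataError
from .signal import DEFAULT_MIN_COVERAGE_FRACTION, SignalTrack

DEFAULT_PROMOTER_SPEC = RegionSpec("tss", upstream_bp=500, downstream_bp=200)
#: gene body runs from (5' end + this offset) to the 3' end
DEFAULT_BODY_OFFSET = 500
#: pseudocount = this fraction of the genome-wide median gene-body score
PSEUDOCOUNT_MEDIAN_FRACTION = 0.01


def _region_means(track, genes, spec, min_cov):
    """Means plus exclusion reasons for one anchored window over all genes."""
    means = np.full(len(genes), np.nan)
    reasons: dict[str, str] = {}
    for i, g in enumerate(genes):
        reg = anchored_region(g, spec)
        if isinstance(reg, GenomicInterval):
            m = track.window_means(
                reg.chrom, [reg.start], [reg.end], min_cov
            )[0]
            means[i] = m
            if math.isnan(m):
                reasons[g.gene_id] = "low_coverage"
        else:
            reasons[g.gene_id] = reg.reason
    return means, reasons


def score_genes(
    track_wt: SignalTrack,
    genes: Sequence[GeneModel],
    track_mut: Optional[SignalTrack] = None,
    promoter_spec: RegionSpec = DEFAULT_PROMOTER_SPEC,
    body_offset: int = DEFAULT_BODY_OFFSET,
    min_coverage_fraction: float = DEFAULT_MIN_COVERAGE_FRACTION,
) -> pd.DataFrame:
    """Score every gene's promoter and gene body on the WT (and mutant) track.

    Returns a DataFrame indexed by gene_id with columns promoter_score,
    genebody_score, genebody_score_mut, log2fc, excluded_reason; the
    pseudocount used for log2fc is recorded in ``df.attrs``.  Genes whose
    body window cannot be formed (span <= *body_offset*) or lacks
    coverage keep their promoter score but have NaN body fields plus a
    reason code.
    """
    genes = list(genes)
    body_spec = RegionSpec("gene_start", downstream_bp=body_offset)
    prom, _ = _region_means(track_wt, genes, promoter_spec,
                            min_coverage_fraction)
    body_wt, reasons = _region_means(track_wt, genes, body_spec,
                                     min_coverage_fraction)
    df = pd.DataFrame(
        {
            "promoter_score": prom,
            "genebody_score": body_wt,
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    if track_mut is not None:
        body_mut, reasons_mut = _region_means(
            track_mut, genes, body_spec, min_coverage_fraction
        )
        for gid, why in reasons_mut.items():
            reasons.setdefault(gid, why)
        df["genebody_score_mut"] = body_mut
        med = np.nanmedian(body_wt) if np.any(np.isfinite(body_wt)) else np.nan
        eps = PSEUDOCOUNT_MEDIAN_FRACTION * med
        if not np.isfinite(eps) or eps <= 0:
            eps = 1e-6
        with np.errstate(invalid="ignore", divide="ignore"):
            df["log2fc"] = np.log2(
                (df["genebody_score_mut"] + eps) / (df["genebody_score"] + eps)
            )
        df.attrs["pseudocount"] = float(eps)
    df["excluded_reason"] = [reasons.get(g.gene_id, "") for g in genes]
    df.attrs["body_offset"] = body_offset
    df.attrs["min_coverage_fraction"] = min_coverage_fraction
    if df[["promoter_score", "genebody_score"]].isna().all(axis=None):
        raise DataError("no gene could be scored on the supplied tracks")
    return df


@dataclass(frozen=True)
class TopFractionCall:
    """The top-``fraction`` genes by gene-body score, ties included."""

    fraction: float
    threshold_score: float
    member_gene_ids: frozenset
    n_scored: int

    @property
    def n_members(self) -> int:
        return len(self.member_gene_ids)


def top_fraction(
    scores: pd.DataFrame, fraction: float, on: str = "wt"
) -> TopFractionCall:
    """Call the top-*fraction* of genes by gene-body level.

    ``on`` selects the ranking track ('wt' or 'mut').  Membership is the
    first ``round(fraction * n_scored)`` genes (banker's rounding) plus
    every gene tied with the last included score, so the threshold is
    never split.
    """
    if not (0 < fraction <= 1):
        raise ConfigError("fraction must be in (0, 1]")
    col = "genebody_score" if on == "wt" else "genebody_score_mut"
    if col not in scores.columns:
        raise DataError(f"scores table lacks column {col}")
    s = scores[col].dropna().sort_values(ascending=False, kind="stable")
    if s.empty:
        raise DataError("no scored genes")
    n_target = round(fraction * len(s))
    if n_target == 0:
        return TopFractionCall(fraction, math.inf, frozenset(), len(s))
    threshold = float(s.iloc[n_target - 1])
    members = frozenset(s.index[s.to_numpy() >= threshold])
    return TopFractionCall(fraction, threshold, members, len(s))


def change_significance(
    genes: Sequence[GeneModel],
    track_wt: SignalTrack,
    track_mut: SignalTrack,
    scores: pd.DataFrame,
    null_draws: int = 10_000,
    seed: int = 0,
    body_offset: int = DEFAULT_BODY_OFFSET,
    min_coverage_fraction: float = DEFAULT_MIN_COVERAGE_FRACTION,
) -> pd.Series:
    """Two-sided empirical p-value for each gene's body log2 fold change.

    For each scoreable gene, *null_draws* random genomic windows of that
    gene's own body length are scored on both tracks; the p-value is
    ``(1 + #{|null lfc| >= |observed lfc|}) / (valid draws + 1)``, floored
    at ``1/(null_draws+1)``.  Draws are independent between genes so the
    p-values are independently calibrated.
    """
    if null_draws < 100:
        raise ConfigError("null_draws must be >= 100")
    if "log2fc" not in scores.columns:
        raise DataError("scores table has no log2fc (mutant track missing?)")
    eps = scores.attrs.get("pseudocount", 1e-6)
    chroms = sorted(set(track_wt.chroms) | set(track_mut.chroms))
    extents = {
        c: max(track_wt.chrom_extent(c), track_mut.chrom_extent(c))
        for c in chroms
    }
    chrom_arr = [c for c in chroms if extents[c] > 0]
    weights = np.array([extents[c] for c in chrom_arr], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    body_spec = RegionSpec("gene_start", downstream_bp=body_offset)

    pvals = pd.Series(np.nan, index=scores.index, name="p_change")
    by_id = {g.gene_id: g for g in genes}
    for gid, obs in scores["log2fc"].items():
        if not np.isfinite(obs):
            continue
        g = by_id[gid]
        reg = anchored_region(g, body_spec)
        if not isinstance(reg, GenomicInterval):
            continue
        L = reg.length
        ci = rng.choice(len(chrom_arr), size=null_draws, p=weights)
        null_abs = np.empty(0)
        parts = []
        for k, c in enumerate(chrom_arr):
            m = ci == k
            n_c = int(m.sum())
            if n_c == 0:
                continue
            hi = max(extents[c] - L, 1)
            starts = rng.integers(0, hi, size=n_c)
            ends = starts + L
            wt = track_wt.window_means(c, starts, ends, min_coverage_fraction)
            mu = track_mut.window_means(c, starts, ends, min_coverage_fraction)
            with np.errstate(invalid="ignore", divide="ignore"):
                lfc = np.log2((mu + eps) / (wt + eps))
            parts.append(lfc[np.isfinite(lfc)])
        null_abs = np.abs(np.concatenate(parts)) if parts else np.empty(0)
        if null_abs.size < 100:
            continue
        k_ge = int(np.sum(null_abs >= abs(obs)))
        pvals[gid] = (1 + k_ge) / (null_abs.size + 1)
    return pvals


def write_scores_tsv(scores: pd.DataFrame, path) -> None:
    """Persist a score table with the columns of a per-gene summary table."""
    out = scores.copy()
    out.insert(0, "gene_id", out.index)
    cols = ["gene_id", "promoter_score", "genebody_score"]
    for c in ("genebody_score_mut", "log2fc", "p_change"):
        if c in out.columns:
            cols.append(c)
    cols.append("excluded_reason")
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_scores_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene_id")
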