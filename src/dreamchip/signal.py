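"""Normalized coverage tracks and metagene profiles.

A :class:`SignalTrack` stores one sample's signal/input ratio as sorted,
non-overlapping runs of constant value per chromosome.  Positions not
covered by any run are *missing* (unmappable in BEADS-style normalized
data) and are excluded from every mean — never treated as zero, which
would bias gene-body scores downward.

Region means use exact prefix sums over the run-length encoding, so a
window mean is O(log n_runs) and large batches of windows (metagene bins,
empirical-null regions) are evaluated with vectorized numpy.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .annotations import GeneModel, GenomicInterval, RegionSpec
from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

#: a region/bin mean is reported missing below this covered fraction
DEFAULT_MIN_COVERAGE_FRACTION = 0.5
#: floor applied before log2 when Z-scoring on the log scale
DEFAULT_LOG_FLOOR = 0.1


class SignalTrack:
    """Run-length encoded per-chromosome signal values."""

    def __init__(self, runs: dict[str, tuple]):
        self.runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._prefix_cache: dict[str, tuple] = {}
        for chrom, (starts, ends, values) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise DataError(f"{chrom}: empty or inverted run")
            if len(starts) > 1:
                bad = np.nonzero(starts[1:] < ends[:-1])[0]
                if bad.size:
                    i = int(bad[0])
                    raise DataError(
                        f"overlapping intervals on {chrom}: "
                        f"[{starts[i]},{ends[i]}) and [{starts[i+1]},{ends[i+1]})"
                    )
            if not np.all(np.isfinite(values)):
                raise DataError(f"{chrom}: non-finite signal values")
            self.runs[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.runs)

    def covered_bp(self) -> int:
        return int(
            sum((e - s).sum() for s, e, _ in self.runs.values())
        )

    def chrom_extent(self, chrom: str) -> int:
        """Highest covered coordinate on *chrom* (0 if absent)."""
        if chrom not in self.runs:
            return 0
        return int(self.runs[chrom][1][-1])

    # -- exact prefix-sum machinery -------------------------------------

    def _prefix(self, chrom):
        if chrom not in self._prefix_cache:
            starts, ends, values = self.runs[chrom]
            lens = (ends - starts).astype(np.float64)
            cum_vlen = np.concatenate(([0.0], np.cumsum(values * lens)))
            cum_len = np.concatenate(([0.0], np.cumsum(lens)))
            self._prefix_cache[chrom] = (starts, ends, values, cum_vlen, cum_len)
        return self._prefix_cache[chrom]

    def _sums_at(self, chrom, pos):
        """(weighted sum, covered length) of everything left of each pos."""
        starts, ends, values, cum_vlen, cum_len = self._prefix(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        j = np.searchsorted(starts, pos, side="right") - 1
        jj = np.maximum(j, 0)
        part = np.clip(pos - starts[jj], 0, ends[jj] - starts[jj]).astype(
            np.float64
        )
        wsum = cum_vlen[jj] + values[jj] * part
        clen = cum_len[jj] + part
        miss = j < 0
        if np.any(miss):
            wsum = np.where(miss, 0.0, wsum)
            clen = np.where(miss, 0.0, clen)
        return wsum, clen

    def window_sums(self, chrom: str, starts, ends):
        """Vectorized (weighted sum, covered bp) over many windows."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self.runs:
            z = np.zeros(starts.shape, dtype=np.float64)
            return z, z.copy()
        s0, l0 = self._sums_at(chrom, starts)
        s1, l1 = self._sums_at(chrom, ends)
        return s1 - s0, l1 - l0

    def window_means(
        self,
        chrom: str,
        starts,
        ends,
        min_coverage_fraction: float = DEFAULT_MIN_COVERAGE_FRACTION,
    ) -> np.ndarray:
        """Vectorized coverage-aware window means (NaN where missing)."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        wsum, clen = self.window_sums(chrom, starts, ends)
        width = np.maximum(ends - starts, 1).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = wsum / clen
        frac = clen / width
        means[(clen <= 0) | (frac < min_coverage_fraction)] = np.nan
        return means

    # -- transforms ------------------------------------------------------

    def map_values(self, fn) -> "SignalTrack":
        return SignalTrack(
            {c: (s.copy(), e.copy(), fn(v)) for c, (s, e, v) in self.runs.items()}
        )

    def weighted_moments(self) -> tuple[float, float]:
        """Coverage-length-weighted mean and population SD of all values."""
        tot = wsum = wsq = 0.0
        for starts, ends, values in self.runs.values():
            lens = (ends - starts).astype(np.float64)
            tot += lens.sum()
            wsum += float(np.dot(values, lens))
            wsq += float(np.dot(values * values, lens))
        if tot == 0:
            raise DataError("empty track")
        mu = wsum / tot
        var = max(wsq / tot - mu * mu, 0.0)
        return mu, math.sqrt(var)


class ZScoreTrack(SignalTrack):
    """A SignalTrack whose values are Z-scores; keeps the transform stats."""

    def __init__(self, runs, mu: float, sigma: float, log2_first: bool = False,
                 log_floor: float = DEFAULT_LOG_FLOOR):
        super().__init__(runs)
        self.mu = mu
        self.sigma = sigma
        self.log2_first = log2_first
        self.log_floor = log_floor


def zscore(
    track: SignalTrack,
    log2_first: bool = False,
    log_floor: float = DEFAULT_LOG_FLOOR,
) -> ZScoreTrack:
    """Z-score a track genome-wide over covered positions.

    mu and sigma are coverage-length-weighted population statistics.  With
    ``log2_first`` the values are log2-transformed (after flooring at
    *log_floor*) before standardizing, giving "log2 Z-scores".  A constant
    track (sigma == 0) yields all zeros with a warning.
    """
    if track.covered_bp() < 2:
        raise DataError("track must cover >= 2 positions to Z-score")
    work = track
    if log2_first:
        work = track.map_values(lambda v: np.log2(np.maximum(v, log_floor)))
    mu, sigma = work.weighted_moments()
    if sigma == 0:
        warnings.warn("constant track: sigma = 0, Z-scores set to 0",
                      stacklevel=2)
        runs = {c: (s, e, np.zeros_like(v))
                for c, (s, e, v) in work.runs.items()}
    else:
        runs = {c: (s, e, (v - mu) / sigma)
                for c, (s, e, v) in work.runs.items()}
    return ZScoreTrack(runs, mu=mu, sigma=sigma, log2_first=log2_first,
                       log_floor=log_floor)


def mean_over(
    track: SignalTrack,
    region: GenomicInterval,
    min_coverage_fraction: float = DEFAULT_MIN_COVERAGE_FRACTION,
) -> float:
    """Length-weighted mean of covered values in *region*.

    Returns NaN ("missing") when the covered fraction of the region is
    below *min_coverage_fraction*.
    """
    m = track.window_means(
        region.chrom,
        np.array([region.start]),
        np.array([region.end]),
        min_coverage_fraction,
    )
    return float(m[0])


# ---------------------------------------------------------------------------
# readers / writers


def read_track(path) -> SignalTrack:
    """Read a bedGraph or wiggle (fixedStep/variableStep) coverage track.

    Wiggle 1-based starts are converted to the internal 0-based half-open
    convention.  Overlapping intervals are an error; negative values are
    allowed (log-scale input) and logged.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    runs: dict[str, list] = {}
    mode = "bedgraph"
    chrom = None
    step = span = 1
    nxt = 0
    saw_negative = False
    for ln in lines:
        ln = ln.strip()
        if not ln or ln.startswith(("#", "track", "browser")):
            continue
        fields = ln.split()
        if fields[0] == "fixedStep":
            kv = dict(f.split("=", 1) for f in fields[1:])
            mode, chrom = "fixed", kv["chrom"]
            step = int(kv.get("step", 1))
            span = int(kv.get("span", step))
            nxt = int(kv["start"]) - 1
            continue
        if fields[0] == "variableStep":
            kv = dict(f.split("=", 1) for f in fields[1:])
            mode, chrom = "variable", kv["chrom"]
            span = int(kv.get("span", 1))
            continue
        if mode == "fixed":
            v = float(fields[0])
            runs.setdefault(chrom, []).append((nxt, nxt + span, v))
            nxt += step
        elif mode == "variable":
            s = int(fields[0]) - 1
            v = float(fields[1])
            runs.setdefault(chrom, []).append((s, s + span, v))
        else:
            if len(fields) < 4:
                raise DataError(f"{path}: bad bedGraph line: {ln!r}")
            c, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            runs.setdefault(c, []).append((s, e, v))
        if float(fields[-1]) < 0:
            saw_negative = True
    if not runs:
        raise DataError(f"{path}: no data lines")
    if saw_negative:
        log.info("%s: track contains negative values (log-scale input?)", path)
    return SignalTrack(
        {
            c: (
                [r[0] for r in rs],
                [r[1] for r in rs],
                [r[2] for r in rs],
            )
            for c, rs in runs.items()
        }
    )


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.runs[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# metagene profiles


@dataclass
class ProfileMatrix:
    """Per-gene binned signal rows, all sharing one column layout.

    ``data`` is genes x bins with NaN marking missing bins; ``columns`` are
    bin-start offsets (bp, single-anchor) or labels (scaled-body layout).
    """

    data: pd.DataFrame
    bin_size: int
    spec: RegionSpec
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id",
                         float_format="%.6g")


def _single_anchor_bins(gene: GeneModel, spec: RegionSpec, bin_size: int):
    a = gene.tss if spec.anchor == "tss" else gene.tts
    n = (spec.upstream_bp + spec.downstream_bp) // bin_size
    i = np.arange(n)
    if gene.strand == "+":
        starts = a - spec.upstream_bp + i * bin_size
    else:
        starts = a + spec.upstream_bp - (i + 1) * bin_size
    return starts, starts + bin_size


def _scaled_bins(gene: GeneModel, spec: RegionSpec, bin_size: int):
    """Flank bins at fixed width plus proportional gene-body slices."""
    body_len = abs(gene.tts - gene.tss)
    nb = spec.scaled_body_bins
    if body_len < nb:
        return None  # less than 1 bp per body bin
    nu = spec.upstream_bp // bin_size
    nd = spec.downstream_bp // bin_size
    sgn = 1 if gene.strand == "+" else -1
    five, three = gene.tss, gene.tts
    up_i = np.arange(nu)
    up_starts = five - sgn * spec.upstream_bp + sgn * up_i * bin_size
    up_ends = up_starts + sgn * bin_size
    edges = five + sgn * (np.arange(nb + 1) * body_len // nb)
    body_starts, body_ends = edges[:-1], edges[1:]
    dn_i = np.arange(nd)
    dn_starts = three + sgn * dn_i * bin_size
    dn_ends = dn_starts + sgn * bin_size
    starts = np.concatenate([up_starts, body_starts, dn_starts])
    ends = np.concatenate([up_ends, body_ends, dn_ends])
    lo, hi = np.minimum(starts, ends), np.maximum(starts, ends)
    return lo, hi


def profile_matrix(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    spec: RegionSpec,
    bin_size: int = 10,
    min_coverage_fraction: float = DEFAULT_MIN_COVERAGE_FRACTION,
) -> ProfileMatrix:
    """Binned per-gene signal matrix, rows oriented 5'->3'.

    Single-anchor specs give fixed-width rows of ``(up+down)/bin_size``
    bins; ``tss_and_tts`` specs give unscaled flanks plus length-scaled
    body bins.  Genes that cannot produce the layout are recorded in
    ``excluded`` and omitted from the matrix.
    """
    if spec.anchor != "tss_and_tts":
        if spec.upstream_bp % bin_size or spec.downstream_bp % bin_size:
            raise ConfigError("bin_size must divide the flank lengths")
        n_bins = (spec.upstream_bp + spec.downstream_bp) // bin_size
        columns = (-spec.upstream_bp + np.arange(n_bins) * bin_size).tolist()
    else:
        if spec.upstream_bp % bin_size or spec.downstream_bp % bin_size:
            raise ConfigError("bin_size must divide the flank lengths")
        nu = spec.upstream_bp // bin_size
        nd = spec.downstream_bp // bin_size
        columns = (
            [f"u{-spec.upstream_bp + i * bin_size}" for i in range(nu)]
            + [f"body{j}" for j in range(spec.scaled_body_bins)]
            + [f"d{i * bin_size}" for i in range(nd)]
        )

    rows, index, excluded = [], [], {}
    for gene in genes:
        if spec.anchor != "tss_and_tts":
            s, e = _single_anchor_bins(gene, spec, bin_size)
            lo, hi = np.minimum(s, e), np.maximum(s, e)
            means = track.window_means(
                gene.chrom, np.clip(lo, 0, None), np.clip(hi, 1, None),
                min_coverage_fraction,
            )
            # bins fully below position 0 can never be covered
            means[hi <= 0] = np.nan
        else:
            bins = _scaled_bins(gene, spec, bin_size)
            if bins is None:
                excluded[gene.gene_id] = "short_gene"
                continue
            lo, hi = bins
            means = track.window_means(
                gene.chrom, np.clip(lo, 0, None), np.clip(hi, 1, None),
                min_coverage_fraction,
            )
            means[hi <= 0] = np.nan
        rows.append(means)
        index.append(gene.gene_id)
    data = pd.DataFrame(
        np.array(rows) if rows else np.empty((0, len(columns))),
        index=index,
        columns=columns,
    )
    return ProfileMatrix(data=data, bin_size=bin_size, spec=spec,
                         excluded=excluded)


def average_profile(matrix: ProfileMatrix) -> pd.DataFrame:
    """Per-bin mean over rows (ignoring missing cells) with per-bin n."""
    if matrix.data.shape[0] == 0:
        raise DataError("no non-excluded rows to average")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(matrix.data.to_numpy(), axis=0)
    n = np.sum(~np.isnan(matrix.data.to_numpy()), axis=0)
    return pd.DataFrame(
        {"mean": means, "n": n}, index=pd.Index(matrix.data.columns, name="bin")
    )


def kmeans_rows(matrix: ProfileMatrix, k: int, seed: int) -> pd.Series:
    """K-means rows into k groups, labeled 1..k by descending mean signal.

    Missing cells are imputed with the row mean before clustering; the
    relabeling makes the output ordering seed-independent when clusters
    are well separated.
    """
    from sklearn.cluster import KMeans

    X = matrix.data.to_numpy(dtype=float)
    if k > X.shape[0]:
        raise ConfigError(f"k={k} exceeds number of rows {X.shape[0]}")
    if np.all(np.isnan(X), axis=1).any():
        raise DataError("row with no covered bins cannot be clustered")
    row_means = np.nanmean(X, axis=1)
    X = np.where(np.isnan(X), row_means[:, None], X)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    cluster_means = np.array(
        [X[km.labels_ == c].mean() if np.any(km.labels_ == c) else -np.inf
         for c in range(k)]
    )
    order = np.argsort(-cluster_means, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return pd.Series(relabel[km.labels_], index=matrix.data.index, name="cluster")
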