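"""Multi-factor peak integration.

Per-factor peak calls are combined by single-linkage merging (two peaks
belong to the same region if they share at least ``min_overlap_bp`` bases;
with half-open intervals, book-ended peaks do *not* merge).  A merged
region carries the set of factors contributing at least one peak, so
"bound by all N factors" regions — e.g. the eight DREAM subunits — are a
simple membership filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotations import (
    GeneModel,
    GenomicInterval,
    RegionSpec,
    anchored_region,
)
from .errors import DataError

DEFAULT_PROMOTER_SPEC = RegionSpec("tss", upstream_bp=500, downstream_bp=200)
DEFAULT_DOWNSTREAM_BP = 500


def _merge_self(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            last = out.pop()
            out.append(
                GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
            )
        else:
            out.append(iv)
    return out


@dataclass
class PeakSet:
    """One factor's peak calls (self-merged and sorted on construction)."""

    factor: str
    peaks: list[GenomicInterval]
    stage: str = ""

    def __post_init__(self) -> None:
        self.peaks = _merge_self(self.peaks)


@dataclass(frozen=True)
class MergedRegion:
    """A single-linkage union of peaks with its contributing factors."""

    interval: GenomicInterval
    members: frozenset

    @property
    def n_factors(self) -> int:
        return len(self.members)


def merge_factor_peaks(
    peak_sets: Sequence[PeakSet],
    min_overlap_bp: int = 1,
) -> list[MergedRegion]:
    """Single-linkage merge of all peaks across factors.

    Two intervals join when they share >= *min_overlap_bp* bases; the
    default 1 means any genuine overlap (book-ended half-open intervals
    stay apart).  Output is in genomic order.
    """
    if not peak_sets:
        raise DataError("need at least one peak set")
    events: list[tuple[str, int, int, str]] = []
    for ps in peak_sets:
        for iv in ps.peaks:
            events.append((iv.chrom, iv.start, iv.end, ps.factor))
    events.sort()
    out: list[MergedRegion] = []
    cur: Optional[list] = None  # [chrom, start, end, members]
    for chrom, start, end, factor in events:
        if (
            cur is not None
            and chrom == cur[0]
            and start <= cur[2] - min_overlap_bp
        ):
            cur[2] = max(cur[2], end)
            cur[3].add(factor)
        else:
            if cur is not None:
                out.append(
                    MergedRegion(
                        GenomicInterval(cur[0], cur[1], cur[2]),
                        frozenset(cur[3]),
                    )
                )
            cur = [chrom, start, end, {factor}]
    if cur is not None:
        out.append(
            MergedRegion(
                GenomicInterval(cur[0], cur[1], cur[2]), frozenset(cur[3])
            )
        )
    return out


def call_all_of_n(
    regions: Sequence[MergedRegion], required_factors: Iterable[str]
) -> list[MergedRegion]:
    """Regions bound by every required factor (e.g. the DREAM-8 call)."""
    required = frozenset(required_factors)
    if not required:
        raise DataError("required_factors must be non-empty")
    seen = set()
    for r in regions:
        seen |= r.members
    missing = required - seen
    if missing:
        warnings.warn(
            f"required factor(s) absent from every region: {sorted(missing)} "
            "(misspelled name?)",
            stacklevel=2,
        )
    hits = [r for r in regions if r.members >= required]
    hits.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return hits


@dataclass(frozen=True)
class StageOverlap:
    a_total: int
    b_total: int
    a_overlapping_b: int
    b_overlapping_a: int
    merged_shared: int


def _count_overlapping(a: Sequence[MergedRegion], b: Sequence[MergedRegion]) -> int:
    trees: dict[str, IntervalTree] = {}
    for r in b:
        trees.setdefault(r.interval.chrom, IntervalTree()).addi(
            r.interval.start, r.interval.end
        )
    n = 0
    for r in a:
        t = trees.get(r.interval.chrom)
        if t is not None and t.overlap(r.interval.start, r.interval.end):
            n += 1
    return n


def stage_overlap(
    regions_a: Sequence[MergedRegion], regions_b: Sequence[MergedRegion]
) -> StageOverlap:
    """Cross-tabulate two region lists (e.g. L3 vs embryo binding).

    ``a_overlapping_b``/``b_overlapping_a`` count regions sharing >= 1 bp
    with any region of the other list; ``merged_shared`` counts
    single-linkage clusters of the pooled lists containing both.
    """
    a_sets = [PeakSet("__a__", [r.interval for r in regions_a])]
    b_sets = [PeakSet("__b__", [r.interval for r in regions_b])]
    pooled = merge_factor_peaks(a_sets + b_sets)
    shared = sum(1 for r in pooled if r.members == {"__a__", "__b__"})
    return StageOverlap(
        a_total=len(regions_a),
        b_total=len(regions_b),
        a_overlapping_b=_count_overlapping(regions_a, regions_b),
        b_overlapping_a=_count_overlapping(regions_b, regions_a),
        merged_shared=shared,
    )


@dataclass(frozen=True)
class RegionGeneAssignment:
    region: MergedRegion
    gene_id: Optional[str]
    location_class: str  # promoter | gene_body | downstream | intergenic
    distance_to_tss: Optional[int]


def _signed_distance(gene: GeneModel, pos: int) -> int:
    """Strand-relative signed distance from TSS (positive = downstream)."""
    return pos - gene.tss if gene.strand == "+" else gene.tss - pos


def assign_to_genes(
    regions: Sequence[MergedRegion],
    genes: Sequence[GeneModel],
    promoter_spec: RegionSpec = DEFAULT_PROMOTER_SPEC,
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
) -> list[RegionGeneAssignment]:
    """Classify each region by its midpoint relative to gene anatomy.

    Priority: promoter window (nearest TSS wins ties, then the
    lower-coordinate gene) > gene body > within *downstream_bp* past a
    TTS > intergenic.  Classes are exclusive and exhaustive.
    """
    if promoter_spec.anchor != "tss":
        raise DataError("promoter_spec must be anchored at the TSS")
    by_id = {g.gene_id: g for g in genes}
    prom_t: dict[str, IntervalTree] = {}
    body_t: dict[str, IntervalTree] = {}
    down_t: dict[str, IntervalTree] = {}
    down_spec = RegionSpec("tts", upstream_bp=0, downstream_bp=downstream_bp)
    for g in genes:
        p = anchored_region(g, promoter_spec)
        if isinstance(p, GenomicInterval):
            prom_t.setdefault(g.chrom, IntervalTree()).addi(
                p.start, p.end, g.gene_id
            )
        body_t.setdefault(g.chrom, IntervalTree()).addi(
            g.start, g.end, g.gene_id
        )
        d = anchored_region(g, down_spec)
        if isinstance(d, GenomicInterval):
            down_t.setdefault(g.chrom, IntervalTree()).addi(
                d.start, d.end, g.gene_id
            )

    def nearest(hits, mid):
        cands = [by_id[h.data] for h in hits]
        cands.sort(
            key=lambda g: (abs(_signed_distance(g, mid)), g.start, g.gene_id)
        )
        return cands[0]

    out: list[RegionGeneAssignment] = []
    for r in regions:
        mid = r.interval.midpoint
        chrom = r.interval.chrom
        gene = None
        klass = "intergenic"
        for trees, name in ((prom_t, "promoter"), (body_t, "gene_body"),
                            (down_t, "downstream")):
            t = trees.get(chrom)
            hits = t.at(mid) if t is not None else ()
            if hits:
                gene = nearest(hits, mid)
                klass = name
                break
        out.append(
            RegionGeneAssignment(
                region=r,
                gene_id=gene.gene_id if gene else None,
                location_class=klass,
                distance_to_tss=_signed_distance(gene, mid) if gene else None,
            )
        )
    return out


def bound_gene_sets(
    assignments: Sequence[RegionGeneAssignment],
    required_factors: Iterable[str],
) -> tuple[set, set]:
    """(bound_by_all_required, bound_by_any) gene sets.

    A gene is "bound" by a region assigned to its promoter or gene body;
    the first set additionally requires the region's members to cover
    every required factor.
    """
    required = frozenset(required_factors)
    bound_any: set = set()
    bound_all: set = set()
    for a in assignments:
        if a.gene_id is None or a.location_class not in ("promoter", "gene_body"):
            continue
        bound_any.add(a.gene_id)
        if a.region.members >= required:
            bound_all.add(a.gene_id)
    return bound_all, bound_any


# ---------------------------------------------------------------------------
# BED I/O


def read_peak_bed(path, factor: Optional[str] = None, stage: str = "") -> PeakSet:
    """Read a factor's peaks from BED; factor defaults to the file stem."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ivs = [
        GenomicInterval(str(r[0]), int(r[1]), int(r[2]))
        for r in df.itertuples(index=False)
    ]
    return PeakSet(factor=factor or path.stem, peaks=ivs, stage=stage)


def write_regions_bed(regions: Sequence[MergedRegion], path) -> None:
    """Merged regions as BED: members comma-joined in col 4, n in col 5."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.interval.chrom, r.interval.start)):
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{','.join(sorted(r.members))}\t{r.n_factors}\n"
            )


def read_regions_bed(path) -> list[MergedRegion]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        members = frozenset(str(row[3]).split(",")) if len(row) > 3 else frozenset()
        out.append(
            MergedRegion(
                GenomicInterval(str(row[0]), int(row[1]), int(row[2])), members
            )
        )
    return out


def write_assignments_tsv(assignments: Sequence[RegionGeneAssignment], path) -> None:
    rows = [
        {
            "chrom": a.region.interval.chrom,
            "start": a.region.interval.start,
            "end": a.region.interval.end,
            "members": ",".join(sorted(a.region.members)),
            "n_factors": a.region.n_factors,
            "gene_id": a.gene_id if a.gene_id is not None else "",
            "location_class": a.location_class,
            "distance_to_tss": a.distance_to_tss
            if a.distance_to_tss is not None
            else "",
        }
        for a in assignments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
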