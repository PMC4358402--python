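"""Gene models and anchored genomic regions.

All coordinates inside the package are 0-based, half-open ``[start, end)``
(the BED convention).  GFF3 input (1-based, closed) is converted on read.

A gene's TSS is represented as a point coordinate such that the first
transcribed base lies immediately 3' of it: for a ``+`` strand gene the TSS
equals ``start``; for a ``-`` strand gene it equals ``end``.  "Upstream" and
"downstream" are always strand-relative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

#: maximum distance (bp) a TSS override may sit outside the gene span
TSS_OVERRIDE_SLACK = 10_000


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """One gene: span, strand, and the TSS/TTS anchors used for scoring.

    ``tss``/``tts`` default to the strand-appropriate span ends and may be
    overridden (e.g. from capped RNA-seq evidence), in which case
    ``tss_source`` records the provenance.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: Optional[int] = None
    tts: Optional[int] = None
    tss_source: str = "annotated"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise DataError(
                f"{self.gene_id}: invalid span {self.start}-{self.end}"
            )
        if self.tss is None:
            self.tss = self.start if self.strand == "+" else self.end
        if self.tts is None:
            self.tts = self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


_ANCHORS = ("tss", "tts", "gene_start", "gene_end", "tss_and_tts")


@dataclass(frozen=True)
class RegionSpec:
    """How to build a region from a gene: an anchor plus strand-relative
    upstream/downstream extents in bp.

    ``gene_start``/``gene_end`` anchor the *whole gene span* trimmed or
    extended at the named end: ``RegionSpec("gene_start", downstream_bp=500)``
    is "from 500 bp downstream of the gene 5' end to the gene 3' end" — the
    gene-body scoring window.  ``tss_and_tts`` describes a scaled-body
    metagene layout (fixed flanks, ``scaled_body_bins`` body bins).
    """

    anchor: str
    upstream_bp: int = 0
    downstream_bp: int = 0
    scaled_body_bins: Optional[int] = None

    def __post_init__(self) -> None:
        if self.anchor not in _ANCHORS:
            raise ConfigError(f"unknown anchor {self.anchor!r}")
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ConfigError("upstream_bp/downstream_bp must be >= 0")
        if self.anchor == "tss_and_tts":
            if not self.scaled_body_bins or self.scaled_body_bins < 1:
                raise ConfigError(
                    "tss_and_tts spec requires positive scaled_body_bins"
                )
        else:
            if self.scaled_body_bins is not None:
                raise ConfigError(
                    "scaled_body_bins only valid with anchor='tss_and_tts'"
                )
            if self.upstream_bp + self.downstream_bp == 0:
                raise ConfigError("region spec would be empty")


@dataclass(frozen=True)
class RegionExclusion:
    """Returned instead of an interval when a gene cannot yield the region."""

    gene_id: str
    reason: str


def anchored_region(
    gene: GeneModel,
    spec: RegionSpec,
    chrom_sizes: Optional[dict] = None,
) -> Union[GenomicInterval, RegionExclusion]:
    """Build the strand-oriented region *spec* describes for *gene*.

    Returns a :class:`RegionExclusion` (never raises) when the region is
    empty — e.g. a gene-body window on a gene shorter than the 5' offset —
    or falls entirely off the chromosome.  Regions are clipped at 0 and,
    when *chrom_sizes* is supplied, at the chromosome end.
    """
    plus = gene.strand == "+"
    up, down = spec.upstream_bp, spec.downstream_bp
    if spec.anchor in ("tss", "tts"):
        a = gene.tss if spec.anchor == "tss" else gene.tts
        start, end = (a - up, a + down) if plus else (a - down, a + up)
    elif spec.anchor == "gene_start":
        # trim `down` bp off the 5' end (extend with `up`); keep 3' end
        if plus:
            start, end = gene.start + down - up, gene.end
        else:
            start, end = gene.start, gene.end - down + up
    elif spec.anchor == "gene_end":
        # keep 5' end; extend `down` bp past / trim `up` bp off the 3' end
        if plus:
            start, end = gene.start, gene.end + down - up
        else:
            start, end = gene.start - down + up, gene.end
    else:  # tss_and_tts: full genomic footprint of the metagene window
        lo, hi = min(gene.tss, gene.tts), max(gene.tss, gene.tts)
        start, end = (lo - up, hi + down) if plus else (lo - down, hi + up)

    if start >= end:
        reason = (
            "short_gene"
            if spec.anchor in ("gene_start", "gene_end")
            else "empty_region"
        )
        return RegionExclusion(gene.gene_id, reason)

    start = max(start, 0)
    if chrom_sizes is not None and gene.chrom in chrom_sizes:
        end = min(end, int(chrom_sizes[gene.chrom]))
    if start >= end:
        return RegionExclusion(gene.gene_id, "off_chromosome")
    return GenomicInterval(gene.chrom, start, end)


# ---------------------------------------------------------------------------
# readers / writers


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    genes = []
    for feat in gffutils.DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        gid = (feat.attributes.get("ID") or feat.attributes.get("Name") or [feat.id])[0]
        # gffutils keeps GFF3 1-based closed coordinates
        genes.append(
            GeneModel(
                gene_id=str(gid).removeprefix("gene:"),
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
            )
        )
    return genes


def _read_bed(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 6:
        raise DataError(f"{path}: BED gene input needs >= 6 columns")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=str(row[3]),
                chrom=str(row[0]),
                start=int(row[1]),
                end=int(row[2]),
                strand=str(row[5]),
            )
        )
    return genes


def read_gene_models(
    annotation_path,
    tss_table_path=None,
    *,
    apply_tss_overrides: bool = True,
    on_duplicate: str = "error",
    keep_chroms: Optional[set] = None,
) -> list[GeneModel]:
    """Read gene models from GFF3 or BED(12), optionally overriding TSSs.

    The TSS table is a TSV with columns ``gene_id`` and ``tss`` (or
    ``tss_position``), 1-based; overridden genes get
    ``tss_source='capped_rnaseq'``.  Overrides landing more than 10 kb
    outside the gene span are rejected with a warning.

    ``on_duplicate``: ``'error'`` (default) raises on a repeated gene_id;
    ``'longest'`` keeps the longest span and logs the collapse.
    """
    path = Path(annotation_path)
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        genes = _read_gff3(path)
    elif suffix == ".bed":
        genes = _read_bed(path)
    else:  # sniff: GFF3 has 9 tab columns with source/type text
        first = path.read_text().lstrip().splitlines()[0]
        genes = _read_gff3(path) if first.startswith("##gff") else _read_bed(path)

    by_id: dict[str, GeneModel] = {}
    n_dup = 0
    for g in genes:
        if g.gene_id in by_id:
            if on_duplicate == "longest":
                n_dup += 1
                if g.length > by_id[g.gene_id].length:
                    by_id[g.gene_id] = g
            else:
                raise DataError(f"duplicate gene_id {g.gene_id!r} in {path}")
        else:
            by_id[g.gene_id] = g
    if n_dup:
        log.info("collapsed %d duplicate gene records to longest span", n_dup)
    genes = list(by_id.values())

    if keep_chroms is not None:
        before = len(genes)
        genes = [g for g in genes if g.chrom in keep_chroms]
        if len(genes) != before:
            log.info(
                "dropped %d genes on chromosomes absent from the signal "
                "tracks", before - len(genes),
            )

    if tss_table_path is not None and apply_tss_overrides:
        tbl = pd.read_csv(tss_table_path, sep="\t")
        col = "tss" if "tss" in tbl.columns else "tss_position"
        if "gene_id" not in tbl.columns or col not in tbl.columns:
            raise DataError(
                f"{tss_table_path}: TSS table needs columns gene_id and "
                "tss/tss_position"
            )
        overrides = dict(zip(tbl["gene_id"].astype(str), tbl[col].astype(int)))
        for g in genes:
            if g.gene_id not in overrides:
                continue
            pos1 = overrides[g.gene_id]  # 1-based base position
            # point-anchor convention: base b (1-based) -> b-1 on '+', b on '-'
            new_tss = pos1 - 1 if g.strand == "+" else pos1
            if not (g.start - TSS_OVERRIDE_SLACK <= new_tss <= g.end + TSS_OVERRIDE_SLACK):
                warnings.warn(
                    f"TSS override for {g.gene_id} at {pos1} is >10 kb outside "
                    "the gene span; override rejected",
                    stacklevel=2,
                )
                continue
            g.tss = new_tss
            g.tss_source = "capped_rnaseq"
    return genes


def write_bed12(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as single-block BED12."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                            g.start, g.end, "0,0,0", 1, g.length, 0,
                        ],
                    )
                )
                + "\n"
            )


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a UCSC two-column chrom.sizes file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))
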