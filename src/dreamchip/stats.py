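"""Target classification and gene-set overlap statistics.

Direct targets are genes both up-regulated in the pocket-protein mutant
and bound at high confidence by the full complex; indirect targets are
up-regulated but bound by no subunit.  Overlaps between gene sets are
tested with the upper tail of the hypergeometric distribution, with
Benjamini-Hochberg correction across a battery of tests run together.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError

DEFAULT_DE_ALPHA = 0.05

LABELS = (
    "direct",
    "indirect",
    "bound_partial_up",
    "bound_unregulated",
    "unbound_unregulated",
)


def read_de_table(path, alpha: float = DEFAULT_DE_ALPHA) -> pd.DataFrame:
    """Read a differential-expression TSV (gene_id, log2fc, padj, rpkm)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"gene_id", "log2fc", "padj"}
    if not needed <= set(df.columns):
        raise DataError(f"{path}: DE table needs columns {sorted(needed)}")
    df = df.set_index("gene_id")
    return annotate_direction(df, alpha)


def annotate_direction(de: pd.DataFrame, alpha: float = DEFAULT_DE_ALPHA) -> pd.DataFrame:
    """Add the up/down/unchanged call at adjusted-p threshold *alpha*."""
    de = de.copy()
    sig = de["padj"] <= alpha
    de["direction"] = np.where(
        sig & (de["log2fc"] > 0),
        "up",
        np.where(sig & (de["log2fc"] < 0), "down", "unchanged"),
    )
    de.attrs["alpha"] = alpha
    return de


def classify_targets(
    de: pd.DataFrame,
    bound_all: set,
    bound_any: set,
    universe: Optional[Iterable] = None,
    alpha: float = DEFAULT_DE_ALPHA,
) -> pd.Series:
    """Label every gene in the universe by binding and derepression.

    direct: up-regulated and bound by all required factors.
    indirect: up-regulated and bound by none.
    bound_partial_up: up-regulated, bound by some but not all factors.
    bound_unregulated / unbound_unregulated: the rest, by boundness.

    Genes in the universe absent from the DE table count as unchanged.
    """
    if "direction" not in de.columns:
        de = annotate_direction(de, alpha)
    universe = set(universe) if universe is not None else set(de.index)
    bound_all = set(bound_all) & universe
    bound_any = set(bound_any) & universe
    if not bound_all <= bound_any:
        raise DataError("bound_all must be a subset of bound_any")
    up = set(de.index[de["direction"] == "up"]) & universe
    labels = {}
    for g in universe:
        if g in up:
            if g in bound_all:
                labels[g] = "direct"
            elif g in bound_any:
                labels[g] = "bound_partial_up"
            else:
                labels[g] = "indirect"
        else:
            labels[g] = (
                "bound_unregulated" if g in bound_any else "unbound_unregulated"
            )
    out = pd.Series(labels, name="label").sort_index()
    out.attrs["alpha"] = alpha
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric upper-tail overlap test between two gene sets."""

    name: str
    k: int
    n_a: int
    n_b: int
    n_universe: int
    p_upper: float
    log10_p: float
    fold: float

    def to_dict(self) -> dict:
        return asdict(self)


def hypergeom_overlap(
    set_a: Iterable, set_b: Iterable, universe: Iterable, name: str = ""
) -> EnrichmentResult:
    """P(X >= k) for the overlap of two gene sets drawn from a universe.

    Computed from the hypergeometric survival function in log space, so
    extreme enrichments keep a meaningful log10 p.  ``fold`` is observed
    over expected overlap: (k/n_a) / (n_b/N).
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    if set(set_a) - universe or set(set_b) - universe:
        raise DataError("test sets must be subsets of the universe")
    N, n_a, n_b = len(universe), len(a), len(b)
    k = len(a & b)
    dist = sps.hypergeom(N, n_b, n_a)
    logp = float(dist.logsf(k - 1))
    p = float(min(math.exp(logp), 1.0))
    if n_a and n_b:
        fold = (k / n_a) / (n_b / N)
    else:
        fold = math.nan
    return EnrichmentResult(
        name=name, k=k, n_a=n_a, n_b=n_b, n_universe=N,
        p_upper=p, log10_p=logp / math.log(10), fold=fold,
    )


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def enrichment_battery(
    tests: Sequence[tuple], universe: Iterable
) -> pd.DataFrame:
    """Run named (name, set_a, set_b) overlap tests with BH correction."""
    results = [hypergeom_overlap(a, b, universe, name=n) for n, a, b in tests]
    df = pd.DataFrame([r.to_dict() for r in results])
    df["q_bh"] = bh_adjust(df["p_upper"].to_numpy())
    return df


@dataclass(frozen=True)
class ConcordanceResult:
    shared_misexpressed: int
    concordant_fraction: Optional[float]


def concordance(
    de_a: pd.DataFrame, de_b: pd.DataFrame, alpha: float = DEFAULT_DE_ALPHA
) -> ConcordanceResult:
    """Direction agreement among genes misexpressed in both tables.

    Over genes called up or down in *both* mutants, the fraction whose
    direction matches.  Symmetric in its arguments; undefined (None)
    when no gene is shared.
    """
    if "direction" not in de_a.columns:
        de_a = annotate_direction(de_a, alpha)
    if "direction" not in de_b.columns:
        de_b = annotate_direction(de_b, alpha)
    mis_a = de_a[de_a["direction"] != "unchanged"]["direction"]
    mis_b = de_b[de_b["direction"] != "unchanged"]["direction"]
    shared = mis_a.index.intersection(mis_b.index)
    if len(shared) == 0:
        return ConcordanceResult(0, None)
    agree = (mis_a.loc[shared] == mis_b.loc[shared]).sum()
    return ConcordanceResult(len(shared), float(agree / len(shared)))


# ---------------------------------------------------------------------------
# RNA-FISH foci ratios


@dataclass(frozen=True)
class FociCounts:
    """Per-focal-plane fluorescent focus counts for one probe/genotype/tissue."""

    probe: str
    genotype: str
    compartment: str  # soma | germline
    counts: tuple

    def __post_init__(self) -> None:
        if len(self.counts) < 1:
            raise DataError("FociCounts needs at least one plane")
        if any(c < 0 or int(c) != c for c in self.counts):
            raise DataError("foci counts must be non-negative integers")


def fish_ratio(mut: FociCounts, wt: FociCounts) -> tuple[float, float]:
    """Mutant / wild-type mean foci ratio with a delta-method SE.

    With means m, w and standard errors of the mean s_m, s_w, the SE of
    the ratio r = m/w is ``sqrt(s_m^2/w^2 + m^2 s_w^2 / w^4)`` to first
    order (plane counts are independent between genotypes).
    """
    if mut.probe != wt.probe or mut.compartment != wt.compartment:
        raise DataError("fish_ratio requires matching probe and compartment")
    if len(mut.counts) < 2 or len(wt.counts) < 2:
        raise DataError("need >= 2 focal planes per genotype")
    m = float(np.mean(mut.counts))
    w = float(np.mean(wt.counts))
    if w == 0:
        raise DataError("wild-type mean count is zero; ratio undefined")
    sem_m = float(np.std(mut.counts, ddof=1) / math.sqrt(len(mut.counts)))
    sem_w = float(np.std(wt.counts, ddof=1) / math.sqrt(len(wt.counts)))
    ratio = m / w
    se = math.sqrt(sem_m**2 / w**2 + (m**2) * sem_w**2 / w**4)
    return ratio, se


def read_fish_counts(path) -> list[FociCounts]:
    """Read a TSV with columns probe, genotype, compartment, plane, count."""
    df = pd.read_csv(path, sep="\t")
    needed = {"probe", "genotype", "compartment", "count"}
    if not needed <= set(df.columns):
        raise DataError(f"{path}: FISH table needs columns {sorted(needed)}")
    out = []
    for (probe, geno, comp), grp in df.groupby(
        ["probe", "genotype", "compartment"], sort=True
    ):
        out.append(
            FociCounts(
                probe=str(probe),
                genotype=str(geno),
                compartment=str(comp),
                counts=tuple(int(c) for c in grp["count"]),
            )
        )
    return out


def fish_ratio_table(
    foci: Sequence[FociCounts], mutant: str, wildtype: str
) -> pd.DataFrame:
    """Ratio table over every probe/compartment present for both genotypes."""
    by_key = {(f.probe, f.genotype, f.compartment): f for f in foci}
    rows = []
    for (probe, geno, comp), f in sorted(by_key.items()):
        if geno != mutant:
            continue
        wt = by_key.get((probe, wildtype, comp))
        if wt is None:
            continue
        ratio, se = fish_ratio(f, wt)
        rows.append(
            {
                "probe": probe,
                "compartment": comp,
                "ratio": ratio,
                "se": se,
                "n_planes_mut": len(f.counts),
                "n_planes_wt": len(wt.counts),
            }
        )
    return pd.DataFrame(rows)
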