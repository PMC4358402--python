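# Methods

This note documents the models, conventions, parameter choices, and known
limitations of the `dreamchip` pipeline.

## Coordinates and gene anchors

All internal coordinates are 0-based half-open (`[start, end)`, the BED
convention); GFF3 input (1-based closed) is converted on read.  A gene's
TSS is a point coordinate with the first transcribed base immediately 3′
of it — `start` on the `+` strand, `end` on the `−` strand — so that a
window "TSS −500..+200" is `[tss-500, tss+200)` on `+` and
`[tss-200, tss+500)` on `−`.  "Upstream"/"downstream" are always
strand-relative, including the gene-body window ("500 bp downstream of
the gene start") which is read as 5′ end + 500 toward 3′; this matches
the strand-relative reading of every other window in the analysis.

TSS overrides (e.g. from capped RNA-seq evidence) are supplied as a
1-based TSV and take precedence over annotated gene ends; an override
landing more than 10 kb outside the gene span is rejected with a warning
as a likely identifier mix-up.  Duplicate gene ids are an error by
default; `on_duplicate="longest"` collapses to the longest span for
isoform-expanded inputs.  The choice of longest span is ours — upstream
annotation pipelines differ and no single convention is canonical.

Regions are clipped at position 0 and, when a chrom.sizes table is
given, at the chromosome end.  A window that becomes empty (short gene,
off-chromosome) is returned as an explicit exclusion with a reason code,
never silently dropped.

## Coverage tracks, missing data, and Z-scores

Tracks are run-length encoded per chromosome; positions covered by no
run are *missing* (normalized ChIP tracks have unmappable gaps) and are
excluded from every mean rather than treated as zero, which would bias
gene-body scores downward.  A region or profile bin whose covered
fraction falls below 0.5 (configurable) is reported missing.  Region
means are computed exactly from prefix sums over the run encoding, so
large batches of windows (profile bins, null draws) are vectorized.

Z-scores standardize a track genome-wide over covered positions using
the coverage-length-weighted mean and *population* SD.  The population
(vs sample) choice is irrelevant at genomic n but fixed for exactness;
Z-scoring an already-Z-scored track is the identity.  "log2 Z-scores"
first floor values at 0.1 (configurable) and log2-transform; both the
linear and log orders are exposed because upstream conventions vary.

Metagene profiles are per-gene binned means, rows oriented 5′→3′
(minus-strand rows reversed), 10 bp bins by default.  The
TSS-and-TTS layout uses fixed-width flanks plus 100 proportional
gene-body bins by default; genes with fewer body bp than bins are
excluded.  K-means grouping of profile rows (k = 3 by default) uses
k-means++ with 10 restarts and a recorded seed; clusters are relabeled
1..k by descending mean signal so labels are stable across seeds when
groups are well separated.

## Peak integration

Co-binding regions are the single-linkage merge of all factors' peaks,
joining intervals that share at least `min_overlap_bp` bases (default 1;
book-ended half-open intervals never merge).  "Bound by all N" regions
are merged regions whose factor membership covers the required set.  The
1-bp single-linkage rule is the simplest defensible overlap criterion
and is exposed as a parameter rather than claimed as canonical.

Regions are assigned to genes by their midpoint, giving mutually
exclusive location classes suited to composition summaries: promoter
window (default TSS −500..+200) first, with ties broken to the nearest
TSS and then the lower-coordinate gene; then gene body; then a 500 bp
window past the TTS ("downstream"); else intergenic.  A gene is "bound"
by regions assigned to its promoter or gene body; downstream regions do
not confer boundness.

## Gene scoring and the change test

Promoter score: mean signal in TSS −500..+200.  Gene-body score: mean
signal from the gene 5′ end +500 bp to the 3′ end; genes spanning
≤500 bp are excluded (reason `short_gene`), and genes whose window is
under-covered are excluded (reason `low_coverage`) while keeping their
promoter score.  The top-k% call (default 5%) ranks gene-body scores
descending — on the wild-type track by default, switchable to the
mutant — takes `round(k·n)` genes (banker's rounding) and includes all
genes tied at the threshold score, so the returned n can slightly exceed
the nominal count.

The wild-type vs mutant change per gene is
`log2((mut+eps)/(wt+eps))` with `eps` = 1% of the genome-wide median
wild-type gene-body score (recorded in the table metadata), which keeps
the statistic finite on zero-signal genes.  Significance is empirical
and assumption-light: for each gene, `null_draws` (default 10,000)
random genomic windows *of that gene's own body length* are scored on
both tracks, and the two-sided p-value is
`(1 + #{|null lfc| >= |observed lfc|}) / (valid draws + 1)`, floored at
`1/(null_draws+1)`.  Draws are independent between genes, so p-values
are independently calibrated.  Limitation: when the genomic background
is heterogeneous (e.g. strong promoter peaks interspersed with flat
gene bodies), null windows overlapping high-signal features have a
wider log-ratio distribution than typical gene bodies and the test
becomes mildly conservative; on a homogeneous background the p-values
are uniform under the null, which is what the calibration test checks.

## Target classes and overlap statistics

With an up/down call at adjusted p ≤ 0.05 (configurable; echoed in
outputs), genes partition into: `direct` (up and bound by all required
factors), `indirect` (up, bound by none), `bound_partial_up` (up, bound
by some but not all — kept distinct because "all-subunit" and
"any-subunit" gene sets answer different questions), and
`bound_unregulated` / `unbound_unregulated`.  The default universe for
all overlap tests is the set of genes with a gene-body score, since
membership in the tested sets requires scoreability; it is
configurable.  Overlap tests use the hypergeometric upper tail computed
in log space (so astronomically small p-values keep a meaningful
log10), one-sided throughout, with Benjamini–Hochberg correction across
the tests reported in one run.

Direction concordance between two mutants is the fraction of genes
misexpressed in both whose directions agree; it is symmetric and
undefined (reported as missing) when no gene is shared.

RNA-FISH ratios divide the mutant's mean per-plane focus count by the
wild type's, per probe and tissue compartment, with a first-order
delta-method SE from the two per-genotype standard errors of the mean.

## The synthetic study

The generator plants the qualitative structure the analysis assumes,
with effect sizes as explicit configuration (no published effect sizes
exist to copy).  Defaults define the study conditions: 2000
non-overlapping genes (lengths uniform 300–5000 bp, so some fall under
the 500 bp scoring minimum; intergenic gaps 400–1500 bp) on one 8 Mb
chromosome; 60% of genes broadly expressed; 5% of genes co-bound
(drawn from broadly expressed genes ≥800 bp, as complex targets are
typical protein-coding genes); 70% of bound genes direct targets.
Tracks have baseline 1.0 at 25 bp resolution, an additive promoter bump
of height 4 over TSS −150..+50 on broadly expressed genes (identical in
both genotypes), a ×4 gene-body plateau on direct targets divided by 2
in the mutant, multiplicative log-normal noise with σ = 0.2, and a flat
H3-like control.  Eight peak sets place a 400 bp peak per factor over
each planted promoter site with ±100 bp jitter, plus factor-specific
Poisson decoys at deliberately unequal rates (base 30 per factor,
increasing by 25% per factor index) placed away from planted sites.

DE tables give detected direct targets log2FC = 1.5 ± 0.3 with
significant adjusted p with probability 0.95; background genes
misexpress at rate 0.02 in either direction.  The second mutant
re-misexpresses 80% of the first mutant's misexpressed genes, flipping
exactly `round((1−c)·shared)` directions so the realized concordance
matches the target c = 0.97 up to rounding — an exact-count
construction chosen so the planted concordance is a property of every
dataset, not a binomial draw.  FISH counts are Poisson per plane
(8 planes; wild-type means 25 soma / 40 germline) with mutant mean
scaled by 2.0 for target probes and 1.0 for the control.

Every component draws from its own seeded substream, so bundles are
bit-reproducible and any piece can be regenerated alone.

What the generator does **not** emulate: read-level noise, mappability
gaps, fragment-size effects, normalization artifacts, correlated noise
between neighboring genes, multi-chromosome genomes (available but not
default), or any relationship between expression level and ChIP signal
beyond the planted flags.  Passing recovery tests therefore shows the
pipeline's logic is correct under its stated assumptions, not that the
biological effect sizes are realistic.

## Problem sizes and determinism

The test suite and the acceptance script run the full study at the
default 2000 genes; calibration checks use 500 genes with 10,000 null
draws per gene, and byte-level determinism is checked on a 400-gene run
— sizes chosen so the whole suite completes in well under a minute of
compute while every code path is exercised at its default parameters.
No output file contains a timestamp; the run manifest records the
config hash, seed, tool version, and per-stage counts, so reruns of the
same config are byte-identical.

## Run configuration schema

```yaml
seed: 1                  # drives K-means and the significance null
simulate:                # either this block ...
  n_genes: 2000
  chrom_length: 8000000
  # any SimConfig field (see dreamchip/simulate.py)
inputs:                  # ... or this one
  genes: genes.gff3      # GFF3 or BED12
  tss_table: tss.tsv     # optional, 1-based
  chrom_sizes: c.sizes   # optional UCSC two-column
  peaks: {lin-35: lin35.bed, efl-1: efl1.bed, ...}
  track_wt: wt.bedgraph
  track_mut: mut.bedgraph
  de_primary: de_lin35.tsv
  de_second: de_htz1.tsv # optional
  fish: fish.tsv         # optional
params:
  promoter_upstream: 500
  promoter_downstream: 200
  genebody_offset: 500
  downstream_bp: 500
  top_fraction: 0.05
  top_on: wt             # or mut
  de_alpha: 0.05
  null_draws: 10000
  min_coverage_fraction: 0.5
  profile_upstream: 1000
  profile_downstream: 2000
  profile_bin_size: 10
  kmeans_k: 3
  min_overlap_bp: 1
  require_factors: null  # default: all supplied factors
```
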