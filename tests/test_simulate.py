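import json
import math

import numpy as np
import pytest

from dreamchip.errors import ConfigError, DataError
from dreamchip.peaks import call_all_of_n, merge_factor_peaks
from dreamchip.scoring import score_genes
from dreamchip.simulate import (
    FACTORS,
    FISH_CONTROL_PROBE,
    FISH_TARGET_PROBES,
    SimConfig,
    Truth,
    generate_bundle,
    generate_de_tables,
    generate_fish_counts,
    generate_genome,
    generate_peaks,
    generate_tracks,
    generate_truth,
)
from dreamchip.stats import concordance, fish_ratio_table, read_fish_counts


def small_cfg(seed=1, **kw):
    kw.setdefault("n_genes", 120)
    kw.setdefault("chrom_length", 600_000)
    return SimConfig(seed=seed, **kw)


class TestGenerateGenome:
    def test_deterministic_for_seed(self):
        g1 = generate_genome(small_cfg(seed=42))
        g2 = generate_genome(small_cfg(seed=42))
        assert [(g.gene_id, g.start, g.end, g.strand) for g in g1] == [
            (g.gene_id, g.start, g.end, g.strand) for g in g2
        ]

    def test_genes_pairwise_disjoint_and_counted(self):
        genes = generate_genome(small_cfg(n_genes=100))
        assert len(genes) == 100
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start

    def test_some_genes_below_body_minimum(self):
        # exclusion rules must be exercised at default length range
        for seed in range(10):
            if any(g.length < 500 for g in generate_genome(small_cfg(seed))):
                break
        else:
            pytest.fail("no gene under 500 bp in 10 seeds")

    def test_overflowing_chromosome_errors(self):
        with pytest.raises(DataError):
            generate_genome(SimConfig(seed=0, n_genes=100, chrom_length=10_000))

    def test_too_few_genes_rejected(self):
        with pytest.raises(ConfigError):
            generate_genome(SimConfig(seed=0, n_genes=5))


class TestGeneratePeaks:
    def test_planted_loci_recovered_by_all_of_n_call(self):
        cfg = small_cfg(fraction_bound=10 / 120)
        genes = generate_genome(cfg)
        truth = generate_truth(genes, cfg)
        assert len(truth.sites) == 10
        peak_sets = generate_peaks(genes, truth, cfg)
        hits = call_all_of_n(merge_factor_peaks(peak_sets), FACTORS)
        recovered = sum(
            any(h.interval.overlaps(site) for h in hits)
            for site in truth.sites
        )
        assert recovered >= 9

    def test_zero_bound_genes_gives_no_cobound_calls(self):
        cfg = small_cfg(fraction_bound=0.0)
        genes = generate_genome(cfg)
        truth = generate_truth(genes, cfg)
        peak_sets = generate_peaks(genes, truth, cfg)
        hits = call_all_of_n(merge_factor_peaks(peak_sets), FACTORS)
        assert hits == []

    def test_no_decoys_means_merged_regions_equal_planted_loci(self):
        cfg = small_cfg(decoy_rate_base=0.0, peak_jitter=0)
        genes = generate_genome(cfg)
        truth = generate_truth(genes, cfg)
        merged = merge_factor_peaks(generate_peaks(genes, truth, cfg))
        assert len(merged) == len(truth.sites)
        for r, site in zip(merged, sorted(truth.sites, key=lambda s: s.start)):
            assert r.interval.overlaps(site)
            assert r.members == set(FACTORS)

    def test_factor_peak_counts_unequal(self):
        cfg = small_cfg()
        genes = generate_genome(cfg)
        truth = generate_truth(genes, cfg)
        counts = {p.factor: len(p.peaks) for p in generate_peaks(genes, truth, cfg)}
        assert len(set(counts.values())) > 1


class TestGenerateTracks:
    def test_noise_free_attenuation_is_exact(self):
        cfg = small_cfg(noise_sd=0.0, body_enrichment_fold=4.0,
                        mutant_attenuation_fold=2.0)
        genes = generate_genome(cfg)
        truth = generate_truth(genes, cfg)
        wt, mut, h3 = generate_tracks(genes, truth, cfg)
        sc = score_genes(wt, genes, mut)
        for gid in truth.direct_gene_ids:
            assert sc.loc[gid, "genebody_score"] == pytest.approx(4.0)
            assert sc.loc[gid, "genebody_score_mut"] == pytest.approx(2.0)
        # pseudocount-free check of the planted ratio
        ratio = (
            sc.loc[sorted(truth.direct_gene_ids), "genebody_score"]
            / sc.loc[sorted(truth.direct_gene_ids), "genebody_score_mut"]
        )
        assert np.allclose(ratio, 2.0)

    def test_noise_free_nontarget_genes_unchanged(self):
        cfg = small_cfg(noise_sd=0.0)
        genes = generate_genome(cfg)
        truth = generate_truth(genes, cfg)
        wt, mut, _ = generate_tracks(genes, truth, cfg)
        sc = score_genes(wt, genes, mut)
        others = sc.drop(index=sorted(truth.direct_gene_ids))
        assert np.allclose(others["log2fc"].dropna(), 0.0)

    def test_promoter_bump_retained_in_mutant(self):
        cfg = small_cfg(noise_sd=0.0)
        genes = generate_genome(cfg)
        truth = generate_truth(genes, cfg)
        wt, mut, _ = generate_tracks(genes, truth, cfg)
        sc = score_genes(wt, genes, mut)
        bound = sorted(truth.bound_gene_ids)
        sw = sc.loc[bound, "promoter_score"]
        # all bound genes are broadly expressed: promoter signal present
        assert (sw > 1.5).all()

    def test_mean_direct_log2fc_near_planted_attenuation(self):
        cfg = SimConfig(seed=3, n_genes=400, chrom_length=2_000_000,
                        fraction_bound=0.4, fraction_direct_given_bound=0.7)
        genes = generate_genome(cfg)
        truth = generate_truth(genes, cfg)
        wt, mut, _ = generate_tracks(genes, truth, cfg)
        sc = score_genes(wt, genes, mut)
        direct = sorted(truth.direct_gene_ids)
        assert len(direct) >= 100
        mean_lfc = sc.loc[direct, "log2fc"].mean()
        assert mean_lfc == pytest.approx(-1.0, abs=0.1)

    def test_h3_control_has_no_planted_structure(self):
        cfg = small_cfg(noise_sd=0.0)
        genes = generate_genome(cfg)
        truth = generate_truth(genes, cfg)
        _, _, h3 = generate_tracks(genes, truth, cfg)
        for _, (_, _, vals) in h3.runs.items():
            assert np.all(vals == 1.0)


class TestGenerateDeTables:
    def test_exact_concordance_when_target_is_one(self):
        cfg = small_cfg(concordance_target=1.0)
        genes = generate_genome(cfg)
        truth = generate_truth(genes, cfg)
        de1, de2 = generate_de_tables(genes, truth, cfg)
        r = concordance(de1, de2, alpha=cfg.de_alpha)
        assert r.concordant_fraction == 1.0

    def test_no_planted_targets_leaves_only_background(self):
        cfg = small_cfg(fraction_bound=0.0)
        genes = generate_genome(cfg)
        truth = generate_truth(genes, cfg)
        de1, _ = generate_de_tables(genes, truth, cfg)
        n_sig = int((de1["padj"] <= cfg.de_alpha).sum())
        # background false positives only: rate 0.02 of 120 genes
        assert n_sig <= 12

    def test_realized_concordance_close_to_target(self):
        for seed in (1, 2, 3):
            cfg = SimConfig(seed=seed, n_genes=2000)
            genes = generate_genome(cfg)
            truth = generate_truth(genes, cfg)
            de1, de2 = generate_de_tables(genes, truth, cfg)
            r = concordance(de1, de2, alpha=cfg.de_alpha)
            assert 0.94 <= r.concordant_fraction <= 1.0

    def test_direct_targets_mostly_detected_up(self):
        cfg = small_cfg()
        genes = generate_genome(cfg)
        truth = generate_truth(genes, cfg)
        de1, _ = generate_de_tables(genes, truth, cfg)
        direct = sorted(truth.direct_gene_ids)
        up = (de1.loc[direct, "padj"] <= cfg.de_alpha) & (
            de1.loc[direct, "log2fc"] > 0
        )
        assert up.mean() >= 0.8


class TestGenerateFishCounts:
    def test_planted_ratio_recovered_within_three_se(self):
        cfg = small_cfg(fish_planes=12)
        truth = generate_truth(generate_genome(cfg), cfg)
        fish = generate_fish_counts(truth, cfg)
        tab = fish_ratio_table(
            read_fish_counts_from_frame(fish), mutant="mut", wildtype="wt"
        )
        for row in tab.itertuples():
            planted = (
                cfg.fish_target_ratio
                if row.probe in FISH_TARGET_PROBES
                else 1.0
            )
            assert abs(row.ratio - planted) <= 3 * row.se + 1e-9

    def test_tables_identical_across_runs(self):
        cfg = small_cfg()
        truth = generate_truth(generate_genome(cfg), cfg)
        f1 = generate_fish_counts(truth, cfg)
        f2 = generate_fish_counts(truth, cfg)
        assert f1.equals(f2)


def read_fish_counts_from_frame(df):
    from dreamchip.stats import FociCounts

    out = []
    for (probe, geno, comp), grp in df.groupby(
        ["probe", "genotype", "compartment"]
    ):
        out.append(
            FociCounts(str(probe), str(geno), str(comp),
                       tuple(int(c) for c in grp["count"]))
        )
    return out


def test_bundle_round_trips_truth_and_is_reproducible(tmp_path):
    cfg = small_cfg(seed=9)
    p1 = generate_bundle(cfg, tmp_path / "b1")
    p2 = generate_bundle(cfg, tmp_path / "b2")
    t1 = Truth.from_json(p1["truth"])
    t2 = Truth.from_json(p2["truth"])
    assert t1.table.equals(t2.table)
    from pathlib import Path

    for key in p1:
        assert Path(p1[key]).read_bytes() == Path(p2[key]).read_bytes()
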