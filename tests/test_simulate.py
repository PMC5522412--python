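"""Synthetic cohort generator: determinism, invariants, planted truth."""

import numpy as np
import pytest
from scipy import stats

from introsel import io as iio
from introsel.simulate import (
    SimConfig,
    TruthRecord,
    generate_constraint_values,
    generate_cohort,
    generate_genes,
    generate_lrt_inputs,
    generate_site_evidence,
    generate_snps,
    plant_introgressed_haplotype,
    plant_sweep_region,
)


class TestGenerateGenes:
    def test_seeded_runs_are_identical_and_seed_sensitive(self):
        g1, _ = generate_genes(SimConfig(seed=1, n_genes=5, n_background_genes=10))
        g2, _ = generate_genes(SimConfig(seed=1, n_genes=5, n_background_genes=10))
        g3, _ = generate_genes(SimConfig(seed=2, n_genes=5, n_background_genes=10))
        assert [(g.chrom, g.start, g.end) for g in g1] == [
            (g.chrom, g.start, g.end) for g in g2
        ]
        assert [(g.start, g.end) for g in g1] != [(g.start, g.end) for g in g3]

    def test_intervals_disjoint_and_features_bounded(self, cohort):
        by_chrom = {}
        for g in cohort.genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
            assert 0.0 <= g.gc_fraction <= 1.0
            assert g.start < g.end
            assert g.module_label in ("M1", "M2", "background")
        for intervals in by_chrom.values():
            intervals.sort()
            for (s1, e1), (s2, _) in zip(intervals, intervals[1:]):
                assert e1 <= s2, "gene intervals overlap"

    def test_rejects_non_positive_counts(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=0)


class TestGenerateSnps:
    def test_schema_and_bounds(self, cohort, small_config):
        for s in cohort.snps[:500]:
            assert set(s.pop_derived_freq) == set(small_config.pop_labels)
            assert all(0.0 <= f <= 1.0 for f in s.pop_derived_freq.values())
            assert all(0.0 <= p <= 1.0 for p in s.neand_prob.values())
        assert len(cohort.snps) > len(cohort.genes)

    def test_background_ancestry_concentrated_near_zero(self, cohort, small_config):
        planted = set(cohort.truth.introgressed_snp_ids)
        probs = [
            p
            for s in cohort.snps
            if s.snp_id not in planted
            for p in s.neand_prob.values()
        ]
        assert np.mean(probs) == pytest.approx(
            small_config.ancestry_background_prob, abs=0.01
        )

    def test_requires_genes(self, small_config):
        with pytest.raises(ValueError):
            generate_snps([], small_config)


class TestPlantedHaplotype:
    def test_planted_snps_are_archaic_specific(self, cohort, small_config):
        planted = [s for s in cohort.snps if s.snp_id in set(cohort.truth.introgressed_snp_ids)]
        assert len(planted) == small_config.n_haplotype_snps == 20
        for s in planted:
            assert s.altai_gt == (s.derived_allele, s.derived_allele)
            assert s.pop_derived_freq["AFR"] == 0.0
            assert s.pop_derived_freq["EUR"] > 0.0
            assert all(p == small_config.ancestry_high_prob for p in s.neand_prob.values())

    def test_full_ld_among_modern_carriers(self, cohort):
        hap = cohort.haplotypes
        modern = [i for i, lab in enumerate(hap.labels) if lab not in ("ALTAI", "DENISOVA")]
        data = hap.data[modern]
        assert data.any(), "at least one modern carrier expected"
        corr = np.corrcoef(data.T)
        assert np.allclose(corr**2, 1.0), "planted SNPs must be in complete LD"

    def test_archaic_rows_carry_haplotype(self, cohort):
        hap = cohort.haplotypes
        for archaic in ("ALTAI", "DENISOVA"):
            row = hap.data[hap.labels.index(archaic)]
            assert row.all()

    def test_zero_frequency_leaves_no_modern_carrier(self):
        config = SimConfig(seed=5, n_genes=2, n_background_genes=5, snps_per_gene=40)
        genes, truth = generate_genes(config)
        snps = generate_snps(genes, config)
        gene = genes[0]
        hap = plant_introgressed_haplotype(snps, gene, config, truth, hap_freq=0.0)
        modern = [i for i, lab in enumerate(hap.labels) if lab not in ("ALTAI", "DENISOVA")]
        assert not hap.data[modern].any()
        # with no modern carrier the archaic allele is absent everywhere,
        # so the archaic-SNP rule cannot fire
        from introsel.introgression import identify_archaic_snps

        planted = [s for s in snps if s.snp_id in set(truth.introgressed_snp_ids)]
        calls = identify_archaic_snps(planted)
        assert all(c.is_archaic is False for c in calls)

    def test_gene_too_small_rejected(self):
        config = SimConfig(seed=5, n_genes=2, n_background_genes=2, snps_per_gene=30)
        genes, truth = generate_genes(config)
        snps = generate_snps(genes, config)
        target = genes[0]
        thin = [s for s in snps if not (s.chrom == target.chrom and target.contains(s.pos))]
        with pytest.raises(ValueError, match="needed for the planted haplotype"):
            plant_introgressed_haplotype(thin, target, config, truth)


class TestPlantedSweep:
    def test_planted_run_spans_configured_width(self, cohort, small_config):
        (chrom, start, end), = cohort.truth.sweep_intervals
        assert end - start >= small_config.sweep_span_bp

    def test_all_member_snps_below_genomewide_fifth_percentile(self, cohort):
        member = set(cohort.truth.sweep_snp_ids)
        scores = [s.s_score for s in cohort.snps]
        q5 = np.percentile(scores, 5)
        assert all(s.s_score < q5 for s in cohort.snps if s.snp_id in member)

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="sweep_span_bp"):
            SimConfig(sweep_span_bp=10_000)


class TestLRTInputs:
    def test_null_pvalues_uniform(self):
        for df in (1, 2):
            table = generate_lrt_inputs(2000, 0.0, 0.0, df, seed=11)
            stats_ = 2.0 * (table.lnl_alt - table.lnl_null)
            pvals = stats.chi2.sf(stats_, df)
            assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_strong_alternative_dominates(self):
        from introsel.selection import bh_adjust, lrt_pvalue

        table = generate_lrt_inputs(300, 1.0, 50.0, 1, seed=13)
        raw = [lrt_pvalue(r.lnl_null, r.lnl_alt, 1)[1] for r in table.itertuples()]
        adjusted = bh_adjust(raw)
        assert np.mean(np.array(adjusted) < 0.05) > 0.95

    def test_zero_ncp_matches_null_distribution(self):
        alt = generate_lrt_inputs(3000, 1.0, 0.0, 1, seed=17)
        null = generate_lrt_inputs(3000, 0.0, 0.0, 1, seed=19)
        stat_alt = 2.0 * (alt.lnl_alt - alt.lnl_null)
        stat_null = 2.0 * (null.lnl_alt - null.lnl_null)
        assert stats.ks_2samp(stat_alt, stat_null).pvalue > 0.01

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            generate_lrt_inputs(10, 0.0, 0.0, 3, seed=1)


class TestSiteEvidence:
    def test_planted_sites_pass_two_methods_background_at_most_one(self):
        from introsel.selection import method_passes

        evidence = generate_site_evidence("G1", [10, 20], seed=3, n_codons=200)
        passing = {}
        for e in evidence:
            if method_passes(e.method, e.score):
                passing.setdefault(e.codon_index, set()).add(e.method)
        assert passing[10] >= {"BEB_M8", "FUBAR"}
        assert passing[20] >= {"BEB_M8", "FUBAR"}
        for codon, methods in passing.items():
            if codon not in (10, 20):
                assert len(methods) <= 1

    def test_out_of_range_site_rejected(self):
        with pytest.raises(ValueError, match="outside codon range"):
            generate_site_evidence("G1", [500], seed=3, n_codons=100)


class TestConstraintValues:
    def test_zero_shift_means_equal(self, cohort):
        records = generate_constraint_values(cohort.genes, 0.0, seed=23)
        f = {r.gene_id: r.f for r in records}
        module = [f[g.gene_id] for g in cohort.genes if g.module_label != "background"]
        background = [f[g.gene_id] for g in cohort.genes if g.module_label == "background"]
        assert abs(np.mean(module) - np.mean(background)) < 0.08

    def test_excessive_shift_rejected(self, cohort):
        with pytest.raises(ValueError, match="outside"):
            generate_constraint_values(cohort.genes, 0.7, seed=23)


class TestCohortDeterminism:
    def test_fixed_seed_gives_identical_digest(self, small_config, cohort):
        again = generate_cohort(
            SimConfig(seed=7, n_genes=12, n_background_genes=120, snps_per_gene=30)
        )
        assert iio.cohort_digest(again) == iio.cohort_digest(cohort)

    def test_truth_entities_exist(self, cohort):
        gene_ids = {g.gene_id for g in cohort.genes}
        snp_ids = {s.snp_id for s in cohort.snps}
        truth: TruthRecord = cohort.truth
        assert set(truth.introgressed_genes) <= gene_ids
        assert set(truth.introgressed_snp_ids) <= snp_ids
        assert set(truth.sweep_snp_ids) <= snp_ids


def test_plant_sweep_requires_two_snps(small_config):
    genes, truth = generate_genes(small_config)
    with pytest.raises(ValueError):
        plant_sweep_region([], small_config, truth, genes[0])
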