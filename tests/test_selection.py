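"""LRT p-values, FDR adjustment, declaration rules, consensus sites."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import bh_oracle
from introsel.datasets import LINEAGE_SITES
from introsel.selection import (
    bh_adjust,
    chi2_upper_tail,
    consensus_branch_sites,
    consensus_phylogeny_sites,
    declare_branch_selection,
    declare_site_model_selection,
    lineage_selected_sites,
    lrt_pvalue,
    module_selection_fraction,
)
from introsel.types import LineageSiteRecord, LRTResult, SiteEvidence


def _result(gene="G", test="M8a_vs_M8", freq="F3X4", p_adj=0.01, stat=5.0, df=1):
    return LRTResult(
        gene_id=gene, test_id=test, codon_freq=freq, lnl_null=0.0,
        lnl_alt=stat / 2.0, stat=stat, df=df, p_raw=p_adj, p_adj=p_adj,
    )


class TestLrtPvalue:
    @pytest.mark.parametrize(
        "stat, df, expected",
        [
            (4.683, 1, 3.047e-2),
            (87.994, 1, 6.566e-21),
            (58.105, 1, 2.485e-14),
            (147.643, 1, 5.678e-34),
            (18.374, 2, 1.023e-4),
            (5.667, 1, 1.73e-2),
        ],
    )
    def test_published_statistics_reproduce_published_p(self, stat, df, expected):
        """Chi-square upper tails of tabulated 2*dlnL statistics."""
        assert chi2_upper_tail(stat, df) == pytest.approx(expected, rel=1e-2)
        _, p = lrt_pvalue(0.0, stat / 2.0, df)
        assert p == pytest.approx(expected, rel=1e-2)

    def test_zero_statistic_gives_p_one(self):
        stat, p = lrt_pvalue(-100.0, -100.0, 1)
        assert (stat, p) == (0.0, 1.0)

    def test_worse_alternative_clamped(self):
        stat, p = lrt_pvalue(-100.0, -105.0, 2)
        assert (stat, p) == (0.0, 1.0)

    def test_monotone_decreasing_in_stat(self):
        stats_ = np.linspace(0, 30, 40)
        for df in (1, 2):
            p = [chi2_upper_tail(s, df) for s in stats_]
            assert all(a >= b for a, b in zip(p, p[1:]))

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            lrt_pvalue(0.0, 1.0, 3)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.05]) == [0.05]

    def test_hand_enumerated_stepup(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_bruteforce_oracle_on_random_vectors(self, rng):
        for _ in range(300):
            p = rng.uniform(size=rng.integers(1, 30)).tolist()
            assert bh_adjust(p) == pytest.approx(bh_oracle(p))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=25))
    def test_oracle_equivalence_property(self, p):
        adjusted = bh_adjust(p)
        assert adjusted == pytest.approx(bh_oracle(p))
        assert all(a >= r - 1e-12 for a, r in zip(adjusted, p))
        assert all(a <= 1.0 for a in adjusted)

    def test_families_adjusted_independently(self):
        p = [0.01, 0.02, 0.3, 0.4]
        joint = bh_adjust(p)
        split = bh_adjust(p, families=["a", "a", "b", "b"])
        assert split[:2] == pytest.approx(bh_oracle([0.01, 0.02]))
        assert split[2:] == pytest.approx(bh_oracle([0.3, 0.4]))
        assert joint == pytest.approx(bh_oracle(p))
        assert split != pytest.approx(joint)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestDeclarations:
    def test_both_codon_models_required(self):
        both = [_result(freq="F3X4", p_adj=0.001), _result(freq="F61", p_adj=0.02)]
        assert declare_branch_selection(both) is True
        one_arm = [_result(freq="F3X4", p_adj=0.001), _result(freq="F61", p_adj=0.3)]
        assert declare_branch_selection(one_arm) is False
        null = [_result(freq="F3X4", p_adj=1.0), _result(freq="F61", p_adj=1.0)]
        assert declare_branch_selection(null) is False

    def test_missing_arm_is_an_error(self):
        with pytest.raises(ValueError, match="missing codon-frequency arm"):
            declare_branch_selection([_result(freq="F3X4")])

    def test_site_model_needs_all_four_arms_significant(self):
        def arms(p_by_arm):
            return [
                _result(test=t, freq=c, p_adj=p_by_arm[(t, c)])
                for t, c in itertools.product(("M7_vs_M8", "M8a_vs_M8"), ("F3X4", "F61"))
            ]

        sig = dict.fromkeys(
            itertools.product(("M7_vs_M8", "M8a_vs_M8"), ("F3X4", "F61")), 0.01
        )
        assert declare_site_model_selection(arms(sig)) is True
        weak = dict(sig)
        weak[("M8a_vs_M8", "F61")] = 0.2
        assert declare_site_model_selection(arms(weak)) is False
        with pytest.raises(ValueError, match="missing arm"):
            declare_site_model_selection(arms(sig)[:3])


class TestModuleFraction:
    def test_published_module_fractions(self):
        from introsel.datasets import M1_SIZE, M2_SIZE, branch_declarations

        declared = branch_declarations()
        assert module_selection_fraction(declared["M1"], M1_SIZE) == 17.0
        assert module_selection_fraction(declared["M2"], M2_SIZE) == 28.6

    def test_zero_declared(self):
        assert module_selection_fraction({}, 10) == 0.0

    def test_zero_module_size_rejected(self):
        with pytest.raises(ValueError):
            module_selection_fraction({}, 0)


class TestConsensusBranchSites:
    def test_intersection_semantics(self):
        beb = [
            SiteEvidence("G", 329, "BEB_branch", 0.96),
            SiteEvidence("G", 500, "BEB_branch", 0.95),
        ]
        meme = [SiteEvidence("G", 329, "MEME", 0.02)]
        sites = consensus_branch_sites(beb, meme)
        assert [s.codon_index for s in sites] == [329]
        assert sites[0].supporting_methods == {"BEB_branch", "MEME"}

    def test_empty_meme_gives_empty_output(self):
        beb = [SiteEvidence("G", 10, "BEB_branch", 0.99)]
        assert consensus_branch_sites(beb, []) == []

    def test_mixed_gene_ids_rejected(self):
        with pytest.raises(ValueError, match="mixed gene ids"):
            consensus_branch_sites(
                [SiteEvidence("A", 1, "BEB_branch", 0.95)],
                [SiteEvidence("B", 1, "MEME", 0.01)],
            )

    def test_roundtrip_with_generator(self):
        from introsel.simulate import generate_site_evidence

        planted = [5, 40, 99]
        evidence = generate_site_evidence("G", planted, seed=31, n_codons=150, family="branch")
        beb = [e for e in evidence if e.method == "BEB_branch"]
        meme = [e for e in evidence if e.method == "MEME"]
        sites = consensus_branch_sites(beb, meme)
        assert [s.codon_index for s in sites] == planted


class TestConsensusPhylogenySites:
    def test_two_of_three_rule(self):
        evidence = [
            SiteEvidence("G", 7, "BEB_M8", 0.95),
            SiteEvidence("G", 7, "FUBAR", 0.92),
            SiteEvidence("G", 7, "REL", 10.0),
            SiteEvidence("G", 8, "REL", 80.0),
        ]
        sites = consensus_phylogeny_sites(evidence)
        assert len(sites) == 1
        assert sites[0].codon_index == 7
        assert sites[0].supporting_methods == {"BEB_M8", "FUBAR"}

    def test_matches_enumeration_of_all_pass_patterns(self):
        """Oracle over all 2^3 pass/fail patterns per codon."""
        passing = {"BEB_M8": 0.95, "FUBAR": 0.93, "REL": 60.0}
        failing = {"BEB_M8": 0.5, "FUBAR": 0.5, "REL": 5.0}
        for codon, pattern in enumerate(
            itertools.product([False, True], repeat=3), start=1
        ):
            evidence = [
                SiteEvidence("G", codon, m, passing[m] if hit else failing[m])
                for m, hit in zip(("BEB_M8", "FUBAR", "REL"), pattern)
            ]
            sites = consensus_phylogeny_sites(evidence)
            assert (len(sites) == 1) == (sum(pattern) >= 2)
            for s in sites:
                assert len(s.supporting_methods) >= 2

    def test_roundtrip_with_generator(self):
        from introsel.simulate import generate_site_evidence

        planted = [3, 77]
        evidence = generate_site_evidence("G", planted, seed=37, n_codons=200)
        sites = consensus_phylogeny_sites(evidence)
        assert [s.codon_index for s in sites] == planted

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            consensus_phylogeny_sites([SiteEvidence("G", 1, "MEME", 0.01)])


class TestLineageSites:
    def test_published_boundary_cases(self):
        kept = lineage_selected_sites(LINEAGE_SITES)
        prs = {r.pr_gamma_ge_1 for r in kept}
        assert 0.901 in prs and 0.752 in prs
        assert len(kept) == len(LINEAGE_SITES), "every tabulated site exceeds 0.75"

    def test_strict_boundary(self):
        boundary = LineageSiteRecord("G", "human", 1, "Ala", "Thr", 0.75)
        assert lineage_selected_sites([boundary]) == []
        just_above = LineageSiteRecord("G", "human", 1, "Ala", "Thr", 0.7501)
        assert lineage_selected_sites([just_above]) == [just_above]


class TestNullCalibration:
    def test_null_lrt_declared_rate_bounded(self):
        """Under fully-null inputs the BH-declared rate stays below
        alpha plus three binomial standard errors."""
        from introsel.simulate import generate_lrt_inputs

        for df in (1, 2):
            table = generate_lrt_inputs(2000, 0.0, 0.0, df, seed=41 + df)
            raw = [lrt_pvalue(r.lnl_null, r.lnl_alt, df)[1] for r in table.itertuples()]
            adjusted = np.array(bh_adjust(raw))
            rate = float(np.mean(adjusted < 0.05))
            bound = 0.05 + 3.0 * np.sqrt(0.05 * 0.95 / len(adjusted))
            assert rate <= bound
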