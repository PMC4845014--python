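import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repmeth import (GenomicInterval, UndefinedScoreError, icr_summary,
                     qualify_cpgs, score_repeats, weighted_region_score,
                     window_scores)
from repmeth.methylation_io import RepeatElement

from _oracles import brute_force_weighted_score
from conftest import make_sample


def paired_samples(covs, region_start=0):
    """Two samples with one CpG per (cov_wt, cov_mut) pair, fully methylated."""
    wt = {("chr1", region_start + 10 * (i + 1)): (cw, 0)
          for i, (cw, _) in enumerate(covs)}
    mut = {("chr1", region_start + 10 * (i + 1)): (cm, 0)
           for i, (_, cm) in enumerate(covs)}
    return make_sample(wt, "wt"), make_sample(mut, "mut")


REGION = GenomicInterval("chr1", 0, 10_000)


class TestQualifyCpgs:
    @pytest.mark.parametrize("covs,kept", [
        ((8, 8), True),      # minimum coverage passes in both samples
        ((7, 8), False),     # below minimum in one sample
        ((10, 5), False),    # 5 < 8 and 5 < 0.6 * 10: removed twice over
        ((30, 18), True),    # 18 >= 0.6 * 30: boundary of the bias rule
        ((30, 17), False),   # 17 < 0.6 * 30: biased coverage removed
        ((17, 30), False),   # rule is symmetric
    ])
    def test_coverage_and_bias_rules(self, covs, kept):
        wt, mut = paired_samples([covs])
        result = qualify_cpgs(wt, mut, REGION)
        assert (len(result) == 1) == kept

    @pytest.mark.parametrize("covs,kept", [
        ((10, 6), True),   # 6 >= 0.6 * 10: bias arithmetic in isolation
        ((10, 5), False),  # 5 < 0.6 * 10
    ])
    def test_bias_arithmetic_below_default_coverage(self, covs, kept):
        # the coverage minimum is relaxed so only the bias rule decides
        wt, mut = paired_samples([covs])
        result = qualify_cpgs(wt, mut, REGION, min_cov=5)
        assert (len(result) == 1) == kept

    def test_site_must_be_present_in_both_samples(self):
        wt = make_sample({("chr1", 10): (20, 0)}, "wt")
        mut = make_sample({("chr1", 20): (20, 0)}, "mut")
        assert qualify_cpgs(wt, mut, REGION) == []

    def test_symmetric_in_samples(self, default_sim):
        wt, mut = default_sim["wt"], default_sim["mut"]
        for elem in default_sim["genome"].repeats[:50]:
            fwd = {c.pos for c in qualify_cpgs(wt, mut, elem)}
            rev = {c.pos for c in qualify_cpgs(mut, wt, elem)}
            assert fwd == rev

    def test_deviation_rule_variant(self):
        # (20, 10): deviation (20-10)/20 = 0.5 <= 0.6 keeps what the
        # ratio reading (10 < 0.6*20) drops
        wt, mut = paired_samples([(20, 10)])
        assert len(qualify_cpgs(wt, mut, REGION, bias_rule="deviation")) == 1
        assert len(qualify_cpgs(wt, mut, REGION, bias_rule="ratio")) == 0

    @pytest.mark.parametrize("kwargs", [
        {"min_cov": 0}, {"bias_fraction": 0.0}, {"bias_fraction": 1.5},
        {"bias_rule": "nope"},
    ])
    def test_bad_arguments(self, kwargs):
        wt, mut = paired_samples([(10, 10)])
        with pytest.raises(ValueError):
            qualify_cpgs(wt, mut, REGION, **kwargs)

    def test_boundary_membership_is_half_open(self):
        # CpG at 1-based pos p has 0-based coordinate p-1
        wt = make_sample({("chr1", 101): (10, 0), ("chr1", 201): (10, 0)}, "wt")
        mut = make_sample({("chr1", 101): (10, 0), ("chr1", 201): (10, 0)}, "mut")
        inside = qualify_cpgs(wt, mut, GenomicInterval("chr1", 100, 200))
        assert [c.pos for c in inside] == [101]  # coord 100 in, coord 200 out


class TestWeightedRegionScore:
    @pytest.mark.parametrize("cpgs,expected", [
        ([(100.0, 10), (0.0, 10)], 50.0),
        ([(80.0, 20), (60.0, 10), (100.0, 10)], 80.0),  # (1600+600+1000)/40
    ])
    def test_hand_computed_examples(self, cpgs, expected):
        assert weighted_region_score(cpgs) == pytest.approx(expected)

    @given(st.floats(0, 100), st.lists(st.integers(1, 500), min_size=1,
                                       max_size=20))
    @settings(deadline=None)
    def test_constant_methylation_any_coverages(self, m, covs):
        assert weighted_region_score([(m, c) for c in covs]) == pytest.approx(m)

    @given(st.lists(st.tuples(st.floats(0, 100), st.integers(1, 300)),
                    min_size=1, max_size=30),
           st.randoms(use_true_random=False), st.integers(2, 7))
    @settings(deadline=None)
    def test_permutation_and_coverage_scaling_invariance(self, cpgs, rnd, k):
        base = weighted_region_score(cpgs)
        shuffled = list(cpgs)
        rnd.shuffle(shuffled)
        assert weighted_region_score(shuffled) == pytest.approx(base)
        assert weighted_region_score([(m, k * c) for m, c in cpgs]) == \
            pytest.approx(base)

    def test_matches_brute_force_oracle_on_random_regions(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = rng.integers(1, 40)
            meth = rng.uniform(0, 100, n)
            cov = rng.integers(1, 200, n)
            assert weighted_region_score(list(zip(meth, cov))) == pytest.approx(
                brute_force_weighted_score(meth, cov), abs=1e-9)

    def test_empty_region_and_zero_coverage_rejected(self):
        with pytest.raises(UndefinedScoreError):
            weighted_region_score([])
        with pytest.raises(ValueError):
            weighted_region_score([(50.0, 0)])


def element(start, end, subfamily="IAPEY"):
    return RepeatElement(GenomicInterval("chr1", start, end), subfamily,
                         "LTR/ERVK")


class TestScoreRepeats:
    @pytest.mark.parametrize("n_cpgs,scored", [(7, False), (8, True)])
    def test_min_cpgs_boundary(self, n_cpgs, scored):
        covs = [(10, 10)] * n_cpgs
        wt, mut = paired_samples(covs)
        result = score_repeats(wt, mut, [element(0, 10_000)])
        assert (result.n_scored == 1) == scored
        assert result.n_excluded == (0 if scored else 1)

    def test_element_without_cpgs_counted_as_excluded(self):
        wt, mut = paired_samples([(10, 10)] * 8)
        result = score_repeats(wt, mut, [element(0, 10_000),
                                         element(50_000, 60_000)])
        assert result.n_scored == 1 and result.n_excluded == 1

    def test_empty_repeat_list(self):
        wt, mut = paired_samples([(10, 10)])
        result = score_repeats(wt, mut, [])
        assert result.scores == [] and result.n_input == 0

    def test_each_sample_weighted_by_own_coverage(self):
        # wt: 10x everywhere; mut: one CpG at 16x dominates its own average
        wt = make_sample({("chr1", p): (10, 0) for p in range(10, 90, 10)}, "wt")
        mut_sites = {("chr1", p): (0, 10) for p in range(10, 90, 10)}
        mut_sites[("chr1", 10)] = (16, 0)
        mut = make_sample(mut_sites, "mut")
        (score,), _ = (score_repeats(wt, mut, [element(0, 100)]).scores,
                       None)
        assert score.meth_wt == pytest.approx(100.0)
        assert score.meth_mut == pytest.approx(100.0 * 16 / (16 + 70))

    def test_recomputation_reproduces_scores_exactly(self, default_sim):
        wt, mut = default_sim["wt"], default_sim["mut"]
        for score in default_sim["scoring"].scores[:100]:
            cpgs = qualify_cpgs(wt, mut, score.region)
            assert len(cpgs) == score.n_cpgs
            assert weighted_region_score(
                [(c.meth_pct_wt, c.cov_wt) for c in cpgs]) == score.meth_wt
            assert weighted_region_score(
                [(c.meth_pct_mut, c.cov_mut) for c in cpgs]) == score.meth_mut


class TestWindows:
    def test_tiling_arithmetic_last_window_short(self):
        wt = make_sample({("chr1", p): (9, 1) for p in
                          (5, 15_000, 21_000)}, "wt")
        mut = make_sample({("chr1", p): (9, 1) for p in
                           (5, 15_000, 21_000)}, "mut")
        result = window_scores(wt, mut, {"chr1": 25_000}, window_size=10_000)
        spans = [(w.window.start, w.window.end) for w in result.windows]
        assert spans == [(0, 10_000), (10_000, 20_000), (20_000, 25_000)]

    def test_constant_methylome_gives_constant_medians(self):
        sites = {("chr1", p): (9, 1) for p in range(100, 50_000, 500)}
        wt, mut = make_sample(sites, "wt"), make_sample(sites, "mut")
        result = window_scores(wt, mut, {"chr1": 50_000})
        assert result.median_wt == pytest.approx(90.0)
        assert result.median_mut == pytest.approx(90.0)

    def test_uncovered_window_absent(self):
        sites = {("chr1", 5): (5, 5)}
        wt, mut = make_sample(sites, "wt"), make_sample(sites, "mut")
        result = window_scores(wt, mut, {"chr1": 30_000})
        assert len(result.windows) == 1
        assert result.windows[0].window.start == 0

    def test_empty_genome_table_rejected(self):
        wt = make_sample({("chr1", 5): (5, 5)}, "wt")
        with pytest.raises(ValueError):
            window_scores(wt, wt, {})


class TestIcrSummary:
    def test_unmethylated_maternal_icr_supports_purity(self):
        sites = {("chr1", p): (0, 10) for p in range(10, 100, 10)}
        wt, mut = make_sample(sites, "wt"), make_sample(sites, "mut")
        table = icr_summary(wt, mut, [(GenomicInterval("chr1", 0, 200),
                                       "maternal")])
        assert table.loc[0, "meth_wt"] == 0.0
        assert bool(table.loc[0, "purity_ok"])

    def test_methylated_maternal_icr_fails_purity(self):
        sites = {("chr1", p): (10, 0) for p in range(10, 100, 10)}
        wt, mut = make_sample(sites, "wt"), make_sample(sites, "mut")
        table = icr_summary(wt, mut, [(GenomicInterval("chr1", 0, 200),
                                       "maternal")])
        assert not bool(table.loc[0, "purity_ok"])

    def test_half_methylated_icr_scores_fifty(self):
        sites = {("chr1", p): (1, 1) for p in range(10, 110, 10)}
        wt, mut = make_sample(sites, "wt"), make_sample(sites, "mut")
        table = icr_summary(wt, mut, [(GenomicInterval("chr1", 0, 200),
                                       "paternal")])
        assert table.loc[0, "meth_wt"] == pytest.approx(50.0)
        assert bool(table.loc[0, "purity_ok"])  # paternal ICRs not flagged
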