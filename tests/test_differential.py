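import numpy as np
import pytest

from repmeth import (GenomicInterval, RegionScore, call_differential,
                     control_class_analysis, random_regions, shift_test,
                     subfamily_counts, tss_proximity)
from repmeth.differential import DifferentialCall
from repmeth.methylation_io import RepeatElement

from _oracles import mannwhitney_exact


def rs(meth_wt, meth_mut, subfamily="IAPEY", start=0, end=1000, chrom="chr1"):
    elem = RepeatElement(GenomicInterval(chrom, start, end), subfamily,
                         "LTR/ERVK")
    return RegionScore(elem, 8, meth_wt, meth_mut)


class TestCallDifferential:
    def test_validated_effect_size_called_hypo(self):
        # the magnitude seen at the validated element: 59% wt vs 26% mutant
        (call,) = call_differential([rs(59.0, 26.0)])
        assert call.direction == "hypo"
        assert call.delta == pytest.approx(-33.0)

    def test_threshold_is_strict(self):
        assert call_differential([rs(50.0, 60.0)]) == []  # delta exactly +10
        assert call_differential([rs(50.0, 60.0001)]) != []

    def test_positive_delta_is_hyper(self):
        (call,) = call_differential([rs(50.0, 65.0)])
        assert call.direction == "hyper"

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        scores = [rs(w, m, start=i * 10, end=i * 10 + 5)
                  for i, (w, m) in enumerate(
                      zip(rng.uniform(0, 100, 200), rng.uniform(0, 100, 200)))]
        calls = call_differential(scores, 10.0)
        n_hypo = sum(c.direction == "hypo" for c in calls)
        n_hyper = sum(c.direction == "hyper" for c in calls)
        expected = sum(abs(s.delta) > 10.0 for s in scores)
        assert n_hypo + n_hyper == len(calls) == expected
        assert len({id(c.score) for c in calls}) == len(calls)


class TestSubfamilyCounts:
    def test_counts_split_by_direction(self):
        calls = ([DifferentialCall(rs(80, 60), "hypo")] * 3
                 + [DifferentialCall(rs(60, 80), "hyper")])
        table = subfamily_counts(calls)
        row = table.iloc[0]
        assert (row["subfamily"], row["n_hypo"], row["n_hyper"]) == ("IAPEY", 3, 1)

    def test_empty_calls_empty_table(self):
        assert subfamily_counts([]).empty

    def test_top_n_truncation_drops_smallest(self):
        calls = []
        for i in range(25):
            # subfamily sub00 has 26 calls, sub01 25, ... sub24 has 2
            for _ in range(26 - i):
                calls.append(DifferentialCall(rs(80, 60, f"sub{i:02d}"), "hypo"))
        table = subfamily_counts(calls, top_n=20)
        assert len(table) == 20
        assert list(table["subfamily"]) == [f"sub{i:02d}" for i in range(20)]

    def test_ties_broken_lexicographically(self):
        calls = [DifferentialCall(rs(80, 60, s), "hypo")
                 for s in ("zeta", "alpha", "mid")]
        table = subfamily_counts(calls)
        assert list(table["subfamily"]) == ["alpha", "mid", "zeta"]


class TestShiftTest:
    def test_identical_vectors_not_significant(self):
        scores = [rs(v, v) for v in np.linspace(10, 90, 30)]
        res = shift_test(scores, scope="all")
        assert res.p_value > 0.99

    def test_small_sample_exact_enumeration_case(self):
        # wt = [4, 5, 6], mut = [1, 2, 3]: every mutant value below every
        # wild-type value, U = 0, exact two-sided p = 0.1
        scores = [rs(w, m) for w, m in zip([4, 5, 6], [1, 2, 3])]
        res = shift_test(scores, scope="all")
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(0.1)

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n1, n2 = rng.integers(2, 5, size=2)
            vals = rng.permutation(40)[: n1 + n2].astype(float)
            mut, wt = vals[:n1], vals[n1:n1 + n2]
            # build scores so that meth_mut and meth_wt carry the two vectors
            scores = [rs(w, m) for w, m in zip(wt, mut[:len(wt)])]
            scores += [rs(wt[0], m) for m in mut[len(wt):]]
            # direct comparison instead: pad to equal lengths via scope=all
            if n1 != n2:
                continue
            u_ref, p_ref = mannwhitney_exact(mut, wt)
            res = shift_test(scores, scope="all")
            assert res.u_statistic == u_ref
            assert res.p_value == pytest.approx(p_ref)

    def test_antisymmetric_under_vector_swap(self):
        rng = np.random.default_rng(4)
        scores = [rs(w, m) for w, m in zip(rng.uniform(0, 100, 15),
                                           rng.uniform(0, 100, 15))]
        mirrored = [rs(s.meth_mut, s.meth_wt) for s in scores]
        fwd = shift_test(scores, scope="all")
        rev = shift_test(mirrored, scope="all")
        n = len(scores)
        assert fwd.u_statistic + rev.u_statistic == pytest.approx(n * n)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_dm_subset_scope_restricts_to_called_elements(self):
        scores = [rs(90, 88) for _ in range(10)] + [rs(90, 40), rs(90, 45)]
        res = shift_test(scores, scope="dm_subset", threshold_pp=10)
        assert res.n == 2

    def test_planted_shift_detected(self, default_sim):
        # default conditions plant hypomethylation in a subfamily subset;
        # the called subset shows a strong distribution shift
        res = shift_test(default_sim["scoring"].scores, scope="dm_subset")
        assert res.p_value < 1e-10

    def test_too_few_elements_rejected(self):
        with pytest.raises(ValueError):
            shift_test([rs(50, 40)], scope="all")
        with pytest.raises(ValueError):
            shift_test([rs(50, 40)] * 5, scope="bogus")


class TestTssProximity:
    def call_at(self, start, end):
        return DifferentialCall(rs(80, 60, start=start, end=end), "hypo")

    @pytest.mark.parametrize("tss_pos,counted", [
        (6000, True),    # 5,000 bp from element end -> within 10 kb
        (11_001, False),  # 10,001 bp away -> outside
        (11_000, True),   # exactly 10,000 bp -> inclusive bound
        (500, True),      # inside the element -> distance 0
    ])
    def test_distance_boundaries(self, tss_pos, counted):
        count, annotated = tss_proximity([self.call_at(0, 1000)],
                                         [("chr1", tss_pos)])
        assert count == (1 if counted else 0)
        if tss_pos == 500:
            assert annotated[0][1] == 0

    def test_monotone_in_max_distance(self):
        rng = np.random.default_rng(3)
        calls = [self.call_at(s, s + 500)
                 for s in rng.integers(0, 500_000, 50) * 2]
        tss = [("chr1", int(p)) for p in rng.integers(0, 1_000_000, 20)]
        counts = [tss_proximity(calls, tss, d)[0]
                  for d in (0, 1000, 5000, 20_000, 10**6)]
        assert counts == sorted(counts)
        assert counts[-1] == len(calls)

    def test_empty_tss_rejected(self):
        with pytest.raises(ValueError):
            tss_proximity([self.call_at(0, 1000)], [])


class TestRandomRegions:
    def test_bad_n_rejected(self):
        with pytest.raises(ValueError):
            random_regions({"chr1": 10_000}, 0, seed=1)

    def test_deterministic_under_seed(self):
        sizes = {"chr1": 100_000, "chr2": 300_000}
        assert random_regions(sizes, 50, seed=9) == \
            random_regions(sizes, 50, seed=9)

    def test_chromosome_choice_proportional_to_length(self):
        sizes = {"chrA": 1_000_000, "chrB": 3_000_000}
        regions = random_regions(sizes, 10_000, length=1000, seed=5)
        frac_b = np.mean([r.chrom == "chrB" for r in regions])
        sd = np.sqrt(0.75 * 0.25 / 10_000)
        assert abs(frac_b - 0.75) <= 3 * sd
        assert all(r.length == 1000 for r in regions)

    def test_chromosome_shorter_than_region_rejected(self):
        with pytest.raises(ValueError):
            random_regions({"chr1": 500}, 5, length=1000, seed=1)


class TestControlClassAnalysis:
    def test_ervk_annotation_reproduces_main_analysis(self, default_sim):
        ervk = [r for r in default_sim["genome"].repeats
                if r.class_family == "LTR/ERVK"]
        res = control_class_analysis(default_sim["wt"], default_sim["mut"],
                                     ervk, "ervk")
        assert res.scoring.n_scored == default_sim["scoring"].n_scored
        assert len(res.calls) == default_sim["n_dm"]

    def test_no_effect_classes_show_no_shift(self, default_sim):
        line1 = [r for r in default_sim["genome"].repeats
                 if r.class_family == "LINE/L1"]
        res = control_class_analysis(default_sim["wt"], default_sim["mut"],
                                     line1, "LINE1")
        assert res.shift.p_value > 0.05
        assert res.fraction_dm < 0.02

    def test_empty_annotation_rejected(self, default_sim):
        with pytest.raises(ValueError):
            control_class_analysis(default_sim["wt"], default_sim["mut"],
                                   [], "empty")
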