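"""Size-distribution statistics, Whi/Lge classification and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist

from sizephenome.datatypes import BenchmarkSet, SizeDistribution, StrainSummary
from sizephenome.phenome import (
    aggregate_replicates,
    calibrate_cutoff,
    classify_strain,
    cluster_profiles,
    normalize,
    percent_size_change,
    reported_reduction_pct,
    screen_report,
    summarize,
)
from conftest import expanded_mean, expanded_median


def _dist(volumes, counts, strain="s", rep="r1"):
    return SizeDistribution(strain, rep, np.asarray(volumes, float), np.asarray(counts, float))


class TestNormalize:
    def test_single_bin_gets_full_weight(self):
        d = _dist([30, 55, 80], [0, 7, 0])
        assert normalize(d).tolist() == [0.0, 1.0, 0.0]

    def test_simple_arithmetic(self):
        d = _dist([1, 2, 3], [1, 1, 2])
        assert normalize(d).tolist() == [0.25, 0.25, 0.5]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize(_dist([1, 2], [0, 0]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_frequencies_sum_to_one(self, seed):
        from sizephenome.synthetic import gen_size_distribution

        d = gen_size_distribution(55, 0.35, 500, n_bins=64, seed=seed)
        assert normalize(d).sum() == pytest.approx(1.0, abs=1e-9)


class TestSummarize:
    def test_single_populated_bin_collapses_all_stats(self):
        d = _dist([40, 55, 70], [0, 100, 0])
        s = summarize(d)
        assert s.mean_fL == s.median_fL == s.mode_fL == 55
        assert s.total_count == 100

    def test_symmetric_distribution(self, simple_dist):
        s = summarize(simple_dist)
        assert s.mean_fL == pytest.approx(50)
        assert s.median_fL == pytest.approx(50)
        assert s.mode_fL == 50

    def test_mode_tie_breaks_to_smallest_volume(self):
        d = _dist([40, 50, 60], [3, 1, 3])
        assert summarize(d).mode_fL == 40

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            summarize(_dist([1, 2], [0, 0]))

    @given(
        n_bins=st.integers(2, 10),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_median_and_mean_match_expanded_cell_list(self, n_bins, seed):
        """Interpolated binned stats agree with the brute-force per-cell
        expansion within half a bin width (median) / exactly (mean)."""
        rng = np.random.default_rng(seed)
        volumes = np.sort(rng.choice(np.arange(10, 200), size=n_bins, replace=False)).astype(float)
        counts = rng.integers(0, 100, size=n_bins).astype(float)
        if counts.sum() == 0:
            counts[rng.integers(n_bins)] = 1
        d = _dist(volumes, counts)
        s = summarize(d)
        half_bin = np.max(np.diff(volumes)) / 2 if n_bins > 1 else 0.5
        assert s.median_fL == pytest.approx(expanded_median(volumes, counts), abs=half_bin)
        assert s.mean_fL == pytest.approx(expanded_mean(volumes, counts))


class TestAggregateReplicates:
    def test_mean_and_sample_sd(self):
        reps = [_dist([37, 38, 39], [0, 1, 0], rep=f"r{i}") for i in range(3)]
        reps[0] = _dist([37, 38, 39], [1, 0, 0], rep="r0")
        reps[2] = _dist([37, 38, 39], [0, 0, 1], rep="r2")
        s = aggregate_replicates(reps)
        assert s.median_fL == pytest.approx(38.0)
        assert s.median_sd_fL == pytest.approx(1.0)
        assert s.n_replicates == 3

    def test_single_replicate_zero_spread(self):
        s = aggregate_replicates([_dist([44], [10])])
        assert (s.median_fL, s.median_sd_fL) == (44.0, 0.0)

    def test_mixed_strains_rejected(self):
        with pytest.raises(ValueError, match="mixed strain ids"):
            aggregate_replicates([_dist([44], [1], strain="a"), _dist([44], [1], strain="b")])

    def test_recovers_generating_median(self):
        from sizephenome.synthetic import gen_size_distribution

        reps = [
            gen_size_distribution(50, 0.35, 5000, seed=s, replicate_id=f"r{s}")
            for s in range(5)
        ]
        assert aggregate_replicates(reps).median_fL == pytest.approx(50, abs=2)


class TestPercentChange:
    @pytest.mark.parametrize(
        "mutant,wt,reduction",
        [
            (44, 55, 20),      # small mutant exactly at the 20% boundary
            (38, 71.7, 47),
            (34, 55, 38),
            (50.2, 71.7, 30),
            (49.2, 71.7, 31),
            (49, 71.7, 32),
            (35, 55, 36),
            (57.3, 71.7, 20),
        ],
    )
    def test_reported_integer_reductions(self, mutant, wt, reduction):
        assert reported_reduction_pct(mutant, wt) == reduction

    def test_signed_change_and_identity(self):
        assert percent_size_change(44, 55) == pytest.approx(-20.0)
        assert percent_size_change(63.3, 63.3) == 0.0

    def test_nonpositive_wt_rejected(self):
        with pytest.raises(ValueError):
            percent_size_change(44, 0)


def _summary(strain, median, sd=0.0, n=3):
    return StrainSummary(strain, median, sd, n)


class TestClassify:
    def test_boundary_inclusive_whi(self):
        call = classify_strain(_summary("hog1", 44), _summary("wt", 55))
        assert call.call == "Whi"
        assert call.percent_change == pytest.approx(-20.0)

    def test_large_mutant(self):
        assert classify_strain(_summary("ptc2", 84.9), _summary("wt", 68)).call == "Lge"

    def test_equal_medians_normal(self):
        call = classify_strain(_summary("m", 60), _summary("wt", 60))
        assert call.call == "normal" and call.percent_change == 0

    def test_direction_antisymmetry(self):
        """Swapping mutant and wt flips Whi <-> Lge when both directions
        exceed the cutoff."""
        a, b = _summary("a", 40), _summary("b", 60)
        assert classify_strain(a, b).call == "Whi"
        assert classify_strain(b, a).call == "Lge"


class TestCalibrateCutoff:
    def _panel(self, changes):
        summaries = {"wt": _summary("wt", 100.0)}
        wt_map = {}
        for name, pct in changes.items():
            summaries[name] = _summary(name, 100.0 + pct)
            wt_map[name] = "wt"
        return summaries, wt_map

    def test_benchmark_minimum_floored(self):
        summaries, wt_map = self._panel(
            {"s1": -38, "s2": -20, "l1": 25, "l2": 31, "l3": 30}
        )
        bench = BenchmarkSet(("s1", "s2"), ("l1", "l2", "l3"))
        assert calibrate_cutoff(summaries, wt_map, bench) == 20

    def test_single_strain_floor(self):
        summaries, wt_map = self._panel({"s1": -33.4})
        assert calibrate_cutoff(summaries, wt_map, BenchmarkSet(("s1",), ())) == 33

    def test_zero_change_benchmark_rejected(self):
        summaries, wt_map = self._panel({"s1": 0})
        with pytest.raises(ValueError, match="s1"):
            calibrate_cutoff(summaries, wt_map, BenchmarkSet(("s1",), ()))

    def test_wrong_sign_rejected(self):
        summaries, wt_map = self._panel({"s1": +25})
        with pytest.raises(ValueError, match="s1"):
            calibrate_cutoff(summaries, wt_map, BenchmarkSet(("s1",), ()))

    def test_missing_strain_rejected(self):
        summaries, wt_map = self._panel({"s1": -25})
        with pytest.raises(ValueError, match="ghost"):
            calibrate_cutoff(summaries, wt_map, BenchmarkSet(("ghost",), ()))


class TestCluster:
    def _profile(self, median, n_bins=64):
        from sizephenome.synthetic import gen_size_distribution

        d = gen_size_distribution(median, 0.2, 4000, n_bins=n_bins, seed=int(median))
        return normalize(d)

    def test_identical_profiles_merge_at_zero(self):
        p = self._profile(50)
        order, Z = cluster_profiles({"a": p, "b": p.copy()})
        assert Z[0, 2] == 0.0
        assert set(order) == {"a", "b"}

    def test_similar_medians_merge_first(self):
        profiles = {"small1": self._profile(40), "small2": self._profile(42),
                    "large": self._profile(80)}
        order, Z = cluster_profiles(profiles)
        # verify against direct distances over all three topologies
        labels = sorted(profiles)
        D = pdist(np.vstack([profiles[l] for l in labels]))
        first_pair = {labels[int(Z[0, 0])], labels[int(Z[0, 1])]}
        assert first_pair == {"small1", "small2"}
        assert np.argmin(D) == 2  # (small1, small2) pair in pdist order
        # the two small strains are adjacent leaves
        assert abs(order.index("small1") - order.index("small2")) == 1

    def test_all_identical_merge_heights_zero(self):
        p = self._profile(55)
        _, Z = cluster_profiles({f"s{i}": p.copy() for i in range(4)})
        assert np.all(Z[:, 2] == 0.0)

    def test_mismatched_layouts_rejected(self):
        with pytest.raises(ValueError, match="bin layout"):
            cluster_profiles({"a": np.ones(4) / 4, "b": np.ones(5) / 5})

    def test_deterministic_leaf_order(self):
        profiles = {"a": self._profile(40), "b": self._profile(60), "c": self._profile(80)}
        assert cluster_profiles(profiles)[0] == cluster_profiles(profiles)[0]


class TestScreenReport:
    def test_counts_by_construction(self):
        summaries = {
            "wt": _summary("wt", 60),
            "w1": _summary("w1", 40), "w2": _summary("w2", 45),
            "l1": _summary("l1", 80),
            "n1": _summary("n1", 58), "n2": _summary("n2", 62),
        }
        wt_map = {s: "wt" for s in summaries if s != "wt"}
        report, counts = screen_report(summaries, wt_map)
        assert counts == {"Whi": 2, "Lge": 1, "normal": 2}
        assert len(report) == 5
        assert set(report.columns) == {
            "strain", "wt", "median_fL", "median_sd_fL", "percent_change", "call"
        }

    def test_empty_mutant_panel(self):
        report, counts = screen_report({"wt": _summary("wt", 60)}, {})
        assert len(report) == 0
        assert counts == {"Whi": 0, "Lge": 0, "normal": 0}

    def test_missing_wt_named(self):
        summaries = {"m": _summary("m", 40)}
        with pytest.raises(ValueError, match="'wt'"):
            screen_report(summaries, {"m": "wt"})

    def test_unmeasured_mutant_named(self):
        summaries = {"wt": _summary("wt", 60)}
        with pytest.raises(ValueError, match="'ghost'"):
            screen_report(summaries, {"ghost": "wt"})
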