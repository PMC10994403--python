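"""Design-weighted estimation and printed-table arithmetic."""

import numpy as np
import pytest

from conftest import make_woman
from geocontracep.survey import (
    background_table,
    coverage_disparity,
    distance_summary_table,
    method_mix_table,
    round_half_up,
    weighted_proportion,
)


def _random_records(rng, n, n_ea=10, p=0.4):
    recs = []
    for i in range(n):
        ea = int(rng.integers(n_ea))
        recs.append(make_woman(
            woman_id=f"W{i}", ea_id=f"EA{ea:03d}",
            weight=float(rng.uniform(0.5, 4.0)),
            residence="urban" if ea % 2 else "rural",
            uses_modern=bool(rng.random() < p),
        ))
    return recs


class TestWeightedProportion:
    def test_equal_weights_reduce_to_unweighted(self):
        recs = [make_woman(woman_id=f"W{i}", ea_id=f"EA{i%8}", uses_modern=i < 44)
                for i in range(100)]
        assert weighted_proportion(recs).estimate == pytest.approx(0.44, abs=1e-12)

    def test_hand_computed_two_records(self):
        recs = [make_woman(woman_id="a", weight=1.0, uses_modern=True),
                make_woman(woman_id="b", weight=3.0, uses_modern=False)]
        assert weighted_proportion(recs).estimate == pytest.approx(0.25, abs=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        recs = _random_records(rng, 200)
        w = np.array([r.weight for r in recs])
        y = np.array([float(r.uses_modern) for r in recs])
        assert weighted_proportion(recs).estimate == pytest.approx(
            (w * y).sum() / w.sum(), abs=1e-12)

    def test_scale_invariance(self, rng):
        recs = _random_records(rng, 150)
        est1 = weighted_proportion(recs)
        scaled = [make_woman(
            woman_id=r.woman_id, ea_id=r.ea_id, weight=r.weight * 7.3,
            residence=r.residence, uses_modern=r.uses_modern) for r in recs]
        est2 = weighted_proportion(scaled)
        assert est1.estimate == pytest.approx(est2.estimate, abs=1e-12)
        assert est1.ci_low == pytest.approx(est2.ci_low, abs=1e-9)
        assert est1.ci_high == pytest.approx(est2.ci_high, abs=1e-9)

    def test_degenerate_groups_one_sided(self):
        zeros = [make_woman(woman_id=f"W{i}", uses_modern=False) for i in range(20)]
        est = weighted_proportion(zeros)
        assert est.estimate == 0.0 and est.ci_low == 0.0 and 0 < est.ci_high < 0.2
        ones = [make_woman(woman_id=f"W{i}", uses_modern=True) for i in range(20)]
        est = weighted_proportion(ones)
        assert est.estimate == 1.0 and est.ci_high == 1.0 and 0.8 < est.ci_low < 1

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            weighted_proportion([])

    def test_ci_width_shrinks_with_n(self):
        widths = {n: [] for n in (100, 1000, 10000)}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            for n in widths:
                recs = _random_records(rng, n, n_ea=max(10, n // 20))
                est = weighted_proportion(recs)
                widths[n].append(est.ci_high - est.ci_low)
        means = [np.mean(widths[n]) for n in (100, 1000, 10000)]
        assert means[0] > means[1] > means[2]


class TestBackgroundTable:
    def test_percent_sums_per_factor(self, small_survey):
        tab = background_table(small_survey.women)
        for factor, grp in tab.groupby("factor"):
            assert grp["percent_weighted"].sum() == pytest.approx(100.0, abs=0.2)

    def test_weighted_percent_arithmetic(self):
        # two-level fixture whose weighted counts mirror a printed table row
        recs = ([make_woman(woman_id=f"W{i}", weight=1960.0 / 10, education="never")
                 for i in range(10)]
                + [make_woman(woman_id=f"X{i}", weight=(4390.0 - 1960.0) / 10,
                              education="primary") for i in range(10)])
        tab = background_table(recs, factors=["education"]).set_index("level")
        assert round_half_up(tab.loc["never", "percent_weighted"]) == 44.6
        assert tab.loc["never", "n_weighted"] + tab.loc["primary", "n_weighted"] == (
            pytest.approx(20.0))  # weighted n normalised to the sample size

    def test_half_up_rounding(self):
        assert round_half_up(44.65) == 44.7
        assert round_half_up(44.649) == 44.6
        assert round_half_up(0.25, 1) == 0.3


class TestMethodMix:
    def test_shares_partition_coverage(self, small_survey):
        tab = method_mix_table(small_survey.women, by="wealth")
        for _, row in tab.iterrows():
            total = sum(row[f"{m}_percent"]
                        for m in ("injectable", "implant", "pill", "other"))
            assert total == pytest.approx(row["mcp_percent"], abs=1e-9)

    def test_level_without_users_all_zero(self):
        recs = [make_woman(woman_id=f"W{i}", wealth="low", uses_modern=False)
                for i in range(5)]
        recs += [make_woman(woman_id=f"X{i}", wealth="high", uses_modern=True)
                 for i in range(5)]
        tab = method_mix_table(recs, by="wealth").set_index("level")
        assert tab.loc["low", "mcp_percent"] == 0.0
        assert tab.loc["low", "injectable_percent"] == 0.0

    def test_total_row_matches_known_mix(self, rng):
        """At coverage 44.2% and mix (.561,.321,.061,.057) the shares are
        ~24.8/14.2/2.7/2.5 of all women in need."""
        mix = {"injectable": 0.561, "implant": 0.321, "pill": 0.061, "other": 0.057}
        levels = list(mix)
        probs = np.array(list(mix.values()))
        probs = probs / probs.sum()
        recs = []
        for i in range(20_000):
            uses = rng.random() < 0.442
            recs.append(make_woman(
                woman_id=f"W{i}", ea_id=f"EA{i%40}", uses_modern=uses,
                method=levels[rng.choice(len(levels), p=probs)] if uses else "none"))
        tab = method_mix_table(recs).iloc[0]
        assert tab["injectable_percent"] == pytest.approx(24.8, abs=1.0)
        assert tab["implant_percent"] == pytest.approx(14.2, abs=1.0)
        assert tab["pill_percent"] == pytest.approx(2.7, abs=1.0)
        assert tab["other_percent"] == pytest.approx(2.5, abs=1.0)


class TestDistanceTable:
    def test_constant_distances(self):
        recs = [make_woman(woman_id=f"W{i}", sdp_distance_km=1.0) for i in range(6)]
        row = distance_summary_table(recs).iloc[-1]
        assert row["mean"] == row["median"] == 1.0
        assert row["sd"] == 0.0

    def test_category_percents_sum(self, small_survey):
        tab = distance_summary_table(small_survey.women)
        for _, row in tab.iterrows():
            assert row["pct_le2km"] + row["pct_2to6km"] + row["pct_gt6km"] == (
                pytest.approx(100.0, abs=0.1))

    def test_matches_direct_statistics_oracle(self, rng):
        d = rng.gamma(2.0, 1.5, size=500)
        recs = [make_woman(woman_id=f"W{i}", sdp_distance_km=float(x))
                for i, x in enumerate(d)]
        row = distance_summary_table(recs).iloc[-1]
        assert row["mean"] == pytest.approx(d.mean(), abs=1e-9)
        assert row["median"] == pytest.approx(np.median(d), abs=1e-9)
        assert row["sd"] == pytest.approx(d.std(ddof=1), abs=1e-9)
        assert row["min"] == pytest.approx(d.min(), abs=1e-12)
        assert row["max"] == pytest.approx(d.max(), abs=1e-12)

    def test_unset_distance_errors(self):
        with pytest.raises(ValueError):
            distance_summary_table([make_woman(sdp_distance_km=None)])


class TestDisparity:
    def _two_group_records(self, p1, p2, n=1000, rng=None):
        rng = rng or np.random.default_rng(0)
        recs = []
        for i in range(n):
            recs.append(make_woman(
                woman_id=f"A{i}", ea_id=f"EA{i%25:03d}", wealth="high",
                uses_modern=bool(rng.random() < p1)))
            recs.append(make_woman(
                woman_id=f"B{i}", ea_id=f"EA{i%25:03d}", wealth="low",
                uses_modern=bool(rng.random() < p2)))
        return recs

    def test_identical_groups_zero_gap(self):
        recs = ([make_woman(woman_id=f"A{i}", wealth="high", uses_modern=i % 2 == 0)
                 for i in range(10)]
                + [make_woman(woman_id=f"B{i}", wealth="low", uses_modern=i % 2 == 0)
                   for i in range(10)])
        out = coverage_disparity(recs, "wealth", "high", "low", n_boot=50)
        assert out["absolute_pp"] == pytest.approx(0.0, abs=1e-12)
        assert out["relative_percent"] == pytest.approx(0.0, abs=1e-12)

    def test_relative_and_absolute_scales(self):
        # exact prevalences via weights: p1 = 0.477, p2 = 0.239
        recs = [
            make_woman(woman_id="a1", ea_id="E1", wealth="high", weight=477.0,
                       uses_modern=True),
            make_woman(woman_id="a0", ea_id="E1", wealth="high", weight=523.0,
                       uses_modern=False),
            make_woman(woman_id="b1", ea_id="E1", wealth="low", weight=239.0,
                       uses_modern=True),
            make_woman(woman_id="b0", ea_id="E1", wealth="low", weight=761.0,
                       uses_modern=False),
        ]
        out = coverage_disparity(recs, "wealth", "high", "low", n_boot=50)
        assert out["absolute_pp"] == pytest.approx(23.8, abs=1e-9)
        assert out["relative_percent"] == pytest.approx(99.58, abs=0.01)

    def test_bootstrap_ci_contains_point(self, rng):
        recs = self._two_group_records(0.5, 0.3, n=800, rng=rng)
        out = coverage_disparity(recs, "wealth", "high", "low", n_boot=200, seed=4)
        lo, hi = out["absolute_ci"]
        assert lo <= out["absolute_pp"] <= hi

    def test_missing_level_errors(self):
        recs = [make_woman(wealth="low")]
        with pytest.raises(ValueError):
            coverage_disparity(recs, "wealth", "high", "low")
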