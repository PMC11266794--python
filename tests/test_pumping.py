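"""Lethargus calling, feeding fractions, rate normalization, group tests."""

import numpy as np
import pytest
from scipy import stats

from larvatime import pumping, synthetic


def raster(pump, l4=None, start=32.0, interval_min=20.0, group="control", iid="w1"):
    times = start + (interval_min / 60.0) * np.arange(len(pump))
    return pumping.PumpingRaster(iid, times, np.asarray(pump), None if l4 is None else np.asarray(l4), group)


class TestCallLethargus:
    def test_simple_episode(self):
        """1,1,1,0,0,0 then L4 at 20-min sampling from 32 h."""
        call = pumping.call_lethargus(raster([1, 1, 1, 0, 0, 0, 1], l4=[0, 0, 0, 0, 0, 0, 1]))
        assert call.entry_h == pytest.approx(33.0)
        assert call.duration_min == pytest.approx(60.0)
        assert call.n_bouts == 1 and not call.fragmented and not call.censored
        assert call.l4_onset_h == pytest.approx(34.0)

    def test_fragmented_episode(self):
        call = pumping.call_lethargus(raster([1, 0, 1, 0, 1], l4=[0, 0, 0, 0, 1]))
        assert call.fragmented and call.n_bouts == 2
        assert call.duration_min == pytest.approx(40.0)
        assert call.longest_bout_min == pytest.approx(20.0)

    def test_censoring(self):
        all_pumping = pumping.call_lethargus(raster([1, 1, 1, 1], l4=[0, 0, 0, 0]))
        assert all_pumping.censored and all_pumping.entry_h is None
        no_l4 = pumping.call_lethargus(raster([1, 1, 0, 0], l4=[0, 0, 0, 0]))
        assert no_l4.censored and no_l4.entry_h == pytest.approx(32.0 + 40 / 60)

    def test_presumed_l4_without_annotation(self):
        call = pumping.call_lethargus(raster([1, 0, 0, 1, 1]))
        assert not call.censored
        assert call.l4_onset_h == pytest.approx(33.0)

    def test_duration_is_interval_times_zero_count(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            p = rng.integers(0, 2, size=12)
            l4 = np.zeros(12, int)
            l4[-1] = 1
            call = pumping.call_lethargus(raster(p, l4=l4))
            assert call.duration_min == pytest.approx(20.0 * np.sum(p[:-1] == 0))

    def test_simulated_recovery_within_one_interval(self):
        params = synthetic.BehaviorSimParams(n_individuals=200, seed=5)
        rasters, truth = synthetic.simulate_pumping_cohort(params)
        errs = []
        for r, rec in zip(rasters, truth.itertuples()):
            call = pumping.call_lethargus(r)
            if rec.censored:
                continue
            errs.append(abs(call.entry_h - rec.onset_drawn_h) * 60.0)
            assert abs(call.duration_min - rec.duration_drawn_min) <= 20.0 + 1e-9
            assert call.fragmented == rec.fragmented
        assert max(errs) <= 20.0 + 1e-9
        assert np.mean(errs) <= 10.0 + 2.0  # ~interval/2 plus discretization bias


class TestCohortStats:
    def test_long_fraction(self):
        calls = {
            "control": [
                pumping.call_lethargus(raster([1, 0, 0, 0, 1], l4=[0, 0, 0, 0, 1])),  # 60 min
                pumping.call_lethargus(raster([0, 0, 0, 0, 0, 0, 1], l4=[0] * 6 + [1])),  # 120 min
            ]
        }
        out = pumping.cohort_lethargus_stats(calls)
        assert out["control"]["long_fraction"] == pytest.approx(0.5)

    def test_identical_groups_zero_differences(self):
        base = [pumping.call_lethargus(raster([1, 0, 0, 1], l4=[0, 0, 0, 1]))]
        out = pumping.cohort_lethargus_stats({"a": base, "b": list(base)})
        assert all(v == pytest.approx(0.0) for v in out["difference"].values())

    def test_all_censored_group_errors(self):
        calls = {"a": [pumping.call_lethargus(raster([1, 1, 1], l4=[0, 0, 0]))]}
        with pytest.raises(ValueError):
            pumping.cohort_lethargus_stats(calls)

    def test_simulated_long_fraction_difference(self):
        """Lower long-mode weight shows up as a lower called long fraction."""
        control = synthetic.BehaviorSimParams(n_individuals=200, long_weight=0.20, seed=2)
        mcp = synthetic.BehaviorSimParams(n_individuals=200, long_weight=0.05, seed=3)
        calls = {}
        for label, params in (("control", control), ("MCP", mcp)):
            rasters, _ = synthetic.simulate_pumping_cohort(params, group_label=label)
            calls[label] = [pumping.call_lethargus(r) for r in rasters]
        out = pumping.cohort_lethargus_stats(calls)
        diff = out["MCP"]["long_fraction"] - out["control"]["long_fraction"]
        # simulated difference -0.15; binomial 95% half-width ~ 0.07 at n=200
        assert diff == pytest.approx(-0.15, abs=0.08)


class TestFeedingFraction:
    def test_pooled_fraction(self):
        rs = [raster([1, 1, 1, 0, 1, 1]), raster([1, 1, 0, 0, 1, 1], iid="w2")]
        frac = pumping.feeding_fraction(rs, (32.0, 32.0 + 5 * 20 / 60))
        assert frac == pytest.approx(9 / 12)

    def test_all_pumping_is_one(self):
        assert pumping.feeding_fraction([raster([1, 1, 1])], (32.0, 33.0)) == 1.0

    def test_bounds_and_monotonicity(self):
        p = np.array([1, 0, 1, 0, 1, 0])
        f0 = pumping.feeding_fraction([raster(p)], (32.0, 34.0))
        flipped = p.copy()
        flipped[1] = 1
        f1 = pumping.feeding_fraction([raster(flipped)], (32.0, 34.0))
        assert 0.0 <= f0 <= f1 <= 1.0

    def test_empty_window_errors(self):
        with pytest.raises(ValueError):
            pumping.feeding_fraction([raster([1, 1])], (50.0, 51.0))


class TestTransitionFractions:
    def test_all_exited(self):
        rs = [raster([1, 1, 1, 0, 0, 1], l4=[0, 0, 0, 0, 0, 1], iid=f"w{i}") for i in range(4)]
        out = pumping.stage_transition_fractions(rs, 34.0)
        assert out["exited_l3_fraction"] == 1.0

    def test_none_exited(self):
        rs = [raster([1, 1, 1, 1], l4=[0, 0, 0, 0])]
        out = pumping.stage_transition_fractions(rs, 33.0)
        assert out["exited_l3_fraction"] == 0.0 and out["entered_l4_fraction"] == 0.0

    def test_median_onset_gives_half_exited(self):
        params = synthetic.BehaviorSimParams(n_individuals=200, onset_mean_h=34.0, seed=7)
        rasters, _ = synthetic.simulate_pumping_cohort(params)
        out = pumping.stage_transition_fractions(rasters, 34.0)
        lo, hi = stats.binom.interval(0.99, 200, 0.5)
        # onsets discretize upward onto the 20-min grid: compare against the
        # drawn-onset criterion at the next grid time
        assert lo / 200 <= out["exited_l3_fraction"] <= hi / 200 + 0.15


class TestPumpingRate:
    def test_rate_and_exclusions(self):
        assert pumping.pumping_rate(45, 10.0)["rate_per_s"] == pytest.approx(4.5)
        assert pumping.pumping_rate(0, 10.0)["reason"] == "no_pumping"
        assert pumping.pumping_rate(30, 10.0, on_lawn=False)["reason"] == "off_lawn"
        with pytest.raises(ValueError):
            pumping.pumping_rate(10, 0.0)


class TestCompareGroups:
    def test_identical_binary_groups(self):
        out = pumping.compare_groups([1, 1, 0, 0], [1, 1, 0, 0], kind="binary")
        assert out["p_value"] == pytest.approx(1.0)
        assert out["effect"] == 0.0

    def test_extreme_binary_difference(self):
        out = pumping.compare_groups([1] * 10, [0] * 10, kind="binary")
        # exact hypergeometric: p = 2 / C(20,10)
        assert out["p_value"] == pytest.approx(2 / 184756)
        assert out["p_value"] < 0.001

    def test_degenerate_continuous_flagged(self):
        out = pumping.compare_groups([1.0, 1.0], [1.0, 1.0])
        assert out["degenerate"] and out["p_value"] == 1.0

    def test_welch_power_on_shifted_normals(self):
        """n=50 per group, 1 SD shift: rejection rate is high."""
        rng = np.random.default_rng(13)
        rejections = sum(
            pumping.compare_groups(rng.normal(0, 1, 50), rng.normal(1, 1, 50))["p_value"] < 0.05
            for _ in range(300)
        )
        assert rejections / 300 > 0.8
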