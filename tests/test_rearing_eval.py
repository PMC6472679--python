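"""Exceedance statistics and framework orchestration."""

import numpy as np
import pandas as pd
import pytest

from sbcc_eval.config import RunConfig
from sbcc_eval.rearing_eval import (
    ABOVE,
    BELOW,
    RearingLimits,
    Scenario,
    evaluate_field,
    longest_run,
    percent_time,
    run_framework,
)


def brute_longest_run(meets: np.ndarray, cadence: float) -> float:
    """Oracle: scan every contiguous index window."""
    n = len(meets)
    best = 0
    for i in range(n):
        for j in range(i, n):
            if all(meets[i : j + 1]):
                best = max(best, j - i + 1)
    return best * cadence / 3600.0


class TestPercentTime:
    def test_all_below(self):
        assert percent_time(np.full(10, 0.01), 0.1, BELOW) == 100.0

    def test_none_below(self):
        assert percent_time(np.full(10, 0.2), 0.1, BELOW) == 0.0

    def test_enumerated_half(self):
        s = np.array([0.05, 0.2, 0.05, 0.3])
        assert percent_time(s, 0.1, BELOW) == pytest.approx(50.0)

    def test_strict_inequality_at_the_limit(self):
        s = np.array([0.1, 0.1])
        assert percent_time(s, 0.1, BELOW) == 0.0
        assert percent_time(s, 0.1, ABOVE) == 0.0

    def test_missing_excluded_from_denominator(self):
        s = np.array([0.05, np.nan, 0.2])
        assert percent_time(s, 0.1, BELOW) == pytest.approx(50.0)

    def test_all_missing_is_error(self):
        with pytest.raises(ValueError, match="all-missing"):
            percent_time(np.array([np.nan, np.nan]), 0.1, BELOW)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(0, 0.3, 50)
        shuffled = rng.permutation(s)
        assert percent_time(s, 0.1, BELOW) == percent_time(shuffled, 0.1, BELOW)


class TestLongestRun:
    def test_no_sample_meets(self):
        assert longest_run(np.full(5, 0.2), 0.1, BELOW, cadence=600.0) == 0.0

    def test_all_samples_meet(self):
        assert longest_run(np.full(6, 0.01), 0.1, BELOW, cadence=600.0) == pytest.approx(1.0)

    def test_enumerated_pattern(self):
        # boolean pattern T,T,F,T,T,T at 10-min cadence -> 3 * 600 s = 0.5 h
        s = np.array([0.05, 0.05, 0.5, 0.05, 0.05, 0.05])
        assert longest_run(s, 0.1, BELOW, cadence=600.0) == pytest.approx(0.5)

    def test_missing_sample_breaks_run(self):
        s = np.array([0.05, np.nan, 0.05, 0.05])
        assert longest_run(s, 0.1, BELOW, cadence=600.0) == pytest.approx(2 * 600 / 3600)

    def test_time_gap_breaks_run(self):
        times = pd.DatetimeIndex(
            ["2016-01-01T00:00", "2016-01-01T00:10", "2016-01-01T02:00", "2016-01-01T02:10"]
        )
        s = np.full(4, 0.05)
        run = longest_run(s, 0.1, BELOW, cadence=600.0, times=times)
        assert run == pytest.approx(2 * 600 / 3600)

    def test_unknown_cadence_is_error(self):
        with pytest.raises(ValueError, match="cadence"):
            longest_run(np.ones(3), 0.1, BELOW, cadence=0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = rng.integers(1, 40)
            s = rng.uniform(0, 0.2, n)
            got = longest_run(s, 0.1, BELOW, cadence=600.0)
            assert got == pytest.approx(brute_longest_run(s < 0.1, 600.0))

    def test_order_sensitivity_regression(self):
        # the pair distinguishes run structure from the marginal distribution
        a = np.array([0.05, 0.05, 0.05, 0.5])
        b = np.array([0.05, 0.5, 0.05, 0.05])
        assert percent_time(a, 0.1, BELOW) == percent_time(b, 0.1, BELOW)
        assert longest_run(a, 0.1, BELOW, 600.0) != longest_run(b, 0.1, BELOW, 600.0)


class TestRearingLimits:
    def test_defaults_are_case_study_values(self):
        lim = RearingLimits()
        assert lim.u_forage == 0.1
        assert lim.u_mobility == 0.27
        assert lim.do_survival == 4.5
        assert lim.do_optimal == 6.4
        assert lim.u_do * 1000 == pytest.approx(1.70, abs=0.01)

    def test_forage_must_be_below_mobility(self):
        with pytest.raises(ValueError, match="mobility"):
            RearingLimits(u_forage=0.3, u_mobility=0.27)


class TestEvaluateField:
    def test_constant_zero_field_extremes(self, small_field):
        zero = small_field
        zero.speed = np.zeros_like(zero.speed)
        report = evaluate_field(zero, RearingLimits(), [Scenario()])
        t = report.table
        assert (t[t.limit == "foraging"].percent_time == 0.0).all()
        assert (t[t.limit == "do_velocity"].percent_time == 100.0).all()

    def test_sample_conservation_per_height(self, small_field):
        report = evaluate_field(small_field, RearingLimits(), [Scenario()])
        t = report.table
        assert ((t.n_valid + t.n_missing) == len(small_field.times)).all()

    def test_surface_exceeds_forage_more_than_seabed(self, default_synth_field):
        report = evaluate_field(default_synth_field, RearingLimits(), [Scenario()])
        sub = report.subset(limit="foraging").sort_values("height")
        pct = sub.percent_time.to_numpy()
        assert np.all(np.diff(pct) >= 0)  # grows toward the surface
        assert pct[-1] > 0  # the sheared tide does exceed the limit aloft

    def test_empty_scenario_list_rejected(self, small_field):
        with pytest.raises(ValueError, match="scenario"):
            evaluate_field(small_field, RearingLimits(), [])

    def test_internal_field_rejected(self, small_field):
        from sbcc_eval.transfer import apply_to_field

        with pytest.raises(ValueError, match="external"):
            evaluate_field(apply_to_field(small_field), RearingLimits(), [Scenario()])


class TestRunFramework:
    @pytest.fixture
    def tiny_config(self):
        cfg = RunConfig()
        cfg.evp.synthetic.duration_days = 3.0
        cfg.evp.synthetic.heights = (1.24, 15.0, 29.0)
        cfg.output.directory = ""  # no files unless outdir given
        return cfg

    def test_rerun_is_byte_identical(self, tiny_config, tmp_path):
        run_framework(tiny_config, outdir=tmp_path / "a")
        run_framework(tiny_config, outdir=tmp_path / "b")
        assert (tmp_path / "a/report.csv").read_bytes() == (tmp_path / "b/report.csv").read_bytes()
        assert (tmp_path / "a/manifest.txt").read_bytes() == (tmp_path / "b/manifest.txt").read_bytes()

    def test_do_exceedance_grows_with_biofouling(self, tiny_config, tmp_path):
        res = run_framework(tiny_config, outdir=tmp_path)
        t = res.report.table
        sub = t[(t.limit == "do_velocity") & (~t.turbulence)]
        for _, grp in sub.groupby("height"):
            pct = grp.sort_values("coverage").percent_time.to_numpy()
            assert np.all(np.diff(pct) >= 0)

    def test_turbulence_never_reduces_mobility_exceedance(self, tiny_config, tmp_path):
        res = run_framework(tiny_config, outdir=tmp_path)
        t = res.report.table
        mob = t[t.limit == "mobility"]
        for (_, _), grp in mob.groupby(["height", "coverage"]):
            on = grp[grp.turbulence].percent_time.iloc[0]
            off = grp[~grp.turbulence].percent_time.iloc[0]
            assert on >= off

    def test_storm_wave_envelope_raises_velocities(self, tiny_config, tmp_path):
        base = run_framework(tiny_config, outdir=tmp_path / "base")
        tiny_config.wave.enabled = True
        wavy = run_framework(tiny_config, outdir=tmp_path / "wave")
        assert wavy.field.speed.mean() > base.field.speed.mean()
        # the envelope is largest at the surface
        boost = wavy.field.speed.mean(axis=0) - base.field.speed.mean(axis=0)
        assert np.all(np.diff(boost) > 0)
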