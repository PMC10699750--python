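"""Closed-phase slope fitting, solubility and the MO2 mass balance."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from swimresp import (
    FishMorphometrics,
    Phase,
    PO2Trace,
    TunnelGeometry,
    compute_mo2,
    fit_po2_slope,
    o2_solubility,
    simulate_po2_trace,
)
from swimresp.errors import DomainError, InsufficientDataError, LeakError
from swimresp.respirometry import background_check, mo2_samples_from_trial
from swimresp.types import SlopeFit


def _trace(t, y, temp=22.0, sal=34.0):
    return PO2Trace(np.asarray(t, float), np.asarray(y, float), temp, sal,
                    Phase("rest"))


def _ols_oracle(t, y):
    """Independent two-pass least-squares slope/intercept."""
    t, y = np.asarray(t, float), np.asarray(y, float)
    tc, yc = t - t.mean(), y - y.mean()
    slope = float(np.sum(tc * yc) / np.sum(tc * tc))
    return slope, float(y.mean() - slope * t.mean())


class TestSlopeFit:
    def test_exact_line_recovered(self):
        t = np.arange(0, 600.0)
        fit = fit_po2_slope(_trace(t, 100.0 - 2.0 * t / 3600.0))
        assert fit.slope_pct_sat_per_h == pytest.approx(-2.0, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert not fit.degenerate

    def test_constant_trace_is_degenerate(self):
        fit = fit_po2_slope(_trace(np.arange(0, 400.0), np.full(400, 100.0)))
        assert fit.slope_pct_sat_per_h == 0.0
        assert fit.r2 == 0.0
        assert fit.degenerate

    def test_wait_period_excluded(self):
        # mixing artefact in the first 2 min must not contaminate the slope
        t = np.arange(0, 500.0)
        y = 100.0 - 5.0 * t / 3600.0
        y[:120] = 100.0
        fit = fit_po2_slope(_trace(t, y), wait_period_s=120.0)
        assert fit.slope_pct_sat_per_h == pytest.approx(-5.0, rel=1e-9)

    def test_too_few_samples_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_po2_slope(_trace(np.arange(0, 140.0), np.full(140, 99.0)))

    def test_matches_independent_ols_oracle_on_noisy_traces(self, rng):
        t = np.arange(0.0, 480.0)
        for _ in range(20):
            y = 100.0 - 4.0 * t / 3600.0 + rng.normal(0, 0.2, t.size)
            fit = fit_po2_slope(_trace(t, y))
            slope, _ = _ols_oracle(t[120:], y[120:])
            assert fit.slope_pct_sat_per_h == pytest.approx(slope * 3600.0, rel=1e-9)

    def test_noisy_slope_recovery_within_3pct(self, fish, tunnel):
        """Simulation oracle: true slope -5 % sat h-1, sd 0.2, 100 seeds."""
        t = np.arange(0.0, 600.0)
        slopes = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            y = 100.0 - 5.0 * t / 3600.0 + r.normal(0, 0.2, t.size)
            slopes.append(fit_po2_slope(_trace(t, y)).slope_pct_sat_per_h)
        assert np.mean(slopes) == pytest.approx(-5.0, rel=0.03)


class TestSolubility:
    def test_monotone_in_temperature_and_salinity(self):
        assert o2_solubility(30, 34) < o2_solubility(22, 34)
        temps = np.arange(0, 41, 5)
        assert all(o2_solubility(t, 0) > o2_solubility(t, 34) for t in temps)

    def test_matches_published_table_value(self):
        # seawater at 25 degC, 35 ppt: 6.72 mg O2 l-1 in standard DO tables
        assert o2_solubility(25.0, 35.0) == pytest.approx(6.72, rel=0.01)

    def test_out_of_range_raises(self):
        with pytest.raises(DomainError):
            o2_solubility(-1.0, 34.0)
        with pytest.raises(DomainError):
            o2_solubility(22.0, 45.0)


class TestComputeMO2:
    def test_hand_arithmetic(self, tunnel):
        fish = FishMorphometrics(0.9, 40.0, 28.0)
        fit = SlopeFit(-1.0, 100.0, 0.99, 300)
        s = compute_mo2(fit, beta=6.0, fish=fish, tunnel=tunnel)
        assert s.mo2 == pytest.approx(1 / 100 * 6.0 * 107.8 / 0.9, rel=1e-12)
        assert s.qc_flag == "pass"

    def test_zero_slope_gives_zero_flagged(self, fish, tunnel):
        fit = SlopeFit(0.0, 100.0, 0.0, 300, degenerate=True)
        s = compute_mo2(fit, 6.0, fish, tunnel)
        assert s.mo2 == 0.0 and s.degenerate

    def test_low_r2_flag_matches_threshold(self, fish, tunnel):
        s = compute_mo2(SlopeFit(-2.0, 100, 0.79, 300), 6.0, fish, tunnel)
        assert s.qc_flag == "low_r2"
        s = compute_mo2(SlopeFit(-2.0, 100, 0.80, 300), 6.0, fish, tunnel)
        assert s.qc_flag == "pass"

    def test_positive_slope_raises_leak(self, fish, tunnel):
        with pytest.raises(LeakError):
            compute_mo2(SlopeFit(2.0, 100, 0.9, 300), 6.0, fish, tunnel)

    @given(scale=st.floats(0.1, 10.0))
    def test_linearity_in_slope(self, scale, tunnel):
        fish = FishMorphometrics(0.9, 40.0, 28.0)
        base = compute_mo2(SlopeFit(-1.0, 100, 0.99, 300), 6.0, fish, tunnel).mo2
        scaled = compute_mo2(SlopeFit(-scale, 100, 0.99, 300), 6.0, fish, tunnel).mo2
        assert scaled == pytest.approx(scale * base, rel=1e-12)

    def test_mass_specific_scaling(self, tunnel):
        """Doubling fish mass at fixed total consumption roughly halves
        mass-specific MO2 (exactly, modulo the displaced-volume term)."""
        f1 = FishMorphometrics(0.9, 40.0, 28.0)
        f2 = FishMorphometrics(1.8, 40.0, 28.0)
        m1 = compute_mo2(SlopeFit(-1.0, 100, 0.99, 300), 6.0, f1, tunnel).mo2
        m2 = compute_mo2(SlopeFit(-1.0, 100, 0.99, 300), 6.0, f2, tunnel).mo2
        assert m2 == pytest.approx(m1 * (108.7 - 1.8) / (108.7 - 0.9) / 2, rel=1e-12)

    def test_noise_free_synthetic_round_trip(self, fish, tunnel):
        trace = simulate_po2_trace(120.0, fish, tunnel, 22.0, 34.0,
                                   duration_s=480, noise_sd=0.0, seed=0)
        fit = fit_po2_slope(trace)
        beta = o2_solubility(22.0, 34.0)
        s = compute_mo2(fit, beta, fish, tunnel)
        assert s.mo2 == pytest.approx(120.0, rel=1e-9)


class TestBackgroundCheck:
    def _empty(self, slope_pct_h):
        t = np.arange(0.0, 480.0)
        return _trace(t, 100.0 + slope_pct_h * t / 3600.0)

    def test_flat_trace_no_adjustment(self, fish, tunnel):
        sample = compute_mo2(SlopeFit(-1.0, 100, 0.99, 300), 6.0, fish, tunnel)
        frac, adj = background_check(self._empty(0.0), sample, fish, tunnel)
        assert frac == 0.0 and adj is sample

    def test_sub_percent_background_recorded_unadjusted(self, fish, tunnel):
        sample = compute_mo2(SlopeFit(-1.0, 100, 0.99, 300), 6.0, fish, tunnel)
        fish_total_mg_h = sample.mo2 * fish.mass_kg
        beta = o2_solubility(22.0, 34.0)
        bg_slope = 0.005 * fish_total_mg_h / (beta * tunnel.volume_l) * 100
        frac, adj = background_check(self._empty(-bg_slope), sample, fish, tunnel)
        assert frac == pytest.approx(0.005, rel=1e-6)
        assert adj.mo2 == sample.mo2

    def test_large_background_subtracted(self, fish, tunnel):
        sample = compute_mo2(SlopeFit(-1.0, 100, 0.99, 300), 6.0, fish, tunnel)
        fish_total_mg_h = sample.mo2 * fish.mass_kg
        beta = o2_solubility(22.0, 34.0)
        bg_slope = 0.05 * fish_total_mg_h / (beta * tunnel.volume_l) * 100
        frac, adj = background_check(self._empty(-bg_slope), sample, fish, tunnel)
        assert frac == pytest.approx(0.05, rel=1e-6)
        assert adj.mo2 == pytest.approx(sample.mo2 * 0.95, rel=1e-6)


def test_trial_slope_fits_match_oracle_everywhere(noise_free_trial_22):
    """Every closed-phase fit equals the independent two-pass OLS solution."""
    for ph in noise_free_trial_22.phases:
        if ph.po2 is None:
            continue
        fit = fit_po2_slope(ph.po2)
        mask = ph.po2.time_s >= ph.po2.time_s[0] + 120.0
        slope, intercept = _ols_oracle(ph.po2.time_s[mask], ph.po2.po2_pct_sat[mask])
        assert fit.slope_pct_sat_per_h == pytest.approx(slope * 3600, rel=1e-9)
        assert fit.intercept_pct_sat == pytest.approx(intercept, rel=1e-9)
    assert mo2_samples_from_trial(noise_free_trial_22)
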