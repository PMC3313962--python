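"""Cosinor fitting, synchronization degree, actograms, histograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clocknet import (LightSchedule, NetworkConfig, SimulationResult,
                      actogram, cosine_fit, default_tau_grid,
                      phase_period_histograms, population_summary,
                      sync_degree)
from clocknet.io import make_fixture
from clocknet.model import light_trace
from clocknet.rhythm import circular_mean_phase


def _cosine(t, M0, A, tau, phi):
    return M0 + A * np.cos(2 * np.pi * (t - phi) / tau)


def _as_result(times, traces, ld_days=5, dd_days=0):
    """Wrap an (N, T) trace bundle as a SimulationResult (PN channel)."""
    N, T = traces.shape
    states = np.zeros((N, 5, T))
    states[:, 4, :] = traces
    sch = LightSchedule(ld_days=ld_days, dd_days=dd_days)
    cfg = NetworkConfig(N=max(N, 2), schedule=sch, dt=0.01, seed=0)
    return SimulationResult(times=times, light=light_trace(times, sch),
                            states=states, config=cfg)


class TestCosineFit:
    @pytest.mark.parametrize("tau_true", [24.0, 23.75])
    def test_exact_recovery_on_grid(self, tau_true):
        t = np.arange(0.0, 120.0001, 0.1)
        fit = cosine_fit(t, _cosine(t, 2.0, 1.5, tau_true, 5.0))
        assert fit.tau == tau_true
        assert fit.M0 == pytest.approx(2.0, abs=1e-9)
        assert fit.A == pytest.approx(1.5, abs=1e-9)
        assert fit.phi == pytest.approx(5.0, abs=1e-9)

    def test_flat_series_flagged_not_crashed(self):
        t = np.arange(0.0, 120.0001, 0.1)
        fit = cosine_fit(t, np.full_like(t, 3.3))
        assert not fit.ok
        assert fit.A == 0.0 and np.isnan(fit.tau)

    def test_noisy_recovery_monte_carlo(self):
        """tau within one grid step and phi within 0.5 h in >= 95 % of
        noisy replicates (SD 0.1 on an amplitude-1.5 rhythm)."""
        t = np.arange(0.0, 120.0001, 0.1)
        clean = _cosine(t, 2.0, 1.5, 23.75, 5.0)
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            fit = cosine_fit(t, clean + rng.normal(0, 0.1, t.size))
            if abs(fit.tau - 23.75) <= 0.25 and abs(fit.phi - 5.0) <= 0.5:
                hits += 1
        assert hits >= 0.95 * n_rep

    @given(st.floats(-11.0, 11.0))
    @settings(deadline=None, max_examples=20)
    def test_phase_invariant_under_full_period_shift(self, phi0):
        t = np.arange(0.0, 120.0001, 0.25)
        a = cosine_fit(t, _cosine(t, 1.0, 1.0, 24.0, phi0))
        b = cosine_fit(t, _cosine(t, 1.0, 1.0, 24.0, phi0 + 24.0))
        assert a.phi == pytest.approx(b.phi, abs=1e-9)

    def test_rss_minimal_on_grid_vs_ols_oracle(self):
        """The returned period beats every other grid period when each
        sub-fit is done independently with statsmodels OLS."""
        import statsmodels.api as sm

        t = np.arange(0.0, 130.0, 0.5)
        rng = np.random.default_rng(7)
        y = _cosine(t, 2.0, 1.0, 25.0, 3.0) + rng.normal(0, 0.2, t.size)
        fit = cosine_fit(t, y)
        for tau in default_tau_grid():
            w = 2 * np.pi / tau
            X = sm.add_constant(np.column_stack([np.cos(w * t), np.sin(w * t)]))
            rss = float(sm.OLS(y, X).fit().ssr)
            assert fit.rss <= rss + 1e-8

    def test_short_window_rejected(self):
        t = np.arange(0.0, 50.0, 0.1)  # < 2 periods of the 32 h candidate
        with pytest.raises(ValueError):
            cosine_fit(t, np.sin(t))


class TestSyncDegree:
    def test_identical_traces_give_one(self):
        t = np.arange(0.0, 120.0, 0.1)
        x = np.tile(_cosine(t, 2, 1, 24, 0), (5, 1))
        assert sync_degree(x) == pytest.approx(1.0)

    def test_antiphase_pair_gives_zero(self):
        t = np.arange(0.0, 120.0, 0.1)
        x = np.vstack([_cosine(t, 2, 1, 24, 0), _cosine(t, 2, 1, 24, 12.0)])
        assert sync_degree(x) == pytest.approx(0.0, abs=1e-6)

    def test_independent_noise_scales_as_one_over_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (50, 5000))
        assert sync_degree(x) == pytest.approx(1 / 50, abs=0.01)

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    @settings(deadline=None, max_examples=20)
    def test_invariant_under_common_affine_map(self, a, b):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 48.0, 0.1)
        x = np.array([_cosine(t, 2, 1, 24, p) for p in (0, 1, 3)])
        x += rng.normal(0, 0.1, x.shape)
        assert sync_degree(a * x + b) == pytest.approx(sync_degree(x), rel=1e-9)

    def test_bounded_between_zero_and_one(self):
        rng = np.random.default_rng(9)
        t = np.arange(0.0, 48.0, 0.1)
        for trial in range(10):
            phases = rng.uniform(0, 24, 6)
            x = np.array([_cosine(t, 2, 1, 24, p) for p in phases])
            x += rng.normal(0, rng.uniform(0.01, 1.0), x.shape)
            r = sync_degree(x)
            assert -1e-9 <= r <= 1.0 + 1e-9

    def test_flat_ensemble_is_sentinel(self):
        assert np.isnan(sync_degree(np.ones((3, 100))))


class TestPopulationSummary:
    def test_procedures_agree_for_identical_neurons(self):
        t = np.arange(0.0, 120.0001, 0.1)
        traces = np.tile(_cosine(t, 2, 1, 24, 3.0), (4, 1))
        res = _as_result(t, traces)
        s1 = population_summary(res, "LD", "per-neuron-then-average")
        s2 = population_summary(res, "LD", "average-then-fit")
        assert s1.tau == s2.tau
        assert s1.phi == pytest.approx(s2.phi, abs=1e-9)

    def test_procedures_close_when_synchronized(self):
        t = np.arange(0.0, 120.0001, 0.1)
        rng = np.random.default_rng(1)
        phis = rng.normal(3.0, 0.3, 8)
        traces = np.array([_cosine(t, 2, 1, 24, p) for p in phis])
        traces += rng.normal(0, 0.05, traces.shape)
        res = _as_result(t, traces)
        s1 = population_summary(res, "LD", "per-neuron-then-average")
        s2 = population_summary(res, "LD", "average-then-fit")
        assert s1.R > 0.7
        assert abs(s1.tau - s2.tau) <= 0.25

    def test_desynchronized_mean_trace_loses_amplitude(self):
        t = np.arange(0.0, 120.0001, 0.1)
        phis = np.linspace(0, 24, 9, endpoint=False)
        traces = np.array([_cosine(t, 2, 1, 24, p) for p in phis])
        res = _as_result(t, traces)
        s2 = population_summary(res, "LD", "average-then-fit")
        mean_A = np.mean([f.A for f in s2.per_neuron])
        assert s2.ensemble_fit.A < 0.2 * mean_A

    def test_missing_condition_raises(self):
        t = np.arange(0.0, 120.0001, 0.1)
        res = _as_result(t, np.tile(_cosine(t, 2, 1, 24, 0), (3, 1)),
                         ld_days=5, dd_days=0)
        with pytest.raises(ValueError):
            population_summary(res, "DD")


class TestActogram:
    def test_shape_is_double_plotted_days(self):
        t = np.arange(0.0, 16 * 24.0, 0.1)
        mat = actogram(t, np.cos(t))
        assert mat.shape == (15, 2 * 240)

    def test_constant_series(self):
        t = np.arange(0.0, 5 * 24.0, 0.1)
        mat = actogram(t, np.full_like(t, 2.5))
        assert np.allclose(mat, 2.5)

    def test_24h_rhythm_has_no_drift(self):
        t = np.arange(0.0, 8 * 24.0, 0.1)
        mat = actogram(t, _cosine(t, 2, 1, 24, 6.0))
        for row in mat[1:]:
            np.testing.assert_allclose(row, mat[0], atol=1e-9)

    def test_25h_rhythm_drifts_one_hour_per_row(self):
        t = np.arange(0.0, 8 * 24.0, 0.1)
        mat = actogram(t, _cosine(t, 2, 1, 25.0, 2.0))
        # peak time within the first-day half moves +1 h per row
        peaks = [np.argmax(row[:240]) * 0.1 for row in mat[:5]]
        np.testing.assert_allclose(np.diff(peaks), 1.0, atol=0.15)

    def test_second_half_equals_next_first_half(self):
        t = np.arange(0.0, 4 * 24.0, 0.1)
        rng = np.random.default_rng(2)
        mat = actogram(t, rng.normal(size=t.size))
        np.testing.assert_allclose(mat[0, 240:], mat[1, :240])


class TestHistograms:
    def test_counts_conserved_and_single_bin_when_identical(self):
        t = np.arange(0.0, 120.0001, 0.1)
        traces = np.tile(_cosine(t, 2, 1, 24, 3.0), (6, 1))
        s = population_summary(_as_result(t, traces), "LD")
        (pe, pc), (te, tc) = phase_period_histograms(s)
        assert pc.sum() == 6 and tc.sum() == 6
        assert (pc > 0).sum() == 1 and (tc > 0).sum() == 1

    def test_counts_sum_to_population(self):
        times, traces, _ = make_fixture(
            "drifting_bundle", {"N": 7, "days": 6, "tau_sd": 0.5}, seed=3)
        s = population_summary(_as_result(times, traces, ld_days=5), "LD")
        (_, pc), (_, tc) = phase_period_histograms(s)
        assert pc.sum() == 7 and tc.sum() == 7


def test_circular_mean_handles_wraparound():
    phis = np.array([11.8, -11.9])  # adjacent across the +/-12 boundary
    m = circular_mean_phase(phis, 24.0)
    assert min(abs(m - 11.95), abs(m + 12.05)) < 0.2
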