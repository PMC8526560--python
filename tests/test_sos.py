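"""Second-order step-response model: closed form, fitting, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from types import SimpleNamespace

from nvckit.sos import (SecondOrderParams, fit_diagnostics, fit_step_response,
                        peak_ratio, step_response)

T_GRID = np.linspace(0.0, 40.0, 401)


def ode_step_response(p: SecondOrderParams, t: np.ndarray) -> np.ndarray:
    """Independent oracle: integrate y''/w^2 + 2 xi y'/w + y = K(u + Tv u').

    The impulsive ``Tv u'`` term is absorbed exactly into the initial
    velocity ``y'(0+) = K Tv w^2``.
    """
    w, xi = p.omega, p.xi

    def rhs(_t, s):
        return [s[1], w * w * (p.K - s[0]) - 2 * xi * w * s[1]]

    sol = solve_ivp(rhs, (t[0], t[-1]), [0.0, p.K * p.Tv * w * w],
                    t_eval=t, method="DOP853", rtol=1e-11, atol=1e-13)
    return sol.y[0]


def _relative_response(p, t=None, gfs=2.0):
    t = np.arange(-5 * gfs, 40 * gfs + 1) / gfs if t is None else t
    v = np.zeros_like(t)
    m = t >= 0
    v[m] = step_response(p, t[m])
    return SimpleNamespace(t=t, v_rel=v)


class TestStepResponse:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(K=st.floats(5, 40), Tv=st.floats(0, 1),
           omega=st.floats(0.05, 0.5), xi=st.floats(0.2, 1.5))
    def test_initial_and_final_value(self, K, Tv, omega, xi):
        p = SecondOrderParams(K, Tv, omega, xi)
        assert step_response(p, 0.0) == pytest.approx(0.0, abs=1e-12)
        t_inf = 60.0 / (xi * omega) if xi <= 1 else 60.0 * xi / omega
        assert step_response(p, t_inf) == pytest.approx(K, rel=1e-6, abs=1e-6)

    @pytest.mark.parametrize("xi", [0.2, 0.4, 0.7, 0.9])
    def test_analytic_percent_overshoot(self, xi):
        """For Tv=0, xi<1 the peak is K(1 + exp(-pi xi / sqrt(1-xi^2)))."""
        p = SecondOrderParams(K=1.0, Tv=0.0, omega=0.3, xi=xi)
        expected = 1 + np.exp(-np.pi * xi / np.sqrt(1 - xi * xi))
        assert peak_ratio(p, window_s=2 * np.pi / (0.3 * np.sqrt(1 - xi**2)) + 1
                          ) == pytest.approx(expected, rel=1e-3)

    def test_agrees_with_ode_at_realistic_parameters(self):
        # typical healthy-control point: K 17.3%, Tv 0.03 s, w 0.22, xi 0.5
        p = SecondOrderParams(K=17.3, Tv=0.03, omega=0.22, xi=0.5)
        diff = np.abs(step_response(p, T_GRID) - ode_step_response(p, T_GRID))
        assert diff.max() < 1e-6

    def test_branches_continuous_at_critical_damping(self):
        # unit gain so the bound measures branch continuity, not the
        # genuine O(K * dy/dxi * 1e-7) parameter sensitivity
        lo = SecondOrderParams(1.0, 0.1, 0.3, 1 - 1e-7)
        mid = SecondOrderParams(1.0, 0.1, 0.3, 1.0)
        hi = SecondOrderParams(1.0, 0.1, 0.3, 1 + 1e-7)
        y_lo, y_mid, y_hi = (step_response(p, T_GRID) for p in (lo, mid, hi))
        assert np.max(np.abs(y_lo - y_hi)) < 1e-6
        assert np.max(np.abs(y_lo - y_mid)) < 1e-6
        # and the critically damped curve itself matches the ODE oracle
        assert np.max(np.abs(y_mid - ode_step_response(mid, T_GRID))) < 1e-6

    def test_overdamped_is_monotone_without_zero(self):
        p = SecondOrderParams(K=20.0, Tv=0.0, omega=0.3, xi=2.5)
        y = step_response(p, T_GRID)
        assert np.all(np.diff(y) >= -1e-12)
        assert y.max() <= p.K + 1e-9

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError):
            SecondOrderParams(np.nan, 0.0, 0.2, 0.5)
        with pytest.raises(ValueError):
            SecondOrderParams(10.0, 0.0, -0.2, 0.5)


class TestFitStepResponse:
    @pytest.mark.parametrize("truth", [
        (15.0, 0.0, 0.20, 0.40),
        (17.3, 0.03, 0.22, 0.50),
        (8.0, 0.5, 0.10, 1.20),
        (35.0, 0.9, 0.45, 0.25),
        (20.0, 0.2, 0.05, 1.50),
    ])
    def test_noiseless_self_consistency(self, truth):
        p = SecondOrderParams(*truth)
        fit = fit_step_response(_relative_response(p))
        assert fit.converged
        got = fit.params.as_array()
        want = p.as_array()
        scale = np.maximum(np.abs(want), 1e-3)
        assert np.max(np.abs(got - want) / scale) < 1e-4
        assert fit.ssr < 1e-10

    def test_zero_response_has_zero_gain(self):
        p = SecondOrderParams(1.0, 0.0, 0.2, 0.5)
        resp = _relative_response(p)
        resp.v_rel[:] = 0.0
        fit = fit_step_response(resp)
        assert abs(fit.params.K) < 1e-6

    def test_homogeneity_scaling_scales_gain_only(self):
        p = SecondOrderParams(12.0, 0.1, 0.25, 0.6)
        base = fit_step_response(_relative_response(p)).params
        resp = _relative_response(p)
        resp.v_rel = 2.5 * resp.v_rel
        scaled = fit_step_response(resp).params
        assert scaled.K == pytest.approx(2.5 * base.K, rel=1e-4)
        assert scaled.omega == pytest.approx(base.omega, rel=1e-4)
        assert scaled.xi == pytest.approx(base.xi, rel=1e-4)

    def test_rate_time_boundary_solution_reported_as_zero(self):
        p = SecondOrderParams(20.0, 0.0, 0.2, 0.5)
        fit = fit_step_response(_relative_response(p))
        assert fit.params.Tv == pytest.approx(0.0, abs=1e-4)

    def test_deterministic_given_identical_inputs(self):
        p = SecondOrderParams(14.0, 0.2, 0.18, 0.45)
        f1 = fit_step_response(_relative_response(p), multi_start=True)
        f2 = fit_step_response(_relative_response(p), multi_start=True)
        assert f1.params == f2.params
        assert f1.ssr == f2.ssr


class TestFitDiagnostics:
    def test_perfect_fit_is_zero(self):
        obs = np.linspace(0, 10, 50)
        ssr, chi2 = fit_diagnostics(obs, obs, 1.0)
        assert ssr == 0.0 and chi2 == 0.0

    def test_constant_offset_algebra(self):
        n, c = 81, 0.7
        obs = np.zeros(n)
        ssr, chi2 = fit_diagnostics(obs + c, obs, 2.0)
        assert ssr == pytest.approx(n * c * c)
        assert chi2 == pytest.approx(n * c * c / 2.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            fit_diagnostics(np.zeros(5), np.zeros(6), 1.0)

    def test_chi2_calibrated_under_correct_model(self, rng):
        """When the model is the generator, chi2/n is ~1."""
        p = SecondOrderParams(20.0, 0.1, 0.22, 0.5)
        ratios = []
        for _ in range(10):
            resp = _relative_response(p)
            resp.v_rel = resp.v_rel + rng.normal(0, 0.9, resp.v_rel.size)
            fit = fit_step_response(resp)
            ratios.append(fit.chi2 / fit.n_points)
        assert 0.5 < np.mean(ratios) < 1.5
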