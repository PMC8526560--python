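"""Self-validation studies: model correctness and parameter recovery.

These routines exercise the package end to end against independent
references — numerical ODE integration for the closed-form step response,
the analytic percent-overshoot identity, and the synthetic generator's
ground truth for full-pipeline recovery — and return summary numbers.
They are what the acceptance script and the acceptance tests run.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np
from scipy import stats
from scipy.integrate import solve_ivp

from .nvc import StimulusProtocol, average_cycles, compute_overshoot
from .pipeline import PipelineConfig, analyze_nvc, analyze_vrco2
from .sos import SecondOrderParams, fit_step_response, step_response
from .synth import (DEFAULT_GROUPS, default_cohort_config,
                    draw_subject_truths, simulate_nvc_recording,
                    simulate_vrco2_recording, subject_seeds)

__all__ = [
    "ode_step_response",
    "forward_model_sweep",
    "overshoot_identity_error",
    "noiseless_recovery_sweep",
    "replicate_cohort_study",
    "averaging_noise_rms",
]

# Deterministic sweep grid spanning the fitting box, including the
# critically damped branch boundary xi = 1.
_SWEEP_K = (5.0, 20.0, 40.0)
_SWEEP_TV = (0.0, 0.5, 1.0)
_SWEEP_OMEGA = (0.05, 0.2, 0.5)
_SWEEP_XI = (0.2, 0.6, 1.0, 1.5)


def ode_step_response(p: SecondOrderParams, t: np.ndarray) -> np.ndarray:
    """Numerically integrate y''/w^2 + 2 xi y'/w + y = K (u + Tv u').

    Independent of the closed form: the impulsive ``Tv u'`` forcing is
    carried exactly by the initial condition ``y'(0+) = K Tv w^2``.
    """
    w, xi = p.omega, p.xi

    def rhs(_t, s):
        return [s[1], w * w * (p.K - s[0]) - 2.0 * xi * w * s[1]]

    sol = solve_ivp(rhs, (float(t[0]), float(t[-1])),
                    [0.0, p.K * p.Tv * w * w], t_eval=t,
                    method="DOP853", rtol=1e-11, atol=1e-13)
    return sol.y[0]


def forward_model_sweep(t_end: float = 40.0, n_t: int = 401) -> dict:
    """Max |closed form - ODE| over a 108-point sweep of the fit box."""
    t = np.linspace(0.0, t_end, n_t)
    worst = 0.0
    n = 0
    for K, Tv, w, xi in itertools.product(_SWEEP_K, _SWEEP_TV,
                                          _SWEEP_OMEGA, _SWEEP_XI):
        p = SecondOrderParams(K, Tv, w, xi)
        err = float(np.max(np.abs(step_response(p, t) - ode_step_response(p, t))))
        worst = max(worst, err)
        n += 1
    return {"max_abs_err": worst, "n_points": n}


def overshoot_identity_error(xi: float = 0.4, omega: float = 0.2,
                             K: float = 15.0) -> dict:
    """Simulated first peak vs the analytic identity K(1+e^{-pi xi/sqrt(1-xi^2)}).

    Valid for Tv = 0 and xi < 1; the peak is located by dense-grid
    maximization over one damped period.
    """
    p = SecondOrderParams(K=K, Tv=0.0, omega=omega, xi=xi)
    wd = omega * np.sqrt(1 - xi * xi)
    t = np.arange(0.0, 2 * np.pi / wd + 0.01, 0.001)
    peak = float(np.max(step_response(p, t)))
    analytic = K * (1.0 + np.exp(-np.pi * xi / np.sqrt(1 - xi * xi)))
    return {"peak": peak, "analytic": analytic,
            "rel_err": abs(peak - analytic) / analytic,
            "peak_ratio": peak / K}


def noiseless_recovery_sweep(seed: int, n_points: int = 40,
                             grid_fs: float = 2.0) -> dict:
    """Fit forward-simulated noiseless curves; max relative parameter error.

    Parameters are drawn uniformly over K in [5, 40], Tv in [0.05, 1],
    omega in [0.05, 0.5], xi in [0.2, 1.5] (a Tv = 0 boundary point is
    checked absolutely since its relative error is undefined).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(-5 * grid_fs, 40 * grid_fs + 1) / grid_fs
    m = t >= 0

    class _Resp:
        pass

    worst = 0.0
    for _ in range(n_points):
        p = SecondOrderParams(rng.uniform(5, 40), rng.uniform(0.05, 1),
                              rng.uniform(0.05, 0.5), rng.uniform(0.2, 1.5))
        r = _Resp()
        r.t, r.v_rel = t, np.where(m, step_response(p, np.maximum(t, 0)), 0.0)
        fit = fit_step_response(r)
        rel = np.max(np.abs(fit.params.as_array() - p.as_array())
                     / np.abs(p.as_array()))
        worst = max(worst, float(rel))
    # Tv = 0 boundary point, absolute error
    p0 = SecondOrderParams(15.0, 0.0, 0.2, 0.4)
    r = _Resp()
    r.t, r.v_rel = t, np.where(m, step_response(p0, np.maximum(t, 0)), 0.0)
    tv_abs = abs(fit_step_response(r).params.Tv)
    return {"max_rel_err": worst, "tv_boundary_abs_err": float(tv_abs),
            "n_points": n_points}


def replicate_cohort_study(seed: int, n_replicates: int = 20,
                           fs: float = 100.0) -> dict:
    """Recover omega and overshoot on replicate control vs HT-DM cohorts.

    Each replicate simulates 17 controls and 30 hypertensive-diabetic
    subjects with the group generative defaults, runs the full pipeline
    per subject, and records cohort means of the recovered natural
    frequency and overshoot plus the Welch two-sample test of the
    control-vs-HT-DM difference in recovered omega.
    """
    pcfg = PipelineConfig()
    om_means = {"control": [], "HT-DM": []}
    ov_means = {"control": [], "HT-DM": []}
    detected = 0
    rep_seeds = [int(s.generate_state(1)[0] % (2**31))
                 for s in np.random.SeedSequence(seed).spawn(n_replicates)]
    for rs in rep_seeds:
        cfg = default_cohort_config(seed=rs, n_per_group=(17, 0, 30), fs=fs)
        truths = draw_subject_truths(cfg)
        seeds = subject_seeds(cfg, 2 * len(truths))
        om = {"control": [], "HT-DM": []}
        ov = {"control": [], "HT-DM": []}
        for i, tr in enumerate(truths):
            rec, ev = simulate_nvc_recording(tr, cfg.protocol, fs=cfg.fs,
                                             seed=seeds[2 * i])
            res = analyze_nvc(rec, ev, pcfg)
            om[tr.group].append(res.fit.params.omega)
            ov[tr.group].append(res.overshoot_pct)
        for g in om:
            om_means[g].append(np.mean(om[g]))
            ov_means[g].append(np.mean(ov[g]))
        p = stats.ttest_ind(om["control"], om["HT-DM"], equal_var=False).pvalue
        detected += p < 0.05
    g = DEFAULT_GROUPS
    return {
        "control_omega_mean": float(np.mean(om_means["control"])),
        "htdm_omega_mean": float(np.mean(om_means["HT-DM"])),
        "control_overshoot_mean": float(np.mean(ov_means["control"])),
        "htdm_overshoot_mean": float(np.mean(ov_means["HT-DM"])),
        "detection_rate": detected / n_replicates,
        "n_replicates": n_replicates,
        "generative": {
            "control_omega": g["control"].omega_mean,
            "htdm_omega": g["HT-DM"].omega_mean,
            "control_overshoot": g["control"].overshoot_mean,
            "htdm_overshoot": g["HT-DM"].overshoot_mean,
            "control_omega_2se": 2 * g["control"].omega_sd / np.sqrt(17),
            "htdm_omega_2se": 2 * g["HT-DM"].omega_sd / np.sqrt(30),
            "control_overshoot_2se": 2 * g["control"].overshoot_sd / np.sqrt(17),
            "htdm_overshoot_2se": 2 * g["HT-DM"].overshoot_sd / np.sqrt(30),
        },
    }


def averaging_noise_rms(seed: int, noise_sd_pct: float = 3.0,
                        n_cycles: int = 10, grid_fs: float = 2.0) -> dict:
    """RMS deviation of the 10-cycle average from truth under 3% noise.

    Per-cycle zero-mean Gaussian noise of ``noise_sd_pct`` on the absolute
    systolic curves should shrink by ~sqrt(n_cycles) on averaging.
    """
    from .nvc import CycleSegment

    rng = np.random.default_rng(seed)
    proto = StimulusProtocol(n_cycles=n_cycles)
    p = SecondOrderParams(15.0, 0.0, 0.2, 0.4)
    t = np.arange(-proto.baseline_s * grid_fs,
                  proto.stim_s * grid_fs + 1) / grid_fs
    y = np.where(t >= 0, step_response(p, np.maximum(t, 0)), 0.0)
    baseline = 40.0
    truth_abs = baseline * (1 + y / 100.0)
    # additive noise of noise_sd_pct points on the relative curve
    segments = [
        CycleSegment(t=t.copy(),
                     v_abs=truth_abs + baseline * rng.normal(
                         0, noise_sd_pct / 100, t.size),
                     onset_s=proto.rest_s + k * proto.cycle_s)
        for k in range(n_cycles)
    ]
    avg = average_cycles(segments, proto)
    rms = float(np.sqrt(np.mean((avg.v_rel - y) ** 2)))
    return {"rms_pct": rms, "n_cycles": n_cycles,
            "noise_sd_pct": noise_sd_pct}


def vrco2_recovery(seed: int, slope_true: float = 1.4, fs: float = 200.0) -> dict:
    """Noiseless end-to-end VRCO2 slope recovery on one synthetic session."""
    truth = replace(
        draw_subject_truths(default_cohort_config(seed=seed,
                                                  n_per_group=(1, 0, 0)))[0],
        vrco2_slope_true=slope_true, noise_sd_pct=0.0, artifact_rate=0.0)
    rec, ev = simulate_vrco2_recording(truth, seed=seed, fs=fs)
    res = analyze_vrco2(rec, ev)
    return {"slope": res.slope, "slope_true": slope_true, "r2": res.r2}
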