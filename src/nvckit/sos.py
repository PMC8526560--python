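"""Second-order linear-system model of the evoked CBFV step response.

The neurovascular coupling response of relative systolic CBFV to a visual
stimulus is modelled as the step response of a second-order transfer
function with one zero,

    G(s) = K (1 + Tv s) / (s^2/omega^2 + 2 xi s/omega + 1),

where ``K`` is the gain (steady-state relative CBFV change, %), ``Tv`` the
rate time (s, controls the initial steepness), ``omega`` the natural
frequency (s^-1, conventionally labelled "Hz" in the TCD literature without
a 2*pi conversion) and ``xi`` the attenuation (dimensionless damping
ratio).  Parameters are estimated by bounded nonlinear least squares on the
stimulus-locked grand-average response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SecondOrderParams",
    "SecondOrderFit",
    "step_response",
    "peak_ratio",
    "fit_step_response",
    "fit_diagnostics",
    "DEFAULT_BOUNDS",
]

# Parameter box for the fit: (lower, upper) for (K, Tv, omega, xi).
# Wide enough to cover all group values reported for healthy and
# hypertensive adults with ample margin.
DEFAULT_BOUNDS = ((-50.0, 0.0, 0.01, 0.05), (100.0, 10.0, 2.0, 3.0))

# Fixed multi-start grid over (omega0, xi0); used when multi_start=True.
_START_GRID = ((0.1, 0.3), (0.1, 1.2), (0.3, 0.3), (0.3, 0.7), (0.5, 1.0))


@dataclass(frozen=True)
class SecondOrderParams:
    """Parameters of the second-order model with zero.

    Attributes
    ----------
    K : float
        Gain: steady-state relative CBFV change, in %.
    Tv : float
        Rate time, in s.  ``Tv >= 0``; boundary solutions at exactly 0 are
        physiologically meaningful (no zero term).
    omega : float
        Natural frequency, in s^-1.  Reported under the "Hz" label in the
        TCD literature; no 2*pi conversion is applied.
    xi : float
        Attenuation (damping ratio), dimensionless, > 0.
    """

    K: float
    Tv: float
    omega: float
    xi: float

    def __post_init__(self) -> None:
        vals = (self.K, self.Tv, self.omega, self.xi)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite second-order parameters: {vals}")
        if self.omega <= 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")
        if self.xi <= 0:
            raise ValueError(f"xi must be > 0, got {self.xi}")
        if self.Tv < 0:
            raise ValueError(f"Tv must be >= 0, got {self.Tv}")

    def as_array(self) -> np.ndarray:
        return np.array([self.K, self.Tv, self.omega, self.xi], dtype=float)


@dataclass(frozen=True)
class SecondOrderFit:
    """Result of fitting the second-order model to an averaged response."""

    params: SecondOrderParams
    ssr: float
    chi2: float
    converged: bool
    n_points: int
    fit_window_s: tuple[float, float]
    model: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def step_response(p: SecondOrderParams, t: Sequence[float] | np.ndarray) -> np.ndarray:
    """Closed-form response of ``G(s)`` to a unit step applied at t = 0.

    The underdamped, critically damped and overdamped regimes are evaluated
    through one complex-exponential formulation, which is continuous across
    the ``xi = 1`` branch boundary to machine precision and overflow-free
    for strongly overdamped systems (both characteristic exponents have
    negative real part, so only decaying exponentials are formed).

    With ``a = xi*omega`` and ``wd = omega*sqrt(1 - xi^2)`` (imaginary when
    overdamped), the no-zero step response is
    ``y0 = K [1 - e^{-a t}(cos(wd t) + a sin(wd t)/wd)]`` and the zero adds
    ``Tv * y0'``, giving ``y = K [1 - ec - (a - Tv omega^2) es]`` where
    ``ec = e^{-a t} cos(wd t)`` and ``es = e^{-a t} sin(wd t)/wd``.

    Satisfies ``y(0) = 0`` and ``y -> K`` as ``t -> inf``.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if t.size and t[0] < 0:
        raise ValueError("step_response requires t >= 0")
    a = p.xi * p.omega
    wd = p.omega * np.sqrt(complex(1.0 - p.xi * p.xi))
    e1 = np.exp((-a + 1j * wd) * t)
    e2 = np.exp((-a - 1j * wd) * t)
    ec = 0.5 * (e1 + e2)
    t_max = float(t[-1]) if t.size else 0.0
    if abs(wd) * t_max < 1e-3:
        # sin(wd t)/wd -> t (1 - (wd t)^2/6): stable through wd = 0.
        z2 = (wd * t) ** 2
        es = t * np.exp(-a * t) * (1.0 - z2 / 6.0)
    else:
        es = (e1 - e2) / (2j * wd)
    y = p.K * (1.0 - ec - (a - p.Tv * p.omega**2) * es)
    y = np.real(y)
    return float(y[0]) if scalar else y


def peak_ratio(p: SecondOrderParams, window_s: float = 40.0, dt: float = 0.005) -> float:
    """Maximum of the unit-gain step response over ``(0, window_s]``.

    For ``Tv = 0`` and ``xi < 1`` this converges to the classical
    percent-overshoot identity ``1 + exp(-pi*xi/sqrt(1-xi^2))`` when the
    first oscillation peak falls inside the window.  Used by the synthetic
    generator to translate an overshoot target into a gain.
    """
    unit = SecondOrderParams(K=1.0, Tv=p.Tv, omega=p.omega, xi=p.xi)
    t = np.arange(dt, window_s + dt / 2, dt)
    return float(np.max(step_response(unit, t)))


def _fit_once(
    x0: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    t: np.ndarray,
    y: np.ndarray,
):
    def resid(x: np.ndarray) -> np.ndarray:
        return step_response(SecondOrderParams(*x), t) - y

    return least_squares(
        resid, x0, bounds=(lb, ub), method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
    )


def fit_step_response(
    resp,
    init: SecondOrderParams | None = None,
    bounds: tuple[Sequence[float], Sequence[float]] = DEFAULT_BOUNDS,
    multi_start: bool = False,
) -> SecondOrderFit:
    """Least-squares fit of the second-order model to an averaged response.

    Parameters
    ----------
    resp
        An :class:`~nvckit.nvc.AveragedResponse` (or any object with ``t``
        in s relative to stimulus onset and ``v_rel`` in %).  Only the
        stimulation window ``t >= 0`` enters the fit; pre-stimulus samples
        define the zero level and supply the noise scale for ``chi2``.
    init
        Optional starting point.  By default ``K0`` is the mean response
        over the last 10 s of stimulation and ``(Tv0, omega0, xi0) =
        (0.1, 0.2, 0.5)``.
    bounds
        Parameter box ``(lower, upper)`` for ``(K, Tv, omega, xi)``.
    multi_start
        Refit from a small fixed grid of ``(omega0, xi0)`` starting points
        and keep the lowest-SSR solution.  Deterministic.

    Never raises on valid input: optimizer failure is reported through
    ``converged=False``, in which case the parameters must be treated as
    missing by downstream consumers.
    """
    t = np.asarray(resp.t, dtype=float)
    v = np.asarray(resp.v_rel, dtype=float)
    mask = t >= 0.0
    tf, yf = t[mask], v[mask]
    if tf.size < 5:
        raise ValueError("averaged response must cover the stimulation window")

    lb = np.asarray(bounds[0], dtype=float)
    ub = np.asarray(bounds[1], dtype=float)
    if init is None:
        tail = tf >= tf[-1] - 10.0
        k0 = float(np.clip(np.mean(yf[tail]), lb[0], ub[0]))
        x0 = np.array([k0, 0.1, 0.2, 0.5])
    else:
        x0 = np.clip(init.as_array(), lb, ub)
    # keep strictly inside the box so trf can move in every direction
    eps = 1e-9 * (ub - lb)
    x0 = np.clip(x0, lb + eps, ub - eps)

    starts = [x0]
    if multi_start:
        for w0, xi0 in _START_GRID:
            s = x0.copy()
            s[2], s[3] = w0, xi0
            starts.append(np.clip(s, lb + eps, ub - eps))

    best = None
    converged = False
    for s in starts:
        try:
            sol = _fit_once(s, lb, ub, tf, yf)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
            converged = bool(sol.success)
    if best is None:
        params = SecondOrderParams(0.0, 0.0, 0.2, 0.5)
        return SecondOrderFit(params, math.inf, math.nan, False, tf.size,
                              (float(tf[0]), float(tf[-1])), np.full_like(tf, np.nan))

    params = SecondOrderParams(*best.x)
    model = step_response(params, tf)
    pre = v[~mask]
    base_var = float(np.var(pre, ddof=1)) if pre.size >= 2 else 0.0
    ssr, chi2 = fit_diagnostics(yf, model, base_var if base_var > 0 else math.nan)
    return SecondOrderFit(
        params=params, ssr=ssr, chi2=chi2, converged=converged,
        n_points=int(tf.size), fit_window_s=(float(tf[0]), float(tf[-1])),
        model=model,
    )


def fit_diagnostics(
    observed: Sequence[float] | np.ndarray,
    modeled: Sequence[float] | np.ndarray,
    baseline_resid_var: float,
) -> tuple[float, float]:
    """Sum of squared residuals and normalized chi-square goodness of fit.

    ``ssr = sum((obs - mod)^2)``; ``chi2 = ssr / baseline_resid_var`` with
    the variance of the averaged signal in the pre-stimulus window as the
    noise-scale estimate.  ``baseline_resid_var`` may be NaN (noise-free
    input), in which case ``chi2`` is NaN.
    """
    obs = np.asarray(observed, dtype=float)
    mod = np.asarray(modeled, dtype=float)
    if obs.shape != mod.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {mod.shape}")
    if obs.size < 2:
        raise ValueError("need at least 2 points")
    ssr = float(np.sum((obs - mod) ** 2))
    if math.isnan(baseline_resid_var):
        return ssr, math.nan
    if baseline_resid_var <= 0:
        raise ValueError("baseline_resid_var must be > 0")
    return ssr, ssr / baseline_resid_var
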