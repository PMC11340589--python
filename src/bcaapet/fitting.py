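"""Estimation of two-tissue kinetic parameters from measured TACs.

The forward model (``solve_2tc`` + ``frame_average``) is fitted to a
frame-averaged time-activity curve by bounded weighted nonlinear least
squares with Latin-hypercube multi-start, since the 4-parameter surface
(K1, k2, k3, vb) can carry local minima.  The net uptake rate Ki is always
derived from the fitted micro-parameters, never fitted directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares
from scipy.stats import qmc

from .errors import ConfigurationError, NonConvergenceError
from .kinetic import (
    DEFAULT_DT_S,
    FrameSchedule,
    KineticParameters,
    PlasmaInputFunction,
    TimeActivityCurve,
    _forward_compartments,
    default_grid,
    macro_ki,
)

__all__ = ["FitOptions", "FitResult", "fit_tac", "frame_weights", "goodness_of_fit"]

#: Generous physiologic bounds for adipose tissue and skeletal muscle.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "K1": (0.0, 2.0),      # mL/min/cm^3
    "k2": (1e-6, 5.0),     # 1/min; tiny floor keeps Ki defined
    "k3": (0.0, 2.0),      # 1/min
    "vb": (0.0, 0.3),      # mL/mL
}

_PARAM_ORDER = ("K1", "k2", "k3", "vb")


@dataclass(frozen=True)
class FitOptions:
    """Configuration of the TAC fit.

    ``weighting`` is "uniform" (default) or "duration_over_value" (a
    count-statistics proxy giving long, low-activity frames more
    influence).
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    weighting: str = "uniform"
    n_starts: int = 10
    seed: int = 0
    tol: float = 1e-8
    dt_s: float = DEFAULT_DT_S
    weight_eps: float = 1e-6

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"bound for {name} has lower > upper")


@dataclass(frozen=True)
class FitResult:
    """Best fit over all restarts."""

    params: KineticParameters
    ki: float
    wrss: float
    converged: bool
    n_restarts_used: int
    per_param_se: dict[str, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "K1": self.params.K1,
            "k2": self.params.k2,
            "k3": self.params.k3,
            "vb": self.params.vb,
            "ki": self.ki,
            "wrss": self.wrss,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
        }
        if self.per_param_se is not None:
            d["per_param_se"] = dict(self.per_param_se)
        return d


def frame_weights(
    schedule: FrameSchedule,
    tac: TimeActivityCurve,
    scheme: str = "uniform",
    eps: float = 1e-6,
) -> np.ndarray:
    """Per-frame fit weights, normalized to mean 1.

    "uniform": all ones.  "duration_over_value": dt_i / max(value_i, eps),
    the usual variance proxy for frame-averaged counts (variance of a frame
    mean scales like value/duration).
    """
    if scheme == "uniform":
        return np.ones(schedule.n_frames)
    if scheme == "duration_over_value":
        w = schedule.durations_min / np.maximum(tac.values, eps)
        return w / w.mean()
    raise ConfigurationError(f"unknown weighting scheme: {scheme!r}")


class _ForwardCache:
    """Precomputed input samples and frame-integration operator.

    Sampling the input function and locating frame boundaries once per fit
    makes a single objective evaluation a pair of O(n) filters plus a small
    matrix product.
    """

    def __init__(
        self,
        schedule: FrameSchedule,
        input_fn: PlasmaInputFunction,
        dt_s: float,
    ):
        self.schedule = schedule
        self.t = default_grid(schedule, dt_s)
        self.h = float(self.t[1] - self.t[0])
        self.cp = input_fn.cp(self.t)
        self.cb = input_fn.cb(self.t)
        self._starts = schedule.frames[:, 0] / 60.0
        self._ends = schedule.frames[:, 1] / 60.0
        self._dur = self._ends - self._starts

    def frame_means(self, theta: np.ndarray) -> np.ndarray:
        K1, k2, k3, vb = theta
        cf, cc = _forward_compartments(K1, k2, k3, self.cp, self.h)
        ct = vb * self.cb + (1.0 - vb) * (cf + cc)
        cum = np.concatenate([[0.0], cumulative_trapezoid(ct, self.t)])
        ia = np.interp(self._starts, self.t, cum)
        ib = np.interp(self._ends, self.t, cum)
        return (ib - ia) / self._dur


def _lhs_starts(bounds: np.ndarray, n: int, seed: int) -> np.ndarray:
    sampler = qmc.LatinHypercube(d=bounds.shape[0], seed=seed)
    u = sampler.random(n)
    return qmc.scale(u, bounds[:, 0], bounds[:, 1])


def fit_tac(
    tac: TimeActivityCurve,
    input_fn: PlasmaInputFunction,
    opts: FitOptions | None = None,
) -> FitResult:
    """Fit (K1, k2, k3, vb) to a measured TAC.

    Runs ``opts.n_starts`` bounded least-squares solves from Latin-hypercube
    starting points (deterministic per ``opts.seed``) and keeps the solution
    with the lowest weighted residual sum of squares; ties break on the
    lexicographically smallest (K1, k2, k3, vb).

    Raises
    ------
    NonConvergenceError
        If every restart fails; carries the best-effort result.
    """
    if opts is None:
        opts = FitOptions()
    values = np.asarray(tac.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("TAC contains non-finite values")
    noise_floor = 0.05 * np.max(np.abs(values)) if values.size else 0.0
    if np.any(values < -noise_floor):
        warnings.warn(
            "TAC contains negative values beyond the noise floor", UserWarning
        )

    cache = _ForwardCache(tac.schedule, input_fn, opts.dt_s)
    w = frame_weights(tac.schedule, tac, opts.weighting, opts.weight_eps)
    sqrt_w = np.sqrt(w)
    bounds = np.array([opts.bounds[p] for p in _PARAM_ORDER], dtype=float)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return sqrt_w * (cache.frame_means(theta) - values)

    starts = _lhs_starts(bounds, opts.n_starts, opts.seed)
    best = None  # (wrss, theta tuple, result)
    any_ok = False
    for x0 in starts:
        try:
            res = least_squares(
                residuals,
                x0,
                bounds=(bounds[:, 0], bounds[:, 1]),
                method="trf",
                xtol=opts.tol,
                ftol=opts.tol,
                gtol=opts.tol,
            )
        except Exception:
            continue
        any_ok = any_ok or res.success
        wrss = float(2.0 * res.cost)
        key = (wrss, tuple(res.x))
        if best is None or key < (best[0], best[1]):
            best = (wrss, tuple(res.x), res)

    if best is None:
        raise NonConvergenceError("all restarts raised", best_result=None)

    wrss, theta, res = best
    params = KineticParameters(K1=theta[0], k2=theta[1], k3=theta[2], vb=theta[3])
    se = _parameter_se(res.jac, wrss, values.size)
    result = FitResult(
        params=params,
        ki=macro_ki(params),
        wrss=wrss,
        converged=any_ok,
        n_restarts_used=opts.n_starts,
        per_param_se=se,
    )
    if not any_ok:
        raise NonConvergenceError("no restart converged", best_result=result)
    return result


def _parameter_se(jac: np.ndarray, wrss: float, n: int) -> dict[str, float] | None:
    p = jac.shape[1]
    if n <= p:
        return None
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj) * (wrss / (n - p))
    except np.linalg.LinAlgError:
        return None
    diag = np.diag(cov)
    if np.any(diag < 0):
        return None
    return {name: float(np.sqrt(d)) for name, d in zip(_PARAM_ORDER, diag)}


def goodness_of_fit(
    tac: TimeActivityCurve,
    fit: FitResult,
    input_fn: PlasmaInputFunction,
    opts: FitOptions | None = None,
) -> tuple[float, float]:
    """Recompute (wrss, aic) for a fit on a TAC.

    AIC = n*ln(wrss/n) + 2p with p = 4 fitted parameters; -inf for an exact
    fit (wrss == 0).
    """
    if opts is None:
        opts = FitOptions()
    cache = _ForwardCache(tac.schedule, input_fn, opts.dt_s)
    w = frame_weights(tac.schedule, tac, opts.weighting, opts.weight_eps)
    pred = cache.frame_means(fit.params.as_array())
    wrss = float(np.sum(w * (pred - tac.values) ** 2))
    n = tac.values.size
    p = 4
    aic = n * np.log(wrss / n) + 2 * p if wrss > 0 else -np.inf
    return wrss, float(aic)


def refit_options_with_seed(opts: FitOptions, seed: int) -> FitOptions:
    """Copy of ``opts`` with a new multi-start seed."""
    return replace(opts, seed=seed)
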