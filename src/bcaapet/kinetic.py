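"""Irreversible two-tissue compartment model for dynamic PET.

The tracer (an L-leucine analog taken up by amino-acid transporters) moves
from arterial blood into a free tissue compartment ``Cf`` with delivery rate
``K1`` (mL/min/cm^3) and back out with rate constant ``k2`` (1/min); from
``Cf`` it is transferred irreversibly (``k4 = 0``) into a contained
compartment ``Cc`` with rate constant ``k3`` (1/min):

    dCf/dt = K1*Cp(t) - (k2 + k3)*Cf(t)
    dCc/dt = k3*Cf(t)

The measurable PET concentration mixes tissue and intravascular signal,

    CT(t) = vb*Cb(t) + (1 - vb)*(Cf(t) + Cc(t)),

with ``vb`` the fractional blood volume (mL/mL).  The macro-parameter of
interest is the net uptake (influx) rate ``Ki = K1*k3/(k2 + k3)``
(mL/min/cm^3), the steady-state clearance of tracer from blood to tissue.

All times are minutes internally; frame schedules are stored in seconds and
converted on use.  Concentrations are kBq/mL and assumed decay-corrected to
injection time, so no physical-decay term appears in the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

from .errors import (
    CoverageError,
    InsufficientDataError,
    InvalidGridError,
    InvalidInputError,
    UndefinedRatioError,
)

__all__ = [
    "KineticParameters",
    "PlasmaInputFunction",
    "TissueCurves",
    "FrameSchedule",
    "TimeActivityCurve",
    "solve_2tc",
    "macro_ki",
    "frame_average",
    "patlak_estimate",
    "default_grid",
    "DEFAULT_DT_S",
]

#: Default fine-grid step for the forward model, seconds.  One tenth of the
#: shortest (5 s) frame; the exponential update below is unconditionally
#: stable, so the step only controls input-sampling resolution.
DEFAULT_DT_S = 0.5


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the irreversible two-tissue model.

    Attributes
    ----------
    K1 : float
        Delivery rate blood -> free compartment, mL/min per cm^3 tissue.
    k2 : float
        Efflux rate constant free compartment -> blood, 1/min.
    k3 : float
        Free -> contained transfer rate constant, 1/min.
    vb : float
        Fractional blood volume, mL blood per mL tissue, in [0, 1).
    k4 : float
        Return rate from the contained compartment; fixed at 0 (irreversible
        trapping).
    """

    K1: float
    k2: float
    k3: float
    vb: float = 0.0
    k4: float = field(default=0.0)

    def __post_init__(self):
        if self.K1 < 0 or self.k2 < 0 or self.k3 < 0:
            raise ValueError("rate constants must be nonnegative")
        if not (0.0 <= self.vb < 1.0):
            raise ValueError("vb must satisfy 0 <= vb < 1")
        if self.k4 != 0.0:
            raise ValueError("model is irreversible: k4 must be 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.k3, self.vb], dtype=float)


def macro_ki(params: KineticParameters) -> float:
    """Net uptake rate Ki = K1*k3/(k2+k3), mL/min per cm^3.

    Raises
    ------
    UndefinedRatioError
        If k2 + k3 == 0, where the ratio is undefined.
    """
    denom = params.k2 + params.k3
    if denom == 0.0:
        raise UndefinedRatioError("Ki undefined when k2 + k3 == 0")
    return params.K1 * params.k3 / denom


class PlasmaInputFunction:
    """Evaluable plasma (Cp) and whole-blood (Cb) tracer concentration.

    By default ``Cb == Cp``: the image-derived aorta curve is fed directly as
    the plasma input with no plasma-to-blood correction, which is the
    convention this model adopts.  A constant plasma/whole-blood ratio may be
    supplied to derive ``Cb = Cp / ratio``.
    """

    def __init__(
        self,
        cp: Callable[[np.ndarray], np.ndarray],
        cb: Callable[[np.ndarray], np.ndarray] | None = None,
        plasma_to_blood_ratio: float | None = None,
    ):
        self._cp = cp
        if cb is not None:
            self._cb = cb
        elif plasma_to_blood_ratio is not None:
            if plasma_to_blood_ratio <= 0:
                raise ValueError("plasma_to_blood_ratio must be positive")
            r = float(plasma_to_blood_ratio)
            self._cb = lambda t: np.asarray(cp(t)) / r
        else:
            self._cb = cp

    def cp(self, t) -> np.ndarray:
        """Plasma concentration at time t (min), kBq/mL."""
        return np.asarray(self._cp(np.asarray(t, dtype=float)), dtype=float)

    def cb(self, t) -> np.ndarray:
        """Whole-blood concentration at time t (min), kBq/mL."""
        return np.asarray(self._cb(np.asarray(t, dtype=float)), dtype=float)

    @classmethod
    def from_table(cls, t_min: Sequence[float], cp: Sequence[float]) -> "PlasmaInputFunction":
        """Linear interpolation through tabulated (t, Cp) samples."""
        t = np.asarray(t_min, dtype=float)
        c = np.asarray(cp, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("t_min must be strictly increasing with >= 2 samples")
        if np.any(c < 0):
            raise InvalidInputError("tabulated Cp contains negative values")
        return cls(lambda x: np.interp(x, t, c))

    @classmethod
    def from_json(cls, spec) -> "PlasmaInputFunction":
        """Build from a JSON spec: {"model": "feng", "params": [...]}, or
        {"model": "tabulated", "t_min": [...], "cp": [...]}.  ``spec`` may be
        a dict, a JSON string, or a path to a JSON file."""
        if isinstance(spec, (str, bytes)):
            s = spec.decode() if isinstance(spec, bytes) else spec
            if s.lstrip().startswith("{"):
                spec = json.loads(s)
            else:
                with open(s) as fh:
                    spec = json.load(fh)
        model = spec.get("model")
        if model == "tabulated":
            return cls.from_table(spec["t_min"], spec["cp"])
        if model == "feng":
            from .synthetic import FengInputParams, feng_input

            return feng_input(FengInputParams(*spec["params"]))
        raise ValueError(f"unknown input-function model: {model!r}")


@dataclass(frozen=True)
class TissueCurves:
    """Continuous-time model output on a fine grid (times in minutes)."""

    t: np.ndarray
    cf: np.ndarray
    cc: np.ndarray
    ct_total: np.ndarray


@dataclass(frozen=True)
class FrameSchedule:
    """Reconstruction frame schedule: contiguous (start_s, end_s) intervals."""

    frames: np.ndarray  # shape (n, 2), seconds post-injection

    def __post_init__(self):
        f = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", f)
        if f.ndim != 2 or f.shape[1] != 2 or f.shape[0] == 0:
            raise ValueError("frames must be a non-empty (n, 2) array")
        if f[0, 0] != 0.0:
            raise ValueError("schedule must start at 0 s")
        if np.any(f[:, 1] <= f[:, 0]):
            raise ValueError("each frame must have end > start")
        if not np.allclose(f[1:, 0], f[:-1, 1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @classmethod
    def canonical(cls) -> "FrameSchedule":
        """The dynamic protocol: 12x5 s, 3x10 s, 3x30 s, 6x60 s, 8x120 s
        (32 frames, 25 min total)."""
        durations = np.repeat([5.0, 10.0, 30.0, 60.0, 120.0], [12, 3, 3, 6, 8])
        ends = np.cumsum(durations)
        starts = ends - durations
        return cls(np.column_stack([starts, ends]))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def durations_s(self) -> np.ndarray:
        return self.frames[:, 1] - self.frames[:, 0]

    @property
    def durations_min(self) -> np.ndarray:
        return self.durations_s / 60.0

    @property
    def mid_times_min(self) -> np.ndarray:
        return (self.frames[:, 0] + self.frames[:, 1]) / 2.0 / 60.0

    @property
    def total_span_s(self) -> float:
        return float(self.frames[-1, 1])

    @property
    def total_span_min(self) -> float:
        return self.total_span_s / 60.0


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged tissue concentration with mid-frame timestamps."""

    schedule: FrameSchedule
    values: np.ndarray  # kBq/mL, one per frame

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.schedule.n_frames,):
            raise ValueError("values must have one entry per frame")

    @property
    def mid_times(self) -> np.ndarray:
        """Frame midpoints in minutes."""
        return self.schedule.mid_times_min

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_start_s": self.schedule.frames[:, 0],
                "frame_end_s": self.schedule.frames[:, 1],
                "mid_time_min": self.mid_times,
                "conc_kBq_per_mL": self.values,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeActivityCurve":
        df = pd.read_csv(path)
        required = {"frame_start_s", "frame_end_s", "mid_time_min", "conc_kBq_per_mL"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"TAC CSV missing columns: {sorted(missing)}")
        schedule = FrameSchedule(
            np.column_stack([df["frame_start_s"].to_numpy(), df["frame_end_s"].to_numpy()])
        )
        return cls(schedule, df["conc_kBq_per_mL"].to_numpy(dtype=float))


def default_grid(schedule: FrameSchedule, dt_s: float = DEFAULT_DT_S) -> np.ndarray:
    """Uniform time grid (minutes) spanning the schedule with step dt_s."""
    n_steps = int(round(schedule.total_span_s / dt_s))
    return np.linspace(0.0, n_steps * dt_s / 60.0, n_steps + 1)


def _phi_coefficients(a: float, h: float) -> tuple[float, float, float, float]:
    """Exact step coefficients for the linear compartment update.

    Returns (alpha, E1, F, G2) with alpha = exp(-a h),
    E1 = int_0^h e^{-a s} ds, F = int_0^h s-weighted kernel = (h - E1)/a,
    G2 = (h^2/2 - F)/a, switching to Taylor series for a*h << 1 to avoid
    cancellation.
    """
    x = a * h
    if x > 1e-4:
        alpha = np.exp(-x)
        e1 = -np.expm1(-x) / a
        f = (h - e1) / a
        g2 = (h * h / 2.0 - f) / a
    else:
        alpha = np.exp(-x)
        e1 = h * (1.0 - x / 2.0 + x * x / 6.0 - x**3 / 24.0)
        f = h * h * (0.5 - x / 6.0 + x * x / 24.0 - x**3 / 120.0)
        g2 = h**3 * (1.0 / 6.0 - x / 24.0 + x * x / 120.0 - x**3 / 720.0)
    return alpha, e1, f, g2


def _forward_compartments(
    K1: float, k2: float, k3: float, cp: np.ndarray, h: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cf and Cc on a uniform grid, given Cp samples on that grid.

    The input is treated as piecewise linear between samples; for that input
    class the exponential update is exact (up to roundoff), so the scheme is
    unconditionally stable at any step.
    """
    n = cp.size
    cf = np.zeros(n)
    cc = np.zeros(n)
    if n < 2 or K1 == 0.0:
        if K1 == 0.0:
            return cf, cc
        raise InvalidGridError("grid must contain at least 2 points")
    a = k2 + k3
    alpha, e1, f, g2 = _phi_coefficients(a, h)
    c0 = cp[:-1]
    m = np.diff(cp) / h
    beta = K1 * (c0 * e1 + m * f)
    # Cf_{j+1} = alpha*Cf_j + beta_j, Cf_0 = 0 -> first-order recursive filter
    cf[1:] = lfilter([1.0], [1.0, -alpha], beta)
    if k3 > 0.0:
        step_int = cf[:-1] * e1 + K1 * (c0 * f + m * g2)
        cc[1:] = k3 * np.cumsum(step_int)
    return cf, cc


def solve_2tc(
    params: KineticParameters,
    input_fn: PlasmaInputFunction,
    t_grid: np.ndarray,
) -> TissueCurves:
    """Solve the irreversible two-tissue system on a uniform grid.

    Parameters
    ----------
    params : KineticParameters
    input_fn : PlasmaInputFunction
        Evaluated at the grid nodes; treated as piecewise linear in between.
    t_grid : array
        Uniform time grid in minutes, starting at 0.

    Returns
    -------
    TissueCurves
        Cf, Cc and the measurable total CT = vb*Cb + (1-vb)*(Cf+Cc).
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise InvalidGridError("t_grid must be 1-D with at least 2 points")
    if t[0] != 0.0:
        raise InvalidGridError("t_grid must start at 0")
    dt = np.diff(t)
    h = dt[0]
    if h <= 0 or not np.allclose(dt, h, rtol=1e-9, atol=1e-12):
        raise InvalidGridError("t_grid must be uniform with positive step")
    cp = input_fn.cp(t)
    cb = input_fn.cb(t)
    # tolerate roundoff-scale negative excursions near bolus onset
    tol = 1e-9 * max(float(np.max(np.abs(cp))), float(np.max(np.abs(cb))), 1.0)
    if np.any(cp < -tol) or np.any(cb < -tol):
        raise InvalidInputError("input function is negative on the grid")
    cp = np.clip(cp, 0.0, None)
    cb = np.clip(cb, 0.0, None)
    cf, cc = _forward_compartments(params.K1, params.k2, params.k3, cp, h)
    ct = params.vb * cb + (1.0 - params.vb) * (cf + cc)
    return TissueCurves(t=t, cf=cf, cc=cc, ct_total=ct)


def frame_average(curves: TissueCurves, schedule: FrameSchedule) -> TimeActivityCurve:
    """Average the continuous CT(t) over each reconstruction frame.

    value_i = (1/dt_i) * integral of CT over frame i, by trapezoidal
    quadrature on the fine grid (frame boundaries interpolated linearly).
    """
    t = curves.t
    starts = schedule.frames[:, 0] / 60.0
    ends = schedule.frames[:, 1] / 60.0
    eps = 1e-9
    if starts[0] < t[0] - eps or ends[-1] > t[-1] + eps:
        raise CoverageError("schedule extends beyond the simulated grid")
    cum = np.concatenate([[0.0], cumulative_trapezoid(curves.ct_total, t)])
    ia = np.interp(starts, t, cum)
    ib = np.interp(ends, t, cum)
    values = (ib - ia) / (ends - starts)
    return TimeActivityCurve(schedule=schedule, values=values)


def patlak_estimate(
    tac: TimeActivityCurve,
    input_fn: PlasmaInputFunction,
    t_star: float = 10.0,
    dt_s: float = DEFAULT_DT_S,
) -> tuple[float, float]:
    """Patlak graphical estimate of the net uptake rate.

    For an irreversible tracer, CT(t)/Cp(t) plotted against the normalized
    integrated input x(t) = int_0^t Cp ds / Cp(t) becomes linear once the
    free compartment equilibrates; the slope estimates Ki (scaled by (1-vb)
    when a blood term is present).  Ordinary least squares over frames with
    mid-time >= ``t_star`` (minutes).

    Returns (slope, intercept).
    """
    mids = tac.mid_times
    late = mids >= t_star
    if np.count_nonzero(late) < 3:
        raise InsufficientDataError("need at least 3 frames with mid_time >= t_star")
    t_dense = np.arange(0.0, mids[-1] + dt_s / 60.0, dt_s / 60.0)
    cp_dense = input_fn.cp(t_dense)
    cum = np.concatenate([[0.0], cumulative_trapezoid(cp_dense, t_dense)])
    cp_mid = input_fn.cp(mids[late])
    if np.any(cp_mid <= 0):
        raise InsufficientDataError("Cp must be positive over the late frames")
    x = np.interp(mids[late], t_dense, cum) / cp_mid
    y = tac.values[late] / cp_mid
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
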