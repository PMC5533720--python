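"""Stress-relaxation analysis of excised cervical tissue.

From a time/displacement/force record the module segments the ramp-and-hold
protocol, converts force to stress via the measured cross-sectional area,
extracts the impulse (per-cycle maximum) and equilibrium (mean of the final
30 s of each hold) stress-opening curves, fits the exponential stiffness law

    Stress = (A/B) * [exp(opening * B) - 1]

(A: stiffness at small displacements, B: exponential rate at large ones),
measures the linear-region slope and its x-intercept, detects tissue failure
as a sudden loss of stress, and reports dilation metrics.  The hydration
helper implements the study's printed water-content formula wet/(wet+dry)
alongside the conventional (wet-dry)/wet.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .synthetic import StressRelaxationTrace, exponential_stress

STANDARD_GRAVITY = 9.80665  # m/s^2


@dataclasses.dataclass(frozen=True)
class ForceCalibration:
    """Two-point voltage -> force map from the unloaded and 100 g records.

    force = (volts - volts_zero) * mass * g / (volts_loaded - volts_zero)
    """

    volts_zero: float
    volts_loaded: float
    mass_kg: float = 0.100

    def force_N(self, volts) -> np.ndarray:
        span = self.volts_loaded - self.volts_zero
        if span == 0:
            raise ValueError("calibration records have equal voltage")
        return (np.asarray(volts, float) - self.volts_zero) * (
            self.mass_kg * STANDARD_GRAVITY / span
        )


# -------------------------------------------------------------- segmentation


@dataclasses.dataclass
class Cycle:
    ramp: slice
    hold: slice
    opening_mm: float


def segment_protocol(trace: StressRelaxationTrace, ramp_eps: float = 0.02) -> list[Cycle]:
    """Identify ramp/hold cycles from the displacement derivative.

    A sample is in a ramp where |d displacement / dt| > ``ramp_eps`` (mm/s);
    each ramp and the following hold form one cycle whose opening is the
    median displacement of the hold.  Raises if no ramps are detectable.
    """
    v = np.gradient(trace.displacement, trace.time)
    moving = np.abs(v) > ramp_eps
    if not moving.any():
        raise ValueError("no detectable ramps in the displacement channel")
    # contiguous runs of moving samples
    edges = np.flatnonzero(np.diff(moving.astype(int)))
    starts = list(edges[moving[edges + 1]] + 1)
    ends = list(edges[~moving[edges + 1]] + 1)
    if moving[0]:
        starts.insert(0, 0)
    if moving[-1]:
        ends.append(moving.size)
    cycles = []
    for i, s in enumerate(starts):
        e = ends[i]
        hold_end = starts[i + 1] if i + 1 < len(starts) else moving.size
        hold = slice(e, hold_end)
        if hold.stop - hold.start < 1:
            continue
        opening = float(np.median(trace.displacement[hold]))
        cycles.append(Cycle(ramp=slice(s, e), hold=hold, opening_mm=opening))
    if not cycles:
        raise ValueError("no complete ramp/hold cycles found")
    return cycles


def stress_curves(
    trace: StressRelaxationTrace,
    cycles: list[Cycle],
    area_mm2: float | None = None,
    window_s: float = 30.0,
) -> pd.DataFrame:
    """Impulse and equilibrium stress per cycle as (opening, stress) series.

    stress = force / area; impulse = maximum stress within the cycle,
    equilibrium = mean stress over the final ``window_s`` seconds of the hold
    (truncated with a warning if the hold is shorter).
    """
    area = trace.area_mm2 if area_mm2 is None else area_mm2
    if area <= 0:
        raise ValueError("cross-sectional area must be > 0")
    stress = trace.force / area
    rows = []
    for c in cycles:
        cyc = slice(c.ramp.start, c.hold.stop)
        impulse = float(stress[cyc].max())
        t_hold = trace.time[c.hold]
        hold_len = t_hold[-1] - t_hold[0] if t_hold.size > 1 else 0.0
        if hold_len < window_s:
            warnings.warn(
                f"hold at {c.opening_mm:.1f} mm is shorter ({hold_len:.1f} s) than "
                f"the {window_s:.0f} s equilibrium window; truncating",
                stacklevel=2,
            )
        w = min(window_s, hold_len)
        m = t_hold >= t_hold[-1] - w
        equilibrium = float(stress[c.hold][m].mean())
        rows.append(dict(opening_mm=c.opening_mm, impulse_stress=impulse,
                         equilibrium_stress=equilibrium))
    return pd.DataFrame(rows)


# ------------------------------------------------------------ stiffness fits


def _linear_region(x: np.ndarray, y: np.ndarray, curvature_tol: float = 0.15):
    """Largest suffix of points whose local second difference is small.

    Curvature is measured as |second difference of y| relative to the span of
    y; returns the slice start index (at least the final 2 points).
    """
    n = x.size
    if n <= 2:
        return 0
    span = max(np.ptp(y), 1e-12)
    d2 = np.abs(np.diff(y, 2)) / span  # length n-2; d2[i] ~ curvature at i+1
    start = n - 2
    # extend the suffix backwards while curvature stays below tolerance
    for i in range(n - 3, -1, -1):
        if d2[i] < curvature_tol:
            start = i
        else:
            break
    return start


@dataclasses.dataclass
class StiffnessFit:
    """Exponential stiffness fit plus the linear-region summary for one curve."""

    A: float
    B: float
    rmse: float
    linear_slope: float
    x_intercept: float
    curve_type: str = ""
    exponential_ok: bool = True

    def predict(self, opening) -> np.ndarray:
        return exponential_stress(opening, self.A, self.B)


class ExponentialStiffness(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares fit of Stress = (A/B)[exp(x B) - 1], A, B >= 0.

    Initialization: A0 = slope of the first two points, B0 = 0.1 /mm; the
    B -> 0 limit is evaluated as A*x so perfectly linear data degenerate
    gracefully.  Fitted attributes: ``A_``, ``B_``, ``rmse_``,
    ``linear_slope_``, ``x_intercept_``, ``exponential_ok_``.
    """

    def __init__(self, curvature_tol: float = 0.15):
        self.curvature_tol = curvature_tol

    def fit(self, X, y):
        x = np.asarray(X, float).reshape(-1)
        y = np.asarray(y, float).reshape(-1)
        if x.size != y.size:
            raise ValueError("openings and stresses must pair up")
        if np.unique(x).size != x.size:
            raise ValueError("openings must be distinct")
        order = np.argsort(x)
        x, y = x[order], y[order]

        start = _linear_region(x, y, self.curvature_tol)
        xl, yl = x[start:], y[start:]
        slope, intercept = np.polyfit(xl, yl, 1)
        self.linear_slope_ = float(slope)
        self.x_intercept_ = float(-intercept / slope) if slope != 0 else np.nan

        if x.size < 3:
            self.A_ = np.nan
            self.B_ = np.nan
            self.rmse_ = np.nan
            self.exponential_ok_ = False
            return self

        a0 = max((y[1] - y[0]) / (x[1] - x[0]), 1e-9)
        res = least_squares(
            lambda p: exponential_stress(x, p[0], p[1]) - y,
            x0=[a0, 0.1],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
        )
        self.A_, self.B_ = (float(v) for v in res.x)
        self.rmse_ = float(np.sqrt(np.mean(res.fun**2)))
        self.exponential_ok_ = bool(res.success)
        return self

    def predict(self, X) -> np.ndarray:
        return exponential_stress(np.asarray(X, float).reshape(-1), self.A_, self.B_)


def fit_exponential(openings, stresses, curve_type: str = "") -> StiffnessFit:
    est = ExponentialStiffness().fit(openings, stresses)
    return StiffnessFit(
        A=est.A_, B=est.B_, rmse=est.rmse_, linear_slope=est.linear_slope_,
        x_intercept=est.x_intercept_, curve_type=curve_type,
        exponential_ok=est.exponential_ok_,
    )


# ------------------------------------------------------- failure and dilation


def detect_failure_and_dilation(
    trace: StressRelaxationTrace,
    cycles: list[Cycle],
    initial_dilation_mm: float | None = None,
    drop_frac: float = 0.5,
    window_s: float = 1.0,
) -> dict:
    """Find the sudden-loss-of-stress failure event and the dilation metrics.

    Failure is the first instant at which stress falls by more than
    ``drop_frac`` of the running within-cycle maximum within ``window_s``
    seconds while displacement is non-decreasing.  Without such an event the
    record is censored: total dilation uses the last achieved displacement.
    """
    init = trace.initial_dilation_mm if initial_dilation_mm is None else initial_dilation_mm
    stress = trace.force / trace.area_mm2
    t = trace.time
    disp = trace.displacement
    fs = 1.0 / np.median(np.diff(t))
    w = max(int(round(window_s * fs)), 1)
    # scan cycle by cycle over the whole record (a truncated failing ramp at
    # the end of the trace belongs to the segment after the last full cycle)
    bounds = [c.ramp.start for c in cycles] + [stress.size]
    fail_idx = None
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        s = stress[b0:b1]
        run_max = np.maximum.accumulate(s)
        for i in range(1, s.size):
            j0 = max(i - w, 0)
            recent_max = s[j0:i].max()
            if recent_max > 0 and (recent_max - s[i]) > drop_frac * run_max[i]:
                k = b0 + i
                if disp[k] >= disp[max(k - 1, 0)] - 1e-9:
                    fail_idx = k
                    break
        if fail_idx is not None:
            break
    if fail_idx is None:
        return dict(
            failure_displacement_mm=np.nan,
            total_dilation_mm=init + float(disp[-1]),
            max_stress=float(stress.max()),
            censored=True,
        )
    return dict(
        failure_displacement_mm=float(disp[fail_idx]),
        total_dilation_mm=init + float(disp[fail_idx]),
        max_stress=float(stress[:fail_idx].max()),
        censored=False,
    )


def water_content(wet_weight: float, dry_weight: float) -> dict:
    """Hydration of a tissue from wet and lyophilized weights.

    ``as_printed`` is the study's formula wet/(wet+dry); ``conventional`` is
    the usual hydration fraction (wet-dry)/wet.  Both are returned, neither
    silently corrected.
    """
    if wet_weight <= 0 or dry_weight <= 0:
        raise ValueError("weights must be positive")
    return dict(
        as_printed=wet_weight / (wet_weight + dry_weight),
        conventional=(wet_weight - dry_weight) / wet_weight,
    )


# ------------------------------------------------------------------ summary


def summarize_trace(
    trace: StressRelaxationTrace,
    *,
    ramp_eps: float = 0.02,
    window_s: float = 30.0,
    drop_frac: float = 0.5,
) -> dict:
    """Full per-tissue mechanics summary: dilations, failure, max stress and
    the impulse/equilibrium exponential and linear fits."""
    cycles = segment_protocol(trace, ramp_eps)
    curves = stress_curves(trace, cycles, window_s=window_s)
    fail = detect_failure_and_dilation(trace, cycles, drop_frac=drop_frac)
    # cycles after failure carry no stiffness information
    good = curves[curves["impulse_stress"] > 0]
    if not fail["censored"]:
        good = good[good["opening_mm"] <= fail["failure_displacement_mm"]]
    imp = fit_exponential(good["opening_mm"], good["impulse_stress"], "impulse")
    eq = fit_exponential(good["opening_mm"], good["equilibrium_stress"], "equilibrium")
    return dict(
        initial_dilation_mm=trace.initial_dilation_mm,
        n_cycles=len(cycles),
        impulse_A=imp.A, impulse_B=imp.B,
        impulse_slope=imp.linear_slope, impulse_x_intercept=imp.x_intercept,
        equilibrium_A=eq.A, equilibrium_B=eq.B,
        equilibrium_slope=eq.linear_slope, equilibrium_x_intercept=eq.x_intercept,
        **fail,
        curves=curves,
    )
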