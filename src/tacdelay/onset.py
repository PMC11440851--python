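"""Cumulative-sum onset fitting: the proposed single-voxel delay algorithm.

The tracer-arrival delay between a tissue voxel and the blood input function
is estimated by fitting each curve's cumulatively summed TAC independently
and subtracting the two onset times (dT = T_tissue - T_input).

A raw single-voxel TAC is too noisy to fit a rise model to directly.  The
running integral suppresses zero-mean noise, so the model fitted here is the
antiderivative of a logistic step:

    A(t)      = a / (1 + exp((c - t)/b))                      (rise model)
    Asum(t)   = a*b*ln(exp((c - t)/b) + 1) + a*(t - c)        (fitted curve)
    T         = c - 3.5*b                                     (onset time)

where ``a`` is the asymptotic slope of the summed curve, ``c`` the centre of
the transition and ``b`` its tightness (b -> 0 is an instantaneous step).
The onset lies before the transition centre; the empirical shape factor 3.5
moves it from the centre back to the foot of the rise.

Robustness machinery around the fit:

* plateau detection/removal — an early spurious bolus passage (e.g. venous
  pass in the injection arm) creates a step then a flat plateau in the
  summed curve; the plateau is subtracted so the fit locks onto the later
  arterial rise;
* multi-range fitting — the summed curve leaves the straight-line asymptote
  once clearance sets in, so up to 10 candidate range endpoints are taken at
  the largest |second derivative| peaks and each range fitted separately;
* filtering and aggregation — fits must reach R^2 >= 0.8 with a positive
  onset inside the fitted range; the top half by R^2 is kept and the median
  of their parameters gives the final onset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit

from .tac_core import CumulativeCurve, TimeActivityCurve, cumulative_sum

__all__ = [
    "SHAPE_FACTOR",
    "OnsetConfig",
    "OnsetFitParams",
    "OnsetFit",
    "OnsetEstimate",
    "PlateauCorrection",
    "sigmoid_model",
    "summed_model",
    "onset_time",
    "detect_plateau",
    "apply_plateau_correction",
    "select_fit_endpoints",
    "fit_summed_range",
    "aggregate_fits",
    "estimate_onset",
    "estimate_delay",
]

logger = logging.getLogger(__name__)

#: Empirical shape factor mapping the transition centre back to the onset
#: foot: T = c - 3.5*b.  A module constant, overridable only through
#: :class:`OnsetConfig` for expert use.
SHAPE_FACTOR = 3.5


@dataclass(frozen=True)
class OnsetConfig:
    """Tunable knobs of the onset pipeline with their defaults.

    Plateau detection scans only the first ``plateau_window_s`` seconds so a
    late flat tail is never mistaken for a pre-arrival plateau; the band is
    relative (``plateau_band_fraction`` of the window maximum) to serve TACs
    of any amplitude.
    """

    plateau_min_points: int = 3
    plateau_band_fraction: float = 0.001
    plateau_window_s: float = 120.0
    max_ranges: int = 10
    r2_min: float = 0.8
    a_bounds: tuple[float, float] = (0.1, 2e7)
    b_bounds: tuple[float, float] = (0.01, 10.0)
    c_bounds: tuple[float, float] = (0.0, 60.0)
    shape_factor: float = SHAPE_FACTOR

    @classmethod
    def from_dict(cls, cfg: dict) -> "OnsetConfig":
        """Build from flat dotted keys, e.g. ``{"plateau.min_points": 5}``."""
        mapping = {
            "plateau.min_points": "plateau_min_points",
            "plateau.band_fraction": "plateau_band_fraction",
            "plateau.window_s": "plateau_window_s",
            "fit.max_ranges": "max_ranges",
            "fit.r2_min": "r2_min",
            "onset.shape_factor": "shape_factor",
        }
        kwargs = {}
        for key, value in cfg.items():
            if key == "fit.bounds":
                for name, bnd in value.items():
                    kwargs[f"{name}_bounds"] = (float(bnd[0]), float(bnd[1]))
            elif key in mapping:
                kwargs[mapping[key]] = value
            else:
                raise KeyError(f"unknown config key: {key}")
        return cls(**kwargs)


@dataclass(frozen=True)
class OnsetFitParams:
    """Parameters (a, b, c) of the rise model; b and c in seconds."""

    a: float
    b: float
    c: float


@dataclass(frozen=True)
class OnsetFit:
    """One bounded fit over a single candidate range.

    A failed optimisation is encoded as ``r_squared = -inf``, never raised.
    """

    params: OnsetFitParams | None
    r_squared: float
    range_end_index: int
    range_end_time: float
    onset_time: float
    at_bound: bool = False


@dataclass(frozen=True)
class OnsetEstimate:
    """Aggregated onset for one curve; ``onset_time`` is NaN on failure."""

    onset_time: float
    n_fits_attempted: int
    n_fits_accepted: int
    used_fallback: bool = False
    median_params: OnsetFitParams | None = None

    @property
    def ok(self) -> bool:
        return self.n_fits_accepted >= 1 and math.isfinite(self.onset_time)


@dataclass(frozen=True)
class PlateauCorrection:
    detected: bool
    plateau_end_index: int = -1
    plateau_level: float = 0.0


def sigmoid_model(t, params: OnsetFitParams):
    """Logistic rise model a / (1 + exp((c - t)/b)); overflow-safe."""
    if params.b <= 0:
        raise ValueError("b must be positive")
    return params.a * expit((np.asarray(t, dtype=float) - params.c) / params.b)


def summed_model(t, params: OnsetFitParams):
    """Antiderivative of the rise model: a*b*ln(exp((c-t)/b) + 1) + a*(t-c).

    Evaluated via ``logaddexp`` so the exponential never overflows; tends to
    0 for t << c and to the asymptote a*(t - c) for t >> c.
    """
    if params.b <= 0:
        raise ValueError("b must be positive")
    t = np.asarray(t, dtype=float)
    # identity: b*ln(exp((c-t)/b)+1) + (t-c) == b*softplus((t-c)/b)
    return params.a * params.b * np.logaddexp(0.0, (t - params.c) / params.b)


def onset_time(params: OnsetFitParams, shape_factor: float = SHAPE_FACTOR) -> float:
    """Onset time T = c - 3.5*b (may be negative; filtered downstream)."""
    return params.c - shape_factor * params.b


def _window_runs(values: np.ndarray, band: float, min_points: int) -> list[tuple[int, int]]:
    """Runs [i, j] of >= min_points consecutive values with spread <= band.

    One run per qualifying end index j, extended as far left as the band
    allows (an exhaustive scan over end positions, so runs starting mid-way
    through a failed longer window are still found).
    """
    runs: list[tuple[int, int]] = []
    n = values.size
    for j in range(min_points - 1, n):
        i = j - min_points + 1
        if np.ptp(values[i : j + 1]) > band:
            continue
        while i > 0 and np.ptp(values[i - 1 : j + 1]) <= band:
            i -= 1
        runs.append((i, j))
    return runs


def detect_plateau(
    curve: CumulativeCurve,
    min_points: int = 3,
    band_fraction: float = 0.001,
    window: float = 120.0,
) -> PlateauCorrection:
    """Find a pre-arrival plateau in the summed TAC.

    Scans only frames with mid-time <= ``window`` and looks for runs of at
    least ``min_points`` consecutive values whose spread is within
    ``band_fraction`` of the window maximum.  Among qualifying runs, the
    last one that is still followed by a genuine rise is reported, so when a
    venous spike precedes the arterial pass the plateau between the two is
    selected and the fit locks onto the arterial rise.
    """
    mid = curve.schedule.mid_time
    values = curve.values
    m = int(np.searchsorted(mid, window, side="right"))
    if m < min_points:
        return PlateauCorrection(False)
    win = values[:m]
    vmax = float(np.max(win))
    band = band_fraction * abs(vmax)
    best: tuple[int, float] | None = None
    for i, j in _window_runs(win, band, min_points):
        level = float(np.mean(win[i : j + 1]))
        tail = values[j + 1 :]
        # only a plateau with activity still to come is a pre-arrival plateau
        if tail.size and float(np.max(tail)) > level + band:
            best = (j, level)
    if best is None:
        return PlateauCorrection(False)
    return PlateauCorrection(True, plateau_end_index=best[0], plateau_level=best[1])


def apply_plateau_correction(curve: CumulativeCurve, corr: PlateauCorrection) -> CumulativeCurve:
    """Zero the curve through the plateau and subtract the plateau level after.

    Values are clipped at zero so noise dips below the plateau level do not
    produce negative summed activity.
    """
    if not corr.detected:
        logger.warning("apply_plateau_correction called without a detected plateau; no-op")
        return curve
    out = curve.values.copy()
    k = corr.plateau_end_index
    out[: k + 1] = 0.0
    out[k + 1 :] = np.maximum(0.0, out[k + 1 :] - corr.plateau_level)
    return CumulativeCurve(curve.schedule, out, plateau_corrected=True)


def second_derivative(curve: CumulativeCurve) -> np.ndarray:
    """Central second differences on the non-uniform mid-time grid.

    Returned array has one value per interior frame (length n-2).
    """
    t = curve.schedule.mid_time
    y = curve.values
    slope = np.diff(y) / np.diff(t)
    return 2.0 * np.diff(slope) / (t[2:] - t[:-2])


def select_fit_endpoints(curve: CumulativeCurve, max_ranges: int = 10) -> list[int]:
    """Candidate range endpoints at the largest |second derivative| peaks.

    Peaks are simple adjacent-comparison local maxima of the absolute second
    derivative (ties keep the earlier index), returned in descending peak
    height, at most ``max_ranges`` of them.  A curve with no interior peaks
    (e.g. a perfect ramp) falls back to the last frame so fitting can
    proceed.
    """
    n = curve.schedule.n_frames
    if n < 5:
        raise ValueError(f"need at least 5 frames to select fit endpoints, got {n}")
    d2 = np.abs(second_derivative(curve))  # d2[k] sits at frame k+1
    peaks: list[tuple[float, int]] = []
    for k in range(1, d2.size - 1):
        if d2[k] > d2[k - 1] and d2[k] >= d2[k + 1] and d2[k] > 0:
            peaks.append((float(d2[k]), k + 1))
    peaks.sort(key=lambda p: (-p[0], p[1]))
    endpoints = [idx for _, idx in peaks[:max_ranges]]
    if not endpoints:
        endpoints = [n - 1]
    return endpoints


def _r_squared(y: np.ndarray, y_fit: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return -math.inf
    ss_res = float(np.sum((y - y_fit) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_summed_range(
    curve: CumulativeCurve,
    end_index: int,
    config: OnsetConfig = OnsetConfig(),
) -> OnsetFit:
    """Bounded least-squares fit of the summed model over frames 0..end_index.

    Optimiser failures are encoded as ``r_squared = -inf`` rather than
    raised; convergence onto a parameter bound is kept but flagged.
    """
    t = curve.schedule.mid_time[: end_index + 1]
    y = curve.values[: end_index + 1]
    end_time = float(curve.schedule.mid_time[end_index])
    failed = OnsetFit(None, -math.inf, end_index, end_time, math.nan)
    if end_index < 4:
        return failed

    lo = np.array([config.a_bounds[0], config.b_bounds[0], config.c_bounds[0]])
    hi = np.array([config.a_bounds[1], config.b_bounds[1], config.c_bounds[1]])
    span = max(t[-1] - t[0], 1e-6)
    a0 = y[-1] / span
    half_idx = int(np.searchsorted(y, y[-1] / 2.0))
    c0 = float(t[min(half_idx, len(t) - 1)])
    x0 = np.clip([a0, 1.0, c0], lo, hi)

    def residuals(x: np.ndarray) -> np.ndarray:
        a, b, c = x
        return a * b * np.logaddexp(0.0, (t - c) / b) - y

    try:
        sol = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf")
    except Exception:
        logger.debug("optimizer raised for range ending at %d", end_index, exc_info=True)
        return failed
    if not sol.success or not np.all(np.isfinite(sol.x)):
        return failed
    params = OnsetFitParams(*sol.x)
    at_bound = bool(np.any(np.isclose(sol.x, lo)) or np.any(np.isclose(sol.x, hi)))
    if at_bound:
        logger.debug("fit ending at %d converged at a parameter bound: %s", end_index, params)
    r2 = _r_squared(y, residuals(sol.x) + y)
    return OnsetFit(
        params,
        r2,
        end_index,
        end_time,
        onset_time(params, config.shape_factor),
        at_bound=at_bound,
    )


def aggregate_fits(fits: Sequence[OnsetFit], config: OnsetConfig = OnsetConfig()) -> OnsetEstimate:
    """Filter per-range fits and take the median over the best half.

    A fit is accepted when R^2 >= ``r2_min``, its onset is positive and the
    onset lies before the end of its fitted range.  Of the accepted fits the
    ceil(n/2) with highest R^2 are kept; the component-wise median of their
    (a, b, c) gives the final onset T = c_med - shape_factor*b_med.
    """
    accepted = [
        f
        for f in fits
        if f.params is not None
        and f.r_squared >= config.r2_min
        and f.onset_time > 0
        and f.onset_time < f.range_end_time
    ]
    if not accepted:
        return OnsetEstimate(math.nan, len(fits), 0)
    accepted.sort(key=lambda f: -f.r_squared)
    top = accepted[: math.ceil(len(accepted) / 2)]
    med = OnsetFitParams(
        a=float(np.median([f.params.a for f in top])),
        b=float(np.median([f.params.b for f in top])),
        c=float(np.median([f.params.c for f in top])),
    )
    return OnsetEstimate(
        onset_time(med, config.shape_factor),
        n_fits_attempted=len(fits),
        n_fits_accepted=len(accepted),
        median_params=med,
    )


def estimate_onset(tac: TimeActivityCurve, config: OnsetConfig = OnsetConfig()) -> OnsetEstimate:
    """Full pipeline: cumulative sum, plateau removal, multi-range fit, median.

    Degenerate curves (all zero, too few frames) yield a failure estimate
    with ``onset_time`` NaN rather than an exception.
    """
    if tac.schedule.n_frames < 5 or not np.any(tac.activity != 0):
        return OnsetEstimate(math.nan, 0, 0)
    curve = cumulative_sum(tac)
    corr = detect_plateau(
        curve,
        min_points=config.plateau_min_points,
        band_fraction=config.plateau_band_fraction,
        window=config.plateau_window_s,
    )
    if corr.detected:
        curve = apply_plateau_correction(curve, corr)
    endpoints = select_fit_endpoints(curve, max_ranges=config.max_ranges)
    fits = [fit_summed_range(curve, e, config) for e in endpoints if e >= 4]
    return aggregate_fits(fits, config)


def estimate_delay(
    tissue: TimeActivityCurve,
    input_fn: TimeActivityCurve,
    config: OnsetConfig = OnsetConfig(),
) -> float:
    """Delay dT = T_tissue - T_input in seconds; NaN if either onset fails.

    Both curves run through the identical onset pipeline, so the systematic
    part of the fitting offset cancels and ``estimate_delay(x, x) == 0``
    exactly for any curve with a successful onset.
    """
    t_tissue = estimate_onset(tissue, config)
    t_input = estimate_onset(input_fn, config)
    if not (t_tissue.ok and t_input.ok):
        return math.nan
    return t_tissue.onset_time - t_input.onset_time
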