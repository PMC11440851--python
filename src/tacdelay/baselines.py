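"""Comparator delay estimators: cross-correlation and a one-tissue model.

Two methods in common use for tracer-arrival delay estimation, implemented
as references against which the cumulative-sum onset algorithm is
benchmarked:

* cross-correlation — both curves are linearly resampled to a uniform grid,
  mean-subtracted, and the lag of highest correlation is taken as the delay.
  By construction this co-aligns the curve *peaks*, so for accumulating
  tissue (small k2) it grossly overestimates the delay.
* one-tissue compartment model with incorporated delay — the tissue curve is
  fitted by dC_T/dt = K1*C_A(t - delay) - k2*C_T with C_T(0) = 0, solved
  exactly on a dense grid by exponential-kernel recursion, frame-averaged
  onto the acquisition schedule, with the delay profiled on a coarse grid
  and then refined jointly with (K1, k2).

Units follow kinetic-modeling convention: K1 in ml/(100 g*min), k2 in 1/min,
tissue density 1 g/ml, so the internal rate constants are K1/6000 and k2/60
in 1/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal
from scipy.integrate import cumulative_trapezoid

from .tac_core import FrameSchedule, TimeActivityCurve

__all__ = [
    "OneTissueFit",
    "OneTissueDelayFitter",
    "xcorr_delay",
    "predict_one_tissue",
    "fit_one_tissue_with_delay",
    "frame_average",
    "K1_PER_SECOND",
]

#: K1 printed in ml/(100 g*min) divided by this is an influx rate in 1/s
#: (assumes tissue density 1 g/ml: 100 g = 100 ml, 1 min = 60 s).
K1_PER_SECOND = 6000.0


@dataclass(frozen=True)
class OneTissueFit:
    """Result of the one-tissue fit: K1 ml/(100 g*min), k2 1/min, delay s."""

    K1: float
    k2: float
    delay: float
    rss: float
    converged: bool


def _resample_uniform(tac: TimeActivityCurve, t_grid: np.ndarray) -> np.ndarray:
    mid = tac.schedule.mid_time
    return np.interp(t_grid, mid, tac.activity, left=tac.activity[0], right=tac.activity[-1])


def xcorr_delay(
    tissue: TimeActivityCurve,
    input_fn: TimeActivityCurve,
    resample_dt: float = 1.0,
    max_lag: float = 120.0,
) -> float:
    """Delay (s) at the maximum of the full discrete cross-correlation.

    Both curves are linearly resampled to a uniform ``resample_dt`` grid over
    their common support and mean-subtracted; positive return means the
    tissue curve lags the input.  Returns NaN for a constant (zero-variance)
    curve, for which the lag is undefined.
    """
    t0 = max(tissue.schedule.mid_time[0], input_fn.schedule.mid_time[0])
    t1 = min(tissue.schedule.mid_time[-1], input_fn.schedule.mid_time[-1])
    t_grid = np.arange(t0, t1 + resample_dt / 2, resample_dt)
    a = _resample_uniform(tissue, t_grid)
    v = _resample_uniform(input_fn, t_grid)
    if np.ptp(a) == 0 or np.ptp(v) == 0:
        return math.nan
    a = a - a.mean()
    v = v - v.mean()
    corr = signal.correlate(a, v, mode="full")
    lags = signal.correlation_lags(a.size, v.size, mode="full") * resample_dt
    keep = np.abs(lags) <= max_lag
    return float(lags[keep][np.argmax(corr[keep])])


def _check_uniform(t_dense: np.ndarray) -> float:
    dt = np.diff(t_dense)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("dense time grid must be uniform")
    return float(dt[0])


def _exp_kernel_response(u: np.ndarray, k2s: float, dt: float) -> np.ndarray:
    """Exact solution of dy/dt = u - k2s*y, y(0)=0, for piecewise-linear u.

    One exponential-integrator step per sample, evaluated as an IIR filter:
    y[n] = alpha*y[n-1] + c1*u[n] + c0*u[n-1].
    """
    kappa = k2s * dt
    alpha = math.exp(-kappa)
    if kappa < 1e-8:
        c1 = c0 = dt / 2.0
    else:
        one_m_alpha = -math.expm1(-kappa)
        i0 = one_m_alpha / k2s
        i1 = (1.0 - one_m_alpha / kappa) / k2s
        c1, c0 = i1, i0 - i1
    y = signal.lfilter([c1, c0], [1.0, -alpha], u)
    # lfilter starts with y[0] = c1*u[0]; remove that homogeneous mode so y(0)=0
    if u[0] != 0.0:
        y = y - c1 * u[0] * alpha ** np.arange(u.size)
    return y


def predict_one_tissue(
    t_dense: np.ndarray,
    input_dense: np.ndarray,
    K1: float,
    k2: float,
    delay: float,
) -> np.ndarray:
    """Tissue curve C_T = K1*C_A(t - delay) (x) exp(-k2*t) on a dense grid.

    ``t_dense`` must be uniform (step <= 0.1 s recommended); K1 in
    ml/(100 g*min), k2 in 1/min, delay in s.  With k2 = 0 this reduces to
    K1 times the running integral of the shifted input.
    """
    if K1 < 0 or k2 < 0:
        raise ValueError("rate constants must be non-negative")
    dt = _check_uniform(t_dense)
    u = np.interp(t_dense - delay, t_dense, input_dense, left=0.0, right=float(input_dense[-1]))
    k1s = K1 / K1_PER_SECOND
    k2s = k2 / 60.0
    return k1s * _exp_kernel_response(u, k2s, dt)


def frame_average(t_dense: np.ndarray, y_dense: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a dense curve over each frame (how PET frames integrate counts)."""
    integral = np.concatenate([[0.0], cumulative_trapezoid(y_dense, t_dense)])
    starts = np.interp(schedule.frame_start, t_dense, integral)
    ends = np.interp(schedule.frame_start + schedule.frame_duration, t_dense, integral)
    return (ends - starts) / schedule.frame_duration


class OneTissueDelayFitter:
    """One-tissue-with-delay fitting against a fixed input function.

    Precomputes, once per input function, the frame-averaged unit-K1 model
    over a (delay, k2) grid: the model is linear in K1, so K1 is profiled in
    closed form per grid point.  The coarse-grid optimum is then refined by
    joint bounded least squares over (K1, k2, delay).  Building the fitter
    once and calling :meth:`fit` per tissue curve is the intended batch use.

    Parameters
    ----------
    input_fn
        Input-function TAC (frame-sampled; densified internally).
    endtime
        Only frames with mid-time <= endtime (s) enter the fit; default 180.
    delay_grid, k2_grid
        Coarse search grids (s and 1/min).  Defaults: -20..60 s step 0.5,
        48 log-spaced k2 from 0.01 to 6 /min.
    dt
        Dense simulation step, s.
    """

    def __init__(
        self,
        input_fn: TimeActivityCurve,
        endtime: float = 180.0,
        delay_grid: np.ndarray | None = None,
        k2_grid: np.ndarray | None = None,
        dt: float = 0.1,
    ) -> None:
        schedule = input_fn.schedule
        self.schedule = schedule
        self.endtime = float(min(endtime, schedule.end_time))
        self.frame_sel = schedule.mid_time <= self.endtime
        self.fit_schedule = FrameSchedule(
            schedule.frame_start[self.frame_sel], schedule.frame_duration[self.frame_sel]
        )
        self.delay_grid = (
            np.arange(-20.0, 60.0 + 1e-9, 0.5) if delay_grid is None else np.asarray(delay_grid)
        )
        self.k2_grid = (
            np.geomspace(0.01, 6.0, 48) if k2_grid is None else np.asarray(k2_grid)
        )
        self.dt = dt
        self.t_dense = np.arange(0.0, schedule.end_time + dt / 2, dt)
        self.input_dense = _resample_uniform(input_fn, self.t_dense)
        self._build_basis()

    def _unit_model(self, k2: float, delay: float) -> np.ndarray:
        """Frame-averaged tissue model for k1s = 1 (1/s)."""
        shifted = np.interp(
            self.t_dense - delay, self.t_dense, self.input_dense,
            left=0.0, right=float(self.input_dense[-1]),
        )
        dense = _exp_kernel_response(shifted, k2 / 60.0, self.dt)
        return frame_average(self.t_dense, dense, self.fit_schedule)

    def _build_basis(self) -> None:
        # shift-invariance: conv of the delayed input == delayed conv, so the
        # k2 response is computed once per k2 and re-sampled per delay
        n_frames = self.fit_schedule.n_frames
        basis = np.empty((self.delay_grid.size, self.k2_grid.size, n_frames))
        for j, k2 in enumerate(self.k2_grid):
            dense = _exp_kernel_response(self.input_dense, k2 / 60.0, self.dt)
            for i, d in enumerate(self.delay_grid):
                shifted = np.interp(self.t_dense - d, self.t_dense, dense,
                                    left=0.0, right=float(dense[-1]))
                basis[i, j] = frame_average(self.t_dense, shifted, self.fit_schedule)
        self._basis = basis.reshape(-1, n_frames)
        self._basis_sq = np.einsum("ij,ij->i", self._basis, self._basis)

    def fit(self, tissue: TimeActivityCurve) -> OneTissueFit:
        if tissue.schedule != self.schedule:
            raise ValueError("tissue and input function must share a frame schedule")
        y = tissue.activity[self.frame_sel]
        num = self._basis @ y
        with np.errstate(divide="ignore", invalid="ignore"):
            k1_unit = np.where(self._basis_sq > 0, num / self._basis_sq, 0.0)
        k1_unit = np.maximum(k1_unit, 0.0)
        rss = float(y @ y) - 2 * k1_unit * num + k1_unit**2 * self._basis_sq
        best = int(np.argmin(rss))
        i, j = divmod(best, self.k2_grid.size)
        d0, k20 = float(self.delay_grid[i]), float(self.k2_grid[j])
        k10 = float(k1_unit[best]) * K1_PER_SECOND

        lo = np.array([0.0, 0.0, float(self.delay_grid[0])])
        hi = np.array([1e5, 60.0, float(self.delay_grid[-1])])
        x0 = np.clip([max(k10, 1e-6), k20, d0], lo, hi)

        def residuals(x: np.ndarray) -> np.ndarray:
            K1, k2, d = x
            return self._unit_model(k2, d) * (K1 / K1_PER_SECOND) - y

        try:
            sol = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf")
            converged = bool(sol.success)
        except Exception:
            converged = False
        if not converged:
            return OneTissueFit(k10, k20, d0, float(rss[best]), False)
        K1, k2, d = sol.x
        return OneTissueFit(float(K1), float(k2), float(d), float(2 * sol.cost), True)


def fit_one_tissue_with_delay(
    tissue: TimeActivityCurve,
    input_fn: TimeActivityCurve,
    endtime: float = 180.0,
) -> OneTissueFit:
    """Convenience wrapper: build a fitter for this input and fit one curve."""
    return OneTissueDelayFitter(input_fn, endtime=endtime).fit(tissue)
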