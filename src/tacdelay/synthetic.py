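"""Synthetic one-tissue-compartment TAC generation for validation.

Validation data are produced by driving the one-tissue compartment model

    dC_T/dt = K1*C_A(t) - k2*C_T(t),    C_T(0) = 0

with a bolus-shaped input function C_A, over a Cartesian grid of influx
(K1), efflux (k2), tracer-arrival delay and multiplicative noise level.
The input function is a parametric gamma-variate bolus with a recirculation
tail, standing in for a measured image-derived input function; presets are
provided per tracer schedule.

Delay is applied by shifting the dense tissue curve and linearly
interpolating back onto the original sampling; noise multiplies each frame
value by an independent N(1, sigma^2) draw, with negative products clipped
to zero (PET activity concentrations are reported non-negative).

The default grid reproduces the benchmark design: K1 from 1 to 350
ml/(100 g*min) in steps of 3.5, k2 from 0.05 to 3 /min in steps of 0.03,
delay from -10 to 10 s in steps of 1 s, sigma from 0 to 0.5 in steps of
0.1.  Noise sigma = 0.1 corresponds roughly to a few hundred voxels
averaged, sigma = 0.4 to a single voxel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .baselines import frame_average, predict_one_tissue
from .tac_core import FrameSchedule, TimeActivityCurve, build_schedule

__all__ = [
    "InputFunctionModel",
    "SimulationSpec",
    "GridSpec",
    "INPUT_PRESETS",
    "SCHEDULES",
    "gamma_variate_input",
    "input_function_tac",
    "simulate_tissue",
    "apply_delay",
    "apply_noise",
    "grid_values",
    "build_grid",
    "default_grid",
]

#: Frame schedules by tracer protocol: 54 frames / 180 s for water,
#: 71 frames / 600 s for FDG-like tracers.
SCHEDULE_SPECS = {
    "h2o": [(40, 1.0), (5, 4.0), (6, 10.0), (3, 20.0)],
    "fdg": [(40, 1.0), (10, 5.0), (15, 10.0), (6, 60.0)],
}


def SCHEDULES(name: str) -> FrameSchedule:
    """Build a named acquisition schedule ('h2o' or 'fdg')."""
    try:
        return build_schedule(SCHEDULE_SPECS[name])
    except KeyError:
        raise KeyError(f"unknown schedule {name!r}; available: {sorted(SCHEDULE_SPECS)}") from None


@dataclass(frozen=True)
class InputFunctionModel:
    """Parametric bolus input function: gamma variate plus recirculation.

    The first-pass bolus is a gamma variate peaking ``alpha*beta`` seconds
    after ``arrival_time`` and normalized to ``peak_amplitude``; the
    recirculation term is a smoothly rising fraction of the peak decaying
    with ``recirculation_decay``.  The curve is identically zero before
    ``arrival_time``.
    """

    arrival_time: float = 12.0
    peak_amplitude: float = 30000.0
    alpha: float = 2.5
    beta: float = 4.0
    recirculation_fraction: float = 0.08
    recirculation_decay: float = 0.01

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("gamma-variate shape and scale must be positive")
        if not (0 <= self.recirculation_fraction < 1):
            raise ValueError("recirculation_fraction must be in [0, 1)")


#: Input-function presets per tracer protocol (amplitudes in Bq/ml).
INPUT_PRESETS = {
    "h2o_idif": InputFunctionModel(
        arrival_time=12.0, peak_amplitude=30000.0, alpha=2.5, beta=4.0,
        recirculation_fraction=0.08, recirculation_decay=0.01,
    ),
    "fdg_idif": InputFunctionModel(
        arrival_time=12.0, peak_amplitude=20000.0, alpha=2.5, beta=6.0,
        recirculation_fraction=0.15, recirculation_decay=0.005,
    ),
}


def gamma_variate_input(model: InputFunctionModel, t_dense: np.ndarray) -> np.ndarray:
    """Evaluate the bolus model on a dense time grid (s) -> Bq/ml."""
    t = np.asarray(t_dense, dtype=float)
    tau = t - model.arrival_time
    pos = tau > 0
    out = np.zeros_like(t)
    tp = tau[pos]
    t_peak = model.alpha * model.beta
    bolus = (tp / t_peak) ** model.alpha * np.exp(model.alpha - tp / model.beta)
    recirc = (
        model.recirculation_fraction
        * (-np.expm1(-tp / t_peak)) ** 2
        * np.exp(-model.recirculation_decay * tp)
    )
    out[pos] = model.peak_amplitude * (bolus + recirc)
    return out


def input_function_tac(
    model: InputFunctionModel, schedule: FrameSchedule, dt: float = 0.1
) -> TimeActivityCurve:
    """Frame-averaged input-function TAC on an acquisition schedule."""
    t_dense = np.arange(0.0, schedule.end_time + dt / 2, dt)
    dense = gamma_variate_input(model, t_dense)
    return TimeActivityCurve(schedule, frame_average(t_dense, dense, schedule))


@dataclass(frozen=True)
class SimulationSpec:
    """One synthetic-tissue configuration.

    K1 in ml/(100 g*min), k2 in 1/min, delay in s, sigma unitless; ``seed``
    drives the per-curve noise stream.
    """

    K1: float
    k2: float
    delay: float
    sigma: float
    seed: int
    schedule: FrameSchedule
    input_model: InputFunctionModel


def apply_delay(t_dense: np.ndarray, y_dense: np.ndarray, d: float) -> np.ndarray:
    """Shift a dense curve by +d seconds (later arrival for d > 0).

    Linear interpolation back onto the original grid; values before the
    shifted start are zero.
    """
    t = np.asarray(t_dense, dtype=float)
    span = t[-1] - t[0]
    if abs(d) > span:
        raise ValueError(f"shift {d} s exceeds grid span {span} s")
    if d == 0:
        return np.asarray(y_dense, dtype=float).copy()
    return np.interp(t - d, t, y_dense, left=0.0, right=float(y_dense[-1]))


def apply_noise(tac: TimeActivityCurve, sigma: float, seed: int) -> TimeActivityCurve:
    """Multiplicative Gaussian noise: activity*N(1, sigma^2), clipped at 0."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return tac
    rng = np.random.default_rng(seed)
    noisy = tac.activity * rng.normal(1.0, sigma, size=tac.activity.size)
    return TimeActivityCurve(tac.schedule, np.maximum(noisy, 0.0))


def simulate_tissue(spec: SimulationSpec, dt: float = 0.1) -> TimeActivityCurve:
    """Generate one synthetic tissue TAC.

    Dense one-tissue solve at zero delay, dense shift by ``spec.delay``,
    integral average onto the frame schedule, then multiplicative noise.
    """
    t_dense = np.arange(0.0, spec.schedule.end_time + dt / 2, dt)
    input_dense = gamma_variate_input(spec.input_model, t_dense)
    tissue_dense = predict_one_tissue(t_dense, input_dense, spec.K1, spec.k2, 0.0)
    tissue_dense = apply_delay(t_dense, tissue_dense, spec.delay)
    tac = TimeActivityCurve(spec.schedule, frame_average(t_dense, tissue_dense, spec.schedule))
    return apply_noise(tac, spec.sigma, spec.seed)


@dataclass(frozen=True)
class GridSpec:
    """(start, step, stop) triples per parameter, inclusive-by-step."""

    K1: tuple[float, float, float] = (1.0, 3.5, 350.0)
    k2: tuple[float, float, float] = (0.05, 0.03, 3.0)
    delay: tuple[float, float, float] = (-10.0, 1.0, 10.0)
    sigma: tuple[float, float, float] = (0.0, 0.1, 0.5)


def grid_values(triple: tuple[float, float, float]) -> np.ndarray:
    """Expand (start, step, stop) to start, start+step, ... <= stop."""
    start, step, stop = (float(x) for x in triple)
    if step <= 0:
        raise ValueError("grid step must be positive")
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return start + step * np.arange(max(n, 0))


def spec_seed(base_seed: int, index: int) -> int:
    """Deterministic per-spec seed derived from a base seed and grid index."""
    return int(np.random.SeedSequence([int(base_seed), int(index)]).generate_state(1)[0] & 0x7FFFFFFF)


def build_grid(
    grid: GridSpec,
    schedule: FrameSchedule,
    input_model: InputFunctionModel,
    base_seed: int = 0,
) -> list[SimulationSpec]:
    """Cartesian product of the grid axes, in (K1, k2, delay, sigma) order.

    Per-spec noise seeds are derived deterministically from ``base_seed``
    and the linear grid index, so the full set is reproducible.
    """
    axes = [grid_values(grid.K1), grid_values(grid.k2), grid_values(grid.delay), grid_values(grid.sigma)]
    specs = []
    for idx, (K1, k2, delay, sigma) in enumerate(itertools.product(*axes)):
        specs.append(
            SimulationSpec(
                K1=float(K1), k2=float(k2), delay=float(delay), sigma=float(sigma),
                seed=spec_seed(base_seed, idx), schedule=schedule, input_model=input_model,
            )
        )
    return specs


def default_grid() -> GridSpec:
    """The benchmark parameter grid (see module docstring for the ranges)."""
    return GridSpec()
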