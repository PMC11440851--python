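"""Uniform callable interface over the three delay-estimation methods."""

from __future__ import annotations

import math
from typing import Callable

from .baselines import OneTissueDelayFitter, xcorr_delay
from .onset import OnsetConfig, estimate_onset
from .tac_core import TimeActivityCurve

__all__ = ["METHODS", "InputOnsetError", "make_estimator"]

METHODS = ("proposed", "xcorr", "onetc")


class InputOnsetError(RuntimeError):
    """The input-function onset could not be estimated; nothing can proceed."""


def make_estimator(
    method: str,
    input_fn: TimeActivityCurve,
    onset_config: OnsetConfig = OnsetConfig(),
    endtime: float = 180.0,
) -> Callable[[TimeActivityCurve], float]:
    """Bind a method name and input function into ``tissue -> delay (s)``.

    Per-input work (the input-function onset for the proposed method, the
    coarse model basis for the one-tissue fitter) is done once here, so the
    returned callable is cheap per tissue curve.  Failures are returned as
    NaN, except an unfittable input function which raises immediately.
    """
    if method == "proposed":
        t_input = estimate_onset(input_fn, onset_config)
        if not t_input.ok:
            raise InputOnsetError("onset estimation failed on the input function")

        def est(tissue: TimeActivityCurve) -> float:
            e = estimate_onset(tissue, onset_config)
            return e.onset_time - t_input.onset_time if e.ok else math.nan

        return est
    if method == "xcorr":
        return lambda tissue: xcorr_delay(tissue, input_fn)
    if method == "onetc":
        fitter = OneTissueDelayFitter(input_fn, endtime=endtime)
        return lambda tissue: fitter.fit(tissue).delay
    raise ValueError(f"unknown method {method!r}; available: {METHODS}")
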