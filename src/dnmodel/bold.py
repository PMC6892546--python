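"""BOLD-amplitude prediction from summed DN responses.

fMRI measures a single amplitude (percent signal change, from a GLM) per
temporal condition rather than a resolved time course. The DN account of
those amplitudes is: simulate the neuronal response to the condition's
contrast time course, sum it over the trial, and scale all condition sums
by one nonnegative gain. The standard condition set is 13 trials of 4.5 s:
one-pulse stimuli of increasing duration (0 = no stimulus up to 533 ms)
and two-pulse stimuli of two 134 ms flashes separated by an increasing
inter-stimulus interval (ISI). The linear baseline predicts amplitude
proportional to total stimulus-on time, hence identical responses for all
two-pulse conditions regardless of ISI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._engine import _safe_r2
from .model import DNParams, dn_response
from .timecourse import StimulusTimecourse, TimeGrid

__all__ = [
    "TrialCondition",
    "BoldPrediction",
    "ONE_PULSE_DURATIONS_MS",
    "TWO_PULSE_ISIS_MS",
    "build_conditions",
    "predict_bold",
    "linear_bold_prediction",
    "BoldGainModel",
]

#: Default one-pulse durations (ms): a doubling series from the 17 ms frame
#: up to the printed 533 ms endpoint, plus the blank condition.
ONE_PULSE_DURATIONS_MS = (0, 17, 33, 67, 134, 267, 533)

#: Default two-pulse inter-stimulus intervals (ms); each pulse lasts 134 ms.
TWO_PULSE_ISIS_MS = (17, 33, 67, 134, 267, 533)

PULSE_MS = 134
TRIAL_LENGTH_S = 4.5


@dataclass(frozen=True)
class TrialCondition:
    """One temporal condition: a single pulse or a pulse pair per trial."""

    kind: str  # "one_pulse" | "two_pulse"
    duration_ms: float  # pulse duration (one_pulse) or per-pulse 134 ms
    isi_ms: float = 0.0
    trial_length_s: float = TRIAL_LENGTH_S

    def __post_init__(self) -> None:
        if self.kind not in ("one_pulse", "two_pulse"):
            raise ValueError(f"unknown condition kind {self.kind!r}")
        if self.duration_ms < 0 or self.isi_ms < 0:
            raise ValueError("durations and ISIs must be nonnegative")

    @property
    def label(self) -> str:
        if self.kind == "one_pulse":
            return f"one_pulse_{self.duration_ms:g}ms"
        return f"two_pulse_isi{self.isi_ms:g}ms"


@dataclass(frozen=True)
class BoldPrediction:
    """A gain-scaled set of predicted condition amplitudes and its accuracy."""

    gain: float
    predicted: np.ndarray
    r2: float
    model: str = "dn"


def _condition_stimulus(cond: TrialCondition, grid: TimeGrid) -> StimulusTimecourse:
    values = np.zeros(grid.n)
    ms = 1e-3
    if cond.kind == "one_pulse":
        on = grid.times < cond.duration_ms * ms - 1e-12
        values[on] = 1.0
    else:
        t = grid.times
        first = t < PULSE_MS * ms - 1e-12
        start2 = (PULSE_MS + cond.isi_ms) * ms
        second = (t >= start2 - 1e-12) & (t < start2 + PULSE_MS * ms - 1e-12)
        values[first | second] = 1.0
    return StimulusTimecourse(grid, values)


def build_conditions(
    durations_ms: Sequence[float] = ONE_PULSE_DURATIONS_MS,
    isis_ms: Sequence[float] = TWO_PULSE_ISIS_MS,
    dt: float = 0.001,
    trial_length_s: float = TRIAL_LENGTH_S,
) -> Tuple[List[StimulusTimecourse], List[TrialCondition]]:
    """Stimulus time courses and metadata for the temporal condition set.

    Defaults give the standard 13 conditions: 7 one-pulse durations
    (including the 0 ms blank) and 6 two-pulse ISIs with 134 ms pulses,
    each on a 4.5 s trial grid at 1 ms resolution.
    """
    grid = TimeGrid(dt=dt, n=int(round(trial_length_s / dt)))
    conditions = [TrialCondition("one_pulse", float(d), trial_length_s=trial_length_s)
                  for d in durations_ms]
    conditions += [TrialCondition("two_pulse", float(PULSE_MS), float(isi),
                                  trial_length_s=trial_length_s)
                   for isi in isis_ms]
    stimuli = [_condition_stimulus(c, grid) for c in conditions]
    return stimuli, conditions


def summed_dn_responses(
    params: DNParams,
    stimuli: Sequence[StimulusTimecourse],
    pool_order: str = "filter_then_power",
) -> np.ndarray:
    """Trial-summed DN response per condition (the neuronal prediction)."""
    return np.array(
        [dn_response(s, params, pool_order=pool_order).values.sum() for s in stimuli]
    )


def _gain_fit(predictor: np.ndarray, measured: np.ndarray) -> Tuple[float, np.ndarray, float]:
    pp = float(predictor @ predictor)
    if pp <= 0:
        raise ValueError("degenerate fit: all predicted responses are zero")
    g = max(float(predictor @ measured) / pp, 0.0)
    predicted = g * predictor
    return g, predicted, _safe_r2(predictor, measured)


def predict_bold(
    params: DNParams,
    stimuli: Optional[Sequence[StimulusTimecourse]] = None,
    measured: Optional[np.ndarray] = None,
    pool_order: str = "filter_then_power",
) -> BoldPrediction:
    """DN prediction of per-condition BOLD amplitudes.

    Sums the DN response over each trial and fits one nonnegative gain
    (percent BOLD per summed-response unit) across all conditions by least
    squares. ``measured`` must hold one amplitude per condition.
    """
    if stimuli is None:
        stimuli, _ = build_conditions()
    sums = summed_dn_responses(params, stimuli, pool_order=pool_order)
    measured = np.asarray(measured, dtype=float)
    if measured.shape != sums.shape:
        raise ValueError("need one measured amplitude per condition")
    g, predicted, r2 = _gain_fit(sums, measured)
    return BoldPrediction(gain=g, predicted=predicted, r2=r2, model="dn")


def linear_bold_prediction(
    stimuli: Optional[Sequence[StimulusTimecourse]] = None,
    measured: Optional[np.ndarray] = None,
) -> BoldPrediction:
    """Linear baseline: amplitude proportional to total stimulus-on time.

    All two-pulse conditions share one predicted value irrespective of
    their ISI, which is exactly the failure mode the DN model corrects.
    """
    if stimuli is None:
        stimuli, _ = build_conditions()
    on_time = np.array([s.values.sum() * s.grid.dt for s in stimuli])
    measured = np.asarray(measured, dtype=float)
    if measured.shape != on_time.shape:
        raise ValueError("need one measured amplitude per condition")
    g, predicted, r2 = _gain_fit(on_time, measured)
    return BoldPrediction(gain=g, predicted=predicted, r2=r2, model="linear")


class BoldGainModel:
    """Estimator face of the BOLD gain fit.

    ``BoldGainModel(params).fit(stimuli, amplitudes)`` fits the single
    gain; ``linear=True`` fits the total-on-time baseline instead (then
    ``params`` is ignored). Fitted state: ``gain_``, ``predicted_``,
    ``r2_``.
    """

    def __init__(
        self,
        params: Optional[DNParams] = None,
        linear: bool = False,
        pool_order: str = "filter_then_power",
    ) -> None:
        self.params = params
        self.linear = linear
        self.pool_order = pool_order

    def get_params(self, deep: bool = True) -> dict:
        return {"params": self.params, "linear": self.linear,
                "pool_order": self.pool_order}

    def set_params(self, **kwargs) -> "BoldGainModel":
        for k, v in kwargs.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "BoldGainModel":
        stimuli = X if X is not None else build_conditions()[0]
        if self.linear:
            pred = linear_bold_prediction(stimuli, y)
        else:
            if self.params is None:
                raise ValueError("a DNParams is required unless linear=True")
            pred = predict_bold(self.params, stimuli, y, pool_order=self.pool_order)
        self.gain_ = pred.gain
        self.predicted_ = pred.predicted
        self.r2_ = pred.r2
        self.prediction_ = pred
        return self

    def predict(self, X) -> np.ndarray:
        if self.linear:
            base = np.array([s.values.sum() * s.grid.dt for s in X])
        else:
            base = summed_dn_responses(self.params, X, pool_order=self.pool_order)
        return self.gain_ * base
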