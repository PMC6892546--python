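"""Uniform time grids and the time-course containers shared across the package.

Everything downstream (stimuli, impulse-response kernels, model responses,
measured traces) lives on a :class:`TimeGrid`: a uniform sampling of time in
seconds, stimulus-locked so that t = 0 is stimulus onset. The default rate is
1 kHz, the rate of the ECoG recordings the model was developed against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeGrid",
    "StimulusTimecourse",
    "ResponseTimecourse",
    "Kernel",
    "GridError",
    "step_stimulus",
]

DEFAULT_DT = 0.001  # seconds; 1 kHz ECoG sampling


class GridError(ValueError):
    """Raised when time grids are invalid or incompatible."""


@dataclass(frozen=True)
class TimeGrid:
    """A uniform time axis.

    Parameters
    ----------
    dt : float
        Sample interval in seconds. Must be positive.
    n : int
        Number of samples. Must be at least 2.
    t0 : float, optional
        Time of the first sample in seconds, stimulus-locked (default 0).
    """

    dt: float
    n: int
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise GridError(f"dt must be positive, got {self.dt}")
        if self.n < 2:
            raise GridError(f"need at least 2 samples, got {self.n}")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) * self.dt

    @property
    def duration(self) -> float:
        """Span from first to last sample, in seconds."""
        return (self.n - 1) * self.dt

    def compatible(self, other: "TimeGrid") -> bool:
        """Whether two grids share a sample interval (within float tolerance)."""
        return bool(np.isclose(self.dt, other.dt, rtol=1e-9, atol=0.0))

    def require_compatible(self, other: "TimeGrid") -> None:
        if not self.compatible(other):
            raise GridError(f"grids have different dt: {self.dt} vs {other.dt}")

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (seconds)."""
        return int(round((t - self.t0) / self.dt))


def _as_array(values, n: int, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{what} must be 1-D, got shape {arr.shape}")
    if arr.shape[0] != n:
        raise GridError(f"{what} has {arr.shape[0]} samples but grid has {n}")
    return arr


@dataclass(frozen=True)
class StimulusTimecourse:
    """A contrast time course: one value in [0, 1] per sample.

    0 means no stimulus, 1 a full-contrast stimulus; intermediate values
    encode stimulus contrast.
    """

    grid: TimeGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = _as_array(self.values, self.grid.n, "stimulus")
        if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
            raise ValueError(
                f"stimulus contrast must lie in [0, 1]; range is "
                f"[{arr.min():g}, {arr.max():g}]"
            )
        object.__setattr__(self, "values", np.clip(arr, 0.0, 1.0))

    def scaled(self, contrast: float) -> "StimulusTimecourse":
        """The same time course scaled by a contrast factor in [0, 1]."""
        return StimulusTimecourse(self.grid, self.values * float(contrast))


@dataclass(frozen=True)
class ResponseTimecourse:
    """A model-stage or measured response, one value per sample.

    ``stage`` labels where in the model cascade the trace sits:
    ``linear`` (convolution output), ``rectified_exponentiated``,
    ``normalized`` (final model output, nonnegative), or ``measured``.
    """

    grid: TimeGrid
    values: np.ndarray = field(repr=False)
    stage: str = "measured"

    _STAGES = ("linear", "rectified_exponentiated", "normalized", "measured")

    def __post_init__(self) -> None:
        arr = _as_array(self.values, self.grid.n, "response")
        if self.stage not in self._STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "normalized" and arr.min() < 0:
            raise ValueError("normalized responses must be nonnegative")
        object.__setattr__(self, "values", arr)


@dataclass(frozen=True)
class Kernel:
    """A causal temporal filter sampled on a grid starting at t = 0.

    ``gamma`` and ``exp_lowpass`` kernels are normalized to unit sum so that
    convolution preserves the scale of a sustained input; ``biphasic``
    kernels sum to 1 - w, the net weight after subtracting the negative lobe.
    """

    grid: TimeGrid
    values: np.ndarray = field(repr=False)
    kind: str = "gamma"

    _KINDS = ("gamma", "biphasic", "exp_lowpass")

    def __post_init__(self) -> None:
        _as_array(self.values, self.grid.n, "kernel")
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if abs(self.grid.t0) > 1e-12:
            raise GridError("kernels are causal: their grid must start at t = 0")


def step_stimulus(
    duration: float,
    grid: TimeGrid,
    onset: float = 0.0,
    contrast: float = 1.0,
) -> StimulusTimecourse:
    """A pulse of the given contrast from ``onset`` to ``onset + duration``.

    Sample times t satisfying onset <= t < onset + duration are set to
    ``contrast``; everything else is 0.
    """
    t = grid.times
    values = np.where((t >= onset - 1e-12) & (t < onset + duration - 1e-12),
                      float(contrast), 0.0)
    return StimulusTimecourse(grid, values)
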