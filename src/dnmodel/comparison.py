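"""Comparison models: instantaneous normalization (CTS) and two temporal channels.

Both models share the DN model's linear front end but differ in what follows:

* **CTS** (compressive temporal summation) normalizes by the *instantaneous*
  drive, ``R = |R_L|^n / (sigma^n + |R_L|^n)``. It is the limit of the DN
  model as the normalization delay tau2 shrinks to zero, and because its
  gain pool never lags the drive it cannot produce the decay after the
  onset transient that sustained stimuli evoke.
* **Two temporal channels**: a weighted sum of a linear sustained channel
  and a squared transient channel, ``a [IRF_s * S] + b [IRF_t * S]^2``.
  Lacking gain control, it scales with contrast but predicts no slowing of
  the response at low contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import default_kernel_grid, make_biphasic_irf, make_gamma_kernel
from .model import _apply_shift, _causal_convolve
from .timecourse import ResponseTimecourse, StimulusTimecourse

__all__ = ["CTSParams", "TwoChannelParams", "cts_response", "two_channel_response"]


@dataclass(frozen=True, kw_only=True)
class CTSParams:
    """Parameters of the instantaneous-normalization (CTS) model.

    Identical to the DN parameterization minus the delay constant tau2.
    The exponent defaults to 2, the value fixed when fitting this model.
    """

    tau1: float
    sigma: float
    n: float = 2.0
    w: float = 0.0
    shift: float = 0.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau1 > 0:
            raise ValueError(f"tau1 must be positive, got {self.tau1}")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must lie in [0, 1], got {self.w}")
        if not self.n > 0:
            raise ValueError(f"n must be positive, got {self.n}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be nonnegative, got {self.sigma}")
        if self.shift < 0:
            raise ValueError(f"shift must be nonnegative, got {self.shift}")


@dataclass(frozen=True)
class TwoChannelParams:
    """Weights and time constant of the two-temporal-channels model.

    ``a`` scales the sustained (linear) channel, ``b`` the transient
    (squared) channel; both must be nonnegative. The transient channel uses
    a maximally biphasic impulse response built from the same gamma family
    as the sustained channel, sharing ``tau1``.
    """

    a: float
    b: float
    tau1: float = 0.05

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError(f"channel weights must be nonnegative, got a={self.a}, b={self.b}")
        if not self.tau1 > 0:
            raise ValueError(f"tau1 must be positive, got {self.tau1}")


def cts_response(stim: StimulusTimecourse, params: CTSParams) -> ResponseTimecourse:
    """Instantaneous-normalization prediction, bounded above by ``gain``."""
    dt = stim.grid.dt
    irf = make_biphasic_irf(params.tau1, params.w, default_kernel_grid(dt, 1.5 * params.tau1))
    rect = np.abs(_causal_convolve(stim.values, irf.values))
    num = rect ** params.n
    den = params.sigma ** params.n + num
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    out = params.gain * _apply_shift(out, params.shift, dt)
    return ResponseTimecourse(stim.grid, out, stage="normalized")


def two_channel_response(
    stim: StimulusTimecourse, params: TwoChannelParams
) -> ResponseTimecourse:
    """Sustained-plus-squared-transient prediction ``a R_s + b R_t^2``."""
    dt = stim.grid.dt
    grid = default_kernel_grid(dt, 1.5 * params.tau1)
    sustained = _causal_convolve(stim.values, make_gamma_kernel(params.tau1, grid).values)
    transient = _causal_convolve(stim.values, make_biphasic_irf(params.tau1, 1.0, grid).values)
    out = params.a * sustained + params.b * transient**2
    return ResponseTimecourse(stim.grid, out, stage="measured")
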