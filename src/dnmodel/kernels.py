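"""Temporal impulse-response and low-pass kernels.

Three kernel families parameterize the model:

* a monophasic gamma ``h(t) = t * exp(-t / tau1)`` (shape m = 2), normalized
  to unit sum, which peaks at t = tau1;
* a biphasic impulse response ``h1 = g(tau1) - w * g(1.5 tau1)``, the
  weighted difference of two unit-sum gammas, whose negative lobe produces a
  response transient at stimulus offset;
* an exponential low-pass ``h2(t) = exp(-t / tau2)``, unit-sum normalized,
  which averages the response history that drives the normalization pool.
"""

from __future__ import annotations

import numpy as np

from .timecourse import GridError, Kernel, TimeGrid

__all__ = [
    "SupportError",
    "make_gamma_kernel",
    "make_biphasic_irf",
    "make_exponential_lowpass",
    "default_kernel_grid",
]

# Fraction of the analytic kernel mass that must fall inside the grid.
_SUPPORT_FRACTION = 0.99

# Kernels are truncated at max(_TAU_MULTIPLE * tau, this span) seconds.
# Seven time constants leave > 99% of the gamma's mass inside the grid
# (five would capture only 96%, tripping the support check).
_MIN_KERNEL_SPAN = 1.2
_TAU_MULTIPLE = 7.0


class SupportError(GridError):
    """Raised when a kernel grid is too short to contain the kernel support."""


def default_kernel_grid(dt: float, tau: float, min_span: float = _MIN_KERNEL_SPAN) -> TimeGrid:
    """Grid spanning ``max(7 * tau, min_span)`` seconds from t = 0 at step dt."""
    span = max(_TAU_MULTIPLE * tau, min_span)
    n = int(round(span / dt)) + 1
    return TimeGrid(dt=dt, n=n, t0=0.0)


def _check_span(captured: float, span: float, tau: float) -> None:
    if captured < _SUPPORT_FRACTION:
        raise SupportError(
            f"kernel grid (span {span:g} s) captures only {captured:.3f} of the "
            f"kernel mass for tau = {tau:g} s; extend the grid"
        )


def make_gamma_kernel(tau1: float, grid: TimeGrid) -> Kernel:
    """Unit-sum gamma kernel ``t * exp(-t / tau1)`` sampled on ``grid``.

    The raw function peaks at t = tau1; normalization by the sample sum
    gives the kernel unit gain so that convolution with a long step
    asymptotes at the step height.
    """
    if not tau1 > 0:
        raise ValueError(f"tau1 must be positive, got {tau1}")
    t = grid.times
    # Mass of t*exp(-t/tau) on [0, T] relative to the full integral tau^2.
    T = t[-1]
    captured = 1.0 - np.exp(-T / tau1) * (1.0 + T / tau1)
    _check_span(captured, T, tau1)
    raw = t * np.exp(-t / tau1)
    return Kernel(grid, raw / raw.sum(), kind="gamma")


def make_biphasic_irf(tau1: float, w: float, grid: TimeGrid) -> Kernel:
    """Biphasic impulse response: unit-sum gamma minus ``w`` times a slower one.

    The second (negative) gamma peaks at exactly 1.5 * tau1. The result sums
    to 1 - w: w = 0 reduces to the monophasic gamma, w = 1 is maximally
    biphasic and integrates to zero, predicting no sustained response.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w must lie in [0, 1], got {w}")
    pos = make_gamma_kernel(tau1, grid)
    neg = make_gamma_kernel(1.5 * tau1, grid)
    return Kernel(grid, pos.values - w * neg.values, kind="biphasic")


def make_exponential_lowpass(tau2: float, grid: TimeGrid) -> Kernel:
    """Unit-sum exponential decay ``exp(-t / tau2)`` sampled on ``grid``.

    Normalization to unit sum makes the normalization pool a weighted
    average of the response history, so a constant input passes through
    unchanged and the semisaturation constant stays contrast-commensurate.
    """
    if not tau2 > 0:
        raise ValueError(f"tau2 must be positive, got {tau2}")
    t = grid.times
    T = t[-1]
    captured = 1.0 - np.exp(-T / tau2)
    _check_span(captured, T, tau2)
    raw = np.exp(-t / tau2)
    return Kernel(grid, raw / raw.sum(), kind="exp_lowpass")
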