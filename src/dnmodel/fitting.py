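"""Functional fitting interface.

Thin wrappers over the estimator classes in :mod:`dnmodel.estimators` and
the shared machinery in :mod:`dnmodel._engine`, for callers who prefer
plain functions and result objects to sklearn-style objects.
"""

from __future__ import annotations

from typing import Optional, Sequence

from ._engine import (
    BIPHASIC_BOUNDS,
    BIPHASIC_SEEDS,
    CONTRAST_FAMILY_SEEDS,
    ConstantDataError,
    FitBounds,
    FitResult,
    GridEvaluator,
    GridFitResult,
    GridRanges,
    ResampleResult,
    ResamplingError,
    SeedingError,
    grid_fit,
    resample_fit,
    scaled_shifted_fit,
    search_fit,
    variance_explained,
)
from .estimators import BiphasicDNModel, ContrastFamilyDNModel, DNTimecourseModel

__all__ = [
    "GridRanges",
    "FitBounds",
    "FitResult",
    "GridFitResult",
    "GridEvaluator",
    "ResampleResult",
    "SeedingError",
    "ResamplingError",
    "ConstantDataError",
    "BIPHASIC_SEEDS",
    "BIPHASIC_BOUNDS",
    "CONTRAST_FAMILY_SEEDS",
    "variance_explained",
    "grid_fit",
    "search_fit",
    "fit_timecourse",
    "fit_contrast_family",
    "fit_biphasic_electrode",
    "scaled_shifted_fit",
    "resample_fit",
]


def fit_timecourse(
    data,
    stim,
    ranges: Optional[GridRanges] = None,
    bounds: Optional[FitBounds] = None,
    pool_order: str = "filter_then_power",
    maxfev: int = 5000,
) -> FitResult:
    """Two-stage DN fit (grid seed + bounded simplex search) to a time course."""
    est = DNTimecourseModel(ranges=ranges, bounds=bounds,
                            pool_order=pool_order, maxfev=maxfev)
    return est.fit(stim, data).result_


def fit_contrast_family(
    psths,
    contrasts: Sequence[float],
    stim=None,
    seeds=None,
    pool_order: str = "filter_then_power",
    maxfev: int = 5000,
    stim_duration: float = 0.2,
) -> FitResult:
    """Fit one DN parameter set jointly to responses at several contrasts."""
    est = ContrastFamilyDNModel(base_stim=stim, duration=stim_duration,
                                seeds=seeds, pool_order=pool_order, maxfev=maxfev)
    return est.fit(contrasts, psths).result_


def fit_biphasic_electrode(
    data,
    stim,
    seeds=None,
    bounds=None,
    pool_order: str = "filter_then_power",
    maxfev: int = 5000,
) -> FitResult:
    """Fit (tau1, w, tau2, sigma, shift) with n fixed at 2 to one electrode."""
    est = BiphasicDNModel(seeds=seeds, bounds=bounds,
                          pool_order=pool_order, maxfev=maxfev)
    return est.fit(stim, data).result_
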