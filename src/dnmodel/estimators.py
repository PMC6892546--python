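"""scikit-learn-style estimators for the delayed-normalization model.

Each estimator follows the fit/predict contract: hyperparameters in the
constructor, data in ``fit``, fitted state in trailing-underscore
attributes. ``X`` is the stimulus side (a :class:`StimulusTimecourse`, a
sequence of them, or contrast levels for the family fit) and ``y`` the
measured response time course(s). The estimators compose with sklearn
utilities that rely only on ``get_params``/``set_params`` cloning.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import _engine
from ._engine import FitBounds, FitResult, GridRanges
from .model import DNParams, dn_response
from .timecourse import StimulusTimecourse, step_stimulus

__all__ = ["DNTimecourseModel", "BiphasicDNModel", "ContrastFamilyDNModel"]


def _store_result(est, result: FitResult) -> None:
    est.result_ = result
    est.params_ = result.params
    est.r2_ = result.r2
    est.sse_ = result.sse
    est.seed_used_ = result.seed_used
    est.n_iterations_ = result.n_iterations
    est.converged_ = result.converged


class DNTimecourseModel(RegressorMixin, BaseEstimator):
    """Standard DN fit: grid seeding then a bounded simplex search.

    Searches (tau1, tau2, n, sigma, shift) with a monophasic impulse
    response (w = 0); the output gain is solved analytically at every
    objective evaluation. Passing several stimulus/response pairs (for
    example the same step at two contrasts) fits one parameter set to all
    of them jointly, which disambiguates the n/sigma trade-off.

    Parameters
    ----------
    ranges : GridRanges, optional
        Seeding-grid ranges (default: 10 steps per parameter over
        tau1, tau2 in [0.07, 1] s, n in [1, 6], sigma in [0.01, 0.5]).
    bounds : FitBounds, optional
        Box bounds of the search stage, including the shift in
        [0.0001, 0.1] s.
    pool_order : str
        Denominator construction; see :func:`dnmodel.model.dn_response`.
    maxfev : int
        Objective-evaluation budget of the simplex search.

    Attributes
    ----------
    params_ : DNParams
        Fitted parameters including profiled gain and shift.
    r2_ : float
        Variance explained (squared Pearson correlation).
    seed_used_ : ndarray
        Winning grid node that seeded the search.
    """

    def __init__(
        self,
        ranges: Optional[GridRanges] = None,
        bounds: Optional[FitBounds] = None,
        pool_order: str = "filter_then_power",
        maxfev: int = 5000,
    ) -> None:
        self.ranges = ranges
        self.bounds = bounds
        self.pool_order = pool_order
        self.maxfev = maxfev

    def fit(self, X, y) -> "DNTimecourseModel":
        result = _engine.fit_timecourse(
            y, X, ranges=self.ranges, bounds=self.bounds,
            pool_order=self.pool_order, maxfev=self.maxfev,
        )
        _store_result(self, result)
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        if isinstance(X, StimulusTimecourse):
            return dn_response(X, self.params_, pool_order=self.pool_order).values
        return [dn_response(s, self.params_, pool_order=self.pool_order).values for s in X]

    def score(self, X, y, sample_weight=None) -> float:
        pred = self.predict(X)
        if isinstance(pred, list):
            pred = np.concatenate(pred)
            y = np.concatenate([_engine._values(d) for d in y])
        return _engine.variance_explained(pred, y)


class BiphasicDNModel(RegressorMixin, BaseEstimator):
    """Per-electrode DN fit with a biphasic impulse response.

    Searches (tau1, w, tau2, sigma, shift) with the exponent fixed at
    n = 2 and the negative IRF lobe peaking at 1.5 * tau1. Four standard
    seed vectors are scored and the best one starts the refinement; the
    per-seed scores are kept in ``seed_scores_``.
    """

    def __init__(
        self,
        seeds: Optional[Sequence[Sequence[float]]] = None,
        bounds: Optional[Sequence] = None,
        pool_order: str = "filter_then_power",
        maxfev: int = 5000,
    ) -> None:
        self.seeds = seeds
        self.bounds = bounds
        self.pool_order = pool_order
        self.maxfev = maxfev

    def fit(self, X, y) -> "BiphasicDNModel":
        result = _engine.fit_biphasic_electrode(
            y, X, seeds=self.seeds, bounds=self.bounds,
            pool_order=self.pool_order, maxfev=self.maxfev,
        )
        _store_result(self, result)
        self.seed_scores_ = result.seed_scores
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        return dn_response(X, self.params_, pool_order=self.pool_order).values


class ContrastFamilyDNModel(RegressorMixin, BaseEstimator):
    """One DN parameter set fit jointly across stimulus contrasts.

    ``fit(X, y)`` takes the contrast levels as ``X`` (values in [0, 1])
    and the matching response time courses as ``y`` (one row per
    contrast). The model input at contrast c is the base stimulus scaled
    by c; by default the base is a ``duration``-second unit-contrast pulse
    on the responses' grid. Two printed seed vectors start unbounded
    simplex searches and the better final objective wins.
    """

    def __init__(
        self,
        base_stim: Optional[StimulusTimecourse] = None,
        duration: float = 0.2,
        seeds: Optional[Sequence[Sequence[float]]] = None,
        pool_order: str = "filter_then_power",
        maxfev: int = 5000,
    ) -> None:
        self.base_stim = base_stim
        self.duration = duration
        self.seeds = seeds
        self.pool_order = pool_order
        self.maxfev = maxfev

    def fit(self, X, y) -> "ContrastFamilyDNModel":
        base = self.base_stim
        if base is None:
            first = y[0]
            if hasattr(first, "grid"):
                base = step_stimulus(self.duration, first.grid)
        self._default_base_ = base
        result = _engine.fit_contrast_family(
            y, X, stim=base, seeds=self.seeds,
            pool_order=self.pool_order, maxfev=self.maxfev,
            stim_duration=self.duration,
        )
        _store_result(self, result)
        self.seed_scores_ = result.seed_scores
        return self

    def predict(self, X, base_stim: Optional[StimulusTimecourse] = None) -> np.ndarray:
        """Predicted response matrix, one row per contrast in ``X``."""
        check_is_fitted(self, "params_")
        base = base_stim or self.base_stim or self._default_base_
        return np.asarray(
            [
                dn_response(base.scaled(c), self.params_, pool_order=self.pool_order).values
                for c in np.asarray(X, dtype=float)
            ]
        )
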