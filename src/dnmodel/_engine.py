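"""Fitting machinery: grid seeding, bounded simplex search, resampling.

This module is internal; the public faces are the estimator classes in
:mod:`dnmodel.estimators` and the thin functional wrappers in
:mod:`dnmodel.fitting`.

Estimation follows a two-stage scheme. A coarse grid over
(tau1, tau2, n, sigma) — 10 steps per parameter, 10^4 nodes — is evaluated
with the output gain solved analytically by least squares at every node,
and the node with the highest variance explained seeds a bounded
derivative-free simplex search over (tau1, tau2, n, sigma, shift), again
with the gain profiled out at each objective evaluation. The grid
predictions do not depend on the data, so they are computed once and
re-scored cheaply against every bootstrap draw or cross-validation fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize
from scipy.stats import pearsonr

from .kernels import default_kernel_grid, make_biphasic_irf, make_exponential_lowpass
from .model import DNParams, _causal_convolve, dn_response
from .timecourse import ResponseTimecourse, StimulusTimecourse

__all__ = [
    "GridRanges",
    "FitBounds",
    "FitResult",
    "ResampleResult",
    "SeedingError",
    "ResamplingError",
    "ConstantDataError",
    "variance_explained",
]

GAIN_FLOOR = 1e-12

#: Seeds printed for the joint contrast-family fit (tau1, tau2, n, sigma, shift).
CONTRAST_FAMILY_SEEDS = (
    (0.1, 0.1, 2.0, 0.2, 0.03),
    (0.1, 0.1, 3.0, 0.1, 0.04),
)

#: Seeds for the per-electrode biphasic fit (tau1, w, tau2, sigma, shift);
#: n is fixed at 2 for that fit.
BIPHASIC_SEEDS = (
    (0.02, 0.8, 0.15, 0.1, 0.05),
    (0.03, 0.8, 0.1, 0.2, 0.05),
    (0.02, 0.4, 0.15, 0.1, 0.05),
    (0.03, 0.4, 0.1, 0.2, 0.05),
)

#: Bounds for the biphasic fit: the printed biphasic seeds (tau1 = 20-30 ms)
#: lie below the standard tau1 lower bound, so that fit gets wider bounds.
BIPHASIC_BOUNDS = ((1e-3, 1.0), (0.0, 1.0), (1e-3, 1.0), (1e-3, 1.0), (0.0, 0.1))


class SeedingError(RuntimeError):
    """Raised when the grid stage cannot produce a usable seed."""


class ResamplingError(ValueError):
    """Raised when a dataset is too small along the resampled axis."""


class ConstantDataError(ValueError):
    """Raised when variance explained is requested against constant data."""


@dataclass(frozen=True)
class GridRanges:
    """Per-parameter (lo, hi) ranges and step count for the seeding grid."""

    tau1: Tuple[float, float] = (0.07, 1.0)
    tau2: Tuple[float, float] = (0.07, 1.0)
    n: Tuple[float, float] = (1.0, 6.0)
    sigma: Tuple[float, float] = (0.01, 0.5)
    n_steps: int = 10

    def __post_init__(self) -> None:
        for name in ("tau1", "tau2", "n", "sigma"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} range must have lo < hi, got ({lo}, {hi})")
        if self.n_steps < 2:
            raise ValueError(f"n_steps must be >= 2, got {self.n_steps}")

    def axes(self) -> dict:
        return {
            name: np.linspace(*getattr(self, name), self.n_steps)
            for name in ("tau1", "tau2", "n", "sigma")
        }


@dataclass(frozen=True)
class FitBounds:
    """Box bounds over (tau1, tau2, n, sigma, shift) for the search fit."""

    lower: Tuple[float, ...] = (0.07, 0.07, 1.0, 0.01, 0.0001)
    upper: Tuple[float, ...] = (1.0, 1.0, 6.0, 0.5, 0.1)

    def __post_init__(self) -> None:
        if len(self.lower) != 5 or len(self.upper) != 5:
            raise ValueError("bounds must cover (tau1, tau2, n, sigma, shift)")
        if any(lo >= hi for lo, hi in zip(self.lower, self.upper)):
            raise ValueError("each lower bound must be below its upper bound")

    def contains(self, theta: np.ndarray, atol: float = 1e-12) -> bool:
        theta = np.asarray(theta, dtype=float)
        lo = np.asarray(self.lower)[: theta.size]
        hi = np.asarray(self.upper)[: theta.size]
        return bool(np.all(theta >= lo - atol) and np.all(theta <= hi + atol))

    def pairs(self) -> List[Tuple[float, float]]:
        return list(zip(self.lower, self.upper))


@dataclass
class FitResult:
    """Outcome of a model fit.

    ``params`` carries the fitted parameter set including the profiled gain
    and the nuisance shift; ``r2`` is the squared Pearson correlation
    between prediction and data.
    """

    params: DNParams
    r2: float
    sse: float
    seed_used: np.ndarray
    n_iterations: int
    converged: bool
    seed_scores: Optional[List[Tuple[np.ndarray, float]]] = None


@dataclass
class ResampleResult:
    """Bootstrap or leave-one-out refits of the DN model.

    ``predictions`` holds one fitted prediction time course per draw/fold;
    ``ci_low``/``ci_high`` are the per-timepoint 25th and 75th percentiles
    (the 50% interval) of those predictions, and ``pred_center`` their
    median. For leave-one-out modes ``cv_r2`` holds the held-out variance
    explained per fold.
    """

    mode: str
    fits: List[FitResult]
    predictions: np.ndarray
    pred_center: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    train_r2: np.ndarray
    cv_r2: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# scoring helpers
# ---------------------------------------------------------------------------

def _values(x) -> np.ndarray:
    if isinstance(x, (ResponseTimecourse, StimulusTimecourse)):
        return x.values
    return np.asarray(x, dtype=float)


def variance_explained(pred, data) -> float:
    """Squared Pearson correlation between a prediction and data.

    Scale- and offset-invariant. Raises :class:`ConstantDataError` when the
    data have no variance (the correlation is undefined there).
    """
    p, d = _values(pred), _values(data)
    if p.shape != d.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {d.shape}")
    if np.ptp(d) == 0:
        raise ConstantDataError("variance explained is undefined for constant data")
    if np.ptp(p) == 0:
        return 0.0
    return float(pearsonr(p, d)[0] ** 2)


def _safe_r2(pred: np.ndarray, data: np.ndarray) -> float:
    """Like :func:`variance_explained` but 0.0 for degenerate inputs."""
    try:
        return variance_explained(pred, data)
    except ConstantDataError:
        return 0.0


def _profiled_gain(pred: np.ndarray, data: np.ndarray) -> float:
    """Closed-form least-squares output gain, clamped to a positive floor."""
    pp = float(pred @ pred)
    if pp <= 0:
        return GAIN_FLOOR
    return max(float(pred @ data) / pp, GAIN_FLOOR)


def _as_stim_list(stim) -> List[StimulusTimecourse]:
    if isinstance(stim, StimulusTimecourse):
        return [stim]
    stims = list(stim)
    if not stims or not all(isinstance(s, StimulusTimecourse) for s in stims):
        raise TypeError("stim must be a StimulusTimecourse or a sequence of them")
    for s in stims[1:]:
        stims[0].grid.require_compatible(s.grid)
    return stims


def _as_data_arrays(data, stims: List[StimulusTimecourse]) -> List[np.ndarray]:
    if isinstance(data, (ResponseTimecourse, np.ndarray)) and (
        not isinstance(data, np.ndarray) or data.ndim == 1
    ):
        arrays = [_values(data)]
    else:
        arrays = [_values(d) for d in data]
    if len(arrays) != len(stims):
        raise ValueError(f"{len(arrays)} data traces for {len(stims)} stimuli")
    for arr, s in zip(arrays, stims):
        if arr.shape[0] != s.grid.n:
            raise ValueError("data and stimulus lengths differ")
    return arrays


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

class DNObjective:
    """Sum-of-squares objective with the output gain profiled out.

    ``mode="standard"`` searches (tau1, tau2, n, sigma, shift) with w = 0;
    ``mode="biphasic"`` searches (tau1, w, tau2, sigma, shift) with n fixed.
    Invalid parameter regions return an infinite objective so unbounded
    simplex searches stay out of them.
    """

    def __init__(
        self,
        stims,
        data,
        mode: str = "standard",
        pool_order: str = "filter_then_power",
        fixed_n: float = 2.0,
    ) -> None:
        self.stims = _as_stim_list(stims)
        self.arrays = _as_data_arrays(data, self.stims)
        self.data = np.concatenate(self.arrays)
        self.mode = mode
        self.pool_order = pool_order
        self.fixed_n = fixed_n
        self.dt = self.stims[0].grid.dt

    def params_from_theta(self, theta) -> Optional[DNParams]:
        theta = np.asarray(theta, dtype=float)
        try:
            if self.mode == "standard":
                tau1, tau2, n, sigma, shift = theta
                return DNParams(tau1=tau1, tau2=tau2, n=n, sigma=sigma,
                                w=0.0, shift=shift)
            tau1, w, tau2, sigma, shift = theta
            return DNParams(tau1=tau1, tau2=tau2, n=self.fixed_n, sigma=sigma,
                            w=w, shift=shift)
        except ValueError:
            return None

    def predict(self, theta) -> Optional[np.ndarray]:
        params = self.params_from_theta(theta)
        if params is None:
            return None
        return np.concatenate(
            [dn_response(s, params, pool_order=self.pool_order).values for s in self.stims]
        )

    def sse(self, theta) -> float:
        pred = self.predict(theta)
        if pred is None or not np.all(np.isfinite(pred)):
            return np.inf
        g = _profiled_gain(pred, self.data)
        resid = self.data - g * pred
        return float(resid @ resid)

    def result(self, theta, seed_used, n_iterations: int, converged: bool) -> FitResult:
        pred = self.predict(theta)
        g = _profiled_gain(pred, self.data)
        resid = self.data - g * pred
        params = self.params_from_theta(theta).replace(gain=g)
        return FitResult(
            params=params,
            r2=_safe_r2(pred, self.data),
            sse=float(resid @ resid),
            seed_used=np.asarray(seed_used, dtype=float),
            n_iterations=n_iterations,
            converged=converged,
        )


# ---------------------------------------------------------------------------
# grid stage
# ---------------------------------------------------------------------------

class GridEvaluator:
    """Precomputed DN predictions at every node of the seeding grid.

    Nodes enumerate (tau1, tau2, n, sigma) in lexicographic order with
    w = 0 and shift = 0; the first node attaining the maximal variance
    explained wins, which makes tie-breaking deterministic. Predictions are
    independent of the data, so one evaluator serves any number of
    bootstrap draws or folds on the same stimuli.
    """

    def __init__(
        self,
        stims,
        ranges: Optional[GridRanges] = None,
        pool_order: str = "filter_then_power",
    ) -> None:
        self.stims = _as_stim_list(stims)
        self.ranges = ranges or GridRanges()
        self.pool_order = pool_order
        axes = self.ranges.axes()
        tau1s, tau2s = axes["tau1"], axes["tau2"]
        ns, sigmas = axes["n"], axes["sigma"]
        dt = self.stims[0].grid.dt
        T = sum(s.grid.n for s in self.stims)
        k = self.ranges.n_steps
        self.nodes = np.empty((k**4, 4))
        self.preds = np.empty((k**4, T))
        row = 0
        for t1 in tau1s:
            irf = make_biphasic_irf(t1, 0.0, default_kernel_grid(dt, 1.5 * t1))
            rects = [np.abs(_causal_convolve(s.values, irf.values)) for s in self.stims]
            for t2 in tau2s:
                h2 = make_exponential_lowpass(t2, default_kernel_grid(dt, t2))
                pools = [np.maximum(_causal_convolve(r, h2.values), 0.0) for r in rects]
                for n_exp in ns:
                    nums = np.concatenate([r**n_exp for r in rects])
                    pool_n = np.concatenate([p**n_exp for p in pools])
                    if pool_order == "power_then_filter":
                        pool_n = np.concatenate(
                            [_causal_convolve(r**n_exp, h2.values) for r in rects]
                        )
                    for sig in sigmas:
                        den = sig**n_exp + pool_n
                        self.preds[row] = np.divide(
                            nums, den, out=np.zeros_like(nums), where=den > 0
                        )
                        self.nodes[row] = (t1, t2, n_exp, sig)
                        row += 1
        # Sufficient statistics for fast correlation against any data vector.
        self._row_sum = self.preds.sum(axis=1)
        self._row_ss = np.einsum("ij,ij->i", self.preds, self.preds)
        self._T = T

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def best(self, data: np.ndarray) -> Tuple[np.ndarray, float, float]:
        """(seed node, profiled gain, r^2) of the best-correlating node."""
        d = np.asarray(data, dtype=float)
        if d.shape[0] != self._T:
            raise ValueError("data length does not match the grid predictions")
        dc = d - d.mean()
        dn = float(dc @ dc)
        if dn <= 0:
            raise SeedingError("cannot seed the fit from constant data")
        num = self.preds @ dc
        pred_var = self._row_ss - self._row_sum**2 / self._T
        valid = pred_var > 1e-300
        if not valid.any():
            raise SeedingError("all grid predictions are constant; cannot seed")
        r2 = np.full(self.n_nodes, -np.inf)
        r2[valid] = num[valid] ** 2 / (pred_var[valid] * dn)
        idx = int(np.argmax(r2))
        pred = self.preds[idx]
        return self.nodes[idx].copy(), _profiled_gain(pred, d), float(r2[idx])


@dataclass
class GridFitResult:
    """Winning grid node: seed vector (tau1, tau2, n, sigma), its gain and r^2."""

    seed: np.ndarray
    gain: float
    r2: float


def grid_fit(
    data,
    stim,
    ranges: Optional[GridRanges] = None,
    evaluator: Optional[GridEvaluator] = None,
    pool_order: str = "filter_then_power",
) -> GridFitResult:
    """Evaluate the seeding grid and return the best node."""
    if evaluator is None:
        evaluator = GridEvaluator(stim, ranges=ranges, pool_order=pool_order)
    arrays = _as_data_arrays(data, evaluator.stims)
    seed, gain, r2 = evaluator.best(np.concatenate(arrays))
    return GridFitResult(seed=seed, gain=gain, r2=r2)


# ---------------------------------------------------------------------------
# simplex search
# ---------------------------------------------------------------------------

_XTOL = 1e-6
_FTOL = 1e-6
_MAXFEV = 5000


def _simplex(
    fun: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: Optional[Sequence[Tuple[float, float]]],
    maxfev: int = _MAXFEV,
):
    """Nelder-Mead with a restart from the first optimum, within one budget."""
    budget1 = max(int(maxfev * 0.6), 1)
    res = minimize(
        fun, x0, method="Nelder-Mead", bounds=bounds,
        options={"xatol": _XTOL, "fatol": _FTOL, "maxfev": budget1},
    )
    res2 = minimize(
        fun, res.x, method="Nelder-Mead", bounds=bounds,
        options={"xatol": _XTOL, "fatol": _FTOL,
                 "maxfev": max(maxfev - res.nfev, 1)},
    )
    best = res2 if res2.fun <= res.fun else res
    best.nit = res.nit + res2.nit
    best.success = bool(res.success or res2.success)
    return best


def search_fit(
    data,
    stim,
    seed,
    bounds: Optional[FitBounds] = None,
    pool_order: str = "filter_then_power",
    maxfev: int = _MAXFEV,
) -> FitResult:
    """Bounded simplex refinement of (tau1, tau2, n, sigma, shift).

    ``seed`` is the 4-vector from the grid stage (shift is then seeded near
    its lower bound) or a full 5-vector. The output gain is profiled out
    analytically at every objective evaluation.
    """
    bounds = bounds or FitBounds()
    seed = np.asarray(seed, dtype=float)
    if seed.size == 4:
        shift0 = float(np.clip(0.001, bounds.lower[4], bounds.upper[4]))
        x0 = np.append(seed, shift0)
    elif seed.size == 5:
        x0 = seed.copy()
    else:
        raise ValueError("seed must have 4 or 5 entries")
    if not bounds.contains(x0):
        raise ValueError(f"seed {x0} lies outside the fit bounds")
    obj = DNObjective(stim, data, mode="standard", pool_order=pool_order)
    res = _simplex(obj.sse, x0, bounds.pairs(), maxfev=maxfev)
    return obj.result(res.x, seed, res.nit, bool(res.success))


def fit_timecourse(
    data,
    stim,
    ranges: Optional[GridRanges] = None,
    bounds: Optional[FitBounds] = None,
    pool_order: str = "filter_then_power",
    maxfev: int = _MAXFEV,
) -> FitResult:
    """Two-stage fit: grid seed, then bounded simplex search."""
    gf = grid_fit(data, stim, ranges=ranges, pool_order=pool_order)
    return search_fit(data, stim, gf.seed, bounds=bounds,
                      pool_order=pool_order, maxfev=maxfev)


def fit_contrast_family(
    psths,
    contrasts: Sequence[float],
    stim: Optional[StimulusTimecourse] = None,
    seeds: Optional[Sequence[Sequence[float]]] = None,
    pool_order: str = "filter_then_power",
    maxfev: int = _MAXFEV,
    stim_duration: float = 0.2,
) -> FitResult:
    """One DN parameter set fit jointly to responses at several contrasts.

    The model input for contrast ``c`` is the base stimulus time course
    scaled by ``c``; a single (tau1, tau2, n, sigma, shift, gain) minimizes
    the summed squared error over all conditions. Each seed in ``seeds``
    (two defaults) starts an unbounded simplex search; the best final
    objective wins.
    """
    psths = list(psths)
    contrasts = np.asarray(list(contrasts), dtype=float)
    if contrasts.min() < 0 or contrasts.max() > 1:
        raise ValueError("contrasts must lie in [0, 1]")
    if len(psths) != contrasts.size:
        raise ValueError(f"{len(psths)} responses for {contrasts.size} contrasts")
    if stim is None:
        first = psths[0]
        if isinstance(first, ResponseTimecourse):
            grid = first.grid
        else:
            # Bare arrays carry no grid; assume the standard 1 kHz sampling.
            from .timecourse import TimeGrid

            grid = TimeGrid(dt=0.001, n=len(np.asarray(first)))
        from .timecourse import step_stimulus

        stim = step_stimulus(stim_duration, grid)
    stims = [stim.scaled(c) for c in contrasts]
    obj = DNObjective(stims, psths, mode="standard", pool_order=pool_order)
    seeds = [np.asarray(s, dtype=float) for s in (seeds or CONTRAST_FAMILY_SEEDS)]
    best = None
    seed_scores = []
    for s in seeds:
        res = _simplex(obj.sse, s, bounds=None, maxfev=maxfev)
        seed_scores.append((s, float(res.fun)))
        if best is None or res.fun < best[0].fun:
            best = (res, s)
    res, seed = best
    fr = obj.result(res.x, seed, res.nit, bool(res.success))
    fr.seed_scores = seed_scores
    return fr


def fit_biphasic_electrode(
    data,
    stim,
    seeds: Optional[Sequence[Sequence[float]]] = None,
    bounds: Optional[Sequence[Tuple[float, float]]] = None,
    pool_order: str = "filter_then_power",
    maxfev: int = _MAXFEV,
) -> FitResult:
    """Per-electrode fit of (tau1, w, tau2, sigma, shift) with n fixed at 2.

    Each of the four default seed vectors is scored first; the best seed
    (highest variance explained) starts the simplex refinement. The
    negative IRF lobe peaks at 1.5 * tau1.
    """
    obj = DNObjective(stim, data, mode="biphasic", fixed_n=2.0, pool_order=pool_order)
    seeds = [np.asarray(s, dtype=float) for s in (seeds or BIPHASIC_SEEDS)]
    seed_scores = []
    for s in seeds:
        pred = obj.predict(s)
        r2 = _safe_r2(pred, obj.data) if pred is not None else -np.inf
        seed_scores.append((s, float(r2)))
    best_seed = max(seed_scores, key=lambda t: t[1])[0]
    res = _simplex(obj.sse, best_seed, list(bounds or BIPHASIC_BOUNDS), maxfev=maxfev)
    fr = obj.result(res.x, best_seed, res.nit, bool(res.success))
    fr.seed_scores = seed_scores
    return fr


# ---------------------------------------------------------------------------
# scaled/shifted-copy analysis
# ---------------------------------------------------------------------------

def scaled_shifted_fit(
    reference,
    target,
    dt: Optional[float] = None,
) -> Tuple[float, float, float]:
    """Best nonnegative scale and integer-sample shift of one trace onto another.

    Returns ``(scale, shift, r2)``. The shift is reported in seconds when a
    sample interval is known (from ``dt`` or the traces' grids), otherwise
    in samples. Used to test whether responses at different contrasts are
    scaled and shifted copies of one another.
    """
    if isinstance(reference, ResponseTimecourse) and isinstance(target, ResponseTimecourse):
        reference.grid.require_compatible(target.grid)
        if dt is None:
            dt = reference.grid.dt
    ref, tgt = _values(reference), _values(target)
    if ref.shape != tgt.shape:
        raise ValueError("reference and target must share a grid")
    if not np.any(ref):
        raise ValueError("reference trace is identically zero")
    n = ref.shape[0]
    best = None  # (sse, shift_samples, scale, pred)
    for s in range(-(n - 1), n):
        shifted = np.zeros(n)
        if s >= 0:
            shifted[s:] = ref[: n - s]
        else:
            shifted[: n + s] = ref[-s:]
        pp = float(shifted @ shifted)
        if pp <= 0:
            continue
        scale = max(0.0, float(shifted @ tgt) / pp)
        resid = tgt - scale * shifted
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, s, scale, scale * shifted)
    _, s, scale, pred = best
    r2 = _safe_r2(pred, tgt)
    shift = s * dt if dt is not None else float(s)
    return float(scale), float(shift), float(r2)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

RESAMPLE_MODES = ("bootstrap_electrodes", "loo_trials", "loo_electrodes")


def resample_fit(
    data: np.ndarray,
    stim,
    mode: str,
    n_draws: int = 100,
    rng_seed: Optional[int] = None,
    ranges: Optional[GridRanges] = None,
    bounds: Optional[FitBounds] = None,
    pool_order: str = "filter_then_power",
    maxfev: int = _MAXFEV,
) -> ResampleResult:
    """Refit the DN model under bootstrap or leave-one-out resampling.

    ``data`` is (units x time): electrodes for the bootstrap and
    electrode-LOO modes, trials for trial-LOO. Bootstrap draws sample units
    with replacement, refit the averaged time course, and summarize the
    per-draw predictions by their median and 25th-75th percentile (50%)
    interval. LOO modes hold one unit out per fold and score the fitted
    prediction against it. Fits of byte-identical averaged traces are
    computed once and reused, which leaves results unchanged.
    """
    if mode not in RESAMPLE_MODES:
        raise ValueError(f"mode must be one of {RESAMPLE_MODES}")
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (units x time)")
    n_units = data.shape[0]
    if n_units < 2:
        raise ResamplingError("need at least 2 units along the resampled axis")

    evaluator = GridEvaluator(stim, ranges=ranges, pool_order=pool_order)
    obj = DNObjective(stim, [data.mean(axis=0)], mode="standard", pool_order=pool_order)
    fit_bounds = bounds or FitBounds()
    cache: dict = {}

    def fit_avg(avg: np.ndarray) -> Tuple[FitResult, np.ndarray]:
        key = avg.tobytes()
        if key not in cache:
            seed, _, _ = evaluator.best(avg)
            fr = search_fit(avg, evaluator.stims, seed, bounds=fit_bounds,
                            pool_order=pool_order, maxfev=maxfev)
            theta = np.array([fr.params.tau1, fr.params.tau2, fr.params.n,
                              fr.params.sigma, fr.params.shift])
            pred = fr.params.gain * obj.predict(theta)
            cache[key] = (fr, pred)
        return cache[key]

    fits: List[FitResult] = []
    preds: List[np.ndarray] = []
    cv_r2: List[float] = []

    if mode == "bootstrap_electrodes":
        rng = np.random.default_rng(rng_seed)
        for _ in range(n_draws):
            idx = rng.integers(0, n_units, size=n_units)
            fr, pred = fit_avg(data[idx].mean(axis=0))
            fits.append(fr)
            preds.append(pred)
    else:
        for u in range(n_units):
            keep = np.arange(n_units) != u
            fr, pred = fit_avg(data[keep].mean(axis=0))
            fits.append(fr)
            preds.append(pred)
            cv_r2.append(_safe_r2(pred, data[u]))

    predictions = np.asarray(preds)
    return ResampleResult(
        mode=mode,
        fits=fits,
        predictions=predictions,
        pred_center=np.median(predictions, axis=0),
        ci_low=np.percentile(predictions, 25, axis=0),
        ci_high=np.percentile(predictions, 75, axis=0),
        train_r2=np.array([f.r2 for f in fits]),
        cv_r2=np.asarray(cv_r2) if cv_r2 else None,
    )
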