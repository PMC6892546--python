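"""Broadband-envelope extraction from raw field-potential voltage.

The target signal of the DN model in intracranial recordings is the
time-varying "broadband" power — envelope power of the voltage across
high-frequency bins (70-210 Hz by default), a proxy for the local
population firing rate. Extraction proceeds per 10-Hz bin to keep the
steep 1/f power decline from letting the lowest frequencies dominate:
band-pass filter, take the squared magnitude of the analytic signal,
then combine bins with a geometric mean so the low-power high-frequency
bins still contribute. Bins containing a line-noise harmonic are dropped.
Trial-averaged traces are converted to fractional change relative to the
pre-stimulus baseline and re-zeroed so every electrode's baseline is 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import butter, buttord, hilbert, sosfiltfilt
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "BandSpec",
    "design_band_bins",
    "bandpass_envelope",
    "combine_bands",
    "epoch_normalize",
    "select_electrodes",
    "bin_by_eccentricity",
    "BroadbandExtractor",
]


class BandDesignError(ValueError):
    """Raised when no usable frequency bins or filters can be designed."""


@dataclass(frozen=True)
class BandSpec:
    """Plan of band-pass bins with line-noise harmonics excluded."""

    bins: Tuple[Tuple[float, float], ...]
    line_freq: float
    excluded_harmonics: Tuple[float, ...]


def design_band_bins(
    f_lo: float = 70.0,
    f_hi: float = 210.0,
    width: float = 10.0,
    line_freq: float = 60.0,
) -> BandSpec:
    """Contiguous ``width``-Hz bins over [f_lo, f_hi], skipping line harmonics.

    A bin is dropped when any multiple of ``line_freq`` falls inside its
    closed interval. The defaults (70-210 Hz, 10 Hz bins, 60 Hz mains)
    yield exactly ten bins, excluding the decades around 120 and 180 Hz.
    ``line_freq = 0`` disables the exclusion.
    """
    if not f_lo < f_hi:
        raise ValueError(f"need f_lo < f_hi, got ({f_lo}, {f_hi})")
    if not width > 0:
        raise ValueError(f"width must be positive, got {width}")
    edges = np.arange(f_lo, f_hi + 1e-9, width)
    harmonics = []
    if line_freq > 0:
        harmonics = [h for h in np.arange(line_freq, f_hi + width, line_freq)
                     if h >= f_lo - width]
    bins = []
    excluded = set()
    for lo, hi in zip(edges[:-1], edges[1:]):
        inside = [h for h in harmonics if lo <= h <= hi]
        if inside:
            excluded.update(inside)
            continue
        bins.append((float(lo), float(hi)))
    if not bins:
        raise BandDesignError("no bins survive the line-noise exclusion")
    return BandSpec(tuple(bins), float(line_freq), tuple(sorted(excluded)))


def _design_filter(band: Tuple[float, float], fs: float):
    lo, hi = band
    nyq = fs / 2.0
    if not 0 < lo < hi:
        raise BandDesignError(f"invalid band {band}")
    if hi + 10.0 >= nyq:
        raise BandDesignError(
            f"band {band} too close to the Nyquist frequency {nyq:g} Hz"
        )
    # Passband ripple < 3 dB, >= 60 dB attenuation 10 Hz beyond the edges.
    order, wn = buttord(wp=[lo, hi], ws=[max(lo - 10.0, 1e-3), hi + 10.0],
                        gpass=3.0, gstop=60.0, fs=fs)
    return butter(order, wn, btype="bandpass", output="sos", fs=fs)


def bandpass_envelope(
    voltage: np.ndarray,
    band: Tuple[float, float],
    fs: float,
) -> np.ndarray:
    """Per-sample envelope power of zero-phase band-passed voltage.

    Filters forward-backward (zero phase) with an order-selected
    Butterworth band-pass, takes the magnitude of the analytic signal as
    the envelope, and returns the squared envelope. Works on any array
    whose last axis is time.
    """
    sos = _design_filter(band, fs)
    filtered = sosfiltfilt(sos, np.asarray(voltage, dtype=float), axis=-1)
    envelope = np.abs(hilbert(filtered, axis=-1))
    return envelope**2


def combine_bands(band_powers: Sequence[np.ndarray]) -> np.ndarray:
    """Pointwise geometric mean of per-band power series.

    The geometric mean keeps the low-power high-frequency bins influential;
    an arithmetic mean would be dominated by the lowest band. Zeros are
    floored at 1e-300 before the log so the result stays finite.
    """
    stack = np.asarray(band_powers, dtype=float)
    if stack.shape[0] < 1:
        raise ValueError("need at least one band")
    if stack.min() < 0:
        raise ValueError("band powers must be nonnegative")
    return np.exp(np.log(np.clip(stack, 1e-300, None)).mean(axis=0))


def epoch_normalize(
    broadband: np.ndarray,
    baseline: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Convert trial broadband to baseline-zeroed fractional signal change.

    ``broadband`` is (electrodes x trials x time); ``baseline`` is a boolean
    mask over the time axis marking the pre-stimulus window. Per electrode:
    average over trials, divide pointwise by the baseline mean, then
    subtract the (post-division) baseline mean so the trial-averaged
    baseline is exactly 0. Values are fractional (multiply by 100 for
    percent signal change).

    Returns ``(normalized, baseline_means)`` where ``normalized`` is
    (electrodes x time) and ``baseline_means`` the pre-normalization
    baseline average per electrode.
    """
    bb = np.asarray(broadband, dtype=float)
    if bb.ndim == 2:
        bb = bb[np.newaxis]
    if bb.ndim != 3:
        raise ValueError("broadband must be (electrodes x trials x time)")
    mask = np.asarray(baseline, dtype=bool)
    if mask.shape[0] != bb.shape[-1] or not mask.any():
        raise ValueError("baseline mask must select samples on the time axis")
    avg = bb.mean(axis=1)
    base = avg[:, mask].mean(axis=1)
    if np.any(base <= 0):
        raise ValueError("nonpositive baseline mean; cannot normalize")
    norm = avg / base[:, None]
    norm = norm - norm[:, mask].mean(axis=1, keepdims=True)
    return norm, base


def baseline_mask(n: int, fs: float, t0: float, window: Tuple[float, float] = (-0.2, 0.0)) -> np.ndarray:
    """Boolean time mask for a window (s) in an epoch starting at ``t0``."""
    t = t0 + np.arange(n) / fs
    return (t >= window[0] - 1e-12) & (t < window[1] - 1e-12)


def select_electrodes(
    trial_avg: np.ndarray,
    stim_mask: np.ndarray,
    base_mask: np.ndarray,
    threshold: float = 1.5,
) -> np.ndarray:
    """Keep mask for responsive electrodes.

    ``trial_avg`` is the pre-normalization trial-averaged broadband
    (electrodes x time). An electrode is kept iff (1) its mean response in
    the stimulus-on window exceeds its baseline mean, and (2) its maximum
    response exceeds ``threshold`` (150% by default) of the baseline mean.
    """
    avg = np.atleast_2d(np.asarray(trial_avg, dtype=float))
    base = avg[:, np.asarray(base_mask, dtype=bool)].mean(axis=1)
    stim_mean = avg[:, np.asarray(stim_mask, dtype=bool)].mean(axis=1)
    keep = (stim_mean > base) & (avg.max(axis=1) > threshold * base)
    if not keep.any():
        warnings.warn("no electrodes pass the selection criteria", stacklevel=2)
    return keep


ECCENTRICITY_BINS = ("foveal", "mid", "peripheral")


def bin_by_eccentricity(eccentricities) -> dict:
    """Group electrode indices into eccentricity bins: <5, 5-10, >10 degrees.

    Boundary values go to the middle bin (5 and 10 degrees are 'mid').
    Returns a dict mapping bin name to an index array.
    """
    ecc = np.asarray(list(eccentricities), dtype=float)
    if np.any(ecc < 0):
        raise ValueError("eccentricities must be nonnegative")
    idx = np.arange(ecc.size)
    return {
        "foveal": idx[ecc < 5.0],
        "mid": idx[(ecc >= 5.0) & (ecc <= 10.0)],
        "peripheral": idx[ecc > 10.0],
    }


class BroadbandExtractor(TransformerMixin, BaseEstimator):
    """Voltage epochs -> baseline-zeroed broadband time courses.

    A transformer over (electrodes x trials x time) voltage arrays. ``fit``
    designs the band plan; ``transform`` filters each surviving bin,
    squares the analytic-signal envelope, combines bins by geometric mean,
    and normalizes the trial average to fractional change with zero
    baseline.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    f_lo, f_hi, width : float
        Bin plan in Hz (defaults: ten 10-Hz bins over 70-210 Hz).
    line_freq : float
        Mains frequency whose harmonics are excluded (0 disables).
    epoch_t0 : float
        Time of the first epoch sample relative to stimulus onset (s).
    baseline : (float, float)
        Pre-stimulus window (s) used for normalization.
    """

    def __init__(
        self,
        fs: float = 1000.0,
        f_lo: float = 70.0,
        f_hi: float = 210.0,
        width: float = 10.0,
        line_freq: float = 60.0,
        epoch_t0: float = -0.2,
        baseline: Tuple[float, float] = (-0.2, 0.0),
    ) -> None:
        self.fs = fs
        self.f_lo = f_lo
        self.f_hi = f_hi
        self.width = width
        self.line_freq = line_freq
        self.epoch_t0 = epoch_t0
        self.baseline = baseline

    def fit(self, X=None, y=None) -> "BroadbandExtractor":
        self.bands_ = design_band_bins(self.f_lo, self.f_hi, self.width, self.line_freq)
        return self

    def raw_broadband(self, X: np.ndarray) -> np.ndarray:
        """Un-normalized broadband power (same leading shape as ``X``)."""
        if not hasattr(self, "bands_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        powers = [bandpass_envelope(X, band, self.fs) for band in self.bands_.bins]
        return combine_bands(powers)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Normalized (electrodes x time) broadband from voltage epochs."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[np.newaxis]
        if X.ndim != 3:
            raise ValueError("X must be (electrodes x trials x time)")
        bb = self.raw_broadband(X)
        mask = baseline_mask(X.shape[-1], self.fs, self.epoch_t0, self.baseline)
        norm, base = epoch_normalize(bb, mask)
        self.baseline_means_ = base
        self.trial_average_ = bb.mean(axis=1)
        return norm
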