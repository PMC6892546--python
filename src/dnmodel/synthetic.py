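"""Synthetic data generators for every analysis path in the package.

These generators stand in for real recordings: DN-generated trials with
additive Gaussian noise (the fit objective is summed squared error on the
trial average, for which Gaussian noise is the matched noise model),
contrast families of PSTH-like responses, raw voltage with a known
broadband amplitude modulation plus mains interference, and a small
multi-electrode demo dataset whose generating parameters follow the
qualitative cortical gradients: summation windows lengthen and gain
control strengthens from V1 to anterior maps, and the biphasic
(offset-transient) weight grows from fovea to periphery.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt

from .model import DNParams, dn_response
from .timecourse import StimulusTimecourse, TimeGrid, step_stimulus

__all__ = [
    "SyntheticSpec",
    "simulate_observation",
    "simulate_contrast_psths",
    "simulate_voltage",
    "make_demo_dataset",
    "DemoDataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for noisy DN observations: truth, stimulus, noise, trials."""

    true_params: DNParams
    stimulus: StimulusTimecourse
    noise_sd: float = 0.0
    n_trials: int = 1
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")


def simulate_observation(spec: SyntheticSpec) -> np.ndarray:
    """Trials of the DN response plus iid Gaussian noise, (trials x time)."""
    clean = dn_response(spec.stimulus, spec.true_params).values
    rng = np.random.default_rng(spec.rng_seed)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_trials, clean.shape[0]))
    return clean[np.newaxis] + noise


def simulate_contrast_psths(
    params: DNParams,
    contrasts: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    duration: float = 0.2,
    grid: Optional[TimeGrid] = None,
    rng_seed: Optional[int] = None,
) -> Tuple[np.ndarray, List[StimulusTimecourse], np.ndarray]:
    """PSTH-like family: one noisy DN response per stimulus contrast.

    Defaults follow the single-unit contrast experiments: ten contrasts in
    equal steps from 0 to 0.9 and a 200 ms pulse. Returns
    ``(psths, stimuli, contrasts)`` with ``psths`` (contrasts x time).
    """
    if contrasts is None:
        contrasts = np.linspace(0.0, 0.9, 10)
    contrasts = np.asarray(list(contrasts), dtype=float)
    if grid is None:
        grid = TimeGrid(dt=0.001, n=int(round((duration + 0.3) / 0.001)))
    base = step_stimulus(duration, grid)
    stimuli = [base.scaled(c) for c in contrasts]
    rng = np.random.default_rng(rng_seed)
    psths = np.stack([dn_response(s, params).values for s in stimuli])
    psths = psths + rng.normal(0.0, noise_sd, size=psths.shape)
    return psths, stimuli, contrasts


def _pink_noise(rng: np.random.Generator, shape: Tuple[int, ...], fs: float) -> np.ndarray:
    """Gaussian noise with a 1/f amplitude spectrum along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0
    return np.fft.irfft(spectrum * scale, n=n, axis=-1)


def simulate_voltage(
    envelope: np.ndarray,
    fs: float = 1000.0,
    n_electrodes: int = 1,
    n_trials: int = 30,
    band: Tuple[float, float] = (70.0, 210.0),
    line_freq: float = 60.0,
    line_amp: float = 0.5,
    pink_amp: float = 1.0,
    carrier_floor: float = 0.25,
    carrier_mod: float = 3.0,
    rng_seed: Optional[int] = None,
) -> np.ndarray:
    """Raw voltage epochs with a known broadband amplitude modulation.

    The signal per trial is: pink-noise background + band-limited Gaussian
    noise (70-210 Hz by default) whose amplitude follows
    ``carrier_floor + carrier_mod * envelope(t)`` + sinusoids at the mains
    frequency and its harmonics. ``envelope`` is one value per sample in
    [0, inf). Returns (electrodes x trials x time).
    """
    env = np.asarray(envelope, dtype=float)
    n = env.shape[0]
    rng = np.random.default_rng(rng_seed)
    sos = butter(4, band, btype="bandpass", output="sos", fs=fs)
    carrier = sosfilt(sos, rng.standard_normal((n_electrodes, n_trials, n)), axis=-1)
    amplitude = carrier_floor + carrier_mod * env
    t = np.arange(n) / fs
    line = np.zeros(n)
    for k in range(1, int(fs / 2 // line_freq) + 1):
        line += line_amp / k * np.sin(2 * np.pi * k * line_freq * t + rng.uniform(0, 2 * np.pi))
    background = pink_amp * _pink_noise(rng, (n_electrodes, n_trials, n), fs)
    return background + amplitude * carrier + line


# ROI-graded generating parameters for the demo dataset. Summation windows
# lengthen and normalization strengthens toward anterior maps; the biphasic
# weight grows with eccentricity within every ROI.
_DEMO_ROIS = ("V1", "V2", "V3", "anterior")
_DEMO_TAU1 = {"V1": 0.08, "V2": 0.09, "V3": 0.10, "anterior": 0.13}
_DEMO_SIGMA = {"V1": 0.10, "V2": 0.08, "V3": 0.06, "anterior": 0.04}
_DEMO_TAU2 = {"V1": 0.10, "V2": 0.11, "V3": 0.12, "anterior": 0.14}
_DEMO_GAIN = {"V1": 7.0, "V2": 4.0, "V3": 2.5, "anterior": 1.5}
_DEMO_W = {"foveal": 0.1, "mid": 0.45, "peripheral": 0.8}
_DEMO_ECC = {"foveal": 2.5, "mid": 7.5, "peripheral": 14.0}


@dataclass
class DemoDataset:
    """A small multi-ROI, multi-eccentricity synthetic electrode package."""

    grid: TimeGrid
    stimulus: StimulusTimecourse
    responses: np.ndarray  # electrodes x time, trial-averaged
    meta: pd.DataFrame  # electrode, roi, ecc_bin, eccentricity
    truth: pd.DataFrame  # generating parameters per electrode


def make_demo_dataset(
    rng_seed: Optional[int] = 0,
    noise_sd: float = 0.02,
    n_trials: int = 30,
) -> DemoDataset:
    """Twelve synthetic electrodes: 4 ROIs x 3 eccentricity bins.

    Responses are trial-averaged noisy DN outputs to the standard 500 ms
    stimulus in a 1.2 s epoch. The ground-truth table carries every
    generating parameter so recovery can be scored exactly.
    """
    grid = TimeGrid(dt=0.001, n=1200)
    stim = step_stimulus(0.5, grid)
    rng = np.random.default_rng(rng_seed)
    rows, truth_rows, traces = [], [], []
    for roi in _DEMO_ROIS:
        for ecc_bin in ("foveal", "mid", "peripheral"):
            params = DNParams(
                tau1=_DEMO_TAU1[roi],
                tau2=_DEMO_TAU2[roi],
                n=2.0,
                sigma=_DEMO_SIGMA[roi],
                w=_DEMO_W[ecc_bin],
                shift=0.002,
                gain=_DEMO_GAIN[roi],
            )
            clean = dn_response(stim, params).values
            noisy = clean + rng.normal(0.0, noise_sd, size=(n_trials, grid.n))
            traces.append(noisy.mean(axis=0))
            eid = f"{roi}_{ecc_bin}"
            rows.append({"electrode": eid, "roi": roi, "ecc_bin": ecc_bin,
                         "eccentricity": _DEMO_ECC[ecc_bin]})
            truth_rows.append({
                "electrode": eid, "tau1": params.tau1, "w": params.w,
                "tau2": params.tau2, "n": params.n, "sigma": params.sigma,
                "shift": params.shift, "gain": params.gain,
            })
    return DemoDataset(
        grid=grid,
        stimulus=stim,
        responses=np.asarray(traces),
        meta=pd.DataFrame(rows),
        truth=pd.DataFrame(truth_rows),
    )
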