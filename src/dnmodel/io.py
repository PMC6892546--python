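"""Delimited-text I/O, fit-result serialization, and run configuration.

Tables are CSV/TSV with a ``time`` column in seconds plus one column per
electrode or condition; voltage epochs travel as one delimited file per
electrode (rows = trials) with a JSON sidecar giving the sampling rate and
epoch start. Configuration is YAML or JSON, validated against the standard
defaults (grid ranges, fit bounds, band plan, condition set).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from ._engine import FitBounds, FitResult, GridRanges
from .bold import ONE_PULSE_DURATIONS_MS, TWO_PULSE_ISIS_MS
from .model import DNParams
from .timecourse import GridError, TimeGrid

__all__ = [
    "load_timeseries_table",
    "save_timeseries_table",
    "save_fit_result",
    "load_params",
    "Config",
    "load_config",
]


class FormatError(ValueError):
    """Raised for malformed input tables or configs."""


def load_timeseries_table(path) -> Tuple[TimeGrid, pd.DataFrame]:
    """Read a delimited table with a ``time`` column and response columns.

    The time column (seconds) must be uniformly spaced; the returned frame
    holds one column per electrode/condition on the inferred grid.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if "time" not in df.columns:
        raise FormatError(f"{path}: no 'time' column")
    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
        raise FormatError(f"{path}: time column is not uniformly spaced")
    grid = TimeGrid(dt=float(steps[0]), n=t.size, t0=float(t[0]))
    data = df.drop(columns="time")
    if data.shape[1] == 0:
        raise FormatError(f"{path}: no response columns")
    return grid, data.astype(float)


def save_timeseries_table(path, grid: TimeGrid, data, columns: Optional[Sequence[str]] = None) -> None:
    """Write responses (time x columns) with a leading ``time`` column."""
    if isinstance(data, pd.DataFrame):
        frame = data.copy()
    else:
        arr = np.atleast_2d(np.asarray(data, dtype=float))
        if arr.shape[0] != grid.n and arr.shape[1] == grid.n:
            arr = arr.T
        names = list(columns) if columns is not None else [f"resp{i}" for i in range(arr.shape[1])]
        frame = pd.DataFrame(arr, columns=names)
    frame.insert(0, "time", grid.times)
    frame.to_csv(path, index=False, float_format="%.10g")


def _params_dict(params: DNParams) -> dict:
    return {k: getattr(params, k) for k in
            ("tau1", "w", "tau2", "n", "sigma", "shift", "gain")}


def save_fit_result(path, result: FitResult, mode: str = "standard",
                    bounds: Optional[FitBounds] = None) -> None:
    """Serialize a fit result as a flat JSON object."""
    payload = {
        "mode": mode,
        **_params_dict(result.params),
        "r2": result.r2,
        "sse": result.sse,
        "seed_used": list(np.asarray(result.seed_used, dtype=float)),
        "n_iterations": result.n_iterations,
        "converged": bool(result.converged),
    }
    if bounds is not None:
        payload["bounds_lower"] = list(bounds.lower)
        payload["bounds_upper"] = list(bounds.upper)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_params(path) -> DNParams:
    """Read model parameters back from a fit-result or parameter JSON."""
    payload = json.loads(Path(path).read_text())
    kwargs = {k: payload[k] for k in ("tau1", "w", "tau2", "n", "sigma", "shift", "gain")
              if k in payload}
    return DNParams(**kwargs)


@dataclass(frozen=True)
class Config:
    """Resolved run configuration with standard defaults."""

    dt: float = 0.001
    fs: float = 1000.0
    epoch_t0: float = -0.2
    stim_duration: float = 0.5
    ranges: GridRanges = field(default_factory=GridRanges)
    bounds: FitBounds = field(default_factory=FitBounds)
    f_lo: float = 70.0
    f_hi: float = 210.0
    band_width: float = 10.0
    line_freq: float = 60.0
    durations_ms: Tuple[float, ...] = ONE_PULSE_DURATIONS_MS
    isis_ms: Tuple[float, ...] = TWO_PULSE_ISIS_MS
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise FormatError(f"dt must be positive, got {self.dt}")
        if not self.fs > 0:
            raise FormatError(f"fs must be positive, got {self.fs}")
        if not self.stim_duration > 0:
            raise FormatError("stim_duration must be positive")
        if not self.f_lo < self.f_hi:
            raise FormatError("need f_lo < f_hi")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise FormatError(f"unknown log level {self.log_level!r}")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["ranges"] = dataclasses.asdict(self.ranges)
        out["bounds"] = dataclasses.asdict(self.bounds)
        return out


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> Config:
    """Build a :class:`Config` from a YAML/JSON file plus overrides.

    Absent fields fall back to the standard defaults; unknown fields and
    out-of-range values raise :class:`FormatError`. An empty file yields
    the full default configuration.
    """
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise FormatError(f"{path}: config must be a mapping")
        raw.update(loaded)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config fields: {sorted(unknown)}")
    try:
        if "ranges" in raw and isinstance(raw["ranges"], dict):
            raw["ranges"] = GridRanges(**{
                k: tuple(v) if isinstance(v, (list, tuple)) else v
                for k, v in raw["ranges"].items()
            })
        if "bounds" in raw and isinstance(raw["bounds"], dict):
            raw["bounds"] = FitBounds(**{k: tuple(v) for k, v in raw["bounds"].items()})
        for key in ("durations_ms", "isis_ms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return Config(**raw)
    except (TypeError, ValueError) as err:
        raise FormatError(f"invalid configuration: {err}") from err
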