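"""Shared data containers and I/O helpers.

The common currency between the imaging and analysis layers is the
:class:`DiameterTrace` (a uniformly sampled inner-diameter time series) and
the :class:`VoltageTrace` (an intracellular recording with an optional TTL
auxiliary channel).  Traces round-trip through plain 2/3-column CSV so that
precomputed data can enter the pipeline without the imaging stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd


class DataError(Exception):
    """Raised when input data violates a precondition (exit code 2 in the CLI)."""


def _check_uniform(t: np.ndarray, rtol: float = 1e-6) -> float:
    """Return the sample period of ``t``, raising :class:`DataError` if non-uniform."""
    if t.ndim != 1 or t.size < 2:
        raise DataError("time axis must be 1-D with at least 2 samples")
    dt = np.diff(t)
    dt0 = float(np.median(dt))
    if dt0 <= 0 or not np.allclose(dt, dt0, rtol=rtol, atol=dt0 * 1e-3):
        raise DataError("non-uniform sampling detected")
    return dt0


@dataclass
class DiameterTrace:
    """Uniformly sampled inner-diameter time series.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds (uniform).
    d : ndarray
        Inner diameter in micrometres.
    fps : float
        Sampling rate in frames per second.
    provenance : str
        Free-text origin ("synthetic", "mmode:<line>", "csv:<path>", ...).
    """

    t: np.ndarray
    d: np.ndarray
    fps: float
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.t.shape != self.d.shape:
            raise DataError("t and d must have the same shape")
        if self.fps <= 0:
            raise DataError("fps must be positive")
        _check_uniform(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) + self.dt

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.t, "value": self.d}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DiameterTrace":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise DataError(f"{path}: expected 2 columns (time_s,value)")
        t = df.iloc[:, 0].to_numpy(float)
        d = df.iloc[:, 1].to_numpy(float)
        dt = _check_uniform(t)
        return cls(t=t, d=d, fps=1.0 / dt, provenance=f"csv:{path}")


@dataclass
class VoltageTrace:
    """Intracellular voltage recording, optionally with a TTL auxiliary channel."""

    t: np.ndarray
    v: np.ndarray
    rate: float
    aux: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise DataError("t and v must have the same shape")
        if self.aux is not None:
            self.aux = np.asarray(self.aux, dtype=float)
            if self.aux.shape != self.t.shape:
                raise DataError("aux channel length mismatch")
        if self.rate <= 0:
            raise DataError("rate must be positive")
        if not np.all(np.isfinite(self.v)):
            raise DataError("voltage contains non-finite values")
        _check_uniform(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    def to_csv(self, path: str | Path) -> None:
        cols = {"time_s": self.t, "mv": self.v}
        if self.aux is not None:
            cols["ttl"] = self.aux
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "VoltageTrace":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise DataError(f"{path}: expected >= 2 columns (time_s,mv[,ttl])")
        t = df.iloc[:, 0].to_numpy(float)
        v = df.iloc[:, 1].to_numpy(float)
        aux = df.iloc[:, 2].to_numpy(float) if df.shape[1] >= 3 else None
        dt = _check_uniform(t)
        return cls(t=t, v=v, rate=1.0 / dt, aux=aux)


@dataclass
class FrameStack:
    """A movie: stack of same-shaped grayscale frames with calibration."""

    frames: np.ndarray  # (n_frames, height, width)
    fps: float
    scale: float  # micrometres per pixel

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise DataError("frames must be a 3-D array (n, h, w)")
        if self.fps <= 0 or self.scale <= 0:
            raise DataError("fps and scale must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        tifffile.imwrite(path, self.frames)

    @classmethod
    def from_tiff(cls, path: str | Path, fps: float, scale: float) -> "FrameStack":
        import tifffile

        return cls(frames=tifffile.imread(path), fps=fps, scale=scale)


@dataclass
class MModeImage:
    """Kymograph: intensity along a fixed sampling line, over time.

    ``pixels`` is space x time; column j is the bilinear sample of frame j
    along ``line`` (0-based pixel-centre coordinates).
    """

    pixels: np.ndarray
    line: Tuple[Tuple[float, float], Tuple[float, float]]
    fps: float
    scale: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise DataError("M-mode pixels must be 2-D (space x time)")

    @property
    def n_columns(self) -> int:
        return int(self.pixels.shape[1])
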