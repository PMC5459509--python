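"""Contraction-phase parsing under a movement-speed threshold.

Each contraction is split into a shortening phase (SP, first supra-threshold
movement episode), an isometric phase (ISO, the sub-threshold span at
minimum diameter between the two movement peaks) and a lengthening phase
(LP, last supra-threshold episode).  Shortening velocity is
(DD - SD) / SP.  The threshold mirrors a user-movable bar: by default it is
relative (15% of the per-beat peak speed) with an absolute um/s override.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .core import DataError, DiameterTrace, _check_uniform
from .beats import BeatTable

__all__ = [
    "SpeedTrace",
    "PhaseTable",
    "LoadReport",
    "movement_trace",
    "parse_phases",
    "shortening_velocity",
    "load_protocol_report",
    "Threshold",
]

#: ("rel", f) = fraction f of the per-beat peak speed; ("abs", v) = v um/s.
Threshold = Tuple[str, float]

MIN_PHASE_FPS = 150.0


@dataclass
class SpeedTrace:
    """|dd/dt| of a diameter trace, um/s."""

    t: np.ndarray
    v: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.v = np.asarray(self.v, float)
        _check_uniform(self.t)


@dataclass
class PhaseTable:
    """Per-beat SP/ISO/LP durations, shortening velocity and threshold used.

    ``df`` columns: onset, sp, iso, lp, velocity, threshold, flagged.
    Beats with fewer than two supra-threshold episodes carry NaN phases and
    ``flagged=True``.
    """

    df: pd.DataFrame
    fps: float

    def __len__(self) -> int:
        return len(self.df)

    @property
    def valid(self) -> pd.DataFrame:
        return self.df[~self.df["flagged"]]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class LoadReport:
    """Per-heart Pre/Load/Post isometric durations and velocities."""

    per_heart: pd.DataFrame   # heart, iso_pre, iso_load, iso_post, vel_*, recovered
    mean_iso: Dict[str, float]
    mean_velocity: Dict[str, float]
    all_recovered: bool


def movement_trace(trace: DiameterTrace, smooth_sigma_s: float = 0.0) -> SpeedTrace:
    """Absolute wall-movement speed via central differences.

    ``smooth_sigma_s`` applies light Gaussian smoothing to the diameter
    before differentiation; 0 keeps the derivative exact on clean data.
    """
    d = trace.d
    sigma = smooth_sigma_s * trace.fps
    if sigma >= 0.5:
        d = gaussian_filter1d(d, sigma)
    v = np.abs(np.gradient(d, trace.t))
    return SpeedTrace(t=trace.t, v=v, fps=trace.fps)


def _episodes(above: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where ``above`` is True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))
                                 .astype(np.int8)))
    return [(int(idx[k]), int(idx[k + 1])) for k in range(0, len(idx), 2)]


def parse_phases(speed: SpeedTrace, bt: BeatTable,
                 threshold: Threshold = ("rel", 0.15)) -> PhaseTable:
    """Parse each beat's speed profile into SP / ISO / LP.

    Episodes are half-open index ranges converted to seconds.  SP is the
    first supra-threshold episode inside the beat window, LP the last, ISO
    the span between them; a beat with fewer than two episodes is flagged.
    """
    kind, value = threshold
    if kind not in ("rel", "abs"):
        raise DataError("threshold kind must be 'rel' or 'abs'")
    if value <= 0:
        raise DataError("threshold must be positive")
    if speed.fps < MIN_PHASE_FPS:
        raise DataError(f"phase parsing requires >= {MIN_PHASE_FPS:.0f} fps")
    dt = 1.0 / speed.fps

    rows = []
    for _, beat in bt.df.iterrows():
        i0 = int(np.searchsorted(speed.t, beat["onset"] - 0.5 * dt))
        i1 = int(np.searchsorted(speed.t, beat["relax_end"] + 0.5 * dt))
        w = speed.v[i0:i1]
        thr = value if kind == "abs" else value * float(w.max()) if w.size else value
        eps = _episodes(w >= thr)
        if len(eps) < 2:
            rows.append({"onset": beat["onset"], "sp": np.nan, "iso": np.nan,
                         "lp": np.nan, "velocity": np.nan, "threshold": thr,
                         "flagged": True})
            continue
        (s0, s1), (l0, l1) = eps[0], eps[-1]
        sp = (s1 - s0) * dt
        lp = (l1 - l0) * dt
        iso = (l0 - s1) * dt
        vel = (beat["dd"] - beat["sd"]) / sp if sp > 0 else np.nan
        rows.append({"onset": beat["onset"], "sp": sp, "iso": iso, "lp": lp,
                     "velocity": vel, "threshold": thr, "flagged": False})
    cols = ["onset", "sp", "iso", "lp", "velocity", "threshold", "flagged"]
    df = pd.DataFrame(rows, columns=cols)
    return PhaseTable(df=df, fps=speed.fps)


def shortening_velocity(dd: float, sd: float, sp: float) -> float:
    """(diastolic diameter - systolic diameter) / shortening phase, um/s."""
    if sp <= 0:
        raise DataError("shortening phase must be positive")
    if dd < sd:
        raise DataError("diastolic diameter must be >= systolic diameter")
    return (dd - sd) / sp


def load_protocol_report(pre: Dict[str, PhaseTable],
                         load: Dict[str, PhaseTable],
                         post: Dict[str, PhaseTable],
                         recovery_rtol: float = 0.25) -> LoadReport:
    """Summarize a Pre / Load (viscous medium) / Post protocol per heart.

    ``recovered`` means the Post mean ISO is within ``recovery_rtol``
    (relative) of the Pre value.
    """
    conditions = {"pre": pre, "load": load, "post": post}
    ids = set(pre)
    for name, tbl in conditions.items():
        if set(tbl) != ids:
            raise DataError(f"missing or extra hearts in condition '{name}'")
    if not ids:
        raise DataError("no hearts provided")

    rows = []
    for hid in sorted(ids):
        row: Dict[str, object] = {"heart": hid}
        for name, tbl in conditions.items():
            valid = tbl[hid].valid
            row[f"iso_{name}"] = float(valid["iso"].mean()) if len(valid) else np.nan
            row[f"vel_{name}"] = float(valid["velocity"].mean()) if len(valid) else np.nan
        denom = max(abs(row["iso_pre"]), 1e-12)
        row["recovered"] = bool(abs(row["iso_post"] - row["iso_pre"]) <= recovery_rtol * denom)
        rows.append(row)
    per = pd.DataFrame(rows)
    return LoadReport(
        per_heart=per,
        mean_iso={n: float(per[f"iso_{n}"].mean()) for n in conditions},
        mean_velocity={n: float(per[f"vel_{n}"].mean()) for n in conditions},
        all_recovered=bool(per["recovered"].all()),
    )
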