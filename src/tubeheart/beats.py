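"""Beat segmentation and headline cardiac statistics.

Segments a diameter trace into contraction/relaxation events and computes
diastolic/systolic intervals (DI/SI), heart period (HP), the arrhythmia
index (sample SD of heart periods normalized to the median heart period),
diastolic/systolic diameters, fractional shortening, binned DI histograms,
and paired pre/post comparisons.

Interval semantics: SI spans contraction onset (departure of the diameter
from the diastolic plateau) through relaxation end (return to the plateau);
DI is the plateau span until the next contraction onset; HP = SI + DI.
Detection uses hysteresis crossings of a threshold relative to a rolling
diastolic baseline, then refines each boundary by extrapolating the local
wall-motion slope back to the plateau level, which recovers piecewise-linear
beats to sub-sample accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .core import DataError, DiameterTrace

__all__ = [
    "SegmentParams",
    "BeatTable",
    "CardiacSummary",
    "DIHistogram",
    "PrePostReport",
    "segment_beats",
    "summarize",
    "di_histogram",
    "compare_pre_post",
]

BEAT_COLUMNS = ["onset", "relax_end", "si", "di", "hp", "dd", "sd"]


@dataclass
class SegmentParams:
    """Tunables for :func:`segment_beats`.

    threshold_frac : detection threshold as a fraction of the local
        diastolic baseline (the "90%" rule).
    baseline_window_s / baseline_q : rolling upper-quantile baseline.
    smooth_sigma_s : Gaussian pre-smoothing of the trace (seconds).
    min_si_s : reject candidate beats shorter than this.
    min_depth_um : a beat must dip at least this far below the threshold.
    """

    threshold_frac: float = 0.90
    baseline_window_s: float = 2.0
    baseline_q: float = 0.95
    smooth_sigma_s: float = 0.005
    min_si_s: float = 0.05
    min_depth_um: float = 2.0


@dataclass
class BeatTable:
    """Per-beat segmentation record.

    ``df`` columns: onset, relax_end, si, di, hp, dd, sd.  ``di`` and ``hp``
    of the final beat are NaN (they need the following onset).
    """

    df: pd.DataFrame
    fps: float

    def __post_init__(self) -> None:
        missing = [c for c in BEAT_COLUMNS if c not in self.df.columns]
        if missing:
            raise DataError(f"BeatTable missing columns {missing}")
        onsets = self.df["onset"].to_numpy()
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise DataError("beat onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def heart_periods(self) -> np.ndarray:
        return self.df["hp"].dropna().to_numpy()

    @property
    def dis(self) -> np.ndarray:
        return self.df["di"].dropna().to_numpy()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fps: float = 0.0) -> "BeatTable":
        return cls(df=pd.read_csv(path), fps=fps)


@dataclass
class CardiacSummary:
    n_beats: int
    mean_di: float
    mean_si: float
    median_hp: float
    ai: Optional[float]   # absent (None) with < 3 heart periods
    dd: float
    sd: float
    fs: float

    def as_dict(self) -> dict:
        return {
            "n_beats": self.n_beats, "mean_di": self.mean_di,
            "mean_si": self.mean_si, "median_hp": self.median_hp,
            "ai": self.ai, "dd": self.dd, "sd": self.sd, "fs": self.fs,
        }


@dataclass
class DIHistogram:
    bin_edges: np.ndarray   # uniform, len = n_bins + 1
    percent: np.ndarray     # % of total DIs per bin, sums to 100
    n_total: int


@dataclass
class PrePostReport:
    per_heart: pd.DataFrame          # heart, di_pre, di_post, delta_di, n_pre, n_post
    mean_di_pre: float
    sem_di_pre: float
    mean_di_post: float
    sem_di_post: float
    mean_delta_di: float
    n_total_pre: int
    n_total_post: int
    n_ratio: float                   # post / pre total beat count
    hist_pre: DIHistogram
    hist_post: DIHistogram


def _rolling_baseline(d: np.ndarray, fps: float, window_s: float, q: float) -> np.ndarray:
    w = max(3, int(round(window_s * fps)))
    return (
        pd.Series(d)
        .rolling(window=w, center=True, min_periods=max(2, w // 4))
        .quantile(q)
        .to_numpy()
    )


def _cross_time(t: np.ndarray, y: np.ndarray, i: int, level: np.ndarray | float) -> float:
    """Linear-interpolated crossing time of ``level`` between samples i-1 and i."""
    lv0 = level[i - 1] if np.ndim(level) else level
    lv1 = level[i] if np.ndim(level) else level
    y0, y1 = y[i - 1] - lv0, y[i] - lv1
    if y1 == y0:
        return float(t[i])
    f = y0 / (y0 - y1)
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def _slope_extrapolate(t: np.ndarray, y: np.ndarray, i: int, target: float,
                       half: int, sign: float) -> float:
    """Extrapolate the local ramp through sample ``i`` back to ``target``.

    Fits a line over a +/-``half``-sample window and returns the time where
    the fit reaches ``target``.  ``sign`` is -1 for a falling ramp (onset)
    and +1 for a rising ramp (relaxation end).  Falls back to the crossing
    time itself if the local slope has the wrong sign.
    """
    lo, hi = max(0, i - half), min(len(y), i + half + 1)
    tw, yw = t[lo:hi], y[lo:hi]
    A = np.polyfit(tw, yw, 1)
    slope = A[0]
    if sign * slope <= 0:
        return float(t[i])
    return float((target - A[1]) / slope)


def segment_beats(trace: DiameterTrace,
                  params: SegmentParams | None = None) -> BeatTable:
    """Hysteresis beat detection with slope-refined boundaries.

    Contraction onset is the downward crossing of ``threshold_frac`` x local
    diastolic baseline (extrapolated back to the plateau); relaxation end is
    the subsequent upward re-crossing (extrapolated forward to the plateau).
    Partial beats at the record edges are discarded.  An empty table (with a
    warning) is returned when no beats are found.
    """
    p = params or SegmentParams()
    if trace.duration < 2.0:
        raise DataError("trace must be at least 2 s long")
    t, fps = trace.t, trace.fps
    sigma = p.smooth_sigma_s * fps
    d = gaussian_filter1d(trace.d, sigma) if sigma >= 0.5 else trace.d.copy()

    baseline = _rolling_baseline(trace.d, fps, p.baseline_window_s, p.baseline_q)
    level = p.threshold_frac * baseline

    below = d < level
    down = np.flatnonzero(~below[:-1] & below[1:]) + 1   # first sample below
    up = np.flatnonzero(below[:-1] & ~below[1:]) + 1     # first sample back above

    episodes: List[Tuple[int, int]] = []
    ui = 0
    for di_idx in down:
        while ui < len(up) and up[ui] <= di_idx:
            ui += 1
        if ui == len(up):
            break  # trailing partial beat
        episodes.append((int(di_idx), int(up[ui])))

    half = max(2, int(round(0.015 * fps)))
    rows = []
    prev_end_idx = 0
    prev_end_time = float(t[0])
    for i0, i1 in episodes:
        if (t[i1] - t[i0]) < p.min_si_s:
            continue
        seg_min = float(d[i0:i1].min())
        if level[i0] - seg_min < p.min_depth_um:
            continue
        # plateau level ahead of this beat: median of near-baseline samples
        # in the preceding gap (excludes ramp tails below 97% of baseline)
        gap = trace.d[prev_end_idx:i0]
        plateau = gap[gap >= 0.97 * baseline[prev_end_idx:i0]]
        dd_val = float(np.median(plateau)) if plateau.size >= 5 else float(baseline[i0])
        onset = _slope_extrapolate(t, d, i0, dd_val, half, sign=-1.0)
        relax_end = _slope_extrapolate(t, d, i1, dd_val, half, sign=+1.0)
        onset = max(onset, prev_end_time)
        relax_end = max(relax_end, onset + 1.0 / fps)
        rows.append({
            "onset": onset, "relax_end": relax_end, "si": relax_end - onset,
            "dd": dd_val, "sd": seg_min,
        })
        prev_end_idx = i1
        prev_end_time = relax_end

    if not rows:
        warnings.warn("no beats detected", stacklevel=2)
        return BeatTable(df=pd.DataFrame(columns=BEAT_COLUMNS), fps=fps)

    df = pd.DataFrame(rows)
    next_onset = df["onset"].shift(-1)
    df["di"] = next_onset - df["relax_end"]
    df["hp"] = next_onset - df["onset"]
    df = df[BEAT_COLUMNS]
    return BeatTable(df=df, fps=fps)


def summarize(bt: BeatTable) -> CardiacSummary:
    """Cohort-free per-record summary; AI requires >= 3 heart periods."""
    if len(bt) < 1:
        raise DataError("summarize requires at least one beat")
    df = bt.df
    hps = bt.heart_periods
    ai: Optional[float] = None
    if hps.size >= 3:
        ai = float(np.std(hps, ddof=1) / np.median(hps))
    dd = float(df["dd"].mean())
    sd = float(df["sd"].mean())
    return CardiacSummary(
        n_beats=len(bt),
        mean_di=float(df["di"].mean()),
        mean_si=float(df["si"].mean()),
        median_hp=float(np.median(hps)) if hps.size else float("nan"),
        ai=ai,
        dd=dd,
        sd=sd,
        fs=(dd - sd) / dd,
    )


def di_histogram(tables: Sequence[BeatTable], bin_width: float = 0.1) -> DIHistogram:
    """Pool DIs across hearts and bin into [k*w, (k+1)*w) as % of total."""
    if bin_width <= 0:
        raise DataError("bin_width must be positive")
    dis = np.concatenate([bt.dis for bt in tables]) if tables else np.array([])
    dis = dis[np.isfinite(dis)]
    if dis.size == 0:
        raise DataError("no diastolic intervals to histogram")
    k_max = int(np.floor(dis.max() / bin_width)) + 1
    edges = np.arange(k_max + 1) * bin_width
    counts, _ = np.histogram(dis, bins=edges)
    # np.histogram closes the last bin; enforce half-open semantics
    on_last_edge = np.isclose(dis, edges[-1])
    if np.any(on_last_edge):  # pragma: no cover - guarded by k_max + 1
        counts[-1] -= int(on_last_edge.sum())
    percent = 100.0 * counts / dis.size
    return DIHistogram(bin_edges=edges, percent=percent, n_total=int(dis.size))


def compare_pre_post(pre: Dict[str, BeatTable], post: Dict[str, BeatTable],
                     bin_width: float = 0.1) -> PrePostReport:
    """Paired pre/post comparison across hearts (same IDs in both dicts)."""
    mismatched = set(pre) ^ set(post)
    if mismatched:
        raise DataError(f"unpaired heart IDs: {sorted(mismatched)}")
    if not pre:
        raise DataError("no hearts to compare")
    rows = []
    for hid in sorted(pre):
        di_pre = float(np.nanmean(pre[hid].df["di"])) if len(pre[hid]) else np.nan
        di_post = float(np.nanmean(post[hid].df["di"])) if len(post[hid]) else np.nan
        rows.append({
            "heart": hid, "di_pre": di_pre, "di_post": di_post,
            "delta_di": di_post - di_pre,
            "n_pre": len(pre[hid]), "n_post": len(post[hid]),
        })
    per = pd.DataFrame(rows)
    n_pre_total = int(per["n_pre"].sum())
    n_post_total = int(per["n_post"].sum())

    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")

    return PrePostReport(
        per_heart=per,
        mean_di_pre=float(per["di_pre"].mean()),
        sem_di_pre=_sem(per["di_pre"]),
        mean_di_post=float(per["di_post"].mean()),
        sem_di_post=_sem(per["di_post"]),
        mean_delta_di=float(per["delta_di"].mean()),
        n_total_pre=n_pre_total,
        n_total_post=n_post_total,
        n_ratio=n_post_total / n_pre_total if n_pre_total else float("nan"),
        hist_pre=di_histogram(list(pre.values()), bin_width),
        hist_post=di_histogram(list(post.values()), bin_width),
    )
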