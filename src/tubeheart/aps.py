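"""Intracellular action-potential feature extraction.

Extracts the per-record resting potential, detects electrical events by
prominence-thresholded peak finding with temporal grouping, classifies each
event (single, EAD-style double peak, burst), and measures amplitudes,
event durations and APD10/50/90 for single-peak events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import DataError, VoltageTrace

__all__ = [
    "EventParams",
    "APEventTable",
    "resting_potential",
    "detect_events",
    "apd",
    "classify_event",
    "record_summary",
]

EVENT_COLUMNS = [
    "onset", "end", "duration_ms", "n_peaks", "max_amplitude_mv", "cls",
    "apd10_ms", "apd50_ms", "apd90_ms",
]


@dataclass
class EventParams:
    """Detection parameters.

    height_over_rest_mv : a peak must exceed rest by this much.
    prominence_mv : minimum local prominence of a peak.
    group_ms : peaks closer than this are merged into one event.
    onset_frac : onset/end level as a fraction of event amplitude above rest.
    apd_reference : "onset" (10%-amplitude upstroke crossing) or "peak".
    """

    height_over_rest_mv: float = 10.0
    prominence_mv: float = 5.0
    group_ms: float = 300.0
    onset_frac: float = 0.10
    apd_reference: str = "onset"


@dataclass
class APEventTable:
    """Per-event records plus the per-record resting potential.

    ``df`` columns: onset, end, duration_ms, n_peaks, max_amplitude_mv,
    cls, apd10_ms, apd50_ms, apd90_ms (APDs NaN for non-single events).
    """

    df: pd.DataFrame
    resting_vm: float
    rate: float

    def __len__(self) -> int:
        return len(self.df)

    @property
    def singles(self) -> pd.DataFrame:
        return self.df[self.df["cls"] == "single"]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def resting_potential(trace: VoltageTrace, min_baseline_s: float = 1.0,
                      band_frac: float = 0.2) -> float:
    """Median of samples in the baseline band (outside depolarized events).

    The band cutoff is the whole-record median plus ``band_frac`` of the
    headroom to the record maximum; this excludes event samples without
    needing event detection first.
    """
    v = trace.v
    med = float(np.median(v))
    cutoff = med + band_frac * (float(v.max()) - med)
    mask = v <= cutoff
    if mask.sum() / trace.rate < min_baseline_s:
        raise DataError("insufficient inter-event baseline (< 1 s)")
    return float(np.median(v[mask]))


def _cross(t: np.ndarray, v: np.ndarray, i0: int, i1: int, level: float,
           rising: bool) -> Optional[float]:
    """First linear-interpolated crossing of ``level`` in [i0, i1)."""
    seg = v[i0:i1]
    if rising:
        hits = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level))
    else:
        hits = np.flatnonzero((seg[:-1] >= level) & (seg[1:] < level))
    if hits.size == 0:
        return None
    j = i0 + int(hits[0])
    y0, y1 = v[j], v[j + 1]
    f = (level - y0) / (y1 - y0) if y1 != y0 else 0.0
    return float(t[j] + f * (t[j + 1] - t[j]))


def classify_event(peak_vs: np.ndarray, peak_ts: np.ndarray,
                   valley_v: float, rest: float,
                   ead_max_gap_s: float = 0.150,
                   full_amp_frac: float = 0.9,
                   onset_frac: float = 0.10) -> str:
    """Classify one event from its peak heights/times and inter-peak valley.

    single: one peak.  ead_double: exactly two peaks, the second smaller and
    rising during the repolarization of the first (valley above the onset
    level, inter-peak gap < 150 ms).  burst: >= 3 peaks, or two
    full-amplitude peaks, or any remaining two-peak morphology.
    """
    n = len(peak_vs)
    if n == 1:
        return "single"
    if n >= 3:
        return "burst"
    amp1 = peak_vs[0] - rest
    amp2 = peak_vs[1] - rest
    if amp2 >= full_amp_frac * amp1:
        return "burst"
    gap = peak_ts[1] - peak_ts[0]
    during_repol = valley_v > rest + onset_frac * amp1
    if peak_vs[1] < peak_vs[0] and gap < ead_max_gap_s and during_repol:
        return "ead_double"
    return "burst"


def apd(trace: VoltageTrace, onset: float, peak_idx: int, rest: float,
        reference: str = "onset",
        fractions: Tuple[float, ...] = (0.10, 0.50, 0.90)) -> Tuple[Optional[float], ...]:
    """APD at the given repolarization fractions, in ms.

    APD_x is the time from the reference point (event onset by default, the
    peak with ``reference="peak"``) to the first decaying-phase crossing of
    rest + (1 - x) * amplitude.
    """
    t, v = trace.t, trace.v
    amp = v[peak_idx] - rest
    ref_t = onset if reference == "onset" else float(t[peak_idx])
    out = []
    for x in fractions:
        level = rest + (1.0 - x) * amp
        tc = _cross(t, v, peak_idx, len(t), level, rising=False)
        out.append(None if tc is None else (tc - ref_t) * 1000.0)
    return tuple(out)


def detect_events(trace: VoltageTrace,
                  params: EventParams | None = None) -> APEventTable:
    """Detect and measure electrical events.

    Peaks are local maxima at least ``height_over_rest_mv`` above the
    resting potential with prominence >= ``prominence_mv``; peaks closer
    than ``group_ms`` are merged into one event.  Event onset/end are the
    crossings of rest + ``onset_frac`` x amplitude; APDs are filled for
    single-peak events.
    """
    p = params or EventParams()
    rest = resting_potential(trace)
    t, v = trace.t, trace.v
    peaks, _ = find_peaks(v, height=rest + p.height_over_rest_mv,
                          prominence=p.prominence_mv)
    rows = []
    if peaks.size:
        gap_samples = p.group_ms / 1000.0 * trace.rate
        breaks = np.flatnonzero(np.diff(peaks) > gap_samples)
        groups = np.split(peaks, breaks + 1)
        for grp in groups:
            rows.append(_measure_event(trace, grp, rest, p))
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return APEventTable(df=df, resting_vm=rest, rate=trace.rate)


def _measure_event(trace: VoltageTrace, grp: np.ndarray, rest: float,
                   p: EventParams) -> dict:
    t, v = trace.t, trace.v
    vmax_idx = int(grp[np.argmax(v[grp])])
    amp = float(v[vmax_idx] - rest)
    level = rest + p.onset_frac * amp
    first, last = int(grp[0]), int(grp[-1])
    # onset: last upward crossing of the level before the first peak
    seg = v[:first + 1]
    ups = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level))
    if ups.size:
        j = int(ups[-1])
        f = (level - v[j]) / (v[j + 1] - v[j]) if v[j + 1] != v[j] else 0.0
        onset = float(t[j] + f * (t[j + 1] - t[j]))
    else:
        onset = float(t[first])
    end = _cross(t, v, last, len(t), level, rising=False)
    if end is None:
        end = float(t[-1])

    if len(grp) == 1:
        cls = "single"
    else:
        valley = float(v[grp[0]:grp[-1] + 1].min())
        cls = classify_event(v[grp].astype(float), t[grp].astype(float),
                             valley, rest, onset_frac=p.onset_frac)
    apds: Tuple[Optional[float], ...] = (None, None, None)
    if cls == "single":
        apds = apd(trace, onset, vmax_idx, rest, reference=p.apd_reference)
    return {
        "onset": onset, "end": float(end),
        "duration_ms": (float(end) - onset) * 1000.0,
        "n_peaks": int(len(grp)), "max_amplitude_mv": amp, "cls": cls,
        "apd10_ms": np.nan if apds[0] is None else apds[0],
        "apd50_ms": np.nan if apds[1] is None else apds[1],
        "apd90_ms": np.nan if apds[2] is None else apds[2],
    }


def record_summary(tables: Dict[str, APEventTable], window_s: float = 30.0,
                   min_singles: int = 20, max_singles: int = 50) -> pd.DataFrame:
    """Per-fly means over ~30 s records.

    APD means use up to ``max_singles`` single-peak events; fewer than
    ``min_singles`` triggers a below-minimum warning (values still emitted).
    """
    if window_s < 30.0:
        warnings.warn(f"analysis window {window_s} s is shorter than the "
                      "standard 30 s", stacklevel=2)
    rows = []
    for fly, tbl in sorted(tables.items()):
        singles = tbl.singles.head(max_singles)
        if 0 < len(singles) < min_singles:
            warnings.warn(f"fly {fly}: only {len(singles)} single-peak APs "
                          f"(< {min_singles})", stacklevel=2)
        rows.append({
            "fly": fly,
            "n_events": len(tbl),
            "resting_vm_mv": tbl.resting_vm,
            "mean_amplitude_mv": float(tbl.df["max_amplitude_mv"].mean())
            if len(tbl) else np.nan,
            "mean_peaks_per_burst": float(tbl.df["n_peaks"].mean())
            if len(tbl) else np.nan,
            "mean_event_duration_ms": float(tbl.df["duration_ms"].mean())
            if len(tbl) else np.nan,
            "n_single": len(singles),
            "mean_apd10_ms": float(singles["apd10_ms"].mean()) if len(singles) else np.nan,
            "mean_apd50_ms": float(singles["apd50_ms"].mean()) if len(singles) else np.nan,
            "mean_apd90_ms": float(singles["apd90_ms"].mean()) if len(singles) else np.nan,
        })
    return pd.DataFrame(rows)
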