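"""TTL-based alignment of optical and electrical recordings.

The image-capture side raises a TTL pulse on an auxiliary channel of the
electrical record for the whole optical recording; locating that pulse puts
both modalities on the electrical clock, after which AP events are matched
1:1 to contraction onsets by greedy nearest-neighbour pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core import DataError, DiameterTrace, VoltageTrace
from .beats import BeatTable
from .aps import APEventTable

__all__ = ["SyncPair", "MatchReport", "locate_ttl", "align", "match_events"]


@dataclass
class SyncPair:
    """Optical trace re-expressed on the electrical clock."""

    voltage: VoltageTrace
    optical: DiameterTrace       # t is electrical time
    offset: float                # electrical time of optical frame 0
    window: Tuple[float, float]  # [t_on, t_off)


@dataclass
class MatchReport:
    n_beats: int
    n_ap_events: int
    n_matched: int
    matched_fraction: float
    median_latency: float  # ap onset - beat onset, s (NaN when no matches)

    def as_dict(self) -> dict:
        return {
            "n_beats": self.n_beats, "n_ap_events": self.n_ap_events,
            "n_matched": self.n_matched,
            "matched_fraction": self.matched_fraction,
            "median_latency": self.median_latency,
        }


def locate_ttl(voltage: VoltageTrace) -> Tuple[float, float]:
    """Locate the TTL pulse at half amplitude; returns the half-open window.

    Errors if the aux channel is missing, flat, or carries more than one
    disjoint pulse.
    """
    if voltage.aux is None:
        raise DataError("voltage record has no auxiliary (TTL) channel")
    aux = voltage.aux
    lo, hi = float(aux.min()), float(aux.max())
    if hi - lo <= 0:
        raise DataError("TTL channel is flat: no pulse found")
    high = aux > (lo + hi) / 2.0
    idx = np.flatnonzero(high)
    runs = [r for r in np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
            if r.size]
    if len(runs) != 1:
        raise DataError(f"expected exactly one TTL pulse, found {len(runs)}")
    run = runs[0]
    t_on = float(voltage.t[run[0]])
    i_off = run[-1] + 1
    t_off = float(voltage.t[i_off]) if i_off < len(voltage.t) \
        else float(voltage.t[-1] + voltage.dt)
    return (t_on, t_off)


def align(voltage: VoltageTrace, optical: DiameterTrace,
          window: Optional[Tuple[float, float]] = None,
          frame_tolerance: int = 2) -> SyncPair:
    """Assign electrical times to optical frames: frame j at t_on + j/fps."""
    if window is None:
        window = locate_ttl(voltage)
    t_on, t_off = window
    n = len(optical.t)
    if n / optical.fps > (t_off - t_on) + frame_tolerance / optical.fps:
        raise DataError(
            f"optical record ({n / optical.fps:.3f} s) exceeds TTL window "
            f"({t_off - t_on:.3f} s) by more than {frame_tolerance} frames"
        )
    t_abs = t_on + np.arange(n) / optical.fps
    shifted = DiameterTrace(t=t_abs, d=optical.d, fps=optical.fps,
                            provenance=optical.provenance + "+aligned")
    return SyncPair(voltage=voltage, optical=shifted, offset=t_on,
                    window=(t_on, t_off))


def match_events(beats: BeatTable, aps: APEventTable,
                 tolerance: float = 0.15) -> MatchReport:
    """Greedy 1:1 nearest-neighbour matching of AP onsets to beat onsets.

    Candidate pairs within ``tolerance`` are taken in order of increasing
    time difference, each onset used at most once; the pairing is symmetric
    in which table is treated as the query.
    """
    if tolerance <= 0:
        raise DataError("tolerance must be positive")
    a = beats.df["onset"].to_numpy(float)
    b = aps.df["onset"].to_numpy(float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        return MatchReport(n_beats=n_a, n_ap_events=n_b, n_matched=0,
                           matched_fraction=0.0, median_latency=float("nan"))
    diff = b[:, None] - a[None, :]
    cand = np.argwhere(np.abs(diff) <= tolerance)
    order = np.argsort(np.abs(diff[cand[:, 0], cand[:, 1]]), kind="stable")
    used_b = np.zeros(n_b, bool)
    used_a = np.zeros(n_a, bool)
    latencies = []
    for k in order:
        i, j = cand[k]
        if used_b[i] or used_a[j]:
            continue
        used_b[i] = used_a[j] = True
        latencies.append(diff[i, j])
    n_matched = len(latencies)
    return MatchReport(
        n_beats=n_a, n_ap_events=n_b, n_matched=n_matched,
        matched_fraction=n_matched / min(n_a, n_b),
        median_latency=float(np.median(latencies)) if latencies else float("nan"),
    )
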