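"""Independent brute-force oracles used to cross-check the pipeline.

Each oracle is a deliberately naive reimplementation (explicit loops,
first-principles formulas) kept independent of the package internals.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import numpy as np


def arrhythmia_index(heart_periods: Sequence[float]) -> float:
    """Sample SD of heart periods / median, by explicit enumeration."""
    hps = sorted(float(h) for h in heart_periods)
    n = len(hps)
    mean = sum(hps) / n
    var = sum((h - mean) ** 2 for h in hps) / (n - 1)
    if n % 2:
        med = hps[n // 2]
    else:
        med = 0.5 * (hps[n // 2 - 1] + hps[n // 2])
    return math.sqrt(var) / med


def phase_scan(speed: np.ndarray, threshold: float, dt: float):
    """Exhaustive threshold-crossing scan: returns (sp, iso, lp) in seconds.

    Walks the speed samples one by one collecting half-open supra-threshold
    runs; SP is the first run, LP the last, ISO the gap between them.
    Returns None when fewer than two runs exist.
    """
    runs: List[Tuple[int, int]] = []
    start = None
    for i, v in enumerate(speed):
        if v >= threshold and start is None:
            start = i
        elif v < threshold and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(speed)))
    if len(runs) < 2:
        return None
    sp = (runs[0][1] - runs[0][0]) * dt
    lp = (runs[-1][1] - runs[-1][0]) * dt
    iso = (runs[-1][0] - runs[0][1]) * dt
    return sp, iso, lp


def peak_scan(v: np.ndarray, rest: float, height_over_rest: float) -> List[int]:
    """Naive local-maximum scan: strictly greater than both neighbours and
    above rest + height_over_rest."""
    out = []
    for i in range(1, len(v) - 1):
        if v[i] > v[i - 1] and v[i] > v[i + 1] and v[i] >= rest + height_over_rest:
            out.append(i)
    return out


def group_peaks(peak_idx: Sequence[int], rate: float, group_s: float) -> List[List[int]]:
    """Naive temporal grouping of peak indices."""
    groups: List[List[int]] = []
    for i in peak_idx:
        if groups and (i - groups[-1][-1]) / rate <= group_s:
            groups[-1].append(i)
        else:
            groups.append([i])
    return groups


def band_centroids(profile: np.ndarray, background: float) -> Tuple[float, float]:
    """Intensity-weighted centroids of the two dark bands of a column.

    Splits the column at its midpoint brightness region: upper half / lower
    half around the global profile centre of darkness.
    """
    w = np.clip(background - profile, 0.0, None)
    mid = len(profile) // 2
    ys = np.arange(len(profile), dtype=float)
    top = float(np.sum(ys[:mid] * w[:mid]) / np.sum(w[:mid]))
    bot = float(np.sum(ys[mid:] * w[mid:]) / np.sum(w[mid:]))
    return top, bot


def count_contractions(d: np.ndarray, dd: float, sd: float) -> int:
    """Count dips of a noise-free trace below the mid-diameter level."""
    level = 0.5 * (dd + sd)
    below = d < level
    return int(np.sum(~below[:-1] & below[1:]))
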