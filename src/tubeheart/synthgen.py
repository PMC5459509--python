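"""Synthetic recordings with analytic ground truth.

Generates diameter traces, movies, intracellular voltage traces, and
TTL-synchronized optical/electrical pairs that emulate the phenotype classes
analysed by the pipeline (regular wildtype rhythm, bradycardic/arrhythmic
mutant-like rhythm, burst-dominated electrical activity, viscous-load
prolongation of the isometric phase).  Every rendered quantity is derived
from a piecewise-linear schedule so that the exact programmed value of each
interval, diameter, phase duration and AP duration is available as ground
truth for testing.

Design notes
------------
* Beat mechanics are piecewise linear: diastolic plateau at ``dd_um``,
  linear shortening over SP down to ``sd_um``, a flat isometric hold over
  ISO, and linear lengthening over LP back to the plateau.
* Each beat's systolic interval is realized exactly as SP+ISO+LP by scaling
  the three nominal phase durations proportionally to the drawn SI, so the
  interval visible in the rendered trace equals the scheduled one.
* Single action potentials use a linear upstroke and linear repolarization,
  making APD10/50/90 closed-form; an optional exponential repolarization is
  available for validation against the analytic log-crossing.
* All randomness flows from ``spec.seed`` through per-purpose child seeds,
  so identical specs reproduce bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import expit

from .core import DataError, DiameterTrace, FrameStack, VoltageTrace

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "BeatTruth",
    "APTruth",
    "TubeGeometry",
    "SyncBundle",
    "preset_spec",
    "PRESET_NAMES",
    "make_beat_schedule",
    "render_diameter_trace",
    "render_movie",
    "render_voltage_trace",
    "render_sync_pair",
]


@dataclass
class SynthSpec:
    """Parameters of a synthetic recording.

    Distribution parameters are (mean, sd) tuples in seconds; diameters in
    micrometres; voltages in mV.  ``noise_sd`` scales additive Gaussian
    noise on the diameter trace (um) and voltage trace (mV).
    """

    preset: str = "wt_young"
    duration_s: float = 30.0
    fps: float = 200.0
    ephys_rate: float = 5000.0
    di_dist: Tuple[float, float] = (0.65, 0.05)
    si_dist: Tuple[float, float] = (0.25, 0.02)
    dd_um: float = 80.0
    sd_um: float = 60.0
    sp_s: float = 0.08
    iso_s: float = 0.04
    lp_s: float = 0.08
    ead_prob: float = 0.05
    burst_prob: float = 0.0
    peaks_per_burst_dist: Tuple[float, float] = (3.0, 1.0)
    rest_vm_mv: float = -42.0
    amp_mv: float = 50.0
    noise_sd: float = 0.5
    seed: int = 0
    # AP waveform shape (not part of the headline parameterization)
    ap_rise_s: float = 0.005
    ap_repol_s: float = 0.10
    burst_interval_s: float = 0.12
    burst_spike_repol_s: float = 0.06
    ap_latency_s: float = 0.0  # AP onset precedes contraction onset by this much

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise DataError("duration_s must be positive")
        if self.fps <= 0:
            raise DataError("fps must be positive")
        if self.ephys_rate <= 0:
            raise DataError("ephys_rate must be positive")
        if not self.sd_um < self.dd_um:
            raise DataError("sd_um must be smaller than dd_um")
        if self.sp_s <= 0 or self.lp_s <= 0 or self.iso_s < 0:
            raise DataError("phase durations must be positive (ISO may be zero)")
        if self.sp_s + self.iso_s + self.lp_s > self.si_dist[0] + 1e-12:
            raise DataError("sp_s + iso_s + lp_s must not exceed mean SI")
        for p in (self.ead_prob, self.burst_prob):
            if not 0.0 <= p <= 1.0:
                raise DataError("probabilities must lie in [0, 1]")
        if self.amp_mv <= 0:
            raise DataError("amp_mv must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


#: Preset parameterizations.  Interval and voltage ranges follow the
#: phenotype classes the pipeline is meant to discriminate: a regular
#: wildtype rhythm (SI 0.2-0.28 s, DI 0.5-0.8 s, resting Vm in -50..-35 mV,
#: ~50 mV AP amplitude), a bradycardic/arrhythmic class with long variable
#: DIs and EAD-prone double-peak APs, a burst-dominated class with many
#: peaks per event, an aged-wildtype intermediate, and a viscous-load class
#: whose isometric phase is doubled.
_PRESETS = {
    "wt_young": dict(
        di_dist=(0.65, 0.05), si_dist=(0.25, 0.02),
        dd_um=80.0, sd_um=60.0, sp_s=0.08, iso_s=0.04, lp_s=0.08,
        ead_prob=0.05, burst_prob=0.0, peaks_per_burst_dist=(3.0, 0.5),
        rest_vm_mv=-42.0, amp_mv=50.0, ap_repol_s=0.10, noise_sd=0.5,
    ),
    "sei_like": dict(
        di_dist=(1.2, 0.40), si_dist=(0.30, 0.04),
        dd_um=75.0, sd_um=63.0, sp_s=0.09, iso_s=0.05, lp_s=0.09,
        ead_prob=0.35, burst_prob=0.15, peaks_per_burst_dist=(3.0, 0.8),
        rest_vm_mv=-38.5, amp_mv=53.0, ap_repol_s=0.16, noise_sd=0.5,
    ),
    "kcnq_like": dict(
        di_dist=(2.2, 0.50), si_dist=(0.30, 0.04),
        dd_um=78.0, sd_um=62.0, sp_s=0.09, iso_s=0.05, lp_s=0.09,
        ead_prob=0.0, burst_prob=0.95, peaks_per_burst_dist=(7.9, 2.2),
        rest_vm_mv=-40.4, amp_mv=53.3, ap_repol_s=0.12, noise_sd=0.5,
    ),
    "wt_old": dict(
        di_dist=(0.95, 0.25), si_dist=(0.28, 0.03),
        dd_um=78.0, sd_um=63.0, sp_s=0.08, iso_s=0.05, lp_s=0.08,
        ead_prob=0.20, burst_prob=0.35, peaks_per_burst_dist=(3.5, 1.0),
        rest_vm_mv=-40.0, amp_mv=48.0, ap_repol_s=0.13, noise_sd=0.5,
    ),
    # Same heart as wt_young beating against a viscous load: the isometric
    # hold is doubled (SI mean raised by the same increment so expected SP
    # and LP are unchanged under proportional realization).
    "load": dict(
        di_dist=(0.65, 0.05), si_dist=(0.30, 0.024),
        dd_um=80.0, sd_um=60.0, sp_s=0.08, iso_s=0.08, lp_s=0.08,
        ead_prob=0.05, burst_prob=0.0, peaks_per_burst_dist=(3.0, 0.5),
        rest_vm_mv=-42.0, amp_mv=50.0, ap_repol_s=0.10, noise_sd=0.5,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset_spec(name: str, **overrides) -> SynthSpec:
    """Build a :class:`SynthSpec` from a named preset, with field overrides."""
    if name not in _PRESETS:
        raise DataError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    spec = SynthSpec(preset=name, **_PRESETS[name])
    if overrides:
        spec = replace(spec, **overrides)
    spec.validate()
    return spec


@dataclass
class BeatTruth:
    onset: float      # contraction onset (start of shortening ramp), s
    si: float         # systolic interval = sp + iso + lp, s
    di: float         # diastolic interval following this beat, s
    dd: float         # diastolic diameter, um
    sd: float         # systolic diameter, um
    sp: float
    iso: float
    lp: float

    @property
    def relax_end(self) -> float:
        return self.onset + self.si

    @property
    def hp(self) -> float:
        return self.si + self.di


@dataclass
class APTruth:
    onset: float              # waveform foot (start of upstroke), s
    n_peaks: int
    event_duration: float     # s, between rest+10%-amplitude crossings
    cls: str                  # "single" | "ead_double" | "burst"
    apd10: Optional[float] = None  # s, single-peak events only
    apd50: Optional[float] = None
    apd90: Optional[float] = None
    ead_u: Optional[float] = None     # EAD position as fraction of repolarization
    ead_frac: Optional[float] = None  # EAD bump height as fraction of amplitude
    onset10: Optional[float] = None   # 10%-amplitude upstroke crossing (analyzer onset)


@dataclass
class GroundTruth:
    """The exact programmed schedule: the oracle for every downstream test."""

    beats: List[BeatTruth]
    ap_events: List[APTruth]
    ttl_window: Optional[Tuple[float, float]] = None
    spec: Optional[SynthSpec] = None

    def __post_init__(self) -> None:
        onsets = [b.onset for b in self.beats]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise DataError("beat onsets must be strictly increasing")
        for b in self.beats:
            if b.sp + b.iso + b.lp > b.si + 1e-9:
                raise DataError("SP+ISO+LP exceeds SI in ground truth")
        for e in self.ap_events:
            if e.n_peaks < 1:
                raise DataError("each AP event must have at least one peak")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "beats": [asdict(b) for b in self.beats],
            "ap_events": [asdict(e) for e in self.ap_events],
            "ttl_window": list(self.ttl_window) if self.ttl_window else None,
        }
        Path(path).write_text(json.dumps(obj, indent=2))


def _rng(spec: SynthSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed), stream])


def make_beat_schedule(spec: SynthSpec) -> GroundTruth:
    """Draw the beat/AP schedule filling ``spec.duration_s``.

    DIs and SIs are drawn from the spec distributions and truncated below at
    two frame periods.  The first contraction onset is at t=0 and a beat is
    kept only if its full SI+DI cycle fits in the record.  Each beat is
    co-scheduled with one electrical event whose class is drawn from
    (burst_prob, ead_prob, else single).
    """
    spec.validate()
    rng = _rng(spec, 0)
    floor = 2.0 / spec.fps
    phase_sum = spec.sp_s + spec.iso_s + spec.lp_s

    beats: List[BeatTruth] = []
    events: List[APTruth] = []
    t = 0.0
    while True:
        si = max(float(rng.normal(*spec.si_dist)), floor)
        di = max(float(rng.normal(*spec.di_dist)), floor)
        if t + si + di > spec.duration_s + 1e-12:
            break
        f = si / phase_sum
        beats.append(
            BeatTruth(onset=t, si=si, di=di, dd=spec.dd_um, sd=spec.sd_um,
                      sp=spec.sp_s * f, iso=spec.iso_s * f, lp=spec.lp_s * f)
        )
        events.append(_schedule_ap(spec, rng, onset=t - spec.ap_latency_s,
                                   gap_after=si + di))
        t += si + di
    if not beats:
        raise DataError(
            f"duration_s={spec.duration_s} too short for a single beat "
            f"(mean cycle {spec.si_dist[0] + spec.di_dist[0]:.3f} s)"
        )
    return GroundTruth(beats=beats, ap_events=events, spec=spec)


def _schedule_ap(spec: SynthSpec, rng: np.random.Generator, onset: float,
                 gap_after: float) -> APTruth:
    """Draw one electrical event co-scheduled with a beat cycle."""
    u = float(rng.uniform())
    rise, repol = spec.ap_rise_s, spec.ap_repol_s
    if u < spec.burst_prob:
        n = max(3, int(round(rng.normal(*spec.peaks_per_burst_dist))))
        # keep the event inside its cycle with a margin larger than the
        # default grouping window, so consecutive events stay distinct
        max_n = 1 + int(max(0.0, gap_after - 0.45 - rise -
                            0.9 * spec.burst_spike_repol_s) // spec.burst_interval_s)
        n = min(n, max(3, max_n))
        dur = 0.9 * rise + (n - 1) * spec.burst_interval_s \
            + 0.9 * spec.burst_spike_repol_s
        return APTruth(onset=onset, n_peaks=n, event_duration=dur, cls="burst",
                       onset10=onset + 0.1 * rise)
    if u < spec.burst_prob + spec.ead_prob:
        ead_u = float(rng.uniform(0.4, 0.6))
        ead_frac = float(rng.uniform(0.30, 0.35))
        dur = 0.9 * rise + 0.9 * repol
        return APTruth(onset=onset, n_peaks=2, event_duration=dur,
                       cls="ead_double", ead_u=ead_u, ead_frac=ead_frac,
                       onset10=onset + 0.1 * rise)
    dur = 0.9 * rise + 0.9 * repol
    # analytic APDs for the linear waveform, referenced to the
    # 10%-amplitude upstroke crossing
    return APTruth(onset=onset, n_peaks=1, event_duration=dur, cls="single",
                   apd10=0.9 * rise + 0.10 * repol,
                   apd50=0.9 * rise + 0.50 * repol,
                   apd90=0.9 * rise + 0.90 * repol,
                   onset10=onset + 0.1 * rise)


def _beat_breakpoints(gt: GroundTruth, spec: SynthSpec,
                      duration: float) -> Tuple[np.ndarray, np.ndarray]:
    """Breakpoints of the piecewise-linear diameter waveform."""
    xs: List[float] = []
    ys: List[float] = []
    if not gt.beats or gt.beats[0].onset > 0:
        xs.append(0.0)
        ys.append(spec.dd_um)
    for b in gt.beats:
        if b.sp + b.iso + b.lp > b.si + 1e-9:
            raise DataError("phase durations exceed SI")
        xs += [b.onset, b.onset + b.sp, b.onset + b.sp + b.iso, b.relax_end]
        ys += [b.dd, b.sd, b.sd, b.dd]
    xs.append(duration)
    ys.append(spec.dd_um)
    return np.asarray(xs), np.asarray(ys)


def render_diameter_trace(gt: GroundTruth, spec: SynthSpec) -> DiameterTrace:
    """Sample the piecewise-linear beat waveform at ``spec.fps``."""
    if spec.fps < 50:
        raise DataError("fps must be >= 50 for diameter rendering")
    n = int(round(spec.duration_s * spec.fps))
    t = np.arange(n) / spec.fps
    xs, ys = _beat_breakpoints(gt, spec, spec.duration_s)
    d = np.interp(t, xs, ys)
    if spec.noise_sd > 0:
        d = d + _rng(spec, 1).normal(0.0, spec.noise_sd, size=n)
    return DiameterTrace(t=t, d=d, fps=spec.fps, provenance=f"synthetic:{spec.preset}")


@dataclass
class TubeGeometry:
    """Rendering geometry for the heart-tube movie.

    The tube axis is horizontal at ``axis_row`` (defaults to the frame
    centre); the two wall bands are dark, ``wall_px`` thick, with their
    *inner* edges separated by the instantaneous diameter.
    """

    height_px: int = 128
    width_px: int = 40
    wall_px: float = 6.0
    scale: float = 1.0  # um per pixel
    axis_row: Optional[float] = None
    background: float = 200.0
    depth: float = 150.0
    edge_softness_px: float = 1.0


def render_movie(trace: DiameterTrace, geometry: TubeGeometry,
                 spec: SynthSpec) -> FrameStack:
    """Render grayscale frames of two dark wall bands around the tube axis.

    Wall inner edges sit at axis +/- d/2 (in pixels, via ``geometry.scale``)
    and each edge is a logistic step of softness ``edge_softness_px`` so the
    intensity-gradient extremum falls exactly on the edge.  Photon (Poisson)
    noise is applied unless ``spec.noise_sd == 0``.
    """
    g = geometry
    c = g.axis_row if g.axis_row is not None else (g.height_px - 1) / 2.0
    r_px = (trace.d / 2.0) / g.scale  # (n_frames,)
    if np.any(c + r_px + g.wall_px >= g.height_px - 1) or np.any(c - r_px - g.wall_px <= 0):
        raise DataError("diameter exceeds frame height for this geometry")

    y = np.arange(g.height_px, dtype=float)[None, :]      # (1, H)
    r = r_px[:, None]                                     # (n, 1)
    s = g.edge_softness_px

    def band(inner: np.ndarray, outward: float) -> np.ndarray:
        # smooth indicator of [inner, inner + outward*wall] along y
        e1 = expit(outward * (y - inner) / s)
        e2 = expit(outward * (y - (inner + outward * g.wall_px)) / s)
        return e1 - e2

    profile = g.background - g.depth * (band(c + r, +1.0) + band(c - r, -1.0))
    frames = np.repeat(profile[:, :, None], g.width_px, axis=2)
    if spec.noise_sd > 0:
        frames = _rng(spec, 2).poisson(np.clip(frames, 0, None)).astype(np.float32)
    else:
        frames = frames.astype(np.float32)
    return FrameStack(frames=frames, fps=trace.fps, scale=g.scale)


def _ap_breakpoints(e: APTruth, spec: SynthSpec) -> Tuple[List[float], List[float]]:
    rest, amp = spec.rest_vm_mv, spec.amp_mv
    rise, repol = spec.ap_rise_s, spec.ap_repol_s
    t0 = e.onset
    if e.cls == "burst":
        xs, ys = [], []
        for k in range(e.n_peaks):
            tk = t0 + k * spec.burst_interval_s
            xs += [tk, tk + rise, tk + rise + spec.burst_spike_repol_s]
            ys += [rest, rest + amp, rest]
        return xs, ys
    if e.cls == "ead_double":
        u, frac = e.ead_u, e.ead_frac
        t_peak = t0 + rise
        t_end = t_peak + repol
        t_e = t_peak + u * repol                  # bump start on the decay
        level_e = rest + (1.0 - u) * amp
        bump_w = min(0.025, 0.5 * (t_end - t_e))  # keep the bump on the decay
        t_back = t_e + bump_w
        level_back = rest + amp * (1.0 - (t_back - t_peak) / repol)
        return (
            [t0, t_peak, t_e, t_e + bump_w / 2.0, t_back, t_end],
            [rest, rest + amp, level_e, level_e + frac * amp, level_back, rest],
        )
    return ([t0, t0 + rise, t0 + rise + repol], [rest, rest + amp, rest])


def render_voltage_trace(gt: GroundTruth, spec: SynthSpec,
                         t_offset: float = 0.0,
                         total_duration: Optional[float] = None) -> VoltageTrace:
    """Render the scheduled electrical events onto a resting baseline.

    ``t_offset`` shifts schedule times into the electrical clock (used for
    TTL-synchronized pairs where the electrical record starts before the
    movie); the record spans ``[0, total_duration)`` on that clock.
    """
    if spec.ephys_rate < 2000:
        raise DataError("ephys_rate must be >= 2 kHz")
    if spec.amp_mv <= 0:
        raise DataError("amp_mv must be positive")
    total = spec.duration_s if total_duration is None else total_duration
    n = int(round(total * spec.ephys_rate))
    t = np.arange(n) / spec.ephys_rate

    xs: List[float] = [0.0]
    ys: List[float] = [spec.rest_vm_mv]
    for e in gt.ap_events:
        ex, ey = _ap_breakpoints(e, spec)
        ex = [x + t_offset for x in ex]
        if ex[0] < xs[-1] - 1e-12:
            raise DataError("overlapping AP events in schedule")
        if ex[0] < 0 or ex[-1] > total:
            continue  # event outside the rendered window
        xs += ex
        ys += ey
    xs.append(total)
    ys.append(spec.rest_vm_mv)
    v = np.interp(t, np.asarray(xs), np.asarray(ys))
    if spec.noise_sd > 0:
        v = v + _rng(spec, 3).normal(0.0, spec.noise_sd, size=n)
    return VoltageTrace(t=t, v=v, rate=spec.ephys_rate)


@dataclass
class SyncBundle:
    """A rendered synchronized pair plus its ground truth."""

    voltage: VoltageTrace     # with TTL aux channel, electrical clock
    trace: DiameterTrace      # optical clock (t=0 at movie start)
    gt: GroundTruth           # times on the optical clock; ttl_window electrical


def render_sync_pair(gt: GroundTruth, spec: SynthSpec,
                     pad_s: float = 2.0, ttl_high_v: float = 5.0) -> SyncBundle:
    """Render voltage + TTL + diameter trace for a synchronized recording.

    The electrical record spans ``[0, pad + duration + pad)``; the movie
    occupies ``[pad, pad + duration)`` and the TTL aux channel is high
    exactly on that half-open window.
    """
    if pad_s < 0:
        raise DataError("pad_s must be non-negative")
    total = spec.duration_s + 2 * pad_s
    voltage = render_voltage_trace(gt, spec, t_offset=pad_s, total_duration=total)
    t_on, t_off = pad_s, pad_s + spec.duration_s
    aux = np.where((voltage.t >= t_on) & (voltage.t < t_off), ttl_high_v, 0.0)
    voltage = VoltageTrace(t=voltage.t, v=voltage.v, rate=voltage.rate, aux=aux)
    trace = render_diameter_trace(gt, spec)
    gt_out = GroundTruth(beats=gt.beats, ap_events=gt.ap_events,
                         ttl_window=(t_on, t_off), spec=spec)
    return SyncBundle(voltage=voltage, trace=trace, gt=gt_out)
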