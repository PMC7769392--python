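"""Fiducial-marker motion, the gating window, and couch corrections.

The fluoroscopic tracking system reports the 3-axis displacement of an
implanted marker from its planned position at the imaging pulse rate
(30/15 Hz for thoracic/abdominal sites, 1 Hz for prostate).  The beam is
enabled only while every axis is inside the gating window (±2.0 mm by
default).  Intrafraction baseline shift (step) and drift (slow ramp) push
the marker out of the window until an operator moves the couch; those
interventions are what the log analytics later counts.

The synthetic respiratory waveform is the standard asymmetric cosine-power
surrogate u(t) = 1 − cos^(2n)(π t / T) with n = 2: u is 0 on the
end-exhale plateau (where the planned position is defined), peaks at 1 at
inhale, and spends most of the cycle near exhale.  Its mean over whole
periods is 1 − C(2n, n)/4^n = 5/8 for n = 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from math import comb

import numpy as np
import pandas as pd
import yaml

AXES = ("LR", "AP", "SI")

#: Per-axis gating-window half width, mm.
DEFAULT_GATE_WINDOW_MM = 2.0

Vec3 = tuple[float, float, float]


@dataclass
class MotionParams:
    """Parameters of the synthetic marker-motion model (all per axis LR/AP/SI)."""

    period_s: float = 4.0
    amplitude_mm: Vec3 = (0.0, 0.0, 0.0)
    drift_rate_mm_per_min: Vec3 = (0.0, 0.0, 0.0)
    shift_events: list[tuple[float, Vec3]] = dataclass_field(default_factory=list)
    noise_sd_mm: Vec3 = (0.0, 0.0, 0.0)
    sampling_hz: float = 30.0
    waveform_exponent: int = 2  #: n in cos^(2n); 2 is the conventional choice

    def validate(self) -> None:
        if not self.period_s > 0:
            raise ValueError(f"period_s must be > 0, got {self.period_s}")
        if not self.sampling_hz > 0:
            raise ValueError(f"sampling_hz must be > 0, got {self.sampling_hz}")
        if any(a < 0 for a in self.amplitude_mm):
            raise ValueError("amplitudes must be >= 0")
        if any(s < 0 for s in self.noise_sd_mm):
            raise ValueError("noise SDs must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "MotionParams":
        d = yaml.safe_load(open(path))
        if "shift_events" in d:
            d["shift_events"] = [(float(t), tuple(v)) for t, v in d["shift_events"]]
        for key in ("amplitude_mm", "drift_rate_mm_per_min", "noise_sd_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class MarkerTrace:
    """Sampled marker displacement from the planned position, plus couch state.

    ``displacement`` is what the tracking system sees (after any couch
    offset already applied); ``couch_offset`` is the cumulative couch shift.
    Both are (n, 3) arrays in mm on a uniform time grid.
    """

    times: np.ndarray
    displacement: np.ndarray
    couch_offset: np.ndarray
    sampling_hz: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.couch_offset = np.asarray(self.couch_offset, dtype=float)
        if self.displacement.shape != (self.times.size, 3):
            raise ValueError("displacement must have shape (n_samples, 3)")
        if self.couch_offset.shape != self.displacement.shape:
            raise ValueError("couch_offset must match displacement shape")

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] + 1.0 / self.sampling_hz) if self.times.size else 0.0

    def copy(self) -> "MarkerTrace":
        return MarkerTrace(
            self.times.copy(), self.displacement.copy(), self.couch_offset.copy(), self.sampling_hz
        )


@dataclass
class GateSignal:
    """Boolean beam-enable series on the trace's time grid (zero-order hold)."""

    times: np.ndarray
    on: np.ndarray
    sampling_hz: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.on = np.asarray(self.on, dtype=bool)
        if self.on.shape != self.times.shape:
            raise ValueError("gate series must match time grid length")


@dataclass(frozen=True)
class CouchAdjustmentEvent:
    """Operator couch move correcting a baseline offset."""

    time_s: float
    shift_mm: Vec3

    @property
    def size_cm(self) -> float:
        dx, dy, dz = self.shift_mm
        return math.sqrt(dx * dx + dy * dy + dz * dz) / 10.0


def respiratory_waveform(t: np.ndarray, period_s: float, exponent: int = 2) -> np.ndarray:
    """u(t) = 1 − cos^(2n)(π t / T), in [0, 1], 0 at end-exhale."""
    return 1.0 - np.cos(np.pi * t / period_s) ** (2 * exponent)


def waveform_mean(exponent: int = 2) -> float:
    """Analytic mean of the waveform over whole periods: 1 − C(2n,n)/4^n."""
    n = exponent
    return 1.0 - comb(2 * n, n) / 4.0**n


def generate_marker_trace(params: MotionParams, duration_s: float, seed: int) -> MarkerTrace:
    """Synthesize a marker trace: respiration + drift + step shifts + noise.

    Deterministic given ``seed``; extending ``duration_s`` with the same seed
    reproduces the shorter trace as a prefix (noise is drawn row-major per
    sample), which lets callers grow a trace on demand.
    """
    params.validate()
    if not duration_s > 0:
        raise ValueError(f"duration_s must be > 0, got {duration_s}")
    hz = params.sampling_hz
    n = int(np.ceil(duration_s * hz))
    t = np.arange(n, dtype=float) / hz
    u = respiratory_waveform(t, params.period_s, params.waveform_exponent)
    disp = np.outer(u, np.asarray(params.amplitude_mm, dtype=float))
    disp += np.outer(t / 60.0, np.asarray(params.drift_rate_mm_per_min, dtype=float))
    for t0, offset in params.shift_events:
        disp[t >= t0] += np.asarray(offset, dtype=float)
    sd = np.asarray(params.noise_sd_mm, dtype=float)
    if np.any(sd > 0):
        rng = np.random.default_rng(seed)
        disp += rng.normal(size=(n, 3)) * sd
    return MarkerTrace(t, disp, np.zeros((n, 3)), hz)


def compute_gate_signal(trace: MarkerTrace, window_mm: float = DEFAULT_GATE_WINDOW_MM) -> GateSignal:
    """Gate is on iff |displacement| <= window_mm on *every* axis (inclusive)."""
    if not window_mm > 0:
        raise ValueError(f"window_mm must be > 0, got {window_mm}")
    if trace.times.size == 0:
        raise ValueError("empty trace")
    on = np.all(np.abs(trace.displacement) <= window_mm, axis=1)
    return GateSignal(trace.times.copy(), on, trace.sampling_hz)


def duty_cycle(gate: GateSignal, t_start: float | None = None, t_end: float | None = None) -> float:
    """Fraction of gate samples in [t_start, t_end) that are on."""
    t0 = gate.times[0] if t_start is None else t_start
    t1 = gate.times[-1] + 1.0 / gate.sampling_hz if t_end is None else t_end
    if not t0 < t1:
        raise ValueError(f"empty window [{t0}, {t1})")
    mask = (gate.times >= t0) & (gate.times < t1)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no gate samples in [{t0}, {t1})")
    return float(gate.on[mask].sum()) / n


def estimate_baseline(trace: MarkerTrace, window_s: float = 15.0, quantile: float = 0.1) -> MarkerTrace:
    """Trailing rolling low-quantile per axis: tracks the end-exhale baseline.

    A plain running median of a large-amplitude respiratory trace sits well
    above baseline (the waveform's median is ≈ 0.75·amplitude), so the
    operator model judges baseline from the exhale envelope instead.
    Warm-up uses an expanding window.
    """
    win = max(1, int(round(window_s * trace.sampling_hz)))
    df = pd.DataFrame(trace.displacement)
    base = df.rolling(win, min_periods=1).quantile(quantile).to_numpy()
    return MarkerTrace(trace.times.copy(), base, trace.couch_offset.copy(), trace.sampling_hz)


def detect_baseline_event(
    trace: MarkerTrace, threshold_mm: float, dwell_s: float
) -> list[float]:
    """Times at which a sustained baseline excursion is flagged.

    The trailing median over ``dwell_s`` is compared per axis against
    ``threshold_mm``; a detection fires on an upward crossing (the median
    was within tolerance and now exceeds it on some axis), and no further
    detection fires within ``dwell_s`` of the previous one.  A persistent
    step therefore yields exactly one detection until the excursion is
    corrected and the detector re-arms.
    """
    if not threshold_mm > 0:
        raise ValueError(f"threshold_mm must be > 0, got {threshold_mm}")
    if not dwell_s > 0:
        raise ValueError(f"dwell_s must be > 0, got {dwell_s}")
    win = max(1, int(round(dwell_s * trace.sampling_hz)))
    med = pd.DataFrame(trace.displacement).rolling(win, min_periods=win).median().to_numpy()
    with np.errstate(invalid="ignore"):
        exceed = np.any(np.abs(med) > threshold_mm, axis=1)
    exceed &= ~np.any(np.isnan(med), axis=1)
    detections: list[float] = []
    armed = True
    last = -np.inf
    for i in range(exceed.size):
        if not exceed[i]:
            armed = True
            continue
        if armed and trace.times[i] - last >= dwell_s:
            detections.append(float(trace.times[i]))
            last = trace.times[i]
        armed = False
    return detections


def apply_couch_adjustment(trace: MarkerTrace, event: CouchAdjustmentEvent) -> MarkerTrace:
    """Return a new trace with the couch shift applied from ``event.time_s`` on.

    Moving the couch by ``shift_mm`` reduces the observed displacement by the
    same vector; samples before the event are untouched.
    """
    if not trace.times[0] <= event.time_s <= trace.times[-1]:
        raise ValueError(
            f"event time {event.time_s} outside trace span "
            f"[{trace.times[0]}, {trace.times[-1]}]"
        )
    out = trace.copy()
    shift = np.asarray(event.shift_mm, dtype=float)
    idx = out.times >= event.time_s
    out.displacement[idx] -= shift
    out.couch_offset[idx] += shift
    return out
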