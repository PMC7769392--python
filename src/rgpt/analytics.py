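"""Session metrics and cohort summaries from machine logs.

Quantities computed per session from the log:

* ``beam_delivery_time`` — TBS: sum over fields of (last spot beam-off −
  first spot beam-on); gaps between fields are excluded.
* ``gating_efficiency`` — the beam-delivery duty cycle actually achieved:
  the fraction of fluoroscopy samples with the gate on, counted within the
  beam-delivery windows.  Gate state is reconstructed from the logged
  transitions at the session's sampling rate so 1 Hz and 30 Hz sessions are
  comparable as fractions.
* ``adjustment_frequency`` — share of sessions with at least one intra-field
  redo-bone-matching signal (recorded between a field's first beam-on and
  last beam-off).
* ``adjustment_size`` — Euclidean norm (cm) of each couch move during the
  delivery windows.

Cohort aggregation reports per-site mean ± sample SD (ddof=1; single-session
categories report SD as not available) with a totals row recomputed from the
pooled per-session values, never as a mean of means.

For consistency of the actual-vs-ideal difference, the simulated ideal time
paired with a log-derived TBS should use the same endpoint convention: the
continuous timeline's ``beam_on_window_s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from . import log_model as lm
from .plan_model import TreatmentPlan


@dataclass
class SessionMetrics:
    session_id: str
    site_category: str
    tbs_s: float  #: actual (gated) beam-delivery time from the log
    tbs_sim_s: float  #: simulated ideal-environment time, same endpoints
    efficiency: float  #: gating duty cycle achieved, in [0, 1]
    n_adjustments: int  #: intra-field redo-bone-matching count
    adjustment_sizes_cm: list[float] = dataclass_field(default_factory=list)

    @property
    def difference_s(self) -> float:
        return self.tbs_s - self.tbs_sim_s


def delivery_windows(log: lm.SessionLog) -> dict[int, tuple[float, float]]:
    """Per field K: (first spot beam-on, last spot beam-off)."""
    first: dict[int, float] = {}
    last: dict[int, float] = {}
    for ev in log.events:
        if ev.kind == lm.SPOT_BEAM_ON:
            first.setdefault(ev.payload["k"], ev.timestamp_s)
        elif ev.kind == lm.SPOT_BEAM_OFF:
            last[ev.payload["k"]] = ev.timestamp_s
    return {k: (first[k], last[k]) for k in first if k in last}


def beam_delivery_time(log: lm.SessionLog) -> float:
    """TBS in seconds; raises on a log without spot events."""
    windows = delivery_windows(log)
    if not windows:
        raise ValueError("log contains no spot beam events")
    return sum(b - a for a, b in windows.values())


def _gate_transitions(log: lm.SessionLog) -> tuple[np.ndarray, np.ndarray]:
    times = [ev.timestamp_s for ev in log.events if ev.kind in (lm.GATE_ON, lm.GATE_OFF)]
    states = [ev.kind == lm.GATE_ON for ev in log.events if ev.kind in (lm.GATE_ON, lm.GATE_OFF)]
    return np.asarray(times, dtype=float), np.asarray(states, dtype=bool)


def _spill_intervals(log: lm.SessionLog) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    start: float | None = None
    for ev in log.events:
        if ev.kind == lm.SPILL_START:
            start = ev.timestamp_s
        elif ev.kind == lm.SPILL_END and start is not None:
            out.append((start, ev.timestamp_s))
            start = None
    return out


def gating_efficiency(
    log: lm.SessionLog,
    sampling_hz: float | None = None,
    *,
    denominator: str = "delivery",
) -> float:
    """Gate-on sample fraction within the beam-delivery windows, in [0, 1].

    ``denominator="delivery"`` counts every fluoroscopy sample of the
    first-on→last-off window of each field; ``"spill"`` restricts the count
    to beam-ready (flat-top) periods within those windows.
    """
    hz = log.sampling_hz if sampling_hz is None else sampling_hz
    if not hz > 0:
        raise ValueError("sampling rate must be positive")
    windows = list(delivery_windows(log).values())
    if not windows:
        raise ValueError("log contains no spot beam events")
    if denominator == "spill":
        clipped = []
        for s0, s1 in _spill_intervals(log):
            for w0, w1 in windows:
                lo, hi = max(s0, w0), min(s1, w1)
                if lo < hi:
                    clipped.append((lo, hi))
        windows = clipped
    elif denominator != "delivery":
        raise ValueError(f"unknown denominator mode {denominator!r}")
    t_hi = max(b for _, b in windows)
    grid = np.arange(int(math.ceil(t_hi * hz)) + 2, dtype=float) / hz
    mask = np.zeros(grid.size, dtype=bool)
    for a, b in windows:
        mask |= (grid >= a) & (grid < b)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("zero-length delivery window at this sampling rate")
    tr_t, tr_s = _gate_transitions(log)
    idx = np.searchsorted(tr_t, grid[mask], side="right") - 1
    on = np.where(idx >= 0, tr_s[np.clip(idx, 0, None)], False)
    return float(on.sum()) / n


def intra_field_adjustment_times(log: lm.SessionLog) -> list[float]:
    """Redo-bone-matching timestamps falling inside a delivery window."""
    windows = delivery_windows(log).values()
    return [
        ev.timestamp_s
        for ev in log.events
        if ev.kind == lm.REDO_BONE_MATCHING
        and any(a <= ev.timestamp_s <= b for a, b in windows)
    ]


def adjustment_frequency(logs: list[lm.SessionLog]) -> float:
    """Fraction of sessions with >= 1 intra-field adjustment."""
    if not logs:
        raise ValueError("empty cohort")
    n_adj = sum(1 for log in logs if intra_field_adjustment_times(log))
    return n_adj / len(logs)


def adjustment_size(log: lm.SessionLog) -> list[float]:
    """Couch-move sizes (cm) during delivery windows, in chronological order."""
    windows = delivery_windows(log).values()
    sizes = []
    for ev in log.events:
        if ev.kind == lm.COUCH_MOVE and any(
            a <= ev.timestamp_s <= b for a, b in windows
        ):
            dx, dy, dz = ev.payload["dx_mm"], ev.payload["dy_mm"], ev.payload["dz_mm"]
            sizes.append(math.sqrt(dx * dx + dy * dy + dz * dz) / 10.0)
    return sizes


def use_factor(plans: list[TreatmentPlan], bin_deg: float = 1.0) -> dict[float, float]:
    """Gantry-angle use factor: per angle bin, the fraction of all fields."""
    angles = [f.gantry_angle_deg for p in plans for f in p.fields]
    if not angles:
        raise ValueError("no fields in input plans")
    counts: dict[float, int] = {}
    for a in angles:
        b = math.floor(a / bin_deg) * bin_deg
        counts[b] = counts.get(b, 0) + 1
    total = len(angles)
    return {b: c / total for b, c in sorted(counts.items())}


def compute_session_metrics(
    log: lm.SessionLog,
    tbs_sim_s: float,
    *,
    sampling_hz: float | None = None,
) -> SessionMetrics:
    """All per-session metrics from one log plus the paired ideal time."""
    return SessionMetrics(
        session_id=log.session_id,
        site_category=log.site_category,
        tbs_s=beam_delivery_time(log),
        tbs_sim_s=tbs_sim_s,
        efficiency=gating_efficiency(log, sampling_hz),
        n_adjustments=len(intra_field_adjustment_times(log)),
        adjustment_sizes_cm=adjustment_size(log),
    )


# ---------------------------------------------------------------------------
# cohort aggregation
# ---------------------------------------------------------------------------

def _summarize(group: list[SessionMetrics]) -> dict:
    tbs = pd.Series([m.tbs_s / 60.0 for m in group])
    sim = pd.Series([m.tbs_sim_s / 60.0 for m in group])
    diff = pd.Series([m.difference_s / 60.0 for m in group])
    eff = pd.Series([m.efficiency * 100.0 for m in group])
    sizes = pd.Series([s for m in group for s in m.adjustment_sizes_cm], dtype=float)
    n_adjusted = sum(1 for m in group if m.n_adjustments > 0)
    return {
        "n_sessions": len(group),
        "tbs_min_mean": tbs.mean(),
        "tbs_min_sd": tbs.std(ddof=1),
        "tbs_sim_min_mean": sim.mean(),
        "tbs_sim_min_sd": sim.std(ddof=1),
        "difference_min_mean": diff.mean(),
        "difference_min_sd": diff.std(ddof=1),
        "efficiency_pct_mean": eff.mean(),
        "efficiency_pct_sd": eff.std(ddof=1),
        "adjustment_frequency_pct": 100.0 * n_adjusted / len(group),
        "n_adjustments": int(sum(m.n_adjustments for m in group)),
        "adjustment_size_cm_mean": sizes.mean() if len(sizes) else float("nan"),
        "adjustment_size_cm_sd": sizes.std(ddof=1) if len(sizes) else float("nan"),
    }


def aggregate(
    metrics: list[SessionMetrics], categories: list[str] | None = None
) -> pd.DataFrame:
    """Per-category mean ± sample SD table with a pooled totals row.

    SD uses ddof=1 and is NaN (rendered "N.A.") for single-session
    categories.  Size statistics pool individual adjustments within the
    category.  The totals row is recomputed from all sessions, not averaged
    over categories.
    """
    if not metrics:
        raise ValueError("no session metrics to aggregate")
    if categories is None:
        categories = sorted({m.site_category for m in metrics})
    unknown = {m.site_category for m in metrics} - set(categories)
    if unknown:
        raise ValueError(f"unknown category label(s): {sorted(unknown)}")
    rows = {}
    for cat in categories:
        group = [m for m in metrics if m.site_category == cat]
        if group:
            rows[cat] = _summarize(group)
    rows["total"] = _summarize(list(metrics))
    return pd.DataFrame.from_dict(rows, orient="index")


def format_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Human-readable twin of the aggregate table: "mean ± SD" strings, N.A. SDs."""
    def fmt(mean, sd, unit=""):
        if pd.isna(mean):
            return "N.A."
        sd_s = "N.A." if pd.isna(sd) else f"{sd:.2f}"
        return f"{mean:.2f} ± {sd_s}{unit}"

    out = pd.DataFrame(index=table.index)
    out["n_sessions"] = table["n_sessions"].astype(int)
    out["continuous_min"] = [
        fmt(r["tbs_sim_min_mean"], r["tbs_sim_min_sd"]) for _, r in table.iterrows()
    ]
    out["gated_min"] = [fmt(r["tbs_min_mean"], r["tbs_min_sd"]) for _, r in table.iterrows()]
    out["difference_min"] = [
        fmt(r["difference_min_mean"], r["difference_min_sd"]) for _, r in table.iterrows()
    ]
    out["efficiency_pct"] = [
        fmt(r["efficiency_pct_mean"], r["efficiency_pct_sd"]) for _, r in table.iterrows()
    ]
    out["adjustment_frequency_pct"] = [
        f"{r['adjustment_frequency_pct']:.1f}" for _, r in table.iterrows()
    ]
    out["adjustment_size_cm"] = [
        fmt(r["adjustment_size_cm_mean"], r["adjustment_size_cm_sd"])
        for _, r in table.iterrows()
    ]
    return out
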