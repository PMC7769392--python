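"""End-to-end synthetic sessions and cohorts with recorded ground truth.

No gated-delivery machine logs are publicly available, so every analytics
operation in this package is exercised against synthetic sessions whose
true quantities are known by construction.  A session is composed as:

    plan → marker trace (respiration + drift/shifts + noise)
         → operator loop (baseline detection → couch correction, logged as
           redo-bone-matching + couch-move)
         → gate signal (±2 mm per-axis window)
         → gated spill-cycle simulation → SessionLog + ground truth

The default cohort reproduces the per-site structure of a reference
clinical population (fields-per-session ranges, CTV ranges, session
counts) at a 5% scale; ``scale=1.0`` gives the full 2810 sessions.  Per-site motion
defaults are chosen so the emergent gating efficiencies order as prostate
≫ lung/liver > pancreas — an ordering, not a value match, since the real
per-site duty-cycle distributions are unpublished.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import log_model as lm
from .analytics import SessionMetrics
from .motion_gating import (
    CouchAdjustmentEvent,
    MarkerTrace,
    MotionParams,
    apply_couch_adjustment,
    compute_gate_signal,
    detect_baseline_event,
    estimate_baseline,
    generate_marker_trace,
)
from .plan_model import EnergyLayer, Field, Spot, TreatmentPlan
from .synchrotron_sim import (
    GateExhaustedError,
    SynchrotronTiming,
    simulate_continuous,
    simulate_gated,
)

_SEED_MOD = 2**31 - 1


def _child_seed(*parts) -> int:
    """Deterministic child seed below 2^31 from a tuple of integers."""
    ss = np.random.SeedSequence(list(int(p) for p in parts))
    return int(ss.generate_state(1)[0] % _SEED_MOD)


@dataclass
class OperatorParams:
    """Model of the operator reacting to baseline shift/drift.

    The operator watches the end-exhale baseline estimate; when its running
    median exceeds the tolerance on any axis, a redo-bone-matching event is
    logged and, after a reaction delay, the couch is moved by the estimated
    offset.  As a fallback, a gate that stays off for a whole
    ``starvation_window_s`` also triggers an intervention — an operator will
    always re-match when the beam refuses to resume, even if the estimated
    offset sits just inside the nominal tolerance.
    """

    threshold_mm: float = 2.0
    dwell_s: float = 10.0
    reaction_delay_s: float = 15.0
    baseline_window_s: float = 15.0
    baseline_quantile: float = 0.1
    starvation_window_s: float = 30.0
    max_events: int = 50


@dataclass
class SiteSpec:
    """Cohort structure and motion statistics for one disease site."""

    name: str
    n_sessions_full: int
    n_plans_full: int
    fields_range: tuple[int, int]
    fields_weights: tuple[float, ...]  #: P(X = lo..hi)
    ctv_range_ml: tuple[float, float]
    fraction_schemes: tuple[int, ...]
    gantry_angles: tuple[float, ...]
    sampling_hz: float
    period_s: float
    amplitude_mm: tuple[float, float, float]
    drift_rate_mm_per_min: tuple[float, float, float]
    noise_sd_mm: tuple[float, float, float]
    shift_mean_per_session: float  #: Poisson mean of step baseline shifts
    shift_magnitude_mm: tuple[float, float]
    shift_window_s: tuple[float, float] = (30.0, 300.0)  #: typical session span
    shift_axis_probs: tuple[float, float, float] = (0.2, 0.3, 0.5)


def default_site_specs() -> dict[str, SiteSpec]:
    """Reference-population structure with per-site synthetic motion defaults."""
    return {
        "prostate": SiteSpec(
            name="prostate",
            n_sessions_full=1868,
            n_plans_full=69,
            fields_range=(2, 4),
            fields_weights=(0.10, 0.15, 0.75),
            ctv_range_ml=(31.4, 154.5),
            fraction_schemes=(30, 21),
            gantry_angles=(90.0, 270.0),
            sampling_hz=1.0,
            period_s=4.0,
            amplitude_mm=(0.6, 0.9, 1.5),
            drift_rate_mm_per_min=(0.02, 0.02, 0.05),
            noise_sd_mm=(0.4, 0.4, 0.6),
            shift_mean_per_session=0.35,
            shift_magnitude_mm=(2.5, 4.5),
            shift_window_s=(20.0, 150.0),
        ),
        "liver": SiteSpec(
            name="liver",
            n_sessions_full=727,
            n_plans_full=45,
            fields_range=(2, 4),
            fields_weights=(0.70, 0.20, 0.10),
            ctv_range_ml=(1.6, 2246.2),
            fraction_schemes=(10, 22, 37, 20),
            gantry_angles=(0.0, 30.0, 60.0, 90.0, 150.0, 180.0, 210.0, 330.0),
            sampling_hz=30.0,
            period_s=4.0,
            amplitude_mm=(1.5, 3.0, 7.0),
            drift_rate_mm_per_min=(0.05, 0.10, 0.45),
            noise_sd_mm=(0.15, 0.15, 0.15),
            shift_mean_per_session=0.35,
            shift_magnitude_mm=(2.5, 4.0),
            shift_window_s=(30.0, 300.0),
        ),
        "pancreas": SiteSpec(
            name="pancreas",
            n_sessions_full=165,
            n_plans_full=8,
            fields_range=(2, 2),
            fields_weights=(1.0,),
            ctv_range_ml=(38.6, 382.3),
            fraction_schemes=(25,),
            gantry_angles=(0.0, 90.0, 180.0, 270.0),
            sampling_hz=30.0,
            period_s=3.5,
            amplitude_mm=(2.0, 3.5, 9.0),
            drift_rate_mm_per_min=(0.10, 0.30, 0.80),
            noise_sd_mm=(0.15, 0.15, 0.15),
            shift_mean_per_session=0.80,
            shift_magnitude_mm=(2.5, 4.0),
            shift_window_s=(30.0, 450.0),
        ),
        "lung": SiteSpec(
            name="lung",
            n_sessions_full=40,
            n_plans_full=4,
            fields_range=(3, 3),
            fields_weights=(1.0,),
            ctv_range_ml=(4.9, 77.6),
            fraction_schemes=(10,),
            gantry_angles=(0.0, 45.0, 90.0, 180.0, 315.0),
            sampling_hz=15.0,
            period_s=3.5,
            amplitude_mm=(1.0, 3.0, 5.5),
            drift_rate_mm_per_min=(0.05, 0.15, 0.60),
            noise_sd_mm=(0.15, 0.15, 0.15),
            shift_mean_per_session=0.70,
            shift_magnitude_mm=(2.5, 4.0),
            shift_window_s=(30.0, 300.0),
        ),
        "adrenal_gland": SiteSpec(
            name="adrenal_gland",
            n_sessions_full=10,
            n_plans_full=1,
            fields_range=(2, 2),
            fields_weights=(1.0,),
            ctv_range_ml=(28.1, 28.1),
            fraction_schemes=(10,),
            gantry_angles=(90.0, 180.0),
            sampling_hz=30.0,
            period_s=4.0,
            amplitude_mm=(1.0, 2.5, 6.0),
            drift_rate_mm_per_min=(0.05, 0.15, 0.60),
            noise_sd_mm=(0.15, 0.15, 0.15),
            shift_mean_per_session=0.30,
            shift_magnitude_mm=(2.5, 4.0),
            shift_window_s=(30.0, 250.0),
        ),
    }


@dataclass
class CohortSpec:
    """A cohort = per-site structure × a scale factor on session counts."""

    sites: dict[str, SiteSpec] = dataclass_field(default_factory=default_site_specs)
    scale: float = 0.05
    operator: OperatorParams = dataclass_field(default_factory=OperatorParams)
    timing: SynchrotronTiming = dataclass_field(default_factory=SynchrotronTiming)
    gate_window_mm: float = 2.0

    def n_sessions(self, site: str) -> int:
        return max(1, round(self.sites[site].n_sessions_full * self.scale))

    def n_plans(self, site: str) -> int:
        return max(1, round(self.sites[site].n_plans_full * self.scale))


@dataclass
class GroundTruth:
    """Quantities the generator knows exactly for one synthetic session."""

    duty_cycle: float  #: gate-on fraction within the delivery windows
    n_intra_field_adjustments: int
    adjustment_sizes_cm: list[float]
    tbs_s: float  #: gated beam window (first-on → last-off per field)
    tbs_sim_s: float  #: continuous beam window, same endpoints
    tbs_cycle_s: float  #: gated time on cycle-start endpoints
    tbs_sim_cycle_s: float  #: continuous time on cycle-start endpoints


@dataclass
class SyntheticSession:
    session_id: str
    plan: TreatmentPlan
    motion: MotionParams
    log: lm.SessionLog
    truth: GroundTruth
    redo_times: list[float]
    couch_events: list[CouchAdjustmentEvent]
    seed: int

    def metrics(self) -> SessionMetrics:
        """Ground-truth session metrics (the analytics twin recomputes these)."""
        return SessionMetrics(
            session_id=self.session_id,
            site_category=self.plan.site_category,
            tbs_s=self.truth.tbs_s,
            tbs_sim_s=self.truth.tbs_sim_s,
            efficiency=self.truth.duty_cycle,
            n_adjustments=self.truth.n_intra_field_adjustments,
            adjustment_sizes_cm=list(self.truth.adjustment_sizes_cm),
        )


# ---------------------------------------------------------------------------
# plan generation
# ---------------------------------------------------------------------------

def generate_plan(
    spec: CohortSpec, category: str, seed: int, plan_id: str = ""
) -> TreatmentPlan:
    """Draw a plan within the site's structural ranges.

    Layer and spot counts scale with CTV (~V^(1/3) layers per field,
    ~V^(2/3) spots per layer) so continuous delivery times land in the
    few-minute band typical of spot-scanning sessions.
    """
    if category not in spec.sites:
        raise KeyError(f"unknown site category {category!r}")
    site = spec.sites[category]
    rng = np.random.default_rng(seed)
    lo, hi = site.fields_range
    x = int(rng.choice(np.arange(lo, hi + 1), p=np.asarray(site.fields_weights)))
    v_lo, v_hi = site.ctv_range_ml
    ctv = float(np.exp(rng.uniform(np.log(v_lo), np.log(v_hi))))
    n_layers = max(4, int(round(8 + 2.6 * ctv ** (1.0 / 3.0) + rng.normal(0, 1))))
    n_spots = max(8, min(250, int(round(40.0 * (ctv / 100.0) ** (2.0 / 3.0) + rng.normal(0, 3)))))
    r_max = min(28.0, 6.0 + 2.2 * ctv ** (1.0 / 3.0))
    lateral = 10.0 * (3.0 * ctv / (4.0 * np.pi)) ** (1.0 / 3.0)  # ~radius in mm
    fields = []
    for k in range(1, x + 1):
        angle = float(rng.choice(site.gantry_angles))
        ranges = np.linspace(r_max, max(0.5, 0.55 * r_max), n_layers)
        layers = []
        for r in ranges:
            xs = rng.uniform(-lateral, lateral, n_spots)
            ys = rng.uniform(-lateral, lateral, n_spots)
            ws = rng.uniform(0.3, 0.9, n_spots)
            layers.append(
                EnergyLayer(
                    range_g_cm2=float(r),
                    spots=tuple(
                        Spot(float(xs[i]), float(ys[i]), float(ws[i]), i + 1)
                        for i in range(n_spots)
                    ),
                )
            )
        fields.append(Field(index=k, gantry_angle_deg=angle, layers=tuple(layers)))
    return TreatmentPlan(
        site_category=category,
        fields=tuple(fields),
        ctv_ml=ctv,
        gating_flag=1,
        fractions=int(rng.choice(site.fraction_schemes)),
        plan_id=plan_id,
    )


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

def _draw_motion(site: SiteSpec, rng: np.random.Generator) -> MotionParams:
    shifts: list[tuple[float, tuple[float, float, float]]] = []
    for _ in range(int(rng.poisson(site.shift_mean_per_session))):
        t0 = float(rng.uniform(*site.shift_window_s))
        mag = float(rng.uniform(*site.shift_magnitude_mm)) * float(rng.choice((-1.0, 1.0)))
        axis = int(rng.choice(3, p=np.asarray(site.shift_axis_probs)))
        vec = [0.0, 0.0, 0.0]
        vec[axis] = mag
        shifts.append((t0, tuple(vec)))
    return MotionParams(
        period_s=site.period_s * float(rng.uniform(0.9, 1.1)),
        amplitude_mm=tuple(a * float(rng.uniform(0.85, 1.15)) for a in site.amplitude_mm),
        drift_rate_mm_per_min=tuple(
            d * float(rng.uniform(0.7, 1.3)) * float(rng.choice((-1.0, 1.0)))
            for d in site.drift_rate_mm_per_min
        ),
        shift_events=sorted(shifts),
        noise_sd_mm=site.noise_sd_mm,
        sampling_hz=site.sampling_hz,
    )


def _operator_loop(
    trace: MarkerTrace, op: OperatorParams, gate_window_mm: float = 2.0
) -> tuple[MarkerTrace, list[float], list[CouchAdjustmentEvent]]:
    """Iteratively detect baseline excursions and inject couch corrections."""
    work = trace
    redo: list[float] = []
    couch: list[CouchAdjustmentEvent] = []
    guard_t = -np.inf
    starve_win = max(1, int(round(op.starvation_window_s * trace.sampling_hz)))
    for _ in range(op.max_events):
        base = estimate_baseline(work, op.baseline_window_s, op.baseline_quantile)
        cands = [
            t for t in detect_baseline_event(base, op.threshold_mm, op.dwell_s) if t > guard_t
        ]
        gate = compute_gate_signal(work, gate_window_mm)
        frac = (
            pd.Series(gate.on.astype(float))
            .rolling(starve_win, min_periods=starve_win)
            .mean()
            .to_numpy()
        )
        starved = np.flatnonzero((frac == 0.0) & (work.times > guard_t))
        if starved.size:
            cands.append(float(work.times[starved[0]]))
        if not cands:
            break
        t_det = min(cands)
        t_fix = t_det + op.reaction_delay_s
        if t_fix > work.times[-1]:
            break
        i = int(np.searchsorted(work.times, t_det))
        shift = tuple(float(v) for v in base.displacement[i])
        event = CouchAdjustmentEvent(time_s=t_fix, shift_mm=shift)
        work = apply_couch_adjustment(work, event)
        redo.append(float(t_det))
        couch.append(event)
        guard_t = t_fix + op.dwell_s
    return work, redo, couch


def generate_session(
    plan: TreatmentPlan,
    motion: MotionParams,
    operator: OperatorParams,
    timing: SynchrotronTiming,
    seed: int,
    session_id: str = "session",
    *,
    gate_window_mm: float = 2.0,
) -> SyntheticSession:
    """Compose trace → operator → gate → gated simulation into a logged session.

    Deterministic given the seed: the marker trace is prefix-stable under
    extension, so re-running with a longer trace (when the gate signal runs
    out before the plan is delivered) reproduces the same session.
    """
    cont_tl, tbs_sim_cycle = simulate_continuous(plan, timing)
    sim_window = cont_tl.beam_on_window_s
    duration = max(180.0, 6.0 * tbs_sim_cycle + 120.0)
    for _ in range(8):
        trace = generate_marker_trace(motion, duration, seed)
        work, redo, couch = _operator_loop(trace, operator, gate_window_mm)
        gate = compute_gate_signal(work, gate_window_mm)
        try:
            timeline, tbs_cycle = simulate_gated(plan, timing, gate, True)
            break
        except GateExhaustedError:
            duration *= 2.0
    else:
        raise GateExhaustedError(
            f"session {session_id}: plan not deliverable within {duration / 2:.0f}s of motion"
        )
    end_t = timeline.total_time_s
    redo = [t for t in redo if t <= end_t]
    couch = [e for e in couch if e.time_s <= end_t]
    log = lm.timeline_to_log(
        timeline,
        plan,
        session_id=session_id,
        sampling_hz=motion.sampling_hz,
        gate=gate,
        redo_events=redo,
        couch_events=couch,
    )
    windows = list(timeline.field_beam_spans().values())
    mask = np.zeros(gate.times.size, dtype=bool)
    for a, b in windows:
        mask |= (gate.times >= a) & (gate.times < b)
    duty = float(gate.on[mask].mean()) if mask.any() else float("nan")
    in_window = lambda t: any(a <= t <= b for a, b in windows)
    truth = GroundTruth(
        duty_cycle=duty,
        n_intra_field_adjustments=sum(1 for t in redo if in_window(t)),
        adjustment_sizes_cm=[e.size_cm for e in couch if in_window(e.time_s)],
        tbs_s=timeline.beam_on_window_s,
        tbs_sim_s=sim_window,
        tbs_cycle_s=tbs_cycle,
        tbs_sim_cycle_s=tbs_sim_cycle,
    )
    return SyntheticSession(
        session_id=session_id,
        plan=plan,
        motion=motion,
        log=log,
        truth=truth,
        redo_times=redo,
        couch_events=couch,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec, seed: int) -> list[SyntheticSession]:
    """Generate every site's sessions; (spec, seed) fully determines each log."""
    sessions: list[SyntheticSession] = []
    for si, (name, site) in enumerate(spec.sites.items()):
        n_plans = spec.n_plans(name)
        plans = [
            generate_plan(
                spec, name, _child_seed(seed, si, 1000 + p), plan_id=f"{name}-p{p + 1:03d}"
            )
            for p in range(n_plans)
        ]
        for s in range(spec.n_sessions(name)):
            plan = plans[s % n_plans]
            rng = np.random.default_rng(_child_seed(seed, si, 2000 + s))
            motion = _draw_motion(site, rng)
            sess_seed = _child_seed(seed, si, 3000 + s)
            sessions.append(
                generate_session(
                    plan,
                    motion,
                    spec.operator,
                    spec.timing,
                    sess_seed,
                    session_id=f"{name}-s{s + 1:04d}",
                    gate_window_mm=spec.gate_window_mm,
                )
            )
    return sessions


def cohort_manifest(sessions: list[SyntheticSession]) -> pd.DataFrame:
    """Ground-truth manifest: one row per session, exact generated values."""
    rows = []
    for s in sessions:
        rows.append(
            {
                "session_id": s.session_id,
                "site_category": s.plan.site_category,
                "plan_id": s.plan.plan_id,
                "x_fields": s.plan.n_fields,
                "ctv_ml": s.plan.ctv_ml,
                "seed": s.seed,
                "true_duty_cycle": s.truth.duty_cycle,
                "tbs_s": s.truth.tbs_s,
                "tbs_sim_s": s.truth.tbs_sim_s,
                "n_intra_field_adjustments": s.truth.n_intra_field_adjustments,
                "adjustment_sizes_cm": json.dumps(s.truth.adjustment_sizes_cm),
            }
        )
    return pd.DataFrame(rows)


def write_cohort(sessions: list[SyntheticSession], outdir: str | Path) -> None:
    """Write per-session logs, unique plan files, and the ground-truth manifest."""
    from .plan_model import save_plan

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written_plans: set[str] = set()
    for s in sessions:
        if s.plan.plan_id not in written_plans:
            save_plan(s.plan, out / f"{s.plan.plan_id}.plan.json")
            written_plans.add(s.plan.plan_id)
        lm.write_log(s.log, out / f"{s.session_id}.log.jsonl")
    cohort_manifest(sessions).to_csv(out / "manifest.csv", index=False)
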