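"""Discrete-event model of synchrotron spill-cycle beam delivery.

The accelerator repeats a magnetic excitation cycle: injection →
acceleration → flat top (beam extractable) → deceleration.  Spots are
delivered only at flat top, one energy layer per cycle (single-energy
extraction), until the spill charge or the maximum flat-top duration is
exhausted; changing energy layer always forces a fresh cycle.

Gated operation adds the waiting function: when the gate signal drops at
flat top the machine holds the spill ("delay gate") and resumes promptly
if the gate returns before a predefined wait limit — multiple gate-on
periods can then be served by one spill ("multiple gating").  If the wait
reaches the limit, or the flat-top/spill budgets run out, the cycle
decelerates and a new one must be prepared.  The legacy mode
(``multiple_gating=False``) models the older operation without the delay
gate: any gate-off at flat top immediately forces deceleration, so each
gate-on period can be served by at most one spill.

Session beam-delivery time (TBS) is accounted per field, from the field's
first cycle start to its last spot beam-off, summed over fields;
inter-field setup is out of scope.  The log-visible window (first spot
beam-on → last beam-off) is exposed on the timeline as
``beam_on_window_s`` — it differs from TBS by exactly one
injection+acceleration ramp per field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import yaml

from .motion_gating import GateSignal
from .plan_model import TreatmentPlan, validate_plan, InvalidPlanError

#: slack for floating-point comparisons of event times (seconds / charge units)
_EPS = 1e-9

CYCLE_START = "cycle_start"
FLAT_TOP_START = "flat_top_start"
SPOT_ON = "spot_on"
SPOT_OFF = "spot_off"
WAIT_START = "wait_start"
WAIT_END = "wait_end"
DECEL_START = "decel_start"
CYCLE_END = "cycle_end"

EVENT_KINDS = (
    CYCLE_START,
    FLAT_TOP_START,
    SPOT_ON,
    SPOT_OFF,
    WAIT_START,
    WAIT_END,
    DECEL_START,
    CYCLE_END,
)


class GateExhaustedError(RuntimeError):
    """The simulation needed gate state beyond the supplied signal's span."""


class SimulationStalledError(RuntimeError):
    """No progress within the configured cycle cap (e.g. gate never on)."""


class UndeliverableSpotError(ValueError):
    """A spot cannot be delivered within one spill under the given timing."""


@dataclass(frozen=True)
class SynchrotronTiming:
    """Excitation-cycle timing and extraction parameters (all configurable).

    Defaults are chosen so a full energy-layer switch
    (deceleration + switch overhead + injection + acceleration) totals 2 s,
    the scale of a per-layer energy change on this machine class.
    """

    injection_s: float = 0.3
    acceleration_s: float = 0.7
    deceleration_s: float = 0.5
    flat_top_max_s: float = 10.0
    spill_charge: float = 200.0  #: max deliverable charge per cycle
    wait_limit_s: float = 5.0  #: waiting-function limit at flat top
    energy_switch_overhead_s: float = 0.5
    spot_rate: float = 100.0  #: charge units / s while beam on
    spot_transition_s: float = 0.002  #: lateral scan move between spots

    def __post_init__(self) -> None:
        for name in (
            "injection_s",
            "acceleration_s",
            "deceleration_s",
            "flat_top_max_s",
            "wait_limit_s",
            "energy_switch_overhead_s",
            "spot_transition_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.spot_rate <= 0 or self.spill_charge <= 0:
            raise ValueError("spot_rate and spill_charge must be > 0")
        if self.wait_limit_s > self.flat_top_max_s:
            raise ValueError("wait_limit_s must not exceed flat_top_max_s")

    @property
    def layer_switch_s(self) -> float:
        return (
            self.deceleration_s
            + self.energy_switch_overhead_s
            + self.injection_s
            + self.acceleration_s
        )

    @classmethod
    def from_yaml(cls, path) -> "SynchrotronTiming":
        return cls(**yaml.safe_load(open(path)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


@dataclass(frozen=True)
class TimelineEvent:
    time_s: float
    kind: str
    data: dict


@dataclass
class DeliveryTimeline:
    """Ordered machine events of one simulated session."""

    events: list[TimelineEvent] = dataclass_field(default_factory=list)

    @property
    def total_time_s(self) -> float:
        return self.events[-1].time_s if self.events else 0.0

    def field_cycle_spans(self) -> dict[int, tuple[float, float]]:
        """Per field: (first cycle_start, last spot_off)."""
        first: dict[int, float] = {}
        last: dict[int, float] = {}
        for ev in self.events:
            k = ev.data.get("field")
            if ev.kind == CYCLE_START and k not in first:
                first[k] = ev.time_s
            elif ev.kind == SPOT_OFF:
                last[k] = ev.time_s
        return {k: (first[k], last[k]) for k in first if k in last}

    def field_beam_spans(self) -> dict[int, tuple[float, float]]:
        """Per field: (first spot_on, last spot_off) — the log-visible window."""
        first: dict[int, float] = {}
        last: dict[int, float] = {}
        for ev in self.events:
            k = ev.data.get("field")
            if ev.kind == SPOT_ON and k not in first:
                first[k] = ev.time_s
            elif ev.kind == SPOT_OFF:
                last[k] = ev.time_s
        return {k: (first[k], last[k]) for k in first if k in last}

    @property
    def beam_on_window_s(self) -> float:
        return sum(b - a for a, b in self.field_beam_spans().values())

    def delivered_charge(self) -> float:
        return sum(ev.data["weight"] for ev in self.events if ev.kind == SPOT_ON)

    def validate(self, plan: TreatmentPlan | None = None) -> list[str]:
        problems: list[str] = []
        prev = -math.inf
        open_spots: set[int] = set()
        seen: list[tuple] = []
        for ev in self.events:
            if ev.time_s < prev - _EPS:
                problems.append(f"time decreases at {ev.kind} ({ev.time_s} < {prev})")
            prev = max(prev, ev.time_s)
            if ev.kind not in EVENT_KINDS:
                problems.append(f"unknown event kind {ev.kind!r}")
            if ev.kind == SPOT_ON:
                sid = ev.data["spot_id"]
                if sid in open_spots:
                    problems.append(f"spot {sid} switched on twice")
                open_spots.add(sid)
                seen.append((ev.data["field"], ev.data["layer"], ev.data["spot_index"]))
            elif ev.kind == SPOT_OFF:
                sid = ev.data["spot_id"]
                if sid not in open_spots:
                    problems.append(f"spot {sid} switched off while not on")
                open_spots.discard(sid)
        if open_spots:
            problems.append(f"spots never switched off: {sorted(open_spots)}")
        if plan is not None:
            expected = [
                (f.index, li, s.index)
                for f in plan.fields
                for li, layer in enumerate(f.layers, start=1)
                for s in layer.spots
            ]
            if sorted(seen) != sorted(expected):
                problems.append(
                    f"delivered spot set differs from plan "
                    f"({len(seen)} delivered vs {len(expected)} planned)"
                )
        return problems


# ---------------------------------------------------------------------------
# gate providers
# ---------------------------------------------------------------------------

class AlwaysOnGate:
    """Ideal environment: the gate signal is always on."""

    span_end = math.inf

    def is_on(self, t: float) -> bool:
        return True

    def next_off_after(self, t: float) -> float:
        return math.inf

    def next_on_at_or_after(self, t: float) -> float:
        return t


class SampledGate:
    """Zero-order-hold view of a sampled :class:`GateSignal`.

    Sample ``i`` governs the half-open interval ``[t_i, t_i + 1/hz)``.
    Queries past the signal span raise :class:`GateExhaustedError` so the
    caller can extend the signal and retry.
    """

    def __init__(self, signal: GateSignal):
        if signal.times.size == 0:
            raise ValueError("empty gate signal")
        on = signal.on
        t = signal.times
        dt = 1.0 / signal.sampling_hz
        self.span_end = float(t[-1] + dt)
        edges = np.flatnonzero(np.diff(on.view(np.int8)))
        starts = list(t[edges[on[edges] == False] + 1]) if edges.size else []
        ends = list(t[edges[on[edges] == True] + 1]) if edges.size else []
        if on[0]:
            starts.insert(0, float(t[0]))
        if on[-1]:
            ends.append(self.span_end)
        self._starts = np.asarray(starts, dtype=float)
        self._ends = np.asarray(ends, dtype=float)

    def _guard(self, t: float) -> None:
        if t >= self.span_end - _EPS:
            raise GateExhaustedError(
                f"gate state needed at t={t:.3f}s but signal ends at {self.span_end:.3f}s"
            )

    def is_on(self, t: float) -> bool:
        self._guard(t)
        i = int(np.searchsorted(self._starts, t, side="right")) - 1
        return i >= 0 and t < self._ends[i]

    def next_off_after(self, t: float) -> float:
        i = int(np.searchsorted(self._starts, t, side="right")) - 1
        if i < 0 or t >= self._ends[i]:
            raise ValueError(f"gate is not on at t={t}")
        return float(self._ends[i])

    def next_on_at_or_after(self, t: float) -> float:
        self._guard(t)
        if self.is_on(t):
            return t
        j = int(np.searchsorted(self._starts, t, side="left"))
        if j >= self._starts.size:
            raise GateExhaustedError(f"no gate-on interval at or after t={t:.3f}s")
        return float(self._starts[j])


def _as_provider(gate) -> AlwaysOnGate | SampledGate:
    if gate is None:
        return AlwaysOnGate()
    if isinstance(gate, (AlwaysOnGate, SampledGate)):
        return gate
    if isinstance(gate, GateSignal):
        return SampledGate(gate)
    raise TypeError(f"cannot interpret {type(gate).__name__} as a gate")


def _check_plan(plan: TreatmentPlan, timing: SynchrotronTiming) -> None:
    rep = validate_plan(plan)
    if not rep.ok:
        raise InvalidPlanError("; ".join(rep.violations))
    for f in plan.fields:
        for li, layer in enumerate(f.layers, start=1):
            for s in layer.spots:
                if s.weight > timing.spill_charge + _EPS:
                    raise UndeliverableSpotError(
                        f"field {f.index} layer {li} spot {s.index}: weight {s.weight} "
                        f"exceeds spill charge {timing.spill_charge}"
                    )
                if s.weight / timing.spot_rate > timing.flat_top_max_s + _EPS:
                    raise UndeliverableSpotError(
                        f"field {f.index} layer {li} spot {s.index}: beam-on time "
                        f"exceeds maximum flat top {timing.flat_top_max_s}s"
                    )


def _tbs_from_spans(first_cycle: dict[int, float], last_off: dict[int, float]) -> float:
    return sum(last_off[k] - first_cycle[k] for k in first_cycle)


# ---------------------------------------------------------------------------
# ideal (continuous) delivery
# ---------------------------------------------------------------------------

def simulate_continuous(
    plan: TreatmentPlan, timing: SynchrotronTiming
) -> tuple[DeliveryTimeline, float]:
    """Deliver the plan in the ideal environment (gate signal always on).

    Returns the event timeline and TBS_sim: the per-field time from first
    cycle start to last spot beam-off, summed over fields.
    """
    _check_plan(plan, timing)
    ev: list[TimelineEvent] = []
    t = 0.0
    uid = 0
    first_cycle: dict[int, float] = {}
    last_off: dict[int, float] = {}
    first_layer = True
    for f in plan.fields:
        for li, layer in enumerate(f.layers, start=1):
            if not first_layer:
                t += timing.energy_switch_overhead_s
            first_layer = False
            tag = {"field": f.index, "layer": li}
            qi = 0
            while qi < len(layer.spots):
                ev.append(TimelineEvent(t, CYCLE_START, dict(tag)))
                first_cycle.setdefault(f.index, t)
                t += timing.injection_s + timing.acceleration_s
                ev.append(TimelineEvent(t, FLAT_TOP_START, dict(tag)))
                ft_deadline = t + timing.flat_top_max_s
                charge_left = timing.spill_charge
                delivered = False
                while qi < len(layer.spots):
                    spot = layer.spots[qi]
                    trans = timing.spot_transition_s if delivered else 0.0
                    beam = spot.weight / timing.spot_rate
                    if spot.weight > charge_left + _EPS:
                        break
                    if t + trans + beam > ft_deadline + _EPS:
                        break
                    t += trans
                    uid += 1
                    data = dict(tag, spot_index=spot.index, spot_id=uid, weight=spot.weight)
                    ev.append(TimelineEvent(t, SPOT_ON, data))
                    t += beam
                    ev.append(TimelineEvent(t, SPOT_OFF, dict(data)))
                    last_off[f.index] = t
                    charge_left -= spot.weight
                    delivered = True
                    qi += 1
                ev.append(TimelineEvent(t, DECEL_START, dict(tag)))
                t += timing.deceleration_s
                ev.append(TimelineEvent(t, CYCLE_END, dict(tag)))
    return DeliveryTimeline(ev), _tbs_from_spans(first_cycle, last_off)


# ---------------------------------------------------------------------------
# gated delivery
# ---------------------------------------------------------------------------

def simulate_gated(
    plan: TreatmentPlan,
    timing: SynchrotronTiming,
    gate,
    multiple_gating: bool = True,
    *,
    wait_accumulates: bool = False,
    max_cycles: int = 100_000,
) -> tuple[DeliveryTimeline, float]:
    """Deliver the plan under a gate signal.

    ``gate`` is a :class:`GateSignal` (or gate provider); with
    ``multiple_gating=True`` the waiting function holds the spill through
    short gate-off intervals (resuming only if the gate returns strictly
    before the wait limit — an exact tie decelerates); with ``False`` the
    legacy mode decelerates on any gate-off at flat top.  ``wait_accumulates`` makes the wait budget shared
    across all gate-off intervals of one spill instead of resetting at each
    gate-on.

    A spot is only started if it can complete before the next gate-off
    (completion exactly at gate-off counts as delivered); otherwise the beam
    holds until the gate drops and the waiting rules apply.
    """
    _check_plan(plan, timing)
    provider = _as_provider(gate)
    ev: list[TimelineEvent] = []
    t = 0.0
    uid = 0
    n_cycles = 0
    first_cycle: dict[int, float] = {}
    last_off: dict[int, float] = {}
    first_layer = True
    for f in plan.fields:
        for li, layer in enumerate(f.layers, start=1):
            if not first_layer:
                t += timing.energy_switch_overhead_s
            first_layer = False
            tag = {"field": f.index, "layer": li}
            qi = 0
            while qi < len(layer.spots):
                n_cycles += 1
                if n_cycles > max_cycles:
                    raise SimulationStalledError(
                        f"no progress after {max_cycles} cycles (gate may never be on)"
                    )
                ev.append(TimelineEvent(t, CYCLE_START, dict(tag)))
                first_cycle.setdefault(f.index, t)
                t += timing.injection_s + timing.acceleration_s
                ev.append(TimelineEvent(t, FLAT_TOP_START, dict(tag)))
                ft_deadline = t + timing.flat_top_max_s
                charge_left = timing.spill_charge
                delivered = False
                wait_used = 0.0
                while True:
                    if qi >= len(layer.spots):
                        break
                    spot = layer.spots[qi]
                    trans = timing.spot_transition_s if delivered else 0.0
                    beam = spot.weight / timing.spot_rate
                    if spot.weight > charge_left + _EPS:
                        break
                    if t + trans + beam > ft_deadline + _EPS:
                        break
                    if provider.is_on(t):
                        off_t = provider.next_off_after(t)
                        if t + trans + beam <= off_t + _EPS:
                            t += trans
                            uid += 1
                            data = dict(
                                tag, spot_index=spot.index, spot_id=uid, weight=spot.weight
                            )
                            ev.append(TimelineEvent(t, SPOT_ON, data))
                            t += beam
                            ev.append(TimelineEvent(t, SPOT_OFF, dict(data)))
                            last_off[f.index] = t
                            charge_left -= spot.weight
                            delivered = True
                            qi += 1
                            continue
                        if off_t >= ft_deadline - _EPS:
                            t = ft_deadline
                            break
                        t = off_t  # hold the beam until the gate drops
                    # gate is off at t
                    if not multiple_gating:
                        break
                    if ft_deadline - t <= _EPS:
                        break
                    ev.append(TimelineEvent(t, WAIT_START, dict(tag)))
                    limit_left = (
                        timing.wait_limit_s - wait_used
                        if wait_accumulates
                        else timing.wait_limit_s
                    )
                    deadline = min(t + limit_left, ft_deadline)
                    on_t = provider.next_on_at_or_after(t)
                    if on_t < deadline - _EPS:
                        ev.append(TimelineEvent(on_t, WAIT_END, dict(tag)))
                        wait_used += on_t - t
                        t = on_t
                        continue
                    ev.append(TimelineEvent(deadline, WAIT_END, dict(tag)))
                    t = deadline
                    break
                ev.append(TimelineEvent(t, DECEL_START, dict(tag)))
                t += timing.deceleration_s
                ev.append(TimelineEvent(t, CYCLE_END, dict(tag)))
    return DeliveryTimeline(ev), _tbs_from_spans(first_cycle, last_off)


# ---------------------------------------------------------------------------
# fixed-timestep verification oracle
# ---------------------------------------------------------------------------

def simulate_timestep_oracle(
    plan: TreatmentPlan,
    timing: SynchrotronTiming,
    gate,
    dt: float = 1e-3,
    multiple_gating: bool = True,
    *,
    wait_accumulates: bool = False,
    max_iterations: int = 500_000_000,
) -> float:
    """Advance the same delivery rules on a fixed time grid; return TBS.

    Written as a plain per-tick state machine, independent of the
    event-driven simulator: each state duration is rounded up to whole
    ticks, so the two agree within one ``dt`` per state transition (and
    exactly when every duration and gate sample time is a multiple of
    ``dt``).
    """
    _check_plan(plan, timing)
    consts = [
        c
        for c in (
            timing.injection_s + timing.acceleration_s,
            timing.deceleration_s,
            timing.energy_switch_overhead_s,
            timing.flat_top_max_s,
            timing.wait_limit_s,
            timing.spot_transition_s,
        )
        if c > 0
    ]
    if consts and dt > min(consts) / 2 + 1e-12:
        raise ValueError(f"dt={dt} too coarse for smallest timing constant {min(consts)}")
    provider = _as_provider(gate)

    def ticks(x: float) -> int:
        return int(math.ceil(x / dt - 1e-9))

    tasks: list[tuple[int, list[float]]] = []
    for f in plan.fields:
        for layer in f.layers:
            tasks.append((f.index, [s.weight for s in layer.spots]))

    first_cycle_k: dict[int, int] = {}
    last_off_k: dict[int, int] = {}
    k = 0
    ti = 0
    state = "new_layer"
    countdown = 0
    qi = 0
    charge_left = 0.0
    delivered = False
    ft_end_k = 0
    wait_start_k: int | None = None
    wait_used_k = 0
    iters = 0
    while ti < len(tasks):
        iters += 1
        if iters > max_iterations:
            raise SimulationStalledError("timestep oracle exceeded iteration cap")
        field_idx, weights = tasks[ti]
        t_now = k * dt
        if state == "new_layer":
            qi = 0
            if ti > 0:
                state, countdown = "switch", ticks(timing.energy_switch_overhead_s)
            else:
                state = "bottom"
        elif state == "switch":
            if countdown > 0:
                countdown -= 1
                k += 1
            else:
                state = "bottom"
        elif state == "bottom":
            first_cycle_k.setdefault(field_idx, k)
            state = "ramp"
            countdown = ticks(timing.injection_s + timing.acceleration_s)
        elif state == "ramp":
            if countdown > 0:
                countdown -= 1
                k += 1
            else:
                ft_end_k = k + ticks(timing.flat_top_max_s)
                charge_left = timing.spill_charge
                delivered = False
                wait_start_k = None
                wait_used_k = 0
                state = "flat"
        elif state == "flat":
            if qi >= len(weights):
                state, countdown = "decel", ticks(timing.deceleration_s)
                continue
            w = weights[qi]
            trans_k = ticks(timing.spot_transition_s) if delivered else 0
            beam_k = ticks(w / timing.spot_rate)
            if w > charge_left + _EPS or k + trans_k + beam_k > ft_end_k:
                state, countdown = "decel", ticks(timing.deceleration_s)
                continue
            if wait_start_k is not None:
                limit_left = (
                    timing.wait_limit_s - wait_used_k * dt
                    if wait_accumulates
                    else timing.wait_limit_s
                )
                deadline_k = min(wait_start_k + ticks(limit_left), ft_end_k)
                if k >= deadline_k:
                    state, countdown = "decel", ticks(timing.deceleration_s)
                    continue
            if provider.is_on(t_now):
                off_t = provider.next_off_after(t_now)
                if wait_start_k is not None:
                    wait_used_k += k - wait_start_k
                    wait_start_k = None
                if (k + trans_k + beam_k) * dt <= off_t + _EPS:
                    state, countdown = "transit", trans_k
                else:
                    k += 1  # hold at flat top until the gate drops
            else:
                if not multiple_gating:
                    state, countdown = "decel", ticks(timing.deceleration_s)
                    continue
                if wait_start_k is None:
                    wait_start_k = k
                k += 1
        elif state == "transit":
            if countdown > 0:
                countdown -= 1
                k += 1
            else:
                state, countdown = "beam", ticks(weights[qi] / timing.spot_rate)
        elif state == "beam":
            if countdown > 0:
                countdown -= 1
                k += 1
            else:
                charge_left -= weights[qi]
                delivered = True
                last_off_k[field_idx] = k
                qi += 1
                state = "flat"
        elif state == "decel":
            if countdown > 0:
                countdown -= 1
                k += 1
            else:
                if qi >= len(weights):
                    ti += 1
                    state = "new_layer"
                else:
                    state = "bottom"
        else:  # pragma: no cover
            raise AssertionError(state)
    return sum(last_off_k[f] - first_cycle_k[f] for f in first_cycle_k) * dt
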