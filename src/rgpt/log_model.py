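"""Open machine-log schema for gated spot-scanning delivery sessions.

The real treatment machine records its control signals in a proprietary
format; this package defines an equivalent open schema carrying the same
signal set: session/field/layer boundaries, spill start/end, spot beam
on/off, gate on/off transitions, the redo-bone-matching signal flagging a
baseline shift/drift intervention, and couch moves with their 3-axis size.

Two dialects are supported and are losslessly interconvertible:

* JSONL (canonical): a schema-versioned header record, then one JSON
  object per event: ``{"t": <s>, "kind": "...", ...payload}``.
* CSV (secondary): ``#``-prefixed header lines, then a fixed-column table.

Timestamps are seconds from session start, serialized at full float
precision so a write/read round trip is bit-identical.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

from . import synchrotron_sim as sync
from .motion_gating import CouchAdjustmentEvent, GateSignal
from .plan_model import TreatmentPlan

LOG_SCHEMA = "rgpt-log/1"

SESSION_START = "session_start"
FIELD_START = "field_start"
LAYER_START = "layer_start"
SPILL_START = "spill_start"
SPOT_BEAM_ON = "spot_beam_on"
SPOT_BEAM_OFF = "spot_beam_off"
GATE_ON = "gate_on"
GATE_OFF = "gate_off"
WAIT_START = "wait_start"
WAIT_END = "wait_end"
REDO_BONE_MATCHING = "redo_bone_matching"
COUCH_MOVE = "couch_move"
SPILL_END = "spill_end"
FIELD_END = "field_end"
SESSION_END = "session_end"

#: required payload keys per event kind
EVENT_PAYLOADS: dict[str, tuple[str, ...]] = {
    SESSION_START: (),
    FIELD_START: ("k",),
    LAYER_START: ("k", "layer"),
    SPILL_START: ("k", "layer"),
    SPOT_BEAM_ON: ("k", "layer", "spot_id"),
    SPOT_BEAM_OFF: ("k", "layer", "spot_id"),
    GATE_ON: (),
    GATE_OFF: (),
    WAIT_START: (),
    WAIT_END: (),
    REDO_BONE_MATCHING: (),
    COUCH_MOVE: ("dx_mm", "dy_mm", "dz_mm"),
    SPILL_END: ("k", "layer"),
    FIELD_END: ("k",),
    SESSION_END: (),
}

#: deterministic ordering of same-timestamp events; gate_on precedes spot
#: events (the gate enables the beam) while gate_off follows spot_beam_off
#: (a spot completing exactly at gate-off counts as delivered)
_SORT_PRIORITY = {
    SESSION_START: 0,
    FIELD_START: 1,
    LAYER_START: 2,
    SPILL_START: 3,
    GATE_ON: 4,
    WAIT_START: 5,
    WAIT_END: 5,
    SPOT_BEAM_ON: 6,
    SPOT_BEAM_OFF: 6,
    GATE_OFF: 7,
    REDO_BONE_MATCHING: 8,
    COUCH_MOVE: 8,
    SPILL_END: 9,
    FIELD_END: 10,
    SESSION_END: 11,
}


class LogValidationError(ValueError):
    """The log violates a schema invariant."""


class LogParseError(ValueError):
    """A log file could not be parsed; carries per-line messages."""

    def __init__(self, problems: list[str]):
        super().__init__("; ".join(problems))
        self.problems = problems


@dataclass(frozen=True)
class LogEvent:
    timestamp_s: float
    kind: str
    payload: dict = dataclass_field(default_factory=dict)


@dataclass
class SessionLog:
    """One treatment session: plan reference plus the ordered event stream."""

    session_id: str
    site_category: str
    x_fields: int  #: X — number of fields per session
    ctv_ml: float  #: V
    gating_flag: int  #: R
    sampling_hz: float  #: fluoroscopy pulse rate used for gate reconstruction
    events: list[LogEvent] = dataclass_field(default_factory=list)


def validate_log(log: SessionLog) -> list[str]:
    """Return every schema violation (empty list means the log is valid)."""
    problems: list[str] = []
    if not log.events:
        return ["log has no events"]
    if log.events[0].kind != SESSION_START:
        problems.append(f"first event must be {SESSION_START}, got {log.events[0].kind}")
    if log.events[-1].kind != SESSION_END:
        problems.append(
            f"log is not terminated: last event must be {SESSION_END}, "
            f"got {log.events[-1].kind}"
        )
    prev = float("-inf")
    open_spots: set = set()
    for i, ev in enumerate(log.events):
        if ev.kind not in EVENT_PAYLOADS:
            problems.append(f"event {i}: unknown kind {ev.kind!r}")
            continue
        missing = [key for key in EVENT_PAYLOADS[ev.kind] if key not in ev.payload]
        if missing:
            problems.append(f"event {i} ({ev.kind}): missing payload keys {missing}")
        if ev.timestamp_s < prev:
            problems.append(
                f"event {i} ({ev.kind}): timestamp {ev.timestamp_s} decreases "
                f"(previous {prev})"
            )
        prev = max(prev, ev.timestamp_s)
        if ev.kind == SPOT_BEAM_ON:
            sid = ev.payload.get("spot_id")
            if sid in open_spots:
                problems.append(f"event {i}: spot {sid} switched on while already on")
            open_spots.add(sid)
        elif ev.kind == SPOT_BEAM_OFF:
            sid = ev.payload.get("spot_id")
            if sid not in open_spots:
                problems.append(f"event {i}: spot {sid} switched off while not on")
            open_spots.discard(sid)
    if open_spots:
        problems.append(f"spots never switched off: {sorted(open_spots, key=str)}")
    return problems


# ---------------------------------------------------------------------------
# JSONL dialect (canonical)
# ---------------------------------------------------------------------------

def _header_dict(log: SessionLog) -> dict:
    return {
        "schema": LOG_SCHEMA,
        "session_id": log.session_id,
        "site_category": log.site_category,
        "x_fields": log.x_fields,
        "ctv_ml": log.ctv_ml,
        "gating_flag": log.gating_flag,
        "sampling_hz": log.sampling_hz,
    }


def write_log(log: SessionLog, path: str | Path) -> None:
    """Write the canonical JSONL dialect; refuses an invariant-violating log."""
    problems = validate_log(log)
    if problems:
        raise LogValidationError("; ".join(problems))
    with open(path, "w") as fh:
        fh.write(json.dumps(_header_dict(log)) + "\n")
        for ev in log.events:
            fh.write(json.dumps({"t": ev.timestamp_s, "kind": ev.kind, **ev.payload}) + "\n")


def _log_from_header_and_events(
    header: dict, events: list[LogEvent], problems: list[str]
) -> SessionLog:
    if header.get("schema") != LOG_SCHEMA:
        raise LogParseError([f"unknown schema version {header.get('schema')!r}"])
    log = SessionLog(
        session_id=header["session_id"],
        site_category=header["site_category"],
        x_fields=header["x_fields"],
        ctv_ml=header["ctv_ml"],
        gating_flag=header["gating_flag"],
        sampling_hz=header["sampling_hz"],
        events=events,
    )
    problems.extend(validate_log(log))
    if problems:
        raise LogParseError(problems)
    return log


def read_log(path: str | Path) -> SessionLog:
    """Read either dialect (sniffed from the first byte) into a validated log."""
    first = open(path).read(1)
    if first == "#":
        return _read_log_csv(path)
    return _read_log_jsonl(path)


def _read_log_jsonl(path: str | Path) -> SessionLog:
    problems: list[str] = []
    events: list[LogEvent] = []
    header: dict | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                problems.append(f"line {lineno}: malformed JSON ({exc.msg})")
                continue
            if lineno == 1:
                header = d
                continue
            if "t" not in d or "kind" not in d:
                problems.append(f"line {lineno}: event missing 't' or 'kind'")
                continue
            events.append(
                LogEvent(
                    timestamp_s=float(d.pop("t")),
                    kind=d.pop("kind"),
                    payload=d,
                )
            )
    if header is None:
        raise LogParseError(["empty file: no header record"])
    return _log_from_header_and_events(header, events, problems)


# ---------------------------------------------------------------------------
# CSV dialect (secondary)
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ("t", "kind", "k", "layer", "spot_id", "dx_mm", "dy_mm", "dz_mm")
_FLOAT_KEYS = ("dx_mm", "dy_mm", "dz_mm")
_INT_KEYS = ("k", "layer", "spot_id")


def write_log_csv(log: SessionLog, path: str | Path) -> None:
    problems = validate_log(log)
    if problems:
        raise LogValidationError("; ".join(problems))
    h = _header_dict(log)
    with open(path, "w", newline="") as fh:
        for key in ("schema", "session_id", "site_category"):
            fh.write(f"# {key}={h[key]}\n")
        fh.write(f"# x_fields={h['x_fields']}\n")
        fh.write(f"# ctv_ml={h['ctv_ml']!r}\n")
        fh.write(f"# gating_flag={h['gating_flag']}\n")
        fh.write(f"# sampling_hz={h['sampling_hz']!r}\n")
        w = csv.writer(fh)
        w.writerow(_CSV_COLUMNS)
        for ev in log.events:
            row = [repr(ev.timestamp_s), ev.kind]
            for key in _CSV_COLUMNS[2:]:
                val = ev.payload.get(key, "")
                row.append(repr(val) if isinstance(val, float) else val)
            w.writerow(row)


def _read_log_csv(path: str | Path) -> SessionLog:
    problems: list[str] = []
    events: list[LogEvent] = []
    meta: dict[str, str] = {}
    with open(path, newline="") as fh:
        header_done = False
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                continue
            if not line.strip():
                continue
            (row,) = csv.reader([line])
            if not header_done:
                if tuple(row) != _CSV_COLUMNS:
                    raise LogParseError([f"line {lineno}: unexpected CSV columns {row}"])
                header_done = True
                continue
            if len(row) != len(_CSV_COLUMNS):
                problems.append(f"line {lineno}: expected {len(_CSV_COLUMNS)} columns")
                continue
            d = dict(zip(_CSV_COLUMNS, row))
            try:
                payload: dict = {}
                for key in _INT_KEYS:
                    if d[key] != "":
                        payload[key] = int(d[key])
                for key in _FLOAT_KEYS:
                    if d[key] != "":
                        payload[key] = float(d[key])
                events.append(LogEvent(float(d["t"]), d["kind"], payload))
            except ValueError as exc:
                problems.append(f"line {lineno}: {exc}")
    if "schema" not in meta:
        raise LogParseError(["missing '# schema=' header line"])
    header = {
        "schema": meta.get("schema"),
        "session_id": meta.get("session_id", ""),
        "site_category": meta.get("site_category", ""),
        "x_fields": int(meta.get("x_fields", "0")),
        "ctv_ml": float(meta.get("ctv_ml", "nan")),
        "gating_flag": int(meta.get("gating_flag", "0")),
        "sampling_hz": float(meta.get("sampling_hz", "nan")),
    }
    return _log_from_header_and_events(header, events, problems)


# ---------------------------------------------------------------------------
# timeline → log conversion
# ---------------------------------------------------------------------------

_TIMELINE_KIND_MAP = {
    sync.FLAT_TOP_START: SPILL_START,
    sync.DECEL_START: SPILL_END,
    sync.WAIT_START: WAIT_START,
    sync.WAIT_END: WAIT_END,
    sync.SPOT_ON: SPOT_BEAM_ON,
    sync.SPOT_OFF: SPOT_BEAM_OFF,
}


def timeline_to_log(
    timeline: sync.DeliveryTimeline,
    plan: TreatmentPlan,
    *,
    session_id: str,
    sampling_hz: float,
    gate: GateSignal | None = None,
    redo_events: tuple[float, ...] | list[float] = (),
    couch_events: tuple[CouchAdjustmentEvent, ...] | list[CouchAdjustmentEvent] = (),
) -> SessionLog:
    """Convert a simulator timeline (plus gate/operator signals) to a SessionLog.

    The conversion is total on valid timelines: cycle boundaries map to
    spill start/end, spot and wait events map one-to-one, gate transitions
    are merged from the sampled signal (including the initial state at t=0),
    and operator events after the session end are dropped.
    """
    end_t = timeline.total_time_s
    raw: list[LogEvent] = [LogEvent(0.0, SESSION_START)]

    # field / layer boundary markers derived from the event stream
    seen_fields: dict[int, float] = {}
    field_last: dict[int, float] = {}
    seen_layers: set = set()
    for ev in timeline.events:
        k = ev.data.get("field")
        if ev.kind == sync.CYCLE_START:
            if k not in seen_fields:
                seen_fields[k] = ev.time_s
                raw.append(LogEvent(ev.time_s, FIELD_START, {"k": k}))
            key = (k, ev.data["layer"])
            if key not in seen_layers:
                seen_layers.add(key)
                raw.append(LogEvent(ev.time_s, LAYER_START, {"k": k, "layer": ev.data["layer"]}))
        elif ev.kind == sync.CYCLE_END:
            field_last[k] = ev.time_s
        mapped = _TIMELINE_KIND_MAP.get(ev.kind)
        if mapped is None:
            continue
        if mapped in (SPOT_BEAM_ON, SPOT_BEAM_OFF):
            payload = {
                "k": k,
                "layer": ev.data["layer"],
                "spot_id": ev.data["spot_id"],
                "spot_index": ev.data["spot_index"],
                "weight": ev.data["weight"],
            }
        elif mapped in (SPILL_START, SPILL_END):
            payload = {"k": k, "layer": ev.data["layer"]}
        else:
            payload = {}
        raw.append(LogEvent(ev.time_s, mapped, payload))
    for k, t_end in field_last.items():
        raw.append(LogEvent(t_end, FIELD_END, {"k": k}))

    if gate is not None:
        on = gate.on
        raw.append(LogEvent(float(gate.times[0]), GATE_ON if on[0] else GATE_OFF))
        for i in range(1, on.size):
            if on[i] != on[i - 1]:
                t = float(gate.times[i])
                if t > end_t:
                    break
                raw.append(LogEvent(t, GATE_ON if on[i] else GATE_OFF))

    for t in redo_events:
        if t <= end_t:
            raw.append(LogEvent(float(t), REDO_BONE_MATCHING))
    for ev in couch_events:
        if ev.time_s <= end_t:
            raw.append(
                LogEvent(
                    float(ev.time_s),
                    COUCH_MOVE,
                    {
                        "dx_mm": float(ev.shift_mm[0]),
                        "dy_mm": float(ev.shift_mm[1]),
                        "dz_mm": float(ev.shift_mm[2]),
                    },
                )
            )
    raw.append(LogEvent(end_t, SESSION_END))
    # sort priorities keep session_start/end bracketing at equal timestamps
    raw.sort(key=lambda ev: (ev.timestamp_s, _SORT_PRIORITY[ev.kind]))
    return SessionLog(
        session_id=session_id,
        site_category=plan.site_category,
        x_fields=plan.n_fields,
        ctv_ml=plan.ctv_ml,
        gating_flag=plan.gating_flag,
        sampling_hz=sampling_hz,
        events=raw,
    )
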