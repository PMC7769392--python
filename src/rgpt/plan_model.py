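"""Treatment-plan hierarchy for spot-scanning proton delivery.

A plan is a list of fields (one gantry angle each), each field an ordered
list of energy layers (one Bragg-peak depth each), each layer an ordered
list of scanned spots.  Spot weights are abstract charge units: combined
with the machine's extraction charge rate they fix the beam-on time per
spot, which is all the delivery simulator needs — absolute monitor-unit
calibration is irrelevant here, as is dose.

The session-level shorthand used throughout the package is ``TBS(X, V, R)``:
beam-delivery time per session with ``X`` fields, clinical target volume
``V`` (ml) and gating flag ``R``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Iterator

SITE_CATEGORIES = ("prostate", "liver", "pancreas", "lung", "adrenal_gland")

#: Machine limit on proton range (water-equivalent, g/cm^2).
MAX_RANGE_G_CM2 = 30.0

PLAN_SCHEMA = "rgpt-plan/1"


class InvalidPlanError(ValueError):
    """Raised when an operation requires a valid plan but validation fails."""


@dataclass(frozen=True)
class Spot:
    """One scanned pencil-beam spot within an energy layer."""

    lateral_x_mm: float
    lateral_y_mm: float
    weight: float  #: delivered charge, arbitrary positive units
    index: int  #: 1-based ordinal within its layer


@dataclass(frozen=True)
class EnergyLayer:
    """All spots sharing one Bragg-peak depth (proton range)."""

    range_g_cm2: float
    spots: tuple[Spot, ...]


@dataclass(frozen=True)
class Field:
    """One beam direction: an ordered stack of energy layers."""

    index: int  #: 1-based ordinal K within the plan
    gantry_angle_deg: float
    layers: tuple[EnergyLayer, ...]


@dataclass(frozen=True)
class TreatmentPlan:
    site_category: str
    fields: tuple[Field, ...]
    ctv_ml: float
    gating_flag: int  #: R — 1 if the gating function is used
    fractions: int = 1
    plan_id: str = ""

    @property
    def n_fields(self) -> int:
        return len(self.fields)


@dataclass
class ValidationReport:
    violations: list[str] = dataclass_field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy == usable
        return self.ok


@dataclass(frozen=True)
class PlanSummary:
    n_fields: int
    n_layers: int
    n_spots: int
    ctv_ml: float


def iter_spots(plan: TreatmentPlan) -> Iterator[tuple[Field, int, EnergyLayer, Spot]]:
    """Yield (field, layer_number, layer, spot) in delivery order; layers 1-based."""
    for f in plan.fields:
        for li, layer in enumerate(f.layers, start=1):
            for spot in layer.spots:
                yield f, li, layer, spot


def validate_plan(plan: TreatmentPlan) -> ValidationReport:
    """Check every structural invariant; an empty report means the plan is usable."""
    rep = ValidationReport()
    v = rep.violations
    if plan.site_category not in SITE_CATEGORIES:
        v.append(f"unknown site_category {plan.site_category!r}")
    if len(plan.fields) < 1:
        v.append("X >= 1 violated: plan has no fields")
    if not plan.ctv_ml > 0:
        v.append(f"V > 0 violated: ctv_ml = {plan.ctv_ml}")
    if plan.gating_flag not in (0, 1):
        v.append(f"gating flag R must be 0 or 1, got {plan.gating_flag}")
    if plan.fractions < 1:
        v.append(f"fractions must be >= 1, got {plan.fractions}")
    for pos, f in enumerate(plan.fields, start=1):
        if f.index != pos:
            v.append(f"field index K not contiguous from 1: position {pos} has K={f.index}")
        if not 0.0 <= f.gantry_angle_deg < 360.0:
            v.append(f"field {f.index}: gantry angle {f.gantry_angle_deg} outside [0, 360)")
        if len(f.layers) < 1:
            v.append(f"field {f.index}: at least 1 energy layer required")
        for li, layer in enumerate(f.layers, start=1):
            if not 0.0 < layer.range_g_cm2 <= MAX_RANGE_G_CM2:
                v.append(
                    f"field {f.index} layer {li}: range {layer.range_g_cm2} g/cm^2 "
                    f"exceeds {MAX_RANGE_G_CM2} g/cm^2 machine limit"
                    if layer.range_g_cm2 > MAX_RANGE_G_CM2
                    else f"field {f.index} layer {li}: range must be positive"
                )
            if len(layer.spots) < 1:
                v.append(f"field {f.index} layer {li}: at least 1 spot required")
            for si, spot in enumerate(layer.spots, start=1):
                if spot.index != si:
                    v.append(
                        f"field {f.index} layer {li}: spot index not contiguous "
                        f"from 1 (position {si} has index {spot.index})"
                    )
                if not spot.weight > 0:
                    v.append(
                        f"field {f.index} layer {li} spot {spot.index}: "
                        f"weight must be > 0, got {spot.weight}"
                    )
    return rep


def plan_summary(plan: TreatmentPlan) -> PlanSummary:
    """Count fields, energy layers and spots (N) of a valid plan."""
    rep = validate_plan(plan)
    if not rep.ok:
        raise InvalidPlanError("; ".join(rep.violations))
    n_layers = sum(len(f.layers) for f in plan.fields)
    n_spots = sum(len(layer.spots) for f in plan.fields for layer in f.layers)
    return PlanSummary(
        n_fields=len(plan.fields), n_layers=n_layers, n_spots=n_spots, ctv_ml=plan.ctv_ml
    )


def total_charge(plan: TreatmentPlan) -> float:
    """Sum of all spot weights (charge units)."""
    return sum(s.weight for _, _, _, s in iter_spots(plan))


# ---------------------------------------------------------------------------
# serialization — documented JSON schema (canonical) and flat CSV (secondary)
# ---------------------------------------------------------------------------

def plan_to_dict(plan: TreatmentPlan) -> dict:
    return {
        "schema": PLAN_SCHEMA,
        "plan_id": plan.plan_id,
        "site_category": plan.site_category,
        "ctv_ml": plan.ctv_ml,
        "gating_flag": plan.gating_flag,
        "fractions": plan.fractions,
        "fields": [
            {
                "index": f.index,
                "gantry_angle_deg": f.gantry_angle_deg,
                "layers": [
                    {
                        "range_g_cm2": layer.range_g_cm2,
                        "spots": [
                            {
                                "x_mm": s.lateral_x_mm,
                                "y_mm": s.lateral_y_mm,
                                "weight": s.weight,
                            }
                            for s in layer.spots
                        ],
                    }
                    for layer in f.layers
                ],
            }
            for f in plan.fields
        ],
    }


def plan_from_dict(d: dict) -> TreatmentPlan:
    if d.get("schema") != PLAN_SCHEMA:
        raise ValueError(f"unknown plan schema {d.get('schema')!r}, expected {PLAN_SCHEMA!r}")
    fields = tuple(
        Field(
            index=fd["index"],
            gantry_angle_deg=fd["gantry_angle_deg"],
            layers=tuple(
                EnergyLayer(
                    range_g_cm2=ld["range_g_cm2"],
                    spots=tuple(
                        Spot(
                            lateral_x_mm=sd["x_mm"],
                            lateral_y_mm=sd["y_mm"],
                            weight=sd["weight"],
                            index=si,
                        )
                        for si, sd in enumerate(ld["spots"], start=1)
                    ),
                )
                for ld in fd["layers"]
            ),
        )
        for fd in d["fields"]
    )
    return TreatmentPlan(
        site_category=d["site_category"],
        fields=fields,
        ctv_ml=d["ctv_ml"],
        gating_flag=d["gating_flag"],
        fractions=d.get("fractions", 1),
        plan_id=d.get("plan_id", ""),
    )


def save_plan(plan: TreatmentPlan, path: str | Path) -> None:
    Path(path).write_text(json.dumps(plan_to_dict(plan), indent=1) + "\n")


def load_plan(path: str | Path) -> TreatmentPlan:
    return plan_from_dict(json.loads(Path(path).read_text()))


_CSV_COLUMNS = ("field", "gantry_angle_deg", "layer", "range_g_cm2", "x_mm", "y_mm", "weight")


def plan_to_csv(plan: TreatmentPlan, path: str | Path) -> None:
    """Flat one-row-per-spot export; plan attributes ride in ``#`` header lines."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema={PLAN_SCHEMA}\n")
        fh.write(f"# plan_id={plan.plan_id}\n")
        fh.write(f"# site_category={plan.site_category}\n")
        fh.write(f"# ctv_ml={plan.ctv_ml!r}\n")
        fh.write(f"# gating_flag={plan.gating_flag}\n")
        fh.write(f"# fractions={plan.fractions}\n")
        w = csv.writer(fh)
        w.writerow(_CSV_COLUMNS)
        for f, li, layer, s in iter_spots(plan):
            w.writerow(
                [
                    f.index,
                    repr(f.gantry_angle_deg),
                    li,
                    repr(layer.range_g_cm2),
                    repr(s.lateral_x_mm),
                    repr(s.lateral_y_mm),
                    repr(s.weight),
                ]
            )


def plan_from_csv(path: str | Path) -> TreatmentPlan:
    meta: dict[str, str] = {}
    rows: list[dict[str, str]] = []
    with open(path, newline="") as fh:
        header_done = False
        reader = None
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                continue
            if not header_done:
                names = next(csv.reader([line]))
                if tuple(names) != _CSV_COLUMNS:
                    raise ValueError(f"unexpected CSV columns {names}")
                header_done = True
                continue
            (row,) = csv.reader([line])
            rows.append(dict(zip(_CSV_COLUMNS, row)))
    if meta.get("schema") != PLAN_SCHEMA:
        raise ValueError(f"unknown plan schema {meta.get('schema')!r}")

    fields: list[dict] = []
    for r in rows:
        k = int(r["field"])
        if not fields or fields[-1]["index"] != k:
            fields.append(
                {"index": k, "gantry_angle_deg": float(r["gantry_angle_deg"]), "layers": []}
            )
        layers = fields[-1]["layers"]
        li = int(r["layer"])
        if not layers or len(layers) != li:
            layers.append({"range_g_cm2": float(r["range_g_cm2"]), "spots": []})
        layers[-1]["spots"].append(
            {"x_mm": float(r["x_mm"]), "y_mm": float(r["y_mm"]), "weight": float(r["weight"])}
        )
    return plan_from_dict(
        {
            "schema": PLAN_SCHEMA,
            "plan_id": meta.get("plan_id", ""),
            "site_category": meta["site_category"],
            "ctv_ml": float(meta["ctv_ml"]),
            "gating_flag": int(meta["gating_flag"]),
            "fractions": int(meta.get("fractions", "1")),
            "fields": fields,
        }
    )
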