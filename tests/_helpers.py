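"""Shared builders for tests: tiny plans, gates and hand-made logs."""

from __future__ import annotations

import numpy as np

from rgpt.log_model import LogEvent, SessionLog
from rgpt.motion_gating import GateSignal
from rgpt.plan_model import EnergyLayer, Field, Spot, TreatmentPlan


def build_plan(
    n_spots: int = 5,
    n_layers: int = 1,
    n_fields: int = 1,
    weight: float = 0.5,
    site: str = "liver",
    ctv: float = 50.0,
    range_g_cm2: float = 10.0,
) -> TreatmentPlan:
    fields = []
    for k in range(1, n_fields + 1):
        layers = tuple(
            EnergyLayer(
                range_g_cm2,
                tuple(Spot(float(i), 0.0, weight, i + 1) for i in range(n_spots)),
            )
            for _ in range(n_layers)
        )
        fields.append(Field(k, 90.0, layers))
    return TreatmentPlan(site, tuple(fields), ctv, 1)


def random_plan(
    rng: np.random.Generator,
    max_fields=3,
    max_layers=4,
    max_spots=30,
    grid_aligned=False,
) -> TreatmentPlan:
    """Small random plan with varied weights, for property-style checks.

    With ``grid_aligned=True`` spot weights are multiples of 0.1 charge
    units, so beam-on durations are whole milliseconds at the default
    100 units/s extraction rate.
    """
    fields = []
    n_fields = int(rng.integers(1, max_fields + 1))
    for k in range(1, n_fields + 1):
        layers = []
        for _ in range(int(rng.integers(1, max_layers + 1))):
            n = int(rng.integers(1, max_spots + 1))
            if grid_aligned:
                ws = rng.integers(2, 16, n) * 0.1
            else:
                ws = rng.uniform(0.2, 1.5, n)
            layers.append(
                EnergyLayer(
                    float(rng.uniform(5, 28)),
                    tuple(Spot(float(i), float(i % 3), float(ws[i]), i + 1) for i in range(n)),
                )
            )
        fields.append(Field(k, float(rng.uniform(0, 359)), tuple(layers)))
    return TreatmentPlan("liver", tuple(fields), float(rng.uniform(10, 500)), 1)


def periodic_gate(
    duration_s: float, period_s: float, on_fraction: float, hz: float = 25.0
) -> GateSignal:
    """Gate that is on for the first on_fraction of every period."""
    times = np.arange(int(round(duration_s * hz))) / hz
    on = (times % period_s) < on_fraction * period_s - 1e-12
    return GateSignal(times, on, hz)


def gate_from_bools(on: np.ndarray, hz: float) -> GateSignal:
    times = np.arange(len(on)) / hz
    return GateSignal(times, np.asarray(on, dtype=bool), hz)


def make_log(events: list[LogEvent], *, hz: float = 1.0, site: str = "liver") -> SessionLog:
    return SessionLog(
        session_id="fixture",
        site_category=site,
        x_fields=1,
        ctv_ml=50.0,
        gating_flag=1,
        sampling_hz=hz,
        events=events,
    )
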