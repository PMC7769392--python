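"""Session-metric definitions and cohort aggregation."""

import numpy as np
import pandas as pd
import pytest

from _helpers import build_plan, make_log
from rgpt.analytics import (
    SessionMetrics,
    adjustment_frequency,
    adjustment_size,
    aggregate,
    beam_delivery_time,
    compute_session_metrics,
    format_cohort_table,
    gating_efficiency,
    use_factor,
)
from rgpt.log_model import LogEvent, timeline_to_log
from rgpt.motion_gating import MotionParams, compute_gate_signal, generate_marker_trace
from rgpt.plan_model import EnergyLayer, Field, Spot, TreatmentPlan
from rgpt.synchrotron_sim import simulate_continuous, simulate_gated


def field_log(spans, redo=(), couch=(), gate_transitions=(), hz=1.0):
    """Hand-built log: per-field spot spans plus optional operator/gate events."""
    ev = [LogEvent(0.0, "session_start")]
    sid = 0
    for k, (a, b) in enumerate(spans, start=1):
        ev.append(LogEvent(a, "field_start", {"k": k}))
        sid += 1
        ev.append(LogEvent(a, "spot_beam_on", {"k": k, "layer": 1, "spot_id": sid}))
        ev.append(LogEvent(b, "spot_beam_off", {"k": k, "layer": 1, "spot_id": sid}))
        ev.append(LogEvent(b, "field_end", {"k": k}))
    for t in redo:
        ev.append(LogEvent(t, "redo_bone_matching"))
    for t, shift in couch:
        ev.append(
            LogEvent(t, "couch_move", {"dx_mm": shift[0], "dy_mm": shift[1], "dz_mm": shift[2]})
        )
    for t, kind in gate_transitions:
        ev.append(LogEvent(t, kind))
    end = max(e.timestamp_s for e in ev)
    ev.append(LogEvent(end, "session_end"))
    ev.sort(key=lambda e: e.timestamp_s)
    return make_log(ev, hz=hz)


class TestBeamDeliveryTime:
    def test_single_field_span(self):
        assert beam_delivery_time(field_log([(0.0, 300.0)])) == 300.0

    def test_gap_between_fields_excluded(self):
        log = field_log([(0.0, 150.0), (270.0, 420.0)])
        assert beam_delivery_time(log) == 300.0

    def test_no_spot_events_rejected(self):
        log = make_log([LogEvent(0.0, "session_start"), LogEvent(1.0, "session_end")])
        with pytest.raises(ValueError):
            beam_delivery_time(log)

    def test_matches_simulator_window_exactly(self, timing):
        plan = build_plan(n_spots=30, n_layers=2, n_fields=2)
        p = MotionParams(amplitude_mm=(0, 0, 5.0), sampling_hz=25.0)
        gate = compute_gate_signal(generate_marker_trace(p, 2000.0, 3))
        tl, _ = simulate_gated(plan, timing, gate, True)
        log = timeline_to_log(tl, plan, session_id="x", sampling_hz=25.0, gate=gate)
        assert beam_delivery_time(log) == tl.beam_on_window_s


class TestGatingEfficiency:
    def test_gate_on_throughout_is_one(self):
        log = field_log([(0.0, 100.0)], gate_transitions=[(0.0, "gate_on")])
        assert gating_efficiency(log) == 1.0

    def test_half_on_is_half(self):
        log = field_log(
            [(0.0, 100.0)], gate_transitions=[(0.0, "gate_on"), (50.0, "gate_off")]
        )
        assert gating_efficiency(log) == 0.5

    def test_618_of_1000_samples(self):
        log = field_log(
            [(0.0, 1000.0)], gate_transitions=[(0.0, "gate_on"), (618.0, "gate_off")], hz=1.0
        )
        assert gating_efficiency(log) == 0.618

    def test_counted_only_inside_delivery_windows(self):
        # gate off only during the inter-field gap → efficiency stays 1
        log = field_log(
            [(0.0, 100.0), (200.0, 300.0)],
            gate_transitions=[(0.0, "gate_on"), (100.0, "gate_off"), (200.0, "gate_on")],
        )
        assert gating_efficiency(log) == 1.0

    def test_zero_length_window_rejected(self):
        log = field_log([(0.25, 0.75)], gate_transitions=[(0.0, "gate_on")], hz=1.0)
        with pytest.raises(ValueError):
            gating_efficiency(log)  # no 1 Hz sample falls inside [0.25, 0.75)


class TestAdjustments:
    def test_two_of_ten_sessions(self):
        logs = [field_log([(0.0, 100.0)]) for _ in range(8)]
        logs += [field_log([(0.0, 100.0)], redo=[50.0]) for _ in range(2)]
        assert adjustment_frequency(logs) == pytest.approx(0.20)

    def test_no_redo_events(self):
        assert adjustment_frequency([field_log([(0.0, 100.0)])]) == 0.0

    def test_redo_outside_delivery_window_not_counted(self):
        log = field_log([(10.0, 100.0)], redo=[5.0, 150.0])
        assert adjustment_frequency([log]) == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            adjustment_frequency([])

    def test_couch_move_norm_in_cm(self):
        log = field_log([(0.0, 100.0)], couch=[(50.0, (1.0, 2.0, 2.0))])
        assert adjustment_size(log) == [pytest.approx(0.30)]

    def test_sizes_in_chronological_order_and_windowed(self):
        log = field_log(
            [(0.0, 100.0)],
            couch=[(20.0, (10.0, 0.0, 0.0)), (60.0, (0.0, 0.0, 5.0)), (150.0, (9.0, 9.0, 9.0))],
        )
        assert adjustment_size(log) == [pytest.approx(1.0), pytest.approx(0.5)]

    def test_no_couch_moves_gives_empty_list(self):
        assert adjustment_size(field_log([(0.0, 100.0)])) == []


class TestUseFactor:
    def _plan_with_angles(self, angles):
        fields = tuple(
            Field(k, a, (EnergyLayer(10.0, (Spot(0, 0, 1.0, 1),)),))
            for k, a in enumerate(angles, start=1)
        )
        return TreatmentPlan("liver", fields, 50.0, 1)

    def test_half_at_ninety(self):
        uf = use_factor([self._plan_with_angles([90.0, 90.0, 180.0, 270.0])])
        assert uf[90.0] == 0.5

    def test_single_field(self):
        assert use_factor([self._plan_with_angles([45.0])]) == {45.0: 1.0}

    def test_fractions_sum_to_one(self):
        from rgpt.synthetic_data import CohortSpec, generate_plan

        plans = [generate_plan(CohortSpec(), "liver", seed=s) for s in range(4)]
        assert sum(use_factor(plans).values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            use_factor([])


def _metric(cat, tbs_min, sim_min=1.0, eff=0.5, n_adj=0, sizes=()):
    return SessionMetrics(
        session_id=f"{cat}-{tbs_min}",
        site_category=cat,
        tbs_s=tbs_min * 60.0,
        tbs_sim_s=sim_min * 60.0,
        efficiency=eff,
        n_adjustments=n_adj,
        adjustment_sizes_cm=list(sizes),
    )


class TestAggregate:
    def test_mean_and_sample_sd(self):
        table = aggregate([_metric("liver", 5.0), _metric("liver", 9.0)])
        assert table.loc["liver", "tbs_min_mean"] == pytest.approx(7.0)
        assert table.loc["liver", "tbs_min_sd"] == pytest.approx(2.8284, abs=1e-4)

    def test_single_session_category_sd_not_available(self):
        table = aggregate([_metric("adrenal_gland", 1.7), _metric("liver", 5.0), _metric("liver", 9.0)])
        assert np.isnan(table.loc["adrenal_gland", "tbs_min_sd"])
        shown = format_cohort_table(table)
        assert "N.A." in shown.loc["adrenal_gland", "gated_min"]

    def test_totals_row_is_pooled_not_mean_of_means(self):
        metrics = [_metric("liver", 4.0), _metric("liver", 6.0), _metric("prostate", 11.0)]
        table = aggregate(metrics)
        # pooled mean (4+6+11)/3 = 7.0, not mean-of-means (5+11)/2 = 8.0
        assert table.loc["total", "tbs_min_mean"] == pytest.approx(7.0)
        assert table.loc["total", "tbs_min_sd"] == pytest.approx(
            np.std([4.0, 6.0, 11.0], ddof=1)
        )

    def test_order_invariance(self):
        metrics = [
            _metric("liver", 4.0, eff=0.3, n_adj=1, sizes=[0.2]),
            _metric("prostate", 11.0, eff=0.9),
            _metric("liver", 6.0, eff=0.4),
        ]
        a = aggregate(metrics)
        b = aggregate(metrics[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown category"):
            aggregate([_metric("liver", 4.0)], categories=["prostate"])


def test_session_metrics_difference_nonnegative_for_simulated_sessions(timing):
    plan = build_plan(n_spots=30, n_layers=2)
    p = MotionParams(amplitude_mm=(0, 0, 6.0), sampling_hz=25.0)
    gate = compute_gate_signal(generate_marker_trace(p, 2000.0, 5))
    tl, _ = simulate_gated(plan, timing, gate, True)
    log = timeline_to_log(tl, plan, session_id="d", sampling_hz=25.0, gate=gate)
    cont_tl, _ = simulate_continuous(plan, timing)
    m = compute_session_metrics(log, cont_tl.beam_on_window_s)
    assert m.difference_s >= 0.0
    # always-on gate: difference exactly zero
    tl2, _ = simulate_gated(plan, timing, None, True)
    log2 = timeline_to_log(
        tl2, plan, session_id="d2", sampling_hz=25.0,
        gate=compute_gate_signal(generate_marker_trace(MotionParams(sampling_hz=25.0), 2000.0, 0)),
    )
    m2 = compute_session_metrics(log2, cont_tl.beam_on_window_s)
    assert m2.difference_s == 0.0 and m2.efficiency == 1.0
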