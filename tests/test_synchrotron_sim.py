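"""Spill-cycle simulator: closed forms, gating semantics, oracle agreement."""

import numpy as np
import pytest

from _helpers import build_plan, gate_from_bools, periodic_gate, random_plan
from rgpt.motion_gating import MotionParams, compute_gate_signal, generate_marker_trace
from rgpt.plan_model import total_charge
from rgpt.synchrotron_sim import (
    GateExhaustedError,
    SampledGate,
    SimulationStalledError,
    SynchrotronTiming,
    UndeliverableSpotError,
    simulate_continuous,
    simulate_gated,
    simulate_timestep_oracle,
)


def motion_gate(seed, duration=2000.0, amp=6.0, hz=25.0, noise=0.1):
    p = MotionParams(
        period_s=4.0, amplitude_mm=(0, 0, amp), noise_sd_mm=(noise,) * 3, sampling_hz=hz
    )
    return compute_gate_signal(generate_marker_trace(p, duration, seed))


class TestContinuousClosedForms:
    @pytest.mark.parametrize("k", [1, 2, 10, 100])
    def test_single_layer_k_spots(self, timing, k):
        w = 0.5
        _, tbs = simulate_continuous(build_plan(n_spots=k, weight=w), timing)
        expected = (
            timing.injection_s
            + timing.acceleration_s
            + k * w / timing.spot_rate
            + (k - 1) * timing.spot_transition_s
        )
        assert tbs == pytest.approx(expected, abs=1e-9)

    def test_multi_layer_adds_switch_cost(self, timing):
        w, k, L = 0.5, 5, 4
        single = (
            timing.injection_s
            + timing.acceleration_s
            + k * w / timing.spot_rate
            + (k - 1) * timing.spot_transition_s
        )
        _, tbs = simulate_continuous(build_plan(n_spots=k, n_layers=L, weight=w), timing)
        expected = L * single + (L - 1) * (timing.deceleration_s + timing.energy_switch_overhead_s)
        assert tbs == pytest.approx(expected, abs=1e-9)

    def test_spill_charge_forces_recycle(self):
        timing = SynchrotronTiming(spill_charge=2.0)
        # 5 spots of weight 1 → 3 cycles (2+2+1)
        tl, tbs = simulate_continuous(build_plan(n_spots=5, weight=1.0), timing)
        assert sum(1 for e in tl.events if e.kind == "cycle_start") == 3
        assert tl.validate(build_plan(n_spots=5, weight=1.0)) == []

    def test_flat_top_limit_forces_recycle(self):
        timing = SynchrotronTiming(flat_top_max_s=0.015, wait_limit_s=0.01, spot_transition_s=0.0)
        tl, _ = simulate_continuous(build_plan(n_spots=3, weight=1.0), timing)
        # each 10 ms spot nearly fills the 15 ms flat top → one cycle per spot
        assert sum(1 for e in tl.events if e.kind == "cycle_start") == 3


class TestIdealLimit:
    def test_always_on_gate_reproduces_continuous_exactly(self, timing):
        plan = build_plan(n_spots=7, n_layers=2, n_fields=2)
        tl_c, tbs_c = simulate_continuous(plan, timing)
        tl_g, tbs_g = simulate_gated(plan, timing, None, True)
        assert tbs_g == tbs_c
        assert tl_g.events == tl_c.events

    def test_fully_on_sampled_gate_matches_continuous_time(self, timing):
        plan = build_plan(n_spots=10, n_layers=2)
        gate = gate_from_bools(np.ones(3000, bool), 25.0)
        _, tbs_g = simulate_gated(plan, timing, gate, True)
        _, tbs_c = simulate_continuous(plan, timing)
        assert tbs_g == tbs_c


class TestGatedSemantics:
    def test_single_spot_delayed_gate_hand_trace(self, timing):
        """Gate off until t=8 s: one wait expiry, one recycle, delivery at 8 s."""
        plan = build_plan(n_spots=1, weight=0.5)
        on = np.zeros(200, bool)
        on[80:] = True  # on from t=8.0 at 10 Hz
        gate = gate_from_bools(on, 10.0)
        tl, tbs = simulate_gated(plan, timing, gate, True)
        # cycle 1: flat top at 1.0, wait expires at 6.0 (limit 5 s), decel to 6.5
        # cycle 2: flat top at 7.5, wait 7.5→8.0, spot 8.0→8.005
        kinds_times = [(e.kind, round(e.time_s, 3)) for e in tl.events]
        assert ("wait_start", 1.0) in kinds_times
        assert ("wait_end", 6.0) in kinds_times
        assert ("decel_start", 6.0) in kinds_times
        assert ("spot_on", 8.0) in kinds_times
        assert tbs == pytest.approx(8.0 + 0.5 / timing.spot_rate, abs=1e-9)

    def test_wait_equal_to_limit_decelerates(self, timing):
        """Gate returning exactly at the wait limit does not rescue the spill."""
        plan = build_plan(n_spots=50, weight=3.0)
        hz = 10.0
        on = np.ones(300, bool)
        on[20:70] = False  # off exactly [2.0, 7.0): 5 s = wait_limit_s
        gate = gate_from_bools(on, hz)
        tl, _ = simulate_gated(plan, timing, gate, True)
        times = {e.kind: [] for e in tl.events}
        for e in tl.events:
            times[e.kind].append(e.time_s)
        assert any(abs(t - 7.0) < 1e-9 for t in times["decel_start"])
        # no spot delivered during the off interval
        assert not any(2.0 < t < 7.4 for t in times["spot_on"])

    def test_short_gap_resumed_within_spill(self, timing):
        plan = build_plan(n_spots=50, weight=3.0)
        on = np.ones(300, bool)
        on[20:40] = False  # 2 s gap < 5 s wait limit
        gate = gate_from_bools(on, 10.0)
        tl, _ = simulate_gated(plan, timing, gate, True)
        kinds = [e.kind for e in tl.events]
        i_ws = kinds.index("wait_start")
        assert kinds[i_ws + 1] == "wait_end"  # resumed, not decelerated
        assert tl.validate(plan) == []

    def test_legacy_mode_decelerates_on_gate_off(self, timing):
        plan = build_plan(n_spots=50, weight=3.0)
        on = np.ones(300, bool)
        on[20:40] = False
        gate = gate_from_bools(on, 10.0)
        tl, _ = simulate_gated(plan, timing, gate, False)
        assert not any(e.kind in ("wait_start", "wait_end") for e in tl.events)
        assert any(abs(e.time_s - 2.0) < 1e-9 and e.kind == "decel_start" for e in tl.events)

    def test_gated_never_faster_than_continuous(self, timing):
        rng = np.random.default_rng(11)
        for i in range(5):
            plan = random_plan(rng)
            gate = motion_gate(i)
            _, tbs_g = simulate_gated(plan, timing, gate, True)
            _, tbs_c = simulate_continuous(plan, timing)
            assert tbs_g >= tbs_c - 1e-9

    def test_spot_conservation_under_gating(self, timing):
        rng = np.random.default_rng(4)
        for i in range(5):
            plan = random_plan(rng)
            tl, _ = simulate_gated(plan, timing, motion_gate(100 + i), True)
            assert tl.validate(plan) == []
            assert tl.delivered_charge() == pytest.approx(total_charge(plan))

    def test_multiple_gating_dominates_legacy(self, timing):
        rng = np.random.default_rng(21)
        for i in range(5):
            plan = random_plan(rng)
            gate = motion_gate(200 + i)
            _, t_multi = simulate_gated(plan, timing, gate, True)
            _, t_leg = simulate_gated(plan, timing, gate, False)
            assert t_multi <= t_leg + 1e-9

    def test_monotone_in_duty_cycle(self, timing):
        plan = build_plan(n_spots=25, n_layers=3, n_fields=2)
        prev = np.inf
        for frac in (0.2, 0.4, 0.6, 0.8, 1.0):
            gate = periodic_gate(3000.0, 4.0, frac)
            _, tbs = simulate_gated(plan, timing, gate, True)
            assert tbs <= prev + 1e-9
            prev = tbs


class TestErrors:
    def test_overweight_spot_undeliverable(self):
        timing = SynchrotronTiming(spill_charge=1.0)
        with pytest.raises(UndeliverableSpotError):
            simulate_gated(build_plan(n_spots=1, weight=2.0), timing, None, True)

    def test_gate_never_on_reported(self, timing):
        gate = gate_from_bools(np.zeros(200, bool), 10.0)
        with pytest.raises((GateExhaustedError, SimulationStalledError)):
            simulate_gated(build_plan(n_spots=1), timing, gate, True)

    def test_cycle_cap_reported(self, timing):
        # gate-on bursts always shorter than the spot: no spill can progress
        on = np.zeros(100_000, bool)
        on[::50] = True  # 0.1 s on every 5 s at 10 Hz
        gate = gate_from_bools(on, 10.0)
        with pytest.raises(SimulationStalledError):
            simulate_gated(build_plan(n_spots=1, weight=50.0), timing, gate, True, max_cycles=3)

    def test_wait_limit_above_flat_top_rejected(self):
        with pytest.raises(ValueError):
            SynchrotronTiming(flat_top_max_s=2.0, wait_limit_s=3.0)


class TestTimestepOracle:
    def test_always_on_single_spot_matches_closed_form(self, timing):
        tbs = simulate_timestep_oracle(build_plan(n_spots=1, weight=0.5), timing, None, 1e-3)
        expected = timing.injection_s + timing.acceleration_s + 0.5 / timing.spot_rate
        assert tbs == pytest.approx(expected, abs=1e-3)

    def test_matches_event_simulator_on_aligned_instances(self, timing):
        rng = np.random.default_rng(8)
        for i in range(3):
            plan = random_plan(rng, max_fields=1, max_layers=2, max_spots=15, grid_aligned=True)
            gate = motion_gate(300 + i, duration=600.0)
            tl, tbs = simulate_gated(plan, timing, gate, True)
            oracle = simulate_timestep_oracle(plan, timing, SampledGate(gate), 1e-3)
            assert abs(oracle - tbs) <= len(tl.events) * 1e-3

    def test_matches_continuous_for_all_on_motion(self, timing):
        plan = build_plan(n_spots=12, n_layers=2)
        p = MotionParams(sampling_hz=25.0)  # zero amplitude → gate always on
        gate = compute_gate_signal(generate_marker_trace(p, 300.0, 0))
        _, tbs_c = simulate_continuous(plan, timing)
        oracle = simulate_timestep_oracle(plan, timing, SampledGate(gate), 1e-3)
        assert abs(oracle - tbs_c) <= 1e-2

    def test_too_coarse_dt_rejected(self, timing):
        with pytest.raises(ValueError):
            simulate_timestep_oracle(build_plan(), timing, None, dt=0.5)
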