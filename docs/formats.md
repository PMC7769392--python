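# File formats

## Plan JSON (`rgpt-plan/1`)

Canonical plan serialization (see `rgpt.plan_model`):

```json
{
  "schema": "rgpt-plan/1",
  "plan_id": "liver-p001",
  "site_category": "liver",
  "ctv_ml": 120.5,
  "gating_flag": 1,
  "fractions": 22,
  "fields": [
    {
      "index": 1,
      "gantry_angle_deg": 90.0,
      "layers": [
        {
          "range_g_cm2": 14.2,
          "spots": [
            {"x_mm": -3.1, "y_mm": 0.8, "weight": 0.61}
          ]
        }
      ]
    }
  ]
}
```

- `fields[].index` is the 1-based field number K, contiguous.
- Spot order within a layer is delivery order; spot indices are implicit
  (1-based position) and re-assigned on load.
- `weight` is positive charge in arbitrary units; `range_g_cm2` must be in
  (0, 30].

A flat CSV twin (`plan_to_csv` / `plan_from_csv`) carries one row per spot
with columns `field,gantry_angle_deg,layer,range_g_cm2,x_mm,y_mm,weight`
and the plan-level attributes in `# key=value` header lines.

## Session log (`rgpt-log/1`)

### JSONL dialect (canonical)

Line 1 is the header record:

```json
{"schema": "rgpt-log/1", "session_id": "liver-s0001", "site_category": "liver",
 "x_fields": 2, "ctv_ml": 120.5, "gating_flag": 1, "sampling_hz": 30.0}
```

Each following line is one event: `{"t": <seconds>, "kind": "...", ...}`.
Timestamps are seconds from session start, nondecreasing, serialized at
full float precision.

| kind | payload | meaning |
|---|---|---|
| `session_start` / `session_end` | — | first / last event |
| `field_start` / `field_end` | `k` | field K begins / ends |
| `layer_start` | `k`, `layer` | first cycle of an energy layer |
| `spill_start` / `spill_end` | `k`, `layer` | flat top begins / deceleration starts |
| `spot_beam_on` / `spot_beam_off` | `k`, `layer`, `spot_id` (+`spot_index`, `weight`) | spot irradiation |
| `gate_on` / `gate_off` | — | gate transition (initial state logged at t=0) |
| `wait_start` / `wait_end` | — | waiting function engaged / released |
| `redo_bone_matching` | — | operator flags baseline shift/drift |
| `couch_move` | `dx_mm`, `dy_mm`, `dz_mm` | couch correction vector |

Invariants enforced on read and write: `session_start` first,
`session_end` last, timestamps nondecreasing, `spot_beam_on`/`off`
properly paired per `spot_id`.  Intra-field adjustment attribution (an
analytics concern) counts `redo_bone_matching` only between a field's
first `spot_beam_on` and last `spot_beam_off`.

### CSV dialect (secondary)

`# key=value` header lines (same fields as the JSONL header), then a table
with columns `t,kind,k,layer,spot_id,dx_mm,dy_mm,dz_mm`; empty cells for
keys a kind does not carry.  `read_log` sniffs the dialect from the first
byte and both dialects parse to the same in-memory `SessionLog`.

## Config YAML

`SynchrotronTiming.from_yaml` and `MotionParams.from_yaml` read flat
key→value mappings matching the dataclass fields, e.g.

```yaml
# timing.yaml
injection_s: 0.3
acceleration_s: 0.7
deceleration_s: 0.5
flat_top_max_s: 10.0
spill_charge: 200.0
wait_limit_s: 5.0
energy_switch_overhead_s: 0.5
spot_rate: 100.0
spot_transition_s: 0.002
```

```yaml
# motion.yaml
period_s: 4.0
amplitude_mm: [1.5, 3.0, 7.0]
drift_rate_mm_per_min: [0.05, 0.1, 0.45]
shift_events: [[120.0, [0.0, 0.0, 3.0]]]
noise_sd_mm: [0.15, 0.15, 0.15]
sampling_hz: 30.0
```

## Cohort output (`rgpt cohort`, `write_cohort`)

One directory containing `<plan_id>.plan.json` per unique plan,
`<session_id>.log.jsonl` per session, and `manifest.csv` — the
ground-truth table with one row per session (`session_id`,
`site_category`, `plan_id`, `x_fields`, `ctv_ml`, `seed`,
`true_duty_cycle`, `tbs_s`, `tbs_sim_s`, `n_intra_field_adjustments`,
`adjustment_sizes_cm` as a JSON list).
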