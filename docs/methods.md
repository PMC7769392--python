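# Methods

## The problem being modelled

Spot-scanning proton therapy of moving targets (liver, pancreas, lung,
prostate, adrenal gland) can gate the beam on an implanted fiducial marker:
fluoroscopic tracking reports the marker's 3-axis displacement from its
planned position at the imaging pulse rate, and the beam is enabled only
while every axis is within a tolerance window (±2.0 mm here).  Gating
interacts with the synchrotron's spill structure — beam exists only during
the flat top of the magnetic excitation cycle — so gated sessions take
substantially longer than the same plan delivered continuously.  This
package simulates that interaction and computes the session-level metrics
used to characterize gated delivery from machine logs: beam-delivery time
versus its ideal-environment simulation, achieved gating duty cycle
("beam-delivery efficiency"), and the frequency and size of intra-field
couch corrections for baseline shift or drift.

## Delivery model

**Plan structure.** A plan is fields → energy layers → spots.  Spot weights
are abstract charge units; with the extraction charge rate (`spot_rate`,
charge/s) they fix beam-on time per spot.  Proton range per layer is capped
at 30 g/cm² (machine limit); dose plays no role.

**Excitation cycle.** Each cycle is injection → acceleration → flat top →
deceleration.  Single-energy extraction: one energy layer per cycle;
switching layers always forces deceleration, an energy-switch overhead, and
a fresh injection+acceleration.  Within a flat top, spots are delivered
back-to-back (weight/`spot_rate` plus a lateral `spot_transition_s` between
consecutive spots of the same spill) until either the spill charge or the
maximum flat-top duration runs out, which forces a recycle on the same
layer.

**Gating and the waiting function.** The gate signal is the sampled
per-axis window test, held between samples (zero-order hold).  A spot
starts only if it can finish before the next gate-off (finishing exactly at
gate-off counts as delivered).  When the gate drops at flat top, the
machine waits; if the gate returns strictly before `wait_limit_s` the spill
resumes (multiple gating — several gate-on periods per spill); if the wait
reaches the limit exactly, or the flat-top budget runs out, the cycle
decelerates.  By default the wait clock resets at each gate-on
(`wait_accumulates=False` — the wait is the elapsed off-interval, not a
per-spill budget); the accumulating variant is a flag.  Legacy mode
(`multiple_gating=False`) has no delay gate: any gate-off at flat top
forces deceleration, so each gate-on period is served by at most one spill.
Note the legacy model cycles deterministically; a respiratory period
commensurate with its retry period (deceleration + injection +
acceleration) can phase-lock pathologically, which is one reason real
pre-delay-gate systems synchronized injection to respiration.

**Time endpoints.** TBS, the session beam-delivery time, is accounted per
field and summed; inter-field setup is out of scope.  Two endpoint
conventions coexist: the simulator's closed-form time runs from the field's
first cycle start to its last spot beam-off (so a single-spot plan takes
injection + acceleration + weight/rate), while the log-visible window runs
from first spot beam-on to last beam-off — exactly one
injection+acceleration ramp less per field.  The analytics layer uses the
log-visible convention for both the actual and the simulated time, so the
gated−continuous difference is nonnegative and is zero precisely when the
gate never drops.

## Timing defaults

The vendor's cycle constants are not public; all values are configuration
with these defaults, chosen so a full layer switch totals 2 s — the scale
of a per-layer energy change on this machine class, and the reason layer
switching dominates continuous delivery time.

| parameter | default | meaning |
|---|---|---|
| `injection_s` | 0.3 s | injection phase |
| `acceleration_s` | 0.7 s | ramp to flat top |
| `deceleration_s` | 0.5 s | ramp down |
| `energy_switch_overhead_s` | 0.5 s | extra per layer change |
| `flat_top_max_s` | 10 s | longest flat top |
| `wait_limit_s` | 5 s | waiting-function limit (≤ flat top) |
| `spill_charge` | 200 | max charge per cycle |
| `spot_rate` | 100 /s | extraction charge rate |
| `spot_transition_s` | 2 ms | lateral move between spots |

## Motion and operator model

Marker displacement per axis is
`amplitude · u(t) + drift_rate · t + Σ step-shifts + noise`, with
`u(t) = 1 − cos⁴(π t/T)` — the standard asymmetric respiratory surrogate
(exhale plateau at 0, inhale peak at 1, mean 5/8 over whole periods).
Sampling is 30/15 Hz for thoracic/abdominal sites and 1 Hz for prostate.

The operator model watches a trailing low-quantile (q = 0.1, 15 s) of the
displacement as an end-exhale baseline estimate; a plain running median
would sit at ≈ 0.75 × amplitude for this waveform and misread respiration
as baseline.  A detection fires on an upward crossing of the running median
of that estimate above the 2 mm tolerance (edge-triggered with a dwell
refractory, so a persistent step fires once until corrected), or — as a
fallback — when the gate has been off for a whole 30 s window, since an
operator always re-matches when the beam refuses to resume.  After a 15 s
reaction delay the couch is moved by the estimated offset; the log records
a redo-bone-matching signal at detection and a couch-move with the shift
vector.  Corrections are imperfect by construction (the estimator carries
quantile bias and noise), which is realistic and exercises re-detection.

## Synthetic cohort

The generator reproduces a reference clinical population's structure per site:
session counts (1868 prostate / 727 liver / 165 pancreas / 40 lung /
10 adrenal = 2810 at full scale; the default is 5%, i.e. 93/36/8/2/1 = 140
sessions), fields-per-session ranges (prostate 2–4, liver 2–4, pancreas 2,
lung 3, adrenal 2), and CTV ranges, with layer counts ∝ V^(1/3) and spots
per layer ∝ V^(2/3) calibrated so continuous session times land in the
few-minute band typical of spot-scanning delivery.  Per-site motion
defaults (amplitudes, drift rates, baseline-shift rates) were chosen once
to reproduce the qualitative clinical picture — gating efficiency ordering
prostate ≫ lung/liver > pancreas, intra-field interventions in roughly 20%
of sessions, couch corrections of ~0.3 cm — not any particular printed
mean.  Every generated session records its ground truth (true duty cycle
within the delivery windows, intra-field adjustment count and sizes, and
both delivery times), so the analytics layer can be tested by exact
recovery.

What the generator does *not* emulate: hysteresis and irregularity of real
breathing (the waveform is quasi-periodic with smooth parameter jitter),
imaging latency and marker-detection failures, correlated multi-axis
baseline motion, couch-move execution time, and any dosimetric feedback.
Passing recovery tests therefore demonstrates that the analytics measure
what the logs contain — not that the synthetic cohort statistics equal
clinical ones.

## Numerical choices

- Gate-window test is inclusive (|d| ≤ 2.0 mm is in-window).
- Tie-breaks: a spot completing exactly at gate-off is delivered; a wait
  reaching the limit exactly decelerates.
- Event-time comparisons use a 1 ns slack; timestamps are serialized at
  full float precision so write/read round trips and the
  log-vs-simulator identities are bit-exact.
- The fixed-timestep oracle rounds each state duration up to whole ticks;
  it agrees with the event-driven simulator within one tick per state
  transition, and exactly on instances whose durations and gate sample
  times are all multiples of the tick.
- Sample SD everywhere is ddof = 1; single-member groups report SD as not
  available ("N.A." in formatted tables).  Cohort totals are pooled
  recomputations over sessions, never means of category means.
- The efficiency denominator is the whole first-on→last-off window per
  field by default; `denominator="spill"` restricts it to beam-ready
  (flat-top) periods.

## Known limitations

- Strict dominance of multiple gating over legacy mode holds for
  respiratory-like gates but is not a theorem of the model (see the
  phase-locking note above).
- The 1 Hz prostate gate aliases the respiratory waveform; prostate gating
  in this model is driven by noise and baseline excursions, as clinically.
- Simulated problem sizes (5% cohort, few-minute sessions) were chosen to
  keep a full pipeline run in tens of seconds on one CPU; `scale=1.0`
  generates the full 2810-session cohort.
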