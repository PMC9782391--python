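# Methods

## Problem and scope

Volatile anesthetics (sevoflurane, isoflurane, desflurane) are potent
greenhouse gases, and most of what leaves the vaporizer is vented unused
when fresh gas flow (FGF) is high. `lowflow` implements the decision-support
and reporting machinery for an FGF-reduction program: a per-minute rule
engine that raises a low-flow advisory when high flow persists during
volatile maintenance, a reporting pipeline that expresses consumption as mL
of liquid agent per MAC-hour (the "gas mileage" of an anesthetic, lower is
better), and a synthetic operating-room cohort simulator that provides
ground truth for every part of the pipeline.

## The advisory rule set

The engine evaluates one flowsheet minute at a time. An advisory fires only
when all seven conditions hold at that minute:

1. a volatile agent is the *set agent* (the volatile agent with the highest
   dial concentration; ties break sevoflurane → isoflurane → desflurane);
2. its dial concentration is > 0;
3. total FGF has *strictly exceeded* the threshold for at least the last
   `lookback` consecutive evaluated minutes;
4. the procedure-start event has occurred;
5. the procedure-stop event has not occurred;
6. the patient is strictly older than the age cutoff;
7. the advisory is neither snoozed nor disabled.

Nitrous oxide is treated purely as a carrier: N₂O without a volatile agent
never fires, N₂O alongside one can. Rule 4 is the sole induction exclusion
(induction legitimately uses high flow); rule 5 excludes emergence.

Defaults: threshold 0.7 L/min, lookback 5 min, snooze 10 min, age cutoff
1 year, evaluated every minute. Site presets: `ucsf`/`uc-c` active
noninterruptive at 0.7 L/min, `uc-a` active interruptive at 0.7, `uc-b`
passive at 1, `uc-d` active noninterruptive at 1.

Decisions made where the design was genuinely open:

* **"Exceeds" is strict** (`fgf > threshold`): a flow exactly at the
  threshold never fires.
* **Grid gaps reset the consecutive-minutes counter.** A missing minute is
  unknown flow, and unknown flow is not evidence of high flow. Equivalently,
  rule 3 requires the trailing `lookback` *grid* minutes to all be present
  and satisfying.
* **Episodes.** While the rules hold continuously the engine fires every
  minute; an uninterrupted run of firing minutes forms one *episode*, and
  episode count is the headline burden metric (per-minute firings are also
  retained, since a production system might refire either way).
* **Snooze keeps the counter running** by default (the condition is still
  tracked while the display is suppressed), so an advisory can re-fire the
  minute the snooze expires. `snooze_resets_counter` opts into the other
  reading.
* **Mode is metadata.** Passive events are logged with `displayed=False`;
  interruptive events carry `requires_acknowledgment=True`; firing logic is
  identical in all three modes, so burden comparisons across sites are
  apples-to-apples.
* **Scripted operator actions** take effect after the evaluation of their
  own minute — the operator reacts to what that minute displayed.

## Consumption metrics

All windows are half-open `[start, stop)` in integer minutes; a record
describes the minute beginning at its timestamp. This prevents double
counting at phase boundaries and makes per-professional volumes over a
partition of maintenance sum exactly to the case volume.

* induction: `[first minute with dial > 0, procedure_start)`
* maintenance: `[procedure_start, min(procedure_stop, anesthetic_gas_stop))`
  where `anesthetic_gas_stop` is the minute of the last nonzero dial.

**Liquid volume.** Two paths. When the machine reports cumulative liquid
consumption, the volume over a window is the difference of the running
total at the window boundaries (a reading at minute *t* includes minute
*t*, so "at the end of `[a, b)`" means the last reading before *b*). When
it does not, the volume is reconstructed minute by minute: the vaporizer
adds `dial%` of agent vapor to the fresh gas, so one minute consumes

    (dial/100) · FGF[L/min] · 1000 / V_vapor   mL liquid,

with `V_vapor = (ρ/MW) · V_m(T_ref)` the vapor yield per mL of liquid
(ideal gas at the reference temperature, default 21 °C; ≈183 mL/mL for
sevoflurane). Cumulative readings take precedence; a >10 % disagreement
between the paths is logged.

**MAC-hours.** `mean(end-tidal %) / MAC_age(agent, age) × window hours`,
with the age-adjusted MAC from the Nickalls–Mapleson relation
`MAC(age) = MAC₄₀ · 10^(−0.00269·(age−40))` (the standard AIMS
implementation; exactly `MAC₄₀` at age 40). The ratio-of-means form follows
the reporting pseudocode convention; it equals the mean of per-minute
ratios because the denominator is constant within a case. The mean is
unweighted over recorded readings; windows with < 80 % end-tidal coverage
are flagged. "No readings" is an error, never treated as zero.

**mL per MAC-hour** is the quotient; `MAC-hours = 0` yields an explicit
NaN with an `undefined_metric` flag and the case is dropped from means
with a logged reason.

**Per-professional metrics** use each sign-in interval intersected with
maintenance; overlapping intervals (supervision) are allowed, so per-role
totals may each equal the case total.

**Exclusions** before aggregation: excluded locations (pediatric
induction, non-OR anesthesia, labor and delivery); more than one volatile
agent with any nonzero dial entry (scanned over the whole recorded case by
default — a single flow-sheet entry suffices — or maintenance-only via a
switch); fewer than 15 minutes of recorded delivery (exactly 15 is
included). Monthly aggregation reports mean mL/MAC-hour per agent, episode
burden per case and per case-hour, and optional cost (user-supplied
cost/mL) and CO₂-equivalents (volume × density × GWP₁₀₀). Months inside
the span with no included cases appear as explicit null rows.

Agent constants (MW, density, MAC₄₀, GWP₁₀₀, reference temperature) live
in an editable YAML table. The shipped GWP₁₀₀ values (sevoflurane 130,
isoflurane 510, desflurane 2540) follow the commonly cited attribution;
inventory year and source vary across reports, so the file labels them as
configuration with provenance, not asserted physical truth.

## Synthetic cohort

Each case: uniform 5–15 min high-flow induction (≈6 L/min) before
procedure start; a maintenance segment whose length is lognormal with mean
110 min and SD 55 min (floored at 20 min — a typical adult OR case mix);
then 3–8 min of high-flow emergence with the dial at zero after the gas
stops (procedure stop coincides with gas stop). The dial is set ≈1.2× the
end-tidal target; end-tidal relaxes exponentially (τ = 5 min) toward the
patient's age-adjusted MAC × `target_mac`. Ages are lognormal (median 40,
σ = 0.6) with a 3 % chance of an infant under 1 year, so the age-cutoff
rule is exercised. Cumulative liquid consumption is written from the same
vaporizer formula the metrics module uses, making the two volume paths
agree by construction — which is exactly what makes the cross-path test a
check of the windowing logic rather than of the formula.

Maintenance FGF is a two-mode mixture — a low-flow practice mode
N(0.5, 0.1) and a high-flow mode N(2.0, 0.3), mixing weight 0.5 — drawn
once per case, **quantized to the 0.1 L/min charting resolution and held
piecewise-constant**. Machines deliver the dialed set point; minute-level
noise around the alert threshold is not a feature of charted flowsheet
data, and modelling it would make the advisory flap and contaminate
response estimation with artificial "spontaneous" reductions. Mild
per-minute variation is retained in induction and emergence, far from any
threshold.

The advisory engine runs concurrently with generation. Behaviour is
memoryless per episode: each new firing episode independently triggers,
with probability `response_probability` (default 0.7), a step down to
`response_fgf` (0.5 L/min) after `response_latency` (2 min). This is the
simplest model that supports parameter recovery; habituation and partial
reductions are out of scope. The latent draws (flow mode, operating level,
episode responses) are returned as a ground-truth table.

`estimate_response_probability` counts an episode as responded when any
recorded minute within `window_minutes` (default 5 = latency + charting
tolerance) after its first firing shows FGF ≤ threshold, and attaches a
Wilson score interval. Zero episodes yield an explicitly undefined
estimate, not zero.

What the simulator does **not** emulate: pharmacokinetic uptake
(end-tidal follows a fixed exponential, not a Severinghaus/Eger model),
circuit physics, hemodynamics, charting artifacts/dropouts beyond clean
grids, within-case practice drift, and alert habituation. Tests that pass
on this cohort therefore validate the engine's temporal logic, the
windowing arithmetic and the estimator's calibration — not the clinical
realism of any particular institution's case mix.

## Numerical choices and degenerate inputs

* Time is integer minutes from the first record; wall-clock input is
  snapped to the floor minute with a warning; duplicate minutes are an
  error; gaps are preserved, never imputed.
* Vapor molar volume is ideal-gas at a configurable reference temperature
  (default 21 °C); no temperature/pressure-corrected vaporizer physics.
* Liquid-consumption arithmetic is exactly additive over any partition of
  an interval and linear in flow, dial and duration.
* Cumulative-volume monotonicity is enforced at validation with a 1e-9
  slack for float round-trips.
* Gas-flow breakdowns must sum to the recorded total within 1e-6.
* A dial that never rises above zero yields empty phase windows flagged
  for exclusion rather than an error.

## Problem sizes used in the tests

Oracle-equivalence runs 1,000 randomized 60–300-minute traces (plus a
derandomized property-based layer); the volume cross-path check uses 200
simulated cases; response-probability calibration uses 100 replicates of
500 cases at p = 0.7 and requires ≥ 90 % CI coverage; burden monotonicity
sweeps five thresholds and five lookbacks over a fixed 60-case
no-response cohort. These sizes give Monte-Carlo error comfortably inside
the assertion tolerances while keeping the suite quick to run.

## Known limitations

* The engine assumes a single case per evaluation stream; concurrent-room
  scheduling is out of scope.
* N₂O carries no MAC contribution or vapor entry; cases maintained on N₂O
  alone are outside the reporting scope (mirroring the alert's behaviour).
* The "set agent" definition (max dial, fixed tie-break) is one reasonable
  operationalization; flowsheets that chart an explicit agent-selection
  event could disagree on tie minutes.
* Cost reporting requires user-supplied prices; none are shipped.
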