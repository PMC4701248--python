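# Methods

This note documents the models, the numerical choices and the design
decisions behind `mcpsim`, and states what the synthetic data and the
test suite do and do not establish.

## Simulation kernel

Components exchange timestamped events over named ports under a global
clock in minutes. The engine sweeps a fixed grid t = 0, dt, …, horizon
(default dt = 0.1–1 min depending on scenario; every bundled horizon is
a multiple of dt). At each grid time it (1) advances every continuous
component one classical RK4 step with inputs held constant over the step
(zero-order hold), (2) lets timed components act, and (3) drains all
events due at that time in FIFO insertion order. Continuous state is
therefore always updated *before* discrete reactions at the same
timestamp, which is the sample-then-react semantics a periodic sensor
needs. RK4 was chosen because the glucose–insulin field is smooth and
non-stiff (three real poles, the fastest ≈ 0.1 min⁻¹), so a fixed-step
fourth-order explicit method at dt ≤ 0.5 min is accurate to far below
any quantity of interest; the convergence-order test verifies the p = 4
error scaling on dx/dt = −x. Determinism is a contract: a trace is a
pure function of the scenario and one root seed, and per-component
random substreams are derived from (seed, crc32(component id)) so adding
a component never perturbs another component's draws.

One kernel subtlety: a controller that samples a continuous signal each
tick sees the value published at the *previous* tick (events are drained
after components act), i.e. the loop has one step of measurement delay.
This is causal, deterministic, and representative of a sampled-data
controller.

## Vital-sign generation

Each modeled sign is a canonical-link GLM over the other signs, glucose,
patient-group dummies (four groups; group 1 is baseline) and the
interactions hr·sbp and hr·gl. The shipped respiratory-rate model
(`REFERENCE_RR_MODEL`) carries its published coefficients digit for
digit; its linear predictor can cross zero at extreme predictor values,
so the absolute value is taken before the inverse-squared link — the
same |·| preprocessing the original model used. Predictions are rounded
(heart rate, respiratory rate and blood pressure to integers; body
temperature to one decimal, since integer temperature is clinically
implausible — both flags are per-model configuration) and clamped to the
per-sign thresholds, whose defaults are the min/max of the calibration
population.

State only changes through interventions: when one sign is written
(by a user script or by the glucose model), every other modeled sign is
recomputed **once** using the post-intervention state. A fixed-point
iteration was deliberately rejected: the models are mutually dependent
and iterating them can cycle; the single pass matches a one-shot
selector semantics and keeps the update idempotent for a sign set to its
own predicted value.

## Glucose–insulin kinetics and control

The Bergman minimal model is implemented in its nonlinear form and in
the operating-point linearization. The endogenous-release term
γ·max(G−h, 0)·t is available behind an `include_gamma` flag but **off by
default**: the equilibrium algebra and the linearized model both omit
it (the fasting/diabetic regime), and the time-multiplied form is kept
only as an option because its provenance in the minimal-model literature
is as an approximation valid for short tests.

Parameter defaults (p₁ = 0.028735, p₂ = 0.028344, p₃ = 5.035·10⁻⁵,
n = 0.0926 min⁻¹, G_b = 81 mg/dL, I_b = 15 μU/mL) are the classical
type-1-diabetic minimal-model values used throughout the glucose-control
literature; τ = 1.389 (μU/mL/min per U/h) corresponds to a 12 L insulin
distribution volume. All are overridable per scenario; none is claimed
to reproduce any particular published waveform.

The equilibrium under constant inputs is closed-form
(X₀ = p₃τr₀/(p₂n), I₀ = I_b + τr₀/n, G₀ = (p₁G_b + D₀ + C₀)/(p₁ + X₀));
the Jacobian at it is upper triangular with diagonal (−p₁−X₀, −p₂, −n),
so the linearized model is always asymptotically stable. The
linearization error is exactly bilinear (−ΔX·ΔG in the glucose
equation), which is why the Richardson ratio in the tests equals 4 to
machine precision.

The PID controller uses error e = G − setpoint, a backward-Euler
integral, and a first-order filtered derivative (pole −N, backward
Euler, so a step decays with ratio 1/(1+N·dt)). Insulin cannot be
negative: the output is clipped at 0, and the integrator is frozen while
clipped with the error still negative (conditional anti-windup). Default
gains come from a SIMC-style rule applied to the linearized insulin
channel: keep the slowest time constant, lump the two faster lags into
an effective delay θ, set Kp = τ₁/(|K|·2θ) and Ki = Kp/min(τ₁, 8θ),
Kd = 0 (the plant is overdamped; derivative action buys nothing at these
bandwidths). The tests verify the resulting closed loop is stable (all
characteristic-polynomial roots in the open left half-plane), holds the
basal equilibrium exactly, and returns glucose to within 5% of the
setpoint after a standard meal pulse (2 mg/dL/min for 30 min).

## Insulin pump

The pump is a timed extended state machine stepped once per minute.
Basal doses fall at the end of each period — every 3 min for the
standard profile (480/day, dose = rate/20 U) and hourly for the
customized profile (24/day, one per-hour rate each) — so a 24 h run
issues exactly 480 or 24 basal deliveries. Mealtime boluses preempt the
basal slot they collide with; a corrective bolus preempts everything.
Doses are delivered atomically per tick (the underlying 0.2 U/s
administration rate is abstracted away, as the device table itself
does).

Mode logic: `Run` is accepted only while the cartridge is FULL or
NORMAL; the pump stops one scheduler tick after the status enters LOW or
EMPTY (one tick is the smallest nonzero delay consistent with
"stop after a delay"; a `warn_only_on_low` switch keeps it running on
LOW for configurations that treat LOW as a warning only). A delivery
whose dose exceeds the remaining level is refused *entirely* and stops
the pump — partial dosing would break the administered-equals-programmed
property. The LOW threshold is not part of the device table; the default
is 10% of capacity, boundary inclusive, configurable.

Two representation choices make the safety invariants structural: the
cartridge level is stored as (initial level − cumulative delivered), so
conservation is an identity of the representation rather than a sum of
hundreds of float subtractions; and the cartridge status is a
single-valued enumeration, so EMPTY∧LOW is unrepresentable in the state
(the A1 monitor still checks the *emitted trace*, which is the artifact
a runtime monitor actually sees).

## Safety monitoring and coverage

Monitors are trace-based only: they scan the (time, component, signal,
value) table, never the implementation, and report the earliest
counterexample with its witness rows. The SR1 stop-delay bound is a
parameter (default one tick) and the verdict reports the observed
worst-case delay. The test suite cross-checks every monitor against an
independently written brute-force scan on both nominal and
fault-injected mutant traces.

Coverage instrumentation records, per decision site, the condition truth
vector and the outcome (recomputed from the site's decision function and
asserted equal — a mismatch is an instrumentation bug, not a coverage
result). Decision coverage is outcomes-observed/2; condition coverage is
per-condition truth values observed; MC/DC uses independence pairs —
two observed evaluations differing in exactly one condition with
different outcomes. CC and MC/DC are reported NA for sites whose
decision is a single atomic condition, and cyclomatic complexity per
function is decision count + 1. Percentages aggregate uniformly over a
function's sites. A nominal healthy-day simulation intentionally leaves
the empty-cartridge branches uncovered; the reported partial coverage of
such runs is the expected, meaningful output.

## Synthetic cohort and GLM fitting

The generator emulates an ICU admission sample through its published
summary measures: per-variable mean, SD and clinical range, and a 37.4%
female share. Rows are multivariate normal, rejection-resampled into the
range box. Because box truncation biases means (directly, and through
correlations), the pre-truncation mean vector is calibrated: a 1-D
truncated-normal solve per variable, then four Monte-Carlo fixed-point
iterations on a deterministic pilot stream, leaving residual bias well
under the sampling noise of any cohort size used here. The population
table publishes no correlations; the defaults (hr–rr 0.30, hr–gl 0.20,
hr–sbp 0.20, others 0) are this package's own choices, made once so that
the interaction terms of the regression designs are estimable, and are
fully overridable. Patient groups come from a configurable rule; the
default is a severity band (1 + count of vitals outside textbook normal
ranges, capped at 4), chosen because the upstream classification rule is
not published.

What the synthetic cohort does *not* emulate: real admission data are
not multivariate normal (skewness, heaping at round values, missing
data, repeated measures), and the true inter-sign dependence structure
is certainly richer than three pairwise correlations. Tests passing on
this cohort therefore establish the correctness of the fitting and
simulation machinery, not the clinical fidelity of any fitted model.

Fitting is IRLS via statsmodels with the canonical links (inverse
squared for inverse-Gaussian, inverse for Gamma), tolerance 1e-8, at
most 100 iterations, Pearson-χ² dispersion; a cohort must have at least
30 records before any fit is attempted. Diagnostics include Pearson and
deviance residuals, hat values, Cook's distances and a simulated
envelope (refits on responses resampled from the fitted distribution).
The independent check in the tests maximizes the family deviance
directly with a generic optimizer and agrees with IRLS to 1e-6 on small
instances; recovery tests confirm 3-SE coverage of known coefficients at
n = 2000. The fitted hr/sbp/pt/gl-design models are packaged defaults of
*this* artifact — the corresponding published models were never printed,
and no invented coefficients are presented as anyone else's.

## Daily-dose calculator

The calculator's formulas are the conventional weight-based rules of
diabetes practice (TDD = 0.5 U/kg, half basal, mealtime boluses from the
bolus share, corrective dose from the 1800 rule), used here only to
program the pump with plausible values; the guideline equations the
original scenario used are not published, so these defaults are
explicitly this package's own. Outputs are clamped to the pump's
configuration bounds.

## Problem sizes

Bundled scenarios run in seconds: 24 h of pump operation at 1-minute
ticks, 10 h of closed-loop control at 0.5-minute steps, cohorts of
200–10,000 patients. These sizes were chosen so every property of
interest (scheduling counts, run-out behavior, calibration of sample
means, recovery of GLM coefficients) is measured at full strength while
the complete suite stays interactive.

## Known limitations

- Sensors are ideal: no noise, drift, dropout or quantization.
- The pump models no occlusion, battery or communication faults, and the
  centralizer/bedside monitor are pass-through relays.
- The GLM patient is memoryless (a static map re-evaluated on
  intervention); it has no autonomous dynamics between interventions.
- Coverage is measured on the simulated trace only — it is runtime
  verification, not static analysis, and says nothing about inputs that
  were never simulated.
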