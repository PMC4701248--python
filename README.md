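# mcpsim

Desk-scale simulation and early validation of **medical cyber-physical
systems** (MCPS): closed loops in which software controllers, medical
sensors and actuators interact with a patient. The package is aimed at
engineers and researchers who want to exercise device logic and
closed-loop control strategies against executable patient models *before*
any hardware or clinical data is involved — and to check safety
requirements and structural coverage on the resulting simulation traces.

## What is inside

**Patient models.**
Basic physiology is generated by per-sign generalized linear models: each
vital sign (heart rate *hr*, respiratory rate *rr*, systolic blood
pressure *sbp*, body temperature *pt*) is predicted from the others plus
blood glucose *gl* through a linear predictor

    η = β₀ + Σᵢ βᵢXᵢ + Σⱼ β₅ⱼX₅ⱼ + β₆X₆ + β₇X₇

(main effects, patient-group dummies, and the interactions X₆ = hr·sbp,
X₇ = hr·gl) followed by the canonical inverse link of its family:
μ = η^(−1/2) for the inverse-Gaussian *rr* model, μ = η^(−1) for the
Gamma models. A published respiratory-rate model is shipped verbatim as
`REFERENCE_RR_MODEL`; the other models are fitted on a synthetic cohort.

Glucose–insulin kinetics follow the Bergman minimal model

    dG/dt = −p₁(G − G_b) − X·G + D(t) + C(t)
    dX/dt = −p₂X + p₃(I − I_b)
    dI/dt = −n(I − I_b) + τ·r(t)

with meal absorption D, glucagon C and the insulin infusion r commanded
by a PID controller G(s) = K_p + K_i/s + K_d·N·s/(s+N). The equilibrium,
the exact state-space linearization and the per-channel transfer
functions are available in closed form, and the default PID gains are
tuned from the linearized insulin channel.

**Device models.** Periodic sensors with clocks aligned to the global
simulation clock, and an insulin pump modeled as a timed extended state
machine: STOP/EXECUTING modes, basal/bolus/corrective delivery
strategies, a U100 cartridge (3.15 mL = 315 U) with FULL/NORMAL/LOW/EMPTY
status gating the mode, and a daily-dose calculator that programs the
pump from the patient profile.

**Verification.** Trace monitors for the pump safety requirements
(SR1: empty cartridge ⇒ EMPTY status ⇒ STOP after one tick; SR2: no
delivery when the dose exceeds the level, and STOP; SR3: administered
basal dose equals the programmed dose; A1: never EMPTY and LOW at once)
and decision/condition/MC-DC coverage of the instrumented pump logic.

**Synthetic cohort.** A generator calibrated to the summary measures of
an ICU admission population (per-variable mean/SD/range, ~37.4% female),
used to fit the vital-sign GLMs by IRLS so the whole pipeline is
self-contained.

## Worked example

```bash
python examples/closed_loop_glucose.py
```

prints (abridged):

```
tuned gains: Kp=0.0103 Ki=0.00029 (U/h per mg/dL), setpoint 81 mg/dL
glucose: basal 81 -> peak 119.0 mg/dL at t=90 min -> 81.0 mg/dL at t=600 min
respiratory rate co-adjusts through its GLM: min 13, max 19 breaths/min over the run
```

A 30-minute meal disturbance pushes glucose from the basal 81 mg/dL to a
peak of 119 mg/dL; the PID controller returns it to the setpoint before
the 10-hour horizon, and because glucose is a predictor of the
respiratory-rate regression model, *rr* shifts with the excursion and
recovers with it. The other examples cover ICU monitoring
(`icu_monitoring.py`), a full pump day with safety verdicts and a
coverage table (`insulin_pump_day.py`), cohort generation plus GLM
fitting (`cohort_and_glm.py`) and the linearization/tuning algebra
(`linearization_and_tuning.py`). The same scenarios are available from
the shell:

```bash
mcpsim simulate examples/configs/insulin_pump.yaml --out out/
mcpsim verify out/trace.csv --properties SR1,SR2,SR3,A1
mcpsim cohort generate --n 1000 --seed 42 --out cohort.csv
```

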