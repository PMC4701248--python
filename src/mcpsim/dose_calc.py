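"""Daily insulin dose calculator.

Computes the three programmed doses the pump consumes — basal rate
(baid), standard mealtime bolus (boid) and corrective bolus (cboid) —
from the patient profile and current glucose.  The formulas are the
conventional weight-based rules of diabetes practice and are this
package's defaults, fully configurable:

* total daily dose   TDD = tdd_factor · weight        (default 0.5 U/kg)
* basal share        basal = basal_fraction · TDD     (default 0.5), as U/h
* meal bolus         boid = TDD / meals_per_day       of the bolus share
* corrective bolus   cboid = (gl − target) / correction_factor, where the
  correction (sensitivity) factor is 1800 / TDD mg/dL per U ("1800 rule"),
  floored at 0.

Outputs are clamped to the pump's configuration bounds (basal rate in
[0.1, 25.0] U/h, boluses ≤ 25 U).
"""

from __future__ import annotations

from dataclasses import dataclass

from .pump import BASAL_RATE_MAX, BASAL_RATE_MIN, BOLUS_MAX
from .vitals import PatientProfile


@dataclass(frozen=True)
class DoseCalculatorConfig:
    tdd_factor: float = 0.5  # U per kg body weight per day
    basal_fraction: float = 0.5  # share of TDD given as basal
    meals_per_day: int = 3
    target_gl: float = 110.0  # mg/dL
    correction_rule: float = 1800.0  # "1800 rule" numerator, mg/dL·U


@dataclass(frozen=True)
class DailyDoses:
    baid: float  # basal rate, U/h
    boid: float  # standard mealtime bolus, U
    cboid: float  # corrective bolus, U
    tdd: float  # total daily dose, U


def insulin_dose_calculator(
    profile: PatientProfile,
    current_gl: float,
    config: DoseCalculatorConfig | None = None,
) -> DailyDoses:
    """Compute (baid, boid, cboid) for one patient; see module docstring."""
    config = config or DoseCalculatorConfig()
    if profile.weight <= 0:
        raise ValueError(f"patient weight must be > 0, got {profile.weight}")
    tdd = config.tdd_factor * profile.weight
    basal_daily = config.basal_fraction * tdd
    baid = basal_daily / 24.0
    baid = min(max(baid, BASAL_RATE_MIN), BASAL_RATE_MAX)
    bolus_share = (1.0 - config.basal_fraction) * tdd
    boid = min(bolus_share / config.meals_per_day, BOLUS_MAX)
    sensitivity = config.correction_rule / tdd  # mg/dL per U
    cboid = max(current_gl - config.target_gl, 0.0) / sensitivity
    cboid = min(cboid, BOLUS_MAX)
    return DailyDoses(baid=baid, boid=boid, cboid=cboid, tdd=tdd)
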