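"""Synthetic ICU-admission cohort generator.

Generates patient tables that emulate the summary measures of an ICU
admission sample (one observation per patient at admission): per-variable
mean, SD and clinical min/max for heart rate, systolic blood pressure,
respiratory rate, body temperature, blood glucose, weight and height,
plus a ~37.4% female share.  Rows are drawn from a multivariate normal
with the target moments and a configurable correlation structure, and
rejection-resampled into the [min, max] box, so all values stay inside
the calibration ranges of the regression models fitted on the cohort.

The population summary table gives no correlations; the defaults below
are this package's own choices — mild positive hr-sbp, hr-gl and hr-rr
dependence — so that the hr*sbp and hr*gl interaction terms of the
regression designs are estimable.

Patient groups (the regression models' categorical predictor) come from
a configurable classification rule; the default is a severity band:
the count of vitals outside textbook normal ranges, capped into four
groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, stats

# Per-variable calibration targets: mean, SD, min, max.
POPULATION_SUMMARY: dict[str, tuple[float, float, float, float]] = {
    "hr": (87.315, 14.263, 40.00, 150.00),
    "sbp": (116.518, 20.049, 48.00, 212.00),
    "rr": (19.216, 5.628, 8.00, 38.00),
    "pt": (37.251, 0.739, 31.70, 41.44),
    "gl": (118.761, 27.802, 47.00, 188.00),
    "weight": (84.300, 20.730, 33.00, 200.00),
    "height": (169.804, 10.379, 124.50, 231.10),
}

FEMALE_FRACTION = 0.374

MIN_COHORT_SIZE = 30  # multiple-regression floor on usable cohorts

# Textbook adult normal ranges used by the default group rule.
NORMAL_BANDS = {
    "hr": (60.0, 100.0),
    "sbp": (90.0, 140.0),
    "rr": (12.0, 20.0),
    "pt": (36.1, 37.8),
    "gl": (70.0, 140.0),
}

_VARS = tuple(POPULATION_SUMMARY)


class CohortSizeError(ValueError):
    """Cohort below the minimum size for multiple regression."""


def severity_group(row: pd.Series) -> int:
    """Default group rule: 1 + count of out-of-band vitals, capped at 4."""
    score = sum(
        not (lo <= row[sign] <= hi) for sign, (lo, hi) in NORMAL_BANDS.items()
    )
    return int(min(score + 1, 4))


def _default_correlation() -> pd.DataFrame:
    corr = pd.DataFrame(np.eye(len(_VARS)), index=_VARS, columns=_VARS)
    for a, b, rho in (("hr", "rr", 0.30), ("hr", "gl", 0.20), ("hr", "sbp", 0.20)):
        corr.loc[a, b] = corr.loc[b, a] = rho
    return corr


@dataclass
class CohortSpec:
    """Calibration targets and sampling configuration for one cohort."""

    n: int = 1000
    seed: int = 0
    targets: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(POPULATION_SUMMARY)
    )
    female_fraction: float = FEMALE_FRACTION
    correlation: pd.DataFrame = field(default_factory=_default_correlation)
    group_rule: Callable[[pd.Series], int] = severity_group

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")
        for var, (mean, sd, lo, hi) in self.targets.items():
            if sd <= 0:
                raise ValueError(f"{var}: SD must be > 0")
            if not lo < mean < hi:
                raise ValueError(
                    f"{var}: infeasible spec, mean {mean} outside range [{lo}, {hi}]"
                )
        eigvals = np.linalg.eigvalsh(self.correlation.loc[list(_VARS), list(_VARS)].to_numpy())
        if eigvals.min() <= 0:
            raise ValueError("correlation matrix must be positive definite")


def _truncation_adjusted_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Pre-truncation location whose [lo, hi]-truncated normal mean is ``mean``.

    Restricting draws to the clinical box shifts the sample mean away
    from the target (most visibly for variables whose range cuts within
    two SDs of the mean); solving the 1-D truncated-normal mean equation
    per variable removes the marginal part of that bias.
    """

    def truncated_mean(m: float) -> float:
        return stats.truncnorm.mean((lo - m) / sd, (hi - m) / sd, loc=m, scale=sd)

    return optimize.brentq(lambda m: truncated_mean(m) - mean, lo, hi, xtol=1e-10)


# Fixed internal stream for the mean calibration below; independent of the
# cohort seed so calibration is part of the generator's definition, not of
# any particular draw.
_CALIBRATION_SEED = 987654321
_CALIBRATION_N = 200_000


def _calibrate_means(
    target_means: np.ndarray, cov: np.ndarray, lows: np.ndarray, highs: np.ndarray
) -> np.ndarray:
    """Pre-truncation mean vector whose box-truncated joint means hit the targets.

    Rejection against the whole box couples the variables: truncating one
    variable shifts the mean of every variable correlated with it.  A few
    Monte-Carlo fixed-point iterations (deterministic pilot stream) solve
    the joint mean equation to well under the sampling noise of any
    realistic cohort size.
    """
    sds = np.sqrt(np.diag(cov))
    m = np.array(
        [
            _truncation_adjusted_mean(mu, sd, lo, hi)
            for mu, sd, lo, hi in zip(target_means, sds, lows, highs)
        ]
    )
    rng = np.random.default_rng(_CALIBRATION_SEED)
    for _ in range(4):
        draw = rng.multivariate_normal(m, cov, size=_CALIBRATION_N, method="cholesky")
        ok = np.all((draw >= lows) & (draw <= highs), axis=1)
        m = m - (draw[ok].mean(axis=0) - target_means)
    return m


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table; deterministic given ``spec.seed``.

    Columns: patient_id, gender, weight, height, group, hr, rr, sbp, pt, gl.
    Every variable lies inside its [min, max]; rows falling outside the
    box are rejection-resampled.
    """
    rng = np.random.default_rng(spec.seed)
    names = [v for v in _VARS if v in spec.targets]
    target_means = np.array([spec.targets[v][0] for v in names])
    sds = np.array([spec.targets[v][1] for v in names])
    lows = np.array([spec.targets[v][2] for v in names])
    highs = np.array([spec.targets[v][3] for v in names])
    corr = spec.correlation.loc[names, names].to_numpy()
    cov = np.outer(sds, sds) * corr
    means = _calibrate_means(target_means, cov, lows, highs)

    rows = np.empty((0, len(names)))
    while rows.shape[0] < spec.n:
        need = spec.n - rows.shape[0]
        draw = rng.multivariate_normal(means, cov, size=max(need, 64), method="cholesky")
        ok = np.all((draw >= lows) & (draw <= highs), axis=1)
        rows = np.vstack([rows, draw[ok]])
    rows = rows[: spec.n]

    df = pd.DataFrame(rows, columns=names)
    df.insert(0, "patient_id", np.arange(1, spec.n + 1))
    gender = np.where(rng.random(spec.n) < spec.female_fraction, "female", "male")
    df.insert(1, "gender", gender)
    df["group"] = df.apply(spec.group_rule, axis=1)
    return df[["patient_id", "gender", "weight", "height", "group", "hr", "rr", "sbp", "pt", "gl"]]


def require_fit_ready(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort for regression fitting (size floor, ranges)."""
    if len(cohort) < MIN_COHORT_SIZE:
        raise CohortSizeError(
            f"cohort has {len(cohort)} records; at least {MIN_COHORT_SIZE} are "
            "required for multiple regression analysis"
        )
    return cohort
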