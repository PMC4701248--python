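"""GLM-based patient vital signs.

An ICU patient is described by four vital signs (heart rate ``hr``,
respiratory rate ``rr``, systolic blood pressure ``sbp``, body
temperature ``pt``) plus blood glucose ``gl`` as a physiological
parameter.  Each modeled sign is generated by a generalized linear model
over the others: a linear predictor

    eta = b0 + sum_i b_i * X_i

over main effects (X1=hr, X2=sbp, X3=pt, X4=gl), patient-group dummy
variables (X52, X53, X54 — baseline group has all dummies 0) and the
interactions X6 = hr*sbp and X7 = hr*gl, followed by the canonical
inverse link of the response family: mu = eta^(-1/2) for the
inverse-Gaussian family and mu = eta^(-1) for the Gamma family.  The
predicted value is optionally passed through |.| before the link,
rounded, and clamped to the sign's clinical thresholds.

``REFERENCE_RR_MODEL`` carries, digit for digit, a published
inverse-Gaussian respiratory-rate regression fitted on an ICU admission
sample; the remaining signs' models are user-supplied (the cohort module
fits defaults on a synthetic cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

# Default clinical thresholds: min/max observed in the ICU admission
# population the models were calibrated to.
DEFAULT_THRESHOLDS: dict[str, tuple[float, float]] = {
    "hr": (40.00, 150.00),
    "sbp": (48.00, 212.00),
    "rr": (8.00, 38.00),
    "pt": (31.70, 41.44),
    "gl": (47.00, 188.00),
}

VITAL_SIGNS = ("hr", "rr", "sbp", "pt")
ALL_SIGNS = ("hr", "rr", "sbp", "pt", "gl")


class LinkDomainError(ValueError):
    """Linear predictor outside the domain of the inverse link."""


class MissingPredictorError(KeyError):
    """A predictor named by a GLMSpec is absent from the predictor vector."""


class InterventionError(ValueError):
    """User intervention outside a sign's thresholds."""


@dataclass(frozen=True)
class PatientProfile:
    """Demographics and group classification of one simulated patient.

    ``group`` is an integer category 1..4; group 1 is the baseline (all
    dummies zero), groups 2..4 set the dummy X5j for j = group.
    """

    gender: str = "female"
    weight: float = 84.3
    height: float = 169.8
    group: int = 1

    def __post_init__(self):
        if self.gender not in ("female", "male"):
            raise ValueError(f"gender must be 'female' or 'male', got {self.gender!r}")
        if self.group not in (1, 2, 3, 4):
            raise ValueError(f"group must be in 1..4, got {self.group}")

    def group_dummies(self) -> dict[str, float]:
        return {f"X5{j}": 1.0 if self.group == j else 0.0 for j in (2, 3, 4)}


@dataclass
class SignThresholds:
    """Per-sign [min, max] clamp ranges."""

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )

    def __post_init__(self):
        for sign, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"threshold min must be < max for {sign}: [{lo}, {hi}]")

    def clamp(self, sign: str, value: float) -> float:
        lo, hi = self.ranges[sign]
        return min(max(value, lo), hi)

    def contains(self, sign: str, value: float) -> bool:
        lo, hi = self.ranges[sign]
        return lo <= value <= hi


@dataclass
class VitalSignsState:
    """Instantaneous vital-sign values of a simulated patient."""

    hr: float = 87.0
    rr: float = 19.0
    sbp: float = 117.0
    pt: float = 37.3
    gl: float = 119.0

    def as_dict(self) -> dict[str, float]:
        return {"hr": self.hr, "rr": self.rr, "sbp": self.sbp, "pt": self.pt, "gl": self.gl}


@dataclass(frozen=True)
class GLMSpec:
    """One vital sign's regression model.

    ``coefficients`` maps predictor names to main-effect/dummy
    coefficients; ``interactions`` maps an interaction name to its factor
    pair and coefficient.  ``use_absolute`` applies |.| to the linear
    predictor before the inverse link (needed when a fitted predictor can
    cross zero); ``round_digits`` is 0 for integer signs, 1 for body
    temperature, or None for no rounding.
    """

    response: str
    family: str  # "inverse-gaussian" | "gamma"
    link: str  # "inverse-squared" | "inverse"
    intercept: float
    coefficients: Mapping[str, float] = field(default_factory=dict)
    interactions: Mapping[str, tuple[tuple[str, str], float]] = field(default_factory=dict)
    use_absolute: bool = False
    round_digits: int | None = 0

    def __post_init__(self):
        if self.family not in ("inverse-gaussian", "gamma"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.link not in ("inverse-squared", "inverse"):
            raise ValueError(f"unknown link {self.link!r}")

    def predictor_vector(self, state: VitalSignsState, profile: PatientProfile) -> dict[str, float]:
        """Assemble named predictor values from patient state and profile."""
        x = dict(state.as_dict())
        x.update(profile.group_dummies())
        x["weight"] = profile.weight
        x["height"] = profile.height
        for name, ((a, b), _) in self.interactions.items():
            for factor in (a, b):
                if factor not in x:
                    raise MissingPredictorError(
                        f"interaction {name} of model for {self.response!r} "
                        f"references unknown predictor {factor!r}"
                    )
            x[name] = x[a] * x[b]
        return x


def eval_linear_predictor(glm: GLMSpec, x: Mapping[str, float]) -> float:
    """eta = b0 + sum over main effects, dummies and interactions."""
    eta = glm.intercept
    for name, beta in glm.coefficients.items():
        if name not in x:
            raise MissingPredictorError(
                f"model for {glm.response!r} needs predictor {name!r}, absent from input"
            )
        eta += beta * x[name]
    for name, (_, beta) in glm.interactions.items():
        if name not in x:
            raise MissingPredictorError(
                f"model for {glm.response!r} needs interaction {name!r}, absent from input"
            )
        eta += beta * x[name]
    return eta


def apply_inverse_link(link: str, eta: float, use_absolute: bool = False) -> float:
    """Canonical inverse links: mu = eta^(-1/2) or mu = eta^(-1)."""
    if use_absolute:
        eta = abs(eta)
    if eta == 0:
        raise LinkDomainError("linear predictor is 0; inverse link undefined")
    if link == "inverse-squared":
        if eta < 0:
            raise LinkDomainError(
                f"negative linear predictor {eta} with inverse-squared link "
                "(set use_absolute to mirror the |.| preprocessing)"
            )
        return eta ** -0.5
    if link == "inverse":
        return 1.0 / eta
    raise ValueError(f"unknown link {link!r}")


def apply_link(link: str, mu: float) -> float:
    """Forward canonical link (inverse of ``apply_inverse_link``)."""
    if mu <= 0:
        raise LinkDomainError(f"link defined for mu > 0, got {mu}")
    return mu ** -2 if link == "inverse-squared" else 1.0 / mu


def predict_vital(
    glm: GLMSpec,
    state: VitalSignsState,
    profile: PatientProfile,
    thresholds: SignThresholds | None = None,
) -> float:
    """Predict one sign: linear predictor -> inverse link -> round -> clamp."""
    thresholds = thresholds or SignThresholds()
    x = glm.predictor_vector(state, profile)
    eta = eval_linear_predictor(glm, x)
    try:
        mu = apply_inverse_link(glm.link, eta, glm.use_absolute)
    except LinkDomainError as exc:
        raise LinkDomainError(f"{glm.response}: {exc}") from exc
    if glm.round_digits is not None:
        mu = round(mu, glm.round_digits) if glm.round_digits else float(round(mu))
    return thresholds.clamp(glm.response, mu)


def apply_intervention(
    state: VitalSignsState,
    sign: str,
    value: float,
    models: Mapping[str, GLMSpec],
    profile: PatientProfile,
    thresholds: SignThresholds | None = None,
) -> VitalSignsState:
    """Hold one sign at ``value`` and recompute every other modeled sign once.

    The recomputation is a single pass through each model using the
    post-intervention state as predictors (no fixed-point iteration: the
    models are mutually dependent and iterating could cycle).
    """
    thresholds = thresholds or SignThresholds()
    if sign not in state.as_dict():
        raise ValueError(f"unknown sign {sign!r}")
    if not thresholds.contains(sign, value):
        lo, hi = thresholds.ranges[sign]
        raise InterventionError(
            f"intervention on {sign} with value {value} outside valid range [{lo}, {hi}]"
        )
    held = replace(state, **{sign: float(value)})
    updates = {}
    for other, glm in models.items():
        if other == sign:
            continue
        updates[other] = predict_vital(glm, held, profile, thresholds)
    return replace(held, **updates)


# Published inverse-Gaussian GLM for respiratory rate, coefficients kept
# as their exact printed decimal strings.  Predictors: X1=hr, X2=sbp,
# X3=pt (deg C), X4=gl, group dummies X52-X54, X6=hr*sbp, X7=hr*gl.
REFERENCE_RR_MODEL = GLMSpec(
    response="rr",
    family="inverse-gaussian",
    link="inverse-squared",
    intercept=float("0.002556"),
    coefficients={
        "hr": float("-0.00005756"),
        "sbp": float("0.00005381"),
        "pt": float("-0.0001206"),
        "gl": float("-0.00001715"),
        "X52": float("-0.0009802"),
        "X53": float("-0.002567"),
        "X54": float("0.001027"),
    },
    interactions={
        "X6": (("hr", "sbp"), float("-0.0000004994")),
        "X7": (("hr", "gl"), float("0.0000001579")),
    },
    use_absolute=True,
    round_digits=0,
)
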