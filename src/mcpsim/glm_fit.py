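"""GLM fitting by IRLS, diagnostics, and packaged vital-sign models.

Two exponential-family models are used for vital signs, each with its
canonical link: inverse-Gaussian with eta = mu^-2 (respiratory rate) and
Gamma with eta = mu^-1 (the remaining signs).  Fitting is iteratively
reweighted least squares via statsmodels; the fit workflow mirrors the
usual model-quality loop (fit, inspect diagnostics, accept): residuals,
leverage, Cook's distances, and a simulated envelope for the half-normal
residual plot are all computed here.

``default_vital_models`` fits the four signs on a synthetic cohort and
packages the results as ``GLMSpec`` instances the patient model consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr

from .cohort import require_fit_ready
from .vitals import GLMSpec

FAMILIES = {
    "inverse-gaussian": ("inverse-squared", sm.families.InverseGaussian),
    "gamma": ("inverse", sm.families.Gamma),
}

FIT_TOL = 1e-8
MAX_ITER = 100


class SingularDesignError(ValueError):
    pass


@dataclass
class FitResult:
    family: str
    link: str
    params: pd.Series  # includes "const"
    bse: pd.Series
    deviance: float
    scale: float
    n_iter: int
    converged: bool
    results: object = field(repr=False, default=None)  # statsmodels GLMResults
    design_columns: list[str] = field(default_factory=list)


@dataclass
class Diagnostics:
    pearson_residuals: np.ndarray
    deviance_residuals: np.ndarray
    leverage: np.ndarray  # hat-matrix diagonal
    cooks_distance: np.ndarray
    envelope_low: np.ndarray  # 2.5% band of ordered |deviance residuals|
    envelope_high: np.ndarray  # 97.5% band
    ordered_abs_residuals: np.ndarray
    fraction_in_envelope: float


def _check_design(X: pd.DataFrame) -> None:
    mat = sm.add_constant(X, has_constant="add").to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        _, _, piv = qr(mat, pivoting=True)
        cols = ["const"] + list(X.columns)
        dependent = sorted(cols[i] for i in piv[rank:])
        raise SingularDesignError(
            f"design matrix is singular; linearly dependent columns: {dependent}"
        )


def fit_glm_irls(
    family: str,
    design: pd.DataFrame,
    response: np.ndarray | pd.Series,
    *,
    tol: float = FIT_TOL,
    max_iter: int = MAX_ITER,
) -> FitResult:
    """Fit a canonical-link GLM by IRLS.

    ``design`` holds named predictors (no intercept column; one is
    added).  The response must be strictly positive and n must exceed
    the coefficient count.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {sorted(FAMILIES)}, got {family!r}")
    link_name, fam_cls = FAMILIES[family]
    y = np.asarray(response, dtype=float)
    n_coef = design.shape[1] + 1
    if len(y) < n_coef + 1:
        raise ValueError(
            f"need at least {n_coef + 1} observations to fit {n_coef} coefficients, got {len(y)}"
        )
    if np.any(y <= 0):
        raise ValueError("response must be strictly positive for this family")
    _check_design(design)
    X = sm.add_constant(design.astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # canonical inverse links trigger DomainWarning
        model = sm.GLM(y, X, family=fam_cls())
        res = model.fit(maxiter=max_iter, tol=tol, scale="X2")
    return FitResult(
        family=family,
        link=link_name,
        params=res.params,
        bse=res.bse,
        deviance=float(res.deviance),
        scale=float(res.scale),
        n_iter=len(res.fit_history.get("deviance", [])),
        converged=bool(res.converged),
        results=res,
        design_columns=list(design.columns),
    )


def _simulate_response(family: str, mu: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    if family == "inverse-gaussian":
        # Var(y) = scale * mu^3  ->  Wald lambda = 1/scale
        return rng.wald(mu, 1.0 / scale)
    # Gamma: Var(y) = scale * mu^2  ->  shape 1/scale, scale mu*scale
    return rng.gamma(1.0 / scale, mu * scale)


def glm_diagnostics(
    fit: FitResult,
    design: pd.DataFrame,
    response: np.ndarray | pd.Series,
    *,
    n_envelope: int = 100,
    seed: int = 0,
) -> Diagnostics:
    """Residual/influence diagnostics plus a simulated envelope.

    The envelope refits the model ``n_envelope`` times on responses
    resampled from the fitted distribution and takes the 2.5%/97.5%
    bands of the ordered absolute deviance residuals.
    """
    if not fit.converged:
        raise ValueError("diagnostics require a converged fit")
    res = fit.results
    infl = res.get_influence(observed=False)
    leverage = np.asarray(infl.hat_matrix_diag)
    cooks = np.asarray(infl.cooks_distance[0])
    pearson = np.asarray(res.resid_pearson)
    devres = np.asarray(res.resid_deviance)

    rng = np.random.default_rng(seed)
    mu = np.asarray(res.fittedvalues)
    sims = np.empty((n_envelope, len(mu)))
    for b in range(n_envelope):
        y_star = _simulate_response(fit.family, mu, fit.scale, rng)
        refit = fit_glm_irls(fit.family, design, y_star)
        sims[b] = np.sort(np.abs(np.asarray(refit.results.resid_deviance)))
    low = np.quantile(sims, 0.025, axis=0)
    high = np.quantile(sims, 0.975, axis=0)
    ordered = np.sort(np.abs(devres))
    inside = np.mean((ordered >= low) & (ordered <= high))
    return Diagnostics(
        pearson_residuals=pearson,
        deviance_residuals=devres,
        leverage=leverage,
        cooks_distance=cooks,
        envelope_low=low,
        envelope_high=high,
        ordered_abs_residuals=ordered,
        fraction_in_envelope=float(inside),
    )


def build_design(cohort: pd.DataFrame, response: str, *, interactions: bool) -> tuple[pd.DataFrame, pd.Series]:
    """Predictor table for one sign's regression on the cohort.

    Main effects are the other three vital signs plus glucose, group
    dummies X52-X54 (group 1 is baseline), and optionally the hr*sbp
    (X6) and hr*gl (X7) interactions.
    """
    signs = ["hr", "rr", "sbp", "pt"]
    if response not in signs:
        raise ValueError(f"response must be one of {signs}, got {response!r}")
    mains = [s for s in signs if s != response] + ["gl"]
    X = cohort[mains].copy()
    for j in (2, 3, 4):
        X[f"X5{j}"] = (cohort["group"] == j).astype(float)
    if interactions:
        X["X6"] = cohort["hr"] * cohort["sbp"]
        X["X7"] = cohort["hr"] * cohort["gl"]
    return X, cohort[response]


def _to_spec(fit: FitResult, response: str, family: str) -> GLMSpec:
    params = fit.params
    interactions = {}
    coefficients = {}
    for name in fit.design_columns:
        if name == "X6":
            interactions["X6"] = (("hr", "sbp"), float(params[name]))
        elif name == "X7":
            interactions["X7"] = (("hr", "gl"), float(params[name]))
        else:
            coefficients[name] = float(params[name])
    return GLMSpec(
        response=response,
        family=family,
        link=fit.link,
        intercept=float(params["const"]),
        coefficients=coefficients,
        interactions=interactions,
        # |.| before the link keeps predictions defined when extreme
        # predictor combinations push the linear predictor through zero
        use_absolute=True,
        round_digits=1 if response == "pt" else 0,
    )


def default_vital_models(cohort: pd.DataFrame) -> dict[str, GLMSpec]:
    """Fit the four vital-sign GLMs on a cohort and package them.

    rr is inverse-Gaussian with the full design (4 mains, 3 group
    dummies, X6 and X7: 10 coefficients with the intercept); hr, sbp and
    pt are Gamma with the analogous main-effects designs.  Deterministic:
    the same cohort gives identical specs.
    """
    require_fit_ready(cohort)
    specs: dict[str, GLMSpec] = {}
    for response in ("rr", "hr", "sbp", "pt"):
        family = "inverse-gaussian" if response == "rr" else "gamma"
        X, y = build_design(cohort, response, interactions=(response == "rr"))
        fit = fit_glm_irls(family, X, y)
        specs[response] = _to_spec(fit, response, family)
    return specs
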