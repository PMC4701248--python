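"""Bergman minimal model of glucose-insulin kinetics.

Three compartments: blood glucose G (mg/dL), remote effective insulin
action X (1/min) and plasma insulin I (uU/mL):

    dG/dt = -p1 (G - Gb) - X G + D(t) + C(t)
    dX/dt = -p2 X + p3 (I - Ib)
    dI/dt = -n (I - Ib) [+ gamma * max(G - h, 0) * t] + tau * r(t)

D is meal glucose absorption, C glucagon infusion (both mg/dL/min), r
the exogenous insulin infusion commanded by the controller, and tau a
unit-conversion factor taking r (U/h) to a plasma concentration rate
(uU/mL/min).  The endogenous-release gamma term is off by default: the
linearized model and the equilibrium algebra used for controller design
omit it, matching the fasting/diabetic regime (no endogenous secretion).

The module also computes the operating point in closed form, the exact
state-space linearization (an upper-triangular Jacobian), and the
transfer-function view of each disturbance channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BergmanParams:
    """Minimal-model kinetic parameters.

    Defaults are this package's, taken from the canonical minimal-model
    control literature for a type-1 diabetic subject; every value is
    overridable per scenario.  tau assumes an insulin distribution
    volume of 12 L: 1 U/h = 1e6 uU / 12000 mL / 60 min = 1.389 uU/mL/min.
    """

    p1: float = 0.028735  # 1/min, glucose effectiveness at basal insulin
    p2: float = 0.028344  # 1/min, decay of remote insulin action
    p3: float = 5.035e-5  # (uU/mL)^-1 min^-2, insulin sensitivity coupling
    n: float = 0.0926  # 1/min, plasma insulin clearance
    gamma: float = 0.0039  # endogenous insulin release rate
    h: float = 79.0  # mg/dL, glucose threshold for endogenous secretion
    Gb: float = 81.0  # mg/dL, basal glucose
    Ib: float = 15.0  # uU/mL, basal insulin
    tau: float = 1e6 / 12000.0 / 60.0  # (uU/mL/min) per (U/h)

    def __post_init__(self):
        for name in ("p1", "p2", "n", "Gb", "Ib", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.p3 < 0:
            raise ValueError(f"p3 must be >= 0, got {self.p3}")


@dataclass
class GlucoseInsulinState:
    """(G, X, I) state; G is clamped at 0 (a warning is logged) if the
    integrator ever drives it negative."""

    G: float
    X: float = 0.0
    I: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.G, self.X, self.I], dtype=float)


@dataclass(frozen=True)
class DisturbanceInput:
    """Exogenous inputs: meal absorption D, glucagon C (mg/dL/min) and
    controller insulin infusion r (U/h, converted by tau)."""

    D: float = 0.0
    C: float = 0.0
    r: float = 0.0

    def __post_init__(self):
        if self.D < 0 or self.C < 0:
            raise ValueError("disturbances D and C must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.D, self.C, self.r], dtype=float)


@dataclass(frozen=True)
class OperatingPoint:
    """Equilibrium (x0, u0) of the gamma-off field; G0 and X0 double as
    the averages G-bar, X-bar of the linearized model."""

    G0: float
    X0: float
    I0: float
    D0: float = 0.0
    C0: float = 0.0
    r0: float = 0.0

    @property
    def x0(self) -> np.ndarray:
        return np.array([self.G0, self.X0, self.I0])

    @property
    def u0(self) -> np.ndarray:
        return np.array([self.D0, self.C0, self.r0])


@dataclass(frozen=True)
class StateSpaceModel:
    """Linearized model dx/dt = A (x - x0) + B (u - u0); output is the G
    channel, C_out = [1, 0, 0]."""

    A: np.ndarray
    B: np.ndarray
    op: OperatingPoint

    @property
    def output_row(self) -> np.ndarray:
        return np.array([1.0, 0.0, 0.0])


def bmm_derivatives(
    state: GlucoseInsulinState | np.ndarray,
    params: BergmanParams,
    u: DisturbanceInput | np.ndarray,
    t: float = 0.0,
    include_gamma: bool = False,
) -> np.ndarray:
    """Nonlinear minimal-model field (dG, dX, dI)."""
    G, X, I = state.as_array() if isinstance(state, GlucoseInsulinState) else np.asarray(state, float)
    D, C, r = u.as_array() if isinstance(u, DisturbanceInput) else np.asarray(u, float)
    p = params
    dG = -p.p1 * (G - p.Gb) - X * G + (D + C)
    dX = -p.p2 * X + p.p3 * (I - p.Ib)
    dI = -p.n * (I - p.Ib) + p.tau * r
    if include_gamma:
        dI += p.gamma * max(G - p.h, 0.0) * t
    return np.array([dG, dX, dI])


def linearized_derivatives(
    state: GlucoseInsulinState | np.ndarray,
    params: BergmanParams,
    u: DisturbanceInput | np.ndarray,
    op: OperatingPoint,
) -> np.ndarray:
    """Linearized field with averages G-bar = G0, X-bar = X0.

    dG/dt = -p1 (G - Gb) - Xbar G - Gbar X + Gbar Xbar + D + C; the X and
    I equations are already linear and carried over unchanged.
    """
    G, X, I = state.as_array() if isinstance(state, GlucoseInsulinState) else np.asarray(state, float)
    D, C, r = u.as_array() if isinstance(u, DisturbanceInput) else np.asarray(u, float)
    p = params
    Gbar, Xbar = op.G0, op.X0
    dG = -p.p1 * (G - p.Gb) - Xbar * G - Gbar * X + Gbar * Xbar + D + C
    dX = -p.p2 * X + p.p3 * (I - p.Ib)
    dI = -p.n * (I - p.Ib) + p.tau * r
    return np.array([dG, dX, dI])


def equilibrium_point(
    params: BergmanParams, u0: tuple[float, float, float] = (0.0, 0.0, 0.0)
) -> OperatingPoint:
    """Closed-form equilibrium of the gamma-off field for constant inputs.

        X0 = p3 tau r0 / (p2 n)
        I0 = Ib + tau r0 / n
        G0 = (p1 Gb + D0 + C0) / (p1 + X0)
    """
    D0, C0, r0 = u0
    p = params
    X0 = p.p3 * p.tau * r0 / (p.p2 * p.n)
    denom = p.p1 + X0
    if denom <= 0:
        raise ValueError(f"degenerate equilibrium denominator p1 + X0 = {denom}")
    G0 = (p.p1 * p.Gb + D0 + C0) / denom
    I0 = p.Ib + p.tau * r0 / p.n
    op = OperatingPoint(G0=G0, X0=X0, I0=I0, D0=D0, C0=C0, r0=r0)
    residual = bmm_derivatives(op.x0, params, op.u0, include_gamma=False)
    if np.max(np.abs(residual)) > 1e-9:
        raise AssertionError(f"equilibrium residual {residual} exceeds 1e-9")
    return op


def linearize(params: BergmanParams, op: OperatingPoint) -> StateSpaceModel:
    """Exact Jacobian linearization at the operating point.

    A is upper triangular with diagonal (-p1 - X0, -p2, -n), so those are
    the eigenvalues; B has unit columns on G for D and C and tau on I for r.
    """
    p = params
    A = np.array(
        [
            [-p.p1 - op.X0, -op.G0, 0.0],
            [0.0, -p.p2, p.p3],
            [0.0, 0.0, -p.n],
        ]
    )
    B = np.array(
        [
            [1.0, 1.0, 0.0],
            [0.0, 0.0, 0.0],
            [0.0, 0.0, p.tau],
        ]
    )
    return StateSpaceModel(A=A, B=B, op=op)


_CHANNELS = {"D": 0, "C": 1, "r": 2}


def ss_to_transfer_gains(model: StateSpaceModel, channel: str) -> tuple[np.ndarray, np.ndarray]:
    """Transfer function G(s) = C (sI - A)^-1 b for one input channel.

    Returns (numerator, denominator) polynomial coefficients in s,
    highest power first.  The denominator is the characteristic
    polynomial (s + p1 + X0)(s + p2)(s + n).
    """
    from scipy import signal

    if channel not in _CHANNELS:
        raise ValueError(f"channel must be one of {sorted(_CHANNELS)}, got {channel!r}")
    b = model.B[:, [_CHANNELS[channel]]]
    num, den = signal.ss2tf(model.A, b, model.output_row[None, :], np.zeros((1, 1)))
    return np.atleast_1d(np.squeeze(num)), np.asarray(den)
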