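"""Discrete PID glucose controller.

Continuous-time parallel form  G(s) = Kp + Ki/s + Kd·N·s/(s+N)  with a
first-order filter (pole at -N) on the derivative, discretized by
backward Euler.  The error convention is e = G - setpoint, so a positive
error (glucose above target) commands more insulin.  Insulin cannot be
negative: the output is clipped at 0 and the integrator is conditionally
frozen while the clip is active (anti-windup).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bergman import BergmanParams, OperatingPoint, equilibrium_point, linearize, ss_to_transfer_gains


@dataclass(frozen=True)
class PIDParams:
    Kp: float
    Ki: float = 0.0
    Kd: float = 0.0
    N: float = 10.0  # 1/min, derivative filter pole location
    setpoint: float = 81.0  # mg/dL

    def __post_init__(self):
        if self.N <= 0:
            raise ValueError(f"derivative filter coefficient N must be > 0, got {self.N}")


@dataclass(frozen=True)
class PIDState:
    integral: float = 0.0  # backward-Euler accumulator of the error, min·mg/dL
    filtered: float = 0.0  # filtered error (state of the derivative filter)


def pid_step(pid: PIDParams, state: PIDState, error: float, dt: float) -> tuple[float, PIDState]:
    """One controller update; returns (insulin command r >= 0, new state).

    Backward-Euler integral; derivative term Kd·N·(e - e_f) where the
    filtered error e_f obeys de_f/dt = N (e - e_f), also backward Euler,
    so a step in e decays geometrically with ratio 1/(1 + N·dt) — the
    discretization of the pole at -N.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    filtered = (state.filtered + pid.N * dt * error) / (1.0 + pid.N * dt)
    deriv_term = pid.Kd * pid.N * (error - filtered)
    integral = state.integral + error * dt
    u = pid.Kp * error + pid.Ki * integral + deriv_term
    if u < 0.0 and error < 0.0:
        # saturated at zero insulin and the error would wind the
        # integrator further down: freeze it at its previous value
        integral = state.integral
        u = pid.Kp * error + pid.Ki * integral + deriv_term
    return max(u, 0.0), PIDState(integral=integral, filtered=filtered)


def tune_pid(
    params: BergmanParams,
    op: OperatingPoint | None = None,
    *,
    closed_loop_tau: float | None = None,
    setpoint: float | None = None,
) -> PIDParams:
    """Model-based default gains from the linearized insulin channel.

    The r→G transfer function at the operating point is
    -G0·p3·tau / ((s+p1+X0)(s+p2)(s+n)): three stable real poles and a
    negative static gain K (insulin lowers glucose).  The rule is a
    SIMC-style PI design on the dominant pole: the slowest time constant
    tau1 is kept, the two faster lags are lumped into an effective delay
    theta, and

        Kp = tau1 / (|K| (tau_c + theta)),   Ki = Kp / min(tau1, 4 (tau_c + theta))

    with tau_c = theta by default.  Kd defaults to 0 (a PI controller is
    adequate for this overdamped plant); N stays at its default.
    """
    op = op or equilibrium_point(params)
    model = linearize(params, op)
    num, den = ss_to_transfer_gains(model, "r")
    poles = np.sort(np.abs(np.roots(den)))  # all real positive magnitudes
    gain = num[-1] / den[-1]  # static gain, negative
    K = abs(gain)
    tau1 = 1.0 / poles[0]
    theta = sum(1.0 / p for p in poles[1:]) / 2.0 + 0.0  # half-rule lumping
    tau_c = closed_loop_tau if closed_loop_tau is not None else theta
    Kp = tau1 / (K * (tau_c + theta))
    tau_i = min(tau1, 4.0 * (tau_c + theta))
    Ki = Kp / tau_i
    return PIDParams(Kp=Kp, Ki=Ki, Kd=0.0, N=10.0, setpoint=setpoint if setpoint is not None else op.G0)


def closed_loop_char_poly(params: BergmanParams, pid: PIDParams, op: OperatingPoint | None = None) -> np.ndarray:
    """Characteristic polynomial of the linear closed loop (PI part only).

    Plant P(s) = num/den on the r channel; controller C(s) = Kp + Ki/s.
    Loop sign: r = C(s)·(G - setpoint), and P's gain is negative, so the
    characteristic polynomial is s·den(s) + |num|·(Kp·s + Ki)... kept in
    the exact signed form s·den + (-num)·(Kp s + Ki).
    """
    op = op or equilibrium_point(params)
    num, den = ss_to_transfer_gains(linearize(params, op), "r")
    s_den = np.polymul(den, [1.0, 0.0])
    ctrl = np.polymul(-num, [pid.Kp, pid.Ki])
    return np.polyadd(s_den, ctrl)
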