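"""Closed-loop diabetic patient: Bergman kinetics under PID control.

Wires a continuous glucose-insulin component, a PID controller and a
disturbance schedule through the simulation engine; optionally couples
the glucose channel into a GLM vitals patient so the other vital signs
co-adjust each step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .bergman import (
    BergmanParams,
    GlucoseInsulinState,
    OperatingPoint,
    bmm_derivatives,
    equilibrium_point,
    linearized_derivatives,
)
from .components import Component, ContinuousComponent
from .engine import run_scenario
from .patient import ICUPatient
from .pid import PIDParams, PIDState, pid_step, tune_pid
from .trace import SimTrace

if TYPE_CHECKING:  # pragma: no cover
    from .engine import Simulator

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DisturbancePulse:
    """A rectangular disturbance: ``channel`` is "D" (meal absorption) or
    "C" (glucagon); magnitude in mg/dL/min, start/duration in minutes."""

    start: float
    duration: float
    channel: str = "D"
    magnitude: float = 0.0

    def __post_init__(self):
        if self.channel not in ("D", "C"):
            raise ValueError(f"channel must be 'D' or 'C', got {self.channel!r}")
        if self.magnitude < 0 or self.duration < 0:
            raise ValueError("magnitude and duration must be non-negative")

    def active(self, t: float) -> bool:
        return self.start <= t < self.start + self.duration


class GlucoseInsulinPatient(ContinuousComponent):
    """Bergman minimal model as a continuous component.

    ``linearized`` switches the field to the operating-point linearization
    (used for the dual-model validation comparison).
    """

    def __init__(
        self,
        id: str,
        params: BergmanParams,
        initial: GlucoseInsulinState | None = None,
        *,
        include_gamma: bool = False,
        linearized: bool = False,
        op: OperatingPoint | None = None,
    ):
        init = initial or GlucoseInsulinState(G=params.Gb, X=0.0, I=params.Ib)
        super().__init__(id, init.as_array(), ["G", "X", "I"])
        self.params = params
        self.include_gamma = include_gamma
        self.linearized = linearized
        self.op = op or (equilibrium_point(params) if linearized else None)
        self.input_ports = {"D": "real", "C": "real", "r": "real"}
        self.output_ports = {"G"}
        self.held_inputs = {"D": 0.0, "C": 0.0, "r": 0.0}

    def derivative(self, t: float, state: np.ndarray, inputs: dict) -> np.ndarray:
        u = np.array([inputs.get("D", 0.0), inputs.get("C", 0.0), inputs.get("r", 0.0)])
        if self.linearized:
            return linearized_derivatives(state, self.params, u, self.op)
        return bmm_derivatives(state, self.params, u, t, self.include_gamma)

    def on_tick(self, t: float, sim: "Simulator") -> None:
        if self.state[0] < 0.0:
            log.warning("glucose went negative at t=%.2f min; clamped to 0", t)
            self.state[0] = 0.0
        sim.emit(self, "G", self.state[0], t)


class PIDGlucoseController(Component):
    """Samples the measured glucose each tick and emits the insulin rate r."""

    kind = "timed-FSM"

    def __init__(self, id: str, pid: PIDParams, dt: float):
        super().__init__(id)
        self.pid = pid
        self.dt = dt
        self.state = PIDState()
        self.input_ports = {"G": "real"}
        self.output_ports = {"r"}
        self.last_r = 0.0

    def on_tick(self, t: float, sim: "Simulator") -> None:
        if "G" not in self.held_inputs:
            return  # no measurement yet (first tick)
        error = self.held_inputs["G"] - self.pid.setpoint
        self.last_r, self.state = pid_step(self.pid, self.state, error, self.dt)
        sim.emit(self, "r", self.last_r, t)


class DisturbanceGenerator(Component):
    """Emits the piecewise-constant D and C signals from a pulse schedule."""

    kind = "timed-FSM"

    def __init__(self, id: str, pulses: Sequence[DisturbancePulse] = ()):
        super().__init__(id)
        self.pulses = list(pulses)
        self.output_ports = {"D", "C"}

    def on_tick(self, t: float, sim: "Simulator") -> None:
        for channel in ("D", "C"):
            level = sum(p.magnitude for p in self.pulses if p.channel == channel and p.active(t))
            sim.emit(self, channel, level, t)


def simulate_closed_loop(
    params: BergmanParams,
    pid: PIDParams | None = None,
    disturbances: Sequence[DisturbancePulse] = (),
    initial: GlucoseInsulinState | None = None,
    horizon: float = 600.0,
    dt: float = 0.5,
    *,
    seed: int = 0,
    linearized: bool = False,
    vitals_patient: ICUPatient | None = None,
) -> SimTrace:
    """Run the glucose control loop and return the full trace.

    With no disturbance and the state at basal, glucose stays at the
    setpoint exactly (the equilibrium is a fixed point of the
    integrator).  Pass ``vitals_patient`` to co-simulate the GLM vitals:
    the glucose channel is written into it each step and the other signs
    recompute through their regression models.
    """
    pid = pid or tune_pid(params)
    patient = GlucoseInsulinPatient(
        "glucose_patient", params, initial, linearized=linearized
    )
    controller = PIDGlucoseController("pid", pid, dt)
    disturb = DisturbanceGenerator("disturbances", disturbances)
    components: list[Component] = [patient, controller, disturb]
    wiring = [
        (("glucose_patient", "G"), ("pid", "G")),
        (("pid", "r"), ("glucose_patient", "r")),
        (("disturbances", "D"), ("glucose_patient", "D")),
        (("disturbances", "C"), ("glucose_patient", "C")),
    ]
    if vitals_patient is not None:
        components.append(vitals_patient)
        wiring.append((("glucose_patient", "G"), (vitals_patient.id, "gl_in")))
    return run_scenario(components, wiring, horizon, dt, seed)
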