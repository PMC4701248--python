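"""Component contracts for the hybrid simulation kernel.

A component has an id, typed input/output ports, and one of three kinds:

* ``continuous`` — declares a state vector and a derivative function and is
  advanced by the fixed-step integrator between event times;
* ``discrete`` — reacts to input events;
* ``timed-FSM`` — a discrete component that additionally acts on every tick
  of the global clock (sensors, the insulin pump).

A port is connected to at most one upstream producer; the engine checks
required inputs are wired before t = 0.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Any

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .engine import Simulator


class Component:
    """Base contract.  Subclasses override ``on_tick`` and/or ``on_event``."""

    kind = "discrete"

    def __init__(self, id: str):
        self.id = id
        self.input_ports: dict[str, str] = {}
        self.output_ports: set[str] = set()
        self.required_inputs: set[str] = set()
        # zero-order hold of the most recent value seen on each input port
        self.held_inputs: dict[str, Any] = {}

    def initialize(self, sim: "Simulator") -> None:
        """Called once before t = 0 events are processed."""

    def on_tick(self, t: float, sim: "Simulator") -> None:
        """Called at every grid time, after continuous advance at that time."""

    def on_event(self, t: float, port: str, value: Any, sim: "Simulator") -> None:
        self.held_inputs[port] = value

    # -- recorded signals -------------------------------------------------
    def signals(self) -> dict[str, float]:
        """Signals sampled into the trace at every grid time (continuous only)."""
        return {}


class ContinuousComponent(Component):
    """Component advanced by the integrator.

    Subclasses set ``state`` (1-D ndarray), ``state_names`` and implement
    ``derivative(t, state, inputs) -> ndarray``.
    """

    kind = "continuous"

    def __init__(self, id: str, state: np.ndarray, state_names: list[str]):
        super().__init__(id)
        self.state = np.asarray(state, dtype=float)
        self.state_names = list(state_names)
        if self.state.shape != (len(self.state_names),):
            raise ValueError("state vector and state_names length mismatch")

    def derivative(self, t: float, state: np.ndarray, inputs: dict[str, Any]) -> np.ndarray:
        raise NotImplementedError

    def signals(self) -> dict[str, float]:
        return dict(zip(self.state_names, self.state))


class ConstantSource(Component):
    """Emits a constant value on port ``value`` at every tick."""

    def __init__(self, id: str, value: float):
        super().__init__(id)
        self.value = value
        self.output_ports = {"value"}

    def on_tick(self, t: float, sim: "Simulator") -> None:
        sim.emit(self, "value", self.value, t)


class Relay(Component):
    """Pass-through aggregation: forwards every input event on port ``out``.

    Models the data centralizer and bedside monitor, which the source
    clinical scenario treats as plain relays/displays.
    """

    def __init__(self, id: str, inputs: list[str]):
        super().__init__(id)
        self.input_ports = {name: "real" for name in inputs}
        self.output_ports = {"out"}

    def on_event(self, t: float, port: str, value: Any, sim: "Simulator") -> None:
        super().on_event(t, port, value, sim)
        sim.emit(self, "out", (port, value), t)
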