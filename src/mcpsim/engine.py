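"""Hybrid simulation engine.

A global clock sweeps a fixed grid t = 0, dt, 2·dt, …, horizon.  At each
grid time the engine first advances every continuous component one RK4
step (continuous update before discrete events at the same timestamp),
then gives timed components their tick, then drains all events due at or
before that time in FIFO order.  The trace is a pure function of the
scenario and the root seed; per-component random substreams are derived
from (seed, crc32(component id)) so adding a component does not perturb
the draws of the others.
"""

from __future__ import annotations

import zlib
from typing import Any, Iterable, Sequence

import numpy as np

from .components import Component, ContinuousComponent
from .events import EventQueue, SimEvent
from .trace import SimTrace

_TIME_TOL = 1e-9


class ConfigurationError(ValueError):
    """Invalid wiring or scenario setup, detected before t = 0."""


class NumericalError(RuntimeError):
    """Non-finite derivative or state during integration."""


def rk4_step(f, t: float, y: np.ndarray, dt: float, inputs: dict[str, Any]) -> np.ndarray:
    """One classical Runge–Kutta step of the field ``f(t, y, inputs)``."""
    k1 = np.asarray(f(t, y, inputs), dtype=float)
    k2 = np.asarray(f(t + dt / 2, y + dt / 2 * k1, inputs), dtype=float)
    k3 = np.asarray(f(t + dt / 2, y + dt / 2 * k2, inputs), dtype=float)
    k4 = np.asarray(f(t + dt, y + dt * k3, inputs), dtype=float)
    return y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)


def advance_continuous(
    component: ContinuousComponent,
    state: np.ndarray,
    inputs: dict[str, Any],
    dt: float,
    t: float = 0.0,
) -> np.ndarray:
    """Advance one continuous component one integrator step.

    Inputs are held constant over the step (zero-order hold).  A
    non-finite derivative aborts with a state dump.
    """
    d0 = np.asarray(component.derivative(t, np.asarray(state, float), inputs), float)
    if not np.all(np.isfinite(d0)):
        raise NumericalError(
            f"non-finite derivative in component {component.id!r} at t={t}: "
            f"state={np.asarray(state)}, derivative={d0}"
        )
    new = rk4_step(component.derivative, t, np.asarray(state, float), dt, inputs)
    if not np.all(np.isfinite(new)):
        raise NumericalError(
            f"integration blow-up in component {component.id!r} at t={t}: state={new}"
        )
    return new


class Simulator:
    """Owns the clock, the event queue, the wiring and the trace."""

    def __init__(
        self,
        components: Sequence[Component],
        connections: Iterable[tuple[tuple[str, str], tuple[str, str]]] = (),
        *,
        seed: int = 0,
    ):
        self.components: dict[str, Component] = {}
        for c in components:
            if c.id in self.components:
                raise ConfigurationError(f"duplicate component id {c.id!r}")
            self.components[c.id] = c
        # (src id, src port) -> list of (dst id, dst port)
        self.connections: dict[tuple[str, str], list[tuple[str, str]]] = {}
        seen_dst: set[tuple[str, str]] = set()
        for (src, sport), (dst, dport) in connections:
            for cid, role in ((src, "source"), (dst, "destination")):
                if cid not in self.components:
                    raise ConfigurationError(f"unknown {role} component {cid!r} in wiring")
            if (dst, dport) in seen_dst:
                raise ConfigurationError(
                    f"input port {dst}.{dport} has more than one upstream producer"
                )
            seen_dst.add((dst, dport))
            self.connections.setdefault((src, sport), []).append((dst, dport))
        self.seed = int(seed)
        self.queue = EventQueue()
        self.now = 0.0
        self.trace = SimTrace(seed=self.seed)
        self._check_required_inputs(seen_dst)

    def _check_required_inputs(self, wired: set[tuple[str, str]]) -> None:
        for c in self.components.values():
            for port in c.required_inputs:
                if (c.id, port) not in wired:
                    raise ConfigurationError(
                        f"required input port {c.id}.{port} is not connected"
                    )

    def rng(self, component_id: str) -> np.random.Generator:
        """Deterministic per-component substream of the root seed."""
        key = zlib.crc32(component_id.encode("utf-8"))
        return np.random.default_rng(np.random.SeedSequence((self.seed, key)))

    def emit(self, component: Component, port: str, value: Any, t: float, delay: float = 0.0) -> None:
        """Emit an output event; it is recorded and delivered at t + delay."""
        self.queue.push(SimEvent(t + delay, component.id, port, value), now=self.now)

    def run(self, horizon: float, dt: float) -> SimTrace:
        if dt <= 0 or horizon <= 0:
            raise ConfigurationError(f"dt and horizon must be positive (dt={dt}, horizon={horizon})")
        self.trace.horizon = horizon
        self.trace.dt = dt
        n_steps = int(round(horizon / dt))
        if abs(n_steps * dt - horizon) > _TIME_TOL * max(1.0, horizon):
            raise ConfigurationError(f"horizon {horizon} is not a multiple of dt {dt}")

        for c in self.components.values():
            c.initialize(self)

        for k in range(n_steps + 1):
            t = k * dt
            self.now = t
            if k > 0:
                for c in self.components.values():
                    if isinstance(c, ContinuousComponent):
                        c.state = advance_continuous(c, c.state, c.held_inputs, dt, t - dt)
            # sample every continuous signal at every grid time
            for c in self.components.values():
                for name, val in c.signals().items():
                    self.trace.record(t, c.id, name, val)
            for c in self.components.values():
                c.on_tick(t, self)
            self._drain(t)
        return self.trace

    def _drain(self, t: float) -> None:
        while True:
            nt = self.queue.peek_time()
            if nt is None or nt > t + _TIME_TOL:
                return
            ev = self.queue.pop()
            self.trace.record(t, ev.source, ev.port, ev.value)
            for dst, dport in self.connections.get((ev.source, ev.port), []):
                self.components[dst].on_event(t, dport, ev.value, self)


def run_scenario(
    components: Sequence[Component],
    connections: Iterable[tuple[tuple[str, str], tuple[str, str]]],
    horizon: float,
    dt: float,
    seed: int,
) -> SimTrace:
    """Build a simulator, run it over [0, horizon] and return the trace.

    Identical components, wiring and seed give a bitwise-identical trace.
    """
    sim = Simulator(components, connections, seed=seed)
    return sim.run(horizon, dt)
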