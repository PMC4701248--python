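"""ICU patient model as a simulation component.

Holds a vital-signs state and a set of per-sign GLMs.  The state only
changes through interventions: a user (or an upstream glucose model)
writes one sign, and every other modeled sign is recomputed once through
its regression model.  Each tick the component publishes every sign on
its output port of the same name, which is what the sensor models sample.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Any, Mapping

from .components import Component
from .vitals import (
    GLMSpec,
    PatientProfile,
    SignThresholds,
    VitalSignsState,
    apply_intervention,
)

if TYPE_CHECKING:  # pragma: no cover
    from .engine import Simulator


class ICUPatient(Component):
    """GLM-driven patient.

    Input ports: ``set_<sign>`` for user interventions and ``gl_in`` for
    a coupled glucose model (values are clamped to the glucose
    thresholds before being applied, since a kinetic model can transiently
    leave the regression model's calibration range).
    Output ports: one per sign (hr, rr, sbp, pt, gl).
    """

    kind = "timed-FSM"

    def __init__(
        self,
        id: str,
        models: Mapping[str, GLMSpec],
        profile: PatientProfile | None = None,
        initial: VitalSignsState | None = None,
        thresholds: SignThresholds | None = None,
    ):
        super().__init__(id)
        self.models = dict(models)
        self.profile = profile or PatientProfile()
        self.state = initial or VitalSignsState()
        self.thresholds = thresholds or SignThresholds()
        self.output_ports = set(self.state.as_dict())
        self.input_ports = {f"set_{s}": "real" for s in self.state.as_dict()}
        self.input_ports["gl_in"] = "real"

    def on_event(self, t: float, port: str, value: Any, sim: "Simulator") -> None:
        super().on_event(t, port, value, sim)
        if port == "gl_in":
            clamped = self.thresholds.clamp("gl", float(value))
            self.state = apply_intervention(
                self.state, "gl", clamped, self.models, self.profile, self.thresholds
            )
        elif port.startswith("set_"):
            sign = port[4:]
            self.state = apply_intervention(
                self.state, sign, float(value), self.models, self.profile, self.thresholds
            )

    def on_tick(self, t: float, sim: "Simulator") -> None:
        for sign, value in self.state.as_dict().items():
            sim.emit(self, sign, value, t)
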