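"""Periodic medical sensors.

A sensor samples one patient signal on a fixed period; its local
sampling clock is aligned to the global simulation clock, so a
measurement is emitted exactly when t is a multiple of the period and
carries the signal value at exactly that instant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Any

from .components import Component
from .engine import ConfigurationError

if TYPE_CHECKING:  # pragma: no cover
    from .engine import Simulator

KNOWN_SIGNALS = ("hr", "rr", "sbp", "pt", "gl", "G")

_TOL = 1e-9


@dataclass(frozen=True)
class SensorConfig:
    id: str
    signal: str  # monitored signal name
    period: float  # minutes

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError(f"sensor period must be > 0, got {self.period}")
        if self.signal not in KNOWN_SIGNALS:
            raise ConfigurationError(
                f"sensor {self.id!r} monitors unknown signal {self.signal!r}; "
                f"known signals: {KNOWN_SIGNALS}"
            )


@dataclass(frozen=True)
class Measurement:
    time: float
    signal: str
    value: float
    sensor_id: str


def sensor_sample(sensor: SensorConfig, value: float, t: float) -> Measurement | None:
    """Emit a measurement iff t lies on the sensor's sampling grid."""
    if t < 0:
        raise ValueError(f"negative time {t}")
    k = round(t / sensor.period)
    if abs(t - k * sensor.period) > _TOL * max(1.0, t):
        return None
    return Measurement(time=t, signal=sensor.signal, value=value, sensor_id=sensor.id)


class Sensor(Component):
    """Engine component: samples its input port on the configured period
    and emits ``measurement`` events.

    Sampling happens on delivery of the monitored signal (the patient
    publishes each sign every tick), so the measured value is the signal
    value at exactly the sampling instant, including t = 0.
    """

    kind = "timed-FSM"

    def __init__(self, config: SensorConfig):
        super().__init__(config.id)
        self.config = config
        self.input_ports = {"in": "real"}
        self.required_inputs = {"in"}
        self.output_ports = {"measurement"}

    def on_event(self, t: float, port: str, value: Any, sim: "Simulator") -> None:
        super().on_event(t, port, value, sim)
        if port != "in":
            return
        m = sensor_sample(self.config, value, t)
        if m is not None:
            sim.emit(self, "measurement", m.value, t)
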