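"""Insulin pump: a timed extended state machine.

The pump delivers insulin in three strategies — continuous *basal*
background doses, scheduled mealtime *standard boluses*, and on-demand
*corrective boluses* — from a cartridge of U100 insulin (100 U/mL; the
default 3.15 mL cartridge holds 315 U).  Operating modes are STOP and
EXECUTING.  The cartridge status (FULL / NORMAL / LOW / EMPTY) gates the
mode: the pump may only (re)start while FULL or NORMAL, and stops one
tick after the status enters LOW or EMPTY.  A delivery whose dose
exceeds the remaining level is refused entirely (no partial dosing) and
stops the pump immediately.

The per-tick step decomposes into the functions ``pump_transition``
(Controller), ``get_strategy_adm_insulin``, ``get_adm_dose``,
``get_adm_period``, ``administer_dose``, ``check_cartridge_level`` and
``reset_count``; each boolean guard is an instrumented decision site so
structural coverage (DC/CC/MCDC) of a simulation can be reported.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Any

from .components import Component
from .coverage import CoverageRecorder

if TYPE_CHECKING:  # pragma: no cover
    from .engine import Simulator

MINUTES_PER_DAY = 1440
STANDARD_BASAL_PERIOD = 3.0  # minutes between fixed basal doses (480/day)
CUSTOMIZED_BASAL_PERIOD = 60.0  # one flexible dose per hour (24/day)
DOSES_PER_DAY_STANDARD = 480


class PumpMode(str, enum.Enum):
    STOP = "STOP"
    EXECUTING = "EXECUTING"


class CartridgeStatus(str, enum.Enum):
    FULL = "FULL"
    NORMAL = "NORMAL"
    LOW = "LOW"
    EMPTY = "EMPTY"


class Strategy(str, enum.Enum):
    BASAL = "BASAL"
    STAND_BOLUS = "STAND_BOLUS"
    CORREC_BOLUS = "CORREC_BOLUS"


ALERT_EMPTY = "Cartridge Empty!"
ALERT_LOW = "Cartridge Low Warning!"
ALERT_OK = "Cartridge Ok!"

BASAL_RATE_MIN = 0.1  # U/h
BASAL_RATE_MAX = 25.0  # U/h
BOLUS_MAX = 25.0  # U


@dataclass(frozen=True)
class PumpConfig:
    """Insulin pump settings; all bounds are enforced at construction."""

    cartridge_ml: float = 3.15
    basal_profile: str = "standard"  # "standard" | "customized"
    basal_rate: float = 1.0  # U/h, standard profile
    basal_rates: tuple[float, ...] | None = None  # 24 hourly U/h, customized
    standard_bolus: float = 4.0  # U
    corrective_bolus: float = 2.0  # U
    bolus_times: tuple[float, ...] = ()  # minutes of day for standard boluses
    low_threshold_fraction: float = 0.10  # LOW at level <= 10% of capacity
    warn_only_on_low: bool = False  # if True, LOW warns but does not stop

    def __post_init__(self):
        if self.cartridge_ml <= 0:
            raise ValueError("cartridge capacity must be positive")
        if self.basal_profile not in ("standard", "customized"):
            raise ValueError(f"unknown basal profile {self.basal_profile!r}")
        rates = self.basal_rates if self.basal_profile == "customized" else (self.basal_rate,)
        if self.basal_profile == "customized":
            if rates is None or len(rates) != 24:
                raise ValueError("customized profile needs 24 hourly basal rates")
        for r in rates:
            if not BASAL_RATE_MIN <= r <= BASAL_RATE_MAX:
                raise ValueError(
                    f"basal rate {r} U/h outside [{BASAL_RATE_MIN}, {BASAL_RATE_MAX}]"
                )
        for name, dose in (("standard_bolus", self.standard_bolus),
                           ("corrective_bolus", self.corrective_bolus)):
            if not 0 <= dose <= BOLUS_MAX:
                raise ValueError(f"{name} {dose} U outside [0, {BOLUS_MAX}]")
        if not 0 < self.low_threshold_fraction < 1:
            raise ValueError("low_threshold_fraction must be in (0, 1)")

    @property
    def capacity(self) -> float:
        """Cartridge capacity in insulin units (U100: 100 U per mL)."""
        return self.cartridge_ml * 100.0

    @property
    def low_threshold(self) -> float:
        return self.low_threshold_fraction * self.capacity


@dataclass(frozen=True)
class DeliveryCommand:
    strategy: Strategy
    dose: float  # programmed dose, U
    adm_profile: str = "standard"


@dataclass(frozen=True)
class PumpState:
    """Runtime pump state.  The cartridge level is derived as
    initial_level - cumulative so conservation holds bitwise."""

    mode: PumpMode = PumpMode.STOP
    initial_level: float = 315.0
    cumulative: float = 0.0  # total insulin administered, U
    status: CartridgeStatus = CartridgeStatus.FULL
    alerts: tuple[str, ...] = ()
    dose_count: int = 0

    @property
    def level(self) -> float:
        return self.initial_level - self.cumulative


class StateCorruptionError(RuntimeError):
    pass


def register_pump_sites(recorder: CoverageRecorder) -> CoverageRecorder:
    """Register every instrumented decision of the pump logic."""
    r = recorder
    r.register_site("checkCartridgeLevel/[level == 0]", ["level == 0"])
    r.register_site("checkCartridgeLevel/[level <= low]", ["level <= low"])
    r.register_site("getStrategyAdmInsulin/[corrective]", ["corrective"])
    r.register_site("getStrategyAdmInsulin/[bolus_due]", ["bolus_due"])
    r.register_site("getStrategyAdmInsulin/[basal_due]", ["basal_due"])
    r.register_site("getAdmDose/[strategy==STAND_BOLUS]", ["strategy==STAND_BOLUS"])
    r.register_site("getAdmDose/[strategy==CORREC_BOLUS]", ["strategy==CORREC_BOLUS"])
    r.register_site("getAdmPeriod/[profile==standard]", ["profile==standard"])
    r.register_site("administerInsulinDose/[level >= dose]", ["level >= dose"])
    r.register_site(
        "Controller/[status == LOW || status == EMPTY]",
        ["status == LOW", "status == EMPTY"],
        lambda v: v[0] or v[1],
    )
    r.register_site(
        "Controller/[status == FULL || status == NORMAL]",
        ["status == FULL", "status == NORMAL"],
        lambda v: v[0] or v[1],
    )
    r.register_site("resetCount/[count >= daily limit]", ["count >= daily limit"])
    return r


def check_cartridge_level(
    level: float, config: PumpConfig, recorder: CoverageRecorder | None = None, t: float = 0.0
) -> tuple[CartridgeStatus, str]:
    """Classify the cartridge level and produce the matching alert."""
    if level < 0 or level > config.capacity:
        raise StateCorruptionError(
            f"cartridge level {level} outside [0, {config.capacity}]"
        )
    is_empty = level == 0
    is_low = level <= config.low_threshold
    if recorder is not None:
        recorder.evaluate("checkCartridgeLevel/[level == 0]", t, **{"level == 0": is_empty})
        if not is_empty:
            recorder.evaluate("checkCartridgeLevel/[level <= low]", t, **{"level <= low": is_low})
    if is_empty:
        return CartridgeStatus.EMPTY, ALERT_EMPTY
    if is_low:
        return CartridgeStatus.LOW, ALERT_LOW
    if level == config.capacity:
        return CartridgeStatus.FULL, ALERT_OK
    return CartridgeStatus.NORMAL, ALERT_OK


def get_adm_period(
    config: PumpConfig, recorder: CoverageRecorder | None = None, t: float = 0.0
) -> float:
    """Basal administration period in minutes for the configured profile."""
    is_standard = config.basal_profile == "standard"
    if recorder is not None:
        recorder.evaluate("getAdmPeriod/[profile==standard]", t, **{"profile==standard": is_standard})
    return STANDARD_BASAL_PERIOD if is_standard else CUSTOMIZED_BASAL_PERIOD


def get_adm_dose(
    strategy: Strategy,
    config: PumpConfig,
    recorder: CoverageRecorder | None = None,
    t: float = 0.0,
) -> float:
    """Programmed dose in U for one delivery of the given strategy."""
    is_stand = strategy is Strategy.STAND_BOLUS
    is_correc = strategy is Strategy.CORREC_BOLUS
    if recorder is not None:
        recorder.evaluate("getAdmDose/[strategy==STAND_BOLUS]", t, **{"strategy==STAND_BOLUS": is_stand})
        if not is_stand:
            recorder.evaluate(
                "getAdmDose/[strategy==CORREC_BOLUS]", t, **{"strategy==CORREC_BOLUS": is_correc}
            )
    if is_stand:
        return config.standard_bolus
    if is_correc:
        return config.corrective_bolus
    period = get_adm_period(config, recorder, t)
    if config.basal_profile == "standard":
        return config.basal_rate * period / 60.0
    hour = int(t // 60) % 24
    return config.basal_rates[hour] * period / 60.0


def get_strategy_adm_insulin(
    t: float,
    config: PumpConfig,
    corrective_requested: bool = False,
    recorder: CoverageRecorder | None = None,
) -> DeliveryCommand | None:
    """Decide which delivery (if any) is due at minute ``t``.

    Corrective boluses preempt everything; a scheduled standard bolus
    preempts basal; basal doses fall at the *end* of each period (t = 3,
    6, … for the standard profile; on the hour for customized), giving
    exactly 480 and 24 doses respectively over a 24 h day.
    """
    period = get_adm_period(config, recorder, t)
    bolus_due = any(abs(t - bt) < 1e-9 for bt in config.bolus_times)
    basal_due = t > 0 and abs(t / period - round(t / period)) < 1e-9
    if recorder is not None:
        recorder.evaluate("getStrategyAdmInsulin/[corrective]", t, corrective=corrective_requested)
        if not corrective_requested:
            recorder.evaluate("getStrategyAdmInsulin/[bolus_due]", t, bolus_due=bolus_due)
            if not bolus_due:
                recorder.evaluate("getStrategyAdmInsulin/[basal_due]", t, basal_due=basal_due)
    if corrective_requested:
        return DeliveryCommand(Strategy.CORREC_BOLUS, get_adm_dose(Strategy.CORREC_BOLUS, config, recorder, t), config.basal_profile)
    if bolus_due:
        return DeliveryCommand(Strategy.STAND_BOLUS, get_adm_dose(Strategy.STAND_BOLUS, config, recorder, t), config.basal_profile)
    if basal_due:
        return DeliveryCommand(Strategy.BASAL, get_adm_dose(Strategy.BASAL, config, recorder, t), config.basal_profile)
    return None


def administer_dose(
    state: PumpState,
    cmd: DeliveryCommand,
    recorder: CoverageRecorder | None = None,
    t: float = 0.0,
) -> tuple[PumpState, float]:
    """Attempt one delivery; returns (new state, insulin actually delivered).

    A dose larger than the remaining level delivers nothing and stops the
    pump (no partial dosing: the administered dose must always equal the
    programmed dose).
    """
    if cmd.dose < 0:
        raise ValueError(f"negative dose {cmd.dose}")
    if state.mode is not PumpMode.EXECUTING:
        raise ValueError("administer_dose requires the pump to be EXECUTING")
    sufficient = state.level >= cmd.dose
    if recorder is not None:
        recorder.evaluate("administerInsulinDose/[level >= dose]", t, **{"level >= dose": sufficient})
    if not sufficient:
        return replace(state, mode=PumpMode.STOP), 0.0
    new = replace(state, cumulative=state.cumulative + cmd.dose, dose_count=state.dose_count + 1)
    return new, cmd.dose


def reset_count(
    state: PumpState, recorder: CoverageRecorder | None = None, t: float = 0.0
) -> PumpState:
    """Reset the daily dose counter once it reaches the per-day maximum."""
    hit = state.dose_count >= DOSES_PER_DAY_STANDARD
    if recorder is not None:
        recorder.evaluate("resetCount/[count >= daily limit]", t, **{"count >= daily limit": hit})
    return replace(state, dose_count=0) if hit else state


def pump_transition(
    state: PumpState,
    user_command: str | None = None,
    config: PumpConfig | None = None,
    recorder: CoverageRecorder | None = None,
    t: float = 0.0,
) -> PumpState:
    """Controller mode logic.

    ``Run`` is accepted only while the cartridge is FULL or NORMAL;
    ``Stop`` always.  While EXECUTING, the pump stops when the status is
    LOW or EMPTY (unless configured to only warn on LOW).
    """
    status = state.status
    stop_on_low = not (config is not None and config.warn_only_on_low)
    if state.mode is PumpMode.EXECUTING:
        is_low, is_empty = status is CartridgeStatus.LOW, status is CartridgeStatus.EMPTY
        guard = (is_low and stop_on_low) or is_empty
        if recorder is not None:
            recorder.evaluate(
                "Controller/[status == LOW || status == EMPTY]",
                t,
                **{"status == LOW": is_low and stop_on_low, "status == EMPTY": is_empty},
            )
        if guard or user_command == "Stop":
            return replace(state, mode=PumpMode.STOP)
        return state
    # STOP mode
    if user_command == "Run":
        is_full = status is CartridgeStatus.FULL
        is_normal = status is CartridgeStatus.NORMAL
        if recorder is not None:
            recorder.evaluate(
                "Controller/[status == FULL || status == NORMAL]",
                t,
                **{"status == FULL": is_full, "status == NORMAL": is_normal},
            )
        if is_full or is_normal:
            return replace(state, mode=PumpMode.EXECUTING)
    return state


def pump_step(
    state: PumpState,
    config: PumpConfig,
    t: float,
    inputs: dict[str, Any] | None = None,
    recorder: CoverageRecorder | None = None,
) -> tuple[PumpState, dict[str, Any]]:
    """One scheduler tick of the pump.

    The mode transition is evaluated against the *previous* tick's
    cartridge status, so a status change to LOW/EMPTY stops the pump on
    the next tick (the one-tick stop delay).  While EXECUTING, the due
    delivery is administered atomically, then the cartridge is
    re-classified and the alert emitted on change.
    """
    inputs = inputs or {}
    state = pump_transition(state, inputs.get("user_command"), config, recorder, t)
    delivered = 0.0
    strategy = None
    programmed = None
    if state.mode is PumpMode.EXECUTING:
        cmd = get_strategy_adm_insulin(t, config, bool(inputs.get("corrective", False)), recorder)
        if cmd is not None:
            strategy = cmd.strategy.value
            programmed = cmd.dose
            state, delivered = administer_dose(state, cmd, recorder, t)
            state = reset_count(state, recorder, t)
    status, alert = check_cartridge_level(state.level, config, recorder, t)
    new_alert = alert if status is not state.status else None
    alerts = state.alerts + (alert,) if new_alert else state.alerts
    state = replace(state, status=status, alerts=alerts)
    outputs = {
        "insulinPumpStatus": state.mode.value,
        "cartridgeStatus": state.status.value,
        "administered": delivered,
        "programmed": programmed,
        "strategy": strategy,
        "level": state.level,
        "cumulative": state.cumulative,
        "alert": new_alert,
    }
    return state, outputs


class InsulinPump(Component):
    """Engine component wrapping the pump state machine.

    Input ports follow the device interface: ``admProfile``, ``baid``,
    ``boid``, ``cboid`` (dose programming), plus ``user_command`` and
    ``corrective`` triggers.  Outputs: ``insulinPumpStatus``,
    ``cartridgeStatus``, ``administered``, plus bookkeeping signals
    (level, programmed, strategy) consumed by the safety monitors.
    """

    kind = "timed-FSM"

    def __init__(
        self,
        id: str,
        config: PumpConfig,
        *,
        start_running: bool = True,
        recorder: CoverageRecorder | None = None,
        delivery_log: list | None = None,
    ):
        super().__init__(id)
        self.config = config
        self.recorder = recorder
        if recorder is not None and not recorder.sites:
            register_pump_sites(recorder)
        level0 = config.capacity
        self.state = PumpState(
            mode=PumpMode.EXECUTING if start_running else PumpMode.STOP,
            initial_level=level0,
            status=CartridgeStatus.FULL,
        )
        self.input_ports = {
            "admProfile": "token", "baid": "real", "boid": "real", "cboid": "real",
            "user_command": "token", "corrective": "bool",
        }
        self.output_ports = {
            "insulinPumpStatus", "cartridgeStatus", "administered", "level",
            "programmed", "strategy", "alert", "cumulative",
        }
        self.delivery_log = delivery_log if delivery_log is not None else []

    def on_tick(self, t: float, sim: "Simulator") -> None:
        inputs = {
            "user_command": self.held_inputs.pop("user_command", None),
            "corrective": self.held_inputs.pop("corrective", False),
        }
        self.state, outputs = pump_step(self.state, self.config, t, inputs, self.recorder)
        for port, value in outputs.items():
            sim.emit(self, port, value, t)
        if outputs["administered"] > 0:
            self.delivery_log.append(
                {"time": t, "strategy": outputs["strategy"], "dose": outputs["administered"],
                 "level_after": self.state.level}
            )
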