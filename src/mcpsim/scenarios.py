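"""Bundled clinical scenarios, configuration loading and result export.

Three proof-of-concept contexts are provided:

* ``icu_monitoring`` — an ICU patient publishing five signals, sampled by
  five periodic sensors, relayed through a data centralizer to a bedside
  monitor.  No actuators.
* ``insulin_pump`` — the insulin pump programmed by a daily-dose
  calculator from the patient profile; the run produces delivery logs,
  safety verdicts for SR1-SR3/A1 and a structural coverage report.
* ``diabetic_closed_loop`` — the Bergman glucose-insulin patient under
  PID control with meal/glucagon disturbances; the glucose channel is
  coupled into the GLM vitals so the other signs co-adjust.

Scenario files are YAML; the seed is mandatory and all device bounds are
validated at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Any

import pandas as pd
import yaml

from .closed_loop import DisturbancePulse, simulate_closed_loop
from .cohort import CohortSpec, generate_cohort
from .components import Component, Relay
from .coverage import CoverageRecorder, CoverageReport, compute_coverage
from .dose_calc import DoseCalculatorConfig, insulin_dose_calculator
from .engine import ConfigurationError, run_scenario
from .glm_fit import default_vital_models
from .bergman import BergmanParams, GlucoseInsulinState
from .patient import ICUPatient
from .pid import PIDParams, tune_pid
from .pump import InsulinPump, PumpConfig, register_pump_sites
from .safety import Verdict, verify_all
from .sensors import Sensor, SensorConfig
from .trace import SimTrace
from .vitals import REFERENCE_RR_MODEL, GLMSpec, PatientProfile, VitalSignsState

if TYPE_CHECKING:  # pragma: no cover
    from .engine import Simulator

SCENARIO_IDS = ("icu_monitoring", "insulin_pump", "diabetic_closed_loop")

_DEFAULTS = {
    "icu_monitoring": {"horizon": 60.0, "dt": 1.0},
    "insulin_pump": {"horizon": 1440.0, "dt": 1.0},
    "diabetic_closed_loop": {"horizon": 600.0, "dt": 0.5},
}


@dataclass
class ScenarioConfig:
    scenario: str
    seed: int
    horizon: float
    dt: float
    patient: dict[str, Any] = field(default_factory=dict)
    initial_vitals: dict[str, float] = field(default_factory=dict)
    sensors: list[dict[str, Any]] = field(default_factory=list)
    pump: dict[str, Any] = field(default_factory=dict)
    dose_calculator: dict[str, Any] = field(default_factory=dict)
    bergman: dict[str, Any] = field(default_factory=dict)
    pid: dict[str, Any] | None = None
    disturbances: list[dict[str, Any]] = field(default_factory=list)
    interventions: list[dict[str, Any]] = field(default_factory=list)
    corrective_times: list[float] = field(default_factory=list)
    fit_vitals: bool = False
    cohort_n: int = 200
    out: str | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIO_IDS:
            raise ConfigurationError(
                f"scenario: unknown id {self.scenario!r}; known: {SCENARIO_IDS}"
            )
        if self.seed is None:
            raise ConfigurationError("seed: a seed is mandatory in every scenario")
        if self.horizon <= 0 or self.dt <= 0:
            raise ConfigurationError("horizon and dt must be positive")
        # constructing the device configs validates every bound now
        self.pump_config()
        if self.patient:
            PatientProfile(**{k: self.patient[k] for k in ("gender", "weight", "height", "group") if k in self.patient})

    def pump_config(self) -> PumpConfig:
        return PumpConfig(**self.pump)

    def profile(self) -> PatientProfile:
        keys = ("gender", "weight", "height", "group")
        return PatientProfile(**{k: self.patient[k] for k in keys if k in self.patient})

    def bergman_params(self) -> BergmanParams:
        return BergmanParams(**self.bergman)


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Parse and validate a YAML scenario file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: scenario file must be a mapping")
    if "scenario" not in raw:
        raise ConfigurationError(f"{path}: missing field 'scenario'")
    if "seed" not in raw:
        raise ConfigurationError(f"{path}: missing field 'seed' (mandatory)")
    sid = raw["scenario"]
    if sid not in SCENARIO_IDS:
        raise ConfigurationError(f"{path}: scenario: unknown id {sid!r}")
    defaults = _DEFAULTS[sid]
    known = {f.name for f in ScenarioConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown fields {sorted(unknown)}")
    merged = {**defaults, **raw}
    try:
        return ScenarioConfig(**merged)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def default_scenario(scenario: str, seed: int = 42, **overrides: Any) -> ScenarioConfig:
    """A ready-to-run configuration for one of the bundled contexts."""
    cfg = {"scenario": scenario, "seed": seed, **_DEFAULTS[scenario], **overrides}
    return ScenarioConfig(**cfg)


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    trace: SimTrace
    verdicts: dict[str, Verdict] = field(default_factory=dict)
    coverage: CoverageReport | None = None
    delivery_log: list[dict[str, Any]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(v.holds for v in self.verdicts.values())


class _EventScheduler(Component):
    """Emits pre-programmed (time, port, value) events (user interventions,
    corrective-bolus button presses)."""

    kind = "timed-FSM"

    def __init__(self, id: str, schedule: list[tuple[float, str, Any]]):
        super().__init__(id)
        self.schedule = sorted(schedule)
        self.output_ports = {p for _, p, _ in schedule}

    def on_tick(self, t: float, sim: "Simulator") -> None:
        for when, port, value in self.schedule:
            if abs(when - t) < 1e-9:
                sim.emit(self, port, value, t)


def _vitals_models(config: ScenarioConfig) -> dict[str, GLMSpec]:
    models = {"rr": REFERENCE_RR_MODEL}
    if config.fit_vitals:
        cohort = generate_cohort(CohortSpec(n=config.cohort_n, seed=config.seed))
        fitted = default_vital_models(cohort)
        fitted["rr"] = REFERENCE_RR_MODEL
        return fitted
    return models


def _run_icu_monitoring(config: ScenarioConfig) -> ScenarioResult:
    patient = ICUPatient(
        "patient",
        _vitals_models(config),
        profile=config.profile(),
        initial=VitalSignsState(**config.initial_vitals) if config.initial_vitals else None,
    )
    sensor_specs = config.sensors or [
        {"id": f"{sig}_sensor", "signal": sig, "period": 3.0} for sig in ("hr", "rr", "sbp", "pt", "gl")
    ]
    sensors = [Sensor(SensorConfig(**s)) for s in sensor_specs]
    centralizer = Relay("centralizer", [s.id for s in sensors])
    bedside = Relay("bedside_monitor", ["in"])
    components: list[Component] = [patient, *sensors, centralizer, bedside]
    wiring = [(("patient", s.config.signal), (s.id, "in")) for s in sensors]
    wiring += [((s.id, "measurement"), ("centralizer", s.id)) for s in sensors]
    wiring.append((("centralizer", "out"), ("bedside_monitor", "in")))
    if config.interventions:
        sched = _EventScheduler(
            "interventions",
            [(iv["time"], f"set_{iv['sign']}", iv["value"]) for iv in config.interventions],
        )
        components.append(sched)
        wiring += [
            ((sched.id, f"set_{iv['sign']}"), ("patient", f"set_{iv['sign']}"))
            for iv in config.interventions
        ]
    trace = run_scenario(components, wiring, config.horizon, config.dt, config.seed)
    return ScenarioResult(config=config, trace=trace)


def _run_insulin_pump(config: ScenarioConfig) -> ScenarioResult:
    profile = config.profile()
    gl0 = config.initial_vitals.get("gl", 119.0)
    doses = insulin_dose_calculator(profile, gl0, DoseCalculatorConfig(**config.dose_calculator))
    pump_kwargs = dict(config.pump)
    pump_kwargs.setdefault("basal_rate", round(doses.baid, 3))
    pump_kwargs.setdefault("standard_bolus", round(min(doses.boid, 25.0), 3))
    pump_kwargs.setdefault("corrective_bolus", round(min(doses.cboid, 25.0), 3))
    pump_config = PumpConfig(**pump_kwargs)
    recorder = register_pump_sites(CoverageRecorder())
    delivery_log: list[dict[str, Any]] = []
    pump = InsulinPump("pump", pump_config, recorder=recorder, delivery_log=delivery_log)
    components: list[Component] = [pump]
    wiring: list = []
    if config.corrective_times:
        sched = _EventScheduler(
            "user", [(t, "corrective", True) for t in config.corrective_times]
        )
        components.append(sched)
        wiring.append((("user", "corrective"), ("pump", "corrective")))
    trace = run_scenario(components, wiring, config.horizon, config.dt, config.seed)
    verdicts = verify_all(trace, component="pump")
    coverage = compute_coverage(recorder)
    return ScenarioResult(config, trace, verdicts, coverage, delivery_log)


def _run_diabetic_closed_loop(config: ScenarioConfig) -> ScenarioResult:
    params = config.bergman_params()
    pid = PIDParams(**config.pid) if config.pid else tune_pid(params)
    pulses = [DisturbancePulse(**d) for d in config.disturbances] or [
        DisturbancePulse(start=60.0, duration=30.0, channel="D", magnitude=2.0)
    ]
    vitals = ICUPatient(
        "vitals",
        _vitals_models(config),
        profile=config.profile(),
        initial=VitalSignsState(**config.initial_vitals) if config.initial_vitals else None,
    )
    trace = simulate_closed_loop(
        params,
        pid,
        pulses,
        GlucoseInsulinState(G=params.Gb, X=0.0, I=params.Ib),
        config.horizon,
        config.dt,
        seed=config.seed,
        vitals_patient=vitals,
    )
    return ScenarioResult(config=config, trace=trace)


_RUNNERS = {
    "icu_monitoring": _run_icu_monitoring,
    "insulin_pump": _run_insulin_pump,
    "diabetic_closed_loop": _run_diabetic_closed_loop,
}


def run_clinical_context(config: ScenarioConfig) -> ScenarioResult:
    """Run one bundled clinical context end to end."""
    return _RUNNERS[config.scenario](config)


def export_outputs(result: ScenarioResult, outdir: str | Path) -> list[Path]:
    """Write trace CSV, delivery log, verdict summary and coverage table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    trace_path = outdir / "trace.csv"
    result.trace.to_csv(trace_path)
    written.append(trace_path)
    if result.delivery_log:
        log_path = outdir / "delivery_log.csv"
        pd.DataFrame(result.delivery_log)[["time", "strategy", "dose", "level_after"]].to_csv(
            log_path, index=False
        )
        written.append(log_path)
    if result.verdicts:
        v_path = outdir / "verdicts.txt"
        lines = []
        for pid_, v in result.verdicts.items():
            status = "HOLDS" if v.holds else f"VIOLATED at t={v.first_violation_time}"
            lines.append(f"{pid_}: {status}")
        v_path.write_text("\n".join(lines) + "\n")
        written.append(v_path)
    if result.coverage is not None:
        c_path = outdir / "coverage.txt"
        c_path.write_text(result.coverage.to_text() + "\n")
        result.coverage.to_csv(outdir / "coverage.csv")
        written += [c_path, outdir / "coverage.csv"]
    return written


def glm_spec_to_dict(spec: GLMSpec) -> dict[str, Any]:
    """Serializable form of a GLMSpec (YAML-friendly)."""
    return {
        "response": spec.response,
        "family": spec.family,
        "link": spec.link,
        "intercept": spec.intercept,
        "coefficients": dict(spec.coefficients),
        "interactions": {k: {"factors": list(f), "coefficient": c} for k, (f, c) in spec.interactions.items()},
        "use_absolute": spec.use_absolute,
        "round_digits": spec.round_digits,
    }


def glm_spec_from_dict(d: dict[str, Any]) -> GLMSpec:
    return GLMSpec(
        response=d["response"],
        family=d["family"],
        link=d["link"],
        intercept=float(d["intercept"]),
        coefficients={k: float(v) for k, v in d.get("coefficients", {}).items()},
        interactions={
            k: ((v["factors"][0], v["factors"][1]), float(v["coefficient"]))
            for k, v in d.get("interactions", {}).items()
        },
        use_absolute=bool(d.get("use_absolute", False)),
        round_digits=d.get("round_digits", 0),
    )
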