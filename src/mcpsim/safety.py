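"""Runtime verification of the insulin-pump safety requirements.

The monitors scan a simulation trace (not the implementation) for:

* SR1 — whenever the cartridge level is 0, the cartridge status is EMPTY
  at that tick and the pump mode is STOP within ``delay`` ticks;
* SR2 — whenever a delivery is attempted with less insulin in the
  cartridge than the programmed dose, nothing is delivered and the pump
  mode is STOP at that tick;
* SR3 — whenever a basal delivery happens, the administered dose equals
  the programmed dose;
* A1  — the cartridge status is never EMPTY and LOW simultaneously.

Each verdict carries the earliest counterexample (time plus the trace
rows establishing it).  An empty trace satisfies every property
vacuously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .trace import SimTrace

PROPERTY_IDS = ("SR1", "SR2", "SR3", "A1")

_REQUIRED_SIGNALS = {
    "SR1": ["level", "cartridgeStatus", "insulinPumpStatus"],
    "SR2": ["level", "programmed", "administered", "insulinPumpStatus"],
    "SR3": ["strategy", "administered", "programmed"],
    "A1": ["cartridgeStatus"],
}


class MissingSignalError(KeyError):
    pass


@dataclass(frozen=True)
class SafetyProperty:
    id: str
    delay: int = 1  # SR1 stop-delay bound, in scheduler ticks

    def __post_init__(self):
        if self.id not in PROPERTY_IDS:
            raise ValueError(f"unknown property {self.id!r}; known: {PROPERTY_IDS}")


@dataclass
class Verdict:
    property_id: str
    holds: bool
    first_violation_time: float | None = None
    witness: list[dict[str, Any]] = field(default_factory=list)
    worst_case_delay: int | None = None  # SR1: observed level-0 -> STOP delay

    def __post_init__(self):
        if (not self.holds) != bool(self.witness):
            raise ValueError("a failing verdict must carry a witness (and only then)")


def _pump_table(trace: SimTrace | pd.DataFrame, component: str, needed: list[str]) -> pd.DataFrame:
    df = trace.to_frame() if isinstance(trace, SimTrace) else pd.DataFrame(trace)
    sel = df[df["component"] == component] if "component" in df else df
    if sel.empty:
        return pd.DataFrame(columns=needed)
    wide = sel.pivot_table(index="time", columns="signal", values="value", aggfunc="last", sort=True)
    # traces re-read from CSV carry strings; the quantitative signals must
    # come back as numbers for the comparisons below
    for col in ("level", "programmed", "administered", "cumulative"):
        if col in wide.columns:
            wide[col] = pd.to_numeric(wide[col], errors="coerce")
    missing = [s for s in needed if s not in wide.columns]
    if missing:
        raise MissingSignalError(
            f"trace lacks signals {missing} of component {component!r} needed by the property"
        )
    return wide


def _witness(wide: pd.DataFrame, times: list[float]) -> list[dict[str, Any]]:
    return [dict({"time": t}, **wide.loc[t].to_dict()) for t in times]


def monitor_trace(
    trace: SimTrace | pd.DataFrame,
    prop: SafetyProperty | str,
    component: str = "pump",
) -> Verdict:
    """Check one safety property over the trace of one pump component."""
    if isinstance(prop, str):
        prop = SafetyProperty(prop)
    wide = _pump_table(trace, component, _REQUIRED_SIGNALS[prop.id])
    if wide.empty:
        return Verdict(prop.id, holds=True)
    times = list(wide.index)

    if prop.id == "SR1":
        worst = 0
        for i, t in enumerate(times):
            if wide.loc[t, "level"] != 0:
                continue
            if wide.loc[t, "cartridgeStatus"] != "EMPTY":
                return Verdict(prop.id, False, t, _witness(wide, [t]))
            window = times[i : i + prop.delay + 1]
            stops = [j for j, tw in enumerate(window) if wide.loc[tw, "insulinPumpStatus"] == "STOP"]
            if not stops:
                return Verdict(prop.id, False, t, _witness(wide, window))
            worst = max(worst, stops[0])
        return Verdict(prop.id, True, worst_case_delay=worst)

    if prop.id == "SR2":
        prev_level = None
        for t in times:
            row = wide.loc[t]
            programmed = row["programmed"]
            if programmed is not None and not (isinstance(programmed, float) and np.isnan(programmed)):
                level_before = prev_level if prev_level is not None else row["level"] + row["administered"]
                if float(programmed) > level_before + 1e-12:
                    ok = row["administered"] == 0 and row["insulinPumpStatus"] == "STOP"
                    if not ok:
                        return Verdict(prop.id, False, t, _witness(wide, [t]))
            prev_level = row["level"]
        return Verdict(prop.id, True)

    if prop.id == "SR3":
        for t in times:
            row = wide.loc[t]
            if row["strategy"] == "BASAL" and row["administered"] and row["administered"] > 0:
                if row["administered"] != row["programmed"]:
                    return Verdict(prop.id, False, t, _witness(wide, [t]))
        return Verdict(prop.id, True)

    if prop.id == "A1":
        df = trace.to_frame() if isinstance(trace, SimTrace) else pd.DataFrame(trace)
        sel = df[(df.get("component") == component) & (df["signal"] == "cartridgeStatus")]
        for t, group in sel.groupby("time"):
            statuses = set(group["value"])
            if {"EMPTY", "LOW"} <= statuses:
                return Verdict(prop.id, False, t, _witness(wide, [t]))
        return Verdict(prop.id, True)

    raise AssertionError("unreachable")


def verify_all(
    trace: SimTrace | pd.DataFrame,
    component: str = "pump",
    delay: int = 1,
    properties: tuple[str, ...] = PROPERTY_IDS,
) -> dict[str, Verdict]:
    """Run every requested monitor; returns verdicts keyed by property id."""
    return {
        pid: monitor_trace(trace, SafetyProperty(pid, delay=delay), component)
        for pid in properties
    }
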