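"""Simulation traces: the timestamped record of every component signal.

A trace is the single artifact downstream analyses consume: safety
monitors scan it, coverage reports are built from instrumentation rows
recorded alongside it, and the CSV export is the external interface.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Any, Iterable

import pandas as pd


@dataclass
class SimTrace:
    """Ordered (time, component, signal, value) samples plus scenario metadata."""

    seed: int | None = None
    horizon: float | None = None
    dt: float | None = None
    _rows: list[tuple[float, str, str, Any]] = field(default_factory=list)

    def record(self, time: float, component: str, signal: str, value: Any) -> None:
        if self._rows and time < self._rows[-1][0]:
            raise ValueError(
                f"trace time must be non-decreasing: got {time} after {self._rows[-1][0]}"
            )
        self._rows.append((time, component, signal, value))

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self):
        return iter(self._rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=["time", "component", "signal", "value"])

    def signal(self, component: str, signal: str) -> pd.DataFrame:
        """Time series of one signal, columns (time, value)."""
        df = self.to_frame()
        sel = df[(df["component"] == component) & (df["signal"] == signal)]
        return sel[["time", "value"]].reset_index(drop=True)

    def pivot(self, component: str, signals: Iterable[str] | None = None) -> pd.DataFrame:
        """Wide per-tick view of one component: one column per signal, indexed by time."""
        df = self.to_frame()
        sel = df[df["component"] == component]
        if signals is not None:
            sel = sel[sel["signal"].isin(list(signals))]
        return sel.pivot_table(
            index="time", columns="signal", values="value", aggfunc="last", sort=True
        )

    def to_csv(self, path_or_buf=None) -> str | None:
        """CSV export, header ``time,component,signal,value``, time to 6 decimals."""
        df = self.to_frame()
        out = df.to_csv(path_or_buf, index=False, float_format="%.6f")
        return out

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()
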