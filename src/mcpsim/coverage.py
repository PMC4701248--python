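"""Structural coverage measurement: decision, condition and MC/DC.

Device logic is instrumented at *decision sites*.  A site is one boolean
decision (e.g. the guard ``[status == LOW || status == EMPTY]``) with a
named vector of atomic conditions and a decision function mapping the
condition vector to the outcome.  During simulation every evaluation is
recorded; afterwards the report computes, per site and rolled up per
function:

* DC  — fraction of the two decision outcomes (true/false) observed;
* CC  — per condition, fraction of its two truth values observed;
* MC/DC — a condition is covered when two observed evaluations differ
  only in that condition and produce different decision outcomes
  (independence pairs);

CC and MC/DC are not applicable (NA) to sites whose decision is a single
atomic condition, mirroring how structural-coverage tables report simple
relational guards.  Cyclomatic complexity per function is decision count
plus one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Mapping

import pandas as pd


class InstrumentationError(RuntimeError):
    """Recorded outcome disagrees with the site's decision function, or
    the site was never registered."""


@dataclass(frozen=True)
class DecisionSite:
    """One instrumented decision: ``id`` is "function/[label]"."""

    id: str
    conditions: tuple[str, ...]
    decision: Callable[[tuple[bool, ...]], bool]

    @property
    def function(self) -> str:
        return self.id.split("/", 1)[0]


@dataclass(frozen=True)
class DecisionRecord:
    site: str
    vector: tuple[bool, ...]
    outcome: bool
    time: float


@dataclass
class CoverageRecorder:
    """Registry of sites plus the evaluation log."""

    sites: dict[str, DecisionSite] = field(default_factory=dict)
    records: list[DecisionRecord] = field(default_factory=list)

    def register_site(
        self,
        site_id: str,
        conditions: Iterable[str],
        decision: Callable[[tuple[bool, ...]], bool] | None = None,
    ) -> DecisionSite:
        conds = tuple(conditions)
        if decision is None:
            if len(conds) != 1:
                raise ValueError("a default decision function exists only for 1-condition sites")
            decision = lambda v: v[0]  # noqa: E731
        site = DecisionSite(site_id, conds, decision)
        self.sites[site_id] = site
        return site

    def record(self, site_id: str, vector: tuple[bool, ...], outcome: bool, t: float = 0.0) -> DecisionRecord:
        """Append one evaluation; the outcome is recomputed and checked."""
        if site_id not in self.sites:
            raise InstrumentationError(f"decision site {site_id!r} was never registered")
        site = self.sites[site_id]
        vector = tuple(bool(v) for v in vector)
        if len(vector) != len(site.conditions):
            raise InstrumentationError(
                f"site {site_id!r} expects {len(site.conditions)} conditions, got {len(vector)}"
            )
        recomputed = bool(site.decision(vector))
        if recomputed != bool(outcome):
            raise InstrumentationError(
                f"instrumentation bug at {site_id!r}: recorded outcome {outcome} "
                f"but the decision function gives {recomputed} for {vector}"
            )
        rec = DecisionRecord(site_id, vector, recomputed, t)
        self.records.append(rec)
        return rec

    def evaluate(self, site_id: str, t: float = 0.0, **conditions: bool) -> bool:
        """Convenience: evaluate a site's decision and record it."""
        site = self.sites[site_id]
        vector = tuple(bool(conditions[name]) for name in site.conditions)
        outcome = bool(site.decision(vector))
        self.record(site_id, vector, outcome, t)
        return outcome


@dataclass
class SiteCoverage:
    site: str
    function: str
    n_conditions: int
    dc: float
    cc: float | None  # None renders as NA
    mcdc: float | None
    uncovered: list[str] = field(default_factory=list)
    condition_cc: dict[str, float] = field(default_factory=dict)
    condition_mcdc: dict[str, bool] = field(default_factory=dict)


@dataclass
class CoverageReport:
    per_site: list[SiteCoverage]
    per_function: pd.DataFrame  # Model Hierarchy / Cyclomatic Complexity / DC / CC / MCDC

    def to_text(self) -> str:
        df = self.per_function.copy()
        return df.to_string(index=False)

    def to_csv(self, path_or_buf=None):
        return self.per_function.to_csv(path_or_buf, index=False)


def _fmt(v: float | None) -> str:
    return "NA" if v is None else f"{v:.0f}%"


def compute_coverage(
    records: Iterable[DecisionRecord] | CoverageRecorder,
    structure: Mapping[str, DecisionSite] | None = None,
) -> CoverageReport:
    """Build a coverage report from recorded evaluations.

    ``records`` may be a recorder (its registry supplies the structure)
    or a record list with an explicit ``structure`` mapping.
    """
    if isinstance(records, CoverageRecorder):
        structure = records.sites
        records = records.records
    if not structure:
        raise ValueError("no registered decision sites")
    records = list(records)
    by_site: dict[str, list[DecisionRecord]] = {sid: [] for sid in structure}
    for rec in records:
        by_site.setdefault(rec.site, []).append(rec)

    site_rows: list[SiteCoverage] = []
    for sid, site in structure.items():
        recs = by_site.get(sid, [])
        outcomes = {r.outcome for r in recs}
        dc = 100.0 * len(outcomes) / 2.0
        uncovered = [f"decision {o}" for o in (True, False) if o not in outcomes]
        condition_cc: dict[str, float] = {}
        condition_mcdc: dict[str, bool] = {}
        if len(site.conditions) <= 1:
            cc = mcdc = None
        else:
            vectors = {r.vector for r in recs}
            for i, cname in enumerate(site.conditions):
                seen = {v[i] for v in vectors}
                condition_cc[cname] = 100.0 * len(seen) / 2.0
                for val in (True, False):
                    if val not in seen:
                        uncovered.append(f"condition {cname} == {val}")
                # independence pair: two observed vectors differing only in i
                # with different decision outcomes
                pair = any(
                    sum(a != b for a, b in zip(v1, v2)) == 1
                    and v1[i] != v2[i]
                    and site.decision(v1) != site.decision(v2)
                    for v1, v2 in combinations(vectors, 2)
                )
                condition_mcdc[cname] = pair
                if not pair:
                    uncovered.append(f"MCDC independence pair for {cname}")
            cc = sum(condition_cc.values()) / len(condition_cc)
            mcdc = 100.0 * sum(condition_mcdc.values()) / len(condition_mcdc)
        site_rows.append(
            SiteCoverage(
                sid, site.function, len(site.conditions), dc, cc, mcdc, uncovered,
                condition_cc, condition_mcdc,
            )
        )

    functions: dict[str, list[SiteCoverage]] = {}
    for row in site_rows:
        functions.setdefault(row.function, []).append(row)

    table = []
    for fname, rows in functions.items():
        dc = sum(r.dc for r in rows) / len(rows)
        multi = [r for r in rows if r.cc is not None]
        cc = sum(r.cc for r in multi) / len(multi) if multi else None
        mcdc = sum(r.mcdc for r in multi) / len(multi) if multi else None
        table.append(
            {
                "Model Hierarchy": f"Function:{fname}",
                "Cyclomatic Complexity": len(rows) + 1,
                "DC": _fmt(dc),
                "CC": _fmt(cc),
                "MCDC": _fmt(mcdc),
            }
        )
    # top-level rollup over all sites
    dc_all = sum(r.dc for r in site_rows) / len(site_rows)
    multi_all = [r for r in site_rows if r.cc is not None]
    cc_all = sum(r.cc for r in multi_all) / len(multi_all) if multi_all else None
    mcdc_all = sum(r.mcdc for r in multi_all) / len(multi_all) if multi_all else None
    table.insert(
        0,
        {
            "Model Hierarchy": "Subsystem:Insulin Pump Software Model",
            "Cyclomatic Complexity": len(site_rows) + 1,
            "DC": _fmt(dc_all),
            "CC": _fmt(cc_all),
            "MCDC": _fmt(mcdc_all),
        },
    )
    return CoverageReport(per_site=site_rows, per_function=pd.DataFrame(table))


def record_decision(
    recorder: CoverageRecorder,
    site_id: str,
    vector: tuple[bool, ...],
    outcome: bool,
    t: float = 0.0,
) -> DecisionRecord:
    """Functional alias for ``CoverageRecorder.record``."""
    return recorder.record(site_id, vector, outcome, t)
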