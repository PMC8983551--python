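"""Validation statistics and report assembly.

The simulator is validated against observed hospital data by comparing
monthly patient arrivals and bed-utilization levels with a two-sided
t-test of H0: μ_real = μ_sim at α = 0.05 (monthly aggregation over two
years gives the canonical 24 observations per series).  The report
assembler collects the criteria table for every scenario design and the
simulation metric table for simulated ones, plus derived comparison lines
(weighted-C1 differences, percent reductions) computed from the rounded
table values exactly as they would be read off the printed table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import (
    CriteriaReport,
    NetworkDesign,
    Region,
    criteria_report,
    round_half_up,
)
from .simulate import (
    ADMITTED_NEAREST,
    DIVERTED,
    PatientRecord,
    SimConfig,
    SimResult,
)

__all__ = [
    "MonthlySeries",
    "TTestResult",
    "MONTH_DAYS",
    "monthly_aggregate",
    "t_test",
    "percent_reduction",
    "ReportBundle",
    "scenario_report",
]

#: Average month length in days used for binning simulator output.
MONTH_DAYS = 30.4


@dataclass(frozen=True)
class MonthlySeries:
    """A labelled series of monthly observations (24 for two years)."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("need at least two monthly observations")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite observation")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def variance(self) -> float:
        return float(np.var(self.values, ddof=1))


@dataclass(frozen=True)
class TTestResult:
    variant: str
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    t: float
    p: float

    @property
    def decision(self) -> str:
        """Retain or reject H0: equal means, at the 5% level."""
        return "retain H0" if self.p >= 0.05 else "reject H0"

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "mean_a": self.mean_a, "mean_b": self.mean_b,
            "var_a": self.var_a, "var_b": self.var_b,
            "t": self.t, "p": self.p, "decision": self.decision,
        }


def monthly_aggregate(
    records: Sequence[PatientRecord],
    network_ids: Sequence[str],
    region: Region,
    design: NetworkDesign,
    config: SimConfig,
) -> tuple[MonthlySeries, MonthlySeries]:
    """Bin simulator output into 30.4-day months for the selected networks.

    Returns (arrival counts per month, utilization percent per month) for
    patients originating in — and beds belonging to — the given networks.
    Bins start at the end of warm-up; a trailing partial bin is dropped.
    """
    if not records:
        raise ValueError("no patient records to aggregate")
    nets = set(network_ids)
    byid = {h.id: h for h in region.hospitals}
    members = {h for h in design.assignment if design.network_of(h) in nets}
    beds_total = sum(byid[h].beds for h in members if byid[h].is_hub)
    if beds_total == 0:
        raise ValueError("selected networks hold no monitored beds")

    w0 = config.warmup
    n_bins = int(config.horizon // MONTH_DAYS)
    if n_bins < 1:
        raise ValueError("records span less than one month past warm-up")
    edges = w0 + MONTH_DAYS * np.arange(n_bins + 1)

    arrivals = np.zeros(n_bins)
    occ_days = np.zeros(n_bins)
    for r in records:
        if r.origin in members and edges[0] <= r.arrival < edges[-1]:
            arrivals[int((r.arrival - w0) // MONTH_DAYS)] += 1
        if r.destination is not None and r.destination in members:
            lo, hi = r.arrival, r.arrival + r.los
            for b in range(n_bins):
                overlap = min(hi, edges[b + 1]) - max(lo, edges[b])
                if overlap > 0:
                    occ_days[b] += overlap
    utilization = occ_days / (MONTH_DAYS * beds_total) * 100.0
    return (
        MonthlySeries("monthly arrivals", tuple(arrivals.tolist())),
        MonthlySeries("utilization %", tuple(utilization.tolist())),
    )


def t_test(a: MonthlySeries, b: MonthlySeries, variant: str = "welch") -> TTestResult:
    """Two-sided t-test of equal means between two monthly series.

    ``variant`` is "pooled" (classical equal-variance), "welch"
    (unequal-variance, the robust default) or "paired" (requires equal
    lengths).  Two identical constant series are a defined limit:
    t = 0, p = 1.
    """
    x, y = np.asarray(a.values, float), np.asarray(b.values, float)
    if variant == "paired" and len(x) != len(y):
        raise ValueError("paired test requires equal-length series")
    if a.variance == 0 and b.variance == 0 and a.mean == b.mean:
        t_stat, p = 0.0, 1.0
    elif variant == "pooled":
        t_stat, p = stats.ttest_ind(x, y, equal_var=True)
    elif variant == "welch":
        t_stat, p = stats.ttest_ind(x, y, equal_var=False)
    elif variant == "paired":
        t_stat, p = stats.ttest_rel(x, y)
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    return TTestResult(
        variant, a.mean, b.mean, a.variance, b.variance, float(t_stat), float(p)
    )


def percent_reduction(old: float, new: float) -> float:
    """Relative reduction from ``old`` to ``new``, in percent.

    Scale-invariant: percent_reduction(cx, cy) == percent_reduction(x, y)
    for any c > 0.
    """
    if old == 0:
        raise ValueError("reduction from zero is undefined")
    return (old - new) / old * 100.0


@dataclass
class ReportBundle:
    """Criteria tables per scenario, simulation tables, comparison lines."""

    criteria: dict[str, CriteriaReport]
    simulation: dict[str, SimResult]
    comparisons: dict[str, dict]

    def to_json_dict(self) -> dict:
        return {
            "criteria": {
                name: json.loads(rep.to_json()) for name, rep in self.criteria.items()
            },
            "simulation": {
                name: res.to_json_dict() for name, res in self.simulation.items()
            },
            "comparisons": self.comparisons,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))


def scenario_report(
    region: Region,
    designs: Mapping[str, NetworkDesign],
    sim_results: Mapping[str, SimResult] | None = None,
    baseline: str | None = None,
) -> ReportBundle:
    """Assemble criteria tables for every scenario and comparison lines.

    ``baseline`` (default: the first design) anchors the comparisons: the
    weighted-C1 difference, and per-network C1/C2 percent reductions for
    networks present in both designs.  Comparisons are computed from the
    2-decimal table values, matching how they would be read off the
    printed report.
    """
    if not designs:
        raise ValueError("no designs to report on")
    names = list(designs)
    if baseline is None:
        baseline = names[0]
    if baseline not in designs:
        raise ValueError(f"missing baseline design {baseline!r}")

    criteria = {name: criteria_report(d, region) for name, d in designs.items()}
    base = criteria[baseline]
    base_rows = {r.network: r for r in base.rows}

    comparisons: dict[str, dict] = {}
    for name in names:
        if name == baseline:
            continue
        rep = criteria[name]
        comp: dict = {}
        if base.weighted_c1 is not None and rep.weighted_c1 is not None:
            comp["weighted_c1_reduction_km"] = round_half_up(
                round_half_up(base.weighted_c1) - round_half_up(rep.weighted_c1)
            )
        per_net = {}
        for row in rep.rows:
            b = base_rows.get(row.network)
            if b is None:
                continue
            entry = {}
            if b.c1_km is not None and row.c1_km is not None and b.c1_km > 0:
                entry["c1_reduction_pct"] = round_half_up(
                    percent_reduction(round_half_up(b.c1_km), round_half_up(row.c1_km))
                )
            if b.c2_per_hub and row.c2_per_hub is not None:
                entry["c2_reduction_pct"] = round_half_up(
                    percent_reduction(b.c2_per_hub, row.c2_per_hub)
                )
            if entry:
                per_net[row.network] = entry
        if per_net:
            comp["per_network"] = per_net
        comparisons[name] = comp

    return ReportBundle(criteria, dict(sim_results or {}), comparisons)
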