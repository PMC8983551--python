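"""Discrete-event simulation of stroke-patient flow through a network design.

Ischemic stroke patients arise in each hospital's catchment as a homogeneous
Poisson process whose rate follows the regional incidence (per 100,000
inhabitants per year) scaled by the ischemic fraction.  A patient needing
mechanical thrombectomy (MT) can only be treated at a stroke center (SC);
all others at any hub.  The routing cascade:

1. nearest eligible hub of the patient's own network with a free monitored
   bed — admission at the nearest hub (0 km when the origin is that hub);
2. otherwise the next-nearest own-network hub with a free bed — *diversion*;
3. otherwise the closest free eligible hub in another network — *rejection
   to another network*;
4. otherwise the patient cannot be placed — *non-treatment*.

Admitted patients hold one monitored bed for a triangular length of stay and
then leave the system.  A warm-up interval is simulated but excluded from
metrics.  Replications use common random numbers: the demand stream
(arrival times, origins, patient classes, lengths of stay) is generated
from the region and seed alone, so two designs compared under the same seed
face bit-identical demand.
"""

from __future__ import annotations

import hashlib
import heapq
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    UNASSIGNED,
    Hospital,
    NetworkDesign,
    Region,
    assign_catchments,
    catchment_population,
)

logger = logging.getLogger("strokenet")

__all__ = [
    "SimConfig",
    "PatientRecord",
    "SimResult",
    "annual_arrival_rate",
    "sample_los",
    "route_patient",
    "expand_unassigned",
    "generate_demand",
    "demand_stream_checksum",
    "simulate_replication",
    "simulate_many",
]

REGULAR = "REGULAR"
MT = "MT"

ADMITTED_NEAREST = "ADMITTED_NEAREST"
DIVERTED = "DIVERTED"
REJECTED = "REJECTED_TO_OTHER_NETWORK"
NOT_TREATED = "NOT_TREATED"


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    incidence
        strokes per 100,000 inhabitants per year.
    ischemic_fraction
        share of strokes that are ischemic infarctions and enter the
        hub transport pathway.
    mt_fraction
        probability that a simulated patient is MT-eligible (treatable
        only at an SC); 0.075 is the midpoint of the reported 5–10% range
        and reproduces ~26 MT-eligible strokes per 100,000 after rounding.
    los
        (min, mode, max) of the triangular length-of-stay distribution, days.
    warmup / horizon
        days simulated before measurement starts / measured days.
    seasonal_amplitude
        optional sinusoidal modulation of the arrival rate (0 = off,
        homogeneous Poisson).
    diversion_denominator
        "origin_patients" divides within-network diversions by all patients
        originating in the network; "network_admissions" divides by
        within-network admissions only.
    """

    incidence: float = 420.0
    ischemic_fraction: float = 0.82
    mt_fraction: float = 0.075
    los: tuple[float, float, float] = (5.8, 11.3, 16.7)
    warmup: float = 60.0
    horizon: float = 365.0
    replications: int = 1000
    base_seed: int = 0
    seasonal_amplitude: float = 0.0
    diversion_denominator: str = "origin_patients"

    def __post_init__(self) -> None:
        for frac in (self.ischemic_fraction, self.mt_fraction):
            if not (0 < frac < 1):
                raise ValueError("fractions must lie strictly in (0, 1)")
        lo, mode, hi = self.los
        if not (lo <= mode <= hi):
            raise ValueError("LOS triangular parameters must satisfy min <= mode <= max")
        if self.warmup < 0 or self.horizon <= 0:
            raise ValueError("warmup must be >= 0 and horizon > 0")
        if self.incidence <= 0:
            raise ValueError("incidence must be positive")
        if self.diversion_denominator not in ("origin_patients", "network_admissions"):
            raise ValueError("unknown diversion denominator")


@dataclass(frozen=True, slots=True)
class PatientRecord:
    """One simulated patient: origin, class, routing outcome, stay."""

    origin: str
    klass: str
    arrival: float
    destination: str | None
    outcome: str
    distance_km: float
    los: float


def annual_arrival_rate(zone_population: float, config: SimConfig) -> float:
    """Ischemic stroke arrivals per year for a catchment population."""
    if zone_population < 0:
        raise ValueError("population must be >= 0")
    return zone_population / 100_000.0 * config.incidence * config.ischemic_fraction


def sample_los(config: SimConfig, rng: np.random.Generator, size=None):
    """Draw length(s) of stay, days, from the triangular distribution."""
    lo, mode, hi = config.los
    return rng.triangular(lo, mode, hi, size=size)


def expand_unassigned(design: NetworkDesign) -> NetworkDesign:
    """Model each independent hub as a singleton network.

    An unaffiliated stroke unit cannot divert internally; giving it a
    one-member network of its own reproduces that behaviour in the routing
    cascade while letting it receive rejected patients from elsewhere.
    """
    assignment = dict(design.assignment)
    for hid in design.unassigned:
        assignment[hid] = f"{UNASSIGNED}:{hid}"
    return NetworkDesign(assignment)


# ---------------------------------------------------------------------------
# Routing
# ---------------------------------------------------------------------------


def _eligible(h: Hospital, klass: str) -> bool:
    return h.is_hub and (klass == REGULAR or h.level == "SC")


def route_patient(
    origin: str,
    klass: str,
    occupancy: Mapping[str, int],
    design: NetworkDesign,
    distances,
    hospitals: Mapping[str, Hospital] | Sequence[Hospital],
) -> tuple[str | None, str]:
    """Route one patient through the admission cascade.

    Pure function of its inputs: no bed is seized.  Returns the chosen
    destination hospital id (or ``None``) and the outcome label.
    """
    if not isinstance(hospitals, Mapping):
        hospitals = {h.id: h for h in hospitals}
    try:
        net = design.network_of(origin)
    except KeyError:
        raise ValueError(f"origin {origin!r} not in design") from None
    if net == UNASSIGNED:
        raise ValueError(
            f"origin {origin!r} is unassigned; expand_unassigned() the design first"
        )

    def free(hid: str) -> bool:
        return occupancy.get(hid, 0) < hospitals[hid].beds

    own = sorted(
        (h for h in design.members(net) if _eligible(hospitals[h], klass)),
        key=lambda h: (distances(origin, h), h),
    )
    for rank, hid in enumerate(own):
        if free(hid):
            return hid, (ADMITTED_NEAREST if rank == 0 else DIVERTED)

    others = sorted(
        (
            h
            for h, n in design.assignment.items()
            if n != net and _eligible(hospitals[h], klass)
        ),
        key=lambda h: (distances(origin, h), h),
    )
    for hid in others:
        if free(hid):
            return hid, REJECTED
    return None, NOT_TREATED


# ---------------------------------------------------------------------------
# Demand stream (common random numbers)
# ---------------------------------------------------------------------------


def generate_demand(
    region: Region, config: SimConfig, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Generate one replication's demand, independent of any network design.

    Returns time-sorted arrays (arrival day, origin index, MT flag, LOS)
    plus the origin id list the index refers to.  Identical region, config
    and seed give bit-identical streams — the common-random-numbers
    contract that makes design comparisons fair.
    """
    if region.catchment is None:
        assign_catchments(region)
    rng = np.random.default_rng(seed)
    T = config.warmup + config.horizon
    origins = region.hospital_ids  # sorted, deterministic
    times_all, origin_all = [], []
    for k, hid in enumerate(origins):
        lam = annual_arrival_rate(catchment_population(region, hid), config) / 365.0
        if config.seasonal_amplitude > 0:
            lam_max = lam * (1 + config.seasonal_amplitude)
            n = rng.poisson(lam_max * T)
            t = rng.uniform(0, T, size=n)
            keep = rng.uniform(0, 1, size=n) < (
                (1 + config.seasonal_amplitude * np.sin(2 * np.pi * t / 365.0))
                / (1 + config.seasonal_amplitude)
            )
            t = t[keep]
        else:
            n = rng.poisson(lam * T)
            t = rng.uniform(0, T, size=n)
        times_all.append(t)
        origin_all.append(np.full(len(t), k, dtype=np.int64))
    times = np.concatenate(times_all) if times_all else np.empty(0)
    origin_idx = np.concatenate(origin_all) if origin_all else np.empty(0, dtype=np.int64)
    order = np.argsort(times, kind="stable")
    times, origin_idx = times[order], origin_idx[order]
    is_mt = rng.uniform(0, 1, size=len(times)) < config.mt_fraction
    los = sample_los(config, rng, size=len(times))
    return times, origin_idx, is_mt, los, origins


def demand_stream_checksum(region: Region, config: SimConfig, seed: int) -> str:
    """Digest of the demand stream; equal digests ⇔ identical demand."""
    times, origin_idx, is_mt, los, _ = generate_demand(region, config, seed)
    h = hashlib.sha256()
    for arr in (times, origin_idx, is_mt, los):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Single replication
# ---------------------------------------------------------------------------


def _routing_tables(
    region: Region, design: NetworkDesign, origins: list[str]
) -> tuple[list[list[list[int]]], list[list[list[int]]]]:
    """Per-origin candidate index lists, sorted by (distance, id).

    ``own[klass][o]`` / ``other[klass][o]`` with klass 0 = REGULAR,
    1 = MT; indices refer to the ``origins`` ordering.
    """
    idx = {hid: i for i, hid in enumerate(origins)}
    byid = {h.id: h for h in region.hospitals}
    own = [[None] * len(origins) for _ in range(2)]
    other = [[None] * len(origins) for _ in range(2)]
    for o, oid in enumerate(origins):
        net = design.network_of(oid)
        for k, klass in enumerate((REGULAR, MT)):
            own_c = sorted(
                (h for h in design.members(net) if _eligible(byid[h], klass)),
                key=lambda h: (region.distances(oid, h), h),
            )
            oth_c = sorted(
                (
                    h
                    for h, n in design.assignment.items()
                    if n != net and _eligible(byid[h], klass)
                ),
                key=lambda h: (region.distances(oid, h), h),
            )
            own[k][o] = [idx[h] for h in own_c]
            other[k][o] = [idx[h] for h in oth_c]
    return own, other


def simulate_replication(
    region: Region, design: NetworkDesign, config: SimConfig, seed: int
) -> list[PatientRecord]:
    """Run one replication and return every patient's record.

    Records with ``arrival < config.warmup`` belong to the warm-up interval
    and are excluded from metrics by the aggregation step (they still
    occupy beds, which is the point of warming up).  Unassigned hubs in the
    design are treated as singleton networks.
    """
    if region.catchment is None:
        assign_catchments(region)
    design = expand_unassigned(design)
    design.validate(region.hospitals)
    byid = {h.id: h for h in region.hospitals}
    for net in design.network_ids:
        for hid in design.members(net):
            if byid[hid].is_hub and byid[hid].beds < 1:
                raise ValueError(f"hub {hid} has no monitored beds")

    times, origin_idx, is_mt, los, origins = generate_demand(region, config, seed)
    own_tab, other_tab = _routing_tables(region, design, origins)
    beds = np.array([byid[h].beds for h in origins], dtype=np.int64)
    dmat = np.array(
        [[region.distances(a, b) for b in origins] for a in origins]
    )

    occ = np.zeros(len(origins), dtype=np.int64)
    departures: list[tuple[float, int]] = []
    records: list[PatientRecord] = []
    for t, o, mt, stay in zip(times.tolist(), origin_idx.tolist(), is_mt.tolist(), los.tolist()):
        while departures and departures[0][0] <= t:
            _, h = heapq.heappop(departures)
            occ[h] -= 1
        k = 1 if mt else 0
        dest = -1
        outcome = NOT_TREATED
        own = own_tab[k][o]
        for rank, h in enumerate(own):
            if occ[h] < beds[h]:
                dest, outcome = h, (ADMITTED_NEAREST if rank == 0 else DIVERTED)
                break
        if dest < 0:
            for h in other_tab[k][o]:
                if occ[h] < beds[h]:
                    dest, outcome = h, REJECTED
                    break
        if dest >= 0:
            occ[dest] += 1
            heapq.heappush(departures, (t + stay, dest))
            records.append(
                PatientRecord(
                    origins[o], MT if mt else REGULAR, t, origins[dest],
                    outcome, float(dmat[o, dest]), stay,
                )
            )
        else:
            records.append(
                PatientRecord(origins[o], MT if mt else REGULAR, t, None,
                              NOT_TREATED, 0.0, stay)
            )
    return records


# ---------------------------------------------------------------------------
# Replication batch and metric aggregation
# ---------------------------------------------------------------------------

METRICS = ("utilization", "rejected_per_year", "diversion_proportion", "distance_km")


@dataclass
class SimResult:
    """Across-replication mean/std of the four flow metrics.

    ``per_network`` maps each reporting group (named networks plus one
    pooled "UNASSIGNED" group for independent hubs) to
    ``{metric: (mean, std) | None}``; ``overall`` holds the hub-count-
    weighted averages, except the travel distance which is patient-weighted
    (total diverted/rejected km over their count).
    """

    per_network: dict[str, dict[str, tuple[float, float] | None]]
    overall: dict[str, tuple[float, float] | None]
    replications: int

    def to_frame(self):
        import pandas as pd

        rows = []
        for net, metrics in list(self.per_network.items()) + [("OVERALL", self.overall)]:
            row: dict = {"network": net}
            for m in METRICS:
                val = metrics.get(m)
                row[f"{m}_mean"] = None if val is None else val[0]
                row[f"{m}_std"] = None if val is None else val[1]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        def enc(d):
            return {
                m: (None if v is None else {"mean": v[0], "std": v[1]})
                for m, v in d.items()
            }

        return {
            "replications": self.replications,
            "per_network": {n: enc(d) for n, d in self.per_network.items()},
            "overall": enc(self.overall),
        }


def _group_of(design: NetworkDesign) -> dict[str, str]:
    """Reporting group per hospital: its network, or UNASSIGNED pooled."""
    return {
        hid: (UNASSIGNED if n == UNASSIGNED else n)
        for hid, n in design.assignment.items()
    }


def _replication_metrics(
    records: list[PatientRecord],
    region: Region,
    design: NetworkDesign,
    config: SimConfig,
) -> dict[str, dict[str, float | None]]:
    byid = {h.id: h for h in region.hospitals}
    group = _group_of(design)
    groups = sorted(set(group.values()))
    w0, w1 = config.warmup, config.warmup + config.horizon

    beds_g = {g: 0 for g in groups}
    hubs_g = {g: 0 for g in groups}
    for hid, g in group.items():
        if byid[hid].is_hub:
            beds_g[g] += byid[hid].beds
            hubs_g[g] += 1

    occ_days = {g: 0.0 for g in groups}
    counts = {g: {"arrivals": 0, "div": 0, "rej": 0, "adm": 0} for g in groups}
    travel = {g: [0.0, 0] for g in groups}  # [km sum, patient count]
    for r in records:
        if r.destination is not None:
            overlap = min(r.arrival + r.los, w1) - max(r.arrival, w0)
            if overlap > 0:
                occ_days[group[r.destination]] += overlap
        if r.arrival < w0:
            continue
        g = group[r.origin]
        counts[g]["arrivals"] += 1
        if r.outcome == DIVERTED:
            counts[g]["div"] += 1
        elif r.outcome == REJECTED:
            counts[g]["rej"] += 1
        if r.outcome in (ADMITTED_NEAREST, DIVERTED):
            counts[g]["adm"] += 1
        if r.outcome in (DIVERTED, REJECTED):
            travel[g][0] += r.distance_km
            travel[g][1] += 1

    out: dict[str, dict[str, float | None]] = {}
    for g in groups:
        util = occ_days[g] / (config.horizon * beds_g[g]) if beds_g[g] else None
        # within a pooled-unassigned or single-hub group no diversion is possible
        can_divert = (g != UNASSIGNED) and hubs_g[g] >= 2
        if config.diversion_denominator == "origin_patients":
            denom = counts[g]["arrivals"]
        else:
            denom = counts[g]["adm"]
        div = (counts[g]["div"] / denom if denom else 0.0) if can_divert else None
        dist = travel[g][0] / travel[g][1] if travel[g][1] else None
        out[g] = {
            "utilization": util,
            "rejected_per_year": counts[g]["rej"] * (365.0 / config.horizon),
            "diversion_proportion": div,
            "distance_km": dist,
            "_travel_km": travel[g][0],
            "_travel_n": travel[g][1],
            "_hubs": hubs_g[g],
        }
    return out


def simulate_many(
    region: Region, design: NetworkDesign, config: SimConfig
) -> SimResult:
    """Run the replication batch and aggregate the four flow metrics.

    Replication r uses seed ``base_seed + r``: two designs simulated with
    the same config face identical demand streams (common random numbers).
    """
    if config.replications < 1:
        raise ValueError("need at least one replication")
    per_rep: list[dict] = []
    for r in range(config.replications):
        records = simulate_replication(region, design, config, config.base_seed + r)
        per_rep.append(_replication_metrics(records, region, design, config))

    groups = sorted(per_rep[0])
    per_network: dict[str, dict[str, tuple[float, float] | None]] = {}
    for g in groups:
        per_network[g] = {}
        for m in METRICS:
            vals = [rep[g][m] for rep in per_rep if rep[g][m] is not None]
            if not vals:
                per_network[g][m] = None
            else:
                arr = np.asarray(vals, dtype=float)
                std = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
                per_network[g][m] = (float(arr.mean()), std)

    # Overall: hub-count-weighted means, except travel distance which is
    # total km over total diverted/rejected patients.
    hubs_w = np.array([per_rep[0][g]["_hubs"] for g in groups], dtype=float)
    overall: dict[str, tuple[float, float] | None] = {}
    for m in ("utilization", "rejected_per_year", "diversion_proportion"):
        rep_vals = []
        for rep in per_rep:
            vals = np.array([np.nan if rep[g][m] is None else rep[g][m] for g in groups])
            mask = ~np.isnan(vals)
            if mask.any():
                rep_vals.append(float((vals[mask] * hubs_w[mask]).sum() / hubs_w[mask].sum()))
        if rep_vals:
            arr = np.asarray(rep_vals)
            overall[m] = (float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0)
        else:
            overall[m] = None
    dist_vals = []
    for rep in per_rep:
        km = sum(rep[g]["_travel_km"] for g in groups)
        n = sum(rep[g]["_travel_n"] for g in groups)
        if n:
            dist_vals.append(km / n)
    if dist_vals:
        arr = np.asarray(dist_vals)
        overall["distance_km"] = (
            float(arr.mean()),
            float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        )
    else:
        overall["distance_km"] = None

    return SimResult(per_network, overall, config.replications)
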