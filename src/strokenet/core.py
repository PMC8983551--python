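"""Domain model for hub-and-spoke stroke-care networks.

A regional stroke system is a set of hospitals — stroke centers (SC) and
stroke units (SU) acting as *hubs* with monitored beds, and
telemedicine-assisted stroke-ready hospitals (TSRH) acting as *spokes* —
partitioned into named networks.  Population zones are mapped to the nearest
hospital (their catchment), and a network design is scored by three criteria:

C1  mean distance from each spoke to its nearest hub within the network (km);
C2  inhabitants served per hub (total catchment population of all member
    hospitals divided by the hub count);
C3  hub-to-spoke ratio.

This module holds the domain types, catchment assignment, the criteria, and
readers/writers for the tabular interchange formats (CSV/JSON/GeoJSON).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("strokenet")

#: Network label marking hubs that belong to no network.
UNASSIGNED = "UNASSIGNED"

#: Care levels. SC and SU are hubs (monitored beds, can admit stroke
#: patients); TSRH are spokes that stabilize and transfer.
LEVELS = ("SC", "SU", "TSRH")
HUB_LEVELS = frozenset({"SC", "SU"})


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as tables in the field print numbers."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Hospital:
    """A care site with planar km coordinates and monitored-bed capacity.

    ``beds`` counts monitored stroke beds: >= 1 for hubs, 0 for spokes
    (TSRHs hold no monitored beds in this model).  ``network`` is the
    initial network membership; :data:`UNASSIGNED` marks independent hubs.
    """

    id: str
    name: str
    x: float
    y: float
    level: str
    beds: int
    network: str = UNASSIGNED

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown care level {self.level!r}")
        if self.is_hub and self.beds < 1:
            raise ValueError(f"hub {self.id} must have >= 1 monitored bed")
        if not self.is_hub and self.beds != 0:
            raise ValueError(f"TSRH {self.id} cannot hold monitored beds")

    @property
    def is_hub(self) -> bool:
        return self.level in HUB_LEVELS


@dataclass(frozen=True)
class PopulationZone:
    """A population zone: centroid (planar km) plus inhabitant count."""

    zone_id: str
    x: float
    y: float
    population: float

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError(f"zone {self.zone_id}: negative population")


class DistanceMatrix:
    """Pairwise travel distances (km) between identified locations.

    Distances need not be symmetric (road distances may be directed); the
    Euclidean construction is.  Diagonal must be zero, entries non-negative.
    """

    def __init__(self, ids: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise ValueError("distance table shape does not match ids")
        if np.any(values < 0):
            raise ValueError("negative distance")
        if np.any(np.diagonal(values) != 0):
            raise ValueError("nonzero self-distance")
        self.ids: tuple[str, ...] = tuple(str(i) for i in ids)
        self._idx = {i: k for k, i in enumerate(self.ids)}
        self.values = values

    def __contains__(self, hid: str) -> bool:
        return hid in self._idx

    def distance(self, from_id: str, to_id: str) -> float:
        try:
            return float(self.values[self._idx[from_id], self._idx[to_id]])
        except KeyError as exc:
            raise KeyError(f"no distance entry for {exc.args[0]!r}") from None

    def __call__(self, from_id: str, to_id: str) -> float:
        return self.distance(from_id, to_id)

    @classmethod
    def from_euclidean(cls, points: Mapping[str, tuple[float, float]]) -> "DistanceMatrix":
        ids = list(points)
        xy = np.array([points[i] for i in ids], dtype=float)
        diff = xy[:, None, :] - xy[None, :, :]
        return cls(ids, np.sqrt((diff**2).sum(axis=2)))

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "DistanceMatrix":
        """Build from a long table with columns from_id, to_id, km."""
        ids = sorted(set(df["from_id"].astype(str)) | set(df["to_id"].astype(str)))
        idx = {i: k for k, i in enumerate(ids)}
        values = np.zeros((len(ids), len(ids)))
        filled = np.eye(len(ids), dtype=bool)
        for row in df.itertuples(index=False):
            i, j = idx[str(row.from_id)], idx[str(row.to_id)]
            values[i, j] = float(row.km)
            filled[i, j] = True
        if not filled.all():
            raise ValueError("incomplete distance table")
        return cls(ids, values)

    def to_long(self) -> pd.DataFrame:
        rows = [
            (a, b, self.values[i, j])
            for i, a in enumerate(self.ids)
            for j, b in enumerate(self.ids)
            if i != j
        ]
        return pd.DataFrame(rows, columns=["from_id", "to_id", "km"])


@dataclass
class NetworkDesign:
    """A partition of hospitals into named networks.

    ``assignment`` maps every hospital id to a network label; the special
    label :data:`UNASSIGNED` marks independent hubs (TSRHs always belong to
    a network).
    """

    assignment: dict[str, str]

    @property
    def network_ids(self) -> list[str]:
        return sorted({n for n in self.assignment.values() if n != UNASSIGNED})

    @property
    def unassigned(self) -> list[str]:
        return sorted(h for h, n in self.assignment.items() if n == UNASSIGNED)

    def members(self, network_id: str) -> list[str]:
        return sorted(h for h, n in self.assignment.items() if n == network_id)

    def network_of(self, hospital_id: str) -> str:
        return self.assignment[hospital_id]

    def validate(self, hospitals: Iterable[Hospital]) -> None:
        """Enforce the partition invariants against a hospital roster."""
        byid = {h.id: h for h in hospitals}
        if set(self.assignment) != set(byid):
            raise ValueError("design does not cover exactly the hospital roster")
        for hid in self.unassigned:
            if not byid[hid].is_hub:
                raise ValueError(f"TSRH {hid} cannot be unassigned")
        for net in self.network_ids:
            mem = self.members(net)
            has_tsrh = any(not byid[h].is_hub for h in mem)
            has_hub = any(byid[h].is_hub for h in mem)
            if has_tsrh and not has_hub:
                raise ValueError(f"network {net} has spokes but no hub")

    def to_dict(self) -> dict:
        return {
            "networks": {n: self.members(n) for n in self.network_ids},
            "unassigned": self.unassigned,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkDesign":
        assignment: dict[str, str] = {}
        for net, ids in d.get("networks", {}).items():
            for hid in ids:
                assignment[str(hid)] = str(net)
        for hid in d.get("unassigned", []):
            assignment[str(hid)] = UNASSIGNED
        return cls(assignment)

    @classmethod
    def from_hospitals(cls, hospitals: Iterable[Hospital]) -> "NetworkDesign":
        return cls({h.id: h.network for h in hospitals})


@dataclass
class Region:
    """Hospitals, population zones, distances: the world the pipeline runs on."""

    hospitals: list[Hospital]
    zones: list[PopulationZone]
    distances: DistanceMatrix
    catchment: dict[str, str] | None = None

    def __post_init__(self) -> None:
        missing = [h.id for h in self.hospitals if h.id not in self.distances]
        if missing:
            raise ValueError(f"distance matrix missing hospitals: {missing}")
        self._byid = {h.id: h for h in self.hospitals}

    def hospital(self, hid: str) -> Hospital:
        return self._byid[hid]

    @property
    def hospital_ids(self) -> list[str]:
        return sorted(self._byid)

    @property
    def hubs(self) -> list[Hospital]:
        return [h for h in self.hospitals if h.is_hub]

    @property
    def total_population(self) -> float:
        return float(sum(z.population for z in self.zones))

    @classmethod
    def from_hospitals_zones(
        cls,
        hospitals: Sequence[Hospital],
        zones: Sequence[PopulationZone],
        distances: DistanceMatrix | None = None,
    ) -> "Region":
        """Assemble a region, defaulting to Euclidean hospital distances."""
        if distances is None:
            distances = DistanceMatrix.from_euclidean({h.id: (h.x, h.y) for h in hospitals})
        return cls(list(hospitals), list(zones), distances)


# ---------------------------------------------------------------------------
# Catchment assignment
# ---------------------------------------------------------------------------


def assign_catchments(region: Region) -> dict[str, str]:
    """Map every population zone to its Euclidean-nearest hospital.

    Ties are broken by lexicographically smallest hospital id so the mapping
    is deterministic.  The mapping is stored on ``region.catchment`` and
    returned.
    """
    if not region.hospitals:
        raise ValueError("no hospitals")
    hosp = sorted(region.hospitals, key=lambda h: h.id)
    hxy = np.array([[h.x, h.y] for h in hosp])
    mapping: dict[str, str] = {}
    for z in region.zones:
        if not (math.isfinite(z.x) and math.isfinite(z.y)):
            raise ValueError(f"zone {z.zone_id}: non-finite coordinates")
        d = np.hypot(hxy[:, 0] - z.x, hxy[:, 1] - z.y)
        mapping[z.zone_id] = hosp[int(np.argmin(d))].id  # argmin keeps first ⇒ smallest id
    region.catchment = mapping
    return mapping


def catchment_population(region: Region, hospital_id: str) -> float:
    """Total population of the zones whose nearest hospital is ``hospital_id``."""
    if hospital_id not in region.distances:
        raise KeyError(f"unknown hospital {hospital_id!r}")
    if region.catchment is None:
        raise ValueError("catchments not assigned; call assign_catchments first")
    return float(
        sum(z.population for z in region.zones if region.catchment[z.zone_id] == hospital_id)
    )


# ---------------------------------------------------------------------------
# Performance criteria (C1, C2, C3)
# ---------------------------------------------------------------------------


def _split_members(
    design: NetworkDesign, network_id: str, hospitals: Mapping[str, Hospital]
) -> tuple[list[str], list[str]]:
    members = design.members(network_id)
    hubs = [h for h in members if hospitals[h].is_hub]
    spokes = [h for h in members if not hospitals[h].is_hub]
    return hubs, spokes


def compute_c1(
    design: NetworkDesign,
    network_id: str,
    distances: DistanceMatrix,
    hospitals: Mapping[str, Hospital] | Sequence[Hospital],
) -> float | None:
    """C1: mean distance from each spoke to its nearest hub in the network.

    Returns ``None`` for a network without spokes (hub-only networks arise
    from clustering); raises if the network has spokes but no hub, where the
    criterion is undefined.
    """
    if not isinstance(hospitals, Mapping):
        hospitals = {h.id: h for h in hospitals}
    hubs, spokes = _split_members(design, network_id, hospitals)
    if not spokes:
        return None
    if not hubs:
        raise ValueError(f"C1 undefined: network {network_id} has spokes but no hubs")
    return float(
        np.mean([min(distances(p, s) for s in hubs) for p in spokes])
    )


def compute_c2(
    design: NetworkDesign, network_id: str, region: Region
) -> float:
    """C2: catchment population of all member hospitals, per hub."""
    hospitals = {h.id: h for h in region.hospitals}
    hubs, _ = _split_members(design, network_id, hospitals)
    if not hubs:
        raise ValueError(f"C2 undefined: network {network_id} has no hubs")
    served = sum(catchment_population(region, m) for m in design.members(network_id))
    return float(served / len(hubs))


def compute_c3(
    design: NetworkDesign,
    network_id: str,
    hospitals: Mapping[str, Hospital] | Sequence[Hospital],
) -> float | None:
    """C3: ratio of hubs to spokes; ``None`` when the network has no spokes."""
    if not isinstance(hospitals, Mapping):
        hospitals = {h.id: h for h in hospitals}
    hubs, spokes = _split_members(design, network_id, hospitals)
    if not spokes:
        return None
    return len(hubs) / len(spokes)


def weighted_mean_c1(
    c1_values: Sequence[float], weights: Sequence[float]
) -> float:
    """Weighted average of per-network C1 values, Σ wᵢ·C1ᵢ / Σ wᵢ."""
    if len(c1_values) != len(weights):
        raise ValueError("c1_values and weights must have equal length")
    w = np.asarray(weights, dtype=float)
    v = np.asarray(c1_values, dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")
    if not np.all(np.isfinite(v)):
        raise ValueError("C1 values must be finite")
    return float((w * v).sum() / w.sum())


@dataclass(frozen=True)
class CriteriaRow:
    network: str
    members: int
    hubs: int
    spokes: int
    c1_km: float | None
    c2_per_hub: float | None
    c3: float | None


@dataclass
class CriteriaReport:
    """Per-network C1/C2/C3 with the weighted-average C1 summary row."""

    rows: list[CriteriaRow]
    weighted_c1: float | None
    weight_mode: str = "members"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.rows])
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "rows": [vars(r) for r in self.rows],
                "weighted_c1": self.weighted_c1,
                "weight_mode": self.weight_mode,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "CriteriaReport":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            rows=[CriteriaRow(**r) for r in d["rows"]],
            weighted_c1=d["weighted_c1"],
            weight_mode=d.get("weight_mode", "members"),
        )


def criteria_report(
    design: NetworkDesign,
    region: Region,
    weight_mode: str = "members",
) -> CriteriaReport:
    """Assemble the per-network criteria table.

    One row per named network (independent hubs carry no criteria of their
    own and are excluded).  The weighted-average C1 uses member counts by
    default; ``weight_mode="hubs"`` weights by hub counts instead.
    Undefined cells (hub-only networks) become ``None`` with a warning.
    """
    if weight_mode not in ("members", "hubs"):
        raise ValueError("weight_mode must be 'members' or 'hubs'")
    if region.catchment is None:
        assign_catchments(region)
    hospitals = {h.id: h for h in region.hospitals}
    rows: list[CriteriaRow] = []
    for net in design.network_ids:
        hubs, spokes = _split_members(design, net, hospitals)
        c1 = c2 = c3 = None
        try:
            c1 = compute_c1(design, net, region.distances, hospitals)
        except ValueError as exc:
            logger.warning("network %s: %s", net, exc)
        try:
            c2 = compute_c2(design, net, region)
        except ValueError as exc:
            logger.warning("network %s: %s", net, exc)
        c3 = compute_c3(design, net, hospitals)
        if c1 is None or c3 is None:
            logger.warning("network %s has no spokes; C1/C3 undefined", net)
        rows.append(
            CriteriaRow(net, len(hubs) + len(spokes), len(hubs), len(spokes), c1, c2, c3)
        )
    scored = [(r.c1_km, r.members if weight_mode == "members" else r.hubs)
              for r in rows if r.c1_km is not None]
    wavg = weighted_mean_c1(*zip(*((v, w) for v, w in scored))) if scored else None
    return CriteriaReport(rows, wavg, weight_mode)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

HOSPITAL_COLUMNS = ["id", "name", "x_km", "y_km", "level", "beds", "network"]
ZONE_COLUMNS = ["zone_id", "x_km", "y_km", "population"]


def read_hospitals(path: str | Path) -> list[Hospital]:
    """Read hospitals.csv; an empty network field means UNASSIGNED."""
    df = pd.read_csv(path, dtype={"id": str, "name": str, "network": str},
                     float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        net = row.network
        if not isinstance(net, str) or not net.strip():
            net = UNASSIGNED
        out.append(
            Hospital(str(row.id), str(row.name), float(row.x_km), float(row.y_km),
                     str(row.level), int(row.beds), net)
        )
    return out


def write_hospitals(hospitals: Iterable[Hospital], path: str | Path) -> None:
    df = pd.DataFrame(
        [(h.id, h.name, h.x, h.y, h.level, h.beds,
          "" if h.network == UNASSIGNED else h.network) for h in hospitals],
        columns=HOSPITAL_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_zones(path: str | Path) -> list[PopulationZone]:
    df = pd.read_csv(path, dtype={"zone_id": str}, float_precision="round_trip")
    return [
        PopulationZone(str(r.zone_id), float(r.x_km), float(r.y_km), float(r.population))
        for r in df.itertuples(index=False)
    ]


def write_zones(zones: Iterable[PopulationZone], path: str | Path) -> None:
    pd.DataFrame(
        [(z.zone_id, z.x, z.y, z.population) for z in zones], columns=ZONE_COLUMNS
    ).to_csv(path, index=False, float_format="%.17g")


def read_distances(path: str | Path) -> DistanceMatrix:
    return DistanceMatrix.from_long(pd.read_csv(path, dtype={"from_id": str, "to_id": str}, float_precision="round_trip"))


def write_distances(distances: DistanceMatrix, path: str | Path) -> None:
    distances.to_long().to_csv(path, index=False, float_format="%.17g")


def read_design(path: str | Path) -> NetworkDesign:
    return NetworkDesign.from_dict(json.loads(Path(path).read_text()))


def write_design(design: NetworkDesign, path: str | Path) -> None:
    Path(path).write_text(json.dumps(design.to_dict(), indent=2))


def region_to_geojson(region: Region, design: NetworkDesign | None = None) -> dict:
    """Export hospitals (and their catchment/network labels) as GeoJSON points."""
    features = []
    for h in region.hospitals:
        props = {"id": h.id, "name": h.name, "level": h.level, "beds": h.beds}
        if design is not None:
            props["network"] = design.network_of(h.id)
        features.append(
            {"type": "Feature",
             "geometry": {"type": "Point", "coordinates": [h.x, h.y]},
             "properties": props}
        )
    for z in region.zones:
        props = {"zone_id": z.zone_id, "population": z.population}
        if region.catchment is not None:
            props["catchment"] = region.catchment[z.zone_id]
        features.append(
            {"type": "Feature",
             "geometry": {"type": "Point", "coordinates": [z.x, z.y]},
             "properties": props}
        )
    return {"type": "FeatureCollection", "features": features}
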