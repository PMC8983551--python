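"""Seeded synthetic regions with the statistical shape of a large federal
stroke system.

The generator emulates a region like Bavaria: ~97 hospitals of which 58 are
hubs (SC/SU) and the rest telemedicine spokes, five historically grown
networks plus 14 independent hubs, ~13 million inhabitants spread very
unevenly over a ~350×300 km area, and 4–22 monitored beds per hub.  Every
draw flows from a single integer seed, so the same spec and seed reproduce
the region bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import (
    UNASSIGNED,
    Hospital,
    NetworkDesign,
    PopulationZone,
    Region,
)

__all__ = ["RegionSpec", "bavaria_like_spec", "generate_region", "size_beds"]


@dataclass(frozen=True)
class RegionSpec:
    """Parameters of the synthetic region generator.

    ``population_concentration`` is the log-scale sigma of the lognormal
    zone-size draw: larger values produce a stronger urban/rural contrast
    (a few very large zones against many small ones).
    """

    n_hospitals: int = 97
    n_hubs: int = 58
    n_sc: int = 13
    n_networks: int = 5
    n_unassigned_hubs: int = 14
    total_population: float = 13_000_000
    area: tuple[float, float] = (350.0, 300.0)
    beds_range: tuple[int, int] = (4, 22)
    population_concentration: float = 1.2
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.n_sc <= self.n_hubs <= self.n_hospitals):
            raise ValueError("need 0 < n_sc <= n_hubs <= n_hospitals")
        if self.n_unassigned_hubs > self.n_hubs:
            raise ValueError("more unassigned hubs than hubs")
        if self.n_networks < 1:
            raise ValueError("need at least one network")
        if self.n_hubs - self.n_unassigned_hubs < self.n_networks:
            raise ValueError("not enough affiliated hubs to seed every network")
        lo, hi = self.beds_range
        if not (1 <= lo <= hi <= 50):
            raise ValueError("beds_range must lie within [1, 50]")
        if self.total_population < 0:
            raise ValueError("negative population")


def bavaria_like_spec(seed: int = 0) -> RegionSpec:
    """Default spec mirroring the published system's headline counts:
    97 hospitals, 58 hubs (13 SC-level), 5 networks, 14 independent hubs,
    13 million inhabitants on 350×300 km, hubs holding 4–22 monitored beds.
    """
    return RegionSpec(seed=seed)


def _clustered_points(
    rng: np.random.Generator,
    n: int,
    area: tuple[float, float],
    centers: np.ndarray,
    urban_fraction: float = 0.6,
    sigma_km: float = 18.0,
) -> np.ndarray:
    """Urban clumps plus rural scatter: the spatial texture of settlement."""
    w, h = area
    n_urban = int(round(n * urban_fraction))
    pts = []
    if n_urban:
        which = rng.integers(0, len(centers), size=n_urban)
        p = centers[which] + rng.normal(0.0, sigma_km, size=(n_urban, 2))
        pts.append(np.clip(p, [0, 0], [w, h]))
    if n - n_urban:
        pts.append(rng.uniform([0, 0], [w, h], size=(n - n_urban, 2)))
    xy = np.vstack(pts)
    return xy[rng.permutation(n)]


#: Denominator of the zone population shares (a power of two).
_SHARE_TOTAL = 1 << 20


def _dyadic_shares(raw: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of 2^20 integer shares (each >= 1)."""
    n = len(raw)
    budget = _SHARE_TOTAL - n
    quota = raw / raw.sum() * budget
    base = np.floor(quota).astype(np.int64)
    remainder = budget - int(base.sum())
    order = np.lexsort((np.arange(n), -(quota - base)))  # largest fractions first
    extra = np.zeros(n, dtype=np.int64)
    extra[order[:remainder]] = 1
    return 1 + base + extra


def _farthest_point_sample(xy: np.ndarray, k: int, start: int) -> list[int]:
    """Greedy max-min spread: pick k well-separated indices from xy."""
    chosen = [start]
    d = np.hypot(*(xy - xy[start]).T)
    while len(chosen) < k:
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.hypot(*(xy - xy[nxt]).T))
    return chosen


def generate_region(spec: RegionSpec) -> tuple[Region, NetworkDesign]:
    """Generate a region and its initial (historically-grown) network design.

    Hospitals are placed by a clustered spatial process; hubs and SC levels
    drawn among them; per-hub beds uniform over ``beds_range``.  Zones
    (three per hospital) get lognormal populations rescaled to exactly
    ``total_population``.  Networks form by seeding one stroke center per
    network, attaching every hospital to the nearest seed, then detaching
    the hubs farthest from their seed as independent (unassigned) units —
    mimicking organically grown, imperfect coverage.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    w, h = spec.area

    n_centers = max(3, spec.n_networks)
    urban_centers = rng.uniform([0.1 * w, 0.1 * h], [0.9 * w, 0.9 * h], size=(n_centers, 2))

    hxy = _clustered_points(rng, spec.n_hospitals, spec.area, urban_centers)

    # Specialist units sit anywhere care is delivered; draw hubs uniformly
    # among the hospitals and SC status uniformly among the hubs.
    hub_idx = sorted(rng.choice(spec.n_hospitals, size=spec.n_hubs, replace=False))
    sc_idx = set(rng.choice(hub_idx, size=spec.n_sc, replace=False).tolist())
    hub_set = set(hub_idx)

    lo, hi = spec.beds_range
    hospitals: list[Hospital] = []
    for i in range(spec.n_hospitals):
        hid = f"H{i:03d}"
        if i in hub_set:
            level = "SC" if i in sc_idx else "SU"
            beds = int(rng.integers(lo, hi + 1))
        else:
            level, beds = "TSRH", 0
        hospitals.append(
            Hospital(hid, f"Hospital {i:03d}", float(hxy[i, 0]), float(hxy[i, 1]), level, beds)
        )

    # Zones: ~3x hospitals, heavy-tailed populations rescaled so the sum is
    # exactly total_population.  Weights are quantized to integer shares of
    # 2^20, so each population is (share * total) / 2^20 — a dyadic rational
    # that floating point adds and doubles without rounding: zone sums are
    # exact in any grouping and scale linearly with the total.
    n_zones = 3 * spec.n_hospitals
    zxy = _clustered_points(rng, n_zones, spec.area, urban_centers, sigma_km=25.0)
    raw = rng.lognormal(mean=0.0, sigma=spec.population_concentration, size=n_zones)
    shares = _dyadic_shares(raw)
    pops = shares.astype(float) * float(spec.total_population) / float(_SHARE_TOTAL)
    zones = [
        PopulationZone(f"Z{i:03d}", float(zxy[i, 0]), float(zxy[i, 1]), float(pops[i]))
        for i in range(n_zones)
    ]

    # Initial networks: one SC seed per network, nearest-seed attachment,
    # then detach the hubs farthest from their seed as independent units.
    sc_list = sorted(sc_idx)
    seed_pool = hxy[sc_list]
    seeds = [sc_list[j] for j in _farthest_point_sample(seed_pool, spec.n_networks, start=0)]
    seed_xy = hxy[seeds]
    names = [f"NET{j + 1}" for j in range(spec.n_networks)]

    d_to_seed = np.hypot(
        hxy[:, 0:1] - seed_xy[:, 0][None, :], hxy[:, 1:2] - seed_xy[:, 1][None, :]
    )
    nearest_seed = d_to_seed.argmin(axis=1)
    assignment = {hospitals[i].id: names[nearest_seed[i]] for i in range(spec.n_hospitals)}

    # Detach the stroke units farthest from their seed; seeds stay, so every
    # network keeps at least one hub.  Non-seed SCs only if SUs run out.
    su_far = sorted(
        ((d_to_seed[i, nearest_seed[i]], hospitals[i].id) for i in hub_idx
         if i not in sc_idx),
        reverse=True,
    )
    sc_far = sorted(
        ((d_to_seed[i, nearest_seed[i]], hospitals[i].id) for i in sc_idx
         if i not in seeds),
        reverse=True,
    )
    for _, hid in (su_far + sc_far)[: spec.n_unassigned_hubs]:
        assignment[hid] = UNASSIGNED

    hospitals = [replace(hp, network=assignment[hp.id]) for hp in hospitals]
    design = NetworkDesign(dict(assignment))
    design.validate(hospitals)

    region = Region.from_hospitals_zones(hospitals, zones)
    return region, design


def size_beds(
    annual_arrivals: float, los_mean: float, target_utilization: float
) -> int:
    """Monitored beds needed to run at a target offered-load utilization.

    ceil(annual_arrivals × los_mean / 365 / target_utilization), at least 1
    — the M/G/c offered-load rule of thumb used to size fixtures.
    """
    if annual_arrivals <= 0 or los_mean <= 0:
        raise ValueError("arrivals and length of stay must be positive")
    if not (0 < target_utilization < 1):
        raise ValueError("target utilization must lie in (0, 1)")
    return max(1, math.ceil(annual_arrivals * los_mean / 365.0 / target_utilization))
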