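"""Alternative network designs by K-means clustering of hospital locations.

K-means (squared Euclidean, Lloyd's algorithm, random-point initialization)
partitions all hospitals of a region into k spatially compact clusters;
each cluster becomes a candidate network.  Because Lloyd's algorithm finds
only local optima, the clustering is restarted many times (default 100)
with independent sub-seeds; degenerate partitions — an empty cluster, or a
cluster with no hub (where C1 is undefined) — are discarded, the survivors
are deduplicated up to cluster relabeling, and each unique survivor is
scored by its member-weighted average C1.  The design with the lowest
score is the redesign proposal for that k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .core import (
    NetworkDesign,
    Region,
    compute_c1,
    weighted_mean_c1,
)

logger = logging.getLogger("strokenet")

__all__ = [
    "ClusterSolution",
    "ClusterRun",
    "canonical_partition",
    "run_kmeans_designs",
    "select_best_design",
]


def canonical_partition(labels: "np.ndarray | list[int]") -> tuple[int, ...]:
    """Relabel clusters by order of first appearance over the item sequence.

    Two label vectors describe the same partition iff their canonical forms
    are equal, making deduplication label-invariant.
    """
    mapping: dict[int, int] = {}
    out = []
    for lab in labels:
        lab = int(lab)
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return tuple(out)


@dataclass(frozen=True)
class ClusterSolution:
    """One unique surviving partition with its score."""

    canonical: tuple[int, ...]
    weighted_c1: float | None
    n_networks: int
    times_found: int


@dataclass
class ClusterRun:
    """The outcome of one restart batch: survivors plus filter bookkeeping."""

    k: int
    restarts: int
    seed: int
    hospital_ids: list[str]
    solutions: list[ClusterSolution]
    n_discarded_empty: int = 0
    n_discarded_hubless: int = 0

    @property
    def n_unique(self) -> int:
        return len(self.solutions)


def _design_from_canonical(
    canonical: tuple[int, ...], hospital_ids: list[str]
) -> NetworkDesign:
    return NetworkDesign(
        {hid: str(lab + 1) for hid, lab in zip(hospital_ids, canonical)}
    )


def _score(design: NetworkDesign, region: Region) -> float | None:
    """Member-weighted average C1 over networks that have spokes."""
    hospitals = {h.id: h for h in region.hospitals}
    values, weights = [], []
    for net in design.network_ids:
        c1 = compute_c1(design, net, region.distances, hospitals)
        if c1 is not None:
            values.append(c1)
            weights.append(len(design.members(net)))
    if not values:
        return None
    return weighted_mean_c1(values, weights)


def run_kmeans_designs(
    region: Region, k: int, restarts: int = 100, seed: int = 0
) -> ClusterRun:
    """Run the restart protocol and collect unique valid partitions.

    Each restart runs Lloyd's algorithm from a fresh random-point
    initialization (max 300 iterations, tolerance 1e-6) on the planar
    coordinates of *all* hospitals.  Partitions with an empty cluster are
    excluded; partitions with a hub-less cluster are additionally excluded
    because C1 is undefined there.  Both exclusion counts are kept.
    """
    ids = sorted(h.id for h in region.hospitals)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of hospitals ({len(ids)})")
    n_hubs = sum(1 for h in region.hospitals if h.is_hub)
    if k > n_hubs:
        raise ValueError(f"k={k} exceeds the number of hubs ({n_hubs})")

    byid = {h.id: h for h in region.hospitals}
    xy = np.array([[byid[i].x, byid[i].y] for i in ids])
    is_hub = np.array([byid[i].is_hub for i in ids])

    rng = np.random.default_rng(seed)
    subseeds = rng.integers(0, 2**31 - 1, size=restarts)

    seen: dict[tuple[int, ...], int] = {}
    counts: dict[tuple[int, ...], int] = {}
    n_empty = n_hubless = 0
    for s in subseeds:
        km = KMeans(
            n_clusters=k, init="random", n_init=1, max_iter=300, tol=1e-6,
            algorithm="lloyd", random_state=int(s),
        ).fit(xy)
        labels = km.labels_
        if len(set(labels.tolist())) < k:
            n_empty += 1
            continue
        hubless = any(not is_hub[labels == c].any() for c in range(k))
        if hubless:
            n_hubless += 1
            continue
        canon = canonical_partition(labels)
        counts[canon] = counts.get(canon, 0) + 1
        seen.setdefault(canon, 1)

    solutions = []
    for canon in seen:
        design = _design_from_canonical(canon, ids)
        solutions.append(
            ClusterSolution(canon, _score(design, region), k, counts[canon])
        )
    solutions.sort(key=lambda s: s.canonical)
    logger.info(
        "k=%d: %d restarts, %d unique valid partitions (%d empty, %d hub-less discarded)",
        k, restarts, len(solutions), n_empty, n_hubless,
    )
    return ClusterRun(k, restarts, seed, ids, solutions, n_empty, n_hubless)


def select_best_design(run: ClusterRun) -> NetworkDesign:
    """The surviving partition with minimal member-weighted average C1.

    Ties (including solutions whose C1 is undefined because no network has
    spokes) break by canonical-form order.
    """
    if not run.solutions:
        raise ValueError("all solutions degenerate")
    best = min(
        run.solutions,
        key=lambda s: (s.weighted_c1 is None, s.weighted_c1, s.canonical),
    )
    return _design_from_canonical(best.canonical, run.hospital_ids)
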