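"""Shared fixtures: hand-built micro-regions and the seeded synthetic region."""

import numpy as np
import pytest

from strokenet import (
    DistanceMatrix,
    Hospital,
    NetworkDesign,
    PopulationZone,
    Region,
    assign_catchments,
    bavaria_like_spec,
    generate_region,
)


def make_hospital(hid, x, y, level="SU", beds=None, network="N1"):
    if beds is None:
        beds = 0 if level == "TSRH" else 8
    return Hospital(hid, f"name-{hid}", x, y, level, beds, network)


@pytest.fixture
def line_region():
    """Four hospitals on a line with three zones; catchments assigned.

    N1: hub A(0,0), spoke P(7,0);  N2: hub B(20,0), spoke Q(26,0).
    """
    hospitals = [
        make_hospital("A", 0.0, 0.0, "SC", 10, "N1"),
        make_hospital("P", 7.0, 0.0, "TSRH", None, "N1"),
        make_hospital("B", 20.0, 0.0, "SU", 6, "N2"),
        make_hospital("Q", 26.0, 0.0, "TSRH", None, "N2"),
    ]
    zones = [
        PopulationZone("z1", 1.0, 0.0, 1000.0),
        PopulationZone("z2", 8.0, 0.0, 2000.0),
        PopulationZone("z3", 21.0, 0.0, 4000.0),
    ]
    region = Region.from_hospitals_zones(hospitals, zones)
    assign_catchments(region)
    return region


@pytest.fixture
def line_design(line_region):
    return NetworkDesign.from_hospitals(line_region.hospitals)


@pytest.fixture(scope="session")
def bavaria_region():
    """The default synthetic region (seeded) with catchments assigned."""
    region, design = generate_region(bavaria_like_spec(seed=2))
    assign_catchments(region)
    return region, design


def random_micro_region(rng, n_hospitals=8, n_hubs=4, n_zones=20, n_networks=2):
    """A small random region for oracle comparisons."""
    xy = rng.uniform(0, 100, size=(n_hospitals, 2))
    hospitals = []
    for i in range(n_hospitals):
        is_hub = i < n_hubs
        level = "SC" if i == 0 else ("SU" if is_hub else "TSRH")
        hospitals.append(
            Hospital(
                f"h{i}", f"h{i}", float(xy[i, 0]), float(xy[i, 1]),
                level, int(rng.integers(2, 10)) if is_hub else 0,
                f"n{i % n_networks}",
            )
        )
    zones = [
        PopulationZone(f"z{j}", float(rng.uniform(0, 100)), float(rng.uniform(0, 100)),
                       float(rng.integers(0, 5000)))
        for j in range(n_zones)
    ]
    region = Region.from_hospitals_zones(hospitals, zones)
    assign_catchments(region)
    return region, NetworkDesign.from_hospitals(hospitals)
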