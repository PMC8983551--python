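"""Catchment assignment, the C1/C2/C3 criteria, and the tabular I/O."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokenet import (
    DistanceMatrix,
    Hospital,
    NetworkDesign,
    PopulationZone,
    Region,
    assign_catchments,
    catchment_population,
    compute_c1,
    compute_c2,
    compute_c3,
    criteria_report,
    round_half_up,
    weighted_mean_c1,
)
from strokenet.core import (
    CriteriaReport,
    read_design,
    read_distances,
    read_hospitals,
    read_zones,
    region_to_geojson,
    write_design,
    write_distances,
    write_hospitals,
    write_zones,
)

from conftest import make_hospital


class TestCatchments:
    def test_single_hospital_takes_all_zones(self):
        hs = [make_hospital("A", 0, 0, "SU")]
        zs = [PopulationZone(f"z{i}", i * 3.0, 1.0, 100.0) for i in range(5)]
        region = Region.from_hospitals_zones(hs, zs)
        assert set(assign_catchments(region).values()) == {"A"}

    def test_nearer_hospital_wins(self):
        hs = [make_hospital("A", 1, 0, "SU"), make_hospital("B", 3, 0, "SU")]
        region = Region.from_hospitals_zones(hs, [PopulationZone("z", 0, 0, 10.0)])
        assert assign_catchments(region)["z"] == "A"

    def test_tie_breaks_to_smallest_id(self):
        hs = [make_hospital("B", 1, 0, "SU"), make_hospital("A", -1, 0, "SU")]
        region = Region.from_hospitals_zones(hs, [PopulationZone("z", 0, 0, 10.0)])
        assert assign_catchments(region)["z"] == "A"

    def test_matches_exhaustive_pairwise_scan(self):
        rng = np.random.default_rng(42)
        hs = [
            make_hospital(f"h{i}", *rng.uniform(0, 50, 2), "SU") for i in range(5)
        ]
        zs = [
            PopulationZone(f"z{j}", *rng.uniform(0, 50, 2), 100.0) for j in range(20)
        ]
        region = Region.from_hospitals_zones(hs, zs)
        got = assign_catchments(region)
        for z in zs:
            expected = min(
                hs, key=lambda h: (np.hypot(h.x - z.x, h.y - z.y), h.id)
            ).id
            assert got[z.zone_id] == expected

    def test_empty_hospital_list_rejected(self):
        empty = Region([], [], DistanceMatrix([], np.zeros((0, 0))))
        with pytest.raises(ValueError, match="no hospitals"):
            assign_catchments(empty)


class TestCatchmentPopulation:
    def test_hospital_without_zones_serves_zero(self, line_region):
        # zone z3 sits nearest B; Q serves nobody
        assert catchment_population(line_region, "Q") == 0.0

    def test_additivity(self):
        hs = [make_hospital("H", 0, 0, "SU")]
        zs = [PopulationZone("a", 1, 0, 1000.0), PopulationZone("b", 2, 0, 1000.0)]
        region = Region.from_hospitals_zones(hs, zs)
        assign_catchments(region)
        assert catchment_population(region, "H") == 2000.0

    def test_unknown_hospital_rejected(self, line_region):
        with pytest.raises(KeyError):
            catchment_population(line_region, "nope")

    def test_matches_groupby_oracle(self, bavaria_region):
        region, _ = bavaria_region
        df = pd.DataFrame(
            {
                "hospital": [region.catchment[z.zone_id] for z in region.zones],
                "population": [z.population for z in region.zones],
            }
        )
        oracle = df.groupby("hospital")["population"].sum()
        for hid in region.hospital_ids:
            assert catchment_population(region, hid) == oracle.get(hid, 0.0)

    def test_population_conserved(self, bavaria_region):
        region, _ = bavaria_region
        total = sum(catchment_population(region, h) for h in region.hospital_ids)
        assert total == sum(z.population for z in region.zones)


class TestC1:
    def test_single_spoke_single_hub(self, line_region, line_design):
        c1 = compute_c1(line_design, "N1", line_region.distances, line_region.hospitals)
        assert c1 == pytest.approx(7.0)

    def test_equidistant_hubs_take_min(self):
        hs = [
            make_hospital("S1", -5, 0, "SU"),
            make_hospital("S2", 5, 0, "SU"),
            make_hospital("P", 0, 0, "TSRH"),
        ]
        design = NetworkDesign.from_hospitals(hs)
        dm = DistanceMatrix.from_euclidean({h.id: (h.x, h.y) for h in hs})
        assert compute_c1(design, "N1", dm, hs) == pytest.approx(5.0)

    def test_matches_min_then_mean_oracle(self):
        rng = np.random.default_rng(7)
        ids = [f"p{i}" for i in range(4)] + [f"s{i}" for i in range(3)]
        d = rng.uniform(1, 100, size=(7, 7))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(ids, d)
        hs = [make_hospital(f"p{i}", 0, 0, "TSRH") for i in range(4)] + [
            make_hospital(f"s{i}", 0, 0, "SU") for i in range(3)
        ]
        design = NetworkDesign.from_hospitals(hs)
        oracle = np.mean(
            [min(dm(f"p{i}", f"s{j}") for j in range(3)) for i in range(4)]
        )
        assert compute_c1(design, "N1", dm, hs) == pytest.approx(oracle)

    def test_hub_only_network_is_undefined_not_error(self):
        hs = [make_hospital("S", 0, 0, "SU")]
        design = NetworkDesign.from_hospitals(hs)
        dm = DistanceMatrix.from_euclidean({"S": (0, 0)})
        assert compute_c1(design, "N1", dm, hs) is None

    def test_spokes_without_hub_rejected(self):
        hs = [make_hospital("P", 0, 0, "TSRH")]
        design = NetworkDesign({"P": "N1"})
        dm = DistanceMatrix.from_euclidean({"P": (0, 0)})
        with pytest.raises(ValueError, match="C1 undefined"):
            compute_c1(design, "N1", dm, hs)

    def test_adding_hub_never_increases_c1(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            pts = {f"p{i}": tuple(rng.uniform(0, 50, 2)) for i in range(3)}
            pts.update({f"s{i}": tuple(rng.uniform(0, 50, 2)) for i in range(3)})
            dm = DistanceMatrix.from_euclidean(pts)
            hs = [make_hospital(f"p{i}", *pts[f"p{i}"], "TSRH") for i in range(3)]
            hs += [make_hospital(f"s{i}", *pts[f"s{i}"], "SU") for i in range(2)]
            extra = make_hospital("s2", *pts["s2"], "SU")
            before = compute_c1(
                NetworkDesign.from_hospitals(hs), "N1", dm, hs
            )
            after = compute_c1(
                NetworkDesign.from_hospitals(hs + [extra]), "N1", dm, hs + [extra]
            )
            assert after <= before + 1e-12


class TestC2C3:
    def test_single_hub_serves_whole_population(self):
        hs = [make_hospital("S", 0, 0, "SU")]
        zs = [PopulationZone("z", 1, 0, 779_100.0)]
        region = Region.from_hospitals_zones(hs, zs)
        assign_catchments(region)
        design = NetworkDesign.from_hospitals(hs)
        assert compute_c2(design, "N1", region) == 779_100.0

    def test_zero_population(self, ):
        hs = [make_hospital("S", 0, 0, "SU")]
        region = Region.from_hospitals_zones(hs, [PopulationZone("z", 1, 0, 0.0)])
        assign_catchments(region)
        assert compute_c2(NetworkDesign.from_hospitals(hs), "N1", region) == 0.0

    def test_c2_divides_by_hub_count(self):
        hs = [make_hospital("S1", 0, 0, "SU"), make_hospital("S2", 10, 0, "SU")]
        zs = [PopulationZone("a", 0, 1, 150_000.0), PopulationZone("b", 10, 1, 250_000.0)]
        region = Region.from_hospitals_zones(hs, zs)
        assign_catchments(region)
        assert compute_c2(NetworkDesign.from_hospitals(hs), "N1", region) == 200_000.0

    def test_c2_without_hubs_rejected(self):
        hs = [make_hospital("P", 0, 0, "TSRH")]
        region = Region.from_hospitals_zones(hs, [PopulationZone("z", 1, 0, 5.0)])
        assign_catchments(region)
        with pytest.raises(ValueError, match="C2 undefined"):
            compute_c2(NetworkDesign({"P": "N1"}), "N1", region)

    @pytest.mark.parametrize(
        "n_hubs,n_spokes,expected",
        [(17, 4, 4.25), (1, 6, 0.17), (3, 3, 1.0)],
    )
    def test_c3_ratio(self, n_hubs, n_spokes, expected):
        hs = [make_hospital(f"s{i}", i, 0, "SU") for i in range(n_hubs)]
        hs += [make_hospital(f"p{i}", i, 5, "TSRH") for i in range(n_spokes)]
        c3 = compute_c3(NetworkDesign.from_hospitals(hs), "N1", hs)
        assert round_half_up(c3) == expected

    def test_c3_without_spokes_undefined(self):
        hs = [make_hospital("S", 0, 0, "SU")]
        assert compute_c3(NetworkDesign.from_hospitals(hs), "N1", hs) is None


class TestWeightedMean:
    def test_identical_values_any_weights(self):
        assert weighted_mean_c1([4.2, 4.2, 4.2], [1, 10, 3]) == pytest.approx(4.2)

    def test_matches_direct_arithmetic(self):
        rng = np.random.default_rng(3)
        v, w = rng.uniform(1, 100, 6), rng.integers(1, 40, 6)
        assert weighted_mean_c1(v, w) == pytest.approx(float((v * w).sum() / w.sum()))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean_c1([1.0, 2.0], [0, 0])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 200, allow_nan=False),
                st.integers(1, 50),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_bounded_by_min_and_max(self, pairs):
        values = [p[0] for p in pairs]
        weights = [p[1] for p in pairs]
        m = weighted_mean_c1(values, weights)
        assert min(values) - 1e-9 <= m <= max(values) + 1e-9


class TestCriteriaReport:
    def test_single_network_weighted_average_is_its_c1(self, line_region):
        hs = [h for h in line_region.hospitals if h.network == "N1"]
        zs = line_region.zones
        region = Region.from_hospitals_zones(hs, zs)
        assign_catchments(region)
        rep = criteria_report(NetworkDesign.from_hospitals(hs), region)
        assert len(rep.rows) == 1
        assert rep.weighted_c1 == pytest.approx(rep.rows[0].c1_km)

    def test_rows_equal_individually_computed_criteria(self, line_region, line_design):
        rep = criteria_report(line_design, line_region)
        hs = {h.id: h for h in line_region.hospitals}
        for row in rep.rows:
            assert row.c1_km == pytest.approx(
                compute_c1(line_design, row.network, line_region.distances, hs)
            )
            assert row.c2_per_hub == pytest.approx(
                compute_c2(line_design, row.network, line_region)
            )
            assert row.c3 == pytest.approx(compute_c3(line_design, row.network, hs))

    def test_weighted_average_between_min_and_max(self, bavaria_region):
        region, design = bavaria_region
        rep = criteria_report(design, region)
        c1s = [r.c1_km for r in rep.rows if r.c1_km is not None]
        assert min(c1s) <= rep.weighted_c1 <= max(c1s)

    def test_current_design_c3_column(self):
        """Hub/spoke counts of the five historical networks give the known
        C3 column (1.18, 4.25, 0.73, 0.71, 0.17)."""
        counts = {  # network -> (hubs, spokes)
            "N1_TEMPIS": (13, 11),
            "N2_STENO": (17, 4),
            "N3_NEVAS": (8, 11),
            "N4_TRANSIT": (5, 7),
            "N5_TESAURUS": (1, 6),
        }
        hs = []
        k = 0
        for net, (nh, nsp) in counts.items():
            for _ in range(nh):
                hs.append(make_hospital(f"h{k:03d}", k * 1.0, 0.0, "SU", 5, net))
                k += 1
            for _ in range(nsp):
                hs.append(make_hospital(f"h{k:03d}", k * 1.0, 3.0, "TSRH", None, net))
                k += 1
        region = Region.from_hospitals_zones(hs, [PopulationZone("z", 0, 0, 1000.0)])
        assign_catchments(region)
        rep = criteria_report(NetworkDesign.from_hospitals(hs), region)
        c3 = [round_half_up(r.c3) for r in rep.rows]
        assert c3 == [1.18, 4.25, 0.73, 0.71, 0.17]

    def test_json_round_trip(self, line_region, line_design, tmp_path):
        rep = criteria_report(line_design, line_region)
        path = tmp_path / "report.json"
        rep.to_json(path)
        back = CriteriaReport.from_json(path)
        assert back.rows == rep.rows
        assert back.weighted_c1 == rep.weighted_c1


class TestIO:
    def test_hospitals_zones_distances_design_round_trip(self, bavaria_region, tmp_path):
        region, design = bavaria_region
        write_hospitals(region.hospitals, tmp_path / "h.csv")
        write_zones(region.zones, tmp_path / "z.csv")
        write_distances(region.distances, tmp_path / "d.csv")
        write_design(design, tmp_path / "design.json")
        hs = read_hospitals(tmp_path / "h.csv")
        zs = read_zones(tmp_path / "z.csv")
        dm = read_distances(tmp_path / "d.csv")
        dsg = read_design(tmp_path / "design.json")
        assert hs == region.hospitals
        assert zs == region.zones
        assert dsg.assignment == design.assignment
        np.testing.assert_allclose(
            dm.values,
            region.distances.values[
                np.ix_(*[[region.distances.ids.index(i) for i in dm.ids]] * 2)
            ],
        )

    def test_geojson_export_covers_everything(self, line_region, line_design):
        gj = region_to_geojson(line_region, line_design)
        assert gj["type"] == "FeatureCollection"
        assert len(gj["features"]) == len(line_region.hospitals) + len(line_region.zones)
        nets = {
            f["properties"].get("network")
            for f in gj["features"]
            if "network" in f["properties"]
        }
        assert nets == {"N1", "N2"}


class TestDesignInvariants:
    def test_partition_covers_roster_exactly(self, bavaria_region):
        region, design = bavaria_region
        design.validate(region.hospitals)
        assert sorted(design.assignment) == region.hospital_ids

    def test_spoke_cannot_be_unassigned(self):
        hs = [make_hospital("P", 0, 0, "TSRH", network="UNASSIGNED")]
        with pytest.raises(ValueError, match="cannot be unassigned"):
            NetworkDesign.from_hospitals(hs).validate(hs)

    def test_network_with_spokes_needs_hub(self):
        hs = [
            make_hospital("P", 0, 0, "TSRH", network="N1"),
            make_hospital("S", 1, 0, "SU", network="N2"),
        ]
        with pytest.raises(ValueError, match="no hub"):
            NetworkDesign.from_hospitals(hs).validate(hs)

    def test_hub_bed_invariants(self):
        with pytest.raises(ValueError):
            Hospital("a", "a", 0, 0, "SU", 0)
        with pytest.raises(ValueError):
            Hospital("a", "a", 0, 0, "TSRH", 3)
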