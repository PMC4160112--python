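"""CSV/GraphML serialization and referential integrity of colony data."""

import numpy as np
import pytest

import polydomy as pm
from polydomy.errors import DomainError, FormatError, IntegrityError


def _write_tables(tmp_path, nests, trees, internest, foraging):
    import pandas as pd

    paths = []
    for name, rows, cols in [
        ("nests.csv", nests, ["nest_id", "colony_id", "x_m", "y_m",
                              "diameter1_m", "diameter2_m", "height_m",
                              "canopy_cover", "population"]),
        ("trees.csv", trees, ["tree_id", "colony_id", "x_m", "y_m"]),
        ("internest_trails.csv", internest,
         ["colony_id", "nest_a", "nest_b", "length_m", "ants_per_m"]),
        ("foraging_trails.csv", foraging,
         ["colony_id", "nest_id", "tree_id", "length_m", "ants_per_m"]),
    ]:
        path = tmp_path / name
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        paths.append(path)
    return paths


NESTS = [
    ("N1", "c1", 0.0, 0.0, 1.0, 1.2, 0.4, 0.3, 50000.0),
    ("N2", "c1", 3.0, 0.0, 0.8, 0.9, 0.3, 0.2, 30000.0),
    ("N3", "c1", 0.0, 4.0, 1.5, 1.4, 0.5, 0.4, 80000.0),
    ("N4", "c1", 5.0, 5.0, 0.5, 0.5, 0.2, 0.1, 10000.0),
]
TREES = [("T1", "c1", -2.0, 0.0)]
TRAILS = [
    ("c1", "N1", "N2", 3.0, 40.0),
    ("c1", "N2", "N3", 5.0, 30.0),
    ("c1", "N3", "N4", 5.1, 20.0),
]
FORAGING = [("c1", "N1", "T1", 2.0, 50.0)]


class TestReadColony:
    def test_counts_preserved(self, tmp_path):
        net = pm.read_colony(*_write_tables(tmp_path, NESTS, TREES, TRAILS, FORAGING))
        assert net.n_nests == 4
        assert net.n_internest_trails == 3
        assert len(net.trees) == 1
        assert len(net.foraging_trails) == 1
        assert net.nests["N1"].population == 50000.0

    def test_dangling_nest_id_reported(self, tmp_path):
        bad = TRAILS + [("c1", "N1", "N99", 2.0, 10.0)]
        with pytest.raises(IntegrityError, match="N99"):
            pm.read_colony(*_write_tables(tmp_path, NESTS, TREES, bad, FORAGING))

    def test_missing_column_named(self, tmp_path):
        paths = _write_tables(tmp_path, NESTS, TREES, TRAILS, FORAGING)
        import pandas as pd

        df = pd.read_csv(paths[0]).drop(columns=["x_m"])
        df.to_csv(paths[0], index=False)
        with pytest.raises(FormatError, match="x_m"):
            pm.read_colony(*paths)

    def test_duplicate_edge_across_orderings_rejected(self, tmp_path):
        bad = TRAILS + [("c1", "N2", "N1", 3.0, 40.0)]
        with pytest.raises(IntegrityError, match="duplicate"):
            pm.read_colony(*_write_tables(tmp_path, NESTS, TREES, bad, FORAGING))

    def test_empty_foraging_table_means_all_nonforaging(self, tmp_path):
        net = pm.read_colony(*_write_tables(tmp_path, NESTS, TREES, TRAILS, []))
        pm.compute_all(net)
        assert all(not n.is_foraging for n in net.nests.values())

    def test_dist_to_10_ants_column_accepted(self, tmp_path):
        import pandas as pd

        paths = _write_tables(tmp_path, NESTS, TREES, TRAILS, FORAGING)
        df = pd.read_csv(paths[2]).rename(columns={"ants_per_m": "dist_to_10_ants_m"})
        df["dist_to_10_ants_m"] = 0.4
        df.to_csv(paths[2], index=False)
        net = pm.read_colony(*paths)
        assert all(
            t.ants_per_metre == pytest.approx(25.0) for t in net.internest_trails
        )

    def test_disconnected_graph_warns_not_fails(self, tmp_path):
        trails = [("c1", "N1", "N2", 3.0, 40.0)]  # N3, N4 isolated
        with pytest.warns(UserWarning, match="disconnected"):
            pm.read_colony(*_write_tables(tmp_path, NESTS, TREES, trails, FORAGING))

    def test_multi_colony_tables_need_selector(self, tmp_path):
        nests = NESTS + [("M1", "c2", 0.0, 0.0, 1.0, 1.0, 0.3, 0.2, 1000.0)]
        paths = _write_tables(tmp_path, nests, TREES, TRAILS, FORAGING)
        with pytest.raises(FormatError, match="colon"):
            pm.read_colony(*paths)
        net = pm.read_colony(*paths, colony_id="c2")
        assert net.n_nests == 1
        assert len(pm.read_study(*paths)) == 2


class TestGraphML:
    def test_round_trip_preserves_attributes(self, tmp_path, demo_colony):
        path = tmp_path / "colony.graphml"
        pm.write_graphml(demo_colony, path)
        back = pm.read_graphml(path)
        assert set(back.nests) == set(demo_colony.nests)
        for nid, nest in demo_colony.nests.items():
            assert back.nests[nid].population == pytest.approx(nest.population)
            assert back.nests[nid].canopy_cover == pytest.approx(nest.canopy_cover)
            assert back.nests[nid].is_foraging == nest.is_foraging
            assert back.nests[nid].amount_of_foraging == pytest.approx(
                nest.amount_of_foraging
            )
        orig = {t.key: t for t in demo_colony.internest_trails}
        readback = {t.key: t for t in back.internest_trails}
        assert set(readback) == set(orig)
        for key, t in orig.items():
            assert readback[key].length == pytest.approx(t.length)
            assert readback[key].strength == pytest.approx(t.strength)
            assert readback[key].category == t.category

    def test_unset_strength_omitted_without_error(self, tmp_path):
        net = pm.ColonyNetwork(colony_id="c")
        net.nests["a"] = pm.Nest(nest_id="a", colony_id="c")
        net.nests["b"] = pm.Nest(nest_id="b", colony_id="c")
        net.internest_trails.append(
            pm.InternestTrail(nest_a="a", nest_b="b", length=1.0, ants_per_metre=2.0)
        )
        path = tmp_path / "g.graphml"
        pm.write_graphml(net, path)
        back = pm.read_graphml(path)
        assert back.internest_trails[0].strength is None

    def test_empty_network_round_trips(self, tmp_path):
        net = pm.ColonyNetwork(colony_id="empty")
        path = tmp_path / "empty.graphml"
        pm.write_graphml(net, path)
        assert pm.read_graphml(path).n_nests == 0


class TestInvariants:
    def test_self_loop_rejected(self):
        with pytest.raises(IntegrityError):
            pm.InternestTrail(nest_a="a", nest_b="a", length=1.0, ants_per_metre=1.0)

    def test_edge_key_is_order_free(self):
        t1 = pm.InternestTrail(nest_a="a", nest_b="b", length=1.0, ants_per_metre=1.0)
        t2 = pm.InternestTrail(nest_a="b", nest_b="a", length=1.0, ants_per_metre=1.0)
        assert t1.key == t2.key

    def test_nest_validation(self):
        with pytest.raises(DomainError):
            pm.Nest(nest_id="x", colony_id="c", canopy_cover=1.5)
        with pytest.raises(DomainError):
            pm.Nest(nest_id="x", colony_id="c", height=-0.1)

    def test_csv_round_trip_via_write_fixture(self, tmp_path, small_study):
        networks, _ = small_study
        pm.write_fixture(networks, tmp_path / "fx")
        back = pm.read_study(
            tmp_path / "fx" / "nests.csv",
            tmp_path / "fx" / "trees.csv",
            tmp_path / "fx" / "internest_trails.csv",
            tmp_path / "fx" / "foraging_trails.csv",
        )
        assert [n.colony_id for n in back] == [n.colony_id for n in networks]
        for a, b in zip(networks, back):
            assert set(a.nests) == set(b.nests)
            assert {t.key for t in a.internest_trails} == {
                t.key for t in b.internest_trails
            }
            for nid in a.nests:
                assert b.nests[nid].population == pytest.approx(
                    a.nests[nid].population
                )
            wa = np.sort([t.ants_per_metre for t in a.internest_trails])
            wb = np.sort([t.ants_per_metre for t in b.internest_trails])
            assert wa == pytest.approx(wb)
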