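"""Generator structure, calibration and reproducibility."""

import json

import networkx as nx
import numpy as np
import pytest

import polydomy as pm
from polydomy.errors import GenerationError
from polydomy.synthetic import _beta, _lognormal


class TestStructure:
    def test_colony_and_trail_counts_within_study_ranges(self):
        for seed in range(5):
            networks, _ = pm.generate_study(pm.GeneratorConfig(seed=seed))
            assert len(networks) == 10
            for net in networks:
                assert 7 <= net.n_nests <= 22
                assert 6 <= net.n_internest_trails <= 30

    def test_internest_graphs_connected_and_simple(self, small_study):
        networks, _ = small_study
        for net in networks:
            g = pm.to_graph(net)
            assert nx.is_connected(g)
            assert not any(a == b for a, b in g.edges)
            keys = [t.key for t in net.internest_trails]
            assert len(keys) == len(set(keys))

    def test_every_foraging_trail_qualifies(self, small_study):
        networks, _ = small_study
        for net in networks:
            for ft in net.foraging_trails:
                assert pm.qualify_foraging_trail(ft.ants_per_metre)

    def test_ground_truth_contract(self, small_study):
        _, truth = small_study
        assert {"seed", "rho_target", "beta", "colonies"} <= set(truth)
        assert truth["rho_target"] == 0.36
        assert truth["n_nff_trails"] > 0


class TestCalibration:
    def test_null_coupling_gives_near_zero_correlation(self):
        rs = []
        for seed in range(40):
            networks, truth = pm.generate_study(
                pm.GeneratorConfig(seed=seed, rho_target=0.0)
            )
            assert truth["beta"] == 0.0
            for net in networks:
                pm.compute_all(net)
            d, s = [], []
            for net in networks:
                for t in net.internest_trails:
                    if t.category == "nF-F":
                        d.append(t.foraging_differential)
                        s.append(t.strength)
            rs.append(np.corrcoef(d, s)[0, 1])
        # baseline strengths share the 1/population denominator with the
        # differential, so the raw-scale null correlation is positive but
        # must stay modest and consistent across replicates
        assert abs(np.mean(rs)) < 0.5

    def test_target_coupling_recovered(self):
        rs = []
        for seed in range(25):
            networks, _ = pm.generate_study(
                pm.GeneratorConfig(seed=seed, rho_target=0.36)
            )
            for net in networks:
                pm.compute_all(net)
            d, s = [], []
            for net in networks:
                for t in net.internest_trails:
                    if t.category == "nF-F":
                        d.append(t.foraging_differential)
                        s.append(t.strength)
            rs.append(np.corrcoef(d, s)[0, 1])
        assert np.mean(rs) == pytest.approx(0.36, abs=0.15)
        assert all(r > 0 for r in rs)

    def test_class_conditional_moments_converge(self):
        # law-of-large-numbers check on the moment-matched samplers
        rng = np.random.default_rng(123)
        cfg = pm.GeneratorConfig()
        for cls in ("F", "nF"):
            sizes = _lognormal(rng, cfg.size_mean[cls], cfg.size_sd[cls], 20000)
            assert np.mean(sizes) == pytest.approx(cfg.size_mean[cls], rel=0.05)
            canopy = _beta(rng, cfg.canopy_mean[cls], cfg.canopy_sd[cls], 20000)
            assert np.mean(canopy) == pytest.approx(cfg.canopy_mean[cls], rel=0.05)
            assert canopy.min() >= 0 and canopy.max() <= 1

    def test_generated_class_means_track_targets(self):
        # pooled over 20 studies; tolerance from the estimated standard error
        cfg = pm.GeneratorConfig()
        pops = {"F": [], "nF": []}
        for seed in range(20):
            networks, truth = pm.generate_study(pm.GeneratorConfig(seed=seed))
            for net in networks:
                flags = truth["colonies"][net.colony_id]["is_foraging"]
                for nid, nest in net.nests.items():
                    pops["F" if flags[nid] else "nF"].append(nest.population)
        for cls in ("F", "nF"):
            x = np.asarray(pops[cls])
            se = x.std() / np.sqrt(x.size)
            assert abs(x.mean() - cfg.size_mean[cls]) < 4 * se

    def test_trail_category_shares_near_published_mix(self):
        counts = {"F-F": 0, "nF-F": 0, "nF-nF": 0}
        for seed in range(20):
            networks, _ = pm.generate_study(pm.GeneratorConfig(seed=seed))
            for net in networks:
                pm.compute_all(net)
                for t in net.internest_trails:
                    counts[t.category] += 1
        total = sum(counts.values())
        assert counts["nF-F"] / total == pytest.approx(0.50, abs=0.1)
        assert counts["F-F"] / total == pytest.approx(0.28, abs=0.12)


class TestFixtures:
    def test_fixed_seed_regenerates_identical_fixture_bytes(self, tmp_path):
        cfg = pm.GeneratorConfig(seed=21)
        for sub in ("a", "b"):
            networks, truth = pm.generate_study(pm.GeneratorConfig(seed=21))
            pm.write_fixture(networks, tmp_path / sub, ground_truth=truth, config=cfg)
        for name in (
            "nests.csv",
            "trees.csv",
            "internest_trails.csv",
            "foraging_trails.csv",
            "ground_truth.json",
            "manifest.json",
        ):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_ground_truth_file_contents(self, tmp_path, small_study):
        networks, truth = small_study
        pm.write_fixture(networks, tmp_path, ground_truth=truth)
        loaded = json.loads((tmp_path / "ground_truth.json").read_text())
        assert loaded["rho_target"] == 0.36
        assert "beta" in loaded and "seed" in loaded

    def test_empty_network_list_gives_manifest_only_fixture(self, tmp_path):
        pm.write_fixture([], tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["colonies"] == []
        import pandas as pd

        assert len(pd.read_csv(tmp_path / "nests.csv")) == 0


class TestConfigValidation:
    def test_invalid_ranges_rejected(self):
        with pytest.raises(GenerationError):
            pm.GeneratorConfig(nests_per_colony=(10, 5)).validate()
        with pytest.raises(GenerationError):
            pm.GeneratorConfig(rho_target=1.0).validate()
        with pytest.raises(GenerationError):
            pm.GeneratorConfig(foraging_ants_per_m=(10.0, 50.0)).validate()
        with pytest.raises(GenerationError):
            pm.GeneratorConfig(max_trails_per_colony=5).validate()

    def test_single_colony_generation(self):
        net, truth = pm.generate_colony(
            pm.GeneratorConfig(seed=4), np.random.default_rng(4)
        )
        assert 7 <= net.n_nests <= 22
        assert nx.is_connected(pm.to_graph(net))
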