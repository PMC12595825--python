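import numpy as np
import pytest

from ystrpop.distance import pairwise_rst
from ystrpop.io import ViewMode, make_view, write_haplotype_table
from ystrpop.rho_tmrca import expected_abs_displacement
from ystrpop.simdata import (
    HOST,
    ScenarioConfig,
    founder_star,
    scenario_library,
    simulate,
)


def small_cfg(**kw):
    defaults = dict(
        model="DIVERGENCE",
        pop_labels=("East", "West"),
        pop_sizes={"East": 60, "West": 60},
        split_time=10,
        burn_in=50,
        sample_sizes={"East": 20, "West": 20},
        seed=1,
    )
    defaults.update(kw)
    return ScenarioConfig(**defaults)


class TestSimulate:
    def test_zero_mutation_rate_gives_identical_haplotypes(self):
        ds, _ = simulate(small_cfg(mu=0.0))
        vecs = {tuple(h.alleles[l] for l in ds.panel.loci) for h in ds.haplotypes}
        assert len(vecs) == 1

    def test_fixed_seed_is_byte_identical(self, tmp_path):
        cfg_a = small_cfg(seed=7)
        cfg_b = small_cfg(seed=7)
        ds_a, truth_a = simulate(cfg_a)
        ds_b, truth_b = simulate(cfg_b)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_haplotype_table(ds_a, pa)
        write_haplotype_table(ds_b, pb)
        assert pa.read_bytes() == pb.read_bytes()
        assert truth_a.haplogroup_labels == truth_b.haplogroup_labels
        assert truth_a.realized_migrants == truth_b.realized_migrants

    def test_sample_larger_than_deme_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(sample_sizes={"East": 100, "West": 10})

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(model="WORMHOLE")

    def test_composite_marker_invariant_holds(self):
        ds, _ = simulate(small_cfg())
        for h in ds.haplotypes:
            assert h.alleles["DYS389II"] >= h.alleles["DYS389I"]

    def test_panmixia_split_labels_show_no_structure(self):
        vals = []
        for seed in range(10):
            cfg = ScenarioConfig(
                model="PANMIXIA",
                pop_labels=("A", "B"),
                pop_sizes={"A": 100, "B": 100},
                split_time=10,
                burn_in=400,
                sample_sizes={"A": 50, "B": 50},
                seed=seed,
            )
            ds, _ = simulate(cfg)
            view = make_view(ds, ViewMode.DISTANCE)
            vals.append(pairwise_rst(view, permutations=0).values[0, 1])
        assert abs(float(np.mean(vals))) < 0.02

    def test_divergence_time_monotonicity(self):
        means = []
        for tau in (20, 200):
            vals = []
            for seed in range(8):
                cfg = small_cfg(split_time=tau, pop_sizes={"East": 500, "West": 500},
                                burn_in=200, seed=seed)
                ds, _ = simulate(cfg)
                view = make_view(ds, ViewMode.DISTANCE)
                vals.append(pairwise_rst(view, permutations=0).values[0, 1])
            means.append(float(np.mean(vals)))
        assert means[1] > means[0]

    def test_migration_recorded_only_on_declared_routes(self):
        cfg = small_cfg(model="DIVERGENCE_MIGRATION", migration=0.05)
        _, truth = simulate(cfg)
        assert set(truth.realized_migrants) == {("East", "West")}
        assert truth.realized_migrants[("East", "West")] > 0

    def test_admixture_pulse_fraction_increases_host_lineages(self):
        freqs = []
        for frac in (0.0, 0.2, 0.6):
            cfg = small_cfg(
                admixture_pulses=[{"target": "West", "time": 5, "fraction": frac}],
                seed=3,
            )
            _, truth = simulate(cfg)
            west = [v for k, v in truth.haplogroup_labels.items() if k.startswith("West")]
            freqs.append(sum(1 for l in west if l == HOST) / len(west))
        assert freqs[0] == 0.0
        assert freqs[0] <= freqs[1] <= freqs[2]
        assert freqs[2] > freqs[1]

    def test_host_haplotypes_are_divergent(self):
        cfg = small_cfg(
            admixture_pulses=[{"target": "West", "time": 5, "fraction": 0.5}], seed=4
        )
        ds, truth = simulate(cfg)
        view = make_view(ds, ViewMode.RHO)
        host_idx = [i for i, s in enumerate(view.sample_ids)
                    if truth.haplogroup_labels[s] == HOST]
        native_idx = [i for i, s in enumerate(view.sample_ids)
                      if truth.haplogroup_labels[s] != HOST]
        assert host_idx and native_idx
        d = np.abs(
            view.matrix[host_idx].mean(axis=0) - view.matrix[native_idx].mean(axis=0)
        ).sum()
        assert d > 2  # deep host divergence separates the lineages


class TestScenarioLibrary:
    def test_preset_inventory(self):
        presets = scenario_library()
        regional = [k for k in presets if k.startswith("iberia_")]
        assert len(regional) == 5
        assert "continental_chain" in presets
        assert len(presets) == 6

    def test_chain_preset_topology(self):
        cfg = scenario_library()["continental_chain"]
        assert cfg.model == "CHAIN_EAST_WEST"
        assert cfg.pop_labels == ("Greece", "Romania", "Slovakia", "Spain")
        assert cfg.migration > 0

    def test_divergence_preset_has_no_migration(self):
        cfg = scenario_library()["iberia_divergence"]
        assert cfg.model == "DIVERGENCE"
        assert cfg.migration == 0.0

    def test_yaml_round_trip(self, tmp_path):
        cfg = scenario_library()["iberia_divergence_bidir"]
        path = tmp_path / "scenario.yaml"
        cfg.to_yaml(path)
        back = ScenarioConfig.from_yaml(path)
        assert back == cfg

    def test_unknown_yaml_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("model: DIVERGENCE\nwarp_drive: 9\n")
        with pytest.raises(ValueError, match="warp_drive"):
            ScenarioConfig.from_yaml(path)


class TestFounderStar:
    def test_depth_zero_all_identical(self):
        ds, truth = founder_star(10, 0, seed=0)
        vecs = {tuple(h.alleles[l] for l in ds.panel.loci) for h in ds.haplotypes}
        assert len(vecs) == 1
        assert truth.genealogy_tmrca == {"Star": 0}

    def test_mean_rho_matches_saturated_expectation(self):
        """Mean rho over seeds equals 15 x E|D|(depth) under the SMM.

        The linear value depth*L*mu (7.5 here) overstates the expectation
        because back mutations partially cancel at depth*mu = 0.5/locus.
        """
        from ystrpop.rho_tmrca import rho as rho_stat

        expected = 15 * expected_abs_displacement(200, 2.5e-3)
        vals = []
        for seed in range(50):
            ds, _ = founder_star(200, 200, seed=seed)
            view = make_view(ds, ViewMode.RHO)
            ids = list(range(view.n))
            root = tuple(int(x) for x in np.asarray(
                [np.bincount(view.matrix[:, j]).argmax() for j in range(view.matrix.shape[1])]
            ))
            vals.append(rho_stat(view, root=root))
        assert float(np.mean(vals)) == pytest.approx(expected, rel=0.10)

    def test_doubling_depth_doubles_mean_rho_in_linear_regime(self):
        means = []
        for depth in (25, 50):
            vals = []
            for seed in range(40):
                ds, _ = founder_star(150, depth, seed=seed)
                view = make_view(ds, ViewMode.RHO)
                from ystrpop.rho_tmrca import rho as rho_stat

                vals.append(rho_stat(view))
            means.append(float(np.mean(vals)))
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.15)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            founder_star(5, -1)
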