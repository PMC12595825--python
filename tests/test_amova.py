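import numpy as np
import pytest

from conftest import two_pop_fixed_difference_view
from helpers_oracles import amova_one_level_oracle
from ystrpop.amova import amova, one_level_components, regional_contrast, squared_step_matrix
from ystrpop.distance import pairwise_rst
from ystrpop.io import ViewMode, view_from_matrix


def random_view(rng, n_per_pop, n_pops=3, loci=4, spread=3):
    rows, pops = [], []
    for p in range(n_pops):
        centre = rng.integers(10, 10 + spread, size=loci)
        for _ in range(n_per_pop):
            rows.append((centre + rng.integers(-1, 2, size=loci)).tolist())
            pops.append(f"P{p}")
    return view_from_matrix(rows, loci=[f"L{i}" for i in range(loci)], populations=pops)


class TestOneLevel:
    def test_worked_two_population_toy(self):
        v = two_pop_fixed_difference_view()
        c = one_level_components(squared_step_matrix(v), list(v.populations))
        assert c["ss_total"] == pytest.approx(4.0)
        assert c["ss_within"] == pytest.approx(0.0)
        assert c["sigma_among"] == pytest.approx(2.0)
        assert c["phi_st"] == pytest.approx(1.0)

    def test_all_identical_is_degenerate(self):
        v = view_from_matrix([[10]] * 6, loci=("L",), populations=["A"] * 3 + ["B"] * 3)
        t = amova(v, permutations=0)
        assert t.rows[0]["ss"] == 0.0
        assert np.isnan(t.rows[0]["percent"])

    def test_matches_bruteforce_oracle_on_random_toys(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            v = random_view(rng, n_per_pop=4, n_pops=3)
            c = one_level_components(squared_step_matrix(v), list(v.populations))
            o = amova_one_level_oracle(v.matrix, list(v.populations))
            for key in ("ss_total", "ss_among", "ss_within", "sigma_among", "sigma_within"):
                assert c[key] == pytest.approx(o[key], abs=1e-10)
            assert c["phi_st"] == pytest.approx(o["phi_st"], abs=1e-10)

    def test_unequal_sizes_match_oracle(self):
        rng = np.random.default_rng(12)
        rows = [[10 + int(rng.integers(0, 3))] for _ in range(9)]
        pops = ["A"] * 2 + ["B"] * 3 + ["C"] * 4
        v = view_from_matrix(rows, loci=("L",), populations=pops)
        c = one_level_components(squared_step_matrix(v), pops)
        o = amova_one_level_oracle(v.matrix, pops)
        assert c["sigma_among"] == pytest.approx(o["sigma_among"], abs=1e-10)

    def test_pooling_populations_collapses_among_component(self):
        rng = np.random.default_rng(13)
        v = random_view(rng, n_per_pop=10, n_pops=2)
        # a single pooled label is no longer a multi-population design
        with pytest.raises(ValueError):
            one_level_components(squared_step_matrix(v), ["ALL"] * v.n)
        # random halves of one homogeneous population: sigma2_among ~ 0
        rows = (10 + rng.integers(-1, 2, size=(40, 4))).tolist()
        labels = rng.permutation(["X"] * 20 + ["Y"] * 20).tolist()
        v2 = view_from_matrix(rows, loci=[f"L{i}" for i in range(4)], populations=labels)
        c = one_level_components(squared_step_matrix(v2), labels)
        assert abs(c["phi_st"]) < 0.1


class TestPhiStEqualsRst:
    def test_two_population_amova_equals_pairwise_rst_exactly(self):
        rng = np.random.default_rng(21)
        v = random_view(rng, n_per_pop=5, n_pops=2)
        c = one_level_components(squared_step_matrix(v), list(v.populations))
        mat = pairwise_rst(v, permutations=0)
        assert mat.values[0, 1] == pytest.approx(c["phi_st"], abs=1e-12)


class TestPermutations:
    def test_pvalues_match_enumeration_on_tiny_instance(self):
        # 2+2 individuals: all 4!/(2!2!) = 6 assignments, statistic symmetric
        v = view_from_matrix(
            [[10], [11], [13], [14]], loci=("L",), populations=("A", "A", "B", "B")
        )
        D = squared_step_matrix(v)
        obs = one_level_components(D, list(v.populations))["phi_st"]
        from itertools import permutations as iperm

        stats = []
        for perm in set(iperm(("A", "A", "B", "B"))):
            stats.append(one_level_components(D, list(perm))["phi_st"])
        exact = sum(1 for s in stats if s >= obs - 1e-12) / len(stats)
        t = amova(v, permutations=4999, seed=2)
        assert t.pvalues["Phi_ST"] == pytest.approx(exact, abs=0.03)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(31)
        v = random_view(rng, n_per_pop=4, n_pops=3)
        a = amova(v, permutations=199, seed=9)
        b = amova(v, permutations=199, seed=9)
        assert a.pvalues == b.pvalues


class TestNestedDesign:
    def test_df_and_percent_invariants(self):
        rng = np.random.default_rng(41)
        v = random_view(rng, n_per_pop=4, n_pops=4)
        groups = {"P0": "G1", "P1": "G1", "P2": "G2", "P3": "G2"}
        t = amova(v, groups=groups, permutations=99, seed=0)
        assert sum(r["df"] for r in t.rows) == v.n - 1
        if all(r["sigma2"] >= 0 for r in t.rows):
            assert sum(r["percent"] for r in t.rows) == pytest.approx(100.0, abs=0.01)
        assert set(t.phi) == {"Phi_ST", "Phi_CT", "Phi_SC"}

    def test_strong_group_structure_detected(self):
        rng = np.random.default_rng(42)
        rows, pops = [], []
        for p, centre in enumerate((10, 11, 30, 31)):
            for _ in range(5):
                rows.append([centre + int(rng.integers(-1, 2))])
                pops.append(f"P{p}")
        v = view_from_matrix(rows, loci=("L",), populations=pops)
        groups = {"P0": "G1", "P1": "G1", "P2": "G2", "P3": "G2"}
        t = amova(v, groups=groups, permutations=0)
        assert t.phi["Phi_CT"] > 0.8


class TestRegionalContrast:
    @staticmethod
    def _cohort(rng, prefix, n_regions, n, sigma_a):
        """Regional samples with among-region variance sigma_a per locus."""
        rows, ids, regions = [], [], {}
        region_names = ("Centre", "North", "South", "West", "East")[:n_regions]
        for r, name in enumerate(region_names):
            shift = rng.normal(0, np.sqrt(sigma_a), size=8)
            for k in range(n):
                noise = rng.normal(0, np.sqrt(2.0), size=8)
                rows.append(np.round(20 + shift + noise).astype(int).tolist())
                sid = f"{prefix}{name}{k}"
                ids.append(sid)
                regions[sid] = name
        return rows, ids, regions

    def test_simulated_six_fold_contrast(self):
        rng = np.random.default_rng(5)
        # within-locus variance ~2; sigma_a chosen for ~3% and ~0.5% among
        rows_a, ids_a, part_a = self._cohort(rng, "a", 5, 60, sigma_a=2.0 * 0.031)
        rows_b, ids_b, part_b = self._cohort(rng, "b", 5, 60, sigma_a=2.0 * 0.005)
        rows = rows_a + rows_b
        ids = ids_a + ids_b
        pops = ["A"] * len(ids_a) + ["B"] * len(ids_b)
        v = view_from_matrix(rows, loci=[f"L{i}" for i in range(8)], populations=pops, sample_ids=ids)
        res = regional_contrast(v, part_a, part_b, permutations=0)
        assert 3.0 < res.ratio < 12.0

    def test_identical_cohorts_ratio_one(self):
        rng = np.random.default_rng(6)
        rows, ids, part = self._cohort(rng, "x", 3, 20, sigma_a=0.1)
        part_b = {f"y{k[1:]}": v for k, v in part.items()}
        ids_b = [f"y{i[1:]}" for i in ids]
        v = view_from_matrix(
            rows + rows,
            loci=[f"L{i}" for i in range(8)],
            populations=["A"] * len(ids) + ["B"] * len(ids),
            sample_ids=ids + ids_b,
        )
        res = regional_contrast(v, part, part_b, permutations=0)
        assert res.ratio == pytest.approx(1.0)

    def test_single_region_cohort_is_error(self):
        rng = np.random.default_rng(7)
        rows, ids, part = self._cohort(rng, "x", 1, 10, sigma_a=0.1)
        v = view_from_matrix(
            rows, loci=[f"L{i}" for i in range(8)], populations=["A"] * len(ids), sample_ids=ids
        )
        with pytest.raises(ValueError):
            regional_contrast(v, part, part, permutations=0)
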