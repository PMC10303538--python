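"""βMNTD/βNTI, Raup–Crick and process classification."""

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from subcomm.assembly import (assembly_analysis, beta_mntd, beta_nti,
                              classify_process, patristic_matrix,
                              process_fractions, rc_bray)
from subcomm.containers import CommunityTable, DistanceMatrix, ValidationError
from subcomm.simulate import preset_config, simulate_dataset


def table_of(taxa, columns):
    return CommunityTable(taxa, [f"s{i}" for i in range(len(columns))],
                          np.array(columns, dtype=float).T)


class TestPatristic:
    def test_hand_path_sums(self, three_tip_tree):
        pdm = patristic_matrix(three_tip_tree)
        d = pdm.to_frame()
        assert d.loc["A", "B"] == pytest.approx(2.0, abs=1e-12)
        assert d.loc["A", "C"] == pytest.approx(3.0, abs=1e-12)
        assert d.loc["B", "C"] == pytest.approx(3.0, abs=1e-12)

    def test_cherry(self):
        pdm = patristic_matrix(TreeNode.read(["(A:1,B:1);"]))
        assert pdm.to_frame().loc["A", "B"] == pytest.approx(2.0)

    def test_four_point_condition_on_yule_trees(self):
        from subcomm.simulate import SimulationConfig, simulate_tree
        rng = np.random.default_rng(0)
        tree = simulate_tree(SimulationConfig(n_taxa=30, seed=14))
        pdm = patristic_matrix(tree)
        for _ in range(50):
            i, j, k, l = rng.choice(30, size=4, replace=False)
            d = pdm.values
            sums = sorted([d[i, j] + d[k, l], d[i, k] + d[j, l],
                           d[i, l] + d[j, k]])
            assert sums[1] == pytest.approx(sums[2], abs=1e-9)


class TestBetaMNTD:
    def test_identical_communities_zero(self, three_tip_tree):
        pdm = patristic_matrix(three_tip_tree)
        t = table_of(["A", "B", "C"], [[1, 2, 3], [1, 2, 3]])
        assert beta_mntd(t, pdm, ("s0", "s1")) == pytest.approx(0.0, abs=1e-12)

    def test_single_taxon_cherry(self):
        pdm = patristic_matrix(TreeNode.read(["(A:1,B:1);"]))
        t = table_of(["A", "B"], [[1, 0], [0, 1]])
        assert beta_mntd(t, pdm, ("s0", "s1")) == pytest.approx(2.0, abs=1e-9)

    def test_weighted_hand_example(self, three_tip_tree):
        # j = {A:0.5, B:0.5}, k = {C:1}: 0.5*[(0.5*3 + 0.5*3) + 1*3] = 3
        pdm = patristic_matrix(three_tip_tree)
        t = table_of(["A", "B", "C"], [[1, 1, 0], [0, 0, 5]])
        assert beta_mntd(t, pdm, ("s0", "s1")) == pytest.approx(3.0, abs=1e-9)

    def test_symmetric_in_pair(self, three_tip_tree):
        pdm = patristic_matrix(three_tip_tree)
        t = table_of(["A", "B", "C"], [[3, 1, 0], [0, 2, 2]])
        assert beta_mntd(t, pdm, ("s0", "s1")) == pytest.approx(
            beta_mntd(t, pdm, ("s1", "s0")), abs=1e-12)

    def test_matches_picante_style_reference(self):
        """Independent oracle: brute-force βMNTD via explicit python loops."""
        rng = np.random.default_rng(4)
        from subcomm.simulate import SimulationConfig, simulate_tree
        tree = simulate_tree(SimulationConfig(n_taxa=12, seed=2))
        pdm = patristic_matrix(tree)
        counts = rng.integers(0, 10, size=(12, 2)).astype(float)
        counts[0, :] = 1  # keep both samples non-empty
        t = CommunityTable(list(pdm.ids), ["x", "y"], counts)
        got = beta_mntd(t, pdm, ("x", "y"))
        # brute force
        rel = counts / counts.sum(axis=0)
        total = 0.0
        for a, b in ((0, 1), (1, 0)):
            for i in range(12):
                if counts[i, a] > 0:
                    dmin = min(pdm.values[i, j] for j in range(12)
                               if counts[j, b] > 0)
                    total += 0.5 * rel[i, a] * dmin
        assert got == pytest.approx(total, abs=1e-12)


class TestBetaNTI:
    def test_identical_communities_undefined(self, three_tip_tree):
        pdm = patristic_matrix(three_tip_tree)
        t = table_of(["A", "B", "C"], [[1, 2, 3], [1, 2, 3]])
        res = beta_nti(t, pdm, n_null=199, seed=0)
        assert bool(res["undefined"].iloc[0])
        assert np.isnan(res["beta_nti"].iloc[0])

    def test_star_phylogeny_undefined(self):
        pdm = patristic_matrix(TreeNode.read(["(A:1,B:1,C:1,D:1);"]))
        t = table_of(["A", "B", "C", "D"], [[1, 1, 0, 0], [0, 0, 1, 1]])
        res = beta_nti(t, pdm, n_null=199, seed=0)
        assert bool(res["undefined"].iloc[0])

    def test_branch_length_scale_invariance(self, sim_dataset):
        table, tree, meta, _ = sim_dataset
        ids = sorted(meta["sample_id"])[:8]
        sub = table.select_samples(ids)
        pdm = patristic_matrix(tree)
        r1 = beta_nti(sub, pdm, n_null=99, seed=5)
        pdm_scaled = DistanceMatrix(pdm.ids, pdm.values * 3.7)
        r2 = beta_nti(sub, pdm_scaled, n_null=99, seed=5)
        valid = ~r1["undefined"]
        assert np.allclose(r1.loc[valid, "beta_nti"],
                           r2.loc[valid, "beta_nti"], atol=1e-9)

    def test_too_few_nulls_rejected(self, three_tip_tree):
        pdm = patristic_matrix(three_tip_tree)
        t = table_of(["A", "B", "C"], [[1, 0, 1], [0, 1, 1]])
        with pytest.raises(ValidationError):
            beta_nti(t, pdm, n_null=1)


class TestRcBray:
    @pytest.fixture
    def shared_pool(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 30, size=(20, 8)).astype(float)
        return CommunityTable([f"t{i}" for i in range(20)],
                              [f"s{i}" for i in range(8)], counts)

    def test_bounded(self, shared_pool):
        rc = rc_bray(shared_pool, ("s0", "s1"), n_null=99, seed=0)
        assert -1.0 <= rc <= 1.0

    def test_identical_samples_rc_minus_one(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 20, size=(25, 6)).astype(float)
        counts[:, 1] = counts[:, 0]  # duplicate sample
        counts[0, :] = np.maximum(counts[0, :], 1)
        t = CommunityTable([f"t{i}" for i in range(25)],
                           [f"s{i}" for i in range(6)], counts)
        rc = rc_bray(t, ("s0", "s1"), n_null=199, seed=0)
        assert rc == pytest.approx(-1.0, abs=1e-9)

    def test_disjoint_samples_in_shared_pool_near_plus_one(self):
        # pool of widely shared taxa, but the focal pair is fully disjoint
        rng = np.random.default_rng(5)
        counts = rng.integers(5, 30, size=(30, 10)).astype(float)
        counts[:15, 0] = 0.0
        counts[15:, 1] = 0.0
        t = CommunityTable([f"t{i}" for i in range(30)],
                           [f"s{i}" for i in range(10)], counts)
        rc = rc_bray(t, ("s0", "s1"), n_null=999, seed=0)
        assert rc > 0.95

    def test_seed_to_seed_spread_small(self, shared_pool):
        rcs = [rc_bray(shared_pool, ("s2", "s5"), n_null=999, seed=s)
               for s in range(5)]
        assert np.ptp(rcs) < 0.1

    def test_richness_above_pool_rejected(self):
        t = table_of(["a", "b"], [[1, 1], [1, 1]])
        with pytest.raises(ValidationError, match="pool"):
            rc_bray(t, ("s0", "s1"), n_null=9, pool=["s0"], seed=0)
        # (pool lacking the pair's sample is also an error)


class TestClassification:
    @pytest.mark.parametrize("bnti, rc, expected", [
        (2.5, 0.0, "variable_selection"),
        (-2.5, 0.0, "homogeneous_selection"),
        (1.0, 0.97, "dispersal_limitation"),
        (1.0, -0.97, "homogenizing_dispersal"),
        (0.5, 0.2, "undominated"),
        (2.0, 0.2, "undominated"),      # boundary |βNTI| = 2 is stochastic
        (0.0, 0.95, "undominated"),     # boundary |RC| = 0.95 is undominated
        (np.nan, 0.5, "undefined"),
    ])
    def test_threshold_logic(self, bnti, rc, expected):
        assert classify_process(bnti, rc) == expected

    def test_fractions_sum_to_one(self):
        df = pd.DataFrame({"process": ["variable_selection"] * 3 +
                           ["undominated"] * 5 + ["dispersal_limitation"] * 2,
                           "group": ["g"] * 10})
        out = process_fractions(df, by=["group"])
        procs = ["variable_selection", "homogeneous_selection",
                 "dispersal_limitation", "homogenizing_dispersal", "undominated"]
        assert out[procs].iloc[0].sum() == pytest.approx(1.0, abs=1e-9)
        assert out["deterministic"].iloc[0] == pytest.approx(0.3)
        assert out["stochastic"].iloc[0] == pytest.approx(0.7)

    def test_all_selection_deterministic_fraction_one(self):
        df = pd.DataFrame({"process": ["variable_selection"] * 4})
        out = process_fractions(df)
        assert out["deterministic"].iloc[0] == 1.0


class TestEndToEnd:
    def test_assembly_analysis_order_independent(self):
        cfg = preset_config("filtering", seed=41, n_taxa=40,
                            n_sites_per_group={"untilled": 6}, read_depth=5000)
        table, tree, _, _ = simulate_dataset(cfg)
        full = assembly_analysis(table, tree, n_null=99, seed=3, rc_all=True)
        # recompute a single pair's RC with its derived child seed: must match
        pidx = 4
        child = np.random.SeedSequence(entropy=3, spawn_key=(pidx,))
        rc = rc_bray(table, (full["sample_1"][pidx], full["sample_2"][pidx]),
                     n_null=99, seed=child)
        assert rc == pytest.approx(full["rc_bray"][pidx], abs=1e-12)
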