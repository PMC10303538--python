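"""Bray–Curtis, PCoA, PERMANOVA, ANOSIM and dispersion homogeneity,
including cross-checks against scikit-bio's independent implementations."""

import numpy as np
import pandas as pd
import pytest

from subcomm.beta import (anosim, bray_curtis, dispersion_homogeneity,
                          pcoa, permanova, permanova_exact)
from subcomm.containers import CommunityTable, DistanceMatrix, ValidationError
from tests.conftest import random_euclidean_dm


def dm_from_points(points):
    pts = np.asarray(points, dtype=float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix([f"s{i}" for i in range(len(pts))], d)


class TestBrayCurtis:
    def test_hand_example(self, small_table):
        # columns [2,0,1] vs [1,1,0]: (1+1+1)/(3+2) = 0.6
        d = bray_curtis(small_table)
        assert d.values[0, 1] == pytest.approx(0.6, abs=1e-9)

    def test_identical_and_disjoint_columns(self):
        table = CommunityTable(["a", "b"], ["s1", "s2", "s3"],
                               np.array([[3.0, 3.0, 0.0], [0.0, 0.0, 5.0]]))
        d = bray_curtis(table)
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == pytest.approx(1.0)

    def test_matches_scipy(self, sim_dataset):
        from scipy.spatial.distance import pdist, squareform
        table, _, _, _ = sim_dataset
        ours = bray_curtis(table).values
        ref = squareform(pdist(table.counts.T, metric="braycurtis"))
        assert np.allclose(ours, ref, atol=1e-12)


class TestPcoa:
    def test_collinear_points_single_axis_reconstructs_distances(self):
        d = dm_from_points([[0.0], [1.0], [3.0], [7.0]])
        res = pcoa(d)
        assert res.eigenvalues[0] > 0
        assert np.all(res.eigenvalues[1:] < 1e-8)
        coords = res.axes[:, [0]]
        recon = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        assert np.allclose(recon, d.values, atol=1e-8)

    def test_euclidean_input_no_negative_eigenvalues(self):
        d = random_euclidean_dm(np.random.default_rng(0), 12)
        res = pcoa(d)
        assert np.all(res.eigenvalues > -1e-8)

    def test_coordinates_centred(self, sim_dataset):
        table, _, _, _ = sim_dataset
        res = pcoa(bray_curtis(table, relative=True))
        assert np.allclose(res.axes.mean(axis=0), 0.0, atol=1e-9)

    def test_matches_skbio(self, sim_dataset):
        import skbio
        table, _, _, _ = sim_dataset
        d = bray_curtis(table, relative=True)
        ours = pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values, d.ids), number_of_dimensions=3)
        assert np.allclose(ours.eigenvalues[:3], ref.eigvals.values[:3], atol=1e-8)
        for ax in range(2):  # eigenvector sign is arbitrary
            assert np.allclose(np.abs(ours.axes[:, ax]),
                               np.abs(ref.samples.values[:, ax]), atol=1e-6)


class TestPermanova:
    def test_no_structure_gives_f_zero_p_one(self):
        table = CommunityTable(["a", "b"], [f"s{i}" for i in range(6)],
                               np.tile([[2.0], [3.0]], 6))
        d = bray_curtis(table)
        res = permanova(d, ["x"] * 3 + ["y"] * 3, n_perm=99, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_monte_carlo_matches_exact_enumeration(self):
        rng = np.random.default_rng(4)
        d = random_euclidean_dm(rng, 6)
        groups = ["x"] * 3 + ["y"] * 3
        exact = permanova_exact(d, groups)
        mc = permanova(d, groups, n_perm=9999, seed=1)
        assert exact.n_permutations == 20
        # binomial error at n=9999 around the exact p
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 9999)
        assert abs(mc.p_value - exact.p_value) < max(4 * se, 0.02)

    def test_separated_clusters_significant(self):
        rng = np.random.default_rng(8)
        pts = np.vstack([rng.normal(0, 0.3, (10, 3)), rng.normal(3, 0.3, (10, 3))])
        d = dm_from_points(pts)
        res = permanova(d, ["a"] * 10 + ["b"] * 10, n_perm=9999, seed=0)
        assert res.p_value <= 0.001 + 1e-9

    def test_matches_skbio_statistic(self, sim_dataset):
        import skbio
        table, _, meta, _ = sim_dataset
        d = bray_curtis(table, relative=True)
        groups = meta.loc[d.ids, "group"].tolist()
        ours = permanova(d, groups, n_perm=9, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, d.ids), groups, permutations=9)
        assert ours.statistic == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_single_member_group_rejected(self):
        d = random_euclidean_dm(np.random.default_rng(1), 5)
        with pytest.raises(ValidationError):
            permanova(d, ["a", "a", "a", "a", "b"])


class TestAnosim:
    def test_perfect_separation_r_is_one(self):
        pts = [[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]]
        res = anosim(dm_from_points(pts), ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)

    def test_null_calibration_mean_r_near_zero(self):
        rng = np.random.default_rng(12)
        rs = []
        for _ in range(200):
            d = random_euclidean_dm(rng, 12)
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            rs.append(anosim(d, labels, n_perm=1, seed=0).statistic)
        assert abs(np.mean(rs)) < 0.05

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        d = random_euclidean_dm(rng, 10)
        labels = ["a"] * 5 + ["b"] * 5
        r1 = anosim(d, labels, n_perm=9, seed=0).statistic
        d2 = DistanceMatrix(d.ids, np.sqrt(d.values))
        r2 = anosim(d2, labels, n_perm=9, seed=0).statistic
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_matches_skbio_statistic(self, sim_dataset):
        import skbio
        table, _, meta, _ = sim_dataset
        d = bray_curtis(table, relative=True)
        groups = meta.loc[d.ids, "group"].tolist()
        ours = anosim(d, groups, n_perm=9, seed=0)
        ref = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(d.values, d.ids), groups, permutations=9)
        assert ours.statistic == pytest.approx(ref["test statistic"], rel=1e-9)


class TestDispersion:
    def test_halved_spread_detected(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 1.0, (15, 4)), rng.normal(0, 0.3, (15, 4))])
        d = dm_from_points(pts)
        per_sample, res = dispersion_homogeneity(
            d, ["wide"] * 15 + ["narrow"] * 15, n_perm=999, seed=0)
        means = per_sample.groupby("group")["distance_to_centroid"].mean()
        assert means["narrow"] < means["wide"]
        assert res.p_value <= 0.05

    def test_single_member_group_distance_zero(self):
        d = random_euclidean_dm(np.random.default_rng(2), 6)
        per_sample, _ = dispersion_homogeneity(
            d, ["a"] * 5 + ["b"], n_perm=9, seed=0)
        assert per_sample.loc[per_sample["group"] == "b",
                              "distance_to_centroid"].iloc[0] == pytest.approx(0.0)

    def test_matches_vegan_betadisper_distances(self, sim_dataset):
        """Non-Euclidean Bray–Curtis input: centroid distances must follow the
        real-minus-imaginary axis correction (betadisper's treatment)."""
        table, _, meta, _ = sim_dataset
        d = bray_curtis(table, relative=True)
        groups = meta.loc[d.ids, "group"]
        per_sample, _ = dispersion_homogeneity(d, groups, n_perm=9, seed=0)
        # independent route: squared distance to centroid computed from the
        # raw distance matrix identity  mean_i d(x,c_g)^2 over group members
        #   d(x, c)^2 = mean_j d(x,j)^2 - (1/2) mean_{j,k} d(j,k)^2
        for g in groups.unique():
            idx = np.flatnonzero((groups == g).to_numpy())
            sub = d.values[np.ix_(idx, idx)] ** 2
            expected = sub.mean(axis=1) - sub.mean() / 2.0
            got = per_sample.loc[per_sample["group"] == g,
                                 "distance_to_centroid"].to_numpy() ** 2
            assert np.allclose(got, np.clip(expected, 0, None), atol=1e-8)
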