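"""UPGMA, tree cutting, PCoA, PERMANOVA, dispersion, decay correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from limnoecol._errors import InvalidConfigError
from limnoecol.diversity import DistanceMatrix
from limnoecol.structure import (
    GroupAssignment,
    cut_tree,
    decay_correlation,
    dispersion_test,
    haversine_km,
    pcoa,
    permanova,
    upgma,
)


def _dm(values, ids):
    return DistanceMatrix(pd.DataFrame(values, index=ids, columns=ids))


def _random_dm(rng, n):
    pts = rng.normal(size=(n, 3))
    ids = [f"s{i}" for i in range(n)]
    return _dm(squareform(pdist(pts)), ids), pts


class TestUpgma:
    def test_hand_three_sample_case(self):
        d = _dm([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ["A", "B", "C"])
        dend = upgma(d)
        assert dend.merges[0] == (("A",), ("B",), 2.0)
        assert dend.merges[1][2] == pytest.approx(4.0)

    def test_all_equal_distances_tie_break_deterministic(self):
        d = _dm(1 - np.eye(4), ["d", "c", "b", "a"])
        dend = upgma(d)
        assert dend.merges[0][0] == ("a",) and dend.merges[0][1] == ("b",)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        d, _ = _random_dm(rng, 8)
        perm = rng.permutation(8)
        ids = list(d.values_df.columns)
        shuffled = DistanceMatrix(
            d.values_df.iloc[perm, perm]
        )
        assert upgma(d).merges == upgma(shuffled).merges

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            d, _ = _random_dm(rng, 8)
            dend = upgma(d)
            z = linkage(d.condensed(), method="average")
            assert sorted(m[2] for m in dend.merges) == pytest.approx(
                sorted(z[:, 2]), rel=1e-10
            )
            # ultrametric cophenetic heights agree pairwise
            coph = squareform(cophenet(z))
            ids = list(d.values_df.columns)
            mine = np.zeros((8, 8))
            for left, right, h in dend.merges:
                for a in left:
                    for b in right:
                        i, j = ids.index(a), ids.index(b)
                        mine[i, j] = mine[j, i] = h
            assert np.allclose(mine, coph, atol=1e-10)

    def test_nan_rejected(self):
        v = 1 - np.eye(3)
        v[0, 1] = v[1, 0] = np.nan
        with pytest.raises(InvalidConfigError):
            upgma(DistanceMatrix(pd.DataFrame(v, index=list("abc"), columns=list("abc"))))


class TestCutTree:
    def test_extreme_ks(self):
        rng = np.random.default_rng(3)
        d, _ = _random_dm(rng, 6)
        dend = upgma(d)
        assert cut_tree(dend, 1).labels.nunique() == 1
        assert cut_tree(dend, 6).labels.nunique() == 6

    def test_hand_case_k2(self):
        d = _dm([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ["A", "B", "C"])
        groups = cut_tree(upgma(d), 2)
        assert groups.labels["A"] == groups.labels["B"] != groups.labels["C"]

    def test_k_out_of_range(self):
        d = _dm([[0, 1], [1, 0]], ["a", "b"])
        with pytest.raises(InvalidConfigError):
            cut_tree(upgma(d), 3)


class TestPcoa:
    def test_collinear_points_one_dominant_axis(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        ids = list("abcd")
        d = _dm(np.abs(x[:, None] - x[None, :]), ids)
        res = pcoa(d)
        ev = res.eigenvalues
        assert ev[0] > 0 and ev[0] > 10 * max(np.abs(ev[1:]).max(), 1e-12)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 2))
        ids = [f"s{i}" for i in range(7)]
        d = _dm(squareform(pdist(pts)), ids)
        res = pcoa(d)
        back = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(back, d.values_df.to_numpy(), atol=1e-8)

    def test_matches_skbio_oracle(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from skbio import DistanceMatrix as SkbioDM

        rng = np.random.default_rng(5)
        d, _ = _random_dm(rng, 6)
        res = pcoa(d)
        ref = skbio_pcoa(SkbioDM(d.values_df.to_numpy(), ids=d.sample_ids))
        n_pos = res.coordinates.shape[1]
        assert np.allclose(
            np.sort(res.eigenvalues[:n_pos]),
            np.sort(ref.eigvals.to_numpy()[:n_pos]),
            atol=1e-8,
        )

    def test_duplicate_samples_coincide(self):
        v = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        res = pcoa(_dm(v, list("abc")))
        assert np.allclose(res.coordinates.loc["a"], res.coordinates.loc["b"], atol=1e-10)


class TestPermanova:
    def test_complete_separation_saturates_p(self):
        # n large enough that no random relabeling reproduces the partition
        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(0, 0.1, (8, 2)), rng.normal(50, 0.1, (8, 2))])
        ids = [f"s{i}" for i in range(16)]
        d = _dm(squareform(pdist(pts)), ids)
        groups = GroupAssignment(pd.Series(["A"] * 8 + ["B"] * 8, index=ids), 2)
        f, r2, p = permanova(d, groups, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)
        assert 0.9 < r2 <= 1.0

    def test_null_case_small_r2(self):
        rng = np.random.default_rng(7)
        d, _ = _random_dm(rng, 12)
        ids = d.sample_ids
        groups = GroupAssignment(pd.Series(["A"] * 6 + ["B"] * 6, index=ids), 2)
        _, r2, p = permanova(d, groups, n_perm=199, seed=1)
        assert r2 < 0.3 and p > 0.05

    def test_singleton_group_rejected(self):
        rng = np.random.default_rng(8)
        d, _ = _random_dm(rng, 5)
        groups = pd.Series(["A"] * 4 + ["B"], index=d.sample_ids)
        with pytest.raises(InvalidConfigError):
            permanova(d, GroupAssignment(groups, 2), n_perm=9, seed=0)

    def test_r2_increases_with_group_separation(self):
        rng = np.random.default_rng(9)
        r2s = []
        for sep in (0.0, 1.0, 3.0, 8.0):
            pts = np.vstack([rng.normal(0, 1, (6, 2)), rng.normal(sep, 1, (6, 2))])
            ids = [f"s{i}" for i in range(12)]
            d = _dm(squareform(pdist(pts)), ids)
            groups = GroupAssignment(pd.Series(["A"] * 6 + ["B"] * 6, index=ids), 2)
            _, r2, _ = permanova(d, groups, n_perm=9, seed=0)
            r2s.append(r2)
        assert all(b > a for a, b in zip(r2s[1:], r2s[2:]))
        assert 0 <= min(r2s) and max(r2s) <= 1


class TestDispersion:
    def test_tight_vs_diffuse_detected(self):
        rng = np.random.default_rng(10)
        pts = np.vstack([rng.normal(0, 0.05, (8, 2)), rng.normal(0, 3.0, (8, 2))])
        ids = [f"s{i}" for i in range(16)]
        d = _dm(squareform(pdist(pts)), ids)
        groups = GroupAssignment(pd.Series(["A"] * 8 + ["B"] * 8, index=ids), 2)
        f, p, disp = dispersion_test(d, groups, n_perm=199, seed=0)
        assert p < 0.05
        assert disp["B"] > disp["A"]

    def test_equal_spread_not_significant(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(16, 2))
        ids = [f"s{i}" for i in range(16)]
        d = _dm(squareform(pdist(pts)), ids)
        groups = GroupAssignment(pd.Series(["A"] * 8 + ["B"] * 8, index=ids), 2)
        _, p, _ = dispersion_test(d, groups, n_perm=199, seed=0)
        assert p > 0.05


class TestDecayCorrelation:
    def test_self_covariate_rho_one(self):
        rng = np.random.default_rng(12)
        d, _ = _random_dm(rng, 8)
        sim = 1 - d.values_df
        rho, _ = decay_correlation(sim, sim, n_perm=19, seed=0)
        assert rho == pytest.approx(1.0)

    def test_independent_matrices_rho_near_zero(self):
        rng = np.random.default_rng(13)
        rhos = []
        for _ in range(20):
            a, _ = _random_dm(rng, 10)
            b, _ = _random_dm(rng, 10)
            b.values_df.index = b.values_df.columns = a.sample_ids
            rho, _ = decay_correlation(1 - a.values_df, b.values_df,
                                       n_perm=19, seed=0)
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.15

    def test_constant_covariate_errors(self):
        rng = np.random.default_rng(14)
        d, _ = _random_dm(rng, 5)
        const = pd.DataFrame(1.0, index=d.sample_ids, columns=d.sample_ids)
        with pytest.raises(InvalidConfigError):
            decay_correlation(1 - d.values_df, const, n_perm=9, seed=0)


class TestHaversine:
    def test_one_degree_of_latitude(self):
        lat = pd.Series({"a": 0.0, "b": 1.0})
        lon = pd.Series({"a": 0.0, "b": 0.0})
        d = haversine_km(lat, lon)
        assert d.loc["a", "b"] == pytest.approx(np.pi * 6371.0088 / 180, rel=1e-9)
        assert d.loc["a", "a"] == 0.0
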