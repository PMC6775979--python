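import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from featherbiome.containers import DistMatrix, OtuTable, SampleMetadata
from featherbiome.ordination import (
    mantel,
    nmds,
    pcoa,
    permanova,
    ward_cluster_heatmap_data,
    ward_merge_sequence,
)

from .conftest import euclidean_dm
from .oracles import mantel_exhaustive, permanova_exhaustive, ward_merge_brute


class TestPcoa:
    def test_euclidean_distances_recovered(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(7, 2))
        res = pcoa(euclidean_dm(pts))
        rec = squareform(pdist(res.coords))
        np.testing.assert_allclose(rec, squareform(pdist(pts)), atol=1e-8)

    def test_collinear_points_single_axis(self):
        d = euclidean_dm([[0.0], [1.0], [2.0]])
        res = pcoa(d)
        pos = res.eigenvalues[res.eigenvalues > 1e-8]
        assert len(pos) == 1
        # the one positive eigenvalue equals the centred sum of squares
        assert pos[0] == pytest.approx(2.0)
        np.testing.assert_allclose(np.sort(res.coords[:, 0]), [-1, 0, 1], atol=1e-9)

    def test_zero_matrix_all_zero_eigenvalues(self):
        d = DistMatrix(list("abc"), np.zeros((3, 3)))
        res = pcoa(d)
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_euclidean_input_no_negative_eigenvalues(self):
        rng = np.random.default_rng(3)
        res = pcoa(euclidean_dm(rng.normal(size=(10, 4))))
        assert res.eigenvalues.min() > -1e-8


class TestNmds:
    def test_exact_config_low_stress(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 2))
        res = nmds(euclidean_dm(pts), k=2, n_restarts=4, seed=0)
        assert res.stress < 0.01

    def test_more_restarts_never_worse(self):
        rng = np.random.default_rng(2)
        d = euclidean_dm(rng.normal(size=(10, 4)))
        s2 = nmds(d, k=2, n_restarts=2, seed=5).stress
        s8 = nmds(d, k=2, n_restarts=8, seed=5).stress
        assert s8 <= s2 + 1e-9

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        d = euclidean_dm(rng.normal(size=(11, 3)))
        d_t = DistMatrix(d.labels, d.values ** 1.7)
        s = nmds(d, k=2, n_restarts=6, seed=1).stress
        s_t = nmds(d_t, k=2, n_restarts=6, seed=1).stress
        assert abs(s - s_t) < 1e-3

    def test_degenerate_all_equal_flagged(self):
        v = np.ones((5, 5)) - np.eye(5)
        with pytest.warns(UserWarning, match="all dissimilarities equal"):
            res = nmds(DistMatrix(list("abcde"), v), k=2, seed=0)
        assert res.stress == 0.0 and not res.converged


class TestPermanova:
    def test_exhaustive_two_groups_of_two(self):
        # two tight pairs far apart: observed F is maximal, p = 1/3
        pts = np.array([[0.0, 0], [0.1, 0], [10, 0], [10.1, 0]])
        d = euclidean_dm(pts)
        groups = ["a", "a", "b", "b"]
        perms = np.array(
            [p for p in itertools.permutations(range(4)) if p != (0, 1, 2, 3)]
        )
        res = permanova(d, groups, permutations=perms)
        F_or, p_or = permanova_exhaustive(d.values ** 2, np.array(groups))
        assert res.statistic == pytest.approx(F_or)
        assert res.p_perm == pytest.approx(p_or) == pytest.approx(1 / 3)

    def test_exhaustive_n5_matches_oracle(self):
        rng = np.random.default_rng(8)
        d = euclidean_dm(rng.normal(size=(5, 2)))
        groups = np.array(["a", "a", "b", "b", "b"])
        perms = np.array(
            [p for p in itertools.permutations(range(5)) if p != tuple(range(5))]
        )
        res = permanova(d, groups, permutations=perms)
        F_or, p_or = permanova_exhaustive(d.values ** 2, groups)
        assert res.statistic == pytest.approx(F_or)
        assert res.p_perm == pytest.approx(p_or)

    def test_single_group_errors(self):
        d = euclidean_dm(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError):
            permanova(d, ["a"] * 4)

    def test_type_one_error_near_nominal(self):
        """Free-permutation PERMANOVA keeps its nominal 5% size."""
        rng = np.random.default_rng(99)
        groups = np.repeat([0, 1], 6)
        rej = 0
        n_sim = 500
        for i in range(n_sim):
            d = euclidean_dm(rng.normal(size=(12, 3)))
            rej += permanova(d, groups, n_perm=199, seed=i).p_perm <= 0.05
        assert 0.03 <= rej / n_sim <= 0.07


class TestMantel:
    def test_perfect_and_inverted_correlation(self):
        rng = np.random.default_rng(4)
        d1 = euclidean_dm(rng.normal(size=(6, 2)))
        assert mantel(d1, d1, n_perm=99, seed=0).statistic == pytest.approx(1.0)
        inv = d1.values.max() - d1.values
        np.fill_diagonal(inv, 0)
        d2 = DistMatrix(d1.labels, inv)
        assert mantel(d1, d2, n_perm=99, seed=0).statistic == pytest.approx(-1.0)

    def test_exhaustive_enumeration_n4(self):
        rng = np.random.default_rng(5)
        d1 = euclidean_dm(rng.normal(size=(4, 2)))
        d2 = euclidean_dm(rng.normal(size=(4, 2)), labels=d1.labels)
        perms = np.array(
            [p for p in itertools.permutations(range(4)) if p != tuple(range(4))]
        )
        res = mantel(d1, d2, permutations=perms)
        r_or, p_or = mantel_exhaustive(d1.values, d2.values)
        assert res.statistic == pytest.approx(r_or)
        assert res.p_perm == pytest.approx(p_or)

    def test_zero_variance_errors(self):
        v = np.ones((4, 4)) - np.eye(4)
        d_flat = DistMatrix(list("abcd"), v)
        d = euclidean_dm(np.random.default_rng(0).normal(size=(4, 2)),
                         labels=list("abcd"))
        with pytest.raises(ValueError, match="variance"):
            mantel(d, d_flat)


class TestWard:
    def test_merge_sequence_matches_ess_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            pts = rng.normal(size=(5, 3))
            got = ward_merge_sequence(pts)
            want = ward_merge_brute(pts)
            assert [set(m) for m in got] == [set(m) for m in want]

    def test_identical_samples_merge_first(self):
        pts = np.array([[0.0, 0], [5, 5], [0, 0], [9, 1]])
        first = ward_merge_sequence(pts)[0]
        assert set(first) == {0, 2}

    def test_heatmap_threshold_and_orders(self, small_study):
        tab, meta = small_study["otu_table"], small_study["metadata"]
        rows, cols, mat = ward_cluster_heatmap_data(tab, meta, 0.0)
        assert mat.shape[0] == len(tab.otu_ids)  # threshold 0 keeps all OTUs
        assert sorted(rows.tolist()) == list(range(mat.shape[0]))
        assert sorted(cols.tolist()) == list(range(mat.shape[1]))
        with pytest.raises(ValueError, match="threshold"):
            ward_cluster_heatmap_data(tab, meta, 2.0)
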