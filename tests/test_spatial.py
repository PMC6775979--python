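import numpy as np
import pandas as pd
import pytest

from featherbiome.containers import DistMatrix, SampleMetadata
from featherbiome.ordination import pcoa
from featherbiome.spatial import (
    adjusted_r2,
    dbrda,
    forward_select,
    geo_distances,
    pcnm,
    species_dummies,
    varpart2,
)

from .conftest import euclidean_dm


def _meta(lat, lon):
    n = len(lat)
    return SampleMetadata(
        pd.DataFrame(
            {"species": ["X"] * n, "locality": ["L"] * n, "lat": lat, "lon": lon},
            index=[f"s{i}" for i in range(n)],
        )
    )


class TestGeo:
    def test_same_point_zero(self):
        d = geo_distances(_meta([50.0, 50.0], [15.0, 15.0]))
        assert d.values[0, 1] == 0.0

    def test_antipodal_half_circumference(self):
        d = geo_distances(_meta([0.0, 0.0], [0.0, 180.0]))
        assert d.values[0, 1] == pytest.approx(np.pi * 6371, rel=1e-9)

    def test_quarter_circumference(self):
        d = geo_distances(_meta([0.0, 0.0], [0.0, 90.0]))
        assert d.values[0, 1] == pytest.approx(6371 * np.pi / 2, rel=1e-9)


class TestPcnm:
    def test_transect_truncation_and_sinusoid(self):
        x = np.arange(10, dtype=float)
        D = np.abs(x[:, None] - x[None, :])
        basis = pcnm(DistMatrix([f"p{i}" for i in range(10)], D))
        assert basis.truncation_distance == pytest.approx(1.0)
        half = np.cos(np.pi * x / 9)
        r = np.corrcoef(basis.vectors[:, 0], half)[0, 1]
        assert abs(r) > 0.9

    def test_three_equidistant_points(self):
        v = np.ones((3, 3)) - np.eye(3)
        basis = pcnm(DistMatrix(list("abc"), v))
        assert basis.vectors.shape[1] <= 2

    def test_large_truncation_equals_plain_pcoa(self):
        rng = np.random.default_rng(0)
        d = euclidean_dm(rng.normal(size=(8, 2)))
        basis = pcnm(d, truncation=1e9)
        ref = pcoa(d)
        lam = ref.eigenvalues[ref.eigenvalues > 1e-8]
        vecs = ref.coords / np.sqrt(lam)
        assert basis.vectors.shape == vecs.shape
        for k in range(vecs.shape[1]):
            assert abs(np.corrcoef(basis.vectors[:, k], vecs[:, k])[0, 1]) == (
                pytest.approx(1.0, abs=1e-9)
            )

    def test_identical_points_error(self):
        with pytest.raises(ValueError):
            pcnm(DistMatrix(list("abc"), np.zeros((3, 3))))

    def test_orthogonal_vectors(self):
        rng = np.random.default_rng(1)
        d = euclidean_dm(rng.normal(size=(9, 2)))
        basis = pcnm(d)
        G = basis.vectors.T @ basis.vectors
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-9)


class TestDbRda:
    def test_hand_built_variances_match_projection(self):
        """Term SS on a 6-sample instance equals explicit hat-matrix algebra."""
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(6, 3))
        d = euclidean_dm(pts)
        x1 = rng.normal(size=(6, 1))
        x2 = rng.normal(size=(6, 1))
        res = dbrda(d, {"x1": x1, "x2": x2}, n_perm=0)
        Y = pcoa(d).coords
        n = 6

        def ss_fit(X):
            Xc = X - X.mean(axis=0)
            H = Xc @ np.linalg.pinv(Xc)
            return ((H @ Y) ** 2).sum()

        ss_full = ss_fit(np.hstack([x1, x2]))
        for name, other in (("x1", x2), ("x2", x1)):
            marg = ss_full - ss_fit(other)
            assert res.table.loc[name, "variance"] == pytest.approx(
                marg / (n - 1), abs=1e-10
            )
        assert res.residual_variance == pytest.approx(
            ((Y ** 2).sum() - ss_full) / (n - 1), abs=1e-10
        )

    def test_saturated_model_zero_residual(self):
        rng = np.random.default_rng(11)
        d = euclidean_dm(rng.normal(size=(5, 2)))
        dummies = np.eye(5)[:, 1:]
        res = dbrda(d, {"all": dummies}, n_perm=0)
        assert res.residual_variance == pytest.approx(0.0, abs=1e-10)

    def test_informative_term_detected_noise_term_not(self):
        rng = np.random.default_rng(12)
        n = 30
        x = rng.normal(size=(n, 1))
        pts = np.hstack([3 * x, rng.normal(size=(n, 1)) * 0.1])
        d = euclidean_dm(pts)
        noise = rng.normal(size=(n, 1))
        res = dbrda(d, {"signal": x, "noise": noise}, n_perm=999, seed=0)
        assert res.table.loc["signal", "p"] <= 0.005
        assert res.table.loc["noise", "p"] > 0.05

    def test_collinear_predictors_named(self):
        rng = np.random.default_rng(13)
        d = euclidean_dm(rng.normal(size=(6, 2)))
        x = rng.normal(size=(6, 1))
        with pytest.raises(ValueError, match="alias"):
            dbrda(d, {"x": x, "x_copy": 2 * x}, n_perm=0)


class TestForwardSelect:
    def test_single_strong_predictor_selected(self):
        rng = np.random.default_rng(14)
        n = 24
        x = rng.normal(size=(n, 1))
        d = euclidean_dm(np.hstack([4 * x, 0.05 * rng.normal(size=(n, 1))]))
        cands = {"signal": x, "n1": rng.normal(size=(n, 1)),
                 "n2": rng.normal(size=(n, 1))}
        assert forward_select(d, cands, alpha=0.05, n_perm=199, seed=0) == ["signal"]

    def test_alpha_one_no_cap_selects_all(self):
        rng = np.random.default_rng(15)
        d = euclidean_dm(rng.normal(size=(12, 3)))
        cands = {"a": rng.normal(size=(12, 1)), "b": rng.normal(size=(12, 1))}
        sel = forward_select(d, cands, alpha=1.0, n_perm=19, seed=0,
                             adj_r2_cap=False)
        assert sorted(sel) == ["a", "b"]

    def test_null_candidates_mostly_empty(self):
        rng = np.random.default_rng(16)
        empty = 0
        n_seeds = 20
        for i in range(n_seeds):
            d = euclidean_dm(rng.normal(size=(16, 3)))
            cands = {f"c{j}": rng.normal(size=(16, 1)) for j in range(3)}
            if not forward_select(d, cands, alpha=0.05, n_perm=199, seed=i):
                empty += 1
        assert empty >= int(0.9 * n_seeds) - 1


class TestAdjustedR2AndVarpart:
    def test_ezekiel_values(self):
        assert adjusted_r2(0.5, 20, 3) == pytest.approx(0.40625)
        assert adjusted_r2(0.37, 20, 0) == pytest.approx(0.37)
        assert adjusted_r2(1.0, 20, 3) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 5, 4)

    def test_identical_sets_pure_fractions_zero(self):
        rng = np.random.default_rng(17)
        d = euclidean_dm(rng.normal(size=(15, 3)))
        x = rng.normal(size=(15, 2))
        vp = varpart2(d, {"x": x}, {"x": x})
        assert vp.a == pytest.approx(0.0, abs=1e-10)
        assert vp.c == pytest.approx(0.0, abs=1e-10)
        assert vp.b == pytest.approx(vp.adj_set1, abs=1e-10)

    def test_fractions_sum_to_one_and_constraints(self):
        rng = np.random.default_rng(18)
        d = euclidean_dm(rng.normal(size=(20, 3)))
        s1 = {"x": rng.normal(size=(20, 2))}
        s2 = {"z": rng.normal(size=(20, 2))}
        vp = varpart2(d, s1, s2)
        assert vp.a + vp.b + vp.c + vp.d == pytest.approx(1.0, abs=1e-12)
        assert vp.a + vp.b == pytest.approx(vp.adj_set1, abs=1e-12)
        assert vp.b + vp.c == pytest.approx(vp.adj_set2, abs=1e-12)

    def test_orthogonal_informative_set(self):
        rng = np.random.default_rng(19)
        n = 30
        x = rng.normal(size=(n, 1))
        d = euclidean_dm(np.hstack([3 * x, 0.2 * rng.normal(size=(n, 1))]))
        z = rng.normal(size=(n, 1))
        vp = varpart2(d, {"x": x}, {"z": z})
        assert vp.a == pytest.approx(vp.adj_set1, abs=0.05)
        assert abs(vp.b) < 0.05


def test_species_dummies_shape(small_study):
    meta = small_study["metadata"]
    dm = species_dummies(meta.species)
    assert dm.shape == (len(meta.sample_ids), 6)
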