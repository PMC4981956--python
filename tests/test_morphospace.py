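"""Regression, PCA and convex-hull overlap, each against an independent oracle."""

import numpy as np
import pandas as pd
import pytest

import eelmorph as em
from eelmorph.errors import RecordError


class TestRegression:
    def test_exact_line_recovered(self):
        x = np.arange(5.0)
        r = em.fit_regression(x, 2 * x + 1)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_minimum_sample_size(self):
        with pytest.raises(RecordError, match="n >= 3"):
            em.fit_regression([0.0, 1.0], [0.0, 3.0])
        r = em.fit_regression([0.0, 1.0, 2.0], [0.0, 3.0, 6.0])
        assert (r.slope, r.intercept) == (pytest.approx(3.0), pytest.approx(0.0))

    def test_constant_x_rejected(self):
        with pytest.raises(RecordError, match="constant"):
            em.fit_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 10, 10)
        y = 3.0 * x + rng.normal(0, 1, 10)
        r = em.fit_regression(x, y)
        # oracle: solve X'X b = X'y directly
        X = np.column_stack([np.ones(10), x])
        b = np.linalg.solve(X.T @ X, X.T @ y)
        assert r.intercept == pytest.approx(b[0], abs=1e-10)
        assert r.slope == pytest.approx(b[1], abs=1e-10)

    def test_ci_band_brackets_fit(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 30)
        y = 2 * x + rng.normal(0, 2, 30)
        r = em.fit_regression(x, y)
        xs = np.linspace(-5, 15, 50)
        lo, hi = r.ci95_band(xs)
        fit = r.predict(xs)
        assert np.all(lo <= fit + 1e-12) and np.all(fit <= hi + 1e-12)


class TestPCA:
    def _table(self, X, cols=None):
        cols = cols or [f"v{i}" for i in range(X.shape[1])]
        return pd.DataFrame(X, columns=cols, index=[f"t{i}" for i in range(X.shape[0])])

    def test_two_variable_closed_form(self):
        # correlation-mode eigenvalues of a 2-variable table are 1 +/- r
        rng = np.random.default_rng(0)
        a = rng.normal(size=200)
        b = 0.6 * a + 0.8 * rng.normal(size=200)
        tab = self._table(np.column_stack([a, b]))
        r = np.corrcoef(a, b)[0, 1]
        res = em.run_pca(tab, mode="correlation")
        assert res.eigenvalues == pytest.approx([1 + r, 1 - r], abs=1e-12)

    def test_single_axis_of_variation(self):
        X = np.zeros((5, 3))
        X[:, 0] = np.arange(5.0)
        X[:, 1] = 2.0 + 1e-12 * np.arange(5)  # keep variables non-constant
        X[:, 2] = 7.0 + 1e-12 * np.arange(5)
        res = em.run_pca(self._table(X), mode="covariance")
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_correlation_trace_conservation(self):
        rng = np.random.default_rng(3)
        tab = self._table(rng.normal(size=(20, 6)))
        res = em.run_pca(tab, mode="correlation")
        assert res.eigenvalues.sum() == pytest.approx(6.0, abs=1e-9)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal_and_sorted(self):
        rng = np.random.default_rng(4)
        tab = self._table(rng.normal(size=(15, 4)))
        res = em.run_pca(tab)
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(4), atol=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_sign_convention_orients_largest_loading_positive(self):
        rng = np.random.default_rng(5)
        tab = self._table(rng.normal(size=(12, 3)))
        res = em.run_pca(tab)
        for j in range(3):
            col = res.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_matches_sklearn_cross_check(self):
        from sklearn.decomposition import PCA as sklearn_pca

        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 5))
        res = em.run_pca(self._table(X), mode="covariance")
        sk = sklearn_pca(n_components=5).fit(X)
        assert np.allclose(np.sort(res.eigenvalues), np.sort(sk.explained_variance_), atol=1e-9)
        assert np.allclose(
            np.abs(res.loadings.T), np.abs(sk.components_), atol=1e-8
        )

    def test_incomplete_rows_excluded_not_fatal(self, caplog):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 3))
        tab = self._table(X)
        tab.iloc[2, 1] = np.nan
        res = em.run_pca(tab)
        assert len(res.taxa) == 9 and "t2" not in res.taxa

    def test_too_few_complete_rows_rejected(self):
        tab = self._table(np.full((3, 2), np.nan))
        with pytest.raises(RecordError, match=">= 3 complete"):
            em.run_pca(tab)


class TestMorphospaceOverlap:
    def _pca_like(self, pts, labels):
        n = pts.shape[0]
        return em.PCAResult(
            variables=["x", "y"], taxa=labels,
            loadings=np.eye(2), eigenvalues=np.ones(2),
            scores=pts, variance_fraction=np.array([0.5, 0.5]), mode="covariance",
        )

    def test_separated_clusters_do_not_overlap(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(10, 2))
        b = rng.normal(size=(10, 2)) + 100.0
        labels = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        pca = self._pca_like(np.vstack([a, b]), labels)
        groups = {t: t[0] for t in labels}
        rep = em.morphospace_overlap(pca, groups)
        assert rep.overlap_taxa == set()

    def test_point_at_other_centroid_reported(self):
        b = np.array([[10.0, 10.0], [12.0, 10.0], [11.0, 12.0], [11.0, 11.0]])
        a = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0], b[:3].mean(axis=0)])
        labels = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        pca = self._pca_like(np.vstack([a, b]), labels)
        rep = em.morphospace_overlap(pca, {t: t[0] for t in labels})
        assert rep.overlap_taxa == {"a3"}

    def test_small_group_rejected(self):
        pts = np.vstack([np.eye(2), [[5.0, 5.0], [6.0, 5.0]]])
        labels = ["a0", "a1", "b0", "b1"]
        pca = self._pca_like(pts, labels)
        with pytest.raises(RecordError, match=">= 3"):
            em.morphospace_overlap(pca, {t: t[0] for t in labels})

    def test_agrees_with_point_in_polygon_oracle(self):
        from shapely.geometry import MultiPoint, Point

        rng = np.random.default_rng(9)
        for _ in range(100):
            na, nb = rng.integers(3, 12, size=2)
            shift = rng.uniform(0, 4)
            a = rng.normal(size=(na, 2))
            b = rng.normal(size=(nb, 2)) + shift
            labels = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
            pca = self._pca_like(np.vstack([a, b]), labels)
            rep = em.morphospace_overlap(pca, {t: t[0] for t in labels})
            hull_a = MultiPoint(a.tolist()).convex_hull
            hull_b = MultiPoint(b.tolist()).convex_hull
            expected = {
                f"a{i}" for i in range(na) if hull_b.covers(Point(*a[i]))
            } | {f"b{i}" for i in range(nb) if hull_a.covers(Point(*b[i]))}
            assert rep.overlap_taxa == expected
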