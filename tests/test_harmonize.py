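import numpy as np
import pytest

import vitaxrd as vx
from vitaxrd.exceptions import NoOverlap, TooFewSamples, UnknownGeometry
from vitaxrd.harmonize import HarmonizedMatrix, apply_scaler


def _profile(q, I, **kw):
    q = np.asarray(q, float)
    kw.setdefault("geometry", "16cm")
    return vx.RadialProfile(q=q, intensity=np.asarray(I, float),
                            n_pixels=np.ones(len(q), int), **kw)


class TestAssignCluster:
    def test_both_geometries(self):
        assert vx.assign_cluster(_profile([1, 2], [0, 0], geometry="16cm")) \
            == "cluster_16cm"
        assert vx.assign_cluster(_profile([1, 2], [0, 0], geometry="2cm")) \
            == "cluster_2cm"

    def test_unknown_geometry(self):
        with pytest.raises(UnknownGeometry):
            vx.assign_cluster(_profile([1, 2], [0, 0], geometry=""))


class TestTrimAndResample:
    def test_constant_profile_cut_arithmetic(self):
        q = np.linspace(0, 100, 501)
        m = vx.trim_and_resample([_profile(q, np.full(len(q), 3.0))],
                                 "cluster_16cm")
        assert m.q_grid[0] == pytest.approx(4.5)
        assert m.q_grid[-1] == pytest.approx(95.5)
        assert np.allclose(m.X, 3.0)
        assert m.X.shape == (1, 50)

    def test_linear_profile_exact(self):
        q = np.linspace(0, 10, 23)
        m = vx.trim_and_resample([_profile(q, 2.5 * q)], "cluster_16cm")
        assert np.allclose(m.X[0], 2.5 * m.q_grid, rtol=0, atol=1e-12)

    def test_intersection_example(self):
        # ranges [0,10] and [2,12]: intersection [2,10], 4.5% of span 8 = 0.36
        a = _profile(np.linspace(0, 10, 101), np.ones(101))
        b = _profile(np.linspace(2, 12, 101), np.ones(101))
        m = vx.trim_and_resample([a, b], "cluster_16cm")
        assert m.q_grid[0] == pytest.approx(2.36)
        assert m.q_grid[-1] == pytest.approx(9.64)

    def test_no_overlap(self):
        a = _profile([0.0, 1.0], [1, 1])
        b = _profile([2.0, 3.0], [1, 1])
        with pytest.raises(NoOverlap):
            vx.trim_and_resample([a, b], "cluster_16cm")

    def test_quadratic_interpolation_error_bound(self):
        # sup-norm error of linear interpolation ≤ h²·max|I''|/8
        q = np.linspace(0, 10, 41)  # source spacing h = 0.25
        m = vx.trim_and_resample([_profile(q, q**2)], "cluster_16cm",
                                 n_points=500)
        err = np.max(np.abs(m.X[0] - m.q_grid**2))
        assert err <= 0.25**2 * 2.0 / 8 + 1e-12


class TestRemoveOutliers:
    def _matrix(self, X):
        n = len(X)
        return HarmonizedMatrix("cluster_16cm", np.arange(X.shape[1], dtype=float),
                                X, ["cancer"] * n, [f"P{i}" for i in range(n)],
                                [f"f{i}" for i in range(n)])

    def test_identical_rows_nothing_removed(self):
        m = self._matrix(np.ones((5, 4)))
        out, log = vx.remove_outliers(m, 3.0)
        assert out.n_samples == 5 and log == []

    def test_infinite_threshold_is_identity(self):
        rng = np.random.default_rng(0)
        m = self._matrix(rng.normal(size=(20, 6)))
        out, log = vx.remove_outliers(m, np.inf)
        assert out.n_samples == 20

    def test_spiked_row_removed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 8)) * 0.1 + 5.0
        X[13, 3] += 10.0
        out, log = vx.remove_outliers(self._matrix(X), 3.0)
        assert [r.sample_id for r in log] == ["f13"]
        assert 3 in log[0].columns

    def test_too_few_samples(self):
        with pytest.raises(TooFewSamples):
            vx.remove_outliers(self._matrix(np.ones((2, 3))), 3.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 5))
        X[7] += 8.0
        m = self._matrix(X)
        perm = rng.permutation(25)
        mp = HarmonizedMatrix(m.cluster, m.q_grid, X[perm],
                              [m.labels[i] for i in perm],
                              [m.patient_ids[i] for i in perm],
                              [m.frame_ids[i] for i in perm])
        out1, _ = vx.remove_outliers(m, 3.0)
        out2, _ = vx.remove_outliers(mp, 3.0)
        assert sorted(out1.frame_ids) == sorted(out2.frame_ids)


class TestStandardize:
    def _matrix(self, X):
        n = len(X)
        return HarmonizedMatrix("cluster_2cm", np.arange(X.shape[1], dtype=float),
                                X, ["cancer"] * n, [f"P{i}" for i in range(n)],
                                [f"f{i}" for i in range(n)])

    def test_full_fit_gives_zero_mean_unit_sd(self):
        rng = np.random.default_rng(3)
        m = self._matrix(rng.normal(2.0, 3.0, size=(40, 6)))
        out = vx.standardize(m)
        assert np.allclose(out.X.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(out.X.std(axis=0), 1.0, atol=1e-9)

    def test_constant_column_unchanged(self):
        X = np.ones((10, 3))
        X[:, 1] = np.arange(10)
        out = vx.standardize(self._matrix(X))
        assert np.allclose(out.X[:, 0], 1.0)
        assert out.scaler_sd[0] == 1.0

    def test_held_out_row_matches_manual_transform(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 4))
        m = self._matrix(X)
        fit_on = np.arange(8)
        out = vx.standardize(m, fit_on=fit_on)
        manual = (X[10] - X[:8].mean(axis=0)) / X[:8].std(axis=0)
        assert np.allclose(out.X[10], manual)
        assert np.allclose(apply_scaler(X[10], out.scaler_mean, out.scaler_sd),
                           manual)

    def test_no_leakage_from_held_out_rows(self):
        # mutating test rows must not change the fitted stats
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 4))
        fit_on = np.arange(8)
        out1 = vx.standardize(self._matrix(X.copy()), fit_on=fit_on)
        X2 = X.copy()
        X2[8:] += 100.0
        out2 = vx.standardize(self._matrix(X2), fit_on=fit_on)
        assert np.array_equal(out1.scaler_mean, out2.scaler_mean)
        assert np.array_equal(out1.scaler_sd, out2.scaler_sd)
        assert np.allclose(out1.X[:8], out2.X[:8])
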