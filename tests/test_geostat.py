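"""Variogram estimation, ordinary kriging and cross-validation."""

import numpy as np
import pytest

from benthoscape.geostat import (EmpiricalVariogram, OrdinaryKriging,
                                 VariogramModel, cross_validate,
                                 empirical_variogram, fit_variogram, krige)
from benthoscape.synthetic import simulate_grf


def dense_ok_oracle(points, values, model, target):
    """Independent ordinary-kriging oracle: assemble and solve the full
    augmented system with a generic dense solver."""
    n = len(points)
    a = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            a[i, j] = model(np.hypot(*(points[i] - points[j])))
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    b = np.array([model(np.hypot(*(p - target))) for p in points] + [1.0])
    sol = np.linalg.solve(a, b)
    lam, mu = sol[:n], sol[n]
    pred = lam @ values
    var = lam @ b[:n] + mu
    return pred, np.sqrt(max(var, 0.0))


class TestVariogramModel:
    def test_gamma_zero_at_origin_and_nondecreasing(self):
        for fam in ("spherical", "exponential", "gaussian"):
            m = VariogramModel(fam, 0.2, 1.0, 1000.0)
            h = np.linspace(0, 5000, 200)
            g = m(h)
            assert g[0] == 0.0
            assert np.all(np.diff(g) >= -1e-12)

    def test_spherical_reaches_sill_at_range(self):
        m = VariogramModel("spherical", 0.1, 0.9, 800.0)
        assert m(800.0) == pytest.approx(1.0)
        assert m(5000.0) == pytest.approx(1.0)

    def test_practical_range_conversion(self):
        assert VariogramModel("exponential", 0, 1, 500).practical_range \
            == pytest.approx(1500.0)
        g = VariogramModel("gaussian", 0, 1, 500)
        assert g(g.practical_range) == pytest.approx(0.95, abs=0.01)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            VariogramModel("spherical", -0.1, 1.0, 100.0)
        with pytest.raises(ValueError):
            VariogramModel("circular", 0.0, 1.0, 100.0)
        with pytest.raises(ValueError):
            VariogramModel("spherical", 0.0, 1.0, 0.0)


class TestEmpiricalVariogram:
    def test_two_point_single_bin(self):
        """One pair with values 0 and 2: gamma = (0-2)^2 / 2 = 2."""
        emp = empirical_variogram(np.array([[0.0, 0.0], [100.0, 0.0]]),
                                  np.array([0.0, 2.0]), cutoff=150.0,
                                  n_bins=1)
        assert emp.semivariances == pytest.approx([2.0])
        assert emp.pair_counts.tolist() == [1]

    def test_hand_enumerated_1d_lags(self):
        """x = {0,1,2}, z = {0,1,3}: gamma(1) = ((0-1)^2+(1-3)^2)/4 = 1.25,
        gamma(2) = (0-3)^2/2 = 4.5."""
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        emp = empirical_variogram(pts, np.array([0.0, 1.0, 3.0]),
                                  cutoff=2.5, n_bins=2)
        assert emp.semivariances == pytest.approx([1.25, 4.5])
        assert emp.pair_counts.tolist() == [2, 1]

    def test_constant_field_flags_zero_variogram(self):
        pts = np.random.default_rng(0).uniform(0, 100, (20, 2))
        with pytest.warns(UserWarning, match="constant"):
            emp = empirical_variogram(pts, np.ones(20))
        assert np.all(emp.semivariances == 0.0)

    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            empirical_variogram(np.array([[0.0, 0.0]]), np.array([1.0]))


class TestFitVariogram:
    def test_noiseless_spherical_self_consistency(self):
        truth = VariogramModel("spherical", 0.1, 1.0, 2000.0)
        h = np.linspace(100, 4000, 15)
        emp = EmpiricalVariogram(h, truth(h), np.full(15, 50), 4000.0)
        fit = fit_variogram(emp, candidates=("spherical",))
        assert fit.nugget == pytest.approx(0.1, rel=1e-3, abs=1e-4)
        assert fit.partial_sill == pytest.approx(1.0, rel=1e-3)
        assert fit.range_m == pytest.approx(2000.0, rel=1e-3)

    def test_family_selection_prefers_generating_family(self):
        truth = VariogramModel("gaussian", 0.05, 1.0, 1200.0)
        h = np.linspace(100, 4000, 20)
        emp = EmpiricalVariogram(h, truth(h), np.full(20, 50), 4000.0)
        fit = fit_variogram(emp)
        assert fit.family == "gaussian"

    def test_pure_nugget_white_noise(self, rng):
        """White noise has a flat variogram: fitted total sill tracks the
        sample variance and any fitted structure is negligible."""
        pts = rng.uniform(0, 1000, (300, 2))
        z = rng.standard_normal(300)
        fit = fit_variogram(empirical_variogram(pts, z))
        emp_first_bin = empirical_variogram(pts, z).bin_centres[0]
        assert fit.sill == pytest.approx(np.var(z), rel=0.15)
        structured = fit.partial_sill < 0.1 * np.var(z) \
            or fit.practical_range <= 2 * emp_first_bin
        assert structured or fit.nugget > 0.8 * np.var(z)

    def test_all_zero_variogram_degenerates(self):
        emp = EmpiricalVariogram(np.array([1.0, 2.0, 3.0]), np.zeros(3),
                                 np.array([5, 5, 5]), 3.0)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_variogram(emp)
        assert fit.nugget == 0.0 and fit.partial_sill == 0.0

    def test_needs_three_bins(self):
        emp = EmpiricalVariogram(np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                                 np.array([5, 5]), 2.0)
        with pytest.raises(ValueError):
            fit_variogram(emp)


class TestOrdinaryKriging:
    def test_exact_interpolation_with_zero_nugget(self, rng):
        model = VariogramModel("spherical", 0.0, 1.0, 2000.0)
        pts = rng.uniform(0, 5000, (25, 2))
        z = rng.standard_normal(25)
        res = krige(pts, z, model, pts)
        assert np.abs(res.predictions - z).max() < 1e-8
        assert res.standard_errors.max() < 1e-6

    def test_symmetric_pair_gives_equal_weights(self):
        model = VariogramModel("exponential", 0.1, 1.0, 500.0)
        pts = np.array([[-100.0, 0.0], [100.0, 0.0]])
        ok = OrdinaryKriging(variogram=model).fit(pts, np.array([1.0, 3.0]))
        lam, _ = ok.weights([0.0, 0.0])
        assert lam == pytest.approx([0.5, 0.5])
        assert ok.predict(np.array([[0.0, 0.0]]))[0] == pytest.approx(2.0)

    def test_matches_dense_solve_oracle(self, rng, spherical_model):
        for _ in range(20):
            n = rng.integers(3, 11)
            pts = rng.uniform(0, 4000, (n, 2))
            z = rng.standard_normal(n)
            target = rng.uniform(0, 4000, 2)
            res = krige(pts, z, spherical_model, target[None, :])
            pred, se = dense_ok_oracle(pts, z, spherical_model, target)
            assert res.predictions[0] == pytest.approx(pred, abs=1e-8)
            assert res.standard_errors[0] == pytest.approx(se, abs=1e-8)

    def test_weights_sum_to_one(self, rng, spherical_model):
        pts = rng.uniform(0, 5000, (40, 2))
        ok = OrdinaryKriging(variogram=spherical_model).fit(
            pts, rng.standard_normal(40))
        for _ in range(10):
            lam, _ = ok.weights(rng.uniform(0, 5000, 2))
            assert lam.sum() == pytest.approx(1.0, abs=1e-10)

    def test_pure_nugget_predicts_equal_weight_mean(self, rng):
        model = VariogramModel("spherical", 1.0, 0.0, 1.0)
        pts = rng.uniform(0, 100, (15, 2))
        z = rng.standard_normal(15)
        ok = OrdinaryKriging(variogram=model).fit(pts, z)
        pred = ok.predict(np.array([[50.0, 50.0]]))
        assert pred[0] == pytest.approx(z.mean(), abs=1e-10)

    def test_se_increases_with_distance_from_single_datum(self):
        model = VariogramModel("spherical", 0.0, 1.0, 1000.0)
        ok = OrdinaryKriging(variogram=model).fit(
            np.array([[0.0, 0.0], [5000.0, 5000.0]]), np.array([1.0, 2.0]))
        targets = np.column_stack([np.linspace(0, 900, 10), np.zeros(10)])
        _, se = ok.predict(targets, return_std=True)
        assert se[0] < 1e-8
        assert np.all(np.diff(se) > 0)

    def test_duplicate_coordinates_averaged_with_warning(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [100.0, 0.0]])
        model = VariogramModel("spherical", 0.0, 1.0, 500.0)
        with pytest.warns(UserWarning, match="duplicate"):
            ok = OrdinaryKriging(variogram=model).fit(
                pts, np.array([1.0, 3.0, 5.0]))
        assert ok.predict(np.array([[0.0, 0.0]]))[0] == pytest.approx(2.0)

    def test_sklearn_params_round_trip(self):
        ok = OrdinaryKriging(n_bins=10)
        assert ok.get_params()["n_bins"] == 10
        ok.set_params(cutoff=500.0)
        assert ok.cutoff == 500.0


class TestCrossValidate:
    def test_smooth_field_unbiased(self, spherical_model):
        """On a smooth simulated field with the generating model supplied,
        CV errors centre on zero."""
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 10000, (120, 2))
        smooth = VariogramModel("spherical", 0.0, 1.0, 4000.0)
        z = simulate_grf(pts, smooth, rng)
        rep = cross_validate(pts, z, smooth, k=5, seed=0)
        assert abs(rep.ME) < 0.05 * np.std(z)
        assert rep.COP > 0.7

    def test_perfect_predictor_degenerate_case(self):
        """With a pure-nugget model on constant data every fold predicts
        the training mean exactly: ME = 0 and residuals vanish."""
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, (30, 2))
        z = np.full(30, 7.0)
        model = VariogramModel("spherical", 1.0, 0.0, 1.0)
        rep = cross_validate(pts, z, model, k=5, seed=1)
        assert rep.ME == pytest.approx(0.0, abs=1e-12)
        assert rep.MSNE == pytest.approx(0.0, abs=1e-20)

    def test_fold_partition_covers_all_points(self, rng, spherical_model):
        pts = rng.uniform(0, 5000, (23, 2))
        z = simulate_grf(pts, spherical_model, rng)
        rep = cross_validate(pts, z, spherical_model, k=5, seed=3)
        assert len(rep.predicted) == 23
        assert np.all(np.isfinite(rep.predicted))

    def test_rejects_bad_k(self, rng):
        pts = rng.uniform(0, 100, (5, 2))
        with pytest.raises(ValueError):
            cross_validate(pts, np.arange(5.0), k=1)
        with pytest.raises(ValueError):
            cross_validate(pts, np.arange(5.0), k=6)
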