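"""Penalized spatial fits: basis properties, oracles, recovery, draws."""

import numpy as np
import pytest

from plsforest.smoothing import (
    LAMBDA_GRID,
    SplineBasis,
    build_basis,
    combine_and_adjust,
    delta_method_log_variance,
    draw_coefficients,
    fit_occupancy,
    fit_potential,
    occupancy_draws,
    potential_draws,
    predict_fields,
)
from plsforest.gridding import GridSpec
from plsforest.synthetic_data import SurfaceSim, simulate_cells


def _grid_coords(n_side, h=1.0):
    xx, yy = np.meshgrid(np.arange(n_side) * h, np.arange(n_side) * h)
    return np.column_stack([xx.ravel(), yy.ravel()])


class TestBasis:
    def test_constant_in_penalty_nullspace(self):
        basis = build_basis(_grid_coords(10), 25)
        # partition of unity: constant coefficients give a constant surface
        assert np.allclose(basis.B.sum(axis=1), 1.0)
        # and the difference penalty annihilates them
        assert np.allclose(basis.S @ np.ones(basis.n_basis), 0.0)

    def test_small_k_cap(self):
        basis = build_basis(_grid_coords(10), 4)
        assert basis.n_basis <= 4

    def test_k_capped_at_cell_count_with_warning(self):
        with pytest.warns(UserWarning, match="capping"):
            basis = build_basis(_grid_coords(4), 100)
        assert basis.n_basis <= 16

    def test_full_column_rank_on_grid(self):
        basis = build_basis(_grid_coords(20), 25)
        assert np.linalg.matrix_rank(basis.B) == basis.n_basis

    def test_penalty_symmetric_psd(self):
        basis = build_basis(_grid_coords(12), 36)
        assert np.allclose(basis.S, basis.S.T)
        assert np.linalg.eigvalsh(basis.S).min() > -1e-10

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            build_basis(np.zeros((5, 2)), 16)


class TestFitOracles:
    def test_gaussian_closed_form(self, small_basis_problem):
        coords, z, w = small_basis_problem
        basis = build_basis(coords, 16)
        lam = 3.7
        fit = fit_potential(np.exp(z), w, basis, lam=lam)
        beta_ref = np.linalg.solve(
            basis.B.T @ (basis.B * w[:, None]) + lam * basis.S,
            basis.B.T @ (w * z))
        assert np.abs(fit.beta - beta_ref).max() <= 1e-8

    def test_binomial_irls_fixed_point(self, small_basis_problem):
        coords, _, _ = small_basis_problem
        rng = np.random.default_rng(0)
        basis = build_basis(coords, 16)
        N = np.full(50, 30.0)
        theta = 1.0 / (1.0 + np.exp(-(0.5 + 0.01 * (coords[:, 0] - 50))))
        n_p = rng.binomial(30, theta).astype(float)
        lam = 5.0
        fit = fit_occupancy(n_p, N, basis, lam=lam)
        # independent IRLS fixed-point iteration
        from scipy.special import expit, logit
        eta = np.clip(logit((n_p + 0.5) / (N + 1)), -15, 15)
        for _ in range(200):
            mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
            wt = N * mu * (1 - mu)
            zz = eta + (n_p / N - mu) / (mu * (1 - mu))
            beta = np.linalg.solve(
                basis.B.T @ (basis.B * wt[:, None]) + lam * basis.S,
                basis.B.T @ (wt * zz))
            eta = np.clip(basis.B @ beta, -15, 15)
        assert np.abs(fit.beta - beta).max() <= 1e-6

    def test_intercept_only_occupancy_is_pooled_proportion(self):
        basis = SplineBasis(B=np.ones((2, 1)), S=np.zeros((1, 1)),
                            coords=np.zeros((2, 2)), k_requested=1,
                            kx=1, ky=1, degree=0)
        fit = fit_occupancy(np.array([3.0, 7.0]), np.array([10.0, 10.0]),
                            basis, lam=1e-10)
        assert np.allclose(fit.predict(), 0.5, atol=1e-6)

    def test_saturated_occupancy_approaches_one(self):
        basis = build_basis(_grid_coords(10), 9)
        N = np.full(100, 20.0)
        fit = fit_occupancy(N.copy(), N, basis)
        assert np.all(fit.predict() > 0.99)

    def test_all_zero_counts_flagged_degenerate(self):
        basis = build_basis(_grid_coords(10), 9)
        N = np.full(100, 20.0)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_occupancy(np.zeros(100), N, basis)
        assert fit.degenerate and np.all(fit.predict() < 0.05)

    def test_constant_data_constant_fit(self, small_basis_problem):
        coords, _, w = small_basis_problem
        basis = build_basis(coords, 16)
        fit = fit_potential(np.full(50, 5.0), w, basis)
        assert np.allclose(fit.predict(), np.log(5.0), atol=1e-8)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_edf_strictly_decreasing_in_lambda(self, small_basis_problem):
        coords, z, w = small_basis_problem
        basis = build_basis(coords, 16)
        edfs = [fit_potential(np.exp(z), w, basis, lam=l).edf
                for l in (0.1, 1.0, 10.0, 100.0, 1000.0)]
        assert all(a > b for a, b in zip(edfs, edfs[1:]))

    def test_too_few_occupied_cells_error(self, small_basis_problem):
        coords, z, w = small_basis_problem
        basis = build_basis(coords, 16)
        ybar = np.full(50, np.nan)
        ybar[:2] = 1.0
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_potential(ybar, w, basis)


class TestRecovery:
    def test_occupancy_surface_recovery(self, grid30, cells30):
        cells, truth = cells30
        basis = build_basis(cells[["x", "y"]].to_numpy(), 250)
        fit = fit_occupancy(cells["n_p"].to_numpy(float),
                            cells["N"].to_numpy(float), basis)
        corr = np.corrcoef(fit.predict(), truth["theta_true"])[0, 1]
        assert corr >= 0.9

    def test_potential_rmse_decreases_with_points_per_cell(self, grid30):
        basis = None
        rmses = []
        for npc in (35, 70, 140):
            cells, truth = simulate_cells(
                SurfaceSim(grid=grid30, sigma2=0.25, N=npc, seed=33))
            if basis is None:
                basis = build_basis(cells[["x", "y"]].to_numpy(), 100)
            fit = fit_potential(cells["ybar"].to_numpy(float),
                                cells["n_p"].to_numpy(float), basis)
            rmses.append(np.sqrt(np.mean(
                (fit.linear_predictor() - truth["m_true"].to_numpy()) ** 2)))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_end_to_end_field_recovery(self, cells30):
        cells, truth = cells30
        basis = build_basis(cells[["x", "y"]].to_numpy(), 250)
        occ = fit_occupancy(cells["n_p"].to_numpy(float), cells["N"].to_numpy(float), basis)
        pot = fit_potential(cells["ybar"].to_numpy(float), cells["n_p"].to_numpy(float), basis)
        f = predict_fields(occ, pot)
        b_true = truth["b_true"].to_numpy()
        mask = b_true > 10
        mare = np.mean(np.abs(f.b - b_true)[mask] / b_true[mask])
        assert mare <= 0.15
        assert np.all(f.theta > 0) and np.all(f.theta < 1) and np.all(f.b >= 0)

    def test_log_scale_smoothing_underestimates_raw_mean(self, grid30):
        # skewed conditional values with few occupied points per cell: the
        # log-scale fit discounts outliers, so the back-transformed smooth
        # sits below the raw arithmetic mean
        cells, _ = simulate_cells(SurfaceSim(
            grid=grid30, theta=lambda u, v: np.full_like(u, 0.07),
            sigma2=1.0, N=70, seed=21))
        basis = build_basis(cells[["x", "y"]].to_numpy(), 100)
        occ = fit_occupancy(cells["n_p"].to_numpy(float), cells["N"].to_numpy(float), basis)
        pot = fit_potential(cells["ybar"].to_numpy(float), cells["n_p"].to_numpy(float), basis)
        f = predict_fields(occ, pot)
        assert f.b.mean() < cells["raw_mean"].mean()

    def test_residual_variance_consistent_with_generator(self, cells30):
        cells, _ = cells30
        basis = build_basis(cells[["x", "y"]].to_numpy(), 250)
        pot = fit_potential(cells["ybar"].to_numpy(float),
                            cells["n_p"].to_numpy(float), basis)
        assert 0.8 <= pot.sigma2 / 0.25 <= 1.2


class TestDraws:
    def test_draw_count_and_reproducibility(self, small_basis_problem):
        coords, z, w = small_basis_problem
        basis = build_basis(coords, 16)
        fit = fit_potential(np.exp(z), w, basis, lam=2.0)
        d1 = draw_coefficients(fit, 250, 12)
        d2 = draw_coefficients(fit, 250, 12)
        assert d1.shape == (250, basis.n_basis)
        assert np.array_equal(d1, d2)
        assert not np.array_equal(d1, draw_coefficients(fit, 250, 13))

    def test_zero_covariance_gives_degenerate_draws(self, small_basis_problem):
        coords, _, w = small_basis_problem
        basis = build_basis(coords, 16)
        fit = fit_potential(np.full(50, 5.0), w, basis)  # sigma2 ~ 0
        d = draw_coefficients(fit, 10, 0)
        assert np.allclose(d, fit.beta, atol=1e-12)

    def test_empirical_covariance_matches_V_beta(self, small_basis_problem):
        coords, z, w = small_basis_problem
        basis = build_basis(coords, 16)
        fit = fit_potential(np.exp(z), w, basis, lam=2.0)
        draws = draw_coefficients(fit, 100_000, 42)
        emp = np.cov(draws.T)
        rel = np.linalg.norm(emp - fit.V_beta) / np.linalg.norm(fit.V_beta)
        assert rel <= 0.05

    def test_adjustment_rules(self):
        theta_hat = np.array([0.01, 0.5])
        theta_draws = np.array([[0.06, 0.4], [0.04, 0.6]])
        m_draws = np.zeros_like(theta_draws)
        cube = combine_and_adjust(theta_draws, m_draws, theta_hat, total=False)
        assert cube.theta[0, 0] == 0.01  # 0.06 > 5 x 0.01: reset
        assert cube.theta[1, 0] == 0.04  # below threshold: unchanged
        cube_total = combine_and_adjust(
            np.array([[0.2]]), np.array([[0.0]]), np.array([0.9995]), total=True)
        assert cube_total.theta[0, 0] == 1.0
        assert cube_total.b[0, 0] == 1.0

    def test_b_draw_is_product(self):
        th = np.array([[0.5]])
        m = np.array([[np.log(100.0)]])
        cube = combine_and_adjust(th, m, np.array([0.5]))
        assert cube.b[0, 0] == pytest.approx(50.0)

    def test_mismatched_grids_error(self):
        with pytest.raises(ValueError, match="mismatched"):
            combine_and_adjust(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros(3))

    def test_draws_respect_bounds_after_adjustment(self, cells30):
        cells, _ = cells30
        basis = build_basis(cells[["x", "y"]].to_numpy(), 100)
        occ = fit_occupancy(cells["n_p"].to_numpy(float), cells["N"].to_numpy(float), basis)
        pot = fit_potential(cells["ybar"].to_numpy(float), cells["n_p"].to_numpy(float), basis)
        th = occupancy_draws(occ, draw_coefficients(occ, 50, 1))
        m = potential_draws(pot, draw_coefficients(pot, 50, 2))
        cube = combine_and_adjust(th, m, occ.predict())
        assert np.all(cube.theta >= 0) and np.all(cube.theta <= 1)
        assert np.all(cube.b >= 0)


class TestFieldsAndDiagnostics:
    def test_product_rule(self):
        # theta = 0.5, m = log 100 -> b = 50; theta = 0 -> b = 0
        basis = SplineBasis(B=np.ones((2, 1)), S=np.zeros((1, 1)),
                            coords=np.zeros((2, 2)), k_requested=1,
                            kx=1, ky=1, degree=0)
        from plsforest.smoothing import SmoothFit
        occ = SmoothFit(basis=basis, beta=np.array([0.0]), V_beta=np.zeros((1, 1)),
                        lam=1.0, edf=1.0, family="binomial")
        pot = SmoothFit(basis=basis, beta=np.array([np.log(100.0)]),
                        V_beta=np.zeros((1, 1)), lam=1.0, edf=1.0,
                        family="log-gaussian", sigma2=0.1)
        f = predict_fields(occ, pot)
        assert np.allclose(f.b, 0.5 * 100.0)

    def test_delta_method_diagnostic_shape(self, small_basis_problem):
        coords, z, w = small_basis_problem
        basis = build_basis(coords, 16)
        fit = fit_potential(np.exp(z), w, basis, lam=2.0)
        v = delta_method_log_variance(fit, w)
        assert v.shape == (50,)
        assert np.all(v[np.isfinite(v)] > 0)

    def test_draws_cube_dataset_roundtrip(self, tmp_path):
        cube = combine_and_adjust(np.full((5, 3), 0.5), np.zeros((5, 3)),
                                  np.full(3, 0.5), seed=1, variable="biomass")
        ds = cube.to_dataset()
        assert ds["b"].shape == (5, 3)
        path = tmp_path / "draws.nc"
        ds.to_netcdf(path, engine="scipy")
        assert path.exists()
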