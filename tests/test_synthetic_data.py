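"""Generators: Poisson forest, corner sampling, cell-level model, fixtures."""

import numpy as np
import pandas as pd
import pytest

from plsforest.gridding import GridSpec
from plsforest.survey_points import CleaningConfig, parse_points
from plsforest.synthetic_data import (
    ForestSim,
    SurfaceSim,
    make_fixture,
    sample_corners,
    simulate_cells,
    simulate_forest,
)


class TestForest:
    def test_poisson_mean_count(self):
        # 1 km^2 at 200 stems/ha: expectation 20,000 trees
        sim = ForestSim(intensity=200.0, extent=(0, 1000.0, 0, 1000.0), seed=1)
        n = len(simulate_forest(sim))
        assert abs(n - 20_000) < 5 * np.sqrt(20_000)

    def test_zero_intensity_empty_forest(self):
        sim = ForestSim(intensity=0.0, extent=(0, 1000.0, 0, 1000.0), seed=1)
        assert simulate_forest(sim).empty

    def test_diameter_law_of_large_numbers(self):
        sim = ForestSim(intensity=100.0, extent=(0, 3200.0, 0, 3200.0), seed=2)
        trees = simulate_forest(sim)
        assert len(trees) > 90_000
        # left truncation at 2 cm barely moves the log-normal mean
        expected = np.exp(sim.dbh_meanlog + sim.dbh_sdlog**2 / 2)
        assert trees["dbh"].mean() == pytest.approx(expected, rel=0.02)
        assert trees["dbh"].min() >= sim.dbh_min

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ForestSim(taxa={"Oak": 0.7, "Pine": 0.7})

    def test_reproducible_by_seed(self):
        sim = ForestSim(intensity=50.0, extent=(0, 500.0, 0, 500.0), seed=9)
        pd.testing.assert_frame_equal(simulate_forest(sim), simulate_forest(sim))


class TestCorners:
    def test_single_tree_forest(self):
        trees = pd.DataFrame({"x": [110.0], "y": [140.0], "dbh": [30.0],
                              "taxon": ["Oak"]})
        corners = sample_corners(trees, (0, 300.0, 0, 300.0), spacing=100.0,
                                 margin=50.0, record="center")
        filled = corners.dropna(subset=["dist1"])
        # the tree appears exactly once per corner (its semicircle only)
        assert (filled["taxon1"] == "Oak").all()
        assert corners["taxon2"].isna().all() or (corners["taxon2"] == "").all()

    def test_dense_forest_every_corner_two_trees(self):
        sim = ForestSim(intensity=300.0, extent=(0, 1500.0, 0, 1500.0), seed=3)
        corners = sample_corners(simulate_forest(sim), sim.extent, spacing=200.0)
        assert corners["dist1"].notna().all() and corners["dist2"].notna().all()

    def test_semicircle_nearest_distance_squared_mean(self):
        # for a Poisson forest the squared semicircle nearest distance has
        # mean 2/(lambda*pi) with lambda in stems/m^2
        lam_ha = 200.0
        sim = ForestSim(intensity=lam_ha, extent=(0, 4700.0, 0, 4700.0), seed=11)
        corners = sample_corners(simulate_forest(sim), sim.extent,
                                 spacing=100.0, record="center")
        assert len(corners) >= 2000
        d = corners[["dist1", "dist2"]].to_numpy(float)
        theory = 2.0 / (lam_ha / 1e4 * np.pi)
        assert (d**2).mean() == pytest.approx(theory, rel=0.05)

    def test_four_quadrant_protocol(self):
        sim = ForestSim(intensity=300.0, extent=(0, 800.0, 0, 800.0), seed=4)
        corners = sample_corners(simulate_forest(sim), sim.extent,
                                 spacing=200.0, protocol="four-quadrant")
        assert {"taxon3", "dist4"} <= set(corners.columns)
        assert corners["dist4"].notna().all()

    def test_round_trip_through_parser(self):
        sim = ForestSim(intensity=250.0, extent=(0, 900.0, 0, 900.0), seed=5)
        corners = sample_corners(simulate_forest(sim), sim.extent, spacing=300.0)
        pts, log = parse_points(corners, CleaningConfig.metric())
        assert log.empty
        assert len(pts) == len(corners)
        assert all(len(p.trees) == 2 for p in pts)


class TestCells:
    def test_full_occupancy(self, grid30):
        cells, _ = simulate_cells(SurfaceSim(grid=grid30, theta=lambda u, v: np.ones_like(u), seed=0))
        assert (cells["n_p"] == cells["N"]).all()

    def test_zero_noise_recovers_m_exactly(self, grid30):
        cells, truth = simulate_cells(SurfaceSim(grid=grid30, sigma2=0.0, seed=0))
        occ = cells["n_p"] > 0
        assert np.allclose(np.log(cells.loc[occ, "ybar"]),
                           truth.loc[occ, "m_true"])

    def test_binomial_mean(self, grid30):
        cells, _ = simulate_cells(SurfaceSim(
            grid=grid30, theta=lambda u, v: np.full_like(u, 0.3), seed=12))
        pooled = (cells["n_p"] / cells["N"]).mean()
        se = np.sqrt(0.3 * 0.7 / 70 / len(cells))
        assert abs(pooled - 0.3) < 4 * se

    def test_decomposition_identity_on_generated_cells(self, cells30):
        cells, _ = cells30
        occ = cells["n_p"] > 0
        lhs = (cells.loc[occ, "n_p"] / cells.loc[occ, "N"]) * cells.loc[occ, "ybar"]
        assert np.allclose(lhs, cells.loc[occ, "raw_mean"], rtol=1e-12)

    def test_truth_stored_alongside(self, cells30):
        cells, truth = cells30
        assert {"theta_true", "m_true", "b_true"} <= set(truth.columns)
        assert len(truth) == len(cells)


class TestFixtures:
    def test_cleaning10_has_three_missing_dbh_rows(self):
        fx = make_fixture("cleaning10")
        missing = (fx[["dbh1", "dbh2"]].astype(str)
                   .apply(lambda c: c.str.strip() == "").any(axis=1))
        assert int(missing.sum()) == 3

    def test_deterministic_bytes(self):
        a = make_fixture("cleaning10").to_csv(index=False)
        b = make_fixture("cleaning10").to_csv(index=False)
        assert a == b

    def test_unknown_name_errors(self):
        with pytest.raises(KeyError, match="unknown fixture"):
            make_fixture("nope")


def test_end_to_end_constant_density_recovery():
    """Forest -> corners -> parser -> point estimators -> grid -> smoothing
    recovers a constant 200 stems/ha intensity within 5%."""
    from plsforest.gridding import aggregate_cells, assign_cells, occupancy_potential_table
    from plsforest.point_estimators import AllometryTable, estimate_points
    from plsforest.smoothing import build_basis, fit_occupancy, fit_potential, predict_fields
    from plsforest.survey_points import TaxonTable, apply_cleaning, standardize_taxa

    sim = ForestSim(intensity=200.0, extent=(0, 4700.0, 0, 4700.0), seed=17)
    corners = sample_corners(simulate_forest(sim), sim.extent, spacing=100.0)
    pts, _ = parse_points(corners, CleaningConfig.metric())
    pts, _ = standardize_taxa(pts, TaxonTable.example())
    pts, _ = apply_cleaning(pts, CleaningConfig.metric())
    totals, _ = estimate_points(pts, AllometryTable.example())
    grid = GridSpec(0, 0, 10, 10, 470.0)
    assigned, dropped = assign_cells(totals, grid)
    assert dropped.empty
    cells = aggregate_cells(assigned, grid, value_cols=("density_raw",))
    tab = occupancy_potential_table(cells, "density_raw")
    basis = build_basis(tab[["x", "y"]].to_numpy(), 16)
    occ = fit_occupancy(tab["n_p"].to_numpy(float), tab["N"].to_numpy(float), basis)
    pot = fit_potential(tab["ybar"].to_numpy(float), tab["n_p"].to_numpy(float), basis)
    fields = predict_fields(occ, pot)
    assert fields.b.mean() == pytest.approx(200.0, rel=0.05)
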