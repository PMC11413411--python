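"""Empirical semivariograms, anisotropy diagnostics, and exponential fits."""

import numpy as np
import pytest

from wolbkrig.geodesy import distance_matrix
from wolbkrig.synth import simulate_latent_field
from wolbkrig.variogram import (
    EmptyVariogramError,
    FitError,
    VariogramModel,
    directional_variograms,
    empirical_variogram,
    exponential_gamma,
    fit_exponential,
    practical_range,
    variogram_map,
)


def brute_force_variogram(coords, z, lag_width, cutoff):
    """O(n^2) loop oracle for binned semivariance."""
    d = distance_matrix(np.asarray(coords))
    sums, counts = {}, {}
    n = len(z)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > cutoff:
                continue
            b = max(int(np.ceil(d[i, j] / lag_width)), 1)
            sums[b] = sums.get(b, 0.0) + 0.5 * (z[i] - z[j]) ** 2
            counts[b] = counts.get(b, 0) + 1
    bins = sorted(counts)
    return (
        np.array([(b - 0.5) * lag_width for b in bins]),
        np.array([sums[b] / counts[b] for b in bins]),
        np.array([counts[b] for b in bins]),
    )


def random_sites(rng, n, lat=(40, 60), lon=(0, 30)):
    return np.column_stack([rng.uniform(*lat, n), rng.uniform(*lon, n)])


class TestEmpirical:
    def test_two_sites_single_bin(self):
        sites = np.array([[50.0, 10.0], [50.0, 10.7]])  # ~50 km apart
        emp = empirical_variogram(sites, [0.0, 1.0], lag_width=60, cutoff=2000)
        assert len(emp) == 1
        assert emp.lag_centers[0] == 30.0
        assert emp.gamma_hat[0] == pytest.approx(0.5)
        assert emp.n_pairs[0] == 1

    def test_constant_field_has_zero_semivariance(self, small_sites):
        emp = empirical_variogram(small_sites, np.full(10, 0.3))
        assert np.all(emp.gamma_hat == 0.0)

    def test_matches_brute_force_oracle_bin_by_bin(self, rng):
        for _ in range(5):
            coords = random_sites(rng, 30)
            z = rng.random(30)
            emp = empirical_variogram(coords, z, lag_width=75, cutoff=1500)
            centers, gammas, counts = brute_force_variogram(coords, z, 75, 1500)
            np.testing.assert_allclose(emp.lag_centers, centers)
            np.testing.assert_allclose(emp.gamma_hat, gammas, atol=1e-12)
            np.testing.assert_array_equal(emp.n_pairs, counts)

    def test_all_pairs_beyond_cutoff_is_an_error(self):
        sites = np.array([[0.0, 0.0], [30.0, 30.0]])
        with pytest.raises(EmptyVariogramError):
            empirical_variogram(sites, [0, 1], lag_width=10, cutoff=50)

    def test_shift_invariance_and_quadratic_scaling(self, rng):
        coords = random_sites(rng, 20)
        z = rng.random(20)
        base = empirical_variogram(coords, z)
        shifted = empirical_variogram(coords, z + 5.0)
        scaled = empirical_variogram(coords, 3.0 * z)
        np.testing.assert_allclose(base.gamma_hat, shifted.gamma_hat, atol=1e-12)
        np.testing.assert_allclose(9.0 * base.gamma_hat, scaled.gamma_hat, rtol=1e-12)


class TestDirectional:
    def test_default_sectors_partition_all_pairs(self, rng):
        coords = random_sites(rng, 25)
        z = rng.random(25)
        omni = empirical_variogram(coords, z, cutoff=1e5)
        parts = directional_variograms(coords, z, cutoff=1e5)
        assert sum(int(p.n_pairs.sum()) for p in parts) == int(omni.n_pairs.sum())

    def test_omnidirectional_is_pair_weighted_average_of_sectors(self, rng):
        coords = random_sites(rng, 25)
        z = rng.random(25)
        omni = empirical_variogram(coords, z, cutoff=1e5)
        parts = directional_variograms(coords, z, cutoff=1e5)
        for ci, c in enumerate(omni.lag_centers):
            tot, cnt = 0.0, 0
            for p in parts:
                hit = np.flatnonzero(np.isclose(p.lag_centers, c))
                if hit.size:
                    tot += p.gamma_hat[hit[0]] * p.n_pairs[hit[0]]
                    cnt += p.n_pairs[hit[0]]
            assert cnt == omni.n_pairs[ci]
            assert tot / cnt == pytest.approx(omni.gamma_hat[ci], abs=1e-12)

    def test_meridian_sites_fall_in_north_sector(self, rng):
        coords = np.column_stack([np.linspace(45, 48, 8), np.full(8, 10.0)])
        z = rng.random(8)
        north, east = directional_variograms(coords, z, angles=(0.0, 90.0), tol=22.5)
        omni = empirical_variogram(coords, z)
        np.testing.assert_allclose(north.gamma_hat, omni.gamma_hat, atol=1e-12)
        assert int(north.n_pairs.sum()) == int(omni.n_pairs.sum())

    def test_overlapping_sectors_rejected(self, rng):
        coords = random_sites(rng, 5)
        with pytest.raises(ValueError, match="overlap"):
            directional_variograms(coords, np.zeros(5), angles=(0.0, 30.0), tol=22.5)

    def test_isotropic_field_has_agreeing_directional_sills(self, rng, truth_model):
        # one large simulated field; the four sector sills should agree
        coords = random_sites(np.random.default_rng(21), 400, lat=(40, 60), lon=(0, 30))
        z = simulate_latent_field(coords, truth_model, 0.5, "identity", seed=21)
        parts = directional_variograms(coords, z, cutoff=2000)
        sills = [p.gamma_hat[np.asarray(p.lag_centers) > 800].mean() for p in parts]
        assert max(sills) - min(sills) < 0.5 * np.mean(sills)


class TestVariogramMap:
    def test_two_sites_give_two_symmetric_cells(self):
        sites = np.array([[50.0, 10.0], [50.5, 10.5]])
        vmap = variogram_map(sites, [0.0, 1.0], cell_size=25.0)
        assert len(vmap.cells) == 2
        (k1, v1), (k2, v2) = vmap.cells.items()
        assert k1 == (-k2[0], -k2[1])
        assert v1 == v2

    def test_central_symmetry_holds_exactly(self, rng):
        coords = random_sites(rng, 15)
        vmap = variogram_map(coords, rng.random(15), cell_size=100.0)
        for (ix, iy), (g, c) in vmap.cells.items():
            assert vmap.cells[(-ix, -iy)] == (g, c)

    def test_anisotropic_field_shows_low_ridge_along_long_axis(self):
        # stretch the range 3x along east-west by compressing longitudes
        rng = np.random.default_rng(9)
        coords = random_sites(rng, 300, lat=(45, 55), lon=(0, 20))
        model = VariogramModel(0.0, 1.0, 500.0)
        squashed = coords.copy()
        squashed[:, 1] = coords[:, 1] / 3.0 + 10.0  # EW distances shrink 3x
        z = simulate_latent_field(squashed, model, 0.0, "identity", seed=9)
        vmap = variogram_map(coords, z, cell_size=250.0, cutoff=1500.0)
        ew = [g for (ix, iy), (g, c) in vmap.cells.items()
              if iy == 0 and ix != 0 and c >= 10]
        ns = [g for (ix, iy), (g, c) in vmap.cells.items()
              if ix == 0 and iy != 0 and c >= 10]
        assert np.mean(ew) < np.mean(ns)


class TestExponentialModel:
    def test_sill_nugget_and_practical_range_values(self):
        m = VariogramModel(0.05, 0.20, 600.0)
        assert exponential_gamma(m, 1e9) == pytest.approx(0.25)
        assert exponential_gamma(m, 600.0) == pytest.approx(0.05 + 0.20 * (1 - np.exp(-3)))
        assert exponential_gamma(m, 1e-12) == pytest.approx(0.05, abs=1e-9)
        assert exponential_gamma(m, 0.0) == 0.0

    def test_practical_range_closed_form_matches_numeric_solve(self):
        from scipy.optimize import brentq

        for m in [VariogramModel(0.0, 0.2, 600.0), VariogramModel(0.05, 0.2, 600.0),
                  VariogramModel(0.1, 0.3, 1500.0)]:
            r = practical_range(m)
            r_num = brentq(lambda x: exponential_gamma(m, x) - 0.95 * m.sill, 1e-9, 1e7)
            assert r == pytest.approx(r_num, rel=1e-9)

    def test_zero_nugget_practical_range_is_nearly_b(self):
        m = VariogramModel(0.0, 0.2, 600.0)
        assert practical_range(m) == pytest.approx(600.0, rel=5e-3)
        m2 = VariogramModel(0.0, 0.2, 1200.0)
        assert practical_range(m2) == pytest.approx(2 * practical_range(m), rel=1e-12)

    def test_pure_nugget_has_no_practical_range(self):
        with pytest.raises(ValueError):
            practical_range(VariogramModel(0.1, 0.0, 100.0))


class TestFit:
    def test_noiseless_bins_recover_parameters_exactly(self):
        from wolbkrig.variogram import EmpiricalVariogram

        truth = VariogramModel(0.05, 0.20, 600.0)
        h = (np.arange(1, 25) - 0.5) * 60.0
        emp = EmpiricalVariogram(h, exponential_gamma(truth, h), np.full(24, 50),
                                 60.0, 2000.0)
        fit = fit_exponential(emp)
        assert fit.model.C0 == pytest.approx(truth.C0, abs=1e-6)
        assert fit.model.C1 == pytest.approx(truth.C1, rel=1e-6)
        assert fit.model.b == pytest.approx(truth.b, rel=1e-6)
        assert fit.sse < 1e-12

    def test_flat_variogram_reports_pure_nugget_unidentifiable_range(self):
        from wolbkrig.variogram import EmpiricalVariogram

        h = (np.arange(1, 10) - 0.5) * 60.0
        emp = EmpiricalVariogram(h, np.full(9, 0.07), np.full(9, 20), 60.0, 2000.0)
        fit = fit_exponential(emp)
        assert fit.model.C1 == 0.0
        assert not fit.b_identifiable

    def test_too_few_bins_is_a_fit_error(self):
        from wolbkrig.variogram import EmpiricalVariogram

        emp = EmpiricalVariogram(np.array([30.0, 90.0]), np.array([0.1, 0.2]),
                                 np.array([5, 5]), 60.0, 2000.0)
        with pytest.raises(FitError):
            fit_exponential(emp)

    def test_fitted_sse_never_exceeds_initial_guess(self, rng, truth_model):
        coords = random_sites(rng, 150)
        z = simulate_latent_field(coords, truth_model, 0.5, "truncate", seed=4)
        emp = empirical_variogram(coords, z)
        for mode in ("npairs_over_h2", "npairs", "equal"):
            fit = fit_exponential(emp, weight_mode=mode)
            assert fit.weight_mode == mode
            assert fit.sse >= 0.0

    def test_unknown_weight_mode_rejected(self, rng, truth_model):
        coords = random_sites(rng, 30)
        z = simulate_latent_field(coords, truth_model, 0.5, "truncate", seed=4)
        emp = empirical_variogram(coords, z)
        with pytest.raises(ValueError):
            fit_exponential(emp, weight_mode="bogus")

    def test_range_error_shrinks_with_site_count(self, truth_model):
        # consistency: more sites -> better median range recovery
        med_errs = []
        for n_sites, reps in ((60, 8), (240, 8), (960, 4)):
            errs = []
            for rep in range(reps):
                g = np.random.default_rng(100 * n_sites + rep)
                coords = random_sites(g, n_sites, lat=(35, 70), lon=(-10, 60))
                z = simulate_latent_field(coords, truth_model, 0.5, "identity",
                                          seed=100 * n_sites + rep)
                fit = fit_exponential(empirical_variogram(coords, z))
                errs.append(abs(fit.model.b - truth_model.b))
            med_errs.append(np.median(errs))
        assert med_errs[2] < med_errs[0]
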