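"""Trajectories derived from a fit: curves, V_A, h2, correlations, eigen."""

import numpy as np
import pytest

from telotraj.basis import LegendreBasis
from telotraj.params import (
    Trajectory,
    additive_variance,
    animal_profiles,
    eigen_analysis,
    fixed_curve,
    genetic_correlation,
    heritability,
)
from telotraj.reml import ModelSpec, fit_reml
from telotraj.simulate import default_truth, sampling_schedule, simulate_herd, \
    simulate_rr_phenotypes

from conftest import tiny_rr_dataset

B = LegendreBasis(2, 0.0, 60.0)
GRID = np.arange(0.0, 61.0)


@pytest.fixture(scope="module")
def fitted():
    truth = default_truth(order=2)
    ped, cows = simulate_herd(220, 20, 70, seed=42)
    sched = sampling_schedule(cows, np.random.default_rng(43))
    pheno, truth = simulate_rr_phenotypes(ped, truth, sched, seed=44)
    fit = fit_reml(pheno, ped, ModelSpec(bounds=(0.0, 60.0)))
    return fit, truth


class TestAdditiveVariance:
    def test_zero_matrix_gives_zero_curve(self):
        t = additive_variance(np.zeros((3, 3)), B, GRID)
        assert np.all(t.values == 0.0)

    def test_identity_gives_squared_basis_norm(self):
        t = additive_variance(np.eye(3), B, GRID)
        phi = B.matrix(GRID)
        assert t.values == pytest.approx(np.sum(phi**2, axis=1))

    def test_intercept_only_is_constant_half(self):
        t = additive_variance(np.diag([1.0, 0.0, 0.0]), B, GRID)
        assert t.values == pytest.approx(np.full(len(GRID), 0.5))

    def test_dimension_mismatch(self):
        # a K larger than the basis cannot be evaluated
        with pytest.raises(ValueError, match="dimension"):
            additive_variance(np.eye(4), B, GRID)

    def test_nonnegative_for_random_psd_matrices(self, rng):
        for _ in range(200):
            M = rng.normal(size=(3, 3))
            K = M @ M.T
            t = additive_variance(K, B, GRID)
            assert np.all(t.values >= -1e-12)


class TestCurvesAndProfiles:
    def test_fixed_curve_values(self, fitted):
        fit, _ = fitted
        curve = fixed_curve(fit, GRID)
        b = fit.beta.to_numpy()[:3]
        phi = B.matrix(GRID)
        assert curve.values == pytest.approx(phi @ b)
        assert np.all(curve.se >= 0)

    def test_profile_of_zero_coefficients_is_flat(self, fitted):
        fit, _ = fitted
        fit2 = fit
        animal = fit2.u.index[0]
        fit2.u.loc[animal] = 0.0
        prof = animal_profiles(fit2, GRID, animals=[animal])[0]
        assert np.all(prof.values == 0.0)

    def test_profile_se_with_identity_pev(self, fitted):
        fit, _ = fitted
        animal = fit.u.index[3]
        j = list(fit.u.index).index(animal)
        fit.u_pev[j] = np.eye(3)
        prof = animal_profiles(fit, GRID, animals=[animal])[0]
        phi = B.matrix(GRID)
        assert prof.se == pytest.approx(np.sqrt(np.sum(phi**2, axis=1)))

    def test_unknown_animal_raises(self, fitted):
        fit, _ = fitted
        with pytest.raises(KeyError):
            animal_profiles(fit, GRID, animals=["nope"])

    def test_profiles_track_true_breeding_curves(self, fitted):
        """BLUP profiles correlate with the simulated genetic deviations."""
        fit, truth = fitted
        phi = B.matrix(GRID)
        cors = []
        for a, u_true in truth.true_breeding_coefficients.items():
            if a not in fit.u.index or not a.startswith("C"):
                continue
            est = phi @ fit.u.loc[a].to_numpy()
            tru = phi @ np.asarray(u_true)
            cors.append(np.corrcoef(est, tru)[0, 1])
        assert np.median(cors) > 0.4


class TestHeritability:
    def test_equal_variances_give_half(self, fitted):
        fit, _ = fitted
        h = heritability(fit, GRID)
        va = additive_variance(fit.vc.K, fit.basis, GRID).values
        expect = va / (va + fit.vc.sigma2_e[0])
        assert h.values == pytest.approx(expect)
        assert np.all((h.values >= 0) & (h.values <= 1))

    def test_delta_se_close_to_parametric_draws(self, fitted, rng):
        """SEs from the delta method track the spread of h2 under draws of the
        variance parameters from their asymptotic distribution."""
        fit, _ = fitted
        h = heritability(fit, GRID)
        draws = []
        L = np.linalg.cholesky(
            fit.theta_cov + 1e-12 * np.eye(len(fit.theta))
        )
        from telotraj.reml import _unpack

        m1 = fit.u.shape[1]
        for _ in range(200):
            th = fit.theta + L @ rng.standard_normal(len(fit.theta))
            K, _, s2e = _unpack(th, m1, False, 1)
            w, V = np.linalg.eigh(K)
            K = (V * np.maximum(w, 0.0)) @ V.T
            phi = fit.basis.matrix(GRID)
            va = np.einsum("ij,jk,ik->i", phi, K, phi)
            draws.append(va / (va + max(s2e[0], 1e-8)))
        sd = np.std(np.array(draws), axis=0)
        mid = GRID[5:-5]  # boundary truncation distorts the tails most
        ratio = h.se[5:-5] / sd[5:-5]
        assert np.all((ratio > 0.6) & (ratio < 1.7))


class TestGeneticCorrelation:
    def test_reference_age_correlates_perfectly_with_itself(self, fitted):
        fit, _ = fitted
        r = genetic_correlation(fit, reference_age=0.0, grid=GRID)
        assert r.values[0] == pytest.approx(1.0)
        assert np.all(np.abs(r.values) <= 1.0 + 1e-12)

    def test_intercept_only_curves_fully_correlated(self):
        r = genetic_correlation(np.diag([1.0, 0.0, 0.0]) + 1e-12 * np.eye(3), B,
                                reference_age=0.0, grid=GRID)
        assert r.values == pytest.approx(np.ones(len(GRID)), abs=1e-5)

    def test_identity_k_gives_basis_cosine(self):
        r = genetic_correlation(np.eye(3), B, reference_age=0.0, grid=GRID)
        phi = B.matrix(GRID)
        phi0 = B.row(0.0)
        cos = phi @ phi0 / (np.linalg.norm(phi0) * np.linalg.norm(phi, axis=1))
        assert r.values == pytest.approx(cos)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero additive variance"):
            genetic_correlation(np.diag([0.0, 1.0, 0.0]), B, reference_age=30.0,
                                grid=GRID)


class TestEigenAnalysis:
    def test_percent_split(self):
        e = eigen_analysis(np.diag([3.0, 1.0]), LegendreBasis(1, 0, 60), GRID)
        assert e.percent == pytest.approx([75.0, 25.0])

    def test_equal_eigenvalues(self):
        e = eigen_analysis(np.eye(3), B, GRID)
        assert e.percent == pytest.approx([100 / 3] * 3)

    def test_leading_eigenfunction_of_intercept_dominated_k_is_flat(self):
        K = np.diag([1.0, 1e-3, 1e-3])
        e = eigen_analysis(K, B, GRID)
        lead = e.eigenfunctions[:, 0]
        assert np.std(lead) < 0.05 * np.mean(np.abs(lead))

    def test_variance_reconstruction(self, rng):
        M = rng.normal(size=(3, 3))
        K = M @ M.T
        e = eigen_analysis(K, B, GRID)
        recon = (e.eigenfunctions**2) @ e.eigenvalues
        va = additive_variance(K, B, GRID).values
        assert np.abs(recon - va).max() < 1e-10


class TestTrajectoryContainer:
    def test_grid_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            Trajectory(np.array([0.0, 0.0]), np.zeros(2), None, "fixed_curve")

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            Trajectory(np.array([0.0, 1.0]), np.zeros(2), np.array([-1.0, 0.0]),
                       "heritability")
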