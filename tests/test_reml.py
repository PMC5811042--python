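"""Mixed model equations and AI-REML estimation."""

import numpy as np
import pandas as pd
import pytest

from telotraj.pedigree import Pedigree
from telotraj.reml import (
    MMEError,
    ModelSpec,
    RemlOptions,
    VarianceComponents,
    build_design,
    build_mme,
    fit_reml,
)
from telotraj.simulate import default_truth, simulate_pedigree, simulate_rr_phenotypes

from conftest import dense_reml_loglik, tiny_rr_dataset


def one_animal_data(y=1.7, age=30.0):
    return pd.DataFrame(
        {
            "animal_id": ["a1"],
            "age_months": [age],
            "log_rltl": [y],
            "birth_year": ["2008"],
            "genetic_group": ["g"],
            "plate": ["p"],
            "row": ["r"],
        }
    )


SIMPLE = ModelSpec(
    order_fixed=0,
    random_effect="intercept",
    fixed_factors=(),
    bounds=(0.0, 60.0),
)


class TestBuildMme:
    def test_single_animal_closed_form(self):
        """Intercept-only fixed effect, order-0 random: C has known entries."""
        ped = Pedigree.from_triples([("a1", None, None)])
        data = one_animal_data()
        design = build_design(data, SIMPLE, pedigree=ped)
        vc = VarianceComponents(
            K=np.array([[0.5]]), sigma2_pe=None, sigma2_e=np.array([0.25]),
            class_bounds=None,
        )
        C, rhs, sl = build_mme(design, vc)
        x = np.sqrt(0.5)  # constant basis function value
        # [x^2/s2   x/s2 ; x/s2   1/s2 + 1/K]
        expect = np.array(
            [[x * x / 0.25, x / 0.25], [x / 0.25, 1 / 0.25 + 1 / 0.5]]
        )
        assert np.abs(C - expect).max() < 1e-12
        assert rhs == pytest.approx([x * 1.7 / 0.25, 1.7 / 0.25])

    def test_duplicated_record_doubles_data_blocks(self):
        ped = Pedigree.from_triples([("a1", None, None)])
        d1 = one_animal_data()
        d2 = pd.concat([d1, d1], ignore_index=True)
        vc = VarianceComponents(np.array([[0.5]]), None, np.array([0.25]), None)
        C1, r1, _ = build_mme(build_design(d1, SIMPLE, pedigree=ped), vc)
        C2, r2, _ = build_mme(build_design(d2, SIMPLE, pedigree=ped), vc)
        Ginv = np.array([[0.0, 0.0], [0.0, 2.0]])
        assert np.abs((C2 - Ginv) - 2 * (C1 - Ginv)).max() < 1e-12
        assert np.abs(r2 - 2 * r1).max() < 1e-12

    def test_unphenotyped_animal_contributes_no_data(self):
        ped = Pedigree.from_triples([("a1", None, None), ("a2", None, None)])
        design = build_design(one_animal_data(), SIMPLE, pedigree=ped)
        vc = VarianceComponents(np.array([[0.5]]), None, np.array([0.25]), None)
        C, rhs, sl = build_mme(design, vc)
        j = sl["genetic"].start + ped.index("a2")
        offdiag = np.delete(C[j], j)
        assert np.all(offdiag == 0.0) and rhs[j] == 0.0
        assert C[j, j] == pytest.approx(2.0)  # pure A^-1 x K^-1 contribution

    def test_missing_pedigree_animal_is_an_error(self):
        ped = Pedigree.from_triples([("other", None, None)])
        with pytest.raises(MMEError, match="absent from pedigree"):
            build_design(one_animal_data(), SIMPLE, pedigree=ped)

    def test_aliased_numeric_covariate_raises(self):
        data = pd.concat([one_animal_data()] * 4, ignore_index=True)
        data["dup"] = 1.0  # proportional to the constant basis column
        model = ModelSpec(
            order_fixed=0, random_effect="none", fixed_factors=(),
            extra_effects=("dup",), bounds=(0.0, 60.0),
        )
        with pytest.raises(MMEError, match="aliased"):
            build_design(data, model)


class TestFitReml:
    def test_matches_dense_likelihood_oracle(self):
        ped, pheno, _ = tiny_rr_dataset(11, [[0.04, 0.005], [0.005, 0.01]])
        model = ModelSpec(
            order_fixed=1, order_random=1,
            fixed_factors=("birth_year", "genetic_group"), bounds=(0.0, 60.0),
        )
        fit = fit_reml(pheno, ped, model)
        design = build_design(pheno, model, pedigree=ped)
        ll = dense_reml_loglik(design, ped.amatrix(), fit.vc.K, fit.vc.sigma2_e[0])
        assert fit.loglik == pytest.approx(ll, abs=1e-8)

    def test_null_genetics_hits_boundary(self):
        ped, pheno, _ = tiny_rr_dataset(5, [[0.0, 0.0], [0.0, 0.0]], s2e=0.02,
                                        n_animals=40)
        model = ModelSpec(
            order_fixed=1, order_random=1,
            fixed_factors=("birth_year", "genetic_group"), bounds=(0.0, 60.0),
        )
        fit = fit_reml(pheno, ped, model)
        phi = fit.basis.matrix(np.arange(0.0, 61.0))[:, :2]
        va = np.einsum("ij,jk,ik->i", phi, fit.vc.K, phi)
        h2 = va / (va + fit.vc.sigma2_e[0])
        assert h2.max() < 0.1

    def test_loglik_invariant_to_record_and_animal_order(self):
        ped, pheno, _ = tiny_rr_dataset(21, [[0.04, 0.005], [0.005, 0.01]])
        model = ModelSpec(
            order_fixed=1, order_random=1,
            fixed_factors=("birth_year", "genetic_group"), bounds=(0.0, 60.0),
        )
        fit1 = fit_reml(pheno, ped, model)
        shuffled = pheno.sample(frac=1.0, random_state=0).reset_index(drop=True)
        fit2 = fit_reml(shuffled, ped, model)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-6)
        assert np.allclose(fit1.theta, fit2.theta, rtol=1e-3, atol=1e-8)

    def test_blup_shrinkage_limits(self):
        # two well-separated records per animal so an order-1 animal curve can
        # interpolate them exactly once the residual variance vanishes
        ped, pheno, _ = tiny_rr_dataset(31, [[0.04, 0.0], [0.0, 0.01]],
                                        ages=[10.0, 50.0])
        model = ModelSpec(
            order_fixed=1, order_random=1,
            fixed_factors=("birth_year", "genetic_group"), bounds=(0.0, 60.0),
        )
        K = np.array([[0.04, 0.0], [0.0, 0.01]])
        # huge residual: all BLUPs shrink to zero
        big = fit_reml(
            pheno, ped, model,
            options=RemlOptions(fix_theta=True, start={"K": K, "sigma2_e": 1e6}),
        )
        assert np.abs(big.u.to_numpy()).max() < 1e-3
        # tiny residual: fitted values approach the observations
        small = fit_reml(
            pheno, ped, model,
            options=RemlOptions(fix_theta=True, start={"K": K, "sigma2_e": 1e-8}),
        )
        design = build_design(pheno, model, pedigree=ped)
        beta = small.beta.to_numpy()
        uvec = small.u.to_numpy().ravel()
        sl = design.slices
        fitted = design.X @ beta + design.W[:, sl["genetic"]] @ uvec
        assert np.abs(fitted - design.y).max() < 1e-3

    def test_fixed_sigma2_matches_projected_closed_form(self):
        """With no genetic term the REML residual variance is RSS/(n-p)."""
        ped, pheno, _ = tiny_rr_dataset(41, [[0.01, 0.0], [0.0, 0.001]])
        model = ModelSpec(
            order_fixed=1, random_effect="none",
            fixed_factors=("birth_year", "genetic_group"), bounds=(0.0, 60.0),
        )
        fit = fit_reml(pheno, ped, model)
        design = build_design(pheno, model)
        X, y = design.X, design.y
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        assert fit.vc.sigma2_e[0] == pytest.approx(rss / (design.n - design.p), rel=1e-6)

    def test_permanent_environment_recovery_and_boundary(self):
        truth = default_truth(order=0)
        truth.k_true = np.array([[0.02]])
        truth.sigma2_e_true = np.array([0.01])
        truth.sigma2_pe_true = 0.02
        ped = simulate_pedigree(60, 3, 4, seed=2)
        rng = np.random.default_rng(3)
        animals = list(ped.ids)
        sched = {a: np.sort(rng.uniform(0, 60, 5)) for a in animals}
        pheno, truth = simulate_rr_phenotypes(ped, truth, sched, seed=4)
        model = ModelSpec(
            order_fixed=1, random_effect="intercept", permanent_env=True,
            fixed_factors=("birth_year", "genetic_group"), bounds=(0.0, 60.0),
        )
        fit = fit_reml(pheno, ped, model)
        i = fit.theta_names.index("sigma2_pe")
        se = np.sqrt(fit.theta_cov[i, i])
        assert abs(fit.vc.sigma2_pe - 0.02) < 3 * se
        # simulated without a PE effect: estimate collapses to the boundary
        truth0 = default_truth(order=0)
        truth0.k_true = np.array([[0.02]])
        truth0.sigma2_e_true = np.array([0.01])
        pheno0, _ = simulate_rr_phenotypes(ped, truth0, sched, seed=5)
        fit0 = fit_reml(pheno0, ped, model)
        # PE should collapse toward the boundary: a small share of the
        # animal-level variance (the genetic/PE split is weakly identified)
        animal_var = fit0.vc.K[0, 0] + fit0.vc.sigma2_pe
        assert fit0.vc.sigma2_pe < 0.25 * animal_var

    def test_ml_loglik_matches_closed_form_without_random_effects(self):
        from telotraj.reml import ml_loglik

        ped, pheno, _ = tiny_rr_dataset(61, [[0.01, 0.0], [0.0, 0.001]])
        model = ModelSpec(
            order_fixed=1, random_effect="none",
            fixed_factors=("birth_year", "genetic_group"), bounds=(0.0, 60.0),
        )
        fit = fit_reml(pheno, ped, model)
        design = build_design(pheno, model)
        r = design.y - design.X @ fit.beta.to_numpy()
        s2 = fit.vc.sigma2_e[0]
        expect = -0.5 * (
            design.n * np.log(2 * np.pi)
            + design.n * np.log(s2)
            + float(r @ r) / s2
        )
        assert ml_loglik(pheno, fit) == pytest.approx(expect, abs=1e-8)

    def test_all_pedigree_animals_receive_coefficients(self):
        ped, pheno, _ = tiny_rr_dataset(51, [[0.04, 0.0], [0.0, 0.01]])
        model = ModelSpec(
            order_fixed=1, order_random=1,
            fixed_factors=("birth_year", "genetic_group"), bounds=(0.0, 60.0),
        )
        fit = fit_reml(pheno, ped, model)
        assert set(fit.u.index) == set(ped.ids)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * len(fit.theta))
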