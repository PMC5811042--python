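"""Synthetic-data generator: determinism and distributional ground truth."""

import numpy as np
import pandas as pd
import pytest

from telotraj.pedigree import Pedigree
from telotraj.simulate import (
    SimulationTruth,
    default_truth,
    sampling_schedule,
    simulate_breeding_values,
    simulate_cq_plates,
    simulate_pedigree,
    simulate_rr_phenotypes,
    simulate_study,
    simulate_survival,
)


class TestPedigreeSim:
    def test_founders_only(self):
        ped = simulate_pedigree(4, 1, 0)
        assert ped.n == 4 and ped.n_founders == 4

    def test_seed_determinism(self):
        a = simulate_pedigree(4, 2, 2, seed=1)
        b = simulate_pedigree(4, 2, 2, seed=1)
        assert a.ids == b.ids
        assert np.array_equal(a.sire, b.sire) and np.array_equal(a.dam, b.dam)

    def test_diagonal_of_a_at_least_one(self):
        ped = simulate_pedigree(100, 3, 2, seed=7)
        assert np.all(np.diag(ped.amatrix()) >= 1.0 - 1e-12)

    def test_invalid_generations(self):
        with pytest.raises(ValueError):
            simulate_pedigree(4, 0, 2)


class TestBreedingValues:
    def test_founder_covariance_matches_k(self, rng):
        ped = Pedigree.from_triples([(f"f{i}", None, None) for i in range(10_000)])
        u = simulate_breeding_values(ped, np.eye(2), rng)
        emp = np.cov(u.T)
        se = 3.0 / np.sqrt(len(u))  # Monte-Carlo 3-SE band for unit variances
        assert np.abs(emp - np.eye(2)).max() < 3 * se

    def test_parent_offspring_covariance_is_half(self, rng):
        n = 8000
        triples = []
        for i in range(n):
            triples += [(f"s{i}", None, None), (f"d{i}", None, None), (f"c{i}", f"s{i}", f"d{i}")]
        ped = Pedigree.from_triples(triples)
        u = simulate_breeding_values(ped, np.eye(2), rng)
        sires = np.array([ped.index(f"s{i}") for i in range(n)])
        kids = np.array([ped.index(f"c{i}") for i in range(n)])
        for k in range(2):
            cov = np.mean(u[sires, k] * u[kids, k])
            assert abs(cov - 0.5) < 3 * np.sqrt(1.0 / n) * 1.5

    def test_non_psd_k_rejected_before_draws(self, rng):
        ped = Pedigree.from_triples([("1", None, None)])
        with pytest.raises(ValueError, match="positive semidefinite"):
            simulate_breeding_values(ped, np.array([[1.0, 2.0], [2.0, 1.0]]), rng)


class TestPhenotypes:
    def test_zero_variance_gives_exact_fixed_part(self):
        ped = simulate_pedigree(6, 2, 2, seed=3)
        truth = default_truth(order=2)
        truth.k_true = np.zeros((3, 3))
        truth.sigma2_e_true = np.array([0.0])
        sched = {a: np.array([0.0, 30.0]) for a in ped.ids[:4]}
        pheno, truth = simulate_rr_phenotypes(ped, truth, sched, seed=5)
        basis = truth.basis
        fe = truth.fixed_effect_values
        for _, r in pheno.iterrows():
            expect = (
                basis.row(r["age_months"]) @ truth.fixed_curve
                + fe["birth_year"][r["birth_year"]]
                + fe["genetic_group"][r["genetic_group"]]
                + fe["plate"][r["plate"]]
                + fe["row"][r["row"]]
            )
            assert r["log_rltl"] == pytest.approx(expect, abs=1e-12)

    def test_schedule_means_match_study_design(self, rng):
        sched = sampling_schedule([f"a{i}" for i in range(4000)], rng)
        counts = np.array([len(v) for v in sched.values()])
        assert counts.min() >= 2 and counts.max() <= 8
        assert abs(counts.mean() - 4.3) < 0.1
        assert all(v[0] == 0.0 for v in sched.values())

    def test_variance_decomposition_at_fixed_age(self, rng):
        # many unrelated phenotyped founders, one record each at age t
        n = 4000
        ped = Pedigree.from_triples([(f"f{i}", None, None) for i in range(n)])
        truth = default_truth(order=2)
        t = 24.0
        sched = {a: np.array([t]) for a in ped.ids}
        pheno, truth = simulate_rr_phenotypes(ped, truth, sched, seed=9)
        phi = truth.basis.row(t)
        expected = float(phi @ truth.k_true @ phi + truth.sigma2_e_true[0])
        # remove the fixed-effect contribution exactly using the stored truth
        fe = truth.fixed_effect_values
        adj = pheno.apply(
            lambda r: r["log_rltl"]
            - fe["birth_year"][r["birth_year"]]
            - fe["genetic_group"][r["genetic_group"]]
            - fe["plate"][r["plate"]]
            - fe["row"][r["row"]],
            axis=1,
        )
        emp = float(np.var(adj, ddof=1))
        se = expected * np.sqrt(2.0 / (n - 1))
        assert abs(emp - expected) < 3 * se


class TestPlatesAndSurvival:
    def test_negative_noise_rejected(self):
        df = pd.DataFrame(
            {"sample_id": ["s"], "animal_id": ["a"], "plate": ["p"], "row": ["r"],
             "target_rltl": [1.0]}
        )
        with pytest.raises(ValueError):
            simulate_cq_plates(df, noise_sd=-0.1)

    def test_noisy_plates_match_lognormal_mean(self):
        from telotraj.qpcr import rltl_from_plates

        n, sd = 1000, 0.05
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "animal_id": [f"a{i}" for i in range(n)],
                "plate": ["p1"] * n,
                "row": ["r1"] * n,
                "target_rltl": np.ones(n),
            }
        )
        plates = simulate_cq_plates(df, e_tel=1.93, e_b2m=1.98, noise_sd=sd, seed=4)
        out, _ = rltl_from_plates(plates)
        vals = out.loc[~out["is_calibrator"], "rltl"].to_numpy()
        s2 = sd**2 * (np.log(1.93) ** 2 + np.log(1.98) ** 2)
        mean_expect = np.exp(s2 / 2)  # lognormal mean
        mc_se = np.sqrt((np.exp(s2) - 1) * np.exp(s2) / n)
        assert abs(vals.mean() - mean_expect) < 3 * mc_se

    def test_censored_fraction_binomial(self):
        truth = default_truth()
        truth.survival_log_hazard_by_cluster = {"c": 0.0}
        sv = simulate_survival({f"a{i}": "c" for i in range(10_000)}, truth,
                               censoring_rate=0.2, seed=8)
        frac = 1.0 - sv["event"].mean()
        assert abs(frac - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 10_000)

    def test_bad_censoring_rate(self):
        truth = default_truth()
        with pytest.raises(ValueError):
            simulate_survival({"a": "maintain"}, truth, censoring_rate=1.0)

    def test_cox_recovers_simulated_hazard_ratio(self):
        from telotraj.survival import fit_cox

        truth = default_truth()
        truth.survival_log_hazard_by_cluster = {"A": 0.0, "B": 0.7}
        assign = {f"a{i}": ("A" if i < 1000 else "B") for i in range(2000)}
        sv = simulate_survival(assign, truth, censoring_rate=0.0, seed=5)
        fit = fit_cox(sv, reference_cluster="A")
        se = float(np.sqrt(np.diag(fit.cov))[0])
        assert abs(fit.coef["B"] - 0.7) < 3 * se


class TestTruthRoundTrip:
    def test_truth_json_roundtrip(self, tmp_path):
        truth = default_truth()
        truth.true_breeding_coefficients = {"a": [0.1, 0.0, 0.0]}
        truth.to_json(tmp_path / "t.json")
        back = SimulationTruth.from_json(tmp_path / "t.json")
        assert np.allclose(back.k_true, truth.k_true)
        assert back.fixed_effect_values == truth.fixed_effect_values

    def test_study_determinism(self):
        s1 = simulate_study(n_females=20, n_sires=4, n_dams=8, seed=3)
        s2 = simulate_study(n_females=20, n_sires=4, n_dams=8, seed=3)
        pd.testing.assert_frame_equal(s1["phenotypes"], s2["phenotypes"])
        pd.testing.assert_frame_equal(s1["survival"], s2["survival"])
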