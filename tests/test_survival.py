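"""Cox proportional hazards on cluster labels, Breslow ties, Wald test."""

import numpy as np
import pandas as pd
import pytest

from telotraj.survival import SurvivalRecord, cox_score_test, fit_cox, wald_test


def table(times, events, clusters):
    return pd.DataFrame(
        {
            "animal_id": [f"a{i}" for i in range(len(times))],
            "time": times,
            "event": events,
            "cluster": clusters,
        }
    )


def grid_maximize(nll, lo=-20.0, hi=20.0, iters=6, points=2001):
    """Coarse-to-fine grid search oracle for a 1-D partial likelihood."""
    for _ in range(iters):
        grid = np.linspace(lo, hi, points)
        vals = np.array([nll(b) for b in grid])
        i = int(np.argmin(vals))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, points - 1)]
    return 0.5 * (lo + hi)


class TestFitCox:
    def test_tied_pair_matches_grid_oracle(self):
        """Two tied events, one per group: Breslow optimum is beta = 0."""
        df = table([3.0, 3.0], [True, True], ["x", "y"])
        fit = fit_cox(df, reference_cluster="y")

        def nll(b):
            return -(b - 2 * np.log(np.exp(b) + 1.0))

        bstar = grid_maximize(nll)
        assert fit.coef["x"] == pytest.approx(bstar, abs=1e-6)
        assert fit.coef["x"] == pytest.approx(0.0, abs=1e-6)

    def test_five_subject_instance_matches_grid_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        events = [True, True, False, True, True]
        clusters = ["g1", "g0", "g1", "g1", "g0"]
        fit = fit_cox(table(times, events, clusters), reference_cluster="g0")
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0])

        def nll(b):
            eta = b * x
            w = np.exp(eta)
            ll = 0.0
            for i, (e) in enumerate(events):
                if e:
                    ll += eta[i] - np.log(w[i:].sum())
            return -ll

        bstar = grid_maximize(nll)
        assert fit.coef["g1"] == pytest.approx(bstar, abs=1e-6)

    def test_separation_warns_and_caps(self):
        df = table([1.0, 2.0], [True, True], ["x", "y"])
        fit = fit_cox(df, reference_cluster="y")
        assert fit.warnings  # monotone likelihood flagged
        assert abs(fit.coef["x"]) >= 15.0

    def test_requires_events_and_two_clusters(self):
        with pytest.raises(ValueError, match="event"):
            fit_cox(table([1.0, 2.0], [False, False], ["x", "y"]))
        with pytest.raises(ValueError, match="two clusters"):
            fit_cox(table([1.0, 2.0], [True, True], ["x", "x"]))

    def test_largest_cluster_is_default_reference(self):
        df = table([1, 2, 3, 4, 5], [True] * 5, ["b", "b", "b", "a", "a"])
        fit = fit_cox(df)
        assert fit.reference == "b"
        assert list(fit.coef.index) == ["a"]

    def test_matches_lifelines_on_continuous_times(self, rng):
        from lifelines import CoxPHFitter

        n = 400
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / np.exp(0.5 * x))
        c = rng.exponential(2.0, n)
        df = table(np.minimum(t, c), t <= c, np.where(x > 0, "hi", "lo"))
        fit = fit_cox(df, reference_cluster="lo")
        ll = CoxPHFitter().fit(
            pd.DataFrame({"t": df["time"], "e": df["event"], "x": x}), "t", "e"
        )
        assert fit.coef["hi"] == pytest.approx(ll.params_["x"], abs=1e-6)
        assert np.sqrt(fit.cov[0, 0]) == pytest.approx(ll.standard_errors_["x"],
                                                       abs=1e-6)

    def test_censoring_time_beyond_last_event_is_irrelevant(self):
        """A censored subject enters the likelihood only through the risk sets
        it joins: moving its censoring time past the last event changes
        nothing."""
        base = table([1.0, 2.0, 3.0, 4.0], [True, True, True, True],
                     ["a", "b", "a", "b"])
        near = pd.concat(
            [base, table([4.5], [False], ["b"]).assign(animal_id="zz")],
            ignore_index=True,
        )
        far = pd.concat(
            [base, table([999.0], [False], ["b"]).assign(animal_id="zz")],
            ignore_index=True,
        )
        f_near = fit_cox(near, reference_cluster="a")
        f_far = fit_cox(far, reference_cluster="a")
        assert f_near.coef["b"] == pytest.approx(f_far.coef["b"], abs=1e-10)
        assert f_near.loglik == pytest.approx(f_far.loglik, abs=1e-10)

    def test_time_rescaling_invariance(self):
        t = [3.0, 8.0, 11.0, 20.0, 25.0]
        e = [True, True, False, True, True]
        c = ["a", "b", "a", "b", "a"]
        f_days = fit_cox(table(t, e, c), reference_cluster="a")
        f_years = fit_cox(table([x / 365.25 for x in t], e, c), reference_cluster="a")
        assert f_days.coef["b"] == pytest.approx(f_years.coef["b"], abs=1e-8)
        assert f_days.loglik == pytest.approx(f_years.loglik, abs=1e-8)

    def test_duplicate_animal_rejected(self):
        df = table([1.0, 2.0], [True, True], ["x", "y"])
        df["animal_id"] = ["a", "a"]
        with pytest.raises(ValueError, match="more than one"):
            fit_cox(df)


class TestWald:
    def test_zero_coefficients_give_p_one(self):
        from telotraj.survival import CoxFit

        fit = CoxFit(
            coef=pd.Series([0.0, 0.0], index=["b", "c"]),
            cov=np.eye(2) * 0.04,
            reference="a",
            loglik=0.0,
            n_events=10,
            n_censored=0,
            converged=True,
        )
        stat, df, p = wald_test(fit)
        assert stat == 0.0 and df == 2 and p == 1.0

    def test_single_coefficient_is_z_squared(self):
        from telotraj.survival import CoxFit

        fit = CoxFit(
            coef=pd.Series([0.6], index=["b"]),
            cov=np.array([[0.04]]),
            reference="a",
            loglik=0.0,
            n_events=10,
            n_censored=0,
            converged=True,
        )
        stat, df, p = wald_test(fit)
        assert stat == pytest.approx((0.6 / 0.2) ** 2)
        assert df == 1


class TestScoreTest:
    def test_score_test_equals_logrank_without_ties(self, rng):
        from lifelines.statistics import logrank_test

        n = 60
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0, n) + rng.uniform(0, 1e-6, n)  # no exact ties
        df = table(t, [True] * n, np.where(x > 0, "hi", "lo"))
        stat, dfree, p = cox_score_test(df, reference_cluster="lo")
        lr = logrank_test(t[x == 0], t[x == 1])
        assert stat == pytest.approx(lr.test_statistic, abs=1e-8)
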