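"""Cox proportional-hazards association between profile cluster and lifespan.

Productive lifespan (days from birth to culling, right-censored for animals
alive at study end) is regressed on the trajectory-cluster factor with a Cox
model: Newton-Raphson maximization of the Breslow partial likelihood (ties in
integer days share a risk set), with the largest cluster as the reference
level.  A Wald chi-square on the k-1 cluster coefficients tests whether the
profiles are associated with lifespan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["SurvivalRecord", "CoxFit", "fit_cox", "wald_test", "cox_score_test"]

COEF_CAP = 20.0  # |log HR| cap signalling monotone likelihood / separation


@dataclass(frozen=True)
class SurvivalRecord:
    animal_id: str
    time: float  # days; event time or maximal known survival time
    event: bool  # True = culled (event), False = right-censored
    cluster: str

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"non-positive survival time for {self.animal_id!r}")


@dataclass
class CoxFit:
    coef: pd.Series  # log hazard ratios, one per non-reference cluster
    cov: np.ndarray
    reference: str
    loglik: float
    n_events: int
    n_censored: int
    converged: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def df(self) -> int:
        return len(self.coef)


def _table(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "animal_id": [r.animal_id for r in records],
                "time": [r.time for r in records],
                "event": [r.event for r in records],
                "cluster": [r.cluster for r in records],
            }
        )
    required = {"animal_id", "time", "event", "cluster"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    if df["animal_id"].duplicated().any():
        dup = df.loc[df["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise ValueError(f"animal {dup!r} has more than one survival record")
    if (df["time"] <= 0).any():
        bad = df.loc[df["time"] <= 0, "animal_id"].iloc[0]
        raise ValueError(f"non-positive survival time for animal {bad!r}")
    return df


def _design(df: pd.DataFrame, reference: str | None) -> tuple[np.ndarray, list[str], str]:
    clusters = df["cluster"].astype(str)
    counts = clusters.value_counts()
    if reference is None:
        # largest cluster; ties broken by name for determinism
        top = counts.max()
        reference = sorted(c for c in counts.index if counts[c] == top)[0]
    levels = [c for c in sorted(counts.index) if c != str(reference)]
    X = np.column_stack(
        [(clusters == lev).to_numpy(dtype=float) for lev in levels]
    ) if levels else np.zeros((len(df), 0))
    return X, levels, str(reference)


def _breslow_quantities(
    times: np.ndarray, events: np.ndarray, X: np.ndarray, beta: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow partial log-likelihood, score and information.

    Records sorted ascending by time; all events at a tied time share the risk
    set starting at the first record with that time.
    """
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    # suffix cumulative sums (risk sets are suffixes of the ascending sort)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    s2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1], axis=0)[
        ::-1
    ]
    # index of the first record sharing each record's time
    first = np.searchsorted(times, times, side="left")
    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    ev = np.nonzero(events)[0]
    for i in ev:
        j = first[i]
        ll += eta[i] - np.log(s0[j])
        xb = s1[j] / s0[j]
        score += X[i] - xb
        info += s2[j] / s0[j] - np.outer(xb, xb)
    return ll, score, info


def fit_cox(
    records,
    reference_cluster: str | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Cox proportional-hazards fit of lifespan on the cluster factor.

    ``records`` is a list of SurvivalRecord or a DataFrame with columns
    animal_id, time, event, cluster.  The reference cluster defaults to the
    largest one.  Raises if no events or fewer than two clusters are present;
    warns and caps coefficients under complete separation (monotone
    likelihood).
    """
    df = _table(records)
    if df["event"].sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    if df["cluster"].nunique() < 2:
        raise ValueError("Cox fit requires at least two clusters present")
    X, levels, reference = _design(df, reference_cluster)
    order = np.argsort(df["time"].to_numpy(), kind="stable")
    times = df["time"].to_numpy(dtype=float)[order]
    events = df["event"].to_numpy(dtype=bool)[order]
    Xs = X[order]

    p = Xs.shape[1]
    beta = np.zeros(p)
    warnings_: list[str] = []
    converged = False
    ll = -np.inf
    for _ in range(max_iter):
        ll, score, info = _breslow_quantities(times, events, Xs, beta)
        if np.linalg.norm(score) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(p), score)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(info) @ score
        # dampen huge steps (separation drives |beta| to infinity)
        nrm = np.max(np.abs(step)) if p else 0.0
        if nrm > 5.0:
            step = step * (5.0 / nrm)
        beta = beta + step
        if np.max(np.abs(beta)) > COEF_CAP:
            beta = np.clip(beta, -COEF_CAP, COEF_CAP)
            warnings_.append(
                "monotone partial likelihood (complete separation between "
                "clusters); coefficient capped at |log HR| = "
                f"{COEF_CAP}"
            )
            logger.warning(warnings_[-1])
            ll, score, info = _breslow_quantities(times, events, Xs, beta)
            break
    else:
        ll, score, info = _breslow_quantities(times, events, Xs, beta)
        if np.linalg.norm(score) < tol:
            converged = True
    if np.max(np.abs(beta), initial=0.0) > 15.0 and not warnings_:
        warnings_.append(
            "monotone partial likelihood suspected (|log HR| > 15); "
            "estimate is effectively a boundary value"
        )
        logger.warning(warnings_[-1])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return CoxFit(
        coef=pd.Series(beta, index=levels, name="log_hazard_ratio"),
        cov=cov,
        reference=reference,
        loglik=float(ll),
        n_events=int(df["event"].sum()),
        n_censored=int((~df["event"].astype(bool)).sum()),
        converged=converged,
        warnings=warnings_,
    )


def wald_test(fit: CoxFit) -> tuple[float, int, float]:
    """Wald chi-square over the cluster coefficients: beta' Cov^-1 beta."""
    beta = fit.coef.to_numpy()
    if beta.size == 0:
        return 0.0, 0, 1.0
    try:
        stat = float(beta @ np.linalg.solve(fit.cov, beta))
    except np.linalg.LinAlgError:
        raise ValueError("singular coefficient covariance; Wald test undefined")
    df = fit.df
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p


def cox_score_test(records, reference_cluster: str | None = None) -> tuple[float, int, float]:
    """Score (log-rank-type) test at beta = 0: U' I^-1 U ~ chi2(k-1).

    With two groups, no ties and no censoring adjustments this equals the
    classical log-rank statistic.
    """
    df = _table(records)
    X, levels, _ = _design(df, reference_cluster)
    order = np.argsort(df["time"].to_numpy(), kind="stable")
    times = df["time"].to_numpy(dtype=float)[order]
    events = df["event"].to_numpy(dtype=bool)[order]
    Xs = X[order]
    _, score, info = _breslow_quantities(times, events, Xs, np.zeros(Xs.shape[1]))
    stat = float(score @ np.linalg.solve(info, score))
    dfree = len(levels)
    return stat, dfree, float(stats.chi2.sf(stat, dfree))
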