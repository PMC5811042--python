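"""Genetic-parameter trajectories derived from a random-regression fit.

All reported curves are quadratic forms in the Legendre basis vector phi(t):
the population fixed curve sum_k b_k phi_k(t), per-animal profiles
sum_k u_jk phi_k(t) (deviations from the fixed curve), the additive genetic
variance V_A(t) = phi(t) K phi(t)', heritability
h2(t) = V_A / (V_A + V_pe + sigma2_e), and the genetic correlation between
ages r(t0, t) = phi(t0) K phi(t)' / sqrt(V_A(t0) V_A(t)).  Standard errors of
the variance-parameter functions use the delta method with the asymptotic
covariance from the average-information matrix; profile standard errors use
each animal's full prediction-error covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import LegendreBasis
from .reml import FitResult, VarianceComponents, _unpack

__all__ = [
    "Trajectory",
    "EigenDecomposition",
    "fixed_curve",
    "animal_profiles",
    "additive_variance",
    "heritability",
    "genetic_correlation",
    "eigen_analysis",
    "trajectories_frame",
]


@dataclass
class Trajectory:
    """An age-indexed curve with optional pointwise standard errors."""

    ages: np.ndarray
    values: np.ndarray
    se: np.ndarray | None
    kind: str
    animal_id: str | None = None

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("trajectory age grid must be strictly increasing")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if np.any(self.se < -1e-12):
                raise ValueError("trajectory SEs must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": self.kind,
                "animal_id": self.animal_id or "",
                "age_month": self.ages,
                "value": self.values,
                "se": self.se if self.se is not None else np.nan,
            }
        )


def trajectories_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    return pd.concat([t.to_frame() for t in trajectories], ignore_index=True)


@dataclass
class EigenDecomposition:
    """Eigen structure of the coefficient covariance K.

    The leading eigenfunction of a K dominated by its intercept entry is close
    to constant over age: most between-animal variance is in curve level, the
    rest in curve shape.
    """

    eigenvalues: np.ndarray  # descending
    percent: np.ndarray  # 100 * lambda / sum(lambda)
    eigenvectors: np.ndarray  # columns match eigenvalues
    eigenfunctions: np.ndarray  # (n_ages, n_coef)
    ages: np.ndarray


def _grid_matrix(basis: LegendreBasis, grid, n_coef: int) -> tuple[np.ndarray, np.ndarray]:
    grid = np.asarray(grid, dtype=float)
    phi = basis.matrix(grid)[:, :n_coef]
    return grid, phi


def fixed_curve(fit: FitResult, grid=None) -> Trajectory:
    """Population mean curve: value(t) = sum_k b_k phi_k(t), with SE."""
    basis = fit.basis
    grid = basis.grid() if grid is None else np.asarray(grid, dtype=float)
    nb = fit.model.order_fixed + 1
    _, phi = _grid_matrix(basis, grid, nb)
    names = [f"poly_{k}" for k in range(nb)]
    idx = [list(fit.beta.index).index(nm) for nm in names]
    b = fit.beta.to_numpy()[idx]
    V = fit.beta_cov[np.ix_(idx, idx)]
    values = phi @ b
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", phi, V, phi), 0.0))
    return Trajectory(grid, values, se, kind="fixed_curve")


def animal_profiles(
    fit: FitResult,
    grid=None,
    animals: list[str] | None = None,
    se_mode: str = "full",
) -> list[Trajectory]:
    """Per-animal curves as deviations from the fixed curve.

    ``se_mode='full'`` uses the animal's full prediction-error covariance,
    sqrt(phi PEV phi'); ``'per_order'`` ignores coefficient covariances and
    combines the per-coefficient SEs only (the simpler bookkeeping some
    analyses use — provided for comparison).
    """
    basis = fit.basis
    grid = basis.grid() if grid is None else np.asarray(grid, dtype=float)
    m1 = fit.u.shape[1]
    _, phi = _grid_matrix(basis, grid, m1)
    all_ids = list(fit.u.index)
    animals = all_ids if animals is None else animals
    out = []
    for a in animals:
        if a not in fit.u.index:
            raise KeyError(f"animal {a!r} not in the fitted pedigree")
        j = all_ids.index(a)
        u = fit.u.loc[a].to_numpy()
        values = phi @ u
        pev = fit.u_pev[j]
        if se_mode == "full":
            se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", phi, pev, phi), 0.0))
        elif se_mode == "per_order":
            se = np.sqrt(phi**2 @ np.diag(pev))
        else:
            raise ValueError(f"unknown se_mode {se_mode!r}")
        out.append(Trajectory(grid, values, se, kind="profile", animal_id=a))
    return out


def additive_variance(
    K: np.ndarray, basis: LegendreBasis, grid=None
) -> Trajectory:
    """V_A(t) = phi(t) K phi(t)'; non-negative whenever K is PSD."""
    K = np.asarray(K, dtype=float)
    grid = basis.grid() if grid is None else np.asarray(grid, dtype=float)
    _, phi = _grid_matrix(basis, grid, K.shape[0])
    if K.shape[0] != phi.shape[1]:
        raise ValueError(
            f"K dimension {K.shape} does not match basis ({phi.shape[1]} functions)"
        )
    va = np.einsum("ij,jk,ik->i", phi, K, phi)
    return Trajectory(grid, va, None, kind="additive_variance")


def _va_of_theta(theta, fit: FitResult, phi: np.ndarray) -> np.ndarray:
    m1 = fit.u.shape[1]
    pe = fit.vc.sigma2_pe is not None
    K, _, _ = _unpack(np.asarray(theta), m1, pe, len(fit.vc.sigma2_e))
    return np.einsum("ij,jk,ik->i", phi, K, phi)


def _h2_of_theta(theta, fit: FitResult, phi: np.ndarray, ages: np.ndarray) -> np.ndarray:
    m1 = fit.u.shape[1]
    pe = fit.vc.sigma2_pe is not None
    K, s2pe, s2e = _unpack(np.asarray(theta), m1, pe, len(fit.vc.sigma2_e))
    vc = VarianceComponents(K, s2pe, s2e, fit.vc.class_bounds)
    va = np.einsum("ij,jk,ik->i", phi, K, phi)
    total = va + (s2pe or 0.0) + vc.residual_at(ages)
    return va / total


def _delta_se(func, theta: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Delta-method SE of a vector-valued function of the variance parameters
    by central finite differences (step 1e-6 of each parameter's scale)."""
    f0 = func(theta)
    grads = np.empty((len(theta), f0.shape[0]))
    for i in range(len(theta)):
        h = 1e-6 * max(abs(theta[i]), 1e-3 * np.max(np.abs(theta)))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        grads[i] = (func(tp) - func(tm)) / (2 * h)
    var = np.einsum("it,ij,jt->t", grads, cov, grads)
    return np.sqrt(np.maximum(var, 0.0))


def heritability(fit: FitResult, grid=None) -> Trajectory:
    """h2(t) = V_A / (V_A + V_pe + sigma2_e), with delta-method SE.

    The permanent-environment variance enters the denominator only when that
    term is in the model.
    """
    basis = fit.basis
    grid = basis.grid() if grid is None else np.asarray(grid, dtype=float)
    m1 = fit.u.shape[1]
    if m1 == 0:
        raise ValueError("heritability requires a genetic random effect in the model")
    _, phi = _grid_matrix(basis, grid, m1)
    va = np.einsum("ij,jk,ik->i", phi, fit.vc.K, phi)
    denom = va + (fit.vc.sigma2_pe or 0.0) + fit.vc.residual_at(grid)
    if np.any(denom <= 0):
        raise ValueError("total variance <= 0 on the heritability grid")
    h2 = va / denom
    se = _delta_se(lambda th: _h2_of_theta(th, fit, phi, grid), fit.theta, fit.theta_cov)
    return Trajectory(grid, h2, se, kind="heritability")


def genetic_correlation(
    fit_or_k,
    basis: LegendreBasis | None = None,
    reference_age: float = 0.0,
    grid=None,
    theta_cov: np.ndarray | None = None,
) -> Trajectory:
    """Genetic correlation of the trait at ``reference_age`` with later ages.

    Accepts either a FitResult (SE via the delta method) or a bare K matrix
    with an explicit basis (no SE).
    """
    if isinstance(fit_or_k, FitResult):
        fit = fit_or_k
        basis = fit.basis
        K = fit.vc.K
        theta, cov = fit.theta, fit.theta_cov
        m1 = K.shape[0]
        pe = fit.vc.sigma2_pe is not None
        n_cl = len(fit.vc.sigma2_e)
    else:
        K = np.asarray(fit_or_k, dtype=float)
        if basis is None:
            raise ValueError("basis required when passing a bare K")
        theta = cov = None
        m1 = K.shape[0]
    grid = basis.grid() if grid is None else np.asarray(grid, dtype=float)
    phi = basis.matrix(grid)[:, :m1]
    phi0 = basis.row(reference_age)[:m1]

    def corr_of_k(Km):
        v0 = float(phi0 @ Km @ phi0)
        vt = np.einsum("ij,jk,ik->i", phi, Km, phi)
        if v0 <= 0 or np.any(vt <= 0):
            raise ValueError(
                "zero additive variance at the reference age or on the grid; "
                "correlation undefined"
            )
        return (phi @ (Km @ phi0)) / np.sqrt(v0 * vt)

    values = corr_of_k(K)
    se = None
    if theta is not None:
        def f(th):
            Km, _, _ = _unpack(np.asarray(th), m1, pe, n_cl)
            return corr_of_k(Km)

        se = _delta_se(f, theta, cov)
    return Trajectory(grid, values, se, kind="correlation")


def eigen_analysis(
    K: np.ndarray, basis: LegendreBasis, grid=None
) -> EigenDecomposition:
    """Eigenvalues (as percent of total coefficient variance) and
    eigenfunctions of the covariance function implied by K."""
    K = np.asarray(K, dtype=float)
    grid = basis.grid() if grid is None else np.asarray(grid, dtype=float)
    w, V = np.linalg.eigh(K)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    total = float(np.sum(w))
    percent = 100.0 * w / total if total > 0 else np.full_like(w, np.nan)
    phi = basis.matrix(grid)[:, : K.shape[0]]
    funcs = phi @ V
    return EigenDecomposition(
        eigenvalues=w, percent=percent, eigenvectors=V, eigenfunctions=funcs, ages=grid
    )
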