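"""Random regression animal model fitted by average-information REML.

The model for a (log-)RLTL record of animal j at age t is

    y = (fixed factors) + sum_k phi_k(t) b_k + sum_k phi_k(t) u_jk [+ pe_j] + e

with phi the Legendre basis, b the fixed regression coefficients, u_j the
animal's random regression coefficients with Var(u) = A (x) K (A = numerator
relationship matrix, K = coefficient covariance), an optional scalar
permanent-environment effect pe_j ~ N(0, sigma2_pe), and residuals with a
homogeneous or age-class-specific variance.

Estimation maximizes the restricted likelihood by Newton steps on the
average-information matrix, with step halving and EM fallback whenever a
proposed update does not improve the likelihood or leaves the PSD cone
(curvature "bending": eigenvalue flooring of K).  The restricted
log-likelihood is computed through the mixed-model-equation identities

    log|V| + log|X'V^-1 X| = log|R| + log|G| + log|C|,
    y'Py = y'R^-1 y - s'W'R^-1 y,

so a single sparse assembly and one dense Cholesky per evaluation suffice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, sparse, stats

from .basis import LegendreBasis
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))

__all__ = [
    "ModelSpec",
    "RemlOptions",
    "VarianceComponents",
    "FitResult",
    "MMEError",
    "ConvergenceError",
    "build_design",
    "build_mme",
    "fit_reml",
    "ml_loglik",
    "backward_eliminate",
    "compare_models",
    "test_residual_heterogeneity",
]


class MMEError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, trace: list[float]):
        super().__init__(msg + f" (logL trace: {trace})")
        self.trace = trace


# --------------------------------------------------------------------------- #
# model specification
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: fixed structure, random structure, residual structure."""

    response: str = "log_rltl"
    age_col: str = "age_months"
    fixed_factors: tuple[str, ...] = ("birth_year", "genetic_group", "plate", "row")
    extra_effects: tuple[str, ...] = ()  # elimination candidates (factor or numeric)
    order_fixed: int = 2
    random_effect: str = "legendre"  # "none" | "intercept" | "legendre"
    order_random: int = 2
    use_pedigree: bool = True
    permanent_env: bool = False
    residual_classes: tuple[float, ...] | None = None  # interior age breakpoints
    bounds: tuple[float, float] | None = None  # basis age bounds; None = from data

    def __post_init__(self) -> None:
        if self.random_effect not in ("none", "intercept", "legendre"):
            raise ValueError(f"unknown random_effect {self.random_effect!r}")
        for o in (self.order_fixed, self.order_random):
            if not (0 <= o <= 5):
                raise ValueError("polynomial orders must be in [0, 5]")

    @property
    def n_coef_random(self) -> int:
        if self.random_effect == "none":
            return 0
        if self.random_effect == "intercept":
            return 1
        return self.order_random + 1


@dataclass(frozen=True)
class RemlOptions:
    max_iter: int = 200
    tol_loglik: float = 1e-8
    tol_param: float = 1e-6
    max_halvings: int = 15
    start: dict | None = None  # optional {"K": ..., "sigma2_pe": ..., "sigma2_e": ...}
    fix_theta: bool = False  # evaluate/solve at the starting values only


@dataclass
class VarianceComponents:
    """Estimated (co)variance structure of the random regression model."""

    K: np.ndarray | None
    sigma2_pe: float | None
    sigma2_e: np.ndarray  # one entry per residual age class
    class_bounds: tuple[float, ...] | None  # interior breakpoints, None = homogeneous

    def residual_class(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        if not self.class_bounds:
            return np.zeros(ages.shape, dtype=int)
        return np.searchsorted(np.asarray(self.class_bounds), ages, side="left")

    def residual_at(self, ages) -> np.ndarray:
        return self.sigma2_e[self.residual_class(ages)]


# --------------------------------------------------------------------------- #
# design / MME assembly
# --------------------------------------------------------------------------- #


@dataclass
class Design:
    X: np.ndarray
    x_names: list[str]
    y: np.ndarray
    W: sparse.csr_matrix  # [X | Z_genetic | Z_pe]
    n_coef: int
    animal_ids: list[str]
    pe_ids: list[str]
    res_class: np.ndarray
    class_counts: np.ndarray
    class_bounds: tuple[float, ...] | None
    basis: LegendreBasis
    ainv: sparse.csr_matrix | None
    log_det_a: float
    a_dot: object  # callable A @ M
    dropped_columns: list[str]
    model: ModelSpec
    # per-residual-class Gram caches: C and rhs are cheap dense sums of these
    wtw: list[np.ndarray] = field(default_factory=list)
    wty: list[np.ndarray] = field(default_factory=list)
    yty: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return len(self.animal_ids)

    @property
    def slices(self) -> dict[str, slice]:
        p = self.p
        ng = self.q * self.n_coef
        return {
            "fixed": slice(0, p),
            "genetic": slice(p, p + ng),
            "pe": slice(p + ng, p + ng + len(self.pe_ids)),
        }


def _fixed_matrix(
    data: pd.DataFrame, model: ModelSpec, basis: LegendreBasis
) -> tuple[np.ndarray, list[str], list[str]]:
    """Fixed design: Legendre regression columns + reference-coded factors.

    Rank-deficient columns are resolved by dropping the last-seen redundant
    factor level (logged); a redundant *numeric* candidate column is an error
    listing the aliased names.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    phi = basis.matrix(data[model.age_col].to_numpy())
    for k in range(model.order_fixed + 1):
        cols.append(phi[:, k])
        names.append(f"poly_{k}")
    numeric: list[str] = []
    for eff in tuple(model.fixed_factors) + tuple(model.extra_effects):
        col = data[eff]
        if pd.api.types.is_numeric_dtype(col) and eff not in model.fixed_factors:
            cols.append(col.to_numpy(dtype=float))
            names.append(eff)
            numeric.append(eff)
        else:
            levels = pd.unique(col.astype(str))
            for lev in levels[1:]:  # first level = reference
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{eff}={lev}")
    X = np.column_stack(cols)
    # rank check via unpivoted QR: a column collinear with *earlier* columns
    # shows a (near-)zero diagonal, so the last-seen redundant column is the
    # one dropped
    _, R = linalg.qr(X, mode="economic")
    diag = np.abs(np.diag(R))
    norms = np.linalg.norm(X, axis=0)
    small = diag <= 1e-8 * np.maximum(norms, 1e-300)
    dropped = []
    if np.any(small):
        drop_idx = sorted(np.nonzero(small)[0])
        dropped = [names[i] for i in drop_idx]
        aliased_numeric = [d for d in dropped if d in numeric]
        if aliased_numeric:
            raise MMEError(
                f"fixed-effect design is singular; aliased columns: {dropped}"
            )
        logger.warning("dropping aliased fixed-effect columns: %s", dropped)
        keep = [i for i in range(X.shape[1]) if i not in set(drop_idx)]
        X = X[:, keep]
        names = [names[i] for i in keep]
    return X, names, dropped


def build_design(
    data: pd.DataFrame,
    model: ModelSpec,
    pedigree: Pedigree | None = None,
    basis: LegendreBasis | None = None,
) -> Design:
    required = [model.response, model.age_col, "animal_id"]
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise MMEError(f"phenotype table missing columns: {missing}")
    ages = data[model.age_col].to_numpy(dtype=float)
    if basis is None:
        bounds = model.bounds or (float(ages.min()), float(ages.max()))
        order = max(model.order_fixed, model.order_random)
        basis = LegendreBasis(order=order, t_min=bounds[0], t_max=bounds[1])
    y = data[model.response].to_numpy(dtype=float)
    X, x_names, dropped = _fixed_matrix(data, model, basis)
    n = len(y)

    m1 = model.n_coef_random
    pheno_animals = list(pd.unique(data["animal_id"].astype(str)))
    if model.random_effect != "none":
        if model.use_pedigree:
            if pedigree is None:
                raise MMEError("pedigree required when use_pedigree=True")
            missing_ped = [a for a in pheno_animals if a not in pedigree._index]
            if missing_ped:
                raise MMEError(
                    f"phenotyped animals absent from pedigree: {missing_ped[:5]}"
                )
            animal_ids = list(pedigree.ids)
            ainv = pedigree.ainverse()
            log_det_a = pedigree.log_det_a()
            a_dot = pedigree.a_dot
        else:
            animal_ids = pheno_animals
            ainv = sparse.identity(len(animal_ids), format="csr")
            log_det_a = 0.0
            a_dot = lambda x: x  # noqa: E731
        a_index = {a: i for i, a in enumerate(animal_ids)}
        rows = np.repeat(np.arange(n), m1)
        anim = data["animal_id"].astype(str).map(a_index).to_numpy()
        cols = (anim[:, None] * m1 + np.arange(m1)[None, :]).ravel()
        if model.random_effect == "intercept":
            vals = np.ones(n)[:, None]
        else:
            vals = basis.matrix(ages)[:, : m1]
        Z = sparse.csr_matrix(
            (vals.ravel(), (rows, cols)), shape=(n, len(animal_ids) * m1)
        )
    else:
        animal_ids, ainv, log_det_a, a_dot = [], None, 0.0, None
        Z = None

    if model.permanent_env:
        pe_ids = pheno_animals
        pe_index = {a: i for i, a in enumerate(pe_ids)}
        pcols = data["animal_id"].astype(str).map(pe_index).to_numpy()
        Zpe = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), pcols)), shape=(n, len(pe_ids))
        )
    else:
        pe_ids, Zpe = [], None

    blocks = [sparse.csr_matrix(X)]
    if Z is not None:
        blocks.append(Z)
    if Zpe is not None:
        blocks.append(Zpe)
    W = sparse.hstack(blocks, format="csr")

    bounds_cb = model.residual_classes
    if bounds_cb:
        res_class = np.searchsorted(np.asarray(bounds_cb), ages, side="left")
        n_classes = len(bounds_cb) + 1
    else:
        res_class = np.zeros(n, dtype=int)
        n_classes = 1
    class_counts = np.bincount(res_class, minlength=n_classes)

    wtw, wty, yty = [], [], []
    for c in range(n_classes):
        mask = res_class == c
        Wc = W[mask]
        wtw.append((Wc.T @ Wc).toarray())
        wty.append(np.asarray(Wc.T @ y[mask]).ravel())
        yty.append(float(y[mask] @ y[mask]))

    return Design(
        X=X,
        x_names=x_names,
        y=y,
        W=W,
        n_coef=m1,
        animal_ids=animal_ids,
        pe_ids=pe_ids,
        res_class=res_class,
        class_counts=class_counts,
        class_bounds=bounds_cb,
        basis=basis,
        ainv=ainv,
        log_det_a=log_det_a,
        a_dot=a_dot,
        dropped_columns=dropped,
        model=model,
        wtw=wtw,
        wty=wty,
        yty=yty,
    )


def build_mme(
    design: Design, vc: VarianceComponents
) -> tuple[np.ndarray, np.ndarray, dict[str, slice]]:
    """Assemble Henderson's mixed model equations C s = rhs at given variances.

    The random-effect block of C carries A^-1 (x) K^-1 (plus I/sigma2_pe for
    the permanent-environment block).
    """
    sl = design.slices
    C = np.zeros_like(design.wtw[0])
    rhs = np.zeros(C.shape[0])
    for c, s2 in enumerate(vc.sigma2_e):
        C += design.wtw[c] / s2
        rhs += design.wty[c] / s2
    if design.n_coef:
        Kinv = np.linalg.inv(vc.K)
        g = sl["genetic"]
        C[g, g] += sparse.kron(design.ainv, Kinv, format="csr").toarray()
    if design.pe_ids:
        pe = sl["pe"]
        idx = np.arange(pe.start, pe.stop)
        C[idx, idx] += 1.0 / vc.sigma2_pe
    return C, rhs, sl


# --------------------------------------------------------------------------- #
# parameter packing
# --------------------------------------------------------------------------- #


def _k_pairs(m1: int) -> list[tuple[int, int]]:
    return [(r, s) for r in range(m1) for s in range(r, m1)]


def _pack(K, s2pe, s2e, m1: int, pe: bool) -> np.ndarray:
    parts = []
    if m1:
        parts.extend(K[r, s] for r, s in _k_pairs(m1))
    if pe:
        parts.append(s2pe)
    parts.extend(s2e)
    return np.array(parts, dtype=float)


def _unpack(theta: np.ndarray, m1: int, pe: bool, n_classes: int):
    i = 0
    K = None
    if m1:
        K = np.zeros((m1, m1))
        for r, s in _k_pairs(m1):
            K[r, s] = K[s, r] = theta[i]
            i += 1
    s2pe = None
    if pe:
        s2pe = float(theta[i])
        i += 1
    s2e = np.array(theta[i : i + n_classes], dtype=float)
    return K, s2pe, s2e


def _theta_names(m1: int, pe: bool, n_classes: int) -> list[str]:
    names = [f"K[{r},{s}]" for r, s in _k_pairs(m1)]
    if pe:
        names.append("sigma2_pe")
    if n_classes == 1:
        names.append("sigma2_e")
    else:
        names.extend(f"sigma2_e[{c}]" for c in range(n_classes))
    return names


def _bend(K: np.ndarray, floor: float, notes: list[str]) -> np.ndarray:
    """Project K back to the PSD cone by flooring its eigenvalues."""
    w, V = np.linalg.eigh(K)
    lo = max(1e-8 * max(np.sum(np.abs(w)), floor), floor)
    if np.min(w) < lo:
        notes.append(f"bent K: eigenvalues {w.tolist()} floored at {lo:.3e}")
        w = np.maximum(w, lo)
        return (V * w) @ V.T
    return K


# Internal optimization coordinates: lower Cholesky factor of K with logged
# diagonal, log sigma2_pe, log sigma2_e.  Newton steps in these coordinates
# cannot leave the PSD cone, and boundary optima (singular K) are reached
# smoothly instead of through projection.


def _chol_pack(K, s2pe, s2e, m1: int, pe: bool) -> np.ndarray:
    parts = []
    if m1:
        L = np.linalg.cholesky(K)
        for r, s in _k_pairs(m1):  # (r,s) r<=s maps to lower entry L[s,r]
            parts.append(np.log(L[r, r]) if r == s else L[s, r])
    if pe:
        parts.append(np.log(s2pe))
    parts.extend(np.log(s2e))
    return np.array(parts, dtype=float)


def _chol_unpack(vtheta: np.ndarray, m1: int, pe: bool, n_classes: int):
    i = 0
    K = None
    if m1:
        L = np.zeros((m1, m1))
        for r, s in _k_pairs(m1):
            L[s, r] = np.exp(vtheta[i]) if r == s else vtheta[i]
            i += 1
        K = L @ L.T
    s2pe = None
    if pe:
        s2pe = float(np.exp(vtheta[i]))
        i += 1
    s2e = np.exp(np.array(vtheta[i : i + n_classes], dtype=float))
    return K, s2pe, s2e


def _chol_jacobian(vtheta: np.ndarray, m1: int, pe: bool, n_classes: int) -> np.ndarray:
    """J = d theta / d vtheta (theta = packed K entries and variances)."""
    pairs = _k_pairs(m1)
    nk = len(pairs)
    ntot = nk + (1 if pe else 0) + n_classes
    J = np.zeros((ntot, ntot))
    if m1:
        L = np.zeros((m1, m1))
        for idx, (r, s) in enumerate(pairs):
            L[s, r] = np.exp(vtheta[idx]) if r == s else vtheta[idx]
        for ti, (a, b) in enumerate(pairs):  # theta entry K[a, b]
            for vi, (r, s) in enumerate(pairs):  # vtheta entry -> L[s, r]
                c, dcol = s, r
                g = 0.0
                if a == c:
                    g += L[b, dcol]
                if b == c:
                    g += L[a, dcol]
                if r == s:  # log-diagonal chain rule
                    g *= L[c, dcol]
                J[ti, vi] = g
    i = nk
    if pe:
        J[i, i] = np.exp(vtheta[i])
        i += 1
    for c in range(n_classes):
        J[i + c, i + c] = np.exp(vtheta[i + c])
    return J


# --------------------------------------------------------------------------- #
# likelihood evaluation
# --------------------------------------------------------------------------- #


class _Eval:
    """One restricted-likelihood evaluation at fixed variance parameters."""

    def __init__(self, design: Design, vc: VarianceComponents):
        self.design = design
        self.vc = vc
        d = design
        self.rinv = 1.0 / vc.sigma2_e[d.res_class]
        C, rhs, self.sl = build_mme(d, vc)
        self.C = C
        try:
            self.cho = linalg.cho_factor(C, lower=True, check_finite=False)
        except linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
            raise MMEError(f"mixed model equations not positive definite: {exc}")
        self.rhs = rhs
        self.sol = linalg.cho_solve(self.cho, rhs, check_finite=False)
        yRy = float(np.sum(np.asarray(d.yty) / vc.sigma2_e))
        self.yPy = yRy - float(self.sol @ rhs)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(self.cho[0]))))
        logdetR = float(np.sum(d.class_counts * np.log(vc.sigma2_e)))
        logdetG = 0.0
        if d.n_coef:
            sign, logdetK = np.linalg.slogdet(vc.K)
            if sign <= 0:
                raise MMEError("K left the PSD cone during evaluation")
            logdetG += d.n_coef * d.log_det_a + d.q * logdetK
        if d.pe_ids:
            logdetG += len(d.pe_ids) * np.log(vc.sigma2_pe)
        self.loglik = -0.5 * (
            (d.n - d.p) * LOG2PI + logdetR + logdetG + logdetC + self.yPy
        )
        self._cinv = None

    @property
    def cinv(self) -> np.ndarray:
        if self._cinv is None:
            # dpotri reuses the Cholesky factor: ~3x cheaper than solving
            # against the identity
            c, info = linalg.lapack.dpotri(self.cho[0], lower=True)
            if info != 0:  # pragma: no cover - guarded by cho_factor above
                raise MMEError(f"dpotri failed with info={info}")
            tri = np.tril(c)
            self._cinv = tri + np.tril(c, -1).T
        return self._cinv

    def p_dot(self, F: np.ndarray) -> np.ndarray:
        """P @ F for column block F: R^-1 (F - W C^-1 W' R^-1 F)."""
        W = self.design.W
        RF = self.rinv[:, None] * F
        sol = linalg.cho_solve(self.cho, W.T @ RF, check_finite=False)
        return self.rinv[:, None] * (F - W @ sol)

    # residuals on the data scale
    @property
    def py(self) -> np.ndarray:
        d = self.design
        return self.rinv * (d.y - d.W @ self.sol)


def _scores_and_ai(ev: _Eval, want_ai: bool = True) -> tuple[np.ndarray, np.ndarray | None]:
    d, vc = ev.design, ev.vc
    m1 = d.n_coef
    pe = bool(d.pe_ids)
    n_classes = len(vc.sigma2_e)
    py = ev.py
    sl = ev.sl
    scores: list[float] = []
    fs: list[np.ndarray] = []

    if m1:
        Kinv = np.linalg.inv(vc.K)
        u = ev.sol[sl["genetic"]]
        U = u.reshape(d.q, m1)
        M1 = d.ainv @ U
        Cuu = ev.cinv[sl["genetic"], sl["genetic"]]
        # v = Z' P y recovered from u via v = (A^-1 (x) K^-1) u
        V = M1 @ Kinv
        for r, s in _k_pairs(m1):
            E = np.zeros((m1, m1))
            E[r, s] = 1.0
            E[s, r] = 1.0
            S = Kinv @ E @ Kinv
            quad = float(np.sum(M1 * (U @ S)))
            t1 = d.q * float(np.sum(E * Kinv))
            kron_sp = sparse.kron(d.ainv, sparse.csr_matrix(S), format="csr")
            t2 = float(kron_sp.multiply(Cuu).sum())
            scores.append(0.5 * (quad - t1 + t2))
            f = d.W[:, sl["genetic"]] @ (d.a_dot(V @ E)).ravel()
            fs.append(np.asarray(f).ravel())
    if pe:
        upe = ev.sol[sl["pe"]]
        s2pe = vc.sigma2_pe
        Cpp = ev.cinv[sl["pe"], sl["pe"]]
        quad = float(upe @ upe) / s2pe**2
        tr = len(d.pe_ids) / s2pe - float(np.trace(Cpp)) / s2pe**2
        scores.append(0.5 * (quad - tr))
        fs.append(np.asarray(d.W[:, sl["pe"]] @ (d.W[:, sl["pe"]].T @ py)).ravel())
    for c in range(n_classes):
        mask = d.res_class == c
        s2 = vc.sigma2_e[c]
        quad = float(np.sum(py[mask] ** 2))
        tr = d.class_counts[c] / s2 - float(np.sum(ev.cinv * d.wtw[c])) / s2**2
        scores.append(0.5 * (quad - tr))
        fs.append(np.where(mask, py, 0.0))

    if not want_ai:
        return np.array(scores), None
    F = np.column_stack(fs)
    PF = ev.p_dot(F)
    AI = 0.5 * (F.T @ PF)
    AI = 0.5 * (AI + AI.T)
    return np.array(scores), AI


def _em_step(ev: _Eval, scores: np.ndarray) -> np.ndarray:
    """Expectation-maximization update (always uphill, slow but safe)."""
    d, vc = ev.design, ev.vc
    m1 = d.n_coef
    pe = bool(d.pe_ids)
    n_classes = len(vc.sigma2_e)
    sl = ev.sl
    K_new, s2pe_new = None, None
    if m1:
        u = ev.sol[sl["genetic"]]
        U = u.reshape(d.q, m1)
        M1 = d.ainv @ U
        Cuu = ev.cinv[sl["genetic"], sl["genetic"]]
        quad = U.T @ M1
        trm = np.zeros((m1, m1))
        for r in range(m1):
            for s in range(m1):
                Crs = Cuu[r::m1, s::m1]
                trm[r, s] = float(d.ainv.multiply(Crs.T).sum())
        K_new = (quad + trm) / d.q
        K_new = 0.5 * (K_new + K_new.T)
    if pe:
        upe = ev.sol[sl["pe"]]
        Cpp = ev.cinv[sl["pe"], sl["pe"]]
        s2pe_new = float(upe @ upe + np.trace(Cpp)) / len(d.pe_ids)
    # residual classes: one-step EM written as a scaled gradient move
    k_len = len(_k_pairs(m1)) if m1 else 0
    i0 = k_len + (1 if pe else 0)
    s2e_new = vc.sigma2_e + 2.0 * vc.sigma2_e**2 * scores[i0:] / np.maximum(
        d.class_counts, 1
    )
    return _pack(K_new, s2pe_new, s2e_new, m1, pe)


# --------------------------------------------------------------------------- #
# fit result
# --------------------------------------------------------------------------- #


@dataclass
class FitResult:
    model: ModelSpec
    basis: LegendreBasis
    beta: pd.Series
    beta_cov: np.ndarray
    u: pd.DataFrame
    u_pev: np.ndarray  # (q, m1, m1) prediction-error covariance blocks
    u_pe: pd.Series | None
    vc: VarianceComponents
    theta: np.ndarray
    theta_names: list[str]
    theta_cov: np.ndarray
    loglik: float
    aic: float
    n_records: int
    n_fixed: int
    converged: bool
    n_iter: int
    loglik_trace: list[float]
    fixed_signature: tuple
    notes: list[str] = field(default_factory=list)

    @property
    def n_var_params(self) -> int:
        return len(self.theta)

    def coef_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.beta_cov)), index=self.beta.index)


def fit_reml(
    data: pd.DataFrame,
    pedigree: Pedigree | None = None,
    model: ModelSpec = ModelSpec(),
    basis: LegendreBasis | None = None,
    options: RemlOptions = RemlOptions(),
) -> FitResult:
    """Fit the random regression model by AI-REML.

    Returns BLUE fixed effects, BLUP random regression coefficients for every
    animal in the pedigree, REML variance components, the restricted
    log-likelihood, AIC (variance parameters only) and the asymptotic
    covariance of the variance parameters from the final average-information
    matrix.
    """
    design = build_design(data, model, pedigree=pedigree, basis=basis)
    d = design
    m1 = d.n_coef
    pe = bool(d.pe_ids)
    n_classes = len(d.class_counts)
    if np.any(d.class_counts == 0):
        raise MMEError("a residual age class contains no records")
    vary = float(np.var(d.y))
    if vary <= 0:
        vary = 1.0
    # boundary floors: K eigenvalues are kept a little away from zero so that
    # K^-1 stays representable; residual/PE variances may go lower
    floor = 1e-6 * vary
    floor_v = 1e-8 * vary
    notes: list[str] = list(f"dropped:{c}" for c in d.dropped_columns)

    # starting values: half the phenotypic variance to the residual, the rest
    # spread over the diagonal of K
    start = options.start or {}
    K = start.get("K")
    if m1:
        K = (
            np.array(K, dtype=float)
            if K is not None
            else np.eye(m1) * (0.5 * vary / m1)
        )
        if K.shape != (m1, m1):
            raise MMEError(f"starting K has shape {K.shape}, expected {(m1, m1)}")
        K = _bend(K, floor, notes)
    else:
        K = None
    s2pe = float(start.get("sigma2_pe", 0.1 * vary)) if pe else None
    s2e_start = start.get("sigma2_e")
    if s2e_start is None:
        s2e = np.full(n_classes, 0.5 * vary)
    else:
        s2e = np.broadcast_to(np.atleast_1d(s2e_start), (n_classes,)).astype(float)
    theta = _pack(K, s2pe, s2e, m1, pe)

    def make_vc(th: np.ndarray) -> VarianceComponents:
        Kv, s2pev, s2ev = _unpack(th, m1, pe, n_classes)
        return VarianceComponents(
            K=Kv, sigma2_pe=s2pev, sigma2_e=s2ev, class_bounds=d.class_bounds
        )

    # optimization runs in log-Cholesky coordinates (PSD cone is built in)
    vtheta = _chol_pack(*_unpack(theta, m1, pe, n_classes), m1, pe)
    lb = np.full(len(theta), -np.inf)
    i = 0
    for r, s in _k_pairs(m1):
        if r == s:
            lb[i] = 0.5 * np.log(floor)
        i += 1
    lb[i:] = np.log(floor_v)

    ev = _Eval(d, make_vc(theta))
    trace = [ev.loglik]
    converged = False
    n_iter = 0
    AI = np.eye(len(theta))
    if options.fix_theta:
        converged = True

    def ai_phase(theta, vtheta, ev, iters):
        """Average-information Newton steps (with EM fallback) in the
        log-Cholesky coordinates.  Returns the updated state and whether the
        spec convergence criteria were met."""
        nonlocal n_iter, AI
        done = False
        for _ in range(iters):
            n_iter += 1
            scores, AI = _scores_and_ai(ev)
            J = _chol_jacobian(vtheta, m1, pe, n_classes)
            g = J.T @ scores
            H = J.T @ AI @ J
            # active set: coordinates pinned at the boundary with an outward
            # gradient are frozen so they don't pollute the free directions
            pinned = (vtheta <= lb + 1e-9) & (g < 0)
            if np.any(pinned):
                g = np.where(pinned, 0.0, g)
                H = H.copy()
                H[pinned, :] = 0.0
                H[:, pinned] = 0.0
                H[pinned, pinned] = 1.0
            try:
                delta = np.linalg.solve(H + 1e-10 * np.eye(len(g)), g)
            except np.linalg.LinAlgError:
                delta = np.linalg.pinv(H) @ g
            if g @ delta <= 0:  # AI not positive along the step: use gradient
                delta = g
            big = np.max(np.abs(delta))
            if big > 3.0:  # trust region in log-Cholesky coordinates
                delta = delta * (3.0 / big)
            pred_gain = 0.5 * float(g @ delta)
            if pred_gain < 0.1 * options.tol_loglik:
                done = True
                break
            accepted = False
            step = 1.0
            for _ in range(options.max_halvings):
                vcand = np.maximum(vtheta + step * delta, lb)
                cand = _pack(*_chol_unpack(vcand, m1, pe, n_classes), m1, pe)
                try:
                    ev_cand = _Eval(d, make_vc(cand))
                except (MMEError, np.linalg.LinAlgError):
                    step *= 0.5
                    continue
                if ev_cand.loglik >= ev.loglik - 1e-12:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                # EM fallback (monotone), mapped back to the cone coordinates
                Kv, s2pev, s2ev = _unpack(_em_step(ev, scores), m1, pe, n_classes)
                if m1:
                    Kv = _bend(Kv, floor, notes)
                if pe:
                    s2pev = max(s2pev, floor_v)
                s2ev = np.maximum(s2ev, floor_v)
                vcand = np.maximum(_chol_pack(Kv, s2pev, s2ev, m1, pe), lb)
                cand = _pack(*_chol_unpack(vcand, m1, pe, n_classes), m1, pe)
                try:
                    ev_cand = _Eval(d, make_vc(cand))
                    accepted = ev_cand.loglik >= ev.loglik - 1e-10
                except (MMEError, np.linalg.LinAlgError):
                    accepted = False
                if not accepted:
                    # cannot move uphill in any direction: stationary
                    done = True
                    break
            rel = np.max(
                np.abs(cand - theta) / np.maximum(np.abs(theta), 1e-3 * vary)
            )
            dll = ev_cand.loglik - ev.loglik
            theta, vtheta, ev = cand, vcand, ev_cand
            trace.append(ev.loglik)
            if abs(dll) < options.tol_loglik and rel < options.tol_param:
                done = True
                break
            # stalled on a boundary ridge: hand to the quasi-Newton phase
            if len(trace) >= 9 and trace[-1] - trace[-9] < 0.01:
                break
        return theta, vtheta, ev, done

    def polish(vtheta, ev):
        """Quasi-Newton ascent on the exact restricted-likelihood gradient;
        picks up where the AI quadratic model degrades (flat ridges along the
        PSD boundary, nearly singular K)."""
        nonlocal n_iter
        from scipy import optimize as _opt

        def fun(v):
            cand = _pack(*_chol_unpack(v, m1, pe, n_classes), m1, pe)
            try:
                evx = _Eval(d, make_vc(cand))
                s, _ = _scores_and_ai(evx, want_ai=False)
            except (MMEError, np.linalg.LinAlgError):
                return 1e10, np.zeros_like(v)
            Jx = _chol_jacobian(v, m1, pe, n_classes)
            return -evx.loglik, -(Jx.T @ s)

        res = _opt.minimize(
            fun,
            vtheta,
            jac=True,
            method="L-BFGS-B",
            bounds=[(l, None) for l in lb],
            options=dict(maxfun=400, ftol=1e-14, gtol=1e-7),
        )
        n_iter += int(res.nit)
        if -res.fun >= ev.loglik - 1e-9:
            vtheta = np.maximum(res.x, lb)
            theta = _pack(*_chol_unpack(vtheta, m1, pe, n_classes), m1, pe)
            ev = _Eval(d, make_vc(theta))
            trace.append(ev.loglik)
            notes.append(f"quasi-Newton polish ({res.nit} iterations)")
            return theta, vtheta, ev
        return None, vtheta, ev

    def stationary(vtheta, ev):
        scores, _ = _scores_and_ai(ev, want_ai=False)
        g = _chol_jacobian(vtheta, m1, pe, n_classes).T @ scores
        at_lb = vtheta <= lb + 1e-9
        proj = np.where(at_lb & (g < 0), 0.0, g)
        return float(np.max(np.abs(proj), initial=0.0))

    if not options.fix_theta:
        for round_ in range(6):
            # later rounds only need a few AI steps to refresh curvature
            theta, vtheta, ev, converged = ai_phase(
                theta, vtheta, ev, min(options.max_iter, 60 if round_ == 0 else 8)
            )
            if converged:
                break
            theta_p, vtheta, ev = polish(vtheta, ev)
            if theta_p is not None:
                theta = theta_p
            grad = stationary(vtheta, ev)
            if grad < 1e-5 * max(1.0, abs(ev.loglik)):
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                "REML did not reach a stationary point "
                f"(projected gradient {stationary(vtheta, ev):.3g})",
                [float(t) for t in trace[-20:]],
            )

    # final quantities
    vc = make_vc(theta)
    scores, AI = (np.zeros(len(theta)), AI) if options.fix_theta else _scores_and_ai(ev)
    try:
        theta_cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        theta_cov = np.linalg.pinv(AI)
    sl = ev.sl
    cinv = ev.cinv
    beta = pd.Series(ev.sol[sl["fixed"]], index=d.x_names, name="estimate")
    beta_cov = cinv[sl["fixed"], sl["fixed"]]
    if m1:
        U = ev.sol[sl["genetic"]].reshape(d.q, m1)
        u = pd.DataFrame(
            U, index=pd.Index(d.animal_ids, name="animal_id"),
            columns=[f"u_{k}" for k in range(m1)],
        )
        Cuu = cinv[sl["genetic"], sl["genetic"]]
        u_pev = np.empty((d.q, m1, m1))
        for j in range(d.q):
            u_pev[j] = Cuu[j * m1 : (j + 1) * m1, j * m1 : (j + 1) * m1]
    else:
        u = pd.DataFrame(columns=["u_0"])
        u_pev = np.zeros((0, 1, 1))
    u_pe = (
        pd.Series(ev.sol[sl["pe"]], index=pd.Index(d.pe_ids, name="animal_id"))
        if pe
        else None
    )
    aic = -2.0 * ev.loglik + 2.0 * len(theta)
    return FitResult(
        model=model,
        basis=d.basis,
        beta=beta,
        beta_cov=beta_cov,
        u=u,
        u_pev=u_pev,
        u_pe=u_pe,
        vc=vc,
        theta=theta,
        theta_names=_theta_names(m1, pe, n_classes),
        theta_cov=theta_cov,
        loglik=float(ev.loglik),
        aic=float(aic),
        n_records=d.n,
        n_fixed=d.p,
        converged=converged,
        n_iter=n_iter,
        loglik_trace=trace,
        fixed_signature=(model.response, tuple(d.x_names)),
        notes=notes,
    )


def ml_loglik(
    data: pd.DataFrame,
    fit: FitResult,
    pedigree: Pedigree | None = None,
) -> float:
    """Full (unrestricted) ML log-likelihood evaluated at a fit's parameters.

    Provided for model comparisons that change the fixed structure, where
    restricted likelihoods are not comparable.
    """
    d = build_design(data, fit.model, pedigree=pedigree, basis=fit.basis)
    vc = fit.vc
    rinv = 1.0 / vc.sigma2_e[d.res_class]
    r = d.y - d.X @ fit.beta.to_numpy()
    logdetR = float(np.sum(d.class_counts * np.log(vc.sigma2_e)))
    if d.n_coef or d.pe_ids:
        C, _, sl = build_mme(d, vc)
        start = sl["genetic"].start
        Crand = C[start:, start:]
        cho = linalg.cho_factor(Crand, lower=True, check_finite=False)
        Wr = d.W[:, start:]
        rhs = Wr.T @ (rinv * r)
        sol = linalg.cho_solve(cho, rhs, check_finite=False)
        quad = float(r @ (rinv * r) - sol @ rhs)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        logdetG = 0.0
        if d.n_coef:
            _, logdetK = np.linalg.slogdet(vc.K)
            logdetG += d.n_coef * d.log_det_a + d.q * logdetK
        if d.pe_ids:
            logdetG += len(d.pe_ids) * np.log(vc.sigma2_pe)
        logdetV = logdetR + logdetG + logdetC
    else:
        quad = float(r @ (rinv * r))
        logdetV = logdetR
    return -0.5 * (d.n * LOG2PI + logdetV + quad)


# --------------------------------------------------------------------------- #
# model selection
# --------------------------------------------------------------------------- #


def _candidate_columns(fit: FitResult, name: str) -> list[int]:
    idx = [
        i
        for i, nm in enumerate(fit.beta.index)
        if nm == name or nm.startswith(f"{name}=")
    ]
    return idx


def backward_eliminate(
    data: pd.DataFrame,
    pedigree: Pedigree | None,
    model: ModelSpec,
    alpha: float = 0.05,
    options: RemlOptions = RemlOptions(),
) -> tuple[ModelSpec, list[dict]]:
    """Backward elimination of candidate fixed effects by conditional Wald tests.

    ``model.extra_effects`` are the candidates; mandatory factors are never
    removed.  Candidates fully aliased with the mandatory design are flagged
    and removed first.  Each round refits the model and removes the least
    significant remaining candidate with p >= alpha.
    """
    trace: list[dict] = []
    current = model
    # aliasing pre-screen: candidate columns inside the span of the mandatory design
    base = replace(model, extra_effects=())
    b_design = build_design(data, base, pedigree=pedigree)
    Xm = b_design.X
    keep: list[str] = []
    for cand in model.extra_effects:
        col = data[cand]
        if pd.api.types.is_numeric_dtype(col):
            M = col.to_numpy(dtype=float)[:, None]
        else:
            levels = pd.unique(col.astype(str))
            M = np.column_stack(
                [(col.astype(str) == lev).to_numpy(dtype=float) for lev in levels[1:]]
            )
        resid = M - Xm @ np.linalg.lstsq(Xm, M, rcond=None)[0]
        if np.max(np.abs(resid)) < 1e-8 * max(1.0, np.max(np.abs(M))):
            trace.append({"effect": cand, "p_value": np.nan, "action": "aliased"})
        else:
            keep.append(cand)
    current = replace(model, extra_effects=tuple(keep))

    while current.extra_effects:
        fit = fit_reml(data, pedigree, current, options=options)
        worst, worst_p = None, -1.0
        for cand in current.extra_effects:
            cols = _candidate_columns(fit, cand)
            if not cols:
                worst, worst_p = cand, np.inf
                continue
            b = fit.beta.to_numpy()[cols]
            V = fit.beta_cov[np.ix_(cols, cols)]
            stat = float(b @ np.linalg.solve(V, b))
            df_c = len(cols)
            p = float(
                stats.f.sf(stat / df_c, df_c, fit.n_records - fit.n_fixed)
            )
            if p > worst_p:
                worst, worst_p = cand, p
        if worst_p >= alpha:
            trace.append(
                {"effect": worst, "p_value": worst_p, "action": "removed"}
            )
            current = replace(
                current,
                extra_effects=tuple(e for e in current.extra_effects if e != worst),
            )
        else:
            for cand in current.extra_effects:
                trace.append(
                    {"effect": cand, "p_value": worst_p, "action": "retained"}
                )
            break
    return current, trace


def compare_models(
    fits: list[FitResult], labels: list[str] | None = None
) -> tuple[pd.DataFrame, int]:
    """Rank REML fits by AIC; prefer the simplest model within 2 units.

    All fits must share data and fixed structure — REML likelihoods are not
    comparable otherwise.
    """
    if not fits:
        raise ValueError("no fits to compare")
    sig = fits[0].fixed_signature
    n = fits[0].n_records
    for f in fits[1:]:
        if f.fixed_signature != sig or f.n_records != n:
            raise ValueError(
                "REML AICs are only comparable across models sharing the same "
                "data and fixed-effect structure; use ml_loglik for the rest"
            )
    labels = labels or [f"model_{i}" for i in range(len(fits))]
    table = pd.DataFrame(
        {
            "model": labels,
            "loglik": [f.loglik for f in fits],
            "n_var_params": [f.n_var_params for f in fits],
            "aic": [f.aic for f in fits],
        }
    )
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table = table.sort_values("aic", kind="stable").reset_index(drop=True)
    within = table[table["delta_aic"] <= 2.0]
    pref_label = within.sort_values(
        ["n_var_params", "aic"], kind="stable"
    ).iloc[0]["model"]
    preferred = labels.index(pref_label)
    return table, preferred


def test_residual_heterogeneity(
    data: pd.DataFrame,
    pedigree: Pedigree | None,
    model: ModelSpec,
    age_classes: tuple[float, ...],
    min_records: int = 10,
    options: RemlOptions = RemlOptions(),
) -> dict:
    """Homogeneous vs age-class-specific residual variance.

    ``age_classes`` are interior breakpoints; classes with fewer than
    ``min_records`` records are merged with their neighbor (warned).  Reports
    the AIC difference and a likelihood-ratio statistic with df = #classes - 1.
    """
    ages = data[model.age_col].to_numpy(dtype=float)
    bounds = list(age_classes)
    while bounds:
        cls = np.searchsorted(np.asarray(bounds), ages, side="left")
        counts = np.bincount(cls, minlength=len(bounds) + 1)
        small = np.nonzero(counts < min_records)[0]
        if small.size == 0:
            break
        c = int(small[0])
        merged = bounds.pop(min(c, len(bounds) - 1))
        logger.warning(
            "residual age class %d has %d < %d records; merged at breakpoint %s",
            c,
            counts[c],
            min_records,
            merged,
        )
    hom = fit_reml(data, pedigree, replace(model, residual_classes=None), options=options)
    if not bounds:
        return {
            "homogeneous": hom,
            "heterogeneous": hom,
            "classes": (),
            "lrt": 0.0,
            "df": 0,
            "p_value": 1.0,
            "delta_aic": 0.0,
            "preferred": "homogeneous",
        }
    het = fit_reml(
        data,
        pedigree,
        replace(model, residual_classes=tuple(bounds)),
        options=options,
    )
    lrt = max(0.0, 2.0 * (het.loglik - hom.loglik))
    df = len(bounds)
    p = float(stats.chi2.sf(lrt, df))
    delta_aic = hom.aic - het.aic  # positive favors heterogeneous
    preferred = "heterogeneous" if het.aic < hom.aic - 2.0 else "homogeneous"
    return {
        "homogeneous": hom,
        "heterogeneous": het,
        "classes": tuple(bounds),
        "lrt": lrt,
        "df": df,
        "p_value": p,
        "delta_aic": delta_aic,
        "preferred": preferred,
    }
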