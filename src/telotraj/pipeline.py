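"""Pipeline orchestration: chainable stages over on-disk artifacts.

Each stage reads/writes tidy CSVs (plus small JSON manifests) in an output
directory, so the CLI subcommands can be run independently or chained by
``run_all``.  Reruns with the same config and seed are byte-identical: no
timestamps are written and every random draw derives from ``RunConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import LegendreBasis
from .clustering import cluster_profiles
from .io import (
    RunConfig,
    read_pedigree,
    read_phenotypes,
    read_plates,
    read_survival,
    write_manifest,
    write_pedigree,
)
from .params import (
    additive_variance,
    animal_profiles,
    eigen_analysis,
    fixed_curve,
    genetic_correlation,
    heritability,
    trajectories_frame,
)
from .qpcr import log_transform, rltl_from_plates
from .reml import FitResult, ModelSpec, RemlOptions, VarianceComponents, fit_reml
from .simulate import simulate_study
from .survival import fit_cox, wald_test

logger = logging.getLogger(__name__)

__all__ = [
    "stage_simulate",
    "stage_rltl",
    "stage_fit",
    "stage_params",
    "stage_cluster",
    "stage_survival",
    "run_all",
    "save_fit",
    "load_fit",
]


def stage_simulate(config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(
        n_females=config.n_females,
        seed=config.seed,
        n_sires=config.n_sires,
        n_dams=config.n_dams,
        cq_noise_sd=config.cq_noise_sd,
        censoring_rate=config.censoring_rate,
    )
    study["phenotypes"].to_csv(out / "phenotypes.csv", index=False)
    write_pedigree(study["pedigree"], out / "pedigree.txt")
    study["plates"].to_csv(out / "plates.csv", index=False)
    study["survival"].to_csv(out / "survival.csv", index=False)
    study["truth"].to_json(out / "truth.json")


def stage_rltl(config: RunConfig, out: Path) -> None:
    plates = read_plates(out / "plates.csv")
    rltl, report = rltl_from_plates(plates)
    rltl = rltl[~rltl["is_calibrator"]].reset_index(drop=True)
    logged, norm = log_transform(rltl.set_index("sample_id")["rltl"])
    rltl["log_rltl"] = logged
    meta = pd.read_csv(out / "phenotypes.csv").drop(columns=["log_rltl"])
    merged = meta.merge(
        rltl[["sample_id", "log_rltl", "rltl"]], on="sample_id", how="inner"
    )
    merged.to_csv(out / "rltl_phenotypes.csv", index=False)
    report.to_csv(out / "qc_report.csv", index=False)
    with open(out / "normality.json", "w") as fh:
        json.dump(
            {
                "shapiro_w": norm.statistic,
                "p_value": norm.p_value,
                "n": norm.n,
                "degenerate": norm.degenerate,
            },
            fh,
            indent=1,
        )


def _model_from_config(config: RunConfig) -> ModelSpec:
    return ModelSpec(
        order_fixed=config.polynomial_order_fixed,
        order_random=config.polynomial_order_random,
        residual_classes=config.residual_classes,
        bounds=config.age_bounds,
    )


def stage_fit(config: RunConfig, out: Path) -> FitResult:
    src = out / "rltl_phenotypes.csv"
    if not src.exists():
        src = out / "phenotypes.csv"
    data = read_phenotypes(src)
    ped = read_pedigree(out / "pedigree.txt")
    model = _model_from_config(config)
    options = RemlOptions(
        max_iter=config.max_iter,
        tol_loglik=config.tol_loglik,
        tol_param=config.tol_param,
    )
    fit = fit_reml(data, ped, model, options=options)
    save_fit(fit, out)
    return fit


def stage_params(config: RunConfig, out: Path, fit: FitResult | None = None) -> None:
    fit = fit or load_fit(out)
    # integer months inside the basis bounds; display cut-off at 60 months
    grid = np.arange(
        np.ceil(fit.basis.t_min), np.floor(min(fit.basis.t_max, 60.0)) + 0.5
    )
    trajs = [
        fixed_curve(fit, grid),
        heritability(fit, grid),
        genetic_correlation(fit, reference_age=fit.basis.t_min, grid=grid),
    ]
    va = additive_variance(fit.vc.K, fit.basis, grid)
    trajectories_frame(trajs + [va]).to_csv(out / "trajectories.csv", index=False)
    # per-animal profiles (phenotyped animals only)
    pheno = pd.read_csv(out / "phenotypes.csv")
    animals = sorted(pheno["animal_id"].astype(str).unique())
    profiles = animal_profiles(fit, grid, animals=animals)
    trajectories_frame(profiles).to_csv(out / "profiles.csv", index=False)
    eig = eigen_analysis(fit.vc.K, fit.basis, grid)
    with open(out / "eigen.json", "w") as fh:
        json.dump(
            {
                "eigenvalues": eig.eigenvalues.tolist(),
                "percent": eig.percent.tolist(),
            },
            fh,
            indent=1,
        )


def stage_cluster(config: RunConfig, out: Path) -> None:
    prof = pd.read_csv(out / "profiles.csv")
    ids = list(pd.unique(prof["animal_id"].astype(str)))
    wide = prof.pivot(index="animal_id", columns="age_month", values="value").loc[ids]
    ages = np.array(sorted(wide.columns.astype(float)))
    P = wide.to_numpy(dtype=float)
    res = cluster_profiles(
        P, k=config.n_clusters, seed=config.seed, ages=ages, animal_ids=ids
    )
    pd.DataFrame({"animal_id": ids, "cluster": res.labels}).to_csv(
        out / "clusters.csv", index=False
    )
    curves = pd.DataFrame(
        {
            "cluster": np.repeat(np.arange(config.n_clusters), len(ages)),
            "age_month": np.tile(ages, config.n_clusters),
            "value": res.centers.ravel(),
        }
    )
    curves.to_csv(out / "cluster_curves.csv", index=False)
    with open(out / "cluster_summary.json", "w") as fh:
        json.dump(
            {
                "proportions": res.proportions.tolist(),
                "within_distance": res.within_distance,
                "seed": res.seed,
            },
            fh,
            indent=1,
        )


def stage_survival(config: RunConfig, out: Path) -> None:
    surv = read_survival(out / "survival.csv")
    clusters = pd.read_csv(out / "clusters.csv", dtype={"animal_id": str})
    merged = surv.drop(columns=["cluster"], errors="ignore").merge(
        clusters.assign(cluster=lambda d: d["cluster"].astype(str)),
        on="animal_id",
        how="inner",
    )
    fit = fit_cox(merged)
    stat, df, p = wald_test(fit)
    with open(out / "cox.json", "w") as fh:
        json.dump(
            {
                "coef": fit.coef.to_dict(),
                "se": np.sqrt(np.diag(fit.cov)).tolist(),
                "reference_cluster": fit.reference,
                "wald_chi2": stat,
                "df": df,
                "p_value": p,
                "n_events": fit.n_events,
                "n_censored": fit.n_censored,
                "warnings": fit.warnings,
            },
            fh,
            indent=1,
        )


def run_all(config: RunConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_simulate(config, out)
    stage_rltl(config, out)
    fit = stage_fit(config, out)
    stage_params(config, out, fit)
    stage_cluster(config, out)
    stage_survival(config, out)
    write_manifest(out / "manifest.json", config)


# --------------------------------------------------------------------------- #
# fit persistence (text artifacts so stages can be chained across processes)
# --------------------------------------------------------------------------- #


def save_fit(fit: FitResult, out: Path) -> None:
    m1 = fit.u.shape[1]
    sol = fit.u.copy()
    sol.insert(0, "animal_id", fit.u.index)
    for r in range(m1):
        for s in range(m1):
            sol[f"pev_{r}{s}"] = fit.u_pev[:, r, s]
    sol.to_csv(out / "solutions.csv", index=False)
    blob = {
        "model": dataclasses.asdict(fit.model),
        "basis": {
            "order": fit.basis.order,
            "t_min": fit.basis.t_min,
            "t_max": fit.basis.t_max,
            "normalized": fit.basis.normalized,
        },
        "beta": {"names": list(fit.beta.index), "values": fit.beta.to_list()},
        "beta_cov": fit.beta_cov.tolist(),
        "vc": {
            "K": fit.vc.K.tolist() if fit.vc.K is not None else None,
            "sigma2_pe": fit.vc.sigma2_pe,
            "sigma2_e": fit.vc.sigma2_e.tolist(),
            "class_bounds": fit.vc.class_bounds,
        },
        "theta": fit.theta.tolist(),
        "theta_names": fit.theta_names,
        "theta_cov": fit.theta_cov.tolist(),
        "loglik": fit.loglik,
        "aic": fit.aic,
        "n_records": fit.n_records,
        "n_fixed": fit.n_fixed,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "loglik_trace": fit.loglik_trace,
        "notes": fit.notes,
    }
    with open(out / "fit.json", "w") as fh:
        json.dump(blob, fh, indent=1, default=float)
        fh.write("\n")


def load_fit(out: Path) -> FitResult:
    with open(Path(out) / "fit.json") as fh:
        blob = json.load(fh)
    model = ModelSpec(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in blob["model"].items()
        }
    )
    basis = LegendreBasis(**blob["basis"])
    sol = pd.read_csv(Path(out) / "solutions.csv", dtype={"animal_id": str})
    m1 = len([c for c in sol.columns if c.startswith("u_")])
    u = sol.set_index("animal_id")[[f"u_{k}" for k in range(m1)]]
    q = len(u)
    pev = np.empty((q, m1, m1))
    for r in range(m1):
        for s in range(m1):
            pev[:, r, s] = sol[f"pev_{r}{s}"].to_numpy()
    vcb = blob["vc"]
    vc = VarianceComponents(
        K=np.array(vcb["K"]) if vcb["K"] is not None else None,
        sigma2_pe=vcb["sigma2_pe"],
        sigma2_e=np.array(vcb["sigma2_e"]),
        class_bounds=tuple(vcb["class_bounds"]) if vcb["class_bounds"] else None,
    )
    return FitResult(
        model=model,
        basis=basis,
        beta=pd.Series(blob["beta"]["values"], index=blob["beta"]["names"]),
        beta_cov=np.array(blob["beta_cov"]),
        u=u,
        u_pev=pev,
        u_pe=None,
        vc=vc,
        theta=np.array(blob["theta"]),
        theta_names=blob["theta_names"],
        theta_cov=np.array(blob["theta_cov"]),
        loglik=blob["loglik"],
        aic=blob["aic"],
        n_records=blob["n_records"],
        n_fixed=blob["n_fixed"],
        converged=blob["converged"],
        n_iter=blob["n_iter"],
        loglik_trace=blob["loglik_trace"],
        fixed_signature=("log_rltl", tuple(blob["beta"]["names"])),
        notes=blob["notes"],
    )
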