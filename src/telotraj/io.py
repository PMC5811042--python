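"""File readers/writers and run configuration.

All tables are headered CSVs with opaque string ids; the pedigree is the
standard 3-column animal/sire/dam file (whitespace- or comma-separated,
0 = unknown parent, unknown parents treated as founders).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_config",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
    "read_plates",
    "read_survival",
    "write_manifest",
]

PHENOTYPE_COLUMNS = [
    "animal_id",
    "age_months",
    "birth_year",
    "genetic_group",
    "plate",
    "row",
]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; all stochastic stages derive from ``seed``."""

    polynomial_order_fixed: int = 2
    polynomial_order_random: int = 2
    age_bounds: tuple[float, float] | None = None  # None = from data
    residual_classes: tuple[float, ...] | None = None  # interior breakpoints
    n_clusters: int = 5
    seed: int = 0
    tol_loglik: float = 1e-8
    tol_param: float = 1e-6
    max_iter: int = 100
    # synthetic-study knobs
    n_females: int = 300
    n_sires: int = 40
    n_dams: int = 120
    cq_noise_sd: float = 0.02
    censoring_rate: float = 0.2

    def __post_init__(self) -> None:
        for o in (self.polynomial_order_fixed, self.polynomial_order_random):
            if not (0 <= o <= 5):
                raise ValueError("polynomial orders must be between 0 and 5")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.residual_classes is not None:
            b = list(self.residual_classes)
            if sorted(b) != b or len(set(b)) != len(b):
                raise ValueError(
                    "residual class breakpoints must be strictly increasing "
                    "(intervals must partition the age range without overlap)"
                )
            if self.age_bounds is not None:
                lo, hi = self.age_bounds
                if b and (b[0] <= lo or b[-1] >= hi):
                    raise ValueError(
                        "residual class breakpoints must lie inside the age bounds"
                    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path) -> RunConfig:
    """Read a RunConfig from TOML or YAML."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    for key in ("age_bounds", "residual_classes"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def read_phenotypes(path, response: str = "log_rltl") -> pd.DataFrame:
    """Read the phenotype table; drop and count rows with missing mandatory
    fields.  The dropped count is logged and stored in ``df.attrs``.

    Either ``log_rltl`` or ``raw_rltl`` must be present; a missing header
    column is a hard error naming the column, a non-numeric age is a
    row-level problem collected into the report.
    """
    df = pd.read_csv(path, dtype=str)
    resp = response
    if resp not in df.columns and "raw_rltl" in df.columns:
        resp = "raw_rltl"
    required = PHENOTYPE_COLUMNS + [resp]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"phenotype file missing required column {col!r}")
    problems: list[dict] = []
    for col in ("age_months", resp):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        for i in df.index[bad]:
            problems.append({"line": int(i) + 2, "column": col, "value": df.loc[i, col]})
        df[col] = num
    mask = df[required].notna().all(axis=1) & df["age_months"].notna()
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.warning("dropped %d phenotype rows with missing/invalid fields", n_dropped)
    if mask.sum() == 0:
        logger.warning("phenotype file %s contains no usable records", path)
    out = df.loc[mask].reset_index(drop=True)
    out["age_months"] = out["age_months"].astype(float)
    out[resp] = out[resp].astype(float)
    out.attrs["n_dropped"] = n_dropped
    out.attrs["problems"] = problems
    return out


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    """3-column animal/sire/dam file; whitespace- or comma-separated."""
    triples = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if ln == 1 and parts[:1] == ["animal_id"]:
                continue  # optional header
            if len(parts) != 3:
                raise ValueError(
                    f"pedigree line {ln}: expected 3 fields, got {len(parts)}"
                )
            triples.append(tuple(parts))
    return Pedigree.from_triples(triples)


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal_id sire dam\n")
        for a, s, d in ped.triples():
            fh.write(f"{a} {s} {d}\n")


def read_plates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["is_calibrator"] = df["is_calibrator"].astype(bool)
    return df


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["event"] = df["event"].astype(bool)
    df["time"] = df["time"].astype(float)
    return df


def write_manifest(path, config: RunConfig, extra: dict | None = None) -> None:
    """JSON run manifest: config, seed and software version (no timestamps, so
    reruns are byte-identical)."""
    manifest = {
        "telotraj_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
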