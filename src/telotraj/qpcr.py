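"""qPCR quantification-cycle records to relative telomere length (RLTL).

RLTL is the efficiency-corrected ratio of telomeric to single-copy-gene (B2M)
amplification, normalized to a calibrator ("golden") sample repeated on every
plate:

    RLTL = E_TEL ** (Cq_TEL(cal) - Cq_TEL(s)) / E_B2M ** (Cq_B2M(cal) - Cq_B2M(s))

Reaction efficiencies E (fold amplification per cycle, in (1, 2]) are taken as
inputs, as produced upstream by baseline-correction software.  DNA-extract QC
(yield, purity ratios, gel integrity) is applied before quantification; RLTL is
log-transformed (natural log) for analysis and checked for normality with the
Shapiro-Wilk test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PlateRecord",
    "QcMetrics",
    "QcResult",
    "compute_rltl",
    "apply_qc",
    "log_transform",
    "rltl_from_plates",
]


@dataclass(frozen=True)
class PlateRecord:
    sample_id: str
    animal_id: str
    plate_id: str
    row_id: str
    cq_tel: float
    cq_b2m: float
    e_tel: float
    e_b2m: float
    is_calibrator: bool = False

    def __post_init__(self) -> None:
        for name, e in (("e_tel", self.e_tel), ("e_b2m", self.e_b2m)):
            if not (1.0 < e <= 2.0):
                raise ValueError(
                    f"{name}={e} outside the admissible efficiency range (1, 2]"
                )


@dataclass(frozen=True)
class QcMetrics:
    yield_ng_per_ul: float
    ratio_260_280: float
    ratio_260_230: float
    gel_integrity: float

    def __post_init__(self) -> None:
        vals = (
            self.yield_ng_per_ul,
            self.ratio_260_280,
            self.ratio_260_230,
            self.gel_integrity,
        )
        if not all(math.isfinite(v) and v >= 0 for v in vals):
            raise ValueError(f"QC metrics must be finite and >= 0, got {vals}")


@dataclass(frozen=True)
class QcResult:
    passed: bool
    reasons: tuple[str, ...]


def compute_rltl(sample: PlateRecord, calibrator: PlateRecord) -> float:
    """Efficiency-corrected calibrator-normalized telomere/B2M ratio."""
    if sample.plate_id != calibrator.plate_id:
        raise ValueError(
            f"sample {sample.sample_id!r} (plate {sample.plate_id!r}) and "
            f"calibrator (plate {calibrator.plate_id!r}) must share a plate: "
            "the calibrator corrects plate-level effects"
        )
    num = sample.e_tel ** (calibrator.cq_tel - sample.cq_tel)
    den = sample.e_b2m ** (calibrator.cq_b2m - sample.cq_b2m)
    return num / den


# QC thresholds: strict inequalities as specified for yield/purity, inclusive
# for the gel integrity score band.
QC_RULES = {
    "yield": lambda m: m.yield_ng_per_ul > 20.0,
    "ratio_260_280": lambda m: m.ratio_260_280 > 1.7,
    "ratio_260_230": lambda m: m.ratio_260_230 > 1.8,
    "gel_integrity": lambda m: 1.0 <= m.gel_integrity <= 2.0,
}


def apply_qc(metrics: QcMetrics) -> QcResult:
    """DNA-extract quality control; never raises, reports every violated rule."""
    reasons = tuple(name for name, ok in QC_RULES.items() if not ok(metrics))
    return QcResult(passed=not reasons, reasons=reasons)


@dataclass(frozen=True)
class NormalityReport:
    statistic: float
    p_value: float
    n: int
    degenerate: bool = False


def log_transform(
    rltl: pd.Series | np.ndarray,
) -> tuple[np.ndarray, NormalityReport]:
    """Natural-log transform with a Shapiro-Wilk normality check.

    Raises on non-positive values, naming the offending sample when the input
    is an indexed Series.
    """
    values = np.asarray(rltl, dtype=float)
    if np.any(values <= 0):
        if isinstance(rltl, pd.Series):
            bad = rltl.index[np.nonzero(values <= 0)[0][0]]
        else:
            bad = int(np.nonzero(values <= 0)[0][0])
        raise ValueError(f"non-positive RLTL for sample {bad!r}; cannot log-transform")
    logged = np.log(values)
    if logged.size < 3 or np.allclose(logged, logged[0]):
        report = NormalityReport(np.nan, np.nan, logged.size, degenerate=True)
    else:
        stat, p = stats.shapiro(logged)
        report = NormalityReport(float(stat), float(p), logged.size)
    return logged, report


def rltl_from_plates(
    plates: pd.DataFrame, efficiency_fallback: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute per-sample RLTL from a plate-level Cq table.

    ``plates`` columns: sample_id, animal_id, plate_id, row_id, cq_tel, cq_b2m,
    e_tel, e_b2m, is_calibrator.  Each plate must contain exactly one
    calibrator record.  Missing per-reaction efficiencies are optionally
    replaced by the plate mean efficiency (``efficiency_fallback``).

    Returns (rltl table, issue report).  The report has one row per dropped or
    patched sample with a reason code.
    """
    required = {
        "sample_id",
        "animal_id",
        "plate_id",
        "row_id",
        "cq_tel",
        "cq_b2m",
        "e_tel",
        "e_b2m",
        "is_calibrator",
    }
    missing = required - set(plates.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    issues: list[dict] = []
    out_rows: list[dict] = []
    for plate_id, grp in plates.groupby("plate_id", sort=False):
        cal = grp[grp["is_calibrator"].astype(bool)]
        if len(cal) != 1:
            raise ValueError(
                f"plate {plate_id!r} has {len(cal)} calibrator records; expected 1"
            )
        grp = grp.copy()
        for col in ("e_tel", "e_b2m"):
            nan = grp[col].isna()
            if nan.any():
                if not efficiency_fallback:
                    raise ValueError(
                        f"missing {col} on plate {plate_id!r} and fallback disabled"
                    )
                fill = float(grp.loc[~nan, col].mean())
                for sid in grp.loc[nan, "sample_id"]:
                    issues.append(
                        {"sample_id": sid, "reason": f"{col}_plate_mean_fallback"}
                    )
                grp.loc[nan, col] = fill
        cal_rec = _record(grp[grp["is_calibrator"].astype(bool)].iloc[0])
        for _, r in grp.iterrows():
            rec = _record(r)
            out_rows.append(
                {
                    "sample_id": rec.sample_id,
                    "animal_id": rec.animal_id,
                    "plate_id": rec.plate_id,
                    "row_id": rec.row_id,
                    "rltl": compute_rltl(rec, cal_rec),
                    "is_calibrator": rec.is_calibrator,
                }
            )
    report = pd.DataFrame(issues, columns=["sample_id", "reason"])
    return pd.DataFrame(out_rows), report


def _record(row: pd.Series) -> PlateRecord:
    return PlateRecord(
        sample_id=str(row["sample_id"]),
        animal_id=str(row["animal_id"]),
        plate_id=str(row["plate_id"]),
        row_id=str(row["row_id"]),
        cq_tel=float(row["cq_tel"]),
        cq_b2m=float(row["cq_b2m"]),
        e_tel=float(row["e_tel"]),
        e_b2m=float(row["e_b2m"]),
        is_calibrator=bool(row["is_calibrator"]),
    )
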