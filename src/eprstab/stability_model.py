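"""Empirical oxidative-stability model linking AUC to PV, TPC and FFA.

The model is linear without intercept on the AUC/1e6 scale:

    AUC / 1e6 = c_PV * PV + c_TPC * TPC + c_FFA * FFA

with PV in micro-equivalents O2 per g oil, TPC in mg caffeic acid per g oil
and FFA in percent of fatty acids.  Coefficients may be supplied (published
values) or refit from records with measured AUC.  Also provides the
saturated-to-polyunsaturated fatty-acid ratio summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OilRecord",
    "StabilityCoefficients",
    "PUBLISHED_COEFFICIENTS",
    "predict_auc",
    "fit_coefficients",
    "model_residuals",
    "sfa_pufa_ratio",
]

EXTRACTION_METHODS = ("ME", "HX", "2-MeTHF", "EtOAc")


@dataclass(frozen=True)
class OilRecord:
    """One oil: extraction method, assay summaries and measured AUC.

    ``fatty_acids`` maps FAME labels (C16:0, C18:0, C18:1, C18:2) to mol
    percentages.  ``*_sd`` fields carry the replicate standard deviations of
    the corresponding measured quantity (used by residual flagging); any
    unmeasured quantity may be None.
    """

    method: str
    yield_pct: float | None = None
    PV: float | None = None  # micro-eq O2 / g oil
    TPC: float | None = None  # mg caffeic acid / g oil
    RSA: float | None = None  # micromol trolox / g oil
    FFA: float | None = None  # % of fatty acids
    fatty_acids: Mapping[str, float] = field(default_factory=dict)
    AUC_measured: float | None = None
    yield_sd: float | None = None
    PV_sd: float | None = None
    TPC_sd: float | None = None
    RSA_sd: float | None = None
    FFA_sd: float | None = None
    fatty_acids_sd: Mapping[str, float] = field(default_factory=dict)
    AUC_sd: float | None = None

    def __post_init__(self) -> None:
        if self.method not in EXTRACTION_METHODS:
            raise ValueError(
                f"method must be one of {EXTRACTION_METHODS}, got {self.method!r}"
            )
        for name in ("yield_pct", "PV", "TPC", "FFA", "AUC_measured"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        fa_total = sum(self.fatty_acids.values())
        if fa_total > 100.0 + 1e-9:
            raise ValueError("fatty-acid percentages must sum to <= 100")
        if any(v < 0 for v in self.fatty_acids.values()):
            raise ValueError("fatty-acid percentages must be non-negative")


@dataclass(frozen=True)
class StabilityCoefficients:
    """Multipliers on the AUC/1e6 scale; signs are carried by the values."""

    c_PV: float
    c_TPC: float
    c_FFA: float

    def __post_init__(self) -> None:
        for v in (self.c_PV, self.c_TPC, self.c_FFA):
            if not np.isfinite(v):
                raise ValueError("coefficients must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.c_PV, self.c_TPC, self.c_FFA])


#: Coefficients as published for myrtle seed oils.
PUBLISHED_COEFFICIENTS = StabilityCoefficients(c_PV=1.62, c_TPC=-12.78, c_FFA=-2.44)


def _design_row(record: OilRecord) -> np.ndarray:
    for name in ("PV", "TPC", "FFA"):
        if getattr(record, name) is None:
            raise ValueError(f"record {record.method!r} is missing {name}")
    return np.array([record.PV, record.TPC, record.FFA], dtype=float)


def predict_auc(record: OilRecord, coef: StabilityCoefficients) -> float:
    """Predicted AUC in arbitrary units: 1e6 * (c_PV*PV + c_TPC*TPC + c_FFA*FFA)."""
    return float(1e6 * _design_row(record) @ coef.as_array())


def fit_coefficients(records: Sequence[OilRecord]) -> StabilityCoefficients:
    """No-intercept least squares on the AUC/1e6 scale.

    With exactly three records this is an exact linear solve.  Raises on a
    rank-deficient design or fewer than three records.
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError("at least 3 records with measured AUC are required")
    X = np.vstack([_design_row(r) for r in records])
    y = np.array(
        [r.AUC_measured for r in records],
        dtype=float,
    )
    if np.any(~np.isfinite(y)):
        raise ValueError("all records must have a measured AUC")
    y = y / 1e6
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("design matrix is rank-deficient")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return StabilityCoefficients(*map(float, coef))


def model_residuals(
    records: Sequence[OilRecord],
    coef: StabilityCoefficients,
    flag_sd_multiple: float = 3.0,
) -> pd.DataFrame:
    """Per-record diagnostics: predicted, measured, |delta|/SD and a flag.

    Records whose absolute prediction error exceeds ``flag_sd_multiple``
    times their replicate SD are flagged.  Records without a reported SD
    get NaN in the ratio column and are never flagged.
    """
    rows = []
    for r in records:
        if r.AUC_measured is None:
            raise ValueError(f"record {r.method!r} has no measured AUC")
        pred = predict_auc(r, coef)
        delta = pred - r.AUC_measured
        ratio = abs(delta) / r.AUC_sd if r.AUC_sd else np.nan
        rows.append(
            {
                "method": r.method,
                "predicted": pred,
                "measured": r.AUC_measured,
                "delta": delta,
                "abs_delta_over_sd": ratio,
                "flagged": bool(ratio > flag_sd_multiple) if np.isfinite(ratio) else False,
            }
        )
    return pd.DataFrame(rows).set_index("method")


def sfa_pufa_ratio(record: OilRecord) -> float:
    """(C16:0 + C18:0) / C18:2 — linoleic acid is the sole PUFA reported."""
    fa = record.fatty_acids
    for key in ("C16:0", "C18:0", "C18:2"):
        if key not in fa:
            raise ValueError(f"fatty acid {key} missing from record {record.method!r}")
    pufa = fa["C18:2"]
    if pufa == 0:
        raise ZeroDivisionError("PUFA (C18:2) percentage is zero")
    return (fa["C16:0"] + fa["C18:0"]) / pufa
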