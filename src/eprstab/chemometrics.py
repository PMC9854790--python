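"""Feature-table preprocessing and PCA for data fusion.

The pipeline order is fixed and enforced: total-signal normalisation of the
LC-MS feature columns, optional fusion with per-sample assay variables
(PV, TPC, RSA, AUC), Pareto scaling, then PCA.  Pareto scaling divides each
mean-centred column by the square root of its sample standard deviation,
tempering — without fully equalising — the dominance of intense features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "PCAModel",
    "ASSAY_COLUMNS",
    "normalize_total_signal",
    "pareto_scale",
    "pca",
    "fuse_variables",
]

ASSAY_COLUMNS = ("PV", "TPC", "RSA", "AUC")

ScalingState = Literal["raw", "total-normalized", "pareto"]


class PipelineOrderError(RuntimeError):
    """A preprocessing stage was invoked out of the enforced order."""


@dataclass
class FeatureMatrix:
    """Sample x feature peak-area table with explicit scaling state.

    ``data`` holds one row per sample (index = sample ids) and one column
    per feature.  ``groups`` labels each sample with its extraction-method
    group.  ``assay_columns`` names the fused assay variables (exempt from
    the non-negativity expected of raw peak areas and excluded from
    total-signal normalisation).
    """

    data: pd.DataFrame
    groups: pd.Series | None = None
    scaling_state: ScalingState = "raw"
    assay_columns: tuple[str, ...] = ()
    block_weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("sample and feature identifiers must be unique")
        if self.data.isna().any().any():
            raise ValueError("missing values are not allowed")
        if self.groups is not None and not self.groups.index.equals(self.data.index):
            raise ValueError("group labels must be indexed by the sample ids")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.assay_columns]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.data.copy(),
            None if self.groups is None else self.groups.copy(),
            self.scaling_state,
            self.assay_columns,
            dict(self.block_weights),
        )


@dataclass(frozen=True)
class PCAModel:
    """SVD-based PCA of a scaled matrix.

    ``scores`` is samples x components, ``loadings`` features x components
    (orthonormal columns), ``r2x`` the per-component fraction of total
    scaled variance.  Component signs are fixed by making each column's
    largest-magnitude loading positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    r2x: np.ndarray
    center: pd.Series

    def __post_init__(self) -> None:
        if np.any(np.diff(self.r2x) > 1e-12):
            raise ValueError("r2x must be non-increasing")
        if self.r2x.sum() > 1.0 + 1e-9:
            raise ValueError("r2x fractions cannot exceed 1")


def normalize_total_signal(matrix: FeatureMatrix) -> FeatureMatrix:
    """Divide each row by its total over the LC-MS feature columns.

    Assay columns are left untouched.  Raises if called after scaling, or
    if any sample has a zero feature sum.
    """
    if matrix.scaling_state != "raw":
        raise PipelineOrderError(
            f"normalize_total_signal requires a raw matrix, got {matrix.scaling_state!r}"
        )
    out = matrix.copy()
    feats = out.feature_columns
    sums = out.data[feats].sum(axis=1)
    zero = sums[sums <= 0]
    if not zero.empty:
        raise ValueError(f"zero total signal for sample(s): {list(zero.index)}")
    out.data[feats] = out.data[feats].div(sums, axis=0)
    out.scaling_state = "total-normalized"
    return out


def fuse_variables(matrix: FeatureMatrix, assay_table: pd.DataFrame) -> FeatureMatrix:
    """Append PV/TPC/RSA/AUC columns to the feature table before scaling.

    ``assay_table`` must provide all four assay values for every sample.
    The fused columns later participate in Pareto scaling like any feature
    (optionally weighted by ``block_weights['assay']``).
    """
    if matrix.scaling_state == "pareto":
        raise PipelineOrderError("cannot fuse assay variables after Pareto scaling")
    missing_cols = [c for c in ASSAY_COLUMNS if c not in assay_table.columns]
    if missing_cols:
        raise ValueError(f"assay table is missing columns: {missing_cols}")
    missing_rows = matrix.data.index.difference(assay_table.index)
    if not missing_rows.empty:
        raise ValueError(f"assay values missing for sample(s): {list(missing_rows)}")
    out = matrix.copy()
    block = assay_table.loc[out.data.index, list(ASSAY_COLUMNS)].astype(float)
    out.data = pd.concat([out.data, block], axis=1)
    out.assay_columns = tuple(ASSAY_COLUMNS)
    return out


def pareto_scale(matrix: FeatureMatrix) -> FeatureMatrix:
    """Per column: subtract the mean, divide by sqrt(sample std, ddof=1).

    Constant columns are left centred (a warning is issued).  An optional
    per-block scalar weight (``block_weights``) multiplies the assay block.
    """
    if matrix.scaling_state == "pareto":
        raise PipelineOrderError("matrix is already Pareto scaled")
    if matrix.data.shape[0] < 2:
        raise ValueError("Pareto scaling needs at least 2 samples")
    out = matrix.copy()
    values = out.data.astype(float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    centred = values - mean
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s) left centred, not scaled",
            stacklevel=2,
        )
    scale = np.sqrt(sd.where(~constant, 1.0))
    scaled = centred / scale
    assay_w = float(matrix.block_weights.get("assay", 1.0))
    if assay_w != 1.0 and matrix.assay_columns:
        scaled[list(matrix.assay_columns)] *= assay_w
    out.data = scaled
    out.scaling_state = "pareto"
    return out


def pca(matrix: FeatureMatrix, n_components: int) -> PCAModel:
    """PCA by singular-value decomposition of the (Pareto-scaled) matrix.

    ``r2x_k = sigma_k^2 / sum(sigma^2)``.  Deterministic up to column sign,
    which is fixed by making the largest-magnitude loading of each
    component positive.  Warns when the input is not Pareto scaled.
    """
    n_samples, n_features = matrix.data.shape
    max_comp = min(n_samples - 1, n_features)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must lie in [1, {max_comp}]")
    if matrix.scaling_state != "pareto":
        warnings.warn(
            f"PCA on a {matrix.scaling_state!r} matrix; Pareto scaling is expected",
            stacklevel=2,
        )
    X = matrix.data.to_numpy(dtype=float)
    center = X.mean(axis=0)
    Xc = X - center  # no-op for a Pareto-scaled matrix
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)

    # sign convention: largest-|loading| entry positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0

    total_var = float(np.sum(s**2))
    r2x = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    scores = pd.DataFrame(
        U[:, :n_components] * s[:n_components], index=matrix.data.index, columns=comp_names
    )
    loadings = pd.DataFrame(
        Vt[:n_components].T, index=matrix.data.columns, columns=comp_names
    )
    return PCAModel(
        scores=scores,
        loadings=loadings,
        r2x=r2x,
        center=pd.Series(center, index=matrix.data.columns),
    )
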