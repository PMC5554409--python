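"""Expression normalization and network smoothing (X' = XV)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import SmoothingMatrix


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values with a processing-stage tag.

    ``data`` rows are samples, columns are genes. ``stage`` is one of
    'raw', 'normalized' (per-gene z-scores of log2 values) or 'smoothed'
    (network-transformed then re-z-scored).
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self):
        if self.stage not in ("raw", "normalized", "smoothed"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("duplicate sample or gene identifiers")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def restrict_genes(self, genes) -> "ExpressionMatrix":
        """Column subset in the given order (all genes must be present)."""
        missing = [g for g in genes if g not in self.data.columns]
        if missing:
            raise KeyError(f"genes not in expression matrix: {missing[:5]}")
        return ExpressionMatrix(data=self.data.loc[:, list(genes)], stage=self.stage)


def zscore_columns(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise z-score (ddof=1); constant columns map to zeros.

    Returns the transformed array and a boolean mask of the constant
    (zero-variance) columns.
    """
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    z = (values - mean) / sd_safe
    z[:, constant] = 0.0
    return z, constant


def normalize_expression(
    X_raw: ExpressionMatrix, log2_first: bool = True
) -> ExpressionMatrix:
    """log2 transform (optional) followed by a per-gene Z-transform.

    After normalization every non-constant gene has mean 0 and sample
    variance 1 across samples; constant genes become all-zero columns
    (they carry no phenotype information) with a warning.
    """
    df = X_raw.data
    if df.isna().any().any():
        bad = df.columns[df.isna().any()][0]
        raise ValueError(f"missing values in raw expression (e.g. gene {bad!r}); refusing to impute")
    if df.shape[0] < 3:
        raise ValueError("need at least 3 samples to normalize")
    values = df.to_numpy(dtype=float)
    if log2_first:
        if np.any(values <= 0):
            i, j = np.argwhere(values <= 0)[0]
            raise ValueError(
                f"non-positive value for gene {df.columns[j]!r} in sample "
                f"{df.index[i]!r}; cannot log2-transform"
            )
        values = np.log2(values)
    z, constant = zscore_columns(values)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance gene(s) set to all-zero columns"
        )
    out = pd.DataFrame(z, index=df.index, columns=df.columns)
    return ExpressionMatrix(data=out, stage="normalized")


def smooth_expression(X: ExpressionMatrix, V: SmoothingMatrix) -> ExpressionMatrix:
    """Network transformation X' = XV followed by per-column Z-transform.

    ``X`` must already be restricted and aligned to ``V.shared_genes`` in
    the same order; a mismatch is an error, never a silent reorder.
    """
    if X.stage != "normalized":
        raise ValueError("smooth_expression expects a normalized matrix")
    if list(X.data.columns) != list(V.shared_genes):
        raise ValueError(
            "gene order of expression matrix does not match the smoothing "
            "matrix; align explicitly with restrict_genes()"
        )
    smoothed = X.data.to_numpy(dtype=float) @ V.V
    z, _ = zscore_columns(smoothed)
    out = pd.DataFrame(z, index=X.data.index, columns=X.data.columns)
    return ExpressionMatrix(data=out, stage="smoothed")
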