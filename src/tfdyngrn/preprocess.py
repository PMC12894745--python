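"""Count filtering, median-of-ratios normalisation and contrast signatures.

The normalisation is the classic RNA-seq size-factor procedure: per
sample, the median over reference genes (genes with strictly positive
counts everywhere) of the ratio count / geometric-mean-across-samples.
Contrast signatures are per-gene Welch t-statistics converted to
z-scores through the normal quantile of the two-sided p-value; they
are the gene-level input of regulon enrichment.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataError, ExpressionMatrix

#: z-scores are capped here: with two-replicate groups a zero within-group
#: variance yields p ≈ 0, whose normal quantile overflows.
Z_CAP = 8.0


def filter_genes(
    counts: ExpressionMatrix, min_count: int = 2, min_samples: int = 2
) -> ExpressionMatrix:
    """Keep genes with count ≥ min_count in ≥ min_samples samples and non-constant values.

    Gene order is preserved; an empty result warns rather than raises.
    """
    if counts.layer != "counts":
        raise DataError("filter_genes expects the counts layer")
    values = counts.data.to_numpy()
    enough = (values >= min_count).sum(axis=1) >= min_samples
    nonconstant = values.max(axis=1) > values.min(axis=1)
    keep = enough & nonconstant
    if not keep.any():
        warnings.warn("gene filter removed every gene", stacklevel=2)
    return ExpressionMatrix(counts.data.loc[keep], layer="counts")


@dataclasses.dataclass
class SizeFactors:
    """Per-sample positive scaling factors (median-of-ratios)."""

    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any() or not np.isfinite(self.factors).all():
            raise DataError("size factors must be finite and positive")


def size_factors(counts: ExpressionMatrix) -> SizeFactors:
    """Median-of-ratios size factors over the all-positive reference genes.

    Factors are rescaled to geometric mean 1 (as for edgeR's TMM
    factors), which makes normalisation idempotent: re-estimating
    factors on normalised data returns exactly 1 for every sample.
    Relative factors (every ratio s_i/s_j) are identical to DESeq2's.
    """
    values = counts.data.to_numpy(dtype=float)
    reference = (values > 0).all(axis=1)
    if not reference.any():
        raise DataError(
            "no gene has strictly positive counts in every sample; "
            "median-of-ratios size factors are undefined (no pseudo-reference "
            "fallback is applied)"
        )
    logs = np.log(values[reference])
    log_geomean = logs.mean(axis=1)
    log_ratios = logs - log_geomean[:, None]
    log_factors = np.median(log_ratios, axis=0)
    log_factors = log_factors - log_factors.mean()
    factors = np.exp(log_factors)
    return SizeFactors(pd.Series(factors, index=counts.data.columns, name="size_factor"))


def normalise(counts: ExpressionMatrix, factors: SizeFactors) -> ExpressionMatrix:
    """Divide each sample's counts by its size factor."""
    if list(factors.factors.index) != list(counts.data.columns):
        raise DataError("size factors do not match the matrix samples")
    data = counts.data / factors.factors
    return ExpressionMatrix(data, layer="normalised")


@dataclasses.dataclass
class SignatureVector:
    """Per-gene t statistic, two-sided p and signed z for one contrast."""

    table: pd.DataFrame  # index: gene; columns: t, p, z

    def __post_init__(self) -> None:
        t = self.table
        if not {"t", "p", "z"} <= set(t.columns):
            raise DataError("signature needs columns t, p, z")
        if not np.isfinite(t["z"]).all():
            raise DataError("signature z-scores must be finite")

    @property
    def z(self) -> pd.Series:
        return self.table["z"]


def contrast_signature(
    norm_expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> SignatureVector:
    """Welch t-test of group A vs group B per gene, converted to z-scores.

    z = sign(t) · Φ⁻¹(1 − p/2), capped at ±Z_CAP. Genes with zero
    variance in both groups and equal means get t = 0, p = 1, z = 0.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise DataError("contrast groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise DataError("each contrast group needs at least 2 samples")
    a = norm_expr.data.loc[:, group_a].to_numpy(dtype=float)
    b = norm_expr.data.loc[:, group_b].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # zero variance in both groups: equal means → no evidence; shifted
    # means → infinite t, p=0, z capped below
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = ~np.isfinite(t)
    with np.errstate(invalid="ignore"):
        shifted = np.sign(diff) * np.inf
    shifted[diff == 0] = 0.0
    t = np.where(degenerate, shifted, t)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    with np.errstate(divide="ignore"):
        z = np.sign(t) * stats.norm.isf(p / 2.0)
    z = np.clip(np.nan_to_num(z, nan=0.0, posinf=Z_CAP, neginf=-Z_CAP), -Z_CAP, Z_CAP)
    z[t == 0] = 0.0
    table = pd.DataFrame({"t": t, "p": p, "z": z}, index=norm_expr.data.index)
    table["p"] = table["p"].clip(lower=np.nextafter(0.0, 1.0), upper=1.0)
    table["t"] = np.where(np.isinf(table["t"]), np.sign(table["t"]) * Z_CAP * 1e6, table["t"])
    return SignatureVector(table)


def standardise_genes(norm_expr: ExpressionMatrix) -> ExpressionMatrix:
    """Centre and scale each gene to unit variance across samples.

    Zero-variance genes become all-zero rows. The per-sample columns of
    the result serve as single-sample signatures for activity scoring.
    """
    if norm_expr.data.shape[1] < 2:
        raise DataError("standardisation needs at least 2 samples")
    values = norm_expr.data.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[~np.isfinite(z)] = 0.0
    z[(sd == 0).ravel(), :] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(z, index=norm_expr.data.index, columns=norm_expr.data.columns),
        layer="standardised",
    )
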