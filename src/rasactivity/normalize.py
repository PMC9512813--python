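"""Count normalization and scaling.

The variance-stabilizing step is a log2(normalized count + 1) surrogate on
median-of-ratios size factors: downstream stages use only rank, mean and
distance structure, which the surrogate preserves, and it is dependency-free
and exactly specified.  An implementation with a dispersion-fitted VST can be
substituted behind the same interface.

The pan-cancer comparison scheme is: per-cohort vst-like transform, then
z-score samples, then z-score genes.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, Scale

logger = logging.getLogger(__name__)


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (the standard count-depth estimate).

    factor_s = median over genes of count_gs / geometric-mean_g, computed over
    genes with all-positive counts.  Identical columns give factors of 1.
    """
    if counts.scale is not Scale.raw_counts:
        raise ValueError("size factors are defined on raw counts")
    arr = counts.values.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; filter all-zero genes first"
        )
    sub = arr[all_positive]
    log_geo_mean = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geo_mean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def vst_like_transform(counts: ExpressionMatrix) -> ExpressionMatrix:
    """log2(count / size_factor + 1) with the scale flag set to vst_like."""
    factors = size_factors(counts)
    values = np.log2(counts.values / factors + 1.0)
    return ExpressionMatrix(values=values, scale=Scale.vst_like, cohort=counts.cohort)


def zscore(
    matrix: ExpressionMatrix,
    over: Literal["genes", "samples", "samples_then_genes"] = "genes",
) -> ExpressionMatrix:
    """Center/scale the chosen axis to mean 0, sd 1 (sample sd, ddof=1).

    Zero-variance rows (over=genes) or columns (over=samples) are dropped
    with a logged warning.  ``samples_then_genes`` composes the two
    single-axis operations in that order.
    """
    if matrix.scale not in (Scale.vst_like, Scale.zscore):
        raise ValueError("z-scoring requires vst_like (or already z-scored) input")
    if over == "samples_then_genes":
        return zscore(zscore(matrix, "samples"), "genes")
    axis = 1 if over == "genes" else 0
    values = matrix.values
    sd = values.std(axis=axis, ddof=1)
    zero = sd == 0
    if zero.all():
        raise ValueError("all features have zero variance")
    if zero.any():
        logger.warning("dropping %d zero-variance %s before z-scoring", int(zero.sum()), over)
        if over == "genes":
            values = values.loc[~zero]
        else:
            values = values.loc[:, ~zero]
        sd = sd[~zero]
    centered = values.sub(values.mean(axis=axis), axis=1 - axis)
    scaled = centered.div(sd, axis=1 - axis)
    cohort = matrix.cohort
    if cohort is not None and over != "genes":
        cohort = cohort.loc[scaled.columns]
    return ExpressionMatrix(values=scaled, scale=Scale.zscore, cohort=cohort)


def pan_cancer_normalize(cohorts: dict[str, ExpressionMatrix]) -> ExpressionMatrix:
    """Normalize cohorts for cross-cancer comparison and merge on shared genes.

    Each cohort is vst-like transformed and z-scored over samples (each
    sample's profile centred and scaled across genes, removing per-sample
    depth and dynamic-range differences); the cohorts are then concatenated
    and z-scored over genes *across the merged matrix*.  Gene z-scoring must
    happen after the merge: done per cohort it would erase exactly the
    between-cohort signature differences the pan-cancer comparison measures.
    Genes absent from any cohort are dropped with a logged count.
    """
    if not cohorts:
        raise ValueError("no cohorts supplied")
    transformed: dict[str, ExpressionMatrix] = {}
    for name, counts in cohorts.items():
        mat = counts if counts.scale is not Scale.raw_counts else vst_like_transform(counts)
        transformed[name] = zscore(mat, "samples")
    shared = None
    for mat in transformed.values():
        shared = mat.gene_ids if shared is None else shared.intersection(mat.gene_ids)
    n_dropped = max(len(m.gene_ids) for m in transformed.values()) - len(shared)
    if n_dropped:
        logger.warning("pan-cancer merge: %d genes not shared across cohorts dropped", n_dropped)
    values = pd.concat([m.values.loc[shared] for m in transformed.values()], axis=1)
    cohort = pd.concat(
        [pd.Series(name, index=m.sample_ids) for name, m in transformed.items()]
    )
    merged = ExpressionMatrix(values=values, scale=Scale.zscore, cohort=cohort)
    return zscore(merged, "genes")
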