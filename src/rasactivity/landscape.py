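"""Pan-cancer activity profiling and multi-region heterogeneity metrics.

Pan-cancer: per-cohort mean RAS index and RAS-pathway mutation-burden
profiles, a kernel-density bimodal split of the cohort means into high- and
low-activity cancer populations, and the burden-vs-index correlation with a
confidence-band outlier flagging.

Multi-region: Euclidean distance distributions between same-patient and
different-patient regions, per-gene intra-/inter-tumour variance components,
and Fisher-exact enrichment of signature genes in the low-intra/high-inter
("clonal expression") variance quadrant.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
import statsmodels.api as sm

from .datamodel import (
    ExpressionMatrix,
    GeneSignature,
    MultiRegionCohort,
    MutationAnnotation,
)
from .stratify import compute_ri

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Cohort profiles


def cohort_ri_profile(
    expr: ExpressionMatrix,
    sig: GeneSignature,
    mutations: MutationAnnotation,
    pathway_genes: Sequence[str] | None = None,
    ras_genes: Sequence[str] = ("KRAS", "HRAS", "NRAS"),
    min_samples: int = 10,
) -> pd.DataFrame:
    """Per-cohort mean RI, pathway mutation burden and isoform frequencies.

    ``expr`` must carry per-sample cohort labels and be normalized with the
    pan-cancer scheme (per-cohort vst-like + z-scoring).  Cohorts with fewer
    than ``min_samples`` samples are excluded with a warning.
    """
    if expr.cohort is None:
        raise ValueError("expression matrix must carry cohort labels")
    if pathway_genes is None:
        if mutations.pathway_genes is None:
            raise ValueError("no pathway gene set available")
        pathway_genes = mutations.pathway_genes
    ri = compute_ri(expr, sig)
    rows = []
    for cohort in sorted(expr.cohort.unique()):
        samples = expr.sample_ids[(expr.cohort == cohort).to_numpy()]
        if len(samples) < min_samples:
            logger.warning("cohort %s: %d samples < %d, excluded", cohort, len(samples), min_samples)
            continue
        burden = mutations.any_altered_mask(samples, pathway_genes).mean()
        row = {
            "cohort": cohort,
            "n": len(samples),
            "mean_ri": float(ri.loc[samples].mean()),
            "pathway_burden": float(burden),
        }
        for gene in ras_genes:
            row[f"freq_{gene}"] = float(mutations.altered_mask(samples, gene).mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("cohort")


# ---------------------------------------------------------------------------
# Bimodal split of cohort means


def bimodal_split(
    cohort_mean_ris: Sequence[float], grid_size: int = 512
) -> dict:
    """Split cohort mean-RI values at the KDE minimum between the two modes.

    A Gaussian kernel density estimate (Silverman bandwidth) is evaluated on
    a fixed grid spanning the data range plus three bandwidths; the threshold
    is the grid minimum between the two largest local maxima.  Raises if the
    density has no interior minimum between two maxima (no bimodal
    structure).  The procedure is deterministic and affine-equivariant.
    """
    values = np.asarray(cohort_mean_ris, dtype=float)
    if len(values) < 6:
        raise ValueError("need >= 6 cohort values")
    kde = stats.gaussian_kde(values, bw_method="silverman")
    bw = kde.factor * values.std(ddof=1)
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, grid_size)
    density = kde(grid)
    interior = np.flatnonzero(
        (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    ) + 1
    if len(interior) < 2:
        raise ValueError("no bimodal structure: fewer than two density maxima")
    top2 = sorted(interior[np.argsort(density[interior])][-2:])
    lo, hi = top2
    between = slice(lo, hi + 1)
    cut = lo + int(np.argmin(density[between]))
    threshold = float(grid[cut])
    assignment = pd.Series(
        np.where(values > threshold, "high", "low"),
        index=getattr(cohort_mean_ris, "index", pd.RangeIndex(len(values))),
    )
    return {"threshold": threshold, "assignment": assignment,
            "grid": grid, "density": density}


def burden_ri_correlation(profile: pd.DataFrame, conf_level: float = 0.99) -> dict:
    """Correlation of pathway mutation burden with cohort mean RI.

    Reports both Pearson and Spearman coefficients with p-values, an OLS
    regression of burden on mean RI with a ``conf_level`` confidence band
    for the mean, and flags cohorts above/below the band.
    """
    x = profile["mean_ri"].to_numpy(dtype=float)
    y = profile["pathway_burden"].to_numpy(dtype=float)
    if len(x) < 5:
        raise ValueError("need >= 5 cohorts")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in burden or mean RI")
    pearson_r, pearson_p = stats.pearsonr(x, y)
    spearman_r, spearman_p = stats.spearmanr(x, y)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X)
    band = pred.conf_int(alpha=1.0 - conf_level)
    flag = np.where(y > band[:, 1], "above", np.where(y < band[:, 0], "below", "within"))
    return {
        "pearson": {"coefficient": float(pearson_r), "p": float(pearson_p)},
        "spearman": {"coefficient": float(spearman_r), "p": float(spearman_p)},
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "band": pd.DataFrame(
            {"fit": pred.predicted_mean, "low": band[:, 0], "high": band[:, 1],
             "flag": flag},
            index=profile.index,
        ),
    }


# ---------------------------------------------------------------------------
# Multi-region heterogeneity


def distance_distributions(
    expr: ExpressionMatrix,
    multiregion: MultiRegionCohort,
    sig: GeneSignature | None = None,
) -> dict:
    """Intra- vs inter-tumour Euclidean distance distributions.

    Distances are computed over the signature-gene submatrix (all genes if no
    signature given) between every sample pair, then partitioned into
    same-patient and different-patient pairs.  Also reports the maximum
    intra-tumour distance per patient.
    """
    samples = [s for s in multiregion.sample_ids if s in expr.sample_ids]
    if len(samples) < len(multiregion.sample_ids):
        logger.warning("%d region samples absent from expression matrix",
                       len(multiregion.sample_ids) - len(samples))
    sub = expr.subset_samples(samples)
    if sig is not None:
        sub = sub.subset_genes(list(sig.genes))
    X = sub.values.to_numpy(dtype=float).T
    dist = squareform(pdist(X, metric="euclidean"))
    patient_of = multiregion.patient_of().loc[samples]
    patients = patient_of.to_numpy()
    same = patients[:, None] == patients[None, :]
    iu = np.triu_indices(len(samples), k=1)
    intra = dist[iu][same[iu]]
    inter = dist[iu][~same[iu]]
    if len(intra) == 0:
        logger.warning("no patient has more than one region: empty intra set")
    max_intra = {}
    for p in np.unique(patients):
        members = np.flatnonzero(patients == p)
        if len(members) > 1:
            max_intra[p] = float(dist[np.ix_(members, members)].max())
    return {
        "intra": intra,
        "inter": inter,
        "max_intra_per_patient": pd.Series(max_intra, dtype=float),
        "median_intra": float(np.median(intra)) if len(intra) else np.nan,
        "median_inter": float(np.median(inter)) if len(inter) else np.nan,
    }


def variance_components(
    expr: ExpressionMatrix, multiregion: MultiRegionCohort
) -> pd.DataFrame:
    """Per-gene intra- (within-patient) and inter- (between-patient) variance.

    Intra is the pooled within-patient variance over patients with >= 2
    regions; inter is the variance of patient mean profiles.  A surrogate
    for externally supplied heterogeneity annotations when none are given.
    """
    patient_of = multiregion.patient_of()
    samples = [s for s in patient_of.index if s in expr.sample_ids]
    values = expr.values.loc[:, samples]
    groups = patient_of.loc[samples]
    patient_means = values.T.groupby(groups).mean().T
    within_ss = np.zeros(len(values))
    within_df = 0
    for p, cols in groups.groupby(groups).groups.items():
        if len(cols) < 2:
            continue
        block = values.loc[:, list(cols)]
        within_ss += ((block.sub(block.mean(axis=1), axis=0)) ** 2).sum(axis=1).to_numpy()
        within_df += len(cols) - 1
    if within_df == 0:
        raise ValueError("need at least one patient with >= 2 regions")
    intra = within_ss / within_df
    inter = patient_means.var(axis=1, ddof=1).to_numpy()
    return pd.DataFrame({"intra_var": intra, "inter_var": inter}, index=values.index)


def classify_variance_quadrants(components: pd.DataFrame) -> pd.DataFrame:
    """Median-split intra/inter variances into the four heterogeneity quadrants."""
    low_intra = components["intra_var"] < components["intra_var"].median()
    high_inter = components["inter_var"] >= components["inter_var"].median()
    return pd.DataFrame({"low_intra": low_intra, "high_inter": high_inter},
                        index=components.index)


def quadrant_enrichment(
    gene_classes: pd.DataFrame, sig: GeneSignature
) -> dict:
    """Enrichment of signature genes in the low-intra/high-inter quadrant.

    fold = (fraction of signature genes in the quadrant) / (fraction of all
    genes in the quadrant); the p-value is a two-sided Fisher exact test on
    the 2x2 table of signature membership x quadrant membership.
    """
    need = {"low_intra", "high_inter"}
    if not need <= set(gene_classes.columns):
        raise ValueError(f"gene classes require columns {sorted(need)}")
    in_quadrant = gene_classes["low_intra"] & gene_classes["high_inter"]
    in_sig = gene_classes.index.isin(sig.genes)
    if not in_quadrant.any() or in_quadrant.all():
        raise ValueError("degenerate quadrant (empty or universal)")
    q = in_quadrant.to_numpy()
    table = np.array([
        [int((in_sig & q).sum()), int((in_sig & ~q).sum())],
        [int((~in_sig & q).sum()), int((~in_sig & ~q).sum())],
    ])
    sig_frac = table[0, 0] / table[0].sum()
    all_frac = q.mean()
    fold = sig_frac / all_frac
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {"fold": float(fold), "p": float(p), "table": table,
            "signature_fraction": float(sig_frac), "background_fraction": float(all_frac)}
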