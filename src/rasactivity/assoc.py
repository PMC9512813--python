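"""Genomic, proteomic and pharmacologic association with activity groups.

All scans share one result shape: per tested feature an effect estimate, a
test statistic, a p-value and a Benjamini-Hochberg FDR, with the correction
applied across the features tested in the same call (one correction scope
per input table).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .datamodel import (
    ActivityGrouping,
    ExpressionMatrix,
    GeneSignature,
    MutationAnnotation,
)

logger = logging.getLogger(__name__)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Variant scans


def variant_rag_scan(
    mutations: MutationAnnotation,
    grouping: ActivityGrouping,
    min_carriers: int = 10,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Chi-square scan of variant carrier frequency across activity groups.

    Variants with more than ``min_carriers`` carriers (strict) are tested on
    a k x 2 table of carrier status per group; BH correction runs across the
    tested variants.  Returns a frame with columns carriers, chi2, p, fdr,
    flagged; an empty frame (warned) if nothing passes the carrier floor.
    """
    samples = grouping.samples
    rows = []
    for gene in mutations.genes():
        mask = mutations.altered_mask(samples, gene)
        carriers = int(mask.sum())
        if carriers <= min_carriers:
            logger.info("variant %s: %d carriers <= %d, excluded", gene, carriers, min_carriers)
            continue
        table = pd.crosstab(grouping.labels, mask)
        if table.shape[1] < 2:
            continue  # carried by every sample (or none): degenerate
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        rows.append({"feature": gene, "carriers": carriers, "chi2": chi2, "p": p})
    if not rows:
        logger.warning("no variant passes the carrier floor (> %d)", min_carriers)
        return pd.DataFrame(columns=["feature", "carriers", "chi2", "p", "fdr", "flagged"])
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"])
    out["flagged"] = out["fdr"] < fdr_threshold
    return out


def genotype_vs_rest_test(
    mutations: MutationAnnotation,
    grouping: ActivityGrouping,
    genotype: str,
    gene: str = "KRAS",
) -> dict:
    """Chi-square of one mutation genotype against all remaining samples.

    Tests whether carriers of e.g. KRAS G12D distribute non-randomly across
    the activity groups relative to everyone else.  Zero carriers is an
    error; a degenerate table (every sample a carrier) is an error; very few
    carriers is allowed with a logged low-power warning.
    """
    samples = grouping.samples
    carriers = mutations.genotype_mask(samples, gene, genotype)
    n_carriers = int(carriers.sum())
    if n_carriers == 0:
        raise ValueError(f"no carriers of {gene} {genotype}")
    if n_carriers == len(samples):
        raise ValueError(f"every sample carries {gene} {genotype}: degenerate table")
    if n_carriers < 5:
        logger.warning("%s %s: only %d carriers; test is low-powered", gene, genotype, n_carriers)
    table = pd.crosstab(grouping.labels, carriers)
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return {"chi2": float(chi2), "p": float(p), "carriers": n_carriers}


# ---------------------------------------------------------------------------
# Group-wise linear models (drug response, protein levels)


def _design_matrix(
    group: pd.Series,
    covariates: pd.DataFrame | None,
    reference_group: str | None,
) -> tuple[pd.DataFrame, list[str]]:
    """Intercept + group dummies (reference dropped) + covariate columns."""
    if isinstance(group.dtype, pd.CategoricalDtype):
        levels = [l for l in group.cat.categories if (group == l).any()]
    else:
        levels = sorted(group.unique())
    ref = reference_group if reference_group is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference group {ref!r} not present")
    group_cols = [l for l in levels if l != ref]
    design = pd.DataFrame({"const": 1.0}, index=group.index)
    for l in group_cols:
        design[f"group[{l}]"] = (group == l).astype(float)
    if covariates is not None:
        for col in covariates.columns:
            vals = covariates[col]
            if vals.dtype == object or isinstance(vals.dtype, pd.CategoricalDtype):
                for lev in sorted(vals.dropna().unique())[1:]:
                    design[f"{col}[{lev}]"] = (vals == lev).astype(float)
            else:
                design[col] = vals.astype(float)
    return design, [f"group[{l}]" for l in group_cols]


def groupwise_linear_assoc(
    values: pd.DataFrame,
    group: pd.Series | ActivityGrouping,
    covariates: pd.DataFrame | None = None,
    reference_group: str | None = None,
    fdr_threshold: float = 0.05,
    abs_effect_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-feature OLS of a feature x sample matrix on activity groups.

    Each feature (drug, protein assay) is regressed on group indicators
    against the reference level plus optional covariates (e.g. KRAS mutation
    status); samples missing a value are excluded per-feature.  Effects are
    group coefficients (e.g. log2 delta-IC50 of high vs low).  BH runs across
    every (feature, group) test of the call.  A feature is flagged when
    fdr < ``fdr_threshold`` and |effect| > ``abs_effect_threshold``.

    Rank-deficient per-feature designs (group confounded with a covariate)
    yield NA rows with a logged reason.
    """
    if isinstance(group, ActivityGrouping):
        group = group.labels
    samples = [s for s in values.columns if s in group.index]
    if len(samples) < len(values.columns):
        logger.warning("%d samples without group labels excluded", len(values.columns) - len(samples))
    group = group.loc[samples]
    cov = covariates.loc[samples] if covariates is not None else None
    design, group_cols = _design_matrix(group, cov, reference_group)

    rows = []
    for feature, vals in values.loc[:, samples].iterrows():
        mask = vals.notna().to_numpy() & design.notna().all(axis=1).to_numpy()
        Xf = design.loc[vals.index[mask]]
        yf = vals[mask].astype(float)
        if len(yf) <= Xf.shape[1]:
            logger.warning("feature %s: too few observations, skipped", feature)
            for g in group_cols:
                rows.append({"feature": feature, "group": g, "effect": np.nan,
                             "stat": np.nan, "p": np.nan})
            continue
        if np.linalg.matrix_rank(Xf.to_numpy()) < Xf.shape[1]:
            logger.warning("feature %s: rank-deficient design (confounded), NA", feature)
            for g in group_cols:
                rows.append({"feature": feature, "group": g, "effect": np.nan,
                             "stat": np.nan, "p": np.nan})
            continue
        fit = sm.OLS(yf.to_numpy(), Xf.to_numpy()).fit()
        for g in group_cols:
            j = list(Xf.columns).index(g)
            rows.append({
                "feature": feature,
                "group": g.removeprefix("group[").removesuffix("]"),
                "effect": fit.params[j],
                "stat": fit.tvalues[j],
                "p": fit.pvalues[j],
            })
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["fdr"] = np.nan
    if tested.any():
        out.loc[tested, "fdr"] = bh_adjust(out.loc[tested, "p"])
    out["flagged"] = (out["fdr"] < fdr_threshold) & (
        out["effect"].abs() > abs_effect_threshold
    )
    return out


# ---------------------------------------------------------------------------
# Target-category enrichment


def hypergeometric_target_enrichment(
    flagged_drugs: Sequence[str],
    all_tested_drugs: Sequence[str],
    target_map: Mapping[str, Sequence[str]],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of drug target categories.

    For each category: p = P(X >= k) with k flagged drugs in the category, K
    tested drugs in the category, n flagged drugs, M tested drugs.  Only
    enrichment (not depletion) is tested; BH runs across categories.
    """
    flagged = set(flagged_drugs)
    tested = list(dict.fromkeys(all_tested_drugs))
    if not flagged <= set(tested):
        raise ValueError("flagged drugs must be a subset of tested drugs")
    if not flagged:
        logger.warning("empty flagged set: nothing to test")
        return pd.DataFrame(columns=["category", "k", "K", "n", "M", "p", "fdr", "flagged"])
    categories = sorted({c for d in tested for c in target_map.get(d, ())})
    M, n = len(tested), len(flagged)
    rows = []
    for cat in categories:
        in_cat = {d for d in tested if cat in target_map.get(d, ())}
        K = len(in_cat)
        k = len(in_cat & flagged)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append({"category": cat, "k": k, "K": K, "n": n, "M": M, "p": p})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"])
    out["flagged"] = out["fdr"] < fdr_threshold
    return out


# ---------------------------------------------------------------------------
# RAG driver genes


def rag_driver_genes(
    expr: ExpressionMatrix,
    sig: GeneSignature,
    grouping: ActivityGrouping,
    deviation_threshold: float = 1.0,
    cut_height: float | None = None,
    n_clusters: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Signature genes whose per-group mean deviates strongly from the cohort.

    Per gene, the deviation vector is (per-group mean) - (global mean); genes
    with max |deviation| above the threshold are clustered on their group-
    mean profiles with correlation distance (1 - r) and Ward linkage.  The
    cluster count comes from ``n_clusters`` or a dendrogram ``cut_height``
    (default 0.5 correlation distance).
    """
    if grouping.k < 2:
        raise ValueError("grouping must have k >= 2")
    genes = list(sig.present_in(expr))
    sub = expr.values.loc[genes, grouping.samples]
    group_means = sub.T.groupby(grouping.labels, observed=False).mean().T
    deviations = group_means.sub(sub.mean(axis=1), axis=0)
    selected = deviations.index[deviations.abs().max(axis=1) > deviation_threshold]
    if len(selected) == 0:
        logger.warning("no gene exceeds |deviation| > %s", deviation_threshold)
        return deviations, pd.Series(dtype=int)
    profiles = group_means.loc[selected]
    if len(selected) == 1:
        return deviations, pd.Series([1], index=selected)
    corr = np.corrcoef(profiles.to_numpy())
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="ward")
    if n_clusters is not None:
        assignment = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        assignment = fcluster(Z, t=cut_height if cut_height is not None else 0.5,
                              criterion="distance")
    return deviations, pd.Series(assignment, index=selected, name="cluster")


# ---------------------------------------------------------------------------
# RI vs mutation status, per cohort


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum: exact for small untied samples, else
    normal approximation with tie correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    exact = (len(x) <= 25 and len(y) <= 25
             and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y))
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def ri_mutation_association(
    ri: pd.Series,
    mutations: MutationAnnotation,
    cohort_labels: pd.Series,
    min_mutants: int = 5,
    ras_genes: Sequence[str] = ("KRAS", "HRAS", "NRAS"),
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-cohort Wilcoxon rank-sum of RI between RAS-mutant and wild-type.

    RAS mutation is the union of the oncogenic isoform calls.  Cohorts with
    fewer than ``min_mutants`` mutants are excluded (logged).  The signed
    effect is the mutant-minus-wild-type median RI difference; BH runs across
    the tested cohorts.
    """
    rows = []
    for cohort in sorted(cohort_labels.unique()):
        samples = cohort_labels.index[cohort_labels == cohort]
        samples = [s for s in samples if s in ri.index]
        mut = mutations.any_altered_mask(samples, ras_genes)
        n_mut = int(mut.sum())
        if n_mut < min_mutants:
            logger.info("cohort %s: %d RAS mutants < %d, excluded", cohort, n_mut, min_mutants)
            continue
        x = ri.loc[mut.index[mut]].to_numpy()
        y = ri.loc[mut.index[~mut]].to_numpy()
        if len(y) == 0:
            logger.info("cohort %s: no wild-type samples, excluded", cohort)
            continue
        stat, p = wilcoxon_rank_sum(x, y)
        rows.append({
            "cohort": cohort, "n_mut": n_mut, "n_wt": len(y),
            "effect": float(np.median(x) - np.median(y)), "stat": stat, "p": p,
        })
    if not rows:
        return pd.DataFrame(columns=["cohort", "n_mut", "n_wt", "effect", "stat", "p", "fdr", "flagged"])
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"])
    out["flagged"] = out["fdr"] < fdr_threshold
    return out
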