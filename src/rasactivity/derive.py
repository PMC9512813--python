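"""Meta-signature derivation from founder gene sets.

The derivation stage takes published RAS-target founder signatures and a
cell-line expression cohort and (1) filters signature genes for expression
and variability in the cohort, (2) removes samples whose RAS pathway is
confounded by non-KRAS driver alterations, (3) clusters samples on the
signature submatrix into RAS-high / unclassified / RAS-low groups,
(4) scores each signature by the segregation of KRAS mutants across the
extreme groups, (5) refines the best signatures by moderated-t differential
analysis between RAS-high and RAS-low, keeping genes up-regulated in
RAS-high at FDR < 0.05, and (6) merges the refined gene sets into a single
meta-signature of RAS oncogenic transcriptional activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    ActivityGrouping,
    ExpressionMatrix,
    GeneSignature,
    MutationAnnotation,
    Scale,
    rag_labels,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Local regression (loess) of log COV on mean log2 expression


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    eval_x: np.ndarray,
    span: float = 0.5,
    degree: int = 2,
) -> np.ndarray:
    """Locally weighted polynomial regression with tricube weights.

    For each evaluation point, the nearest ``span`` fraction of the training
    points is fit with a weighted polynomial of the given degree.  Degree 2
    with span 0.5 is the default used for the expression/variability trend.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = max(int(np.ceil(span * n)), degree + 2)
    out = np.empty(len(eval_x))
    for i, x0 in enumerate(np.asarray(eval_x, dtype=float)):
        d = np.abs(x - x0)
        nearest = np.argpartition(d, k - 1)[:k]
        dn = d[nearest]
        h = dn.max()
        if h == 0:
            out[i] = y[nearest].mean()
            continue
        w = (1.0 - (dn / h) ** 3) ** 3
        dx = x[nearest] - x0
        design = np.vander(dx, degree + 1, increasing=True)
        wd = design * w[:, None]
        beta, *_ = np.linalg.lstsq(wd.T @ design, wd.T @ y[nearest], rcond=None)
        out[i] = beta[0]
    return out


# ---------------------------------------------------------------------------
# Signature gene filtering


def filter_signature_genes(
    sig: GeneSignature,
    expr: ExpressionMatrix,
    exclusion_sets: Sequence[GeneSignature] = (),
    min_log2_mean: float = 6.0,
    *,
    span: float = 0.5,
    degree: int = 2,
    cov_on_linear: bool = True,
) -> GeneSignature:
    """Keep signature genes that are expressed and variable in the cohort.

    Genes in any exclusion set (e.g. immune signatures) are removed first.
    The log coefficient of variation is modelled against mean log2 expression
    across *all* genes of the matrix by local regression; signature genes are
    kept iff their COV residual is positive and their mean log2 expression
    exceeds ``min_log2_mean``.  ``cov_on_linear`` computes the COV on the
    un-logged scale before taking logs (the default interpretation).
    """
    if expr.scale is Scale.raw_counts:
        raise ValueError("filtering expects log-scale expression (vst_like)")
    excluded = set()
    for ex in exclusion_sets:
        excluded.update(ex.genes)
    genes = [g for g in sig.genes if g not in excluded]
    n_excluded = len(sig.genes) - len(genes)
    if n_excluded:
        logger.info("signature %s: %d genes removed by exclusion sets", sig.name, n_excluded)
    present = [g for g in genes if g in expr.gene_ids]
    if len(present) < len(genes):
        logger.warning(
            "signature %s: %d genes absent from expression matrix dropped",
            sig.name, len(genes) - len(present),
        )

    values = expr.values.to_numpy(dtype=float)
    mean_log2 = values.mean(axis=1)
    if cov_on_linear:
        linear = np.exp2(values)
        cov = linear.std(axis=1, ddof=1) / linear.mean(axis=1)
    else:
        mu = np.abs(mean_log2)
        cov = values.std(axis=1, ddof=1) / np.where(mu > 0, mu, np.nan)
    ok = np.isfinite(cov) & (cov > 0)
    if ok.sum() < 50:
        raise ValueError(f"only {int(ok.sum())} genes available to fit the COV trend (need >= 50)")
    log_cov = np.log(cov[ok])

    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    idx = np.array([gene_pos[g] for g in present])
    fitted = loess_fit(mean_log2[ok], log_cov, mean_log2[idx], span=span, degree=degree)
    with np.errstate(invalid="ignore"):
        residual = np.where(ok[idx], np.log(np.where(cov[idx] > 0, cov[idx], np.nan)) - fitted, -np.inf)
    keep = (residual > 0) & (mean_log2[idx] > min_log2_mean)
    kept = [g for g, k in zip(present, keep) if k]
    if not kept:
        raise ValueError(
            f"signature {sig.name}: no genes pass the filter "
            f"(residual>0: {int((residual > 0).sum())}, "
            f"mean>{min_log2_mean}: {int((mean_log2[idx] > min_log2_mean).sum())})"
        )
    logger.info("signature %s: %d/%d genes retained by expression filter",
                sig.name, len(kept), len(sig.genes))
    return GeneSignature(
        name=sig.name, genes=tuple(kept),
        provenance=f"{sig.provenance}|expression-filtered".lstrip("|"),
    )


def exclude_confounded_samples(
    expr: ExpressionMatrix,
    mutations: MutationAnnotation,
    allowed_driver: str = "KRAS",
) -> ExpressionMatrix:
    """Drop samples with RAS-pathway alterations other than the allowed driver.

    Non-KRAS pathway drivers (BRAF, EGFR, ...) can activate RAS signalling and
    would confound the KRAS-mutant enrichment readout; they are removed before
    clustering.  Without a pathway annotation this is the identity (warned).
    """
    if mutations.pathway_genes is None:
        logger.warning("no pathway gene set attached; no samples excluded")
        return expr
    confounded = mutations.pathway_altered_other_than(expr.sample_ids, allowed=allowed_driver)
    keep = expr.sample_ids[~confounded.to_numpy()]
    if len(keep) == 0:
        raise ValueError("all samples carry confounding pathway alterations")
    n_removed = expr.shape[1] - len(keep)
    if n_removed:
        logger.info("excluded %d samples with non-%s pathway alterations",
                    n_removed, allowed_driver)
    return expr.subset_samples(keep)


# ---------------------------------------------------------------------------
# Activity grouping


def cluster_activity_groups(
    expr: ExpressionMatrix, sig: GeneSignature, k: int
) -> ActivityGrouping:
    """Ward (D2) hierarchical clustering of samples on the signature genes.

    Samples are clustered on the signature-gene submatrix with Euclidean
    distance and Ward linkage; the dendrogram is cut into exactly ``k``
    clusters and labels assigned by ascending per-cluster mean signature
    expression (k=3: low/unclassified/high; k=5: RAG-0..RAG-4).  Ties in
    cluster means are broken by descending cluster size then lowest sample
    index.  The per-sample RAS index (mean signature expression) is attached.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    genes = sig.present_in(expr)
    if not genes:
        raise ValueError("no signature genes present in expression matrix")
    sub = expr.values.loc[list(genes)]
    n = sub.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    X = sub.to_numpy(dtype=float).T  # samples x genes
    Z = linkage(X, method="ward")
    assignment = fcluster(Z, t=k, criterion="maxclust")

    ri = pd.Series(X.mean(axis=1), index=sub.columns, name="RI")
    order = []
    for c in np.unique(assignment):
        members = np.flatnonzero(assignment == c)
        order.append((ri.iloc[members].mean(), -len(members), members.min(), c))
    order.sort()
    labels = rag_labels(k)
    label_of_cluster = {c: labels[rank] for rank, (_, _, _, c) in enumerate(order)}
    label_series = pd.Series(
        pd.Categorical(
            [label_of_cluster[c] for c in assignment], categories=labels, ordered=True
        ),
        index=sub.columns,
    )
    group_mean = ri.groupby(label_series, observed=False).mean().loc[list(labels)]
    return ActivityGrouping(labels=label_series, ri=ri, group_mean_ri=group_mean, k=k)


def grouping_from_labels(
    labels: pd.Series, expr: ExpressionMatrix, sig: GeneSignature, k: int
) -> ActivityGrouping:
    """Build an :class:`ActivityGrouping` from externally supplied labels.

    Used when labels come from a classifier or a planted design rather than
    from clustering.  Labels must use the ordered names for the given k and
    may violate the mean-ordering invariant only if expression is unrelated
    to the labels, in which case label names are re-ranked by group mean RI.
    """
    genes = sig.present_in(expr)
    sub = expr.values.loc[list(genes), labels.index]
    ri = pd.Series(sub.mean(axis=0), index=labels.index, name="RI")
    names = rag_labels(k)
    observed = [n for n in names if (labels == n).any()]
    means = {n: ri[labels == n].mean() for n in observed}
    remap = {old: names[rank] for rank, old in enumerate(sorted(observed, key=means.get))}
    # pad with unused labels so the categorical has exactly k categories
    relabelled = labels.map(remap)
    label_series = pd.Series(
        pd.Categorical(relabelled, categories=names, ordered=True), index=labels.index
    )
    group_mean = ri.groupby(label_series, observed=False).mean()
    group_mean = group_mean.loc[list(names)].ffill().fillna(ri.mean())
    group_mean = group_mean.cummax()  # enforce the ascending invariant on empty groups
    return ActivityGrouping(labels=label_series, ri=ri, group_mean_ri=group_mean, k=k)


# ---------------------------------------------------------------------------
# Signature evaluation


def evaluate_signature_chisq(
    grouping: ActivityGrouping,
    mutations: MutationAnnotation,
    driver: str = "KRAS",
) -> dict:
    """Pearson chi-square of driver mutation across the high vs low groups.

    Unclassified (intermediate) samples are excluded from the 2x2 table.  The
    test is run without continuity correction.  An empty margin raises with a
    suggestion to fall back to Fisher's exact test.
    """
    labels = grouping.labels
    extremes = labels.cat.categories[[0, -1]]
    mask = labels.isin(extremes)
    samples = labels.index[mask]
    mut = mutations.altered_mask(samples, driver)
    high = labels.loc[samples] == extremes[-1]
    table = np.array([
        [int((high & mut).sum()), int((high & ~mut).sum())],
        [int((~high & mut).sum()), int((~high & ~mut).sum())],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(
            "chi-square table has an empty margin; consider Fisher's exact test"
        )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "p": float(p), "table": table}


def glm_loglik_score(
    grouping: ActivityGrouping,
    mutations: MutationAnnotation,
    driver: str = "KRAS",
) -> float:
    """Maximized binomial log-likelihood of mutation status across groups.

    The GLM is saturated in the group factor, so the maximized log-likelihood
    has the closed form sum_g n_g [p_g log p_g + (1-p_g) log(1-p_g)] with the
    per-group mutation fractions plugged in.  Higher values mean better
    segregation of mutants by the grouping.  Unclassified samples (the
    intermediate k=3 group) are excluded, as in the chi-square evaluation.
    """
    labels = grouping.labels
    if "unclassified" in labels.cat.categories:
        mask = labels != "unclassified"
        labels = labels[mask]
        logger.info("GLM score: %d unclassified samples excluded", int((~mask).sum()))
    samples = labels.index
    mut = mutations.altered_mask(samples, driver).to_numpy()
    groups = labels.to_numpy()
    used = [g for g in labels.cat.categories if (groups == g).any()]
    if len(used) < 2:
        logger.warning("single group: returning null-model log-likelihood")
    ll = 0.0
    for g in used:
        m = mut[groups == g]
        n, s = len(m), int(m.sum())
        for count, prob in ((s, s / n), (n - s, 1 - s / n)):
            if count > 0:
                ll += count * np.log(prob)
    return float(ll)


# ---------------------------------------------------------------------------
# Moderated-t differential refinement


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(variances: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments scaled-inverse-chi-square prior on gene variances.

    Matches the mean and variance of log s^2 under the hierarchical model
    (log s^2 is a shifted log-F), returning the prior df d0 (may be inf) and
    prior variance s0^2.
    """
    z = np.log(variances[variances > 0])
    e_adjust = digamma(df / 2.0) - np.log(df / 2.0)
    excess = np.var(z, ddof=1) - polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(np.mean(z) - e_adjust))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = np.exp(np.mean(z) - e_adjust + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def moderated_t_table(
    values: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    *,
    shrink: bool = True,
) -> pd.DataFrame:
    """Per-gene moderated two-sample t between sample groups a (high) and b (low).

    Pooled per-gene variances are shrunk toward a signature-wide prior whose
    df and scale are estimated by method of moments; ``shrink=False`` gives
    the ordinary pooled-variance t (used as an oracle in tests).  Returns a
    frame with columns mean_high, mean_low, delta, t, p, fdr.
    """
    a = values.loc[:, list(group_a)].to_numpy(dtype=float)
    b = values.loc[:, list(group_b)].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    df = n1 + n2 - 2
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ss = (a - mean_a[:, None]) ** 2
    ss2 = (b - mean_b[:, None]) ** 2
    pooled_var = (ss.sum(axis=1) + ss2.sum(axis=1)) / df

    if shrink:
        d0, s0_sq = _fit_variance_prior(pooled_var, df)
        if np.isinf(d0):
            var_tilde = np.full_like(pooled_var, s0_sq)
            total_df = 1e6
        else:
            var_tilde = (d0 * s0_sq + df * pooled_var) / (d0 + df)
            total_df = d0 + df
    else:
        var_tilde = pooled_var
        total_df = df

    se = np.sqrt(var_tilde * (1.0 / n1 + 1.0 / n2))
    delta = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), min(total_df, 1e6))
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"mean_high": mean_a, "mean_low": mean_b, "delta": delta,
         "t": t, "p": p, "fdr": fdr},
        index=values.index,
    )


def refine_signature(
    sig: GeneSignature,
    grouping: ActivityGrouping,
    expr: ExpressionMatrix,
    fdr_threshold: float = 0.05,
    *,
    shrink: bool = True,
) -> tuple[GeneSignature, pd.DataFrame]:
    """Select signature genes driving the high/low split.

    Runs a moderated-t differential analysis of signature genes between the
    extreme (high vs low) activity groups and keeps genes with FDR below the
    threshold *and* higher mean in the high group.
    """
    labels = grouping.labels
    cats = labels.cat.categories
    high = labels.index[labels == cats[-1]]
    low = labels.index[labels == cats[0]]
    genes = sig.present_in(expr)
    stats_table = moderated_t_table(
        expr.values.loc[list(genes)], high, low, shrink=shrink
    )
    selected = stats_table.index[
        (stats_table["fdr"] < fdr_threshold) & (stats_table["delta"] > 0)
    ]
    if len(selected) == 0:
        raise ValueError(f"signature {sig.name}: no genes pass fdr<{fdr_threshold}")
    logger.info("signature %s: %d/%d genes retained by differential refinement",
                sig.name, len(selected), len(genes))
    refined = GeneSignature(
        name=f"{sig.name}_refined",
        genes=tuple(selected),
        provenance=f"{sig.provenance}|refined fdr<{fdr_threshold}".lstrip("|"),
    )
    return refined, stats_table


def build_meta_signature(
    refined_signatures: Sequence[GeneSignature], name: str = "meta"
) -> GeneSignature:
    """Union of refined signatures, ordered by first appearance.

    Per-gene provenance records which parent signatures contributed the gene
    (the parent-membership annotation of the derivation figure).
    """
    if not refined_signatures:
        raise ValueError("no refined signatures supplied")
    order: list[str] = []
    parents: dict[str, list[str]] = {}
    for sig in refined_signatures:
        for g in sig.genes:
            if g not in parents:
                order.append(g)
                parents[g] = []
            parents[g].append(sig.name)
    if not order:
        raise ValueError("union of refined signatures is empty")
    return GeneSignature(
        name=name,
        genes=tuple(order),
        provenance="merged:" + "+".join(s.name for s in refined_signatures),
        parents={g: tuple(p) for g, p in parents.items()},
    )


# ---------------------------------------------------------------------------
# End-to-end derivation


@dataclass
class DerivationResult:
    """Everything the derivation stage produces for one founder signature."""

    filtered: GeneSignature
    grouping: ActivityGrouping
    chi2: float
    chi2_p: float
    glm_loglik: float
    refined: GeneSignature
    gene_stats: pd.DataFrame


def derive_signature(
    sig: GeneSignature,
    expr: ExpressionMatrix,
    mutations: MutationAnnotation,
    *,
    exclusion_sets: Sequence[GeneSignature] = (),
    min_log2_mean: float = 6.0,
    fdr_threshold: float = 0.05,
    driver: str = "KRAS",
) -> DerivationResult:
    """Filter, cluster, evaluate and refine a single founder signature."""
    clean = exclude_confounded_samples(expr, mutations, allowed_driver=driver)
    filtered = filter_signature_genes(
        sig, clean, exclusion_sets=exclusion_sets, min_log2_mean=min_log2_mean
    )
    grouping = cluster_activity_groups(clean, filtered, k=3)
    chisq = evaluate_signature_chisq(grouping, mutations, driver=driver)
    loglik = glm_loglik_score(grouping, mutations, driver=driver)
    refined, gene_stats = refine_signature(
        filtered, grouping, clean, fdr_threshold=fdr_threshold
    )
    return DerivationResult(
        filtered=filtered,
        grouping=grouping,
        chi2=chisq["chi2"],
        chi2_p=chisq["p"],
        glm_loglik=loglik,
        refined=refined,
        gene_stats=gene_stats,
    )
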