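"""Signature filtering, activity clustering, evaluation and refinement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rasactivity import derive, normalize
from rasactivity.datamodel import (
    ActivityGrouping,
    ExpressionMatrix,
    GeneSignature,
    MutationAnnotation,
    Scale,
)


def make_grouping(labels_dict, ri_dict, k):
    from rasactivity.datamodel import rag_labels
    labels = pd.Series(labels_dict)
    ri = pd.Series(ri_dict)
    names = rag_labels(k)
    means = ri.groupby(labels).mean().reindex(names).ffill().bfill().cummax()
    return ActivityGrouping(labels=labels, ri=ri, group_mean_ri=means, k=k)


def mutations_from(mutant_samples, gene="KRAS", pathway=None):
    rows = [{"sample": s, "gene": gene, "altered": 1, "genotype": pd.NA}
            for s in mutant_samples]
    return MutationAnnotation(
        table=pd.DataFrame(rows, columns=["sample", "gene", "altered", "genotype"]),
        pathway_genes=pathway,
    )


class TestFilterSignatureGenes:
    def test_mean_floor_removes_low_expression_genes(self, vst_cohort, founder_signature):
        """Raising the mean floor removes genes regardless of their COV residual."""
        vst, _, truth = vst_cohort
        sig, _ = founder_signature
        default = derive.filter_signature_genes(sig, vst, min_log2_mean=6.0)
        strict = derive.filter_signature_genes(sig, vst, min_log2_mean=9.0)
        mean_log2 = vst.values.mean(axis=1)
        assert set(strict.genes) <= set(default.genes)
        assert all(mean_log2[g] > 9.0 for g in strict.genes)
        dropped = set(default.genes) - set(strict.genes)
        assert dropped and all(mean_log2[g] <= 9.0 for g in dropped)

    def test_exclusion_set_removed_before_fitting(self, vst_cohort, founder_signature):
        vst, _, _ = vst_cohort
        sig, _ = founder_signature
        immune = GeneSignature("immune", sig.genes[:5])
        filtered = derive.filter_signature_genes(sig, vst, exclusion_sets=[immune])
        assert not set(immune.genes) & set(filtered.genes)

    def test_planted_genes_retained_background_matches_residual_fraction(
        self, vst_cohort, founder_signature
    ):
        """Direct COV/mean recomputation: planted high-mean/high-COV genes survive."""
        vst, _, truth = vst_cohort
        sig, decoys = founder_signature
        filtered = derive.filter_signature_genes(sig, vst)
        planted_kept = len(set(truth.planted_genes) & set(filtered.genes))
        assert planted_kept / len(truth.planted_genes) >= 0.95
        # recompute the criteria directly for the decoys as an oracle
        vals = vst.values
        linear = np.exp2(vals)
        cov = linear.std(axis=1, ddof=1) / linear.mean(axis=1)
        mean_log2 = vals.mean(axis=1)
        fitted = derive.loess_fit(
            mean_log2.to_numpy(), np.log(cov.to_numpy()), mean_log2.loc[decoys].to_numpy()
        )
        expect = ((np.log(cov.loc[decoys].to_numpy()) - fitted > 0)
                  & (mean_log2.loc[decoys] > 6.0))
        got = [g in set(filtered.genes) for g in decoys]
        assert got == expect.tolist()

    def test_too_few_genes_to_fit_errors(self):
        values = pd.DataFrame(np.random.default_rng(0).normal(7, 1, (20, 10)),
                              index=[f"g{i}" for i in range(20)],
                              columns=[f"s{i}" for i in range(10)])
        expr = ExpressionMatrix(values, Scale.vst_like)
        with pytest.raises(ValueError, match="50"):
            derive.filter_signature_genes(GeneSignature("s", ("g0",)), expr)


class TestExcludeConfoundedSamples:
    def test_kras_only_kept_braf_removed(self, tiny_matrix):
        muts = MutationAnnotation(
            table=pd.DataFrame({
                "sample": ["s1", "s2"], "gene": ["KRAS", "BRAF"],
                "altered": [1, 1], "genotype": [pd.NA, pd.NA]}),
            pathway_genes=("KRAS", "BRAF", "EGFR"),
        )
        kept = derive.exclude_confounded_samples(tiny_matrix, muts)
        assert list(kept.sample_ids) == ["s1", "s3"]

    def test_no_pathway_annotation_is_identity(self, tiny_matrix, caplog):
        muts = mutations_from(["s1"])
        with caplog.at_level("WARNING"):
            kept = derive.exclude_confounded_samples(tiny_matrix, muts)
        assert list(kept.sample_ids) == ["s1", "s2", "s3"]

    def test_all_samples_confounded_errors(self, tiny_matrix):
        muts = MutationAnnotation(
            table=pd.DataFrame({
                "sample": ["s1", "s2", "s3"], "gene": ["BRAF"] * 3,
                "altered": [1, 1, 1], "genotype": [pd.NA] * 3}),
            pathway_genes=("KRAS", "BRAF"),
        )
        with pytest.raises(ValueError, match="all samples"):
            derive.exclude_confounded_samples(tiny_matrix, muts)


class TestClusterActivityGroups:
    def test_three_blobs_recovered_with_ordered_labels(self):
        rng = np.random.default_rng(0)
        centers = {"low": 0.0, "unclassified": 4.0, "high": 8.0}
        cols, truth = [], []
        for label, c in centers.items():
            for i in range(12):
                cols.append(c + rng.normal(0, 0.3, 10))
                truth.append(label)
        values = pd.DataFrame(np.array(cols).T,
                              index=[f"g{i}" for i in range(10)],
                              columns=[f"s{i}" for i in range(36)])
        expr = ExpressionMatrix(values, Scale.vst_like)
        sig = GeneSignature("s", tuple(values.index))
        grouping = derive.cluster_activity_groups(expr, sig, k=3)
        assert (grouping.labels.astype(str).to_numpy() == np.array(truth)).all()
        assert grouping.group_mean_ri.is_monotonic_increasing

    def test_k_must_be_at_least_two(self, tiny_matrix):
        sig = GeneSignature("s", ("g1", "g2"))
        with pytest.raises(ValueError, match="k"):
            derive.cluster_activity_groups(tiny_matrix, sig, k=1)

    def test_k_exceeding_samples_errors(self, tiny_matrix):
        sig = GeneSignature("s", ("g1", "g2"))
        with pytest.raises(ValueError, match="exceeds"):
            derive.cluster_activity_groups(tiny_matrix, sig, k=4)

    def test_duplicate_samples_land_together(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, (5, 8))
        base[:, 1] = base[:, 0]  # duplicate sample
        base[:, 4:] += 6.0
        values = pd.DataFrame(base, index=[f"g{i}" for i in range(5)],
                              columns=[f"s{i}" for i in range(8)])
        expr = ExpressionMatrix(values, Scale.vst_like)
        grouping = derive.cluster_activity_groups(
            expr, GeneSignature("s", tuple(values.index)), k=2)
        assert grouping.labels["s0"] == grouping.labels["s1"]

    def test_ri_equals_mean_signature_value(self, tiny_matrix):
        sig = GeneSignature("s", ("g1", "g2"))
        grouping = derive.cluster_activity_groups(tiny_matrix, sig, k=2)
        assert np.allclose(grouping.ri, tiny_matrix.values.mean(axis=0))


class TestEvaluateSignatureChisq:
    def test_perfect_separation_chi2_20(self):
        labels = {f"h{i}": "high" for i in range(10)} | {f"l{i}": "low" for i in range(10)}
        ri = {s: (2.0 if v == "high" else 1.0) for s, v in labels.items()}
        grouping = make_grouping(labels, ri, k=3)
        muts = mutations_from([f"h{i}" for i in range(10)])
        res = derive.evaluate_signature_chisq(grouping, muts)
        assert res["chi2"] == pytest.approx(20.0)
        assert res["p"] == pytest.approx(7.744e-6, rel=1e-3)

    def test_independence_gives_zero(self):
        labels = {f"h{i}": "high" for i in range(10)} | {f"l{i}": "low" for i in range(10)}
        ri = {s: (2.0 if v == "high" else 1.0) for s, v in labels.items()}
        grouping = make_grouping(labels, ri, k=3)
        muts = mutations_from([f"h{i}" for i in range(5)] + [f"l{i}" for i in range(5)])
        res = derive.evaluate_signature_chisq(grouping, muts)
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_unclassified_excluded_from_table(self):
        labels = ({f"h{i}": "high" for i in range(5)}
                  | {f"u{i}": "unclassified" for i in range(5)}
                  | {f"l{i}": "low" for i in range(5)})
        ri = {s: {"low": 1.0, "unclassified": 2.0, "high": 3.0}[v] for s, v in labels.items()}
        grouping = make_grouping(labels, ri, k=3)
        muts = mutations_from([f"h{i}" for i in range(5)] + [f"u{i}" for i in range(5)])
        res = derive.evaluate_signature_chisq(grouping, muts)
        assert res["table"].sum() == 10  # unclassified not counted

    def test_empty_margin_suggests_fisher(self):
        labels = {f"h{i}": "high" for i in range(4)} | {f"l{i}": "low" for i in range(4)}
        ri = {s: (2.0 if v == "high" else 1.0) for s, v in labels.items()}
        grouping = make_grouping(labels, ri, k=3)
        muts = mutations_from([])
        with pytest.raises(ValueError, match="Fisher"):
            derive.evaluate_signature_chisq(grouping, muts)


class TestGlmLoglik:
    def test_single_group_closed_form(self):
        labels = {f"s{i}": "high" for i in range(10)}
        grouping = make_grouping(labels, {f"s{i}": 1.0 for i in range(10)}, k=3)
        muts = mutations_from([f"s{i}" for i in range(5)])
        ll = derive.glm_loglik_score(grouping, muts)
        assert ll == pytest.approx(10 * np.log(0.5))

    def test_perfect_separation_loglik_zero(self):
        labels = {f"h{i}": "high" for i in range(6)} | {f"l{i}": "low" for i in range(6)}
        ri = {s: (2.0 if v == "high" else 1.0) for s, v in labels.items()}
        grouping = make_grouping(labels, ri, k=3)
        muts = mutations_from([f"h{i}" for i in range(6)])
        assert derive.glm_loglik_score(grouping, muts) == pytest.approx(0.0)

    def test_merging_groups_never_increases_loglik(self):
        rng = np.random.default_rng(3)
        n = 60
        samples = [f"s{i}" for i in range(n)]
        fine = ["RAG-0", "RAG-1", "RAG-2", "RAG-3", "RAG-4"] * (n // 5)
        muts = mutations_from([s for s, g in zip(samples, fine)
                               if rng.random() < {"RAG-0": 0.1, "RAG-1": 0.2, "RAG-2": 0.4,
                                                  "RAG-3": 0.6, "RAG-4": 0.9}[g]])
        ri5 = {s: float(g[-1]) for s, g in zip(samples, fine)}
        g5 = make_grouping(dict(zip(samples, fine)), ri5, k=5)
        coarse = {s: ("low" if g in ("RAG-0", "RAG-1") else "high" if g in ("RAG-3", "RAG-4")
                      else "unclassified") for s, g in zip(samples, fine)}
        # drop the unclassified to get a strictly coarser 2-way split of extremes
        keep = {s: v for s, v in coarse.items() if v != "unclassified"}
        g2 = make_grouping(keep, {s: ri5[s] for s in keep}, k=3)
        ll5 = derive.glm_loglik_score(g5, muts)
        # restrict the 5-group score to the same samples for a fair nesting
        fine_kept = {s: g for s, g in zip(samples, fine) if s in keep}
        g5_kept = make_grouping(fine_kept, {s: ri5[s] for s in keep}, k=5)
        assert derive.glm_loglik_score(g5_kept, muts) >= derive.glm_loglik_score(g2, muts) - 1e-12


@pytest.fixture(scope="module")
def refine_setup():
    rng = np.random.default_rng(4)
    n_per = 50
    samples = [f"h{i}" for i in range(n_per)] + [f"l{i}" for i in range(n_per)]
    planted = [f"p{i}" for i in range(40)]
    nulls = [f"n{i}" for i in range(160)]
    values = pd.DataFrame(rng.normal(8, 1, (200, 2 * n_per)),
                          index=planted + nulls, columns=samples)
    values.loc[planted, samples[:n_per]] += 2.0
    expr = ExpressionMatrix(values, Scale.vst_like)
    labels = {s: ("high" if s.startswith("h") else "low") for s in samples}
    ri = dict(values.mean(axis=0))
    grouping = make_grouping(labels, ri, k=3)
    sig = GeneSignature("s", tuple(values.index))
    return expr, grouping, sig, planted, nulls


class TestRefineSignature:
    def test_planted_recovery_and_false_inclusion(self, refine_setup):
        expr, grouping, sig, planted, nulls = refine_setup
        refined, table = derive.refine_signature(sig, grouping, expr)
        got = set(refined.genes)
        assert len(got & set(planted)) / len(planted) >= 0.95
        assert len(got & set(nulls)) <= 0.05 * len(nulls)
        assert ((table["fdr"] >= 0) & (table["fdr"] <= 1)).all()

    def test_identical_gene_excluded_with_t_zero(self, refine_setup):
        expr, grouping, sig, *_ = refine_setup
        values = expr.values.copy()
        values.loc["flat"] = 5.0
        expr2 = ExpressionMatrix(values, Scale.vst_like)
        sig2 = GeneSignature("s", tuple(values.index))
        refined, table = derive.refine_signature(sig2, grouping, expr2)
        assert "flat" not in refined.genes
        assert table.loc["flat", "t"] == 0.0

    def test_no_shrinkage_equals_plain_pooled_t(self, refine_setup):
        """With the prior disabled the statistic is the ordinary two-sample t."""
        expr, grouping, sig, *_ = refine_setup
        high = grouping.samples_with("high")
        low = grouping.samples_with("low")
        table = derive.moderated_t_table(expr.values, high, low, shrink=False)
        for gene in list(expr.gene_ids)[:20]:
            t, p = stats.ttest_ind(expr.values.loc[gene, high],
                                   expr.values.loc[gene, low])
            assert table.loc[gene, "t"] == pytest.approx(t, rel=1e-10)
            assert table.loc[gene, "p"] == pytest.approx(p, rel=1e-10)

    def test_group_smaller_than_two_errors(self, refine_setup):
        expr, _, sig, *_ = refine_setup
        labels = {s: ("high" if i == 0 else "low") for i, s in enumerate(expr.sample_ids)}
        ri = {s: float(i) for i, s in enumerate(expr.sample_ids)}
        grouping = make_grouping(labels, ri, k=3)
        with pytest.raises(ValueError, match=">= 2"):
            derive.refine_signature(sig, grouping, expr)


class TestBuildMetaSignature:
    def test_union_preserves_first_appearance_and_parents(self):
        a = GeneSignature("A", ("x", "y"))
        b = GeneSignature("B", ("y", "z"))
        meta = derive.build_meta_signature([a, b])
        assert meta.genes == ("x", "y", "z")
        assert meta.parents["y"] == ("A", "B")

    def test_single_input_identity(self):
        a = GeneSignature("A", ("x", "y"))
        meta = derive.build_meta_signature([a])
        assert meta.genes == a.genes

    def test_disjoint_sizes_add(self):
        a = GeneSignature("A", ("a1", "a2", "a3"))
        b = GeneSignature("B", ("b1", "b2", "b3", "b4"))
        assert len(derive.build_meta_signature([a, b])) == 7

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            derive.build_meta_signature([])


def test_chisq_and_glm_agree_on_nested_separations():
    """Strictly better mutant segregation raises both chi-square and GLM score."""
    n = 40
    samples = [f"s{i}" for i in range(2 * n)]
    labels = {s: ("high" if i < n else "low") for i, s in enumerate(samples)}
    ri = {s: (2.0 if v == "high" else 1.0) for s, v in labels.items()}
    grouping = make_grouping(labels, ri, k=3)
    prev_chi2, prev_ll = -np.inf, -np.inf
    for n_high_mut, n_low_mut in [(24, 16), (32, 8), (40, 0)]:
        muts = mutations_from([f"s{i}" for i in range(n_high_mut)]
                              + [f"s{i}" for i in range(n, n + n_low_mut)])
        chi2 = derive.evaluate_signature_chisq(grouping, muts)["chi2"]
        ll = derive.glm_loglik_score(grouping, muts)
        assert chi2 > prev_chi2 and ll > prev_ll
        prev_chi2, prev_ll = chi2, ll
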