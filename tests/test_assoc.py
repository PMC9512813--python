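"""Association scans: variants, drugs, target categories, RI vs mutation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rasactivity import assoc, simulate
from rasactivity.datamodel import (
    ActivityGrouping,
    ExpressionMatrix,
    GeneSignature,
    MutationAnnotation,
    Scale,
    rag_labels,
)


def grouping_of(label_list, samples=None, k=5):
    samples = samples or [f"s{i}" for i in range(len(label_list))]
    labels = pd.Series(label_list, index=samples)
    ri = pd.Series([float(rag_labels(k).index(l)) for l in label_list], index=samples)
    means = ri.groupby(labels).mean().reindex(rag_labels(k)).ffill().bfill().cummax()
    return ActivityGrouping(labels=labels, ri=ri, group_mean_ri=means, k=k)


def mutation_table(rows):
    return MutationAnnotation(
        table=pd.DataFrame(rows, columns=["sample", "gene", "altered", "genotype"])
    )


class TestVariantRagScan:
    def test_carrier_floor_is_strict(self):
        grouping = grouping_of([rag_labels(5)[i % 5] for i in range(100)])
        rows = [{"sample": f"s{i}", "gene": "RARE", "altered": 1, "genotype": pd.NA}
                for i in range(8)]
        result = assoc.variant_rag_scan(mutation_table(rows), grouping, min_carriers=10)
        assert result.empty

    def test_uniform_variant_not_flagged(self):
        grouping = grouping_of([rag_labels(5)[i % 5] for i in range(200)])
        rows = [{"sample": f"s{i}", "gene": "EVEN", "altered": 1, "genotype": pd.NA}
                for i in range(0, 200, 4)]  # 25% in every group
        result = assoc.variant_rag_scan(mutation_table(rows), grouping)
        assert not result["flagged"].any()
        assert result["p"].iloc[0] > 0.5

    def test_confined_variant_flagged_matches_direct_chi2(self):
        """Variant confined to one of five equal groups: flagged, chi2 verified."""
        n = 500
        labels = [rag_labels(5)[i % 5] for i in range(n)]
        grouping = grouping_of(labels)
        carriers = [f"s{i}" for i in range(n) if labels[i] == "RAG-4"][:20]
        rows = [{"sample": s, "gene": "DRV", "altered": 1, "genotype": pd.NA}
                for s in carriers]
        result = assoc.variant_rag_scan(mutation_table(rows), grouping)
        assert result.loc[result.feature == "DRV", "flagged"].iloc[0]
        # direct oracle
        mask = np.isin([f"s{i}" for i in range(n)], carriers)
        table = pd.crosstab(pd.Series(labels), pd.Series(mask))
        chi2, p, *_ = stats.chi2_contingency(table.to_numpy(), correction=False)
        assert result.loc[result.feature == "DRV", "chi2"].iloc[0] == pytest.approx(chi2)


class TestGenotypeVsRest:
    def test_universal_genotype_degenerate(self):
        grouping = grouping_of(["low"] * 5 + ["high"] * 5, k=2)
        rows = [{"sample": f"s{i}", "gene": "KRAS", "altered": 1, "genotype": "G12D"}
                for i in range(10)]
        with pytest.raises(ValueError, match="degenerate"):
            assoc.genotype_vs_rest_test(mutation_table(rows), grouping, "G12D")

    def test_zero_carriers_error(self):
        grouping = grouping_of(["low"] * 5 + ["high"] * 5, k=2)
        with pytest.raises(ValueError, match="no carriers"):
            assoc.genotype_vs_rest_test(mutation_table([]), grouping, "G12D")

    def test_single_carrier_low_power_warning(self, caplog):
        grouping = grouping_of(["low"] * 10 + ["high"] * 10, k=2)
        rows = [{"sample": "s0", "gene": "KRAS", "altered": 1, "genotype": "G12C"}]
        with caplog.at_level("WARNING"):
            res = assoc.genotype_vs_rest_test(mutation_table(rows), grouping, "G12C")
        assert res["p"] > 0.3
        assert any("low-powered" in r.message for r in caplog.records)

    def test_null_p_uniform_under_permutation(self):
        """Genotype independent of groups: permutation p-values are uniform."""
        rng = np.random.default_rng(6)
        n = 500
        labels = [rag_labels(5)[i % 5] for i in range(n)]
        pvals = []
        for rep in range(200):
            carriers = rng.choice(n, 150, replace=False)
            rows = [{"sample": f"s{i}", "gene": "KRAS", "altered": 1, "genotype": "G12V"}
                    for i in carriers]
            grouping = grouping_of(labels)
            pvals.append(
                assoc.genotype_vs_rest_test(mutation_table(rows), grouping, "G12V")["p"]
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestGroupwiseLinearAssoc:
    def test_flat_feature_not_flagged(self):
        group = pd.Series(["low"] * 10 + ["high"] * 10,
                          index=[f"s{i}" for i in range(20)])
        values = pd.DataFrame({f"s{i}": [5.0] for i in range(20)}, index=["flat"])
        res = assoc.groupwise_linear_assoc(values, group, reference_group="low")
        assert res["effect"].iloc[0] == pytest.approx(0.0)
        assert not res["flagged"].any()

    def test_planted_shift_flagged_with_sign(self, drug_cohort):
        table, dtruth, state = drug_cohort
        res = assoc.groupwise_linear_assoc(
            table.values.T, state, reference_group="low", abs_effect_threshold=1.0
        )
        flagged = set(res.loc[res.flagged, "feature"])
        assert set(dtruth.shifted_drugs) <= flagged
        effects = res.set_index("feature").loc[list(dtruth.shifted_drugs), "effect"]
        assert (effects < -1).all()  # sensitivity: lower IC50 in the high group

    def test_mutation_confounded_shift_absorbed_by_covariate(self):
        """A shift fully attributable to KRAS leaves the group coefficient ~0."""
        rng = np.random.default_rng(8)
        n = 400
        samples = [f"s{i}" for i in range(n)]
        kras = rng.random(n) < 0.5
        # group correlates with mutation but the response depends only on KRAS
        group = np.where(kras & (rng.random(n) < 0.9), "high",
                         np.where(rng.random(n) < 0.5, "high", "low"))
        y = 2.0 * kras + rng.normal(0, 0.3, n)
        values = pd.DataFrame([y], index=["drug"], columns=samples)
        covs = pd.DataFrame({"kras": kras.astype(float)}, index=samples)
        res = assoc.groupwise_linear_assoc(
            values, pd.Series(group, index=samples), covariates=covs,
            reference_group="low",
        )
        assert abs(res["effect"].iloc[0]) < 0.15
        # closed-form OLS oracle on the same design
        X = np.c_[np.ones(n), group == "high", kras.astype(float)]
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert res["effect"].iloc[0] == pytest.approx(beta[1], abs=1e-10)

    def test_confounded_design_yields_na(self, caplog):
        samples = [f"s{i}" for i in range(10)]
        group = pd.Series(["low"] * 5 + ["high"] * 5, index=samples)
        covs = pd.DataFrame({"same": [0.0] * 5 + [1.0] * 5}, index=samples)
        values = pd.DataFrame([np.arange(10.0)], index=["d"], columns=samples)
        with caplog.at_level("WARNING"):
            res = assoc.groupwise_linear_assoc(values, group, covariates=covs)
        assert res["effect"].isna().all()
        assert any("rank-deficient" in r.message for r in caplog.records)

    def test_missing_values_excluded_per_feature(self):
        samples = [f"s{i}" for i in range(30)]
        group = pd.Series(["low"] * 15 + ["high"] * 15, index=samples)
        rng = np.random.default_rng(2)
        y = np.r_[rng.normal(0, 1, 15), rng.normal(3, 1, 15)]
        y_missing = y.copy()
        y_missing[:3] = np.nan
        values = pd.DataFrame([y, y_missing], index=["full", "gappy"], columns=samples)
        res = assoc.groupwise_linear_assoc(values, group, reference_group="low")
        assert res["p"].notna().all()


class TestHypergeometricEnrichment:
    def test_exact_combinatorial_example(self):
        """Universe 10, category 5, all 5 flagged in category: p = 1/252."""
        tested = [f"d{i}" for i in range(10)]
        target_map = {d: ("CAT",) if i < 5 else ("OTHER",) for i, d in enumerate(tested)}
        res = assoc.hypergeometric_target_enrichment(tested[:5], tested, target_map)
        p_cat = res.set_index("category").loc["CAT", "p"]
        assert p_cat == pytest.approx(1 / 252)

    def test_absent_category_p_near_one(self):
        tested = [f"d{i}" for i in range(20)]
        target_map = {d: ("RARE",) if i == 19 else ("COMMON",) for i, d in enumerate(tested)}
        res = assoc.hypergeometric_target_enrichment(tested[:5], tested, target_map)
        assert res.set_index("category").loc["RARE", "p"] == pytest.approx(1.0, abs=0.3)
        assert res.set_index("category").loc["RARE", "k"] == 0

    def test_saturated_flagging_all_p_one(self):
        tested = [f"d{i}" for i in range(12)]
        target_map = {d: (f"C{i % 3}",) for i, d in enumerate(tested)}
        res = assoc.hypergeometric_target_enrichment(tested, tested, target_map)
        assert np.allclose(res["p"], 1.0)

    def test_empty_flagged_set_warns(self, caplog):
        with caplog.at_level("WARNING"):
            res = assoc.hypergeometric_target_enrichment([], ["d1"], {"d1": ("C",)})
        assert res.empty

    def test_flagged_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            assoc.hypergeometric_target_enrichment(["x"], ["d1"], {})


@pytest.fixture(scope="module")
def driver_setup():
    n_per = 12
    labels = [l for l in rag_labels(5) for _ in range(n_per)]
    samples = [f"s{i}" for i in range(5 * n_per)]
    rng = np.random.default_rng(10)
    values = pd.DataFrame(rng.normal(0, 0.05, (4, 5 * n_per)),
                          index=["flat", "rag4_up", "twin_a", "twin_b"],
                          columns=samples)
    rag4 = [s for s, l in zip(samples, labels) if l == "RAG-4"]
    values.loc["rag4_up", rag4] += 1.5
    profile = np.repeat([0.0, 0.5, 1.0, 1.5, 2.0], n_per)
    values.loc["twin_a"] += profile
    values.loc["twin_b"] += profile
    expr = ExpressionMatrix(values, Scale.vst_like)
    grouping = grouping_of(labels, samples=samples)
    sig = GeneSignature("s", tuple(values.index))
    return expr, grouping, sig


class TestRagDriverGenes:
    def test_flat_gene_excluded(self, driver_setup):
        expr, grouping, sig = driver_setup
        deviations, clusters = assoc.rag_driver_genes(expr, sig, grouping)
        assert "flat" not in clusters.index
        assert abs(deviations.loc["flat"]).max() < 0.5

    def test_rag4_elevated_gene_selected(self, driver_setup):
        expr, grouping, sig = driver_setup
        _, clusters = assoc.rag_driver_genes(expr, sig, grouping)
        assert "rag4_up" in clusters.index

    def test_identical_profiles_cluster_together(self, driver_setup):
        expr, grouping, sig = driver_setup
        _, clusters = assoc.rag_driver_genes(expr, sig, grouping)
        assert clusters["twin_a"] == clusters["twin_b"]


class TestRiMutationAssociation:
    def test_small_cohort_excluded(self):
        ri = pd.Series(np.arange(20.0), index=[f"s{i}" for i in range(20)])
        cohorts = pd.Series(["A"] * 10 + ["B"] * 10, index=ri.index)
        rows = [{"sample": f"s{i}", "gene": "KRAS", "altered": 1, "genotype": pd.NA}
                for i in range(4)]  # 4 mutants in A, none in B
        res = assoc.ri_mutation_association(ri, mutation_table(rows), cohorts)
        assert res.empty

    def test_identical_distributions_p_near_one(self):
        rng = np.random.default_rng(3)
        n = 100
        ri = pd.Series(rng.normal(0, 1, n), index=[f"s{i}" for i in range(n)])
        cohorts = pd.Series(["A"] * n, index=ri.index)
        rows = [{"sample": f"s{i}", "gene": "NRAS", "altered": 1, "genotype": pd.NA}
                for i in rng.choice(n, 30, replace=False)]
        res = assoc.ri_mutation_association(ri, mutation_table(rows), cohorts)
        assert res["p"].iloc[0] > 0.05

    def test_planted_shift_flagged_positive_matches_ranksum_oracle(self):
        rng = np.random.default_rng(4)
        n_mut, n_wt = 100, 50
        samples = [f"s{i}" for i in range(n_mut + n_wt)]
        ri = pd.Series(np.r_[rng.normal(1, 1, n_mut), rng.normal(0, 1, n_wt)],
                       index=samples)
        cohorts = pd.Series(["A"] * (n_mut + n_wt), index=samples)
        rows = [{"sample": s, "gene": "KRAS", "altered": 1, "genotype": pd.NA}
                for s in samples[:n_mut]]
        res = assoc.ri_mutation_association(ri, mutation_table(rows), cohorts)
        assert res["flagged"].iloc[0] and res["effect"].iloc[0] > 0
        stat, p = stats.mannwhitneyu(ri[samples[:n_mut]], ri[samples[n_mut:]],
                                     alternative="two-sided")
        assert res["p"].iloc[0] == pytest.approx(p)


def test_bh_matches_brute_force_definition():
    """BH equals sorted p*m/i with a cumulative minimum, on random vectors."""
    rng = np.random.default_rng(12)
    for _ in range(50):
        m = int(rng.integers(1, 40))
        p = rng.random(m)
        got = assoc.bh_adjust(p)
        order = np.argsort(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(adj, 1.0)
        assert np.allclose(got, expect)


@pytest.fixture(scope="module")
def drug_cohort():
    _, _, truth = simulate.generate_cell_line_cohort(
        n_samples=120, n_genes=60, n_signature_genes=10, seed=21
    )
    table, dtruth = simulate.generate_drug_response(
        truth, n_drugs=80, n_shifted=8, shift=2.0, seed=21
    )
    return table, dtruth, truth.activity_state
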