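"""Synthetic cohorts with planted ground truth.

Each generator plants the latent structure the corresponding analysis stage
assumes and returns a :class:`SyntheticTruth` describing exactly what was
planted, so that recovery can be scored against construction rather than
against external data.

The statistical models:

* **Cell-line cohorts** -- negative-binomial counts (log-normal per-gene base
  abundance, configurable dispersion) with a latent two-state RAS-activity
  factor; planted signature genes shift by ``effect_size`` log2 units in
  high-activity samples.  Driver-mutation probability follows a logistic
  model on the activity state, so the planted odds ratio is exact by
  construction.
* **Tumor cohorts** -- a continuous latent activity index drives both planted
  gene expression and an exponential survival time with hazard
  ``lambda0 * exp(log_hr * index)``; censoring is independent exponential.
* **Multi-region cohorts** -- per-gene values decompose into patient
  (inter-tumour) and region (intra-tumour) variance components, each drawn
  from a low/high class, so quadrant enrichment of a planted gene subset is
  known in advance.
* **Drug response** -- normal log-IC50 noise with planted activity-dependent
  shifts concentrated in one target category and an optional mutation-driven
  confound.

One seed governs a cohort; sub-streams per component are derived
deterministically from it via :class:`numpy.random.SeedSequence` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DrugResponseTable,
    ExpressionMatrix,
    MultiRegionCohort,
    MutationAnnotation,
    Scale,
    SurvivalTable,
)

#: RAS-pathway driver genes whose alteration can confound KRAS-centric
#: analyses (upstream RTKs and parallel RAS-pathway members), plus KRAS.
RAS_PATHWAY_GENES = (
    "KRAS", "BRAF", "EGFR", "ERBB2", "FGFR1", "FGFR2", "FGFR3",
    "HRAS", "JAK2", "KIT", "NRAS", "RET",
)


@dataclass
class SyntheticTruth:
    """What a generator planted, recorded for oracle-based scoring."""

    seed: int
    planted_genes: tuple[str, ...] = ()
    sample_ids: tuple[str, ...] = ()
    activity_state: pd.Series | None = None  # "high"/"low" per sample
    activity_index: pd.Series | None = None  # continuous latent index
    effect_size: float = 0.0
    mutation_or: float | None = None
    planted_log_hr: float | None = None
    gene_classes: pd.DataFrame | None = None  # multi-region variance classes
    shifted_drugs: tuple[str, ...] = ()
    planted_category: str | None = None
    extras: dict = field(default_factory=dict)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws parameterized by mean and dispersion alpha.

    var = mean + alpha * mean**2; alpha -> 0 recovers Poisson.
    """
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_cell_line_cohort(
    n_samples: int = 150,
    n_genes: int = 5000,
    n_signature_genes: int = 200,
    effect_size: float = 2.0,
    mutation_or: float = 10.0,
    seed: int = 0,
    *,
    p_high: float = 0.5,
    p_mut_low: float = 0.15,
    pathway_mut_rate: float = 0.1,
    dispersion: float = 0.15,
    library_size_sd: float = 0.2,
    activity_sd: float | None = None,
    intermediate_fraction: float = 0.2,
    planted_log2_mean_range: tuple[float, float] = (7.0, 10.0),
    background_log2_mean_range: tuple[float, float] = (2.0, 10.0),
) -> tuple[ExpressionMatrix, MutationAnnotation, SyntheticTruth]:
    """Cell-line cohort with a latent two-state RAS-activity factor.

    Planted signature genes gain ``effect_size`` log2 units of mean expression
    in high-activity samples; KRAS mutation odds are ``mutation_or``-fold
    higher in the high state; ``pathway_mut_rate`` of samples additionally
    carry a non-KRAS RAS-pathway alteration (independent of state) to
    exercise the confounder-exclusion logic.

    Real cohorts show graded pathway activity, not two point clouds: an
    ``intermediate_fraction`` of samples expresses the planted genes at half
    the effect size (the population the three-way grouping labels
    "unclassified"), and every sample carries ``activity_sd`` of within-state
    dispersion (default a tenth of the effect size, so a null effect stays
    exactly null).  Mutation odds depend only on the binary state, keeping
    the planted odds ratio exact by construction.
    """
    if n_signature_genes >= n_genes:
        raise ValueError("n_signature_genes must be < n_genes")
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if mutation_or <= 0:
        raise ValueError("mutation odds ratio must be > 0")

    r_state, r_mean, r_counts, r_mut, r_path, r_lib = _streams(seed, 6)

    samples = [f"CL{i:04d}" for i in range(n_samples)]
    planted = [f"SIG{i:04d}" for i in range(n_signature_genes)]
    background = [f"BG{i:05d}" for i in range(n_genes - n_signature_genes)]
    genes = planted + background

    state = r_state.random(n_samples) < p_high  # True = high activity
    if activity_sd is None:
        activity_sd = 0.1 * effect_size
    intermediate = r_state.random(n_samples) < intermediate_fraction
    activity_level = effect_size * state.astype(float)
    activity_level[intermediate] = 0.5 * effect_size
    activity_level += activity_sd * r_state.standard_normal(n_samples)

    log2_mean = np.empty(n_genes)
    log2_mean[: len(planted)] = r_mean.uniform(*planted_log2_mean_range, len(planted))
    log2_mean[len(planted):] = r_mean.uniform(*background_log2_mean_range, len(background))

    shift = np.zeros((n_genes, n_samples))
    shift[: len(planted), :] = activity_level[None, :]
    mu = 2.0 ** (log2_mean[:, None] + shift)
    lib = np.exp(r_lib.normal(0.0, library_size_sd, n_samples))
    counts = _nb_counts(r_counts, mu * lib[None, :], dispersion).astype(float)

    expr = ExpressionMatrix(
        values=pd.DataFrame(counts, index=genes, columns=samples),
        scale=Scale.raw_counts,
    )

    odds_low = p_mut_low / (1.0 - p_mut_low)
    p_mut = np.where(
        state, mutation_or * odds_low / (1.0 + mutation_or * odds_low), p_mut_low
    )
    kras_mut = r_mut.random(n_samples) < p_mut

    rows = [
        {"sample": s, "gene": "KRAS", "altered": 1, "genotype": "G12D"}
        for s, m in zip(samples, kras_mut) if m
    ]
    other_pathway = [g for g in RAS_PATHWAY_GENES if g != "KRAS"]
    pathway_hit = r_path.random(n_samples) < pathway_mut_rate
    for s, hit in zip(samples, pathway_hit):
        if hit:
            gene = other_pathway[int(r_path.integers(len(other_pathway)))]
            rows.append({"sample": s, "gene": gene, "altered": 1, "genotype": pd.NA})
    mutations = MutationAnnotation(
        table=pd.DataFrame(rows, columns=["sample", "gene", "altered", "genotype"]),
        pathway_genes=RAS_PATHWAY_GENES,
    )

    truth = SyntheticTruth(
        seed=seed,
        planted_genes=tuple(planted),
        sample_ids=tuple(samples),
        activity_state=pd.Series(np.where(state, "high", "low"), index=samples),
        activity_index=pd.Series(activity_level, index=samples),
        effect_size=effect_size,
        mutation_or=mutation_or,
        extras={"kras_mutant": pd.Series(kras_mut, index=samples),
                "pathway_confounded": pd.Series(pathway_hit, index=samples),
                "intermediate": pd.Series(intermediate, index=samples),
                "activity_sd": activity_sd},
    )
    return expr, mutations, truth


def generate_tumor_cohort(
    n_samples: int = 300,
    n_genes: int = 2000,
    n_signature_genes: int = 100,
    effect_size: float = 1.0,
    planted_log_hr: float = float(np.log(2.0)),
    censor_rate: float = 0.3,
    seed: int = 0,
    *,
    hazard_covariate: str = "index",
    baseline_hazard: float = 1.0 / 1000.0,
    mutation_or: float = 4.0,
    p_mut_low: float = 0.15,
    dispersion: float = 0.15,
) -> tuple[ExpressionMatrix, MutationAnnotation, SurvivalTable, SyntheticTruth]:
    """Tumor cohort with a continuous latent activity index driving survival.

    Survival times are exponential with hazard
    ``baseline_hazard * exp(planted_log_hr * z)`` where ``z`` is the standard
    normal activity index (``hazard_covariate="index"``) or the 0/1 KRAS
    mutation indicator (``hazard_covariate="mutation"``).  Censoring is
    independent exponential, calibrated so the expected censored fraction is
    approximately ``censor_rate``.
    """
    if not np.isfinite(planted_log_hr):
        raise ValueError("planted_log_hr must be finite")
    if not (0.0 <= censor_rate < 1.0):
        raise ValueError("censor_rate must be in [0, 1)")
    if hazard_covariate not in ("index", "mutation"):
        raise ValueError("hazard_covariate must be 'index' or 'mutation'")

    r_idx, r_counts, r_mut, r_surv, r_cens, r_cov = _streams(seed, 6)

    samples = [f"T{i:04d}" for i in range(n_samples)]
    planted = [f"SIG{i:04d}" for i in range(n_signature_genes)]
    background = [f"BG{i:05d}" for i in range(n_genes - n_signature_genes)]
    genes = planted + background

    index = r_idx.standard_normal(n_samples)

    log2_mean = np.concatenate([
        r_counts.uniform(6.0, 10.0, len(planted)),
        r_counts.uniform(2.0, 10.0, len(background)),
    ])
    shift = np.zeros((n_genes, n_samples))
    shift[: len(planted), :] = effect_size * index[None, :]
    mu = 2.0 ** (log2_mean[:, None] + shift)
    counts = _nb_counts(r_counts, mu, dispersion).astype(float)
    expr = ExpressionMatrix(
        values=pd.DataFrame(counts, index=genes, columns=samples),
        scale=Scale.raw_counts,
    )

    odds_low = p_mut_low / (1.0 - p_mut_low)
    p_mut = np.where(
        index > 0, mutation_or * odds_low / (1.0 + mutation_or * odds_low), p_mut_low
    )
    kras_mut = r_mut.random(n_samples) < p_mut
    mutations = MutationAnnotation(
        table=pd.DataFrame(
            [{"sample": s, "gene": "KRAS", "altered": 1, "genotype": "G12C"}
             for s, m in zip(samples, kras_mut) if m],
            columns=["sample", "gene", "altered", "genotype"],
        ),
        pathway_genes=RAS_PATHWAY_GENES,
    )

    z = index if hazard_covariate == "index" else kras_mut.astype(float)
    hazard = baseline_hazard * np.exp(planted_log_hr * z)
    event_time = r_surv.exponential(1.0 / hazard)
    if censor_rate > 0:
        mu_c = baseline_hazard * censor_rate / (1.0 - censor_rate)
        censor_time = r_cens.exponential(1.0 / mu_c, n_samples)
    else:
        censor_time = np.full(n_samples, np.inf)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    age = r_cov.normal(66.0, 9.0, n_samples)
    stage = r_cov.choice(["I", "II", "III", "IV"], n_samples, p=[0.5, 0.25, 0.17, 0.08])
    sex = r_cov.choice(["F", "M"], n_samples)
    survival = SurvivalTable(
        data=pd.DataFrame(
            {
                "time": np.maximum(time, 1e-3),
                "event": event.astype(int),
                "activity_index": index,
                "kras_mut": kras_mut.astype(int),
                "age": age,
                "stage": stage,
                "sex": sex,
            },
            index=samples,
        )
    )

    truth = SyntheticTruth(
        seed=seed,
        planted_genes=tuple(planted),
        sample_ids=tuple(samples),
        activity_index=pd.Series(index, index=samples),
        effect_size=effect_size,
        mutation_or=mutation_or,
        planted_log_hr=planted_log_hr,
        extras={"hazard_covariate": hazard_covariate,
                "kras_mutant": pd.Series(kras_mut, index=samples)},
    )
    return expr, mutations, survival, truth


def generate_multiregion_cohort(
    n_patients: int = 40,
    regions_per_patient: int = 3,
    sigma_intra: float = 1.2,
    sigma_inter: float = 1.5,
    seed: int = 0,
    *,
    n_genes: int = 2000,
    n_signature_genes: int = 100,
    low_sigma_factor: float = 0.25,
    clonal_signature_fraction: float = 0.75,
    noise_sd: float = 0.1,
) -> tuple[ExpressionMatrix, MultiRegionCohort, SyntheticTruth]:
    """Multi-region cohort with planted intra-/inter-tumour variance classes.

    Each gene draws a low/high class independently for its intra-tumour
    (region) and inter-tumour (patient) variance components; "low" scales the
    corresponding sigma by ``low_sigma_factor``.  A planted signature takes
    ``clonal_signature_fraction`` of its genes from the low-intra/high-inter
    quadrant -- the clonal-expression pattern -- and the rest uniformly from
    the other quadrants, so the expected quadrant-enrichment fold is known.
    """
    if sigma_intra < 0 or sigma_inter < 0:
        raise ValueError("sigma components must be >= 0")
    if regions_per_patient < 1:
        raise ValueError("regions_per_patient must be >= 1")

    r_cls, r_pat, r_reg, r_noise, r_sig = _streams(seed, 5)

    genes = [f"G{i:05d}" for i in range(n_genes)]
    patients = [f"P{i:03d}" for i in range(n_patients)]
    regions = {
        p: tuple(f"{p}_R{j}" for j in range(regions_per_patient)) for p in patients
    }
    samples = [s for p in patients for s in regions[p]]

    intra_high = r_cls.random(n_genes) < 0.5
    inter_high = r_cls.random(n_genes) < 0.5
    sd_intra = np.where(intra_high, sigma_intra, low_sigma_factor * sigma_intra)
    sd_inter = np.where(inter_high, sigma_inter, low_sigma_factor * sigma_inter)

    base = r_pat.uniform(5.0, 10.0, n_genes)
    patient_eff = r_pat.standard_normal((n_genes, n_patients)) * sd_inter[:, None]
    values = np.empty((n_genes, len(samples)))
    col = 0
    for pi in range(n_patients):
        region_eff = r_reg.standard_normal((n_genes, regions_per_patient)) * sd_intra[:, None]
        block = base[:, None] + patient_eff[:, [pi]] + region_eff
        values[:, col: col + regions_per_patient] = block
        col += regions_per_patient
    values += r_noise.standard_normal(values.shape) * noise_sd

    quadrant4 = ~intra_high & inter_high  # low intra, high inter: clonal-like
    idx_q4 = np.flatnonzero(quadrant4)
    idx_other = np.flatnonzero(~quadrant4)
    n_clonal = int(round(clonal_signature_fraction * n_signature_genes))
    n_clonal = min(n_clonal, len(idx_q4))
    pick_q4 = r_sig.choice(idx_q4, n_clonal, replace=False)
    pick_other = r_sig.choice(idx_other, n_signature_genes - n_clonal, replace=False)
    signature_idx = np.sort(np.concatenate([pick_q4, pick_other]))
    signature_genes = tuple(genes[i] for i in signature_idx)

    gene_classes = pd.DataFrame(
        {
            "low_intra": ~intra_high,
            "high_inter": inter_high,
            "sd_intra": sd_intra,
            "sd_inter": sd_inter,
            "in_signature": np.isin(np.arange(n_genes), signature_idx),
        },
        index=genes,
    )

    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        scale=Scale.vst_like,
    )
    cohort = MultiRegionCohort(regions=regions)
    truth = SyntheticTruth(
        seed=seed,
        planted_genes=signature_genes,
        sample_ids=tuple(samples),
        gene_classes=gene_classes,
        extras={"sigma_intra": sigma_intra, "sigma_inter": sigma_inter,
                "low_sigma_factor": low_sigma_factor,
                "clonal_signature_fraction": clonal_signature_fraction},
    )
    return expr, cohort, truth


def generate_drug_response(
    truth: SyntheticTruth,
    n_drugs: int = 200,
    n_shifted: int = 20,
    shift: float = 1.5,
    confound_with_mutation: float = 0.0,
    seed: int = 0,
    *,
    n_categories: int = 10,
    noise_sd: float = 0.5,
    missing_rate: float = 0.05,
) -> tuple[DrugResponseTable, SyntheticTruth]:
    """Log-IC50 table with planted activity-dependent sensitivity shifts.

    ``truth`` is the :class:`SyntheticTruth` of a cell-line cohort (supplies
    sample ids and the high/low activity state).  The ``n_shifted`` planted
    drugs have log-IC50 lowered by ``shift`` in high-activity lines
    (sensitivity) and are all annotated with one planted target category so
    category enrichment among flagged drugs is known by construction.  A
    positive ``confound_with_mutation`` additionally lowers log-IC50 in
    KRAS-mutant lines for the planted drugs, exercising covariate correction.
    """
    if n_shifted > n_drugs:
        raise ValueError("n_shifted must be <= n_drugs")
    if truth.activity_state is None:
        raise ValueError("truth must carry a per-sample activity state")

    r_base, r_noise, r_cat, r_miss = _streams(seed, 4)

    samples = list(truth.sample_ids)
    high = (truth.activity_state.loc[samples] == "high").to_numpy()
    kras = truth.extras.get("kras_mutant")
    kras = kras.loc[samples].to_numpy() if kras is not None else np.zeros(len(samples), bool)

    drugs = [f"DRUG{i:04d}" for i in range(n_drugs)]
    shifted = drugs[:n_shifted]

    base = r_base.normal(0.0, 1.0, n_drugs)
    values = base[None, :] + r_noise.normal(0.0, noise_sd, (len(samples), n_drugs))
    values[np.ix_(high, range(n_shifted))] -= shift
    if confound_with_mutation:
        values[np.ix_(kras, range(n_shifted))] -= confound_with_mutation
    if missing_rate:
        values[r_miss.random(values.shape) < missing_rate] = np.nan

    planted_category = "CAT_PLANTED"
    other = [f"CAT{i:02d}" for i in range(1, n_categories)]
    target_map = {d: (planted_category,) for d in shifted}
    for d in drugs[n_shifted:]:
        target_map[d] = (other[int(r_cat.integers(len(other)))],)

    table = DrugResponseTable(
        values=pd.DataFrame(values, index=samples, columns=drugs),
        target_map=target_map,
    )
    drug_truth = SyntheticTruth(
        seed=seed,
        sample_ids=tuple(samples),
        activity_state=truth.activity_state,
        shifted_drugs=tuple(shifted),
        planted_category=planted_category,
        extras={"shift": shift, "confound_with_mutation": confound_with_mutation},
    )
    return table, drug_truth


def generate_rag_cohort(
    n_samples: int = 400,
    n_genes: int = 30,
    n_informative: int = 10,
    n_classes: int = 5,
    separation: float = 3.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series, SyntheticTruth]:
    """Z-scored expression with well-separated planted activity classes.

    Class ``c`` shifts all informative genes by ``c * separation`` before
    z-scoring; the remaining genes are pure noise.  Used to exercise the
    classifier, importance ranking and signature-reduction machinery against
    a known class structure.
    """
    if n_informative > n_genes:
        raise ValueError("n_informative must be <= n_genes")
    r_lab, r_val = _streams(seed, 2)

    samples = [f"S{i:04d}" for i in range(n_samples)]
    genes = [f"G{i:03d}" for i in range(n_genes)]
    labels = np.repeat(np.arange(n_classes), int(np.ceil(n_samples / n_classes)))[:n_samples]
    labels = labels[r_lab.permutation(n_samples)]

    values = r_val.standard_normal((n_genes, n_samples))
    values[:n_informative, :] += separation * labels[None, :]
    # z-score genes so the matrix satisfies the classifier's scale contract
    values = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, ddof=1, keepdims=True)

    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), scale=Scale.zscore
    )
    label_series = pd.Series([f"RAG-{c}" for c in labels], index=samples)
    truth = SyntheticTruth(
        seed=seed,
        planted_genes=tuple(genes[:n_informative]),
        sample_ids=tuple(samples),
        extras={"labels": label_series, "separation": separation},
    )
    return expr, label_series, truth
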