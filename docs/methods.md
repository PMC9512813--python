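# Methods

## The problem and the approach

KRAS mutation status alone is a poor predictor of outcome in lung
adenocarcinoma, because many KRAS wild-type tumours activate RAS signalling
through other pathway members or non-genetic routes.  This package measures
RAS *transcriptional* activity instead: it refines published RAS-target gene
sets against cell-line expression data into a compact meta-signature, scores
each sample with the **RAS index (RI)** — the mean signature-gene expression —
and stratifies patients into five **RAS Activity Groups (RAG-0 … RAG-4)** by
Ward hierarchical clustering of the signature submatrix.  Downstream modules
associate the groups with mutations, drug response and survival, classify new
samples with an SVM, profile activity across cancer cohorts and quantify
multi-region (intra-tumour) heterogeneity.

All statistical machinery is exercised end-to-end on synthetic cohorts with
planted ground truth, so every recovery claim the test suite makes is scored
against construction.

## Pipeline stages

### Normalization (`normalize`)

Counts are normalized with median-of-ratios size factors and transformed as
`log2(count/size_factor + 1)`.  This is a variance-stabilizing *surrogate*:
downstream stages consume only rank, mean and distance structure, which the
surrogate preserves, and it is dependency-free and exactly specified.  A
dispersion-fitted transform can be substituted behind the same interface.

Pan-cancer comparison: each cohort is transformed and z-scored over samples
(removing per-sample depth and dynamic-range differences), the cohorts are
merged, and genes are z-scored **across the merged matrix**.  Gene z-scoring
must follow the merge — applied per cohort it would centre every cohort to
zero and destroy the between-cohort activity differences the pan-cancer
profile measures.

### Signature derivation (`derive`)

1. **Gene filtering.**  Genes from exclusion sets (e.g. immune signatures)
   are removed; the log coefficient of variation is regressed on mean log2
   expression over *all* genes with a tricube-weighted local polynomial
   (span 0.5, degree 2), and signature genes are kept iff their residual is
   positive and their mean log2 expression exceeds 6.  The COV is computed
   on the linear scale then logged (a config switch allows log-scale COV;
   the convention is not standardized).
2. **Confounder exclusion.**  Samples altered in a RAS-pathway gene other
   than KRAS (BRAF, EGFR, ERBB2, FGFR1-3, HRAS, JAK2, KIT, NRAS, RET) are
   removed: such drivers can activate RAS signalling without a KRAS
   mutation and would dilute the KRAS-enrichment readout.
3. **Three-way grouping.**  Samples are clustered on the signature submatrix
   (Euclidean distance, Ward linkage, squared-distance updates); the
   dendrogram is cut into three clusters labelled low / unclassified / high
   by ascending mean signature expression.  Mean ties break by cluster size
   (descending) then lowest sample index.
4. **Evaluation.**  Pearson chi-square (no continuity correction) of KRAS
   mutation across the high and low clusters, and the maximized binomial
   log-likelihood of a mutation-on-group GLM (closed form, saturated in
   groups).  Unclassified samples are excluded from both — the sources do
   not state this for the GLM; we apply it uniformly and log the count.
5. **Refinement.**  A moderated two-sample t between the high and low groups
   per signature gene: pooled variances are shrunk toward a signature-wide
   scaled-inverse-chi-square prior whose df and scale come from
   method-of-moments on log s² (trigamma inversion, as in standard
   empirical-Bayes differential expression).  Genes with BH-FDR < 0.05 *and*
   higher mean in the high group are kept.  No fold-change filter is applied
   (the source names only the FDR rule).
6. **Meta-signature.**  The union of refined founder signatures, ordered by
   first appearance, with per-gene parent-signature provenance.

### Stratification and classification (`stratify`)

`assign_rags` is the same Ward clustering with k=5 and labels RAG-0 … RAG-4.
The classifier is an RBF-kernel SVM trained on z-scored expression with a
seeded stratified 80/20 split; the kernel width is set analytically from the
0.1/0.9 quantiles of pairwise squared distances (`gamma = 1/(q10+q90)`) and
the cost is tuned over {0.25, 0.5, 1, 2, 4} by stratified 10-fold
cross-validation ("cv with 10 iterations" is ambiguous; 10-fold chosen).
Gene importance is random-forest permutation importance (500 trees, 10
repeats, ties broken by gene id); `reduce_signature` retrains the same
protocol on importance-ranked prefixes and reports the smallest panel at
maximum accuracy plus the smallest panels meeting per-class sensitivity
(0.8) and specificity (0.9) floors.

Models serialize to a single JSON holding the gene list, per-gene training
mean/sd, kernel parameters and the training set; loading refits the SVM,
which is deterministic given data and hyperparameters, so serialized and
in-memory models predict identically (tested).

### Association scans (`assoc`)

Per-variant k×2 chi-square across groups with a strict `> 10` carrier floor;
per-genotype carrier-vs-rest chi-square; per-feature OLS of drug response or
protein level on group indicators with optional covariates (e.g. KRAS
status), missing values excluded per-feature and rank-deficient designs
reported as NA; one-sided hypergeometric target-category enrichment
(enrichment only, matching the question asked); per-cohort Wilcoxon rank-sum
of RI between RAS-mutant and wild-type samples (exact below n=25 without
ties, tie-corrected normal approximation otherwise), cohorts with fewer than
5 mutants excluded.  BH correction always runs across the tests of one call
— one correction scope per input table (separate screen releases are
corrected separately).

### Survival (`survival`)

Cox models are partial-likelihood fits with Efron tie handling (lifelines).
Categorical terms are dummy-coded against an explicit reference level
(stage is treated as categorical, not ordinal); age can enter as a
restricted cubic spline (Harrell basis, 3 knots at the 10/50/90th
percentiles).  Confidence bounds are reported at the 5th/95th percentiles.
Nested models are compared by likelihood ratio; a negative statistic is an
error (never clipped silently), and identical models give chi2=0, p=1.

Fold-change curves: for a fit containing a continuous RI term, the
cohort-average predicted survival is recomputed with every RI multiplied and
divided by the fold.  For a single-covariate model this equals the baseline
power transform `S0(t)^exp(beta*(s*x - xbar))` (verified to 1e-6).

PFS derivation: time zero is the first chemotherapy start; the event is the
earliest of recurrence, progressive-disease outcome, stage progression above
the baseline stage, death, start of a non-chemotherapy therapy, or a gap of
more than six months (182.64 days) between chemotherapy blocks — the gap
endpoint is timed at the earlier block's end, since the sources do not state
the timestamp.  Without an endpoint the interval censors at the last
follow-up if no neoplasm was recorded, else at the last favourable outcome
(stable disease / progression-free / partial response).  Every interval is
annotated with the rule that fired.

Prognostic gene selection: an L1-penalized Cox path (coordinate-descent
elastic net) with the penalty chosen by Verweij–van Houwelingen
cross-validated partial likelihood (`penalty="L1"`, default) or by BIC along
the path with k = nonzero coefficients and n = events (`penalty="BIC"`);
both selection criteria use our own Breslow partial log-likelihood.  The two
modes exist because the sources describe both a Lasso and an
information-criterion variant of this analysis.

### Landscape (`landscape`)

Cohort profiles carry mean RI, RAS-pathway mutation-burden ratio and isoform
frequencies (cohorts under 10 samples are excluded).  The bimodal split of
cohort mean RIs uses a Gaussian KDE (Silverman bandwidth) on a fixed
512-point grid spanning the range ± 3 bandwidths; the threshold is the grid
minimum between the two largest density maxima; a unimodal density is an
error, and the construction is deterministic and affine-equivariant.  Burden
vs mean-RI correlation reports both Pearson and Spearman (the sources use
both) with an OLS line and a 99% confidence band; cohorts outside the band
are flagged above/below.

Multi-region metrics: Euclidean distances over the signature submatrix
partitioned into same-patient (intra) and different-patient (inter) pairs;
per-gene variance components (pooled within-patient variance; variance of
patient means) median-split into four quadrants when no external
heterogeneity annotation is supplied — a surrogate for externally derived
classifications, clearly labelled as such; and Fisher-exact enrichment of
signature genes in the low-intra/high-inter ("clonal expression") quadrant.

## Synthetic cohorts: what they emulate, and what they do not

- **Cell lines** — negative-binomial counts (dispersion 0.15, log-normal
  library sizes), log-uniform per-gene abundance, a latent RAS-activity
  factor with binary high/low state (p_high 0.5), an intermediate-activity
  subpopulation (20% of samples at half effect) and within-state dispersion
  (0.1 × effect).  The intermediate population matters: it is the
  "unclassified" group the three-way clustering assumes, and without it the
  dendrogram cut of two point clouds is arbitrary.  KRAS mutation follows a
  logistic on the binary state so the planted odds ratio is exact (baseline
  rate 0.15 in low-activity samples); 10% of samples carry a non-KRAS
  pathway alteration to exercise the exclusion logic.
- **Tumor cohorts** — a continuous standard-normal activity index drives
  planted gene expression and an exponential survival time with hazard
  `lambda0 * exp(log_hr * index)` (or the mutation indicator); censoring is
  independent exponential calibrated to the requested rate.
- **Multi-region cohorts** — per-gene patient and region variance components
  each drawn from a low/high class (low = 0.25 × sigma), with the planted
  signature taking 75% of its genes from the low-intra/high-inter class, so
  the expected quadrant-enrichment fold is 0.75/0.25 = 3.
- **Drug response** — normal log-IC50 noise, planted sensitivity shifts in
  high-activity lines concentrated in one target category, optional
  mutation-driven confounding, 5% missingness.

Not emulated: gene-gene correlation beyond the single activity factor,
per-gene dispersion trends, batch effects, copy-number or fusion events,
real mutation co-occurrence structure.  Passing tests therefore demonstrate
that the statistical machinery recovers planted structure under its stated
assumptions — not that the signature derived from any real cohort is
correct.

One seed governs a cohort; per-component sub-streams spawn deterministically
from it, and identical seeds give byte-identical outputs.

## Numerical choices and degenerate inputs

- Chi-square tests never apply a continuity correction (uniform policy).
- Cluster-mean ties break deterministically (size descending, lowest sample
  index); dendrogram construction is scipy's Ward on observations, which
  matches the squared-distance (D2) update rule.
- Zero-variance genes are dropped with a logged warning before z-scoring;
  an all-constant matrix is an error.
- The moderated-t prior df may be infinite (all variances equal); the
  implementation caps the t reference df at 1e6.
- Complete separation in a Cox fit (|coef| > 20 or non-convergence) raises,
  naming the terms.
- Same-day PFS endpoints map to a 0.5-day interval to keep times positive.
- Problem sizes in the test-suite simulations (e.g. 150 × 5 000 derivation
  cohorts, 50 Cox replicates at n=500, 200-replicate null calibrations) were
  chosen as the smallest sizes at which the planted effects are
  well-resolved, keeping the full suite around a minute of compute.

## Known limitations

- The vst surrogate is not a dispersion-fitted transform; absolute
  transformed values differ from such tools even though ranks and distances
  agree closely at moderate counts.
- The chi-square evaluation of the 3-way grouping operates on the extreme
  clusters only; when the dendrogram cut leaves a small extreme cluster the
  test is underpowered — a property of the published procedure, visible in
  the synthetic experiments near odds ratio 10.
- Mutation tables cannot distinguish untested genes from wild-type; both
  read as not altered.
- The SVM reports no calibrated probabilities, and only the RBF kernel is
  implemented.
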