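"""Cox proportional-hazards analyses and progression-free-survival derivation.

Cox models are fit by partial-likelihood maximization with Efron tie
handling (via lifelines); categorical terms use an explicit reference level
and age can be expanded with a restricted cubic spline.  Nested models are
compared by likelihood-ratio test.  Fold-change survival curves visualise a
continuous activity-index term by predicting the cohort-average survival
under a multiplicative shift of every index value.  A rule engine converts
dated treatment/outcome histories into progression-free-survival intervals,
and a penalized Cox fit selects the prognostic subset of signature genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from scipy import stats

from .datamodel import ExpressionMatrix, SurvivalTable

logger = logging.getLogger(__name__)

Z_90 = float(stats.norm.ppf(0.95))  # 5-95% confidence bounds


# ---------------------------------------------------------------------------
# Restricted cubic spline basis (Harrell parameterization)


def restricted_cubic_spline(
    x: pd.Series, n_knots: int = 3, knots: Sequence[float] | None = None
) -> pd.DataFrame:
    """Restricted cubic spline basis: linear in the tails, k-2 extra terms."""
    x_arr = x.to_numpy(dtype=float)
    if knots is None:
        qs = {3: [0.1, 0.5, 0.9], 4: [0.05, 0.35, 0.65, 0.95],
              5: [0.05, 0.275, 0.5, 0.725, 0.95]}
        if n_knots not in qs:
            raise ValueError("n_knots must be 3, 4 or 5")
        knots = np.quantile(x_arr, qs[n_knots])
    t = np.asarray(knots, dtype=float)
    k = len(t)
    out = {f"{x.name}_rcs1": x_arr}
    denom = (t[-1] - t[0]) ** 2

    def pos3(v: np.ndarray) -> np.ndarray:
        return np.clip(v, 0.0, None) ** 3

    for j in range(k - 2):
        term = (
            pos3(x_arr - t[j])
            - pos3(x_arr - t[k - 2]) * (t[-1] - t[j]) / (t[-1] - t[k - 2])
            + pos3(x_arr - t[-1]) * (t[k - 2] - t[j]) / (t[-1] - t[k - 2])
        ) / denom
        out[f"{x.name}_rcs{j + 2}"] = term
    return pd.DataFrame(out, index=x.index)


# ---------------------------------------------------------------------------
# Cox fitting


@dataclass
class CoxFit:
    """A fitted Cox model with its design and forest-plot-ready summary.

    ``summary`` columns: coef, se, hr, ci_low, ci_high, p (confidence bounds
    at the 5th/95th percentiles).  ``design`` retains the exact expanded
    covariate frame used for the fit so nested comparisons and predictions
    reuse the same records.
    """

    model: CoxPHFitter
    design: pd.DataFrame  # time, event + expanded covariates
    terms: tuple[str, ...]
    columns: tuple[str, ...]
    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    formula: str

    def baseline_survival(self) -> pd.Series:
        return self.model.baseline_survival_.iloc[:, 0]


def _expand_terms(
    survival: SurvivalTable,
    terms: Sequence[str],
    reference: dict[str, str] | None,
    spline_age_knots: int | None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    data = survival.data
    reference = reference or {}
    design = pd.DataFrame(index=data.index)
    columns_of: dict[str, list[str]] = {}
    for term in terms:
        if term not in data.columns:
            raise ValueError(f"unknown covariate {term!r}")
        col = data[term]
        if term == "age" and spline_age_knots:
            basis = restricted_cubic_spline(col, n_knots=spline_age_knots)
            design = pd.concat([design, basis], axis=1)
            columns_of[term] = list(basis.columns)
        elif col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = (list(col.cat.categories)
                      if isinstance(col.dtype, pd.CategoricalDtype)
                      else sorted(col.dropna().unique()))
            ref = reference.get(term, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found for {term!r}")
            cols = []
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{term}[{lev}]"
                design[name] = (col == lev).astype(float)
                cols.append(name)
            columns_of[term] = cols
        else:
            design[term] = col.astype(float)
            columns_of[term] = [term]
    return design, columns_of


def fit_cox(
    survival: SurvivalTable,
    terms: Sequence[str],
    reference: dict[str, str] | None = None,
    spline_age_knots: int | None = None,
    min_events: int = 10,
) -> CoxFit:
    """Fit a Cox proportional-hazards model to the named covariates.

    Categorical terms are dummy-coded against an explicit reference level
    (first level by default; pass e.g. ``reference={"rag": "RAG-0"}``).
    ``spline_age_knots`` expands the ``age`` term as a restricted cubic
    spline.  Requires at least ``min_events`` events and two distinct event
    times; monotone likelihood (complete separation) raises naming the term.
    """
    if survival.n_events < min_events:
        raise ValueError(f"need >= {min_events} events, have {survival.n_events}")
    event_times = survival.data.loc[survival.data["event"], "time"]
    if event_times.nunique() < 2:
        raise ValueError("need >= 2 distinct event times")
    design, columns_of = _expand_terms(survival, terms, reference, spline_age_knots)
    frame = pd.concat([survival.data[["time", "event"]], design], axis=1)
    complete = frame.notna().all(axis=1)
    if not complete.all():
        logger.warning("%d records with missing covariates dropped", int((~complete).sum()))
        frame = frame.loc[complete]
    fitter = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=ConvergenceWarning)
        try:
            fitter.fit(frame.assign(event=frame["event"].astype(int)),
                       duration_col="time", event_col="event")
        except (ConvergenceError, ConvergenceWarning) as err:
            raise ValueError(f"Cox fit failed to converge (terms {list(terms)}): {err}") from err
    coefs = fitter.params_
    if (coefs.abs() > 20).any():
        bad = coefs.index[coefs.abs() > 20].tolist()
        raise ValueError(f"monotone likelihood / complete separation in terms {bad}")
    se = fitter.standard_errors_
    summary = pd.DataFrame({
        "coef": coefs,
        "se": se,
        "hr": np.exp(coefs),
        "ci_low": np.exp(coefs - Z_90 * se),
        "ci_high": np.exp(coefs + Z_90 * se),
        "p": fitter.summary["p"],
    })
    return CoxFit(
        model=fitter,
        design=frame,
        terms=tuple(terms),
        columns=tuple(design.columns),
        summary=summary,
        log_likelihood=float(fitter.log_likelihood_),
        n=len(frame),
        n_events=int(frame["event"].sum()),
        formula="Surv(time, event) ~ " + " + ".join(terms),
    )


def lrt_compare(full: CoxFit, reduced: CoxFit) -> dict:
    """Likelihood-ratio test between nested Cox fits on the same records."""
    if not set(reduced.columns) <= set(full.columns):
        raise ValueError("models are not nested (reduced columns not a subset)")
    if full.n != reduced.n or not full.design.index.equals(reduced.design.index):
        raise ValueError("models were fit on different records")
    chi2 = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if chi2 < -1e-8:
        raise ValueError(
            f"negative LRT statistic ({chi2:.3g}): full model failed to converge"
        )
    chi2 = max(chi2, 0.0)
    df = len(full.columns) - len(reduced.columns)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return {"chi2": float(chi2), "df": df, "p": p}


def predict_fold_change_curves(
    fit: CoxFit, ri_term: str = "ri", fold: float = 2.0
) -> pd.DataFrame:
    """Cohort-average survival curves under a fold-change of the RI term.

    Returns the observed-cohort average predicted curve plus the curves with
    every RI value multiplied and divided by ``fold`` (columns observed,
    increased, decreased).  All curves are monotone non-increasing from 1.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if ri_term not in fit.columns:
        raise ValueError(f"fit does not contain a continuous {ri_term!r} term")
    covs = fit.design[list(fit.columns)]
    curves = {}
    for name, scale in (("observed", 1.0), ("increased", fold), ("decreased", 1.0 / fold)):
        X = covs.copy()
        X[ri_term] = X[ri_term] * scale
        surv = fit.model.predict_survival_function(X)
        curves[name] = surv.mean(axis=1)
    return pd.DataFrame(curves)


# ---------------------------------------------------------------------------
# PFS rule engine


#: treatment gap (days) beyond which a break in chemotherapy counts as a
#: progression endpoint (6 months)
GAP_DAYS = 6 * 30.44

FAVOURABLE_OUTCOMES = ("stable_disease", "progression_free", "partial_response")
_STAGE_ORDER = {"I": 1, "II": 2, "III": 3, "IV": 4}


def _stage_rank(value: str) -> int:
    v = str(value).upper().lstrip("STAGE ").strip()
    if v not in _STAGE_ORDER:
        raise ValueError(f"unrecognised stage {value!r}")
    return _STAGE_ORDER[v]


def derive_pfs_intervals(
    history: pd.DataFrame, chemotherapy: str = "chemotherapy"
) -> tuple[SurvivalTable, pd.DataFrame]:
    """Derive progression-free-survival intervals from event streams.

    ``history`` is long-format with columns patient, day, record, value.
    Record types: ``treatment_start``/``treatment_end`` (value = therapy
    name), ``outcome`` (value = e.g. progressive_disease, stable_disease),
    ``recurrence``, ``stage`` (value = I..IV), ``death``, ``neoplasm``,
    ``follow_up``.

    Time zero is the first chemotherapy start.  The event time is the
    earliest of: a recurrence, a progressive-disease outcome, a progression
    in reported stage, death, the start of a non-chemotherapy therapy, or a
    gap of more than six months between chemotherapy blocks (timed at the
    earlier block's end).  Without an endpoint the interval is censored at
    the last follow-up if no neoplasm was recorded, else at the last
    favourable outcome (stable disease, progression-free, partial response).
    Patients without a chemotherapy start are skipped with a logged reason;
    an endpoint dated before time zero is a data error.
    """
    required = {"patient", "day", "record", "value"}
    if not required <= set(history.columns):
        raise ValueError(f"history requires columns {sorted(required)}")
    rows, annotations = [], []
    for patient, events in history.groupby("patient", sort=False):
        events = events.sort_values("day", kind="stable")
        chemo_starts = events[
            (events["record"] == "treatment_start") & (events["value"] == chemotherapy)
        ]
        if chemo_starts.empty:
            logger.warning("patient %s: no chemotherapy start, skipped", patient)
            continue
        t0 = float(chemo_starts["day"].iloc[0])

        baseline_stage = None
        pre = events[(events["record"] == "stage") & (events["day"] <= t0)]
        if not pre.empty:
            baseline_stage = _stage_rank(pre["value"].iloc[-1])

        candidates: list[tuple[float, str]] = []
        for _, ev in events.iterrows():
            day = float(ev["day"])
            rel = day - t0
            record, value = ev["record"], ev["value"]
            if record == "recurrence":
                candidates.append((rel, "recurrence"))
            elif record == "outcome" and value == "progressive_disease":
                candidates.append((rel, "progressive_disease"))
            elif record == "death":
                candidates.append((rel, "death"))
            elif record == "stage" and day > t0:
                rank = _stage_rank(value)
                if baseline_stage is not None and rank > baseline_stage:
                    candidates.append((rel, "stage_progression"))
                baseline_stage = rank if baseline_stage is None else max(baseline_stage, rank)
            elif record == "treatment_start" and day > t0 and value != chemotherapy:
                candidates.append((rel, "alternative_therapy"))

        # chemotherapy blocks for the gap rule
        starts = [float(d) for d in events.loc[
            (events["record"] == "treatment_start") & (events["value"] == chemotherapy), "day"]]
        ends = [float(d) for d in events.loc[
            (events["record"] == "treatment_end") & (events["value"] == chemotherapy), "day"]]
        for end in sorted(ends):
            later = [s for s in sorted(starts) if s > end]
            if later and later[0] - end > GAP_DAYS:
                candidates.append((end - t0, "treatment_gap"))

        if candidates:
            time, rule = min(candidates, key=lambda c: (c[0], c[1]))
            if time < 0:
                raise ValueError(
                    f"patient {patient}: endpoint ({rule}) dated before chemotherapy start"
                )
            if time == 0:
                time = 0.5  # same-day endpoint: half-day interval keeps times positive
            rows.append({"patient": patient, "time": time, "event": 1})
            annotations.append({"patient": patient, "rule": rule})
            continue

        neoplasm = events[events["record"] == "neoplasm"]
        follow_ups = events[events["record"] == "follow_up"]
        favourable = events[
            (events["record"] == "outcome") & events["value"].isin(FAVOURABLE_OUTCOMES)
        ]
        if neoplasm.empty and not follow_ups.empty:
            time = float(follow_ups["day"].iloc[-1]) - t0
            rule = "censor_last_follow_up"
        elif not favourable.empty:
            time = float(favourable["day"].iloc[-1]) - t0
            rule = "censor_favourable_outcome"
        else:
            logger.warning("patient %s: no endpoint and no censoring anchor, skipped", patient)
            continue
        if time <= 0:
            logger.warning("patient %s: censoring time not after start, skipped", patient)
            continue
        rows.append({"patient": patient, "time": time, "event": 0})
        annotations.append({"patient": patient, "rule": rule})

    frame = pd.DataFrame(rows).set_index("patient") if rows else pd.DataFrame(
        columns=["time", "event"])
    table = SurvivalTable(data=frame)
    return table, pd.DataFrame(annotations).set_index("patient") if annotations else pd.DataFrame()


# ---------------------------------------------------------------------------
# Penalized prognostic gene selection


def breslow_partial_loglik(
    beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow partial log-likelihood of a Cox model at the given coefficients."""
    eta = X @ beta
    order = np.argsort(-time, kind="stable")
    eta_sorted = eta[order]
    log_risk = np.logaddexp.accumulate(eta_sorted)
    ll = 0.0
    t_sorted = time[order]
    e_sorted = event[order]
    # samples with tied times must share the full risk set
    i = 0
    n = len(order)
    while i < n:
        j = i
        while j < n and t_sorted[j] == t_sorted[i]:
            j += 1
        denom = log_risk[j - 1]
        for m in range(i, j):
            if e_sorted[m]:
                ll += eta_sorted[m] - denom
        i = j
    return float(ll)


def select_prognostic_genes(
    expr: ExpressionMatrix,
    survival: SurvivalTable,
    penalty: str = "L1",
    seed: int = 0,
    n_folds: int = 5,
    n_alphas: int = 30,
) -> dict:
    """Sparse penalized Cox selection of prognostic signature genes.

    Genes are standardized internally and entered jointly into an
    L1-penalized Cox model (coordinate-descent elastic-net path).  The
    penalty weight is chosen by cross-validated partial likelihood
    (``penalty="L1"``; Verweij-van Houwelingen criterion) or by BIC along
    the path (``penalty="BIC"``).  Returns the selected genes, their
    coefficients and the per-sample mean-expression score of the subset.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    if penalty not in ("L1", "BIC"):
        raise ValueError("penalty must be 'L1' or 'BIC'")
    if survival.n_events < 30:
        raise ValueError(f"need >= 30 events, have {survival.n_events}")
    samples = [s for s in expr.sample_ids if s in survival.data.index]
    X_raw = expr.values.loc[:, samples].to_numpy(dtype=float).T
    mean, sd = X_raw.mean(axis=0), X_raw.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    X = (X_raw - mean) / sd
    time = survival.data.loc[samples, "time"].to_numpy(dtype=float)
    event = survival.data.loc[samples, "event"].to_numpy(dtype=bool)
    y = Surv.from_arrays(event=event, time=time)

    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.05, fit_baseline_model=False
    )
    path.fit(X, y)
    alphas = np.asarray(path.alphas_)
    coefs = path.coef_  # genes x alphas

    if penalty == "BIC":
        scores = []
        for j in range(len(alphas)):
            beta = coefs[:, j]
            k = int((beta != 0).sum())
            ll = breslow_partial_loglik(beta, X, time, event)
            scores.append(-2.0 * ll + k * np.log(event.sum()))
        best = int(np.argmin(scores))
    else:
        rng = np.random.default_rng(seed)
        folds = rng.permutation(len(samples)) % n_folds
        cv_ll = np.zeros(len(alphas))
        for f in range(n_folds):
            train = folds != f
            sub = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, alphas=list(alphas), fit_baseline_model=False
            )
            try:
                sub.fit(X[train], Surv.from_arrays(event=event[train], time=time[train]))
            except Exception:
                continue
            for j, alpha in enumerate(alphas):
                beta = sub.coef_[:, min(j, sub.coef_.shape[1] - 1)]
                full_ll = breslow_partial_loglik(beta, X, time, event)
                train_ll = breslow_partial_loglik(beta, X[train], time[train], event[train])
                cv_ll[j] += full_ll - train_ll
        best = int(np.argmax(cv_ll))

    beta = coefs[:, best]
    selected = np.flatnonzero(beta != 0)
    if len(selected) == 0:
        raise ValueError("no gene survives the chosen penalty")
    genes = [expr.gene_ids[i] for i in selected]
    score = pd.Series(
        expr.values.loc[genes, samples].mean(axis=0), index=samples, name="score"
    )
    return {
        "genes": genes,
        "coefficients": pd.Series(beta[selected], index=genes),
        "alpha": float(alphas[best]),
        "score": score,
        "alphas": alphas,
        "n_selected_path": (coefs != 0).sum(axis=0),
    }
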