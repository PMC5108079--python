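"""Outcome-validation statistics for septal-fibrosis criteria.

Endpoint adjudication, Youden-optimal ROC cutoffs, 2x2 diagnostics, annual
event rates with an exact Poisson comparison, Kaplan–Meier and log-rank,
Cox proportional-hazards fits (Efron ties, Schoenfeld PH diagnostic),
category-free net reclassification, ICC(A,1) agreement and Bland–Altman.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import proportional_hazard_test
from scipy import stats as sps
from statsmodels.stats.rates import test_poisson_2indep

from .core import AgreementResult, CollinearityError, CovariateEffect, DiagnosticResult, FitError, SurvivalFit

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ("cardiac_death", "appropriate_icd", "scd", "noncardiac_death")


# ---------------------------------------------------------------------------
# Endpoint adjudication
# ---------------------------------------------------------------------------


def adjudicate_endpoints(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derive composite endpoints from per-patient raw event indicators.

    The primary composite is cardiac death or appropriate ICD therapy; the
    secondary (arrhythmic) composite is appropriate ICD therapy or sudden
    cardiac death.  A patient with several qualifying events counts once, at
    the earliest qualifying time.  Non-cardiac death censors at the death
    time.  Event times default to ``followup_years``; optional
    ``time_<event>`` columns override them per component.

    Returns a copy with ``primary_event``, ``primary_time``,
    ``secondary_event`` and ``secondary_time`` columns appended.

    Raises
    ------
    ValueError
        If any event time exceeds the recorded follow-up (conflicting
        dates), listing the offending patient ids.
    """
    df = cohort.copy()
    if (df["followup_years"] <= 0).any():
        bad = df.loc[df["followup_years"] <= 0, "patient_id"].tolist()
        raise ValueError(f"non-positive follow-up for patients: {bad}")

    times = {}
    for ev in EVENT_COLUMNS:
        flag = df[ev].astype(bool)
        tcol = f"time_{ev}"
        t = df[tcol] if tcol in df else df["followup_years"]
        times[ev] = np.where(flag, t, np.inf)
        conflict = flag & (np.asarray(t) > np.asarray(df["followup_years"]) + 1e-9)
        if conflict.any():
            bad = df.loc[conflict, "patient_id"].tolist()
            raise ValueError(f"event time after follow-up for patients: {bad}")

    def composite(components: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
        t = np.minimum.reduce([times[c] for c in components])
        event = np.isfinite(t)
        return event, np.where(event, t, df["followup_years"])

    df["primary_event"], df["primary_time"] = composite(("cardiac_death", "appropriate_icd"))
    df["secondary_event"], df["secondary_time"] = composite(("appropriate_icd", "scd"))
    return df


# ---------------------------------------------------------------------------
# ROC cutoff and diagnostics
# ---------------------------------------------------------------------------


def roc_optimal_cutoff(values, outcomes) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    A case is test-positive when its marker value strictly exceeds the
    cutoff.  Candidate cutoffs are the midpoints between consecutive
    distinct marker values; ties in J are broken toward higher specificity
    (then toward the higher cutoff).  Returns ``(cutoff, sensitivity_pct,
    specificity_pct)``.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and outcomes must be matching 1-D arrays")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present for ROC analysis")
    distinct = np.unique(v)
    if distinct.size < 2:
        raise ValueError("all marker values are equal; no cutoff separates the classes")
    cutoffs = 0.5 * (distinct[:-1] + distinct[1:])

    order = np.argsort(v, kind="stable")
    v_sorted, y_sorted = v[order], y[order]
    # events / non-events with value <= c, via cumulative counts at the
    # rightmost index where v_sorted <= cutoff
    cum_pos = np.cumsum(y_sorted)
    cum_neg = np.cumsum(~y_sorted)
    idx = np.searchsorted(v_sorted, cutoffs, side="right") - 1
    fn = cum_pos[idx]
    tn = cum_neg[idx]
    sens = (n_pos - fn) / n_pos
    spec = tn / n_neg
    j = sens + spec - 1.0

    best = np.lexsort((cutoffs, spec, j))[-1]
    return float(cutoffs[best]), float(100 * sens[best]), float(100 * spec[best])


def diagnostic_metrics(test_positive, outcomes) -> DiagnosticResult:
    """Standard 2x2 diagnostic rates (in %) and the count of missed events.

    ``n_missed`` is the number of outcome-positive patients the test called
    negative (false negatives).
    """
    t = np.asarray(test_positive).astype(bool)
    y = np.asarray(outcomes).astype(bool)
    if t.shape != y.shape:
        raise ValueError("test and outcome vectors must have the same length")
    tp = int((t & y).sum())
    fp = int((t & ~y).sum())
    fn = int((~t & y).sum())
    tn = int((~t & ~y).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both outcome classes must be present")
    if tp + fp == 0 or tn + fn == 0:
        logger.warning("a test margin is empty; the corresponding predictive value is undefined")
    return DiagnosticResult(
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        ppv=100.0 * tp / (tp + fp) if tp + fp else float("nan"),
        npv=100.0 * tn / (tn + fn) if tn + fn else float("nan"),
        n_missed=fn,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


# ---------------------------------------------------------------------------
# Event rates and survival
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventRates:
    """Events per 100 patient-years per group, with an exact Poisson comparison."""

    rates: dict
    events: dict
    person_years: dict
    p_value: float | None


def annual_event_rate(times, events, groups) -> EventRates:
    """Per-group event rate per 100 patient-years.

    ``times`` is the time to first event or censoring, so person-time
    bookkeeping is invariant to splitting a record into consecutive pieces.
    With exactly two groups, the rates are compared with an exact
    conditional Poisson test.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    g = np.asarray(groups)
    if np.any(t < 0) or (t.sum() <= 0):
        raise ValueError("follow-up times must be non-negative with positive total")
    labels = list(pd.unique(g))
    rates, counts, pys = {}, {}, {}
    for lab in labels:
        sel = g == lab
        py = float(t[sel].sum())
        if py <= 0:
            raise ValueError(f"group {lab!r} has zero person-time")
        counts[lab] = int(e[sel].sum())
        pys[lab] = py
        rates[lab] = 100.0 * counts[lab] / py
    p = None
    if len(labels) == 2:
        a, b = labels
        if counts[a] + counts[b] == 0:
            p = 1.0
        else:
            p = float(
                test_poisson_2indep(
                    counts[a], pys[a], counts[b], pys[b], method="exact-cond"
                ).pvalue
            )
    return EventRates(rates=rates, events=counts, person_years=pys, p_value=p)


@dataclass(frozen=True)
class KmEstimate:
    """Kaplan–Meier product-limit estimate plus follow-up summaries."""

    times: np.ndarray
    survival: np.ndarray
    median_followup: float
    iqr_followup: float

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KmEstimate:
    """Product-limit survival estimate (non-increasing, S(0) = 1)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    q1, med, q3 = np.percentile(t, [25, 50, 75])
    return KmEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median_followup=float(med),
        iqr_followup=float(q3 - q1),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    ea = np.asarray(events_a).astype(bool)
    eb = np.asarray(events_b).astype(bool)
    if len(np.asarray(times_a)) == 0 or len(np.asarray(times_b)) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(times_a, times_b, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------


def _check_collinearity(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    if x.shape[1] < 2:
        return
    std = x.std(axis=0)
    if np.any(std == 0):
        name = design.columns[int(np.argmax(std == 0))]
        raise CollinearityError(f"covariate {name!r} is constant")
    corr = np.corrcoef(x, rowvar=False)
    iu = np.triu_indices_from(corr, k=1)
    worst = np.argmax(np.abs(corr[iu]))
    if np.abs(corr[iu][worst]) > 0.9999:
        a, b = design.columns[iu[0][worst]], design.columns[iu[1][worst]]
        raise CollinearityError(f"covariates {a!r} and {b!r} are collinear")
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < x.shape[1]:
        raise CollinearityError(f"covariate matrix {list(design.columns)} is rank deficient")


def cox_fit(
    cohort: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "primary_time",
    event_col: str = "primary_event",
    run_ph_test: bool = True,
) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron tie handling).

    Reports per-covariate hazard ratio, Wald 95 % CI, Wald chi-square and p,
    plus a scaled-Schoenfeld-residual proportional-hazards test p per
    covariate.  Collinear covariates and non-convergent (e.g. monotone)
    likelihoods raise explicit errors.
    """
    cols = list(covariates) + [duration_col, event_col]
    df = cohort[cols].copy()
    df[event_col] = df[event_col].astype(bool)
    n_events = int(df[event_col].sum())
    if n_events == 0:
        raise FitError("no events observed; Cox model cannot be fitted")
    _check_collinearity(df[list(covariates)])

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise FitError(
            f"Cox fit failed to converge for covariates {covariates}: {err}"
        ) from err

    summary = cph.summary
    effects = []
    for name in covariates:
        row = summary.loc[name]
        z = float(row["z"])
        effects.append(
            CovariateEffect(
                name=name,
                hazard_ratio=float(row["exp(coef)"]),
                ci_lower=float(row["exp(coef) lower 95%"]),
                ci_upper=float(row["exp(coef) upper 95%"]),
                chi2=z * z,
                p=float(row["p"]),
            )
        )
    ph_p: dict[str, float] = {}
    if run_ph_test and n_events >= 3:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ph = proportional_hazard_test(cph, df, time_transform="rank")
            ph_p = {str(k): float(v) for k, v in ph.summary["p"].items()}
        except Exception:  # diagnostic only; never fail the fit
            logger.warning("proportional-hazards diagnostic could not be computed")
    return SurvivalFit(
        effects=tuple(effects),
        log_likelihood=float(cph.log_likelihood_),
        n=int(len(df)),
        n_events=n_events,
        ph_test_p=ph_p,
    )


def cox_predicted_risk(
    cohort: pd.DataFrame,
    covariates: list[str],
    horizon: float,
    duration_col: str = "primary_time",
    event_col: str = "primary_event",
) -> np.ndarray:
    """Predicted event probability by ``horizon`` years from a Cox fit."""
    df = cohort[list(covariates) + [duration_col, event_col]].copy()
    df[event_col] = df[event_col].astype(bool)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    surv = cph.predict_survival_function(df[list(covariates)], times=[horizon])
    return 1.0 - surv.iloc[0].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Net reclassification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NriResult:
    """Category-free (continuous) net reclassification index."""

    nri: float
    ci_lower: float
    ci_upper: float
    p: float
    nri_events: float
    nri_nonevents: float


def nri(base_risk, augmented_risk, outcomes, alpha: float = 0.05) -> NriResult:
    """Category-free NRI between two risk models.

    ``NRI = [P(up|event) - P(down|event)] + [P(down|non-event) -
    P(up|non-event)]`` where "up" means the augmented model assigns a
    strictly higher risk than the base model.  The CI uses the standard
    asymptotic variance of the two proportions.
    """
    b = np.asarray(base_risk, dtype=float)
    a = np.asarray(augmented_risk, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    if not (b.shape == a.shape == y.shape):
        raise ValueError("risk and outcome vectors must have the same length")
    n_e, n_ne = int(y.sum()), int((~y).sum())
    if n_e == 0 or n_ne == 0:
        raise ValueError("both outcome classes must be present")
    up = a > b
    down = a < b
    if not (up.any() or down.any()):
        logger.warning("all risk pairs tied; NRI is 0")
        return NriResult(0.0, 0.0, 0.0, 1.0, 0.0, 0.0)
    pu_e = up[y].mean()
    pd_e = down[y].mean()
    pu_ne = up[~y].mean()
    pd_ne = down[~y].mean()
    nri_e = pu_e - pd_e
    nri_ne = pd_ne - pu_ne
    total = nri_e + nri_ne
    var = (pu_e + pd_e - nri_e**2) / n_e + (pu_ne + pd_ne - nri_ne**2) / n_ne
    se = float(np.sqrt(var))
    z = sps.norm.ppf(1 - alpha / 2)
    p = 2 * sps.norm.sf(abs(total) / se) if se > 0 else (0.0 if total else 1.0)
    return NriResult(
        nri=float(total),
        ci_lower=float(total - z * se),
        ci_upper=float(total + z * se),
        p=float(p),
        nri_events=float(nri_e),
        nri_nonevents=float(nri_ne),
    )


def nri_bootstrap_ci(
    base_risk, augmented_risk, outcomes, n_boot: int = 1000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float]:
    """Percentile bootstrap CI for the category-free NRI."""
    b = np.asarray(base_risk, dtype=float)
    a = np.asarray(augmented_risk, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    rng = np.random.default_rng(seed)
    vals = []
    n = len(y)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if y[idx].all() or not y[idx].any():
            continue
        vals.append(nri(b[idx], a[idx], y[idx]).nri)
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Agreement
# ---------------------------------------------------------------------------


def icc(ratings, alpha: float = 0.05) -> AgreementResult:
    """Two-way random-effects, absolute-agreement, single-measure ICC.

    ``ratings`` is an ``(n_subjects, k_raters)`` array with no missing
    cells; the CI is the McGraw–Wong F-based interval.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("ratings must be (>=3 subjects, >=2 raters)")
    if not np.isfinite(x).all():
        raise ValueError("ratings contain missing or non-finite cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    if np.allclose(row_means, row_means[0]):
        raise ValueError("zero between-subject variance; ICC is undefined")
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    r = float((msr - mse) / denom)

    if mse == 0 and msc == 0:
        return AgreementResult(icc=r, icc_ci=(r, r))
    a = k * r / (n * (1 - r)) if r < 1 else np.inf
    b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
    if np.isinf(a) or np.isinf(b):
        return AgreementResult(icc=r, icc_ci=(r, r))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return AgreementResult(icc=r, icc_ci=(float(lower), float(upper)))


def bland_altman(first, second) -> AgreementResult:
    """Bland–Altman bias and 95 % limits of agreement for paired readings.

    Returns bias (mean difference, second - first), the SD of the
    differences, and limits ``bias +/- 1.96 * SD``.
    """
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need >= 2 measurement pairs")
    diff = b - a
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
    )


def bland_altman_points(first, second) -> pd.DataFrame:
    """Per-pair (mean, difference) plot data for a Bland–Altman chart."""
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    return pd.DataFrame({"mean": (a + b) / 2.0, "difference": b - a})
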