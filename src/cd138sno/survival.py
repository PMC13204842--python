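"""Survival and association statistics for the CD138 cohort analysis.

Recurrence-free survival (time from surgery to first recurrence, censored at
last follow-up) is summarized with the Kaplan-Meier product-limit estimator
and compared between CD138 groups with the log-rank test. Prognostic factors
are modeled with Cox proportional hazards regression (Efron tie handling,
Wald confidence intervals and p-values), the proportional-hazards assumption
is checked on scaled Schoenfeld residuals, and discrimination is measured
with Harrell's concordance index. Group-vs-covariate associations use the
Pearson chi-square test (Fisher's exact test when expected counts are small),
and score comparisons use the Mann-Whitney U test and Spearman rank
correlation.

Model fitting and the classical tests are delegated to lifelines and
scipy.stats behind this module's interface; the conventions fixed here
(no Yates correction by default, minimum-likelihood two-sided Fisher p,
exact Mann-Whitney only without ties at small n) are the ones that reproduce
the published breast-cancer contingency statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test
from lifelines.utils import concordance_index as _lifelines_concordance


@dataclass(frozen=True)
class SurvivalRecord:
    case_id: str
    time: float  # follow-up duration, > 0
    event: int  # 1 recurrence, 0 censored

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"case {self.case_id!r}: time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"case {self.case_id!r}: event must be 0/1, got {self.event}")


@dataclass
class KMCurve:
    event_times: np.ndarray  # ascending distinct event times
    at_risk: np.ndarray  # number at risk just before each event time
    events: np.ndarray  # events at each event time
    survival: np.ndarray  # product-limit estimate after each event time


@dataclass
class CoxFit:
    summary: pd.DataFrame  # per covariate: coef, hr, ci_low, ci_high, p
    c_index: float
    converged: bool
    flag: Optional[str] = None  # set when convergence is suspect
    schoenfeld_p: dict = field(default_factory=dict)
    _model: Optional[CoxPHFitter] = field(default=None, repr=False)
    _data: Optional[pd.DataFrame] = field(default=None, repr=False)


def _check_times_events(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape or times.ndim != 1 or len(times) == 0:
        raise ValueError("times and events must be nonempty 1-D arrays of equal length")
    if (times <= 0).any():
        raise ValueError("all survival times must be > 0")
    if set(np.unique(events)) - {0, 1}:
        raise ValueError("event flags must be 0/1")
    return times, events


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function.

    Cases censored exactly at an event time are counted at risk at that time
    (the standard convention).
    """
    times, events = _check_times_events(times, events)
    kmf = KaplanMeierFitter().fit(times, events)
    table = kmf.event_table
    at_events = table[table["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    return KMCurve(
        event_times=at_events.index.to_numpy(dtype=float),
        at_risk=at_events["at_risk"].to_numpy(dtype=int),
        events=at_events["observed"].to_numpy(dtype=int),
        survival=surv.loc[at_events.index].to_numpy(dtype=float),
    )


def logrank_test(
    times: Sequence[float], events: Sequence[int], groups: Sequence
) -> tuple[float, int, float]:
    """k-sample log-rank test; returns (chi_square, df = k-1, p)."""
    times, events = _check_times_events(times, events)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if events.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), len(labels) - 1, float(res.p_value)


def cox_fit(
    covariates: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[int],
    ties: str = "efron",
    run_schoenfeld: bool = True,
    schoenfeld_transform: str = "identity",
) -> CoxFit:
    """Cox proportional-hazards regression via partial likelihood.

    Efron's approximation handles tied event times by default; ``ties=
    "breslow"`` switches to the Breslow convention (fit via statsmodels'
    PHReg on that path). Confidence intervals and p-values are Wald-based.
    Monotone partial likelihood (separation) is detected from the optimizer's
    diagnostics and flagged with ``converged=False`` rather than raised;
    collinear covariates raise a ValueError.
    """
    times, events = _check_times_events(times, events)
    if len(covariates) != len(times):
        raise ValueError("covariates and survival data length mismatch")
    if len(times) <= covariates.shape[1]:
        raise ValueError("need more cases than covariates")
    if events.sum() < 1:
        raise ValueError("Cox regression needs at least one event")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")

    df = covariates.reset_index(drop=True).astype(float).copy()
    df["_time"] = times
    df["_event"] = events

    if ties == "breslow":
        return _cox_fit_breslow(df, covariates.columns)

    model = CoxPHFitter()
    flag = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            model.fit(df, duration_col="_time", event_col="_event")
        except ConvergenceError as err:
            raise ValueError(f"Cox fit failed (collinear or degenerate covariates): {err}") from err
        convergence_msgs = [str(w.message) for w in caught if issubclass(w.category, ConvergenceWarning)]
    if convergence_msgs:
        flag = "; ".join(convergence_msgs)
    converged = not convergence_msgs

    raw = model.summary
    summary = pd.DataFrame(
        {
            "coef": raw["coef"],
            "hr": raw["exp(coef)"],
            "ci_low": raw["exp(coef) lower 95%"],
            "ci_high": raw["exp(coef) upper 95%"],
            "p": raw["p"],
        }
    )
    fit = CoxFit(
        summary=summary,
        c_index=float(model.concordance_index_),
        converged=converged,
        flag=flag,
        _model=model,
        _data=df,
    )
    if run_schoenfeld and converged and events.sum() >= 2:
        fit.schoenfeld_p = schoenfeld_check(fit, time_transform=schoenfeld_transform)
    return fit


def _cox_fit_breslow(df: pd.DataFrame, columns) -> CoxFit:
    """Breslow-tie Cox fit (statsmodels PHReg), same summary layout."""
    from scipy.stats import norm
    from statsmodels.duration.hazard_regression import PHReg

    model = PHReg(
        df["_time"], df[list(columns)], status=df["_event"], ties="breslow"
    )
    res = model.fit()
    coefs = np.asarray(res.params)
    ses = np.asarray(res.bse)
    z975 = norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coef": coefs,
            "hr": np.exp(coefs),
            "ci_low": np.exp(coefs - z975 * ses),
            "ci_high": np.exp(coefs + z975 * ses),
            "p": 2 * norm.sf(np.abs(coefs / ses)),
        },
        index=pd.Index(columns, name="covariate"),
    )
    risk = df[list(columns)].to_numpy() @ coefs
    c = concordance_index(risk, df["_time"].to_numpy(), df["_event"].to_numpy(dtype=int))
    return CoxFit(summary=summary, c_index=c, converged=True, flag="ties=breslow")


def schoenfeld_check(fit: CoxFit, time_transform: str = "identity") -> dict[str, float]:
    """Proportional-hazards check on scaled Schoenfeld residuals.

    Correlates the scaled residuals with (transformed) event time; the
    identity transform is the default, the Kaplan-Meier transform available
    via ``time_transform="km"``. Returns a per-covariate p-value.
    """
    if fit._model is None or fit._data is None:
        raise ValueError("fit carries no model internals")
    n_events = int(fit._data["_event"].sum())
    if n_events < 2:
        raise ValueError("Schoenfeld check needs at least 2 events")
    if not fit.converged:
        raise ValueError("Schoenfeld check requires a converged fit")
    res = proportional_hazard_test(fit._model, fit._data, time_transform=time_transform)
    return {str(k): float(v) for k, v in res.summary["p"].items()}


def concordance_index(
    risk_scores: Sequence[float], times: Sequence[float], events: Sequence[int]
) -> float:
    """Harrell's C over usable pairs (higher risk should fail earlier).

    A pair is comparable iff the shorter follow-up ends in an event; tied risk
    scores count one half.
    """
    times, events = _check_times_events(times, events)
    risk = np.asarray(risk_scores, dtype=float)
    if risk.shape != times.shape:
        raise ValueError("risk scores and survival data length mismatch")
    return float(_lifelines_concordance(times, -risk, events))


def chisq_test(
    table: Sequence[Sequence[float]], yates: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c table.

    No continuity correction by default; ``yates=True`` applies it (2x2).
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin")
    res = stats.chi2_contingency(counts, correction=yates)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Two-sidedness follows the minimum-likelihood convention: the p-value sums
    hypergeometric probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's.
    """
    counts = np.asarray(table)
    if counts.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    if not np.issubdtype(counts.dtype, np.integer):
        as_int = counts.astype(int)
        if not np.array_equal(as_int, counts):
            raise ValueError("Fisher exact test requires integer counts")
        counts = as_int
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    return float(stats.fisher_exact(counts, alternative="two-sided").pvalue)


def mannwhitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p.

    The null distribution is enumerated exactly when the pooled sample has at
    most 20 observations and no ties; otherwise the normal approximation with
    tie correction is used. When U equals its null mean n_x*n_y/2 the
    two-sided p is reported as exactly 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u, p = float(res.statistic), float(res.pvalue)
    if u == len(x) * len(y) / 2.0:
        p = 1.0
    return u, min(p, 1.0)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with the t-approximation p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman requires paired data of length >= 3")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("spearman undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def association_2x2_variants(table: Sequence[Sequence[int]]) -> dict[str, float]:
    """All three association p-values for a 2x2 table.

    Published IHC contingency tables do not always state which variant was
    used per row, so the Pearson, Yates-corrected and Fisher-exact p-values
    are reported side by side, with the minimum expected count to guide the
    chi-square-vs-Fisher choice.
    """
    counts = np.asarray(table, dtype=int)
    expected = stats.contingency.expected_freq(counts)
    out = {
        "p_pearson": np.nan,
        "p_yates": np.nan,
        "p_fisher": fisher_exact(counts),
        "min_expected": float(expected.min()),
    }
    if (counts.sum(axis=0) > 0).all() and (counts.sum(axis=1) > 0).all():
        out["p_pearson"] = chisq_test(counts, yates=False)[2]
        out["p_yates"] = chisq_test(counts, yates=True)[2]
    out["suggested_test"] = "fisher" if out["min_expected"] < 5 else "chi_square"
    return out
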