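"""Cohort statistics: group tests, correlation, survival, subgroup forest,
scenario classification, and the clinicopathological summary table.

All tests are two-sided. The Mann-Whitney U and Wilcoxon signed-rank tests
switch between an exact enumeration of the permutation null (small samples,
ties handled through midranks) and the tie-corrected normal approximation
(large samples, delegated to scipy). Survival estimation uses the
Kaplan-Meier product limit and Cox proportional-hazards partial likelihood
with Efron tie handling (lifelines); multivariate models are built by
screening univariate fits at p < 0.1 and backward elimination on
likelihood-ratio removal tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .model import AnalysisConfig

__all__ = [
    "TestResult",
    "CoxResult",
    "SurvivalAtHorizon",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "chi_square",
    "spearman",
    "km_survival_at",
    "logrank_test",
    "cox_univariate",
    "cox_multivariate_backward",
    "subgroup_forest",
    "scenario_classify",
    "scenario_analysis",
    "table_one",
    "round_half_away",
]

_EPS = 1e-12


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    estimate: float | None = None  # e.g. Spearman's rho

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0 + _EPS:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass
class CoxResult:
    variable: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    events: int
    coef: float = math.nan
    converged: bool = True

    @property
    def estimable(self) -> bool:
        return self.converged and np.isfinite(self.hr)


@dataclass
class SurvivalAtHorizon:
    """Survival at a horizon: product-limit estimate and the crude proportion.

    ``crude`` is the alive fraction among patients with follow-up reaching
    the horizon or a prior death; it equals the Kaplan-Meier estimate when
    nobody is censored before the horizon.
    """

    km: float
    crude: float | None
    n: int
    n_eligible: int


# ---------------------------------------------------------------------------
# rank tests


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of all rank splits (midranks under ties) when both
    groups have at most 8 observations; otherwise the tie- and
    continuity-corrected normal approximation (the correction keeps the two
    regimes within 0.02 of each other at the switchover).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    ranks = st.rankdata(np.concatenate([x, y]))
    u_x = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if n1 <= 8 and n2 <= 8:
        mu = n1 * n2 / 2
        dev = abs(u_x - mu)
        hits = total = 0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            hits += abs(u - mu) >= dev - _EPS
            total += 1
        p = hits / total
    else:
        res = st.mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic", use_continuity=True)
        p = float(res.pvalue)
    return TestResult("Mann-Whitney U", u_x, min(p, 1.0), (n1, n2))


def wilcoxon_signed_rank(differences) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped. Exact enumeration of the 2**n sign
    patterns (midranks of tied magnitudes) when at most 15 nonzero pairs
    remain; normal approximation otherwise. The statistic is W+, the rank
    sum of the positive differences.
    """
    d = np.asarray(differences, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = st.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= 15:
        mu = n * (n + 1) / 4
        dev = abs(w_pos - mu)
        sums = np.zeros(1)
        for r in ranks:  # subset sums over sign patterns
            sums = np.concatenate([sums, sums + r])
        p = float(np.mean(np.abs(sums - mu) >= dev - _EPS))
    else:
        res = st.wilcoxon(d, alternative="two-sided", correction=True,
                          method="approx")
        p = float(res.pvalue)
    return TestResult("Wilcoxon signed-rank", w_pos, min(p, 1.0), (n,))


def chi_square(table, correction: bool = False) -> TestResult:
    """Pearson chi-square on an r x c contingency table.

    No continuity correction by default; pass ``correction=True`` for the
    Yates-corrected variant on 2 x 2 tables.
    """
    table = np.asarray(table, float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need a contingency table of at least 2 x 2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("a marginal total is zero")
    res = st.chi2_contingency(table, correction=correction)
    return TestResult("chi-square", float(res.statistic), float(res.pvalue),
                      tuple(int(v) for v in table.sum(axis=1)))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (midranks for ties, t-approximation p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return TestResult("Spearman", math.nan, math.nan, (len(x),),
                          estimate=math.nan)
    rho, p = st.spearmanr(x, y)
    return TestResult("Spearman", float(rho), float(p), (len(x),),
                      estimate=float(rho))


# ---------------------------------------------------------------------------
# survival


def km_survival_at(times, events, horizon: float) -> SurvivalAtHorizon:
    """Kaplan-Meier survival probability at ``horizon`` months.

    Also reports the crude alive proportion among subjects whose follow-up
    reached the horizon or who died before it (None when nobody is
    eligible).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if len(times) == 0:
        raise ValueError("empty group")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    km = float(kmf.predict(horizon))
    eligible = (times >= horizon) | (events & (times < horizon))
    crude = float(np.mean(times[eligible] >= horizon)) if eligible.any() else None
    return SurvivalAtHorizon(km=km, crude=crude, n=len(times),
                             n_eligible=int(eligible.sum()))


def logrank_test(times, events, groups) -> TestResult:
    """k-group log-rank test (chi-square with k-1 degrees of freedom)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if not events.any():
        raise ValueError("no events observed")
    res = multivariate_logrank_test(times, groups, events)
    return TestResult("log-rank", float(res.test_statistic),
                      float(res.p_value), tuple(int(c) for c in counts))


def _fit_cox(df: pd.DataFrame, covariates: list[str],
             duration_col: str, event_col: str) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[[duration_col, event_col, *covariates]],
                duration_col=duration_col, event_col=event_col)
    return cph


def cox_univariate(df: pd.DataFrame, covariate: str,
                   duration_col: str = "os_months",
                   event_col: str = "os_event") -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron tie handling).

    Rows with a missing covariate are dropped. Degenerate fits (complete
    separation, no events, no covariate variation) are returned flagged
    ``converged=False`` rather than raising.
    """
    data = df[[duration_col, event_col, covariate]].dropna()
    n = len(data)
    events = int(data[event_col].sum())
    try:
        cph = _fit_cox(data, [covariate], duration_col, event_col)
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return CoxResult(covariate, math.nan, math.nan, math.nan, math.nan,
                         n, events, converged=False)
    row = cph.summary.loc[covariate]
    se = float(row["se(coef)"])
    converged = bool(np.isfinite(se) and se < 1e3)
    return CoxResult(
        variable=covariate,
        hr=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        p_value=float(row["p"]),
        n=n, events=events, coef=float(row["coef"]), converged=converged,
    )


@dataclass
class BackwardEliminationResult:
    screened: list[str]           # candidates passing univariate screening
    retained: list[str]           # covariates in the final model
    results: list[CoxResult]      # final-model per-covariate results
    removal_steps: list[tuple[str, float]] = dc_field(default_factory=list)


def cox_multivariate_backward(df: pd.DataFrame, candidates: list[str],
                              config: AnalysisConfig | None = None,
                              duration_col: str = "os_months",
                              event_col: str = "os_event",
                              ) -> BackwardEliminationResult:
    """Multivariate Cox model built by screening and backward elimination.

    Candidates enter when their univariate p-value is below
    ``config.univariate_entry_p``; the model then repeatedly drops the
    covariate whose likelihood-ratio removal test has the largest p-value,
    while that p-value is at least ``config.backward_removal_p``. An empty
    final model is a valid outcome.
    """
    config = config or AnalysisConfig()
    screened = []
    for cov in candidates:
        res = cox_univariate(df, cov, duration_col, event_col)
        if res.converged and res.p_value < config.univariate_entry_p:
            screened.append(cov)
    retained = list(screened)
    steps: list[tuple[str, float]] = []
    data = df[[duration_col, event_col, *screened]].dropna()

    def loglik(covs: list[str]) -> float:
        if not covs:  # null partial likelihood, recovered from any LR test
            cph = _fit_cox(data, [retained[0]] if retained else [screened[0]],
                           duration_col, event_col)
            return float(cph.log_likelihood_
                         - cph.log_likelihood_ratio_test().test_statistic / 2)
        return float(_fit_cox(data, covs, duration_col, event_col).log_likelihood_)

    while retained:
        ll_full = loglik(retained)
        removal_p = {}
        for cov in retained:
            reduced = [c for c in retained if c != cov]
            lr = max(2 * (ll_full - loglik(reduced)), 0.0)
            removal_p[cov] = float(st.chi2.sf(lr, df=1))
        worst = max(removal_p, key=removal_p.get)  # type: ignore[arg-type]
        if removal_p[worst] >= config.backward_removal_p:
            steps.append((worst, removal_p[worst]))
            retained.remove(worst)
        else:
            break

    results: list[CoxResult] = []
    if retained:
        cph = _fit_cox(data, retained, duration_col, event_col)
        for cov in retained:
            row = cph.summary.loc[cov]
            results.append(CoxResult(
                variable=cov, hr=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p_value=float(row["p"]), n=len(data),
                events=int(data[event_col].sum()), coef=float(row["coef"]),
            ))
    return BackwardEliminationResult(screened=screened, retained=retained,
                                     results=results, removal_steps=steps)


# ---------------------------------------------------------------------------
# subgroup forest, scenarios, summary table


def subgroup_forest(df: pd.DataFrame, score_col: str,
                    stratifiers: list[str],
                    duration_col: str = "os_months",
                    event_col: str = "os_event") -> pd.DataFrame:
    """Per-stratum univariate Cox of survival on the cluster score.

    Each continuous stratifier is dichotomized at its cohort median
    (strictly above = high); within each stratum the score (high = 1 vs
    low = 0) is fitted against overall survival. Strata where a score level
    has no events are flagged non-estimable.
    """
    rows = []
    score01 = (df[score_col] == "high").astype(float) \
        if df[score_col].dtype == object else df[score_col].astype(float)
    work = df.assign(_score=score01)
    for var in stratifiers:
        values = work[var].astype(float)
        med = float(values.dropna().median())
        for stratum, mask in (("low", values <= med), ("high", values > med)):
            sub = work[mask & values.notna()]
            n = len(sub)
            entry = {
                "variable": var, "stratum": stratum, "n": n,
                "events": int(sub[event_col].sum()) if n else 0,
                "hr": math.nan, "ci_low": math.nan, "ci_high": math.nan,
                "p_value": math.nan, "estimable": False,
            }
            events_per_level = sub.groupby("_score")[event_col].sum() if n else None
            if (
                n >= 2
                and sub["_score"].nunique() == 2
                and events_per_level is not None
                and (events_per_level > 0).all()
            ):
                res = cox_univariate(sub, "_score", duration_col, event_col)
                if res.estimable:
                    entry.update(hr=res.hr, ci_low=res.ci_low,
                                 ci_high=res.ci_high, p_value=res.p_value,
                                 estimable=True)
            rows.append(entry)
    return pd.DataFrame(rows)


def scenario_classify(score_label: str, tfh_fraction: float | None,
                      tfh_median: float) -> int | None:
    """Three-scenario classification from the score and the Tfh fraction.

    Scenario 1: score low (whatever the Tfh fraction). Scenario 2: score
    high, Tfh fraction at or below the cohort median. Scenario 3: score high,
    Tfh fraction above the median. None when the score is high but the Tfh
    fraction is undefined.
    """
    if score_label not in ("high", "low"):
        raise ValueError(f"score label must be 'high' or 'low', got {score_label!r}")
    if score_label == "low":
        return 1
    if tfh_fraction is None or (isinstance(tfh_fraction, float) and math.isnan(tfh_fraction)):
        return None
    return 3 if tfh_fraction > tfh_median else 2


def scenario_analysis(df: pd.DataFrame, config: AnalysisConfig,
                      score_col: str = "cd20_cluster_score",
                      tfh_col: str = "tfh_fraction",
                      duration_col: str = "os_months",
                      event_col: str = "os_event") -> dict:
    """Per-scenario survival at the horizon plus the k-group log-rank test."""
    tfh_median = float(df[tfh_col].dropna().median())
    scen = df.apply(
        lambda r: scenario_classify(r[score_col], r[tfh_col], tfh_median), axis=1
    )
    out: dict = {"tfh_median": tfh_median, "scenarios": {},
                 "n_unclassifiable": int(scen.isna().sum())}
    classified = df[scen.notna()].assign(_scenario=scen.dropna().astype(int))
    for s, grp in classified.groupby("_scenario"):
        surv = km_survival_at(grp[duration_col], grp[event_col],
                              config.survival_horizon)
        out["scenarios"][int(s)] = {
            "n": int(len(grp)),
            "km_at_horizon": surv.km,
            "crude_at_horizon": surv.crude,
        }
    if classified["_scenario"].nunique() >= 2 and classified[event_col].any():
        lr = logrank_test(classified[duration_col], classified[event_col],
                          classified["_scenario"])
        out["logrank_p"] = lr.p_value
        out["logrank_statistic"] = lr.statistic
    return out


def round_half_away(x: float) -> int:
    """Round half away from zero (87.5 -> 88)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


#: Categorical clinical variables summarized by table_one, with level order.
TABLE_ONE_CATEGORICALS: dict[str, list[str] | None] = {
    "sex": None, "pT": None, "pN": None, "pStage": None,
    "grade": None, "lvi": None,
}


def table_one(clinical: pd.DataFrame, group: pd.Series,
              config: AnalysisConfig | None = None) -> tuple[pd.DataFrame, dict[str, float]]:
    """Clinicopathological summary stratified by a two-level grouping.

    Categorical variables get per-group counts and percentages (percent of
    group size, rounded half away from zero) and a Pearson chi-square
    p-value; age gets median (IQR) and a Mann-Whitney p-value. Five-year
    survival status (alive/dead at the configured horizon) is derived from
    the outcome columns when present. Empty groups yield empty columns, not
    errors.
    """
    config = config or AnalysisConfig()
    group = group.reindex(clinical.index)
    levels = [lv for lv in ("low", "high") if (group == lv).any()]
    levels = levels or sorted(group.dropna().unique())
    rows = []
    pvalues: dict[str, float] = {}

    if "age" in clinical:
        for lv in levels:
            ages = clinical.loc[group == lv, "age"].dropna()
            rows.append({
                "variable": "age", "level": "median (IQR)", "group": lv,
                "count": len(ages),
                "display": (f"{ages.median():g} ({ages.quantile(.25):g}-"
                            f"{ages.quantile(.75):g})") if len(ages) else "",
            })
        groups_ages = [clinical.loc[group == lv, "age"].dropna() for lv in levels]
        if len(levels) == 2 and all(len(g) for g in groups_ages):
            pvalues["age"] = mann_whitney_u(groups_ages[0], groups_ages[1]).p_value

    derived = clinical.copy()
    if {"os_months", "os_event"}.issubset(clinical.columns):
        horizon = config.survival_horizon
        dead = clinical["os_event"].astype(bool) & (clinical["os_months"] < horizon)
        derived["survival_status"] = np.where(dead, "dead", "alive")

    cat_vars = [v for v in (*TABLE_ONE_CATEGORICALS, "survival_status")
                if v in derived.columns]
    for var in cat_vars:
        col = derived[var]
        var_levels = sorted(col.dropna().unique(), key=str)
        counts = np.zeros((len(var_levels), len(levels)))
        for j, lv in enumerate(levels):
            size = int((group == lv).sum())
            for i, vl in enumerate(var_levels):
                c = int(((group == lv) & (col == vl)).sum())
                counts[i, j] = c
                pct = round_half_away(100 * c / size) if size else None
                rows.append({
                    "variable": var, "level": str(vl), "group": lv,
                    "count": c,
                    "display": f"{c} ({pct}%)" if size else "",
                })
        if counts.shape == (len(var_levels), 2) and len(var_levels) >= 2 \
                and counts.sum(axis=0).min() > 0 and counts.sum(axis=1).min() > 0:
            pvalues[var] = chi_square(counts).p_value
    return pd.DataFrame(rows), pvalues
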