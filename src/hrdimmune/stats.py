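"""Survival and association statistics for cohort analyses.

Thin, validated wrappers around lifelines and scipy covering the tests a
chemotherapy-response cohort analysis needs: Kaplan-Meier curves with the
log-rank test, Cox proportional-hazards fits (Efron tie handling) with
Wald confidence intervals, nested-model likelihood-ratio comparison, a
time-fixed ROC/AUC at a survival horizon, Fisher's exact test with both
sidedness variants, and rank-based group comparisons (Wilcoxon rank-sum
with continuity correction, Kruskal-Wallis) with optional permutation
p-values and Benjamini-Hochberg correction across features.

All tests are two-sided by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

@dataclass
class KmResult:
    curves: dict[str, KaplanMeierFitter]
    chi2: float
    p_value: float

    def survival_at(self, t: float) -> dict[str, float]:
        """Product-limit survival probability of each group at time t."""
        return {g: float(kmf.predict(t)) for g, kmf in self.curves.items()}


def km_logrank(times, events, groups) -> KmResult:
    """Kaplan-Meier curves per group and the log-rank test across groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank test requires at least 2 groups")
    if events.sum() < 1:
        raise ValueError("log-rank test requires at least 1 event")
    curves = {}
    for g in np.unique(groups):
        kmf = KaplanMeierFitter()
        mask = groups == g
        kmf.fit(times[mask], events[mask], label=str(g))
        curves[str(g)] = kmf
    res = multivariate_logrank_test(times, groups, events)
    return KmResult(curves=curves, chi2=float(res.test_statistic), p_value=float(res.p_value))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Per-covariate estimates plus the model log-likelihood."""

    summary: pd.DataFrame  # coef, hr, ci_lower, ci_upper, p per covariate
    log_likelihood: float
    n: int
    events: int
    terms: tuple[str, ...]

    def hazard_ratio(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.summary.loc[term]
        return float(row["ci_lower"]), float(row["ci_upper"])

    def p_value(self, term: str) -> float:
        return float(self.summary.loc[term, "p"])


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
) -> CoxFit:
    """Cox proportional-hazards fit by partial-likelihood maximisation
    (Efron handling of ties); hazard ratios with 95% Wald intervals."""
    events = int(data[event_col].sum())
    if events < len(covariates) + 5:
        raise ValueError(
            f"too few events ({events}) for {len(covariates)} covariates"
        )
    df = data[[duration_col, event_col, *covariates]].copy()
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines raises ConvergenceError subtypes
        raise RuntimeError(
            f"Cox model failed to converge for covariates {covariates}: {exc}"
        ) from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        events=events,
        terms=tuple(covariates),
    )


def lr_test(nested: CoxFit, full: CoxFit) -> tuple[float, float]:
    """Likelihood-ratio comparison of nested Cox models: 2*delta-log-
    likelihood against chi-square with delta-df degrees of freedom."""
    if not set(nested.terms) <= set(full.terms):
        raise ValueError(
            f"models are not nested: {nested.terms} is not a subset of {full.terms}"
        )
    if nested.n != full.n or nested.events != full.events:
        raise ValueError("nested and full models must be fit on the same data")
    df = len(full.terms) - len(nested.terms)
    stat = max(0.0, 2.0 * (full.log_likelihood - nested.log_likelihood))
    if df == 0:
        return stat, 1.0
    return stat, float(sps.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Time-fixed ROC
# ---------------------------------------------------------------------------

def roc_at_time(scores, times, events, horizon: float = 60.0) -> float:
    """AUC of a risk score for experiencing the event by ``horizon``.

    Cases are samples with an event at or before the horizon; controls are
    samples followed event-free beyond it.  Samples censored before the
    horizon are excluded.  The AUC is the Mann-Whitney rank statistic of
    the scores (ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    case = (times <= horizon) & (events == 1)
    control = times > horizon
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError(
            f"time-fixed ROC at {horizon} needs both cases ({int(case.sum())}) "
            f"and controls ({int(control.sum())})"
        )
    x, y = scores[case], scores[control]
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[: len(x)].sum()
    u = r1 - len(x) * (len(x) + 1) / 2
    return float(u / (len(x) * len(y)))


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_two_sided: float
    p_greater: float
    p_less: float


def fisher_exact(table) -> FisherResult:
    """Fisher's exact test on a 2x2 table, reporting both sidedness
    variants (two-sided p sums hypergeometric outcomes no more probable
    than the observed one)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t < 0) or np.any(t != np.floor(t)):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(int)
    orr, p_two = sps.fisher_exact(t, alternative="two-sided")
    _, p_gt = sps.fisher_exact(t, alternative="greater")
    _, p_lt = sps.fisher_exact(t, alternative="less")
    return FisherResult(float(orr), float(p_two), float(p_gt), float(p_lt))


# ---------------------------------------------------------------------------
# Rank-based group comparisons
# ---------------------------------------------------------------------------

def _rank_sum_statistic(values: np.ndarray, mask1: np.ndarray) -> float:
    ranks = sps.rankdata(values)
    return float(ranks[mask1].sum())


def _single_compare(
    values: np.ndarray,
    groups: np.ndarray,
    method: str,
    permutations: int,
    rng: np.random.Generator,
) -> float:
    labels = np.unique(groups)
    if np.all(values == values[0]):
        warnings.warn("constant values: comparison p set to 1")
        return 1.0
    if method == "wilcoxon":
        if len(labels) != 2:
            raise ValueError("wilcoxon comparison requires exactly 2 groups")
        x = values[groups == labels[0]]
        y = values[groups == labels[1]]
        if permutations > 0:
            mask1 = groups == labels[0]
            obs = abs(_rank_sum_statistic(values, mask1) - mask1.sum() * (len(values) + 1) / 2)
            exceed = 0
            for _ in range(permutations):
                perm = rng.permutation(mask1)
                stat = abs(
                    _rank_sum_statistic(values, perm) - mask1.sum() * (len(values) + 1) / 2
                )
                if stat >= obs - 1e-12:
                    exceed += 1
            return (1 + exceed) / (1 + permutations)
        return float(
            sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    if method == "kruskal":
        samples = [values[groups == g] for g in labels]
        if permutations > 0:
            obs = sps.kruskal(*samples).statistic
            sizes = [len(s) for s in samples]
            exceed = 0
            for _ in range(permutations):
                pv = rng.permutation(values)
                parts = np.split(pv, np.cumsum(sizes)[:-1])
                if sps.kruskal(*parts).statistic >= obs - 1e-12:
                    exceed += 1
            return (1 + exceed) / (1 + permutations)
        return float(sps.kruskal(*samples).pvalue)
    raise ValueError(f"unknown method {method!r}")


def group_compare(
    values,
    groups,
    method: str = "wilcoxon",
    fdr: bool = False,
    permutations: int = 0,
    seed: int = 0,
):
    """Rank-based comparison of a variable (or a features x samples table)
    across groups.

    ``method``: "wilcoxon" (two-group rank-sum, normal approximation with
    continuity correction) or "kruskal".  With ``permutations`` > 0 the
    p-value is the add-one permutation estimate
    ``(1 + #{permuted >= observed}) / (1 + permutations)``.  For a table
    input, Benjamini-Hochberg correction across features is applied when
    ``fdr`` is set.

    Returns a float p for a vector input, or a DataFrame (p, optionally
    fdr) indexed by feature for a table input.
    """
    groups = np.asarray(groups)
    if np.unique(groups).size < 2:
        raise ValueError("need at least 2 groups")
    for g in np.unique(groups):
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    rng = np.random.default_rng(seed)
    if isinstance(values, pd.DataFrame):
        ps = {
            feat: _single_compare(
                row.to_numpy(dtype=float), groups, method, permutations, rng
            )
            for feat, row in values.iterrows()
        }
        out = pd.DataFrame({"p": pd.Series(ps)})
        if fdr:
            out["fdr"] = bh_adjust(out["p"].to_numpy())
        return out
    return _single_compare(np.asarray(values, dtype=float), groups, method, permutations, rng)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
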