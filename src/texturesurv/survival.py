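"""Group comparisons and univariate survival analysis.

Thin, opinionated wrappers around scipy and lifelines: 2x2 categorical tests
(Fisher exact by default — the variant whose p-values match typical clinical
baseline tables), Mann-Whitney U for continuous group comparisons,
Kaplan-Meier fits with restricted mean survival and its 95% CI, and the
two-group log-rank test.  Disease-free survival (DFS) is time from resection
to recurrence or death from any cause, censored at last follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

DAYS_PER_MONTH = 30.4375


def derive_dfs(resection_date: date,
               recurrence_date: date | None,
               death_date: date | None,
               last_followup_date: date) -> tuple[float, bool]:
    """Disease-free survival in months and the event indicator.

    The event is recurrence or death from any cause, whichever comes first;
    patients with neither are censored at the last follow-up.  Months are
    days / 30.4375.
    """
    event_dates = [d for d in (recurrence_date, death_date) if d is not None]
    for d in event_dates + [last_followup_date]:
        if d < resection_date:
            raise ValueError("event/follow-up date precedes the resection date")
    if event_dates:
        end = min(event_dates)
        return (end - resection_date).days / DAYS_PER_MONTH, True
    return (last_followup_date - resection_date).days / DAYS_PER_MONTH, False


def two_by_two_test(table: np.ndarray, method: str = "fisher") -> float:
    """P-value of a 2x2 contingency-table test.

    ``method`` is one of ``"fisher"`` (exact, two-sided by the
    point-probability rule; the default), ``"pearson"`` (chi-square without
    continuity correction) or ``"yates"`` (continuity-corrected chi-square).
    A zero row/column margin is an error for the chi-square variants; Fisher
    returns 1 there.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any() or t.sum() < 1:
        raise ValueError("table must be 2x2 with non-negative counts and n >= 1")
    if method == "fisher":
        return float(stats.fisher_exact(t).pvalue)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-square test undefined for a zero margin; use Fisher")
    if method == "pearson":
        return float(stats.chi2_contingency(t, correction=False)[1])
    if method == "yates":
        return float(stats.chi2_contingency(t, correction=True)[1])
    raise ValueError(f"unknown method {method!r}")


def mann_whitney(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (for the first group) and its two-sided p-value.

    Exact p when the smaller group has at most 8 observations and there are
    no ties; tie-corrected normal approximation (with continuity correction)
    otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class KMFit:
    """A Kaplan-Meier product-limit fit.

    ``mean_survival`` is the restricted mean survival time (area under the
    curve up to the largest observed time) with a Greenwood-based normal 95%
    CI.
    """

    timeline: np.ndarray
    survival: np.ndarray
    event_times: np.ndarray
    mean_survival: float
    mean_ci: tuple[float, float]
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def km_fit(times: np.ndarray, events: np.ndarray) -> KMFit:
    """Kaplan-Meier estimate with restricted mean survival and 95% CI.

    The restricted mean is the exact step-function integral of the
    product-limit curve up to the largest observed time; its variance is the
    standard Greenwood-based estimator
    ``sum_i A_i^2 d_i / (n_i (n_i - d_i))`` over event times, where ``A_i``
    is the area under the curve from ``t_i`` to the restriction time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("km_fit requires at least one subject")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter().fit(times, events)
    t_max = float(times.max())
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)

    starts = timeline[timeline < t_max]
    heights = surv[timeline < t_max]
    ends = np.r_[starts[1:], t_max]

    def _area_from(a: float) -> float:
        seg = np.clip(ends - np.maximum(starts, a), 0.0, None)
        return float(heights @ seg)

    rmst = _area_from(0.0)
    table = kmf.event_table
    var = 0.0
    for t_i, d_i, n_i in zip(table.index.to_numpy(dtype=float),
                             table["observed"].to_numpy(dtype=float),
                             table["at_risk"].to_numpy(dtype=float)):
        if d_i == 0 or t_i >= t_max or n_i == d_i:
            continue
        a_i = _area_from(t_i)
        var += a_i * a_i * d_i / (n_i * (n_i - d_i))
    se = float(np.sqrt(var))
    return KMFit(
        timeline=timeline,
        survival=surv,
        event_times=np.unique(times[events]),
        mean_survival=float(rmst),
        mean_ci=(float(rmst - 1.959963984540054 * se), float(rmst + 1.959963984540054 * se)),
        n=int(times.size),
        n_events=int(events.sum()),
    )


@dataclass
class LogRankResult:
    """Two-group log-rank test (chi-squared, 1 df)."""

    statistic: float
    p_value: float


def logrank(times: np.ndarray, events: np.ndarray, group: np.ndarray) -> LogRankResult:
    """Standard observed-minus-expected log-rank test between two groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError("logrank requires exactly two non-empty groups")
    if not events.any():
        raise ValueError("logrank requires at least one event")
    in_b = group == labels[1]
    res = _lifelines_logrank(times[~in_b], times[in_b], events[~in_b], events[in_b])
    return LogRankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))
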