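"""Cox proportional hazards with hierarchical forward-stepwise selection.

The partial likelihood is maximized by Newton-Raphson with step halving;
tied event times are handled by the Breslow approximation by default (the
behaviour of the classic clinical statistics packages) with Efron as an
option.  Variables enter the model one at a time, each step adding the
candidate with the smallest likelihood-ratio p-value among those below the
entry threshold; there is no removal step.  Candidates are pre-screened by a
univariate log-rank test (or Mann-Whitney on the continuous feature) at the
same threshold, mirroring the convention of entering only variables
significant in univariate Kaplan-Meier analysis.

Per-variable reporting is Wald-based: hazard ratio ``exp(beta)``, 95% CI
``exp(beta +/- 1.96 se)``, and the two-sided normal p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cutpoint import CutoffResult, dichotomize
from .survival import logrank, mann_whitney
from .texture import FEATURE_NAMES

_Z975 = 1.959963984540054


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to maximize the partial likelihood."""


def _partial_loglik_derivs(beta: np.ndarray, X: np.ndarray, times: np.ndarray,
                           events: np.ndarray, ties: str
                           ) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient, and information (negative Hessian)."""
    n, k = X.shape
    order = np.argsort(-times, kind="stable")
    ts, Xs, es = times[order], X[order], events[order]
    eta = Xs @ beta if k else np.zeros(n)
    w = np.exp(eta)

    cum0 = np.cumsum(w)
    cum1 = np.cumsum(w[:, None] * Xs, axis=0) if k else np.zeros((n, 0))
    xxw = w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]) if k else np.zeros((n, 0, 0))
    cum2 = np.cumsum(xxw, axis=0)

    ll = 0.0
    grad = np.zeros(k)
    info = np.zeros((k, k))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        d_idx = np.arange(i, j + 1)[es[i : j + 1]]
        d = d_idx.size
        if d:
            S0, S1, S2 = cum0[j], cum1[j], cum2[j]
            ll += float(eta[d_idx].sum())
            grad += Xs[d_idx].sum(axis=0)
            if ties == "breslow":
                ll -= d * np.log(S0)
                m = S1 / S0
                grad -= d * m
                info += d * (S2 / S0 - np.outer(m, m))
            elif ties == "efron":
                s0d = w[d_idx].sum()
                s1d = (w[d_idx, None] * Xs[d_idx]).sum(axis=0)
                s2d = (w[d_idx, None, None] * Xs[d_idx, :, None] * Xs[d_idx, None, :]).sum(axis=0)
                for r in range(d):
                    f = r / d
                    S0r = S0 - f * s0d
                    S1r = S1 - f * s1d
                    S2r = S2 - f * s2d
                    ll -= np.log(S0r)
                    m = S1r / S0r
                    grad -= m
                    info += S2r / S0r - np.outer(m, m)
            else:
                raise ValueError(f"unknown tie handling {ties!r}")
        i = j + 1
    return ll, grad, info


@dataclass
class CoxFit:
    """A fitted Cox model."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    ties: str
    n: int
    n_events: int
    n_iter: int
    converged: bool

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def hr_ci(self) -> np.ndarray:
        lo = np.exp(self.coef - _Z975 * self.se)
        hi = np.exp(self.coef + _Z975 * self.se)
        return np.column_stack([lo, hi])

    @property
    def p_values(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        ci = self.hr_ci
        return pd.DataFrame({
            "variable": self.names,
            "coef": self.coef,
            "hr": self.hr,
            "hr_ci_low": ci[:, 0],
            "hr_ci_high": ci[:, 1],
            "p_value": self.p_values,
        })


def cox_fit(X: np.ndarray, times: np.ndarray, events: np.ndarray,
            names: list[str] | None = None, ties: str = "breslow",
            max_iter: int = 60, tol: float = 1e-9) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton-Raphson.

    Raises :class:`ConvergenceError` on non-convergence and flags monotone
    likelihood (separation) when a coefficient diverges.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and np.asarray(times).size != 1:
        X = X.T
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n, k = X.shape
    if names is None:
        names = [f"x{i}" for i in range(k)]
    if not events.any():
        raise ValueError("Cox model requires at least one event")

    ll_null, _, _ = _partial_loglik_derivs(np.zeros(0), X[:, :0], times, events, ties)
    beta = np.zeros(k)
    ll, grad, info = _partial_loglik_derivs(beta, X, times, events, ties)
    n_iter = 0
    for n_iter in range(1, (max_iter + 1) if k else 1):
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # Step halving keeps the likelihood monotone.
        for _ in range(30):
            cand = beta + step
            ll_new, grad_new, info_new = _partial_loglik_derivs(cand, X, times, events, ties)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.max(np.abs(beta)) > 20.0:
            raise ConvergenceError(
                "monotone partial likelihood (separation): coefficient diverged "
                f"for {names[int(np.argmax(np.abs(beta)))]!r}"
            )
    converged = bool(np.max(np.abs(grad)) < 1e-6) if k else True
    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(max |gradient| = {np.max(np.abs(grad)):.2e})"
        )
    cov = np.linalg.inv(info) if k else np.zeros((0, 0))
    return CoxFit(
        names=list(names), coef=beta, se=np.sqrt(np.diag(cov)), cov=cov,
        loglik=float(ll), loglik_null=float(ll_null), ties=ties,
        n=n, n_events=int(events.sum()), n_iter=n_iter, converged=converged,
    )


def cox_score_test(x: np.ndarray, times: np.ndarray, events: np.ndarray,
                   ties: str = "breslow") -> float:
    """Score (Rao) test statistic for a single covariate at beta = 0.

    Without tied event times this equals the two-group log-rank chi-square
    when ``x`` is a binary group indicator.
    """
    X = np.asarray(x, dtype=float).reshape(-1, 1)
    _, g, info = _partial_loglik_derivs(np.zeros(1), X,
                                        np.asarray(times, float),
                                        np.asarray(events, bool), ties)
    return float(g[0] ** 2 / info[0, 0])


@dataclass
class CoxResult:
    """Outcome of one forward-stepwise Cox model."""

    selected_variables: list[str]
    hr: dict[str, float]
    hr_ci: dict[str, tuple[float, float]]
    p_value: dict[str, float]
    step_trace: list[dict]
    fit: CoxFit | None
    excluded: dict[str, str] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        if self.fit is None:
            return pd.DataFrame(
                columns=["variable", "coef", "hr", "hr_ci_low", "hr_ci_high", "p_value"]
            )
        return self.fit.summary()


def cox_forward_stepwise(covariates: pd.DataFrame, times: np.ndarray,
                         events: np.ndarray, entry_p: float = 0.05,
                         ties: str = "breslow",
                         prescreen: bool = True) -> CoxResult:
    """Hierarchical forward-stepwise Cox model on dichotomized covariates.

    ``covariates`` holds one 0/1 (or numeric) column per candidate variable.
    Constant columns are excluded with a "no variation" flag; with
    ``prescreen=True`` candidates must first pass a univariate log-rank test
    at ``entry_p``.  Each step adds the candidate with the smallest
    likelihood-ratio p-value below ``entry_p``; variables causing separation
    are flagged and skipped.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    excluded: dict[str, str] = {}
    candidates: list[str] = []
    for name in covariates.columns:
        col = covariates[name].to_numpy(dtype=float)
        if np.unique(col).size < 2:
            excluded[name] = "no variation"
            continue
        if prescreen:
            try:
                if np.unique(col).size == 2:
                    p = logrank(times, events, col).p_value
                else:
                    # Non-binary candidate: univariate Cox score test.
                    p = float(stats.chi2.sf(cox_score_test(col, times, events, ties), 1))
            except ValueError:
                excluded[name] = "univariate screen not applicable"
                continue
            if p >= entry_p:
                excluded[name] = f"univariate screen p = {p:.4f}"
                continue
        candidates.append(name)

    selected: list[str] = []
    trace: list[dict] = []
    ll_cur = cox_fit(np.empty((times.size, 0)), times, events, names=[], ties=ties).loglik
    remaining = list(candidates)
    step = 0
    while remaining:
        step += 1
        best: tuple[float, str, CoxFit] | None = None
        step_ps: dict[str, float] = {}
        for name in list(remaining):
            cols = selected + [name]
            try:
                fit = cox_fit(covariates[cols].to_numpy(dtype=float), times, events,
                              names=cols, ties=ties)
            except ConvergenceError:
                excluded[name] = "separation / non-convergence"
                remaining.remove(name)
                continue
            lr = 2.0 * (fit.loglik - ll_cur)
            p = float(stats.chi2.sf(max(lr, 0.0), 1))
            step_ps[name] = p
            if best is None or p < best[0]:
                best = (p, name, fit)
        if best is None or best[0] >= entry_p:
            break
        p, name, fit = best
        selected.append(name)
        remaining.remove(name)
        ll_cur = fit.loglik
        trace.append({"step": step, "added": name, "lr_p": p,
                      "loglik": fit.loglik, "candidate_p": step_ps})

    if not selected:
        return CoxResult([], {}, {}, {}, trace, None, excluded)
    fit = cox_fit(covariates[selected].to_numpy(dtype=float), times, events,
                  names=selected, ties=ties)
    ci = fit.hr_ci
    return CoxResult(
        selected_variables=selected,
        hr={n: float(h) for n, h in zip(selected, fit.hr)},
        hr_ci={n: (float(ci[i, 0]), float(ci[i, 1])) for i, n in enumerate(selected)},
        p_value={n: float(p) for n, p in zip(selected, fit.p_values)},
        step_trace=trace,
        fit=fit,
        excluded=excluded,
    )


def feature_column(name: str, sigma: float) -> str:
    """Canonical feature-table column name, e.g. ``average_1.5``."""
    return f"{name}_{sigma:g}"


def per_filter_cox(features: pd.DataFrame, clinical: pd.DataFrame,
                   cutoffs: dict[str, CutoffResult],
                   sigmas: tuple[float, ...],
                   entry_p: float = 0.05, ties: str = "breslow",
                   screen: str = "logrank") -> dict[float, CoxResult]:
    """One stepwise Cox model per filter scale.

    For each sigma the candidate set is that scale's texture features,
    dichotomized at their ROC cutoffs and coded as the indicator of the
    *above-cutoff* group (so hazard ratios compare ``> cutoff`` against
    ``<= cutoff`` regardless of which side is high-risk), plus nodal status
    coded positive = 1.  ``screen`` selects the univariate filter applied
    before stepwise entry: ``"logrank"`` on the dichotomized variable (the
    default), ``"mannwhitney"`` on the continuous feature between recurrence
    groups, or ``"none"``.
    """
    if screen not in ("logrank", "mannwhitney", "none"):
        raise ValueError(f"unknown screen {screen!r}")
    times = clinical["dfs_months"].to_numpy(dtype=float)
    events = clinical["event"].to_numpy(dtype=bool)
    nodal = (clinical["nodal_status"] == "positive").to_numpy(dtype=float)
    recur = clinical["recurrence"].to_numpy(dtype=bool)

    out: dict[float, CoxResult] = {}
    for sigma in sigmas:
        cols = {}
        excluded: dict[str, str] = {}
        for name in FEATURE_NAMES:
            col = feature_column(name, sigma)
            if col not in features.columns or col not in cutoffs:
                continue
            vals = features[col].to_numpy(dtype=float)
            cut = cutoffs[col]
            above = dichotomize(vals, cut.cutoff, "gt").astype(float)
            if np.unique(above).size < 2:
                excluded[name] = "no variation"
                continue
            if screen == "mannwhitney":
                _, p = mann_whitney(vals[recur], vals[~recur])
            elif screen == "logrank":
                try:
                    p = logrank(times, events, above).p_value
                except ValueError:
                    excluded[name] = "univariate screen not applicable"
                    continue
            else:
                p = 0.0
            if p >= entry_p and screen != "none":
                excluded[name] = f"univariate screen p = {p:.4f}"
                continue
            cols[name] = above
        # Nodal status is always screened by univariate log-rank (unless no screen).
        include_nodal = True
        if screen != "none" and np.unique(nodal).size == 2:
            try:
                include_nodal = logrank(times, events, nodal).p_value < entry_p
            except ValueError:
                include_nodal = False
        if include_nodal and np.unique(nodal).size == 2:
            cols["nodal"] = nodal
        elif "nodal" not in excluded:
            excluded["nodal"] = "univariate screen failed or no variation"
        X = pd.DataFrame(cols, index=clinical.index)
        result = cox_forward_stepwise(
            X, times, events, entry_p=entry_p, ties=ties, prescreen=False,
        )
        result.excluded.update(excluded)
        out[float(sigma)] = result
    return out
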