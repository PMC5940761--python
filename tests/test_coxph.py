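"""Cox partial likelihood, Newton-Raphson fit, and forward-stepwise selection."""

import math

import numpy as np
import pandas as pd
import pytest

from texturesurv import SyntheticConfig, youden_cutoff
from texturesurv.coxph import (
    ConvergenceError,
    cox_fit,
    cox_forward_stepwise,
    cox_score_test,
    feature_column,
    per_filter_cox,
    _partial_loglik_derivs,
)
from texturesurv.survival import logrank
from texturesurv.synthetic import generate_clinical_cohort, records_to_frame


def _random_survival(rng, n=40, beta=0.8, k=1):
    X = rng.normal(size=(n, k))
    t = rng.exponential(1 / np.exp(X @ np.full(k, beta)))
    t = np.round(t, 3) + 1e-4  # occasional ties
    e = rng.random(n) < 0.75
    if not e.any():
        e[0] = True
    return X, t, e


class TestCoxFit:
    def test_matches_brute_force_likelihood_grid(self):
        # Four subjects, one binary covariate, no ties: grid-search the
        # hand-written partial likelihood and compare the maximizer.
        x = np.array([1.0, 0.0, 1.0, 0.0])
        times = np.array([2.0, 4.0, 5.0, 7.0])
        events = np.array([1, 1, 1, 0], bool)

        def pl(beta):
            # Event at t=2 (x=1): risk {all}; t=4 (x=0): risk {x=0,1,0};
            # t=5 (x=1): risk {x=1,0}.
            import numpy as np
            w = np.exp(beta * x)
            return (math.log(w[0] / w.sum())
                    + math.log(w[1] / (w[1] + w[2] + w[3]))
                    + math.log(w[2] / (w[2] + w[3])))

        grid = np.arange(-3, 3, 1e-4)
        best = grid[np.argmax([pl(b) for b in grid])]
        fit = cox_fit(x, times, events)
        assert fit.coef[0] == pytest.approx(best, abs=1e-4)

    def test_gradient_vanishes_at_solution(self, rng):
        for _ in range(10):
            X, t, e = _random_survival(rng, k=2)
            fit = cox_fit(X, t, e)
            _, grad, _ = _partial_loglik_derivs(fit.coef, X, t, e, "breslow")
            assert np.linalg.norm(grad) < 1e-6

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_matches_lifelines(self, rng, ties):
        # lifelines implements Efron ties; compare on tie-free data for
        # breslow (both reduce to the same likelihood) and tied for efron.
        from lifelines import CoxPHFitter

        X = rng.normal(size=(60, 2))
        t = rng.exponential(1 / np.exp(0.5 * X[:, 0] - 0.3 * X[:, 1]))
        if ties == "efron":
            t = np.ceil(t * 8) / 8  # introduce ties
        e = rng.random(60) < 0.8
        fit = cox_fit(X, t, e, ties=ties)
        df = pd.DataFrame({"t": t, "e": e, "x0": X[:, 0], "x1": X[:, 1]})
        ref = CoxPHFitter().fit(df, "t", "e")
        assert fit.coef == pytest.approx(ref.params_.to_numpy(), abs=1e-4)
        assert fit.se == pytest.approx(ref.standard_errors_.to_numpy(), abs=1e-4)
        assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-5)

    def test_score_test_equals_logrank_without_ties(self, rng):
        for _ in range(10):
            n = 30
            t = rng.permutation(np.arange(1, n + 1)).astype(float)  # no ties
            e = rng.random(n) < 0.8
            g = rng.random(n) < 0.5
            if e.sum() == 0 or g.all() or not g.any():
                continue
            stat = cox_score_test(g.astype(float), t, e)
            ref = logrank(t, e, g).statistic
            assert stat == pytest.approx(ref, abs=1e-6)

    def test_separation_raises(self):
        # Perfectly ordered covariate: monotone likelihood.
        x = np.array([1, 1, 1, 0, 0, 0.0])
        t = np.array([1, 2, 3, 10, 11, 12.0])
        e = np.ones(6, bool)
        with pytest.raises(ConvergenceError):
            cox_fit(x, t, e)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(np.ones((3, 1)), np.arange(1.0, 4.0), np.zeros(3, bool))


class TestForwardStepwise:
    def test_strong_effect_selected(self, rng):
        n = 150
        x = (rng.random(n) < 0.5).astype(float)
        noise = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1 / np.exp(1.2 * x)) + 0.01
        e = rng.random(n) < 0.85
        cov = pd.DataFrame({"signal": x, "noise": noise})
        res = cox_forward_stepwise(cov, t, e)
        assert "signal" in res.selected_variables
        assert res.hr["signal"] > 1
        lo, hi = res.hr_ci["signal"]
        assert lo <= res.hr["signal"] <= hi

    def test_constant_covariate_flagged(self, rng):
        n = 60
        t = rng.exponential(1, n) + 0.01
        e = np.ones(n, bool)
        cov = pd.DataFrame({"flat": np.ones(n)})
        res = cox_forward_stepwise(cov, t, e)
        assert res.excluded["flat"] == "no variation"
        assert res.selected_variables == []

    def test_step_trace_contains_selected(self, rng):
        n = 200
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1 / np.exp(0.9 * x1 + 0.7 * x2)) + 0.01
        e = rng.random(n) < 0.9
        res = cox_forward_stepwise(pd.DataFrame({"a": x1, "b": x2}), t, e)
        traced = [step["added"] for step in res.step_trace]
        assert set(res.selected_variables) <= set(traced)

    def test_nodal_hr_recovery_in_stepwise(self):
        cfg = SyntheticConfig(n_patients=1000, seed=11,
                              hazard_coefficients={"nodal": math.log(2.0)})
        df = records_to_frame(generate_clinical_cohort(cfg))
        cov = pd.DataFrame({"nodal": (df.nodal_status == "positive").astype(float)})
        res = cox_forward_stepwise(cov, df.dfs_months.to_numpy(),
                                   df.event.to_numpy(bool))
        assert res.selected_variables == ["nodal"]
        assert 1.7 <= res.hr["nodal"] <= 2.3


class TestPerFilterCox:
    @staticmethod
    def _toy_inputs(seed=0, n=120):
        rng = np.random.default_rng(seed)
        cfg = SyntheticConfig(n_patients=n, seed=seed)
        clin = records_to_frame(generate_clinical_cohort(cfg))
        sigmas = (0.0, 1.0, 1.5, 2.0, 2.5)
        feats = {}
        for sg in sigmas:
            for name in ("average", "standard_deviation"):
                true = clin.true_mean_hu if name == "average" else clin.true_sd_hu
                feats[feature_column(name, sg)] = true + rng.normal(0, 1, n)
        features = pd.DataFrame(feats)
        labels = clin.recurrence.to_numpy(bool)
        cutoffs = {c: youden_cutoff(features[c].to_numpy(), labels, feature_id=c)
                   for c in features.columns}
        return features, clin, cutoffs, sigmas

    def test_five_filter_blocks_give_five_models(self):
        features, clin, cutoffs, sigmas = self._toy_inputs()
        out = per_filter_cox(features, clin, cutoffs, sigmas=sigmas)
        assert sorted(out) == [0.0, 1.0, 1.5, 2.0, 2.5]

    def test_mannwhitney_screen_switch_runs(self):
        features, clin, cutoffs, sigmas = self._toy_inputs()
        out = per_filter_cox(features, clin, cutoffs, sigmas=(0.0,),
                             screen="mannwhitney")
        assert 0.0 in out

    def test_null_cohort_rarely_selects_texture(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(800 + s)
            cfg = SyntheticConfig(n_patients=88, seed=800 + s,
                                  hazard_coefficients={"average": 0.0, "sd": 0.0,
                                                       "nodal": 0.0})
            clin = records_to_frame(generate_clinical_cohort(cfg))
            # Features unrelated to outcome by construction.
            features = pd.DataFrame({
                feature_column("average", 0.0): rng.normal(size=88),
                feature_column("standard_deviation", 0.0): rng.normal(size=88),
            })
            labels = clin.recurrence.to_numpy(bool)
            cutoffs = {c: youden_cutoff(features[c].to_numpy(), labels,
                                        feature_id=c)
                       for c in features.columns}
            res = per_filter_cox(features, clin, cutoffs, sigmas=(0.0,))[0.0]
            hits += bool([v for v in res.selected_variables if v != "nodal"])
        assert hits <= 5
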