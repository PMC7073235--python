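"""Diagnostic logistic regression, bivariate meta-analysis, heterogeneity."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from mirnetdx.meta import (
    Study2x2,
    bayesian_meta,
    fit_diagnostic_lr,
    heterogeneity_i2,
)
from mirnetdx.synthetic import CohortSpec, generate_mirna_cohorts, generate_study_tables

FAST_MCMC = dict(chains=2, iterations=3000)


def _expr(x, ids=None):
    x = np.asarray(x, dtype=float)
    idx = ids or [f"s{i}" for i in range(len(x))]
    return pd.DataFrame({"bm": x}, index=idx)


class TestStudy2x2:
    def test_margins_and_validation(self):
        s = Study2x2("a", tp=8, fn=2, tn=9, fp=1)
        assert s.cases == 10 and s.controls == 10
        assert s.sensitivity == 0.8 and s.specificity == 0.9
        with pytest.raises(ValueError):
            Study2x2("b", tp=-1, fn=2, tn=3, fp=4)
        with pytest.raises(ValueError):
            Study2x2("c", tp=0, fn=0, tn=3, fp=4)


class TestDiagnosticLR:
    def test_perfectly_separable_gives_perfect_table(self):
        x = np.r_[np.full(10, 5.0) + np.arange(10) * 0.01, np.zeros(10)]
        labels = ["case"] * 10 + ["control"] * 10
        table, coef = fit_diagnostic_lr(_expr(x), labels)
        assert (table.tp, table.tn, table.fp, table.fn) == (10, 10, 0, 0)
        assert coef[0] > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_diagnostic_lr(_expr(np.arange(6)), ["case"] * 6)

    def test_null_accuracy_near_chance(self):
        rng = np.random.default_rng(4)
        ses, sps = [], []
        for _ in range(30):
            x = rng.normal(size=400)
            labels = ["case"] * 200 + ["control"] * 200
            t, _ = fit_diagnostic_lr(_expr(x), labels)
            ses.append(t.sensitivity)
            sps.append(t.specificity)
        assert abs(np.mean(ses) - 0.5) < 0.06
        assert abs(np.mean(sps) - 0.5) < 0.06

    def test_combined_biomarkers_beat_singles(self):
        """Two informative markers: combined se+sp >= singles, most seeds."""
        wins = 0
        for seed in range(7):
            spec = CohortSpec(n_studies=1, cases_per_study=150,
                              controls_per_study=150, mu_se=float(logit(0.75)),
                              mu_sp=float(logit(0.75)), tau_se=0.0, tau_sp=0.0,
                              rho=0.0, seed=seed)
            cohorts, _ = generate_mirna_cohorts(["a", "b"], spec)
            expr, labels = next(iter(cohorts.values()))
            both, _ = fit_diagnostic_lr(expr, labels)
            single_best = max(
                fit_diagnostic_lr(expr[[c]], labels)[0].sensitivity
                + fit_diagnostic_lr(expr[[c]], labels)[0].specificity
                for c in ("a", "b")
            )
            wins += (both.sensitivity + both.specificity) >= single_best
        assert wins >= 4

    def test_youden_cutoff_not_worse_in_sample(self):
        rng = np.random.default_rng(9)
        x = np.r_[rng.normal(1.0, 1, 50), rng.normal(0, 1, 50)]
        labels = ["case"] * 50 + ["control"] * 50
        fixed, _ = fit_diagnostic_lr(_expr(x), labels, cutoff=0.5)
        youden, _ = fit_diagnostic_lr(_expr(x), labels, cutoff="youden")
        assert (youden.sensitivity + youden.specificity
                >= fixed.sensitivity + fixed.specificity)


class TestBayesianMeta:
    def test_no_heterogeneity_limit_matches_pooled_mle(self):
        """tau = 0 truth, identical large studies: posterior ~ pooled MLE."""
        spec = CohortSpec(n_studies=10, cases_per_study=300,
                          controls_per_study=300, mu_se=float(logit(0.8)),
                          mu_sp=float(logit(0.85)), tau_se=0.0, tau_sp=0.0,
                          rho=0.0, seed=3)
        studies, _ = generate_study_tables(spec)
        mle_se = sum(s.tp for s in studies) / sum(s.cases for s in studies)
        mle_sp = sum(s.tn for s in studies) / sum(s.controls for s in studies)
        post = bayesian_meta(studies, seed=1, **FAST_MCMC)
        assert abs(post.pooled_se - mle_se) < 0.02
        assert abs(post.pooled_sp - mle_sp) < 0.02

    def test_doubling_counts_narrows_credible_interval(self):
        spec = CohortSpec(n_studies=8, cases_per_study=40, controls_per_study=40,
                          tau_se=0.2, tau_sp=0.2, seed=5)
        studies, _ = generate_study_tables(spec)
        doubled = [
            Study2x2(s.study_id, tp=2 * s.tp, fp=2 * s.fp, tn=2 * s.tn, fn=2 * s.fn)
            for s in studies
        ]
        p1 = bayesian_meta(studies, seed=2, **FAST_MCMC)
        p2 = bayesian_meta(doubled, seed=2, **FAST_MCMC)
        assert (p2.ci_se[1] - p2.ci_se[0]) < (p1.ci_se[1] - p1.ci_se[0])

    def test_case_control_swap_symmetry(self):
        spec = CohortSpec(n_studies=12, cases_per_study=80, controls_per_study=60,
                          mu_se=float(logit(0.8)), mu_sp=float(logit(0.7)),
                          tau_se=0.25, tau_sp=0.25, rho=-0.2, seed=6)
        studies, _ = generate_study_tables(spec)
        swapped = [
            Study2x2(s.study_id, tp=s.tn, fn=s.fp, tn=s.tp, fp=s.fn)
            for s in studies
        ]
        p1 = bayesian_meta(studies, seed=3, **FAST_MCMC)
        p2 = bayesian_meta(swapped, seed=3, **FAST_MCMC)
        assert abs(p1.pooled_se - p2.pooled_sp) < 0.02
        assert abs(p1.pooled_sp - p2.pooled_se) < 0.02

    def test_predictive_interval_at_least_credible_width(self):
        spec = CohortSpec(n_studies=15, cases_per_study=100,
                          controls_per_study=100, tau_se=0.5, tau_sp=0.5, seed=7)
        studies, _ = generate_study_tables(spec)
        post = bayesian_meta(studies, seed=4, **FAST_MCMC)
        assert (post.pred_interval_se[1] - post.pred_interval_se[0]
                >= post.ci_se[1] - post.ci_se[0])
        assert 0.0 <= post.pred_se <= 1.0 and 0.0 <= post.pooled_se <= 1.0

    def test_heterogeneity_widens_predictive_interval(self):
        widths = []
        for tau in (0.0, 0.5, 1.0):
            spec = CohortSpec(n_studies=20, cases_per_study=150,
                              controls_per_study=150, tau_se=tau, tau_sp=tau,
                              rho=0.0, seed=8)
            studies, _ = generate_study_tables(spec)
            post = bayesian_meta(studies, seed=5, **FAST_MCMC)
            widths.append(post.pred_interval_se[1] - post.pred_interval_se[0])
        assert widths[0] < widths[1] < widths[2]

    def test_robust_agrees_with_gaussian_without_outliers(self):
        spec = CohortSpec(n_studies=15, cases_per_study=100,
                          controls_per_study=100, tau_se=0.2, tau_sp=0.2, seed=9)
        studies, _ = generate_study_tables(spec)
        g = bayesian_meta(studies, robust=False, seed=6, **FAST_MCMC)
        r = bayesian_meta(studies, robust=True, seed=6, **FAST_MCMC)
        assert abs(g.pooled_se - r.pooled_se) < 0.03
        assert abs(g.pooled_sp - r.pooled_sp) < 0.03


class TestHeterogeneity:
    def test_identical_studies_zero(self):
        studies = [Study2x2(f"s{i}", tp=40, fn=10, tn=45, fp=5) for i in range(5)]
        for margin in ("sensitivity", "specificity"):
            res = heterogeneity_i2(studies, margin)
            assert res.q == pytest.approx(0.0, abs=1e-12)
            assert res.i2 == 0.0

    def test_two_discordant_studies_closed_form(self):
        """se 45/50 vs 25/50: Q computed by hand exceeds the 75% band."""
        studies = [
            Study2x2("a", tp=45, fn=5, tn=1, fp=1),
            Study2x2("b", tp=25, fn=25, tn=1, fp=1),
        ]
        res = heterogeneity_i2(studies, "sensitivity")
        # independent closed form: w = 1/(1/x + 1/(n-x)), Q = sum w (y - ybar)^2
        y = np.array([np.log(45 / 5), np.log(25 / 25)])
        w = 1.0 / np.array([1 / 45 + 1 / 5, 1 / 25 + 1 / 25])
        ybar = (w * y).sum() / w.sum()
        q = float((w * (y - ybar) ** 2).sum())
        assert res.q == pytest.approx(q)
        assert res.i2 > 75.0

    def test_zero_cells_continuity_corrected(self):
        studies = [
            Study2x2("a", tp=50, fn=0, tn=10, fp=10),
            Study2x2("b", tp=30, fn=20, tn=10, fp=10),
        ]
        res = heterogeneity_i2(studies, "sensitivity")
        assert np.isfinite(res.q) and 0.0 <= res.i2 <= 100.0

    def test_needs_two_studies(self):
        with pytest.raises(ValueError):
            heterogeneity_i2([Study2x2("a", tp=1, fn=1, tn=1, fp=1)])
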