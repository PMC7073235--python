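"""Generator contracts: determinism, planted ground truth, calibration."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit
from scipy.stats import kstest

from mirnetdx.synthetic import (
    CohortSpec,
    ExpressionSpec,
    InteractomeSpec,
    generate_expression,
    generate_interactome,
    generate_mirna_cohorts,
    generate_study_tables,
    generate_survival,
)


class TestInteractome:
    def test_single_regulator_fixed_degree(self):
        """One miRNA, degenerate degree law: every target is exclusive."""
        spec = InteractomeSpec(n_mirna=1, n_gene=3, mean_targets_per_mirna=3,
                               degree_dispersion=0.0, tf_fraction=0.0, seed=0)
        inter, _ = generate_interactome(spec)
        assert len(inter.edges) == 3
        reg = Counter(g for _, g in inter.edges)
        assert all(c == 1 for c in reg.values())

    def test_deterministic_given_seed(self):
        spec = InteractomeSpec(n_mirna=20, n_gene=200, mean_targets_per_mirna=15,
                               planted_biomarkers=("b1", "b2"),
                               planted_exclusive_targets=4, seed=11)
        a, ta = generate_interactome(spec)
        b, tb = generate_interactome(spec)
        assert a.edges == b.edges and ta == tb

    def test_planted_exclusive_targets_are_exact_ground_truth(self):
        spec = InteractomeSpec(n_mirna=15, n_gene=300, mean_targets_per_mirna=10,
                               planted_biomarkers=("b1",),
                               planted_exclusive_targets=5, seed=3)
        inter, truth = generate_interactome(spec)
        reg = Counter(g for _, g in inter.edges)
        for g in truth.exclusive["b1"]:
            assert reg[g] == 1 and (("b1", g) in set(inter.edges))
        # brute-force exclusive count is at least the planted number
        excl = sum(
            1 for m, g in inter.edges if m == "b1" and reg[g] == 1
        )
        assert excl >= 5

    def test_planted_tf_share_meets_boost(self):
        spec = InteractomeSpec(n_mirna=30, n_gene=500, mean_targets_per_mirna=20,
                               tf_fraction=0.1, planted_biomarkers=("b1",),
                               planted_exclusive_targets=4,
                               planted_tf_boost=0.3, seed=5)
        inter, truth = generate_interactome(spec)
        targets = {g for m, g in inter.edges if m == "b1"}
        non_excl = targets - set(truth.exclusive["b1"])
        share = len(non_excl & inter.tf_genes) / len(non_excl)
        assert share >= 0.3

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            InteractomeSpec(n_mirna=0, n_gene=10)
        with pytest.raises(ValueError):
            InteractomeSpec(n_mirna=2, n_gene=10, tf_fraction=0.0,
                            planted_biomarkers=("b",), planted_tf_boost=0.5)


class TestExpression:
    def _inter(self, seed=0):
        return generate_interactome(
            InteractomeSpec(n_mirna=5, n_gene=100, mean_targets_per_mirna=20,
                            seed=seed)
        )[0]

    def test_truth_set_bookkeeping(self):
        inter = self._inter()
        for k in (0, 7, 30):
            spec = ExpressionSpec(n_de_genes=k, seed=2, n_cases=4, n_controls=4)
            _, _, truth = generate_expression(inter, spec)
            assert len(truth) == k

    def test_must_de_always_included(self):
        inter = self._inter()
        must = sorted(inter.genes)[:5]
        spec = ExpressionSpec(n_de_genes=10, seed=2, n_cases=4, n_controls=4)
        _, _, truth = generate_expression(inter, spec, must_de=must)
        assert set(must) <= truth and len(truth) == 10

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ExpressionSpec(n_cases=1, n_controls=10)

    def test_deterministic_and_platforms_shaped(self):
        inter = self._inter()
        for platform in ("array", "counts"):
            spec = ExpressionSpec(platform=platform, n_de_genes=5, seed=8,
                                  n_cases=3, n_controls=4)
            m1, l1, t1 = generate_expression(inter, spec)
            m2, _, t2 = generate_expression(inter, spec)
            pd.testing.assert_frame_equal(m1, m2)
            assert t1 == t2
            assert m1.shape == (len(inter.genes), 7)
        assert (m1.to_numpy() >= 0).all()  # counts platform emits counts


class TestCohorts:
    def test_degenerate_random_effects_share_one_accuracy(self):
        spec = CohortSpec(n_studies=5, tau_se=0.0, tau_sp=0.0, rho=0.0, seed=1)
        _, truth = generate_mirna_cohorts(["m"], spec)
        assert truth["se"].nunique() == 1 and truth["sp"].nunique() == 1

    def test_zero_logit_means_chance_accuracy(self):
        spec = CohortSpec(n_studies=4, mu_se=0.0, mu_sp=0.0, tau_se=0.0,
                          tau_sp=0.0, rho=0.0, seed=2)
        _, truth = generate_mirna_cohorts(["m"], spec)
        assert np.allclose(truth["se"], 0.5) and np.allclose(truth["sp"], 0.5)

    def test_threshold_classifier_attains_drawn_accuracy(self):
        """Empirical (se, sp) of the calibrated threshold matches the draw."""
        spec = CohortSpec(n_studies=3, cases_per_study=4000,
                          controls_per_study=4000, mu_se=float(logit(0.8)),
                          mu_sp=float(logit(0.7)), tau_se=0.2, tau_sp=0.2,
                          rho=-0.3, seed=3)
        cohorts, truth = generate_mirna_cohorts(["m"], spec)
        for study, (expr, labels) in cohorts.items():
            x = expr["m"].to_numpy()
            y = (labels == "case").to_numpy()
            thr = truth.loc[study, "threshold"]
            se_hat = np.mean(x[y] > thr)
            sp_hat = np.mean(x[~y] <= thr)
            assert abs(se_hat - truth.loc[study, "se"]) < 0.03
            assert abs(sp_hat - truth.loc[study, "sp"]) < 0.03

    def test_study_tables_margins(self):
        spec = CohortSpec(n_studies=6, cases_per_study=30, controls_per_study=20,
                          seed=4)
        studies, truth = generate_study_tables(spec)
        assert len(studies) == 6
        for s in studies:
            assert s.cases == 30 and s.controls == 20

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(rho=1.5)


class TestSurvival:
    def test_no_censoring_all_events(self):
        t = generate_survival(n=50, rate=0.2, censor_rate=0.0, seed=5)
        assert (t["event"] == 1).all() and (t["time"] > 0).all()

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_survival(n=10, rate=-1.0)
        with pytest.raises(ValueError):
            generate_survival(n=1, rate=1.0)

    def test_association_shortens_high_expression_survival(self):
        x = np.repeat([0.0, 3.0], 300)
        t = generate_survival(n=600, rate=0.1, assoc=1.5, expression=x, seed=6)
        assert t["time"][x == 3.0].mean() < t["time"][x == 0.0].mean()

    def test_null_association_logrank_p_uniform_small(self):
        """Fast smoke version of the null-uniformity check (full in acceptance)."""
        from mirnetdx.survival import logrank_test, split_by_expression

        ps = []
        for seed in range(60):
            t = generate_survival(n=60, rate=0.2, assoc=0.0,
                                  censor_rate=0.05, seed=seed)
            t["group"] = split_by_expression(t["expression"])
            ps.append(logrank_test(t).p)
        assert kstest(ps, "uniform").pvalue > 0.01
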