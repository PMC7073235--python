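"""Logistic-regression diagnostic tables and Bayesian bivariate meta-analysis.

Each cohort's biomarker expression is turned into a 2x2 diagnostic table by
an (L2-stabilized) logistic regression classified at a probability cutoff.
The tables then feed a bivariate random-effects meta-analysis:

    tp_i ~ Binomial(cases_i, se_i),   tn_i ~ Binomial(controls_i, sp_i)
    (logit se_i, logit sp_i) ~ N2(mu, Sigma / w_i)

with Sigma = diag(tau) R(rho) diag(tau).  The Gaussian model fixes w_i = 1;
the robust scale-mixture variant draws w_i ~ Gamma(df/2, df/2), giving
Student-t study effects.  Priors: mu ~ N(0, 2.5^2), tau ~ half-N(1),
rho ~ Uniform(-1, 1).  Inference is Metropolis-within-Gibbs with conjugate
updates for mu and the mixture weights.  Pooled sensitivity/specificity are
posterior medians of ilogit(mu); predictive values come from posterior draws
of a new study's effect.

Heterogeneity is summarized separately by Cochran's Q / I-squared on
logit-transformed per-study proportions (moment-based, with a 0.5
continuity correction on zero cells).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "Study2x2",
    "MetaPosterior",
    "HeterogeneityResult",
    "fit_diagnostic_lr",
    "bayesian_meta",
    "heterogeneity_i2",
]


@dataclass(frozen=True)
class Study2x2:
    """TP/FP/TN/FN counts for one cohort and biomarker (set)."""

    study_id: str
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cases == 0 or self.controls == 0:
            raise ValueError("study needs at least one case and one control")

    @property
    def cases(self) -> int:
        return self.tp + self.fn

    @property
    def controls(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / self.cases

    @property
    def specificity(self) -> float:
        return self.tn / self.controls


@dataclass
class MetaPosterior:
    """Posterior draws and summaries of the bivariate meta-analysis."""

    draws: dict[str, np.ndarray]
    pooled_se: float
    pooled_sp: float
    ci_se: tuple[float, float]
    ci_sp: tuple[float, float]
    pred_se: float
    pred_sp: float
    pred_interval_se: tuple[float, float]
    pred_interval_sp: tuple[float, float]
    rhat: dict[str, float]
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "pooled_se": self.pooled_se,
            "pooled_sp": self.pooled_sp,
            "ci_se": list(self.ci_se),
            "ci_sp": list(self.ci_sp),
            "pred_se": self.pred_se,
            "pred_sp": self.pred_sp,
            "pred_interval_se": list(self.pred_interval_se),
            "pred_interval_sp": list(self.pred_interval_sp),
            "rhat": {k: float(v) for k, v in self.rhat.items()},
            "converged": self.converged,
            "warnings": list(self.warnings),
        }


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    i2: float  # percentage in [0, 100]


# ---------------------------------------------------------------------------
# logistic-regression 2x2 tables


def fit_diagnostic_lr(
    expression: pd.DataFrame,
    labels,
    study_id: str = "study",
    cutoff: float | str = 0.5,
    c_penalty: float = 100.0,
    cross_validate: bool = False,
    seed: int = 0,
) -> tuple[Study2x2, np.ndarray]:
    """Fit a logistic diagnostic model and assemble the 2x2 table.

    Parameters
    ----------
    expression
        samples x biomarkers matrix (single- or multi-biomarker).
    labels
        "case" / "control" per sample, aligned with the rows.
    cutoff
        probability cutoff (default 0.5) or ``"youden"`` to maximize
        sensitivity + specificity on the fitted probabilities.
    c_penalty
        inverse L2 penalty strength; the small quadratic penalty keeps the
        fit stable under complete separation.
    cross_validate
        if True, classify from stratified 5-fold out-of-fold probabilities
        instead of in-sample fits.

    Returns (table, fitted coefficients incl. intercept last).
    """
    labels = pd.Series(labels, index=expression.index) if not isinstance(
        labels, pd.Series
    ) else labels.reindex(expression.index)
    y = (labels == "case").to_numpy(dtype=int)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("study needs at least 2 cases and 2 controls")
    x = expression.to_numpy(dtype=float)

    model = LogisticRegression(C=c_penalty, solver="lbfgs", max_iter=1000)
    if cross_validate:
        n_splits = min(5, int(y.sum()), int((1 - y).sum()))
        kf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        prob = np.empty(len(y))
        for train, test in kf.split(x, y):
            prob[test] = model.fit(x[train], y[train]).predict_proba(x[test])[:, 1]
        model.fit(x, y)  # coefficients reported from the full fit
    else:
        model.fit(x, y)
        prob = model.predict_proba(x)[:, 1]

    if cutoff == "youden":
        grid = np.unique(prob)
        best, thr = -np.inf, 0.5
        for t in grid:
            pred = prob > t
            se = pred[y == 1].mean()
            sp = (~pred[y == 0]).mean()
            if se + sp > best:
                best, thr = se + sp, t
    else:
        thr = float(cutoff)
    pred = prob > thr
    table = Study2x2(
        study_id=study_id,
        tp=int(np.sum(pred & (y == 1))),
        fn=int(np.sum(~pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
        fp=int(np.sum(pred & (y == 0))),
    )
    coef = np.concatenate([model.coef_.ravel(), model.intercept_])
    return table, coef


# ---------------------------------------------------------------------------
# bivariate random-effects MCMC


def _binom_loglik(theta, tp, cases, tn, controls):
    t1, t2 = theta[:, 0], theta[:, 1]
    return (
        tp * t1
        - cases * np.logaddexp(0.0, t1)
        + tn * t2
        - controls * np.logaddexp(0.0, t2)
    )


def _re_logpdf(theta, mu, tau1, tau2, rho, w):
    """Per-study log density of N2(mu, Sigma/w) at theta."""
    d1 = (theta[:, 0] - mu[0]) / tau1
    d2 = (theta[:, 1] - mu[1]) / tau2
    om = 1.0 - rho * rho
    q = (d1 * d1 - 2.0 * rho * d1 * d2 + d2 * d2) / om
    return (
        -np.log(2.0 * np.pi)
        - np.log(tau1 * tau2)
        - 0.5 * np.log(om)
        + np.log(w)
        - 0.5 * w * q
    )


def _sigma_inv(tau1, tau2, rho):
    om = 1.0 - rho * rho
    return (
        np.array(
            [
                [1.0 / tau1**2, -rho / (tau1 * tau2)],
                [-rho / (tau1 * tau2), 1.0 / tau2**2],
            ]
        )
        / om
    )


def _run_chain(
    tp, cases, tn, controls, robust, t_df, prior_mu_sd, prior_tau_sd,
    n_iter, burn, rng,
):
    s = len(tp)
    se0 = (tp + 0.5) / (cases + 1.0)
    sp0 = (tn + 0.5) / (controls + 1.0)
    theta = np.column_stack([logit(se0), logit(sp0)])
    mu = theta.mean(axis=0)
    tau = np.maximum(theta.std(axis=0), 0.1)
    rho = 0.0
    w = np.ones(s)

    step_theta = np.full(s, 0.3)
    step_scalar = np.full(3, 0.3)  # log tau_se, log tau_sp, atanh rho
    acc_theta = np.zeros(s)
    acc_scalar = np.zeros(3)
    window = 50

    keep = n_iter - burn
    out = {k: np.empty(keep) for k in
           ("mu_se", "mu_sp", "tau_se", "tau_sp", "rho", "pred_se", "pred_sp")}

    def scalar_logpost(t1, t2, r):
        ll = _re_logpdf(theta, mu, t1, t2, r, w).sum()
        prior = (
            -0.5 * (t1 / prior_tau_sd) ** 2
            - 0.5 * (t2 / prior_tau_sd) ** 2
        )
        return ll + prior

    for it in range(n_iter):
        # --- study effects (vectorized random-walk MH) ---
        cur = _binom_loglik(theta, tp, cases, tn, controls) + _re_logpdf(
            theta, mu, tau[0], tau[1], rho, w
        )
        prop = theta + rng.normal(size=(s, 2)) * step_theta[:, None]
        new = _binom_loglik(prop, tp, cases, tn, controls) + _re_logpdf(
            prop, mu, tau[0], tau[1], rho, w
        )
        accept = np.log(rng.random(s)) < new - cur
        theta[accept] = prop[accept]
        acc_theta += accept

        # --- mu (conjugate Gibbs) ---
        sinv = _sigma_inv(tau[0], tau[1], rho)
        prec = w.sum() * sinv + np.eye(2) / prior_mu_sd**2
        b = sinv @ (w[:, None] * theta).sum(axis=0)
        cov = np.linalg.inv(prec)
        mu = cov @ b + np.linalg.cholesky(cov) @ rng.normal(size=2)

        # --- mixture weights (conjugate Gibbs, robust variant only) ---
        if robust:
            d = theta - mu
            q = np.einsum("ij,jk,ik->i", d, sinv, d)
            w = rng.gamma((t_df + 2.0) / 2.0, 2.0 / (t_df + q))

        # --- tau, rho (random-walk MH on unconstrained scales) ---
        cur_sc = scalar_logpost(tau[0], tau[1], rho)
        for j in range(3):
            if j < 2:
                prop_tau = tau.copy()
                prop_tau[j] = tau[j] * np.exp(rng.normal() * step_scalar[j])
                new_sc = scalar_logpost(prop_tau[0], prop_tau[1], rho)
                # Jacobian of the log transform
                logr = new_sc - cur_sc + np.log(prop_tau[j] / tau[j])
                if np.log(rng.random()) < logr:
                    tau = prop_tau
                    cur_sc = new_sc
                    acc_scalar[j] += 1
            else:
                z = np.arctanh(rho) + rng.normal() * step_scalar[j]
                prop_rho = np.tanh(z)
                new_sc = scalar_logpost(tau[0], tau[1], prop_rho)
                # uniform prior on rho; Jacobian d rho / d z = 1 - rho^2
                logr = new_sc - cur_sc + np.log1p(-prop_rho**2) - np.log1p(-rho**2)
                if np.log(rng.random()) < logr:
                    rho = prop_rho
                    cur_sc = new_sc
                    acc_scalar[j] += 1

        # --- adaptation during burn-in ---
        if it < burn and (it + 1) % window == 0:
            rate_t = acc_theta / window
            step_theta *= np.exp(0.3 * (rate_t - 0.35))
            rate_s = acc_scalar / window
            step_scalar *= np.exp(0.3 * (rate_s - 0.35))
            acc_theta[:] = 0.0
            acc_scalar[:] = 0.0

        if it >= burn:
            k = it - burn
            out["mu_se"][k], out["mu_sp"][k] = mu
            out["tau_se"][k], out["tau_sp"][k] = tau
            out["rho"][k] = rho
            w_new = rng.gamma(t_df / 2.0, 2.0 / t_df) if robust else 1.0
            c = rho * tau[0] * tau[1]
            sig = np.array([[tau[0] ** 2, c], [c, tau[1] ** 2]]) / w_new
            sig[np.diag_indices(2)] += 1e-12
            th_new = mu + np.linalg.cholesky(sig) @ rng.normal(size=2)
            out["pred_se"][k] = expit(th_new[0])
            out["pred_sp"][k] = expit(th_new[1])
    return out


def _split_rhat(chains: list[np.ndarray]) -> float:
    """Split-chain potential scale reduction factor."""
    halves = []
    for c in chains:
        h = len(c) // 2
        halves.extend([c[:h], c[h : 2 * h]])
    m = len(halves)
    n = len(halves[0])
    if n < 2:
        return np.nan
    means = np.array([h.mean() for h in halves])
    vars_ = np.array([h.var(ddof=1) for h in halves])
    w = vars_.mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def bayesian_meta(
    studies: Sequence[Study2x2],
    robust: bool = False,
    t_df: float = 4.0,
    prior_mu_sd: float = 2.5,
    prior_tau_sd: float = 1.0,
    chains: int = 4,
    iterations: int = 10_000,
    seed: int = 0,
) -> MetaPosterior:
    """Fit the bivariate random-effects model by Metropolis-within-Gibbs.

    Half of each chain is discarded as burn-in.  Non-convergence (split
    R-hat > 1.1 on any of mu/tau/rho) is reported through the ``converged``
    flag and a warning; results are still returned.
    """
    if len(studies) < 1:
        raise ValueError("need at least one study")
    tp = np.array([s.tp for s in studies], dtype=float)
    cases = np.array([s.cases for s in studies], dtype=float)
    tn = np.array([s.tn for s in studies], dtype=float)
    controls = np.array([s.controls for s in studies], dtype=float)
    burn = iterations // 2

    chain_draws = []
    for c in range(chains):
        rng = np.random.default_rng((seed + 100_003 * c) % 2**31)
        chain_draws.append(
            _run_chain(
                tp, cases, tn, controls, robust, t_df, prior_mu_sd,
                prior_tau_sd, iterations, burn, rng,
            )
        )

    draws = {
        k: np.concatenate([cd[k] for cd in chain_draws]) for k in chain_draws[0]
    }
    rhat = {
        k: _split_rhat([cd[k] for cd in chain_draws])
        for k in ("mu_se", "mu_sp", "tau_se", "tau_sp", "rho")
    }
    converged = all(np.isnan(v) or v < 1.1 for v in rhat.values())
    warn_msgs = []
    if not converged:
        msg = "MCMC may not have converged: " + ", ".join(
            f"{k} R-hat={v:.3f}" for k, v in rhat.items() if v >= 1.1
        )
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        warn_msgs.append(msg)

    pooled_se_draws = expit(draws["mu_se"])
    pooled_sp_draws = expit(draws["mu_sp"])
    q = lambda a, lo, hi: (float(np.percentile(a, lo)), float(np.percentile(a, hi)))
    return MetaPosterior(
        draws=draws,
        pooled_se=float(np.median(pooled_se_draws)),
        pooled_sp=float(np.median(pooled_sp_draws)),
        ci_se=q(pooled_se_draws, 2.5, 97.5),
        ci_sp=q(pooled_sp_draws, 2.5, 97.5),
        pred_se=float(np.median(draws["pred_se"])),
        pred_sp=float(np.median(draws["pred_sp"])),
        pred_interval_se=q(draws["pred_se"], 2.5, 97.5),
        pred_interval_sp=q(draws["pred_sp"], 2.5, 97.5),
        rhat=rhat,
        converged=converged,
        warnings=warn_msgs,
    )


# ---------------------------------------------------------------------------
# heterogeneity


def heterogeneity_i2(
    studies: Sequence[Study2x2], margin: str = "sensitivity"
) -> HeterogeneityResult:
    """Cochran's Q and I-squared on logit per-study proportions.

    Zero cells get a 0.5 continuity correction (applied to both numerator
    and denominator of the affected study).  I2 = max(0, (Q - df) / Q) * 100.
    """
    if len(studies) < 2:
        raise ValueError("heterogeneity needs at least 2 studies")
    if margin == "sensitivity":
        x = np.array([s.tp for s in studies], dtype=float)
        n = np.array([s.cases for s in studies], dtype=float)
    elif margin == "specificity":
        x = np.array([s.tn for s in studies], dtype=float)
        n = np.array([s.controls for s in studies], dtype=float)
    else:
        raise ValueError(f"unknown margin {margin!r}")
    zero = (x == 0) | (x == n)
    x = np.where(zero, x + 0.5, x)
    n = np.where(zero, n + 1.0, n)
    y = np.log(x / (n - x))
    var = 1.0 / x + 1.0 / (n - x)
    w = 1.0 / var
    ybar = np.sum(w * y) / np.sum(w)
    q_stat = float(np.sum(w * (y - ybar) ** 2))
    df = len(studies) - 1
    i2 = max(0.0, (q_stat - df) / q_stat) * 100.0 if q_stat > 0 else 0.0
    return HeterogeneityResult(q=q_stat, df=df, i2=i2)
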