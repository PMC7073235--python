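# Methods

This note documents the models implemented in `mirnetdx`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want to know.

## Discovery model

### Disease network and scores

The interactome is a bipartite edge set miRNA → gene with a TF flag per
gene. The disease network keeps exactly the edges whose gene passes the
differential-expression screen and whose miRNA belongs to the
disease-related universe. "Single-line regulation" is formalized as: a
target whose regulator count *in the disease network* equals 1, so NSR is a
property of the restricted graph (the same miRNA can have different NSR on
different platforms, because the DEG sets differ). TFP is tf_count /
n_targets on the restricted graph; zero-target miRNAs score 0 and are
flagged rather than dropped.

### Enrichment test

For a focal miRNA the library forms differences d_j = x_focal − x_j
against every other miRNA and applies a one-sided one-sample Wilcoxon
signed-rank test (alternative: focal greater). Zero differences are
dropped; with ≤ 25 non-zero differences the exact conditional null
distribution given the tie pattern is computed by dynamic programming over
doubled midranks, otherwise a normal approximation with midrank tie
correction (Var = Σr²/4) and a 0.5 continuity correction is used. All
differences zero gives p = 1. Applying a *paired* test to an unpaired
comparison is deliberate — it reproduces the published scoring behaviour,
where even NSR = 1 can be strongly significant when most other miRNAs score
0 — and an unpaired rank-sum variant (`method="rank_sum"`) is provided for
sensitivity analysis. No multiple-testing correction is applied to the
enrichment p-values, mirroring the published raw-0.05 rule.

Selection keeps miRNAs with NSR ≥ 1, p_NSR < 0.05, tf_count ≥ 1 and
p_TFP < 0.05. The published "TFP ≥ 1" threshold is read as "targets at
least one TF", because reported TFP values are fractions below 1. Candidate
lists from the two platforms are intersected.

### Topology filter

Degree and normalized betweenness (Brandes accumulation, normalization by
(N−1)(N−2)/2 pairs) are computed on the unweighted bipartite disease
network. Candidates must (a) be differentially expressed at the miRNA level
(BH-adjusted p < 0.05) and (b) lie within `k_sigma` (default 2) of the
known-biomarker centroid in standardized (log1p degree, betweenness) space.
Standardization uses rank-based normal scores (van der Waerden): the
betweenness distribution on these networks is zero-inflated with a tiny
MAD, which makes a median/MAD z-score put even the known biomarkers dozens
of "robust SDs" from their own centroid; normal scores keep a 2-unit window
meaningful for arbitrarily skewed features. The original description of
this step is qualitative ("clustered into the same level"), so the
quantitative rule here is a declared operationalization. The filter is a
*level-match*: decoys genuinely at the biomarkers' network level pass it
and must be removed by the DE condition instead.

## Verification model

### Logistic 2×2 tables

Per cohort, a logistic regression of case status on one or several
biomarkers is fitted with a small L2 penalty (`C = 100`), which handles
complete separation without failure; samples with fitted probability above
0.5 are classified cases and the in-sample confusion matrix is the study's
2×2 table. In-sample classification reflects the workflow being modelled;
a stratified 5-fold cross-validated mode and a Youden-optimal cutoff are
available by argument since the original procedure is not fully specified.
In-sample fitting inflates accuracy by O(1/√n) on null data — visible in
the calibration tests as a ~0.02 excess over 0.5 at n = 500.

### Bivariate random-effects meta-analysis

The exact binomial likelihood is used per margin (no continuity
correction), with bivariate-normal random effects on the logit scale and an
optional scale-mixture robustification: per-study weights w_i ~
Gamma(df/2, df/2) (default df = 4) give Student-t study effects. Priors:
mu ~ N(0, 2.5²) per component (weakly informative on the logit scale),
tau ~ half-N(1), rho ~ Uniform(−1, 1). The sampler is
Metropolis-within-Gibbs: vectorized random-walk MH for the study effects,
conjugate Gibbs draws for mu and for the mixture weights, random-walk MH on
log tau and atanh rho with Jacobian terms, step sizes adapted toward 35%
acceptance during burn-in only (so the post-burn-in chain is a fixed-kernel
Markov chain). Defaults: 4 chains × 10,000 iterations, first half
discarded; the end-to-end orchestrator uses 2 × 4,000 because it runs six
fits on small cohorts, where that length already yields split-R-hat near 1
for the pooled quantities. Convergence is monitored by split-chain R-hat on
mu, tau, rho; values above 1.1 produce a warning but results are still
emitted. Pooled sensitivity/specificity are posterior *medians* of
ilogit(mu) (invariant under the logit transform, unlike ilogit of the
posterior mean); predictive values are medians of posterior-predictive
draws of a new study's ilogit effect, and their 95% interval is at least as
wide as the credible interval whenever tau > 0.

With few studies the correlation rho is weakly identified; pooled and
predictive probabilities are the quantities this package treats as
reliable.

### Heterogeneity

I² is moment-based and intentionally separate from the Bayesian model:
per-study proportions are logit-transformed (0.5 continuity correction on
zero cells only), weighted by inverse estimated variance, and Cochran's
Q gives I² = max(0, (Q − df)/Q) · 100. The conventional "I² < 25% = low
heterogeneity" screen behaves as advertised only asymptotically: under a
true tau = 0, P(I² < 25%) = P(Q < 4df/3), which under the chi-square null
first reaches 0.90 at df = 32 and also requires per-study 2×2 cells large
enough for the plug-in variances (small cells bias the variance estimates
and over-disperse Q). At a six-cohort scale the screen flags ~15–25% of
truly homogeneous meta-analyses — a known small-sample property, not an
implementation artifact.

### Survival

Kaplan–Meier estimation and the log-rank test are computed with lifelines
behind thin wrappers; groups come from a median split on expression (ties
to the low group). The grouping variable is expression, not survival time:
splitting on the outcome itself would invalidate the test, so the
ambiguous published phrasing is resolved in the only statistically valid
direction.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions under which the pipeline is
validated; all are bit-reproducible given a seed.

**Interactome** (defaults: 200 miRNAs, 2000 genes, 10% TFs, mean 80
targets/miRNA, NB2 dispersion 0.5, 5 planted biomarkers with 8 exclusive
targets and TF share ≥ 0.30 each). Target counts follow a negative
binomial with Var = m + 0.5 m² (heavy-tailed, two parameters);
`degree_dispersion = 0` degenerates to a fixed degree, used by tests that
need deterministic edge counts. Planted biomarkers receive their base
targets at exactly the mean degree — the generator's expression of the
premise that biomarkers occupy a common network level, without which the
similarity filter has no cluster to match. Exclusive targets are reserved
genes assigned last and never rewired, so brute-force exclusivity counts
are exact ground truth; TF-boost targets are preferentially TFs already
covered by other miRNAs (so they add no spurious exclusivity) and are
recorded in `PlantedTruth` because they must be in the DE set for the boost
to survive the network restriction. The high default target coverage
(~16000 edges over 2000 genes) makes background exclusive-DE targets rare,
which is what gives the NSR statistic its specificity; sparser interactomes
degrade it, as they would for the real method.

**Expression** (defaults: 300 DE of 2000 genes, |log2FC| ~ N(2, 0.4²) with
random sign, 40+40 samples). Array platform: Gaussian noise (sd 0.6) on a
log scale around per-gene baselines. Counts platform: NB counts
(dispersion 0.1) with log-normal library-size variation, screened via
log2-CPM with a 0.5 pseudo-count. The DE-gene sets of the two platforms
are drawn independently (beyond the mandatory planted targets), which is
what makes the platform intersection informative. Not emulated:
probe-level effects, batch structure, correlated genes, composition-aware
normalization (TMM/DESeq-style) — with a large DE mass fraction plain CPM
shows the classic composition bias.

**Cohorts.** Study-level (logit se, logit sp) are drawn from a bivariate
normal (defaults: 6 studies of 12 cases + 8 controls, mu at (0.75, 0.72)
on the probability scale, tau 0.3, rho −0.4). Per-sample expression is
unit-variance Gaussian, class separation Δ_i = Φ⁻¹(se_i) + Φ⁻¹(sp_i) and
decision threshold Φ⁻¹(sp_i), which attains the drawn accuracies exactly
in expectation; each biomarker carries an independent realization of the
same study accuracy, so multi-biomarker combination genuinely improves
separation (by √k for k markers). `generate_study_tables` samples the
binomial 2×2 tables directly from the drawn accuracies — the exact
generative model of the meta-analysis, used for parameter-recovery
experiments so that classifier optimism does not contaminate them.

**Survival.** Exponential event times with log-hazard linear in centered
expression, independent exponential censoring. The pipeline default
association is 0, i.e. the planted biomarkers are diagnostic but *not*
prognostic, and the log-rank stage is expected to return null results.

Passing tests on these generators show that the statistics, filters and
samplers do what they claim under their own assumptions. They do not show
robustness to real-data pathologies: mis-annotated interactome edges,
correlated expression, cohort batch effects, or non-proportional hazards.

## Problem sizes

Default validation runs use 200 miRNAs × 2000 genes for discovery, 25
simulated studies of 200+200 for meta-analysis recovery, 60 replicates of
60 studies for the heterogeneity screen, and 200 replicates for survival
null calibration — sizes at which every Monte-Carlo tolerance in the test
suite has comfortable margin.

## Known limitations

- The signed-rank enrichment test is hypersensitive in large miRNA
  universes: any score above the bulk of the distribution is significant.
  Specificity of the selection comes from the NSR ≥ 1 / tf_count ≥ 1 count
  thresholds, not from the p-values alone.
- I² screening is anti-conservative with few studies (see above).
- In-sample logistic tables carry finite-sample optimism; use
  `cross_validate=True` when that matters.
- rho (the se/sp correlation) is poorly identified with < ~20 studies.
- Identifiers are opaque strings; no miRBase normalization is attempted
  ("-5p/-3p" suffixes are preserved verbatim).
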