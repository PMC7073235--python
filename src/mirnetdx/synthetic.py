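"""Synthetic interactomes, expression cohorts and survival tables.

Every input the discovery pipeline consumes can be generated here with
planted ground truth, so the whole workflow is testable offline:

* a bipartite miRNA->gene interactome with heavy-tailed target degrees, a
  TF-flagged gene subset, and planted biomarker miRNAs carrying a fixed
  number of exclusive targets and an elevated TF-target share;
* two-group gene expression on a microarray-like (log-normal noise) or an
  RNA-seq-like (negative binomial counts) platform, with a known DE set;
* multi-cohort diagnostic miRNA expression whose study-level accuracy
  follows a bivariate normal random-effects law on the logit scale;
* exponential survival times with a configurable log-linear association
  between hazard and expression.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .meta import Study2x2
from .network import Interactome

__all__ = [
    "InteractomeSpec",
    "ExpressionSpec",
    "CohortSpec",
    "PlantedTruth",
    "generate_interactome",
    "generate_expression",
    "generate_mirna_expression",
    "generate_mirna_cohorts",
    "generate_study_tables",
    "generate_survival",
]


@dataclass(frozen=True)
class InteractomeSpec:
    """Parameters of the synthetic bipartite interactome.

    ``degree_dispersion`` controls the heavy tail of the per-miRNA target
    count: 0 gives a fixed degree of round(mean), otherwise counts follow a
    negative binomial with variance ``m + dispersion * m**2``.  Each planted
    biomarker receives ``planted_exclusive_targets`` genes targeted by no
    other miRNA and enough TF targets to push its TF share to at least
    ``planted_tf_boost``.
    """

    n_mirna: int
    n_gene: int
    tf_fraction: float = 0.10
    mean_targets_per_mirna: float = 80.0
    degree_dispersion: float = 0.5
    planted_biomarkers: tuple[str, ...] = ()
    planted_exclusive_targets: int = 8
    planted_tf_boost: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "planted_biomarkers", tuple(self.planted_biomarkers)
        )
        if self.n_mirna < 1 or self.n_gene < 1:
            raise ValueError("interactome needs at least one miRNA and one gene")
        if not 0.0 <= self.tf_fraction <= 1.0:
            raise ValueError("tf_fraction must lie in [0, 1]")
        if self.mean_targets_per_mirna <= 0:
            raise ValueError("mean_targets_per_mirna must be positive")
        if self.degree_dispersion < 0:
            raise ValueError("degree_dispersion must be non-negative")
        if self.planted_biomarkers:
            if self.planted_exclusive_targets < 1:
                raise ValueError("planted_exclusive_targets must be >= 1")
            if len(self.planted_biomarkers) > self.n_mirna:
                raise ValueError("more planted biomarkers than miRNAs")
        if (
            self.planted_biomarkers
            and self.planted_tf_boost > 0
            and self.tf_fraction * self.n_gene < 1
        ):
            raise ValueError("TF boost requires at least one TF gene")
        if not 0.0 <= self.planted_tf_boost < 1.0:
            raise ValueError("planted_tf_boost must lie in [0, 1)")


@dataclass(frozen=True)
class ExpressionSpec:
    """Two-group expression generator settings for one platform."""

    platform: str = "array"  # "array" | "counts"
    n_de_genes: int = 300
    lfc_mean: float = 2.0
    lfc_sd: float = 0.4
    noise_sd: float = 0.6
    nb_dispersion: float = 0.1
    n_cases: int = 40
    n_controls: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.platform not in ("array", "counts"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.n_de_genes < 0:
            raise ValueError("n_de_genes must be non-negative")
        if self.noise_sd <= 0 or self.nb_dispersion <= 0:
            raise ValueError("noise_sd and nb_dispersion must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Between-study law for per-cohort diagnostic accuracy.

    Study-level (logit sensitivity, logit specificity) pairs are drawn from
    a bivariate normal with means ``(mu_se, mu_sp)``, standard deviations
    ``(tau_se, tau_sp)`` and correlation ``rho``.
    """

    n_studies: int = 6
    cases_per_study: int = 12
    controls_per_study: int = 8
    mu_se: float = float(logit(0.75))
    mu_sp: float = float(logit(0.72))
    tau_se: float = 0.3
    tau_sp: float = 0.3
    rho: float = -0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("need at least one study")
        if self.cases_per_study < 2 or self.controls_per_study < 2:
            raise ValueError("each study needs >= 2 cases and >= 2 controls")
        if self.tau_se < 0 or self.tau_sp < 0:
            raise ValueError("between-study SDs must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        # PSD check of the implied 2x2 covariance
        cov = self.covariance
        if np.linalg.eigvalsh(cov).min() < -1e-12:
            raise ValueError("implied covariance is not positive semi-definite")

    @property
    def covariance(self) -> np.ndarray:
        c = self.rho * self.tau_se * self.tau_sp
        return np.array([[self.tau_se**2, c], [c, self.tau_sp**2]])


# ---------------------------------------------------------------------------
# interactome


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth attached to a generated interactome.

    ``exclusive`` maps each planted biomarker to its reserved exclusive
    target genes (targeted by no other miRNA); ``tf_boost`` maps it to the
    TF genes added to raise its TF-target share.  The union of all listed
    genes is the mandatory DE set that makes the planted signal visible in
    the disease-restricted network.
    """

    exclusive: dict[str, tuple[str, ...]]
    tf_boost: dict[str, tuple[str, ...]]

    @property
    def mandatory_de(self) -> list[str]:
        out: list[str] = []
        for d in (self.exclusive, self.tf_boost):
            for genes in d.values():
                out.extend(genes)
        return sorted(set(out))


def generate_interactome(
    spec: InteractomeSpec,
) -> tuple[Interactome, PlantedTruth]:
    """Draw a bipartite interactome with planted biomarkers.

    Returns the interactome and the planted ground truth; exclusive targets
    are created last and never rewired, so they are exact ground truth for
    the NSR statistic.
    """
    rng = np.random.default_rng(spec.seed)
    planted = list(spec.planted_biomarkers)
    fill = [f"miR-sim-{i:04d}" for i in range(spec.n_mirna - len(planted))]
    if set(planted) & set(fill):
        raise ValueError("planted biomarker names collide with generated names")
    mirnas = planted + fill

    genes = np.array([f"GENE{i:05d}" for i in range(spec.n_gene)])
    perm = rng.permutation(spec.n_gene)
    n_excl = len(planted) * spec.planted_exclusive_targets
    if n_excl >= spec.n_gene:
        raise ValueError("gene universe too small for the requested exclusive targets")
    exclusive_pool = genes[perm[:n_excl]]
    free = genes[perm[n_excl:]]

    n_tf = int(np.floor(spec.tf_fraction * spec.n_gene))
    n_tf = min(n_tf, free.size)
    tf_genes = {str(g) for g in free[:n_tf]}  # TFs never sit in the exclusive pool

    # heavy-tailed target counts; planted biomarkers sit at the mean degree
    # (a common "network level"), which is the regularity the filter exploits
    m = spec.mean_targets_per_mirna
    if spec.degree_dispersion == 0:
        ks = np.full(len(mirnas), int(round(m)))
    else:
        r = 1.0 / spec.degree_dispersion
        ks = rng.negative_binomial(r, r / (r + m), size=len(mirnas))
        ks[: len(planted)] = int(round(m))
    ks = np.clip(ks, 0, free.size)

    targets: dict[str, set[str]] = {}
    for mir, k in zip(mirnas, ks):
        chosen = rng.choice(free, size=int(k), replace=False) if k else []
        targets[mir] = {str(g) for g in chosen}

    # TF boost for planted miRNAs: prefer TFs already covered by another miRNA
    tf_boost: dict[str, tuple[str, ...]] = {}
    if planted and spec.planted_tf_boost > 0:
        coverage: dict[str, int] = {}
        for mir, t in targets.items():
            for g in t:
                coverage[g] = coverage.get(g, 0) + 1
        for mir in planted:
            t = targets[mir]
            n_t, n_tf_t = len(t), len(t & tf_genes)
            need = int(np.ceil(
                (spec.planted_tf_boost * n_t - n_tf_t)
                / (1.0 - spec.planted_tf_boost)
            ))
            if need <= 0:
                continue
            covered = [g for g in tf_genes if g not in t and coverage.get(g, 0) >= 1]
            uncovered = [g for g in tf_genes if g not in t and coverage.get(g, 0) == 0]
            pool = sorted(covered) + sorted(uncovered)
            if need > len(pool):
                raise ValueError("not enough TF genes to satisfy planted_tf_boost")
            add = pool[:need]
            t.update(add)
            tf_boost[mir] = tuple(add)
            for g in add:
                coverage[g] = coverage.get(g, 0) + 1

    # exclusive targets, assigned last and never shared
    exclusive: dict[str, tuple[str, ...]] = {}
    for i, mir in enumerate(planted):
        sl = exclusive_pool[
            i * spec.planted_exclusive_targets : (i + 1) * spec.planted_exclusive_targets
        ]
        exclusive[mir] = tuple(str(g) for g in sl)
        targets[mir].update(sl)

    edges = tuple(sorted((mir, g) for mir, t in targets.items() for g in t))
    inter = Interactome(
        edges=edges, tf_genes=frozenset(tf_genes), mirna_universe=frozenset(mirnas)
    )
    return inter, PlantedTruth(exclusive=exclusive, tf_boost=tf_boost)


# ---------------------------------------------------------------------------
# expression


def _two_group_array(
    ids: Sequence[str],
    lfc: dict[str, float],
    noise_sd: float,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    """Log-scale two-group matrix with Gaussian noise around per-id baselines."""
    ids = list(ids)
    base = rng.normal(7.0, 1.0, size=len(ids))
    shift = np.array([lfc.get(i, 0.0) for i in ids])
    cols = [f"case_{j}" for j in range(n_cases)] + [
        f"control_{j}" for j in range(n_controls)
    ]
    mean = np.concatenate(
        [
            np.tile((base + shift)[:, None], (1, n_cases)),
            np.tile(base[:, None], (1, n_controls)),
        ],
        axis=1,
    )
    mat = mean + rng.normal(0.0, noise_sd, size=mean.shape)
    labels = pd.Series(
        ["case"] * n_cases + ["control"] * n_controls, index=cols, name="group"
    )
    return pd.DataFrame(mat, index=ids, columns=cols), labels


def generate_expression(
    interactome: Interactome,
    spec: ExpressionSpec,
    must_de: Iterable[str] = (),
) -> tuple[pd.DataFrame, pd.Series, set[str]]:
    """Two-group expression for the interactome's genes with a known DE set.

    ``must_de`` genes (typically the planted biomarkers' exclusive targets)
    are always part of the ground-truth DE set; the rest of the
    ``n_de_genes`` slots are filled at random.  Returns (matrix, labels,
    true DE set).
    """
    genes = sorted(interactome.genes)
    must = [str(g) for g in dict.fromkeys(must_de)]
    missing = set(must) - set(genes)
    if missing:
        raise ValueError(f"must_de genes absent from interactome: {sorted(missing)[:5]}")
    if spec.n_de_genes > len(genes):
        raise ValueError("n_de_genes exceeds the gene universe")
    if spec.n_de_genes < len(must):
        raise ValueError("n_de_genes smaller than the mandatory DE set")

    rng = np.random.default_rng(spec.seed)
    remaining = [g for g in genes if g not in set(must)]
    extra = rng.choice(
        np.array(remaining), size=spec.n_de_genes - len(must), replace=False
    ) if spec.n_de_genes > len(must) else np.array([], dtype=object)
    truth = set(must) | {str(g) for g in extra}

    signs = rng.choice([-1.0, 1.0], size=len(truth))
    sizes = rng.normal(spec.lfc_mean, spec.lfc_sd, size=len(truth))
    lfc = {g: s * e for g, s, e in zip(sorted(truth), signs, sizes)}

    if spec.platform == "array":
        mat, labels = _two_group_array(
            genes, lfc, spec.noise_sd, spec.n_cases, spec.n_controls, rng
        )
        return mat, labels, truth

    # counts platform: NB around per-gene baseline means, library-size variation
    base = rng.lognormal(mean=4.0, sigma=1.0, size=len(genes))
    shift = np.array([2.0 ** lfc.get(g, 0.0) for g in genes])
    cols = [f"case_{j}" for j in range(spec.n_cases)] + [
        f"control_{j}" for j in range(spec.n_controls)
    ]
    libfac = rng.lognormal(mean=0.0, sigma=0.2, size=len(cols))
    mean = np.concatenate(
        [
            np.tile((base * shift)[:, None], (1, spec.n_cases)),
            np.tile(base[:, None], (1, spec.n_controls)),
        ],
        axis=1,
    ) * libfac[None, :]
    r = 1.0 / spec.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mean))
    labels = pd.Series(
        ["case"] * spec.n_cases + ["control"] * spec.n_controls,
        index=cols,
        name="group",
    )
    return pd.DataFrame(counts, index=genes, columns=cols), labels, truth


def generate_mirna_expression(
    mirnas: Sequence[str],
    de_mirnas: Iterable[str],
    lfc_mean: float = 2.0,
    lfc_sd: float = 0.3,
    noise_sd: float = 0.6,
    n_cases: int = 40,
    n_controls: int = 40,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Array-style two-group miRNA matrix with the given miRNAs DE (upregulated)."""
    rng = np.random.default_rng(seed)
    de = list(dict.fromkeys(de_mirnas))
    lfc = {m: rng.normal(lfc_mean, lfc_sd) for m in de}
    return _two_group_array(list(mirnas), lfc, noise_sd, n_cases, n_controls, rng)


# ---------------------------------------------------------------------------
# diagnostic cohorts


def _draw_study_accuracy(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    mean = np.array([spec.mu_se, spec.mu_sp])
    draws = rng.multivariate_normal(
        mean, spec.covariance, size=spec.n_studies, method="svd"
    )
    return pd.DataFrame(
        {
            "study": [f"study_{i + 1}" for i in range(spec.n_studies)],
            "se": expit(draws[:, 0]),
            "sp": expit(draws[:, 1]),
        }
    ).set_index("study")


def generate_mirna_cohorts(
    biomarkers: Sequence[str], spec: CohortSpec
) -> tuple[dict[str, tuple[pd.DataFrame, pd.Series]], pd.DataFrame]:
    """Per-study biomarker expression realizing drawn (se, sp) accuracies.

    Class-conditional expression is unit-variance Gaussian per biomarker:
    controls ~ N(0, 1), cases ~ N(delta_i, 1) with
    ``delta_i = Phi^-1(se_i) + Phi^-1(sp_i)``, so a threshold at
    ``Phi^-1(sp_i)`` attains exactly (se_i, sp_i) in expectation.  Each
    biomarker carries an independent noise realization of the same study
    accuracy, so combining biomarkers increases separation.

    Returns ({study: (samples x biomarkers, labels)}, truth table with the
    drawn se/sp and the implied separation per study).
    """
    if not biomarkers:
        raise ValueError("need at least one biomarker")
    rng = np.random.default_rng(spec.seed)
    truth = _draw_study_accuracy(spec, rng)
    truth["delta"] = norm.ppf(truth["se"]) + norm.ppf(truth["sp"])
    truth["threshold"] = norm.ppf(truth["sp"])
    cohorts: dict[str, tuple[pd.DataFrame, pd.Series]] = {}
    for study, row in truth.iterrows():
        n_ca, n_co = spec.cases_per_study, spec.controls_per_study
        idx = [f"{study}_case_{j}" for j in range(n_ca)] + [
            f"{study}_control_{j}" for j in range(n_co)
        ]
        x = rng.normal(0.0, 1.0, size=(n_ca + n_co, len(biomarkers)))
        x[:n_ca] += row["delta"]
        labels = pd.Series(
            ["case"] * n_ca + ["control"] * n_co, index=idx, name="group"
        )
        cohorts[study] = (
            pd.DataFrame(x, index=idx, columns=list(biomarkers)),
            labels,
        )
    return cohorts, truth


def generate_study_tables(spec: CohortSpec) -> tuple[list[Study2x2], pd.DataFrame]:
    """Draw per-study 2x2 tables directly from the random-effects law.

    tp_i ~ Binomial(cases, se_i) and tn_i ~ Binomial(controls, sp_i) with
    (se_i, sp_i) drawn as in :func:`generate_mirna_cohorts`; this is the
    exact generative model of the bivariate meta-analysis.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _draw_study_accuracy(spec, rng)
    studies = []
    for study, row in truth.iterrows():
        tp = int(rng.binomial(spec.cases_per_study, row["se"]))
        tn = int(rng.binomial(spec.controls_per_study, row["sp"]))
        studies.append(
            Study2x2(
                study_id=str(study),
                tp=tp,
                fn=spec.cases_per_study - tp,
                tn=tn,
                fp=spec.controls_per_study - tn,
            )
        )
    return studies, truth


# ---------------------------------------------------------------------------
# survival


def generate_survival(
    n: int,
    rate: float,
    assoc: float = 0.0,
    expression: np.ndarray | None = None,
    censor_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival with log-hazard linear in (centered) expression.

    hazard_i = rate * exp(assoc * (x_i - mean(x))); censoring is independent
    exponential with rate ``censor_rate`` (0 = no censoring).
    """
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if rate <= 0 or censor_rate < 0:
        raise ValueError("rates must be positive (censor_rate may be 0)")
    rng = np.random.default_rng(seed)
    x = (
        rng.normal(0.0, 1.0, size=n)
        if expression is None
        else np.asarray(expression, dtype=float)
    )
    if x.size != n:
        raise ValueError("expression length must equal n")
    lam = rate * np.exp(assoc * (x - x.mean()))
    t_event = rng.exponential(1.0 / lam)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "time": time,
            "event": event,
            "expression": x,
        }
    ).set_index("sample_id")
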