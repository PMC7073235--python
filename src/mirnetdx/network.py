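"""Disease-specific miRNA-mRNA networks and topology-based biomarker scores.

The prediction model works on a bipartite regulatory network.  A full
miRNA->mRNA interactome is restricted to disease-related miRNAs and
differentially expressed genes; each miRNA is then scored by

* **NSR** -- the number of its single-line-regulated targets, i.e. DE genes
  whose regulator count in the restricted network is exactly one, and
* **TFP** -- the fraction of its in-network targets annotated as
  transcription factors,

and each score is tested for enrichment against all other miRNAs with a
one-sided Wilcoxon test.  Candidates pass if NSR >= 1 with p < 0.05 and they
target at least one TF with TFP p < 0.05; candidate lists from independent
platforms are intersected.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .stats import rank_sum_greater, signed_rank_greater

logger = logging.getLogger(__name__)

__all__ = [
    "Interactome",
    "DiseaseNetwork",
    "build_disease_network",
    "compute_scores",
    "wilcoxon_enrichment",
    "score_mirnas",
    "select_candidates",
    "overlap_platforms",
]


@dataclass(frozen=True)
class Interactome:
    """Bipartite miRNA->gene edge set with TF annotations.

    Parameters
    ----------
    edges
        (mirna_id, gene_id) pairs; duplicates are rejected.
    tf_genes
        Gene identifiers flagged as transcription factors.
    mirna_universe
        Disease-related miRNAs eligible for scoring.
    """

    edges: tuple[tuple[str, str], ...]
    tf_genes: frozenset[str] = field(default_factory=frozenset)
    mirna_universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        edges = tuple((str(m), str(g)) for m, g in self.edges)
        if len(set(edges)) != len(edges):
            raise ValueError("interactome contains duplicate edges")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "tf_genes", frozenset(self.tf_genes))
        universe = frozenset(self.mirna_universe) or frozenset(m for m, _ in edges)
        object.__setattr__(self, "mirna_universe", universe)

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.edges)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.edges) | self.tf_genes


@dataclass(frozen=True)
class DiseaseNetwork:
    """Interactome restricted to DE genes and disease miRNAs."""

    edges: tuple[tuple[str, str], ...]
    mirnas: tuple[str, ...]  # requested universe, incl. zero-target miRNAs
    regulator_count: dict[str, int]

    def targets_of(self, mirna: str) -> set[str]:
        return {g for m, g in self.edges if m == mirna}


def _de_gene_set(deg) -> set[str]:
    if isinstance(deg, pd.DataFrame):
        if "is_de" not in deg.columns:
            raise ValueError("DE table lacks an 'is_de' column")
        return set(deg.index[deg["is_de"].astype(bool)].astype(str))
    return {str(g) for g in deg}


def build_disease_network(
    interactome: Interactome, deg, mirna_list: Iterable[str]
) -> DiseaseNetwork:
    """Restrict the interactome to DE genes and the given miRNA list.

    Raises ``ValueError`` naming the empty side if either input or the
    restricted edge set is empty.
    """
    de_genes = _de_gene_set(deg)
    if not de_genes:
        raise ValueError("cannot build disease network: DEG set is empty")
    mirnas = list(dict.fromkeys(str(m) for m in mirna_list))
    if not mirnas:
        raise ValueError("cannot build disease network: miRNA list is empty")
    mset = set(mirnas)
    edges = tuple(
        (m, g) for m, g in interactome.edges if m in mset and g in de_genes
    )
    if not edges:
        raise ValueError(
            "restricted network is empty: no interactome edge joins the given "
            "miRNA list to the DEG set"
        )
    reg = Counter(g for _, g in edges)
    return DiseaseNetwork(edges=edges, mirnas=tuple(mirnas), regulator_count=dict(reg))


def compute_scores(net: DiseaseNetwork, tf_genes: Iterable[str]) -> pd.DataFrame:
    """Per-miRNA NSR, TF count and TFP on the disease network.

    Zero-target miRNAs are scored 0 with ``zero_targets=True`` and a logged
    warning; TFP is tf_count / n_targets otherwise.
    """
    tf = {str(g) for g in tf_genes}
    targets: dict[str, set[str]] = {m: set() for m in net.mirnas}
    for m, g in net.edges:
        targets.setdefault(m, set()).add(g)
    rows = []
    n_zero = 0
    for m in net.mirnas:
        t = targets.get(m, set())
        n_t = len(t)
        nsr = sum(1 for g in t if net.regulator_count[g] == 1)
        tf_count = len(t & tf)
        tfp = tf_count / n_t if n_t else 0.0
        n_zero += n_t == 0
        rows.append((m, n_t, nsr, tf_count, tfp, n_t == 0))
    if n_zero:
        logger.warning("%d miRNA(s) have no targets in the disease network", n_zero)
    return pd.DataFrame(
        rows, columns=["mirna_id", "n_targets", "nsr", "tf_count", "tfp", "zero_targets"]
    ).set_index("mirna_id")


def wilcoxon_enrichment(
    scores: pd.DataFrame, metric: str, method: str = "signed_rank"
) -> pd.Series:
    """One-sided enrichment p-value of each miRNA's score vs. all others.

    ``metric`` is ``"nsr"`` or ``"tfp"``.  The default compares the focal
    miRNA through a one-sample signed-rank test on focal-minus-other
    differences (alternative: focal greater); ``method="rank_sum"`` is the
    unpaired alternative for sensitivity analysis.
    """
    if metric not in ("nsr", "tfp"):
        raise ValueError(f"unknown metric {metric!r}")
    if len(scores) < 2:
        raise ValueError("enrichment test needs at least 2 scored miRNAs")
    x = scores[metric].to_numpy(dtype=float)
    p = np.empty(len(x))
    for i, xi in enumerate(x):
        others = np.delete(x, i)
        if method == "signed_rank":
            p[i] = signed_rank_greater(xi - others)
        elif method == "rank_sum":
            p[i] = rank_sum_greater(xi, others)
        else:
            raise ValueError(f"unknown method {method!r}")
    return pd.Series(p, index=scores.index, name=f"p_{metric}")


def score_mirnas(
    net: DiseaseNetwork, tf_genes: Iterable[str], method: str = "signed_rank"
) -> pd.DataFrame:
    """Scores plus their enrichment p-values (columns ``p_nsr``, ``p_tfp``)."""
    scores = compute_scores(net, tf_genes)
    scores["p_nsr"] = wilcoxon_enrichment(scores, "nsr", method=method)
    scores["p_tfp"] = wilcoxon_enrichment(scores, "tfp", method=method)
    return scores


def select_candidates(
    scores: pd.DataFrame,
    nsr_min: int = 1,
    alpha_nsr: float = 0.05,
    tf_count_min: int = 1,
    alpha_tfp: float = 0.05,
) -> pd.DataFrame:
    """Apply the NSR/TFP selection filter; returns the passing rows.

    Keeps miRNAs with nsr >= nsr_min, p_nsr < alpha_nsr, tf_count >=
    tf_count_min and p_tfp < alpha_tfp (the published "TFP >= 1" rule is read
    as "targets at least one TF", since TFP itself is a fraction below 1).
    Rows are ordered by p_nsr ascending.
    """
    for col in ("nsr", "tf_count", "p_nsr", "p_tfp"):
        if col not in scores.columns:
            raise ValueError(f"scores table lacks column {col!r}")
    keep = (
        (scores["nsr"] >= nsr_min)
        & (scores["p_nsr"] < alpha_nsr)
        & (scores["tf_count"] >= tf_count_min)
        & (scores["p_tfp"] < alpha_tfp)
    )
    return scores.loc[keep].sort_values("p_nsr")


def overlap_platforms(selected_a, selected_b) -> list[str]:
    """Intersect two platforms' candidate sets, ordered by platform-a p_nsr."""

    def _ids(sel) -> list[str]:
        if isinstance(sel, pd.DataFrame):
            return [str(i) for i in sel.index]
        return [str(i) for i in sel]

    ids_a, ids_b = _ids(selected_a), _ids(selected_b)
    common = set(ids_a) & set(ids_b)
    if isinstance(selected_a, pd.DataFrame) and "p_nsr" in selected_a.columns:
        order = selected_a.loc[list(common), "p_nsr"].sort_values().index
        return [str(i) for i in order]
    return [i for i in ids_a if i in common]
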