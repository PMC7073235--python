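"""Degree/betweenness topology features and similarity-based filtering.

Biomarker miRNAs tend to occupy similar positions in the miRNA-gene
network.  This module computes exact degree and normalized shortest-path
betweenness on the unweighted bipartite disease network and keeps the
candidates that (a) are differentially expressed at the miRNA level and
(b) lie within a robust-z distance of the known-biomarker centroid in
standardized (log(1 + degree), betweenness) space.
"""

from __future__ import annotations

import logging
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import DiseaseNetwork

logger = logging.getLogger(__name__)

__all__ = ["compute_topology", "filter_by_similarity"]


def compute_topology(net: DiseaseNetwork) -> pd.DataFrame:
    """Exact degree and normalized betweenness for every network node.

    Betweenness uses Brandes' shortest-path accumulation on the unweighted
    bipartite graph, normalized by (N-1)(N-2)/2 pairs so values lie in
    [0, 1]; disconnected graphs are handled per component by the pair count.

    Returns a DataFrame indexed by node id with columns ``degree``,
    ``betweenness`` and ``is_mirna``.
    """
    g = nx.Graph()
    mirna_nodes = set(net.mirnas)
    g.add_nodes_from(mirna_nodes)
    for m, gene in net.edges:
        g.add_edge(m, gene)
    bet = nx.betweenness_centrality(g, normalized=True)
    rows = [
        (node, g.degree(node), bet[node], node in mirna_nodes)
        for node in g.nodes
    ]
    return (
        pd.DataFrame(rows, columns=["node", "degree", "betweenness", "is_mirna"])
        .set_index("node")
        .sort_index()
    )


def _robust_z(values: np.ndarray) -> np.ndarray:
    """Rank-based normal scores (van der Waerden): a robust standardization.

    Midranks are mapped through the normal quantile function, so the result
    is unit-normal-scaled regardless of how skewed or heavy-tailed the raw
    feature is (betweenness spans orders of magnitude on these networks,
    which makes a median/MAD z-score degenerate).
    """
    from scipy import stats as sps

    r = sps.rankdata(values)
    return sps.norm.ppf((r - 0.5) / values.size)


def filter_by_similarity(
    candidates: Sequence[str],
    known_biomarkers: Sequence[str],
    features: pd.DataFrame,
    de_mirna_table: pd.DataFrame | None = None,
    k_sigma: float = 2.0,
    de_alpha: float = 0.05,
) -> list[str]:
    """Keep candidates that are DE and topologically similar to known markers.

    A candidate passes when (a) its adjusted p-value in ``de_mirna_table``
    is below ``de_alpha`` (skipped if no table is given) and (b) its
    Euclidean distance to the known-biomarker centroid, in robust-z
    standardized (log1p degree, betweenness) space, is at most ``k_sigma``.
    With an empty known set the similarity filter is skipped with a warning.
    """
    candidates = [str(c) for c in candidates]
    known = [str(k) for k in known_biomarkers]
    missing = [k for k in known if k not in features.index]
    if missing:
        raise ValueError(f"known biomarkers absent from features: {missing}")

    kept = candidates
    if de_mirna_table is not None:
        if "p_adj" not in de_mirna_table.columns:
            raise ValueError("miRNA DE table lacks a 'p_adj' column")
        de_ok = set(
            de_mirna_table.index[de_mirna_table["p_adj"] < de_alpha].astype(str)
        )
        kept = [c for c in kept if c in de_ok]

    if not known:
        logger.warning("no known biomarkers given; similarity filter skipped")
        return kept

    feats = features.loc[features["is_mirna"]] if "is_mirna" in features else features
    z = np.column_stack(
        [
            _robust_z(np.log1p(feats["degree"].to_numpy(dtype=float))),
            _robust_z(feats["betweenness"].to_numpy(dtype=float)),
        ]
    )
    zed = pd.DataFrame(z, index=feats.index, columns=["zdeg", "zbet"])
    centroid = zed.loc[known].mean(axis=0).to_numpy()
    out = []
    for c in kept:
        if c not in zed.index:
            continue
        dist = float(np.linalg.norm(zed.loc[c].to_numpy() - centroid))
        if dist <= k_sigma:
            out.append(c)
    return out
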