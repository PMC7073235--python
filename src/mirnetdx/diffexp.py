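"""Two-group differential expression screen.

Produces the DEG set that restricts the disease network.  Microarray-style
input (already on a log scale) gets a per-gene Welch t-test; RNA-seq counts
are first transformed to log2-CPM with a 0.5 pseudo-count and then tested
the same way.  P-values are Benjamini-Hochberg adjusted across genes, and a
gene is DE when ``p_adj < alpha`` and ``|log2FC| >= lfc_min``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["differential_expression", "log_cpm"]


def log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2 counts-per-million with a 0.5 pseudo-count (library +1)."""
    vals = counts.to_numpy(dtype=float)
    if np.any(vals < 0) or not np.allclose(vals, np.rint(vals)):
        raise ValueError("counts platform requires non-negative integer values")
    lib = vals.sum(axis=0)
    cpm = (vals + 0.5) / (lib + 1.0)[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm), index=counts.index, columns=counts.columns)


def differential_expression(
    matrix: pd.DataFrame,
    labels,
    platform: str = "array",
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Welch t-test per gene with BH adjustment.

    Parameters
    ----------
    matrix
        genes x samples expression; log-scale for ``platform="array"``,
        non-negative integer counts for ``platform="counts"``.
    labels
        per-sample group labels, ``"case"`` / ``"control"``, aligned with the
        matrix columns (a mapping or a sequence).
    alpha, lfc_min
        DE thresholds on the adjusted p-value and on |log2 fold change|.

    Returns
    -------
    DataFrame indexed by gene with columns ``lfc``, ``p``, ``p_adj``,
    ``is_de``.  lfc is mean(case) - mean(control) on the log scale.  Genes
    that are constant in both groups get p = 1 by convention.
    """
    labels = pd.Series(labels, index=matrix.columns) if not isinstance(
        labels, pd.Series
    ) else labels.reindex(matrix.columns)
    if labels.isna().any():
        raise ValueError("every sample column needs a group label")
    case_cols = labels.index[labels == "case"]
    ctrl_cols = labels.index[labels == "control"]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("each group needs at least 2 samples")

    if platform == "counts":
        matrix = log_cpm(matrix)
    elif platform != "array":
        raise ValueError(f"unknown platform {platform!r}")

    a = matrix[case_cols].to_numpy(dtype=float)
    b = matrix[ctrl_cols].to_numpy(dtype=float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)  # all-constant genes: p = 1
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {"lfc": lfc, "p": p, "p_adj": p_adj}, index=matrix.index
    )
    out["is_de"] = (out["p_adj"] < alpha) & (out["lfc"].abs() >= lfc_min)
    return out
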