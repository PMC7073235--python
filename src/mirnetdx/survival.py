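"""Kaplan-Meier estimation and log-rank comparison of expression groups.

The prognostic check splits patients at the median biomarker expression
into high/low groups, estimates each group's survival function with the
product-limit estimator and compares the groups with the standard
observed-minus-expected log-rank chi-square (1 df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = ["LogRankResult", "km_estimate", "logrank_test", "split_by_expression"]


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


def km_estimate(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group.

    ``table`` needs ``time`` and ``event`` columns and optionally ``group``
    (a single group named ``"all"`` is assumed otherwise).  Each returned
    step table has columns ``time`` and ``survival`` and starts at
    S(0) = 1; with every subject censored the estimate stays at 1.
    """
    if (table["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    groups = table["group"] if "group" in table.columns else pd.Series(
        "all", index=table.index
    )
    out: dict[str, pd.DataFrame] = {}
    for name, sub in table.groupby(groups, sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"].astype(bool))
        sf = kmf.survival_function_
        out[str(name)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        ).reset_index(drop=True)
    return out


def logrank_test(table: pd.DataFrame) -> LogRankResult:
    """Two-group log-rank test; zero observed events give p = 1 with a warning."""
    if "group" not in table.columns:
        raise ValueError("log-rank test needs a 'group' column")
    names = sorted(table["group"].unique())
    if len(names) != 2:
        raise ValueError("log-rank test needs exactly two non-empty groups")
    if int(table["event"].sum()) == 0:
        warnings.warn("no observed events; log-rank p set to 1", RuntimeWarning)
        return LogRankResult(chi2=0.0, df=1, p=1.0)
    a = table[table["group"] == names[0]]
    b = table[table["group"] == names[1]]
    res = _ll_logrank(
        a["time"], b["time"],
        event_observed_A=a["event"].astype(bool),
        event_observed_B=b["event"].astype(bool),
    )
    chi2 = float(res.test_statistic)
    return LogRankResult(chi2=chi2, df=1, p=float(res.p_value))


def split_by_expression(
    expression, rule: str = "median_expression"
) -> np.ndarray:
    """Median split into "high"/"low" groups; ties go to the low group."""
    if rule != "median_expression":
        raise ValueError(f"unknown split rule {rule!r}")
    x = np.asarray(expression, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 subjects for a median split")
    if np.all(x == x[0]):
        raise ValueError("expression is constant; cannot split")
    med = np.median(x)
    return np.where(x > med, "high", "low")
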