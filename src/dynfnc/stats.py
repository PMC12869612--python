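"""Per-connection group comparisons with Benjamini-Hochberg correction.

Edge values (static FNC, dFNC-STD, or per-state subject-specific states)
are compared between groups with a two-sample t-test (Welch by default),
p-values are FDR-corrected with the step-up Benjamini-Hochberg procedure
within each test context, and significant edges are reported with their
direction of change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class EdgeTestResult:
    """Edge-wise group comparison for one context (sFNC / dFNC-STD / state)."""

    context: str
    table: pd.DataFrame  # edge, mean_a, mean_b, t, p, p_adj, direction, significant
    q: float
    group_a: str = "HC"
    group_b: str = "TLE"


def two_sample_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    equal_var: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided two-sample t-test per edge (Welch unless ``equal_var``).

    Edges with zero variance in both groups get t = 0, p = 1 when the
    means are equal (degenerate but well-defined null).
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    same_mean = np.isclose(a.mean(axis=0), b.mean(axis=0))
    t[degenerate & same_mean] = 0.0
    p[degenerate & same_mean] = 1.0
    t[degenerate & ~same_mean] = np.inf * np.sign(
        (a.mean(axis=0) - b.mean(axis=0))[degenerate & ~same_mean]
    )
    p[degenerate & ~same_mean] = 0.0
    return t, p


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (capped at 1, monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def edge_tests(
    values_a: np.ndarray,
    values_b: np.ndarray,
    context: str,
    edge_names: Sequence[str] | None = None,
    q: float = 0.05,
    equal_var: bool = False,
    group_a: str = "HC",
    group_b: str = "TLE",
) -> EdgeTestResult:
    """Full edge-wise comparison for one context, BH-corrected within it.

    Direction labels follow the sign of ``mean_b - mean_a`` (increased /
    decreased in the comparison group); significance is strict:
    ``p_adj < q``.
    """
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    t, p = two_sample_test(a, b, equal_var=equal_var)
    p_adj = bh_adjust(p)
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    diff = mean_b - mean_a
    m = t.size
    names = list(edge_names) if edge_names is not None else [f"e{i}" for i in range(m)]
    table = pd.DataFrame(
        {
            "edge": names,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(diff > 0, "increased", "decreased"),
            "significant": p_adj < q,
        }
    )
    return EdgeTestResult(context=context, table=table, q=q, group_a=group_a, group_b=group_b)


def significant_edges(result: EdgeTestResult, q: float | None = None) -> pd.DataFrame:
    """Edges with adjusted p strictly below ``q`` (default: the result's q)."""
    q = result.q if q is None else q
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    tab = result.table
    return tab[tab["p_adj"] < q].reset_index(drop=True)
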