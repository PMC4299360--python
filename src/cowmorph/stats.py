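"""Contingency-table statistics with SPSS-compatible conventions.

Three procedures, implemented from first principles so that every published
convention is explicit:

* Pearson chi-square with **no** continuity correction.
* Linear-by-linear association (Mantel-Haenszel) trend statistic
  ``(N - 1) * r**2`` on ordinal scores, 1 degree of freedom.
* Two-sample rank-sum on ordered categories: midranks per tied block,
  tie-corrected variance, normal approximation, no continuity correction.

Only the chi-square and normal distribution tails come from scipy; the
statistics themselves are computed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist, norm as _norm_dist

from .aggregate import ContingencyTable

__all__ = ["StatResult", "pearson_chi2", "linear_by_linear", "ranksum_ordered"]


@dataclass(frozen=True)
class StatResult:
    """Outcome of one test: statistic, degrees of freedom, p, auxiliaries."""

    method: str
    statistic: float
    p_value: float
    df: Optional[int] = None
    expected: Optional[np.ndarray] = field(default=None, repr=False)
    mean_ranks: Optional[tuple[float, float]] = None

    def to_json(self) -> str:
        payload: dict = {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
        }
        if self.df is not None:
            payload["df"] = self.df
        if self.mean_ranks is not None:
            payload["mean_ranks"] = list(self.mean_ranks)
        return json.dumps(payload)


def _counts(table: ContingencyTable | np.ndarray) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return np.asarray(table.counts, dtype=float)
    return np.asarray(table, dtype=float)


def pearson_chi2(table: ContingencyTable | np.ndarray) -> StatResult:
    """Pearson chi-square test of independence, without continuity correction.

    ``statistic = sum (obs - exp)^2 / exp`` with
    ``exp = row_total * col_total / grand_total`` and
    ``df = (R - 1)(C - 1)``; the p-value is the chi-square upper tail.

    Raises
    ------
    ValueError
        If any row or column margin is zero (the category carries no
        observations, so its expected counts vanish); the message names it.
    """
    counts = _counts(table)
    if counts.ndim != 2:
        raise ValueError("pearson_chi2 expects a two-dimensional table")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    labels_r = table.row_labels if isinstance(table, ContingencyTable) else None
    labels_c = table.col_labels if isinstance(table, ContingencyTable) else None
    for i, tot in enumerate(row_tot):
        if tot == 0:
            name = labels_r[i] if labels_r else f"row {i}"
            raise ValueError(f"zero margin: empty category {name!r}")
    for j, tot in enumerate(col_tot):
        if tot == 0:
            name = labels_c[j] if labels_c else f"column {j}"
            raise ValueError(f"zero margin: empty category {name!r}")
    n = counts.sum()
    expected = np.outer(row_tot, col_tot) / n
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    p = float(_chi2_dist.sf(stat, df))
    return StatResult(
        method="pearson_chi2", statistic=stat, p_value=p, df=df, expected=expected
    )


def linear_by_linear(
    table: ContingencyTable | np.ndarray,
    row_scores: Optional[Sequence[float]] = None,
    col_scores: Optional[Sequence[float]] = None,
) -> StatResult:
    """Linear-by-linear (Mantel-Haenszel) association trend statistic.

    ``statistic = (N - 1) * r**2`` where ``r`` is the Pearson correlation of
    the row and column scores over the N observations of the table; 1 degree
    of freedom.  Default scores are consecutive integers in category order:
    rows ``1..R`` and columns ``0..C-1`` (the first column often being a
    reference/"none" category).  The statistic is invariant under any affine
    rescaling of either score vector, so only the spacing pattern matters.

    Raises
    ------
    ValueError
        If the scores on either axis are effectively constant over the
        observed support (zero variance), which makes r undefined.
    """
    counts = _counts(table)
    n_rows, n_cols = counts.shape
    rs = (
        np.arange(1, n_rows + 1, dtype=float)
        if row_scores is None
        else np.asarray(row_scores, dtype=float)
    )
    cs = (
        np.arange(n_cols, dtype=float)
        if col_scores is None
        else np.asarray(col_scores, dtype=float)
    )
    if rs.shape != (n_rows,) or cs.shape != (n_cols,):
        raise ValueError("score vectors must match the table dimensions")
    n = counts.sum()
    if n <= 1:
        raise ValueError("need at least two observations")
    w = counts / n
    wr = w.sum(axis=1)
    wc = w.sum(axis=0)
    mean_r = float(wr @ rs)
    mean_c = float(wc @ cs)
    var_r = float(wr @ (rs - mean_r) ** 2)
    var_c = float(wc @ (cs - mean_c) ** 2)
    if var_r <= 0 or var_c <= 0:
        axis = "row" if var_r <= 0 else "column"
        raise ValueError(f"degenerate scores: {axis} scores constant over support")
    cov = float((w * np.outer(rs - mean_r, cs - mean_c)).sum())
    r = cov / np.sqrt(var_r * var_c)
    stat = float((n - 1) * r * r)
    p = float(_chi2_dist.sf(stat, 1))
    return StatResult(method="linear_by_linear", statistic=stat, p_value=p, df=1)


def ranksum_ordered(
    group_counts_1: Sequence[float], group_counts_2: Sequence[float]
) -> StatResult:
    """Two-sample rank-sum on shared ordered categories (tie-corrected).

    Every observation in an ordered category receives that category's
    midrank; the test statistic is the standardized rank sum of group 1,

        Z = |W1 - n1 (N + 1) / 2| / sd,
        Var = (n1 n2 / 12) [ (N + 1) - sum(t^3 - t) / (N (N - 1)) ],

    with the sum over tie-block sizes ``t`` (here, the category totals).
    The two-sided p-value uses the normal approximation without continuity
    correction.  Mean ranks per group are returned; their weighted mean is
    exactly ``(N + 1) / 2``.
    """
    g1 = np.asarray(group_counts_1, dtype=float)
    g2 = np.asarray(group_counts_2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1:
        raise ValueError("groups must be count vectors over the same categories")
    if np.any(g1 < 0) or np.any(g2 < 0):
        raise ValueError("counts must be non-negative")
    n1, n2 = g1.sum(), g2.sum()
    if n1 == 0 or n2 == 0:
        raise ValueError("empty group")
    total = g1 + g2
    n = total.sum()
    if n < 2:
        raise ValueError("need at least two observations in total")
    # midrank of tie block ending at cumulative count c with block size t
    cum = np.cumsum(total)
    midranks = cum - (total - 1) / 2.0
    w1 = float(g1 @ midranks)
    w2 = float(g2 @ midranks)
    mean_ranks = (float(w1 / n1), float(w2 / n2))
    expected_w1 = n1 * (n + 1) / 2.0
    tie_term = float(((total**3 - total).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations in one category
        return StatResult(
            method="ranksum_ordered", statistic=0.0, p_value=1.0, mean_ranks=mean_ranks
        )
    z = float(abs(w1 - expected_w1) / np.sqrt(var))
    p = float(2.0 * _norm_dist.sf(z))
    return StatResult(
        method="ranksum_ordered", statistic=z, p_value=p, mean_ranks=mean_ranks
    )
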