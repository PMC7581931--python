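"""Downstream statistics on habitat-score tables.

Two questions recur in habitat-based community analysis.  First, do
samples from a given source environment carry higher scores for the
matching group of categories than everything else?  That is a two-sample
comparison, handled with the Mann-Whitney U test.  Second, does a
grouped score track an environmental gradient (salinity, age, distance
along a river)?  That is Spearman rank correlation.  Both are two-sided
by default because no direction is assumed a priori.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupTestResult",
    "GradientResult",
    "mann_whitney_u",
    "spearman_rho",
    "group_score_test",
    "gradient_correlation",
    "benjamini_hochberg",
    "results_table",
]


@dataclass(frozen=True)
class GroupTestResult:
    """A Mann-Whitney comparison of grouped scores, in-group vs out-group."""

    group_label: str
    n_in: int
    n_out: int
    U: float
    p_value: float
    median_in: float
    median_out: float


@dataclass(frozen=True)
class GradientResult:
    """Spearman correlation between a grouped score and a gradient."""

    rho: float
    p_value: float
    n: int


def _has_ties(x: Sequence[float], y: Sequence[float]) -> bool:
    pooled = list(x) + list(y)
    return len(set(pooled)) != len(pooled)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U test; returns ``(U, p_value)`` with U taken for ``x``.

    Ties are handled with midranks.  With ``method="auto"`` the p-value
    is exact when the smaller group has at most 8 observations and the
    pooled data is tie-free, and otherwise uses the normal approximation
    with tie correction (and continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        method = (
            "exact"
            if min(x.size, y.size) <= 8 and not _has_ties(x, y)
            else "asymptotic"
        )
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> GradientResult:
    """Spearman rank correlation (Pearson on midranks, t-based p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input: rank correlation is undefined")
    res = sps.spearmanr(x, y)
    return GradientResult(rho=float(res.statistic), p_value=float(res.pvalue),
                          n=int(x.size))


def group_score_test(
    scores: pd.DataFrame,
    sample_labels: Mapping[str, str],
    target_label: str,
    category_group: Iterable[str],
    alternative: str = "two-sided",
) -> GroupTestResult:
    """Test whether target-labeled samples score higher on a category group.

    ``scores`` is a sample x category table.  The scores of the listed
    categories are summed per sample; samples labeled ``target_label``
    form the in-group and all other labeled samples the out-group, and
    the two are compared with :func:`mann_whitney_u` (U reported for the
    in-group).
    """
    group = [c for c in category_group if c in scores.columns]
    sums = scores[group].sum(axis=1) if group else pd.Series(0.0, index=scores.index)
    labeled = [s for s in scores.index if s in sample_labels]
    sums = sums.loc[labeled].dropna()
    labels = pd.Series({s: sample_labels[s] for s in sums.index})
    in_vals = sums[labels == target_label]
    out_vals = sums[labels != target_label]
    if in_vals.empty or out_vals.empty:
        raise ValueError(
            f"need samples both with and without label {target_label!r}"
        )
    U, p = mann_whitney_u(in_vals, out_vals, alternative=alternative)
    return GroupTestResult(
        group_label=target_label,
        n_in=int(in_vals.size),
        n_out=int(out_vals.size),
        U=U,
        p_value=p,
        median_in=float(in_vals.median()),
        median_out=float(out_vals.median()),
    )


def gradient_correlation(
    scores: pd.DataFrame,
    metadata: Mapping[str, float] | pd.Series,
    category_group: Iterable[str],
) -> GradientResult:
    """Spearman correlation of a grouped score sum against a gradient.

    Samples missing either the gradient value or a mapped score are
    dropped; at least 3 usable samples are required.
    """
    meta = pd.Series(dict(metadata)) if not isinstance(metadata, pd.Series) else metadata
    group = [c for c in category_group if c in scores.columns]
    sums = scores[group].sum(axis=1) if group else pd.Series(0.0, index=scores.index)
    usable = [
        s for s in scores.index
        if s in meta.index and pd.notna(meta[s]) and pd.notna(sums[s])
        and not scores.loc[s].isna().all()
    ]
    if len(usable) < len(scores.index):
        import logging

        logging.getLogger(__name__).warning(
            "%d sample(s) dropped for missing metadata or scores",
            len(scores.index) - len(usable),
        )
    if len(usable) < 3:
        raise ValueError("need at least 3 samples with both score and gradient")
    return spearman_rho(meta[usable].to_numpy(), sums[usable].to_numpy())


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, for multi-group screens."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float))


def results_table(results: Iterable[GroupTestResult | GradientResult]) -> pd.DataFrame:
    """Flatten test results into the TSV-ready reporting layout."""
    rows = []
    for r in results:
        if isinstance(r, GroupTestResult):
            rows.append(
                {"test": "mann_whitney_u", "group": r.group_label,
                 "n_in": r.n_in, "n_out": r.n_out,
                 "statistic": r.U, "p_value": r.p_value,
                 "median_in": r.median_in, "median_out": r.median_out}
            )
        else:
            rows.append(
                {"test": "spearman", "group": "", "n_in": r.n, "n_out": 0,
                 "statistic": r.rho, "p_value": r.p_value,
                 "median_in": np.nan, "median_out": np.nan}
            )
    return pd.DataFrame(rows)
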