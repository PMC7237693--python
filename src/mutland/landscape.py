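"""Cross-dataset comparison of mutation-density landscapes.

Pearson correlation matrices between standardized (unranked) densities,
partial correlations controlling for genomic covariates, the
diagonal-split test (does a third dataset's density differ between
windows ranked hotter in A than in B and vice versa), and the 95th/5th
quantile fold-enrichment dispersion summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mutland.landscape")


@dataclass
class TestResult:
    """A hypothesis-test outcome with its effect size and group sizes."""

    name: str
    statistic: float
    p_value: float
    effect_size: float
    n1: int
    n2: int
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p value outside [0, 1]")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be >= 1")


def _window_key(table: pd.DataFrame) -> pd.Index:
    return pd.MultiIndex.from_arrays([table["chrom"], table["start"]])


def correlation_matrix(
    tables: Mapping[str, pd.DataFrame], on: str = "z"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of per-window densities.

    ``on`` selects the representation: ``"z"`` (standardized, unranked;
    the default, and identical to correlating raw densities since
    Pearson is affine-invariant), ``"d"`` or ``"rank"``.  All tables
    must cover the identical retained-window set.

    Returns (r matrix, p matrix) as DataFrames indexed by dataset name.
    """
    names = list(tables)
    if len(names) < 2:
        raise ValueError("need at least two datasets")
    keys = {name: _window_key(t) for name, t in tables.items()}
    ref = keys[names[0]]
    for name in names[1:]:
        if not ref.equals(keys[name]):
            diff = ref.symmetric_difference(keys[name])
            raise ValueError(
                f"window sets differ between {names[0]!r} and {name!r}: "
                f"{len(diff)} mismatched windows, e.g. {list(diff[:5])}"
            )
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            res = stats.pearsonr(tables[a][on].to_numpy(), tables[b][on].to_numpy())
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


def partial_correlation(x, y, controls) -> float:
    """Pearson correlation of x and y after linearly removing controls.

    Equivalent to the classical recursive partial-correlation formula:
    both variables are regressed (with intercept) on the control matrix
    and the residuals are correlated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(controls, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n = len(x)
    if len(y) != n or len(C) != n:
        raise ValueError("x, y and controls must share the sample dimension")
    X = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("collinear controls: design matrix is rank deficient")
    beta_x, *_ = np.linalg.lstsq(X, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(X, y, rcond=None)
    rx = x - X @ beta_x
    ry = y - X @ beta_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("zero residual variance; partial correlation undefined")
    return float(stats.pearsonr(rx, ry).statistic)


def mann_whitney(
    a, b, alternative: str = "two-sided", exact_max_n: int = 25
) -> tuple[float, float]:
    """Two-sided (by default) Mann-Whitney U.

    Exact null distribution when the smaller group has at most
    ``exact_max_n`` observations and there are no ties; otherwise the
    normal approximation with tie and continuity corrections, mirroring
    R's wilcox.test switchover behaviour.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def diagonal_split_test(
    rank_a, rank_b, response, label_a: str = "A", label_b: str = "B"
) -> TestResult:
    """Mann-Whitney test of a response variable across the diagonal split.

    Windows are divided by which dataset ranks them hotter: group 1 has
    rank_a > rank_b, group 2 the reverse.  Exactly tied ranks leave the
    dichotomy undefined; those windows are excluded and counted in the
    metadata.  The response (typically tumor mutation density) is then
    compared across the groups with a two-sided Mann-Whitney U; the
    rank-biserial correlation is reported as effect size.
    """
    rank_a = np.asarray(rank_a, dtype=float)
    rank_b = np.asarray(rank_b, dtype=float)
    response = np.asarray(response, dtype=float)
    if not (len(rank_a) == len(rank_b) == len(response)):
        raise ValueError("rank and response vectors must be aligned")
    g1 = rank_a > rank_b
    g2 = rank_a < rank_b
    n_tied = int(len(rank_a) - g1.sum() - g2.sum())
    if g1.sum() == 0 or g2.sum() == 0:
        raise ValueError(
            f"degenerate split: group sizes {int(g1.sum())} and {int(g2.sum())}"
        )
    u, p = mann_whitney(response[g1], response[g2])
    n1, n2 = int(g1.sum()), int(g2.sum())
    rank_biserial = 1.0 - 2.0 * u / (n1 * n2)
    result = TestResult(
        name="diagonal_split",
        statistic=u,
        p_value=p,
        effect_size=rank_biserial,
        n1=n1,
        n2=n2,
        metadata={"ties_excluded": n_tied, "group1": f"{label_a}>{label_b}", "group2": f"{label_b}>{label_a}"},
    )
    logger.info(
        "diagonal_split %s vs %s n1=%d n2=%d ties=%d U=%g p=%g",
        label_a,
        label_b,
        n1,
        n2,
        n_tied,
        u,
        p,
    )
    return result


def quantile_fold_enrichment(densities, q_low: float = 0.05, q_high: float = 0.95) -> float:
    """Ratio of the high to the low quantile of a density distribution.

    Uses linear-interpolation quantiles (R type 7).  Undefined when the
    low quantile is not strictly positive.
    """
    d = np.asarray(densities, dtype=float)
    lo = float(np.quantile(d, q_low))
    hi = float(np.quantile(d, q_high))
    if lo <= 0:
        raise ValueError(f"{q_low:g} quantile is {lo:g} <= 0; fold-enrichment undefined")
    return hi / lo
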