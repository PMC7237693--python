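"""Trinucleotide enrichment and landscape-difference statistics.

Four related procedures:

* sequential whole-genome enrichment of trinucleotide classes between
  two datasets (chi-squared on class-vs-rest tables, re-run in
  decreasing significance order while removing already-tested classes
  from the totals, since class counts are not independent);
* a coherence filter keeping only classes where two replicate runs agree
  in significance and enrichment direction;
* the trinucleotide-difference test: per class, the two-sample
  Kolmogorov-Smirnov test between the rank-difference distributions
  (species A - tumor) and (species B - tumor), with effect size
  dsigma = SD(A - tumor) - SD(B - tumor) (both distributions have mean
  zero because ranks are permutations of the same window set; positive
  dsigma means the tumor landscape is more similar to B);
* the signature-difference test: per mutational signature, regress the
  per-tumor-type dsigma of each class on the signature's mutation load
  across tumor types, then chi-squared on the 2x2 table of
  (regression-significant x globally-significant) classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .trinuc import CLASS_GC_COUNT, CLASS_LABELS, N_CLASSES

logger = logging.getLogger("mutland.difftests")


# ---------------------------------------------------------------- chi-squared


def chi2_2x2(a: float, b: float, c: float, d: float, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared on [[a, b], [c, d]], df = 1.

    No continuity correction by default (at genome-scale counts it is
    negligible); ``yates=True`` applies the Yates correction for parity
    with R's default 2x2 behaviour.  Degenerate tables (a zero margin)
    return statistic 0 and p = 1.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.min() < 0:
        raise ValueError("negative cell count")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    total = table.sum()
    if total == 0 or np.any(rows == 0) or np.any(cols == 0):
        return 0.0, 1.0
    expected = np.outer(rows, cols) / total
    diff = np.abs(table - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    return stat, float(stats.chi2.sf(stat, df=1))


# ------------------------------------------------------- sequential enrichment


def sequential_enrichment_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    labels: Sequence[str] = CLASS_LABELS,
    yates: bool = False,
) -> pd.DataFrame:
    """Sequential class-vs-rest chi-squared enrichment between datasets.

    Stage 1 tests every class T on the 2x2 table
    [count_A(T), rest_A; count_B(T), rest_B].  Classes are then ordered
    from most to least significant (ascending stage-1 p; ties broken by
    descending statistic, then label) and re-tested in that order, with
    the counts of all previously tested classes removed from the totals.

    Fold-enrichment E_T = (fraction of T in A) / (fraction of T in B)
    always uses the raw genome-wide fractions.  Classes absent from both
    datasets get E_T = NaN and p = 1, flagged.
    """
    counts_a = np.asarray(counts_a, dtype=np.int64)
    counts_b = np.asarray(counts_b, dtype=np.int64)
    k = len(labels)
    if counts_a.shape != (k,) or counts_b.shape != (k,):
        raise ValueError("count vectors must match the label list")
    tot_a = int(counts_a.sum())
    tot_b = int(counts_b.sum())
    if tot_a == 0 or tot_b == 0:
        raise ValueError("both datasets need a positive total count")

    stage1 = np.array(
        [
            chi2_2x2(counts_a[i], tot_a - counts_a[i], counts_b[i], tot_b - counts_b[i], yates)
            for i in range(k)
        ]
    )
    chi1, p1 = stage1[:, 0], stage1[:, 1]
    both_zero = (counts_a == 0) & (counts_b == 0)

    order = sorted(range(k), key=lambda i: (p1[i], -chi1[i], labels[i]))
    iteration = np.empty(k, dtype=np.int64)
    chi2_seq = np.empty(k)
    p_seq = np.empty(k)
    used_a = 0
    used_b = 0
    for it, i in enumerate(order, start=1):
        iteration[i] = it
        rest_a = tot_a - used_a - counts_a[i]
        rest_b = tot_b - used_b - counts_b[i]
        chi2_seq[i], p_seq[i] = chi2_2x2(counts_a[i], rest_a, counts_b[i], rest_b, yates)
        used_a += counts_a[i]
        used_b += counts_b[i]

    with np.errstate(divide="ignore", invalid="ignore"):
        enrichment = (counts_a / tot_a) / (counts_b / tot_b)
    enrichment = np.where(both_zero, np.nan, enrichment)
    p_seq = np.where(both_zero, 1.0, p_seq)

    return pd.DataFrame(
        {
            "count_a": counts_a,
            "count_b": counts_b,
            "enrichment": enrichment,
            "chi2_stage1": chi1,
            "p_stage1": p1,
            "iteration": iteration,
            "chi2": chi2_seq,
            "p": p_seq,
            "undefined": both_zero,
        },
        index=pd.Index(labels, name="class"),
    )


def coherence_filter(
    run1: pd.DataFrame, run2: pd.DataFrame, alpha: float = 1e-5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep classes where two enrichment runs agree in significance and
    direction.

    Agreement means: both runs on the same side of ``alpha`` (sequential
    p), and the same sign of log enrichment.  Returns (kept rows of
    run1, dropped rows annotated with the disagreement reason).
    """
    if not run1.index.equals(run2.index):
        raise ValueError("enrichment runs cover different class sets")

    def direction(e):
        v = e.to_numpy(dtype=float)
        out = np.full(len(v), np.nan)
        ok = np.isfinite(v) & (v > 0)
        out[ok] = np.sign(np.log(v[ok]))
        return out

    sig1 = run1["p"] < alpha
    sig2 = run2["p"] < alpha
    dir1 = direction(run1["enrichment"])
    dir2 = direction(run2["enrichment"])
    same_sig = sig1.to_numpy() == sig2.to_numpy()
    same_dir = (dir1 == dir2) | (np.isnan(dir1) & np.isnan(dir2))
    keep = same_sig & same_dir
    reasons = np.where(
        ~same_sig & ~same_dir,
        "significance+direction",
        np.where(~same_sig, "significance", "direction"),
    )
    dropped = run1.loc[~keep].copy()
    dropped["reason"] = reasons[~keep]
    return run1.loc[keep].copy(), dropped


# ------------------------------------------------------------- GC regression


def gc_regression(response, gc_counts=None) -> tuple[float, float, float]:
    """OLS of a per-class response on the triplet's G+C base count (0-3).

    The GC count is taken over the three folded reference bases of each
    class.  Returns (slope, intercept, two-sided slope p value).
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(CLASS_GC_COUNT if gc_counts is None else gc_counts, dtype=float)
    if len(x) != len(y):
        raise ValueError("response length must match the class list")
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(y) < 3:
        raise ValueError("need at least 3 finite responses")
    if np.all(x == x[0]):
        raise ValueError("all GC counts equal; slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.params[1]), float(model.params[0]), float(model.pvalues[1])


# -------------------------------------------------- trinucleotide difference


def ks_test(a, b, exact_max_nm: int = 10_000) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov D and p.

    Exact p when n*m <= ``exact_max_nm`` and the pooled sample is
    tie-free; the asymptotic form otherwise (ties, which arise from tied
    ranks, always take the asymptotic route).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) * len(b) <= exact_max_nm and not has_ties) else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DifferenceResult:
    """Per-class outcome of the trinucleotide-difference test."""

    label: str
    D: float
    p_value: float
    dsigma: float  # SD(rank_A - rank_tumor) - SD(rank_B - rank_tumor)
    n: int


def trinuc_difference_test(
    rank_a, rank_b, rank_tumor, label: str = ""
) -> DifferenceResult:
    """KS test between the two rank-difference distributions.

    ``rank_a``, ``rank_b`` and ``rank_tumor`` are the per-class window
    ranks of the same window set in species A, species B and the tumor
    dataset.  Both difference distributions have mean 0 (ranks are
    permutations of the same values), so the difference of their sample
    standard deviations is the effect size; positive dsigma means the
    tumor distribution is more similar to species B.
    """
    ra = np.asarray(rank_a, dtype=float)
    rb = np.asarray(rank_b, dtype=float)
    rt = np.asarray(rank_tumor, dtype=float)
    if not (len(ra) == len(rb) == len(rt)):
        raise ValueError("rank vectors must be aligned over the same windows")
    if len(ra) < 2:
        raise ValueError("need at least 2 windows")
    da = ra - rt
    db = rb - rt
    D, p = ks_test(da, db)
    dsigma = float(np.std(da, ddof=1) - np.std(db, ddof=1))
    return DifferenceResult(label=label, D=D, p_value=p, dsigma=dsigma, n=len(ra))


def trinuc_difference_table(
    ranks_a: np.ndarray, ranks_b: np.ndarray, ranks_tumor: np.ndarray,
    labels: Sequence[str] = CLASS_LABELS,
) -> pd.DataFrame:
    """Run the trinucleotide-difference test for every class column."""
    if not (ranks_a.shape == ranks_b.shape == ranks_tumor.shape):
        raise ValueError("rank matrices must share window x class shape")
    rows = []
    for j, lab in enumerate(labels):
        res = trinuc_difference_test(ranks_a[:, j], ranks_b[:, j], ranks_tumor[:, j], lab)
        rows.append((lab, res.D, res.p_value, res.dsigma, res.n))
    return pd.DataFrame(
        rows, columns=["class", "D", "p", "dsigma", "n"]
    ).set_index("class")


# ------------------------------------------------------- signature difference


@dataclass
class SignatureLoadTable:
    """Mutation load attributed to each signature per tumor type.

    ``loads``: DataFrame (tumor type x signature) of attributed mutation
    counts; ``samples``: same shape, number of samples in which the
    signature was detected; ``artifact``: per-signature flag for known
    sequencing-artifact signatures.
    """

    loads: pd.DataFrame
    samples: pd.DataFrame
    artifact: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if (self.loads.to_numpy() < 0).any():
            raise ValueError("negative mutation load")
        if not self.loads.index.equals(self.samples.index) or not self.loads.columns.equals(
            self.samples.columns
        ):
            raise ValueError("loads and samples tables must align")

    def eligible_signatures(self, min_samples: int = 2, min_types: int = 2):
        """Non-artifact signatures detected in >= min_samples samples in
        >= min_types tumor types."""
        out = []
        for sig in self.loads.columns:
            if self.artifact.get(sig, False):
                continue
            if int((self.samples[sig] >= min_samples).sum()) >= min_types:
                out.append(sig)
        return out


def _ols_slope_pvalues(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Two-sided slope p values of OLS fits of each column of Y on x."""
    n = len(x)
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    yc = Y - Y.mean(axis=0)
    slope = (xc @ yc) / sxx
    resid = yc - np.outer(xc, slope)
    dof = n - 2
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / se, np.inf)
    return 2.0 * stats.t.sf(np.abs(t), dof)


def signature_difference_test(
    per_type_effects: pd.DataFrame,
    load_table: SignatureLoadTable,
    global_significance: np.ndarray,
    alpha_reg: float = 0.05,
    min_samples: int = 2,
    min_types: int = 2,
    yates: bool = True,
) -> pd.DataFrame:
    """Associate signature mutation loads with landscape differences.

    ``per_type_effects`` is the (tumor type x 96 class) matrix of dsigma
    effect sizes from per-tumor-type trinucleotide-difference runs;
    ``global_significance`` is the per-class boolean from the pooled run
    (p < 0.05 by convention).  For each eligible signature, every
    class's dsigma is regressed across tumor types on the signature's
    load; classes are cross-classified by regression-slope significance
    (p < ``alpha_reg``) against global significance, and a chi-squared
    test on that 2x2 table scores the signature.  Unlike the
    genome-scale enrichment tables, this table classifies only 96
    classes, so the Yates continuity correction (R's 2x2 default) is on
    by default to keep the sparse-table test conservative.  Raw p
    values are Bonferroni-adjusted across the tested signatures.
    """
    if per_type_effects.shape[1] != N_CLASSES:
        raise ValueError("per-type effects must have one column per class")
    global_significance = np.asarray(global_significance, dtype=bool)
    if global_significance.shape != (N_CLASSES,):
        raise ValueError("global significance must be a 96-vector of booleans")
    types = per_type_effects.index
    if len(types) < 3:
        raise ValueError("need at least 3 tumor types for the per-class regressions")
    loads = load_table.loads.reindex(types)
    if loads.isna().any().any():
        raise ValueError("load table missing tumor types present in the effects matrix")

    rows = []
    skipped = []
    for sig in load_table.eligible_signatures(min_samples=min_samples, min_types=min_types):
        x = loads[sig].to_numpy(dtype=float)
        if np.all(x == x[0]):
            skipped.append(sig)
            logger.info("signature %s skipped: zero-variance load", sig)
            continue
        pvals = _ols_slope_pvalues(x, per_type_effects.to_numpy(dtype=float))
        reg_sig = pvals < alpha_reg
        table = (
            int(np.sum(reg_sig & global_significance)),
            int(np.sum(reg_sig & ~global_significance)),
            int(np.sum(~reg_sig & global_significance)),
            int(np.sum(~reg_sig & ~global_significance)),
        )
        chi2, p = chi2_2x2(*table, yates=yates)
        rows.append((sig, chi2, p, table[0], table[1], table[2], table[3]))
    if not rows:
        raise ValueError("no testable signatures (all artifact, rare, or degenerate)")
    out = pd.DataFrame(
        rows,
        columns=["signature", "chi2", "p", "n_both", "n_reg_only", "n_global_only", "n_neither"],
    ).set_index("signature")
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    out.attrs["skipped"] = skipped
    return out


# ------------------------------------------------------------ summary report


def top_enrichment_signature_report(
    enrichment: pd.DataFrame,
    signatures: pd.DataFrame,
    top_fraction: float = 0.10,
    min_component: float = 0.05,
) -> pd.DataFrame:
    """Match the most enriched classes against signature compositions.

    Takes the top ``top_fraction`` of classes by |log enrichment| in
    each direction (enriched in A, enriched in B) and reports every
    signature in which such a class accounts for at least
    ``min_component`` of the signature's mutations.
    """
    if len(signatures.columns) == 0 or len(enrichment) == 0:
        return pd.DataFrame(columns=["class", "direction", "enrichment", "signature", "component"])
    e = enrichment["enrichment"].to_numpy(dtype=float)
    finite = np.isfinite(e) & (e > 0)
    log_e = np.full(len(e), np.nan)
    log_e[finite] = np.log10(e[finite])
    k = max(1, int(round(top_fraction * len(enrichment))))
    rows = []
    for direction, side in (("A", log_e > 0), ("B", log_e < 0)):
        idx = np.flatnonzero(side & finite)
        if len(idx) == 0:
            continue
        top = idx[np.argsort(-np.abs(log_e[idx]))][:k]
        for i in top:
            label = enrichment.index[i]
            if label not in signatures.index:
                raise KeyError(f"class {label!r} missing from the signature matrix")
            for sig in signatures.columns:
                comp = float(signatures.loc[label, sig])
                if comp >= min_component:
                    rows.append((label, direction, float(e[i]), sig, comp))
    return pd.DataFrame(rows, columns=["class", "direction", "enrichment", "signature", "component"])
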