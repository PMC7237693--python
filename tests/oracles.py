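"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive quantities from first principles
(enumeration, per-base loops) and never call the package code they
check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def exact_mannwhitney_p(a, b) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney by enumerating all group labelings.

    Returns (U of sample a, p).  U counts pairs (x in a, y in b) with
    x > y, plus half-ties, matching the classical definition.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n1 = len(a)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    u_obs = u_stat(a, b)
    us = []
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in idx if i not in comb]
        us.append(u_stat(ga, gb))
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def exact_ks_p(a, b) -> tuple[float, float]:
    """Two-sided exact KS by enumerating all group labelings.

    Returns (D, P(D' >= D)) under the permutation null.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def d_stat(x, y):
        grid = np.unique(np.concatenate([x, y]))
        fx = np.searchsorted(np.sort(x), grid, side="right") / len(x)
        fy = np.searchsorted(np.sort(y), grid, side="right") / len(y)
        return np.max(np.abs(fx - fy))

    d_obs = d_stat(a, b)
    ds = []
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        ds.append(d_stat(pooled[mask], pooled[~mask]))
    ds = np.array(ds)
    return float(d_obs), float(np.mean(ds >= d_obs - 1e-12))


def per_base_pass(mappability, callability, cnv, length, max_poor=0.25) -> np.ndarray:
    """Per-base boolean evaluation of the mask-combination rule.

    ``mappability`` and ``cnv`` are interval lists; ``callability`` maps
    species -> list of per-sample interval lists.
    """

    def covered(iv_list):
        v = np.zeros(length, dtype=bool)
        for s, e in iv_list:
            v[s:e] = True
        return v

    ok = covered(mappability)
    for species, samples in callability.items():
        counts = np.zeros(length)
        for iv in samples:
            counts += covered(iv)
        poor = (len(samples) - counts) / len(samples)
        ok &= poor < max_poor
    ok &= ~covered(cnv)
    return ok


def per_base_window_fraction(pass_vec: np.ndarray, start: int, end: int) -> float:
    return float(pass_vec[start:end].mean())


def per_base_overlap_fraction(
    pass_vec: np.ndarray, feat_vec: np.ndarray, start: int, end: int
) -> float:
    p = pass_vec[start:end]
    if p.sum() == 0:
        return float("nan")
    return float((p & feat_vec[start:end]).sum() / p.sum())
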