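"""Windowed mutation densities: variant filters, counting, z-scores, ranks.

Density for window w is d_w = n_w / f_w where n_w counts in-mask SNVs
(segregating sites once each; somatic events weighted by multiplicity)
and f_w is the window's passing fraction, yielding mutations per Mbp of
window length.  Densities are standardized within each dataset and
ranked ascending (rank 1 = coldest window, average ties) so that
landscapes with different distribution shapes can be compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals
from .catalogs import SOMATIC, VariantCatalog
from .intervals import MaskSet

logger = logging.getLogger("mutland.density")

DENSITY_COLUMNS = ["chrom", "start", "end", "n", "d", "z", "rank"]


@dataclass
class FilterTallies:
    missingness: int = 0
    indel_proximity: int = 0
    het_excess: int = 0
    fixed_derived: int = 0

    def as_dict(self) -> Dict[str, int]:
        return {
            "missingness": self.missingness,
            "indel_proximity": self.indel_proximity,
            "het_excess": self.het_excess,
            "fixed_derived": self.fixed_derived,
        }


def filter_variants(
    catalog: VariantCatalog,
    max_missing: float = 0.20,
    max_het_fraction: float = 0.80,
    indel_distance: int = 5,
    drop_fixed_derived: bool = True,
) -> Tuple[VariantCatalog, FilterTallies]:
    """Quality filters applied before any counting.

    Removes records with >= ``max_missing`` missing genotypes (inclusive,
    so 2 of 10 missing is removed), any variant -- SNV or InDel -- within
    ``indel_distance`` bp of an InDel (inclusive distance; misalignment
    guard), and records where heterozygotes are strictly more than
    ``max_het_fraction`` of the called genotypes (mismapping guard).
    Sites where every called genotype is homozygous alternate are fixed
    in the sample and not segregating; they are dropped too by default.
    Genotype-based rules only apply in population mode; requesting them
    on a somatic catalog is an error.

    Returns the filtered catalog and per-rule removal tallies (a record
    violating several rules is tallied under each).
    """
    n = len(catalog)
    tallies = FilterTallies()
    if n == 0:
        return catalog, tallies
    if catalog.mode == SOMATIC:
        # genotype summaries are undefined for somatic catalogs
        if np.any(catalog.n_called > 0):
            raise ValueError("genotype-based filters are undefined for somatic catalogs")
        removed = _near_indel(catalog, indel_distance)
        tallies.indel_proximity = int(removed.sum())
        return catalog.take(~removed), tallies

    sample_count = catalog.n_samples
    if sample_count <= 0:
        raise ValueError("population-mode catalog without a sample count")

    miss = catalog.n_missing / sample_count >= max_missing
    near = _near_indel(catalog, indel_distance)
    called = catalog.n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(called > 0, catalog.n_het / np.maximum(called, 1), 0.0)
    het = het_frac > max_het_fraction
    fixed = np.zeros(n, dtype=bool)
    if drop_fixed_derived:
        fixed = (called > 0) & (catalog.n_het == 0) & (catalog.n_hom_alt == called)

    tallies.missingness = int(miss.sum())
    tallies.indel_proximity = int(near.sum())
    tallies.het_excess = int(het.sum())
    tallies.fixed_derived = int(fixed.sum())
    removed = miss | near | het | fixed
    return catalog.take(~removed), tallies


def _near_indel(catalog: VariantCatalog, distance: int) -> np.ndarray:
    """Records within ``distance`` bp (inclusive) of an InDel record.

    An InDel is never its own neighbour, but two nearby InDels remove
    each other.
    """
    flag = np.zeros(len(catalog), dtype=bool)
    is_indel = ~catalog.is_snv
    for ci in np.unique(catalog.chrom):
        on_ci = catalog.chrom == ci
        ind_pos = np.sort(catalog.pos[on_ci & is_indel])
        if len(ind_pos) == 0:
            continue
        idx = np.flatnonzero(on_ci)
        pos = catalog.pos[idx]
        n_near = np.searchsorted(ind_pos, pos + distance, side="right") - np.searchsorted(
            ind_pos, pos - distance, side="left"
        )
        # an InDel sees itself in the neighbourhood count; discount it
        n_near = n_near - is_indel[idx].astype(np.int64)
        flag[idx] = n_near >= 1
    return flag


def count_window_variants(
    catalog: VariantCatalog,
    windows: pd.DataFrame,
    mask: MaskSet,
    mode: str | None = None,
) -> np.ndarray:
    """SNV count per window row (segregating sites or mutational events).

    An SNV contributes to a window iff its position lies inside the
    window and inside the pass mask; overlapping windows each count it.
    ``segregating`` counts each site once; ``events`` weights by the
    record multiplicity (repeated somatic mutations are independent
    events).  InDels never count.
    """
    if mode is None:
        mode = "events" if catalog.mode == SOMATIC else "segregating"
    if mode not in ("segregating", "events"):
        raise ValueError("mode must be 'segregating' or 'events'")
    counts = np.zeros(len(windows), dtype=np.int64)
    win_chrom = windows["chrom"].to_numpy()
    win_start = windows["start"].to_numpy()
    win_end = windows["end"].to_numpy()
    snv = catalog.is_snv
    n_in_mask = 0
    n_outside = 0
    for ci, name in enumerate(catalog.chrom_names):
        sel = snv & (catalog.chrom == ci)
        if not np.any(sel):
            continue
        pos = catalog.pos[sel]
        w = catalog.multiplicity[sel] if mode == "events" else np.ones(sel.sum(), dtype=np.int64)
        in_mask = mask.contains(name, pos)
        pos, w = pos[in_mask], w[in_mask]
        order = np.argsort(pos, kind="stable")
        pos, w = pos[order], w[order]
        wpref = np.concatenate([[0], np.cumsum(w)])
        rows = np.flatnonzero(win_chrom == name)
        lo = np.searchsorted(pos, win_start[rows], side="left")
        hi = np.searchsorted(pos, win_end[rows], side="left")
        counts[rows] = wpref[hi] - wpref[lo]
        n_in_mask += len(pos)
        if len(rows):
            win_union = intervals.merge(
                np.stack([win_start[rows], win_end[rows]], axis=1)
            )
            n_outside += int((~intervals.contains(win_union, pos)).sum())
        else:
            n_outside += len(pos)
    if n_outside:
        logger.info(
            "count_window_variants dataset=%s outside_windows=%d in_mask=%d",
            catalog.dataset,
            n_outside,
            n_in_mask,
        )
    return counts


def compute_density(counts: np.ndarray, windows: pd.DataFrame) -> np.ndarray:
    """d_w = n_w / f_w, in mutations per Mbp of window length."""
    f_w = windows["f_w"].to_numpy()
    retained = windows["retained"].to_numpy()
    if np.any(retained & (f_w <= 0)):
        raise AssertionError("retained window with zero passing fraction")
    d = np.full(len(windows), np.nan)
    d[retained] = counts[retained] / f_w[retained]
    scale = 1_000_000 / (windows["end"].to_numpy() - windows["start"].to_numpy())
    return d * scale


def standardize(values: np.ndarray) -> np.ndarray:
    """Z-scores with the sample SD (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    sd = np.std(v, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardize a constant (zero-variance) distribution")
    return (v - np.mean(v)) / sd


def rank_windows(values: np.ndarray) -> np.ndarray:
    """Ascending ranks 1..N (1 = lowest density), average ties."""
    return stats.rankdata(np.asarray(values, dtype=float), method="average")


def density_table(
    catalog: VariantCatalog,
    windows: pd.DataFrame,
    mask: MaskSet,
    mode: str | None = None,
) -> pd.DataFrame:
    """Full per-window density table over the retained windows."""
    counts = count_window_variants(catalog, windows, mask, mode=mode)
    d = compute_density(counts, windows)
    keep = windows["retained"].to_numpy()
    out = windows.loc[keep, ["chrom", "start", "end"]].reset_index(drop=True)
    out["n"] = counts[keep]
    out["d"] = d[keep]
    out["z"] = standardize(out["d"].to_numpy())
    out["rank"] = rank_windows(out["d"].to_numpy())
    out.attrs["dataset"] = catalog.dataset
    return out


@dataclass
class CpGSplit:
    cpg_t: VariantCatalog
    non_cpg: VariantCatalog
    other_at_cpg: VariantCatalog
    n_no_context: int


def split_by_cpg(catalog: VariantCatalog, reference) -> CpGSplit:
    """Partition SNVs into CpG>T transitions, non-CpG SNVs, and the
    remainder (other substitutions at CpG sites).

    A position participates in a reference CpG when the reference has C
    followed by G on either strand: ref C with G to the right, or ref G
    with C to the left.  CpG>T means C>T at such a C (or G>A at such a
    G).  SNVs at a CpG with any other substitution belong to neither
    density and are returned separately; chromosome-edge records without
    context are excluded and counted.
    """
    snv = catalog.snvs()
    n = len(snv)
    at_cpg = np.zeros(n, dtype=bool)
    cpg_t = np.zeros(n, dtype=bool)
    has_ctx = np.zeros(n, dtype=bool)
    for ci, name in enumerate(snv.chrom_names):
        on_ci = snv.chrom == ci
        if not np.any(on_ci):
            continue
        pos = snv.pos[on_ci]
        ctx_ok = reference.has_context(name, pos)
        has_ctx[on_ci] = ctx_ok
        idx = np.flatnonzero(on_ci)[ctx_ok]
        left, center, right = reference.context_codes(name, snv.pos[idx])
        ref = snv.ref[idx]
        alt = snv.alt[idx]
        fwd = (ref == 1) & (right == 2)  # C followed by G
        rev = (ref == 2) & (left == 1)  # G preceded by C
        at_cpg[idx] = fwd | rev
        cpg_t[idx] = (fwd & (alt == 3)) | (rev & (alt == 0))
        del center
    return CpGSplit(
        cpg_t=snv.take(cpg_t),
        non_cpg=snv.take(has_ctx & ~at_cpg),
        other_at_cpg=snv.take(at_cpg & ~cpg_t),
        n_no_context=int(n - has_ctx.sum()),
    )
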