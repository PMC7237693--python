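"""Trinucleotide mutation classes, spectra and the high-confidence filter.

Every SNV is classified into one of 96 folded trinucleotide classes: the
substitution plus its immediate 5'/3' reference flanks, represented on
the pyrimidine strand (12 raw substitution types x 16 flank combinations,
halved by strand folding).  Class ordering follows the COSMIC SBS
convention -- substitution blocks C>A, C>G, C>T, T>A, T>C, T>G, flanks
alphabetical within each block -- so external signature tables align
positionally without a mapping step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals
from .catalogs import SOMATIC, VariantCatalog
from .reference import BASES, complement_codes
from .intervals import MaskSet

PYRIMIDINES = (1, 3)  # C, T
SUBSTITUTIONS = [(1, 0), (1, 2), (1, 3), (3, 0), (3, 1), (3, 2)]
SUBSTITUTION_LABELS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

# (center, alt) -> substitution block, -1 where not a pyrimidine substitution
_SUB_BLOCK = np.full((4, 4), -1, dtype=np.int8)
for _k, (_c, _a) in enumerate(SUBSTITUTIONS):
    _SUB_BLOCK[_c, _a] = _k

N_CLASSES = 96

CLASS_LABELS: Tuple[str, ...] = tuple(
    f"{BASES[l]}[{SUBSTITUTION_LABELS[b]}]{BASES[r]}"
    for b in range(6)
    for l in range(4)
    for r in range(4)
)

# per-class pyrimidine-strand encoding
CLASS_LEFT = np.array([l for b in range(6) for l in range(4) for r in range(4)], dtype=np.uint8)
CLASS_RIGHT = np.array([r for b in range(6) for l in range(4) for r in range(4)], dtype=np.uint8)
CLASS_CENTER = np.array(
    [SUBSTITUTIONS[b][0] for b in range(6) for _ in range(16)], dtype=np.uint8
)
CLASS_ALT = np.array([SUBSTITUTIONS[b][1] for b in range(6) for _ in range(16)], dtype=np.uint8)

# folded trinucleotide context id in 0..31: (center==T)*16 + left*4 + right
CLASS_CONTEXT = (CLASS_CENTER == 3).astype(np.int64) * 16 + CLASS_LEFT * 4 + CLASS_RIGHT
N_CONTEXTS = 32

# CpG>T transition classes: N[C>T]G
CPG_T_CLASSES = np.array(
    [i for i in range(N_CLASSES) if CLASS_CENTER[i] == 1 and CLASS_ALT[i] == 3 and CLASS_RIGHT[i] == 2]
)

CLASS_GC_COUNT = (
    np.isin(CLASS_LEFT, (1, 2)).astype(int)
    + np.isin(CLASS_CENTER, (1, 2)).astype(int)
    + np.isin(CLASS_RIGHT, (1, 2)).astype(int)
)


def class_index(label: str) -> int:
    return CLASS_LABELS.index(label)


def classify_codes(left, center, right, ref, alt) -> np.ndarray:
    """Vectorised folded classification from base codes.

    ``ref`` must equal ``center``; purine-reference records are
    reverse-complemented (which also swaps the flanks) before labelling.
    Returns class indices in 0..95, or -1 for records containing an
    ambiguous base.
    """
    left = np.asarray(left, dtype=np.uint8)
    center = np.asarray(center, dtype=np.uint8)
    right = np.asarray(right, dtype=np.uint8)
    ref = np.asarray(ref, dtype=np.uint8)
    alt = np.asarray(alt, dtype=np.uint8)
    ok = (left <= 3) & (center <= 3) & (right <= 3) & (ref <= 3) & (alt <= 3)
    if not np.all(center[ok] == ref[ok]):
        raise ValueError("context centre base must equal the reference allele")
    if np.any(ref[ok] == alt[ok]):
        raise ValueError("ref and alt must differ")

    l = left.copy()
    c = center.copy()
    r = right.copy()
    a = alt.copy()
    purine = ok & ((c == 0) | (c == 2))
    l[purine], r[purine] = complement_codes(right[purine]), complement_codes(left[purine])
    c[purine] = complement_codes(center[purine])
    a[purine] = complement_codes(alt[purine])

    out = np.full(left.shape, -1, dtype=np.int64)
    block = _SUB_BLOCK[c[ok], a[ok]]
    out[ok] = block.astype(np.int64) * 16 + l[ok] * 4 + r[ok]
    return out


def classify_variant(context: str, ref: str, alt: str) -> str:
    """Classify a single SNV given its 3-base reference context."""
    if len(context) != 3:
        raise ValueError("context must be exactly 3 bases")
    codes = [BASES.index(b) for b in context.upper()]
    idx = classify_codes(
        np.array([codes[0]]),
        np.array([codes[1]]),
        np.array([codes[2]]),
        np.array([BASES.index(ref.upper())]),
        np.array([BASES.index(alt.upper())]),
    )[0]
    if idx < 0:
        raise ValueError("ambiguous base in context")
    return CLASS_LABELS[idx]


def classify_catalog(catalog: VariantCatalog, reference) -> np.ndarray:
    """Class index per record; -1 for InDels and context-less records."""
    out = np.full(len(catalog), -1, dtype=np.int64)
    snv = catalog.is_snv
    for ci, name in enumerate(catalog.chrom_names):
        sel = snv & (catalog.chrom == ci)
        if not np.any(sel):
            continue
        pos = catalog.pos[sel]
        has_ctx = reference.has_context(name, pos)
        idx = np.flatnonzero(sel)[has_ctx]
        l, c, r = reference.context_codes(name, pos[has_ctx])
        out[idx] = classify_codes(l, c, r, catalog.ref[idx], catalog.alt[idx])
    return out


def count_classes(
    catalog: VariantCatalog, reference, mode: str | None = None
) -> Tuple[np.ndarray, Dict[str, int]]:
    """Genome-wide marginal 96-vector of class counts.

    ``mode`` defaults to the catalog's own: somatic catalogs count each
    repeated mutation (multiplicity) as an independent event.
    """
    mode = mode or ("events" if catalog.mode == SOMATIC else "segregating")
    cls = classify_catalog(catalog, reference)
    valid = cls >= 0
    w = catalog.multiplicity if mode == "events" else np.ones(len(catalog), dtype=np.int64)
    counts = np.bincount(cls[valid], weights=w[valid], minlength=N_CLASSES).astype(np.int64)
    info = {
        "n_records": int(len(catalog)),
        "n_classified": int(valid.sum()),
        "n_unclassified": int(len(catalog) - catalog.is_snv.sum())
        + int(catalog.is_snv.sum() - valid.sum()),
    }
    return counts, info


def window_class_matrix(
    catalog: VariantCatalog,
    windows: pd.DataFrame,
    mask: MaskSet,
    reference,
    mode: str | None = None,
) -> np.ndarray:
    """Per-window x 96-class count matrix over retained windows.

    A variant contributes to every overlapping retained window provided
    it lies in the pass mask; weights follow ``mode`` as in
    :func:`count_classes`.
    """
    mode = mode or ("events" if catalog.mode == SOMATIC else "segregating")
    cls = classify_catalog(catalog, reference)
    weights = (
        catalog.multiplicity if mode == "events" else np.ones(len(catalog), dtype=np.int64)
    )
    out = np.zeros((len(windows), N_CLASSES), dtype=np.int64)
    win_chrom = windows["chrom"].to_numpy()
    win_start = windows["start"].to_numpy()
    win_end = windows["end"].to_numpy()
    for ci, name in enumerate(catalog.chrom_names):
        sel = (catalog.chrom == ci) & (cls >= 0)
        if not np.any(sel):
            continue
        pos = catalog.pos[sel]
        in_mask = mask.contains(name, pos)
        pos = pos[in_mask]
        c = cls[sel][in_mask]
        w = weights[sel][in_mask]
        order = np.argsort(pos, kind="stable")
        pos, c, w = pos[order], c[order], w[order]
        rows = np.flatnonzero(win_chrom == name)
        lo = np.searchsorted(pos, win_start[rows], side="left")
        hi = np.searchsorted(pos, win_end[rows], side="left")
        for row, a, b in zip(rows, lo, hi):
            if a < b:
                out[row] += np.bincount(c[a:b], weights=w[a:b], minlength=N_CLASSES).astype(
                    np.int64
                )
    return out


def spectrum(counts) -> np.ndarray:
    """96-class mutation spectrum: the fraction of all counted
    trinucleotide mutations falling in each class."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (N_CLASSES,):
        raise ValueError(f"expected a {N_CLASSES}-vector of counts")
    if np.any(counts < 0):
        raise ValueError("negative class count")
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot compute a spectrum from zero mutations")
    return counts / total


def mixture_vector(signatures: pd.DataFrame, weights: Mapping[str, float]) -> np.ndarray:
    """Weighted combination of signature columns (e.g. 0.1*SBS1 + 0.9*SBS5)."""
    w = dict(weights)
    missing = [s for s in w if s not in signatures.columns]
    if missing:
        raise KeyError(f"signatures not in matrix: {missing}")
    if abs(sum(w.values()) - 1.0) > 1e-6:
        raise ValueError("mixture weights must sum to 1")
    vec = np.zeros(N_CLASSES)
    for name, wt in w.items():
        vec += wt * signatures[name].to_numpy()
    return vec


def spectrum_mixture_correlation(
    spec: np.ndarray, signatures: pd.DataFrame, weights: Mapping[str, float] | None = None
) -> float:
    """Pearson correlation between a 96-class spectrum and a signature
    mixture, default 0.1 x SBS1 + 0.9 x SBS5 (CpG>T transitions dominate
    SBS1 and make up roughly 10% of germline trinucleotide mutations)."""
    if weights is None:
        weights = {"SBS1": 0.1, "SBS5": 0.9}
    if list(signatures.index) != list(CLASS_LABELS):
        raise ValueError("signature matrix rows must follow the canonical class ordering")
    mix = mixture_vector(signatures, weights)
    spec = np.asarray(spec, dtype=float)
    if spec.shape != (N_CLASSES,):
        raise ValueError("spectrum must be a 96-vector")
    if np.std(spec) == 0 or np.std(mix) == 0:
        raise ValueError("degenerate (constant) spectrum or mixture; correlation undefined")
    r, _ = stats.pearsonr(spec, mix)
    return float(r)


@dataclass
class HighConfidenceResult:
    catalogs: Dict[str, VariantCatalog]
    windows: pd.DataFrame  # adds f_hq and retained_hq columns
    tallies: Dict[str, Dict[str, int]]  # species -> rule -> removed count


def _indel_frequency(catalog: VariantCatalog) -> np.ndarray:
    ind = ~catalog.is_snv
    freq = np.zeros(len(catalog))
    called = np.maximum(catalog.n_called, 1)
    freq[ind] = (catalog.n_het[ind] + 2 * catalog.n_hom_alt[ind]) / (2 * called[ind])
    return freq


def high_confidence_filter(
    catalogs: Dict[str, VariantCatalog],
    consistency_mask: MaskSet,
    windows: pd.DataFrame,
    base_mask: MaskSet,
    min_pass: float = 0.5,
    border_distance: int = 1,
    indel_freq_threshold: float = 0.5,
) -> HighConfidenceResult:
    """Species-exclusive high-confidence SNV filter.

    Keeps an SNV iff it (1) lies where the trinucleotide context is
    identical across all reference genomes (the supplied consistency
    mask), (2) is absent from every other species' catalog at the same
    position, (3) sits with its full context inside the pass mask (no
    base within ``border_distance`` of a pass/fail border), (4) is not
    part of a multinucleotide variant (no same-species SNV within 1 bp),
    (5) does not overlap a same-species InDel, and (6) does not overlap
    another species' InDel at population frequency >= 50%.

    Windows are re-retained only where at least ``min_pass`` of the
    window passes the combined original + consistency filter.
    """
    if consistency_mask is None:
        raise ValueError("a cross-reference consistency mask is required")
    combined = base_mask.intersection(consistency_mask)

    # positions of SNVs and qualifying InDel spans per species, per chromosome
    other_snv_pos: Dict[str, Dict[int, np.ndarray]] = {}
    indel_spans: Dict[str, Dict[int, np.ndarray]] = {}
    hifreq_indel_spans: Dict[str, Dict[int, np.ndarray]] = {}
    for sp, cat in catalogs.items():
        freq = _indel_frequency(cat)
        other_snv_pos[sp] = {}
        indel_spans[sp] = {}
        hifreq_indel_spans[sp] = {}
        for ci in range(len(cat.chrom_names)):
            on_ci = cat.chrom == ci
            other_snv_pos[sp][ci] = np.sort(cat.pos[on_ci & cat.is_snv])
            ind = on_ci & ~cat.is_snv
            spans = np.stack([cat.pos[ind], cat.pos[ind] + cat.ref_len[ind]], axis=1)
            indel_spans[sp][ci] = spans
            hi = ind & (freq >= indel_freq_threshold)
            hifreq_indel_spans[sp][ci] = np.stack(
                [cat.pos[hi], cat.pos[hi] + cat.ref_len[hi]], axis=1
            )

    def in_spans(spans: np.ndarray, pos: np.ndarray) -> np.ndarray:
        if len(spans) == 0:
            return np.zeros(len(pos), dtype=bool)
        return intervals.contains(spans, pos)

    out_catalogs: Dict[str, VariantCatalog] = {}
    tallies: Dict[str, Dict[str, int]] = {}
    for sp, cat in catalogs.items():
        snv = cat.snvs()
        n = len(snv)
        rules = {
            "consistency": np.zeros(n, dtype=bool),
            "not_exclusive": np.zeros(n, dtype=bool),
            "mask_border": np.zeros(n, dtype=bool),
            "multinucleotide": np.zeros(n, dtype=bool),
            "own_indel": np.zeros(n, dtype=bool),
            "other_indel": np.zeros(n, dtype=bool),
        }
        for ci, name in enumerate(cat.chrom_names):
            on_ci = snv.chrom == ci
            if not np.any(on_ci):
                continue
            pos = snv.pos[on_ci]
            rules["consistency"][on_ci] = ~consistency_mask.contains(name, pos)
            shared = np.zeros(len(pos), dtype=bool)
            for other, positions in other_snv_pos.items():
                if other == sp:
                    continue
                shared |= np.isin(pos, positions[ci])
            rules["not_exclusive"][on_ci] = shared
            # the full trinucleotide context must sit in the pass region
            ctx_ok = np.ones(len(pos), dtype=bool)
            for off in range(-border_distance, border_distance + 1):
                ctx_ok &= combined.contains(name, pos + off)
            rules["mask_border"][on_ci] = ~ctx_ok
            own = np.sort(pos)
            nearest = np.searchsorted(own, pos)
            mnv = np.zeros(len(pos), dtype=bool)
            for off in (-1, 1):
                mnv |= np.isin(pos + off, own)
            rules["multinucleotide"][on_ci] = mnv
            rules["own_indel"][on_ci] = in_spans(indel_spans[sp][ci], pos)
            other_hit = np.zeros(len(pos), dtype=bool)
            for other in catalogs:
                if other == sp:
                    continue
                other_hit |= in_spans(hifreq_indel_spans[other][ci], pos)
            rules["other_indel"][on_ci] = other_hit
        removed = np.zeros(n, dtype=bool)
        for flags in rules.values():
            removed |= flags
        out_catalogs[sp] = snv.take(~removed)
        tallies[sp] = {rule: int(flags.sum()) for rule, flags in rules.items()}
        tallies[sp]["kept"] = int((~removed).sum())

    win = windows.copy()
    f_hq = np.zeros(len(win))
    for name in win["chrom"].unique():
        rows = win["chrom"] == name
        covered = intervals.clipped_length(
            combined.restricted(name), win.loc[rows, "start"].to_numpy(), win.loc[rows, "end"].to_numpy()
        )
        f_hq[rows.to_numpy()] = covered / (
            win.loc[rows, "end"].to_numpy() - win.loc[rows, "start"].to_numpy()
        )
    win["f_hq"] = f_hq
    win["retained_hq"] = win["retained"] & (win["f_hq"] >= min_pass)
    return HighConfidenceResult(catalogs=out_catalogs, windows=win, tallies=tallies)
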