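"""Accessibility-mask combination, window construction, feature aggregation.

The analyzable genome is defined by intersecting a mappability mask,
per-sample callability masks (a base fails when it is poorly callable in
>= 25% of any species' samples, i.e. passes only when callable in more
than 75% of each group) and the complement of known copy-number-variable
regions.  Fixed-length overlapping windows are then tiled across each
chromosome and scored by the fraction f_w of their bases passing the
combined mask; windows with f_w below the retention threshold (default
>= 50%) are dropped from all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

from . import intervals
from .intervals import MaskSet

WINDOW_COLUMNS = ["chrom", "start", "end", "f_w", "retained"]


def combine_masks(
    mappability: MaskSet,
    callability: Mapping[str, Sequence[MaskSet]],
    cnv: MaskSet | None,
    genome_sizes: Mapping[str, int],
    max_poor_fraction: float = 0.25,
) -> MaskSet:
    """Combine accessibility masks into the pass/fail genome.

    A base passes iff it is mappable, AND for every species group
    independently it is callable in more than ``1 - max_poor_fraction``
    of that group's samples (poor callability in >= 25% of either group
    fails the base), AND it does not fall in a CNV interval.
    """
    for species, masks in callability.items():
        if len(masks) == 0:
            raise ValueError(f"species group {species!r} has no samples; callability fraction undefined")
    out: Dict[str, np.ndarray] = {}
    for chrom, length in genome_sizes.items():
        passing = intervals.merge(mappability.restricted(chrom))
        for species, masks in callability.items():
            n = len(masks)
            # callable fraction must strictly exceed 1 - max_poor_fraction
            # (poor in >= max_poor_fraction fails); epsilon guards the
            # exact-boundary case, e.g. 3 of 4 callable fails
            need = int(np.floor(n * (1 - max_poor_fraction) + 1e-9)) + 1
            good = intervals.coverage_at_least([m.restricted(chrom) for m in masks], need)
            passing = intervals.intersect(passing, good)
        if cnv is not None:
            passing = intervals.intersect(
                passing, intervals.complement(cnv.restricted(chrom), length)
            )
        out[chrom] = passing
    prov = ("mappability",) + tuple(f"callability:{s}" for s in callability)
    if cnv is not None:
        prov = prov + ("cnv",)
    return MaskSet(out, provenance=prov)


def make_windows(
    genome_sizes: Mapping[str, int],
    mask: MaskSet,
    window_size: int,
    step: int,
    min_pass: float = 0.5,
) -> pd.DataFrame:
    """Tile fixed-length overlapping windows and score passing fractions.

    Windows start at 0, step, 2*step, ... on each chromosome and only
    windows fully contained in the chromosome are emitted, so every f_w
    shares the same denominator.  Retention is inclusive:
    f_w >= ``min_pass``.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if step < 1 or step > window_size:
        raise ValueError("step must satisfy 0 < step <= window_size")
    frames = []
    for chrom, length in genome_sizes.items():
        if window_size > length:
            continue
        starts = np.arange(0, length - window_size + 1, step, dtype=np.int64)
        ends = starts + window_size
        covered = intervals.clipped_length(mask.restricted(chrom), starts, ends)
        f_w = covered / window_size
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "f_w": f_w,
                    "retained": f_w >= min_pass,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return pd.concat(frames, ignore_index=True)


@dataclass
class FeatureTrack:
    """A genomic feature as intervals, optionally with per-interval values.

    ``mode`` selects how the feature is summarised per window:
    ``"overlap"`` -- fraction of the window's *passing* bases covered by
    the feature; ``"mean"`` -- value-weighted mean over passing bases.
    """

    intervals: Dict[str, np.ndarray]
    values: Dict[str, np.ndarray] | None = None
    mode: str = "overlap"
    name: str = "feature"

    def __post_init__(self):
        if self.mode not in ("overlap", "mean"):
            raise ValueError("aggregation mode must be 'overlap' or 'mean'")
        if self.mode == "mean" and self.values is None:
            raise ValueError("mean-mode tracks need per-interval values")
        if self.values is not None:
            for c, vals in self.values.items():
                vals = np.asarray(vals, dtype=float)
                if not np.all(np.isfinite(vals)):
                    raise ValueError(f"non-finite feature value on {c}")
                if len(vals) != len(self.intervals[c]):
                    raise ValueError("values and intervals disagree in length")
                self.values[c] = vals


def aggregate_feature(
    track: FeatureTrack, windows: pd.DataFrame, mask: MaskSet
) -> np.ndarray:
    """Per-window feature summary over passing bases.

    Returns one value per window row; windows with zero passing bases get
    NaN (flagged, not silently zeroed).
    """
    out = np.full(len(windows), np.nan)
    for chrom in windows["chrom"].unique():
        rows = np.flatnonzero((windows["chrom"] == chrom).to_numpy())
        starts = windows["start"].to_numpy()[rows]
        ends = windows["end"].to_numpy()[rows]
        pass_iv = mask.restricted(chrom)
        pass_len = intervals.clipped_length(pass_iv, starts, ends)
        feat_iv = intervals.merge(track.intervals.get(chrom, np.empty((0, 2), dtype=np.int64)))
        if track.mode == "overlap":
            both = intervals.intersect(feat_iv, pass_iv)
            cov = intervals.clipped_length(both, starts, ends)
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(pass_len > 0, cov / np.maximum(pass_len, 1), np.nan)
            vals = np.where(pass_len > 0, vals, np.nan)
        else:
            raw_iv = track.intervals.get(chrom, np.empty((0, 2), dtype=np.int64))
            raw_vals = track.values.get(chrom, np.empty(0))
            vals = np.full(len(rows), np.nan)
            for k, (s, e) in enumerate(zip(starts, ends)):
                if pass_len[k] == 0:
                    continue
                total = 0.0
                weight = 0
                for (fs, fe), v in zip(raw_iv, raw_vals):
                    if fe <= s or fs >= e:
                        continue
                    seg = np.array([[max(fs, s), min(fe, e)]])
                    covered = intervals.clipped_length(pass_iv, seg[:, 0], seg[:, 1])[0]
                    total += v * covered
                    weight += covered
                vals[k] = total / weight if weight > 0 else np.nan
        out[rows] = vals
    return out
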