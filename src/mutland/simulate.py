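"""Synthetic genomes, masks and multi-dataset variant catalogs.

The generator emulates the statistical structure the landscape analysis
assumes, so every downstream stage is testable without consortium data:

* toy reference chromosomes whose per-window CpG-dinucleotide density
  follows a configurable (skewed by default) island profile -- CpG>T
  classes can only be placed at reference CpG sites, which concentrates
  them where CpG density is high;
* a latent per-window log-intensity field shared across datasets with a
  configurable cross-dataset Pearson correlation matrix (the latent
  field is log-normal: an exponentiated Gaussian guarantees positive
  rates and preserves rank correlations; the true generative model of
  regional mutation-rate variation is unknown, so this is an explicit
  stand-in);
* variant catalogs per dataset with trinucleotide classes drawn from
  per-dataset signature mixtures, genotype summaries with injected
  missingness and heterozygote excess, InDels, and somatic multiplicity,
  so that every downstream filter fires on default fixtures.

The latent field actually lives on non-overlapping `step`-length tiles:
overlapping windows share sequence, hence must share intensity.  A
window's expected count is the sum over its tiles, and cross-dataset
correlations at the window level equal the configured tile-level ones.
With ``step == window_size`` tiles and windows coincide.

Determinism: one global seed; each stage derives a child generator from
the seed and the stage name, so regenerating one stage never perturbs
the others.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import trinuc
from .catalogs import INDEL, POPULATION, SNV, SOMATIC, VariantCatalog
from .difftests import SignatureLoadTable
from .intervals import MaskSet, complement, merge
from .reference import Reference, complement_codes

logger = logging.getLogger("mutland.simulate")

DEFAULT_DATASETS = ("human", "chimpanzee", "tumor")
# Emulates the observed structure: strong germline-germline correlation,
# weak human-tumor, intermediate ape-tumor.
DEFAULT_CORRELATION = np.array(
    [
        [1.00, 0.65, 0.16],
        [0.65, 1.00, 0.55],
        [0.16, 0.55, 1.00],
    ]
)


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the global seed."""
    key = zlib.crc32(stage.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def synthetic_signature_matrix(
    n_null: int = 3, seed: int = 0, artifact: int = 1
) -> Tuple[pd.DataFrame, Dict[str, bool]]:
    """Synthetic stand-in for a COSMIC-style SBS probability matrix.

    The real COSMIC vectors are external data; this constructs
    qualitatively similar synthetic columns: ``SBS1`` concentrates ~88%
    of its mass on the four N[C>T]G CpG-transition classes (deamination
    clock), ``SBS5`` and ``SBS40`` are flat-ish clock-like signatures
    with gentle random variation, plus ``n_null`` featureless null
    signatures and ``artifact`` flagged artifact signatures.

    Returns (96 x S DataFrame indexed by class label, artifact flags).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(zlib.crc32(b"signatures"),)))
    idx = pd.Index(trinuc.CLASS_LABELS, name="class")
    cols = {}

    sbs1 = np.full(trinuc.N_CLASSES, 0.12 / (trinuc.N_CLASSES - 4))
    sbs1[trinuc.CPG_T_CLASSES] = 0.88 / 4
    cols["SBS1"] = sbs1

    def flatish(cpg_mass: float, spread: float) -> np.ndarray:
        v = rng.dirichlet(np.full(trinuc.N_CLASSES, spread))
        v[trinuc.CPG_T_CLASSES] = cpg_mass / 4
        other = np.setdiff1d(np.arange(trinuc.N_CLASSES), trinuc.CPG_T_CLASSES)
        v[other] *= (1 - cpg_mass) / v[other].sum()
        return v

    cols["SBS5"] = flatish(cpg_mass=0.02, spread=60.0)
    cols["SBS40"] = flatish(cpg_mass=0.02, spread=40.0)
    for i in range(n_null):
        cols[f"SBSN{i + 1}"] = rng.dirichlet(np.full(trinuc.N_CLASSES, 5.0))
    flags = {name: False for name in cols}
    for i in range(artifact):
        name = f"SBSA{i + 1}"
        cols[name] = rng.dirichlet(np.full(trinuc.N_CLASSES, 2.0))
        flags[name] = True
    mat = pd.DataFrame(cols, index=idx)
    return mat, flags


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic run.

    Lengths are bp; rates are per-variant probabilities; the intensity
    correlation is the cross-dataset Pearson matrix of the latent
    per-tile log-intensities.
    """

    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    window_size: int = 100_000
    step: int = 50_000
    dataset_names: Tuple[str, ...] = DEFAULT_DATASETS
    dataset_modes: Tuple[str, ...] | None = None  # inferred from names when None
    intensity_correlation: np.ndarray = dc_field(
        default_factory=lambda: DEFAULT_CORRELATION.copy()
    )
    mean_mutations_per_window: float | Tuple[float, ...] = 1000.0
    latent_sd: float = 0.25
    spectrum_mixtures: Dict[str, Dict[str, float]] | None = None
    signatures: pd.DataFrame | None = None
    signature_artifacts: Dict[str, bool] | None = None
    cpg_island_profile: np.ndarray | None = None  # per-tile multiplier
    cpg_rate: float = 0.01  # mean CpG-dinucleotide starts per base
    mask_fail_rate: float = 0.05
    missing_rate: float = 0.02
    het_excess_rate: float = 0.02
    indel_rate: float = 0.02
    fixed_rate: float = 0.005
    recurrence_rate: float = 0.01
    n_samples: int = 8
    tumor_samples: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.chrom_length < 3:
            raise ValueError("chrom_length < 3: no interior trinucleotide context")
        if self.window_size > self.chrom_length:
            raise ValueError("window_size must not exceed chrom_length")
        if self.step < 1 or self.step > self.window_size:
            raise ValueError("0 < step <= window_size required")
        if self.window_size % self.step != 0:
            raise ValueError("step must divide window_size (tile scheme)")
        if self.chrom_length % self.step != 0:
            raise ValueError("step must divide chrom_length")
        d = len(self.dataset_names)
        sigma = np.asarray(self.intensity_correlation, dtype=float)
        if sigma.shape != (d, d):
            raise ValueError("intensity correlation must be (n_datasets, n_datasets)")
        if not np.allclose(sigma, sigma.T):
            raise ValueError("intensity correlation must be symmetric")
        if not np.allclose(np.diag(sigma), 1.0):
            raise ValueError("intensity correlation must have a unit diagonal")
        eig = np.linalg.eigvalsh(sigma)
        if eig[0] < -1e-8:
            raise ValueError(
                f"intensity correlation is not positive semi-definite: "
                f"eigenvalue {eig[0]:.6g} < 0"
            )
        self.intensity_correlation = sigma
        if self.dataset_modes is None:
            self.dataset_modes = tuple(
                SOMATIC if name.startswith("tumor") else POPULATION
                for name in self.dataset_names
            )
        if len(self.dataset_modes) != d:
            raise ValueError("dataset_modes must align with dataset_names")
        for m in self.dataset_modes:
            if m not in (POPULATION, SOMATIC):
                raise ValueError(f"unknown dataset mode {m!r}")
        for name, value in (
            ("cpg_rate", self.cpg_rate),
            ("mask_fail_rate", self.mask_fail_rate),
            ("missing_rate", self.missing_rate),
            ("het_excess_rate", self.het_excess_rate),
            ("indel_rate", self.indel_rate),
            ("fixed_rate", self.fixed_rate),
            ("recurrence_rate", self.recurrence_rate),
        ):
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.signatures is None:
            self.signatures, flags = synthetic_signature_matrix(seed=self.seed)
            if self.signature_artifacts is None:
                self.signature_artifacts = flags
        if self.signature_artifacts is None:
            self.signature_artifacts = {c: False for c in self.signatures.columns}
        colsums = self.signatures.to_numpy().sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError("signature columns must sum to 1")
        if self.spectrum_mixtures is None:
            mixtures: Dict[str, Dict[str, float]] = {}
            for name, mode in zip(self.dataset_names, self.dataset_modes):
                if mode == SOMATIC:
                    mixtures[name] = {"SBS1": 0.1, "SBS5": 0.5, "SBS40": 0.4}
                else:
                    mixtures[name] = {"SBS1": 0.1, "SBS5": 0.9}
            self.spectrum_mixtures = mixtures
        for name in self.dataset_names:
            mix = self.spectrum_mixtures.get(name)
            if mix is None:
                raise ValueError(f"no spectrum mixture for dataset {name!r}")
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"spectrum mixture for {name!r} must sum to 1")
            for sig in mix:
                if sig not in self.signatures.columns:
                    raise ValueError(f"mixture of {name!r} references unknown signature {sig!r}")
        if np.isscalar(self.mean_mutations_per_window):
            self.mean_mutations_per_window = tuple(
                [float(self.mean_mutations_per_window)] * d
            )
        elif len(self.mean_mutations_per_window) != d:
            raise ValueError("mean_mutations_per_window must be scalar or per dataset")

    # ------------------------------------------------------------ geometry

    @property
    def chrom_names(self) -> Tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))

    @property
    def genome_sizes(self) -> Dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}

    @property
    def tiles_per_chrom(self) -> int:
        return self.chrom_length // self.step

    @property
    def n_tiles(self) -> int:
        return self.n_chromosomes * self.tiles_per_chrom

    @property
    def windows_per_chrom(self) -> int:
        return (self.chrom_length - self.window_size) // self.step + 1

    @property
    def tiles_per_window(self) -> int:
        return self.window_size // self.step

    def tile_table(self) -> pd.DataFrame:
        starts = np.arange(self.tiles_per_chrom, dtype=np.int64) * self.step
        frames = [
            pd.DataFrame({"chrom": c, "start": starts, "end": starts + self.step})
            for c in self.chrom_names
        ]
        return pd.concat(frames, ignore_index=True)


# ------------------------------------------------------------------ reference


def simulate_reference(config: SimulationConfig) -> Tuple[Reference, MaskSet]:
    """Toy reference with a controlled CpG-island landscape.

    Background bases are drawn iid but CpG dinucleotides are suppressed;
    CpGs are then planted per tile at a rate proportional to the CpG
    island profile, so the per-window CpG count is directly proportional
    to the profile.  Returns the reference and the planted CpG sites as
    a mask-style annotation.
    """
    rng = child_rng(config.seed, "reference")
    tiles = config.tile_table()
    profile = config.cpg_island_profile
    if profile is None:
        prof_rng = child_rng(config.seed, "cpg_profile")
        profile = np.exp(prof_rng.normal(0.0, 1.0, size=len(tiles)))
    profile = np.asarray(profile, dtype=float)
    if len(profile) != len(tiles):
        raise ValueError(
            f"cpg_island_profile must have one value per tile ({len(tiles)})"
        )
    if np.any(profile < 0):
        raise ValueError("cpg_island_profile must be non-negative")
    rel = profile / profile.mean() if profile.mean() > 0 else profile

    chroms: Dict[str, np.ndarray] = {}
    cpg_iv: Dict[str, np.ndarray] = {}
    base_p = np.array([0.3, 0.2, 0.2, 0.3])
    tpc = config.tiles_per_chrom
    for ci, name in enumerate(config.chrom_names):
        seq = rng.choice(4, size=config.chrom_length, p=base_p).astype(np.uint8)
        # suppress background CpGs so planted ones control the density
        for _ in range(8):
            cg = np.flatnonzero((seq[:-1] == 1) & (seq[1:] == 2))
            if len(cg) == 0:
                break
            seq[cg + 1] = rng.choice(np.array([0, 1, 3], dtype=np.uint8), size=len(cg))
        tile_rel = rel[ci * tpc : (ci + 1) * tpc]
        lam = config.cpg_rate * config.step * tile_rel
        counts = rng.poisson(lam)
        planted: List[np.ndarray] = []
        for t, k in enumerate(counts):
            if k == 0:
                continue
            lo = max(t * config.step, 1)
            hi = min(t * config.step + config.step, config.chrom_length - 2)
            if hi <= lo:
                continue
            cand = np.sort(rng.integers(lo, hi, size=k))
            keep = np.ones(len(cand), dtype=bool)
            last = -10
            for j, p in enumerate(cand):
                if p - last < 2:
                    keep[j] = False
                else:
                    last = p
            planted.append(cand[keep])
        pos = np.concatenate(planted) if planted else np.empty(0, dtype=np.int64)
        seq[pos] = 1
        seq[pos + 1] = 2
        chroms[name] = seq
        cpg_iv[name] = merge(np.stack([pos, pos + 2], axis=1)) if len(pos) else np.empty(
            (0, 2), dtype=np.int64
        )
    return Reference(chroms), MaskSet(cpg_iv, provenance=("cpg_islands",))


# ---------------------------------------------------------------- density field


@dataclass
class SimulatedField:
    """Latent log-intensities and positive rates per tile per dataset."""

    tiles: pd.DataFrame  # chrom, start, end
    latent: np.ndarray  # (n_tiles, n_datasets) correlated Gaussians
    rates: np.ndarray  # (n_tiles, n_datasets) expected SNVs per tile
    dataset_names: Tuple[str, ...]


def simulate_density_field(config: SimulationConfig) -> SimulatedField:
    """Correlated log-normal intensity field.

    One zero-mean Gaussian vector per tile across datasets with the
    configured correlation, scaled by ``latent_sd`` and exponentiated.
    Rates are normalised so each dataset's expected per-window total
    (summing each window's tiles, windows overlapping) equals
    ``mean_mutations_per_window``.
    """
    sigma = config.intensity_correlation
    eig = np.linalg.eigvalsh(sigma)
    if eig[0] < -1e-8:
        raise ValueError(f"correlation not PSD: eigenvalue {eig[0]:.6g} < 0")
    rng = child_rng(config.seed, "field")
    d = len(config.dataset_names)
    n = config.n_tiles
    # eigen factorisation tolerates singular matrices (e.g. off-diagonal 1)
    w, v = np.linalg.eigh(sigma)
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, d)) @ factor.T
    latent = config.latent_sd * z
    rates = np.exp(latent)

    tiles = config.tile_table()
    tpw = config.tiles_per_window
    tpc = config.tiles_per_chrom
    # multiplicity of each tile = number of windows containing it
    mult = np.empty(n)
    per_chrom = np.minimum(
        np.minimum(np.arange(tpc) + 1, tpc - np.arange(tpc)), tpw
    ).astype(float)
    for ci in range(config.n_chromosomes):
        mult[ci * tpc : (ci + 1) * tpc] = per_chrom
    n_windows = config.windows_per_chrom * config.n_chromosomes
    for j, mean_mut in enumerate(config.mean_mutations_per_window):
        target = mean_mut * n_windows
        rates[:, j] *= target / float(mult @ rates[:, j])
    return SimulatedField(
        tiles=tiles, latent=latent, rates=rates, dataset_names=config.dataset_names
    )


# --------------------------------------------------------------------- masks


def simulate_masks(
    config: SimulationConfig,
) -> Tuple[MaskSet, Dict[str, List[MaskSet]], MaskSet]:
    """Mappability, per-sample callability and CNV masks.

    Failing intervals are scattered so the combined pass fraction is
    high but every mask type removes something.
    """
    rng = child_rng(config.seed, "masks")
    L = config.chrom_length

    def failing(rate: float, mean_len: int) -> Dict[str, np.ndarray]:
        out = {}
        for c in config.chrom_names:
            n_iv = rng.poisson(rate * L / mean_len)
            if n_iv == 0:
                out[c] = np.empty((0, 2), dtype=np.int64)
                continue
            starts = np.sort(rng.integers(0, L - mean_len, size=n_iv))
            lens = rng.integers(mean_len // 2, mean_len * 2, size=n_iv)
            out[c] = merge(np.stack([starts, np.minimum(starts + lens, L)], axis=1))
        return out

    mappability = MaskSet(
        {c: complement(iv, L) for c, iv in failing(config.mask_fail_rate, 2000).items()},
        provenance=("mappability",),
    )
    callability: Dict[str, List[MaskSet]] = {}
    for name, mode in zip(config.dataset_names, config.dataset_modes):
        if mode != POPULATION:
            continue
        callability[name] = [
            MaskSet(
                {
                    c: complement(iv, L)
                    for c, iv in failing(config.mask_fail_rate / 2, 1000).items()
                },
                provenance=(f"callability:{name}:{s}",),
            )
            for s in range(config.n_samples)
        ]
    # CNV regions are large; one window-scale block per chromosome makes
    # sure some windows fall below the retention threshold
    cnv_iv = failing(config.mask_fail_rate / 2, 5000)
    for c in config.chrom_names:
        start = int(rng.integers(0, max(L - config.window_size, 1)))
        block = np.array([[start, min(start + config.window_size, L)]], dtype=np.int64)
        cnv_iv[c] = merge(np.concatenate([cnv_iv[c].reshape(-1, 2), block]))
    cnv = MaskSet(cnv_iv, provenance=("cnv",))
    return mappability, callability, cnv


def simulate_consistency_mask(config: SimulationConfig, fail_rate: float = 0.03) -> MaskSet:
    """Cross-reference trinucleotide-consistency mask.

    Stands in for the regions where the trinucleotide sequence is
    identical (accounting for strand) across all reference genomes;
    real cross-genome mapping is outside the generator's scope, so the
    failing intervals are random.
    """
    rng = child_rng(config.seed, "consistency")
    L = config.chrom_length
    out = {}
    for c in config.chrom_names:
        n_iv = rng.poisson(fail_rate * L / 500)
        if n_iv == 0:
            out[c] = np.array([[0, L]], dtype=np.int64)
            continue
        starts = np.sort(rng.integers(0, L - 500, size=n_iv))
        lens = rng.integers(100, 1000, size=n_iv)
        fail = merge(np.stack([starts, np.minimum(starts + lens, L)], axis=1))
        out[c] = complement(fail, L)
    return MaskSet(out, provenance=("consistency",))


# ------------------------------------------------------------------ catalogs


def _context_pools(reference: Reference, chrom: str) -> List[np.ndarray]:
    """Sorted positions per folded trinucleotide context (32 pools)."""
    seq = reference.chroms[chrom]
    l, c, r = seq[:-2], seq[1:-1], seq[2:]
    purine = (c == 0) | (c == 2)
    lf = np.where(purine, complement_codes(r), l)
    cf = np.where(purine, complement_codes(c), c)
    rf = np.where(purine, complement_codes(l), r)
    ctx = (cf == 3).astype(np.int64) * 16 + lf.astype(np.int64) * 4 + rf.astype(np.int64)
    order = np.argsort(ctx, kind="stable")
    pos = np.arange(1, len(seq) - 1, dtype=np.int64)[order]
    ctx_sorted = ctx[order]
    bounds = np.searchsorted(ctx_sorted, np.arange(trinuc.N_CONTEXTS + 1))
    return [np.sort(pos[bounds[k] : bounds[k + 1]]) for k in range(trinuc.N_CONTEXTS)]


def _reassign_empty(k: np.ndarray, widths: np.ndarray, ctx_label: int, chrom: str) -> np.ndarray:
    """Move requested draws from empty tiles to the nearest non-empty tile."""
    empty = np.flatnonzero((widths == 0) & (k > 0))
    if len(empty) == 0:
        return k
    nonempty = np.flatnonzero(widths > 0)
    if len(nonempty) == 0:
        logger.warning(
            "no position with context %d on %s; dropping %d requested draws",
            ctx_label,
            chrom,
            int(k[empty].sum()),
        )
        k = k.copy()
        k[empty] = 0
        return k
    k = k.copy()
    moved = 0
    for t in empty:
        j = nonempty[np.argmin(np.abs(nonempty - t))]
        moved += int(k[t])
        k[j] += k[t]
        k[t] = 0
    logger.warning(
        "context %d unavailable in %d tiles on %s; reassigned %d draws to nearest tiles",
        ctx_label,
        len(empty),
        chrom,
        moved,
    )
    return k


def _sample_positions(
    rng: np.random.Generator,
    pool: np.ndarray,
    tile_edges: np.ndarray,
    k: np.ndarray,
    unique: bool,
    ctx_label: int,
    chrom: str,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample k[t] positions from the context pool within each tile.

    Returns (positions, tile index per position, overflow per tile),
    ordered tile-major.  With ``unique`` the draw is without replacement
    within a tile; when a tile's pool is smaller than its request the
    excess is returned as overflow so the caller can place it at other
    contexts in the *same* tile (keeping the spatial intensity field
    intact).  Tiles with no compatible context at all have their draws
    reassigned to the nearest tile that has one.
    """
    lo = np.searchsorted(pool, tile_edges[:-1])
    hi = np.searchsorted(pool, tile_edges[1:])
    widths = hi - lo
    k = _reassign_empty(np.asarray(k, dtype=np.int64), widths, ctx_label, chrom)
    overflow = np.zeros(len(k), dtype=np.int64)
    if unique:
        over = np.flatnonzero(k > widths)
        if len(over):
            k = k.copy()
            overflow[over] = k[over] - widths[over]
            k[over] = widths[over]
            logger.info(
                "context %d pool exhausted in %d tiles on %s; %d draws fall back to other contexts",
                ctx_label,
                len(over),
                chrom,
                int(overflow.sum()),
            )
    total = int(k.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), overflow
    rep_lo = np.repeat(lo, k)
    rep_w = np.repeat(widths, k)
    tile_of = np.repeat(np.arange(len(k)), k)
    idx = rep_lo + (rng.random(total) * rep_w).astype(np.int64)
    if unique:
        for _ in range(12):
            order = np.argsort(idx, kind="stable")
            sidx = idx[order]
            dup_sorted = np.zeros(total, dtype=bool)
            dup_sorted[1:] = sidx[1:] == sidx[:-1]
            dup = np.zeros(total, dtype=bool)
            dup[order] = dup_sorted
            if not dup.any():
                break
            n_dup = int(dup.sum())
            idx[dup] = rep_lo[dup] + (rng.random(n_dup) * rep_w[dup]).astype(np.int64)
        else:
            # give up on the stragglers; they will be dropped below
            pass
        order = np.argsort(idx, kind="stable")
        sidx = idx[order]
        dup_sorted = np.zeros(total, dtype=bool)
        dup_sorted[1:] = sidx[1:] == sidx[:-1]
        dup = np.zeros(total, dtype=bool)
        dup[order] = dup_sorted
        if dup.any():
            logger.warning("dropping %d unresolvable duplicate positions", int(dup.sum()))
            keep = ~dup
            idx, tile_of = idx[keep], tile_of[keep]
    return pool[idx], tile_of, overflow


def _sfs_genotypes(
    rng: np.random.Generator, n: int, n_samples: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_het, n_hom_alt, n_called) under a 1/k site-frequency spectrum.

    Alt-allele counts k are drawn with P(k) proportional to 1/k over
    1..2S-1 (segregating, never fixed); heterozygote counts follow the
    random-pairing expectation with a parity fix.
    """
    S = n_samples
    kk = np.arange(1, 2 * S)
    p = (1.0 / kk) / np.sum(1.0 / kk)
    k = rng.choice(kk, size=n, p=p)
    p_het = (2 * S - k) / (2 * S - 1)
    n_het = rng.binomial(k, p_het)
    parity = (k - n_het) % 2
    n_het = n_het + parity
    upper = np.minimum(k, 2 * S - k)
    n_het = np.minimum(n_het, upper - ((upper - k) % 2 == 1))
    n_het = np.maximum(n_het, k % 2)
    n_hom = (k - n_het) // 2
    n_called = np.full(n, S, dtype=np.int64)
    return n_het.astype(np.int64), n_hom.astype(np.int64), n_called


@dataclass
class SimulatedCatalogs:
    catalogs: Dict[str, VariantCatalog]
    load_table: SignatureLoadTable


def simulate_variant_catalogs(
    config: SimulationConfig, field: SimulatedField, reference: Reference
) -> SimulatedCatalogs:
    """Place SNVs and nuisance records according to the intensity field.

    Per tile and dataset the SNV count is Poisson with the field's rate;
    each SNV is attributed to a signature drawn from the dataset's
    mixture, classified from that signature's 96-class distribution, and
    placed at a uniformly chosen compatible reference context (CpG>T
    classes only at CpG sites).  Population datasets receive genotype
    summaries from a 1/k frequency spectrum plus injected missingness,
    heterozygote excess and fixed-derived records at the configured
    rates; somatic datasets aggregate repeated draws into multiplicities
    and receive a per-tumor-type signature load table.  InDels are
    scattered at ``indel_rate``.  Deterministic given the config seed.
    """
    sig_names = [
        s for s in config.signatures.columns
        if any(s in config.spectrum_mixtures[d] for d in config.dataset_names)
    ]
    sig_probs = {s: config.signatures[s].to_numpy(dtype=float) for s in sig_names}
    tpc = config.tiles_per_chrom
    load_rows: Dict[str, Dict[str, float]] = {}

    catalogs: Dict[str, VariantCatalog] = {}
    for j, (name, mode) in enumerate(zip(config.dataset_names, config.dataset_modes)):
        rng = child_rng(config.seed, f"catalog:{name}")
        mix = config.spectrum_mixtures[name]
        mix_sigs = list(mix)
        mix_w = np.array([mix[s] for s in mix_sigs])
        load_rows[name] = {s: 0.0 for s in sig_names}

        parts = {
            "chrom": [],
            "pos": [],
            "ref": [],
            "alt": [],
            "kind": [],
            "ref_len": [],
            "alt_len": [],
            "multiplicity": [],
            "n_called": [],
            "n_missing": [],
            "n_het": [],
            "n_hom_alt": [],
        }

        def emit(ci, pos, ref, alt, kind, ref_len, alt_len, mult, gt):
            parts["chrom"].append(np.full(len(pos), ci, dtype=np.int16))
            parts["pos"].append(pos.astype(np.int64))
            parts["ref"].append(ref.astype(np.uint8))
            parts["alt"].append(alt.astype(np.uint8))
            parts["kind"].append(np.full(len(pos), kind, dtype=np.uint8))
            parts["ref_len"].append(ref_len.astype(np.int32))
            parts["alt_len"].append(alt_len.astype(np.int32))
            parts["multiplicity"].append(mult.astype(np.int32))
            n_het, n_hom, n_called, n_missing = gt
            parts["n_called"].append(n_called.astype(np.int32))
            parts["n_missing"].append(n_missing.astype(np.int32))
            parts["n_het"].append(n_het.astype(np.int32))
            parts["n_hom_alt"].append(n_hom.astype(np.int32))

        for ci, chrom in enumerate(config.chrom_names):
            pools = _context_pools(reference, chrom)
            seq = reference.chroms[chrom]
            tile_edges = np.arange(tpc + 1, dtype=np.int64) * config.step
            rates = field.rates[ci * tpc : (ci + 1) * tpc, j]
            counts = rng.poisson(rates)
            # signature attribution, then class within signature
            per_sig = rng.multinomial(counts, mix_w) if len(mix_w) > 1 else counts[:, None]
            class_counts = np.zeros((tpc, trinuc.N_CLASSES), dtype=np.int64)
            for si, s in enumerate(mix_sigs):
                n_s = per_sig[:, si]
                load_rows[name][s] += float(n_s.sum())
                class_counts += rng.multinomial(n_s, sig_probs[s])
            # place class draws context by context
            overflow_total = np.zeros(tpc, dtype=np.int64)
            for ctx in range(trinuc.N_CONTEXTS):
                cls_ids = np.flatnonzero(trinuc.CLASS_CONTEXT == ctx)
                k_tile_cls = class_counts[:, cls_ids]  # (tiles, 3)
                k_tile = k_tile_cls.sum(axis=1)
                if k_tile.sum() == 0:
                    continue
                pos, tile_of, overflow = _sample_positions(
                    rng, pools[ctx], tile_edges, k_tile, unique=(mode == POPULATION),
                    ctx_label=ctx, chrom=chrom,
                )
                overflow_total += overflow
                # class label per draw, tile-major to match the sampler
                cls = np.repeat(
                    np.tile(cls_ids, tpc), k_tile_cls.ravel()
                )
                cls = cls[: len(pos)] if len(cls) != len(pos) else cls
                g = seq[pos]
                pyr = (g == 1) | (g == 3)
                alt = np.where(
                    pyr, trinuc.CLASS_ALT[cls], complement_codes(trinuc.CLASS_ALT[cls])
                )
                if mode == POPULATION:
                    gt = _sfs_genotypes(rng, len(pos), config.n_samples)
                    gt = gt + (np.zeros(len(pos), dtype=np.int64),)
                    emit(
                        ci, pos, g, alt, SNV,
                        np.ones(len(pos)), np.ones(len(pos)),
                        np.ones(len(pos)), gt,
                    )
                else:
                    # aggregate repeated positions into multiplicities
                    key = pos * 4 + trinuc.CLASS_ALT[cls]
                    uniq, first, mult = np.unique(key, return_index=True, return_counts=True)
                    extra = rng.random(len(uniq)) < config.recurrence_rate
                    mult = mult + extra
                    z = np.zeros(len(uniq), dtype=np.int64)
                    emit(
                        ci, pos[first], g[first], alt[first], SNV,
                        np.ones(len(uniq)), np.ones(len(uniq)),
                        mult, (z, z, z, z),
                    )

            if overflow_total.sum() > 0:
                # uniqueness overflow stays in its tile at whatever context
                # is available, so the per-tile count (and the density
                # field) is preserved exactly
                p_over = np.repeat(np.arange(tpc), overflow_total) * config.step + (
                    rng.random(int(overflow_total.sum())) * (config.step - 2)
                ).astype(np.int64) + 1
                ref_o = seq[p_over]
                alt_o = (ref_o + rng.integers(1, 4, size=len(p_over)).astype(np.uint8)) % 4
                if mode == POPULATION:
                    gt = _sfs_genotypes(rng, len(p_over), config.n_samples)
                    gt = gt + (np.zeros(len(p_over), dtype=np.int64),)
                else:
                    z = np.zeros(len(p_over), dtype=np.int64)
                    gt = (z, z, z, z)
                emit(
                    ci, p_over, ref_o, alt_o, SNV,
                    np.ones(len(p_over)), np.ones(len(p_over)), np.ones(len(p_over)), gt,
                )

            # nuisance records: anywhere in the tile, summaries force each filter
            def uniform_positions(rate_scale: float) -> Tuple[np.ndarray, np.ndarray]:
                kk = rng.poisson(rates * rate_scale)
                total = int(kk.sum())
                if total == 0:
                    return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
                rep = np.repeat(np.arange(tpc), kk)
                p = rep * config.step + (rng.random(total) * (config.step - 2)).astype(
                    np.int64
                ) + 1
                return p, rep

            def random_alt(refs: np.ndarray) -> np.ndarray:
                shift = rng.integers(1, 4, size=len(refs)).astype(np.uint8)
                return (refs + shift) % 4

            S = config.n_samples
            if mode == POPULATION:
                p_miss, _ = uniform_positions(config.missing_rate)
                n_missing = np.full(len(p_miss), int(np.ceil(0.2 * S)), dtype=np.int64)
                refm = seq[p_miss]
                emit(
                    ci, p_miss, refm, random_alt(refm), SNV,
                    np.ones(len(p_miss)), np.ones(len(p_miss)), np.ones(len(p_miss)),
                    (
                        np.ones(len(p_miss), dtype=np.int64),
                        np.zeros(len(p_miss), dtype=np.int64),
                        np.full(len(p_miss), S, dtype=np.int64) - n_missing,
                        n_missing,
                    ),
                )
                p_het, _ = uniform_positions(config.het_excess_rate)
                refh = seq[p_het]
                emit(
                    ci, p_het, refh, random_alt(refh), SNV,
                    np.ones(len(p_het)), np.ones(len(p_het)), np.ones(len(p_het)),
                    (
                        np.full(len(p_het), S, dtype=np.int64),
                        np.zeros(len(p_het), dtype=np.int64),
                        np.full(len(p_het), S, dtype=np.int64),
                        np.zeros(len(p_het), dtype=np.int64),
                    ),
                )
                p_fix, _ = uniform_positions(config.fixed_rate)
                reff = seq[p_fix]
                emit(
                    ci, p_fix, reff, random_alt(reff), SNV,
                    np.ones(len(p_fix)), np.ones(len(p_fix)), np.ones(len(p_fix)),
                    (
                        np.zeros(len(p_fix), dtype=np.int64),
                        np.full(len(p_fix), S, dtype=np.int64),
                        np.full(len(p_fix), S, dtype=np.int64),
                        np.zeros(len(p_fix), dtype=np.int64),
                    ),
                )
            p_ind, _ = uniform_positions(config.indel_rate)
            refi = seq[p_ind]
            ref_len = rng.integers(2, 5, size=len(p_ind))
            if mode == POPULATION:
                gt = _sfs_genotypes(rng, len(p_ind), S)
                gt = gt + (np.zeros(len(p_ind), dtype=np.int64),)
            else:
                z = np.zeros(len(p_ind), dtype=np.int64)
                gt = (z, z, z, z)
            emit(
                ci, p_ind, refi, refi, INDEL,
                ref_len, np.ones(len(p_ind)), np.ones(len(p_ind)), gt,
            )

        cols = {k: np.concatenate(v) if v else np.empty(0) for k, v in parts.items()}
        cat = VariantCatalog(
            dataset=name,
            mode=mode,
            chrom_names=config.chrom_names,
            chrom=cols["chrom"].astype(np.int16),
            pos=cols["pos"].astype(np.int64),
            ref=cols["ref"].astype(np.uint8),
            alt=cols["alt"].astype(np.uint8),
            kind=cols["kind"].astype(np.uint8),
            ref_len=cols["ref_len"].astype(np.int32),
            alt_len=cols["alt_len"].astype(np.int32),
            multiplicity=cols["multiplicity"].astype(np.int32),
            n_called=cols["n_called"].astype(np.int32),
            n_missing=cols["n_missing"].astype(np.int32),
            n_het=cols["n_het"].astype(np.int32),
            n_hom_alt=cols["n_hom_alt"].astype(np.int32),
            n_samples=config.n_samples if mode == POPULATION else 0,
        ).sorted()
        catalogs[name] = cat

    somatic_names = [
        n for n, m in zip(config.dataset_names, config.dataset_modes) if m == SOMATIC
    ]
    index = somatic_names if somatic_names else list(config.dataset_names)
    loads = pd.DataFrame(
        {s: [load_rows[n][s] for n in index] for s in sig_names}, index=pd.Index(index, name="tumor_type")
    )
    samples = pd.DataFrame(
        {
            s: [
                (config.tumor_samples if load_rows[n][s] > 0 else 0) for n in index
            ]
            for s in sig_names
        },
        index=loads.index,
    )
    artifacts = {s: bool(config.signature_artifacts.get(s, False)) for s in sig_names}
    load_table = SignatureLoadTable(loads=loads, samples=samples, artifact=artifacts)
    return SimulatedCatalogs(catalogs=catalogs, load_table=load_table)


def recovery_config(
    seed: int = 0,
    n_windows: int = 5000,
    mean_mutations_per_window: float = 3000.0,
    intensity_correlation: np.ndarray | None = None,
) -> SimulationConfig:
    """Desk-scale study conditions for landscape-correlation recovery.

    Two chromosomes of 30 kb windows with 15 kb steps (a stand-in for the
    1 Mbp / 500 kb geometry) totalling ``n_windows`` windows, three
    datasets with the qualitative real-data correlation structure
    (germline-germline 0.65, human-tumor 0.16, ape-tumor 0.55), and
    enough mutations per window that Poisson counting noise attenuates
    the configured Pearson correlations by under ~2%.
    """
    step = 15_000
    per_chrom = n_windows // 2
    chrom_length = (per_chrom + 1) * step
    return SimulationConfig(
        n_chromosomes=2,
        chrom_length=chrom_length,
        window_size=2 * step,
        step=step,
        mean_mutations_per_window=mean_mutations_per_window,
        intensity_correlation=(
            DEFAULT_CORRELATION.copy()
            if intensity_correlation is None
            else np.asarray(intensity_correlation, dtype=float)
        ),
        seed=seed,
    )


# ------------------------------------------------ signature-difference design


@dataclass
class SignatureDifferenceDesign:
    """Constructed ground truth for the signature-difference test."""

    per_type_effects: pd.DataFrame  # tumor type x 96 dsigma values
    load_table: SignatureLoadTable
    global_significance: np.ndarray  # per-class boolean, pooled run
    driver: str
    driven_classes: np.ndarray


def simulate_signature_difference_design(
    n_types: int = 16,
    n_driven_classes: int = 30,
    beta: float = 1.0,
    noise_sd: float = 0.35,
    seed: int = 0,
    signature_names: Sequence[str] = ("SBS1", "SBS5", "SBS40", "SBSN1", "SBSN2", "SBSN3"),
    driver: str = "SBS5",
) -> SignatureDifferenceDesign:
    """Statistic-level design with one signature driving the effects.

    Tumor-type mutation loads are drawn independently per signature;
    for ``n_driven_classes`` designated classes the per-type effect size
    is ``beta`` x (standardised driver load) + noise, and those classes
    are also the globally significant ones.  All other classes are pure
    noise.  The signature-difference test should flag the driver and
    only the driver.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(zlib.crc32(b"sigdesign"),)))
    sigs = list(signature_names)
    if driver not in sigs:
        raise ValueError("driver must be among the signature names")
    types = [f"tumor_type_{i + 1}" for i in range(n_types)]
    # Null loads are made exactly orthogonal to the driver load: a
    # "null" signature must carry no driver signal, and with a handful
    # of tumor types even chance sample correlation would leak the
    # injected effects into its per-class regressions.  Residualising on
    # the raw scale and shifting back to positivity keeps the Pearson
    # correlation with the driver at exactly zero (shift-invariance).
    raw = rng.lognormal(mean=8.0, sigma=0.8, size=(n_types, len(sigs)))
    di = sigs.index(driver)
    xd = raw[:, di]
    X = np.column_stack([np.ones(n_types), xd])
    for jj in range(len(sigs)):
        if jj == di:
            continue
        beta_j, *_ = np.linalg.lstsq(X, raw[:, jj], rcond=None)
        resid = raw[:, jj] - X @ beta_j
        raw[:, jj] = resid - resid.min() + 0.2 * np.exp(8.0)
    loads = pd.DataFrame(
        raw,
        index=pd.Index(types, name="tumor_type"),
        columns=sigs,
    )
    samples = pd.DataFrame(
        rng.integers(2, 40, size=(n_types, len(sigs))), index=loads.index, columns=sigs
    )
    driven = rng.choice(trinuc.N_CLASSES, size=n_driven_classes, replace=False)
    x = loads[driver].to_numpy()
    xz = (x - x.mean()) / x.std()
    effects = rng.normal(0.0, noise_sd, size=(n_types, trinuc.N_CLASSES))
    effects[:, driven] += beta * xz[:, None]
    per_type = pd.DataFrame(effects, index=loads.index, columns=list(trinuc.CLASS_LABELS))
    global_sig = np.zeros(trinuc.N_CLASSES, dtype=bool)
    global_sig[driven] = True
    return SignatureDifferenceDesign(
        per_type_effects=per_type,
        load_table=SignatureLoadTable(
            loads=loads, samples=samples, artifact={s: False for s in sigs}
        ),
        global_significance=global_sig,
        driver=driver,
        driven_classes=np.sort(driven),
    )
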