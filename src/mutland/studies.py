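"""Self-contained synthetic studies exercising the full analysis.

Each function runs a complete, seeded experiment at desk scale and
returns its summary statistics: landscape-correlation recovery, type-I
calibration of the diagonal-split test, spectrum/signature-mixture
correlation, and the constructed signature-difference detection study.
They are used by the examples and by the reproducibility script, and
are ordinary package API.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd

from . import trinuc
from .density import density_table, filter_variants, rank_windows, standardize
from .difftests import signature_difference_test
from .landscape import TestResult, correlation_matrix, diagonal_split_test, quantile_fold_enrichment
from .simulate import (
    SimulationConfig,
    child_rng,
    recovery_config,
    simulate_density_field,
    simulate_masks,
    simulate_reference,
    simulate_signature_difference_design,
    simulate_variant_catalogs,
)
from .windows import combine_masks, make_windows

logger = logging.getLogger("mutland.studies")


@dataclass
class RecoveryResult:
    correlations: pd.DataFrame  # recovered Pearson r between dataset z-scores
    configured: pd.DataFrame  # the generating correlation matrix
    split: TestResult  # diagonal-split test, tumor response
    fold_enrichment: Dict[str, float]
    n_windows: int


def landscape_recovery(
    seed: int = 0,
    n_windows: int = 5000,
    mean_mutations_per_window: float = 3000.0,
) -> RecoveryResult:
    """Full-pipeline recovery of a configured correlation structure.

    Simulates human/chimpanzee/tumor catalogs over ``n_windows``
    overlapping windows with the qualitative real-data correlation
    structure (0.65 germline-germline, 0.16 human-tumor, 0.55
    ape-tumor), runs masks -> windows -> filters -> densities, and
    measures the recovered pairwise correlations plus the
    diagonal-split test of the tumor response (the human-specific
    distortion is the configured human-tumor deficit).
    """
    cfg = recovery_config(
        seed=seed,
        n_windows=n_windows,
        mean_mutations_per_window=mean_mutations_per_window,
    )
    reference, _ = simulate_reference(cfg)
    field = simulate_density_field(cfg)
    sim = simulate_variant_catalogs(cfg, field, reference)
    mapp, call, cnv = simulate_masks(cfg)
    mask = combine_masks(mapp, call, cnv, cfg.genome_sizes)
    wins = make_windows(cfg.genome_sizes, mask, cfg.window_size, cfg.step)
    tables = {}
    for name, cat in sim.catalogs.items():
        filtered, _ = filter_variants(cat)
        tables[name] = density_table(filtered, wins, mask)
    r, _ = correlation_matrix(tables, on="z")
    split = diagonal_split_test(
        tables["human"]["rank"].to_numpy(),
        tables["chimpanzee"]["rank"].to_numpy(),
        tables["tumor"]["z"].to_numpy(),
        label_a="human",
        label_b="chimpanzee",
    )
    fold = {
        name: quantile_fold_enrichment(t["d"].to_numpy()) for name, t in tables.items()
    }
    configured = pd.DataFrame(
        cfg.intensity_correlation,
        index=list(cfg.dataset_names),
        columns=list(cfg.dataset_names),
    )
    return RecoveryResult(
        correlations=r,
        configured=configured,
        split=split,
        fold_enrichment=fold,
        n_windows=int(wins["retained"].sum()),
    )


def diagonal_split_type_i(
    seed: int = 0,
    n_replicates: int = 1000,
    n_windows: int = 500,
    alpha: float = 0.05,
    mean_mutations_per_window: float = 100.0,
) -> Dict[str, float]:
    """Type-I calibration of the diagonal-split test under a symmetric null.

    The two species are exchangeable with respect to the tumor response
    (equal species-tumor correlations), so the split carries no
    information and rejections at level alpha should occur at rate
    ~alpha.  Each replicate draws a fresh correlated intensity field and
    Poisson window counts; ranks and the Mann-Whitney test then run
    exactly as in the real analysis.
    """
    window = 10_000
    sigma = np.array([[1.0, 0.65, 0.5], [0.65, 1.0, 0.5], [0.5, 0.5, 1.0]])
    rejections = 0
    for i in range(n_replicates):
        cfg = SimulationConfig(
            n_chromosomes=1,
            chrom_length=n_windows * window,
            window_size=window,
            step=window,
            intensity_correlation=sigma,
            mean_mutations_per_window=mean_mutations_per_window,
            seed=seed * 1_000_003 % (2**31 - 1) + i,
        )
        field = simulate_density_field(cfg)
        rng = child_rng(cfg.seed, "calibration_counts")
        counts = rng.poisson(field.rates)
        res = diagonal_split_test(
            rank_windows(counts[:, 0]),
            rank_windows(counts[:, 1]),
            standardize(counts[:, 2].astype(float)),
        )
        rejections += res.p_value < alpha
    return {
        "rejection_rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "n_windows": n_windows,
        "alpha": alpha,
    }


def mixture_spectrum_study(
    seed: int = 0, n_mutations: int = 100_000
) -> Dict[str, float]:
    """Spectrum of simulated SNVs vs the generating signature mixture.

    Draws ~``n_mutations`` germline SNVs from the 0.1 x SBS1 + 0.9 x
    SBS5 mixture, classifies them from the emitted reference, and
    correlates the resulting 96-class spectrum with the mixture vector.
    """
    n_windows = 100
    window = 20_000
    cfg = SimulationConfig(
        n_chromosomes=1,
        chrom_length=n_windows * window,
        window_size=window,
        step=window,
        dataset_names=("human",),
        dataset_modes=("population",),
        intensity_correlation=np.array([[1.0]]),
        mean_mutations_per_window=n_mutations / n_windows,
        missing_rate=0.0,
        het_excess_rate=0.0,
        indel_rate=0.0,
        fixed_rate=0.0,
        cpg_rate=0.02,
        # flat island profile: every tile offers ample CpG contexts, so
        # the emitted classes are a clean multinomial draw of the mixture
        cpg_island_profile=np.ones(n_windows),
        seed=seed,
    )
    reference, _ = simulate_reference(cfg)
    field = simulate_density_field(cfg)
    sim = simulate_variant_catalogs(cfg, field, reference)
    counts, _ = trinuc.count_classes(sim.catalogs["human"], reference)
    spec = trinuc.spectrum(counts)
    r = trinuc.spectrum_mixture_correlation(
        spec, cfg.signatures, {"SBS1": 0.1, "SBS5": 0.9}
    )
    return {"r": r, "n_mutations": int(counts.sum())}


def signature_difference_detection(
    seed: int = 0, n_seeds: int = 10, alpha: float = 0.05
) -> Dict[str, float]:
    """Detection study for the signature-difference test.

    Over ``n_seeds`` constructed designs where one signature's mutation
    load linearly drives the injected per-tumor-type effect sizes of 30
    globally significant classes, counts how often the driver is flagged
    at Bonferroni-corrected significance and how often any null
    signature is falsely flagged.
    """
    detected = 0
    false_positives = 0
    for i in range(n_seeds):
        design = simulate_signature_difference_design(seed=seed * 7919 % (2**31 - 1) + i)
        res = signature_difference_test(
            design.per_type_effects, design.load_table, design.global_significance
        )
        if res.loc[design.driver, "p_bonferroni"] < alpha:
            detected += 1
        others = res.drop(index=design.driver)
        false_positives += int((others["p_bonferroni"] < alpha).sum())
    return {
        "detection_rate": detected / n_seeds,
        "null_false_positives": false_positives,
        "n_seeds": n_seeds,
    }
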