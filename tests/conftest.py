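"""Shared fixtures: tiny genomes, toy catalogs, and the filter fixture."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mutland.catalogs import INDEL, POPULATION, SNV, VariantCatalog

# reproducible property tests regardless of environment
settings.register_profile("mutland", derandomize=True, deadline=None)
settings.load_profile("mutland")
from mutland.intervals import MaskSet
from mutland.reference import BASES, Reference


def make_catalog(
    records,
    mode: str = POPULATION,
    chrom_names=("chr1",),
    n_samples: int = 10,
    dataset: str = "toy",
) -> VariantCatalog:
    """Build a catalog from dicts with keys pos, ref, alt, and optional
    kind/ref_len/multiplicity/n_missing/n_het/n_hom_alt/chrom."""
    n = len(records)

    def col(key, default):
        return np.array([r.get(key, default) for r in records])

    n_missing = col("n_missing", 0)
    return VariantCatalog.from_arrays(
        dataset=dataset,
        mode=mode,
        chrom_names=chrom_names,
        chrom=col("chrom", 0),
        pos=col("pos", 0),
        ref=np.array([BASES.index(r.get("ref", "A")) for r in records]),
        alt=np.array([BASES.index(r.get("alt", "C")) for r in records]),
        kind=np.array([INDEL if r.get("kind") == "InDel" else SNV for r in records]),
        ref_len=col("ref_len", 1),
        alt_len=col("alt_len", 1),
        multiplicity=col("multiplicity", 1),
        n_called=(
            np.full(n, n_samples) - n_missing if mode == POPULATION else np.zeros(n, int)
        ),
        n_missing=n_missing if mode == POPULATION else np.zeros(n, int),
        n_het=col("n_het", 1) if mode == POPULATION else np.zeros(n, int),
        n_hom_alt=col("n_hom_alt", 0) if mode == POPULATION else np.zeros(n, int),
        n_samples=n_samples if mode == POPULATION else 0,
    )


@pytest.fixture
def tiny_reference() -> Reference:
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list(BASES), size=2000))
    return Reference.from_strings({"chr1": seq})


@pytest.fixture
def whole_mask() -> MaskSet:
    return MaskSet({"chr1": np.array([[0, 2000]])})


@pytest.fixture
def filter_fixture():
    """20-variant population catalog violating each quality filter once.

    Survivors are the hand-enumerated complement: the missingness record
    (pos 200, 2/10 missing), the SNV at distance 3 from the InDel at 302
    (pos 305), the 9/10-heterozygote record (pos 400), and the
    fixed-derived record (pos 500) are removed; the boundary cases (8/10
    het at 450, 1/10 missing at 250, SNV at distance 6 from the InDel at
    pos 610) and the lone InDel survive.
    """
    records = [
        {"pos": 100},  # clean
        {"pos": 200, "n_missing": 2},  # 20% missing -> removed (inclusive)
        {"pos": 250, "n_missing": 1},  # 10% missing -> kept
        {"pos": 302, "kind": "InDel", "ref_len": 3},  # lone InDel -> kept
        {"pos": 305},  # 3 bp from InDel -> removed
        {"pos": 308},  # 6 bp from InDel -> kept (distance > 5)
        {"pos": 400, "n_het": 9},  # 90% het -> removed (> 80%)
        {"pos": 450, "n_het": 8},  # exactly 80% het -> kept (strict >)
        {"pos": 500, "n_het": 0, "n_hom_alt": 10},  # fixed derived -> removed
    ] + [{"pos": 600 + 10 * i} for i in range(11)]  # clean fillers
    catalog = make_catalog(records, n_samples=10)
    survivors = {100, 250, 302, 308, 450} | {600 + 10 * i for i in range(11)}
    tallies = {"missingness": 1, "indel_proximity": 1, "het_excess": 1, "fixed_derived": 1}
    return catalog, survivors, tallies
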