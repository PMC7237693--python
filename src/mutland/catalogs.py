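"""Columnar variant catalogs.

A :class:`VariantCatalog` holds one dataset's SNV/InDel records as flat
numpy arrays (positions 0-based internally; VCF positions are converted
on read).  Population-mode catalogs carry per-record genotype summaries
(n_called / n_missing / n_het / n_hom_alt over a fixed sample count);
somatic and de novo catalogs carry an event multiplicity instead, so
repeated mutations can be counted as independent mutational events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .reference import BASES

POPULATION = "population"
SOMATIC = "somatic"

SNV = 0
INDEL = 1


@dataclass
class VariantCatalog:
    dataset: str
    mode: str  # POPULATION or SOMATIC
    chrom_names: Tuple[str, ...]
    chrom: np.ndarray  # int16 index into chrom_names
    pos: np.ndarray  # int64, 0-based
    ref: np.ndarray  # uint8 base code of the (first) reference base
    alt: np.ndarray  # uint8 base code of the (first) alternate base
    kind: np.ndarray  # uint8, SNV or INDEL
    ref_len: np.ndarray  # int32 reference-allele length (1 for SNVs)
    alt_len: np.ndarray  # int32 alternate-allele length (1 for SNVs)
    multiplicity: np.ndarray  # int32, >=1; always 1 in population mode
    n_called: np.ndarray  # int32 genotype summaries (population mode)
    n_missing: np.ndarray
    n_het: np.ndarray
    n_hom_alt: np.ndarray
    n_samples: int = 0

    def __post_init__(self):
        n = len(self.pos)
        for name in (
            "chrom",
            "ref",
            "alt",
            "kind",
            "ref_len",
            "alt_len",
            "multiplicity",
            "n_called",
            "n_missing",
            "n_het",
            "n_hom_alt",
        ):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has wrong length")
        if self.mode not in (POPULATION, SOMATIC):
            raise ValueError(f"unknown catalog mode {self.mode!r}")
        if self.mode == POPULATION and n:
            if np.any(self.multiplicity != 1):
                raise ValueError("population-mode records must have multiplicity 1")
            if np.any(self.n_called + self.n_missing != self.n_samples):
                raise ValueError("n_called + n_missing must equal the sample count")
        snv = self.kind == SNV
        if np.any(self.ref_len[snv] != 1) or np.any(self.alt_len[snv] != 1):
            raise ValueError("SNV records must have single-base ref and alt")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def is_snv(self) -> np.ndarray:
        return self.kind == SNV

    def take(self, index) -> "VariantCatalog":
        """Row subset (boolean mask or integer index), preserving order."""
        cols = {
            name: getattr(self, name)[index]
            for name in (
                "chrom",
                "pos",
                "ref",
                "alt",
                "kind",
                "ref_len",
                "alt_len",
                "multiplicity",
                "n_called",
                "n_missing",
                "n_het",
                "n_hom_alt",
            )
        }
        return VariantCatalog(
            dataset=self.dataset,
            mode=self.mode,
            chrom_names=self.chrom_names,
            n_samples=self.n_samples,
            **cols,
        )

    def sorted(self) -> "VariantCatalog":
        order = np.lexsort((self.pos, self.chrom))
        return self.take(order)

    def snvs(self) -> "VariantCatalog":
        return self.take(self.is_snv)

    def indels(self) -> "VariantCatalog":
        return self.take(~self.is_snv)

    def chrom_name_array(self) -> np.ndarray:
        return np.asarray(self.chrom_names)[self.chrom]

    def to_dataframe(self) -> pd.DataFrame:
        base = np.array(list(BASES + "N"))
        ref = base[np.minimum(self.ref, 4)]
        alt = base[np.minimum(self.alt, 4)]
        return pd.DataFrame(
            {
                "chrom": pd.Categorical.from_codes(
                    self.chrom.astype(np.int64), categories=list(self.chrom_names)
                ),
                "pos": self.pos,
                "ref": ref,
                "alt": alt,
                "kind": np.where(self.kind == SNV, "SNV", "InDel"),
                "ref_len": self.ref_len,
                "alt_len": self.alt_len,
                "multiplicity": self.multiplicity,
                "n_called": self.n_called,
                "n_missing": self.n_missing,
                "n_het": self.n_het,
                "n_hom_alt": self.n_hom_alt,
            }
        )

    @classmethod
    def empty(
        cls, dataset: str, mode: str, chrom_names: Tuple[str, ...], n_samples: int = 0
    ) -> "VariantCatalog":
        z = lambda dt: np.empty(0, dtype=dt)
        return cls(
            dataset=dataset,
            mode=mode,
            chrom_names=tuple(chrom_names),
            chrom=z(np.int16),
            pos=z(np.int64),
            ref=z(np.uint8),
            alt=z(np.uint8),
            kind=z(np.uint8),
            ref_len=z(np.int32),
            alt_len=z(np.int32),
            multiplicity=z(np.int32),
            n_called=z(np.int32),
            n_missing=z(np.int32),
            n_het=z(np.int32),
            n_hom_alt=z(np.int32),
            n_samples=n_samples,
        )

    @classmethod
    def from_arrays(
        cls,
        dataset: str,
        mode: str,
        chrom_names: Tuple[str, ...],
        chrom,
        pos,
        ref,
        alt,
        *,
        kind=None,
        ref_len=None,
        alt_len=None,
        multiplicity=None,
        n_called=None,
        n_missing=None,
        n_het=None,
        n_hom_alt=None,
        n_samples: int = 0,
    ) -> "VariantCatalog":
        n = len(pos)

        def col(x, default, dtype):
            if x is None:
                return np.full(n, default, dtype=dtype)
            return np.asarray(x, dtype=dtype)

        return cls(
            dataset=dataset,
            mode=mode,
            chrom_names=tuple(chrom_names),
            chrom=np.asarray(chrom, dtype=np.int16),
            pos=np.asarray(pos, dtype=np.int64),
            ref=np.asarray(ref, dtype=np.uint8),
            alt=np.asarray(alt, dtype=np.uint8),
            kind=col(kind, SNV, np.uint8),
            ref_len=col(ref_len, 1, np.int32),
            alt_len=col(alt_len, 1, np.int32),
            multiplicity=col(multiplicity, 1, np.int32),
            n_called=col(n_called, n_samples, np.int32),
            n_missing=col(n_missing, 0, np.int32),
            n_het=col(n_het, 0, np.int32),
            n_hom_alt=col(n_hom_alt, 0, np.int32),
            n_samples=n_samples,
        )


def concat(catalogs) -> VariantCatalog:
    catalogs = list(catalogs)
    first = catalogs[0]
    for c in catalogs[1:]:
        if c.chrom_names != first.chrom_names or c.mode != first.mode:
            raise ValueError("cannot concatenate catalogs with different genomes/modes")
    cols = {}
    for name in (
        "chrom",
        "pos",
        "ref",
        "alt",
        "kind",
        "ref_len",
        "alt_len",
        "multiplicity",
        "n_called",
        "n_missing",
        "n_het",
        "n_hom_alt",
    ):
        cols[name] = np.concatenate([getattr(c, name) for c in catalogs])
    return VariantCatalog(
        dataset=first.dataset,
        mode=first.mode,
        chrom_names=first.chrom_names,
        n_samples=first.n_samples,
        **cols,
    )
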