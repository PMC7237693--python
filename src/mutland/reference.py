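"""In-memory reference sequences with fast trinucleotide-context lookup.

Sequences are held as uint8 base codes (A=0, C=1, G=2, T=3) so that
context classification over millions of variants is a couple of fancy
indexing operations rather than string slicing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in _CODE.items():
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i
_DECODE_LUT = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string to base codes; non-ACGT becomes 255."""
    return _ENCODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    if np.any(codes > 3):
        raise ValueError("cannot decode ambiguous base code")
    return _DECODE_LUT[codes].tobytes().decode()


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes]


@dataclass
class Reference:
    """Genome as a mapping of chromosome name -> uint8 code array."""

    chroms: Dict[str, np.ndarray]

    def __post_init__(self):
        for name, arr in self.chroms.items():
            if arr.dtype != np.uint8:
                self.chroms[name] = np.asarray(arr, dtype=np.uint8)

    def __iter__(self) -> Iterator[str]:
        return iter(self.chroms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    @property
    def sizes(self) -> Dict[str, int]:
        return {c: len(a) for c, a in self.chroms.items()}

    def base(self, chrom: str, positions) -> np.ndarray:
        return self.chroms[chrom][np.asarray(positions, dtype=np.int64)]

    def context_codes(self, chrom: str, positions) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(left, centre, right) base codes for 0-based positions.

        Positions at the chromosome ends have no full context; callers
        must pre-filter with :meth:`has_context`.
        """
        pos = np.asarray(positions, dtype=np.int64)
        seq = self.chroms[chrom]
        if np.any((pos < 1) | (pos > len(seq) - 2)):
            raise IndexError("position without full trinucleotide context")
        return seq[pos - 1], seq[pos], seq[pos + 1]

    def has_context(self, chrom: str, positions) -> np.ndarray:
        pos = np.asarray(positions, dtype=np.int64)
        return (pos >= 1) & (pos <= len(self.chroms[chrom]) - 2)

    def sequence(self, chrom: str, start: int = 0, end: int | None = None) -> str:
        return decode(self.chroms[chrom][start:end])

    @classmethod
    def from_strings(cls, seqs: Mapping[str, str]) -> "Reference":
        return cls({c: encode(s) for c, s in seqs.items()})
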