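"""Trinucleotide classification, spectra and the high-confidence filter."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutland import trinuc
from mutland.intervals import MaskSet
from mutland.reference import BASES
from tests.conftest import make_catalog

COMP = dict(zip("ACGT", "TGCA"))


def revcomp(s: str) -> str:
    return "".join(COMP[b] for b in reversed(s))


class TestClassification:
    def test_pyrimidine_context_is_identity(self):
        assert trinuc.classify_variant("ACG", "C", "T") == "A[C>T]G"
        assert trinuc.classify_variant("TTA", "T", "G") == "T[T>G]A"

    def test_purine_context_is_folded(self):
        # TGT with G>A reverse-complements to ACA with C>T
        assert trinuc.classify_variant("TGT", "G", "A") == "A[C>T]A"
        assert trinuc.classify_variant("CGT", "G", "A") == "A[C>T]G"

    def test_enumeration_folds_192_to_96(self):
        seen = {}
        for l, c, r, a in product(BASES, repeat=4):
            if a == c:
                continue
            seen.setdefault(trinuc.classify_variant(l + c + r, c, a), 0)
            seen[trinuc.classify_variant(l + c + r, c, a)] += 1
        assert len(seen) == trinuc.N_CLASSES == 96
        assert set(seen.values()) == {2}
        assert set(seen) == set(trinuc.CLASS_LABELS)

    @settings(max_examples=200, deadline=None)
    @given(
        st.sampled_from(BASES),
        st.sampled_from(BASES),
        st.sampled_from(BASES),
        st.sampled_from(BASES),
    )
    def test_folding_involution(self, l, c, r, a):
        if a == c:
            return
        direct = trinuc.classify_variant(l + c + r, c, a)
        folded = trinuc.classify_variant(revcomp(l + c + r), COMP[c], COMP[a])
        assert direct == folded

    def test_mismatched_center_rejected(self):
        with pytest.raises(ValueError):
            trinuc.classify_variant("ACG", "G", "T")

    def test_class_ordering_follows_substitution_blocks(self):
        # six blocks of 16, flanks alphabetical within each block
        for b, sub in enumerate(trinuc.SUBSTITUTION_LABELS):
            block = trinuc.CLASS_LABELS[b * 16 : (b + 1) * 16]
            assert all(f"[{sub}]" in lab for lab in block)
            assert list(block) == sorted(block)


class TestSpectrum:
    def test_point_mass_and_scale_invariance(self):
        counts = np.zeros(96)
        counts[17] = 40
        spec = trinuc.spectrum(counts)
        assert spec[17] == 1.0 and spec.sum() == 1.0
        mixed = np.arange(96, dtype=float) + 1
        assert np.allclose(trinuc.spectrum(mixed), trinuc.spectrum(3 * mixed))

    def test_uniform_and_zero(self):
        assert np.allclose(trinuc.spectrum(np.full(96, 5)), 1 / 96)
        with pytest.raises(ValueError):
            trinuc.spectrum(np.zeros(96))

    def test_merge_spectrum_is_count_weighted_average(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 50, 96)
        b = rng.integers(0, 50, 96)
        merged = trinuc.spectrum(a + b)
        expect = (
            trinuc.spectrum(a) * a.sum() + trinuc.spectrum(b) * b.sum()
        ) / (a.sum() + b.sum())
        assert np.allclose(merged, expect)


class TestMixtureCorrelation:
    def test_exact_mixture_gives_r_one(self):
        from mutland.simulate import synthetic_signature_matrix

        sigs, _ = synthetic_signature_matrix(seed=1)
        mix = trinuc.mixture_vector(sigs, {"SBS1": 0.1, "SBS5": 0.9})
        r = trinuc.spectrum_mixture_correlation(mix, sigs)
        assert r == pytest.approx(1.0)

    def test_degenerate_spectrum_flagged(self):
        from mutland.simulate import synthetic_signature_matrix

        sigs, _ = synthetic_signature_matrix(seed=1)
        with pytest.raises(ValueError):
            trinuc.spectrum_mixture_correlation(np.full(96, 1 / 96), sigs * 0 + 1 / 96)

    def test_weights_must_sum_to_one(self):
        from mutland.simulate import synthetic_signature_matrix

        sigs, _ = synthetic_signature_matrix(seed=1)
        with pytest.raises(ValueError):
            trinuc.mixture_vector(sigs, {"SBS1": 0.4, "SBS5": 0.4})


class TestHighConfidenceFilter:
    def _windows(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [0],
                "end": [2000],
                "f_w": [1.0],
                "retained": [True],
            }
        )

    def test_each_rule_fires_once(self, tiny_reference):
        base = MaskSet({"chr1": np.array([[0, 1000], [1200, 2000]])})
        consistency = MaskSet({"chr1": np.array([[0, 600], [700, 2000]])})
        human = make_catalog(
            [
                {"pos": 100},  # clean -> kept
                {"pos": 650},  # outside consistency mask -> removed
                {"pos": 300},  # shared with chimp -> removed
                {"pos": 999},  # context touches mask border -> removed
                {"pos": 400},
                {"pos": 401},  # 400/401 adjacent -> multinucleotide, both removed
                {"pos": 500},  # overlaps own InDel span -> removed
                {"pos": 499, "kind": "InDel", "ref_len": 3},
                {"pos": 800},  # overlaps chimp high-frequency InDel -> removed
            ],
            dataset="human",
        )
        chimp = make_catalog(
            [
                {"pos": 300},
                {"pos": 799, "kind": "InDel", "ref_len": 4, "n_het": 2, "n_hom_alt": 8},
                {"pos": 120},  # clean chimp SNV
            ],
            dataset="chimp",
        )
        res = trinuc.high_confidence_filter(
            {"human": human, "chimp": chimp}, consistency, self._windows(), base
        )
        kept_h = set(res.catalogs["human"].pos.tolist())
        assert kept_h == {100}
        t = res.tallies["human"]
        assert t["consistency"] == 1
        assert t["not_exclusive"] == 1
        assert t["mask_border"] >= 1
        assert t["multinucleotide"] == 2
        assert t["own_indel"] == 1
        assert t["other_indel"] == 1
        # chimp loses the shared variant but keeps its exclusive one
        assert 120 in res.catalogs["chimp"].pos.tolist()
        assert 300 not in res.catalogs["chimp"].pos.tolist()

    def test_low_frequency_other_indel_does_not_remove(self, tiny_reference):
        base = MaskSet({"chr1": np.array([[0, 2000]])})
        consistency = MaskSet({"chr1": np.array([[0, 2000]])})
        human = make_catalog([{"pos": 800}], dataset="human")
        chimp = make_catalog(
            [{"pos": 799, "kind": "InDel", "ref_len": 4, "n_het": 1, "n_hom_alt": 0}],
            dataset="chimp",
        )
        res = trinuc.high_confidence_filter(
            {"human": human, "chimp": chimp}, consistency, self._windows(), base
        )
        assert 800 in res.catalogs["human"].pos.tolist()

    def test_missing_consistency_mask_rejected(self):
        with pytest.raises(ValueError):
            trinuc.high_confidence_filter(
                {}, None, self._windows(), MaskSet({"chr1": np.array([[0, 2000]])})
            )

    def test_recurrent_cpg_removed_disproportionately(self, tiny_reference):
        """Cross-species recurrence concentrates at CpG sites, so the
        species-exclusivity rule removes proportionally more CpG>T than
        non-CpG records."""
        seq = tiny_reference.chroms["chr1"]
        taken: list[int] = []

        def spaced(candidates, k):
            out = []
            for p in candidates:
                if all(abs(p - q) > 2 for q in taken):
                    out.append(p)
                    taken.append(p)
                if len(out) == k:
                    break
            return out

        cpg_pos = spaced(
            (int(p) for p in np.flatnonzero((seq[:-1] == 1) & (seq[1:] == 2)) if 2 < p < 1990),
            20,
        )
        non_pos = spaced(
            (
                int(p)
                for p in range(10, 1990)
                if seq[p] in (1, 3) and seq[p + 1] != 2 and seq[p - 1] != 1
            ),
            20,
        )
        # recurrent: 80% of CpG>T shared across species, 10% of non-CpG
        human = make_catalog(
            [{"pos": p, "ref": "C", "alt": "T"} for p in cpg_pos]
            + [{"pos": p, "ref": "C" if seq[p] == 1 else "T", "alt": "A"} for p in non_pos],
            dataset="human",
        )
        chimp = make_catalog(
            [{"pos": p, "ref": "C", "alt": "T"} for p in cpg_pos[:16]]
            + [{"pos": p, "ref": "C" if seq[p] == 1 else "T", "alt": "A"} for p in non_pos[:2]],
            dataset="chimp",
        )
        base = MaskSet({"chr1": np.array([[0, 2000]])})
        consistency = MaskSet({"chr1": np.array([[0, 2000]])})
        res = trinuc.high_confidence_filter(
            {"human": human, "chimp": chimp}, consistency, self._windows(), base
        )
        kept = set(res.catalogs["human"].pos.tolist())
        cpg_removed = sum(1 for p in cpg_pos if p not in kept) / len(cpg_pos)
        non_removed = sum(1 for p in non_pos if p not in kept) / len(non_pos)
        assert cpg_removed > non_removed

    def test_window_reretention_uses_combined_mask(self):
        base = MaskSet({"chr1": np.array([[0, 2000]])})
        consistency = MaskSet({"chr1": np.array([[0, 800]])})  # 40% of the window
        res = trinuc.high_confidence_filter(
            {"s": make_catalog([{"pos": 10}])}, consistency, self._windows(), base
        )
        assert res.windows["f_hq"].iloc[0] == pytest.approx(0.4)
        assert not bool(res.windows["retained_hq"].iloc[0])
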