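"""Variant filters, window counting, density, standardization, CpG split."""

import numpy as np
import pandas as pd
import pytest

from mutland.catalogs import SOMATIC
from mutland.density import (
    compute_density,
    count_window_variants,
    density_table,
    filter_variants,
    rank_windows,
    split_by_cpg,
    standardize,
)
from mutland.intervals import MaskSet
from mutland.reference import Reference
from tests.conftest import make_catalog


class TestFilterVariants:
    def test_missingness_boundary_inclusive(self):
        cat = make_catalog([{"pos": 10, "n_missing": 2}, {"pos": 20, "n_missing": 1}])
        out, t = filter_variants(cat)
        assert list(out.pos) == [20]
        assert t.missingness == 1

    def test_indel_proximity_inclusive_distance(self):
        cat = make_catalog(
            [
                {"pos": 102, "kind": "InDel"},
                {"pos": 105},  # distance 3 -> removed
                {"pos": 107},  # distance 5 -> removed (inclusive)
                {"pos": 108},  # distance 6 -> kept
            ]
        )
        out, t = filter_variants(cat)
        assert set(out.pos) == {102, 108}
        assert t.indel_proximity == 2

    def test_het_excess_strict(self):
        cat = make_catalog([{"pos": 1, "n_het": 9}, {"pos": 2, "n_het": 8}])
        out, t = filter_variants(cat)
        assert list(out.pos) == [2]
        assert t.het_excess == 1

    def test_hand_enumerated_fixture(self, filter_fixture):
        catalog, survivors, tallies = filter_fixture
        out, t = filter_variants(catalog)
        assert set(out.pos.tolist()) == survivors
        assert t.as_dict() == tallies

    def test_somatic_rejects_genotype_filters(self):
        cat = make_catalog([{"pos": 5}], mode=SOMATIC)
        cat.n_called[:] = 3  # malformed: somatic with genotype data
        with pytest.raises(ValueError):
            filter_variants(cat)

    def test_somatic_indel_proximity_still_applies(self):
        cat = make_catalog(
            [{"pos": 50, "kind": "InDel"}, {"pos": 52}, {"pos": 80}], mode=SOMATIC
        )
        out, t = filter_variants(cat)
        assert set(out.pos) == {50, 80}
        assert t.indel_proximity == 1


def windows_df(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "f_w"])
    df["retained"] = True
    return df


class TestCounting:
    def test_masked_variant_contributes_zero(self):
        cat = make_catalog([{"pos": 50}, {"pos": 150}])
        mask = MaskSet({"chr1": np.array([[100, 200]])})
        w = windows_df([("chr1", 0, 200, 1.0)])
        assert count_window_variants(cat, w, mask)[0] == 1

    def test_overlapping_windows_both_count(self):
        cat = make_catalog([{"pos": 150}])
        mask = MaskSet({"chr1": np.array([[0, 400]])})
        w = windows_df([("chr1", 0, 200, 1.0), ("chr1", 100, 300, 1.0)])
        assert list(count_window_variants(cat, w, mask)) == [1, 1]

    def test_multiplicity_modes(self):
        cat = make_catalog([{"pos": 10, "multiplicity": 3}], mode=SOMATIC)
        mask = MaskSet({"chr1": np.array([[0, 100]])})
        w = windows_df([("chr1", 0, 100, 1.0)])
        assert count_window_variants(cat, w, mask, mode="events")[0] == 3
        assert count_window_variants(cat, w, mask, mode="segregating")[0] == 1

    def test_indels_never_counted(self):
        cat = make_catalog([{"pos": 10, "kind": "InDel"}, {"pos": 20}])
        mask = MaskSet({"chr1": np.array([[0, 100]])})
        w = windows_df([("chr1", 0, 100, 1.0)])
        assert count_window_variants(cat, w, mask)[0] == 1

    def test_unit_multiplicity_modes_agree(self):
        rng = np.random.default_rng(4)
        cat = make_catalog([{"pos": int(p)} for p in rng.integers(0, 1000, 50)], mode=SOMATIC)
        mask = MaskSet({"chr1": np.array([[0, 1000]])})
        w = windows_df([("chr1", 0, 500, 1.0), ("chr1", 500, 1000, 1.0)])
        a = count_window_variants(cat, w, mask, mode="events")
        b = count_window_variants(cat, w, mask, mode="segregating")
        assert np.array_equal(a, b)
        assert a.sum() == 50

    def test_disjoint_windows_sum_to_total(self):
        rng = np.random.default_rng(9)
        cat = make_catalog([{"pos": int(p)} for p in np.unique(rng.integers(0, 900, 60))])
        mask = MaskSet({"chr1": np.array([[0, 1000]])})
        w = windows_df([("chr1", s, s + 100, 1.0) for s in range(0, 1000, 100)])
        counts = count_window_variants(cat, w, mask)
        assert counts.sum() == len(cat)


class TestDensityMath:
    def test_density_formula(self):
        w = windows_df([("chr1", 0, 1_000_000, 0.8), ("chr1", 0, 1_000_000, 1.0)])
        d = compute_density(np.array([40, 7]), w)
        assert d[0] == pytest.approx(50.0)
        assert d[1] == pytest.approx(7.0)

    def test_zero_count_zero_density(self):
        w = windows_df([("chr1", 0, 1_000_000, 0.5)])
        assert compute_density(np.array([0]), w)[0] == 0.0

    def test_standardize_basics(self):
        z = standardize(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(z, [-1, 0, 1])  # sample SD = 1
        rng = np.random.default_rng(0)
        z = standardize(rng.normal(5, 3, 200))
        assert np.mean(z) == pytest.approx(0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1)
        with pytest.raises(ValueError):
            standardize(np.full(5, 2.0))

    def test_ranks_average_ties_and_monotone(self):
        assert list(rank_windows(np.array([5.0, 5.0, 7.0]))) == [1.5, 1.5, 3.0]
        assert list(rank_windows(np.arange(4.0))) == [1, 2, 3, 4]
        rng = np.random.default_rng(2)
        d = rng.normal(size=50)
        assert np.array_equal(rank_windows(d), rank_windows(standardize(d)))


class TestSplitByCpG:
    @pytest.fixture
    def cpg_reference(self):
        #          0123456789
        return Reference.from_strings({"chr1": "AACGTTGTAC"})

    def test_forward_cpg_transition(self, cpg_reference):
        cat = make_catalog([{"pos": 2, "ref": "C", "alt": "T"}])
        split = split_by_cpg(cat, cpg_reference)
        assert len(split.cpg_t) == 1 and len(split.non_cpg) == 0

    def test_reverse_strand_cpg(self, cpg_reference):
        # G at pos 3 preceded by C: reverse-strand CpG; G>A is the transition
        cat = make_catalog([{"pos": 3, "ref": "G", "alt": "A"}])
        split = split_by_cpg(cat, cpg_reference)
        assert len(split.cpg_t) == 1

    def test_non_cpg_purine(self, cpg_reference):
        # G at pos 6 preceded by T: not a CpG site
        cat = make_catalog([{"pos": 6, "ref": "G", "alt": "A"}])
        split = split_by_cpg(cat, cpg_reference)
        assert len(split.non_cpg) == 1 and len(split.cpg_t) == 0

    def test_other_substitution_at_cpg_is_neither(self, cpg_reference):
        cat = make_catalog([{"pos": 2, "ref": "C", "alt": "A"}])
        split = split_by_cpg(cat, cpg_reference)
        assert len(split.cpg_t) == 0 and len(split.non_cpg) == 0
        assert len(split.other_at_cpg) == 1

    def test_partition_is_complete(self, tiny_reference):
        rng = np.random.default_rng(17)
        pos = np.unique(rng.integers(0, 2000, 300))
        recs = []
        for p in pos:
            ref = tiny_reference.sequence("chr1", p, p + 1)
            alts = [b for b in "ACGT" if b != ref]
            recs.append({"pos": int(p), "ref": ref, "alt": alts[rng.integers(0, 3)]})
        cat = make_catalog(recs)
        split = split_by_cpg(cat, tiny_reference)
        total = len(split.cpg_t) + len(split.non_cpg) + len(split.other_at_cpg)
        assert total + split.n_no_context == len(cat)

    def test_density_table_end_to_end(self, tiny_reference):
        rng = np.random.default_rng(1)
        pos = np.unique(rng.integers(0, 2000, 120))
        cat = make_catalog([{"pos": int(p)} for p in pos])
        mask = MaskSet({"chr1": np.array([[0, 2000]])})
        w = windows_df([("chr1", 0, 1000, 1.0), ("chr1", 500, 1500, 1.0), ("chr1", 1000, 2000, 1.0)])
        dt = density_table(cat, w, mask)
        assert set(dt.columns) >= {"n", "d", "z", "rank"}
        assert np.mean(dt["z"]) == pytest.approx(0, abs=1e-9)
        assert sorted(dt["rank"]) == [1, 2, 3] or len(set(dt["rank"])) <= 3
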