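"""Enrichment, coherence, GC regression, KS-based difference tests."""

import numpy as np
import pandas as pd
import pytest

from mutland import trinuc
from mutland.difftests import (
    chi2_2x2,
    coherence_filter,
    gc_regression,
    ks_test,
    sequential_enrichment_test,
    signature_difference_test,
    top_enrichment_signature_report,
    trinuc_difference_table,
    trinuc_difference_test,
)
from tests.oracles import exact_ks_p


class TestChi2:
    def test_hand_expanded_toy_table(self):
        # [[30,70],[10,90]]: expecteds 20/80/20/80 -> sum (O-E)^2/E = 12.5
        stat, p = chi2_2x2(30, 70, 10, 90)
        assert stat == pytest.approx(12.5)

    def test_degenerate_margins(self):
        assert chi2_2x2(0, 0, 5, 5) == (0.0, 1.0)

    def test_yates_smaller(self):
        s0, _ = chi2_2x2(8, 2, 3, 7)
        s1, _ = chi2_2x2(8, 2, 3, 7, yates=True)
        assert s1 < s0


class TestSequentialEnrichment:
    def test_fold_enrichment_ratio(self):
        a = np.zeros(96, dtype=int)
        b = np.zeros(96, dtype=int)
        a[0], b[0] = 30, 10
        a[1], b[1] = 70, 90
        res = sequential_enrichment_test(a, b)
        assert res["enrichment"].iloc[0] == pytest.approx(3.0)
        assert res["chi2_stage1"].iloc[0] == pytest.approx(12.5)

    def test_two_class_removal_rule(self):
        """Iteration 2 must test against totals with iteration-1 counts removed."""
        # class 0 hugely significant, class 1 clearly second, the
        # remaining mass spread thinly so no rest-class dominates
        a = np.full(96, 4, dtype=int)
        b = np.full(96, 9, dtype=int)
        a[0], b[0] = 500, 100
        a[1], b[1] = 120, 40
        tot_a, tot_b = a.sum(), b.sum()
        res = sequential_enrichment_test(a, b)
        assert res["iteration"].iloc[0] == 1
        assert res["iteration"].iloc[1] == 2
        # manual second-iteration table: class 0 removed from both totals
        stat2, p2 = chi2_2x2(120, tot_a - 500 - 120, 40, tot_b - 100 - 40)
        assert res["chi2"].iloc[1] == pytest.approx(stat2)
        assert res["p"].iloc[1] == pytest.approx(p2)

    def test_iteration_one_equals_plain_chi2(self):
        rng = np.random.default_rng(0)
        a = rng.integers(10, 500, 96)
        b = rng.integers(10, 500, 96)
        res = sequential_enrichment_test(a, b)
        top = res[res["iteration"] == 1].iloc[0]
        assert top["chi2"] == pytest.approx(top["chi2_stage1"])
        assert top["p_stage1"] == res["p_stage1"].min()

    def test_iterations_are_permutation(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 100, 96)
        b = rng.integers(0, 100, 96)
        res = sequential_enrichment_test(a, b)
        assert sorted(res["iteration"]) == list(range(1, 97))

    def test_zero_zero_class_flagged(self):
        a = np.ones(96, dtype=int) * 10
        b = np.ones(96, dtype=int) * 10
        a[5] = b[5] = 0
        res = sequential_enrichment_test(a, b)
        assert bool(res["undefined"].iloc[5])
        assert np.isnan(res["enrichment"].iloc[5])
        assert res["p"].iloc[5] == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a = rng.integers(1, 300, 96)
        b = rng.integers(1, 300, 96)
        r_ab = sequential_enrichment_test(a, b)
        r_ba = sequential_enrichment_test(b, a)
        assert np.allclose(
            r_ab["enrichment"].to_numpy(), 1.0 / r_ba["enrichment"].to_numpy()
        )
        assert np.allclose(r_ab["chi2_stage1"], r_ba["chi2_stage1"])


class TestCoherence:
    def _mk(self, p, e):
        return pd.DataFrame(
            {"p": p, "enrichment": e},
            index=pd.Index([f"c{i}" for i in range(len(p))], name="class"),
        )

    def test_identical_runs_keep_all(self):
        r = self._mk([1e-8, 0.5], [2.0, 0.9])
        kept, dropped = coherence_filter(r, r.copy(), alpha=1e-5)
        assert len(kept) == 2 and len(dropped) == 0

    def test_significance_disagreement_dropped(self):
        r1 = self._mk([1e-8], [2.0])
        r2 = self._mk([0.2], [2.0])
        kept, dropped = coherence_filter(r1, r2, alpha=1e-5)
        assert len(kept) == 0
        assert dropped["reason"].iloc[0] == "significance"

    def test_direction_disagreement_dropped(self):
        r1 = self._mk([1e-8], [2.0])
        r2 = self._mk([1e-8], [0.5])
        kept, dropped = coherence_filter(r1, r2, alpha=1e-5)
        assert len(kept) == 0
        assert dropped["reason"].iloc[0] == "direction"

    def test_mismatched_classes_rejected(self):
        r1 = self._mk([0.1], [1.5])
        r2 = self._mk([0.1, 0.2], [1.5, 1.0])
        with pytest.raises(ValueError):
            coherence_filter(r1, r2)


class TestGcRegression:
    def test_exact_fit(self):
        slope, intercept, p = gc_regression([2.0, 4.0, 6.0], gc_counts=[1, 2, 3])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_slope(self):
        slope, _, _ = gc_regression([1.0, 2.0, 4.0], gc_counts=[1, 2, 3])
        assert slope == pytest.approx(1.5)  # Sxy/Sxx = 3/2

    def test_uses_class_gc_counts_by_default(self):
        response = trinuc.CLASS_GC_COUNT.astype(float) * 2 + 1
        slope, intercept, p = gc_regression(response)
        assert slope == pytest.approx(2.0)
        assert p < 1e-10

    def test_constant_gc_rejected(self):
        with pytest.raises(ValueError):
            gc_regression([1.0, 2.0, 3.0], gc_counts=[2, 2, 2])


class TestKS:
    @pytest.mark.parametrize(
        "a,b",
        [
            ([1, 2, 3], [4, 5, 6]),
            ([1, 4, 7], [2, 3, 9]),
            ([1, 2, 3, 10], [4, 5, 6]),
            ([5, 1, 8, 2], [3, 9, 11, 0]),
        ],
    )
    def test_exact_p_matches_enumeration(self, a, b):
        d_oracle, p_oracle = exact_ks_p(a, b)
        d, p = ks_test(a, b)
        assert d == pytest.approx(d_oracle)
        assert p == pytest.approx(p_oracle)

    def test_separated_samples(self):
        d, p = ks_test([1, 2, 3], [4, 5, 6])
        assert d == 1.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings reach D=1


class TestTrinucDifference:
    def test_effect_size_and_sign(self):
        # rank differences [-2,0,2] vs [-1,0,1]: dsigma = 2 - 1 = 1
        rank_t = np.array([2.0, 2.0, 2.0])
        rank_a = rank_t + np.array([-2.0, 0.0, 2.0])
        rank_b = rank_t + np.array([-1.0, 0.0, 1.0])
        res = trinuc_difference_test(rank_a, rank_b, rank_t)
        assert res.dsigma == pytest.approx(1.0)  # tumor more similar to B

    def test_identical_species(self):
        r = np.array([1.0, 2.0, 3.0, 4.0])
        res = trinuc_difference_test(r, r, r[::-1].copy())
        assert res.D == 0.0
        assert res.dsigma == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        ra = rng.permutation(np.arange(1.0, 21))
        rb = rng.permutation(np.arange(1.0, 21))
        rt = rng.permutation(np.arange(1.0, 21))
        r1 = trinuc_difference_test(ra, rb, rt)
        r2 = trinuc_difference_test(rb, ra, rt)
        assert r1.dsigma == pytest.approx(-r2.dsigma)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.D == pytest.approx(r2.D)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            trinuc_difference_test([1.0], [1.0], [1.0])

    def test_table_runs_all_classes(self):
        rng = np.random.default_rng(4)
        shape = (30, 96)
        mk = lambda: np.column_stack(
            [rng.permutation(np.arange(1.0, 31)) for _ in range(96)]
        )
        out = trinuc_difference_table(mk(), mk(), mk())
        assert len(out) == 96
        assert (out["p"] <= 1).all() and (out["p"] >= 0).all()


class TestSymmetricNull:
    def test_dsigma_symmetric_and_p_never_extreme(self):
        """With exchangeable species the effect size is centred on zero
        and the KS p never reaches the 1e-5 reporting threshold."""
        rng = np.random.default_rng(31)
        n = 100
        dsigmas = []
        for _ in range(100):
            ra = rng.permutation(np.arange(1.0, n + 1))
            rb = rng.permutation(np.arange(1.0, n + 1))
            rt = rng.permutation(np.arange(1.0, n + 1))
            res = trinuc_difference_test(ra, rb, rt)
            assert res.p_value >= 1e-5
            dsigmas.append(res.dsigma)
        dsigmas = np.asarray(dsigmas)
        # sign balance: neither direction dominates
        assert 20 <= int((dsigmas > 0).sum()) <= 80
        assert abs(dsigmas.mean()) < np.std(dsigmas)


class TestSignatureDifference:
    def test_driver_flagged_nulls_not(self):
        from mutland.simulate import simulate_signature_difference_design

        design = simulate_signature_difference_design(seed=5)
        res = signature_difference_test(
            design.per_type_effects, design.load_table, design.global_significance
        )
        assert res.loc[design.driver, "p_bonferroni"] < 0.05
        others = res.drop(index=design.driver)
        assert (others["p_bonferroni"] >= 0.05).all()

    def test_constant_load_skipped(self):
        from mutland.simulate import simulate_signature_difference_design

        design = simulate_signature_difference_design(seed=6)
        lt = design.load_table
        lt.loads["SBSN1"] = 7.0  # degenerate predictor
        res = signature_difference_test(
            design.per_type_effects, lt, design.global_significance
        )
        assert "SBSN1" not in res.index
        assert "SBSN1" in res.attrs["skipped"]

    def test_regression_slope_closed_form(self):
        from mutland.difftests import _ols_slope_pvalues

        x = np.array([1.0, 2.0, 3.0])
        Y = np.array([[1.0], [2.0], [4.0]])
        xc = x - x.mean()
        slope = (xc @ (Y[:, 0] - Y[:, 0].mean())) / np.sum(xc**2)
        assert slope == pytest.approx(1.5)
        p = _ols_slope_pvalues(x, Y)
        assert 0 <= p[0] <= 1

    def test_artifact_and_rare_signatures_excluded(self):
        from mutland.simulate import simulate_signature_difference_design

        design = simulate_signature_difference_design(seed=7)
        lt = design.load_table
        lt.artifact["SBSN2"] = True
        lt.samples["SBSN3"] = 1  # never >= 2 samples
        eligible = lt.eligible_signatures()
        assert "SBSN2" not in eligible and "SBSN3" not in eligible


class TestTopEnrichmentReport:
    def _enrichment(self, e):
        return pd.DataFrame(
            {"enrichment": e}, index=pd.Index(list(trinuc.CLASS_LABELS), name="class")
        )

    def test_component_threshold(self):
        e = np.ones(96)
        e[0] = 4.0  # strongly enriched in A
        sigs = pd.DataFrame(
            {"S_hi": np.full(96, (1 - 0.06) / 95), "S_lo": np.full(96, (1 - 0.04) / 95)},
            index=pd.Index(list(trinuc.CLASS_LABELS), name="class"),
        )
        sigs.iloc[0, 0] = 0.06
        sigs.iloc[0, 1] = 0.04
        report = top_enrichment_signature_report(self._enrichment(e), sigs)
        hit = report[report["class"] == trinuc.CLASS_LABELS[0]]
        assert set(hit["signature"]) == {"S_hi"}

    def test_empty_signature_matrix(self):
        sigs = pd.DataFrame(index=pd.Index(list(trinuc.CLASS_LABELS), name="class"))
        report = top_enrichment_signature_report(self._enrichment(np.ones(96)), sigs)
        assert len(report) == 0
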