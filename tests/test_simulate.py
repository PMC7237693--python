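"""Synthetic-data generator: determinism, validation, statistical targets."""

import numpy as np
import pytest

from mutland import trinuc
from mutland.catalogs import SOMATIC
from mutland.simulate import (
    SimulationConfig,
    simulate_density_field,
    simulate_masks,
    simulate_reference,
    simulate_variant_catalogs,
    synthetic_signature_matrix,
)


def small_config(**kw):
    base = dict(
        n_chromosomes=1,
        chrom_length=400_000,
        window_size=20_000,
        step=10_000,
        mean_mutations_per_window=120.0,
        seed=11,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_non_psd_correlation_rejected_with_eigenvalue(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            small_config(intensity_correlation=bad)

    def test_asymmetric_rejected(self):
        bad = np.eye(3)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            small_config(intensity_correlation=bad)

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError, match="context"):
            SimulationConfig(chrom_length=2, window_size=1, step=1)

    def test_rates_bounded(self):
        with pytest.raises(ValueError, match="missing_rate"):
            small_config(missing_rate=1.5)

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_config(
                spectrum_mixtures={
                    n: {"SBS1": 0.5, "SBS5": 0.2}
                    for n in ("human", "chimpanzee", "tumor")
                }
            )

    def test_window_must_fit_chromosome(self):
        with pytest.raises(ValueError):
            SimulationConfig(chrom_length=10_000, window_size=20_000, step=10_000)


class TestSignatureMatrix:
    def test_columns_sum_to_one(self):
        sigs, flags = synthetic_signature_matrix(seed=2)
        assert np.allclose(sigs.to_numpy().sum(axis=0), 1.0)
        assert (sigs.to_numpy() >= 0).all()
        assert list(sigs.index) == list(trinuc.CLASS_LABELS)

    def test_sbs1_concentrates_on_cpg_transitions(self):
        sigs, _ = synthetic_signature_matrix(seed=2)
        cpg_mass = sigs["SBS1"].to_numpy()[trinuc.CPG_T_CLASSES].sum()
        assert cpg_mass > 0.8
        assert sigs["SBS5"].to_numpy()[trinuc.CPG_T_CLASSES].sum() < 0.1

    def test_artifact_flags(self):
        _, flags = synthetic_signature_matrix(seed=2, artifact=1)
        assert flags["SBSA1"] is True and flags["SBS1"] is False


class TestReference:
    def test_determinism(self):
        cfg = small_config()
        ref1, cpg1 = simulate_reference(cfg)
        ref2, cpg2 = simulate_reference(cfg)
        assert all(
            np.array_equal(ref1.chroms[c], ref2.chroms[c]) for c in ref1.chroms
        )
        assert all(
            np.array_equal(cpg1.intervals[c], cpg2.intervals[c]) for c in cpg1.intervals
        )

    def test_constant_profile_uniform_cpg(self):
        cfg = small_config(cpg_island_profile=np.ones(40), cpg_rate=0.02)
        ref, _ = simulate_reference(cfg)
        seq = ref.chroms["chr1"]
        cg = (seq[:-1] == 1) & (seq[1:] == 2)
        per_tile = np.add.reduceat(cg, np.arange(0, len(cg), 10_000))
        # equal expectation across tiles: spread should look Poisson-ish
        assert per_tile.std() < 3 * np.sqrt(per_tile.mean())

    def test_profile_ratio_recovered_by_direct_scan(self):
        """Planted CpG density follows the island profile (ratio ~10)."""
        cfg = SimulationConfig(
            n_chromosomes=1,
            chrom_length=400_000,
            window_size=200_000,
            step=200_000,
            cpg_island_profile=np.array([1.0, 10.0]),
            cpg_rate=0.02,
            seed=5,
        )
        ref, _ = simulate_reference(cfg)
        seq = ref.chroms["chr1"]
        cg = (seq[:-1] == 1) & (seq[1:] == 2)
        n1 = int(cg[:200_000].sum())
        n2 = int(cg[200_000:].sum())
        assert n2 / n1 == pytest.approx(10.0, rel=0.15)


class TestDensityField:
    def test_identity_correlation_independent(self):
        cfg = small_config(intensity_correlation=np.eye(3))
        fld = simulate_density_field(cfg)
        c = np.corrcoef(fld.latent.T)
        n = len(fld.latent)
        assert abs(c[0, 1]) < 3 / np.sqrt(n)
        assert abs(c[0, 2]) < 3 / np.sqrt(n)

    def test_perfect_correlation_degenerate(self):
        sigma = np.ones((3, 3))
        cfg = small_config(intensity_correlation=sigma)
        fld = simulate_density_field(cfg)
        c = np.corrcoef(fld.latent.T)
        assert c[0, 1] == pytest.approx(1.0)

    def test_expected_totals_scaled(self):
        cfg = small_config(mean_mutations_per_window=50.0)
        fld = simulate_density_field(cfg)
        n_windows = cfg.windows_per_chrom * cfg.n_chromosomes
        tpw = cfg.tiles_per_window
        tpc = cfg.tiles_per_chrom
        mult = np.minimum(np.minimum(np.arange(tpc) + 1, tpc - np.arange(tpc)), tpw)
        assert mult @ fld.rates[:, 0] == pytest.approx(50.0 * n_windows)

    def test_latent_correlation_recovered(self):
        """Configured 0.65 recovered within the Fisher-z tolerance."""
        cfg = SimulationConfig(
            n_chromosomes=1,
            chrom_length=50_000_000,
            window_size=10_000,
            step=10_000,
            intensity_correlation=np.array(
                [[1.0, 0.65, 0.16], [0.65, 1.0, 0.55], [0.16, 0.55, 1.0]]
            ),
            seed=3,
        )
        fld = simulate_density_field(cfg)
        c = np.corrcoef(fld.latent.T)
        assert c[0, 1] == pytest.approx(0.65, abs=0.03)


class TestCatalogs:
    def test_determinism_byte_identical(self):
        cfg = small_config()
        ref, _ = simulate_reference(cfg)
        fld = simulate_density_field(cfg)
        s1 = simulate_variant_catalogs(cfg, fld, ref)
        s2 = simulate_variant_catalogs(cfg, fld, ref)
        for n in cfg.dataset_names:
            a, b = s1.catalogs[n], s2.catalogs[n]
            assert np.array_equal(a.pos, b.pos)
            assert np.array_equal(a.alt, b.alt)
            assert np.array_equal(a.n_het, b.n_het)

    def test_zero_mean_empty_catalogs(self):
        cfg = small_config(
            mean_mutations_per_window=0.0,
            missing_rate=0.0,
            het_excess_rate=0.0,
            indel_rate=0.0,
            fixed_rate=0.0,
        )
        ref, _ = simulate_reference(cfg)
        fld = simulate_density_field(cfg)
        sim = simulate_variant_catalogs(cfg, fld, ref)
        assert all(len(c) == 0 for c in sim.catalogs.values())

    def test_point_mass_spectrum_round_trip(self):
        """SNVs drawn from a single-class signature classify back to it."""
        sigs, flags = synthetic_signature_matrix(seed=1)
        point = sigs.copy()
        label = "A[C>T]G"  # CpG transition: exercises context placement
        point["POINT"] = 0.0
        point.loc[label, "POINT"] = 1.0
        cfg = small_config(
            signatures=point,
            signature_artifacts={**flags, "POINT": False},
            spectrum_mixtures={
                n: {"POINT": 1.0} for n in ("human", "chimpanzee", "tumor")
            },
            mean_mutations_per_window=40.0,
            missing_rate=0.0,
            het_excess_rate=0.0,
            indel_rate=0.0,
            fixed_rate=0.0,
            cpg_rate=0.03,
        )
        ref, _ = simulate_reference(cfg)
        fld = simulate_density_field(cfg)
        sim = simulate_variant_catalogs(cfg, fld, ref)
        cat = sim.catalogs["human"]
        cls = trinuc.classify_catalog(cat, ref)
        target = trinuc.CLASS_LABELS.index(label)
        # overflow fallback may leave a small remainder at other classes
        assert np.mean(cls == target) > 0.95

    def test_somatic_multiplicity_and_loads(self):
        cfg = small_config(recurrence_rate=0.3)
        ref, _ = simulate_reference(cfg)
        fld = simulate_density_field(cfg)
        sim = simulate_variant_catalogs(cfg, fld, ref)
        tumor = sim.catalogs["tumor"]
        assert tumor.mode == SOMATIC
        assert (tumor.multiplicity >= 1).all()
        assert tumor.multiplicity.max() >= 2
        assert set(sim.load_table.loads.index) == {"tumor"}
        assert sim.load_table.loads.sum(axis=1).iloc[0] > 0

    def test_every_filter_triggered_by_defaults(self):
        from mutland.density import filter_variants

        cfg = small_config()
        ref, _ = simulate_reference(cfg)
        fld = simulate_density_field(cfg)
        sim = simulate_variant_catalogs(cfg, fld, ref)
        _, t = filter_variants(sim.catalogs["human"])
        assert t.missingness > 0
        assert t.het_excess > 0
        assert t.indel_proximity > 0
        assert t.fixed_derived > 0

    def test_population_summaries_consistent(self):
        cfg = small_config()
        ref, _ = simulate_reference(cfg)
        fld = simulate_density_field(cfg)
        sim = simulate_variant_catalogs(cfg, fld, ref)
        cat = sim.catalogs["human"]
        assert np.all(cat.n_called + cat.n_missing == cat.n_samples)
        assert np.all(cat.n_het + cat.n_hom_alt <= cat.n_called)
        assert np.all(cat.multiplicity == 1)


class TestMasks:
    def test_masks_cover_most_of_genome(self):
        cfg = small_config()
        mapp, call, cnv = simulate_masks(cfg)
        assert 0.8 * cfg.chrom_length < mapp.pass_length("chr1") <= cfg.chrom_length
        assert set(call) == {"human", "chimpanzee"}
        assert len(call["human"]) == cfg.n_samples
        assert cnv.pass_length() > 0  # CNV mask stores failing intervals

    def test_default_masks_produce_sub_threshold_windows(self):
        """The window-scale CNV blocks push some windows below 50%."""
        from mutland.windows import combine_masks, make_windows

        cfg = small_config()
        mapp, call, cnv = simulate_masks(cfg)
        mask = combine_masks(mapp, call, cnv, cfg.genome_sizes)
        wt = make_windows(cfg.genome_sizes, mask, cfg.window_size, cfg.step)
        assert (~wt["retained"]).sum() > 0
        assert wt["retained"].sum() > 0.5 * len(wt)
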