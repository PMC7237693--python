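"""End-to-end orchestration: simulate -> masks/windows -> densities ->
landscape comparisons -> trinucleotide spectra -> difference tests.

Each stage reads its inputs from the output directory (so any stage can
be re-run from cached upstream outputs), writes plain-text outputs, and
records row counts, filter tallies and file digests in a JSON run
manifest.  Identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, density, difftests, io, landscape, simulate, trinuc, windows as win
from .catalogs import POPULATION, SOMATIC
from .intervals import MaskSet
from .simulate import SimulationConfig

logger = logging.getLogger("mutland.pipeline")

STAGES = ("simulate", "windows", "density", "compare", "trinuc", "enrich", "difftest", "sigtest")


def demo_config(seed: int = 0) -> SimulationConfig:
    """Small default study: two species-like panels plus four tumor types.

    Correlation structure mirrors the qualitative real-data pattern:
    strong between germlines, weak human-tumor, intermediate ape-tumor,
    strong among tumor types.
    """
    names = ("human", "chimpanzee", "tumor_a", "tumor_b", "tumor_c", "tumor_d")
    d = len(names)
    sigma = np.full((d, d), 0.55)
    sigma[0, 1] = sigma[1, 0] = 0.65
    sigma[0, 2:] = sigma[2:, 0] = 0.16
    sigma[2:, 2:] = 0.75
    np.fill_diagonal(sigma, 1.0)
    # clip tiny negative eigenvalues introduced by the block construction
    w, v = np.linalg.eigh(sigma)
    if w[0] < 0:
        sigma = v @ np.diag(np.clip(w, 1e-6, None)) @ v.T
        dd = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(dd, dd)
    return SimulationConfig(
        n_chromosomes=3,
        chrom_length=1_200_000,
        window_size=40_000,
        step=20_000,
        dataset_names=names,
        intensity_correlation=sigma,
        mean_mutations_per_window=40.0,
        seed=seed,
    )


def load_config(path) -> tuple[SimulationConfig, dict]:
    """Parse a YAML run config into the simulation config + stage options."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = dict(raw.get("simulate", {}))
    if "seed" in raw:
        sim.setdefault("seed", raw["seed"])
    if "intensity_correlation" in sim:
        sim["intensity_correlation"] = np.asarray(sim["intensity_correlation"], dtype=float)
    if "dataset_names" in sim:
        sim["dataset_names"] = tuple(sim["dataset_names"])
    if "dataset_modes" in sim:
        sim["dataset_modes"] = tuple(sim["dataset_modes"])
    config = SimulationConfig(**sim) if sim else demo_config(seed=raw.get("seed", 0))
    options = {k: v for k, v in raw.items() if k not in ("simulate",)}
    return config, options


def _config_snapshot(config: SimulationConfig) -> dict:
    snap = {}
    for k, v in vars(config).items():
        if isinstance(v, np.ndarray):
            snap[k] = v.tolist()
        elif isinstance(v, pd.DataFrame):
            snap[k] = {"columns": list(v.columns), "sha256": _digest_bytes(v.to_csv().encode())}
        else:
            snap[k] = v if not isinstance(v, tuple) else list(v)
    return snap


def _digest_bytes(b: bytes) -> str:
    return hashlib.sha256(b).hexdigest()


def _digest_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    stages: Dict[str, dict] = field(default_factory=dict)
    files: Dict[str, str] = field(default_factory=dict)

    def record_file(self, outdir: Path, path: Path) -> None:
        self.files[str(path.relative_to(outdir))] = _digest_file(path)

    def save(self, outdir: Path) -> None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "config": self.config,
                    "stages": self.stages,
                    "files": self.files,
                },
                fh,
                indent=2,
                default=str,
            )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class PipelineRun:
    """Executes pipeline stages against one output directory."""

    def __init__(self, config: SimulationConfig, outdir, options: dict | None = None):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.options = options or {}
        self.manifest = RunManifest(config=_config_snapshot(config), seed=config.seed)

    # --------------------------------------------------------------- helpers

    def path(self, name: str) -> Path:
        return self.outdir / name

    def _write_table(self, df: pd.DataFrame, name: str, index: bool = False) -> None:
        io.write_table(df, self.path(name), index=index)
        self.manifest.record_file(self.outdir, self.path(name))

    def _population_names(self) -> List[str]:
        return [
            n
            for n, m in zip(self.config.dataset_names, self.config.dataset_modes)
            if m == POPULATION
        ]

    def _somatic_names(self) -> List[str]:
        return [
            n
            for n, m in zip(self.config.dataset_names, self.config.dataset_modes)
            if m == SOMATIC
        ]

    def _mode_of(self, name: str) -> str:
        return dict(zip(self.config.dataset_names, self.config.dataset_modes))[name]

    def _load_reference(self):
        return io.read_fasta(self.path("reference.fa"))

    def _load_mask(self, name: str) -> MaskSet:
        return io.read_bed(self.path(name), provenance=(name,))

    def _load_catalog(self, dataset: str):
        return io.read_vcf(
            self.path(f"variants_{dataset}.vcf"),
            mode=self._mode_of(dataset),
            dataset=dataset,
            chrom_sizes=self.config.genome_sizes,
        )

    def _load_filtered_catalogs(self) -> Dict[str, "density.VariantCatalog"]:
        out = {}
        for name in self.config.dataset_names:
            cat, _ = density.filter_variants(self._load_catalog(name))
            out[name] = cat
        return out

    # ---------------------------------------------------------------- stages

    def stage_simulate(self) -> dict:
        cfg = self.config
        reference, cpg = simulate.simulate_reference(cfg)
        io.write_fasta(reference, self.path("reference.fa"))
        io.write_bed(cpg, self.path("cpg_islands.bed"))
        mappability, callability, cnv = simulate.simulate_masks(cfg)
        io.write_bed(mappability, self.path("mappability.bed"))
        io.write_bed(cnv, self.path("cnv.bed"))
        for species, masks in callability.items():
            for i, m in enumerate(masks):
                io.write_bed(m, self.path(f"callability_{species}_{i + 1}.bed"))
        consistency = simulate.simulate_consistency_mask(cfg)
        io.write_bed(consistency, self.path("consistency.bed"))
        field_ = simulate.simulate_density_field(cfg)
        sim = simulate.simulate_variant_catalogs(cfg, field_, reference)
        counts = {}
        for name, cat in sim.catalogs.items():
            io.write_vcf(cat, reference, self.path(f"variants_{name}.vcf"))
            counts[name] = len(cat)
        io.write_signatures(cfg.signatures, self.path("signatures.tsv"))
        io.write_loads(sim.load_table, self.path("loads.tsv"))
        for p in sorted(self.outdir.glob("*.bed")) + sorted(self.outdir.glob("*.vcf")) + [
            self.path("reference.fa"),
            self.path("signatures.tsv"),
            self.path("loads.tsv"),
        ]:
            self.manifest.record_file(self.outdir, p)
        return {"records": counts}

    def outputs_simulate(self) -> List[str]:
        names = [f"variants_{n}.vcf" for n in self.config.dataset_names]
        return ["reference.fa", "cpg_islands.bed", "mappability.bed", "cnv.bed",
                "consistency.bed", "signatures.tsv", "loads.tsv"] + names

    def stage_windows(self) -> dict:
        cfg = self.config
        mappability = self._load_mask("mappability.bed")
        cnv = self._load_mask("cnv.bed")
        callability = {
            sp: [
                self._load_mask(f"callability_{sp}_{i + 1}.bed")
                for i in range(cfg.n_samples)
            ]
            for sp in self._population_names()
        }
        mask = win.combine_masks(mappability, callability, cnv, cfg.genome_sizes)
        io.write_bed(mask, self.path("combined_mask.bed"))
        self.manifest.record_file(self.outdir, self.path("combined_mask.bed"))
        table = win.make_windows(
            cfg.genome_sizes,
            mask,
            cfg.window_size,
            cfg.step,
            min_pass=self.options.get("windows", {}).get("min_pass", 0.5),
        )
        self._write_table(table, "windows.tsv")
        return {
            "pass_bp": mask.pass_length(),
            "windows": int(len(table)),
            "retained": int(table["retained"].sum()),
        }

    def outputs_windows(self) -> List[str]:
        return ["combined_mask.bed", "windows.tsv"]

    def stage_density(self) -> dict:
        cfg = self.config
        mask = self._load_mask("combined_mask.bed")
        table = io.read_windows(self.path("windows.tsv"))
        reference = self._load_reference()
        info: dict = {"filters": {}, "records": {}}
        for name in cfg.dataset_names:
            cat = self._load_catalog(name)
            filtered, tallies = density.filter_variants(cat)
            info["filters"][name] = tallies.as_dict()
            info["records"][name] = {"raw": len(cat), "filtered": len(filtered)}
            dt = density.density_table(filtered, table, mask)
            self._write_table(dt, f"density_{name}.tsv")
            split = density.split_by_cpg(filtered, reference)
            for suffix, sub in (("cpgt", split.cpg_t), ("noncpg", split.non_cpg)):
                dsub = density.density_table(sub, table, mask)
                self._write_table(dsub, f"density_{name}_{suffix}.tsv")
            info["records"][name]["cpg_t"] = len(split.cpg_t)
            info["records"][name]["non_cpg"] = len(split.non_cpg)
            info["records"][name]["other_at_cpg"] = len(split.other_at_cpg)
        return info

    def outputs_density(self) -> List[str]:
        out = []
        for n in self.config.dataset_names:
            out += [f"density_{n}.tsv", f"density_{n}_cpgt.tsv", f"density_{n}_noncpg.tsv"]
        return out

    def stage_compare(self) -> dict:
        cfg = self.config
        info: dict = {}
        for suffix, label in (("", "all"), ("_cpgt", "cpgt"), ("_noncpg", "noncpg")):
            tables = {
                n: io.read_density(self.path(f"density_{n}{suffix}.tsv"))
                for n in cfg.dataset_names
            }
            r, p = landscape.correlation_matrix(tables, on="z")
            self._write_table(r.rename_axis("dataset"), f"correlation_{label}.tsv", index=True)
            self._write_table(p.rename_axis("dataset"), f"correlation_{label}_p.tsv", index=True)
            if label == "all":
                fold = {
                    n: landscape.quantile_fold_enrichment(
                        tables[n]["d"].to_numpy() + 1e-9
                    )
                    for n in cfg.dataset_names
                }
                self._write_table(
                    pd.DataFrame(
                        {"dataset": list(fold), "fold_95_5": list(fold.values())}
                    ),
                    "fold_enrichment.tsv",
                )
                info["fold_95_5"] = fold
                pops = self._population_names()
                soms = self._somatic_names()
                rows = []
                if len(pops) >= 2:
                    for a in range(len(pops)):
                        for b in range(a + 1, len(pops)):
                            for s in soms:
                                res = landscape.diagonal_split_test(
                                    tables[pops[a]]["rank"].to_numpy(),
                                    tables[pops[b]]["rank"].to_numpy(),
                                    tables[s]["z"].to_numpy(),
                                    label_a=pops[a],
                                    label_b=pops[b],
                                )
                                rows.append(
                                    (
                                        pops[a],
                                        pops[b],
                                        s,
                                        res.statistic,
                                        res.p_value,
                                        res.effect_size,
                                        res.n1,
                                        res.n2,
                                        res.metadata["ties_excluded"],
                                    )
                                )
                if rows:
                    self._write_table(
                        pd.DataFrame(
                            rows,
                            columns=[
                                "dataset_a",
                                "dataset_b",
                                "response",
                                "U",
                                "p",
                                "rank_biserial",
                                "n1",
                                "n2",
                                "ties",
                            ],
                        ),
                        "diagonal_split.tsv",
                    )
        return info

    def outputs_compare(self) -> List[str]:
        return [
            "correlation_all.tsv",
            "correlation_cpgt.tsv",
            "correlation_noncpg.tsv",
            "fold_enrichment.tsv",
        ]

    def stage_trinuc(self) -> dict:
        cfg = self.config
        reference = self._load_reference()
        mask = self._load_mask("combined_mask.bed")
        table = io.read_windows(self.path("windows.tsv"))
        consistency = self._load_mask("consistency.bed")
        catalogs = self._load_filtered_catalogs()
        pops = {n: catalogs[n] for n in self._population_names()}
        hq = trinuc.high_confidence_filter(pops, consistency, table, mask)
        self._write_table(hq.windows, "windows_hq.tsv")
        signatures = io.read_signatures(self.path("signatures.tsv"))
        spectra = {}
        corr = {}
        for name, cat in {**hq.catalogs, **{n: catalogs[n] for n in self._somatic_names()}}.items():
            counts, _ = trinuc.count_classes(cat, reference)
            pd.DataFrame({"class": list(trinuc.CLASS_LABELS), "count": counts}).to_csv(
                self.path(f"trinuc_counts_{name}.tsv"), sep="\t", index=False
            )
            self.manifest.record_file(self.outdir, self.path(f"trinuc_counts_{name}.tsv"))
            if counts.sum() > 0:
                spectra[name] = trinuc.spectrum(counts)
                corr[name] = trinuc.spectrum_mixture_correlation(spectra[name], signatures)
        spec_df = pd.DataFrame(spectra, index=pd.Index(trinuc.CLASS_LABELS, name="class"))
        self._write_table(spec_df, "spectra.tsv", index=True)
        self._write_table(
            pd.DataFrame(
                {"dataset": list(corr), "r_sbs1_sbs5_mixture": list(corr.values())}
            ),
            "spectrum_mixture_correlation.tsv",
        )
        return {
            "hq_tallies": hq.tallies,
            "mixture_correlation": corr,
        }

    def outputs_trinuc(self) -> List[str]:
        return ["windows_hq.tsv", "spectra.tsv", "spectrum_mixture_correlation.tsv"] + [
            f"trinuc_counts_{n}.tsv" for n in self._population_names()
        ]

    def stage_enrich(self) -> dict:
        pops = self._population_names()
        if len(pops) < 2:
            return {"skipped": "needs >= 2 population datasets"}
        counts = {
            n: pd.read_csv(self.path(f"trinuc_counts_{n}.tsv"), sep="\t")["count"].to_numpy()
            for n in pops
        }
        a, b = pops[0], pops[1]
        result = difftests.sequential_enrichment_test(counts[a], counts[b])
        self._write_table(result, f"enrichment_{a}_vs_{b}.tsv", index=True)
        alpha = self.options.get("enrich", {}).get("alpha", 1e-5)
        info: dict = {"pair": [a, b], "significant": int((result["p"] < alpha).sum())}
        e = result["enrichment"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logE = np.where(e > 0, np.log10(np.maximum(e, 1e-300)), np.nan)
        ok = np.isfinite(logE)
        slope, intercept, pval = difftests.gc_regression(np.where(ok, logE, np.nan))
        self._write_table(
            pd.DataFrame(
                [("log10_enrichment", slope, intercept, pval)],
                columns=["response", "slope", "intercept", "p"],
            ),
            "gc_regression_enrichment.tsv",
        )
        info["gc_slope_p"] = pval
        signatures = io.read_signatures(self.path("signatures.tsv"))
        report = difftests.top_enrichment_signature_report(result, signatures)
        self._write_table(report, "top_enrichment_signatures.tsv")
        return info

    def outputs_enrich(self) -> List[str]:
        pops = self._population_names()
        if len(pops) < 2:
            return []
        return [
            f"enrichment_{pops[0]}_vs_{pops[1]}.tsv",
            "gc_regression_enrichment.tsv",
            "top_enrichment_signatures.tsv",
        ]

    def _class_ranks(self, catalogs, reference, mask, table) -> Dict[str, np.ndarray]:
        keep = table[table["retained_hq"]].reset_index(drop=True) if "retained_hq" in table else table[table["retained"]].reset_index(drop=True)
        keep = keep.copy()
        keep["retained"] = True
        ranks = {}
        for name, cat in catalogs.items():
            mat = trinuc.window_class_matrix(cat, keep, mask, reference)
            ranks[name] = np.column_stack(
                [density.rank_windows(mat[:, j]) for j in range(trinuc.N_CLASSES)]
            )
        return ranks

    def stage_difftest(self) -> dict:
        pops = self._population_names()
        soms = self._somatic_names()
        if len(pops) < 2 or len(soms) < 1:
            return {"skipped": "needs 2 population datasets and a tumor dataset"}
        reference = self._load_reference()
        mask = self._load_mask("combined_mask.bed")
        table = io.read_windows(self.path("windows_hq.tsv"))
        catalogs = self._load_filtered_catalogs()
        pooled = {n: catalogs[n] for n in (pops[0], pops[1])}
        pooled["__tumor__"] = (
            catalogs[soms[0]]
            if len(soms) == 1
            else _merge_somatic([catalogs[s] for s in soms])
        )
        ranks = self._class_ranks(pooled, reference, mask, table)
        result = difftests.trinuc_difference_table(
            ranks[pops[0]], ranks[pops[1]], ranks["__tumor__"]
        )
        self._write_table(result, f"trinuc_difference_{pops[0]}_vs_{pops[1]}.tsv", index=True)
        slope, intercept, pval = difftests.gc_regression(result["dsigma"].to_numpy())
        self._write_table(
            pd.DataFrame(
                [("dsigma", slope, intercept, pval)],
                columns=["response", "slope", "intercept", "p"],
            ),
            "gc_regression_difference.tsv",
        )
        alpha = self.options.get("difftest", {}).get("alpha", 1e-5)
        return {
            "pair": [pops[0], pops[1]],
            "significant": int((result["p"] < alpha).sum()),
            "gc_slope_p": pval,
        }

    def outputs_difftest(self) -> List[str]:
        pops = self._population_names()
        if len(pops) < 2 or len(self._somatic_names()) < 1:
            return []
        return [
            f"trinuc_difference_{pops[0]}_vs_{pops[1]}.tsv",
            "gc_regression_difference.tsv",
        ]

    def stage_sigtest(self) -> dict:
        pops = self._population_names()
        soms = self._somatic_names()
        if len(pops) < 2 or len(soms) < 3:
            return {"skipped": "needs >= 3 tumor types for per-type regressions"}
        reference = self._load_reference()
        mask = self._load_mask("combined_mask.bed")
        table = io.read_windows(self.path("windows_hq.tsv"))
        catalogs = self._load_filtered_catalogs()
        ranked = {n: catalogs[n] for n in (pops[0], pops[1], *soms)}
        ranks = self._class_ranks(ranked, reference, mask, table)
        pooled_tumor = _merge_somatic([catalogs[s] for s in soms])
        ranks["__pooled__"] = self._class_ranks(
            {"__pooled__": pooled_tumor}, reference, mask, table
        )["__pooled__"]
        pooled = difftests.trinuc_difference_table(
            ranks[pops[0]], ranks[pops[1]], ranks["__pooled__"]
        )
        global_sig = (pooled["p"] < 0.05).to_numpy()
        effects = pd.DataFrame(
            {
                s: difftests.trinuc_difference_table(
                    ranks[pops[0]], ranks[pops[1]], ranks[s]
                )["dsigma"].to_numpy()
                for s in soms
            },
            index=list(trinuc.CLASS_LABELS),
        ).T
        load_table = io.read_loads(self.path("loads.tsv"))
        result = difftests.signature_difference_test(effects, load_table, global_sig)
        self._write_table(result, "signature_difference.tsv", index=True)
        return {"tested": list(result.index)}

    def outputs_sigtest(self) -> List[str]:
        if len(self._population_names()) < 2 or len(self._somatic_names()) < 3:
            return []
        return ["signature_difference.tsv"]

    # ------------------------------------------------------------------ run

    def run(self, stages: Sequence[str] | None = None, force: bool = False) -> RunManifest:
        stages = list(stages) if stages is not None else list(STAGES)
        for s in stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        upstream_ran = False
        for stage in STAGES:
            if stage not in stages:
                continue
            outputs = getattr(self, f"outputs_{stage}")()
            cached = outputs and all(self.path(o).exists() for o in outputs)
            if cached and not force and not upstream_ran:
                self.manifest.stages[stage] = {"status": "cached"}
                for o in outputs:
                    self.manifest.record_file(self.outdir, self.path(o))
                continue
            t0 = time.time()
            try:
                info = getattr(self, f"stage_{stage}")()
            except Exception as exc:
                self.manifest.stages[stage] = {
                    "status": "failed",
                    "error": str(exc),
                    "invalid_outputs": outputs,
                }
                self.manifest.save(self.outdir)
                raise StageError(stage, exc) from exc
            upstream_ran = True
            status = "skipped" if info.get("skipped") else "ok"
            self.manifest.stages[stage] = {
                "status": status,
                "seconds": round(time.time() - t0, 3),
                **info,
            }
            logger.info("stage %s %s (%.1fs)", stage, status, time.time() - t0)
        self.manifest.save(self.outdir)
        return self.manifest


def _merge_somatic(catalogs):
    from . import catalogs as cat_mod

    merged = cat_mod.concat([c for c in catalogs])
    merged.dataset = "tumor_pooled"
    return merged


def run_pipeline(
    config: SimulationConfig | str | Path,
    outdir,
    stages: Sequence[str] | None = None,
    force: bool = False,
    options: dict | None = None,
) -> RunManifest:
    """Run the pipeline from a config object or YAML path."""
    if isinstance(config, (str, Path)):
        config, opts = load_config(config)
        options = {**opts, **(options or {})}
    run = PipelineRun(config, outdir, options=options)
    return run.run(stages=stages, force=force)
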