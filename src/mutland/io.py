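"""Standard-format I/O: FASTA, VCF, BED/bedGraph, signature and load TSVs.

Conventions: BED and all internal coordinates are 0-based half-open; VCF
positions are 1-based and converted on read/write.  Population-mode VCFs
carry per-sample GT fields which are summarised on read; somatic VCFs
carry the event multiplicity in the ``EVENTS`` INFO key.  Readers reject
malformed input rather than coercing it, and report offending line
numbers or columns.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from . import trinuc
from .catalogs import INDEL, POPULATION, SNV, SOMATIC, VariantCatalog
from .intervals import MaskSet, merge
from .reference import BASES, Reference, encode
from .windows import FeatureTrack

logger = logging.getLogger("mutland.io")

MULTIPLICITY_KEY = "EVENTS"


# -------------------------------------------------------------------- FASTA


def write_fasta(reference: Reference, path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom in reference:
            fh.write(f">{chrom}\n")
            seq = reference.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> Reference:
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    chroms = {name: encode(str(fa[name][:])) for name in fa.keys()}
    fa.close()
    return Reference(chroms)


# ---------------------------------------------------------------------- BED


def write_bed(mask: MaskSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, iv in mask.intervals.items():
            for s, e in iv:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(path, provenance: Tuple[str, ...] = ()) -> MaskSet:
    out: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line with fewer than 3 fields")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if s < 0 or e <= s:
                raise ValueError(f"{path}:{lineno}: invalid interval [{s}, {e})")
            out.setdefault(parts[0], []).append((s, e))
    return MaskSet({c: merge(np.array(v)) for c, v in out.items()}, provenance=provenance)


def write_bedgraph(track: FeatureTrack, path) -> None:
    if track.values is None:
        raise ValueError("bedGraph output needs a valued track")
    with open(path, "w") as fh:
        for chrom, iv in track.intervals.items():
            for (s, e), v in zip(iv, track.values[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path, mode: str = "mean", name: str = "feature") -> FeatureTrack:
    iv: Dict[str, List[Tuple[int, int]]] = {}
    vals: Dict[str, List[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph line with fewer than 4 fields")
            try:
                s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph fields") from exc
            if not np.isfinite(v):
                raise ValueError(f"{path}:{lineno}: non-finite value")
            iv.setdefault(parts[0], []).append((s, e))
            vals.setdefault(parts[0], []).append(v)
    return FeatureTrack(
        intervals={c: np.array(v, dtype=np.int64) for c, v in iv.items()},
        values={c: np.array(v) for c, v in vals.items()},
        mode=mode,
        name=name,
    )


# ---------------------------------------------------------------------- VCF


def _vcf_header(
    chrom_sizes: Mapping[str, int], mode: str, samples: Sequence[str]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in chrom_sizes.items():
        header.contigs.add(chrom, length=length)
    if mode == SOMATIC:
        header.info.add(MULTIPLICITY_KEY, 1, "Integer", "Number of independent mutational events")
    else:
        header.formats.add("GT", 1, "String", "Genotype")
        for s in samples:
            header.add_sample(s)
    return header


def write_vcf(catalog: VariantCatalog, reference: Reference, path) -> None:
    """Write a catalog as an uncompressed VCF.

    Population catalogs get per-sample GT columns reconstructed from the
    genotype summaries (an arbitrary but deterministic assignment of
    het / hom-alt / missing genotypes to sample slots); somatic catalogs
    get the multiplicity INFO key.
    """
    sizes = {c: reference.length(c) for c in catalog.chrom_names}
    samples = [f"S{i + 1}" for i in range(catalog.n_samples)]
    header = _vcf_header(sizes, catalog.mode, samples)
    cat = catalog.sorted()
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i in range(len(cat)):
            chrom = cat.chrom_names[cat.chrom[i]]
            pos = int(cat.pos[i])
            if cat.kind[i] == SNV:
                ref = BASES[cat.ref[i]]
                alt = BASES[cat.alt[i]]
            else:
                end = min(pos + int(cat.ref_len[i]), reference.length(chrom))
                ref = reference.sequence(chrom, pos, end)
                if int(cat.alt_len[i]) > 1:
                    alt = ref[0] * int(cat.alt_len[i])  # synthetic insertion body
                else:
                    alt = ref[0]
            rec = vcf.new_record(
                contig=chrom, start=pos, stop=pos + len(ref), alleles=(ref, alt)
            )
            if cat.mode == SOMATIC:
                rec.info[MULTIPLICITY_KEY] = int(cat.multiplicity[i])
            else:
                gts: List[Tuple] = []
                n_het, n_hom = int(cat.n_het[i]), int(cat.n_hom_alt[i])
                n_miss = int(cat.n_missing[i])
                for s in range(cat.n_samples):
                    if s < n_het:
                        gts.append((0, 1))
                    elif s < n_het + n_hom:
                        gts.append((1, 1))
                    elif s < n_het + n_hom + n_miss:
                        gts.append((None, None))
                    else:
                        gts.append((0, 0))
                for s, name in enumerate(samples):
                    rec.samples[name]["GT"] = gts[s]
            vcf.write(rec)


def read_vcf(
    path, mode: str, dataset: str, chrom_sizes: Mapping[str, int] | None = None
) -> VariantCatalog:
    """Read a VCF into a catalog (1-based positions converted to 0-based).

    ``mode`` selects the dialect: population VCFs must carry GT fields,
    somatic VCFs may carry the multiplicity INFO key (default 1).
    Multi-allelic records are treated as one record per alt allele.
    """
    if mode not in (POPULATION, SOMATIC):
        raise ValueError(f"unknown mode {mode!r}")
    cols = {
        k: []
        for k in (
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
    with pysam.VariantFile(str(path)) as vcf:
        contigs = list(vcf.header.contigs)
        contig_idx = {c: i for i, c in enumerate(contigs)}
        lengths = {c: vcf.header.contigs[c].length for c in contigs}
        n_samples = len(vcf.header.samples)
        if mode == POPULATION and n_samples == 0:
            raise ValueError("population-mode VCF without sample columns")
        for rec in vcf:
            pos = rec.start  # already 0-based in pysam
            if chrom_sizes is not None:
                bound = chrom_sizes.get(rec.contig)
            else:
                bound = lengths.get(rec.contig)
            if bound is not None and not (0 <= pos < bound):
                raise ValueError(
                    f"{path}: position {rec.pos} outside chromosome {rec.contig} (length {bound})"
                )
            for alt in rec.alts or ():
                ref = rec.ref
                is_snv = len(ref) == 1 and len(alt) == 1 and set(ref + alt) <= set(BASES)
                if mode == POPULATION:
                    n_het = n_hom = n_miss = n_called = 0
                    for s in rec.samples.values():
                        gt = s.get("GT")
                        if gt is None or any(g is None for g in gt):
                            n_miss += 1
                            continue
                        n_called += 1
                        if all(g >= 1 for g in gt):
                            n_hom += 1
                        elif any(g >= 1 for g in gt):
                            n_het += 1
                    mult = 1
                else:
                    n_het = n_hom = n_miss = n_called = 0
                    mult = int(rec.info.get(MULTIPLICITY_KEY, 1))
                cols["chrom"].append(contig_idx[rec.contig])
                cols["pos"].append(pos)
                cols["ref"].append(BASES.index(ref[0]) if ref[0] in BASES else 255)
                cols["alt"].append(BASES.index(alt[0]) if alt[0] in BASES else 255)
                cols["kind"].append(SNV if is_snv else INDEL)
                cols["ref_len"].append(len(ref))
                cols["alt_len"].append(len(alt))
                cols["multiplicity"].append(mult)
                cols["n_called"].append(n_called)
                cols["n_missing"].append(n_miss)
                cols["n_het"].append(n_het)
                cols["n_hom_alt"].append(n_hom)
    return VariantCatalog.from_arrays(
        dataset=dataset,
        mode=mode,
        chrom_names=tuple(contigs),
        chrom=np.array(cols["chrom"], dtype=np.int16),
        pos=np.array(cols["pos"], dtype=np.int64),
        ref=np.array(cols["ref"], dtype=np.uint8),
        alt=np.array(cols["alt"], dtype=np.uint8),
        kind=np.array(cols["kind"], dtype=np.uint8),
        ref_len=np.array(cols["ref_len"], dtype=np.int32),
        alt_len=np.array(cols["alt_len"], dtype=np.int32),
        multiplicity=np.array(cols["multiplicity"], dtype=np.int32),
        n_called=np.array(cols["n_called"], dtype=np.int32),
        n_missing=np.array(cols["n_missing"], dtype=np.int32),
        n_het=np.array(cols["n_het"], dtype=np.int32),
        n_hom_alt=np.array(cols["n_hom_alt"], dtype=np.int32),
        n_samples=(n_samples if mode == POPULATION else 0),
    )


# ------------------------------------------------------------------- tables


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_windows(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "start", "end", "f_w", "retained"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: window table missing columns {sorted(need - set(df.columns))}")
    return df


def read_density(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "start", "end", "n", "d", "z", "rank"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: density table missing columns {sorted(need - set(df.columns))}")
    return df


def write_signatures(signatures: pd.DataFrame, path) -> None:
    signatures.rename_axis("class").to_csv(path, sep="\t")


def read_signatures(path) -> pd.DataFrame:
    """COSMIC-style signature TSV: class rows x signature columns.

    Validates the canonical 96-class row set and unit column sums.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    got = set(df.index)
    want = set(trinuc.CLASS_LABELS)
    if got != want:
        unknown = sorted(got - want)[:5]
        missing = sorted(want - got)[:5]
        raise ValueError(
            f"{path}: bad class labels (unknown e.g. {unknown}, missing e.g. {missing})"
        )
    df = df.loc[list(trinuc.CLASS_LABELS)]
    sums = df.to_numpy(dtype=float).sum(axis=0)
    bad = [c for c, s in zip(df.columns, sums) if abs(s - 1.0) > 1e-6]
    if bad:
        raise ValueError(f"{path}: signature columns not summing to 1: {bad}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative signature probability")
    return df


def write_loads(load_table, path) -> None:
    rows = []
    for t in load_table.loads.index:
        for s in load_table.loads.columns:
            rows.append(
                (
                    t,
                    s,
                    float(load_table.loads.loc[t, s]),
                    int(load_table.samples.loc[t, s]),
                    int(bool(load_table.artifact.get(s, False))),
                )
            )
    pd.DataFrame(
        rows, columns=["tumor_type", "signature", "mutations", "n_samples", "artifact"]
    ).to_csv(path, sep="\t", index=False)


def read_loads(path):
    from .difftests import SignatureLoadTable

    df = pd.read_csv(path, sep="\t")
    need = {"tumor_type", "signature", "mutations", "n_samples", "artifact"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: load table missing columns {sorted(need - set(df.columns))}")
    loads = df.pivot(index="tumor_type", columns="signature", values="mutations")
    samples = df.pivot(index="tumor_type", columns="signature", values="n_samples").astype(int)
    artifact = {
        s: bool(df.loc[df["signature"] == s, "artifact"].iloc[0]) for s in loads.columns
    }
    return SignatureLoadTable(loads=loads, samples=samples, artifact=artifact)
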