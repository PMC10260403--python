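"""Cohort serialization: TSV tables plus a VCF view of the rare variants.

Everything round-trips losslessly through :func:`read_cohort`; the VCF
(v4.2, single-allele records, GT field) is written and read with pysam.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .simulate import Cohort

__all__ = ["write_cohort", "read_cohort", "write_vcf", "read_vcf"]

_FILES = {
    "common_genotypes": "common_genotypes.tsv",
    "common_info": "common_variants.tsv",
    "rare_genotypes": "rare_genotypes.tsv",
    "annotations": "annotations.tsv",
    "phenotypes": "phenotypes.tsv",
    "truth_genes": "truth_genes.tsv",
    "truth_polygenic": "truth_polygenic.tsv",
    "vcf": "rare_variants.vcf",
}


def write_cohort(cohort: Cohort, directory) -> dict[str, Path]:
    """Write all cohort tables (TSV) and the rare-variant VCF to `directory`."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {directory}: {exc}") from exc

    paths = {k: directory / v for k, v in _FILES.items()}
    cohort.common_genotypes.to_csv(paths["common_genotypes"], sep="\t", index_label="sample_id")
    cohort.common_info.to_csv(paths["common_info"], sep="\t", index=False)
    cohort.rare_genotypes.to_csv(paths["rare_genotypes"], sep="\t", index_label="sample_id")
    cohort.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    cohort.truth_gene_effects.to_csv(paths["truth_genes"], sep="\t", index=False)
    pd.DataFrame(
        {"sample_id": cohort.phenotypes["sample_id"], "polygenic": cohort.truth_polygenic}
    ).to_csv(paths["truth_polygenic"], sep="\t", index=False)
    write_vcf(cohort.rare_genotypes, cohort.annotations, paths["vcf"])
    return paths


def read_cohort(directory) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    p = {k: directory / v for k, v in _FILES.items()}
    common = pd.read_csv(p["common_genotypes"], sep="\t", index_col="sample_id")
    common.index.name = None
    rare = pd.read_csv(p["rare_genotypes"], sep="\t", index_col="sample_id")
    rare.index.name = None
    # "NA" is a real LoF-confidence level, so disable default NA parsing and
    # coerce the numeric columns explicitly (empty fields become NaN)
    ann = pd.read_csv(
        p["annotations"], sep="\t", dtype=str,
        keep_default_na=False, na_values=[""],
    )
    for col in ("pos", "mpc", "pli", "maf"):
        if col in ann.columns:
            ann[col] = pd.to_numeric(ann[col])
    if "pos" in ann.columns:
        ann["pos"] = ann["pos"].astype("int64", errors="ignore")
    pheno = pd.read_csv(p["phenotypes"], sep="\t", dtype={"center": str})
    truth = pd.read_csv(p["truth_genes"], sep="\t")
    poly = pd.read_csv(p["truth_polygenic"], sep="\t")["polygenic"].to_numpy()
    info = pd.read_csv(p["common_info"], sep="\t", dtype={"chrom": str})
    return Cohort(
        common_genotypes=common,
        common_info=info,
        rare_genotypes=rare,
        annotations=ann,
        phenotypes=pheno,
        truth_gene_effects=truth,
        truth_polygenic=poly,
    )


def write_vcf(genotypes: pd.DataFrame, annotations: pd.DataFrame, path) -> Path:
    """Write rare variants as a VCF v4.2 with GT fields (one ALT per record)."""
    path = Path(path)
    header = pysam.VariantHeader()
    header.add_meta("source", "cogexome-simulator")
    contigs = (
        sorted(annotations["chrom"].unique(), key=lambda c: (len(str(c)), str(c)))
        if not annotations.empty
        else []
    )
    for c in contigs:
        header.contigs.add(str(c), length=2_000_000_000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.info.add("GENE", 1, "String", "Gene symbol")
    samples = list(genotypes.index)
    for s in samples:
        header.add_sample(str(s))

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        ann_sorted = annotations.sort_values(["chrom", "pos"]) if not annotations.empty else annotations
        for row in ann_sorted.itertuples(index=False):
            rec = vcf.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,  # VCF positions are 1-based
                alleles=(row.ref, row.alt),
                id=row.variant_id,
            )
            rec.info["GENE"] = row.gene
            dosages = genotypes[row.variant_id].to_numpy()
            for s, d in zip(samples, dosages):
                if np.isnan(d):
                    rec.samples[str(s)]["GT"] = (None, None)
                else:
                    d = int(d)
                    rec.samples[str(s)]["GT"] = (0, 0) if d == 0 else ((0, 1) if d == 1 else (1, 1))
            vcf.write(rec)
    return path


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a single-allele GT VCF back into (dosage matrix, site table)."""
    cols: dict[str, np.ndarray] = {}
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            gt = np.array(
                [
                    np.nan
                    if None in rec.samples[s]["GT"]
                    else sum(rec.samples[s]["GT"])
                    for s in samples
                ],
                dtype=float,
            )
            cols[rec.id] = gt
            rows.append(
                {
                    "variant_id": rec.id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "gene": rec.info.get("GENE"),
                }
            )
    genotypes = pd.DataFrame(cols, index=samples) if cols else pd.DataFrame(index=samples)
    return genotypes, pd.DataFrame(rows)
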