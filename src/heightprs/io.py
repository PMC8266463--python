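"""Readers and writers for the package's on-disk formats.

All formats are plain text: the cohort and growth tables are TSV, and
genotypes round-trip either through a wide dosage TSV (samples x
variants) or through an uncompressed VCFv4.2 carrying both GT and DS per
sample. The two genotype formats are interchangeable on re-read.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import (
    FAMILY_COLUMNS,
    GROWTH_COLUMNS,
    VARIANT_COLUMNS,
    GenotypeMatrix,
    TrioCohort,
)
from .errors import FormatError, IntegrityError


# -- cohort tables -------------------------------------------------------

def write_cohort_tsv(cohort: TrioCohort, path: str) -> None:
    cohort.families.to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort_tsv(path: str, growth_path: str | None = None) -> TrioCohort:
    families = pd.read_csv(path, sep="\t", dtype={"sex": str})
    missing = [c for c in FAMILY_COLUMNS if c not in families.columns]
    if missing:
        raise FormatError(f"cohort TSV {path} missing columns {missing}")
    growth = (
        read_growth_tsv(growth_path)
        if growth_path is not None
        else pd.DataFrame(columns=GROWTH_COLUMNS)
    )
    return TrioCohort(families=families, growth=growth)


def write_growth_tsv(cohort: TrioCohort, path: str) -> None:
    cohort.growth.to_csv(path, sep="\t", index=False)


def read_growth_tsv(path: str) -> pd.DataFrame:
    growth = pd.read_csv(path, sep="\t")
    missing = [c for c in GROWTH_COLUMNS if c not in growth.columns]
    if missing:
        raise FormatError(f"growth TSV {path} missing columns {missing}")
    return growth


# -- genotypes: wide dosage TSV ------------------------------------------

def write_dosage_tsv(genotypes: GenotypeMatrix, path: str) -> None:
    """Samples x variants dosage table; a header block carries alleles.

    Layout: four '#'-prefixed metadata rows (chrom, pos, effect_allele,
    other_allele, one column per variant), then a header row
    ``sample_id<TAB>var1...``, then one row per sample with dosages in
    {0,1,2} or empty for missing.
    """
    v = genotypes.variants
    with open(path, "w") as fh:
        for col in ("chrom", "pos", "effect_allele", "other_allele"):
            fh.write("#" + col + "\t" + "\t".join(map(str, v[col])) + "\n")
        fh.write("sample_id\t" + "\t".join(v["id"]) + "\n")
        d = genotypes.dosages
        for i, sid in enumerate(genotypes.sample_ids):
            row = ["" if x < 0 else str(int(x)) for x in d[i]]
            fh.write(str(sid) + "\t" + "\t".join(row) + "\n")


def read_dosage_tsv(path: str) -> GenotypeMatrix:
    meta: dict[str, list[str]] = {}
    with open(path) as fh:
        line = fh.readline()
        while line.startswith("#"):
            key, *vals = line.rstrip("\n").split("\t")
            meta[key[1:]] = vals
            line = fh.readline()
        header = line.rstrip("\n").split("\t")
        if not header or header[0] != "sample_id":
            raise FormatError(f"{path}: expected 'sample_id' header row")
        variant_ids = header[1:]
        sample_ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            sample_ids.append(parts[0])
            rows.append([-1 if x == "" else int(x) for x in parts[1:]])
    for col in ("chrom", "pos", "effect_allele", "other_allele"):
        if col not in meta:
            raise FormatError(f"{path}: missing '#{col}' metadata row")
    variants = pd.DataFrame(
        {
            "id": variant_ids,
            "chrom": meta["chrom"],
            "pos": [int(p) for p in meta["pos"]],
            "effect_allele": meta["effect_allele"],
            "other_allele": meta["other_allele"],
        }
    )
    return GenotypeMatrix(
        sample_ids=np.array(sample_ids, dtype=object),
        variants=variants,
        dosages=np.array(rows, dtype=np.int8),
    )


# -- genotypes: VCF ------------------------------------------------------

_GT_BY_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(genotypes: GenotypeMatrix, path: str) -> None:
    """Uncompressed VCFv4.2; ALT is the counted (effect) allele.

    Each sample field carries GT and DS so either can be used on re-read.
    """
    v = genotypes.variants
    contigs = list(dict.fromkeys(v["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=heightprs\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect-allele dosage">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, genotypes.sample_ids))
            + "\n"
        )
        d = genotypes.dosages
        for j in range(genotypes.n_variants):
            row = v.iloc[j]
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                str(row["id"]),
                str(row["other_allele"]),
                str(row["effect_allele"]),
                ".",
                "PASS",
                ".",
                "GT:DS",
            ]
            calls = [
                f"{_GT_BY_DOSAGE[int(x)]}:{'.' if x < 0 else int(x)}" for x in d[:, j]
            ]
            fh.write("\t".join(fields + calls) + "\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read dosages from a VCF via cyvcf2 (GT field; ALT counted)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = np.array(vcf.samples, dtype=object)
    ids, chroms, poss, eff, oth, rows = [], [], [], [], [], []
    for var in vcf:
        ids.append(var.ID)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        oth.append(var.REF)
        eff.append(var.ALT[0])
        gt = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dos = np.full(len(gt), -1, dtype=np.int8)
        dos[gt == 0] = 0
        dos[gt == 1] = 1
        dos[gt == 3] = 2
        rows.append(dos)
    vcf.close()
    variants = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "effect_allele": eff, "other_allele": oth}
    )
    return GenotypeMatrix(
        sample_ids=sample_ids,
        variants=variants,
        dosages=np.array(rows, dtype=np.int8).T if rows else np.zeros((len(sample_ids), 0), np.int8),
    )


# -- bundled cohort writer ----------------------------------------------

def write_cohort(
    cohort: TrioCohort,
    genotypes: GenotypeMatrix | None,
    outdir: str,
    genotype_format: str = "tsv",
) -> dict[str, str]:
    """Write cohort + growth (+ genotypes) under ``outdir``.

    Returns the mapping of artifact name to path. Raises
    :class:`IntegrityError` when cohort ids lack genotype rows.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "cohort": os.path.join(outdir, "cohort.tsv"),
        "growth": os.path.join(outdir, "growth.tsv"),
    }
    if genotypes is not None:
        cohort.check_genotype_ids(genotypes)
        if genotype_format == "tsv":
            paths["genotypes"] = os.path.join(outdir, "genotypes.tsv")
            write_dosage_tsv(genotypes, paths["genotypes"])
        elif genotype_format == "vcf":
            paths["genotypes"] = os.path.join(outdir, "genotypes.vcf")
            write_vcf(genotypes, paths["genotypes"])
        else:
            raise FormatError(f"unknown genotype format {genotype_format!r}")
    write_cohort_tsv(cohort, paths["cohort"])
    write_growth_tsv(cohort, paths["growth"])
    return paths
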