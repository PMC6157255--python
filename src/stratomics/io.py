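"""Reading and writing the pipeline's standard file formats.

Genotypes travel as VCF v4.2 (GT fields, ``./.`` for missing, multi-allelic
records skipped with a warning); methylation, covariates, TG visits, and
family structure as UTF-8 tab-delimited tables with ``.`` for missing.
Coordinates are 1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    AlignmentError,
    Cohort,
    FamilyStructure,
    GenotypeMatrix,
    MethylationMatrix,
    validate_covariates,
    validate_tg,
)

logger = logging.getLogger(__name__)


def read_vcf(path) -> GenotypeMatrix:
    """Load a VCF into an additive dosage matrix (alt-allele counts).

    ``./.`` genotypes become missing; multi-allelic records are skipped with
    a logged warning.
    """
    path = str(path)
    vcf = VCF(path, gts012=True)
    sample_ids = np.array(vcf.samples, dtype=object)
    rows, snp_ids, chroms, positions, refs, alts = [], [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("skipping multi-allelic record %s at %s:%d",
                           rec.ID, rec.CHROM, rec.POS)
            continue
        # gts012: 0/1/2 = alt count, 3 = missing
        g = rec.gt_types.astype(float)
        g[g == 3] = np.nan
        rows.append(g)
        snp_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
    vcf.close()
    dosages = (np.vstack(rows).T if rows
               else np.empty((len(sample_ids), 0)))
    return GenotypeMatrix(dosages, sample_ids, np.array(snp_ids, dtype=object),
                          np.array(chroms, dtype=object),
                          np.array(positions, dtype=np.int64),
                          np.array(refs, dtype=object), np.array(alts, dtype=object))


_GT_CODES = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Emit a minimal VCF v4.2 with GT fields; missing dosage becomes ./."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, G.sample_ids)) + "\n")
        for j in range(G.n_snps):
            gts = ["./." if np.isnan(d) else _GT_CODES[d] for d in G.dosages[:, j]]
            fh.write(f"{G.chromosomes[j]}\t{G.positions[j]}\t{G.snp_ids[j]}\t"
                     f"{G.ref[j]}\t{G.alt[j]}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def write_methylation(M: MethylationMatrix, path) -> None:
    df = pd.DataFrame(M.betas, columns=M.cpg_ids)
    df.insert(0, "sample_id", M.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.10g")


def read_methylation(path, chromosomes=None, positions=None) -> MethylationMatrix:
    """Read a samples x sites beta TSV; optional site coordinate arrays."""
    df = pd.read_csv(path, sep="\t", na_values=".")
    cpg_ids = np.array(df.columns[1:], dtype=object)
    betas = df.iloc[:, 1:].to_numpy(dtype=float)
    m = len(cpg_ids)
    if chromosomes is None:
        chromosomes = np.full(m, "NA", dtype=object)
    if positions is None:
        positions = np.arange(1, m + 1, dtype=np.int64)
    return MethylationMatrix(betas, df.iloc[:, 0].to_numpy(object),
                             cpg_ids, np.asarray(chromosomes, dtype=object),
                             np.asarray(positions, dtype=np.int64))


def write_covariates(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# sex: 0=female 1=male; smoking: 0=non-smoker 1=smoker\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=".")


def write_tg(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.10g")


def write_families(fam: FamilyStructure, path) -> None:
    pd.DataFrame({"sample_id": fam.sample_ids, "family_id": fam.family_ids,
                  "role": fam.roles}).to_csv(path, sep="\t", index=False)


def read_families(path) -> FamilyStructure:
    df = pd.read_csv(path, sep="\t")
    roles = (df["role"].to_numpy(object) if "role" in df.columns
             else np.full(len(df), "sibling", dtype=object))
    return FamilyStructure(df["sample_id"].to_numpy(object),
                           df["family_id"].to_numpy(object), roles)


def read_tables(meth_path, covar_path, tg_path):
    """Load and validate the methylation, covariate, and TG tables."""
    meth = read_methylation(meth_path)
    covars = validate_covariates(pd.read_csv(covar_path, sep="\t", comment="#",
                                             na_values="."))
    tg = validate_tg(pd.read_csv(tg_path, sep="\t", na_values="."))
    return meth, covars, tg


def assemble_cohort(
    genotypes: GenotypeMatrix,
    methylation: MethylationMatrix,
    covariates: pd.DataFrame,
    tg: pd.DataFrame,
    families: FamilyStructure,
    truth: dict | None = None,
) -> Cohort:
    """Intersect sample sets, drop incomplete samples, align all components.

    A sample is retained only if it has all four TG visits, methylation,
    covariates, a family assignment, and at least one non-missing genotype.
    Dropped counts are logged per reason; an empty intersection is fatal.
    """
    covariates = validate_covariates(covariates)
    tg = validate_tg(tg)

    sets = {
        "genotypes": set(genotypes.sample_ids[
            (~np.isnan(genotypes.dosages)).any(axis=1)
            if genotypes.n_snps else np.ones(genotypes.n_samples, bool)]),
        "methylation": set(methylation.sample_ids),
        "covariates": set(covariates["sample_id"]),
        "tg": set(tg["sample_id"]),
        "families": set(families.sample_ids),
    }
    keep = set.intersection(*sets.values())
    for name, s in sets.items():
        dropped = len(s) - len(s & keep)
        if dropped:
            logger.info("assemble_cohort: %d samples present in %s dropped elsewhere",
                        dropped, name)
    if not keep:
        raise AlignmentError("no samples shared by all inputs")

    order = [s for s in families.sample_ids if s in keep]
    pos = {s: i for i, s in enumerate(order)}

    def idx_of(ids):
        sel = [(pos[s], i) for i, s in enumerate(ids) if s in keep]
        sel.sort()
        return np.array([i for _, i in sel], dtype=int)

    fam_idx = idx_of(families.sample_ids)
    cohort = Cohort(
        genotypes=genotypes.select_samples(idx_of(genotypes.sample_ids)),
        methylation=methylation.select_samples(idx_of(methylation.sample_ids)),
        covariates=covariates.iloc[idx_of(covariates["sample_id"])].reset_index(drop=True),
        tg=tg.iloc[idx_of(tg["sample_id"])].reset_index(drop=True),
        families=families.subset(fam_idx),
        truth=truth,
    )
    logger.info("assemble_cohort: %d samples retained", cohort.n_samples)
    return cohort


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write a cohort as the pipeline's standard input files; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "meth": out / "methylation.tsv",
        "covar": out / "covariates.tsv",
        "tg": out / "tg_visits.tsv",
        "fam": out / "families.tsv",
        "truth": out / "truth.json",
    }
    write_vcf(cohort.genotypes, paths["vcf"])
    write_methylation(cohort.methylation, paths["meth"])
    write_covariates(cohort.covariates, paths["covar"])
    write_tg(cohort.tg, paths["tg"])
    write_families(cohort.families, paths["fam"])
    if cohort.truth is not None:
        with open(paths["truth"], "w") as fh:
            json.dump(cohort.truth, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}


def read_cohort(vcf_path, meth_path, covar_path, tg_path, fam_path,
                truth_path=None) -> Cohort:
    """Read the standard files and assemble an aligned cohort."""
    geno = read_vcf(vcf_path)
    meth, covars, tg = read_tables(meth_path, covar_path, tg_path)
    fam = read_families(fam_path)
    truth = None
    if truth_path is not None and Path(truth_path).exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
    return assemble_cohort(geno, meth, covars, tg, fam, truth)
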