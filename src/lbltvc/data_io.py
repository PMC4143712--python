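"""Genotype/phenotype tables: reading, validation, writing, cohort join.

Genotype TSV dialect: one row per individual, an ``id`` column, then two
columns per SNP (``<snp>_1``, ``<snp>_2``) holding alleles from {A,C,G,T};
missing genotypes are coded "0" in both columns (half-calls are invalid).
Phenotype TSV is long format with columns ``id, exam, y, smoke, age, sex`` —
one row per individual per examination, 1-4 exams, ages strictly increasing
within an individual, sex constant.  Individuals with any missing genotype at
the SNPs under consideration are flagged for exclusion; individuals with
fewer than 4 exams are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ALLELES = {"A", "C", "G", "T"}
MISSING = "0"


class ValidationError(ValueError):
    pass


@dataclass
class GenotypeTable:
    """Unphased genotypes for unrelated individuals at an ordered SNP set."""

    individual_ids: list[str]
    snp_ids: list[str]
    # genotypes[i][s] = (allele1, allele2) or (MISSING, MISSING)
    genotypes: list[list[tuple[str, str]]]
    snp_positions: list[int] | None = None
    flagged_excluded: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.snp_positions is not None:
            pos = np.asarray(self.snp_positions)
            if len(pos) != len(self.snp_ids):
                raise ValidationError("positions/snp_ids length mismatch")
            if np.any(np.diff(pos) <= 0):
                raise ValidationError("SNP positions must be strictly increasing")
        for ind, row in zip(self.individual_ids, self.genotypes):
            if len(row) != len(self.snp_ids):
                raise ValidationError(f"individual {ind}: wrong number of SNPs")
            for s, (a, b) in zip(self.snp_ids, row):
                if (a == MISSING) != (b == MISSING):
                    raise ValidationError(
                        f"individual {ind}, SNP {s}: half-called genotype")
                if a != MISSING and (a not in VALID_ALLELES or b not in VALID_ALLELES):
                    raise ValidationError(
                        f"individual {ind}, SNP {s}: invalid alleles {a}/{b}")
        self.flagged_excluded |= {
            ind for ind, row in zip(self.individual_ids, self.genotypes)
            if any(a == MISSING for a, _ in row)}

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeTable":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        pos = ([self.snp_positions[i] for i in idx]
               if self.snp_positions is not None else None)
        return GenotypeTable(
            individual_ids=list(self.individual_ids),
            snp_ids=list(snp_ids),
            genotypes=[[row[i] for i in idx] for row in self.genotypes],
            snp_positions=pos)


@dataclass
class PhenotypeTable:
    """Longitudinal binary phenotype with smoking, age and sex per record."""

    df: pd.DataFrame  # columns: id, exam, y, smoke, age, sex

    def __post_init__(self):
        required = ["id", "exam", "y", "smoke", "age", "sex"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"phenotype table lacks columns {missing}")
        df = self.df.sort_values(["id", "exam"]).reset_index(drop=True)
        for col in ("y", "smoke", "sex"):
            if not df[col].isin([0, 1]).all():
                raise ValidationError(f"column {col} must be binary 0/1")
        for ind, grp in df.groupby("id", sort=False):
            if not 1 <= len(grp) <= 4:
                raise ValidationError(
                    f"individual {ind}: {len(grp)} exams (must be 1-4)")
            if len(grp) > 1 and np.any(np.diff(grp["age"].to_numpy()) <= 0):
                raise ValidationError(
                    f"individual {ind}: ages not strictly increasing")
            if grp["sex"].nunique() > 1:
                raise ValidationError(f"individual {ind}: sex varies across exams")
        self.df = df

    @property
    def individual_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["id"]))


@dataclass
class Cohort:
    """Inner join of validated genotype and phenotype tables."""

    genotypes: GenotypeTable
    phenotypes: PhenotypeTable

    @property
    def n(self) -> int:
        return len(self.genotypes.individual_ids)

    def block_genotypes(self, snp_ids: list[str] | None = None
                        ) -> list[list[tuple[str, str]]]:
        tab = (self.genotypes if snp_ids is None
               else self.genotypes.subset_snps(snp_ids))
        return tab.genotypes


def read_genotypes(path, dialect: str = "tsv") -> GenotypeTable:
    """Read a genotype table (``tsv`` dialect above, or ``vcf``)."""
    if dialect == "tsv":
        return _read_genotypes_tsv(path)
    if dialect == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_genotypes_tsv(path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns:
        raise ValidationError("genotype TSV must have an 'id' column")
    allele_cols = [c for c in df.columns if c != "id" and c != "pos"]
    snp_ids = []
    for c in allele_cols:
        if not (c.endswith("_1") or c.endswith("_2")):
            raise ValidationError(f"unexpected genotype column {c!r}")
        base = c[:-2]
        if base not in snp_ids:
            snp_ids.append(base)
    for s in snp_ids:
        for suffix in ("_1", "_2"):
            if s + suffix not in df.columns:
                raise ValidationError(f"SNP {s}: missing column {s + suffix}")
    genotypes = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        rowd = row._asdict()
        try:
            genotypes.append([(str(rowd[s + "_1"]).upper(),
                               str(rowd[s + "_2"]).upper()) for s in snp_ids])
        except KeyError as exc:  # pragma: no cover - guarded above
            raise ValidationError(f"line {row_num}: malformed row") from exc
    return GenotypeTable(individual_ids=[str(i) for i in df["id"]],
                         snp_ids=snp_ids, genotypes=genotypes)


def _read_genotypes_vcf(path) -> GenotypeTable:
    """Biallelic SNPs from a VCF; phase in GT separators is discarded."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required for VCF input") from exc
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    snp_ids, positions, per_snp = [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            raise ValidationError(
                f"{var.CHROM}:{var.POS}: only biallelic SNPs are supported")
        alleles = (var.REF, var.ALT[0])
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        positions.append(var.POS)
        calls = []
        for gt in var.genotypes:  # [a0, a1, phased]
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                calls.append((MISSING, MISSING))
            else:
                calls.append((alleles[a0], alleles[a1]))
        per_snp.append(calls)
    genotypes = [[per_snp[s][i] for s in range(len(snp_ids))]
                 for i in range(len(ids))]
    return GenotypeTable(individual_ids=ids, snp_ids=snp_ids,
                         genotypes=genotypes, snp_positions=positions)


def write_genotypes_tsv(table: GenotypeTable, path) -> None:
    cols = {"id": table.individual_ids}
    for s_idx, s in enumerate(table.snp_ids):
        cols[s + "_1"] = [row[s_idx][0] for row in table.genotypes]
        cols[s + "_2"] = [row[s_idx][1] for row in table.genotypes]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    df["id"] = df["id"].astype(str)
    return PhenotypeTable(df=df)


def write_phenotypes_tsv(table: PhenotypeTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def join_cohort(genotypes: GenotypeTable, phenotypes: PhenotypeTable,
                logger=None) -> Cohort:
    """Inner join on individual id, dropping genotype-flagged individuals."""
    geno_ids = [i for i in genotypes.individual_ids
                if i not in genotypes.flagged_excluded]
    pheno_ids = set(phenotypes.individual_ids)
    kept = [i for i in geno_ids if i in pheno_ids]
    if not kept:
        raise ValidationError("genotype and phenotype ids do not overlap")
    n_dropped = (len(set(genotypes.individual_ids) | pheno_ids) - len(kept))
    if logger is not None:
        logger.info("cohort join: kept %d individuals, dropped %d",
                    len(kept), n_dropped)
    keep_set = set(kept)
    idx = [i for i, ind in enumerate(genotypes.individual_ids) if ind in keep_set]
    gt = GenotypeTable(
        individual_ids=[genotypes.individual_ids[i] for i in idx],
        snp_ids=list(genotypes.snp_ids),
        genotypes=[genotypes.genotypes[i] for i in idx],
        snp_positions=(list(genotypes.snp_positions)
                       if genotypes.snp_positions is not None else None))
    pt = PhenotypeTable(df=phenotypes.df[phenotypes.df["id"].isin(keep_set)]
                        .reset_index(drop=True))
    # align phenotype individual order to genotype order
    order = {ind: i for i, ind in enumerate(gt.individual_ids)}
    pt.df = (pt.df.assign(_o=pt.df["id"].map(order))
             .sort_values(["_o", "exam"]).drop(columns="_o")
             .reset_index(drop=True))
    return Cohort(genotypes=gt, phenotypes=pt)
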