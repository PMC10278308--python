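"""Readers and writers for the tabular and VCF formats shared by all stages.

Conventions: all coordinates are 1-based inclusive (VCF convention); TSV
matrices carry sample ids in the first column and feature ids in the header
row.  The VCF dialect is deliberately minimal — biallelic sites, a single
GT FORMAT field, diploid unphased genotypes — which is all the dosage-based
scans need.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GenotypeMatrix,
    MetabolitePanel,
    SNPMap,
    TraitTable,
    TruthTable,
)

_GT_TO_DOSAGE = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "0|0": 0, "0|1": 1, "1|0": 1, "1|1": 2}


def write_genotypes_tsv(geno: GenotypeMatrix, matrix_path, map_path) -> None:
    geno.dosages.to_csv(matrix_path, sep="\t", index_label="accession")
    geno.snp_map.table.to_csv(map_path, sep="\t", index=False)


def read_genotypes_tsv(matrix_path, map_path) -> GenotypeMatrix:
    dosages = pd.read_csv(matrix_path, sep="\t", index_col="accession")
    dosages.columns.name = "snp_id"
    snp_map = SNPMap(pd.read_csv(map_path, sep="\t"))
    return GenotypeMatrix(dosages, snp_map)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal GT-only VCF (diploid, unphased, placeholder alleles)."""
    path = Path(path)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in geno.snp_map.table["chromosome"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        samples = "\t".join(geno.accessions)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        dosages = geno.dosages.to_numpy()
        for j, row in enumerate(geno.snp_map.table.itertuples(index=False)):
            gts = "\t".join(gt_strings[int(d)] for d in dosages[:, j])
            fh.write(
                f"{row.chromosome}\t{row.position}\t{row.snp_id}\tA\tT\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path, missing_cap: float = 0.2) -> GenotypeMatrix:
    """Read a GT-only VCF into a dosage matrix.

    Multi-allelic records are skipped with a warning.  SNPs with a missing
    fraction above ``missing_cap`` are dropped; remaining missing calls are
    mean-imputed and rounded to the nearest dosage.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = variant.gt_types.astype(float)
        dose = np.where(gt == 3, 2.0, gt)
        dose[gt == 2] = np.nan
        missing = np.isnan(dose)
        if missing.mean() > missing_cap:
            continue
        if missing.any():
            dose[missing] = np.round(np.nanmean(dose))
        snp_id = variant.ID or f"{variant.CHROM}_{variant.POS}"
        rows.append((snp_id, variant.CHROM, variant.POS))
        cols.append(dose.astype(np.int64))
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic record(s)")
    snp_map = SNPMap(pd.DataFrame(rows, columns=["snp_id", "chromosome", "position"]))
    dosages = pd.DataFrame(
        np.column_stack(cols),
        index=pd.Index(samples, name="accession"),
        columns=snp_map.snp_ids,
    )
    return GenotypeMatrix(dosages, snp_map)


def write_metabolites_tsv(panel: MetabolitePanel, matrix_path, classes_path=None) -> None:
    panel.abundances.to_csv(matrix_path, sep="\t", index_label="accession")
    if classes_path is not None:
        panel.classes.rename("class").to_csv(classes_path, sep="\t", index_label="metabolite")


def read_metabolites_tsv(matrix_path, classes_path=None, year: str = "unknown_year") -> MetabolitePanel:
    abundances = pd.read_csv(matrix_path, sep="\t", index_col="accession")
    if classes_path is not None:
        classes = pd.read_csv(classes_path, sep="\t", index_col="metabolite")["class"]
    else:
        classes = pd.Series("unknown", index=abundances.columns)
    return MetabolitePanel(abundances, classes, year)


def write_expression_tsv(expr: ExpressionMatrix, matrix_path, map_path) -> None:
    expr.expression.to_csv(matrix_path, sep="\t", index_label="accession")
    expr.gene_map.to_csv(map_path, sep="\t", index=False)


def read_expression_tsv(matrix_path, map_path) -> ExpressionMatrix:
    expression = pd.read_csv(matrix_path, sep="\t", index_col="accession")
    gene_map = pd.read_csv(map_path, sep="\t")
    return ExpressionMatrix(expression, gene_map)


def write_trait_tsv(trait: TraitTable, path) -> None:
    trait.values.to_csv(path, sep="\t", index_label="accession")


def read_trait_tsv(path) -> TraitTable:
    return TraitTable(pd.read_csv(path, sep="\t", index_col="accession"))


def write_truth_tsv(truth: TruthTable, path) -> None:
    """Serialize the planted truth as a long-format TSV."""
    rows = []
    for met, snp, eff in truth.planted_mqtl:
        rows.append(("mqtl", met, snp, eff, ""))
    for gene, snp, eff, cis in truth.planted_eqtl:
        rows.append(("eqtl", gene, snp, eff, "cis" if cis else "trans"))
    for gene, lab in truth.planted_modules.items():
        rows.append(("module", gene, "", lab, ""))
    for feat, w in truth.trait_weights.items():
        rows.append(("trait_weight", feat, "", w, ""))
    for met, h2 in truth.h2_target.items():
        rows.append(("h2_target", met, "", h2, ""))
    pd.DataFrame(
        rows, columns=["record", "feature_id", "snp_id", "value", "flag"]
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    truth = TruthTable()
    for row in df.itertuples(index=False):
        if row.record == "mqtl":
            truth.planted_mqtl.append((row.feature_id, row.snp_id, float(row.value)))
        elif row.record == "eqtl":
            truth.planted_eqtl.append(
                (row.feature_id, row.snp_id, float(row.value), row.flag == "cis")
            )
        elif row.record == "module":
            truth.planted_modules[row.feature_id] = int(float(row.value))
        elif row.record == "trait_weight":
            truth.trait_weights[row.feature_id] = float(row.value)
        elif row.record == "h2_target":
            truth.h2_target[row.feature_id] = float(row.value)
    return truth
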