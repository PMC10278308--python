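"""Core data containers shared across the analysis stages.

All tabular payloads are pandas objects: a :class:`GenotypeMatrix` wraps an
accession x SNP dosage DataFrame plus a SNP map, a :class:`MetabolitePanel`
wraps an accession x metabolite log2-abundance DataFrame plus class labels,
and so on.  The containers validate their structural invariants on
construction so that downstream stages can assume consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Closed vocabulary of metabolite compound classes; anything else is "unknown".
METABOLITE_CLASSES = (
    "flavonoid",
    "lipid",
    "amino acid derivative",
    "nucleic acid derivative",
    "phenylethanoid",
    "terpenoid",
    "other",
    "unknown",
)


@dataclass
class SNPMap:
    """Physical map of the SNP panel.

    Parameters
    ----------
    table : DataFrame with columns ``snp_id``, ``chromosome``, ``position``
        (1-based base pairs).  Positions must be strictly increasing within
        a chromosome and SNP ids unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"snp_id", "chromosome", "position"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"SNP map missing columns: {sorted(missing)}")
        if self.table["snp_id"].duplicated().any():
            raise ValueError("SNP ids must be unique")
        for chrom, grp in self.table.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        self.table = self.table.reset_index(drop=True)

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.table["snp_id"])

    def position_of(self, snp_id: str) -> tuple[str, int]:
        row = self.table.loc[self.table["snp_id"] == snp_id]
        if row.empty:
            raise KeyError(f"unknown SNP id: {snp_id}")
        return str(row["chromosome"].iloc[0]), int(row["position"].iloc[0])

    def subset(self, snp_ids) -> "SNPMap":
        keep = self.table["snp_id"].isin(set(snp_ids))
        return SNPMap(self.table.loc[keep].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypeMatrix:
    """Accession x SNP dosage matrix (0/1/2 minor-allele counts) plus map."""

    dosages: pd.DataFrame
    snp_map: SNPMap

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.snp_map.table["snp_id"]):
            raise ValueError("dosage columns must equal the SNP map, in order")
        values = self.dosages.to_numpy()
        if np.isnan(values).any():
            raise ValueError("dosages contain missing values; impute first")
        if not np.isin(values, (0, 1, 2)).all():
            raise ValueError("dosages must be integers in {0, 1, 2}")

    @property
    def accessions(self) -> pd.Index:
        return self.dosages.index

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> pd.Series:
        """Minor allele frequency per SNP: min(f, 1-f), f = mean dosage / 2."""
        f = self.dosages.mean(axis=0) / 2.0
        return pd.concat([f, 1.0 - f], axis=1).min(axis=1).rename("maf")

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        snp_ids = [s for s in self.snp_map.table["snp_id"] if s in set(snp_ids)]
        return GenotypeMatrix(self.dosages[snp_ids], self.snp_map.subset(snp_ids))


@dataclass
class MetabolitePanel:
    """Accession x metabolite log2 relative abundances with class labels."""

    abundances: pd.DataFrame
    classes: pd.Series
    year: str

    def __post_init__(self) -> None:
        self.classes = self.classes.reindex(self.abundances.columns).fillna("unknown")
        bad = set(self.classes) - set(METABOLITE_CLASSES)
        if bad:
            raise ValueError(f"unknown metabolite classes: {sorted(bad)}")

    @property
    def metabolites(self) -> pd.Index:
        return self.abundances.columns

    @property
    def accessions(self) -> pd.Index:
        return self.abundances.index


@dataclass
class ExpressionMatrix:
    """Accession x gene expression with a gene map (chromosome/start/end/strand)."""

    expression: pd.DataFrame
    gene_map: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chromosome", "start", "end", "strand"}
        missing = required - set(self.gene_map.columns)
        if missing:
            raise ValueError(f"gene map missing columns: {sorted(missing)}")
        if self.gene_map["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")
        mapped = set(self.gene_map["gene_id"])
        unmapped = [g for g in self.expression.columns if g not in mapped]
        if unmapped:
            raise ValueError(f"genes missing from the gene map: {unmapped[:5]}...")

    @property
    def genes(self) -> pd.Index:
        return self.expression.columns

    @property
    def accessions(self) -> pd.Index:
        return self.expression.index

    def gene_entry(self, gene_id: str) -> pd.Series:
        row = self.gene_map.loc[self.gene_map["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(f"unknown gene id: {gene_id}")
        return row.iloc[0]


@dataclass
class TraitTable:
    """Per-environment trait values (seed oil content, percent) per accession."""

    values: pd.DataFrame  # accession x environment

    @property
    def accessions(self) -> pd.Index:
        return self.values.index

    @property
    def environments(self) -> pd.Index:
        return self.values.columns

    def mean_across_environments(self) -> pd.Series:
        return self.values.mean(axis=1).rename("trait")


@dataclass
class TruthTable:
    """Planted ground truth recorded by the synthetic generators.

    Every downstream recovery test reads only this object: it is the closed
    oracle against which mQTL mapping, eQTL classification, module detection,
    marker selection, and network assembly are scored.
    """

    planted_mqtl: list[tuple[str, str, float]] = field(default_factory=list)
    planted_eqtl: list[tuple[str, str, float, bool]] = field(default_factory=list)
    planted_modules: dict[str, int] = field(default_factory=dict)
    trait_weights: dict[str, float] = field(default_factory=dict)
    h2_target: dict[str, float] = field(default_factory=dict)

    def validate_against(
        self,
        geno: "GenotypeMatrix | None" = None,
        metabolite_ids=None,
        gene_ids=None,
    ) -> None:
        if geno is not None:
            snps = set(geno.snp_map.table["snp_id"])
            for _, snp, _ in self.planted_mqtl:
                if snp not in snps:
                    raise ValueError(f"planted mQTL SNP not in genotypes: {snp}")
            for _, snp, _, _ in self.planted_eqtl:
                if snp not in snps:
                    raise ValueError(f"planted eQTL SNP not in genotypes: {snp}")
        if metabolite_ids is not None:
            mets = set(metabolite_ids)
            for met, _, _ in self.planted_mqtl:
                if met not in mets:
                    raise ValueError(f"planted mQTL metabolite unknown: {met}")
        if gene_ids is not None:
            genes = set(gene_ids)
            for gene, _, _, _ in self.planted_eqtl:
                if gene not in genes:
                    raise ValueError(f"planted eQTL gene unknown: {gene}")
            for gene in self.planted_modules:
                if gene not in genes:
                    raise ValueError(f"module gene unknown: {gene}")
        for met, h2 in self.h2_target.items():
            if not 0.0 <= h2 <= 1.0:
                raise ValueError(f"h2_target out of [0,1] for {met}: {h2}")


@dataclass
class QTL:
    """A clustered block of significant SNPs for one or more phenotypes."""

    qtl_id: str
    chromosome: str
    start: int
    end: int
    lead_snp: str
    lead_p: float
    member_snps: list[str]
    phenotype_ids: set[str]

    def __post_init__(self) -> None:
        if not self.start <= self.end:
            raise ValueError("QTL interval must satisfy start <= end")

    def gap_to(self, other: "QTL") -> float:
        """Base-pair gap between two intervals; 0 if they overlap; inf across chromosomes."""
        if self.chromosome != other.chromosome:
            return float("inf")
        return float(max(0, max(self.start, other.start) - min(self.end, other.end)))
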