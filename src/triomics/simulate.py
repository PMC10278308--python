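"""Synthetic genotype / metabolome / expression / trait generators.

The generators emulate the study design the pipeline is built for: a natural
population of ~388 inbred rapeseed accessions genotyped at biallelic SNPs
with MAF > 5% arranged in ~100-kb LD blocks, seed metabolites measured on a
log2 scale in two years with tunable broad-sense heritability, a seed
transcriptome with planted cis/trans eQTLs and block-correlated co-expression
modules, and a seed-oil-content trait (percent) driven by a subset of
metabolites and genes plus environment noise.

Every planted effect is recorded in a :class:`~triomics.datatypes.TruthTable`
so downstream recovery is scored against a closed oracle.  All generators are
deterministic for a fixed seed.

LD model: within each block a latent Gaussian process with exponential
distance decay is drawn per haplotype and thresholded at the per-SNP allele
frequency; blocks are mutually independent.  This is the simplest mechanism
that yields within-block r^2 decaying with distance and near-zero
between-block r^2.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import (
    METABOLITE_CLASSES,
    ExpressionMatrix,
    GenotypeMatrix,
    MetabolitePanel,
    SNPMap,
    TraitTable,
    TruthTable,
)

# Desk-scale defaults preserving the study's ratios: 388 accessions /
# millions of SNPs / 2173 metabolites / 70,781 genes scaled to a workstation.
DEFAULT_N_ACCESSIONS = 400
DEFAULT_N_SNPS = 2000
DEFAULT_N_CHROMOSOMES = 4
DEFAULT_N_METABOLITES = 200
DEFAULT_N_GENES = 1000
DEFAULT_N_YEARS = 2
DEFAULT_N_ENVIRONMENTS = 5
DEFAULT_BLOCK_BP = 100_000
#: Mean inter-SNP spacing (bp); ~20 SNPs per 100-kb block at desk scale.
DEFAULT_SPACING_BP = 5_000

# Class frequencies mirror the annotated fraction of the study panel:
# 440 of 2173 quantified metabolites carried a class annotation.
_CLASS_PROBS = {
    "amino acid derivative": 80 / 2173,
    "nucleic acid derivative": 38 / 2173,
    "lipid": 60 / 2173,
    "flavonoid": 92 / 2173,
    "phenylethanoid": 29 / 2173,
    "terpenoid": 42 / 2173,
    "other": 99 / 2173,
    "unknown": 1733 / 2173,
}


def generate_genotypes(
    n_accessions: int = DEFAULT_N_ACCESSIONS,
    n_snps: int = DEFAULT_N_SNPS,
    n_chromosomes: int = DEFAULT_N_CHROMOSOMES,
    maf_range: tuple[float, float] = (0.05, 0.5),
    block_bp: int = DEFAULT_BLOCK_BP,
    spacing_bp: int = DEFAULT_SPACING_BP,
    decay_bp: float | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate a diploid dosage matrix with block LD structure.

    Each chromosome receives ``n_snps // n_chromosomes`` SNPs (the remainder
    goes to the first chromosomes) at jittered ~``spacing_bp`` intervals.
    Within each ``block_bp`` window a shared latent Gaussian with kernel
    ``exp(-d / decay_bp)`` is drawn independently for the two haplotypes of
    every accession and thresholded at the quantile of the per-SNP allele
    frequency (drawn uniformly from ``maf_range``).

    Parameters
    ----------
    decay_bp : correlation length of the latent process; defaults to
        ``block_bp / 3`` so r^2 decays visibly within a block.
    """
    if n_accessions <= 0 or n_snps <= 0 or n_chromosomes <= 0:
        raise ValueError("dimensions must be positive")
    if n_snps < n_chromosomes:
        raise ValueError("need at least one SNP per chromosome")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if decay_bp is None:
        decay_bp = block_bp / 3.0

    rng = np.random.default_rng(seed)
    per_chrom = [n_snps // n_chromosomes] * n_chromosomes
    for i in range(n_snps % n_chromosomes):
        per_chrom[i] += 1

    rows = []
    dosage_cols = []
    snp_counter = 0
    for ci in range(n_chromosomes):
        chrom = f"chr{ci + 1:02d}"
        m = per_chrom[ci]
        gaps = rng.integers(1, 2 * spacing_bp, size=m)
        positions = np.cumsum(gaps)
        freqs = rng.uniform(lo, hi, size=m)
        # group SNPs into independent blocks by position
        block_ids = positions // block_bp
        for b in np.unique(block_ids):
            idx = np.flatnonzero(block_ids == b)
            pos_b = positions[idx].astype(float)
            dist = np.abs(pos_b[:, None] - pos_b[None, :])
            cov = np.exp(-dist / decay_bp)
            # jitter keeps Cholesky stable for near-duplicate positions
            chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(idx)))
            thresh = norm.ppf(freqs[idx])
            alleles = np.zeros((n_accessions, len(idx)), dtype=np.int64)
            for _hap in range(2):
                z = rng.standard_normal((n_accessions, len(idx))) @ chol.T
                alleles += (z < thresh).astype(np.int64)
            dosage_cols.append(alleles)
        for j in range(m):
            rows.append((f"snp{snp_counter:05d}", chrom, int(positions[j])))
            snp_counter += 1

    snp_map = SNPMap(pd.DataFrame(rows, columns=["snp_id", "chromosome", "position"]))
    accessions = [f"acc{i:04d}" for i in range(n_accessions)]
    dosages = pd.DataFrame(
        np.concatenate(dosage_cols, axis=1),
        index=pd.Index(accessions, name="accession"),
        columns=snp_map.snp_ids,
    )
    return GenotypeMatrix(dosages, snp_map)


def _centered_dosage(geno: GenotypeMatrix, snp_id: str) -> np.ndarray:
    g = geno.dosages[snp_id].to_numpy(dtype=float)
    return g - g.mean()


def generate_metabolome(
    geno: GenotypeMatrix,
    truth: TruthTable,
    n_metabolites: int = DEFAULT_N_METABOLITES,
    n_years: int = DEFAULT_N_YEARS,
    seed: int = 0,
    baseline_mean: float = 10.0,
    baseline_sd: float = 2.0,
    polygenic_var: float = 1.0,
) -> list[MetabolitePanel]:
    """Simulate per-year log2 metabolite panels with controlled heritability.

    For metabolite *j* with target broad-sense heritability ``h2`` the
    accession-level genetic value is the sum of its planted SNP effects plus
    an accession random effect topped up so total genetic variance is at
    least ``polygenic_var``; the year-specific residual variance is then set
    to ``Vg * (1 - h2) / h2`` so the realized H2 matches the target in
    expectation.  ``h2 = 0`` metabolites carry no genetic signal at all;
    ``h2 = 1`` metabolites have no year-to-year noise.
    """
    if n_years < 2:
        raise ValueError("heritability needs replication: n_years must be >= 2")
    truth.validate_against(geno=geno)
    rng = np.random.default_rng(seed)
    n = geno.n_accessions
    met_ids = [f"met{j:04d}" for j in range(n_metabolites)]

    effects_by_met: dict[str, list[tuple[str, float]]] = {}
    for met, snp, eff in truth.planted_mqtl:
        effects_by_met.setdefault(met, []).append((snp, eff))

    # default heritability for metabolites the truth table leaves unset:
    # uniform over [0.2, 0.9] approximating the wide observed spread.
    # Drawn unconditionally so the random stream (and hence the output for a
    # fixed seed) does not depend on how much of the truth table is filled in.
    h2_defaults = rng.uniform(0.2, 0.9, size=n_metabolites)
    h2_all = {
        m: float(truth.h2_target.get(m, h2_defaults[j]))
        for j, m in enumerate(met_ids)
    }
    truth.h2_target.update(h2_all)

    genetic = np.zeros((n, n_metabolites))
    ve = np.zeros(n_metabolites)
    means = rng.normal(baseline_mean, baseline_sd, size=n_metabolites)
    for j, met in enumerate(met_ids):
        h2 = h2_all[met]
        if h2 <= 0.0:
            ve[j] = polygenic_var
            continue
        g = np.zeros(n)
        for snp, eff in effects_by_met.get(met, []):
            g += eff * _centered_dosage(geno, snp)
        var_snp = float(np.var(g))
        extra = max(0.0, polygenic_var - var_snp)
        if extra > 0:
            g = g + rng.normal(0.0, math.sqrt(extra), size=n)
        vg = float(np.var(g))
        genetic[:, j] = g
        ve[j] = 0.0 if h2 >= 1.0 else vg * (1.0 - h2) / h2

    classes = pd.Series(
        rng.choice(list(_CLASS_PROBS), size=n_metabolites, p=list(_CLASS_PROBS.values())),
        index=met_ids,
    )
    panels = []
    for y in range(n_years):
        noise = rng.standard_normal((n, n_metabolites)) * np.sqrt(ve)[None, :]
        values = means[None, :] + genetic + noise
        panels.append(
            MetabolitePanel(
                abundances=pd.DataFrame(
                    values, index=geno.accessions, columns=met_ids
                ),
                classes=classes.copy(),
                year=f"year{y + 1}",
            )
        )
    return panels


def generate_expression(
    geno: GenotypeMatrix,
    truth: TruthTable,
    n_genes: int = DEFAULT_N_GENES,
    seed: int = 0,
    module_weight: float = 0.78,
    noise_sd: float = 1.0,
    gene_length_bp: int = 2_000,
    cis_window_bp: int = 1_000_000,
) -> ExpressionMatrix:
    """Simulate expression with planted co-expression modules and eQTLs.

    Genes sharing a planted module label load on a common latent factor with
    weight ``module_weight`` (within-module correlation ~ ``module_weight**2``
    before eQTL effects).  Planted eQTL effects are added on top; the
    ``cis`` flag recorded in the truth table is validated against the
    generated gene map using the ``cis_window_bp`` distance rule.
    """
    truth.validate_against(geno=geno)
    rng = np.random.default_rng(seed)
    n = geno.n_accessions
    gene_ids = [f"gene{j:05d}" for j in range(n_genes)]
    known_genes = set(gene_ids)
    for gene in truth.planted_modules:
        if gene not in known_genes:
            raise ValueError(f"module spec references absent gene: {gene}")
    for gene, _, _, _ in truth.planted_eqtl:
        if gene not in known_genes:
            raise ValueError(f"eQTL spec references absent gene: {gene}")

    # lay genes uniformly along the SNP map's chromosomes
    chrom_extent = (
        geno.snp_map.table.groupby("chromosome")["position"].max().to_dict()
    )
    chroms = sorted(chrom_extent)
    map_rows = []
    for j, gene in enumerate(gene_ids):
        chrom = chroms[j % len(chroms)]
        start = int(rng.integers(1, max(2, chrom_extent[chrom])))
        map_rows.append(
            (gene, chrom, start, start + gene_length_bp, "+" if j % 2 == 0 else "-")
        )
    gene_map = pd.DataFrame(
        map_rows, columns=["gene_id", "chromosome", "start", "end", "strand"]
    )
    # planted cis eQTLs pin the gene next to its SNP so the distance rule holds
    gm = gene_map.set_index("gene_id")
    for gene, snp, _eff, cis in truth.planted_eqtl:
        chrom, pos = geno.snp_map.position_of(snp)
        if cis:
            gm.loc[gene, ["chromosome", "start", "end"]] = (
                chrom,
                max(1, pos - gene_length_bp // 2),
                max(1, pos - gene_length_bp // 2) + gene_length_bp,
            )
        elif gm.loc[gene, "chromosome"] == chrom and (
            abs(int(gm.loc[gene, "start"]) - pos) <= cis_window_bp
            or abs(int(gm.loc[gene, "end"]) - pos) <= cis_window_bp
        ):
            other = [c for c in chroms if c != chrom]
            gm.loc[gene, "chromosome"] = other[0] if other else chrom
    gene_map = gm.reset_index()

    module_of = truth.planted_modules
    labels = sorted({m for m in module_of.values() if m != 0})
    factors = {lab: rng.standard_normal(n) for lab in labels}

    w = float(module_weight)
    expr = rng.standard_normal((n, n_genes)) * noise_sd
    expr_df = pd.DataFrame(expr, index=geno.accessions, columns=gene_ids)
    for gene, lab in module_of.items():
        if lab == 0:
            continue
        expr_df[gene] = w * factors[lab] + math.sqrt(max(0.0, 1 - w * w)) * expr_df[gene]
    for gene, snp, eff, _cis in truth.planted_eqtl:
        expr_df[gene] = expr_df[gene] + eff * _centered_dosage(geno, snp)
    return ExpressionMatrix(expr_df, gene_map)


def generate_trait(
    panels: list[MetabolitePanel],
    expr: ExpressionMatrix | None,
    truth: TruthTable,
    n_environments: int = DEFAULT_N_ENVIRONMENTS,
    noise_sd: float = 1.0,
    seed: int = 0,
    base_soc: float = 40.0,
) -> TraitTable:
    """Simulate per-environment seed oil content (percent).

    SOC for accession *i* in every environment is ``base_soc`` plus the
    weighted sum of the designated metabolite (year-averaged) and gene
    values, standardized per feature, plus independent Gaussian environment
    noise.  The sign of each planted weight equals the sign of the realized
    trait-feature correlation in expectation.
    """
    if not truth.trait_weights:
        raise ValueError("trait_weights must be non-empty")
    rng = np.random.default_rng(seed)
    mean_panel = sum(p.abundances for p in panels) / len(panels)
    accessions = panels[0].accessions
    signal = np.zeros(len(accessions))
    for feat, weight in truth.trait_weights.items():
        if feat in mean_panel.columns:
            x = mean_panel[feat].to_numpy(dtype=float)
        elif expr is not None and feat in expr.expression.columns:
            x = expr.expression[feat].to_numpy(dtype=float)
        else:
            raise ValueError(f"trait weight references unknown feature: {feat}")
        sd = x.std()
        if sd > 0:
            x = (x - x.mean()) / sd
        signal = signal + weight * x
    values = {
        f"env{e + 1}": base_soc + signal + rng.normal(0.0, noise_sd, len(accessions))
        for e in range(n_environments)
    }
    return TraitTable(pd.DataFrame(values, index=accessions))


def default_truth(
    geno: GenotypeMatrix,
    n_metabolites: int = DEFAULT_N_METABOLITES,
    n_genes: int = DEFAULT_N_GENES,
    n_marker_metabolites: int = 30,
    n_shared_loci: int = 5,
    n_hotspot_metabolites: int = 12,
    n_modules: int = 6,
    module_size: int = 60,
    mqtl_effect: float = 0.7,
    eqtl_effect: float = 0.8,
    seed: int = 0,
) -> TruthTable:
    """Construct the standard planted-truth design used by the pipeline.

    The design plants (i) ``n_shared_loci`` loci where a metabolite mQTL and
    a gene cis-eQTL co-localize in the same LD block (the metabolite-QTL-gene
    paths the triple network must recover), (ii) one pleiotropic hotspot SNP
    affecting ``n_hotspot_metabolites`` metabolites, (iii) ``n_modules``
    co-expression modules of ``module_size`` genes, and (iv) trait weights on
    the marker metabolites (most negative, some positive, echoing the
    observed predominance of negatively SOC-correlated metabolites) and on
    the genes at the shared loci.
    """
    rng = np.random.default_rng(seed)
    met_ids = [f"met{j:04d}" for j in range(n_metabolites)]
    gene_ids = [f"gene{j:05d}" for j in range(n_genes)]
    snp_ids = list(geno.snp_map.table["snp_id"])

    # spread planted SNPs far apart so their QTLs do not merge
    n_needed = n_shared_loci + 1 + 5
    planted_snps = [
        snp_ids[int(i)]
        for i in np.linspace(0, len(snp_ids) - 1, n_needed).round()
    ]
    shared_snps = planted_snps[:n_shared_loci]
    hotspot_snp = planted_snps[n_shared_loci]
    extra_snps = planted_snps[n_shared_loci + 1 :]

    truth = TruthTable()
    markers = list(rng.choice(met_ids, size=n_marker_metabolites, replace=False))
    # shared loci: metabolite k and gene k both mapped to shared SNP k
    shared_genes = list(rng.choice(gene_ids, size=n_shared_loci, replace=False))
    for k, snp in enumerate(shared_snps):
        truth.planted_mqtl.append((markers[k], snp, mqtl_effect))
        truth.planted_eqtl.append((shared_genes[k], snp, eqtl_effect, True))
    # hotspot: one block detected by many marker metabolites
    hot_mets = markers[: min(n_hotspot_metabolites, len(markers))]
    for met in hot_mets:
        truth.planted_mqtl.append((met, hotspot_snp, mqtl_effect))
    # a few additional trans eQTLs on genes outside the shared set
    trans_genes = [g for g in gene_ids if g not in set(shared_genes)][:5]
    for gene, snp in zip(trans_genes, extra_snps):
        truth.planted_eqtl.append((gene, snp, eqtl_effect, False))

    # modules over genes not already planted as eQTL targets
    free_genes = [
        g for g in gene_ids if g not in set(shared_genes) | set(trans_genes)
    ]
    pos = 0
    for lab in range(1, n_modules + 1):
        for g in free_genes[pos : pos + module_size]:
            truth.planted_modules[g] = lab
        pos += module_size
    # the first module also hosts the shared-locus genes (core-module genes)
    for g in shared_genes:
        truth.planted_modules[g] = 1

    # trait weights: predominance of negative marker metabolites
    n_neg = max(1, int(round(0.8 * len(markers))))
    for i, met in enumerate(markers):
        truth.trait_weights[met] = -0.4 if i < n_neg else 0.4
    for g in shared_genes:
        truth.trait_weights[g] = -0.3
    # marker metabolites get high heritability so two-year signal is stable
    for met in markers:
        truth.h2_target[met] = 0.8
    return truth
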