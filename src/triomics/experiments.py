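"""Calibration and recovery experiments on synthetic data.

These functions quantify, under the planted-truth generators, the pipeline
properties a user should expect before trusting results on real data: the
type-I error of the mixed-model scan, the probability that a planted mQTL
surfaces as the lead SNP of a clustered QTL, the fidelity of module
detection, the fraction of planted metabolite-gene links recovered by the
triple network, and the AUC margin of peak-SNP prediction over the
random-SNP null.  Each experiment is deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import association, coexpression, metabolome, network, prediction, simulate, twas
from .datatypes import TraitTable, TruthTable


def lmm_type1_error(
    n_accessions: int = 400,
    n_snps: int = 500,
    n_phenotypes: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Pooled per-SNP rejection rate at ``alpha`` under the global null.

    One LD-structured genotype panel is scanned against ``n_phenotypes``
    independent standard-normal phenotypes; the fraction of all per-SNP
    p-values below ``alpha`` estimates the realized type-I error, which
    should sit near ``alpha`` for a calibrated test.
    """
    rng = np.random.default_rng(seed)
    geno = simulate.generate_genotypes(
        n_accessions=n_accessions, n_snps=n_snps, seed=int(rng.integers(2**31))
    )
    geno = association.maf_filter(geno)
    K = association.kinship(geno)
    ctx = association.LmmContext.build(geno, K)
    n_reject = 0
    n_total = 0
    for _ in range(n_phenotypes):
        y = pd.Series(rng.standard_normal(n_accessions), index=geno.accessions)
        scan = association.lmm_scan(geno, y, context=ctx)
        n_reject += int((scan.table["p"] < alpha).sum())
        n_total += scan.n_tests
    return n_reject / n_total


def mqtl_lead_recovery(
    n_reps: int = 50,
    n_accessions: int = 400,
    n_snps: int = 500,
    variance_explained: float = 0.2,
    seed: int = 0,
) -> float:
    """Fraction of replicates where a planted mQTL is its QTL's lead SNP.

    Each replicate plants one SNP explaining ``variance_explained`` of a
    metabolite's variance, scans with the mixed model at the reciprocal
    Bonferroni threshold, chains significant SNPs into QTLs, and scores
    success iff some QTL's lead SNP is exactly the planted SNP.
    """
    rng = np.random.default_rng(seed)
    geno = simulate.generate_genotypes(
        n_accessions=n_accessions, n_snps=n_snps, seed=int(rng.integers(2**31))
    )
    geno = association.maf_filter(geno)
    K = association.kinship(geno)
    ctx = association.LmmContext.build(geno, K)
    threshold = association.bonferroni_threshold(geno.n_snps)
    snp_ids = list(geno.snp_map.table["snp_id"])
    hits = 0
    for rep in range(n_reps):
        planted = snp_ids[int(rng.integers(geno.n_snps))]
        g = geno.dosages[planted].to_numpy(dtype=float)
        g = g - g.mean()
        vg = g.var()
        if vg == 0:
            continue
        # scale so the SNP explains the requested variance fraction
        ve = vg * (1.0 - variance_explained) / variance_explained
        y = g + rng.normal(0.0, np.sqrt(ve), n_accessions)
        scan = association.lmm_scan(
            geno, pd.Series(y, index=geno.accessions),
            context=ctx, threshold=threshold, phenotype_id=f"rep{rep}",
        )
        qtls = association.cluster_qtls(scan)
        if any(q.lead_snp == planted for q in qtls):
            hits += 1
    return hits / n_reps


def module_recovery_ari(
    n_reps: int = 25,
    n_accessions: int = 100,
    n_block_genes: int = 50,
    n_noise_genes: int = 20,
    within_cor: float = 0.8,
    seed: int = 0,
) -> float:
    """Median adjusted Rand index of module detection on two planted blocks.

    Each replicate simulates two blocks of ``n_block_genes`` genes with
    within-block correlation ``within_cor`` and zero between-block
    correlation, plus independent noise genes; modules are detected from
    the TOM of the soft-thresholded adjacency and compared with the
    planted labels (over the planted genes) by ARI.
    """
    rng = np.random.default_rng(seed)
    aris = []
    for _ in range(n_reps):
        geno = simulate.generate_genotypes(
            n_accessions=n_accessions, n_snps=20, n_chromosomes=2,
            seed=int(rng.integers(2**31)),
        )
        truth = TruthTable()
        n_genes = 2 * n_block_genes + n_noise_genes
        gene_ids = [f"gene{j:05d}" for j in range(n_genes)]
        for j in range(n_block_genes):
            truth.planted_modules[gene_ids[j]] = 1
            truth.planted_modules[gene_ids[n_block_genes + j]] = 2
        expr = simulate.generate_expression(
            geno, truth, n_genes=n_genes,
            module_weight=float(np.sqrt(within_cor)),
            seed=int(rng.integers(2**31)),
        )
        adj = coexpression.soft_adjacency(expr, beta=6)
        tom = coexpression.tom_similarity(adj)
        modules = coexpression.detect_modules(tom, min_module_size=30)
        planted = pd.Series(truth.planted_modules)
        detected = modules.labels.reindex(planted.index)
        aris.append(adjusted_rand_score(planted.to_numpy(), detected.to_numpy()))
    return float(np.median(aris))


def network_link_recovery(
    n_reps: int = 10,
    n_accessions: int = 300,
    n_snps: int = 600,
    n_metabolites: int = 30,
    n_genes: int = 100,
    n_shared_loci: int = 5,
    seed: int = 0,
) -> float:
    """Median fraction of planted metabolite-gene links appearing as
    metabolite-QTL-gene paths in the triple network.

    Each replicate plants ``n_shared_loci`` loci where a metabolite's mQTL
    and a gene's cis-eQTL share a SNP, runs the full chain exactly as the
    pipeline does (mGWAS on markers, mTWAS, eGWAS on mTWAS-significant
    genes, network assembly), and measures recovery against the truth.
    """
    rng = np.random.default_rng(seed)
    fractions = []
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2**31))
        geno = simulate.generate_genotypes(
            n_accessions=n_accessions, n_snps=n_snps, seed=rep_seed
        )
        truth = simulate.default_truth(
            geno, n_metabolites=n_metabolites, n_genes=n_genes,
            n_marker_metabolites=10, n_shared_loci=n_shared_loci,
            n_hotspot_metabolites=0, n_modules=2, module_size=20,
            mqtl_effect=1.0, eqtl_effect=1.2, seed=rep_seed + 1,
        )
        panels = simulate.generate_metabolome(
            geno, truth, n_metabolites=n_metabolites, seed=rep_seed + 2
        )
        expr = simulate.generate_expression(
            geno, truth, n_genes=n_genes, seed=rep_seed + 3
        )
        geno_f = association.maf_filter(geno)
        K = association.kinship(geno_f)
        ctx = association.LmmContext.build(geno_f, K)
        thr = association.bonferroni_threshold(geno_f.n_snps)

        planted_mets = sorted({m for m, _, _ in truth.planted_mqtl})
        mqtls = {}
        for met in planted_mets:
            scan = association.lmm_scan(
                geno_f, panels[0].abundances[met], context=ctx,
                phenotype_id=met, threshold=thr,
            )
            qtls = association.cluster_qtls(scan)
            if qtls:
                mqtls[met] = qtls
        mtwas_results = twas.mtwas_scan(
            expr, panels[0], marker_metabolites=planted_mets,
            threshold=1.0 / n_genes,
        )
        sig_genes = sorted(set(mtwas_results.loc[mtwas_results["significant"], "gene"]))
        eqtls = {}
        for gene in sig_genes:
            scan = association.lmm_scan(
                geno_f, expr.expression[gene], context=ctx,
                phenotype_id=gene, threshold=thr,
            )
            qtls = association.cluster_qtls(scan)
            if qtls:
                eqtls[gene] = qtls
        G = network.build_triple_network(mqtls, eqtls, mtwas_results)
        paths = network.metabolite_qtl_gene_paths(G)
        planted_links = set()
        snp_to_mets = {}
        for met, snp, _ in truth.planted_mqtl:
            snp_to_mets.setdefault(snp, set()).add(met)
        for gene, snp, _, _ in truth.planted_eqtl:
            for met in snp_to_mets.get(snp, ()):
                planted_links.add((met, gene))
        fractions.append(
            len(planted_links & paths) / len(planted_links) if planted_links else np.nan
        )
    return float(np.nanmedian(fractions))


def prediction_contrast(
    n_reps: int = 9,
    n_accessions: int = 300,
    n_snps: int = 400,
    n_peak_snps: int = 6,
    variance_explained: float = 0.5,
    baseline_repeats: int = 100,
    seed: int = 0,
) -> dict:
    """Peak-SNP vs random-SNP prediction contrast on planted-signal panels.

    Each replicate plants ``n_peak_snps`` SNPs jointly explaining
    ``variance_explained`` of the oil-content trait, discretizes accessions
    into low/medium/high by K-means, and compares the per-class test AUC of
    a forest on the peak SNPs against the mean AUC of forests on
    ``baseline_repeats`` random SNP draws.  Returns per-class medians of
    the peak AUC, baseline AUC, and their difference.
    """
    rng = np.random.default_rng(seed)
    peak_aucs: dict[str, list] = {}
    base_aucs: dict[str, list] = {}
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2**31))
        geno = simulate.generate_genotypes(
            n_accessions=n_accessions, n_snps=n_snps, seed=rep_seed
        )
        snps = list(geno.snp_map.table["snp_id"])
        peak = [snps[int(i)] for i in np.linspace(5, len(snps) - 5, n_peak_snps).round()]
        X = geno.dosages[peak].to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        beta = rng.choice([-1.0, 1.0], n_peak_snps)
        gsig = Xc @ beta
        vg = gsig.var()
        ve = vg * (1.0 - variance_explained) / variance_explained
        soc_vals = 40.0 + 3.0 * (gsig + rng.normal(0, np.sqrt(ve), n_accessions)) / np.sqrt(vg + ve)
        soc = TraitTable(
            pd.DataFrame(
                {f"env{e + 1}": soc_vals + rng.normal(0, 0.5, n_accessions) for e in range(5)},
                index=geno.accessions,
            )
        )
        rep = prediction.prediction_experiment(
            geno, soc, peak, baseline_repeats=baseline_repeats, seed=rep_seed
        )
        for cls in rep.peak_auc:
            peak_aucs.setdefault(cls, []).append(rep.peak_auc[cls])
            base_aucs.setdefault(cls, []).append(rep.baseline_auc[cls])
    out = {}
    for cls in peak_aucs:
        pk = float(np.nanmedian(peak_aucs[cls]))
        bs = float(np.nanmedian(base_aucs[cls]))
        gap = float(
            np.nanmedian(np.asarray(peak_aucs[cls]) - np.asarray(base_aucs[cls]))
        )
        out[cls] = {"peak_auc": pk, "baseline_auc": bs, "gap": gap}
    return out


def heritability_recovery(
    n_reps: int = 50,
    n_accessions: int = 388,
    h2_target: float = 0.7,
    seed: int = 0,
) -> float:
    """Median broad-sense heritability estimate at a planted target.

    Each replicate simulates a two-year metabolite with H2 = ``h2_target``
    and re-estimates it with the one-way variance-component estimator.
    """
    rng = np.random.default_rng(seed)
    geno = simulate.generate_genotypes(
        n_accessions=n_accessions, n_snps=20, n_chromosomes=2,
        seed=int(rng.integers(2**31)),
    )
    estimates = []
    for _ in range(n_reps):
        truth = TruthTable(h2_target={"met0000": h2_target})
        panels = simulate.generate_metabolome(
            geno, truth, n_metabolites=1, seed=int(rng.integers(2**31))
        )
        res = metabolome.broad_sense_heritability(panels)
        estimates.append(float(res.loc["met0000", "H2"]))
    return float(np.median(estimates))
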