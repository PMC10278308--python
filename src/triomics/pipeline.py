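"""Configuration and end-to-end orchestration.

:class:`PipelineConfig` collects every analysis threshold in one serializable
object — the marker-selection and network correlation cutoffs, the MAF
filter, the LD-block window, the Bonferroni convention, the co-expression
power and module size, the hotspot rule, and the prediction hyperparameters —
with defaults matching the study design.

:func:`run_pipeline` chains the stages (simulate -> metabolome -> mGWAS ->
mTWAS -> eGWAS -> co-expression -> triple network -> prediction) on either
simulated or user-supplied inputs, writes every stage output as TSV/GraphML
into a run directory, and records a manifest of SHA-256 hashes so a rerun
with the same config and seed is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import association, coexpression, io, metabolome, network, prediction, simulate, twas
from .datatypes import GenotypeMatrix, TruthTable

logger = logging.getLogger("triomics")


@dataclass
class PipelineConfig:
    # thresholds from the study design
    r_marker: float = 0.2
    r_network: float = 0.35
    maf_min: float = 0.05
    qtl_window_bp: int = 100_000
    bonferroni_convention: str = "reciprocal"
    beta: float = 6.0
    min_module_size: int = 30
    hotspot_min: int = 10  # strict: hotspot iff detected by > hotspot_min phenotypes
    cis_window_bp: int = 1_000_000
    k_levels: int = 3
    kmeans_random_state: int = 2
    rf_n_estimators: int = 300
    rf_max_features: int = 3
    baseline_repeats: int = 100
    split_ratio: float = 2.0
    n_peak_snps: int = 6
    seed: int = 0
    # synthetic-data scale (desk-scale defaults preserving the study ratios)
    n_accessions: int = simulate.DEFAULT_N_ACCESSIONS
    n_snps: int = simulate.DEFAULT_N_SNPS
    n_chromosomes: int = simulate.DEFAULT_N_CHROMOSOMES
    n_metabolites: int = simulate.DEFAULT_N_METABOLITES
    n_genes: int = simulate.DEFAULT_N_GENES
    n_years: int = simulate.DEFAULT_N_YEARS
    n_environments: int = simulate.DEFAULT_N_ENVIRONMENTS

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    outdir,
    simulate_inputs: bool = True,
    genotype_paths: tuple | None = None,
    run_prediction: bool = True,
) -> dict:
    """Run the full chain and return a summary dict (also written to disk).

    With ``simulate_inputs=True`` the synthetic generators produce all
    inputs under the configured scale and the planted truth is saved next
    to the outputs.  Otherwise ``genotype_paths`` etc. must point at the
    TSV inputs (not yet wired for every stage; the simulated route is the
    primary entry point).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_path = outdir / "config.yaml"
    config.to_yaml(cfg_path)

    if not simulate_inputs:
        raise NotImplementedError(
            "external-input orchestration is limited to the io readers; "
            "call the stage functions directly for custom data"
        )

    # --- stage 1: simulate -------------------------------------------------
    geno = simulate.generate_genotypes(
        n_accessions=config.n_accessions,
        n_snps=config.n_snps,
        n_chromosomes=config.n_chromosomes,
        seed=config.seed,
    )
    truth = simulate.default_truth(
        geno,
        n_metabolites=config.n_metabolites,
        n_genes=config.n_genes,
        seed=config.seed + 1,
    )
    panels = simulate.generate_metabolome(
        geno, truth, n_metabolites=config.n_metabolites,
        n_years=config.n_years, seed=config.seed + 2,
    )
    expr = simulate.generate_expression(
        geno, truth, n_genes=config.n_genes, seed=config.seed + 3,
        cis_window_bp=config.cis_window_bp,
    )
    trait = simulate.generate_trait(
        panels, expr, truth, n_environments=config.n_environments,
        seed=config.seed + 4,
    )
    io.write_genotypes_tsv(geno, outdir / "genotypes.tsv", outdir / "snp_map.tsv")
    for panel in panels:
        io.write_metabolites_tsv(
            panel, outdir / f"metabolites_{panel.year}.tsv",
            outdir / "metabolite_classes.tsv",
        )
    io.write_expression_tsv(expr, outdir / "expression.tsv", outdir / "gene_map.tsv")
    io.write_trait_tsv(trait, outdir / "trait.tsv")
    io.write_truth_tsv(truth, outdir / "truth.tsv")
    logger.info("simulated %d accessions, %d SNPs, %d metabolites, %d genes",
                geno.n_accessions, geno.n_snps, config.n_metabolites, config.n_genes)

    # --- stage 2: metabolome ----------------------------------------------
    herit = metabolome.broad_sense_heritability(panels)
    herit.to_csv(outdir / "heritability.tsv", sep="\t")
    soc_mean = trait.mean_across_environments()
    markers = metabolome.select_marker_metabolites(
        panels[0], soc_mean, r_threshold=config.r_marker
    )
    markers.to_csv(outdir / "marker_metabolites.tsv", sep="\t")
    marker_ids = list(markers.index[markers["selected"]])
    net_edges = metabolome.correlation_network(
        panels[0], soc_mean, r_threshold=config.r_network
    )
    net_edges.to_csv(outdir / "metabolite_network.tsv", sep="\t", index=False)
    logger.info("selected %d marker metabolites (|r| > %.2f)",
                len(marker_ids), config.r_marker)

    # --- stage 3: mGWAS ----------------------------------------------------
    geno_f = association.maf_filter(geno, config.maf_min)
    K = association.kinship(geno_f)
    ctx = association.LmmContext.build(geno_f, K)
    gwas_threshold = association.bonferroni_threshold(
        geno_f.n_snps, config.bonferroni_convention
    )
    mqtls: dict[str, list] = {}
    for met in marker_ids:
        scan = association.lmm_scan(
            geno_f, panels[0].abundances[met], context=ctx,
            phenotype_id=met, threshold=gwas_threshold,
        )
        qtls = association.cluster_qtls(scan, window_bp=config.qtl_window_bp)
        association.annotate_lead_positions(qtls, geno_f.snp_map)
        if qtls:
            mqtls[met] = qtls
    hotspots = association.detect_hotspots(
        mqtls, window_bp=config.qtl_window_bp, min_phenotypes=config.hotspot_min
    )
    n_mqtl = sum(len(v) for v in mqtls.values())
    logger.info("mGWAS: %d SNPs after MAF filter, %d mQTLs, %d hotspots",
                geno_f.n_snps, n_mqtl, len(hotspots))

    # --- stage 4: mTWAS ----------------------------------------------------
    mtwas_threshold = association.bonferroni_threshold(
        expr.expression.shape[1], config.bonferroni_convention
    )
    mtwas_results = twas.mtwas_scan(
        expr, panels[0], marker_metabolites=marker_ids, threshold=mtwas_threshold
    )
    mtwas_results.to_csv(outdir / "mtwas.tsv", sep="\t", index=False)
    gene_hits = twas.summarize_gene_hits(mtwas_results)
    sig_genes = sorted(set(mtwas_results.loc[mtwas_results["significant"], "gene"]))
    logger.info("mTWAS: %d significant pairs over %d genes",
                int(mtwas_results["significant"].sum()), len(sig_genes))

    # --- stage 5: eGWAS on mTWAS-significant genes -------------------------
    eqtls: dict[str, list] = {}
    eqtl_rows = []
    for gene in sig_genes:
        scan = association.lmm_scan(
            geno_f, expr.expression[gene], context=ctx,
            phenotype_id=gene, threshold=gwas_threshold,
        )
        qtls = association.cluster_qtls(scan, window_bp=config.qtl_window_bp)
        association.annotate_lead_positions(qtls, geno_f.snp_map)
        if qtls:
            eqtls[gene] = qtls
            entry = expr.gene_entry(gene)
            for q in qtls:
                eqtl_rows.append(
                    (gene, q.qtl_id, q.chromosome, q.start, q.end, q.lead_snp,
                     q.lead_p,
                     association.classify_eqtl(q, entry, config.cis_window_bp))
                )
    pd.DataFrame(
        eqtl_rows,
        columns=["gene", "qtl_id", "chromosome", "start", "end",
                 "lead_snp", "lead_p", "regulation_class"],
    ).to_csv(outdir / "eqtls.tsv", sep="\t", index=False)
    logger.info("eGWAS: %d genes with eQTLs", len(eqtls))

    # --- stage 6: co-expression modules ------------------------------------
    adj = coexpression.soft_adjacency(expr, beta=config.beta)
    tom = coexpression.tom_similarity(adj)
    modules = coexpression.detect_modules(
        tom, min_module_size=config.min_module_size, beta=config.beta
    )
    modules.labels.rename("module").to_csv(outdir / "modules.tsv", sep="\t",
                                           index_label="gene")
    eig = coexpression.module_eigengene(expr, modules)
    eig.to_csv(outdir / "eigengenes.tsv", sep="\t", index_label="accession")
    targets = panels[0].abundances[marker_ids].copy()
    targets["SOC"] = soc_mean
    module_trait = coexpression.module_trait_correlation(eig, targets)
    module_trait.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
    logger.info("co-expression: %d modules", int((modules.labels.max() or 0)))

    # --- stage 7: triple network -------------------------------------------
    G = network.build_triple_network(
        mqtls, eqtls, mtwas_results, modules.labels, window_bp=config.qtl_window_bp
    )
    network.export_graph(G, outdir / "triple_network.graphml", fmt="graphml")
    network.export_graph(G, outdir / "triple_network.tsv", fmt="edge-tsv")
    candidates = network.prioritize_candidates(G, module_trait)
    candidates.to_csv(outdir / "candidate_genes.tsv", sep="\t", index=False)
    summary_net = network.network_summary(G)
    logger.info("triple network: %d nodes, %d edges",
                summary_net["n_nodes"], summary_net["n_edges"])

    # --- stage 8: prediction -----------------------------------------------
    report = None
    if run_prediction:
        peak_snps = _peak_snps(mqtls, eqtls, config.n_peak_snps)
        if len(peak_snps) >= 2:
            rep = prediction.prediction_experiment(
                geno_f, trait, peak_snps,
                n_estimators=config.rf_n_estimators,
                max_features=config.rf_max_features,
                baseline_repeats=config.baseline_repeats,
                split_ratio=config.split_ratio,
                kmeans_random_state=config.kmeans_random_state,
                seed=config.seed + 5,
            )
            report = {
                "peak_snps": peak_snps,
                "peak_auc": rep.peak_auc,
                "baseline_auc": rep.baseline_auc,
                "n_train": rep.n_train,
                "n_test": rep.n_test,
            }
            with open(outdir / "prediction.json", "w") as fh:
                json.dump(report, fh, indent=2)
            logger.info("prediction: peak AUC %s vs baseline %s",
                        rep.peak_auc, rep.baseline_auc)

    summary = {
        "n_accessions": geno.n_accessions,
        "n_snps_after_maf": geno_f.n_snps,
        "n_marker_metabolites": len(marker_ids),
        "n_mqtls": n_mqtl,
        "n_hotspots": len(hotspots),
        "n_mtwas_pairs": int(mtwas_results["significant"].sum()),
        "n_egwas_genes": len(eqtls),
        "n_modules": int(modules.labels.max() or 0),
        "network": summary_net,
        "prediction": report,
        "max_gene_hits": int(gene_hits.max()) if len(gene_hits) else 0,
        "heritability_mean": float(herit["H2"].mean()),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    manifest = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary


def _peak_snps(mqtls: dict, eqtls: dict, n_peaks: int) -> list[str]:
    """Lead SNPs of the most significant co-localized mQTLs (distinct loci)."""
    mq_all = [q for qs in mqtls.values() for q in qs]
    eq_all = [q for qs in eqtls.values() for q in qs]
    coloc_ids = {a for a, _ in association.colocalize(mq_all, eq_all)}
    ranked = sorted(
        (q for q in mq_all if q.qtl_id in coloc_ids),
        key=lambda q: q.lead_p,
    )
    if not ranked:  # fall back to the strongest mQTLs overall
        ranked = sorted(mq_all, key=lambda q: q.lead_p)
    peaks: list[str] = []
    for q in ranked:
        if q.lead_snp not in peaks:
            peaks.append(q.lead_snp)
        if len(peaks) == n_peaks:
            break
    return peaks
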