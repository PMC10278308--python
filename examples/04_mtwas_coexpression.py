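"""mTWAS and co-expression modules.

Regresses every marker metabolite on every gene's expression (significance
at the strict 1/N_genes rule), then finds WGCNA-style modules from the
soft-thresholded (beta = 6) topological overlap and correlates module
eigengenes with the trait and the markers.
"""

import triomics as t

geno = t.simulate.generate_genotypes(n_accessions=300, n_snps=400, seed=1)
truth = t.simulate.default_truth(geno, n_metabolites=60, n_genes=300,
                                 n_marker_metabolites=15, n_modules=4,
                                 module_size=50, seed=2)
panels = t.simulate.generate_metabolome(geno, truth, n_metabolites=60, seed=3)
expr = t.simulate.generate_expression(geno, truth, n_genes=300, seed=4)
trait = t.simulate.generate_trait(panels, expr, truth, seed=5)

marker_ids = sorted({m for m, _, _ in truth.planted_mqtl}
                    | {m for m in truth.trait_weights if m.startswith("met")})
res = t.twas.mtwas_scan(expr, panels[0], marker_metabolites=marker_ids)
print(f"mTWAS: {int(res['significant'].sum())} significant gene-metabolite "
      f"pairs at p < 1/{expr.expression.shape[1]}")
hits = t.twas.summarize_gene_hits(res)
print(f"top gene {hits.idxmax()} associated with {hits.max()} metabolites")

adj = t.coexpression.soft_adjacency(expr, beta=6)
tom = t.coexpression.tom_similarity(adj)
modules = t.coexpression.detect_modules(tom, min_module_size=30)
print(f"modules: {modules.labels.max()} detected, sizes "
      f"{modules.sizes().to_dict()}")
eig = t.coexpression.module_eigengene(expr, modules)
targets = panels[0].abundances[marker_ids].copy()
targets["SOC"] = trait.mean_across_environments()
mt = t.coexpression.module_trait_correlation(eig, targets)
soc_rows = mt.loc[(mt["target"] == "SOC") & mt["significant"]]
for row in soc_rows.itertuples(index=False):
    print(f"{row.module} vs SOC: r = {row.r:.2f}, p = {row.p:.2e}")
# Modules whose eigengene tracks SOC are the co-expression neighborhoods the
# candidate-gene ranking later rewards.
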