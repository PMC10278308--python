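"""Simulate a complete study panel with planted, recorded ground truth.

Generates a diversity panel (accessions x SNPs in 100-kb LD blocks), a
two-year seed metabolome with controlled heritability, a seed transcriptome
with planted modules and eQTLs, and a multi-environment seed-oil-content
trait driven by a subset of the metabolites.
"""

import triomics as t

geno = t.simulate.generate_genotypes(n_accessions=400, n_snps=2000, seed=1)
truth = t.simulate.default_truth(geno, seed=2)
panels = t.simulate.generate_metabolome(geno, truth, seed=3)
expr = t.simulate.generate_expression(geno, truth, seed=4)
trait = t.simulate.generate_trait(panels, expr, truth, seed=5)

print(f"genotypes : {geno.n_accessions} accessions x {geno.n_snps} SNPs, "
      f"MAF in [{geno.maf().min():.3f}, {geno.maf().max():.3f}]")
print(f"metabolome: {len(panels)} years x {panels[0].abundances.shape[1]} metabolites "
      f"(log2 scale)")
print(f"expression: {expr.expression.shape[1]} genes, "
      f"{len(set(truth.planted_modules.values()))} planted modules")
print(f"trait     : SOC over {trait.values.shape[1]} environments, "
      f"mean {trait.values.mean().mean():.1f}%")
print(f"planted   : {len(truth.planted_mqtl)} mQTL effects, "
      f"{len(truth.planted_eqtl)} eQTL effects, "
      f"{len(truth.trait_weights)} trait weights")
# The truth table is the closed oracle every downstream recovery is scored
# against; nothing else in the pipeline sees it.
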