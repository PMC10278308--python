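"""Screen marker metabolites: heritability, trait correlation, enrichment.

Selects metabolites whose log2 abundance correlates with seed oil content
beyond |r| > 0.2, estimates each metabolite's broad-sense heritability from
the two-year replication, and tests whether a compound class is
over-represented among the markers with an exact hypergeometric tail.
"""

import triomics as t

geno = t.simulate.generate_genotypes(n_accessions=388, n_snps=200, seed=1)
truth = t.simulate.default_truth(geno, n_genes=100, n_marker_metabolites=30, seed=2)
panels = t.simulate.generate_metabolome(geno, truth, seed=3)
expr = t.simulate.generate_expression(geno, truth, n_genes=100, seed=9)
trait = t.simulate.generate_trait(panels, expr, truth, seed=4)
soc = trait.mean_across_environments()

herit = t.metabolome.broad_sense_heritability(panels)
markers = t.metabolome.select_marker_metabolites(panels[0], soc, r_threshold=0.2)
sel = markers.loc[markers["selected"]]
print(f"H2 over all metabolites: mean {herit['H2'].mean():.2f} "
      f"(range {herit['H2'].min():.2f}-{herit['H2'].max():.2f})")
print(f"marker metabolites (|r| > 0.2): {len(sel)} "
      f"({(sel['sign'] == 'positive').sum()} positive, "
      f"{(sel['sign'] == 'negative').sum()} negative)")
print(f"markers are more heritable: {herit.loc[sel.index, 'H2'].mean():.2f} "
      f"vs {herit['H2'].mean():.2f} overall")

panel = panels[0]
p = t.metabolome.class_enrichment(
    panel.classes, panel.metabolites, sel.index, "flavonoid"
)
n_flav = (panel.classes.loc[sel.index] == "flavonoid").sum()
print(f"flavonoid enrichment among markers: {n_flav}/{len(sel)} hits, P = {p:.3g}")

edges = t.metabolome.correlation_network(panel, soc, r_threshold=0.35)
print(f"correlation network (|r| > 0.35): {len(edges)} edges, "
      f"{int(edges['is_trait_edge'].sum())} SOC-metabolite edges")
# Markers inherit the trait's genetics, so their H2 sits above the panel
# average — the pattern that motivates using them as intermediate phenotypes.
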