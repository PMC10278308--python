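"""Predict oil-content level from peak SNPs, against a random-SNP null.

Accessions are discretized into low/medium/high SOC classes by K-means
(k = 3), split 2:1 stratified, and classified by a random forest
(300 trees, 3 features per split) on six planted peak SNPs.  The same
forest on random SNP draws (100 repeats) provides the null contrast.
"""

import numpy as np
import pandas as pd
import triomics as t

rng = np.random.default_rng(7)
geno = t.simulate.generate_genotypes(n_accessions=300, n_snps=400, seed=7)
snps = list(geno.snp_map.table["snp_id"])
peak = [snps[int(i)] for i in np.linspace(5, len(snps) - 5, 6).round()]
X = geno.dosages[peak].to_numpy(float)
gsig = (X - X.mean(0)) @ rng.choice([-1.0, 1.0], 6)
noise = rng.normal(0, gsig.std(), 300)  # peak SNPs explain ~50% of variance
soc_vals = 40 + 3 * (gsig + noise) / np.std(gsig + noise)
soc = t.TraitTable(pd.DataFrame(
    {f"env{e}": soc_vals + rng.normal(0, 0.5, 300) for e in range(1, 6)},
    index=geno.accessions))

report = t.prediction.prediction_experiment(
    geno, soc, peak, baseline_repeats=100, seed=7)
print(f"train/test: {report.n_train}/{report.n_test} accessions (2:1, stratified)")
for cls in ("low", "medium", "high"):
    print(f"{cls:>6}: peak-SNP AUC {report.peak_auc[cls]:.2f}  "
          f"random-SNP mean AUC {report.baseline_auc[cls]:.2f}")
# Peak SNPs separate the extreme classes well above the ~0.5 random-SNP
# null; the medium class, squeezed between both boundaries, is hardest —
# the same ordering the marker-assisted-selection use case cares about.
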