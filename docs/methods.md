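# Methods

This note documents the statistical procedures, the synthetic-data model,
the defaults and why they were chosen, and what the test suite does and
does not establish about behavior on real data.

## Mixed-model association scan

The scan implements the single-spectral-decomposition linear mixed model:
for phenotype y (a metabolite's log2 abundance, a gene's expression, or the
trait itself),

    y = 1·b0 + g·b + u + e,   u ~ N(0, σg² K),   e ~ N(0, σe² I),

with K the VanRaden-standardized genomic relationship matrix
Z Z'/m, Z_ij = (x_ij − 2p_j)/√(2p_j(1−p_j)).  K is eigendecomposed once
per panel (`LmmContext`); the ratio δ = σe²/σg² is fitted once on the
intercept-only model by bounded maximum likelihood over log10 δ ∈ [−5, 5];
each SNP is then tested by weighted least squares on the rotated data with
a Wald t-test on n − 2 degrees of freedom, the residual variance
re-estimated per SNP.  Fitting δ once on the null rather than per SNP is
the standard fast approximation; with K = I the procedure collapses
exactly to per-SNP ordinary least squares (asserted to 1e−8 in the tests).
Constant (monomorphic) SNPs receive p = 1 with se = ∞ as a flag.
Population-structure covariates beyond K are deliberately absent; the
kinship term absorbs relatedness, and the calibration experiment
(realized type-I error ≈ 0.05 on LD-structured null panels) is the check
that this suffices for the simulated design.

**Thresholds.** The genome-wide and transcriptome-wide significance
thresholds use the *reciprocal* convention 1/N_tests (1/8,274,830 ≈
1.2e−7 for the SNP panel; 1/70,781 ≈ 1.41e−5 for the gene set), which is
the convention the reported thresholds follow; α/N is available as an
option.

## QTL clustering, hotspots, co-localization

True LD-block boundaries for the panel are not available, so blocks are
approximated by fixed-distance chaining: significant SNPs on a chromosome
belong to one QTL iff connected by successive gaps ≤ 100 kb
(single linkage).  The lead SNP is the minimum-p member, ties broken to
the lower coordinate.  Hotspots merge QTLs across phenotypes with the same
chaining rule and require strictly more than 10 distinct phenotypes.
mQTL–eQTL co-localization pairs intervals on the same chromosome with gap
≤ 100 kb (overlap ⇒ gap 0).  cis/trans eQTL classification uses the lead
SNP's distance to the gene body with a 1-Mb window — a conventional choice,
configurable, as no window is standard across studies.

## Heritability

Broad-sense heritability per metabolite uses a one-way random-effects
decomposition with accession as the group and year as the replicate:
MS_between = r·Var(accession means), MS_within = pooled within-accession
variance, V_g = max(0, (MS_between − MS_within)/r), V_e = MS_within,
H² = V_g/(V_g + V_e) clipped to [0, 1].  In an inbred-line panel the
between-accession variance is total genetic variance, so the intraclass
correlation is a broad-sense estimate.  Zero-variance metabolites get
H² = 0 with a warning.  An entry-mean basis (dividing V_e by r) was not
used; the choice is documented here because the replicate basis is the
more conservative of the two defensible conventions.

## Marker metabolites and enrichment

Selection is strict |r| > 0.2 (Pearson, pairwise-complete, metabolites
with < 50% presence dropped).  Trait values pair with the matched-year
panel by default; a mean-across-environments reduction is what the
pipeline passes.  Class enrichment is the exact hypergeometric upper tail
P(X ≥ k) with N the universe, K the class members, n the hits — no normal
approximation; the tests verify it against full pmf enumeration for small
N.  The correlation network uses strict |r| > 0.35 with trait–metabolite
edges flagged.

## mTWAS

Per (gene, metabolite) simple linear regression; the two-sided slope
p-value is computed from the Pearson correlation
(t = r√(n−2)/√(1−r²)), which is identical whichever variable is treated
as the response — asserted as a test.  Significance is strict
p < 1/N_genes; no additional multiple-testing correction is applied
because the reciprocal rule *is* the correction in this design (an FDR
option exists but is off).

## Co-expression modules

Unsigned adjacency a_ij = |cor|^β with β = 6 (signed available),
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), average-linkage
hierarchical clustering of 1 − TOM with a *static* cut at 0.995 of the
merge-height range — a documented simplification of the dynamic hybrid
tree cut; clusters below 30 genes are unassigned (label 0) and modules are
renumbered by size.  Eigengenes are unit-variance first principal
components of the standardized module submatrix, oriented so the mean
correlation with member genes is non-negative.  Module–target p-values use
the exact t transform (n − 2 df), cross-checked against a permutation null
in the tests.  Whether co-expression should run on all genes or only
mTWAS-significant genes is ambiguous in the source design; both entry
points work (`soft_adjacency` takes any `ExpressionMatrix`), and the
pipeline default uses all genes.

## Triple network and candidate ranking

QTL nodes exist only where an mQTL and an eQTL co-localize; co-localized
pairs sharing a contributing QTL merge into one locus (union-find) whose
coordinates are the union interval.  Both counting conventions — raw
co-localized pairs and merged loci — are reported, since "QTLs detected
simultaneously" can be read either way.  Candidate genes require ≥ 1
co-localized QTL and ≥ 1 significant mTWAS pair and are ranked
lexicographically by (distinct marker metabolites, supporting QTLs,
membership in a trait-significant module): a transparent, reproducible
substitute for manual functional-annotation filtering, which is outside
scope.

## Prediction

Mean SOC across environments is discretized by K-means (k = 3,
random_state = 2) into low/medium/high by ascending centroid; the split is
2:1 stratified by level (the per-class train/test counts of the original
design imply stratification; the seed is exposed).  The forest uses
n_estimators = 300 and max_features = 3 (features considered per split).
AUC is one-vs-rest per class from class probabilities, midrank ties
(equivalently the Mann–Whitney concordance, asserted on small instances).
The null draws 6 random SNPs without replacement, excluding the peak set,
100 times; note random draws can land in LD with causal blocks, so the
null mean can sit slightly above 0.5.

## Synthetic-data model

*Genotypes.* Per chromosome, SNP positions are jittered ~5-kb steps; per
100-kb block a latent Gaussian with kernel exp(−d/L), L = block_bp/3, is
drawn independently for two haplotypes per accession and thresholded at
each SNP's allele-frequency quantile (frequencies uniform in the MAF
range).  Blocks are independent, so between-block r² is ~0 while
within-block r² decays with distance (mean ≈ 0.1 at the default decay).
This is the simplest mechanism producing block LD; it does not model
population structure, admixture, or missingness.

*Metabolome.* Metabolite = baseline + planted SNP effects + accession
random effect (topped up so genetic variance ≥ 1) + Gaussian year noise
with variance V_g(1 − h²)/h², giving realized H² ≈ the target (recovered
within ±0.1 at n = 388).  The Gaussian-on-log2 noise model is a stand-in:
the actual quantification noise of LC–MS abundances is not specified
anywhere and real panels will have heavier tails and missingness.

*Expression.* Module genes load weight w on a shared latent factor
(within-module correlation ≈ w²; default w = 0.78); planted eQTL effects
add on top; cis-eQTL genes are placed next to their SNP so the distance
rule holds by construction.

*Trait.* SOC (percent) = 40 + Σ weights · standardized feature values +
per-environment Gaussian noise, so each planted weight's sign equals the
expected trait correlation sign.  The default planted design
(`default_truth`) sets 80% of marker-metabolite weights negative, echoing
the observed predominance of negatively oil-correlated metabolites, and
plants: shared metabolite/gene loci (the network's recovery targets), one
pleiotropic hotspot, six co-expression modules, and high (0.8)
heritability for markers.

**What passing tests show, and don't.** Recovery and calibration results
hold under this generator: Gaussian noise, independent LD blocks, no
structure, no missing data, additive effects.  They demonstrate the
correctness of the machinery and its behavior at realistic effect sizes,
not performance under confounding, non-additive architecture, or assay
artifacts present in real panels.

## Problem sizes

Desk-scale defaults preserve the study's ratios: 400 accessions, 2,000
SNPs on 4 chromosomes, 200 metabolites, 1,000 genes, 2 years, 5
environments.  The calibration/recovery experiments in
`triomics.experiments` use: 400 × 500 panels with 200 null phenotypes for
type-I error; 50 replicates for mQTL lead recovery (20% variance SNP);
25 replicates for two-block module ARI; 10 replicates of the full
mini-chain for network-link recovery; and a median over 9 replicates for
the peak-vs-random prediction contrast (each replicate fits 101 forests of
300 trees, which dominates the runtime; 9 is the package's chosen balance
of stability against cost).

## Numerical notes and degenerate inputs

Eigenvalues of K clipped at 0; a 1e−10 jitter stabilizes the block
Cholesky for near-duplicate positions; p-values clipped away from exact 0;
constant SNPs/genes/metabolites are flagged or excluded with warnings
rather than propagating NaN; all-equal SOC makes K-means degenerate and is
an error; QTL lead ties break to the lower coordinate; module labels are
size-ordered so numbering is deterministic.  Coordinates are 1-based
inclusive everywhere (VCF convention).  All generators and the pipeline
are bit-reproducible for a fixed seed, verified via the run manifest.

## Known limitations

No imputation, structure/PC correction, conditional or multi-locus
models, fine-mapping, penalized TWAS, dynamic tree cut, GO enrichment, or
BLUP trait reduction (a mean across environments stands in).  The
headline counts of the motivating study (131 markers, 445 mQTLs, 139
modules, 21,000-edge network, AUC 0.61/0.54/0.72) depend on its deposited
data and are not reproduction targets; the package reproduces the
*procedures* and verifies them on planted truth.
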