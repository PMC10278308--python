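"""Generator contracts: determinism, allele frequencies, LD block structure,
heritability control, module correlation structure, and trait coupling."""

import numpy as np
import pandas as pd
import pytest

import triomics as t
from triomics.datatypes import TruthTable


def test_symmetric_allele_frequency_gives_mean_dosage_one():
    g = t.simulate.generate_genotypes(
        n_accessions=400, n_snps=1, n_chromosomes=1, maf_range=(0.5, 0.5), seed=3
    )
    mean = g.dosages.to_numpy().mean()
    # binomial(2, 0.5) mean 1.0; 3 sigma of the mean at n=400
    assert abs(mean - 1.0) < 3 * np.sqrt(0.5 / 400) + 0.05


def test_same_seed_identical_genotypes():
    a = t.simulate.generate_genotypes(n_accessions=50, n_snps=80, seed=7)
    b = t.simulate.generate_genotypes(n_accessions=50, n_snps=80, seed=7)
    pd.testing.assert_frame_equal(a.dosages, b.dosages)
    pd.testing.assert_frame_equal(a.snp_map.table, b.snp_map.table)


def test_within_block_ld_exceeds_between_block_ld():
    """Brute-force all-pairs r^2: within-block mean must exceed between-block."""
    g = t.simulate.generate_genotypes(
        n_accessions=400, n_snps=2000, n_chromosomes=4, block_bp=100_000, seed=5
    )
    X = g.dosages.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    R = np.corrcoef(X[:, keep], rowvar=False) ** 2
    tab = g.snp_map.table.loc[keep].reset_index(drop=True)
    block = tab["chromosome"].astype(str) + "_" + (tab["position"] // 100_000).astype(str)
    same_block = (block.to_numpy()[:, None] == block.to_numpy()[None, :])
    off_diag = ~np.eye(len(tab), dtype=bool)
    within = R[same_block & off_diag].mean()
    between = R[~same_block & off_diag].mean()
    assert within > 5 * between
    assert within > 0.05


def test_invalid_generator_arguments():
    with pytest.raises(ValueError):
        t.simulate.generate_genotypes(n_accessions=0, n_snps=10)
    with pytest.raises(ValueError):
        t.simulate.generate_genotypes(n_accessions=10, n_snps=10, maf_range=(0.0, 0.6))


def test_maf_respects_filter_bound_at_scale():
    g = t.simulate.generate_genotypes(
        n_accessions=400, n_snps=500, maf_range=(0.1, 0.5), seed=9
    )
    maf = g.maf()
    # sampling error around the drawn frequency; bound loosened accordingly
    assert (maf > 0.05).all()
    assert maf.max() <= 0.5


class TestMetabolome:
    def test_h2_one_means_no_year_noise(self, small_geno):
        truth = TruthTable(h2_target={f"met{j:04d}": 1.0 for j in range(5)})
        panels = t.simulate.generate_metabolome(
            small_geno, truth, n_metabolites=5, seed=1
        )
        pd.testing.assert_frame_equal(panels[0].abundances, panels[1].abundances)

    def test_h2_zero_means_no_between_year_correlation(self, small_geno):
        truth = TruthTable(h2_target={f"met{j:04d}": 0.0 for j in range(30)})
        panels = t.simulate.generate_metabolome(
            small_geno, truth, n_metabolites=30, seed=2
        )
        rs = [
            np.corrcoef(
                panels[0].abundances.iloc[:, j], panels[1].abundances.iloc[:, j]
            )[0, 1]
            for j in range(30)
        ]
        assert abs(np.mean(rs)) < 0.1

    def test_needs_replication(self, small_geno):
        with pytest.raises(ValueError):
            t.simulate.generate_metabolome(small_geno, TruthTable(), n_years=1)

    def test_h2_recovery(self):
        """H2 estimator recovers a planted 0.7 within 0.1 (median of reps)."""
        est = t.experiments.heritability_recovery(n_reps=15, h2_target=0.7, seed=4)
        assert abs(est - 0.7) < 0.1


class TestExpression:
    def test_within_module_correlation_exceeds_between(self, small_expr):
        X = small_expr.expression
        m1 = [f"gene{j:05d}" for j in range(0, 30, 2)]
        m2 = [f"gene{j:05d}" for j in range(1, 30, 2)]
        corr = X.corr().abs()
        within = np.mean(
            [corr.loc[a, b] for i, a in enumerate(m1) for b in m1[i + 1 :]]
        )
        between = np.mean([corr.loc[a, b] for a in m1 for b in m2])
        assert within > between + 0.2

    def test_no_structure_means_independence(self, small_geno):
        expr = t.simulate.generate_expression(
            small_geno, TruthTable(), n_genes=40, seed=5
        )
        corr = expr.expression.corr().to_numpy()
        off = corr[~np.eye(40, dtype=bool)]
        assert np.abs(off).mean() < 0.12

    def test_unknown_module_gene_rejected(self, small_geno):
        truth = TruthTable(planted_modules={"nonexistent": 1})
        with pytest.raises(ValueError):
            t.simulate.generate_expression(small_geno, truth, n_genes=10, seed=0)

    def test_planted_cis_eqtl_recovered_in_cis_window(self, small_geno):
        """Large-effect cis eQTL: the top associated SNP lies in the cis window."""
        snp = small_geno.snp_map.table["snp_id"].iloc[50]
        hits = 0
        reps = 10
        for rep in range(reps):
            truth = TruthTable(planted_eqtl=[("gene00000", snp, 1.5, True)])
            expr = t.simulate.generate_expression(
                small_geno, truth, n_genes=20, seed=100 + rep
            )
            K = t.association.kinship(small_geno)
            scan = t.association.lmm_scan(
                small_geno, expr.expression["gene00000"], K=K
            )
            top = scan.table.sort_values("p").iloc[0]
            entry = expr.gene_entry("gene00000")
            same_chrom = str(entry["chromosome"]) == str(top["chromosome"])
            dist = min(
                abs(int(top["position"]) - int(entry["start"])),
                abs(int(top["position"]) - int(entry["end"])),
            )
            if same_chrom and dist <= 1_000_000:
                hits += 1
        assert hits >= 0.9 * reps


class TestTrait:
    def test_single_metabolite_weight_one_no_noise(self, small_geno):
        truth = TruthTable(trait_weights={"met0000": 1.0})
        panels = t.simulate.generate_metabolome(small_geno, truth, n_metabolites=3, seed=6)
        trait = t.simulate.generate_trait(panels, None, truth, noise_sd=0.0, seed=7)
        met_mean = sum(p.abundances["met0000"] for p in panels) / 2
        r = np.corrcoef(trait.values.iloc[:, 0], met_mean)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_zero_weights_yield_no_markers_at_threshold(self):
        geno = t.simulate.generate_genotypes(n_accessions=388, n_snps=40, seed=8)
        truth = TruthTable(trait_weights={f"met{j:04d}": 0.0 for j in range(50)})
        panels = t.simulate.generate_metabolome(geno, truth, n_metabolites=50, seed=9)
        trait = t.simulate.generate_trait(panels, None, truth, seed=10)
        markers = t.metabolome.select_marker_metabolites(
            panels[0], trait.mean_across_environments(), r_threshold=0.2
        )
        assert int(markers["selected"].sum()) == 0

    def test_negative_weight_markers_recovered_with_sign(self):
        """20 planted negative-weight metabolites, mutually correlated through
        a shared pleiotropic locus (as pathway-linked markers are), are
        recovered among the selected markers with negative sign."""
        recovered = []
        for rep in range(5):
            geno = t.simulate.generate_genotypes(
                n_accessions=388, n_snps=40, seed=20 + rep
            )
            shared_snp = geno.snp_map.table["snp_id"].iloc[10]
            truth = TruthTable(
                planted_mqtl=[(f"met{j:04d}", shared_snp, 0.7) for j in range(20)],
                trait_weights={f"met{j:04d}": -0.6 for j in range(20)},
                h2_target={f"met{j:04d}": 0.8 for j in range(20)},
            )
            panels = t.simulate.generate_metabolome(
                geno, truth, n_metabolites=60, seed=30 + rep
            )
            trait = t.simulate.generate_trait(
                panels, None, truth, noise_sd=1.0, seed=40 + rep
            )
            markers = t.metabolome.select_marker_metabolites(
                panels[0], trait.mean_across_environments()
            )
            sel = markers.loc[markers["selected"] & (markers["sign"] == "negative")]
            recovered.append(
                len(set(sel.index) & {f"met{j:04d}" for j in range(20)})
            )
        assert np.median(recovered) >= 18

    def test_empty_weights_rejected(self, small_panel):
        with pytest.raises(ValueError):
            t.simulate.generate_trait(small_panel, None, TruthTable(), seed=0)
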