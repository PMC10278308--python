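"""Mixed-model scan and locus post-processing, checked against closed-form
OLS, brute-force clustering, and direct-construction oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import triomics as t
from triomics.association import (
    AssociationScan,
    bonferroni_threshold,
    classify_eqtl,
    cluster_qtls,
    colocalize,
    detect_hotspots,
    haplotype_compare,
    kinship,
    lmm_scan,
    maf_filter,
)
from triomics.datatypes import QTL


class TestMafFilter:
    def test_monomorphic_removed_and_symmetric_kept(self, small_geno):
        g = small_geno
        dosages = g.dosages.copy()
        dosages.iloc[:, 0] = 0  # kill one SNP
        gm = t.GenotypeMatrix(dosages, g.snp_map)
        filtered = maf_filter(gm, 0.05)
        assert dosages.columns[0] not in filtered.dosages.columns

    def test_matches_per_snp_recount(self, small_geno):
        filtered = maf_filter(small_geno, 0.05)
        survivors = set(filtered.dosages.columns)
        for snp in small_geno.dosages.columns:
            f = small_geno.dosages[snp].mean() / 2
            maf = min(f, 1 - f)
            assert (snp in survivors) == (maf > 0.05)


class TestKinship:
    def test_symmetric_psd(self, small_geno):
        K = kinship(small_geno).to_numpy()
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_duplicate_accessions_duplicate_rows(self, small_geno):
        dosages = small_geno.dosages.copy()
        dosages.iloc[1] = dosages.iloc[0]
        K = kinship(t.GenotypeMatrix(dosages, small_geno.snp_map))
        Kv = K.to_numpy()
        assert np.allclose(Kv[0], Kv[1])
        # duplicated accessions are each other's closest relatives
        assert Kv[0, 1] == pytest.approx(Kv[0, 0])


class TestLmmScan:
    def test_identity_kinship_equals_ols(self, small_geno, identity_K):
        rng = np.random.default_rng(4)
        y = pd.Series(rng.standard_normal(small_geno.n_accessions),
                      index=small_geno.accessions)
        scan = lmm_scan(small_geno, y, K=identity_K)
        n = small_geno.n_accessions
        for j in range(0, small_geno.n_snps, 7):
            x = small_geno.dosages.iloc[:, j].to_numpy(dtype=float)
            if x.std() == 0:
                continue
            res = stats.linregress(x, y.to_numpy())
            assert scan.table["p"].iloc[j] == pytest.approx(res.pvalue, abs=1e-8)
            assert scan.table["beta"].iloc[j] == pytest.approx(res.slope, rel=1e-8)

    def test_location_scale_invariance(self, small_geno, identity_K):
        rng = np.random.default_rng(5)
        y = pd.Series(rng.standard_normal(small_geno.n_accessions),
                      index=small_geno.accessions)
        p1 = lmm_scan(small_geno, y, K=identity_K).table["p"]
        p2 = lmm_scan(small_geno, 3.0 * y + 10.0, K=identity_K).table["p"]
        assert np.allclose(p1, p2, atol=1e-10)

    def test_constant_snp_flagged(self, small_geno, identity_K):
        dosages = small_geno.dosages.copy()
        dosages.iloc[:, 3] = 2
        gm = t.GenotypeMatrix(dosages, small_geno.snp_map)
        y = pd.Series(np.arange(gm.n_accessions, dtype=float), index=gm.accessions)
        scan = lmm_scan(gm, y, K=identity_K)
        assert scan.table["p"].iloc[3] == 1.0
        assert np.isinf(scan.table["se"].iloc[3])

    def test_planted_snp_is_genome_wide_lead(self, small_geno):
        rng = np.random.default_rng(6)
        K = kinship(small_geno)
        snp = small_geno.dosages.columns[37]
        g = small_geno.dosages[snp].to_numpy(dtype=float)
        g = g - g.mean()
        ve = g.var() * 4  # 20% variance explained
        y = pd.Series(g + rng.normal(0, np.sqrt(ve), len(g)),
                      index=small_geno.accessions)
        scan = lmm_scan(small_geno, y, K=K)
        assert scan.table.sort_values("p").iloc[0]["snp_id"] == snp


class TestBonferroni:
    def test_reciprocal_matches_printed_thresholds(self):
        assert f"{bonferroni_threshold(8_274_830):.1e}" == "1.2e-07"
        assert f"{bonferroni_threshold(70_781):.2e}" == "1.41e-05"

    def test_trivial_and_conventions(self):
        assert bonferroni_threshold(1) == 1.0
        assert bonferroni_threshold(100, "alpha_over_n", alpha=0.05) == pytest.approx(5e-4)
        with pytest.raises(ValueError):
            bonferroni_threshold(10, "fdr")

    def test_monotone_decreasing(self):
        ns = [10, 100, 1000, 10_000]
        vals = [bonferroni_threshold(n) for n in ns]
        assert all(a > b for a, b in zip(vals, vals[1:]))


def _scan_from_positions(positions, pvals, chrom="chr01", phenotype="pheno"):
    table = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(len(positions))],
            "chromosome": chrom,
            "position": positions,
            "beta": 0.1,
            "se": 0.01,
            "p": pvals,
        }
    )
    return AssociationScan(phenotype, table, len(positions), threshold=1.0)


class TestClusterQtls:
    def test_gap_within_window_one_qtl(self):
        scan = _scan_from_positions([10_000, 90_000], [1e-9, 1e-8])
        qtls = cluster_qtls(scan, window_bp=100_000)
        assert len(qtls) == 1
        assert qtls[0].lead_snp == "s0"  # smaller p

    def test_gap_beyond_window_two_qtls(self):
        scan = _scan_from_positions([10_000, 150_000], [1e-9, 1e-8])
        assert len(cluster_qtls(scan, window_bp=100_000)) == 2

    def test_lead_tie_breaks_to_lower_position(self):
        scan = _scan_from_positions([10_000, 20_000], [1e-9, 1e-9])
        assert cluster_qtls(scan)[0].lead_snp == "s0"

    def test_matches_bruteforce_single_linkage(self):
        rng = np.random.default_rng(7)
        positions = np.sort(rng.choice(np.arange(1, 5_000_000), 200, replace=False))
        pvals = rng.uniform(1e-12, 1e-8, 200)
        scan = _scan_from_positions(list(positions), list(pvals))
        qtls = cluster_qtls(scan, window_bp=100_000)
        # brute-force single linkage: union-find over all pairs <= window
        parent = list(range(200))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(200):
            for j in range(i + 1, 200):
                if abs(int(positions[i]) - int(positions[j])) <= 100_000:
                    parent[find(i)] = find(j)
        expected = {}
        for i in range(200):
            expected.setdefault(find(i), set()).add(f"s{i}")
        got = {frozenset(q.member_snps) for q in qtls}
        assert got == {frozenset(s) for s in expected.values()}
        # union of members equals the significant set
        assert set().union(*got) == {f"s{i}" for i in range(200)}

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(8)
        positions = np.sort(rng.choice(np.arange(1, 2_000_000), 50, replace=False))
        pvals = rng.uniform(1e-10, 1e-9, 50)
        scan = _scan_from_positions(list(positions), list(pvals))
        perm = rng.permutation(50)
        scan_perm = AssociationScan(
            "pheno", scan.table.iloc[perm].reset_index(drop=True), 50, threshold=1.0
        )
        a = {frozenset(q.member_snps) for q in cluster_qtls(scan)}
        b = {frozenset(q.member_snps) for q in cluster_qtls(scan_perm)}
        assert a == b


def _qtl(qid, chrom, start, end, phenos=("m1",), lead_p=1e-9):
    return QTL(qid, chrom, start, end, "lead", lead_p, ["lead"], set(phenos))


class TestHotspotsAndColocalization:
    def test_hotspot_strictly_more_than_min(self):
        qtls = {
            f"m{i}": [_qtl(f"q{i}", "chr01", 50_000, 60_000, (f"m{i}",))]
            for i in range(11)
        }
        assert len(detect_hotspots(qtls, min_phenotypes=10)) == 1
        ten = {k: v for k, v in list(qtls.items())[:10]}
        assert detect_hotspots(ten, min_phenotypes=10) == []

    def test_colocalize_rules_and_symmetry(self):
        a = [_qtl("a1", "chr01", 100_000, 200_000)]
        b_same = [_qtl("b1", "chr01", 100_000, 200_000)]
        b_far = [_qtl("b2", "chr01", 350_001, 400_000)]
        b_other = [_qtl("b3", "chr02", 100_000, 200_000)]
        assert colocalize(a, b_same) == [("a1", "b1")]
        assert colocalize(a, b_far) == []  # gap 150,001 bp
        assert colocalize(a, b_other) == []
        fwd = colocalize(a, b_same)
        rev = colocalize(b_same, a)
        assert {(x, y) for x, y in fwd} == {(y, x) for x, y in rev}

    def test_colocalize_matches_bruteforce(self):
        rng = np.random.default_rng(9)
        def random_qtls(prefix, n):
            out = []
            for i in range(n):
                s = int(rng.integers(1, 3_000_000))
                out.append(_qtl(f"{prefix}{i}", f"chr{rng.integers(1, 3):02d}",
                                s, s + int(rng.integers(1, 50_000))))
            return out
        A, B = random_qtls("a", 30), random_qtls("b", 30)
        got = set(colocalize(A, B, window_bp=100_000))
        expected = set()
        for qa in A:
            for qb in B:
                if qa.chromosome == qb.chromosome:
                    gap = max(0, max(qa.start, qb.start) - min(qa.end, qb.end))
                    if gap <= 100_000:
                        expected.add((qa.qtl_id, qb.qtl_id))
        assert got == expected


class TestClassifyEqtl:
    def test_lead_inside_gene_body_is_cis(self):
        q = _qtl("q", "chr01", 90_000, 110_000)
        q._lead_position = 100_000
        gene = pd.Series({"gene_id": "g", "chromosome": "chr01",
                          "start": 95_000, "end": 105_000, "strand": "+"})
        assert classify_eqtl(q, gene) == "cis"

    def test_other_chromosome_is_trans(self):
        q = _qtl("q", "chr02", 90_000, 110_000)
        q._lead_position = 100_000
        gene = pd.Series({"gene_id": "g", "chromosome": "chr01",
                          "start": 95_000, "end": 105_000, "strand": "+"})
        assert classify_eqtl(q, gene) == "trans"

    def test_window_boundary(self):
        gene = pd.Series({"gene_id": "g", "chromosome": "chr01",
                          "start": 1_000_000, "end": 1_002_000, "strand": "+"})
        near = _qtl("q1", "chr01", 1, 10)
        near._lead_position = 500_000  # 500 kb away
        far = _qtl("q2", "chr01", 1, 10)
        far._lead_position = 2_500_000 + 2_000  # > 1 Mb beyond gene end
        assert classify_eqtl(near, gene, cis_window_bp=1_000_000) == "cis"
        assert classify_eqtl(far, gene, cis_window_bp=1_000_000) == "trans"


class TestHaplotypeCompare:
    def test_monomorphic_rejected(self, small_geno):
        dosages = small_geno.dosages.copy()
        snp = dosages.columns[0]
        dosages[snp] = 1
        gm = t.GenotypeMatrix(dosages, small_geno.snp_map)
        vals = pd.Series(np.arange(gm.n_accessions, dtype=float), index=gm.accessions)
        with pytest.raises(ValueError, match="monomorphic"):
            haplotype_compare(gm, snp, vals)

    def test_planted_shift_detected(self, small_geno):
        rng = np.random.default_rng(10)
        maf = small_geno.maf()
        snp = maf.idxmax()  # most balanced SNP
        g = small_geno.dosages[snp]
        vals = pd.Series(rng.standard_normal(len(g)), index=g.index)
        vals[g == 2] += 2.0  # 2 SD shift between homozygote groups
        res = haplotype_compare(small_geno, snp, vals)
        assert res.p_value < 0.01
        assert res.group_means["hom_alt"] > res.group_means["hom_ref"]
        assert sum(res.group_sizes.values()) == len(g)

    def test_null_p_is_uniform(self, small_geno):
        """KS check that rank-sum p-values are uniform under the null."""
        rng = np.random.default_rng(11)
        maf = small_geno.maf()
        snp = maf.idxmax()
        pvals = []
        for _ in range(200):
            vals = pd.Series(rng.standard_normal(small_geno.n_accessions),
                             index=small_geno.accessions)
            pvals.append(haplotype_compare(small_geno, snp, vals).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
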