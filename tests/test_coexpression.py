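"""Co-expression: adjacency and TOM against hand calculations, module
detection on planted blocks, eigengene properties, module-trait inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import triomics as t
from triomics.coexpression import (
    detect_modules,
    module_eigengene,
    module_trait_correlation,
    scale_free_fit,
    soft_adjacency,
    tom_similarity,
)
from triomics.datatypes import ExpressionMatrix


def _expr_from_df(df):
    gm = pd.DataFrame(
        {
            "gene_id": df.columns,
            "chromosome": "chr01",
            "start": np.arange(1, len(df.columns) + 1) * 1000,
            "end": np.arange(1, len(df.columns) + 1) * 1000 + 500,
            "strand": "+",
        }
    )
    return ExpressionMatrix(df, gm)


class TestSoftAdjacency:
    def test_known_values(self):
        x = np.linspace(-1, 1, 20)
        df = pd.DataFrame({"g0": x, "g1": 2 * x + 1}, index=[f"a{i}" for i in range(20)])
        adj = soft_adjacency(_expr_from_df(df), beta=6)
        assert adj.loc["g0", "g1"] == pytest.approx(1.0)

    def test_half_correlation_power_six(self):
        corr = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        adj = soft_adjacency(corr, beta=6, mode="unsigned")
        assert adj.loc["a", "b"] == pytest.approx(0.015625)
        signed = soft_adjacency(corr, beta=6, mode="signed")
        assert signed.loc["a", "b"] == pytest.approx(0.75**6)

    def test_elementwise_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((30, 6)),
                          index=[f"a{i}" for i in range(30)],
                          columns=[f"g{j}" for j in range(6)])
        adj = soft_adjacency(_expr_from_df(df), beta=6)
        for a in df.columns:
            for b in df.columns:
                expected = 1.0 if a == b else abs(np.corrcoef(df[a], df[b])[0, 1]) ** 6
                assert adj.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_bounds_and_symmetry(self, small_expr):
        adj = soft_adjacency(small_expr, beta=6)
        A = adj.to_numpy()
        assert np.allclose(A, A.T)
        assert A.min() >= 0 and A.max() <= 1
        assert np.allclose(np.diag(A), 1.0)


class TestTom:
    def test_three_node_hand_calculation(self):
        A = pd.DataFrame(
            [[1.0, 0.5, 0.5], [0.5, 1.0, 0.0], [0.5, 0.0, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        tom = tom_similarity(A)
        assert tom.loc["b", "c"] == pytest.approx(1 / 6)
        assert tom.loc["a", "a"] == 1.0

    def test_shared_full_neighborhood_gives_one(self):
        A = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        tom = tom_similarity(A)
        assert np.allclose(tom.to_numpy(), 1.0)

    def test_empty_adjacency_zero_offdiag(self):
        A = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        tom = tom_similarity(A).to_numpy()
        assert np.allclose(tom, np.eye(4))

    def test_bounds_and_symmetry(self, small_expr):
        tom = tom_similarity(soft_adjacency(small_expr, beta=6)).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1


class TestModules:
    def test_two_planted_blocks_perfectly_recovered(self, small_geno):
        from triomics.datatypes import TruthTable
        truth = TruthTable()
        for j in range(40):
            truth.planted_modules[f"gene{j:05d}"] = 1 + (j % 2)
        expr = t.simulate.generate_expression(
            small_geno, truth, n_genes=90, module_weight=float(np.sqrt(0.8)), seed=21
        )
        tom = tom_similarity(soft_adjacency(expr, beta=6))
        modules = detect_modules(tom, min_module_size=15)
        planted = pd.Series(truth.planted_modules)
        detected = modules.labels.reindex(planted.index)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(planted.to_numpy(), detected.to_numpy()) == 1.0

    def test_independent_genes_unassigned(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.standard_normal((80, 60)),
                          index=[f"a{i}" for i in range(80)],
                          columns=[f"g{j}" for j in range(60)])
        tom = tom_similarity(soft_adjacency(_expr_from_df(df), beta=6))
        modules = detect_modules(tom, min_module_size=30, cut_height=0.05)
        assert (modules.labels == 0).all()

    def test_labels_form_partition(self, small_expr):
        tom = tom_similarity(soft_adjacency(small_expr, beta=6))
        modules = detect_modules(tom, min_module_size=10)
        assert set(modules.labels.index) == set(small_expr.genes)
        assert modules.labels.notna().all()
        sizes = modules.sizes()
        # labels ordered by size, largest first
        assert list(sizes.sort_index().to_numpy()) == sorted(sizes, reverse=True)


class TestEigengene:
    def test_identical_genes_recover_shared_profile(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        df = pd.DataFrame({f"g{j}": x for j in range(5)},
                          index=[f"a{i}" for i in range(50)])
        expr = _expr_from_df(df)
        from triomics.coexpression import CoexpressionModules
        modules = CoexpressionModules(labels=pd.Series(1, index=df.columns))
        eig = module_eigengene(expr, modules)
        r = np.corrcoef(eig["ME1"], x)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_pc1_maximizes_variance(self, small_expr):
        from triomics.coexpression import CoexpressionModules
        members = list(small_expr.genes[:20])
        modules = CoexpressionModules(
            labels=pd.Series([1 if g in members else 0 for g in small_expr.genes],
                             index=small_expr.genes)
        )
        eig = module_eigengene(small_expr, modules)
        sub = small_expr.expression[members].to_numpy()
        sub = (sub - sub.mean(0)) / sub.std(0)
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        pc1_var = (s[0] ** 2)
        rng = np.random.default_rng(4)
        for _ in range(100):
            d = rng.standard_normal(len(members))
            d /= np.linalg.norm(d)
            assert (sub @ d).var() * sub.shape[0] <= pc1_var + 1e-8

    def test_sign_flip_invariance_up_to_orientation(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((40, 6)),
                          index=[f"a{i}" for i in range(40)],
                          columns=[f"g{j}" for j in range(6)])
        from triomics.coexpression import CoexpressionModules
        labels = pd.Series(1, index=df.columns)
        e1 = module_eigengene(_expr_from_df(df), CoexpressionModules(labels=labels))
        e2 = module_eigengene(_expr_from_df(-df), CoexpressionModules(labels=labels.copy()))
        r = np.corrcoef(e1["ME1"], e2["ME1"])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)


class TestScaleFree:
    def test_single_beta_r2_bounded(self, small_expr):
        res = scale_free_fit(small_expr, beta_grid=[6])
        assert len(res) == 1
        r2 = res["r_squared"].iloc[0]
        assert res["degenerate"].iloc[0] or (0 <= r2 <= 1)

    def test_degenerate_equal_correlations_flagged(self):
        x = np.linspace(-1, 1, 10)
        df = pd.DataFrame({f"g{j}": x * (j + 1) for j in range(5)},
                          index=[f"a{i}" for i in range(10)])
        res = scale_free_fit(_expr_from_df(df), beta_grid=[2])
        assert bool(res["degenerate"].iloc[0])

    def test_r2_improves_with_beta_on_modular_data(self, small_expr):
        res = scale_free_fit(small_expr, beta_grid=[1, 6])
        ok = res.dropna(subset=["r_squared"])
        if len(ok) == 2:
            assert ok["r_squared"].iloc[1] >= ok["r_squared"].iloc[0] - 0.1


class TestModuleTrait:
    def test_eigengene_equals_trait(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(60)
        eig = pd.DataFrame({"ME1": x}, index=[f"a{i}" for i in range(60)])
        targets = pd.DataFrame({"SOC": x}, index=eig.index)
        res = module_trait_correlation(eig, targets)
        assert res["r"].iloc[0] == pytest.approx(1.0)

    def test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(7)
        n = 100
        x = rng.standard_normal(n)
        y = 0.35 * x + rng.standard_normal(n)
        eig = pd.DataFrame({"ME1": x}, index=[f"a{i}" for i in range(n)])
        targets = pd.DataFrame({"SOC": y}, index=eig.index)
        res = module_trait_correlation(eig, targets)
        r_obs = res["r"].iloc[0]
        p_closed = res["p"].iloc[0]
        perms = 20_000
        count = 0
        yv = np.asarray(y)
        for _ in range(perms):
            r = np.corrcoef(x, rng.permutation(yv))[0, 1]
            if abs(r) >= abs(r_obs):
                count += 1
        p_perm = (count + 1) / (perms + 1)
        se = np.sqrt(max(p_closed, 1 / perms) * (1 - p_closed) / perms)
        assert abs(p_perm - p_closed) < max(5 * se, 2e-3)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(8)
        n = 80
        pvals = []
        for _ in range(200):
            eig = pd.DataFrame({"ME1": rng.standard_normal(n)},
                               index=[f"a{i}" for i in range(n)])
            targets = pd.DataFrame({"SOC": rng.standard_normal(n)}, index=eig.index)
            pvals.append(module_trait_correlation(eig, targets)["p"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
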