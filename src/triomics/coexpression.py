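"""WGCNA-style co-expression analysis.

Soft-thresholded adjacency (|cor|^beta, default beta = 6), topological
overlap similarity, average-linkage hierarchical module detection with a
static tree cut, module eigengenes (first principal components), and
module-trait/metabolite correlation.

The static cut (at a fixed fraction of the merge-height range) is a
documented simplification of the dynamic hybrid tree cut; small clusters
(< min_module_size genes) are left unassigned (label 0) and module labels
are ordered by size, largest first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import ExpressionMatrix


def soft_adjacency(
    expr_or_corr: ExpressionMatrix | pd.DataFrame,
    beta: float = 6,
    mode: str = "unsigned",
) -> pd.DataFrame:
    """Soft-thresholded co-expression adjacency.

    unsigned: a_ij = |cor(i,j)|^beta;  signed: a_ij = ((1+cor)/2)^beta.
    Symmetric with unit diagonal, entries in [0, 1].
    """
    if isinstance(expr_or_corr, ExpressionMatrix):
        corr = np.corrcoef(expr_or_corr.expression.to_numpy(dtype=float), rowvar=False)
        genes = expr_or_corr.expression.columns
    else:
        corr = expr_or_corr.to_numpy(dtype=float)
        genes = expr_or_corr.columns
    corr = np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)
    if mode == "unsigned":
        adj = np.abs(corr) ** beta
    elif mode == "signed":
        adj = ((1.0 + corr) / 2.0) ** beta
    else:
        raise ValueError(f"unknown mode: {mode}")
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=genes, columns=genes)


def scale_free_fit(
    expr: ExpressionMatrix,
    beta_grid=(1, 2, 3, 4, 5, 6, 7, 8),
    mode: str = "unsigned",
    n_bins: int = 10,
) -> pd.DataFrame:
    """R^2 of the log-log degree-distribution fit per candidate power.

    Connectivity k_i = sum_{j != i} a_ij is binned; the frequency p(k) per
    bin is regressed on log10(mean k) in log space.  A grid with fewer than
    two occupied bins is flagged (R^2 = NaN, degenerate = True).
    """
    corr = np.corrcoef(expr.expression.to_numpy(dtype=float), rowvar=False)
    corr = np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)
    rows = []
    for beta in beta_grid:
        adj = np.abs(corr) ** beta if mode == "unsigned" else ((1 + corr) / 2) ** beta
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=0)
        if k.max() - k.min() < 1e-8:  # all-equal connectivity: nothing to fit
            rows.append((beta, np.nan, True))
            continue
        edges = np.linspace(k.min(), k.max(), n_bins + 1)
        which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
        ks, ps = [], []
        for b in range(n_bins):
            sel = which == b
            if sel.sum() > 0 and k[sel].mean() > 0:
                ks.append(k[sel].mean())
                ps.append(sel.mean())
        if len(ks) < 2:
            rows.append((beta, np.nan, True))
            continue
        lk, lp = np.log10(ks), np.log10(ps)
        slope, intercept, r, _, _ = stats.linregress(lk, lp)
        rows.append((beta, float(r**2), False))
    return pd.DataFrame(rows, columns=["beta", "r_squared", "degenerate"])


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; diagonal 1.
    """
    A = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=0)
    L = A @ A  # since diag(A)=0, (A^2)_ij = sum_{u != i,j} a_iu a_uj + 0
    num = L + A
    den = np.minimum.outer(k, k) + 1.0 - A
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


@dataclass
class CoexpressionModules:
    """Module assignment (0 = unassigned) plus eigengenes and the soft power."""

    labels: pd.Series  # gene -> int label
    eigengenes: pd.DataFrame | None = None  # accession x module ("ME<k>")
    beta: float = 6.0

    def sizes(self) -> pd.Series:
        return self.labels[self.labels > 0].value_counts().sort_index()


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float | None = None,
    beta: float = 6.0,
) -> CoexpressionModules:
    """Average-linkage clustering of 1 - TOM with a static cut.

    ``cut_height`` defaults to 0.995 of the merge-height range.  Clusters
    smaller than ``min_module_size`` are unassigned (label 0); surviving
    modules are renumbered 1, 2, ... by decreasing size.
    """
    genes = tom.index
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0
    Z = linkage(squareform(dissim, checks=False), method="average")
    heights = Z[:, 2]
    if cut_height is None:
        lo, hi = float(heights.min()), float(heights.max())
        cut_height = lo + 0.995 * (hi - lo)
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    keep = sizes.index[sizes >= min_module_size]
    labels[~labels.isin(keep)] = 0
    # renumber by size, largest first
    order = labels[labels > 0].value_counts().index
    remap = {old: new for new, old in enumerate(order, start=1)}
    remap[0] = 0
    labels = labels.map(remap)
    return CoexpressionModules(labels=labels.astype(int), beta=beta)


def module_eigengene(
    expr: ExpressionMatrix, modules: CoexpressionModules
) -> pd.DataFrame:
    """First principal component per module of the standardized expression.

    Each eigengene is scaled to unit variance and oriented so its mean
    correlation with the module's member genes is non-negative.
    """
    X = expr.expression
    out = {}
    for lab in sorted(set(modules.labels) - {0}):
        members = modules.labels.index[modules.labels == lab]
        sub = X[members].to_numpy(dtype=float)
        sub = sub - sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=0)
        sub = sub / np.where(sd > 0, sd, 1.0)
        # PC1 via SVD of the standardized accession x gene submatrix
        u, s, _ = np.linalg.svd(sub, full_matrices=False)
        pc1 = u[:, 0] * s[0]
        sd1 = pc1.std(ddof=0)
        if sd1 > 0:
            pc1 = (pc1 - pc1.mean()) / sd1
        if np.mean([np.corrcoef(pc1, sub[:, j])[0, 1] for j in range(sub.shape[1])]) < 0:
            pc1 = -pc1
        out[f"ME{lab}"] = pc1
    eig = pd.DataFrame(out, index=X.index)
    modules.eigengenes = eig
    return eig


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    targets: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson r and two-sided p of each eigengene against each target column.

    p-values come from the exact t transform with n - 2 degrees of freedom.
    Returns a tidy DataFrame {module, target, r, p, significant}.
    """
    shared = eigengenes.index.intersection(targets.index)
    E = eigengenes.loc[shared]
    T = targets.loc[shared]
    n = len(shared)
    rows = []
    for mod in E.columns:
        ev = E[mod].to_numpy(dtype=float)
        for tgt in T.columns:
            tv = T[tgt].to_numpy(dtype=float)
            ok = np.isfinite(ev) & np.isfinite(tv)
            m = int(ok.sum())
            if m < 3 or ev[ok].std() == 0 or tv[ok].std() == 0:
                continue
            r = float(np.corrcoef(ev[ok], tv[ok])[0, 1])
            r = max(-1.0, min(1.0, r))
            if abs(r) >= 1.0:
                p = float(np.nextafter(0, 1))
            else:
                t = r * np.sqrt(m - 2) / np.sqrt(1 - r * r)
                p = float(2 * stats.t.sf(abs(t), m - 2))
            rows.append((mod, tgt, r, p, p < alpha))
    return pd.DataFrame(rows, columns=["module", "target", "r", "p", "significant"])
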