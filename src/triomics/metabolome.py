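"""Metabolome-side analysis: normalization, broad-sense heritability,
marker-metabolite selection, compound-class enrichment, and the
metabolite correlation network.

The central screening step identifies *marker metabolites* — metabolites
whose log2 abundance is Pearson-correlated with seed oil content beyond a
threshold (default |r| > 0.2) — which downstream become the phenotypes of
the metabolite GWAS and the anchors of the triple network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MetabolitePanel


def log2_normalize(
    raw: pd.DataFrame,
    zero_floor: float | None = None,
    classes: pd.Series | None = None,
    year: str = "pooled",
) -> MetabolitePanel:
    """log2-transform raw positive abundances into a :class:`MetabolitePanel`.

    Zeros are replaced by ``zero_floor`` (default: half the smallest positive
    value in the table) before transformation; negative values are an error.
    The transform is monotone and exactly invertible via ``2**x``.
    """
    values = raw.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("raw abundances must be non-negative")
    if (values == 0).any():
        if zero_floor is None:
            positive = values[values > 0]
            if positive.size == 0:
                raise ValueError("all abundances are zero")
            zero_floor = float(positive.min()) / 2.0
        values = np.where(values == 0, zero_floor, values)
    out = pd.DataFrame(np.log2(values), index=raw.index, columns=raw.columns)
    if classes is None:
        classes = pd.Series("unknown", index=raw.columns)
    return MetabolitePanel(out, classes, year)


@dataclass
class HeritabilityResult:
    metabolite_id: str
    H2: float
    Vg: float
    Ve: float


def broad_sense_heritability(
    panels: list[MetabolitePanel],
) -> pd.DataFrame:
    """Broad-sense heritability per metabolite from multi-year replicates.

    One-way random-effects decomposition with accession as the grouping
    factor and year as the replicate:

        Vg = max(0, (MS_between - MS_within) / r),  Ve = MS_within,
        H2 = Vg / (Vg + Ve), clipped to [0, 1],

    where ``r`` is the number of years.  In an inbred-line panel the
    between-accession variance captures total genetic variance, so the
    intraclass correlation is a broad-sense estimate.

    Returns a DataFrame indexed by metabolite with columns H2, Vg, Ve.
    """
    if len(panels) < 2:
        raise ValueError("need at least two years of data")
    shared_acc = panels[0].accessions
    shared_met = panels[0].metabolites
    for p in panels[1:]:
        shared_acc = shared_acc.intersection(p.accessions)
        shared_met = shared_met.intersection(p.metabolites)
    if len(shared_acc) < 2:
        raise ValueError("need at least two shared accessions")
    r = len(panels)
    n = len(shared_acc)
    # stack: years x accessions x metabolites
    stack = np.stack(
        [p.abundances.loc[shared_acc, shared_met].to_numpy(dtype=float) for p in panels]
    )
    acc_means = stack.mean(axis=0)  # n x m
    grand = acc_means.mean(axis=0)  # m
    ms_between = r * ((acc_means - grand) ** 2).sum(axis=0) / (n - 1)
    ms_within = ((stack - acc_means[None]) ** 2).sum(axis=(0, 1)) / (n * (r - 1))
    vg = np.maximum(0.0, (ms_between - ms_within) / r)
    ve = ms_within
    total = vg + ve
    zero_var = total <= 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} metabolite(s) with zero variance; H2 set to 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = np.where(zero_var, 0.0, vg / np.where(zero_var, 1.0, total))
    h2 = np.clip(h2, 0.0, 1.0)
    return pd.DataFrame(
        {"H2": h2, "Vg": vg, "Ve": ve}, index=pd.Index(shared_met, name="metabolite")
    )


def _pairwise_pearson(
    X: pd.DataFrame, y: pd.Series, min_presence: float = 0.5
) -> pd.DataFrame:
    """Pearson r (and n) of each column of X against y on pairwise-complete rows.

    Columns present in fewer than ``min_presence`` of rows are dropped;
    constant columns yield NaN r.
    """
    shared = X.index.intersection(y.index)
    X = X.loc[shared]
    y = y.loc[shared]
    out = {}
    yv = y.to_numpy(dtype=float)
    for col in X.columns:
        xv = X[col].to_numpy(dtype=float)
        ok = np.isfinite(xv) & np.isfinite(yv)
        if ok.mean() < min_presence or ok.sum() < 3:
            continue
        xs, ys = xv[ok], yv[ok]
        if xs.std() == 0 or ys.std() == 0:
            out[col] = (np.nan, int(ok.sum()))
            continue
        out[col] = (float(np.corrcoef(xs, ys)[0, 1]), int(ok.sum()))
    return pd.DataFrame(out, index=["r", "n"]).T


def select_marker_metabolites(
    panel: MetabolitePanel,
    trait: pd.Series,
    r_threshold: float = 0.2,
) -> pd.DataFrame:
    """Select trait-correlated marker metabolites at strict |r| > ``r_threshold``.

    Returns a DataFrame indexed by metabolite with columns ``r``, ``n``,
    ``sign`` ("positive"/"negative"), and boolean ``selected``.  Metabolites
    whose correlation is undefined (constant values) are excluded with a
    warning.
    """
    table = _pairwise_pearson(panel.abundances, trait)
    undef = table["r"].isna()
    if undef.any():
        warnings.warn(
            f"excluded {int(undef.sum())} metabolite(s) with undefined correlation"
        )
        table = table.loc[~undef]
    table = table.copy()
    table["sign"] = np.where(table["r"] >= 0, "positive", "negative")
    table["selected"] = table["r"].abs() > r_threshold
    table["n"] = table["n"].astype(int)
    table.index.name = "metabolite"
    return table


def class_enrichment(
    classes: pd.Series,
    universe,
    hits,
    target_class: str,
) -> float:
    """Exact upper-tail hypergeometric enrichment of a compound class.

    With ``N = |universe|``, ``K`` members of ``target_class`` in the
    universe, ``n = |hits|`` and ``k`` members of the class among the hits,
    returns ``P(X >= k)`` for X hypergeometric(N, K, n) — the probability of
    seeing at least as many class members in a random draw of the same size.
    """
    universe = set(universe)
    hits = set(hits)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    in_class = {m for m in universe if classes.get(m) == target_class}
    N, K, n = len(universe), len(in_class), len(hits)
    k = len(hits & in_class)
    if K == 0 and k > 0:
        raise ValueError("inconsistent annotation: hits in a class absent from universe")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def correlation_network(
    panel: MetabolitePanel,
    trait: pd.Series | None = None,
    r_threshold: float = 0.35,
    trait_name: str = "SOC",
) -> pd.DataFrame:
    """Metabolite-metabolite (and optionally trait-metabolite) correlation edges.

    Returns an undirected edge list with columns ``node_a``, ``node_b``,
    ``r``, ``is_trait_edge`` holding every pair with |r| strictly above
    ``r_threshold``.  Trait edges use ``trait_name`` as one endpoint.
    """
    X = panel.abundances
    cols = list(X.columns)
    corr = X.corr()  # pairwise-complete by default
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > r_threshold:
                rows.append((a, b, float(r), False))
    if trait is not None:
        tcorr = _pairwise_pearson(X, trait)
        for met, row in tcorr.iterrows():
            if np.isfinite(row["r"]) and abs(row["r"]) > r_threshold:
                rows.append((trait_name, met, float(row["r"]), True))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "r", "is_trait_edge"])
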