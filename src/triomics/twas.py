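"""Metabolite transcriptome-wide association (mTWAS).

Each (gene, marker metabolite) pair is tested by simple linear regression of
the metabolite on the gene's expression; the two-sided p-value on the slope
is identical whichever variable is taken as the response, so the scan is
computed from the Pearson correlation:  t = r * sqrt(n-2) / sqrt(1-r^2).
Significance uses the strict ``p < 1/N_genes`` rule.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, MetabolitePanel


def mtwas_scan(
    expr: ExpressionMatrix,
    panel: MetabolitePanel,
    marker_metabolites=None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Regress every marker metabolite on every gene's expression.

    Parameters
    ----------
    marker_metabolites : iterable of metabolite ids to scan (default: all
        metabolites in the panel).
    threshold : significance threshold; default ``1 / n_genes``.

    Returns a tidy DataFrame with columns ``gene``, ``metabolite``,
    ``slope`` (metabolite per unit expression), ``r``, ``p``,
    ``significant``.  Constant genes are excluded with a warning.
    """
    mets = (
        list(marker_metabolites)
        if marker_metabolites is not None
        else list(panel.metabolites)
    )
    shared = expr.accessions.intersection(panel.accessions)
    if len(shared) < 30:
        raise ValueError("need at least 30 shared accessions")
    E = expr.expression.loc[shared].to_numpy(dtype=float)
    M = panel.abundances.loc[shared, mets].to_numpy(dtype=float)
    n = len(shared)
    if threshold is None:
        threshold = 1.0 / expr.expression.shape[1]

    e_sd = E.std(axis=0, ddof=0)
    keep = e_sd > 0
    if not keep.all():
        warnings.warn(f"excluded {int((~keep).sum())} constant gene(s)")
    genes = np.asarray(expr.expression.columns)[keep]
    Ek = E[:, keep]
    e_sd = e_sd[keep]

    Ec = Ek - Ek.mean(axis=0)
    Mc = M - M.mean(axis=0)
    m_sd = Mc.std(axis=0, ddof=0)
    m_sd_safe = np.where(m_sd > 0, m_sd, 1.0)
    # genes x metabolites correlation
    R = (Ec.T @ Mc) / n / np.outer(e_sd, m_sd_safe)
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = R * np.sqrt(n - 2) / np.sqrt(1.0 - R**2)
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p = np.where(np.abs(R) >= 1.0, np.nextafter(0, 1), p)
    slope = R * (m_sd_safe[None, :] / e_sd[:, None])

    gene_idx, met_idx = np.meshgrid(
        np.arange(len(genes)), np.arange(len(mets)), indexing="ij"
    )
    out = pd.DataFrame(
        {
            "gene": genes[gene_idx.ravel()],
            "metabolite": np.asarray(mets)[met_idx.ravel()],
            "slope": slope.ravel(),
            "r": R.ravel(),
            "p": np.clip(p.ravel(), np.nextafter(0, 1), 1.0),
        }
    )
    out = out.loc[m_sd[met_idx.ravel()] > 0].reset_index(drop=True)
    out["significant"] = out["p"] < threshold
    return out


def summarize_gene_hits(results: pd.DataFrame) -> pd.Series:
    """Per-gene count of significantly associated marker metabolites."""
    sig = results.loc[results["significant"]]
    counts = sig.groupby("gene")["metabolite"].nunique()
    return counts.reindex(results["gene"].unique(), fill_value=0).rename("n_metabolites")
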