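"""Mixed-model association scans and locus-level post-processing.

The scan is a single-spectral-decomposition linear mixed model in the
FaST-LMM style: the phenotype is modelled as

    y = 1*b0 + g*b + u + e,   u ~ N(0, sg^2 K),  e ~ N(0, se^2 I)

with K a genomic relationship matrix.  K is eigendecomposed once; the
variance-component ratio delta = se^2/sg^2 is fitted once on the null model
by maximum likelihood on the rotated data; each SNP is then tested by
weighted least squares on the rotated scale with a Wald t-test (df = n - 2).
With K = I this reduces exactly to per-SNP ordinary least squares.

Locus post-processing follows the study design: significant SNPs are chained
into QTLs by 100-kb single-linkage distance clustering (an LD-block proxy),
QTLs hit by many phenotypes are flagged as hotspots, and mQTL/eQTL interval
co-localization within 100 kb links metabolites to genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import GenotypeMatrix, QTL, SNPMap


def maf_filter(geno: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs with minor allele frequency strictly above ``maf_min``."""
    maf = geno.maf()
    keep = maf.index[maf > maf_min]
    return geno.subset_snps(keep)


def kinship(geno: GenotypeMatrix) -> pd.DataFrame:
    """Centered, standardized genomic relationship matrix (VanRaden-style).

    Z_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)),  K = Z Z' / m.

    Monomorphic SNPs are dropped.  K is symmetric positive semidefinite by
    construction.
    """
    X = geno.dosages.to_numpy(dtype=float)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs for kinship")
    Xp = X[:, poly]
    pp = p[poly]
    Z = (Xp - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
    K = Z @ Z.T / Z.shape[1]
    return pd.DataFrame(K, index=geno.accessions, columns=geno.accessions)


@dataclass
class AssociationScan:
    """Per-SNP association results for one phenotype."""

    phenotype_id: str
    table: pd.DataFrame  # columns: snp_id, chromosome, position, beta, se, p
    n_tests: int
    threshold: float | None = None

    def significant(self, threshold: float | None = None) -> pd.DataFrame:
        thr = threshold if threshold is not None else self.threshold
        if thr is None:
            raise ValueError("no significance threshold configured")
        return self.table.loc[self.table["p"] < thr]


@dataclass
class LmmContext:
    """Precomputed spectral context reused across phenotypes on one panel.

    Holds the eigendecomposition of K and the rotated genotype matrix, which
    are phenotype-independent: scanning many metabolites or genes against
    the same panel costs one decomposition total.
    """

    geno: GenotypeMatrix
    eigvals: np.ndarray
    U: np.ndarray
    G_rot: np.ndarray  # U' G, n x m
    ones_rot: np.ndarray

    @classmethod
    def build(cls, geno: GenotypeMatrix, K: pd.DataFrame) -> "LmmContext":
        Kv = K.loc[geno.accessions, geno.accessions].to_numpy(dtype=float)
        eigvals, U = np.linalg.eigh(Kv)
        eigvals = np.maximum(eigvals, 0.0)
        G = geno.dosages.to_numpy(dtype=float)
        return cls(
            geno=geno,
            eigvals=eigvals,
            U=U,
            G_rot=U.T @ G,
            ones_rot=U.T @ np.ones(Kv.shape[0]),
        )


def _null_delta(yt: np.ndarray, xt: np.ndarray, eigvals: np.ndarray) -> float:
    """ML fit of delta = se^2/sg^2 on the intercept-only rotated model."""
    n = yt.shape[0]

    def neg_loglik(log_delta: float) -> float:
        delta = 10.0 ** log_delta
        w = 1.0 / (eigvals + delta)
        xw = xt * w
        beta = (xw @ yt) / (xw @ xt)
        resid = yt - xt * beta
        sigma2 = (w * resid**2).sum() / n
        return 0.5 * (np.log(eigvals + delta).sum() + n * np.log(sigma2) + n)

    res = optimize.minimize_scalar(neg_loglik, bounds=(-5.0, 5.0), method="bounded")
    return 10.0 ** float(res.x)


def lmm_scan(
    geno: GenotypeMatrix,
    phenotype: pd.Series,
    K: pd.DataFrame | None = None,
    context: LmmContext | None = None,
    phenotype_id: str = "phenotype",
    threshold: float | None = None,
) -> AssociationScan:
    """Genome-wide mixed-model scan of one phenotype.

    Parameters
    ----------
    K : kinship matrix; required unless ``context`` is given.
    context : precomputed :class:`LmmContext` (shared decomposition) for
        scanning many phenotypes against the same genotype panel.

    Constant SNPs receive ``p = 1`` and ``beta = 0`` (flagged via se = inf).
    """
    if context is None:
        if K is None:
            raise ValueError("provide either K or a precomputed context")
        context = LmmContext.build(geno, K)
    y = phenotype.reindex(context.geno.accessions).to_numpy(dtype=float)
    finite = np.isfinite(y)
    if finite.sum() < 30:
        raise ValueError("phenotype must be finite for at least 30 accessions")
    if not finite.all():
        raise ValueError("missing phenotype values not supported; subset accessions")
    n = y.shape[0]
    yt = context.U.T @ y
    xt = context.ones_rot
    delta = _null_delta(yt, xt, context.eigvals)
    w = 1.0 / (context.eigvals + delta)
    sw = np.sqrt(w)

    y_w = yt * sw
    x_w = xt * sw
    G_w = context.G_rot * sw[:, None]

    # project the intercept out of phenotype and genotypes (partitioned WLS)
    xx = x_w @ x_w
    y_r = y_w - x_w * ((x_w @ y_w) / xx)
    G_r = G_w - np.outer(x_w, (x_w @ G_w) / xx)

    gg = np.einsum("ij,ij->j", G_r, G_r)
    gy = G_r.T @ y_w
    yy = float(y_r @ y_r)
    const = gg <= 1e-12
    gg_safe = np.where(const, 1.0, gg)
    beta = gy / gg_safe
    rss = np.maximum(yy - beta**2 * gg_safe, 0.0)
    df = n - 2
    sigma2 = rss / df
    se = np.sqrt(sigma2 / gg_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    beta = np.where(const, 0.0, beta)
    se = np.where(const, np.inf, se)
    p = np.where(const, 1.0, p)

    table = pd.DataFrame(
        {
            "snp_id": context.geno.snp_map.table["snp_id"].to_numpy(),
            "chromosome": context.geno.snp_map.table["chromosome"].to_numpy(),
            "position": context.geno.snp_map.table["position"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": np.clip(p, np.nextafter(0, 1), 1.0),
        }
    )
    return AssociationScan(
        phenotype_id=phenotype_id,
        table=table,
        n_tests=int(table.shape[0]),
        threshold=threshold,
    )


def bonferroni_threshold(
    n_tests: int, convention: str = "reciprocal", alpha: float = 0.05
) -> float:
    """Genome-wide significance threshold.

    ``reciprocal`` returns ``1 / n_tests`` (the convention matching the
    printed thresholds 1.2e-7 for ~8.27M SNPs and 1.41e-5 for 70,781 genes);
    ``alpha_over_n`` returns the textbook ``alpha / n_tests``.
    """
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    if convention == "reciprocal":
        return 1.0 / n_tests
    if convention == "alpha_over_n":
        return alpha / n_tests
    raise ValueError(f"unknown convention: {convention}")


def cluster_qtls(
    scan: AssociationScan,
    window_bp: int = 100_000,
    threshold: float | None = None,
    qtl_prefix: str = "QTL",
) -> list[QTL]:
    """Chain significant SNPs into QTLs by single-linkage distance clustering.

    Two significant SNPs on the same chromosome belong to the same QTL iff
    they are connected by a chain of significant SNPs with successive gaps
    <= ``window_bp`` (the LD-block proxy).  The lead SNP is the member with
    minimal p; ties break to the smaller coordinate.
    """
    sig = scan.significant(threshold)
    qtls: list[QTL] = []
    counter = 0
    for chrom, grp in sig.groupby("chromosome", sort=True):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > window_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            members = grp.iloc[s : e + 1]
            lead = members.sort_values(["p", "position"]).iloc[0]
            qtls.append(
                QTL(
                    qtl_id=f"{qtl_prefix}_{scan.phenotype_id}_{counter}",
                    chromosome=str(chrom),
                    start=int(members["position"].min()),
                    end=int(members["position"].max()),
                    lead_snp=str(lead["snp_id"]),
                    lead_p=float(lead["p"]),
                    member_snps=list(members["snp_id"]),
                    phenotype_ids={scan.phenotype_id},
                )
            )
            counter += 1
    return qtls


@dataclass
class Hotspot:
    chromosome: str
    start: int
    end: int
    phenotype_ids: set[str] = field(default_factory=set)
    qtl_ids: list[str] = field(default_factory=list)

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotype_ids)


def merge_qtls(qtls: list[QTL], window_bp: int = 100_000) -> list[Hotspot]:
    """Merge QTL intervals across phenotypes by gap-<=window chaining."""
    merged: list[Hotspot] = []
    by_chrom: dict[str, list[QTL]] = {}
    for q in qtls:
        by_chrom.setdefault(q.chromosome, []).append(q)
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda q: (q.start, q.end))
        current: Hotspot | None = None
        for q in group:
            if current is not None and q.start - current.end <= window_bp:
                current.end = max(current.end, q.end)
                current.phenotype_ids |= q.phenotype_ids
                current.qtl_ids.append(q.qtl_id)
            else:
                current = Hotspot(chrom, q.start, q.end, set(q.phenotype_ids), [q.qtl_id])
                merged.append(current)
    return merged


def detect_hotspots(
    qtls_by_phenotype: dict[str, list[QTL]],
    window_bp: int = 100_000,
    min_phenotypes: int = 10,
) -> list[Hotspot]:
    """Find loci detected by strictly more than ``min_phenotypes`` phenotypes.

    QTLs from all phenotypes are merged by the same distance-chaining rule
    used for clustering; a merged locus is a hotspot iff its distinct
    phenotype count exceeds ``min_phenotypes`` (strict inequality).
    """
    all_qtls = [q for qs in qtls_by_phenotype.values() for q in qs]
    return [
        h for h in merge_qtls(all_qtls, window_bp) if h.n_phenotypes > min_phenotypes
    ]


def colocalize(
    a: list[QTL], b: list[QTL], window_bp: int = 100_000
) -> list[tuple[str, str]]:
    """All (a, b) QTL pairs on the same chromosome with interval gap <= window."""
    pairs = []
    for qa in a:
        for qb in b:
            if qa.gap_to(qb) <= window_bp:
                pairs.append((qa.qtl_id, qb.qtl_id))
    return pairs


def classify_eqtl(
    qtl: QTL, gene_entry: pd.Series, cis_window_bp: int = 1_000_000
) -> str:
    """Classify an eQTL as ``cis`` or ``trans`` by lead-SNP-to-gene distance.

    cis iff the lead SNP lies on the gene's chromosome within
    ``cis_window_bp`` of the gene body (distance 0 inside the body).
    """
    if str(gene_entry["chromosome"]) != qtl.chromosome:
        return "trans"
    lead_pos = _lead_position(qtl)
    start, end = int(gene_entry["start"]), int(gene_entry["end"])
    if start <= lead_pos <= end:
        return "cis"
    dist = min(abs(lead_pos - start), abs(lead_pos - end))
    return "cis" if dist <= cis_window_bp else "trans"


def _lead_position(qtl: QTL) -> int:
    if getattr(qtl, "_lead_position", None) is not None:
        return qtl._lead_position  # type: ignore[attr-defined]
    # fall back to interval midpoint when the map is unavailable
    return (qtl.start + qtl.end) // 2


def annotate_lead_positions(qtls: list[QTL], snp_map: SNPMap) -> None:
    """Attach exact lead-SNP coordinates to QTLs for cis/trans calls."""
    lookup = dict(
        zip(snp_map.table["snp_id"], snp_map.table["position"].astype(int))
    )
    for q in qtls:
        q._lead_position = lookup[q.lead_snp]  # type: ignore[attr-defined]


@dataclass
class HaplotypeComparison:
    snp_id: str
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    p_value: float


def haplotype_compare(
    geno: GenotypeMatrix,
    snp_id: str,
    values: pd.Series,
    test: str = "wilcoxon",
) -> HaplotypeComparison:
    """Compare a phenotype between the two homozygote groups at one SNP.

    Accessions are grouped by biallelic genotype class (dosage 0 / 1 / 2);
    the test contrasts the homozygote groups (0 vs 2) with a two-sided
    Wilcoxon rank-sum test (or Student's t with ``test="t"``); heterozygotes
    are reported separately but not tested.
    """
    g = geno.dosages[snp_id].reindex(values.index)
    ok = g.notna() & values.notna()
    g, v = g[ok], values[ok]
    groups = {
        "hom_ref": v[g == 0].to_numpy(dtype=float),
        "het": v[g == 1].to_numpy(dtype=float),
        "hom_alt": v[g == 2].to_numpy(dtype=float),
    }
    if len(groups["hom_ref"]) == 0 or len(groups["hom_alt"]) == 0:
        raise ValueError(f"monomorphic: SNP {snp_id} lacks both homozygote classes")
    if test == "wilcoxon":
        stat = stats.ranksums(groups["hom_ref"], groups["hom_alt"])
    elif test == "t":
        stat = stats.ttest_ind(groups["hom_ref"], groups["hom_alt"])
    else:
        raise ValueError(f"unknown test: {test}")
    means = {
        k: (float(np.mean(arr)) if arr.size else float("nan"))
        for k, arr in groups.items()
    }
    if groups["het"].size == 0:
        warnings.warn(f"no heterozygotes at {snp_id}")
    return HaplotypeComparison(
        snp_id=snp_id,
        group_means=means,
        group_sizes={k: int(arr.size) for k, arr in groups.items()},
        p_value=float(stat.pvalue),
    )
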