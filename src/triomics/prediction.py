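"""SNP-based seed-oil-content level prediction.

Accessions are discretized into low / medium / high oil-content classes by
K-means on the mean SOC across environments (k = 3), split 2:1 into
stratified train/test sets, and classified by a random forest on the
genotypes of a handful of peak (lead) SNPs.  Performance is one-vs-rest ROC
AUC per class, contrasted against the mean AUC of forests trained on
repeatedly drawn random SNP sets — the permuted-marker null that shows the
peak SNPs carry real signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .datatypes import GenotypeMatrix, TraitTable

LEVELS = ("low", "medium", "high")


@dataclass
class SocLevels:
    """Per-accession oil-content class with the K-means centroids."""

    levels: pd.Series  # accession -> "low"/"medium"/"high"
    centroids: dict[str, float]
    clustered_values: pd.Series

    def counts(self) -> pd.Series:
        return self.levels.value_counts().reindex(LEVELS, fill_value=0)


def classify_soc_levels(
    soc: TraitTable, k: int = 3, random_state: int = 2
) -> SocLevels:
    """K-means discretization of mean-across-environment SOC into k levels.

    Cluster labels are renamed low < medium < high by ascending centroid.
    All-equal SOC values make the clustering degenerate and raise an error.
    """
    values = soc.mean_across_environments().dropna()
    if len(values) < k:
        raise ValueError("need at least k accessions with complete data")
    if values.nunique() == 1:
        raise ValueError("degenerate clustering: all SOC values are equal")
    km = KMeans(n_clusters=k, random_state=random_state, n_init=10)
    raw = km.fit_predict(values.to_numpy().reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    if k != len(LEVELS):
        names = [f"level{i + 1}" for i in range(k)]
    else:
        names = list(LEVELS)
    rename = {int(cluster): names[rank] for rank, cluster in enumerate(order)}
    levels = pd.Series([rename[c] for c in raw], index=values.index)
    centroids = {
        names[rank]: float(km.cluster_centers_.ravel()[cluster])
        for rank, cluster in enumerate(order)
    }
    return SocLevels(levels=levels, centroids=centroids, clustered_values=values)


def split_train_test(
    levels: SocLevels, ratio: float = 2.0, seed: int = 0
) -> tuple[pd.Index, pd.Index]:
    """Stratified train/test split with |train| : |test| = ratio : 1."""
    test_frac = 1.0 / (1.0 + ratio)
    train_idx, test_idx = train_test_split(
        levels.levels.index,
        test_size=test_frac,
        stratify=levels.levels.to_numpy(),
        random_state=seed,
    )
    return pd.Index(train_idx), pd.Index(test_idx)


def train_rf(
    geno_subset: GenotypeMatrix,
    levels: SocLevels,
    train_accessions: pd.Index,
    n_estimators: int = 300,
    max_features: int = 3,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit a random forest on feature-SNP dosages of the training accessions.

    ``max_features`` is the number of features considered per split (capped
    at the number of feature SNPs).
    """
    X = geno_subset.dosages.loc[train_accessions].to_numpy(dtype=float)
    y = levels.levels.loc[train_accessions].to_numpy()
    model = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features=min(max_features, X.shape[1]),
        random_state=seed,
    )
    model.fit(X, y)
    return model


def evaluate_auc(
    model: RandomForestClassifier,
    geno_subset: GenotypeMatrix,
    levels: SocLevels,
    test_accessions: pd.Index,
) -> dict[str, float]:
    """One-vs-rest ROC AUC per class from the forest's class probabilities."""
    X = geno_subset.dosages.loc[test_accessions].to_numpy(dtype=float)
    y = levels.levels.loc[test_accessions].to_numpy()
    proba = model.predict_proba(X)
    out = {}
    for i, cls in enumerate(model.classes_):
        onevrest = (y == cls).astype(int)
        if onevrest.min() == onevrest.max():
            out[str(cls)] = float("nan")
        else:
            out[str(cls)] = float(roc_auc_score(onevrest, proba[:, i]))
    return out


def random_snp_baseline(
    geno: GenotypeMatrix,
    levels: SocLevels,
    train_accessions: pd.Index,
    test_accessions: pd.Index,
    n_features: int = 6,
    repeats: int = 100,
    exclude_snps=(),
    n_estimators: int = 300,
    max_features: int = 3,
    seed: int = 0,
) -> dict[str, float]:
    """Mean per-class AUC of forests trained on random SNP draws.

    Each repeat draws ``n_features`` SNPs uniformly without replacement from
    the panel excluding ``exclude_snps`` (the peak set), trains a forest
    with the same hyperparameters, and evaluates on the same test split.
    """
    rng = np.random.default_rng(seed)
    pool = [s for s in geno.snp_map.table["snp_id"] if s not in set(exclude_snps)]
    if len(pool) < n_features:
        raise ValueError("not enough SNPs to draw the random baseline")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for rep in range(repeats):
        chosen = list(rng.choice(pool, size=n_features, replace=False))
        sub = geno.subset_snps(chosen)
        model = train_rf(
            sub,
            levels,
            train_accessions,
            n_estimators=n_estimators,
            max_features=max_features,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        aucs = evaluate_auc(model, sub, levels, test_accessions)
        for cls, auc in aucs.items():
            if np.isfinite(auc):
                sums[cls] = sums.get(cls, 0.0) + auc
                counts[cls] = counts.get(cls, 0) + 1
    return {cls: sums[cls] / counts[cls] for cls in sums}


@dataclass
class PredictionReport:
    peak_auc: dict[str, float]
    baseline_auc: dict[str, float]
    n_train: int
    n_test: int
    n_estimators: int
    max_features: int
    baseline_repeats: int


def prediction_experiment(
    geno: GenotypeMatrix,
    soc: TraitTable,
    peak_snps: list[str],
    n_estimators: int = 300,
    max_features: int = 3,
    baseline_repeats: int = 100,
    split_ratio: float = 2.0,
    kmeans_random_state: int = 2,
    seed: int = 0,
) -> PredictionReport:
    """Full peak-vs-random prediction contrast for one panel."""
    levels = classify_soc_levels(soc, random_state=kmeans_random_state)
    train_idx, test_idx = split_train_test(levels, ratio=split_ratio, seed=seed)
    sub = geno.subset_snps(peak_snps)
    model = train_rf(
        sub, levels, train_idx,
        n_estimators=n_estimators, max_features=max_features, seed=seed,
    )
    peak_auc = evaluate_auc(model, sub, levels, test_idx)
    baseline = random_snp_baseline(
        geno, levels, train_idx, test_idx,
        n_features=len(peak_snps), repeats=baseline_repeats,
        exclude_snps=peak_snps, n_estimators=n_estimators,
        max_features=max_features, seed=seed,
    )
    return PredictionReport(
        peak_auc=peak_auc,
        baseline_auc=baseline,
        n_train=len(train_idx),
        n_test=len(test_idx),
        n_estimators=n_estimators,
        max_features=max_features,
        baseline_repeats=baseline_repeats,
    )
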