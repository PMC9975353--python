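"""Result quantification: set overlaps, clustering quality, recovery.

Hypergeometric overlap tests compare the identified feature sets of
two clusters against a shared feature universe; the matrix variant
produces the -log10(p) heatmap used to diagnose cluster relatedness
and the partition-split self-consistency check. Clustering quality is
scored with silhouette, Calinski-Harabasz and Davies-Bouldin on either
the restricted latent means of a trained model or a PCA of the data.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .aggregation import ConsensusRanking
from .simulate import RegulatoryGroundTruth

__all__ = [
    "hypergeom_overlap",
    "overlap_matrix",
    "clustering_metrics",
    "optimal_k_scan",
    "recovery_score",
]


def hypergeom_overlap(set_a: Iterable[str], set_b: Iterable[str], universe_n: int) -> float:
    """Upper-tail hypergeometric probability of the observed overlap.

    ``P(X >= |A & B|)`` when ``|B|`` items are drawn from a universe of
    ``universe_n`` containing ``|A|`` marked items. An empty set on
    either side gives p = 1.
    """
    a, b = set(set_a), set(set_b)
    k = len(a & b)
    if universe_n < len(a | b):
        raise ValueError("universe smaller than the union of the two sets")
    if k > min(len(a), len(b)):  # unreachable for real sets; guards bad callers
        raise ValueError("overlap exceeds the smaller set")
    if not a or not b:
        return 1.0
    return float(hypergeom.sf(k - 1, universe_n, len(a), len(b)))


def overlap_matrix(sets: Mapping[str, Iterable[str]], universe_n: int) -> pd.DataFrame:
    """Symmetric clusters x clusters -log10(p) overlap heatmap table."""
    names = list(sets)
    frozen = {n: set(sets[n]) for n in names}
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i:]:
            p = hypergeom_overlap(frozen[a], frozen[b], universe_n)
            v = -np.log10(max(p, 1e-300))
            out.loc[a, b] = out.loc[b, a] = v
    return out


def clustering_metrics(
    embedding: np.ndarray, labels: Sequence[str]
) -> tuple[float, float, float]:
    """(silhouette, Calinski-Harabasz, Davies-Bouldin) for a labelling."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("clustering metrics need at least 2 clusters")
    emb = np.asarray(embedding, dtype=float)
    return (
        float(silhouette_score(emb, labels)),
        float(calinski_harabasz_score(emb, labels)),
        float(davies_bouldin_score(emb, labels)),
    )


def optimal_k_scan(
    data: np.ndarray,
    k_range: Sequence[int],
    seed: int = 0,
    use_pca: bool = True,
    n_components: int = 20,
) -> pd.DataFrame:
    """k-means scan over candidate cluster numbers.

    Clusters the embedding (PCA of ``data`` by default; pass
    ``use_pca=False`` for a precomputed embedding such as restricted
    latent means) for each k and scores it with the three metrics.
    The returned table carries one row per k plus an ``is_best_*``
    flag per metric (max for silhouette/CH, min for DB).
    """
    k_range = list(k_range)
    data = np.asarray(data, dtype=float)
    if not k_range:
        raise ValueError("empty k range")
    if any(k < 2 or k > data.shape[0] - 1 for k in k_range):
        raise ValueError("k values must lie in [2, n_cells - 1]")
    emb = data
    if use_pca and data.shape[1] > n_components:
        emb = PCA(n_components=n_components, random_state=seed).fit_transform(data)
    rows = []
    for k in k_range:
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(emb)
        sil, ch, db = clustering_metrics(emb, labels.astype(str))
        rows.append({"k": k, "silhouette": sil, "calinski_harabasz": ch, "davies_bouldin": db})
    table = pd.DataFrame(rows)
    table["is_best_silhouette"] = table["silhouette"] == table["silhouette"].max()
    table["is_best_calinski_harabasz"] = (
        table["calinski_harabasz"] == table["calinski_harabasz"].max()
    )
    table["is_best_davies_bouldin"] = table["davies_bouldin"] == table["davies_bouldin"].min()
    return table


def recovery_score(
    consensus: Mapping[str, ConsensusRanking],
    truth: RegulatoryGroundTruth,
    min_confidence: float = 0.5,
) -> float:
    """Macro-averaged fraction of true active-module TFs identified.

    For every cluster present in the consensus, the fraction of the
    ground truth's active TFs that appear in the cluster's identified
    set (confidence >= ``min_confidence``); averaged over clusters.
    """
    fractions = []
    for cluster_id, ranking in consensus.items():
        true_tfs = truth.active_tfs(cluster_id)  # raises for unknown clusters
        if not true_tfs:
            continue
        identified = set(ranking.identified(min_confidence))
        fractions.append(len(identified & set(true_tfs)) / len(true_tfs))
    if not fractions:
        raise ValueError("no cluster with ground-truth TFs found")
    return float(np.mean(fractions))
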