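"""Consensus rankings across the ensemble.

Primary method: Robust Rank Aggregation (RRA). Each feature's
normalized ranks across the ``m`` truncated lists (rank/n within the
full feature universe of size ``n``; 1 for lists where it fell below
the cut-off) are sorted, and the score is

    rho = min_k BetaCDF(r_(k); k, m - k + 1),

the smallest order-statistic tail probability under the uniform null,
Bonferroni-corrected by the number of lists. Small rho means the
feature sits higher across lists than uniform chance allows.

A simplified meta-analysis-by-information-content (MAIC) aggregator is
provided as a secondary method for mixing ranked and unranked lists
with data-driven list weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .types import RankedList

__all__ = [
    "ConsensusRanking",
    "rra_rho",
    "aggregate_cluster",
    "feature_confidence",
    "MaicList",
    "maic_aggregate",
]


def rra_rho(normalized_ranks: np.ndarray, m: int) -> tuple[float, float]:
    """RRA score for one feature.

    ``normalized_ranks`` must already be padded to length ``m`` with
    r = 1 for lists that do not rank the feature. Returns ``(rho,
    corrected)`` with ``corrected = min(rho * m, 1)``.
    """
    r = np.sort(np.asarray(normalized_ranks, dtype=float))
    if r.size != m:
        raise ValueError(f"expected {m} ranks, got {r.size}")
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError("normalized ranks must lie in (0, 1]")
    k = np.arange(1, m + 1)
    rho = float(np.min(beta_dist.cdf(r, k, m - k + 1)))
    return rho, min(rho * m, 1.0)


@dataclass
class ConsensusRanking:
    """Aggregated per-cluster ranking with confidence.

    ``table`` columns: feature_id, rho, corrected, score
    (-log10 corrected, for display), confidence (fraction of models
    ranking the feature above the cut-off), n_models.
    Rows are sorted by rho ascending, ties by feature_id.
    """

    cluster_id: str
    table: pd.DataFrame
    m: int  # number of aggregated lists
    n: int  # feature universe size

    def __post_init__(self) -> None:
        t = self.table
        if np.any((t["rho"] <= 0) | (t["rho"] > 1)):
            raise ValueError("rho must lie in (0, 1]")
        if np.any(t["corrected"] < t["rho"] - 1e-12):
            raise ValueError("corrected score must be >= rho")

    @property
    def features(self) -> list[str]:
        return list(self.table["feature_id"])

    def identified(self, min_confidence: float = 0.5) -> list[str]:
        """Features above the cut-off in at least ``min_confidence`` of models."""
        t = self.table
        return list(t.loc[t["confidence"] >= min_confidence, "feature_id"])


def feature_confidence(feature: str, lists: list[RankedList]) -> float:
    """Fraction of ensemble models ranking ``feature`` above the cut-off.

    A feature absent from every truncated list has confidence 0 by
    contract.
    """
    if not lists:
        raise ValueError("no lists given")
    hits = sum(feature in rl.truncated() for rl in lists)
    return hits / len(lists)


def aggregate_cluster(lists: list[RankedList], universe_size: int) -> ConsensusRanking:
    """RRA consensus over one cluster's truncated per-model rankings.

    Normalized rank r = rank / universe_size for features above a
    list's cut-off; features below the cut-off (or absent) contribute
    r = 1 — truncation is treated as evidence of absence.
    """
    if len(lists) < 2:
        raise ValueError("need at least 2 lists to aggregate")
    m = len(lists)
    cluster_id = lists[0].cluster_id
    ranks: dict[str, list[float]] = {}
    seen: set[str] = set()
    for rl in lists:
        seen.update(rl.features)
        for rank, feat in enumerate(rl.truncated(), start=1):
            if rank > universe_size:
                raise ValueError("universe smaller than an observed rank")
            ranks.setdefault(feat, []).append(rank / universe_size)

    above_counts = {f: len(v) for f, v in ranks.items()}
    rows = []
    for feat in sorted(seen):
        r = ranks.get(feat, [])
        padded = np.concatenate([r, np.ones(m - len(r))]) if len(r) < m else np.asarray(r)
        rho, corrected = rra_rho(padded, m)
        rows.append(
            {
                "feature_id": feat,
                "rho": rho,
                "corrected": corrected,
                "score": -np.log10(max(corrected, 1e-300)),
                "confidence": above_counts.get(feat, 0) / m,
                "n_models": above_counts.get(feat, 0),
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["rho", "feature_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return ConsensusRanking(cluster_id=cluster_id, table=table, m=m, n=universe_size)


@dataclass
class MaicList:
    """One input list for MAIC: ordered features, a category tag, and
    whether the order is informative (ranked) or not."""

    features: list[str]
    category: str = "default"
    ranked: bool = True
    name: str = ""


def maic_aggregate(
    lists: list[MaicList], tol: float = 1e-6, max_iter: int = 100
) -> pd.DataFrame:
    """Simplified meta-analysis by information content.

    Iterates between (a) scoring each feature as the sum over
    categories of its best weighted list contribution (rank-discounted
    for ranked lists) and (b) re-weighting each list by the root-mean
    score of its members, with weights normalized to a unit maximum.
    Deterministic given input order; warns if not converged within
    ``max_iter`` iterations and returns the last iterate.
    """
    if not lists or any(len(l.features) == 0 for l in lists):
        raise ValueError("MAIC requires non-empty input lists")
    features = sorted({f for l in lists for f in l.features})
    weights = np.ones(len(lists))
    scores = {f: 0.0 for f in features}
    rank_factor = [
        {f: (1.0 - i / len(l.features)) if l.ranked else 1.0 for i, f in enumerate(l.features)}
        for l in lists
    ]
    categories = sorted({l.category for l in lists})
    for _ in range(max_iter):
        new_scores = {}
        for f in features:
            total = 0.0
            for cat in categories:
                contribs = [
                    weights[i] * rank_factor[i][f]
                    for i, l in enumerate(lists)
                    if l.category == cat and f in rank_factor[i]
                ]
                if contribs:
                    total += max(contribs)
            new_scores[f] = total
        new_weights = np.array(
            [np.sqrt(np.mean([new_scores[f] for f in l.features])) for l in lists]
        )
        if new_weights.max() > 0:
            new_weights = new_weights / new_weights.max()
        delta = max(
            max(abs(new_scores[f] - scores[f]) for f in features),
            float(np.max(np.abs(new_weights - weights))),
        )
        scores, weights = new_scores, new_weights
        if delta < tol:
            break
    else:
        warnings.warn("MAIC did not converge; returning last iterate", RuntimeWarning)
    out = pd.DataFrame(
        {"feature_id": features, "score": [scores[f] for f in features]}
    ).sort_values(["score", "feature_id"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)
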