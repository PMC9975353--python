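"""Ranked feature lists and the bin-and-rotate knee/elbow cut-off.

A weight mapping row is sorted into a descending curve; the cut-off is
the knee of that curve, found by splitting the curve into ``n_bins``
equal bins, rotating the first bin so the chord from its first data
point to its (upper-)median data point lies on the x-axis, and taking
the rotated-y maximum. The elbow is the mirror construction on the last
bin (rotated-y minimum). The per-cluster cut-off used for aggregation
is the median of the per-model knee indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import RankedList, WeightMapping

__all__ = [
    "CutoffSet",
    "rank_features",
    "find_knee",
    "find_elbow",
    "median_cutoff",
    "compute_cutoffs",
    "apply_cutoffs",
]


def rank_features(mapping: WeightMapping, cluster_id: str) -> RankedList:
    """Descending-score ranking of one cluster's weight-mapping row.

    Ties are broken lexicographically by feature id, which makes the
    ordering fully deterministic.
    """
    if cluster_id not in mapping.cluster_ids:
        raise KeyError(f"unknown cluster {cluster_id!r}")
    row = mapping.scores[mapping.cluster_ids.index(cluster_id)]
    order = sorted(range(len(row)), key=lambda j: (-row[j], mapping.feature_ids[j]))
    return RankedList(
        cluster_id=cluster_id,
        features=[mapping.feature_ids[j] for j in order],
        scores=row[np.asarray(order)],
        model_id=mapping.model_id,
    )


def _bin_bounds(n: int, n_bins: int) -> list[tuple[int, int]]:
    """Half-open index ranges of ``n_bins`` equal-size (+-1) bins."""
    edges = np.linspace(0, n, n_bins + 1).round().astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_bins)]


def _check_curve(y: np.ndarray, n_bins: int) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if y.size < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} points for {n_bins} bins")
    if np.any(np.diff(y) > 1e-12):
        raise ValueError("curve must be sorted non-increasing")
    return y


def _rotated_ordinates(y_bin: np.ndarray, frm: int, to: int) -> np.ndarray | None:
    """Rotate the bin's (x, y) points so the frm->to chord is flat.

    x is normalized to [0, 1] across the bin, y to [0, 1] over the bin's
    own range; returns the rotated y coordinates, or None for a constant
    bin (no drop/rise to locate). The chord direction matters: reversing
    it rotates by an extra half-turn and negates the ordinates.
    """
    s = y_bin.size
    lo, hi = float(y_bin.min()), float(y_bin.max())
    if hi - lo <= 0:
        return None
    x = np.linspace(0.0, 1.0, s)
    yn = (y_bin - lo) / (hi - lo)
    theta = math.atan2(yn[to] - yn[frm], x[to] - x[frm])
    # rotate by -theta: y' = -x sin(theta) + y cos(theta)
    return -x * math.sin(theta) + yn * math.cos(theta)


def _upper_median_index(size: int) -> int:
    # 0-based position of the bin's "median data point" (upper median)
    return min(int(math.ceil(size / 2)), size - 1)


def find_knee(y: np.ndarray, n_bins: int = 10) -> int | None:
    """1-based index of the knee (pronounced drop) in a descending curve.

    The search is restricted to the first bin; the chord runs from the
    bin's first data point to its upper-median data point, and the knee
    is the rotated-y maximum (ties to the smallest index). Returns None
    when the first bin is constant.
    """
    y = _check_curve(y, n_bins)
    start, stop = _bin_bounds(y.size, n_bins)[0]
    y_bin = y[start:stop]
    rot = _rotated_ordinates(y_bin, frm=0, to=_upper_median_index(y_bin.size))
    if rot is None:
        return None
    # ties (e.g. colinear points) resolve to the smallest index
    return start + int(np.flatnonzero(rot >= rot.max() - 1e-9)[0]) + 1


def find_elbow(y: np.ndarray, n_bins: int = 10) -> int | None:
    """1-based index of the elbow in the last bin (mirror of the knee).

    The chord runs from the last bin's lower-median data point to its
    last data point; the elbow is the rotated-y minimum. Returns None
    when the last bin is constant.
    """
    y = _check_curve(y, n_bins)
    start, stop = _bin_bounds(y.size, n_bins)[-1]
    y_bin = y[start:stop]
    s = y_bin.size
    med = s - 1 - _upper_median_index(s)  # mirrored median position
    rot = _rotated_ordinates(y_bin, frm=med, to=s - 1)
    if rot is None:
        return None
    return start + int(np.flatnonzero(rot <= rot.min() + 1e-9)[0]) + 1


def median_cutoff(cutoffs: list[int]) -> int:
    """Median of per-model cut-off indices; even counts round half up."""
    if not cutoffs:
        raise ValueError(
            "no cut-offs to aggregate: every model's knee search returned None; "
            "inspect the weight curves (they may be flat)"
        )
    vals = sorted(int(c) for c in cutoffs)
    if any(v < 1 for v in vals):
        raise ValueError("cut-off indices must be >= 1")
    n = len(vals)
    if n % 2 == 1:
        return vals[n // 2]
    return int(math.floor((vals[n // 2 - 1] + vals[n // 2]) / 2.0 + 0.5))


@dataclass
class CutoffSet:
    """Per-(model, cluster) knees plus the per-cluster median cut-off."""

    n_bins: int
    per_model: dict[tuple[str, str], int | None]  # (model_id, cluster_id) -> knee
    per_cluster: dict[str, int]  # cluster_id -> median cut-off

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if any(v is not None and v < 1 for v in self.per_model.values()):
            raise ValueError("cut-offs must be >= 1")


def compute_cutoffs(mappings: list[WeightMapping], n_bins: int = 10) -> CutoffSet:
    """Knee per (model, cluster), then the median knee per cluster."""
    if not mappings:
        raise ValueError("no weight mappings given")
    cluster_ids = mappings[0].cluster_ids
    per_model: dict[tuple[str, str], int | None] = {}
    per_cluster: dict[str, int] = {}
    for c in cluster_ids:
        knees = []
        for m in mappings:
            rl = rank_features(m, c)
            knee = find_knee(rl.scores, n_bins)
            per_model[(m.model_id, c)] = knee
            if knee is not None:
                knees.append(knee)
        per_cluster[c] = median_cutoff(knees)
    return CutoffSet(n_bins=n_bins, per_model=per_model, per_cluster=per_cluster)


def apply_cutoffs(
    mappings: list[WeightMapping], cutoffs: CutoffSet
) -> dict[str, list[RankedList]]:
    """Per cluster: each model's ranking truncated at the shared median cut-off."""
    out: dict[str, list[RankedList]] = {}
    for c in mappings[0].cluster_ids:
        cut = cutoffs.per_cluster[c]
        lists = []
        for m in mappings:
            rl = rank_features(m, c)
            rl.cutoff_index = min(cut, len(rl))
            lists.append(rl)
        out[c] = lists
    return out
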