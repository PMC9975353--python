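"""Core data containers shared across the pipeline.

All containers are thin, validated wrappers around numpy arrays with
explicit identifier lists, so that every downstream table can be traced
back to named cells, clusters and features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "ClusterAssignment",
    "ModelConfig",
    "WeightMapping",
    "RankedList",
]

_ROW_SUM_TOL = 1e-6


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass(frozen=True)
class ExpressionMatrix:
    """Cells x features non-negative expression (or accessibility) matrix.

    Attributes
    ----------
    values
        Dense array of shape ``(n_cells, n_features)``; counts or any
        non-negative transformation thereof.
    feature_ids, cell_ids
        Unique string identifiers for columns and rows respectively.
    """

    values: np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values contain NaN/Inf")
        if np.any(values < 0):
            raise ValueError("expression values contain negative entries")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", _check_unique(self.feature_ids, "feature_ids"))
        object.__setattr__(self, "cell_ids", _check_unique(self.cell_ids, "cell_ids"))
        if len(self.feature_ids) != values.shape[1]:
            raise ValueError("feature_ids length does not match column count")
        if len(self.cell_ids) != values.shape[0]:
            raise ValueError("cell_ids length does not match row count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ClusterAssignment:
    """Cells x clusters membership weights in [0, 1].

    One-hot rows encode a hard clustering; mixed rows encode soft or
    partial identities (transitional cells, archetype mixtures). Soft
    rows must sum to one.
    """

    weights: np.ndarray
    cluster_ids: list[str]
    cell_ids: list[str]
    is_hard: bool = False

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        if weights.ndim != 2:
            raise ValueError("assignment weights must be a 2-D matrix")
        if np.any(weights < -_ROW_SUM_TOL) or np.any(weights > 1 + _ROW_SUM_TOL):
            raise ValueError("assignment weights must lie in [0, 1]")
        weights = np.clip(weights, 0.0, 1.0)
        sums = weights.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _ROW_SUM_TOL):
            raise ValueError("assignment rows must sum to 1 (within 1e-6)")
        if self.is_hard:
            one_hot = (weights == 1.0).sum(axis=1) == 1
            if not np.all(one_hot & (np.isin(weights, (0.0, 1.0)).all(axis=1))):
                raise ValueError("is_hard=True requires one-hot rows")
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "cluster_ids", _check_unique(self.cluster_ids, "cluster_ids"))
        object.__setattr__(self, "cell_ids", _check_unique(self.cell_ids, "cell_ids"))
        if len(self.cluster_ids) != weights.shape[1]:
            raise ValueError("cluster_ids length does not match column count")
        if len(self.cell_ids) != weights.shape[0]:
            raise ValueError("cell_ids length does not match row count")

    @property
    def n_clusters(self) -> int:
        return self.weights.shape[1]

    def hard_labels(self) -> np.ndarray:
        """Cluster id of the argmax weight per cell."""
        idx = np.argmax(self.weights, axis=1)
        return np.asarray([self.cluster_ids[i] for i in idx])

    @classmethod
    def from_labels(
        cls, labels: Sequence[str], cell_ids: Sequence[str], cluster_ids: Sequence[str] | None = None
    ) -> "ClusterAssignment":
        labels = [str(x) for x in labels]
        if cluster_ids is None:
            cluster_ids = sorted(set(labels))
        index = {c: j for j, c in enumerate(cluster_ids)}
        weights = np.zeros((len(labels), len(cluster_ids)))
        for i, lab in enumerate(labels):
            weights[i, index[lab]] = 1.0
        return cls(weights=weights, cluster_ids=list(cluster_ids), cell_ids=list(cell_ids), is_hard=True)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of a single restricted-latent VAE.

    ``alpha`` scales the reconstruction error and ``beta`` the KL
    divergence (beta-VAE style); ``latent_offset`` shifts the centre of
    the latent prior. Each cluster owns a contiguous block of
    ``latent_units_per_cluster`` latent units gated by the (smoothed)
    assignment weights.
    """

    alpha: float = 1.0
    beta: float = 1.0
    latent_offset: float = 0.0
    activation: str = "mish"
    encoder_units: int = 256
    decoder_units: int = 512
    latent_units_per_cluster: int = 8
    label_smoothing_eps: float = 0.1
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    normalize: bool = True  # library-size normalize + log1p before fitting
    nonneg_decoder: bool = True  # constrain decoder weights to be >= 0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not 0 <= self.label_smoothing_eps < 1:
            raise ValueError("label_smoothing_eps must lie in [0, 1)")
        if self.encoder_units < 1 or self.decoder_units < 1:
            raise ValueError("encoder/decoder units must be >= 1")
        if self.latent_units_per_cluster < 1:
            raise ValueError("latent_units_per_cluster must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if self.activation not in ("mish", "relu"):
            raise ValueError("activation must be 'mish' or 'relu'")

    def with_overrides(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class WeightMapping:
    """Clusters x features relevance scores from one trained decoder.

    ``scores[c, g]`` is the summed absolute linear path weight from
    cluster ``c``'s latent block to output feature ``g``.
    """

    scores: np.ndarray
    cluster_ids: list[str]
    feature_ids: list[str]
    model_id: str = ""

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2:
            raise ValueError("scores must be a 2-D matrix")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores contain NaN/Inf")
        if np.any(scores < 0):
            raise ValueError("scores must be non-negative")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "cluster_ids", _check_unique(self.cluster_ids, "cluster_ids"))
        object.__setattr__(self, "feature_ids", _check_unique(self.feature_ids, "feature_ids"))
        if scores.shape != (len(self.cluster_ids), len(self.feature_ids)):
            raise ValueError("scores shape does not match id lists")


@dataclass
class RankedList:
    """Descending-score feature ranking for one (model, cluster) pair.

    ``cutoff_index`` is 1-based and inclusive: the list's "identified"
    features are ``features[:cutoff_index]``.
    """

    cluster_id: str
    features: list[str]
    scores: np.ndarray
    cutoff_index: int | None = None
    model_id: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.features) != self.scores.size:
            raise ValueError("features and scores length mismatch")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")
        if self.cutoff_index is not None:
            if not 1 <= self.cutoff_index <= len(self.features):
                raise ValueError("cutoff_index out of range")

    def truncated(self) -> list[str]:
        """Features at or above the cut-off (all features if no cut-off)."""
        if self.cutoff_index is None:
            return list(self.features)
        return list(self.features[: self.cutoff_index])

    def __len__(self) -> int:
        return len(self.features)
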