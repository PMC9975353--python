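"""Deep ensembles of resVAE models and decoder weight-mapping extraction.

An ensemble is a hyperparameter grid crossed with seeded replicates.
Each trained decoder yields one clusters x features relevance matrix:
the summed absolute linear path weight from a cluster's latent block
through the decoder to each output feature. Nonlinearities are ignored
for extraction (linear-path surrogate), which keeps the mapping
architecture-agnostic and exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import TrainedModel, train_model
from .types import ClusterAssignment, ExpressionMatrix, ModelConfig, WeightMapping

__all__ = ["EnsembleConfig", "extract_weight_mapping", "run_ensemble", "default_grid"]

logger = logging.getLogger(__name__)


def default_grid() -> list[dict]:
    """Default hyperparameter grid: alpha x beta in {1, 2}, mish activation."""
    return [
        {"alpha": a, "beta": b, "activation": "mish"}
        for a in (1.0, 2.0)
        for b in (1.0, 2.0)
    ]


@dataclass(frozen=True)
class EnsembleConfig:
    """Grid of model-config overrides crossed with seeded replicates.

    The total model count is ``len(grid) * replicates_per_setting``;
    ``seeds`` must provide one unique seed per model (grid-major,
    replicate-minor order). When ``seeds`` is empty, seeds are derived
    deterministically from ``base.seed``.
    """

    base: ModelConfig = field(default_factory=ModelConfig)
    grid: tuple = tuple()
    replicates_per_setting: int = 4
    seeds: tuple = tuple()

    def __post_init__(self) -> None:
        if self.replicates_per_setting < 1:
            raise ValueError("replicates_per_setting must be >= 1")
        grid = tuple(dict(g) for g in (self.grid or default_grid()))
        object.__setattr__(self, "grid", grid)
        n = len(grid) * self.replicates_per_setting
        seeds = tuple(self.seeds) if self.seeds else tuple(self.base.seed + i for i in range(n))
        if len(seeds) != n:
            raise ValueError(f"need {n} seeds, got {len(seeds)}")
        if len(set(seeds)) != len(seeds):
            raise ValueError("seeds must be unique")
        object.__setattr__(self, "seeds", seeds)

    @property
    def n_models(self) -> int:
        return len(self.grid) * self.replicates_per_setting

    def model_configs(self) -> list[tuple[str, ModelConfig]]:
        """(model_id, config) pairs in grid-major, seed-minor order."""
        out = []
        i = 0
        for gi, overrides in enumerate(self.grid):
            for ri in range(self.replicates_per_setting):
                cfg = self.base.with_overrides(seed=int(self.seeds[i]), **overrides)
                out.append((f"g{gi}_r{ri}_s{self.seeds[i]}", cfg))
                i += 1
        return out


def extract_weight_mapping(model: TrainedModel) -> WeightMapping:
    """Clusters x features absolute decoder path weights.

    ``score(c, g) = sum_{i in block(c)} (|W_1| |W_2| ... |W_k|)[i, g]``
    over the decoder weight chain; biases are excluded (they are
    feature-global, not cluster-specific). Negating any single weight
    leaves the scores unchanged.
    """
    chain = model.decoder_weights()
    path = np.abs(chain[0])
    for w in chain[1:]:
        path = path @ np.abs(w)
    u = model.config.latent_units_per_cluster
    n_clusters = len(model.cluster_ids)
    scores = path.reshape(n_clusters, u, -1).sum(axis=1)
    return WeightMapping(
        scores=scores,
        cluster_ids=list(model.cluster_ids),
        feature_ids=list(model.feature_ids),
        model_id=model.model_id,
    )


def run_ensemble(
    data: ExpressionMatrix,
    assignment: ClusterAssignment,
    ens: EnsembleConfig,
    return_models: bool = False,
):
    """Train the grid and extract one weight mapping per model.

    Model order is deterministic (grid-major, replicate-minor). A model
    that fails to train is logged and skipped; at least two survivors
    are required.
    """
    configs = ens.model_configs()
    if len(configs) < 2:
        raise ValueError("an ensemble needs at least 2 models")
    mappings: list[WeightMapping] = []
    models: list[TrainedModel] = []
    for model_id, cfg in configs:
        try:
            model = train_model(data, assignment, cfg, model_id=model_id)
        except ValueError:
            # invalid inputs fail every model identically; re-raise early
            raise
        except Exception:  # noqa: BLE001 - isolate per-model numeric failures
            logger.exception("model %s failed to train; skipped", model_id)
            continue
        mappings.append(extract_weight_mapping(model))
        if return_models:
            models.append(model)
    if len(mappings) < 2:
        raise RuntimeError("fewer than 2 ensemble models trained successfully")
    if return_models:
        return mappings, models
    return mappings
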