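"""End-to-end convenience: ensemble -> cut-offs -> consensus per cluster."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .aggregation import ConsensusRanking, aggregate_cluster
from .ensemble import EnsembleConfig, run_ensemble
from .ranking import CutoffSet, apply_cutoffs, compute_cutoffs
from .types import ClusterAssignment, ExpressionMatrix, RankedList, WeightMapping

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced, keyed by cluster where relevant."""

    mappings: list[WeightMapping]
    cutoffs: CutoffSet
    truncated_lists: dict[str, list[RankedList]]
    consensus: dict[str, ConsensusRanking]

    def identified_sets(self, min_confidence: float = 0.5) -> dict[str, list[str]]:
        """Per-cluster features above the cut-off in a majority of models."""
        return {c: r.identified(min_confidence) for c, r in self.consensus.items()}

    def consensus_table(self) -> pd.DataFrame:
        """All clusters' consensus rankings stacked into one tidy table."""
        frames = []
        for c, r in self.consensus.items():
            t = r.table.copy()
            t.insert(0, "cluster_id", c)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)


def run_pipeline(
    data: ExpressionMatrix,
    assignment: ClusterAssignment,
    ens: EnsembleConfig | None = None,
    n_bins: int = 10,
) -> PipelineResult:
    """Train the ensemble and aggregate each cluster's rankings.

    Steps: train ``ens`` and extract one weight mapping per model;
    rank each cluster's features per model; find the knee of each
    descending weight curve and take the per-cluster median across
    models; truncate every model's list there; RRA-aggregate the
    truncated lists over the full feature universe.
    """
    ens = ens or EnsembleConfig()
    mappings = run_ensemble(data, assignment, ens)
    cutoffs = compute_cutoffs(mappings, n_bins=n_bins)
    truncated = apply_cutoffs(mappings, cutoffs)
    universe = len(data.feature_ids)
    consensus = {c: aggregate_cluster(lists, universe) for c, lists in truncated.items()}
    return PipelineResult(
        mappings=mappings, cutoffs=cutoffs, truncated_lists=truncated, consensus=consensus
    )
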