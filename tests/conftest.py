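import numpy as np
import pytest

from resvae_ensemble import (
    ClusterAssignment,
    ExpressionMatrix,
    ModelConfig,
    SimulationConfig,
    simulate_bifurcation,
)


@pytest.fixture(scope="session")
def tiny_bifurcation():
    """Small bifurcation dataset for fast training tests."""
    cfg = SimulationConfig(
        n_cells_per_population=30, n_targets=150, n_housekeeping=8, seed=7
    )
    data, hard, soft, truth = simulate_bifurcation(cfg)
    return cfg, data, hard, soft, truth


@pytest.fixture(scope="session")
def tiny_model_config():
    """Small but real training configuration."""
    return ModelConfig(
        epochs=20,
        encoder_units=64,
        decoder_units=96,
        latent_units_per_cluster=4,
        seed=42,
    )


@pytest.fixture
def toy_matrix():
    values = np.array([[1.0, 0.0, 2.0], [0.0, 3.0, 1.0], [2.0, 1.0, 0.0], [1.0, 1.0, 1.0]])
    return ExpressionMatrix(
        values=values, feature_ids=["g1", "g2", "g3"], cell_ids=["c1", "c2", "c3", "c4"]
    )


@pytest.fixture
def toy_assignment():
    return ClusterAssignment.from_labels(
        ["a", "a", "b", "b"], ["c1", "c2", "c3", "c4"], cluster_ids=["a", "b"]
    )
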