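"""Tests for ensemble training and weight-mapping extraction."""

import numpy as np
import pytest

from resvae_ensemble import (
    EnsembleConfig,
    ModelConfig,
    extract_weight_mapping,
    rank_features,
    run_ensemble,
    train_model,
)
from resvae_ensemble.ensemble import default_grid
from resvae_ensemble.model import TrainedModel


def _toy_model(w_d1, w_d2, u=1):
    """Hand-built TrainedModel with a fixed decoder, for extraction tests."""
    w_d1 = np.asarray(w_d1, dtype=float)
    w_d2 = np.asarray(w_d2, dtype=float)
    n_latent, hidden = w_d1.shape
    n_feat = w_d2.shape[1]
    n_clusters = n_latent // u
    cfg = ModelConfig(epochs=1, latent_units_per_cluster=u, encoder_units=2, decoder_units=hidden)
    params = {
        "W_e": np.zeros((n_feat, 2)), "b_e": np.zeros(2),
        "W_mu": np.zeros((2, n_latent)), "b_mu": np.zeros(n_latent),
        "W_ls": np.zeros((2, n_latent)), "b_ls": np.zeros(n_latent),
        "W_d1": w_d1, "b_d1": np.zeros(hidden),
        "W_d2": w_d2, "b_d2": np.zeros(n_feat),
    }
    return TrainedModel(
        config=cfg, params=params, loss_history=[0.0],
        cluster_ids=[f"k{i}" for i in range(n_clusters)],
        feature_ids=[f"g{i}" for i in range(n_feat)],
        model_id="toy",
    )


class TestExtractWeightMapping:
    def test_hand_set_weights_match_path_enumeration(self):
        # u=1, 2 latent, 2 hidden, 2 genes: score = |W1| @ |W2|
        m = _toy_model([[1.0, 0.0], [0.0, 2.0]], [[3.0, 0.0], [0.0, 4.0]])
        np.testing.assert_allclose(extract_weight_mapping(m).scores, [[3.0, 0.0], [0.0, 8.0]])

    def test_brute_force_path_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        u, n_clusters, hidden, n_feat = 2, 3, 4, 5
        w1 = rng.normal(size=(u * n_clusters, hidden))
        w2 = rng.normal(size=(hidden, n_feat))
        scores = extract_weight_mapping(_toy_model(w1, w2, u=u)).scores
        brute = np.zeros((n_clusters, n_feat))
        for c in range(n_clusters):
            for g in range(n_feat):
                for i in range(c * u, (c + 1) * u):
                    for h in range(hidden):
                        brute[c, g] += abs(w1[i, h]) * abs(w2[h, g])
        np.testing.assert_allclose(scores, brute, rtol=1e-12)

    def test_sign_invariance(self):
        w1, w2 = [[1.0, -2.0], [0.5, 2.0]], [[3.0, 1.0], [-1.0, 4.0]]
        base = extract_weight_mapping(_toy_model(w1, w2)).scores
        w1_neg = [[-1.0, -2.0], [0.5, 2.0]]
        np.testing.assert_allclose(extract_weight_mapping(_toy_model(w1_neg, w2)).scores, base)

    def test_zero_decoder_gives_zero_scores(self):
        m = _toy_model(np.zeros((2, 2)), np.zeros((2, 3)))
        assert np.all(extract_weight_mapping(m).scores == 0)

    def test_nan_parameters_rejected(self):
        with pytest.raises(ValueError):
            _toy_model([[np.nan, 0.0], [0.0, 1.0]], np.eye(2))


class TestEnsembleConfig:
    def test_model_count_and_order(self):
        ens = EnsembleConfig(replicates_per_setting=2)
        assert ens.n_models == len(default_grid()) * 2
        ids = [mid for mid, _ in ens.model_configs()]
        assert ids == sorted(ids, key=lambda s: (int(s.split("_")[0][1:]), int(s.split("_")[1][1:])))

    def test_duplicate_seeds_rejected(self):
        with pytest.raises(ValueError):
            EnsembleConfig(grid=[{"alpha": 1.0}], replicates_per_setting=2, seeds=(1, 1))

    def test_seed_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            EnsembleConfig(grid=[{"alpha": 1.0}], replicates_per_setting=2, seeds=(1,))


@pytest.fixture(scope="module")
def small_ensemble(tiny_bifurcation, tiny_model_config):
    _, data, hard, _, _ = tiny_bifurcation
    ens = EnsembleConfig(
        base=tiny_model_config.with_overrides(epochs=120),
        grid=[{"alpha": 1.0}, {"alpha": 2.0}],
        replicates_per_setting=2,
    )
    return run_ensemble(data, hard, ens), data, hard, ens


class TestRunEnsemble:

    def test_one_mapping_per_model(self, small_ensemble):
        mappings, _, _, ens = small_ensemble
        assert len(mappings) == 4 == ens.n_models
        assert [m.model_id for m in mappings] == [mid for mid, _ in ens.model_configs()]

    def test_deterministic_across_runs(self, small_ensemble, tiny_bifurcation):
        mappings, data, hard, ens = small_ensemble
        again = run_ensemble(data, hard, ens)
        for a, b in zip(mappings, again):
            np.testing.assert_array_equal(a.scores, b.scores)

    def test_fewer_than_two_models_rejected(self, tiny_bifurcation, tiny_model_config):
        _, data, hard, _, _ = tiny_bifurcation
        ens = EnsembleConfig(base=tiny_model_config, grid=[{"alpha": 1.0}], replicates_per_setting=1)
        with pytest.raises(ValueError):
            run_ensemble(data, hard, ens)

    def test_true_module_tfs_outrank_housekeeping(self, small_ensemble, tiny_bifurcation):
        """In a terminal population, true branch-module TFs score above
        housekeeping genes (median over the ensemble)."""
        mappings, _, _, _ = small_ensemble
        _, _, _, _, truth = tiny_bifurcation
        true_tfs = truth.active_tfs("sEndC")
        hk = truth.housekeeping()
        med_scores = np.median(
            np.stack([m.scores[m.cluster_ids.index("sEndC")] for m in mappings]), axis=0
        )
        idx = {f: j for j, f in enumerate(mappings[0].feature_ids)}
        tf_median = np.median([med_scores[idx[f]] for f in true_tfs])
        hk_median = np.median([med_scores[idx[f]] for f in hk])
        assert tf_median > hk_median

    def test_rank_dispersion_lower_for_true_tfs(self, small_ensemble, tiny_bifurcation):
        """Across models, true TFs keep steadier ranks than housekeeping
        genes in their home cluster (the 'thick uniform lines' property)."""
        mappings, _, _, _ = small_ensemble
        _, _, _, _, truth = tiny_bifurcation
        true_tfs = truth.active_tfs("sEndC")
        hk = truth.housekeeping()
        ranks = {f: [] for f in true_tfs + hk}
        for m in mappings:
            rl = rank_features(m, "sEndC")
            pos = {f: i for i, f in enumerate(rl.features)}
            for f in ranks:
                ranks[f].append(pos[f])

        def iqr(v):
            return np.subtract(*np.percentile(v, [75, 25]))

        tf_iqr = np.median([iqr(ranks[f]) for f in true_tfs])
        hk_iqr = np.median([iqr(ranks[f]) for f in hk])
        assert tf_iqr < hk_iqr


class TestFeaturePermutationEquivariance:
    """Permuting feature columns (with correspondingly permuted initial
    parameters) permutes the extracted scores and nothing else."""

    def test_extraction_is_equivariant(self):
        rng = np.random.default_rng(4)
        w1 = rng.normal(size=(2, 3))
        w2 = rng.normal(size=(3, 5))
        perm = rng.permutation(5)
        base = extract_weight_mapping(_toy_model(w1, w2)).scores
        permuted = extract_weight_mapping(_toy_model(w1, w2[:, perm])).scores
        np.testing.assert_allclose(permuted, base[:, perm])

    def test_training_step_is_equivariant(self):
        from resvae_ensemble.model import _batch_forward_backward, _init_params

        cfg = ModelConfig(epochs=1, encoder_units=6, decoder_units=7,
                          latent_units_per_cluster=2, seed=0)
        rng = np.random.default_rng(8)
        n_feat, n_latent = 5, 4
        params = _init_params(rng, n_feat, n_latent, cfg)
        x = rng.uniform(size=(3, n_feat))
        mask = np.repeat(rng.uniform(0.5, 1.0, size=(3, 2)), 2, axis=1)
        eps = rng.standard_normal((3, n_latent))
        loss, grads = _batch_forward_backward(params, x, mask, eps, cfg)

        perm = rng.permutation(n_feat)
        p2 = {k: v.copy() for k, v in params.items()}
        p2["W_e"] = params["W_e"][perm]
        p2["W_d2"] = params["W_d2"][:, perm]
        p2["b_d2"] = params["b_d2"][perm]
        loss2, grads2 = _batch_forward_backward(p2, x[:, perm], mask, eps, cfg)
        assert loss2 == pytest.approx(loss, rel=1e-12)
        np.testing.assert_allclose(grads2["W_d2"], grads["W_d2"][:, perm], atol=1e-12)
        np.testing.assert_allclose(grads2["W_e"], grads["W_e"][perm], atol=1e-12)
        np.testing.assert_allclose(grads2["W_d1"], grads["W_d1"], atol=1e-12)
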