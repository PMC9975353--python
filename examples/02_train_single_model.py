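"""Train one restricted-latent VAE and read off its weight mapping.

A single model already ranks a terminal population's true module TFs
near the top of its cluster block, but single-model rankings are noisy
-- that is what the ensemble (example 03) fixes.
"""

from resvae_ensemble import (
    ModelConfig,
    SimulationConfig,
    extract_weight_mapping,
    find_knee,
    rank_features,
    simulate_bifurcation,
    train_model,
)

cfg = SimulationConfig(n_cells_per_population=60, n_targets=150, n_housekeeping=8, seed=3)
data, hard, _, truth = simulate_bifurcation(cfg)

model_cfg = ModelConfig(epochs=80, encoder_units=64, decoder_units=96,
                        latent_units_per_cluster=4, seed=12)
model = train_model(data, hard, model_cfg)
print(f"loss: {model.loss_history[0]:.1f} (epoch 1) -> {model.final_loss:.1f} (epoch {model_cfg.epochs})")

mapping = extract_weight_mapping(model)
ranking = rank_features(mapping, "sEndC")
knee = find_knee(ranking.scores, n_bins=10)
print(f"sEndC knee cut-off at rank {knee} of {len(ranking)}")

true_tfs = set(truth.active_tfs("sEndC"))
top = ranking.features[:15]
print("top 15 features for sEndC (* = true active-module TF):")
for i, f in enumerate(top, 1):
    mark = " *" if f in true_tfs else ""
    print(f"  {i:>2}. {f}{mark}")
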