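"""Restricted-latent variational autoencoder (resVAE).

The latent space is partitioned into one contiguous block per cluster;
after sampling, each block is multiplied by the cell's (smoothed)
membership weight for that cluster. A cell therefore only writes to the
latent blocks of clusters it belongs to, which is what makes decoder
weights attributable to clusters downstream.

Loss: ``alpha * sum((x - x_hat)^2) + beta * KL`` with the analytic
Gaussian divergence ``KL = 1/2 sum(e^logvar + (s - mu)^2 - 1 - logvar)``
centred on the latent offset ``s``. With ``alpha = beta = 1`` this is
the standard VAE objective. Optimization uses RAdam wrapped in
Lookahead; weights are initialized He-uniform under ReLU and
Glorot-uniform under mish, the pairing the activations call for.

By default the decoder is an additive-programs decoder: its weights
are constrained non-negative (projected gradient steps) and it
consumes the magnitude of the restricted latent, ``|z * mask|``. The
output bias then learns the baseline expression profile and each
cluster's latent block can only add expression on top of it —
mirroring how transcriptional programs act — so decoder weight mass
stays attributable to the clusters that actually use it. Reading the
latent through its magnitude makes program activation sign-free, which
removes a dead-unit trap where a block whose posterior mean drifts
negative could never recover against non-negative weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import ACTIVATIONS, RAdamLookahead, init_for_activation
from .types import ClusterAssignment, ExpressionMatrix, ModelConfig

_MAX_GRAD_NORM = 5000.0

__all__ = [
    "LatentState",
    "TrainedModel",
    "smooth_labels",
    "restrict_latent",
    "vae_loss",
    "preprocess",
    "train_model",
]


@dataclass
class LatentState:
    """Latent posterior for a batch: means, log-variances and samples.

    ``block_map[c]`` is the half-open index range of cluster ``c``'s
    latent block; blocks are contiguous, disjoint and equally sized.
    """

    mu: np.ndarray
    log_sigma: np.ndarray
    z: np.ndarray
    block_map: dict[str, tuple[int, int]]


@dataclass
class TrainedModel:
    """A fitted resVAE: config, parameters and training trace."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    loss_history: list[float]
    cluster_ids: list[str]
    feature_ids: list[str]
    model_id: str = ""

    def __post_init__(self) -> None:
        if len(self.loss_history) != self.config.epochs:
            raise ValueError("loss history length must equal epochs")
        for name, p in self.params.items():
            if not np.all(np.isfinite(p)):
                raise ValueError(f"parameter {name} contains NaN/Inf")

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1]

    @property
    def n_latent(self) -> int:
        return len(self.cluster_ids) * self.config.latent_units_per_cluster

    def block_map(self) -> dict[str, tuple[int, int]]:
        u = self.config.latent_units_per_cluster
        return {c: (i * u, (i + 1) * u) for i, c in enumerate(self.cluster_ids)}

    def decoder_weights(self) -> list[np.ndarray]:
        """Decoder weight matrices, latent-side first (biases excluded)."""
        return [self.params["W_d1"], self.params["W_d2"]]

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and log-variance for (preprocessed) input rows."""
        act, _ = ACTIVATIONS[self.config.activation]
        h = act(x @ self.params["W_e"] + self.params["b_e"])
        mu = h @ self.params["W_mu"] + self.params["b_mu"]
        log_sigma = h @ self.params["W_ls"] + self.params["b_ls"]
        return mu, log_sigma

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.config.nonneg_decoder:
            z = np.abs(z)  # additive-programs decoder is sign-free
        act, _ = ACTIVATIONS[self.config.activation]
        h = act(z @ self.params["W_d1"] + self.params["b_d1"])
        return h @ self.params["W_d2"] + self.params["b_d2"]

    def restricted_latent_means(
        self, data: ExpressionMatrix, assignment: ClusterAssignment
    ) -> np.ndarray:
        """Per-cell posterior means masked by the assignment (embedding)."""
        x = preprocess(data.values, self.config.normalize)
        mu, _ = self.encode(x)
        smoothed = smooth_labels(assignment, self.config.label_smoothing_eps)
        mask = np.repeat(smoothed.weights, self.config.latent_units_per_cluster, axis=1)
        return mu * mask


def smooth_labels(assignment: ClusterAssignment, eps: float) -> ClusterAssignment:
    """Label smoothing: one-hot rows become ``(1-eps)*y + eps/K``.

    Soft rows already encode uncertainty and are left untouched; rows
    keep summing to one either way.
    """
    if not 0 <= eps < 1:
        raise ValueError("eps must lie in [0, 1)")
    if eps == 0 or not assignment.is_hard:
        return assignment
    k = assignment.n_clusters
    weights = (1.0 - eps) * assignment.weights + eps / k
    return ClusterAssignment(
        weights=weights,
        cluster_ids=assignment.cluster_ids,
        cell_ids=assignment.cell_ids,
        is_hard=False,
    )


def restrict_latent(z: np.ndarray, assignment_row: np.ndarray, units_per_cluster: int) -> np.ndarray:
    """Gate a sampled latent vector by per-cluster assignment weights.

    Block ``c`` of ``z`` (length ``units_per_cluster``) is multiplied by
    ``assignment_row[c]``. Works on a single vector or a batch (rows).
    """
    z = np.asarray(z, dtype=float)
    row = np.asarray(assignment_row, dtype=float)
    mask = np.repeat(row, units_per_cluster, axis=-1)
    if mask.shape[-1] != z.shape[-1]:
        raise ValueError(
            f"latent length {z.shape[-1]} != n_clusters*u = {mask.shape[-1]}"
        )
    return z * mask


def vae_loss(
    x_in: np.ndarray,
    x_rec: np.ndarray,
    mu: np.ndarray,
    log_sigma: np.ndarray,
    s: float = 0.0,
    alpha: float = 1.0,
    beta: float = 1.0,
) -> float:
    """Weighted VAE objective for one sample (or summed over a batch)."""
    x_in, x_rec = np.asarray(x_in, float), np.asarray(x_rec, float)
    mu, log_sigma = np.asarray(mu, float), np.asarray(log_sigma, float)
    for a in (x_in, x_rec, mu, log_sigma):
        if np.any(np.isnan(a)):
            raise ValueError("NaN in vae_loss inputs")
    if x_in.shape != x_rec.shape or mu.shape != log_sigma.shape:
        raise ValueError("shape mismatch in vae_loss inputs")
    rec = np.sum((x_in - x_rec) ** 2)
    kl = 0.5 * np.sum(np.exp(log_sigma) + (s - mu) ** 2 - 1.0 - log_sigma)
    return float(alpha * rec + beta * kl)


def preprocess(values: np.ndarray, normalize: bool) -> np.ndarray:
    """Library-size normalization to the median total, then log1p.

    With ``normalize=False`` the raw values are used unchanged.
    """
    values = np.asarray(values, dtype=float)
    if not normalize:
        return values
    totals = values.sum(axis=1)
    target = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
    scale = np.where(totals > 0, target / np.maximum(totals, 1e-12), 1.0)
    return np.log1p(values * scale[:, None])


def _init_params(
    rng: np.random.Generator, n_features: int, n_latent: int, config: ModelConfig
) -> dict[str, np.ndarray]:
    init = init_for_activation(config.activation)
    he, hd = config.encoder_units, config.decoder_units
    return {
        "W_e": init(rng, n_features, he),
        "b_e": np.zeros(he),
        "W_mu": init(rng, he, n_latent),
        "b_mu": np.zeros(n_latent),
        "W_ls": init(rng, he, n_latent),
        "b_ls": np.zeros(n_latent),
        "W_d1": init(rng, n_latent, hd),
        "b_d1": np.zeros(hd),
        "W_d2": init(rng, hd, n_features),
        "b_d2": np.zeros(n_features),
    }


def _batch_forward_backward(
    params: dict[str, np.ndarray],
    x: np.ndarray,
    mask: np.ndarray,
    eps_noise: np.ndarray,
    config: ModelConfig,
) -> tuple[float, dict[str, np.ndarray]]:
    """One minibatch pass; returns (mean loss, gradients).

    Explicit backpropagation through
    encoder -> (mu, logvar) -> reparameterized sample -> assignment mask
    -> decoder. The mask is constant w.r.t. parameters, so its gradient
    contribution is a plain elementwise factor on the latent path.
    """
    act, act_grad = ACTIVATIONS[config.activation]
    alpha, beta, s = config.alpha, config.beta, config.latent_offset
    b = x.shape[0]

    pre1 = x @ params["W_e"] + params["b_e"]
    h1 = act(pre1)
    mu = h1 @ params["W_mu"] + params["b_mu"]
    ls = h1 @ params["W_ls"] + params["b_ls"]
    ls = np.clip(ls, -10.0, 10.0)  # guards exp() early in training
    sd = np.exp(0.5 * ls)
    z = mu + sd * eps_noise
    zr = z * mask
    # additive-programs decoder reads the latent magnitude (sign-free)
    z_in = np.abs(zr) if config.nonneg_decoder else zr
    pre2 = z_in @ params["W_d1"] + params["b_d1"]
    h2 = act(pre2)
    x_rec = h2 @ params["W_d2"] + params["b_d2"]

    resid = x - x_rec
    rec = np.sum(resid**2)
    kl = 0.5 * np.sum(np.exp(ls) + (s - mu) ** 2 - 1.0 - ls)
    loss = (alpha * rec + beta * kl) / b

    # backward pass (all gradients of the mean loss)
    d_xrec = -2.0 * alpha * resid / b
    g = {}
    g["W_d2"] = h2.T @ d_xrec
    g["b_d2"] = d_xrec.sum(axis=0)
    d_h2 = d_xrec @ params["W_d2"].T
    d_pre2 = d_h2 * act_grad(pre2)
    g["W_d1"] = z_in.T @ d_pre2
    g["b_d1"] = d_pre2.sum(axis=0)
    d_zin = d_pre2 @ params["W_d1"].T
    if config.nonneg_decoder:
        d_zin = d_zin * np.sign(zr)
    d_z = d_zin * mask
    d_mu = d_z + beta * (mu - s) / b
    d_ls = d_z * eps_noise * 0.5 * sd + beta * (np.exp(ls) - 1.0) / (2.0 * b)
    g["W_mu"] = h1.T @ d_mu
    g["b_mu"] = d_mu.sum(axis=0)
    g["W_ls"] = h1.T @ d_ls
    g["b_ls"] = d_ls.sum(axis=0)
    d_h1 = d_mu @ params["W_mu"].T + d_ls @ params["W_ls"].T
    d_pre1 = d_h1 * act_grad(pre1)
    g["W_e"] = x.T @ d_pre1
    g["b_e"] = d_pre1.sum(axis=0)

    # clip the global gradient norm; spikes from the sampled KL path can
    # otherwise destabilize high-alpha/high-beta settings
    norm = np.sqrt(sum(float(np.sum(v * v)) for v in g.values()))
    if norm > _MAX_GRAD_NORM:
        scale = _MAX_GRAD_NORM / norm
        for k in g:
            g[k] *= scale
    return float(loss), g


def train_model(
    data: ExpressionMatrix,
    assignment: ClusterAssignment,
    config: ModelConfig,
    model_id: str = "",
) -> TrainedModel:
    """Fit one resVAE; bit-for-bit reproducible for a fixed seed.

    A single generator seeded from ``config.seed`` drives weight
    initialization, minibatch shuffling and the reparameterization
    noise, in that order, so two runs with identical inputs produce
    identical parameters.
    """
    if data.n_cells == 0 or data.n_features == 0:
        raise ValueError("empty expression matrix")
    if data.cell_ids != assignment.cell_ids:
        raise ValueError("data and assignment cell ids do not match")
    if not np.any(data.values > 0):
        raise ValueError("all feature columns are zero; nothing to fit")

    x = preprocess(data.values, config.normalize)
    smoothed = smooth_labels(assignment, config.label_smoothing_eps)
    mask_full = np.repeat(smoothed.weights, config.latent_units_per_cluster, axis=1)
    n_latent = assignment.n_clusters * config.latent_units_per_cluster

    rng = np.random.default_rng(config.seed)
    params = _init_params(rng, data.n_features, n_latent, config)
    if config.nonneg_decoder:
        # additive-programs decoder: the bias learns the baseline profile
        # and each latent block can only add expression on top of it,
        # which keeps decoder weight mass cluster-specific
        params["W_d1"] = np.abs(params["W_d1"])
        params["W_d2"] = np.abs(params["W_d2"])
    opt = RAdamLookahead(params, learning_rate=config.learning_rate)

    n = data.n_cells
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            eps_noise = rng.standard_normal((idx.size, n_latent))
            loss, grads = _batch_forward_backward(
                params, x[idx], mask_full[idx], eps_noise, config
            )
            opt.step(grads)
            if config.nonneg_decoder:
                # projected step: clip both the fast and the Lookahead
                # slow weights back onto the non-negative orthant
                for key in ("W_d1", "W_d2"):
                    np.maximum(params[key], 0.0, out=params[key])
                    np.maximum(opt.slow[key], 0.0, out=opt.slow[key])
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / n_batches)

    return TrainedModel(
        config=config,
        params=params,
        loss_history=history,
        cluster_ids=list(assignment.cluster_ids),
        feature_ids=list(data.feature_ids),
        model_id=model_id,
    )
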