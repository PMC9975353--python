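"""Numerical building blocks for the VAE: activations, initializers, optimizer.

Everything here operates on plain numpy arrays. The network is small
(two hidden layers) so explicit forward/backward passes in the model
module are both faster to audit and fast enough in practice.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "mish",
    "mish_grad",
    "relu",
    "relu_grad",
    "he_uniform",
    "glorot_uniform",
    "init_for_activation",
    "RAdamLookahead",
]


def _softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x) computed stably for large |x|
    return np.logaddexp(0.0, x)


def mish(x):
    """Mish activation: ``x * tanh(softplus(x))``.

    Smooth, non-monotone below zero with a minimum near -0.31, and
    numerically stable for large ``|x|`` via the log-sum-exp softplus.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("mish requires finite input")
    return x * np.tanh(_softplus(x))


def mish_grad(x: np.ndarray) -> np.ndarray:
    """Derivative of mish: ``tanh(sp(x)) + x * sigmoid(x) * sech^2(sp(x))``."""
    x = np.asarray(x, dtype=float)
    sp = _softplus(x)
    t = np.tanh(sp)
    sig = 0.5 * (1.0 + np.tanh(0.5 * x))  # stable sigmoid
    return t + x * sig * (1.0 - t * t)


def relu(x):
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def relu_grad(x: np.ndarray) -> np.ndarray:
    return (np.asarray(x, dtype=float) > 0).astype(float)


ACTIVATIONS = {"mish": (mish, mish_grad), "relu": (relu, relu_grad)}


def he_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """He uniform init, U(-sqrt(6/fan_in), +sqrt(6/fan_in)); pairs with ReLU."""
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform, U(+-sqrt(6/(fan_in+fan_out))); pairs with tanh-family."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_for_activation(activation: str):
    """Kernel initializer matched to the activation.

    He uniform with ReLU; Glorot uniform with mish (a tanh-based
    activation). The pairing is fixed, not configurable.
    """
    if activation == "relu":
        return he_uniform
    if activation == "mish":
        return glorot_uniform
    raise ValueError(f"unknown activation {activation!r}")


class RAdamLookahead:
    """Rectified Adam wrapped in the Lookahead mechanism.

    RAdam rectifies Adam's adaptive learning rate in the early,
    high-variance steps (falling back to SGD-with-momentum while the
    variance estimate is untrustworthy), removing the need for a manual
    warm-up. Lookahead keeps a set of slow weights that are pulled
    towards the fast (RAdam) weights every ``sync_period`` steps by a
    factor ``slow_step``, then resets the fast weights to the slow ones.

    Parameters are a dict name -> array; ``step`` updates them in place.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        sync_period: int = 6,
        slow_step: float = 0.5,
    ) -> None:
        self.params = params
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.sync_period = sync_period
        self.slow_step = slow_step
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.slow = {k: v.copy() for k, v in params.items()}
        self.rho_inf = 2.0 / (1.0 - beta2) - 1.0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        t = self.t
        b1, b2 = self.beta1, self.beta2
        rho_t = self.rho_inf - 2.0 * t * b2**t / (1.0 - b2**t)
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**t)
            if rho_t > 4.0:
                # variance rectification term of RAdam
                v_hat = np.sqrt(self.v[k] / (1 - b2**t))
                r = np.sqrt(
                    ((rho_t - 4) * (rho_t - 2) * self.rho_inf)
                    / ((self.rho_inf - 4) * (self.rho_inf - 2) * rho_t)
                )
                p -= self.lr * r * m_hat / (v_hat + self.eps)
            else:
                p -= self.lr * m_hat
        if self.t % self.sync_period == 0:
            for k, p in self.params.items():
                self.slow[k] += self.slow_step * (p - self.slow[k])
                p[...] = self.slow[k]
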