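"""Minimal deterministic neural-network core (NumPy).

Dense layers, ReLU, inverted dropout, softmax + cross-entropy gradients and a
hand-rolled Adagrad optimizer. Everything is driven by explicit
``numpy.random.Generator`` instances so that identical seeds give bitwise
identical training runs on one machine.
"""

from __future__ import annotations

import numpy as np

EPS_ADAGRAD = 1e-10
EPS_LOGPROB = 1e-12


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def softplus(z: np.ndarray) -> np.ndarray:
    # stable: log(1+e^z) = max(z,0) + log1p(e^{-|z|})
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


def cross_entropy_from_probs(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log probability of the true class, probabilities clipped at 1e-12."""
    labels = np.asarray(labels)
    if labels.ndim != 1 or probs.shape[0] != labels.shape[0]:
        raise ValueError("probabilities and labels disagree in length")
    if labels.size and (labels.min() < 0 or labels.max() >= probs.shape[1]):
        raise ValueError("label outside [0, K)")
    p = np.clip(probs[np.arange(len(labels)), labels], EPS_LOGPROB, None)
    return float(-np.log(p).mean())


class Adagrad:
    """Per-parameter Adagrad: accumulate squared gradients, scale the step."""

    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = float(lr)
        self.accum = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            self.accum[k] += g * g
            params[k] -= self.lr * g / (np.sqrt(self.accum[k]) + EPS_ADAGRAD)


class ResidualMLP:
    """Fully connected net with ReLU hidden layers and one skip connection.

    ``residual=(s, d)`` adds the (post-dropout) activation of hidden layer
    ``s`` to the pre-activation of hidden layer ``d`` (1-based indices), so
    information from the initial stage flows directly into the terminal stage.
    Hidden widths at ``s`` and ``d`` must match.
    """

    def __init__(
        self,
        input_dim: int,
        hidden_dims: tuple[int, ...],
        output_dim: int,
        residual: tuple[int, int] | None = (1, 5),
        dropout_rate: float = 0.1,
        seed: int = 0,
    ):
        if residual is not None:
            s, d = residual
            if not (1 <= s < d <= len(hidden_dims)):
                raise ValueError("residual source must precede destination within hidden layers")
            if hidden_dims[s - 1] != hidden_dims[d - 1]:
                raise ValueError(
                    f"residual width mismatch: layer {s} has {hidden_dims[s - 1]} units, "
                    f"layer {d} has {hidden_dims[d - 1]}"
                )
        self.hidden_dims = tuple(hidden_dims)
        self.residual = residual
        self.dropout_rate = float(dropout_rate)
        rng = np.random.default_rng(seed)
        dims = [input_dim, *hidden_dims, output_dim]
        self.params: dict[str, np.ndarray] = {}
        for i in range(len(dims) - 1):
            self.params[f"W{i}"] = he_init(rng, dims[i], dims[i + 1])
            self.params[f"b{i}"] = np.zeros(dims[i + 1])

    @property
    def n_hidden(self) -> int:
        return len(self.hidden_dims)

    def forward(
        self, X: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, dict]:
        """Return logits and the cache needed for backprop."""
        L = self.n_hidden
        p = self.dropout_rate if train else 0.0
        a_drop = [X]  # post-dropout activations, index 0 = input
        zs, masks = [], [None]
        for l in range(1, L + 1):
            z = a_drop[l - 1] @ self.params[f"W{l - 1}"] + self.params[f"b{l - 1}"]
            if self.residual is not None and l == self.residual[1]:
                z = z + a_drop[self.residual[0]]
            a = relu(z)
            if p > 0.0:
                mask = (rng.random(a.shape) >= p) / (1.0 - p)
                a = a * mask
            else:
                mask = None
            zs.append(z)
            masks.append(mask)
            a_drop.append(a)
        logits = a_drop[L] @ self.params[f"W{L}"] + self.params[f"b{L}"]
        return logits, {"a_drop": a_drop, "zs": zs, "masks": masks}

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        L = self.n_hidden
        a_drop, zs, masks = cache["a_drop"], cache["zs"], cache["masks"]
        grads: dict[str, np.ndarray] = {}
        grads[f"W{L}"] = a_drop[L].T @ dlogits
        grads[f"b{L}"] = dlogits.sum(axis=0)
        da = [np.zeros_like(a) for a in a_drop]  # grads w.r.t. post-dropout activations
        da[L] = dlogits @ self.params[f"W{L}"].T
        for l in range(L, 0, -1):
            g = da[l]
            if masks[l] is not None:
                g = g * masks[l]
            dz = g * (zs[l - 1] > 0)
            if self.residual is not None and l == self.residual[1]:
                da[self.residual[0]] += dz
            grads[f"W{l - 1}"] = a_drop[l - 1].T @ dz
            grads[f"b{l - 1}"] = dz.sum(axis=0)
            da[l - 1] += dz @ self.params[f"W{l - 1}"].T
        return grads

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(X, train=False)
        return softmax(logits)

    def get_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(params[k], dtype=np.float64).copy()
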