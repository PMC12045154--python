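"""Attention-enhanced marker-gene selection (ACOSG).

Two independent per-gene signals are fused:

* a penalized cosine score: the cosine similarity ``lambda`` between a gene's
  expression vector (over all cells) and each cell type's 0/1 indicator
  vector, penalized by the gene's similarity to every other type — high
  scores mark genes expressed specifically in one type;
* a supervised attention importance: a small classifier with a learned
  per-gene multiplicative gate is trained to predict the reference labels,
  and the softmax-normalized mean absolute gate activation becomes a
  per-gene weight.

The fused score ranks genes per cell type and the top genes form the feature
panel consumed by the classifier.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import Adagrad, relu, sigmoid, softmax, softplus
from .core_data import ExpressionDataset, LabelVocabulary

__all__ = [
    "AttentionConfig",
    "GeneScoreTable",
    "cosine_lambda",
    "cosg_score",
    "train_attention",
    "fuse_and_select",
    "score_genes",
]


def cosine_lambda(ds: ExpressionDataset, labels: np.ndarray, K: int) -> np.ndarray:
    """Cosine similarity between each gene and each cell-type indicator.

    ``lambda[g, k] = <x_g, u_k> / (||x_g|| * ||u_k||)`` where ``x_g`` is gene
    ``g``'s (normalized) expression over all cells and ``u_k`` the 0/1
    membership vector of type ``k``. All-zero genes get 0 for every type.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape[0] != ds.n_obs:
        raise ValueError("labels length does not match observation count")
    if labels.size and (labels.min() < 0 or labels.max() >= K):
        raise ValueError(f"labels must lie in [0, {K})")
    X = ds.matrix  # n x G
    U = np.zeros((ds.n_obs, K))
    U[np.arange(ds.n_obs), labels] = 1.0
    numer = X.T @ U  # G x K
    gene_norms = np.linalg.norm(X, axis=0)
    type_norms = np.sqrt(U.sum(axis=0))
    denom = gene_norms[:, None] * type_norms[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    return lam


def cosg_score(lambda_matrix: np.ndarray, mu: float = 1.0) -> np.ndarray:
    """Penalize each gene/type cosine by the gene's similarity to other types.

    ``score[g, k] = sign(l) * l^2 / (l^2 + mu * sum_{i != k} lambda[g, i]^2)``
    with ``l = lambda[g, k]``; 0 where the denominator vanishes. ``mu``
    balances specificity against raw similarity: at ``mu = 0`` the score
    collapses to ``sign(lambda)`` for every nonzero entry, while large ``mu``
    demands exclusivity.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    lam = np.asarray(lambda_matrix, dtype=np.float64)
    sq = lam**2
    other = sq.sum(axis=1, keepdims=True) - sq
    denom = sq + mu * other
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, np.sign(lam) * sq / np.where(denom > 0, denom, 1.0), 0.0)


@dataclass
class AttentionConfig:
    """Hyper-parameters of the gated attention classifier."""

    epochs: int = 30
    learning_rate: float = 0.01
    batch_size: int = 128
    hidden_units: int = 64
    seed: int = 0


def _gene_keyed_rows(gene_names: list[str], n_cols: int, scale: float, seed: int) -> np.ndarray:
    """Per-gene weight rows seeded by gene identity, not column position.

    Keying the initialization to the gene name makes the whole attention
    training equivariant under permutations of the input gene order.
    """
    W = np.empty((len(gene_names), n_cols))
    for i, name in enumerate(gene_names):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
        W[i] = rng.normal(0.0, scale, size=n_cols)
    return W


def train_attention(
    ds: ExpressionDataset,
    labels: np.ndarray,
    config: AttentionConfig | None = None,
) -> np.ndarray:
    """Train the gated classifier and return per-gene attention weights.

    The gate is a learned per-gene scalar passed through softplus that
    multiplies the input before a single 64-unit ReLU hidden layer and a
    softmax output. After training, gene ``g``'s importance is the mean over
    training cells of ``|softplus(s_g) * x_{cg}|``, softmax-normalized over
    genes so the weights sum to 1.
    """
    cfg = config or AttentionConfig()
    labels = np.asarray(labels, dtype=np.int64)
    K = int(labels.max()) + 1 if labels.size else 0
    if K < 2:
        raise ValueError("attention requires >=2 classes")
    X = ds.matrix
    n, G = X.shape
    H = cfg.hidden_units

    # gate initialized so softplus(s) = 1 (identity pass-through)
    s = np.full(G, np.log(np.e - 1.0))
    W1 = _gene_keyed_rows(ds.gene_names, H, np.sqrt(2.0 / G), cfg.seed)
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0xA77E])
    b1 = np.zeros(H)
    W2 = rng.normal(0.0, np.sqrt(2.0 / H), size=(H, K))
    b2 = np.zeros(K)

    params = {"s": s, "W1": W1, "b1": b1, "W2": W2, "b2": b2}
    opt = Adagrad(params, cfg.learning_rate)

    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], labels[idx]
            gate = softplus(params["s"])
            xg = xb * gate
            z1 = xg @ params["W1"] + params["b1"]
            h = relu(z1)
            probs = softmax(h @ params["W2"] + params["b2"])
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grads = {
                "W2": h.T @ dlogits,
                "b2": dlogits.sum(axis=0),
            }
            dh = dlogits @ params["W2"].T
            dz1 = dh * (z1 > 0)
            grads["W1"] = xg.T @ dz1
            grads["b1"] = dz1.sum(axis=0)
            dxg = dz1 @ params["W1"].T
            grads["s"] = (dxg * xb).sum(axis=0) * sigmoid(params["s"])
            opt.step(params, grads)

    gate = softplus(params["s"])
    activation = np.abs(X * gate).mean(axis=0)
    weights = softmax(activation)
    return weights


def fuse_and_select(
    cosg_scores: np.ndarray,
    attention_weight: np.ndarray,
    gene_names: list[str],
    n_top: int = 50,
    per_type: bool = True,
) -> list[str]:
    """Fuse COSG scores with attention weights and pick the feature panel.

    ``fused[g, k] = cosg[g, k] * attention[g] / max(attention)``. With
    ``per_type`` the top ``n_top`` genes of each type are unioned; otherwise
    the top ``n_top`` by max-over-types fused score are taken. Ties break by
    lexicographic gene name; the returned panel follows the input gene order.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    cosg_scores = np.asarray(cosg_scores, dtype=np.float64)
    G, K = cosg_scores.shape
    if len(gene_names) != G or len(attention_weight) != G:
        raise ValueError("gene_names / attention_weight length mismatch")
    if n_top > G:
        warnings.warn(f"n_top={n_top} exceeds gene count {G}; clamping")
        n_top = G
    a = np.asarray(attention_weight, dtype=np.float64)
    fused = cosg_scores * (a / a.max())[:, None]

    def top_of(col: np.ndarray) -> list[int]:
        order = sorted(range(G), key=lambda g: (-col[g], gene_names[g]))
        return order[:n_top]

    if per_type:
        chosen: set[int] = set()
        for k in range(K):
            chosen.update(top_of(fused[:, k]))
    else:
        chosen = set(top_of(fused.max(axis=1)))
    return [gene_names[g] for g in range(G) if g in chosen]


@dataclass
class GeneScoreTable:
    """All per-(gene, type) scores behind a feature-panel selection."""

    gene_names: list[str]
    vocab: LabelVocabulary
    lambda_matrix: np.ndarray  # G x K cosine similarities
    cosg_scores: np.ndarray  # G x K penalized scores
    attention_weight: np.ndarray  # per-gene, sums to 1
    mu: float
    n_top: int
    fused_scores: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.attention_weight, dtype=np.float64)
        if not np.isclose(a.sum(), 1.0, atol=1e-6):
            raise ValueError("attention weights must sum to 1")
        self.fused_scores = self.cosg_scores * (a / a.max())[:, None]

    def select_panel(self, n_top: int | None = None, per_type: bool = True) -> list[str]:
        return fuse_and_select(
            self.cosg_scores,
            self.attention_weight,
            self.gene_names,
            n_top=n_top if n_top is not None else self.n_top,
            per_type=per_type,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (gene, cell type)."""
        G, K = self.cosg_scores.shape
        return pd.DataFrame(
            {
                "gene": np.repeat(self.gene_names, K),
                "cell_type": list(self.vocab.types) * G,
                "lambda": self.lambda_matrix.ravel(),
                "cosg_score": self.cosg_scores.ravel(),
                "attention_weight": np.repeat(self.attention_weight, K),
                "fused_score": self.fused_scores.ravel(),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def score_genes(
    ds: ExpressionDataset,
    labels: np.ndarray,
    vocab: LabelVocabulary,
    mu: float = 1.0,
    n_top: int = 50,
    attention: AttentionConfig | None = None,
) -> GeneScoreTable:
    """Run the full ACOSG scoring stage on a normalized, labeled reference."""
    K = len(vocab)
    lam = cosine_lambda(ds, labels, K)
    scores = cosg_score(lam, mu=mu)
    weights = train_attention(ds, labels, attention)
    return GeneScoreTable(ds.gene_names, vocab, lam, scores, weights, mu, n_top)
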