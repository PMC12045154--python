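"""The cell-typing network: a five-hidden-layer residual MLP.

The network maps standardized log-expression of the selected gene panel to a
softmax over cell types. Hidden widths form a symmetric bottleneck
(256-128-64-128-256) so the skip connection can add the first hidden layer's
activations to the last hidden layer's pre-activations ("initial and terminal
stage" connection), keeping an uninterrupted information path through the
bottleneck. Training minimizes cross-entropy with mini-batch Adagrad and
keeps the parameters with the best stratified-validation loss.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Adagrad, ResidualMLP, cross_entropy_from_probs, softmax
from .core_data import ExpressionDataset, LabelVocabulary

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "TrainedClassifier",
    "CellTypeProbabilityMatrix",
    "build_network",
    "cross_entropy",
    "train",
    "predict",
    "hard_labels",
    "save_model",
    "load_model",
]

MODEL_FORMAT_TAG = "dsct-model-v1"


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the classifier; exactly five hidden layers."""

    input_dim: int
    output_dim: int
    hidden_dims: tuple[int, ...] = (256, 128, 64, 128, 256)
    residual: tuple[int, int] = (1, 5)
    activation: str = "relu"
    dropout_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if self.output_dim < 2:
            raise ValueError("output_dim must be >= 2")
        if len(self.hidden_dims) != 5:
            raise ValueError("exactly 5 hidden layers required")
        s, d = self.residual
        if not 1 <= s < d <= 5:
            raise ValueError("residual source must precede destination")
        if self.hidden_dims[s - 1] != self.hidden_dims[d - 1]:
            raise ValueError(
                f"residual width mismatch: {self.hidden_dims[s - 1]} vs {self.hidden_dims[d - 1]}"
            )
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


def build_network(input_dim: int, K: int, **overrides) -> NetworkSpec:
    """Construct a :class:`NetworkSpec` with defaults, applying overrides."""
    if "hidden_dims" in overrides:
        overrides["hidden_dims"] = tuple(overrides["hidden_dims"])
    if "residual" in overrides:
        overrides["residual"] = tuple(overrides["residual"])
    return NetworkSpec(input_dim=input_dim, output_dim=K, **overrides)


@dataclass
class TrainingConfig:
    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 128
    validation_fraction: float = 0.1
    seed: int = 0
    early_stop_patience: int = 10

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid epochs/batch_size")
        if not 0.0 <= self.validation_fraction <= 0.5:
            raise ValueError("validation_fraction must be in [0, 0.5]")
        if self.early_stop_patience < 0:
            raise ValueError("early_stop_patience must be >= 0")


@dataclass
class CellTypeProbabilityMatrix:
    """Observations x cell types, every row on the probability simplex."""

    matrix: np.ndarray
    obs_ids: list[str]
    vocab: LabelVocabulary

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (len(self.obs_ids), len(self.vocab)):
            raise ValueError("probability matrix shape mismatch")
        if self.matrix.size:
            if self.matrix.min() < 0 or self.matrix.max() > 1:
                raise ValueError("probabilities must lie in [0, 1]")
            sums = self.matrix.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-6:
                raise ValueError("rows must sum to 1 within 1e-6")


@dataclass
class TrainedClassifier:
    """A trained network together with everything needed to apply it."""

    spec: NetworkSpec
    net: ResidualMLP
    panel: list[str]
    vocab: LabelVocabulary
    gene_mean: np.ndarray  # reference per-gene mean (standardization)
    gene_std: np.ndarray  # reference per-gene std, zeros replaced by 1
    train_history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.panel) != self.spec.input_dim:
            raise ValueError("panel length must equal spec.input_dim")
        if len(self.vocab) != self.spec.output_dim:
            raise ValueError("vocabulary size must equal spec.output_dim")


def cross_entropy(probabilities: np.ndarray, true_labels: np.ndarray) -> float:
    """Mean -ln p(true class); probabilities clipped below at 1e-12."""
    return cross_entropy_from_probs(np.asarray(probabilities, dtype=np.float64),
                                    true_labels)


def _stratified_split(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class held-out validation indices (at least 1 per class)."""
    train_idx, val_idx = [], []
    for k in np.unique(labels):
        idx = np.flatnonzero(labels == k)
        if fraction > 0 and len(idx) < 2:
            raise ValueError(f"class {k} has fewer than 2 observations; cannot hold out validation")
        idx = rng.permutation(idx)
        n_val = max(1, int(round(fraction * len(idx)))) if fraction > 0 else 0
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def train(
    reference: ExpressionDataset,
    labels: np.ndarray,
    vocab: LabelVocabulary,
    spec: NetworkSpec | None = None,
    cfg: TrainingConfig | None = None,
) -> TrainedClassifier:
    """Fit the classifier on a normalized reference restricted to the panel.

    The reference's gene order defines the panel. Inputs are standardized per
    gene (zero mean, unit variance) using reference statistics; the same
    statistics are later re-applied to spatial data. Mini-batch Adagrad
    minimizes cross-entropy; the parameters with the best validation loss are
    kept. Fully deterministic given ``cfg.seed``.
    """
    cfg = cfg or TrainingConfig()
    labels = np.asarray(labels, dtype=np.int64)
    K = len(vocab)
    if K < 2:
        raise ValueError("need >= 2 cell types")
    if labels.size and (labels.min() < 0 or labels.max() >= K):
        raise ValueError("label code outside vocabulary")
    if spec is None:
        spec = build_network(reference.n_genes, K)
    if spec.input_dim != reference.n_genes:
        raise ValueError("spec.input_dim must equal reference gene count")

    mean = reference.matrix.mean(axis=0)
    std = reference.matrix.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    X = (reference.matrix - mean) / std

    net = ResidualMLP(
        spec.input_dim,
        spec.hidden_dims,
        spec.output_dim,
        residual=spec.residual,
        dropout_rate=spec.dropout_rate,
        seed=cfg.seed,
    )
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0xD5C7])
    if cfg.validation_fraction > 0:
        tr_idx, val_idx = _stratified_split(labels, cfg.validation_fraction, rng)
    else:
        tr_idx, val_idx = np.arange(len(labels)), np.array([], dtype=np.int64)
    X_tr, y_tr = X[tr_idx], labels[tr_idx]
    X_val, y_val = X[val_idx], labels[val_idx]

    opt = Adagrad(net.params, cfg.learning_rate)
    history: list[dict] = []
    best_val = np.inf
    best_params = net.get_params()
    since_best = 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X_tr))
        for bstart in range(0, len(X_tr), cfg.batch_size):
            idx = order[bstart : bstart + cfg.batch_size]
            xb, yb = X_tr[idx], y_tr[idx]
            logits, cache = net.forward(xb, train=True, rng=rng)
            probs = softmax(logits)
            batch_loss = cross_entropy_from_probs(probs, yb)
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {bstart // cfg.batch_size}"
                )
            dlogits = probs
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            opt.step(net.params, net.backward(cache, dlogits))

        tr_probs = net.predict_proba(X_tr)
        rec = {
            "epoch": epoch,
            "train_loss": cross_entropy_from_probs(tr_probs, y_tr),
            "train_acc": float((tr_probs.argmax(axis=1) == y_tr).mean()),
        }
        if len(val_idx):
            val_probs = net.predict_proba(X_val)
            rec["val_loss"] = cross_entropy_from_probs(val_probs, y_val)
            rec["val_acc"] = float((val_probs.argmax(axis=1) == y_val).mean())
            if rec["val_loss"] < best_val:
                best_val = rec["val_loss"]
                best_params = net.get_params()
                since_best = 0
            else:
                since_best += 1
        history.append(rec)
        if len(val_idx) and cfg.early_stop_patience > 0 and since_best >= cfg.early_stop_patience:
            break

    if len(val_idx) and cfg.epochs > 0:
        net.set_params(best_params)

    return TrainedClassifier(
        spec=spec,
        net=net,
        panel=list(reference.gene_names),
        vocab=vocab,
        gene_mean=mean,
        gene_std=std,
        train_history=history,
    )


def predict(model: TrainedClassifier, spatial: ExpressionDataset) -> CellTypeProbabilityMatrix:
    """Apply the trained classifier to (normalized) spatial data.

    Every panel gene must be present; observations are classified
    independently of one another and of their coordinates.
    """
    missing = sorted(set(model.panel) - set(spatial.gene_names))
    if missing:
        raise KeyError(f"spatial data lacks {len(missing)} panel gene(s): {missing[:10]}")
    ds = spatial.subset_genes(model.panel)
    X = (ds.matrix - model.gene_mean) / model.gene_std
    probs = model.net.predict_proba(X)
    return CellTypeProbabilityMatrix(probs, ds.obs_ids, model.vocab)


def hard_labels(pm: CellTypeProbabilityMatrix) -> list[str]:
    """Argmax cell type per observation; ties go to the lowest vocabulary index."""
    return [pm.vocab[i] for i in pm.matrix.argmax(axis=1)]


def save_model(model: TrainedClassifier, path: str | Path) -> None:
    """Persist a model as a directory: JSON metadata + npz weight archive."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": MODEL_FORMAT_TAG,
        "spec": asdict(model.spec),
        "panel": model.panel,
        "vocab": list(model.vocab.types),
        "gene_mean": model.gene_mean.tolist(),
        "gene_std": model.gene_std.tolist(),
        "train_history": model.train_history,
    }
    (path / "model.json").write_text(json.dumps(meta, indent=1))
    np.savez(path / "weights.npz", **model.net.params)


def load_model(path: str | Path) -> TrainedClassifier:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    if meta.get("format") != MODEL_FORMAT_TAG:
        raise ValueError(f"unrecognized model format in {path}")
    sd = meta["spec"]
    spec = NetworkSpec(
        input_dim=sd["input_dim"],
        output_dim=sd["output_dim"],
        hidden_dims=tuple(sd["hidden_dims"]),
        residual=tuple(sd["residual"]),
        activation=sd["activation"],
        dropout_rate=sd["dropout_rate"],
    )
    net = ResidualMLP(
        spec.input_dim,
        spec.hidden_dims,
        spec.output_dim,
        residual=spec.residual,
        dropout_rate=spec.dropout_rate,
        seed=0,
    )
    with np.load(path / "weights.npz") as npz:
        net.set_params({k: npz[k] for k in npz.files})
    return TrainedClassifier(
        spec=spec,
        net=net,
        panel=list(meta["panel"]),
        vocab=LabelVocabulary(tuple(meta["vocab"])),
        gene_mean=np.asarray(meta["gene_mean"], dtype=np.float64),
        gene_std=np.asarray(meta["gene_std"], dtype=np.float64),
        train_history=meta["train_history"],
    )
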