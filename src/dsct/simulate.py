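"""Synthetic paired reference/spatial datasets with known ground truth.

Counts are negative-binomial (overdispersed, like real UMI data). Each cell
type owns a disjoint block of marker genes whose mean is elevated by a fold
change, so the expected top markers are known a priori. Spatial data places
observations in the unit square; the ``layers`` layout assigns types to
horizontal bands, mimicking laminar tissue architecture. With
``cells_per_spot > 1`` each capture spot sums the counts of several cells
drawn from a y-position-dependent type mixture, and the true per-spot mixing
proportions are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import ExpressionDataset, LabelVocabulary
from .evaluation import ReferenceMap

__all__ = [
    "SimulationConfig",
    "SpatialTruth",
    "simulate_reference",
    "simulate_spatial",
    "ground_truth_reference_map",
    "expected_marker_genes",
]


@dataclass
class SimulationConfig:
    """Generative parameters for one paired reference/spatial simulation."""

    K: int = 5
    G: int = 500
    markers_per_type: int = 40
    fold_change: float = 4.0
    base_mean: float = 2.0
    dispersion: float = 0.5  # inverse NB size; larger = more overdispersed
    n_ref_per_type: int = 200
    n_spatial: int = 1000
    layout: str = "layers"
    cells_per_spot: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.G < 1:
            raise ValueError("K and G must be positive")
        if self.markers_per_type < 0 or self.K * self.markers_per_type > self.G:
            raise ValueError("K * markers_per_type must not exceed G")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise ValueError("base_mean and dispersion must be positive")
        if self.n_ref_per_type < 1 or self.n_spatial < 1 or self.cells_per_spot < 1:
            raise ValueError("counts must be positive")
        if self.layout not in ("layers", "random"):
            raise ValueError("layout must be 'layers' or 'random'")

    @property
    def vocab(self) -> LabelVocabulary:
        return LabelVocabulary(tuple(f"type_{k}" for k in range(self.K)))

    @property
    def gene_names(self) -> list[str]:
        return [f"gene_{g:04d}" for g in range(self.G)]

    def type_means(self) -> np.ndarray:
        """K x G expected counts: base mean, elevated on each type's marker block."""
        means = np.full((self.K, self.G), self.base_mean)
        m = self.markers_per_type
        for k in range(self.K):
            means[k, k * m : (k + 1) * m] *= self.fold_change
        return means


def expected_marker_genes(cfg: SimulationConfig) -> dict[str, list[str]]:
    """The marker block each type's counts were elevated on."""
    m = cfg.markers_per_type
    names = cfg.gene_names
    return {f"type_{k}": names[k * m : (k + 1) * m] for k in range(cfg.K)}


def _nb_draw(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    size_param = 1.0 / dispersion
    p = size_param / (size_param + means)
    return rng.negative_binomial(size_param, p).astype(np.float64)


def simulate_reference(cfg: SimulationConfig) -> ExpressionDataset:
    """Labeled single-cell reference: ``n_ref_per_type`` cells per type."""
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 1])
    means = cfg.type_means()
    labels = np.repeat(np.arange(cfg.K), cfg.n_ref_per_type)
    X = _nb_draw(rng, means[labels], cfg.dispersion)
    return ExpressionDataset(
        X,
        cfg.gene_names,
        [f"ref_{i}" for i in range(len(labels))],
        labels=[f"type_{k}" for k in labels],
        layer_tag="raw",
    )


@dataclass
class SpatialTruth:
    """Ground truth accompanying a simulated spatial dataset."""

    proportions: np.ndarray  # n_spatial x K, rows sum to 1
    vocab: LabelVocabulary

    @property
    def labels(self) -> list[str]:
        """Dominant type per observation (exact at single-cell resolution)."""
        return [self.vocab[k] for k in self.proportions.argmax(axis=1)]


def _band_of(y: np.ndarray, K: int) -> np.ndarray:
    return np.minimum((y * K).astype(np.int64), K - 1)


def simulate_spatial(cfg: SimulationConfig) -> tuple[ExpressionDataset, SpatialTruth]:
    """Spatial dataset with coordinates plus its ground truth.

    ``cells_per_spot == 1`` gives single-cell resolution: each observation is
    one cell of the type of its band (``layers``) or a uniformly random type
    (``random``), and the truth proportions are one-hot. With larger spots,
    the constituent cells' types are drawn from a mixture whose weights decay
    with distance between the spot's y coordinate and each band's center
    (Gaussian kernel, bandwidth 1/(2K)), so mixing is strongest near band
    boundaries; spot counts are the summed single-cell counts.
    """
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 2])
    means = cfg.type_means()
    coords = rng.random((cfg.n_spatial, 2))
    n, K = cfg.n_spatial, cfg.K

    if cfg.cells_per_spot == 1:
        if cfg.layout == "layers":
            types = _band_of(coords[:, 1], K)
        else:
            types = rng.integers(0, K, size=n)
        X = _nb_draw(rng, means[types], cfg.dispersion)
        proportions = np.zeros((n, K))
        proportions[np.arange(n), types] = 1.0
    else:
        if cfg.layout == "layers":
            centers = (np.arange(K) + 0.5) / K
            bw = 1.0 / (2 * K)
            w = np.exp(-(((coords[:, 1][:, None] - centers[None, :]) / bw) ** 2))
            w = w / w.sum(axis=1, keepdims=True)
        else:
            w = np.full((n, K), 1.0 / K)
        cell_counts = np.vstack([rng.multinomial(cfg.cells_per_spot, w[i]) for i in range(n)])
        X = np.zeros((n, cfg.G))
        for k in range(K):
            ck = cell_counts[:, k]
            # sum of m iid NB draws == NB with m-fold mean and size
            nonzero = ck > 0
            if nonzero.any():
                size_param = ck[nonzero, None] / cfg.dispersion
                mu = ck[nonzero, None] * means[k][None, :]
                p = size_param / (size_param + mu)
                X[nonzero] += rng.negative_binomial(size_param, p).astype(np.float64)
        proportions = cell_counts / cfg.cells_per_spot

    ds = ExpressionDataset(
        X,
        cfg.gene_names,
        [f"spot_{i}" for i in range(n)],
        coords=coords,
        layer_tag="raw",
    )
    return ds, SpatialTruth(proportions, cfg.vocab)


def ground_truth_reference_map(truth: SpatialTruth) -> ReferenceMap:
    """Wrap simulation ground truth as the evaluation module's reference map."""
    one_hot = np.all(np.isin(truth.proportions, (0.0, 1.0)))
    source = "annotation_onehot" if one_hot else "true_proportions"
    return ReferenceMap(truth.proportions.copy(), source, truth.vocab)
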