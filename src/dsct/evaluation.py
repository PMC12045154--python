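"""Multi-metric evaluation of predicted cell-type maps.

A prediction (observations x types probability matrix) is compared
column-by-column against a reference map — either a one-hot encoding of
prior annotations or the max-scaled summed expression of each type's top
marker genes. Five similarity metrics are computed per type and averaged:
cosine similarity (COS), Pearson correlation (PPMC), a global structural
similarity index (SSIM), Kullback-Leibler divergence (KL) and
Jensen-Shannon divergence (JS). Competing methods are then ranked per
metric (best rank = number of methods, ties averaged) and the mean rank,
normalized by the number of methods, is the Acc Score in (0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classifier import CellTypeProbabilityMatrix
from .core_data import ExpressionDataset, LabelVocabulary

__all__ = [
    "ReferenceMap",
    "EvaluationReport",
    "build_reference_map",
    "metric_cos",
    "metric_ppmc",
    "metric_ssim",
    "metric_kl",
    "metric_js",
    "aggregate_metrics",
    "acc_score",
    "confusion_matrix",
    "proportion_similarity",
    "HIGHER_IS_BETTER",
    "DEFAULT_ACC_METRICS",
]

HIGHER_IS_BETTER = {"COS": True, "PPMC": True, "SSIM": True, "KL": False, "JS": False}
DEFAULT_ACC_METRICS = ("COS", "PPMC", "SSIM", "KL")


@dataclass
class ReferenceMap:
    """Ground-truth map the prediction is scored against."""

    matrix: np.ndarray  # observations x K, non-negative
    source: str  # annotation_onehot | marker_gene_sum | true_proportions
    vocab: LabelVocabulary

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.vocab):
            raise ValueError("reference map shape mismatch with vocabulary")
        if self.matrix.size and self.matrix.min() < 0:
            raise ValueError("reference map has negative entries")
        if self.source not in ("annotation_onehot", "marker_gene_sum", "true_proportions"):
            raise ValueError(f"unknown source {self.source!r}")


def build_reference_map(
    spatial: ExpressionDataset,
    vocab: LabelVocabulary,
    markers: dict[str, list[str]] | None = None,
    labels: list[str] | None = None,
) -> ReferenceMap:
    """One-hot annotation map, or summed marker expression per type.

    Marker mode sums the (normalized) expression of each type's marker genes
    per observation and max-scales every column to [0, 1] — the conventional
    stand-in for ground truth when no prior annotation exists.
    """
    if labels is None:
        labels = spatial.labels
    if markers is not None:
        gene_idx = {g: i for i, g in enumerate(spatial.gene_names)}
        cols = []
        for t in vocab.types:
            genes = [g for g in markers.get(t, []) if g in gene_idx]
            if not genes:
                raise ValueError(f"no marker genes available in spatial data for type {t!r}")
            col = spatial.matrix[:, [gene_idx[g] for g in genes]].sum(axis=1)
            m = col.max()
            cols.append(col / m if m > 0 else col)
        return ReferenceMap(np.column_stack(cols), "marker_gene_sum", vocab)
    if labels is not None:
        onehot = np.zeros((spatial.n_obs, len(vocab)))
        for i, l in enumerate(labels):
            if l not in vocab.index_of:
                raise KeyError(f"label {l!r} not in vocabulary")
            onehot[i, vocab.index_of[l]] = 1.0
        return ReferenceMap(onehot, "annotation_onehot", vocab)
    raise ValueError("need either markers or labels to build a reference map")


def metric_cos(p: np.ndarray, r: np.ndarray) -> float:
    """Cosine similarity; 0 when either vector is all-zero."""
    p = np.asarray(p, dtype=np.float64).ravel()
    r = np.asarray(r, dtype=np.float64).ravel()
    denom = np.linalg.norm(p) * np.linalg.norm(r)
    return float(np.dot(p, r) / denom) if denom > 0 else 0.0


def metric_ppmc(p: np.ndarray, r: np.ndarray) -> float:
    """Pearson correlation; 0 (with a warning) when a vector is constant."""
    p = np.asarray(p, dtype=np.float64).ravel()
    r = np.asarray(r, dtype=np.float64).ravel()
    if p.std() == 0 or r.std() == 0:
        warnings.warn("constant vector in Pearson correlation; returning 0")
        return 0.0
    return float(np.corrcoef(p, r)[0, 1])


def metric_ssim(p: np.ndarray, r: np.ndarray, C1: float = 0.01**2, C2: float = 0.03**2) -> float:
    """Global (single-window) structural similarity with dynamic range L=1.

    Both inputs are first max-scaled to [0, 1]; the luminance/contrast/
    structure composite is evaluated once over the whole vector rather than
    over a sliding window, because observations form an unordered point set,
    not a raster.
    """
    p = np.asarray(p, dtype=np.float64).ravel()
    r = np.asarray(r, dtype=np.float64).ravel()
    if p.max() > 0:
        p = p / p.max()
    if r.max() > 0:
        r = r / r.max()
    mu_p, mu_r = p.mean(), r.mean()
    var_p, var_r = p.var(), r.var()
    cov = ((p - mu_p) * (r - mu_r)).mean()
    return float(
        ((2 * mu_p * mu_r + C1) * (2 * cov + C2))
        / ((mu_p**2 + mu_r**2 + C1) * (var_p + var_r + C2))
    )


def _to_simplex(v: np.ndarray, eps: float) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64).ravel() + eps
    return v / v.sum()


def metric_kl(p: np.ndarray, r: np.ndarray, eps: float = 1e-12) -> float:
    """KL(r || p) in nats: information lost when p approximates the reference r.

    Both vectors are shifted by ``eps`` and renormalized to the simplex so
    zeros stay finite.
    """
    ps, rs = _to_simplex(p, eps), _to_simplex(r, eps)
    return float(np.sum(rs * np.log(rs / ps)))


def metric_js(p: np.ndarray, r: np.ndarray, eps: float = 1e-12) -> float:
    """Jensen-Shannon divergence in nats, symmetric and bounded by ln 2."""
    ps, rs = _to_simplex(p, eps), _to_simplex(r, eps)
    m = 0.5 * (ps + rs)
    return float(0.5 * np.sum(ps * np.log(ps / m)) + 0.5 * np.sum(rs * np.log(rs / m)))


_METRIC_FUNCS = {
    "COS": metric_cos,
    "PPMC": metric_ppmc,
    "SSIM": metric_ssim,
    "KL": metric_kl,
    "JS": metric_js,
}


def aggregate_metrics(pm: CellTypeProbabilityMatrix, ref: ReferenceMap) -> dict[str, float]:
    """Each metric per cell-type column, averaged (unweighted) over types."""
    if pm.matrix.shape != ref.matrix.shape:
        raise ValueError("prediction and reference shapes differ")
    if tuple(pm.vocab.types) != tuple(ref.vocab.types):
        raise ValueError("prediction and reference vocabularies differ")
    out: dict[str, float] = {}
    for name, fn in _METRIC_FUNCS.items():
        vals = [fn(pm.matrix[:, k], ref.matrix[:, k]) for k in range(len(pm.vocab))]
        out[name] = float(np.mean(vals))
    return out


def acc_score(
    table: pd.DataFrame, metrics: tuple[str, ...] = DEFAULT_ACC_METRICS
) -> pd.Series:
    """Rank-averaged accuracy score per method.

    ``table`` has one row per method and one column per metric. For each
    metric the methods are ranked so the BEST gets rank M (number of
    methods); higher is better for COS/PPMC/SSIM, lower for KL/JS; ties get
    the average rank. The Acc Score is the mean rank divided by M, in (0, 1].
    """
    if len(table) < 2:
        raise ValueError("acc_score needs >= 2 methods")
    missing = [m for m in metrics if m not in table.columns]
    if missing:
        raise ValueError(f"missing metric column(s): {missing}")
    if table[list(metrics)].isna().any().any():
        raise ValueError("missing metric value")
    ranks = pd.DataFrame(index=table.index, columns=list(metrics), dtype=float)
    for m in metrics:
        vals = table[m].to_numpy(dtype=np.float64)
        ranks[m] = rankdata(vals if HIGHER_IS_BETTER[m] else -vals)
    return ranks.mean(axis=1) / len(table)


def confusion_matrix(
    predicted: list[str], annotated: list[str], vocab: LabelVocabulary | None = None
) -> tuple[pd.DataFrame, float]:
    """Row-normalized overlap of annotated (rows) vs predicted (columns) types.

    Entry (i, j) is the fraction of cells annotated as type i that were
    predicted as type j; overall accuracy is the fraction of agreeing cells.
    """
    if len(predicted) != len(annotated):
        raise ValueError("label vectors differ in length")
    if vocab is None:
        types: list[str] = []
        for l in list(annotated) + list(predicted):
            if l not in types:
                types.append(l)
        vocab = LabelVocabulary(tuple(types))
    K = len(vocab)
    counts = np.zeros((K, K))
    for a, p in zip(annotated, predicted):
        counts[vocab.index_of[a], vocab.index_of[p]] += 1
    rowsum = counts.sum(axis=1, keepdims=True)
    norm = np.divide(counts, rowsum, out=np.zeros_like(counts), where=rowsum > 0)
    acc = float(np.mean([a == p for a, p in zip(annotated, predicted)]))
    df = pd.DataFrame(norm, index=list(vocab.types), columns=list(vocab.types))
    return df, acc


def proportion_similarity(
    pm: CellTypeProbabilityMatrix,
    reference_proportions: np.ndarray,
    use_hard_labels: bool = False,
) -> tuple[float, float]:
    """(PPMC, COS) between predicted and reference cell-type proportions.

    Predicted proportions are the column means of the probability matrix, or
    hard-label frequencies when ``use_hard_labels`` is set.
    """
    ref = np.asarray(reference_proportions, dtype=np.float64).ravel()
    if len(ref) != len(pm.vocab):
        raise ValueError("reference proportions length mismatch")
    if use_hard_labels:
        hard = pm.matrix.argmax(axis=1)
        pred = np.bincount(hard, minlength=len(pm.vocab)) / len(hard)
    else:
        pred = pm.matrix.mean(axis=0)
    return metric_ppmc(pred, ref), metric_cos(pred, ref)


@dataclass
class EvaluationReport:
    """Per-method metric values, ranks, Acc Scores, optional confusion matrix."""

    values: pd.DataFrame  # methods x metrics
    acc_scores: pd.Series
    metrics_ranked: tuple[str, ...] = DEFAULT_ACC_METRICS
    confusion: pd.DataFrame | None = None
    overall_accuracy: float | None = None

    @property
    def ranks(self) -> pd.DataFrame:
        M = len(self.values)
        ranks = pd.DataFrame(index=self.values.index, columns=list(self.metrics_ranked),
                             dtype=float)
        for m in self.metrics_ranked:
            vals = self.values[m].to_numpy(dtype=np.float64)
            ranks[m] = rankdata(vals if HIGHER_IS_BETTER[m] else -vals)
        del M
        return ranks

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        for m in self.metrics_ranked:
            out[f"rank_{m}"] = self.ranks[m]
        out["acc_score"] = self.acc_scores
        out.to_csv(path, sep="\t", float_format="%.10g")


def evaluate_methods(
    predictions: dict[str, CellTypeProbabilityMatrix], ref: ReferenceMap
) -> EvaluationReport:
    """Score >= 2 competing probability matrices against one reference map."""
    if len(predictions) < 2:
        raise ValueError("benchmark needs >= 2 methods")
    rows = {name: aggregate_metrics(pm, ref) for name, pm in predictions.items()}
    values = pd.DataFrame.from_dict(rows, orient="index")
    return EvaluationReport(values=values, acc_scores=acc_score(values))
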