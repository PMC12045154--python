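"""Data containers and IO shared by every stage of the pipeline.

The common currency is :class:`ExpressionDataset`: an observations x genes
matrix (cells for a single-cell reference, cells or spots for spatial data)
with gene names, observation ids, optional per-observation cell-type labels
and optional 2-D coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger("dsct")

__all__ = [
    "ExpressionDataset",
    "LabelVocabulary",
    "read_dataset",
    "intersect_genes",
    "normalize",
    "encode_labels",
    "write_probability_matrix",
    "read_probability_matrix",
]


@dataclass
class ExpressionDataset:
    """Observations x genes expression matrix plus metadata.

    Parameters
    ----------
    matrix
        Dense float array of shape ``(n_obs, n_genes)``, non-negative and
        finite. Raw counts (``layer_tag="raw"``) must be whole numbers.
    gene_names
        Ordered, unique gene identifiers (matrix columns).
    obs_ids
        Ordered, unique observation identifiers (matrix rows).
    labels
        Optional per-observation cell-type strings (reference data).
    coords
        Optional ``(n_obs, 2)`` array of spatial x/y positions.
    layer_tag
        ``"raw"`` or ``"normalized"``.
    """

    matrix: np.ndarray
    gene_names: list[str]
    obs_ids: list[str]
    labels: list[str] | None = None
    coords: np.ndarray | None = None
    layer_tag: str = "raw"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.gene_names = [str(g) for g in self.gene_names]
        self.obs_ids = [str(o) for o in self.obs_ids]
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        n, g = self.matrix.shape
        if n != len(self.obs_ids):
            raise ValueError(f"matrix has {n} rows but {len(self.obs_ids)} obs_ids")
        if g != len(self.gene_names):
            raise ValueError(f"matrix has {g} columns but {len(self.gene_names)} gene names")
        if len(set(self.gene_names)) != g:
            raise ValueError("duplicate gene names")
        if len(set(self.obs_ids)) != n:
            raise ValueError("duplicate observation ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains non-finite entries")
        if self.matrix.size and self.matrix.min() < 0:
            raise ValueError("matrix contains negative entries")
        if self.layer_tag not in ("raw", "normalized"):
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")
        if self.layer_tag == "raw" and self.matrix.size:
            if not np.allclose(self.matrix, np.round(self.matrix)):
                raise ValueError("raw layer must contain integer counts")
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != n:
                raise ValueError("labels length mismatch")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.float64)
            if self.coords.shape != (n, 2):
                raise ValueError("coords must be (n_obs, 2)")

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        """Restrict (and reorder) to ``genes``; all must be present."""
        index = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from dataset: {missing[:10]}")
        cols = [index[g] for g in genes]
        return replace(self, matrix=self.matrix[:, cols], gene_names=list(genes))


@dataclass(frozen=True)
class LabelVocabulary:
    """Ordered set of cell-type names with a bijective name -> index map."""

    types: tuple[str, ...]
    index_of: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.types)) != len(self.types):
            raise ValueError("duplicate cell-type names")
        object.__setattr__(self, "index_of", {t: i for i, t in enumerate(self.types)})

    def __len__(self) -> int:
        return len(self.types)

    def __getitem__(self, i: int) -> str:
        return self.types[i]


def _dedup_genes(names: list[str], matrix: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Keep the first occurrence of each duplicated gene name, warn loudly."""
    seen: dict[str, int] = {}
    keep: list[int] = []
    for i, g in enumerate(names):
        if g not in seen:
            seen[g] = i
            keep.append(i)
    if len(keep) != len(names):
        dropped = len(names) - len(keep)
        warnings.warn(f"dropped {dropped} duplicated gene name(s), keeping first occurrence")
        logger.warning("dropped %d duplicated gene columns", dropped)
        return [names[i] for i in keep], matrix[:, keep]
    return names, matrix


def read_dataset(
    path: str | Path,
    format: str | None = None,
    labels_col: str | None = None,
) -> ExpressionDataset:
    """Read an expression dataset from h5ad, a Matrix-Market directory, or CSV.

    ``format`` is one of ``h5ad``, ``mtx_dir``, ``csv``; inferred from the
    path when omitted. Counts are returned with ``layer_tag="raw"``.
    For h5ad, ``labels_col`` names the ``.obs`` column holding cell-type
    labels; spatial coordinates are taken from ``.obsm["spatial"]`` if present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if format is None:
        if path.is_dir():
            format = "mtx_dir"
        elif path.suffix == ".h5ad":
            format = "h5ad"
        else:
            format = "csv"

    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.layers["counts"] if "counts" in adata.layers else adata.X
        X = np.asarray(X.todense() if sparse.issparse(X) else X, dtype=np.float64)
        labels = None
        if labels_col is not None:
            if labels_col not in adata.obs:
                raise KeyError(f"obs column {labels_col!r} not found in {path}")
            labels = adata.obs[labels_col].astype(str).tolist()
        coords = None
        if "spatial" in adata.obsm:
            coords = np.asarray(adata.obsm["spatial"], dtype=np.float64)[:, :2]
        genes, X = _dedup_genes(adata.var_names.astype(str).tolist(), X)
        return ExpressionDataset(X, genes, adata.obs_names.astype(str).tolist(),
                                 labels=labels, coords=coords, layer_tag="raw")

    if format == "mtx_dir":
        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        barcodes_f = path / "barcodes.tsv"
        for f in (mtx, genes_f, barcodes_f):
            if not f.exists():
                raise FileNotFoundError(f"mtx_dir is missing {f}")
        X = np.asarray(spio.mmread(mtx).todense(), dtype=np.float64)  # genes x cells, 10x layout
        genes = [line.split("\t")[0] for line in genes_f.read_text().splitlines() if line]
        barcodes = [line.strip() for line in barcodes_f.read_text().splitlines() if line]
        if X.shape[0] != len(genes):
            raise ValueError(f"{genes_f}: {len(genes)} genes but matrix has {X.shape[0]} rows")
        if X.shape[1] != len(barcodes):
            raise ValueError(f"{barcodes_f}: {len(barcodes)} barcodes but matrix has {X.shape[1]} columns")
        X = X.T  # observations x genes
        genes, X = _dedup_genes(genes, X)
        labels = None
        labels_f = path / "labels.tsv"
        if labels_f.exists():
            labels = [line.strip() for line in labels_f.read_text().splitlines() if line]
        coords = None
        coords_f = path / "coords.tsv"
        if coords_f.exists():
            coords = np.loadtxt(coords_f, delimiter="\t", ndmin=2)
        return ExpressionDataset(X, genes, barcodes, labels=labels, coords=coords, layer_tag="raw")

    if format == "csv":
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        # header parsed by hand: pandas would rename duplicated gene columns
        df = pd.read_csv(path, header=None, skiprows=1, index_col=0, sep=sep)
        df.columns = header[1:]
        non_numeric = [c for c, d in zip(df.columns, df.dtypes) if not np.issubdtype(d, np.number)]
        if non_numeric:
            raise ValueError(f"{path}: non-numeric entries in column(s) {non_numeric[:5]}")
        X = df.to_numpy(dtype=np.float64)
        genes, X = _dedup_genes([str(c) for c in df.columns], X)
        return ExpressionDataset(X, genes, [str(i) for i in df.index], layer_tag="raw")

    raise ValueError(f"unknown format {format!r}")


def intersect_genes(
    reference: ExpressionDataset, spatial: ExpressionDataset
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Restrict both datasets to their shared genes, in reference gene order.

    Only genes measured in both the reference and the spatial assay can inform
    label transfer; everything downstream operates on this intersection.
    """
    if reference.n_genes == 0 or spatial.n_genes == 0:
        raise ValueError("cannot intersect empty datasets")
    spatial_set = set(spatial.gene_names)
    shared = [g for g in reference.gene_names if g in spatial_set]
    if not shared:
        raise ValueError("no shared genes between reference and spatial data")
    return reference.subset_genes(shared), spatial.subset_genes(shared)


def normalize(
    ds: ExpressionDataset, target_sum: float = 1e4, log_transform: bool = True
) -> ExpressionDataset:
    """Library-size normalization: scale each row to ``target_sum``, then log1p.

    All-zero rows are left all-zero (counted in a warning). Applied identically
    to reference and spatial data so the classifier sees one scale.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    if ds.layer_tag != "raw":
        raise ValueError("normalize expects a raw-count dataset")
    row_sums = ds.matrix.sum(axis=1)
    zero_rows = int((row_sums == 0).sum())
    if zero_rows:
        warnings.warn(f"{zero_rows} all-zero observation(s) left unnormalized")
    safe = np.where(row_sums == 0, 1.0, row_sums)
    X = ds.matrix * (target_sum / safe)[:, None]
    if log_transform:
        X = np.log1p(X)
    return replace(ds, matrix=X, layer_tag="normalized")


def encode_labels(ds: ExpressionDataset) -> tuple[LabelVocabulary, np.ndarray]:
    """Map cell-type strings to integer codes, vocabulary in first-appearance order."""
    if ds.labels is None:
        raise ValueError("dataset has no labels")
    if any(l == "" for l in ds.labels):
        raise ValueError("empty label string present")
    types: list[str] = []
    seen: set[str] = set()
    for l in ds.labels:
        if l not in seen:
            seen.add(l)
            types.append(l)
    vocab = LabelVocabulary(tuple(types))
    codes = np.array([vocab.index_of[l] for l in ds.labels], dtype=np.int64)
    return vocab, codes


def write_probability_matrix(pm, path: str | Path) -> None:
    """Write a cell-type probability matrix as CSV (obs ids + one column per type)."""
    path = Path(path)
    df = pd.DataFrame(pm.matrix, index=pm.obs_ids, columns=list(pm.vocab.types))
    df.index.name = "obs_id"
    df.to_csv(path, float_format="%.12g")


def read_probability_matrix(path: str | Path):
    """Round-trip companion of :func:`write_probability_matrix`."""
    from .classifier import CellTypeProbabilityMatrix

    df = pd.read_csv(path, index_col=0)
    vocab = LabelVocabulary(tuple(str(c) for c in df.columns))
    return CellTypeProbabilityMatrix(df.to_numpy(dtype=np.float64),
                                     [str(i) for i in df.index], vocab)
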