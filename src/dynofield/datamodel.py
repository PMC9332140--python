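"""Layered expression container and standard-format I/O.

The central container is :class:`LayeredMatrix`: a cells x genes stack of
named count layers (``u`` unspliced, ``s`` spliced, ``l`` labeled/new,
``r`` total) with per-cell labeling times, experiment type and group labels.
Matrices are cells x genes everywhere in this package.  MatrixMarket files
are written 1-based per the standard; internal indices are 0-based.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field as _field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

KNOWN_LAYERS = {"u", "s", "l", "r"}
EXPERIMENT_TYPES = {"conventional", "one_shot", "kinetics", "degradation"}

MODEL_FORMAT_VERSION = 1

__all__ = [
    "LayeredMatrix",
    "EmbeddingSpace",
    "NeighborGraph",
    "read_layers",
    "write_layers",
    "normalize_and_log",
    "knn_graph",
    "save_model",
    "load_model",
]


class SchemaError(ValueError):
    """Unknown layer name or malformed metadata."""


@dataclass
class LayeredMatrix:
    """Cells x genes counts with named layers and per-cell labeling metadata."""

    layers: dict[str, np.ndarray]
    cell_ids: list[str]
    gene_ids: list[str]
    label_time: np.ndarray | None = None          # hours
    experiment_type: str = "conventional"
    group: np.ndarray | None = None
    size_factors: np.ndarray | None = None
    extra_layers: dict[str, np.ndarray] = _field(default_factory=dict)

    def __post_init__(self):
        if not self.layers:
            raise ValueError("at least one layer required")
        shapes = {k: np.asarray(v).shape for k, v in self.layers.items()}
        ref = next(iter(shapes.values()))
        if any(s != ref for s in shapes.values()):
            raise ValueError(f"layer shape mismatch: {shapes}")
        if ref != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"layers are {ref} but there are {len(self.cell_ids)} cells "
                f"and {len(self.gene_ids)} genes")
        for name, mat in self.layers.items():
            mat = np.asarray(mat, dtype=float)
            if np.any(mat < 0):
                raise ValueError(f"layer {name!r} has negative entries")
            self.layers[name] = mat
        if self.experiment_type not in EXPERIMENT_TYPES:
            raise SchemaError(f"unknown experiment type {self.experiment_type!r}")
        if self.label_time is not None:
            self.label_time = np.asarray(self.label_time, dtype=float)
            if self.label_time.shape != (len(self.cell_ids),):
                raise ValueError("label_time must have one entry per cell")
            n_distinct = np.unique(self.label_time).size
            if self.experiment_type == "one_shot" and n_distinct != 1:
                raise ValueError("one_shot experiments need a constant label time")
            if self.experiment_type in ("kinetics", "degradation") and n_distinct < 2:
                raise ValueError(
                    f"{self.experiment_type} experiments need >=2 distinct label times")
        if "l" in self.layers and "r" in self.layers:
            if np.any(self.layers["r"] - self.layers["l"] < -1e-9):
                raise ValueError("total layer r must dominate labeled layer l")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def layer(self, name: str) -> np.ndarray:
        if name in self.layers:
            return self.layers[name]
        if name in self.extra_layers:
            return self.extra_layers[name]
        raise KeyError(name)

    def subset_cells(self, mask) -> "LayeredMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        lm = LayeredMatrix(
            layers={k: v[idx] for k, v in self.layers.items()},
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            label_time=None if self.label_time is None else self.label_time[idx],
            experiment_type=self.experiment_type,
            group=None if self.group is None else np.asarray(self.group)[idx],
            size_factors=None if self.size_factors is None else self.size_factors[idx],
        )
        lm.extra_layers = {k: v[idx] for k, v in self.extra_layers.items()}
        return lm


@dataclass
class EmbeddingSpace:
    """A linear embedding: genes x k orthonormal loadings Q, gene-space center
    mu, and cell coordinates in the embedded space."""

    loadings: np.ndarray        # genes x k, orthonormal columns
    center: np.ndarray          # genes
    coords: np.ndarray          # cells x k
    name: str = "pca"
    gene_ids: list[str] | None = None

    def __post_init__(self):
        Q = np.asarray(self.loadings, dtype=float)
        gram = Q.T @ Q
        if not np.allclose(gram, np.eye(Q.shape[1]), atol=1e-8):
            raise ValueError("loading columns must be orthonormal (QᵀQ = I)")
        self.loadings = Q
        self.center = np.asarray(self.center, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.center.shape[0] != Q.shape[0]:
            raise ValueError("center length must equal number of genes")

    def project(self, Y: np.ndarray) -> np.ndarray:
        """Gene space -> embedded space: (Y - mu) Q."""
        return (np.asarray(Y) - self.center) @ self.loadings

    def lift(self, X: np.ndarray) -> np.ndarray:
        """Embedded space -> gene space: X Qᵀ + mu."""
        return np.asarray(X) @ self.loadings.T + self.center

    def gene_index(self, gene: str) -> int:
        if self.gene_ids is None:
            raise KeyError("embedding has no gene identifiers")
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in loadings") from None


@dataclass
class NeighborGraph:
    indices: np.ndarray      # cells x K
    distances: np.ndarray    # cells x K, ascending per row
    K: int

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(np.diff(self.distances, axis=1) < -1e-12):
            raise ValueError("distances must be sorted ascending per row")


def _read_matrix(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".mtx":
        return np.asarray(scipy.io.mmread(path).todense(), dtype=float)
    return pd.read_csv(path, header=None).to_numpy(dtype=float)


def read_layers(matrix_paths: dict[str, str | Path], cells_path: str | Path,
                genes_path: str | Path, meta_path: str | Path | None = None,
                ) -> LayeredMatrix:
    """Read layered counts from MTX/CSV matrices plus cell/gene TSVs and a
    metadata table.

    Each matrix file is either MatrixMarket (``.mtx``, cells x genes) or a
    headerless dense CSV.  Per-layer cell files may permute cells relative to
    the first layer; rows are realigned by identifier.  ``meta_path`` is a CSV
    with a ``cell_id`` column and optional ``label_time`` (hours),
    ``experiment_type`` and ``group`` columns.
    """
    unknown = set(matrix_paths) - KNOWN_LAYERS
    if unknown:
        raise SchemaError(f"unknown layer name(s) {sorted(unknown)}")
    cells = pd.read_csv(cells_path, header=None, sep="\t")[0].astype(str).tolist()
    genes = pd.read_csv(genes_path, header=None, sep="\t")[0].astype(str).tolist()
    layers = {}
    for name, p in matrix_paths.items():
        p = Path(p)
        mat = _read_matrix(p)
        if mat.shape != (len(cells), len(genes)):
            raise ValueError(
                f"layer {name!r} has shape {mat.shape}, expected "
                f"({len(cells)}, {len(genes)})")
        # a sibling <layer>.cells.tsv declares this layer's own row order;
        # rows are realigned to the master cell order by identifier
        own_cells_path = p.parent / (p.stem + ".cells.tsv")
        if own_cells_path.exists():
            own = pd.read_csv(own_cells_path, header=None, sep="\t")[0] \
                .astype(str).tolist()
            if sorted(own) != sorted(cells):
                raise ValueError(f"layer {name!r} cell ids disagree with master list")
            perm = [own.index(c) for c in cells]
            mat = mat[perm]
        layers[name] = mat
    label_time = None
    experiment_type = "conventional"
    group = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path)
        if "cell_id" in meta.columns:
            meta = meta.set_index("cell_id").loc[cells]
        if "label_time" in meta.columns:
            label_time = meta["label_time"].to_numpy(dtype=float)
        if "experiment_type" in meta.columns:
            experiment_type = str(meta["experiment_type"].iloc[0])
        if "group" in meta.columns:
            group = meta["group"].to_numpy()
    return LayeredMatrix(layers=layers, cell_ids=cells, gene_ids=genes,
                         label_time=label_time, experiment_type=experiment_type,
                         group=group)


def write_layers(lm: LayeredMatrix, outdir: str | Path, fmt: str = "mtx") -> dict[str, Path]:
    """Write each layer as MTX (1-based, per the format standard) or dense CSV,
    plus cells.tsv, genes.tsv and meta.csv.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, mat in lm.layers.items():
        if fmt == "mtx":
            p = outdir / f"{name}.mtx"
            scipy.io.mmwrite(p, sp.coo_matrix(mat))
        else:
            p = outdir / f"{name}.csv"
            pd.DataFrame(mat).to_csv(p, header=False, index=False)
        paths[name] = p
    pd.Series(lm.cell_ids).to_csv(outdir / "cells.tsv", header=False, index=False, sep="\t")
    pd.Series(lm.gene_ids).to_csv(outdir / "genes.tsv", header=False, index=False, sep="\t")
    meta = pd.DataFrame({"cell_id": lm.cell_ids})
    if lm.label_time is not None:
        meta["label_time"] = lm.label_time
    meta["experiment_type"] = lm.experiment_type
    if lm.group is not None:
        meta["group"] = lm.group
    meta.to_csv(outdir / "meta.csv", index=False)
    paths["meta"] = outdir / "meta.csv"
    paths["cells"] = outdir / "cells.tsv"
    paths["genes"] = outdir / "genes.tsv"
    return paths


def normalize_and_log(lm: LayeredMatrix, target_total: float = 10_000.0,
                      log: bool = True) -> LayeredMatrix:
    """Size-factor normalize every layer by the same per-cell factor, then log1p.

    The per-cell total is taken from layer ``r`` if present, else ``s`` + ``u``,
    else the single available layer; each cell's factor scales its counts so
    the total reaches ``target_total``.  Cells with zero total are dropped with
    a warning.  The zero pattern and within-cell cross-layer proportions are
    preserved.
    """
    import warnings

    if "r" in lm.layers:
        totals = lm.layers["r"].sum(axis=1)
    elif "s" in lm.layers and "u" in lm.layers:
        totals = (lm.layers["s"] + lm.layers["u"]).sum(axis=1)
    else:
        totals = next(iter(lm.layers.values())).sum(axis=1)
    keep = totals > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} cell(s) with zero total counts")
    out = lm.subset_cells(keep)
    factors = target_total / totals[keep]
    transform = (lambda m: np.log1p(m)) if log else (lambda m: m)
    out.layers = {k: transform(v * factors[:, None]) for k, v in out.layers.items()}
    out.extra_layers = {k: transform(v * factors[:, None]) for k, v in out.extra_layers.items()}
    out.size_factors = factors
    return out


def knn_graph(X: np.ndarray, K: int = 30) -> NeighborGraph:
    """Exact Euclidean K-nearest-neighbor graph, self excluded, ties broken by
    ascending index (deterministic)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if K <= 0:
        raise ValueError("K must be positive")
    if K >= n:
        raise ValueError("K must be smaller than the number of points")
    nn = NearestNeighbors(n_neighbors=K + 1, algorithm="brute").fit(X)
    dist, idx = nn.kneighbors(X)
    # drop self (distance 0 to own index); guard duplicated points where the
    # self column may not be first after tie-breaking
    indices = np.empty((n, K), dtype=int)
    distances = np.empty((n, K))
    for i in range(n):
        row_i, row_d = idx[i], dist[i]
        order = np.lexsort((row_i, row_d))  # distance, then index
        row_i, row_d = row_i[order], row_d[order]
        m = row_i != i
        sel = np.flatnonzero(m)[:K]
        indices[i] = row_i[sel]
        distances[i] = row_d[sel]
    return NeighborGraph(indices=indices, distances=distances, K=K)


def save_model(model, path: str | Path) -> Path:
    """Serialize a fitted VectorFieldModel to a single ``.npz`` archive."""
    path = Path(path)
    arrays = {
        "control_points": model.control_points,
        "coefficients": model.coefficients,
        "posterior": model.posterior,
        "loss_trace": np.asarray(model.loss_trace),
    }
    scalars = {
        "format_version": MODEL_FORMAT_VERSION,
        "bandwidth": model.bandwidth,
        "regularization": model.regularization,
        "sigma2": model.sigma2,
        "inlier_fraction": model.inlier_fraction,
        "outlier_volume": model.outlier_volume,
    }
    np.savez(path, header=json.dumps(scalars), **arrays)
    return path


def load_model(path: str | Path):
    """Load a model archive written by :func:`save_model`.

    Raises ValueError on version mismatch and on truncated/invalid archives.
    """
    from .vectorfield import VectorFieldModel

    try:
        with np.load(path, allow_pickle=False) as data:
            header = json.loads(str(data["header"]))
            if header.get("format_version") != MODEL_FORMAT_VERSION:
                raise ValueError(
                    f"incompatible model format version {header.get('format_version')!r}; "
                    f"this build reads version {MODEL_FORMAT_VERSION}")
            model = VectorFieldModel(
                control_points=data["control_points"],
                coefficients=data["coefficients"],
                bandwidth=float(header["bandwidth"]),
                regularization=float(header["regularization"]),
                sigma2=float(header["sigma2"]),
                inlier_fraction=float(header["inlier_fraction"]),
                outlier_volume=float(header["outlier_volume"]),
                posterior=data["posterior"],
                loss_trace=list(data["loss_trace"]),
            )
    except (OSError, KeyError, json.JSONDecodeError, zipfile.BadZipFile) as exc:
        raise ValueError(f"cannot parse model archive {path}: {exc}") from exc
    return model
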