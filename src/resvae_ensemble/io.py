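"""Readers and writers for expression matrices, assignments and results.

Supported matrix formats: MatrixMarket MTX with sibling features.tsv /
barcodes.tsv (10x-style, genes-major by default and transposed to
cells x features on read), dense CSV/TSV (cells x features, first
column = cell ids), and AnnData .h5ad (X, obs_names, var_names only).
Peak identifiers such as ``chr1:1000-1500`` are kept verbatim; no
genomic interpretation is attempted.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import ClusterAssignment, ExpressionMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_assignments",
    "write_assignments",
    "write_manifest",
]

logger = logging.getLogger(__name__)


def _dedup(ids: list[str]) -> list[str]:
    """Suffix duplicate ids deterministically: x, x.1, x.2, ..."""
    seen: dict[str, int] = {}
    out = []
    for i in ids:
        if i in seen:
            seen[i] += 1
            out.append(f"{i}.{seen[i]}")
        else:
            seen[i] = 0
            out.append(i)
    return out


def _detect_format(path: Path) -> str:
    if path.is_dir() or path.suffix == ".mtx":
        return "mtx"
    if path.suffix == ".h5ad":
        return "h5ad"
    if path.suffix in (".csv", ".tsv", ".txt"):
        return "csv"
    raise ValueError(f"cannot auto-detect format of {path}")


def read_matrix(
    path: str | Path,
    fmt: str = "auto",
    genes_major: bool = True,
    drop_zero_features: bool = False,
) -> ExpressionMatrix:
    """Load a cells x features matrix from MTX, CSV/TSV or .h5ad.

    ``genes_major`` (MTX only) transposes a features x cells matrix to
    the internal cells x features orientation. With
    ``drop_zero_features`` all-zero columns are removed (and logged).
    """
    path = Path(path)
    if fmt == "auto":
        fmt = _detect_format(path)
    if fmt == "mtx":
        mtx_dir = path if path.is_dir() else path.parent
        mtx_file = path if path.suffix == ".mtx" else mtx_dir / "matrix.mtx"
        values = scipy.io.mmread(mtx_file)
        if scipy.sparse.issparse(values):
            values = values.toarray()
        values = np.asarray(values, dtype=float)
        features = pd.read_csv(mtx_dir / "features.tsv", sep="\t", header=None)[0].astype(str)
        barcodes = pd.read_csv(mtx_dir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
        if genes_major:
            values = values.T
        if values.shape != (len(barcodes), len(features)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(barcodes)} barcodes x {len(features)} features"
            )
        cell_ids, feature_ids = list(barcodes), list(features)
    elif fmt == "csv":
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        cell_ids, feature_ids = [str(i) for i in df.index], [str(c) for c in df.columns]
    elif fmt == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        values = adata.X
        if scipy.sparse.issparse(values):
            values = values.toarray()
        values = np.asarray(values, dtype=float)
        cell_ids = [str(i) for i in adata.obs_names]
        feature_ids = [str(i) for i in adata.var_names]
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if np.any(values < 0):
        raise ValueError("matrix contains negative values")
    deduped = _dedup(feature_ids)
    if deduped != feature_ids:
        logger.warning("duplicate feature ids were suffixed deterministically")
    feature_ids = deduped
    if drop_zero_features:
        keep = values.sum(axis=0) > 0
        if not keep.all():
            logger.info("dropping %d all-zero features", int((~keep).sum()))
            values = values[:, keep]
            feature_ids = [f for f, k in zip(feature_ids, keep) if k]
    return ExpressionMatrix(values=values, feature_ids=feature_ids, cell_ids=cell_ids)


def write_matrix(data: ExpressionMatrix, path: str | Path, fmt: str = "auto") -> None:
    """Write a matrix as an MTX directory, dense CSV/TSV, or .h5ad."""
    path = Path(path)
    if fmt == "auto":
        fmt = "mtx" if (path.suffix == "" or path.is_dir()) else _detect_format(path)
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", scipy.sparse.csr_matrix(data.values.T))
        pd.Series(data.feature_ids).to_csv(path / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(data.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    elif fmt == "csv":
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        pd.DataFrame(data.values, index=data.cell_ids, columns=data.feature_ids).to_csv(path, sep=sep)
    elif fmt == "h5ad":
        import anndata

        anndata.AnnData(
            X=data.values,
            obs=pd.DataFrame(index=data.cell_ids),
            var=pd.DataFrame(index=data.feature_ids),
        ).write_h5ad(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_assignments(
    path: str | Path, mode: str, data: ExpressionMatrix | None = None
) -> ClusterAssignment:
    """Load cluster assignments and align them to a matrix's cell order.

    ``mode='hard'``: two-column (cell, cluster) table -> one-hot.
    ``mode='soft'``: cell x cluster numeric table; rows are
    renormalized to sum to one (with a warning beyond 1e-3 deviation).
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    if mode == "hard":
        df = pd.read_csv(path, sep=sep)
        cells = df.iloc[:, 0].astype(str).tolist()
        labels = df.iloc[:, 1].astype(str).tolist()
        assignment = ClusterAssignment.from_labels(labels, cells)
    elif mode == "soft":
        df = pd.read_csv(path, sep=sep, index_col=0)
        weights = df.to_numpy(dtype=float)
        sums = weights.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("soft assignment has a non-positive row sum")
        if np.any(np.abs(sums - 1.0) > 1e-3):
            warnings.warn("soft assignment rows renormalized to sum to 1", UserWarning)
        weights = weights / sums[:, None]
        assignment = ClusterAssignment(
            weights=weights,
            cluster_ids=[str(c) for c in df.columns],
            cell_ids=[str(i) for i in df.index],
            is_hard=False,
        )
    else:
        raise ValueError("mode must be 'hard' or 'soft'")

    if data is not None:
        index = {c: i for i, c in enumerate(assignment.cell_ids)}
        missing = [c for c in data.cell_ids if c not in index]
        if missing:
            raise ValueError(f"cells missing from assignment: {missing[:10]}")
        order = [index[c] for c in data.cell_ids]
        assignment = ClusterAssignment(
            weights=assignment.weights[order],
            cluster_ids=assignment.cluster_ids,
            cell_ids=list(data.cell_ids),
            is_hard=assignment.is_hard,
        )
    return assignment


def write_assignments(assignment: ClusterAssignment, path: str | Path) -> None:
    """Hard assignments as (cell, cluster) CSV; soft as a cell x cluster table."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    if assignment.is_hard:
        pd.DataFrame(
            {"cell": assignment.cell_ids, "cluster": assignment.hard_labels()}
        ).to_csv(path, sep=sep, index=False)
    else:
        pd.DataFrame(
            assignment.weights, index=assignment.cell_ids, columns=assignment.cluster_ids
        ).to_csv(path, sep=sep)


def write_manifest(path: str | Path, **entries) -> None:
    """JSON run manifest (configs, seeds, versions) for exact replay."""
    import resvae_ensemble

    manifest = {"resvae_ensemble_version": resvae_ensemble.__version__, **entries}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
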