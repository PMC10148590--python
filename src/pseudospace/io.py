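"""Readers, writers and the SC/ST harmonization step.

On-disk conventions
-------------------
* CSV/TSV expression: first column = observation id, header row = gene names;
  set ``orientation="gene_by_obs"`` for the transposed layout (first column =
  gene name, header = observation ids).
* MatrixMarket: ``<file>.mtx`` in coordinate format (rows = observations
  unless ``orientation="gene_by_obs"``) with plain-text companions
  ``<file>.genes.txt`` and ``<file>.obs.txt``, one name per line.
* Coordinate table: CSV with header ``obs_id,x,y``.
* Label table: CSV with header ``obs_id,label``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import ExpressionDataset, SpatialReference

logger = logging.getLogger(__name__)

__all__ = [
    "load_expression",
    "write_expression",
    "load_spatial_reference",
    "load_labels",
    "write_coords",
    "write_labels",
    "preprocess_pair",
]

_SEPS = {"csv": ",", "tsv": "\t"}


def _mtx_companions(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("")
    return base.with_suffix(".genes.txt"), base.with_suffix(".obs.txt")


def load_expression(
    path: str | Path,
    fmt: str = "csv",
    orientation: str = "obs_by_gene",
) -> ExpressionDataset:
    """Read an expression matrix as observations x genes.

    ``layer_tag`` is inferred as ``"counts"`` iff every entry is a
    non-negative integer, else ``"normalized"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if orientation not in ("obs_by_gene", "gene_by_obs"):
        raise ValueError(f"unknown orientation {orientation!r}")

    if fmt in _SEPS:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(_SEPS[fmt])[1:]
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise ValueError(f"duplicate gene names in {path}: {dupes[:10]}")
        df = pd.read_csv(path, sep=_SEPS[fmt], index_col=0)
        bad = df.columns[~df.apply(
            lambda c: pd.to_numeric(c, errors="coerce").notna().all()
        )]
        if len(bad):
            col = bad[0]
            row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(
                f"non-numeric value at row {row!r}, column {col!r} in {path}"
            )
        matrix = df.to_numpy(dtype=float)
        row_names = [str(i) for i in df.index]
        col_names = [str(c) for c in df.columns]
    elif fmt == "mtx":
        genes_path, obs_path = _mtx_companions(path)
        for p in (genes_path, obs_path):
            if not p.exists():
                raise FileNotFoundError(f"missing MTX companion file {p}")
        mat = scipy.io.mmread(path)
        matrix = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        gene_names = genes_path.read_text().split()
        obs_ids = obs_path.read_text().split()
        row_names, col_names = obs_ids, gene_names
        if orientation == "gene_by_obs":
            row_names, col_names = gene_names, obs_ids
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if orientation == "gene_by_obs":
        matrix = matrix.T
        row_names, col_names = col_names, row_names

    layer = "counts" if _looks_like_counts(matrix) else "normalized"
    return ExpressionDataset(
        matrix=matrix, gene_names=col_names, obs_ids=row_names, layer_tag=layer
    )


def _looks_like_counts(matrix: np.ndarray) -> bool:
    return bool((matrix >= 0).all() and np.array_equal(matrix, np.round(matrix)))


def write_expression(
    ds: ExpressionDataset,
    path: str | Path,
    fmt: str = "csv",
    orientation: str = "obs_by_gene",
) -> None:
    """Write a dataset in any of the supported on-disk layouts."""
    path = Path(path)
    if fmt in _SEPS:
        df = pd.DataFrame(ds.matrix, index=ds.obs_ids, columns=ds.gene_names)
        if orientation == "gene_by_obs":
            df = df.T
        df.to_csv(path, sep=_SEPS[fmt])
    elif fmt == "mtx":
        genes_path, obs_path = _mtx_companions(path)
        mat = ds.matrix if orientation == "obs_by_gene" else ds.matrix.T
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(mat))
        genes_path.write_text("\n".join(ds.gene_names) + "\n")
        obs_path.write_text("\n".join(ds.obs_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_spatial_reference(
    expr_path: str | Path,
    coords_path: str | Path,
    fmt: str = "csv",
    orientation: str = "obs_by_gene",
) -> SpatialReference:
    """Read an expression matrix and its ``obs_id,x,y`` coordinate table.

    Coordinates are re-ordered to the expression observation order; the two
    id sets must match exactly.
    """
    expr = load_expression(expr_path, fmt=fmt, orientation=orientation)
    coords_df = pd.read_csv(coords_path)
    required = {"obs_id", "x", "y"}
    if not required.issubset(coords_df.columns):
        raise ValueError(
            f"coordinate table must have columns obs_id,x,y; got "
            f"{list(coords_df.columns)}"
        )
    coords_df["obs_id"] = coords_df["obs_id"].astype(str)
    coord_ids = set(coords_df["obs_id"])
    expr_ids = set(expr.obs_ids)
    missing = sorted(expr_ids - coord_ids)
    extra = sorted(coord_ids - expr_ids)
    if missing:
        raise ValueError(f"coordinates missing for observations: {missing[:10]}")
    if extra:
        raise ValueError(f"coordinate rows without expression: {extra[:10]}")
    coords_df = coords_df.set_index("obs_id").loc[expr.obs_ids, ["x", "y"]]
    coords = coords_df.to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    return SpatialReference(expr=expr, coords=coords)


def load_labels(path: str | Path, obs_ids: list[str] | None = None) -> list[str]:
    """Read an ``obs_id,label`` table, optionally reordered to ``obs_ids``."""
    df = pd.read_csv(path)
    if not {"obs_id", "label"}.issubset(df.columns):
        raise ValueError("label table must have columns obs_id,label")
    df["obs_id"] = df["obs_id"].astype(str)
    if obs_ids is None:
        return [str(x) for x in df["label"]]
    series = df.set_index("obs_id")["label"]
    missing = [o for o in obs_ids if o not in series.index]
    if missing:
        raise ValueError(f"labels missing for observations: {missing[:10]}")
    return [str(series[o]) for o in obs_ids]


def write_coords(obs_ids: list[str], coords: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        {"obs_id": obs_ids, "x": coords[:, 0], "y": coords[:, 1]}
    ).to_csv(path, index=False)


def write_labels(obs_ids: list[str], labels, path: str | Path) -> None:
    pd.DataFrame({"obs_id": obs_ids, "label": list(labels)}).to_csv(
        path, index=False
    )


def preprocess_pair(
    sc: ExpressionDataset,
    st: ExpressionDataset,
    n_hvg: int | None = 2000,
    target_sum: float = 1e4,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Harmonize genes and normalize a single-cell / spatial pair.

    Both datasets are restricted to the lexicographically sorted intersection
    of their gene sets (the shared feature space the kernel embedding needs),
    optionally down to the ``n_hvg`` most variable genes judged on the
    single-cell side. Counts layers are scaled per observation to
    ``target_sum`` total and log(1+x)-transformed; datasets already tagged
    ``"normalized"`` pass through unchanged, which makes the step idempotent.
    """
    shared = sorted(set(sc.gene_names) & set(st.gene_names))
    if len(shared) < 2:
        raise ValueError(
            f"gene intersection too small ({len(shared)} shared genes)"
        )
    sc_n = _normalize(sc.subset_genes(shared), target_sum)
    st_n = _normalize(st.subset_genes(shared), target_sum)

    if n_hvg is not None and n_hvg < len(shared):
        variances = sc_n.matrix.var(axis=0)
        top = np.argsort(variances)[::-1][:n_hvg]
        keep = sorted(sc_n.gene_names[j] for j in top)
        sc_n = sc_n.subset_genes(keep)
        st_n = st_n.subset_genes(keep)
    elif n_hvg is not None and n_hvg > len(shared):
        logger.warning(
            "n_hvg=%d exceeds the %d shared genes; keeping all", n_hvg, len(shared)
        )
    return sc_n, st_n


def _normalize(ds: ExpressionDataset, target_sum: float) -> ExpressionDataset:
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    if ds.layer_tag == "normalized":
        return ds
    totals = ds.matrix.sum(axis=1, keepdims=True)
    zero_rows = (totals == 0).ravel()
    if zero_rows.any():
        logger.warning(
            "%d all-zero observations retained as zeros", int(zero_rows.sum())
        )
    scaled = np.divide(
        ds.matrix * target_sum, totals, out=np.zeros_like(ds.matrix),
        where=totals > 0,
    )
    return ExpressionDataset(
        matrix=np.log1p(scaled),
        gene_names=list(ds.gene_names),
        obs_ids=list(ds.obs_ids),
        labels=None if ds.labels is None else list(ds.labels),
        layer_tag="normalized",
    )
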