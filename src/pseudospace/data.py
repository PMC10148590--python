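"""Core in-memory containers for expression matrices and spatial references.

The two containers below are deliberately light-weight (dense numpy matrix +
plain python index lists) rather than AnnData: every downstream stage here
needs dense linear algebra on modest matrices, and a thin container keeps the
invariants explicit and cheap to validate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExpressionDataset", "SpatialReference"]


@dataclass
class ExpressionDataset:
    """An observations x genes expression matrix with named axes.

    Parameters
    ----------
    matrix : ndarray of shape (n_obs, n_genes)
        Expression values; raw counts or normalized, per ``layer_tag``.
    gene_names : list of str
        Unique gene identifiers, one per column.
    obs_ids : list of str
        Unique observation (cell/spot) identifiers, one per row.
    labels : list of str, optional
        Categorical annotation per observation (e.g. cell type).
    layer_tag : {"counts", "normalized"}
        Which layer the matrix holds. A counts layer must be non-negative.
    """

    matrix: np.ndarray
    gene_names: list[str]
    obs_ids: list[str]
    labels: list[str] | None = None
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError(f"matrix must be 2-D, got shape {self.matrix.shape}")
        n_obs, n_genes = self.matrix.shape
        if len(self.obs_ids) != n_obs:
            raise ValueError(
                f"{len(self.obs_ids)} obs_ids for {n_obs} matrix rows"
            )
        if len(self.gene_names) != n_genes:
            raise ValueError(
                f"{len(self.gene_names)} gene_names for {n_genes} matrix columns"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            dupes = _duplicates(self.gene_names)
            raise ValueError(f"duplicate gene names: {sorted(dupes)[:10]}")
        if len(set(self.obs_ids)) != len(self.obs_ids):
            dupes = _duplicates(self.obs_ids)
            raise ValueError(f"duplicate observation ids: {sorted(dupes)[:10]}")
        if self.labels is not None and len(self.labels) != n_obs:
            raise ValueError(
                f"{len(self.labels)} labels for {n_obs} observations"
            )
        if self.layer_tag not in ("counts", "normalized"):
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")
        if not np.isfinite(self.matrix).all():
            raise ValueError("matrix contains NaN or Inf")
        if self.layer_tag == "counts" and (self.matrix < 0).any():
            raise ValueError("counts layer contains negative values")

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        """Return a copy restricted to ``genes`` in the given order."""
        index = {g: j for j, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present: {missing[:10]}")
        cols = [index[g] for g in genes]
        return ExpressionDataset(
            matrix=self.matrix[:, cols].copy(),
            gene_names=list(genes),
            obs_ids=list(self.obs_ids),
            labels=None if self.labels is None else list(self.labels),
            layer_tag=self.layer_tag,
        )


@dataclass
class SpatialReference:
    """An :class:`ExpressionDataset` plus 2-D coordinates per observation."""

    expr: ExpressionDataset
    coords: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"coords must be (n, 2), got {self.coords.shape}")
        if self.coords.shape[0] != self.expr.n_obs:
            raise ValueError(
                f"{self.coords.shape[0]} coordinate rows for "
                f"{self.expr.n_obs} observations"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates contain NaN or Inf")

    @property
    def n_obs(self) -> int:
        return self.expr.n_obs


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        (dupes if x in seen else seen).add(x)
    return dupes
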