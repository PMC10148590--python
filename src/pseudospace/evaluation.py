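"""Reconstruction and clustering quality metrics.

Pairwise-distance Pearson correlation scores how well a reconstructed
coordinate set preserves the cell-to-cell geometry of the true one (it is
invariant to rotation, translation and uniform scaling, which a regression
in an arbitrary frame cannot and need not recover). ARI and NMI score
partitions against ground-truth labels. Normalized group distances summarize
how far groups sit from each other on a 0-1 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
)
from sklearn.model_selection import train_test_split

__all__ = [
    "EvalReport",
    "pairwise_distance_pcc",
    "adjusted_rand_index",
    "normalized_mutual_information",
    "normalized_group_distances",
    "batch_separability",
]


@dataclass
class EvalReport:
    """Bundle of evaluation metrics for one reconstruction/clustering run."""

    pairwise_pcc: float | None = None
    ari: float | None = None
    nmi: float | None = None
    per_group_distance_summary: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "pairwise_pcc": self.pairwise_pcc,
            "ari": self.ari,
            "nmi": self.nmi,
            **self.extras,
        }
        if self.per_group_distance_summary is not None:
            out["per_group_distance_summary"] = (
                self.per_group_distance_summary.to_dict(orient="records")
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": k, "value": v}
            for k, v in self.to_dict().items()
            if isinstance(v, (int, float)) and v is not None
        ]
        return pd.DataFrame(rows)


def pairwise_distance_pcc(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    max_pairs: int | None = None,
    seed: int = 0,
) -> float:
    """Pearson correlation of the two upper-triangle distance vectors.

    ``max_pairs`` (optional) subsamples pairs for very large n; all
    n(n-1)/2 pairs are used by default.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    da, db = pdist(a), pdist(b)
    if max_pairs is not None and len(da) > max_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(da), size=max_pairs, replace=False)
        da, db = da[keep], db[keep]
    if da.std() == 0 or db.std() == 0:
        raise ValueError("zero-variance distance vector (coincident points)")
    return float(np.corrcoef(da, db)[0, 1])


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-adjusted Rand index between two partitions."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    if len(labels_a) < 2:
        raise ValueError("need at least 2 observations")
    return float(adjusted_rand_score(labels_a, labels_b))


def normalized_mutual_information(labels_a, labels_b) -> float:
    """NMI with the arithmetic-mean entropy normalizer; 0 if either
    partition is constant (zero entropy)."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    if len(set(labels_a)) < 2 or len(set(labels_b)) < 2:
        return 0.0
    return float(
        normalized_mutual_info_score(
            labels_a, labels_b, average_method="arithmetic"
        )
    )


def normalized_group_distances(
    coords: np.ndarray,
    labels,
    group_a: str | None = None,
    group_b: str | None = None,
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Cross-group pairwise distances, min-max normalized globally.

    Distances are normalized by the global pairwise-distance range of the
    whole embedding, so entries lie in [0, 1]. Give either ``group_a`` and
    ``group_b`` for one row, or ``reference_group`` for one row per other
    group versus the reference. Self-comparisons exclude self-pairs.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray([str(x) for x in labels])
    all_d = pdist(coords)
    d_min, d_max = all_d.min(), all_d.max()
    span = d_max - d_min if d_max > d_min else 1.0

    if reference_group is not None:
        others = [g for g in np.unique(labels) if g != reference_group]
        pairs = [(g, reference_group) for g in others]
    elif group_a is not None and group_b is not None:
        pairs = [(group_a, group_b)]
    else:
        raise ValueError("give group_a+group_b or reference_group")

    rows = []
    for ga, gb in pairs:
        ia, ib = labels == ga, labels == gb
        if not ia.any() or not ib.any():
            raise ValueError(f"empty group in pair ({ga!r}, {gb!r})")
        d = cdist(coords[ia], coords[ib])
        if ga == gb:
            d = d[~np.eye(d.shape[0], dtype=bool)].ravel()
            n_pairs = d.size
        else:
            d = d.ravel()
            n_pairs = d.size
        norm = (d - d_min) / span
        norm = np.clip(norm, 0.0, 1.0)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "median": float(np.median(norm)) if n_pairs else np.nan,
                "sd": float(norm.std()) if n_pairs else np.nan,
                "n_pairs": int(n_pairs),
            }
        )
    return pd.DataFrame(rows)


def batch_separability(
    features: np.ndarray,
    batch_labels,
    seed: int = 0,
    test_size: float = 0.5,
) -> float:
    """Held-out accuracy of a linear (logistic) classifier separating batches.

    ~0.5 means the batches are indistinguishable in this feature space;
    values near 1 mean a strong batch effect.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray([str(b) for b in batch_labels])
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_size, random_state=seed, stratify=y
    )
    sd = Xtr.std(axis=0)
    mu = Xtr.mean(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit((Xtr - mu) / sd, ytr)
    return float(clf.score((Xte - mu) / sd, yte))
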