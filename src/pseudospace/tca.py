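"""Transfer component analysis: a shared latent space for SC and ST data.

The batch effect between dissociated single-cell data (source, n1 cells) and
a spatial reference (target, n2 spots/cells) is treated as a distribution
shift. We seek an m-dimensional transform of the joint kernel matrix that
minimizes the kernel-embedded maximum mean discrepancy (MMD) between the two
domains while preserving overall data variance.

With the combined kernel matrix K over the n1+n2 observations, the MMD
coefficient matrix L (entries 1/n1^2, 1/n2^2, -1/(n1*n2) by domain block) and
the centering matrix H = I - (1/n) 11^T, the transform W in R^{(n1+n2) x m}
solves

    min_W  tr(W^T K L K W) + mu * tr(W^T W)   s.t.  W^T K H K W = I,

whose stationary points satisfy (I + mu*K L K) W = K H K W Z. The columns of
W are the eigenvectors of the m smallest eigenvalues of
(K H K)^{-1} (I + mu*K L K): small eigenvalues simultaneously shrink the
cross-domain MMD (numerator) and keep the centered-kernel variance
(denominator) large. The latent features are the rows of K W, split back
into the source block X'_S and target block X'_T.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "KernelSpec",
    "TcaModel",
    "build_coefficient_matrix_L",
    "build_centering_matrix_H",
    "compute_kernel",
    "mmd_trace",
    "fit_tca",
    "embed",
]

#: hard cap on the joint kernel size before Nystrom subsampling kicks in
MAX_KERNEL_OBS = 5000


@dataclass
class KernelSpec:
    """Kernel family for the joint SC+ST kernel matrix.

    ``kind="linear"`` gives K = X X^T; ``kind="rbf"`` gives
    K_ij = exp(-gamma * ||x_i - x_j||^2) with ``gamma`` either a positive
    number or ``"median-heuristic"`` (gamma = 1 / (2 * median pairwise
    distance squared), resolved on the combined data).
    """

    kind: str = "linear"
    gamma: float | str = "median-heuristic"

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "rbf" and self.gamma != "median-heuristic":
            if not (np.isfinite(self.gamma) and self.gamma > 0):
                raise ValueError("gamma must be positive and finite")

    def resolve_gamma(self, X: np.ndarray) -> float:
        if self.gamma != "median-heuristic":
            return float(self.gamma)
        med = np.median(pdist(X)) if X.shape[0] > 1 else 1.0
        if med <= 0:
            med = 1.0
        return 1.0 / (2.0 * med**2)


@dataclass
class TcaModel:
    """A fitted transfer-component transform."""

    m: int
    mu: float
    ridge: float
    W: np.ndarray                 # (n1+n2) x m
    eigenvalues: np.ndarray       # m, ascending
    K: np.ndarray                 # joint kernel over the fitted observations
    train_obs_split: tuple[int, int]
    spec: KernelSpec
    # data the kernel was evaluated on (needed to extend to held-out rows)
    X_fit: np.ndarray = field(repr=False, default=None)  # type: ignore
    gamma_: float | None = None
    # full-data row kernels when the ST side was subsampled for fitting
    _K_full_source: np.ndarray | None = field(repr=False, default=None)
    _K_full_target: np.ndarray | None = field(repr=False, default=None)
    #: hash of the gene list the kernel was computed over (set by callers
    #: that know the gene names; guards against applying W to other genes)
    gene_fingerprint: str | None = None

    def save(self, path) -> None:
        """Persist the fitted transform as a single ``.npz`` archive."""
        meta = {
            "m": self.m, "mu": self.mu, "ridge": self.ridge,
            "n1": self.train_obs_split[0], "n2": self.train_obs_split[1],
            "kind": self.spec.kind, "gamma": self.spec.gamma,
            "gamma_": self.gamma_, "gene_fingerprint": self.gene_fingerprint,
        }
        arrays = {
            "W": self.W, "eigenvalues": self.eigenvalues, "K": self.K,
            "X_fit": self.X_fit, "meta": np.frombuffer(
                json.dumps(meta).encode(), dtype=np.uint8
            ),
        }
        if self._K_full_source is not None:
            arrays["K_full_source"] = self._K_full_source
            arrays["K_full_target"] = self._K_full_target
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TcaModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"].tobytes()).decode())
            return cls(
                m=int(meta["m"]),
                mu=float(meta["mu"]),
                ridge=float(meta["ridge"]),
                W=data["W"],
                eigenvalues=data["eigenvalues"],
                K=data["K"],
                train_obs_split=(int(meta["n1"]), int(meta["n2"])),
                spec=KernelSpec(meta["kind"], meta["gamma"]),
                X_fit=data["X_fit"],
                gamma_=meta["gamma_"],
                _K_full_source=data.get("K_full_source"),
                _K_full_target=data.get("K_full_target"),
                gene_fingerprint=meta["gene_fingerprint"],
            )

    def kernel_rows(self, X_new: np.ndarray) -> np.ndarray:
        """Kernel between new observations and the fitted ones."""
        if self.spec.kind == "linear":
            return X_new @ self.X_fit.T
        d2 = (
            np.sum(X_new**2, axis=1)[:, None]
            + np.sum(self.X_fit**2, axis=1)[None, :]
            - 2.0 * X_new @ self.X_fit.T
        )
        return np.exp(-self.gamma_ * np.maximum(d2, 0.0))


def build_coefficient_matrix_L(n1: int, n2: int) -> np.ndarray:
    """MMD coefficient matrix: tr(K L) is the squared MMD between domains.

    L is the outer product v v^T of v = (1/n1, ..., -1/n2, ...), hence
    symmetric PSD of rank one with zero row sums.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("n1 and n2 must be positive")
    v = np.concatenate([np.full(n1, 1.0 / n1), np.full(n2, -1.0 / n2)])
    return np.outer(v, v)


def build_centering_matrix_H(n: int) -> np.ndarray:
    """Centering matrix H = I - (1/n) 11^T (symmetric, idempotent)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.eye(n) - np.full((n, n), 1.0 / n)


def compute_kernel(
    Xs: np.ndarray, Xt: np.ndarray, spec: KernelSpec
) -> np.ndarray:
    """Joint (n1+n2) x (n1+n2) kernel over stacked source and target rows."""
    Xs = np.asarray(Xs, dtype=float)
    Xt = np.asarray(Xt, dtype=float)
    if Xs.shape[1] != Xt.shape[1]:
        raise ValueError(
            f"feature mismatch: source has {Xs.shape[1]} columns, "
            f"target has {Xt.shape[1]}"
        )
    X = np.vstack([Xs, Xt])
    if spec.kind == "linear":
        K = X @ X.T
    else:
        gamma = spec.resolve_gamma(X)
        sq = np.sum(X**2, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
        K = np.exp(-gamma * np.maximum(d2, 0.0))
        np.fill_diagonal(K, 1.0)
    return 0.5 * (K + K.T)


def mmd_trace(K: np.ndarray, L: np.ndarray) -> float:
    """tr(K L): the squared MMD between the two domains under kernel K."""
    return float(np.trace(K @ L))


def fit_tca(
    Xs: np.ndarray,
    Xt: np.ndarray,
    spec: KernelSpec | None = None,
    m: int = 50,
    mu: float = 1.0,
    ridge: float | None = None,
    seed: int = 0,
    max_obs: int = MAX_KERNEL_OBS,
) -> TcaModel:
    """Fit the transfer-component transform on a source/target pair.

    Solves the symmetric-definite generalized eigenproblem
    (I + mu*K L K) w = lambda (K H K + ridge*I) w and keeps the eigenvectors
    of the ``m`` smallest eigenvalues, each rescaled so w^T (K H K) w = 1
    where that quadratic form is positive. ``ridge`` defaults to
    1e-8 * tr(K H K)/(n1+n2) and is escalated tenfold (up to 1e-2 on the same
    relative scale) if the solver rejects the right-hand side; K H K is
    always rank-deficient because H centers.

    When n1+n2 exceeds ``max_obs`` the target side is uniformly subsampled
    (seeded) to max_obs - n1 anchor rows for the kernel, and the final
    embedding is extended to all rows via the Nystrom formula K_new W.
    """
    spec = spec or KernelSpec()
    Xs = np.asarray(Xs, dtype=float)
    Xt = np.asarray(Xt, dtype=float)
    if mu <= 0:
        raise ValueError("mu must be positive")
    n1, n2 = Xs.shape[0], Xt.shape[0]

    Xt_fit = Xt
    subsampled = False
    if n1 + n2 > max_obs:
        n_anchor = max_obs - n1
        if n_anchor < 2:
            raise ValueError(
                f"n1={n1} leaves fewer than 2 target anchors under "
                f"max_obs={max_obs}"
            )
        rng = np.random.default_rng(seed)
        anchor_idx = np.sort(rng.choice(n2, size=n_anchor, replace=False))
        Xt_fit = Xt[anchor_idx]
        subsampled = True
        logger.info(
            "kernel capped: using %d of %d target rows as anchors",
            n_anchor, n2,
        )

    n2_fit = Xt_fit.shape[0]
    n = n1 + n2_fit
    if m > n - 1:
        raise ValueError(f"m={m} exceeds n1+n2-1={n - 1}")

    K = compute_kernel(Xs, Xt_fit, spec)
    L = build_coefficient_matrix_L(n1, n2_fit)
    H = build_centering_matrix_H(n)

    KHK = K @ H @ K
    KHK = 0.5 * (KHK + KHK.T)
    A = np.eye(n) + mu * (K @ L @ K)
    A = 0.5 * (A + A.T)

    ridge_scale = max(np.trace(KHK) / n, np.finfo(float).tiny)
    rel_ridge = 1e-8 if ridge is None else ridge / ridge_scale
    last_err: Exception | None = None
    while True:
        ridge_val = rel_ridge * ridge_scale if ridge is None else ridge
        B = KHK + ridge_val * np.eye(n)
        try:
            eigvals, eigvecs = scipy.linalg.eigh(
                A, B, subset_by_index=(0, m - 1)
            )
            break
        except scipy.linalg.LinAlgError as err:  # B not positive definite
            last_err = err
            if ridge is not None or rel_ridge >= 1e-2:
                cond = np.linalg.cond(B)
                raise np.linalg.LinAlgError(
                    f"generalized eigensolver failed (cond(B) ~ {cond:.2e}, "
                    f"ridge {ridge_val:.2e})"
                ) from last_err
            rel_ridge *= 10.0
            logger.warning("eigensolver failed; escalating ridge to %g "
                           "(relative)", rel_ridge)
    ridge_val = rel_ridge * ridge_scale if ridge is None else ridge

    W = np.asarray(eigvecs, dtype=float)
    if np.iscomplexobj(eigvecs) and np.abs(np.imag(eigvecs)).max() > 1e-8:
        raise np.linalg.LinAlgError("complex eigenvectors beyond tolerance")

    # normalize to the constraint w^T (K H K) w = 1 where possible
    for j in range(W.shape[1]):
        q = float(W[:, j] @ KHK @ W[:, j])
        if q > 1e-12:
            W[:, j] /= np.sqrt(q)
        else:
            W[:, j] /= np.linalg.norm(W[:, j])
            logger.warning(
                "eigenvector %d lies in the null space of K H K; "
                "unit-normalized instead", j,
            )

    model = TcaModel(
        m=m,
        mu=mu,
        ridge=ridge_val,
        W=W,
        eigenvalues=np.asarray(eigvals, dtype=float),
        K=K,
        train_obs_split=(n1, n2_fit),
        spec=spec,
        X_fit=np.vstack([Xs, Xt_fit]),
        gamma_=spec.resolve_gamma(np.vstack([Xs, Xt_fit]))
        if spec.kind == "rbf" else None,
    )
    if subsampled:
        model._K_full_source = model.kernel_rows(Xs)
        model._K_full_target = model.kernel_rows(Xt)
    return model


def embed(model: TcaModel) -> tuple[np.ndarray, np.ndarray]:
    """Latent features (X'_S, X'_T): the source/target row blocks of K W."""
    if model._K_full_source is not None:
        return (
            model._K_full_source @ model.W,
            model._K_full_target @ model.W,
        )
    n1, _ = model.train_obs_split
    KW = model.K @ model.W
    return KW[:n1], KW[n1:]
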