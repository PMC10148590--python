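"""Top-level Model/Results interface.

:class:`PseudoSpaceModel` is built from a single-cell expression dataset and
a spatial reference; :meth:`PseudoSpaceModel.fit` runs harmonization, the
transfer-component co-embedding and the coordinate regression, returning a
:class:`PseudoSpaceResults` that carries the latent features, the predicted
pseudo-space, diagnostics and a ``summary()`` table. Space-informed
clustering and evaluation hang off the results object.

Example
-------
>>> from pseudospace import PseudoSpaceModel, simulate_paired, SimConfig
>>> pair = simulate_paired(SimConfig(n_genes=500, n_sc=150, n_st=150, seed=7))
>>> res = PseudoSpaceModel(pair.sc, pair.st, m=20, seed=7).fit()
>>> res.pseudo_space.coords.shape
(150, 2)
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import clustering as _clustering
from . import evaluation as _evaluation
from . import io as _io
from . import regression as _regression
from . import tca as _tca
from ._utils import stage_seed
from .data import ExpressionDataset, SpatialReference

__all__ = ["PseudoSpaceModel", "PseudoSpaceResults"]


class PseudoSpaceModel:
    """Assigns spatial positions to dissociated single cells.

    Parameters
    ----------
    sc : ExpressionDataset
        Single-cell expression (counts or normalized).
    st : SpatialReference
        Spatial reference: expression plus 2-D coordinates.
    kernel : KernelSpec, optional
        Kernel of the joint co-embedding (linear by default).
    m : int
        Latent dimension of the shared feature space.
    mu : float
        Trade-off between MMD reduction and transform complexity.
    ridge : float, optional
        Explicit ridge on the variance operator; auto-scaled if omitted.
    n_hvg : int or None
        Highly-variable-gene cut applied during harmonization.
    target_sum : float
        Per-cell total for count normalization.
    space_config : SpaceModelConfig, optional
        Coordinate-regression hyper-parameters.
    seed : int
        Global seed; every stochastic stage derives its own stream from it.
    """

    def __init__(
        self,
        sc: ExpressionDataset,
        st: SpatialReference,
        kernel: _tca.KernelSpec | None = None,
        m: int = 50,
        mu: float = 1.0,
        ridge: float | None = None,
        n_hvg: int | None = 2000,
        target_sum: float = 1e4,
        space_config: _regression.SpaceModelConfig | None = None,
        seed: int = 0,
    ) -> None:
        self.sc = sc
        self.st = st
        self.kernel = kernel or _tca.KernelSpec()
        self.m = m
        self.mu = mu
        self.ridge = ridge
        self.n_hvg = n_hvg
        self.target_sum = target_sum
        self.space_config = space_config or _regression.SpaceModelConfig()
        self.seed = seed

    @classmethod
    def from_files(
        cls,
        sc_path: str,
        st_expr_path: str,
        st_coords_path: str,
        fmt: str = "csv",
        orientation: str = "obs_by_gene",
        **kwargs,
    ) -> "PseudoSpaceModel":
        """Build a model straight from on-disk matrices (see :mod:`.io`)."""
        sc = _io.load_expression(sc_path, fmt=fmt, orientation=orientation)
        st = _io.load_spatial_reference(
            st_expr_path, st_coords_path, fmt=fmt, orientation=orientation
        )
        return cls(sc, st, **kwargs)

    def fit(self) -> "PseudoSpaceResults":
        """Run harmonize -> co-embed -> coordinate regression."""
        sc_n, st_n = _io.preprocess_pair(
            self.sc, self.st.expr, n_hvg=self.n_hvg, target_sum=self.target_sum
        )
        tca_model = _tca.fit_tca(
            sc_n.matrix,
            st_n.matrix,
            spec=self.kernel,
            m=self.m,
            mu=self.mu,
            ridge=self.ridge,
            seed=stage_seed(self.seed, "tca"),
        )
        tca_model.gene_fingerprint = hashlib.sha256(
            "\n".join(sc_n.gene_names).encode()
        ).hexdigest()[:16]
        latent_sc, latent_st = _tca.embed(tca_model)

        cfg = replace(self.space_config, seed=stage_seed(self.seed, "space"))
        space_model = _regression.fit_space_model(
            latent_st, self.st.coords, cfg
        )
        pseudo = _regression.predict_pseudo_space(
            space_model, latent_sc, obs_ids=list(sc_n.obs_ids)
        )

        n1, n2 = tca_model.train_obs_split
        L = _tca.build_coefficient_matrix_L(n1, n2)
        mmd_before = _tca.mmd_trace(tca_model.K, L)
        KW = tca_model.K @ tca_model.W
        mmd_after = float(np.trace(KW.T @ L @ KW))
        diagnostics = {
            "n_sc": self.sc.n_obs,
            "n_st": self.st.n_obs,
            "n_genes_used": sc_n.n_genes,
            "latent_dim": self.m,
            "mmd_before": mmd_before,
            "mmd_after_embedding": mmd_after,
            "final_training_loss": space_model.loss_curve[-1],
            "n_epochs": len(space_model.loss_curve),
        }
        return PseudoSpaceResults(
            model=self,
            sc_normalized=sc_n,
            st_normalized=st_n,
            tca_model=tca_model,
            latent_sc=latent_sc,
            latent_st=latent_st,
            space_model=space_model,
            pseudo_space=pseudo,
            diagnostics=diagnostics,
        )


@dataclass
class PseudoSpaceResults:
    """Fitted co-embedding + pseudo-space, with clustering and evaluation."""

    model: PseudoSpaceModel
    sc_normalized: ExpressionDataset
    st_normalized: ExpressionDataset
    tca_model: _tca.TcaModel
    latent_sc: np.ndarray
    latent_st: np.ndarray
    space_model: _regression.SpaceModel
    pseudo_space: _regression.PseudoSpace
    diagnostics: dict = field(default_factory=dict)
    cluster_result: _clustering.ClusterResult | None = None

    def cluster(
        self,
        target_k: int | None = None,
        resolution: float | None = None,
        weight_config: _clustering.SpaceWeightConfig | None = None,
        use_space: bool = True,
    ) -> _clustering.ClusterResult:
        """Space-informed Leiden clustering of the single cells.

        With ``use_space=False`` the expression KNN graph is clustered
        unweighted (the conventional expression-only baseline).
        """
        cfg = weight_config or _clustering.SpaceWeightConfig()
        seed = stage_seed(self.model.seed, "cluster")
        edges, _ = _clustering.build_expression_graph(
            self.sc_normalized, n_pcs=cfg.n_pcs, k_expr=cfg.k_expr, seed=seed
        )
        if use_space:
            weights = _clustering.compute_space_weights(
                self.pseudo_space.coords, edges, cfg
            )
        else:
            weights = np.ones(len(edges))
        graph = _clustering.SpaceWeightedGraph(
            nodes=list(self.sc_normalized.obs_ids), edges=edges, weights=weights
        )
        result = _clustering.space_informed_leiden(
            graph, target_k=target_k, resolution=resolution, seed=seed
        )
        if use_space:
            self.cluster_result = result
        return result

    def evaluate(
        self,
        truth_coords: np.ndarray | None = None,
        truth_labels=None,
        cluster_result: _clustering.ClusterResult | None = None,
    ) -> _evaluation.EvalReport:
        """Score the reconstruction (and clustering, if available)."""
        report = _evaluation.EvalReport()
        if truth_coords is not None:
            report.pairwise_pcc = _evaluation.pairwise_distance_pcc(
                truth_coords, self.pseudo_space.coords
            )
        cr = cluster_result or self.cluster_result
        if truth_labels is not None and cr is not None:
            report.ari = _evaluation.adjusted_rand_index(
                truth_labels, cr.labels
            )
            report.nmi = _evaluation.normalized_mutual_information(
                truth_labels, cr.labels
            )
        report.extras.update(
            {k: v for k, v in self.diagnostics.items()
             if isinstance(v, (int, float))}
        )
        return report

    def summary(self) -> str:
        """Human-readable run summary."""
        d = self.diagnostics
        lines = [
            "Pseudo-space reconstruction results",
            "=" * 48,
            f"{'SC cells':<28}{d['n_sc']:>20}",
            f"{'ST observations':<28}{d['n_st']:>20}",
            f"{'genes used':<28}{d['n_genes_used']:>20}",
            f"{'latent dimension (m)':<28}{d['latent_dim']:>20}",
            f"{'kernel':<28}{self.model.kernel.kind:>20}",
            f"{'MMD before (tr KL)':<28}{d['mmd_before']:>20.6g}",
            f"{'MMD after embedding':<28}{d['mmd_after_embedding']:>20.6g}",
            f"{'final training loss':<28}{d['final_training_loss']:>20.6g}",
        ]
        if self.cluster_result is not None:
            lines += [
                f"{'clusters':<28}{self.cluster_result.n_clusters:>20}",
                f"{'resolution used':<28}"
                f"{self.cluster_result.resolution_used:>20.4g}",
            ]
        lines.append("=" * 48)
        return "\n".join(lines)

    def plot_pseudo_space(self, labels=None, ax=None):
        """Scatter the predicted pseudo-space (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        coords = self.pseudo_space.coords
        if labels is None and self.cluster_result is not None:
            labels = self.cluster_result.labels
        if labels is None:
            ax.scatter(coords[:, 0], coords[:, 1], s=8)
        else:
            labels = np.asarray([str(x) for x in labels])
            for lab in np.unique(labels):
                sel = labels == lab
                ax.scatter(coords[sel, 0], coords[sel, 1], s=8, label=lab)
            ax.legend(markerscale=2, fontsize=8)
        ax.set_xlabel("pseudo-space x")
        ax.set_ylabel("pseudo-space y")
        return ax
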