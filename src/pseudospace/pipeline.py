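"""End-to-end orchestration with file outputs and a run manifest.

``run_pipeline`` wires the stages together: load -> harmonize -> co-embed ->
coordinate regression -> (optional) space-informed clustering -> (optional)
evaluation against supplied truth. Outputs are plain CSV/JSON in the
configured directory; a manifest records the config hash, the derived stage
seeds and package versions so any run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import clustering as _clustering
from . import evaluation as _evaluation
from . import io as _io
from . import regression as _regression
from . import tca as _tca
from ._utils import stage_seed
from .model import PseudoSpaceModel, PseudoSpaceResults

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    """Everything one end-to-end run needs."""

    sc_path: str
    st_expr_path: str
    st_coords_path: str
    out_dir: str
    fmt: str = "csv"
    orientation: str = "obs_by_gene"
    kernel: str = "linear"
    gamma: float | str = "median-heuristic"
    m: int = 50
    mu: float = 1.0
    n_hvg: int | None = 2000
    target_sum: float = 1e4
    space: _regression.SpaceModelConfig = field(
        default_factory=_regression.SpaceModelConfig
    )
    weights: _clustering.SpaceWeightConfig = field(
        default_factory=_clustering.SpaceWeightConfig
    )
    target_k: int | None = None
    resolution: float | None = None
    sc_labels_path: str | None = None
    sc_truth_coords_path: str | None = None
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_COERCERS = {
    "m": int, "mu": float, "n_hvg": lambda v: None if v == "none" else int(v),
    "target_sum": float, "target_k": int, "resolution": float, "seed": int,
}


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file into a :class:`RunConfig`.

    Keys of the nested space/weight configs are addressed as
    ``space.epochs = 500`` or ``weights.l = 20``.
    """
    kwargs: dict = {}
    space_kwargs: dict = {}
    weight_kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key.startswith("space."):
            space_kwargs[key[6:]] = _coerce_nested(key[6:], value,
                                                  _regression.SpaceModelConfig)
        elif key.startswith("weights."):
            weight_kwargs[key[8:]] = _coerce_nested(key[8:], value,
                                                    _clustering.SpaceWeightConfig)
        else:
            kwargs[key] = _COERCERS.get(key, str)(value)
    if space_kwargs:
        kwargs["space"] = _regression.SpaceModelConfig(**space_kwargs)
    if weight_kwargs:
        kwargs["weights"] = _clustering.SpaceWeightConfig(**weight_kwargs)
    return RunConfig(**kwargs)


def _coerce_nested(key: str, value: str, cls) -> object:
    ftypes = {f.name: f.type for f in dataclasses.fields(cls)}
    if key not in ftypes:
        raise ValueError(f"unknown config key {cls.__name__}.{key}")
    for caster in (int, float):
        try:
            return caster(value)
        except ValueError:
            continue
    return value


def run_pipeline(cfg: RunConfig) -> PseudoSpaceResults:
    """Execute the full workflow and write all outputs under ``cfg.out_dir``.

    The clustering stage runs only when ``target_k`` or ``resolution`` is
    given (spatial reconstruction alone is a valid endpoint); evaluation runs
    only when truth labels/coordinates are supplied.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name: str):
        logger.info("stage: %s", name)

    _stage("load")
    try:
        model = PseudoSpaceModel.from_files(
            cfg.sc_path, cfg.st_expr_path, cfg.st_coords_path,
            fmt=cfg.fmt, orientation=cfg.orientation,
            kernel=_tca.KernelSpec(kind=cfg.kernel, gamma=cfg.gamma)
            if cfg.kernel == "rbf" else _tca.KernelSpec(kind=cfg.kernel),
            m=cfg.m, mu=cfg.mu, n_hvg=cfg.n_hvg, target_sum=cfg.target_sum,
            space_config=cfg.space, seed=cfg.seed,
        )
    except Exception as err:
        raise RuntimeError(f"stage 'load' failed: {err}") from err

    _stage("embed+reconstruct")
    try:
        results = model.fit()
    except Exception as err:
        raise RuntimeError(f"stage 'fit' failed: {err}") from err

    obs_ids = list(results.sc_normalized.obs_ids)
    emb_sc = pd.DataFrame(
        results.latent_sc, index=obs_ids,
        columns=[f"TC{j + 1}" for j in range(results.latent_sc.shape[1])],
    )
    emb_sc.index.name = "obs_id"
    emb_sc.to_csv(out / "latent_sc.csv")
    emb_st = pd.DataFrame(
        results.latent_st, index=list(results.st_normalized.obs_ids),
        columns=[f"TC{j + 1}" for j in range(results.latent_st.shape[1])],
    )
    emb_st.index.name = "obs_id"
    emb_st.to_csv(out / "latent_st.csv")
    _io.write_coords(obs_ids, results.pseudo_space.coords,
                     out / "pseudo_space.csv")

    cluster_result = None
    if cfg.target_k is not None or cfg.resolution is not None:
        _stage("cluster")
        try:
            cluster_result = results.cluster(
                target_k=cfg.target_k, resolution=cfg.resolution,
                weight_config=cfg.weights,
            )
        except Exception as err:
            raise RuntimeError(f"stage 'cluster' failed: {err}") from err
        _io.write_labels(obs_ids, cluster_result.labels, out / "clusters.csv")

    report = None
    truth_labels = None
    truth_coords = None
    if cfg.sc_labels_path:
        truth_labels = _io.load_labels(cfg.sc_labels_path, obs_ids)
    if cfg.sc_truth_coords_path:
        truth = pd.read_csv(cfg.sc_truth_coords_path)
        truth["obs_id"] = truth["obs_id"].astype(str)
        truth = truth.set_index("obs_id").loc[obs_ids, ["x", "y"]]
        truth_coords = truth.to_numpy(dtype=float)
    if truth_labels is not None or truth_coords is not None:
        _stage("evaluate")
        report = results.evaluate(
            truth_coords=truth_coords, truth_labels=truth_labels,
            cluster_result=cluster_result,
        )
        (out / "evaluation.json").write_text(
            json.dumps(report.to_dict(), indent=2, default=float)
        )
        report.to_frame().to_csv(out / "evaluation.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "global_seed": cfg.seed,
        "stage_seeds": {
            s: stage_seed(cfg.seed, s) for s in ("tca", "space", "cluster")
        },
        "numpy_version": np.__version__,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
    (out / "summary.txt").write_text(results.summary() + "\n")
    return results
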