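"""Pseudo-space reconstruction: regress spatial coordinates on latent features.

The spatial reference supplies (latent feature, coordinate) training pairs;
a two-layer perceptron (one hidden layer of 128 units, ReLU or sigmoid,
Adam with lr 1e-3 and betas 0.9/0.999, MSE loss) learns [x, y] ~ X'_T and is
then applied to the single-cell latent features X'_S, assigning every
dissociated cell a 2-D position in the reference's coordinate frame — its
pseudo-space location.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

__all__ = [
    "SpaceModelConfig",
    "CoordinateScaler",
    "SpaceModel",
    "PseudoSpace",
    "fit_space_model",
    "predict_pseudo_space",
]


@dataclass
class SpaceModelConfig:
    """Hyper-parameters of the coordinate regression MLP.

    Defaults reproduce the stated architecture: 128 hidden units, Adam with
    learning rate 1e-3 and betas (0.9, 0.999), MSE loss. Schedule choices the
    architecture leaves open default to 1000 epochs of seeded, shuffled
    mini-batches of 128 (deterministic for a fixed seed; full-batch training
    takes too few optimizer steps to fit the coordinate surface) with
    per-axis min-max coordinate scaling.
    """

    hidden_units: int = 128
    activation: str = "relu"          # "relu" or "sigmoid"
    learning_rate: float = 1e-3
    adam_betas: tuple[float, float] = (0.9, 0.999)
    epochs: int = 1000
    batch_size: int | str = 128
    seed: int = 0
    coordinate_scaling: str = "minmax"  # "minmax", "zscore" or "none"

    def __post_init__(self) -> None:
        if self.activation not in ("relu", "sigmoid"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.coordinate_scaling not in ("minmax", "zscore", "none"):
            raise ValueError(
                f"unknown coordinate_scaling {self.coordinate_scaling!r}"
            )
        if self.hidden_units < 1 or self.epochs < 1:
            raise ValueError("hidden_units and epochs must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class CoordinateScaler:
    """Invertible per-axis coordinate transform fitted on the reference."""

    mode: str = "minmax"
    shift_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def fit(self, coords: np.ndarray) -> "CoordinateScaler":
        coords = np.asarray(coords, dtype=float)
        if self.mode == "minmax":
            lo, hi = coords.min(axis=0), coords.max(axis=0)
            self.shift_ = lo
            self.scale_ = np.where(hi > lo, hi - lo, 1.0)
        elif self.mode == "zscore":
            sd = coords.std(axis=0)
            self.shift_ = coords.mean(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.shift_ = np.zeros(coords.shape[1])
            self.scale_ = np.ones(coords.shape[1])
        return self

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, dtype=float) - self.shift_) / self.scale_

    def inverse_transform(self, scaled: np.ndarray) -> np.ndarray:
        return np.asarray(scaled, dtype=float) * self.scale_ + self.shift_


@dataclass
class SpaceModel:
    """A fitted coordinate-regression model plus its coordinate scaler."""

    net: MLPRegressor
    scaler: CoordinateScaler
    n_features: int
    config: SpaceModelConfig
    loss_curve: list[float] = field(default_factory=list)

    def predict_scaled(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected (n, {self.n_features}) features, got {X.shape}"
            )
        pred = self.net.predict(X)
        return pred.reshape(X.shape[0], -1)

    def save(self, path) -> None:
        """Persist layer weights, scaler and config as one ``.npz`` archive."""
        meta = {
            "config": dataclasses.asdict(self.config),
            "n_features": self.n_features,
            "scaler_mode": self.scaler.mode,
            "out_activation": self.net.out_activation_,
        }
        arrays = {
            "scaler_shift": self.scaler.shift_,
            "scaler_scale": self.scaler.scale_,
            "loss_curve": np.asarray(self.loss_curve),
            "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        }
        for i, (w, b) in enumerate(zip(self.net.coefs_, self.net.intercepts_)):
            arrays[f"coef_{i}"] = w
            arrays[f"intercept_{i}"] = b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SpaceModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"].tobytes()).decode())
            cfg_dict = meta["config"]
            cfg_dict["adam_betas"] = tuple(cfg_dict["adam_betas"])
            cfg = SpaceModelConfig(**cfg_dict)
            coefs, intercepts = [], []
            i = 0
            while f"coef_{i}" in data:
                coefs.append(data[f"coef_{i}"])
                intercepts.append(data[f"intercept_{i}"])
                i += 1
            net = MLPRegressor(
                hidden_layer_sizes=(cfg.hidden_units,),
                activation="logistic" if cfg.activation == "sigmoid"
                else "relu",
            )
            net.coefs_ = coefs
            net.intercepts_ = intercepts
            net.n_layers_ = len(coefs) + 1
            net.n_outputs_ = coefs[-1].shape[1]
            net.out_activation_ = meta["out_activation"]
            net.n_features_in_ = meta["n_features"]
            scaler = CoordinateScaler(
                mode=meta["scaler_mode"],
                shift_=data["scaler_shift"],
                scale_=data["scaler_scale"],
            )
            return cls(
                net=net,
                scaler=scaler,
                n_features=meta["n_features"],
                config=cfg,
                loss_curve=list(map(float, data["loss_curve"])),
            )


@dataclass
class PseudoSpace:
    """Predicted 2-D positions of single cells in the reference frame."""

    coords: np.ndarray                    # n1 x 2, reference units
    scaling_record: CoordinateScaler
    obs_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"coords must be (n, 2), got {self.coords.shape}")
        if not np.isfinite(self.coords).all():
            raise ValueError("pseudo-space coordinates contain NaN or Inf")

    @property
    def scaled_coords(self) -> np.ndarray:
        return self.scaling_record.transform(self.coords)


def fit_space_model(
    Xt_latent: np.ndarray,
    coords: np.ndarray,
    cfg: SpaceModelConfig | None = None,
) -> SpaceModel:
    """Train the MLP mapping reference latent features to coordinates.

    Deterministic for a fixed ``cfg.seed`` (seeded initialization and
    seeded batch shuffling).
    """
    cfg = cfg or SpaceModelConfig()
    Xt_latent = np.asarray(Xt_latent, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if Xt_latent.shape[0] != coords.shape[0]:
        raise ValueError("feature and coordinate row counts differ")
    if Xt_latent.shape[0] < 10:
        raise ValueError("need at least 10 reference observations")
    if not (np.isfinite(Xt_latent).all() and np.isfinite(coords).all()):
        raise ValueError("NaN/Inf in training inputs")

    scaler = CoordinateScaler(cfg.coordinate_scaling).fit(coords)
    y = scaler.transform(coords)
    n = Xt_latent.shape[0]
    batch = n if cfg.batch_size == "full" else min(int(cfg.batch_size), n)

    net = MLPRegressor(
        hidden_layer_sizes=(cfg.hidden_units,),
        activation="logistic" if cfg.activation == "sigmoid" else "relu",
        solver="adam",
        alpha=0.0,
        batch_size=batch,
        learning_rate_init=cfg.learning_rate,
        beta_1=cfg.adam_betas[0],
        beta_2=cfg.adam_betas[1],
        max_iter=cfg.epochs,
        shuffle=True,
        random_state=cfg.seed,
        tol=0.0,
        n_iter_no_change=cfg.epochs,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(Xt_latent, y)
    losses = list(map(float, net.loss_curve_))
    if not np.isfinite(losses[-1]):
        raise FloatingPointError(
            "training loss diverged (NaN/Inf); try a lower learning_rate"
        )
    return SpaceModel(
        net=net,
        scaler=scaler,
        n_features=Xt_latent.shape[1],
        config=cfg,
        loss_curve=losses,
    )


def predict_pseudo_space(
    model: SpaceModel,
    Xs_latent: np.ndarray,
    obs_ids: list[str] | None = None,
) -> PseudoSpace:
    """Apply a fitted coordinate model to single-cell latent features."""
    scaled = model.predict_scaled(Xs_latent)
    return PseudoSpace(
        coords=model.scaler.inverse_transform(scaled),
        scaling_record=model.scaler,
        obs_ids=obs_ids,
    )
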