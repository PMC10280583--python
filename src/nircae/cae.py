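"""1-D convolutional autoencoder for NIR spectra.

The encoder compresses a spectrum (default 700 absorbance channels) through
two tanh convolution + max-pooling stages and two dense layers into a small
tanh bottleneck (default 32 latent variables); the decoder mirrors it with
a dense expansion, two upsampling stages and three stride-1 transposed
convolutions back to full length. Default architecture:

    encoder: Conv1D(16, k5, same, tanh) -> MaxPool(2)
             -> Conv1D(32, k5, same, tanh) -> MaxPool(2)
             -> Flatten(5600) -> Dense(64, tanh) -> Dense(32, tanh)
    decoder: Dense(5600, tanh) -> Reshape(175, 32)
             -> ConvT(32, k3, same, tanh) -> Upsample(2)
             -> ConvT(16, k3, same, tanh) -> Upsample(2)
             -> ConvT(1, k3, same, linear)

Training is unsupervised (reference values are never seen): inputs are
scaled (channel-wise calibration-mean centering, global-range division;
see ConvolutionalAutoencoder) on the calibration set, the mean
squared reconstruction error is minimised with Adam (lr 0.001, beta1 0.9,
beta2 0.999), and training stops at ``max_epochs`` (default 20) or when the
validation loss rises on two consecutive epochs, restoring the weights of
the best-validation epoch.

:class:`ConvolutionalAutoencoder` follows the scikit-learn transformer
API: ``fit(X)`` trains, ``transform(X)`` returns the latent matrix,
``inverse_transform(H)`` decodes back to absorbance units.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .nn import (
    Adam,
    Conv1D,
    Dense,
    EarlyStopping,
    Flatten,
    MaxPool1D,
    Reshape,
    Upsample1D,
    forward_layers,
    mse_loss_and_grad,
    reconstruction_loss_and_grads,
)


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class CAEConfig:
    """Architecture and training hyperparameters of the autoencoder."""

    input_length: int = 700
    encoder_kernel: int = 5
    decoder_kernel: int = 3
    latent_dim: int = 32
    encoder_filters: tuple[int, int] = (16, 32)
    dense_hidden: int = 64
    pool_size: int = 2
    batch_size: int = 8
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    max_epochs: int = 20
    patience: int = 2
    val_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.input_length % self.pool_size ** 2 != 0:
            raise ValueError(
                f"input_length {self.input_length} must be divisible by "
                f"pool_size^2 = {self.pool_size ** 2}"
            )
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.encoder_kernel % 2 == 0 or self.decoder_kernel % 2 == 0:
            raise ValueError("kernel sizes must be odd (same padding)")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder_filters"] = list(self.encoder_filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CAEConfig":
        d = dict(d)
        if "encoder_filters" in d:
            d["encoder_filters"] = tuple(d["encoder_filters"])
        return cls(**d)


def build_layers(config: CAEConfig, rng: np.random.Generator):
    """Instantiate the encoder and decoder layer lists for a config."""
    config.validate()
    f1, f2 = config.encoder_filters
    ke, kd, p = config.encoder_kernel, config.decoder_kernel, config.pool_size
    pooled = config.input_length // p ** 2
    flat = pooled * f2
    encoder = [
        Conv1D(1, f1, ke, "tanh", rng=rng, name="conv1"),
        MaxPool1D(p, name="pool1"),
        Conv1D(f1, f2, ke, "tanh", rng=rng, name="conv2"),
        MaxPool1D(p, name="pool2"),
        Flatten(name="flatten"),
        Dense(flat, config.dense_hidden, "tanh", rng=rng, name="dense1"),
        Dense(config.dense_hidden, config.latent_dim, "tanh", rng=rng,
              name="bottleneck"),
    ]
    decoder = [
        Dense(config.latent_dim, flat, "tanh", rng=rng, name="expand"),
        Reshape((pooled, f2), name="reshape"),
        Conv1D(f2, f2, kd, "tanh", rng=rng, name="convT1"),
        Upsample1D(p, name="upsample1"),
        Conv1D(f2, f1, kd, "tanh", rng=rng, name="convT2"),
        Upsample1D(p, name="upsample2"),
        Conv1D(f1, 1, kd, "linear", rng=rng, name="convT3"),
    ]
    return encoder, decoder


class ConvolutionalAutoencoder(BaseEstimator, TransformerMixin):
    """Unsupervised latent-variable extractor for NIR spectra.

    Parameters mirror :class:`CAEConfig`; see the module docstring for the
    architecture. ``fit`` expects an (n_samples, input_length) absorbance
    matrix (the calibration set); targets are never used.

    Attributes
    ----------
    encoder_layers_, decoder_layers_ : trained layer lists.
    x_center_, x_scale_ : input scaling fitted on calibration (per-channel
        means and the global half-range scalar).
    training_log_ : DataFrame with epoch, train_loss, val_loss.
    stopped_early_ : True iff validation loss rose on ``patience``
        consecutive epochs before ``max_epochs``.
    best_val_loss_ : validation loss of the restored weights.
    """

    def __init__(self, input_length=700, encoder_kernel=5, decoder_kernel=3,
                 latent_dim=32, encoder_filters=(16, 32), dense_hidden=64,
                 pool_size=2, batch_size=8, learning_rate=1e-3, beta1=0.9,
                 beta2=0.999, eps=1e-8, max_epochs=20, patience=2,
                 val_fraction=0.2, seed=0):
        self.input_length = input_length
        self.encoder_kernel = encoder_kernel
        self.decoder_kernel = decoder_kernel
        self.latent_dim = latent_dim
        self.encoder_filters = encoder_filters
        self.dense_hidden = dense_hidden
        self.pool_size = pool_size
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    @property
    def config(self) -> CAEConfig:
        return CAEConfig(**{k: getattr(self, k) for k in
                            CAEConfig.__dataclass_fields__})

    # -- scaling -----------------------------------------------------------
    # Each channel is centered on its calibration mean and the whole matrix
    # is divided by half the global calibration range: the dataset's full
    # contrast maps onto roughly [-1, 1] (tanh-compatible) while the
    # network's operating point stays at zero, where tanh is linear at
    # initialization. Per-channel variance scaling is deliberately avoided:
    # it would whiten away the amplitude structure and saturate the
    # bottleneck.

    def _scale(self, X):
        return (X - self.x_center_) / self.x_scale_

    def _unscale(self, Xs):
        return Xs * self.x_scale_ + self.x_center_

    # -- training ----------------------------------------------------------

    def fit(self, X, y=None):
        """Train on calibration spectra (unsupervised; ``y`` is ignored)."""
        cfg = self.config
        cfg.validate()
        X = check_array(X)
        if X.shape[1] != cfg.input_length:
            raise ValueError(
                f"expected {cfg.input_length} channels, got {X.shape[1]}"
            )
        rng = np.random.default_rng(cfg.seed)
        encoder, decoder = build_layers(cfg, rng)
        layers = encoder + decoder

        self.x_center_ = X.mean(axis=0)
        half_range = (X.max() - X.min()) / 2.0
        self.x_scale_ = half_range if half_range > 1e-12 else 1.0
        Xs = self._scale(X)[:, :, None]

        n = Xs.shape[0]
        n_val = max(1, int(round(cfg.val_fraction * n)))
        if n_val >= n:
            raise ValueError("calibration set too small for a validation split")
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        x_train, x_val = Xs[train_idx], Xs[val_idx]

        params = [p for lay in layers for p in lay.params]
        grads = [g for lay in layers for g in lay.grads]
        opt = Adam(params, cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.eps)
        stopper = EarlyStopping(cfg.patience)
        best_weights = [p.copy() for p in params]
        log = []

        def _eval(xblock):
            pred = forward_layers(layers, xblock)
            return mse_loss_and_grad(pred, xblock)[0]

        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(len(x_train))
            for start in range(0, len(order), cfg.batch_size):
                batch = x_train[order[start:start + cfg.batch_size]]
                loss = reconstruction_loss_and_grads(layers, batch)
                if not np.isfinite(loss):
                    raise DivergenceError(
                        f"non-finite training loss at epoch {epoch}"
                    )
                opt.step(grads)
            train_loss = _eval(x_train)
            val_loss = _eval(x_val)
            log.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss})
            stop = stopper.update(epoch, val_loss)
            if stopper.best_epoch == epoch:
                best_weights = [p.copy() for p in params]
            if stop:
                break

        for p, w in zip(params, best_weights):
            p[...] = w
        self.encoder_layers_ = encoder
        self.decoder_layers_ = decoder
        self.training_log_ = pd.DataFrame(log)
        self.stopped_early_ = stopper.stopped
        self.best_val_loss_ = stopper.best_loss
        self.n_features_in_ = X.shape[1]
        return self

    # -- inference ---------------------------------------------------------

    def transform(self, X):
        """Encode spectra into the (n, latent_dim) latent matrix."""
        check_is_fitted(self, "encoder_layers_")
        X = check_array(X)
        if X.shape[1] != self.input_length:
            raise ValueError(
                f"expected {self.input_length} channels, got {X.shape[1]}"
            )
        Xs = self._scale(X)[:, :, None]
        return forward_layers(self.encoder_layers_, Xs)

    def inverse_transform(self, H):
        """Decode latent vectors back to absorbance units, shape (n, L)."""
        check_is_fitted(self, "decoder_layers_")
        H = check_array(H)
        out = forward_layers(self.decoder_layers_, H)
        return self._unscale(out[:, :, 0])

    def reconstruct(self, X):
        """Encode then decode; output shape equals input shape."""
        return self.inverse_transform(self.transform(X))

    # -- introspection -----------------------------------------------------

    def parameter_table(self) -> pd.DataFrame:
        """Per-layer output shapes and trainable-parameter counts.

        Built from the (untrained) architecture, so it is available before
        ``fit``; counts are sizes of the actual weight arrays.
        """
        cfg = self.config
        encoder, decoder = build_layers(cfg, np.random.default_rng(cfg.seed))
        rows = []
        x = np.zeros((1, cfg.input_length, 1))
        for part, layers in (("encoder", encoder), ("decoder", decoder)):
            for lay in layers:
                x = lay.forward(x)
                rows.append({
                    "part": part,
                    "layer": lay.name,
                    "type": type(lay).__name__,
                    "output_shape": tuple(x.shape[1:]),
                    "n_parameters": lay.n_parameters,
                })
        return pd.DataFrame(rows)

    def encoder_output_lengths(self) -> list[int]:
        """Sequence/feature length after each encoder layer."""
        table = self.parameter_table()
        enc = table[table["part"] == "encoder"]
        return [int(s[0]) for s in enc["output_shape"]]

    @property
    def n_parameters_(self) -> int:
        return int(self.parameter_table()["n_parameters"].sum())

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        """Persist config (JSON), weights (npz) and training log (CSV)."""
        check_is_fitted(self, "encoder_layers_")
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "config.json"), "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=1)
        arrays = {"x_center": self.x_center_,
                  "x_scale": np.asarray(self.x_scale_)}
        for part, layers in (("enc", self.encoder_layers_),
                             ("dec", self.decoder_layers_)):
            for i, lay in enumerate(layers):
                for j, p in enumerate(lay.params):
                    arrays[f"{part}_{i}_{j}"] = p
        np.savez(os.path.join(directory, "weights.npz"), **arrays)
        self.training_log_.to_csv(
            os.path.join(directory, "training_log.csv"), index=False)

    @classmethod
    def load(cls, directory) -> "ConvolutionalAutoencoder":
        with open(os.path.join(directory, "config.json")) as fh:
            cfg = CAEConfig.from_dict(json.load(fh))
        model = cls(**cfg.to_dict())
        arrays = np.load(os.path.join(directory, "weights.npz"))
        encoder, decoder = build_layers(cfg, np.random.default_rng(cfg.seed))
        for part, layers in (("enc", encoder), ("dec", decoder)):
            for i, lay in enumerate(layers):
                for j in range(len(lay.params)):
                    lay.params[j][...] = arrays[f"{part}_{i}_{j}"]
        model.encoder_layers_ = encoder
        model.decoder_layers_ = decoder
        model.x_center_ = arrays["x_center"]
        model.x_scale_ = float(arrays["x_scale"])
        model.training_log_ = pd.read_csv(
            os.path.join(directory, "training_log.csv"))
        model.stopped_early_ = bool(
            len(model.training_log_) < cfg.max_epochs)
        model.best_val_loss_ = float(model.training_log_["val_loss"].min())
        model.n_features_in_ = cfg.input_length
        return model


DEFAULT_SEARCH_SPACE = {
    "kernel_size": [3, 5, 7],
    "latent_dim": [2, 4, 8, 16, 32],
    "batch_size": [8, 16, 32],
}


def random_search(calibration, space=None, n_trials=5, seed=0,
                  base_config: CAEConfig | None = None):
    """Random hyperparameter search over a lookup table.

    Samples configurations uniformly *without replacement* from the
    Cartesian product of the ``space`` axes (``kernel_size`` sets the
    encoder kernel; ``latent_dim`` and ``batch_size`` map directly), trains
    each on the calibration spectra, and ranks by best validation loss.
    Ties break toward smaller latent dimension, then fewer parameters.

    Returns ``(best_config, trial_log)`` where trial_log is a DataFrame
    with one row per trial.
    """
    space = dict(DEFAULT_SEARCH_SPACE if space is None else space)
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("search space must be non-empty")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    keys = sorted(space)
    combos = list(itertools.product(*(space[k] for k in keys)))
    if n_trials > len(combos):
        raise ValueError(
            f"n_trials={n_trials} exceeds the {len(combos)} unique "
            "configurations in the lookup table"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(combos), size=n_trials, replace=False)

    base = base_config or CAEConfig()
    records = []
    for trial, ci in enumerate(picks):
        choice = dict(zip(keys, combos[ci]))
        cfg = CAEConfig.from_dict(base.to_dict())
        if "kernel_size" in choice:
            cfg.encoder_kernel = int(choice["kernel_size"])
        if "latent_dim" in choice:
            cfg.latent_dim = int(choice["latent_dim"])
        if "batch_size" in choice:
            cfg.batch_size = int(choice["batch_size"])
        cfg.seed = seed
        model = ConvolutionalAutoencoder(**cfg.to_dict()).fit(calibration)
        records.append({
            "trial": trial,
            **choice,
            "val_loss": model.best_val_loss_,
            "latent_dim_used": cfg.latent_dim,
            "n_parameters": model.n_parameters_,
            "config": cfg,
        })
    log = pd.DataFrame(records)
    order = log.sort_values(
        ["val_loss", "latent_dim_used", "n_parameters"],
        kind="stable").index
    best_cfg = log.loc[order[0], "config"]
    return best_cfg, log.drop(columns="config")
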