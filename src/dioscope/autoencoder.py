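"""Pyramidal autoencoder over residue-pair distance vectors.

The network is a stack of fully connected layers whose widths descend
from the input dimension in fixed steps to a minimum width, pass through
a narrow coding layer, and mirror back up — e.g. for 1900-dimensional
inputs with a 300-node step, a 400-node floor and a 100-node code:
1900-1600-1300-1000-700-400-100-400-700-1000-1300-1600-1900 (13 layers).
It is trained by minibatch Adam on the mean squared reconstruction error
of apo-form distance vectors, with patience-based early stopping on a
held-out validation split and restoration of the best-validation weights.
Hidden activations are ReLU, the output layer is linear (distances are
non-negative reals kept on their physical Å scale).

Applied to holo-form vectors, the apo-trained network reproduces apo-like
fluctuation patterns and distorts holo-specific ones; the per-element
input-minus-output residual (the DIO vector, see :mod:`dioscope.dio_cluster`)
localises those distortions in time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "AEConfig",
    "AEModel",
    "TrainReport",
    "build_pyramid",
    "split_train_val",
    "train_ae",
    "reconstruct",
    "mse",
    "save_model",
    "load_model",
]


@dataclass
class AEConfig:
    """Architecture and optimisation settings.

    Defaults match the full-scale configuration used for 1900-step distance
    vectors; reduced settings (smaller widths, fewer epochs) are appropriate
    for short windows and small systems.
    """

    input_dim: int
    min_width: int = 400
    width_step: int = 300
    coding_dim: int = 100
    learning_rate: float = 1e-5
    batch_size: int = 100
    max_epochs: int = 100_000
    train_fraction: float = 0.8
    patience: int = 500
    seed: int = 0
    activation: str = "relu"

    @classmethod
    def desk_scale(cls, input_dim: int, seed: int = 0, **overrides) -> "AEConfig":
        """Reduced profile for short windows and small synthetic systems."""
        kwargs = dict(
            input_dim=input_dim,
            min_width=100,
            width_step=50,
            coding_dim=20,
            learning_rate=1e-3,
            batch_size=100,
            max_epochs=400,
            patience=50,
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.min_width > self.input_dim:
            raise ValueError(
                f"min_width {self.min_width} exceeds input_dim {self.input_dim}"
            )
        if self.coding_dim >= self.min_width:
            raise ValueError("coding_dim must be smaller than min_width")
        if self.activation != "relu":
            raise ValueError("only relu hidden activation is supported")


@dataclass
class AEModel:
    layer_widths: list[int]
    weights: list[np.ndarray] = field(repr=False)
    biases: list[np.ndarray] = field(repr=False)
    config: AEConfig

    @property
    def input_dim(self) -> int:
        return self.layer_widths[0]


@dataclass
class TrainReport:
    train_loss: np.ndarray
    val_loss: np.ndarray
    stopped_epoch: int
    best_epoch: int
    best_validation_loss: float
    n_train: int
    n_val: int


def build_pyramid(config: AEConfig) -> list[int]:
    """Symmetric layer-width schedule: descent, coding layer, mirrored ascent."""
    widths = [config.input_dim]
    while widths[-1] - config.width_step >= config.min_width:
        widths.append(widths[-1] - config.width_step)
    encoder = widths
    return encoder + [config.coding_dim] + encoder[::-1]


def split_train_val(n_rows: int, fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly random disjoint train/validation index split.

    ``|train| = floor(fraction * n_rows)``; reproducible given the seed.
    """
    if n_rows < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    n_train = int(np.floor(fraction * n_rows))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _init_params(widths: list[int], rng: np.random.Generator):
    weights, biases = [], []
    for d_in, d_out in zip(widths[:-1], widths[1:]):
        scale = np.sqrt(2.0 / d_in)  # He initialisation for ReLU stacks
        weights.append(rng.normal(0.0, scale, size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    return weights, biases


def _forward(weights, biases, X):
    """Returns the list of layer activations, input first, output last."""
    acts = [X]
    h = X
    last = len(weights) - 1
    for l, (W, b) in enumerate(zip(weights, biases)):
        z = h @ W + b
        h = z if l == last else np.maximum(z, 0.0)
        acts.append(h)
    return acts


def _backward(weights, acts, target):
    """Gradients of mean squared error w.r.t. weights and biases."""
    n, d = target.shape
    grads_W = [None] * len(weights)
    grads_b = [None] * len(weights)
    delta = 2.0 * (acts[-1] - target) / (n * d)
    for l in range(len(weights) - 1, -1, -1):
        grads_W[l] = acts[l].T @ delta
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ weights[l].T) * (acts[l] > 0.0)
    return grads_W, grads_b


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train_ae(matrix, config: AEConfig) -> tuple[AEModel, TrainReport]:
    """Train the autoencoder on the rows of a feature matrix.

    ``matrix`` may be a :class:`~dioscope.md_features.FeatureMatrix` or a
    plain 2-D array.  Training minimises minibatch MSE with Adam and stops
    when the validation loss has not improved for ``config.patience``
    epochs; the returned model carries the best-validation weights.
    """
    X = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    if X.ndim != 2:
        raise ValueError("training data must be 2-D")
    n_rows, n_cols = X.shape
    if n_cols != config.input_dim:
        raise ValueError(f"matrix has {n_cols} columns, config.input_dim is {config.input_dim}")
    if n_rows < config.batch_size:
        raise ValueError(f"{n_rows} rows < batch_size {config.batch_size}")

    widths = build_pyramid(config)
    rng = np.random.default_rng(config.seed)
    weights, biases = _init_params(widths, rng)
    opt = _Adam(weights + biases, config.learning_rate)

    train_idx, val_idx = split_train_val(n_rows, config.train_fraction, config.seed)
    X_train, X_val = X[train_idx], X[val_idx]

    best_val = np.inf
    best_epoch = 0
    best_params = None
    train_hist, val_hist = [], []
    since_improve = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(X_train))
        epoch_loss = 0.0
        n_seen = 0
        for start in range(0, len(order), config.batch_size):
            batch = X_train[order[start : start + config.batch_size]]
            acts = _forward(weights, biases, batch)
            gw, gb = _backward(weights, acts, batch)
            opt.step(weights + biases, gw + gb)
            epoch_loss += mse_rows(acts[-1], batch).mean() * len(batch)
            n_seen += len(batch)
        train_loss = epoch_loss / n_seen
        val_out = _forward(weights, biases, X_val)[-1]
        val_loss = float(mse_rows(val_out, X_val).mean())
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch} (train {train_loss}, val {val_loss}); "
                "reduce the learning rate or rescale inputs"
            )
        train_hist.append(train_loss)
        val_hist.append(val_loss)

        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_params = ([W.copy() for W in weights], [b.copy() for b in biases])
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                break

    weights, biases = best_params
    model = AEModel(layer_widths=widths, weights=weights, biases=biases, config=config)
    report = TrainReport(
        train_loss=np.asarray(train_hist),
        val_loss=np.asarray(val_hist),
        stopped_epoch=len(train_hist),
        best_epoch=best_epoch,
        best_validation_loss=float(best_val),
        n_train=len(train_idx),
        n_val=len(val_idx),
    )
    return model, report


def reconstruct(model: AEModel, matrix) -> np.ndarray:
    """Forward pass (inspection): reconstructed rows, no parameter updates."""
    X = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValueError(
            f"expected (*, {model.input_dim}) input, got {X.shape}"
        )
    if X.shape[0] == 0:
        return X.copy()
    return _forward(model.weights, model.biases, X)[-1]


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared difference of two equal-length vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def mse_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise mean squared difference of two equal-shape matrices."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return ((a - b) ** 2).mean(axis=1)


def save_model(model: AEModel, path: str) -> None:
    arrays = {f"W{l}": W for l, W in enumerate(model.weights)}
    arrays.update({f"b{l}": b for l, b in enumerate(model.biases)})
    arrays["config_json"] = np.array(json.dumps(asdict(model.config)))
    arrays["layer_widths"] = np.asarray(model.layer_widths)
    np.savez(path, **arrays)


def load_model(path: str) -> AEModel:
    with np.load(path, allow_pickle=False) as data:
        config = AEConfig(**json.loads(str(data["config_json"])))
        widths = [int(w) for w in data["layer_widths"]]
        n_layers = len(widths) - 1
        weights = [data[f"W{l}"] for l in range(n_layers)]
        biases = [data[f"b{l}"] for l in range(n_layers)]
    return AEModel(layer_widths=widths, weights=weights, biases=biases, config=config)
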