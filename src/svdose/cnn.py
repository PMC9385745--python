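"""The 3D CNN dose classifier: architecture, training, epoch selection.

The binary classifier is a four-block 3D convolutional network: 16, 32, 64
and 64 filters of size 3x3x3, each block ReLU-activated and followed by
2x2x2 max pooling; the flattened features pass through dense layers of 256
and 64 units (ReLU) into a single sigmoid output giving the probability of
the *low-dose* (positive) class.  Training minimises binary cross-entropy
with Adam at step size 1e-4.

The per-epoch train/test accuracy and loss histories drive post-hoc model
selection: the optimal epoch is the test-loss minimum, and a divergence flag
marks the characteristic overfitting signature where the training loss keeps
falling while the test loss rises for every subsequent epoch.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import nn


@dataclass
class CNNConfig:
    """Architecture and optimisation hyper-parameters."""

    conv_filters: tuple[int, ...] = (16, 32, 64, 64)
    kernel_size: int = 3
    pool_size: int = 2
    dense_units: tuple[int, ...] = (256, 64)
    learning_rate: float = 1e-4
    epochs: int = 10
    batch_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 4:
            raise ValueError("the architecture uses exactly four conv blocks")
        if len(self.dense_units) != 2:
            raise ValueError("exactly two dense layers precede the output")
        if self.kernel_size != 3 or self.pool_size != 2:
            raise ValueError("kernel 3x3x3 / pool 2x2x2 are fixed")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class TrainingHistory:
    """Per-epoch metrics on the training and monitoring (test) sets.

    ``train_*`` metrics are epoch-running averages over minibatches (the
    standard fit-loop convention); ``test_*`` metrics are end-of-epoch
    evaluations.  Per-epoch prediction vectors are retained so every recorded
    loss can be recomputed independently.  ``optimal_epoch`` is 1-based.
    """

    train_accuracy: list = field(default_factory=list)
    test_accuracy: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    test_loss: list = field(default_factory=list)
    train_predictions: list = field(default_factory=list)  # (probs, labels)/epoch
    test_predictions: list = field(default_factory=list)
    optimal_epoch: Optional[int] = None
    divergence: Optional[bool] = None
    config_hash: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.test_loss)

    def validate(self) -> None:
        for acc in (*self.train_accuracy, *self.test_accuracy):
            if not 0.0 <= acc <= 1.0:
                raise ValueError("accuracies must lie in [0, 1]")
        for loss in (*self.train_loss, *self.test_loss):
            if loss < 0:
                raise ValueError("losses must be non-negative")
        if self.optimal_epoch is not None and not (
            1 <= self.optimal_epoch <= self.n_epochs
        ):
            raise ValueError("optimal epoch outside the trained range")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.n_epochs + 1),
                "train_accuracy": self.train_accuracy,
                "test_accuracy": self.test_accuracy,
                "train_loss": self.train_loss,
                "test_loss": self.test_loss,
            }
        )


def build_model(config: CNNConfig, input_shape: tuple[int, int, int]):
    """Assemble the four-conv-block network for a given input volume shape.

    Each spatial extent must survive four 2x halvings, i.e. be a multiple of
    16 and at least 16.  Returns the model; its textual summary (layer-wise
    output shapes and parameter counts) comes from :func:`summarize`.
    """
    for name, ext in zip("length width depth".split(), input_shape):
        if ext < 16 or ext % 16:
            raise ValueError(
                f"input {name} extent {ext} does not support four 2x poolings "
                "(needs a multiple of 16, at least 16)"
            )
    rng = np.random.default_rng(config.seed)
    layers: list[nn.Layer] = []
    c_in = 1
    for i, c_out in enumerate(config.conv_filters):
        layers.append(nn.Conv3D(c_in, c_out, rng, first=(i == 0)))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool3D())
        c_in = c_out
    layers.append(nn.Flatten())
    spatial = [ext // 16 for ext in input_shape]
    n_flat = int(np.prod(spatial)) * config.conv_filters[-1]
    n_in = n_flat
    for units in config.dense_units:
        layers.append(nn.Dense(n_in, units, rng, relu_fan=True))
        layers.append(nn.ReLU())
        n_in = units
    layers.append(nn.Dense(n_in, 1, rng, relu_fan=False))
    model = nn.Sequential(layers)
    model.input_shape = tuple(input_shape)
    model.config = config
    return model


def summarize(model) -> str:
    """Keras-style textual summary with output shapes and parameter counts."""
    lines = ["layer                output shape              params"]
    shape = list(model.input_shape) + [1]
    total = 0
    for layer in model.layers:
        if isinstance(layer, nn.Conv3D):
            shape[-1] = layer.c_out
            n = layer.n_params
            name = f"conv3d_3x3x3_{layer.c_out}"
        elif isinstance(layer, nn.ReLU):
            n, name = 0, "relu"
        elif isinstance(layer, nn.MaxPool3D):
            shape[:3] = [s // 2 for s in shape[:3]]
            n, name = 0, "maxpool_2x2x2"
        elif isinstance(layer, nn.Flatten):
            shape = [int(np.prod(shape))]
            n, name = 0, "flatten"
        elif isinstance(layer, nn.Dense):
            shape = [layer.weight.shape[1]]
            n = layer.n_params
            name = f"dense_{layer.weight.shape[1]}"
        else:  # pragma: no cover
            n, name = 0, type(layer).__name__
        total += n
        lines.append(f"{name:<20} {str(tuple(shape)):<25} {n:>7d}")
    lines.append(f"sigmoid output       {(1,)!s:<25} {0:>7d}")
    lines.append(f"total parameters: {total}")
    return "\n".join(lines)


def _accuracy(probs: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean((probs > 0.5).astype(int) == labels))


def train(
    model,
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    test_y: np.ndarray,
    config: Optional[CNNConfig] = None,
    checkpoint_dir=None,
    verbose: bool = False,
) -> TrainingHistory:
    """Train with Adam/BCE, recording per-epoch metrics on both sets.

    Shuffling and weight initialisation are fully seeded, so repeated runs
    with one seed on one device reproduce the same history.  Checkpoints
    (weights + per-epoch predictions) are written per epoch when
    ``checkpoint_dir`` is given.  A non-finite loss aborts with a diagnostic.
    """
    config = config or model.config
    train_y = np.asarray(train_y).ravel().astype(np.float64)
    test_y = np.asarray(test_y).ravel().astype(np.float64)
    if not set(np.unique(train_y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary (0/1)")
    opt = nn.Adam(model.layers, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    history = TrainingHistory(config_hash=config.hash())
    n = len(train_x)
    if checkpoint_dir is not None:
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        epoch_probs = np.empty(n, dtype=np.float64)
        epoch_labels = train_y[order]
        loss_sum = 0.0
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            xb = train_x[sel]
            yb = train_y[sel]
            logits = model.forward(xb, train=True)
            z = logits.ravel().astype(np.float64)
            probs = nn.sigmoid(z)
            batch_loss = nn.bce_with_logits(z, yb)
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, samples {sel.tolist()}: "
                    f"logits {z.tolist()}"
                )
            loss_sum += batch_loss * len(sel)
            epoch_probs[start:start + len(sel)] = probs
            dz = ((probs - yb) / len(sel)).astype(np.float32)[:, None]
            model.backward(dz)
            opt.step()
        train_loss = loss_sum / n
        train_acc = _accuracy(epoch_probs, epoch_labels)
        test_probs = model.predict_proba(test_x)
        test_loss = nn.bce_from_probs(test_probs, test_y)
        test_acc = _accuracy(test_probs, test_y)
        history.train_loss.append(train_loss)
        history.train_accuracy.append(train_acc)
        history.test_loss.append(test_loss)
        history.test_accuracy.append(test_acc)
        history.train_predictions.append((epoch_probs, epoch_labels))
        history.test_predictions.append((test_probs, test_y.copy()))
        if verbose:
            print(
                f"epoch {epoch:2d}: train loss {train_loss:.4f} "
                f"acc {train_acc:.3f} | test loss {test_loss:.4f} acc {test_acc:.3f}"
            )
        if checkpoint_dir is not None:
            np.savez_compressed(
                checkpoint_dir / f"epoch_{epoch:02d}.npz",
                *model.get_weights(),
                train_probs=epoch_probs,
                train_labels=epoch_labels,
                test_probs=test_probs,
                test_labels=test_y,
            )
    if history.n_epochs >= 2:
        history.optimal_epoch, history.divergence = select_optimal_epoch(history)
    else:
        history.optimal_epoch, history.divergence = 1, False
    history.validate()
    return history


def predict(model, x: np.ndarray, return_labels: bool = False):
    """Class-membership probabilities (and optionally hard labels).

    Probabilities are the sigmoid of the output logit, in (0, 1); the
    decision threshold is 0.5, with an exact 0.5 assigned to the negative
    (high-dose) class.
    """
    x = np.asarray(x, dtype=np.float32)
    if x.shape[1:4] != model.input_shape:
        raise ValueError(
            f"input spatial shape {x.shape[1:4]} != model input {model.input_shape}"
        )
    probs = model.predict_proba(x)
    if return_labels:
        return probs, (probs > 0.5).astype(int)
    return probs


def select_optimal_epoch(history: TrainingHistory) -> tuple[int, bool]:
    """Pick the optimally trained state from the loss curves.

    Returns ``(epoch, divergence)`` where ``epoch`` (1-based) is the earliest
    test-loss minimum, and ``divergence`` is True when, for every later
    epoch, the training loss keeps decreasing while the test loss keeps
    increasing — the overfitting signature seen at the train/test curve
    divergence point.
    """
    if history.n_epochs < 2:
        raise ValueError("need at least 2 epochs to select an optimal state")
    test = np.asarray(history.test_loss)
    train_l = np.asarray(history.train_loss)
    best = int(np.argmin(test))  # argmin takes the earliest tie
    later = np.arange(best + 1, len(test))
    if len(later) == 0:
        return best + 1, False
    diverges = bool(
        np.all(np.diff(train_l[best:]) < 0) and np.all(np.diff(test[best:]) > 0)
    )
    return best + 1, diverges
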