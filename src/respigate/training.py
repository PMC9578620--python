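"""Mini-batch training with adaptive-moment estimation.

Protocol defaults follow the study configuration for all three
predictors: Adam with learning rate 1e-4, L2 weight decay 2e-4,
beta1 = 0.9, beta2 = 0.999, mini-batches of 300 pairs, 100 epochs, and
best-validation checkpointing (the parameter snapshot with the lowest
validation loss seen so far is retained and restored at the end).  The
loss is mean-squared error, matching the RMSE evaluation metric.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from ._io import load_arrays, save_arrays
from .errors import DivergenceError, InvalidTrainingError
from .models import _BaseModel, build_model, spec_from_dict, spec_to_dict
from .preprocessing import WindowedDataset

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class TrainingProtocol:
    """Optimizer and schedule hyperparameters."""

    learning_rate: float = 1e-4
    weight_decay: float = 2e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 300
    epochs: int = 100
    eps: float = 1e-8
    shuffle_seed: int = 0


@dataclass
class TrainState:
    """Training progress with best-validation checkpointing."""

    epoch: int = 0
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_val_loss: float = float("inf")
    best_epoch: int = -1
    best_params: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def current_val_loss(self) -> float:
        return self.val_losses[-1] if self.val_losses else float("inf")


class _Adam:
    """Adam with L2-coupled weight decay (decay added to the gradient)."""

    def __init__(self, params, protocol: TrainingProtocol):
        self.params = params
        self.p = protocol
        self.m = [np.zeros_like(t.data) for t in params]
        self.v = [np.zeros_like(t.data) for t in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        p = self.p
        bc1 = 1.0 - p.beta1**self.t
        bc2 = 1.0 - p.beta2**self.t
        for i, tensor in enumerate(self.params):
            g = tensor.grad
            if g is None:
                continue
            g = g + p.weight_decay * tensor.data
            self.m[i] = p.beta1 * self.m[i] + (1.0 - p.beta1) * g
            self.v[i] = p.beta2 * self.v[i] + (1.0 - p.beta2) * g * g
            m_hat = self.m[i] / bc1
            v_hat = self.v[i] / bc2
            tensor.data -= (p.learning_rate * m_hat / (np.sqrt(v_hat) + p.eps)).astype(
                tensor.data.dtype
            )

    def zero_grad(self) -> None:
        for t in self.params:
            t.grad = None


def mse_loss(model: _BaseModel, inputs: np.ndarray, targets: np.ndarray):
    pred = model.forward(inputs)
    diff = pred - np.asarray(targets, dtype=pred.data.dtype)
    return (diff * diff).mean()


def evaluate_loss(model: _BaseModel, dataset: WindowedDataset,
                  batch_size: int = 2048) -> float:
    pred = model.predict(dataset.inputs, batch_size=batch_size)
    return float(np.mean((pred - dataset.targets) ** 2))


def train(
    model: _BaseModel,
    train_windows: WindowedDataset,
    val_windows: WindowedDataset,
    protocol: TrainingProtocol = TrainingProtocol(),
) -> TrainState:
    """Fit ``model`` and return the :class:`TrainState`.

    After each epoch the validation loss is evaluated; the best snapshot
    is kept whenever the current validation loss is strictly smaller than
    the best so far, and is restored into the model before returning.
    """
    if train_windows.n_pairs == 0 or val_windows.n_pairs == 0:
        raise InvalidTrainingError("training and validation datasets must be non-empty")
    params = model.parameters()
    opt = _Adam(params, protocol)
    rng = np.random.default_rng(protocol.shuffle_seed)
    state = TrainState()
    n = train_windows.n_pairs
    for epoch in range(protocol.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, n, protocol.batch_size):
            idx = order[lo:lo + protocol.batch_size]
            opt.zero_grad()
            loss = mse_loss(model, train_windows.inputs[idx], train_windows.targets[idx])
            value = float(loss.data)
            if not np.isfinite(value):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += value
            n_batches += 1
        state.epoch = epoch + 1
        state.train_losses.append(epoch_loss / max(n_batches, 1))
        val_loss = evaluate_loss(model, val_windows)
        if not np.isfinite(val_loss):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
        state.val_losses.append(val_loss)
        if val_loss < state.best_val_loss:
            state.best_val_loss = val_loss
            state.best_epoch = epoch + 1
            state.best_params = model.state_dict()
    if state.best_params:
        model.load_state_dict(state.best_params)
    return state


def save_checkpoint(
    path: str | Path,
    model: _BaseModel,
    state: TrainState,
    protocol: TrainingProtocol,
    extra: dict[str, Any] | None = None,
) -> Path:
    """Single-file archive: parameter arrays + spec/protocol/metrics."""
    attrs = {
        "version": CHECKPOINT_VERSION,
        "spec": spec_to_dict(model.spec),
        "protocol": asdict(protocol),
        "best_val_loss": state.best_val_loss,
        "best_epoch": state.best_epoch,
        "epochs_run": state.epoch,
    }
    if extra:
        attrs.update(extra)
    return save_arrays(path, model.state_dict(), attrs)


def load_checkpoint(path: str | Path) -> tuple[_BaseModel, dict[str, Any]]:
    arrays, attrs = load_arrays(path)
    if attrs.get("version") != CHECKPOINT_VERSION:
        raise InvalidTrainingError(f"unsupported checkpoint version in {path}")
    model = build_model(spec_from_dict(attrs["spec"]))
    model.load_state_dict(arrays)
    return model, attrs
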