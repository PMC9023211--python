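"""Mini-batch RMSProp training of the reuploading classifier.

The default configuration mirrors the published classifier set-up: four
qubits, six layers, learning rate 0.01, RMSProp, batch size 26, 50 epochs.
All randomness (initial angles, epoch shuffles) flows from a single integer
seed, so a repeated run reproduces the result bitwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import model
from .model import AnsatzConfig
from .scores import LabelledDataset

__all__ = [
    "TrainConfig",
    "RMSPropState",
    "TrainResult",
    "rmsprop_step",
    "split_dataset",
    "train",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; defaults are the published configuration."""

    n_qubits: int = 4
    n_layers: int = 6
    learning_rate: float = 0.01
    optimizer: str = "rmsprop"
    batch_size: int = 26
    epochs: int = 50
    seed: int = 0
    rho: float = 0.9
    epsilon: float = 1e-8
    readout_qubits: tuple[int, ...] = (0, 1)
    gradient_method: str = "fd"

    def __post_init__(self) -> None:
        if min(self.n_qubits, self.n_layers, self.batch_size, self.epochs) < 1:
            raise ValueError("counts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie in (0, 1)")
        if self.optimizer != "rmsprop":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        object.__setattr__(self, "readout_qubits", tuple(self.readout_qubits))

    def ansatz(self) -> AnsatzConfig:
        return AnsatzConfig(self.n_qubits, self.n_layers, self.readout_qubits)


@dataclass
class RMSPropState:
    """Running mean of squared gradients plus a step counter."""

    accumulator: np.ndarray
    step_count: int = 0

    @classmethod
    def zeros(cls, shape: tuple[int, ...]) -> "RMSPropState":
        return cls(np.zeros(shape))


@dataclass
class TrainResult:
    params: np.ndarray
    loss_history: list[float]
    config: TrainConfig
    train_accuracy_history: list[float] = field(default_factory=list)


def rmsprop_step(
    params: np.ndarray,
    grads: np.ndarray,
    state: RMSPropState,
    config: TrainConfig,
) -> tuple[np.ndarray, RMSPropState]:
    """One RMSProp update.

    acc <- rho * acc + (1 - rho) * g**2
    params <- params - lr * g / (sqrt(acc) + eps)
    """
    params = np.asarray(params, dtype=np.float64)
    grads = np.asarray(grads, dtype=np.float64)
    if params.shape != grads.shape or params.shape != state.accumulator.shape:
        raise ValueError("params, grads and accumulator shapes must match")
    acc = config.rho * state.accumulator + (1 - config.rho) * grads**2
    new_params = params - config.learning_rate * grads / (np.sqrt(acc) + config.epsilon)
    return new_params, RMSPropState(acc, state.step_count + 1)


def split_dataset(
    dataset: LabelledDataset, train_fraction: float = 0.7, seed: int = 0
) -> tuple[LabelledDataset, LabelledDataset]:
    """Stratified train/test split (disjoint, exhaustive, seeded).

    Per class, round(train_fraction * class size) samples go to the train
    half; every class must contribute at least 2 samples so both halves can
    be non-degenerate.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in range(dataset.n_classes):
        members = np.flatnonzero(dataset.labels == c)
        if members.size == 0:
            continue
        if members.size < 2:
            raise ValueError(f"class {c} has {members.size} sample(s); need >= 2 to split")
        members = rng.permutation(members)
        n_train = int(round(train_fraction * members.size))
        train_idx.append(members[:n_train])
        test_idx.append(members[n_train:])
    return (
        dataset.subset(np.sort(np.concatenate(train_idx))),
        dataset.subset(np.sort(np.concatenate(test_idx))),
    )


def train(dataset: LabelledDataset, config: TrainConfig) -> TrainResult:
    """Fit the circuit on ``dataset`` and return params plus loss history.

    Per epoch: seeded shuffle, partition into batches of ``batch_size``
    (final partial batch kept), one RMSProp step per batch from the
    gradient of the batch cross-entropy.  ``loss_history`` records the
    sample-weighted mean of the pre-update batch losses, one entry per
    epoch.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if config.epochs < 1:
        raise ValueError("epochs must be >= 1")
    ansatz = config.ansatz()
    if dataset.labels.max() >= ansatz.n_classes:
        raise ValueError(
            f"dataset has labels up to {dataset.labels.max()} but the readout "
            f"distinguishes only {ansatz.n_classes} classes"
        )
    rng = np.random.default_rng(config.seed)
    params = model.init_params(ansatz, rng)
    state = RMSPropState.zeros(ansatz.param_shape)
    n = len(dataset)
    loss_history: list[float] = []
    acc_history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = (dataset.scores[idx], dataset.labels[idx])
            loss, grad = model.loss_and_gradient(
                params, batch, ansatz, method=config.gradient_method
            )
            epoch_loss += loss * idx.size
            params, state = rmsprop_step(params, grad, state, config)
        mean_loss = epoch_loss / n
        preds = model.predict_batch(params, dataset.scores, ansatz)
        train_acc = float(np.mean(preds == dataset.labels))
        loss_history.append(mean_loss)
        acc_history.append(train_acc)
        log.info(
            "epoch %d/%d  mean_loss=%.6f  train_acc=%.4f",
            epoch + 1, config.epochs, mean_loss, train_acc,
        )
    return TrainResult(params, loss_history, config, acc_history)
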