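"""Data-reuploading variational circuit classifier.

The ansatz acts on four qubits (configurable) and repeats one layer pattern:
a general rotation ``Rot(phi, theta, omega)`` on every qubit followed by a
linear cascade of CNOTs (0->1, 1->2, 2->3).  The input score vector ``x`` is
*re-uploaded* in every layer by adding ``pi * x_q`` to all three trainable
angles of qubit ``q``, so one layer carries exactly ``3 * n_qubits``
trainable angles (12 on four qubits; 72 for the six-layer default).

Class readout is the joint Born-rule marginal of the readout qubits: with
readout qubits (0, 1) the four outcomes 00, 01, 10, 11 map to class labels
0-3.  A two-class model reads a single qubit instead.

Gradients come either from central finite differences (the baseline
definition of correctness here) or from the parameter-shift rule, which is
exact for these rotation generators; both are exposed and must agree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import quantum
from .quantum import StateVector, apply_1q, apply_cnot, gate_rot, marginal_probs, zero_state

__all__ = [
    "AnsatzConfig",
    "init_params",
    "build_layer",
    "forward",
    "forward_batch",
    "predict",
    "predict_batch",
    "cross_entropy_loss",
    "gradient",
    "loss_and_gradient",
    "save_checkpoint",
    "load_checkpoint",
    "EPS_CLIP",
]

#: Probability clip inside the cross-entropy, -log(p + EPS_CLIP).
EPS_CLIP = 1e-12

#: Central finite-difference step for the baseline gradient.
FD_STEP = 1e-6


@dataclass(frozen=True)
class AnsatzConfig:
    """Shape of the variational circuit.

    ``readout_qubits`` determines the number of classes: ``2**len(readout)``
    outcomes are interpreted as labels in lexicographic bit order.
    """

    n_qubits: int = 4
    n_layers: int = 6
    readout_qubits: tuple[int, ...] = (0, 1)

    def __post_init__(self) -> None:
        if self.n_qubits < 2 or self.n_qubits > quantum.MAX_QUBITS:
            raise ValueError(f"n_qubits must be in [2, {quantum.MAX_QUBITS}]")
        if self.n_layers < 1:
            raise ValueError("n_layers must be positive")
        ro = tuple(self.readout_qubits)
        object.__setattr__(self, "readout_qubits", ro)
        if len(set(ro)) != len(ro) or not all(0 <= q < self.n_qubits for q in ro):
            raise ValueError(f"invalid readout qubits {ro} for {self.n_qubits} qubits")

    @property
    def n_classes(self) -> int:
        return 2 ** len(self.readout_qubits)

    @property
    def param_shape(self) -> tuple[int, int, int]:
        return (self.n_layers, self.n_qubits, 3)

    @property
    def n_params(self) -> int:
        return self.n_layers * self.n_qubits * 3


def init_params(config: AnsatzConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw initial angles uniformly from (-pi, pi)."""
    return rng.uniform(-np.pi, np.pi, size=config.param_shape)


def _check_params(params: np.ndarray, config: AnsatzConfig) -> np.ndarray:
    params = np.asarray(params, dtype=np.float64)
    if params.shape != config.param_shape:
        raise ValueError(
            f"params shape {params.shape} does not match ansatz {config.param_shape}"
        )
    if not np.all(np.isfinite(params)):
        raise ValueError("params contain non-finite entries")
    return params


def _encode_features(x: Sequence[float], n_qubits: int) -> np.ndarray:
    """Map a score vector onto per-qubit angle offsets (pi * x_q).

    A vector shorter than the register is tiled cyclically when its length
    divides ``n_qubits`` (two-class scores on the four-qubit circuit);
    anything else is a dimension mismatch.
    """
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    if x.size == 0 or n_qubits % x.size != 0:
        raise ValueError(
            f"score vector of length {x.size} does not fit {n_qubits} qubits"
        )
    return np.tile(x, n_qubits // x.size)


def build_layer(state: StateVector, layer_angles: np.ndarray, x: Sequence[float]) -> StateVector:
    """One ansatz layer: data-shifted Rot on every qubit, then a CNOT cascade."""
    n = state.n_qubits
    layer_angles = np.asarray(layer_angles, dtype=np.float64)
    if layer_angles.shape != (n, 3):
        raise ValueError(f"layer angles shape {layer_angles.shape}, expected {(n, 3)}")
    xq = _encode_features(x, n)
    for q in range(n):
        phi, theta, omega = layer_angles[q] + np.pi * xq[q]
        state = apply_1q(state, gate_rot(phi, theta, omega), q)
    for q in range(n - 1):
        state = apply_cnot(state, q, q + 1)
    return state


def forward(params: np.ndarray, x: Sequence[float], config: AnsatzConfig) -> np.ndarray:
    """Class probability vector for one sample (reference scalar path)."""
    params = _check_params(params, config)
    state = zero_state(config.n_qubits)
    for layer in range(config.n_layers):
        state = build_layer(state, params[layer], x)
    return marginal_probs(state, config.readout_qubits)


# ---------------------------------------------------------------------------
# Vectorized engine: runs many (sample, angle-shift) circuit variants at once.
# Must agree with the scalar path above to machine precision (tested).
# ---------------------------------------------------------------------------


def _batch_probs(eff_angles: np.ndarray, config: AnsatzConfig) -> np.ndarray:
    """Readout probabilities for a stack of effective angle tensors.

    eff_angles: (M, n_layers, n_qubits, 3) -- trainable angles with the
    data offsets already added.  Returns (M, n_classes).
    """
    n = config.n_qubits
    m = eff_angles.shape[0]
    states = np.zeros((m, 2**n), dtype=np.complex128)
    states[:, 0] = 1.0
    perms = [quantum.cnot_permutation(n, q, q + 1) for q in range(n - 1)]
    for layer in range(config.n_layers):
        for q in range(n):
            phi = eff_angles[:, layer, q, 0]
            theta = eff_angles[:, layer, q, 1]
            omega = eff_angles[:, layer, q, 2]
            c = np.cos(theta / 2)
            s = np.sin(theta / 2)
            g00 = np.exp(-0.5j * (phi + omega)) * c
            g01 = -np.exp(0.5j * (phi - omega)) * s
            g10 = np.exp(-0.5j * (phi - omega)) * s
            g11 = np.exp(0.5j * (phi + omega)) * c
            view = states.reshape(m, 2**q, 2, 2 ** (n - q - 1))
            s0 = view[:, :, 0, :]
            s1 = view[:, :, 1, :]
            new = np.empty_like(view)
            new[:, :, 0, :] = g00[:, None, None] * s0 + g01[:, None, None] * s1
            new[:, :, 1, :] = g10[:, None, None] * s0 + g11[:, None, None] * s1
            states = new.reshape(m, 2**n)
        for perm in perms:
            states = states[:, perm]
    probs = np.abs(states) ** 2
    ro = config.readout_qubits
    shaped = probs.reshape((m,) + (2,) * n)
    drop = tuple(ax + 1 for ax in range(n) if ax not in ro)
    kept = shaped.sum(axis=drop) if drop else shaped
    order = [0] + [1 + sorted(ro).index(q) for q in ro]
    return kept.transpose(order).reshape(m, config.n_classes)


def _effective_angles(params: np.ndarray, X: np.ndarray, config: AnsatzConfig) -> np.ndarray:
    """(B, L, Q, 3) effective angles: params + pi * x_q on every angle."""
    offsets = np.stack([_encode_features(row, config.n_qubits) for row in X])
    return params[None, :, :, :] + np.pi * offsets[:, None, :, None]


def forward_batch(params: np.ndarray, X: np.ndarray, config: AnsatzConfig) -> np.ndarray:
    """Class probabilities for every row of ``X``; shape (B, n_classes)."""
    params = _check_params(params, config)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    return _batch_probs(_effective_angles(params, X, config), config)


def predict(params: np.ndarray, x: Sequence[float], config: AnsatzConfig) -> int:
    """Argmax class for one sample; ties resolve to the lowest class index."""
    return int(np.argmax(forward(params, x, config)))


def predict_batch(params: np.ndarray, X: np.ndarray, config: AnsatzConfig) -> np.ndarray:
    return np.argmax(forward_batch(params, X, config), axis=1)


def _as_arrays(batch) -> tuple[np.ndarray, np.ndarray]:
    """Accept a LabelledDataset, an (X, y) pair, or a list of (x, label)."""
    if hasattr(batch, "scores") and hasattr(batch, "labels"):
        X, y = batch.scores, batch.labels
    elif isinstance(batch, tuple) and len(batch) == 2 and np.ndim(batch[0]) == 2:
        X, y = batch
    else:
        pairs = list(batch)
        if not pairs:
            raise ValueError("batch must be non-empty")
        X = np.stack([np.asarray(x, dtype=np.float64) for x, _ in pairs])
        y = np.array([label for _, label in pairs])
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] == 0:
        raise ValueError("batch must be non-empty")
    if X.shape[0] != y.shape[0]:
        raise ValueError("scores and labels disagree in length")
    return X, y


def cross_entropy_loss(params: np.ndarray, batch, config: AnsatzConfig) -> float:
    """Mean -log(p_true + eps) over the batch (eps = 1e-12)."""
    X, y = _as_arrays(batch)
    if y.min() < 0 or y.max() >= config.n_classes:
        raise ValueError("labels out of range for the configured readout")
    probs = forward_batch(params, X, config)
    return float(np.mean(-np.log(probs[np.arange(len(y)), y] + EPS_CLIP)))


def loss_and_gradient(
    params: np.ndarray, batch, config: AnsatzConfig, method: str = "fd"
) -> tuple[float, np.ndarray]:
    """Batch loss and its gradient with respect to every trainable angle.

    ``method='fd'`` uses central finite differences with step 1e-6 on the
    loss itself; ``method='parameter-shift'`` uses the exact two-point shift
    rule per readout probability, chained through the cross-entropy.  Both
    evaluate 2 * n_params circuit variants per sample, batched into a single
    vectorized simulation.
    """
    params = _check_params(params, config)
    X, y = _as_arrays(batch)
    if y.min() < 0 or y.max() >= config.n_classes:
        raise ValueError("labels out of range for the configured readout")
    if method not in ("fd", "parameter-shift"):
        raise ValueError(f"unknown gradient method {method!r}")
    delta = FD_STEP if method == "fd" else np.pi / 2

    B = X.shape[0]
    P = config.n_params
    base = _effective_angles(params, X, config)  # (B, L, Q, 3)
    eff = np.broadcast_to(base[:, None], (B, 2 * P + 1) + config.param_shape).copy()
    flat = eff.reshape(B, 2 * P + 1, P)
    cols = np.arange(P)
    flat[:, 1 + 2 * cols, cols] += delta
    flat[:, 2 + 2 * cols, cols] -= delta

    probs = _batch_probs(eff.reshape(-1, *config.param_shape), config)
    probs = probs.reshape(B, 2 * P + 1, config.n_classes)
    p_true = probs[np.arange(B), :, y]  # (B, 2P + 1)

    loss = float(np.mean(-np.log(p_true[:, 0] + EPS_CLIP)))
    plus = p_true[:, 1 + 2 * cols]
    minus = p_true[:, 2 + 2 * cols]
    if method == "fd":
        per_sample = (-np.log(plus + EPS_CLIP) + np.log(minus + EPS_CLIP)) / (2 * delta)
    else:
        per_sample = -(plus - minus) / 2 / (p_true[:, 0, None] + EPS_CLIP)
    grad = per_sample.mean(axis=0).reshape(config.param_shape)
    return loss, grad


def gradient(params: np.ndarray, batch, config: AnsatzConfig, method: str = "fd") -> np.ndarray:
    """Gradient of :func:`cross_entropy_loss`; see :func:`loss_and_gradient`."""
    return loss_and_gradient(params, batch, config, method=method)[1]


# ---------------------------------------------------------------------------
# Checkpoint I/O
# ---------------------------------------------------------------------------


def save_checkpoint(
    path: str | Path,
    params: np.ndarray,
    config: AnsatzConfig,
    seed: int | None = None,
    metadata: dict | None = None,
) -> None:
    """Write params + config as JSON; floats round-trip bit-exactly."""
    params = _check_params(params, config)
    doc = {
        "config": {
            "n_qubits": config.n_qubits,
            "n_layers": config.n_layers,
            "readout_qubits": list(config.readout_qubits),
        },
        "angles": params.tolist(),
        "seed": seed,
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_checkpoint(path: str | Path) -> tuple[np.ndarray, AnsatzConfig, dict]:
    """Read a checkpoint back; returns (params, config, full document)."""
    doc = json.loads(Path(path).read_text())
    cfg = doc["config"]
    config = AnsatzConfig(
        n_qubits=int(cfg["n_qubits"]),
        n_layers=int(cfg["n_layers"]),
        readout_qubits=tuple(cfg["readout_qubits"]),
    )
    params = _check_params(np.array(doc["angles"], dtype=np.float64), config)
    return params, config, doc
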