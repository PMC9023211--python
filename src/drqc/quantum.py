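"""Exact dense statevector simulation for few-qubit circuits.

All states are full complex amplitude vectors of length ``2**n_qubits``
(double precision).  Qubit 0 is the *leftmost* tensor factor, i.e. the most
significant bit of the computational-basis index: on two qubits, basis index
``2`` is the state |10> with qubit 0 in |1>.  Gates are plain ndarrays;
every application preserves the L2 norm exactly up to floating-point error.

There is no shot noise and no density-matrix machinery here: the classifier
built on top reads exact Born-rule probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MAX_QUBITS",
    "StateVector",
    "zero_state",
    "gate_hadamard",
    "gate_rx",
    "gate_ry",
    "gate_rz",
    "gate_rot",
    "is_unitary",
    "apply_1q",
    "apply_cnot",
    "measure_probs",
    "marginal_probs",
]

#: Largest register a dense 2**n amplitude vector is allowed to represent.
MAX_QUBITS = 12

_NORM_ATOL = 1e-10
_UNITARY_ATOL = 1e-10


@dataclass(frozen=True)
class StateVector:
    """Pure state of an ``n_qubits`` register as complex amplitudes.

    Invariants checked at construction: the amplitude vector has length
    exactly ``2**n_qubits`` and unit L2 norm (tolerance 1e-10).
    """

    amplitudes: np.ndarray
    n_qubits: int = field(default=0)

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=np.complex128)
        object.__setattr__(self, "amplitudes", amps)
        n = self.n_qubits if self.n_qubits else int(np.log2(amps.size))
        object.__setattr__(self, "n_qubits", n)
        if amps.ndim != 1 or amps.size != 2**n:
            raise ValueError(
                f"amplitude vector of length {amps.size} does not match "
                f"2**{n} basis states"
            )
        norm = np.linalg.norm(amps)
        if abs(norm - 1.0) > _NORM_ATOL:
            raise ValueError(f"state norm {norm!r} deviates from 1 by more than {_NORM_ATOL}")

    def probabilities(self) -> np.ndarray:
        return np.abs(self.amplitudes) ** 2


def zero_state(n_qubits: int) -> StateVector:
    """Prepare |0...0> on ``n_qubits`` qubits (1 <= n_qubits <= 12)."""
    if not isinstance(n_qubits, (int, np.integer)) or isinstance(n_qubits, bool):
        raise ValueError("n_qubits must be an integer")
    if n_qubits < 1 or n_qubits > MAX_QUBITS:
        raise ValueError(f"n_qubits must be in [1, {MAX_QUBITS}], got {n_qubits}")
    amps = np.zeros(2**n_qubits, dtype=np.complex128)
    amps[0] = 1.0
    return StateVector(amps, int(n_qubits))


def gate_hadamard() -> np.ndarray:
    """H = (1/sqrt 2) [[1, 1], [1, -1]]; maps |0> to (|0>+|1>)/sqrt 2."""
    return np.array([[1, 1], [1, -1]], dtype=np.complex128) / np.sqrt(2.0)


def _check_angle(*angles: float) -> None:
    for a in angles:
        if not np.isfinite(a):
            raise ValueError(f"rotation angle must be finite, got {a!r}")


def gate_rx(phi: float) -> np.ndarray:
    """Rotation by ``phi`` about the Bloch x-axis: exp(-i phi X / 2)."""
    _check_angle(phi)
    c, s = np.cos(phi / 2), np.sin(phi / 2)
    return np.array([[c, -1j * s], [-1j * s, c]], dtype=np.complex128)


def gate_ry(phi: float) -> np.ndarray:
    """Rotation by ``phi`` about the Bloch y-axis: exp(-i phi Y / 2).

    The off-diagonal entries are real (-sin, +sin); see the methods note for
    why this standard form is used.
    """
    _check_angle(phi)
    c, s = np.cos(phi / 2), np.sin(phi / 2)
    return np.array([[c, -s], [s, c]], dtype=np.complex128)


def gate_rz(phi: float) -> np.ndarray:
    """Rotation by ``phi`` about the Bloch z-axis: diag(e^{-i phi/2}, e^{i phi/2})."""
    _check_angle(phi)
    return np.array(
        [[np.exp(-0.5j * phi), 0], [0, np.exp(0.5j * phi)]], dtype=np.complex128
    )


def gate_rot(phi: float, theta: float, omega: float) -> np.ndarray:
    """General single-qubit rotation RZ(omega) @ RY(theta) @ RZ(phi).

    Geometrically: spin about the z-axis by ``phi``, then the y-axis by
    ``theta``, then the z-axis again by ``omega``.  Any single-qubit unitary
    equals this product up to a global phase.
    """
    _check_angle(phi, theta, omega)
    return gate_rz(omega) @ gate_ry(theta) @ gate_rz(phi)


def is_unitary(gate: np.ndarray, atol: float = _UNITARY_ATOL) -> bool:
    gate = np.asarray(gate)
    if gate.ndim != 2 or gate.shape[0] != gate.shape[1]:
        return False
    eye = np.eye(gate.shape[0])
    return bool(np.max(np.abs(gate.conj().T @ gate - eye)) < atol)


def apply_1q(state: StateVector, gate: np.ndarray, qubit: int) -> StateVector:
    """Apply a single-qubit gate to the addressed qubit of ``state``."""
    n = state.n_qubits
    if not 0 <= qubit < n:
        raise IndexError(f"qubit index {qubit} out of range for {n} qubits")
    gate = np.asarray(gate, dtype=np.complex128)
    if gate.shape != (2, 2):
        raise ValueError(f"expected a 2x2 gate, got shape {gate.shape}")
    if not is_unitary(gate):
        raise ValueError("gate matrix is not unitary")
    left = 2**qubit
    right = 2 ** (n - qubit - 1)
    t = state.amplitudes.reshape(left, 2, right)
    out = np.einsum("ab,ibj->iaj", gate, t).reshape(-1)
    return StateVector(out, n)


def apply_cnot(state: StateVector, control: int, target: int) -> StateVector:
    """Flip ``target`` on every basis state whose ``control`` bit is 1."""
    n = state.n_qubits
    if control == target:
        raise ValueError("control and target must be distinct qubits")
    for q in (control, target):
        if not 0 <= q < n:
            raise IndexError(f"qubit index {q} out of range for {n} qubits")
    perm = cnot_permutation(n, control, target)
    return StateVector(state.amplitudes[perm], n)


def cnot_permutation(n_qubits: int, control: int, target: int) -> np.ndarray:
    """Basis-index permutation realizing CNOT (an involution)."""
    idx = np.arange(2**n_qubits)
    cmask = 1 << (n_qubits - 1 - control)
    tmask = 1 << (n_qubits - 1 - target)
    return np.where(idx & cmask, idx ^ tmask, idx)


def measure_probs(state: StateVector) -> np.ndarray:
    """Born-rule outcome distribution over all 2**n basis states."""
    return state.probabilities()


def marginal_probs(state: StateVector, qubits: Sequence[int]) -> np.ndarray:
    """Marginal outcome distribution of the listed qubits, in listed order.

    Entry ``k`` is the probability that reading out the listed qubits gives
    the bit pattern of ``k`` (first listed qubit = most significant bit).
    """
    n = state.n_qubits
    qubits = list(qubits)
    if len(set(qubits)) != len(qubits):
        raise ValueError(f"duplicate qubit indices in {qubits}")
    for q in qubits:
        if not 0 <= q < n:
            raise ValueError(f"qubit index {q} out of range for {n} qubits")
    probs = state.probabilities().reshape((2,) * n)
    drop = tuple(ax for ax in range(n) if ax not in qubits)
    kept = probs.sum(axis=drop) if drop else probs
    # axes of `kept` are the retained qubits in increasing index order
    order = [sorted(qubits).index(q) for q in qubits]
    return kept.transpose(order).reshape(-1)
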