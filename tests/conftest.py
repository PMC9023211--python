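import numpy as np
import pytest

from drqc import AnsatzConfig, GeneratorConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ansatz():
    """The default four-qubit, six-layer circuit with a two-qubit readout."""
    return AnsatzConfig()


@pytest.fixture
def small_dataset():
    """Separable 4-class score vectors, small enough for fast training tests."""
    return generate(GeneratorConfig(n_per_class=30, seed=11))


def kron_apply_1q(amps: np.ndarray, gate: np.ndarray, qubit: int, n: int) -> np.ndarray:
    """Oracle: build I x ... x G x ... x I explicitly and multiply."""
    full = np.array([[1.0]], dtype=np.complex128)
    for q in range(n):
        full = np.kron(full, gate if q == qubit else np.eye(2))
    return full @ amps


def kron_cnot_matrix(n: int, control: int, target: int) -> np.ndarray:
    """Oracle: dense 2^n x 2^n CNOT built basis state by basis state."""
    dim = 2**n
    mat = np.zeros((dim, dim), dtype=np.complex128)
    for j in range(dim):
        bits = [(j >> (n - 1 - q)) & 1 for q in range(n)]
        if bits[control]:
            bits[target] ^= 1
        i = sum(b << (n - 1 - q) for q, b in enumerate(bits))
        mat[i, j] = 1.0
    return mat
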