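import numpy as np
import pytest

from qdinn.data_io import generate_fixtures
from qdinn.quantum import CircuitGeometry, QDILayer, QDIParams


def dense_single_qubit_unitary(n_qubits: int, qubit: int, m: np.ndarray) -> np.ndarray:
    """Independent dense operator: kron(I_high, m, I_low), little-endian."""
    return np.kron(
        np.kron(np.eye(2 ** (n_qubits - 1 - qubit)), m), np.eye(2 ** qubit)
    )


def dense_cnot_unitary(n_qubits: int, control: int, target: int) -> np.ndarray:
    """Independent dense CNOT built directly from basis-state action."""
    dim = 2 ** n_qubits
    u = np.zeros((dim, dim))
    for i in range(dim):
        j = i ^ (1 << target) if (i >> control) & 1 else i
        u[j, i] = 1.0
    return u


def random_state(n_qubits: int, rng: np.random.Generator) -> np.ndarray:
    amps = rng.normal(size=2 ** n_qubits) + 1j * rng.normal(size=2 ** n_qubits)
    return amps / np.linalg.norm(amps)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_geometry():
    # 3 qubits, 2 blocks: big enough to entangle, small enough to brute-force
    return CircuitGeometry(
        n_qubits=3, n_blocks=2, layers_initial=2, layers_per_block=2
    )


@pytest.fixture(scope="session")
def small_layer(small_geometry):
    return QDILayer(small_geometry)


@pytest.fixture(scope="session")
def small_params(small_geometry):
    return QDIParams.initialize(small_geometry, np.random.default_rng(7))


@pytest.fixture(scope="session")
def tiny_bundle():
    """3 drugs x 8 cells = 24 responses; used by pipeline/model tests."""
    return generate_fixtures(3, 8, seed=42, noise_sd=0.1)
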