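"""Dense statevector simulation of few-qubit circuits.

A pure state of ``q`` qubits is a unit-norm complex vector of 2**q
amplitudes. Basis states are labelled little-endian: qubit ``j`` corresponds
to bit ``j`` of the basis index, so qubit 0 ("the first qubit") is the least
significant bit, and the all-zeros ground state is index 0.

All kernels operate on arrays of shape ``(..., 2**q)`` so that a batch of
statevectors (one circuit evaluated at many data points, sharing gate
structure) is propagated with the same NumPy calls as a single state. Batched
per-sample rotation angles are supported where a gate encodes data.

Gate matrices follow the standard convention

* ``RX(t) = exp(-i t X / 2)``, ``RY(t) = exp(-i t Y / 2)``,
  ``RZ(t) = exp(-i t Z / 2) = diag(e^{-it/2}, e^{+it/2})``
* ``CNOT`` flips the target qubit on basis states where the control bit is 1.

CNOTs permute basis states, so they (and chains of them) are applied as
precomputed index permutations — one gather instead of per-gate arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "Statevector",
    "apply_rx",
    "apply_ry",
    "apply_rz",
    "apply_cnot",
    "apply_rotation",
    "apply_pauli",
    "rotation_matrix",
    "cnot_permutation",
    "compose_permutations",
    "z_expectation",
    "zero_state",
]

_PAULI = {
    "x": np.array([[0, 1], [1, 0]], dtype=complex),
    "y": np.array([[0, -1j], [1j, 0]], dtype=complex),
    "z": np.array([[1, 0], [0, -1]], dtype=complex),
}


def zero_state(n_qubits: int, batch: int | None = None) -> np.ndarray:
    """The ground state |0...0> as amplitudes, optionally batched."""
    dim = 2 ** n_qubits
    shape = (dim,) if batch is None else (batch, dim)
    state = np.zeros(shape, dtype=complex)
    state[..., 0] = 1.0
    return state


def rotation_matrix(axis: str, theta) -> np.ndarray:
    """The 2x2 single-qubit rotation exp(-i theta P/2) for P in {X, Y, Z}.

    ``theta`` may be a scalar or an array; for array input the matrix is
    batched with shape ``theta.shape + (2, 2)``.
    """
    t = np.asarray(theta, dtype=float)
    c, s = np.cos(t / 2), np.sin(t / 2)
    m = np.empty(t.shape + (2, 2), dtype=complex)
    if axis == "x":
        m[..., 0, 0] = c
        m[..., 0, 1] = -1j * s
        m[..., 1, 0] = -1j * s
        m[..., 1, 1] = c
    elif axis == "y":
        m[..., 0, 0] = c
        m[..., 0, 1] = -s
        m[..., 1, 0] = s
        m[..., 1, 1] = c
    elif axis == "z":
        m[..., 0, 0] = np.exp(-1j * t / 2)
        m[..., 0, 1] = 0
        m[..., 1, 0] = 0
        m[..., 1, 1] = np.exp(1j * t / 2)
    else:
        raise ValueError(f"unknown rotation axis {axis!r}")
    return m


def _n_qubits(state: np.ndarray) -> int:
    dim = state.shape[-1]
    n = dim.bit_length() - 1
    if 2 ** n != dim:
        raise ValueError(f"state dimension {dim} is not a power of two")
    return n


def _check_qubit(n: int, qubit: int) -> None:
    if not 0 <= qubit < n:
        raise IndexError(f"qubit {qubit} out of range for {n}-qubit state")


def apply_single_qubit(
    state: np.ndarray, qubit: int, matrix: np.ndarray
) -> np.ndarray:
    """Apply a 2x2 matrix to one qubit of ``state``.

    ``matrix`` has shape (2, 2), or (B, 2, 2) for a per-sample gate acting on
    a batch of shape (B, dim).
    """
    n = _n_qubits(state)
    _check_qubit(n, qubit)
    lead = state.shape[:-1]
    hi, lo = 2 ** (n - 1 - qubit), 2 ** qubit
    s = state.reshape(lead + (hi, 2, lo))
    a0, a1 = s[..., 0, :], s[..., 1, :]
    if matrix.ndim == 2:
        m = matrix
        out0 = m[0, 0] * a0 + m[0, 1] * a1
        out1 = m[1, 0] * a0 + m[1, 1] * a1
    else:
        m = matrix.reshape(lead + (1, 2, 2))
        out0 = m[..., 0, 0:1] * a0 + m[..., 0, 1:2] * a1
        out1 = m[..., 1, 0:1] * a0 + m[..., 1, 1:2] * a1
    out = np.empty_like(s)
    out[..., 0, :] = out0
    out[..., 1, :] = out1
    return out.reshape(state.shape)


def apply_rotation(state: np.ndarray, qubit: int, axis: str, theta) -> np.ndarray:
    """Apply RX/RY/RZ (``axis`` in {x,y,z}) by angle ``theta`` (radians).

    A per-sample angle array of shape (B,) is allowed for batched states.
    """
    return apply_single_qubit(state, qubit, rotation_matrix(axis, theta))


def apply_rx(state, qubit, theta):
    """Rotate ``qubit`` about X by ``theta``."""
    return apply_rotation(state, qubit, "x", theta)


def apply_ry(state, qubit, theta):
    """Rotate ``qubit`` about Y by ``theta``."""
    return apply_rotation(state, qubit, "y", theta)


def apply_rz(state, qubit, theta):
    """Rotate ``qubit`` about Z by ``theta`` (diagonal phase gate)."""
    return apply_rotation(state, qubit, "z", theta)


def apply_pauli(state: np.ndarray, qubit: int, which: str) -> np.ndarray:
    """Apply a Pauli X, Y or Z to one qubit (used by adjoint gradients)."""
    return apply_single_qubit(state, qubit, _PAULI[which])


@lru_cache(maxsize=None)
def cnot_permutation(n_qubits: int, control: int, target: int) -> np.ndarray:
    """Basis-index permutation implementing CNOT(control -> target)."""
    if control == target:
        raise ValueError("control and target qubits must differ")
    _check_qubit(n_qubits, control)
    _check_qubit(n_qubits, target)
    idx = np.arange(2 ** n_qubits)
    flipped = idx ^ (1 << target)
    return np.where((idx >> control) & 1 == 1, flipped, idx)


def compose_permutations(n_qubits: int, pairs) -> np.ndarray:
    """Compose a sequence of CNOTs (applied left to right) into one gather.

    Returns ``perm`` such that ``state[..., perm]`` equals applying
    ``CNOT(c, t)`` for each ``(c, t)`` in ``pairs`` in order.
    """
    perm = np.arange(2 ** n_qubits)
    for control, target in pairs:
        perm = perm[cnot_permutation(n_qubits, control, target)]
    return perm


def apply_cnot(state: np.ndarray, control: int, target: int) -> np.ndarray:
    """Apply CNOT: flip ``target`` where the ``control`` bit is 1."""
    n = _n_qubits(state)
    return state[..., cnot_permutation(n, control, target)]


def z_expectation(state: np.ndarray, qubit: int) -> np.ndarray:
    """<Z> of one qubit: +1 weight where its bit is 0, -1 where it is 1."""
    n = _n_qubits(state)
    _check_qubit(n, qubit)
    signs = 1.0 - 2.0 * ((np.arange(2 ** n) >> qubit) & 1)
    return ((state.real ** 2 + state.imag ** 2) * signs).sum(axis=-1)


@dataclass
class Statevector:
    """A single q-qubit pure state with convenience gate methods.

    Thin object wrapper over the array kernels; the training path uses the
    batched kernels directly.
    """

    amplitudes: np.ndarray
    n_qubits: int = 8

    @classmethod
    def zero(cls, n_qubits: int = 8) -> "Statevector":
        return cls(zero_state(n_qubits), n_qubits)

    def _wrap(self, amps: np.ndarray) -> "Statevector":
        return Statevector(amps, self.n_qubits)

    def rx(self, qubit: int, theta: float) -> "Statevector":
        return self._wrap(apply_rx(self.amplitudes, qubit, theta))

    def ry(self, qubit: int, theta: float) -> "Statevector":
        return self._wrap(apply_ry(self.amplitudes, qubit, theta))

    def rz(self, qubit: int, theta: float) -> "Statevector":
        return self._wrap(apply_rz(self.amplitudes, qubit, theta))

    def cnot(self, control: int, target: int) -> "Statevector":
        return self._wrap(apply_cnot(self.amplitudes, control, target))

    def z_expectation(self, qubit: int = 0) -> float:
        return float(z_expectation(self.amplitudes, qubit))

    @property
    def norm(self) -> float:
        return float(np.sqrt((np.abs(self.amplitudes) ** 2).sum()))

    def probabilities(self) -> np.ndarray:
        return np.abs(self.amplitudes) ** 2
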