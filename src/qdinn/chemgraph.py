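"""SMILES-to-graph conversion with binary atom features.

Drugs are represented as molecular graphs over heavy atoms: a node-feature
matrix ``X`` (one 78-dimensional binary row per atom) and a symmetric binary
adjacency matrix ``A`` (1 where a chemical bond joins two atoms). Hydrogens
are implicit and never become nodes; bond order, stereochemistry and isotopes
are carried by the SMILES string but not encoded beyond connectivity — the
downstream graph-convolutional encoder consumes only ``X`` and ``A``.

The 78 features per atom are the concatenation of four one-hot blocks plus a
flag, in this fixed order:

* element symbol, 44 slots (:data:`ELEMENTS`; the last slot is a catch-all
  ``Unknown`` for any symbol outside the list),
* heavy-atom degree, 11 slots (0–10),
* total attached hydrogens, 11 slots (0–10),
* implicit valence, 11 slots (0–10),
* aromaticity flag, 1 slot.

Charged or isotopic atoms receive the same features as their parent element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = [
    "ELEMENTS",
    "N_ATOM_FEATURES",
    "MolecularGraph",
    "atom_features",
    "smiles_to_graph",
    "dump_graph",
]

#: Element vocabulary, frozen ordering; index 43 ("Unknown") is the fallback
#: slot for any symbol not listed.
ELEMENTS: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg",
    "Na", "Ca", "Fe", "As", "Al", "I", "B", "V", "K", "Tl",
    "Yb", "Sb", "Sn", "Ag", "Pd", "Co", "Se", "Ti", "Zn", "H",
    "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn", "Zr", "Cr",
    "Pt", "Hg", "Pb", "Unknown",
)

_N_ELEMENT_SLOTS = len(ELEMENTS)  # 44
_COUNT_SLOTS = 11  # one-hot over 0..10

#: Total atom-feature dimension: 44 + 11 + 11 + 11 + 1.
N_ATOM_FEATURES = _N_ELEMENT_SLOTS + 3 * _COUNT_SLOTS + 1


@dataclass
class MolecularGraph:
    """A drug molecule as (node features, adjacency).

    Attributes
    ----------
    node_features : ndarray of shape (n_atoms, 78)
        Binary atom-feature rows (see module docstring for the layout).
    adjacency : ndarray of shape (n_atoms, n_atoms)
        Symmetric binary matrix with zero diagonal; ``adjacency[i, j] == 1``
        iff a bond joins heavy atoms ``i`` and ``j``.
    drug_id : str
        Free-form label (defaults to the source SMILES).
    """

    node_features: np.ndarray
    adjacency: np.ndarray
    drug_id: str = ""
    _norm_adj_cache: np.ndarray | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    def validate(self) -> None:
        """Raise ``ValueError`` if the structural invariants are violated."""
        x, a = self.node_features, self.adjacency
        if x.ndim != 2 or x.shape[1] != N_ATOM_FEATURES:
            raise ValueError(
                f"node_features must be (N, {N_ATOM_FEATURES}), got {x.shape}"
            )
        n = x.shape[0]
        if n < 1:
            raise ValueError("graph must contain at least one atom")
        if a.shape != (n, n):
            raise ValueError(f"adjacency must be ({n}, {n}), got {a.shape}")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0.0, 1.0)).all() or not np.isin(x, (0.0, 1.0)).all():
            raise ValueError("adjacency and node_features must be binary")
        row_sums = x.sum(axis=1)
        if not np.isin(row_sums, (4, 5)).all():
            raise ValueError("each atom row must contain 4 or 5 ones")


def _one_hot(value: int, size: int, what: str) -> np.ndarray:
    if not 0 <= value < size:
        raise ValueError(f"{what} must be in [0, {size - 1}], got {value}")
    v = np.zeros(size)
    v[value] = 1.0
    return v


def atom_features(
    symbol: str,
    degree: int,
    total_hydrogens: int,
    implicit_valence: int,
    is_aromatic: bool,
) -> np.ndarray:
    """Build the 78-dimensional binary feature vector for one atom.

    ``degree``, ``total_hydrogens`` and ``implicit_valence`` must each lie in
    [0, 10]; an unknown ``symbol`` maps to the final "Unknown" element slot.
    """
    element = np.zeros(_N_ELEMENT_SLOTS)
    try:
        element[ELEMENTS.index(symbol)] = 1.0
    except ValueError:
        element[-1] = 1.0
    return np.concatenate(
        [
            element,
            _one_hot(degree, _COUNT_SLOTS, "degree"),
            _one_hot(total_hydrogens, _COUNT_SLOTS, "total_hydrogens"),
            _one_hot(implicit_valence, _COUNT_SLOTS, "implicit_valence"),
            [1.0 if is_aromatic else 0.0],
        ]
    )


def smiles_to_graph(smiles: str, drug_id: str | None = None) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    One node per heavy atom, in RDKit's canonical atom order; undirected
    edges wherever a bond exists. Deterministic: the same string always
    yields identical matrices.

    Raises
    ------
    ValueError
        If the string does not parse or describes an empty molecule.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES string: {smiles!r}")
    n = mol.GetNumAtoms()
    if n == 0:
        raise ValueError(f"SMILES describes an empty molecule: {smiles!r}")
    x = np.zeros((n, N_ATOM_FEATURES))
    for atom in mol.GetAtoms():
        x[atom.GetIdx()] = atom_features(
            atom.GetSymbol(),
            atom.GetDegree(),
            atom.GetTotalNumHs(),
            atom.GetImplicitValence(),
            atom.GetIsAromatic(),
        )
    a = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        a[i, j] = a[j, i] = 1.0
    return MolecularGraph(x, a, drug_id if drug_id is not None else smiles)


def dump_graph(graph: MolecularGraph) -> str:
    """Render a graph as plain text for debugging.

    Emits one ``drug_id<TAB>i<TAB>j`` line per undirected edge (i < j),
    followed by one ``drug_id<TAB>i<TAB>feat:<comma-joined 0/1>`` line per
    atom.
    """
    lines = []
    n = graph.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if graph.adjacency[i, j]:
                lines.append(f"{graph.drug_id}\t{i}\t{j}")
    for i in range(n):
        feats = ",".join(str(int(v)) for v in graph.node_features[i])
        lines.append(f"{graph.drug_id}\t{i}\tfeat:{feats}")
    return "\n".join(lines) + "\n"
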