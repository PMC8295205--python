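"""Molecular graphs with binary adjacency.

A molecule is represented as an undirected graph: one node per atom, one
edge per covalent bond.  Bond orders and aromaticity are deliberately
collapsed to 1 — the scattering transform downstream consumes a plain 0/1
adjacency matrix built from the 2D connectivity, never from geometry.

Hydrogens are included as graph nodes by default because the classical
force fields used for node attributes assign parameters (type, charge,
Lennard-Jones r and epsilon) to hydrogen atoms as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class DisconnectedMoleculeError(ValueError):
    """Raised for multi-fragment inputs (salts, mixtures, 'A.B' SMILES)."""


@dataclass(frozen=True)
class MolecularGraph:
    """Graph view of one molecule.

    Attributes
    ----------
    n : int
        Number of atoms (graph nodes), >= 1.
    adjacency : ndarray of shape (n, n)
        Symmetric 0/1 matrix with zero diagonal; ``adjacency[i, j] == 1``
        exactly when atoms i and j share a covalent bond of any order.
    node_order : list of int
        Stable atom indices (the toolkit's atom ordering after optional
        hydrogen addition); row/column i of ``adjacency`` is atom
        ``node_order[i]``.
    smiles_canonical : str
        Canonical SMILES of the parsed structure.
    mol_weight : float
        Standard average molecular weight in daltons.
    element_set : frozenset of str
        Element symbols present in the (hydrogen-complete) structure.
    """

    n: int
    adjacency: np.ndarray
    node_order: list[int]
    smiles_canonical: str
    mol_weight: float
    element_set: frozenset[str]
    mol: Chem.Mol = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.shape != (self.n, self.n):
            raise ValueError(f"adjacency shape {a.shape} != ({self.n}, {self.n})")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if self.n >= 2 and np.any(a.sum(axis=1) == 0):
            raise DisconnectedMoleculeError(
                "isolated atom in a multi-atom molecule"
            )

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES of a molecule; idempotent, writing-invariant."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    return max(frags, key=lambda m: m.GetNumAtoms())


def graph_from_mol(mol: Chem.Mol, add_hydrogens: bool = True) -> MolecularGraph:
    """Build a :class:`MolecularGraph` from an already-parsed molecule."""
    if add_hydrogens:
        mol = Chem.AddHs(mol)
    n = mol.GetNumAtoms()
    if n < 1:
        raise SmilesParseError("molecule has no atoms")
    adjacency = np.zeros((n, n), dtype=np.int64)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i, j] = 1
        adjacency[j, i] = 1
    # element_set is taken from the hydrogen-complete structure so that H
    # counts as present even when the graph itself is heavy-atom only
    mol_h = mol if add_hydrogens else Chem.AddHs(mol)
    elements = frozenset(a.GetSymbol() for a in mol_h.GetAtoms())
    return MolecularGraph(
        n=n,
        adjacency=adjacency,
        node_order=list(range(n)),
        smiles_canonical=Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(mol))),
        mol_weight=float(Descriptors.MolWt(mol)),
        element_set=elements,
        mol=mol,
    )


def parse_smiles(
    smiles: str,
    add_hydrogens: bool = True,
    on_disconnected: str = "reject",
) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Parameters
    ----------
    smiles : str
        Input SMILES; must be non-empty and parseable.
    add_hydrogens : bool, default True
        Include explicit hydrogens as graph nodes.
    on_disconnected : {"reject", "largest"}, default "reject"
        Policy for multi-fragment inputs: reject with
        :class:`DisconnectedMoleculeError`, or keep the largest fragment.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ValueError("smiles must be a non-empty string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        if on_disconnected == "largest":
            mol = _largest_fragment(mol)
        else:
            raise DisconnectedMoleculeError(
                f"multi-fragment SMILES (use on_disconnected='largest'): {smiles!r}"
            )
    return graph_from_mol(mol, add_hydrogens=add_hydrogens)


def read_smi(path) -> list[tuple[str, str]]:
    """Read a .smi file: one record per line, SMILES then optional ID.

    Returns (smiles, id) pairs; missing IDs become sequential ``mol{i}``.
    """
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            smi = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{i}"
            records.append((smi, mol_id))
    return records


def write_smi(path, records) -> None:
    """Write (smiles, id) pairs to a .smi file."""
    with open(path, "w") as fh:
        for smi, mol_id in records:
            fh.write(f"{smi} {mol_id}\n")


def read_sdf(path) -> list[tuple[str, str]]:
    """Read a V2000 SDF file and return (canonical smiles, id) pairs."""
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        records.append((Chem.MolToSmiles(mol), name or f"mol{i}"))
    return records
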