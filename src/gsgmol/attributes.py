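"""Per-atom attributes and their encoding as graph signals.

The node signal fed to the scattering transform concatenates, per atom:
partial charge, Lennard-Jones radius r, Lennard-Jones well depth epsilon
(three scalar channels, passed through raw), and a one-hot encoding of the
atom type over a *frozen* vocabulary, so the signal width is
N = 3 + |vocabulary| independent of the dataset at hand.

Providers are pluggable.  Builtin:

* ``mmff94`` / ``uff`` / ``gaff`` / ``ghemical`` — Open Babel typing with
  LJ parameters from the force field's own tables (see ``forcefields``).
* ``fallback`` — element-symbol atom types, Gasteiger partial charges and
  tabulated element LJ constants; requires no typing backend.
* :class:`AttributeTableProvider` — pre-computed per-atom attribute tables
  (CSV), e.g. for parameters produced by external tools.

Atom types may optionally be coarsened through a user-supplied grouping
(label -> group) before one-hot encoding; the default is to use every
native force-field type as its own category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit.Chem import AllChem

from . import forcefields
from .forcefields import AtomTypingError
from .graphs import MolecularGraph

SCALAR_CHANNELS = ("charge", "lj_r", "lj_eps")


@dataclass(frozen=True)
class AtomAttributes:
    """Force-field attributes of one atom."""

    atom_type: str
    charge: float
    lj_radius: float
    lj_welldepth: float


@dataclass(frozen=True)
class TypeVocabulary:
    """Ordered atom-type label list, optionally coarsened by a grouping.

    ``grouping`` maps native labels to group names; when present it must be
    total over ``labels``.  ``effective_labels`` is what the one-hot block
    encodes: the native labels, or the groups in order of first appearance.
    """

    provider_name: str
    labels: tuple[str, ...]
    grouping: dict[str, str] | None = None

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("vocabulary labels must be unique")
        if self.grouping is not None:
            missing = [l for l in self.labels if l not in self.grouping]
            if missing:
                raise ValueError(
                    f"grouping is not total over labels; missing {missing[:5]}"
                )

    @property
    def effective_labels(self) -> tuple[str, ...]:
        if self.grouping is None:
            return self.labels
        seen: dict[str, None] = {}
        for label in self.labels:
            seen.setdefault(self.grouping[label], None)
        return tuple(seen)

    def encode(self, label: str) -> int:
        """Column index of a native label in the one-hot block."""
        target = self.grouping[label] if self.grouping else label
        try:
            return self.effective_labels.index(target)
        except ValueError:
            raise KeyError(
                f"atom type {label!r} is not in the {self.provider_name!r} "
                "vocabulary (no silent fallback bucket)"
            ) from None


@dataclass(frozen=True)
class NodeSignals:
    """The graph signal x: one row per atom, N attribute channels."""

    matrix: np.ndarray
    channel_names: tuple[str, ...]

    @property
    def N(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class MoleculeSkipped:
    """A molecule a backend refused to type, with the reason."""

    smiles: str
    provider: str
    reason: str


class _OpenBabelProvider:
    def __init__(self, name: str):
        self.name = name

    def vocabulary(self) -> TypeVocabulary:
        return TypeVocabulary(self.name, forcefields.type_vocabulary(self.name))

    def assign(self, graph: MolecularGraph, mol_id=None) -> list[AtomAttributes]:
        params = forcefields.openbabel_atom_parameters(graph.mol, self.name)
        return [
            AtomAttributes(atom_type=t, charge=c, lj_radius=r, lj_welldepth=e)
            for t, c, r, e in params
        ]


class FallbackProvider:
    """Element types + Gasteiger charges + element LJ constants.

    Entirely RDKit-based; useful when no typing backend is available and as
    the deterministic default for synthetic data.
    """

    name = "fallback"
    elements = tuple(forcefields.ELEMENT_LJ)

    def vocabulary(self) -> TypeVocabulary:
        return TypeVocabulary(self.name, self.elements)

    def assign(self, graph: MolecularGraph, mol_id=None) -> list[AtomAttributes]:
        mol = graph.mol
        AllChem.ComputeGasteigerCharges(mol)
        out = []
        for atom in mol.GetAtoms():
            sym = atom.GetSymbol()
            if sym not in forcefields.ELEMENT_LJ:
                raise AtomTypingError(f"fallback: unsupported element {sym!r}")
            q = atom.GetDoubleProp("_GasteigerCharge")
            if not np.isfinite(q):
                raise AtomTypingError("fallback: non-finite Gasteiger charge")
            r, eps = forcefields.ELEMENT_LJ[sym]
            out.append(AtomAttributes(sym, float(q), r, eps))
        return out


class AttributeTableProvider:
    """Pre-computed per-atom attributes from a CSV table.

    Expected columns: ``mol_id, atom_index, atom_type, charge, lj_radius,
    lj_welldepth``; atom_index follows the molecule's node order.
    """

    name = "table"

    def __init__(self, table: pd.DataFrame | str, labels=None):
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table)
        required = {
            "mol_id", "atom_index", "atom_type",
            "charge", "lj_radius", "lj_welldepth",
        }
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"attribute table missing columns {sorted(missing)}")
        self.table = table
        self._labels = (
            tuple(labels)
            if labels is not None
            else tuple(sorted(table["atom_type"].astype(str).unique()))
        )

    def vocabulary(self) -> TypeVocabulary:
        return TypeVocabulary(self.name, self._labels)

    def assign(self, graph: MolecularGraph, mol_id=None) -> list[AtomAttributes]:
        rows = self.table[self.table["mol_id"] == mol_id]
        if len(rows) != graph.n:
            raise AtomTypingError(
                f"table: {len(rows)} rows for mol_id {mol_id!r}, graph has "
                f"{graph.n} atoms"
            )
        rows = rows.sort_values("atom_index")
        return [
            AtomAttributes(
                str(r.atom_type), float(r.charge),
                float(r.lj_radius), float(r.lj_welldepth),
            )
            for r in rows.itertuples()
        ]


_BUILTIN = {"mmff94", "uff", "gaff", "ghemical"}


def get_provider(provider: str):
    """Resolve a provider id to a provider object."""
    if not isinstance(provider, str):  # already a provider object
        return provider
    if provider in _BUILTIN:
        return _OpenBabelProvider(provider)
    if provider == "fallback":
        return FallbackProvider()
    raise KeyError(
        f"unknown attribute provider {provider!r}; "
        f"builtin: {sorted(_BUILTIN) + ['fallback']}"
    )


def assign_attributes(graph: MolecularGraph, provider="mmff94", mol_id=None):
    """One :class:`AtomAttributes` per node, aligned with node_order.

    Raises :class:`AtomTypingError` when the backend refuses the molecule;
    callers building datasets catch it and record a :class:`MoleculeSkipped`.
    """
    attrs = get_provider(provider).assign(graph, mol_id=mol_id)
    if len(attrs) != graph.n:
        raise AtomTypingError(
            f"{provider}: {len(attrs)} attribute records for {graph.n} atoms"
        )
    return attrs


def encode_signals(attrs, vocab: TypeVocabulary) -> NodeSignals:
    """Encode attributes as the signal matrix: [charge, r, eps | one-hot].

    Out-of-vocabulary atom types raise ``KeyError`` naming the label.
    """
    width = len(vocab.effective_labels)
    n = len(attrs)
    matrix = np.zeros((n, 3 + width))
    for i, a in enumerate(attrs):
        matrix[i, 0] = a.charge
        matrix[i, 1] = a.lj_radius
        matrix[i, 2] = a.lj_welldepth
        matrix[i, 3 + vocab.encode(a.atom_type)] = 1.0
    names = SCALAR_CHANNELS + tuple(f"type:{l}" for l in vocab.effective_labels)
    return NodeSignals(matrix=matrix, channel_names=names)


def load_grouping(path) -> dict[str, str]:
    """Read a label->group mapping file (CSV with 2 columns, or whitespace)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        sep = "," if "," in first else None
        fh.seek(0)
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(sep)]
            if parts[0].lower() in ("label", "atom_type") and not mapping:
                continue  # header
            if len(parts) < 2:
                raise ValueError(f"bad grouping line: {line!r}")
            mapping[parts[0]] = parts[1]
    return mapping
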