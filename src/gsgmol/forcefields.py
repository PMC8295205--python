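"""Classical force-field backends for per-atom attributes.

Each backend types a molecule and reports, per atom: an atom-type label
from the force field's own vocabulary, a partial charge (elementary-charge
units), and the two Lennard-Jones parameters — radius r and well-depth
epsilon — exactly as that force field tabulates them (Rmin/2 vs sigma
conventions and units are passed through untouched and recorded in the
channel metadata; no conversion is attempted).

The four open force fields (MMFF94, UFF, GAFF, Ghemical) are driven through
Open Babel's OBForceField plugins: the molecule is handed to ``Setup`` and
types/charges are read back per atom.  LJ parameters are then looked up in
the force field's parameter table by atom type:

* UFF      — ``UFF.prm``     ``param <type> r1 theta0 x1 D1 ...`` (x1, D1)
* Ghemical — ``ghemical.prm``  ``vdw <type> <r> <eps>``
* GAFF     — ``gaff.dat``      MOD4 RE section: ``<type> <Rmin/2> <eps>``
* MMFF94   — ``mmffvdw.par``   per-type (alpha, N, A, G); the self
  parameters follow the MMFF94 combination rules,
      R*_II   = A_I * alpha_I^(1/4)
      eps_II  = 181.16 G_I^2 alpha_I^2 / (2 sqrt(alpha_I/N_I) R*_II^6)

Typing is done on the 2D (coordinate-free) molecule: the force fields
assign types and charges from connectivity alone, and the downstream graph
construction is explicitly 2D.
"""

from __future__ import annotations

import functools
import glob
import os
import sys


class AtomTypingError(RuntimeError):
    """A backend refused or failed to type a molecule (recorded, not fatal)."""


def _have_openbabel() -> bool:
    try:
        from openbabel import openbabel  # noqa: F401
        return True
    except Exception:
        return False


@functools.lru_cache(maxsize=1)
def _data_dir() -> str:
    """Locate Open Babel's data directory (parameter tables)."""
    env = os.environ.get("BABEL_DATADIR")
    if env and os.path.isdir(env):
        return env
    for pattern in (
        os.path.join(sys.prefix, "share", "openbabel", "*"),
        "/usr/share/openbabel/*",
        "/usr/local/share/openbabel/*",
    ):
        hits = sorted(d for d in glob.glob(pattern) if os.path.isdir(d))
        if hits:
            return hits[-1]
    raise FileNotFoundError("Open Babel data directory not found")


def _data_file(name: str) -> str:
    path = os.path.join(_data_dir(), name)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return path


@functools.lru_cache(maxsize=None)
def lj_table(forcefield: str) -> dict[str, tuple[float, float]]:
    """atom-type -> (lj_radius, lj_welldepth) for one force field."""
    ff = forcefield.lower()
    table: dict[str, tuple[float, float]] = {}
    if ff == "uff":
        with open(_data_file("UFF.prm"), encoding="latin-1") as fh:
            for line in fh:
                parts = line.split()
                if len(parts) >= 6 and parts[0] == "param":
                    table[parts[1]] = (float(parts[4]), float(parts[5]))
    elif ff == "ghemical":
        with open(_data_file("ghemical.prm"), encoding="latin-1") as fh:
            for line in fh:
                parts = line.split()
                if len(parts) >= 4 and parts[0] == "vdw":
                    table[parts[1]] = (float(parts[2]), float(parts[3]))
    elif ff == "gaff":
        in_vdw = False
        with open(_data_file("gaff.dat"), encoding="latin-1") as fh:
            for line in fh:
                if line.startswith("MOD4"):
                    in_vdw = True
                    continue
                if in_vdw:
                    parts = line.split()
                    if len(parts) < 3:
                        if table:
                            break
                        continue
                    try:
                        r, eps = float(parts[1]), float(parts[2])
                    except ValueError:
                        continue
                    table[parts[0]] = (r, eps)
    elif ff in ("mmff94", "mmff94s"):
        with open(_data_file("mmffvdw.par"), encoding="latin-1") as fh:
            for line in fh:
                parts = line.split()
                if len(parts) >= 5 and parts[0].isdigit():
                    alpha, n_i, a_i, g_i = map(float, parts[1:5])
                    r_star = a_i * alpha**0.25
                    eps = (
                        181.16 * g_i**2 * alpha**2
                        / (2.0 * (alpha / n_i) ** 0.5)
                        / r_star**6
                    )
                    table[parts[0]] = (r_star, eps)
    else:
        raise KeyError(f"no LJ table reader for force field {forcefield!r}")
    if not table:
        raise AtomTypingError(f"empty LJ table for {forcefield!r}")
    return table


@functools.lru_cache(maxsize=None)
def type_vocabulary(forcefield: str) -> tuple[str, ...]:
    """Frozen, dataset-independent atom-type label list of one force field.

    Compiled from the force field's shipped parameter table so one-hot
    widths never depend on the molecules seen.
    """
    keys = lj_table(forcefield).keys()
    ff = forcefield.lower()
    if ff in ("mmff94", "mmff94s"):
        return tuple(sorted(keys, key=int))
    return tuple(sorted(keys))


def obmol_from_rdkit(mol):
    """Build an OBMol from an RDKit mol, preserving atom order exactly.

    Atom i of the RDKit molecule is atom i+1 of the OBMol, so per-atom
    backend output stays aligned with the graph's node_order.
    """
    from openbabel import openbabel as ob
    from rdkit import Chem

    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    obmol = ob.OBMol()
    obmol.BeginModify()
    for atom in kek.GetAtoms():
        a = obmol.NewAtom()
        a.SetAtomicNum(atom.GetAtomicNum())
        a.SetFormalCharge(atom.GetFormalCharge())
    for bond in kek.GetBonds():
        order = int(round(bond.GetBondTypeAsDouble()))
        obmol.AddBond(bond.GetBeginAtomIdx() + 1, bond.GetEndAtomIdx() + 1, order)
    obmol.EndModify()
    obmol.SetTotalCharge(Chem.GetFormalCharge(kek))
    return obmol


def openbabel_atom_parameters(mol, forcefield: str):
    """Per-atom (atom_type, charge, lj_radius, lj_welldepth) via Open Babel.

    Raises :class:`AtomTypingError` when the force field cannot set up the
    molecule or an assigned type has no LJ entry.
    """
    if not _have_openbabel():
        raise AtomTypingError(
            "Open Babel python bindings are required for force field "
            f"{forcefield!r} (providers mmff94/uff/gaff/ghemical)"
        )
    from openbabel import openbabel as ob

    obmol = obmol_from_rdkit(mol)
    ff = ob.OBForceField.FindForceField(forcefield)
    if ff is None:
        raise KeyError(f"Open Babel force field {forcefield!r} not found")
    if not ff.Setup(obmol):
        raise AtomTypingError(f"{forcefield}: Setup failed (untypeable molecule)")
    if not ff.GetAtomTypes(obmol):
        raise AtomTypingError(f"{forcefield}: atom typing failed")
    if not ff.GetPartialCharges(obmol):
        raise AtomTypingError(f"{forcefield}: partial-charge assignment failed")

    table = lj_table(forcefield)
    out = []
    for atom in ob.OBMolAtomIter(obmol):
        tdata = atom.GetData("FFAtomType")
        cdata = atom.GetData("FFPartialCharge")
        if tdata is None or cdata is None:
            raise AtomTypingError(f"{forcefield}: missing per-atom data")
        atype = ob.toPairData(tdata).GetValue()
        charge = float(ob.toPairData(cdata).GetValue())
        if atype not in table:
            raise AtomTypingError(
                f"{forcefield}: no LJ parameters for atom type {atype!r}"
            )
        r, eps = table[atype]
        out.append((atype, charge, r, eps))
    return out


# Element-level LJ constants (vdW distance x_I in Angstrom, well depth D_I in
# kcal/mol) from the published UFF element table; used by the self-contained
# fallback provider that needs no typing backend.
ELEMENT_LJ: dict[str, tuple[float, float]] = {
    "H": (2.886, 0.044),
    "C": (3.851, 0.105),
    "N": (3.660, 0.069),
    "O": (3.500, 0.060),
    "F": (3.364, 0.050),
    "P": (4.147, 0.305),
    "S": (4.035, 0.274),
    "Cl": (3.947, 0.227),
    "Br": (4.189, 0.251),
    "I": (4.500, 0.339),
}
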