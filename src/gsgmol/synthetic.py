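"""Synthetic molecule-like fixtures with planted, known structure.

Generates chemically valid SMILES from a small grammar of valence-
respecting fragments (alkyl chains and branches, ethers, amines, amides,
thioethers, aryl rings, halogenated carbons, and an explicit sulfonyl
connector), so that force-field typing backends can process every output.
Fragments begin and end on carbon, which keeps heteroatoms separated when
fragments are concatenated.  Ground truth is recorded at construction
time — which molecules carry a planted S(=O)(=O) group, each molecule's
element set, and which records are rewritten-SMILES duplicates — so
curation and dedup logic can be checked against exact planted memberships
rather than against the toolkit being tested.

Regression targets are linear in the zeroth-order (q=1) scattering
moments with Gaussian noise of known standard deviation, giving the
predictor a recoverable signal with a known noise floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from rdkit import Chem

from .featurize import GSGFeaturizer
from .scattering import GSGConfig

# fragment -> heteroatoms it introduces (C and H are always present)
_PLAIN_FRAGMENTS = ("C", "CC", "CCC", "C(C)C", "c1ccccc1")
_HETERO_FRAGMENTS = {
    "N": ("CNC", "C(=O)NC"),
    "O": ("COC", "C(=O)C"),
    "S": ("CSC",),
    "F": ("C(F)C",),
    "Cl": ("C(Cl)C",),
    "Br": ("C(Br)C",),
}
# every element a fragment introduces (the amide brings O as well as N)
_FRAGMENT_ELEMENTS = {
    "CNC": {"N"}, "C(=O)NC": {"N", "O"},
    "COC": {"O"}, "C(=O)C": {"O"},
    "CSC": {"S"},
    "C(F)C": {"F"}, "C(Cl)C": {"Cl"}, "C(Br)C": {"Br"},
}
_SULFONYL_FRAGMENT = "CS(=O)(=O)C"  # planted only; introduces S and O


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``element_palette`` maps heteroatom symbols to the probability that a
    molecule receives at least one fragment containing that element.
    ``noise_sd`` and ``signal_sd`` (both in log P units) set the regression
    target's noise floor and signal spread.
    """

    n_molecules: int = 100
    size_range: tuple[int, int] = (3, 8)  # fragments per molecule
    element_palette: dict = field(
        default_factory=lambda: {"N": 0.7, "O": 0.7, "S": 0.4}
    )
    plant_sulfonyl_fraction: float = 0.3
    duplicate_fraction: float = 0.0
    noise_sd: float = 0.3
    signal_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("plant_sulfonyl_fraction", "duplicate_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.size_range[0] < 1:
            raise ValueError("size_range minimum must be >= 1")
        bad = set(self.element_palette) - set(_HETERO_FRAGMENTS)
        if bad:
            raise ValueError(f"unsupported palette elements: {sorted(bad)}")


@dataclass(frozen=True)
class SyntheticMolecule:
    """One generated record with its planted ground truth."""

    mol_id: str
    smiles: str
    logp: float
    planted_sulfonyl: bool
    element_set: frozenset[str]
    is_duplicate: bool
    parent_id: str | None = None


def _build_smiles(rng, spec: FixtureSpec, plant_sulfonyl: bool) -> tuple[str, frozenset]:
    n_frag = int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
    elements = {"C", "H"}
    pool = list(_PLAIN_FRAGMENTS)
    for elem, prob in sorted(spec.element_palette.items()):
        if rng.random() < prob:
            pool.extend(_HETERO_FRAGMENTS[elem])
    pieces = [pool[int(rng.integers(len(pool)))] for _ in range(n_frag)]
    if plant_sulfonyl:
        pieces.insert(int(rng.integers(len(pieces) + 1)), _SULFONYL_FRAGMENT)
    smiles = "C" + "".join(pieces)
    for piece in pieces:
        elements.update(_FRAGMENT_ELEMENTS.get(piece, ()))
    if plant_sulfonyl:
        elements.update({"S", "O"})
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, f"generator produced invalid SMILES {smiles!r}"
    return Chem.MolToSmiles(mol), frozenset(elements)


def generate_molecules(spec: FixtureSpec) -> list[SyntheticMolecule]:
    """Generate SMILES with planted sulfonyl / element / duplicate flags.

    Exactly ``round(duplicate_fraction * n_molecules)`` records are
    rewritten-SMILES duplicates of earlier records, and exactly
    ``round(plant_sulfonyl_fraction * n_unique)`` unique molecules carry
    the sulfonyl group.  Fixed seed => identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n_dup = int(round(spec.duplicate_fraction * spec.n_molecules))
    n_unique = spec.n_molecules - n_dup
    if n_unique < 1:
        raise ValueError("duplicate_fraction leaves no unique molecules")
    n_sulf = int(round(spec.plant_sulfonyl_fraction * n_unique))
    sulf_idx = set(rng.choice(n_unique, size=n_sulf, replace=False).tolist())

    seen: set[str] = set()
    uniques: list[SyntheticMolecule] = []
    i = 0
    attempts = 0
    while len(uniques) < n_unique:
        attempts += 1
        if attempts > 50 * n_unique:
            raise RuntimeError("fixture generation failed to find enough "
                               "distinct molecules; widen size_range")
        smi, elems = _build_smiles(rng, spec, plant_sulfonyl=i in sulf_idx)
        if smi in seen:
            continue  # accidental duplicate of an earlier unique; resample
        seen.add(smi)
        uniques.append(SyntheticMolecule(
            mol_id=f"syn{i:05d}",
            smiles=smi,
            logp=float(rng.normal(2.0, 1.5)),
            planted_sulfonyl=i in sulf_idx,
            element_set=elems,
            is_duplicate=False,
        ))
        i += 1

    records = list(uniques)
    if n_dup:
        parents = rng.choice(n_unique, size=n_dup, replace=True)
        for k, pidx in enumerate(parents):
            parent = uniques[int(pidx)]
            mol = Chem.MolFromSmiles(parent.smiles)
            rewritten = Chem.MolToRandomSmilesVect(
                mol, 1, randomSeed=int(rng.integers(1, 2**31 - 1))
            )[0]
            records.append(SyntheticMolecule(
                mol_id=f"dup{k:05d}",
                smiles=rewritten,
                logp=parent.logp,
                planted_sulfonyl=parent.planted_sulfonyl,
                element_set=parent.element_set,
                is_duplicate=True,
                parent_id=parent.mol_id,
            ))
    return records


def generate_regression(spec: FixtureSpec, gsg_config: GSGConfig | None = None,
                        provider: str = "fallback"):
    """Features + targets linear in zeroth-order moments with known noise.

    Returns ``(X, y, info)`` where ``info`` records the (rescaled) channel
    weights, the noise and signal standard deviations, the SMILES used and
    the feature names.  The weights act on the q=1 zeroth-order moment
    columns and are rescaled once so the noiseless signal has standard
    deviation ``spec.signal_sd`` over the generated set.
    """
    if gsg_config is None:
        gsg_config = GSGConfig()
    rng = np.random.default_rng(spec.seed + 1)
    mols = [m for m in generate_molecules(spec) if not m.is_duplicate]
    smiles = [m.smiles for m in mols]
    tr = GSGFeaturizer(provider=provider, J=gsg_config.J, Q=gsg_config.Q,
                       orders=gsg_config.orders, on_error="raise").fit()
    X = tr.transform(smiles)
    names = list(tr.feature_names_)
    s0_cols = [i for i, nm in enumerate(names) if nm.endswith("|S0|q1")]
    w = rng.normal(size=len(s0_cols))
    signal = X[:, s0_cols] @ w
    sd = signal.std()
    if sd == 0:
        raise RuntimeError("degenerate fixture: zero signal variance")
    w *= spec.signal_sd / sd
    signal = X[:, s0_cols] @ w
    y = signal + rng.normal(0.0, spec.noise_sd, size=len(signal))
    info = {
        "weights": {names[c]: float(wc) for c, wc in zip(s0_cols, w)},
        "noise_sd": spec.noise_sd,
        "signal_sd": spec.signal_sd,
        "smiles": smiles,
        "feature_names": names,
        "s0_columns": s0_cols,
    }
    return X, y, info


def write_fixtures(records, out_dir, spec: FixtureSpec | None = None) -> None:
    """Write fixtures as .smi + a ground-truth/spec JSON sidecar."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "molecules.smi"), "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles} {rec.mol_id}\n")
    truth = {
        rec.mol_id: {
            "smiles": rec.smiles,
            "logp": rec.logp,
            "planted_sulfonyl": rec.planted_sulfonyl,
            "element_set": sorted(rec.element_set),
            "is_duplicate": rec.is_duplicate,
            "parent_id": rec.parent_id,
        }
        for rec in records
    }
    sidecar = {"ground_truth": truth}
    if spec is not None:
        sidecar["spec"] = asdict(spec)
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
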