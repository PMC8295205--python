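"""Dataset curation: deduplication and structure-based filters.

Reproduces the subsetting scheme used to assemble sulfonyl-focused log P
training sets: canonical-SMILES deduplication, an exact element-set filter
(the molecule must contain *all* required elements and *no* others), a
SMARTS substructure filter (default: the sulfonyl moiety S(=O)(=O)), and an
inclusive molecular-weight window.  The four classic presets:

* DB1 — no criteria (everything that parses and types),
* DB2 — element set exactly {C, N, O, S, H},
* DB3 — contains a sulfonyl group,
* DB4 — both,

plus ``S7_TEST``: sulfonyl + exact elements + the molecular-weight window
of the SAMPL7 challenge molecules (227.285–365.476 Da, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from .graphs import MolecularGraph, SmilesParseError, parse_smiles

SULFONYL_SMARTS = "S(=O)(=O)"
SAMPL7_ELEMENTS = frozenset({"C", "N", "O", "S", "H"})
SAMPL7_MW_WINDOW = (227.285, 365.476)


@dataclass(frozen=True)
class FilterSpec:
    """Conjunction of curation criteria; unset criteria are skipped.

    An empty spec is legal and keeps everything (the DB1 preset).
    """

    required_elements: frozenset[str] | None = None
    substructure: str | None = None
    mw_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.required_elements is not None:
            object.__setattr__(
                self, "required_elements", frozenset(self.required_elements)
            )
            if not self.required_elements:
                raise ValueError("required_elements must be non-empty when set")
        if self.mw_range is not None:
            low, high = self.mw_range
            if not low < high:
                raise ValueError("mw_range must satisfy low < high")
        if self.substructure is not None:
            if Chem.MolFromSmarts(self.substructure) is None:
                raise ValueError(f"invalid SMARTS: {self.substructure!r}")


PRESETS: dict[str, FilterSpec] = {
    "DB1": FilterSpec(),
    "DB2": FilterSpec(required_elements=SAMPL7_ELEMENTS),
    "DB3": FilterSpec(substructure=SULFONYL_SMARTS),
    "DB4": FilterSpec(required_elements=SAMPL7_ELEMENTS,
                      substructure=SULFONYL_SMARTS),
    "S7_TEST": FilterSpec(required_elements=SAMPL7_ELEMENTS,
                          substructure=SULFONYL_SMARTS,
                          mw_range=SAMPL7_MW_WINDOW),
}


@dataclass
class CurationReport:
    """Bookkeeping for one curation pass; every input record is accounted
    for: n_kept + rejections + duplicates + parse failures + typing
    failures = n_input."""

    n_input: int = 0
    n_after_dedup: int = 0
    n_failed_typing: int = 0
    n_kept: int = 0
    rejection_log: dict = field(default_factory=dict)
    rejection_counts: dict = field(default_factory=dict)
    duplicate_conflicts: dict = field(default_factory=dict)

    def reject(self, key, reason: str):
        self.rejection_log[key] = reason
        self.rejection_counts[reason] = self.rejection_counts.get(reason, 0) + 1

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_dedup": self.n_after_dedup,
            "n_failed_typing": self.n_failed_typing,
            "n_kept": self.n_kept,
            "rejection_counts": self.rejection_counts,
            "duplicate_conflicts": {
                k: v for k, v in self.duplicate_conflicts.items()
            },
        }


def deduplicate(records) -> tuple[list[tuple[str, float]], CurationReport]:
    """Collapse records to one per canonical SMILES (first occurrence wins).

    ``records`` is an iterable of (smiles, logp).  Unparseable entries are
    logged and dropped, never fatal.  Conflicting logP values among
    duplicates are logged with the spread of the discarded values.
    """
    report = CurationReport()
    kept: dict[str, float] = {}
    for i, (smi, logp) in enumerate(records):
        report.n_input += 1
        try:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise SmilesParseError(smi)
            can = Chem.MolToSmiles(mol)
        except Exception:
            report.reject((i, smi), "parse_error")
            continue
        if can in kept:
            report.reject((i, smi), "duplicate")
            if logp is not None and kept[can] is not None and logp != kept[can]:
                report.duplicate_conflicts.setdefault(can, []).append(
                    float(logp)
                )
        else:
            kept[can] = logp
    report.n_after_dedup = len(kept)
    report.n_kept = len(kept)
    return list(kept.items()), report


def element_filter(graph: MolecularGraph, required) -> bool:
    """True iff the molecule's element set equals ``required`` *exactly* —
    molecules with extra elements or missing any required one fail."""
    required = frozenset(required)
    if not required:
        raise ValueError("required element set must be non-empty")
    return graph.element_set == required


def substructure_filter(graph: MolecularGraph, smarts: str = SULFONYL_SMARTS) -> bool:
    """True iff the SMARTS pattern matches the molecule at least once."""
    pattern = Chem.MolFromSmarts(smarts)
    if pattern is None:
        raise ValueError(f"invalid SMARTS: {smarts!r}")
    return graph.mol.HasSubstructMatch(pattern)


def mw_window_filter(graph: MolecularGraph, low: float, high: float) -> bool:
    """True iff low <= molecular weight <= high (both bounds inclusive)."""
    if not low < high:
        raise ValueError("mw window must satisfy low < high")
    return low <= graph.mol_weight <= high


def matches_spec(graph: MolecularGraph, spec: FilterSpec) -> tuple[bool, str | None]:
    """Apply a FilterSpec conjunctively; returns (kept, first failed criterion)."""
    if spec.required_elements is not None and not element_filter(
        graph, spec.required_elements
    ):
        return False, "element_set"
    if spec.substructure is not None and not substructure_filter(
        graph, spec.substructure
    ):
        return False, "substructure"
    if spec.mw_range is not None and not mw_window_filter(
        graph, *spec.mw_range
    ):
        return False, "mol_weight"
    return True, None


def build_subset(records, spec: FilterSpec | str,
                 deduplicated: bool = False):
    """Curate (smiles, logp) records under a FilterSpec or preset name.

    Deduplicates first (unless ``deduplicated=True``), then applies the
    element / substructure / molecular-weight criteria conjunctively.
    Returns (kept records, :class:`CurationReport`).
    """
    if isinstance(spec, str):
        spec = PRESETS[spec.upper() if spec.lower().startswith("db") else spec]
    if deduplicated:
        records = list(records)
        report = CurationReport(n_input=len(records),
                                n_after_dedup=len(records))
    else:
        records, report = deduplicate(records)
        report.n_kept = 0
    kept = []
    for smi, logp in records:
        try:
            graph = parse_smiles(smi, add_hydrogens=True,
                                 on_disconnected="reject")
        except Exception as exc:
            report.reject(smi, f"parse_error:{type(exc).__name__}")
            continue
        ok, why = matches_spec(graph, spec)
        if ok:
            kept.append((graph.smiles_canonical, logp))
        else:
            report.reject(smi, why)
    report.n_kept = len(kept)
    return kept, report
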