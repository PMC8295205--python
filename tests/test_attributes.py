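"""Atom attributes: providers, vocabularies, one-hot signal encoding."""

import numpy as np
import pytest
from rdkit.Chem import AllChem

from gsgmol.attributes import (
    AtomAttributes,
    AttributeTableProvider,
    TypeVocabulary,
    assign_attributes,
    encode_signals,
    get_provider,
    load_grouping,
)
from gsgmol.forcefields import AtomTypingError, lj_table
from gsgmol.graphs import parse_smiles

PROVIDERS = ["mmff94", "uff", "gaff", "ghemical", "fallback"]


class TestProviders:
    def test_methane_fallback(self):
        g = parse_smiles("C")
        attrs = assign_attributes(g, "fallback")
        assert len(attrs) == 5
        assert sorted(a.atom_type for a in attrs) == ["C", "H", "H", "H", "H"]
        assert sum(a.charge for a in attrs) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("provider", PROVIDERS)
    def test_record_count_equals_node_count(self, provider):
        g = parse_smiles("CC(=O)NS(=O)(=O)c1ccccc1")
        attrs = assign_attributes(g, provider)
        assert len(attrs) == g.n
        for a in attrs:
            assert np.isfinite([a.charge, a.lj_radius, a.lj_welldepth]).all()

    @pytest.mark.parametrize("provider", PROVIDERS)
    def test_types_in_declared_vocabulary(self, provider):
        g = parse_smiles("CCOS(=O)(=O)N")
        vocab = get_provider(provider).vocabulary()
        for a in assign_attributes(g, provider):
            assert a.atom_type in vocab.labels

    def test_unknown_provider_is_configuration_error(self):
        with pytest.raises(KeyError):
            get_provider("cgenff-proprietary")

    def test_untypeable_molecule_raises_typed_failure(self):
        # selenium is outside the fallback element table
        g = parse_smiles("[SeH2]")
        with pytest.raises(AtomTypingError):
            assign_attributes(g, "fallback")

    def test_typing_is_deterministic(self):
        g1 = parse_smiles("CCS(=O)(=O)NC")
        g2 = parse_smiles("CCS(=O)(=O)NC")
        a1 = assign_attributes(g1, "mmff94")
        a2 = assign_attributes(g2, "mmff94")
        assert a1 == a2


class TestMMFFLJCrossCheck:
    @pytest.mark.parametrize("smiles", ["CCO", "CS(=O)(=O)N", "c1ccncc1"])
    def test_table_formula_matches_rdkit(self, smiles):
        """MMFF94 self vdW (R*_II, eps_II) from the parameter table +
        combination rules must agree with RDKit's MMFF implementation."""
        g = parse_smiles(smiles)
        attrs = assign_attributes(g, "mmff94")
        props = AllChem.MMFFGetMoleculeProperties(g.mol)
        assert props is not None
        for i, a in enumerate(attrs):
            rd_type = str(props.GetMMFFAtomType(i))
            assert rd_type == a.atom_type  # OB and RDKit agree on the type
            r_unscaled, eps_unscaled, _, _ = props.GetMMFFVdWParams(i, i)
            assert a.lj_radius == pytest.approx(r_unscaled, rel=1e-6)
            assert a.lj_welldepth == pytest.approx(eps_unscaled, rel=1e-6)


class TestEncodeSignals:
    def test_layout_width(self):
        vocab = TypeVocabulary("toy", ("a", "b", "c", "d", "e"))
        attrs = [AtomAttributes("c", 0.1, 1.0, 0.2)]
        sig = encode_signals(attrs, vocab)
        assert sig.matrix.shape == (1, 8)  # 3 scalars + 5 one-hot
        assert sig.matrix[0, :3].tolist() == [0.1, 1.0, 0.2]
        assert sig.matrix[0, 3:].sum() == 1.0

    def test_one_hot_rows_sum_to_one(self):
        g = parse_smiles("CCON")
        vocab = get_provider("fallback").vocabulary()
        sig = encode_signals(assign_attributes(g, "fallback"), vocab)
        assert np.array_equal(sig.matrix[:, 3:].sum(axis=1), np.ones(g.n))

    def test_out_of_vocabulary_is_loud(self):
        vocab = TypeVocabulary("toy", ("a", "b"))
        with pytest.raises(KeyError, match="zzz"):
            encode_signals([AtomAttributes("zzz", 0.0, 1.0, 1.0)], vocab)

    def test_degenerate_grouping_single_column(self):
        vocab = TypeVocabulary("toy", ("a", "b", "c"),
                               grouping={"a": "g", "b": "g", "c": "g"})
        attrs = [AtomAttributes(t, 0.0, 1.0, 1.0) for t in "abc"]
        sig = encode_signals(attrs, vocab)
        assert sig.matrix.shape == (3, 4)
        assert np.array_equal(sig.matrix[:, 3], np.ones(3))

    def test_re_encoding_bit_identical(self):
        g = parse_smiles("CCS(=O)(=O)O")
        vocab = get_provider("mmff94").vocabulary()
        m1 = encode_signals(assign_attributes(g, "mmff94"), vocab).matrix
        m2 = encode_signals(assign_attributes(g, "mmff94"), vocab).matrix
        assert np.array_equal(m1, m2)


class TestVocabulary:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            TypeVocabulary("toy", ("a", "a"))

    def test_grouping_must_be_total(self):
        with pytest.raises(ValueError):
            TypeVocabulary("toy", ("a", "b"), grouping={"a": "g"})

    def test_36_group_mapping_gives_39_channels(self, tmp_path):
        # user-supplied coarsening file: native types -> 36 groups
        native = [str(t) for t in range(1, 100)]
        path = tmp_path / "groups.csv"
        with open(path, "w") as fh:
            fh.write("atom_type,group\n")
            for i, t in enumerate(native):
                fh.write(f"{t},G{i % 36}\n")
        grouping = load_grouping(path)
        vocab = TypeVocabulary("mmff94", tuple(native), grouping)
        assert len(vocab.effective_labels) == 36
        attrs = [AtomAttributes("1", 0.0, 1.0, 1.0)]
        assert encode_signals(attrs, vocab).matrix.shape == (1, 39)

    def test_builtin_vocabularies_frozen_and_nonempty(self):
        for provider in PROVIDERS:
            v1 = get_provider(provider).vocabulary()
            v2 = get_provider(provider).vocabulary()
            assert v1.labels == v2.labels
            assert len(v1.labels) > 5


class TestAttributeTable:
    def test_round_trip(self):
        import pandas as pd

        g = parse_smiles("CO", add_hydrogens=False)
        table = pd.DataFrame({
            "mol_id": ["m1", "m1"],
            "atom_index": [0, 1],
            "atom_type": ["CT", "OH"],
            "charge": [0.1, -0.5],
            "lj_radius": [1.9, 1.7],
            "lj_welldepth": [0.1, 0.2],
        })
        provider = AttributeTableProvider(table)
        attrs = provider.assign(g, mol_id="m1")
        assert attrs[1] == AtomAttributes("OH", -0.5, 1.7, 0.2)

    def test_row_count_mismatch(self):
        import pandas as pd

        g = parse_smiles("CCO", add_hydrogens=False)
        table = pd.DataFrame({
            "mol_id": ["m1"], "atom_index": [0], "atom_type": ["CT"],
            "charge": [0.0], "lj_radius": [1.0], "lj_welldepth": [1.0],
        })
        with pytest.raises(AtomTypingError):
            AttributeTableProvider(table).assign(g, mol_id="m1")


def test_lj_tables_physical():
    for ff in ["mmff94", "uff", "gaff", "ghemical"]:
        table = lj_table(ff)
        radii = np.array([r for r, _ in table.values()])
        depths = np.array([e for _, e in table.values()])
        # GAFF tabulates r = 0 for some hydrogens (e.g. water H), so the
        # radii bound is nonnegative rather than strictly positive
        assert (radii >= 0).all()
        assert (depths >= 0).all()
        assert radii.max() > 1.0
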