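import pytest
from hypothesis import given, settings, strategies as st

from cass import fixtures as fx
from cass.molfile_io import (
    MolfileError,
    ValenceError,
    add_implicit_hydrogens,
    molecular_formula,
    normalize_formula,
    parse_element_token,
    parse_molfile,
    parse_sdf,
    serialize_molfile,
    serialize_sdf,
)

ACETONE_MOLFILE = """acetone

  comment
  4  3  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0
    0.0000    0.0000    0.0000 O   0  0  0  0  0
  1  2  1  0
  2  3  1  0
  2  4  2  0
M  END
"""


class TestElementTokens:
    @pytest.mark.parametrize(
        "token, mode, elements, contextual",
        [
            ("H|O|N", "any_of", {"H", "O", "N"}, False),
            ("!H", "not_of", {"H"}, False),
            ("C*", "exact", {"C"}, True),
            ("C", "exact", {"C"}, False),
            ("F|Cl|Br|I", "any_of", {"F", "Cl", "Br", "I"}, False),
            ("!H*", "not_of", {"H"}, True),
            ("A", "wildcard", set(), False),
            ("A*", "wildcard", set(), True),
        ],
    )
    def test_grammar(self, token, mode, elements, contextual):
        spec = parse_element_token(token)
        assert spec.mode == mode
        assert set(spec.elements) == elements
        assert spec.contextual is contextual

    @pytest.mark.parametrize("token", ["", "!", "|O", "O|", "!H|O", "*"])
    def test_malformed_tokens_rejected(self, token):
        with pytest.raises(MolfileError):
            parse_element_token(token)

    def test_matching_semantics(self):
        assert parse_element_token("H|O|N").matches("O")
        assert not parse_element_token("H|O|N").matches("C")
        assert parse_element_token("!H").matches("C")
        assert not parse_element_token("!H").matches("H")
        assert parse_element_token("A").matches("Se")


class TestParseMolfile:
    def test_acetone_record(self):
        mol = parse_molfile(ACETONE_MOLFILE)
        assert mol.n_atoms == 4
        assert mol.n_bonds == 3
        assert [a.symbol for a in mol.atoms] == ["C", "C", "C", "O"]
        assert mol.bonds[2].order == 2

    def test_bond_to_missing_atom_is_error(self):
        bad = ACETONE_MOLFILE.replace("  1  2  1  0", "  0  2  1  0")
        with pytest.raises(MolfileError):
            parse_molfile(bad)

    def test_aromatic_bond_rejected_with_kekule_hint(self):
        bad = ACETONE_MOLFILE.replace("  2  4  2  0", "  2  4  4  0")
        with pytest.raises(MolfileError, match="Kekulé"):
            parse_molfile(bad)

    def test_extended_symbol_rejected_in_standard_dialect(self):
        bad = ACETONE_MOLFILE.replace(" O   0", " !H  0")
        with pytest.raises(MolfileError):
            parse_molfile(bad, dialect="standard")
        mol = parse_molfile(bad, dialect="extended")
        assert mol.atoms[3].spec.mode == "not_of"

    def test_truncated_record_is_error(self):
        with pytest.raises(MolfileError):
            parse_molfile("\n".join(ACETONE_MOLFILE.splitlines()[:6]))

    def test_chg_property_line_wins_over_atom_block(self):
        text = ACETONE_MOLFILE.replace(
            "M  END", "M  CHG  1   4  -1\nM  END"
        )
        mol = parse_molfile(text)
        assert mol.atoms[3].formal_charge == -1


class TestParseSdf:
    def test_two_records_in_order(self):
        two = ACETONE_MOLFILE + "$$$$\n" + ACETONE_MOLFILE.replace(
            "acetone", "again"
        ) + "$$$$\n"
        mols = parse_sdf(two)
        assert [m.name for m in mols] == ["acetone", "again"]

    def test_empty_input(self):
        assert parse_sdf("") == []

    def test_malformed_record_reported_with_ordinal(self):
        bad = ACETONE_MOLFILE + "$$$$\nnot a molfile\n$$$$\n"
        with pytest.raises(MolfileError, match="record 2"):
            parse_sdf(bad, strict=True)
        assert len(parse_sdf(bad, strict=False)) == 1

    def test_id_field_captured(self):
        rec = ACETONE_MOLFILE + "> <ID>\nC00207\n\n$$$$\n"
        (mol,) = parse_sdf(rec)
        assert mol.id == "C00207"


class TestImplicitHydrogens:
    def test_acetone_completion(self):
        mol = add_implicit_hydrogens(parse_molfile(ACETONE_MOLFILE))
        assert mol.n_atoms == 10
        assert mol.n_bonds == 9
        assert molecular_formula(mol) == "C3H6O"

    def test_idempotent(self):
        once = add_implicit_hydrogens(parse_molfile(ACETONE_MOLFILE))
        twice = add_implicit_hydrogens(once)
        assert twice.n_atoms == once.n_atoms
        assert twice.n_bonds == once.n_bonds

    def test_overbonded_atom_raises_valence_error(self):
        text = ACETONE_MOLFILE.replace("  2  3  1  0", "  2  3  3  0")
        with pytest.raises(ValenceError, match="atom 2"):
            add_implicit_hydrogens(parse_molfile(text))

    def test_charge_shifts_target_valence(self):
        # Methylammonium: N+ takes four bonds, three of them new hydrogens.
        text = (
            "methylammonium\n\n\n  2  1  0  0  0  0  0  0  0  0999 V2000\n"
            "    0.0 0.0 0.0 C   0  0\n"
            "    0.0 0.0 0.0 N   0  0\n"
            "  1  2  1  0\n"
            "M  CHG  1   2   1\nM  END\n"
        )
        mol = add_implicit_hydrogens(parse_molfile(text))
        assert molecular_formula(mol) == "CH6N"

    @pytest.mark.parametrize("name", sorted(fx.COMPOUND_REGISTRY))
    def test_registry_compounds_reach_literature_formula(self, name):
        spec = fx.COMPOUND_REGISTRY[name]
        mol = fx.build_compound(name)
        assert molecular_formula(mol) == spec.expected_formula
        assert (mol.n_atoms, mol.n_bonds) == (
            spec.expected_atoms, spec.expected_bonds
        )

    @pytest.mark.parametrize("name", sorted(fx.COMPOUND_REGISTRY))
    def test_bond_count_equals_atoms_minus_one_plus_rings(self, name):
        import networkx as nx

        from tests.conftest import to_networkx

        mol = fx.build_compound(name)
        g = to_networkx(mol)
        assert nx.is_connected(g)
        rings = mol.n_bonds - mol.n_atoms + 1
        assert rings >= 0
        assert len(nx.cycle_basis(g)) == rings


class TestFormula:
    def test_hill_order_and_explicit_ones(self):
        mol = fx.build_compound("glycerol")
        assert molecular_formula(mol) == "C3H8O3"
        acetone = fx.build_compound("acetone")
        assert molecular_formula(acetone, explicit_ones=True) == "C3H6O1"

    def test_query_has_no_formula(self, groups):
        with pytest.raises(MolfileError):
            molecular_formula(groups["carboxylic acid"].query)

    def test_normalization_bridges_renderings(self):
        assert normalize_formula("C3H6O") == normalize_formula("C3H6O1")


class TestRoundTrip:
    @pytest.mark.parametrize("name", sorted(fx.COMPOUND_REGISTRY))
    def test_compound_round_trip(self, name):
        mol = fx.build_compound(name)
        back = parse_molfile(serialize_molfile(mol), dialect="standard")
        assert [a.symbol for a in back.atoms] == [a.symbol for a in mol.atoms]
        assert sorted((b.key(), b.order) for b in back.bonds) == sorted(
            (b.key(), b.order) for b in mol.bonds
        )

    def test_query_round_trip_preserves_specs(self, groups):
        q = groups["carboxylic acid"].query
        back = parse_molfile(
            serialize_molfile(q, dialect="extended"), dialect="extended"
        )
        assert [a.spec for a in back.atoms] == [a.spec for a in q.atoms]

    def test_sdf_round_trip(self):
        mols = [fx.build_compound(n, mol_id=f"X{i}")
                for i, n in enumerate(["acetone", "ethanol"])]
        back = parse_sdf(serialize_sdf(mols))
        assert [m.id for m in back] == ["X0", "X1"]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 10))
    def test_random_molecule_round_trip(self, seed, n):
        mol = fx.random_molecule(seed, n)
        back = parse_molfile(serialize_molfile(mol), dialect="standard")
        assert [a.symbol for a in back.atoms] == [a.symbol for a in mol.atoms]
        assert sorted(b.key() + (b.order,) for b in back.bonds) == sorted(
            b.key() + (b.order,) for b in mol.bonds
        )
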