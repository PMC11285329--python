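"""Mass arithmetic, adduct algebra and structure-consistency checks.

Monoisotopic/average masses are cross-checked against an independent
oracle (direct summation over :mod:`pyteomics.mass` isotope data), and
structure masses against RDKit's own descriptors, so the package's element
tables and the toolkit never vouch for themselves.
"""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from speclean import chem

ADENINE_SMILES = "C1=NC2=NC=NC(=C2N1)N"


# --- independent mass oracle -------------------------------------------------


def oracle_monoisotopic(formula_text: str) -> float:
    """Brute-force summation over the pyteomics isotope table."""
    from pyteomics.mass import nist_mass

    total = 0.0
    for symbol, count in chem.parse_formula(formula_text).items():
        isotopes = nist_mass[symbol]
        best = max((k for k in isotopes if k != 0), key=lambda k: isotopes[k][1])
        total += count * isotopes[best][0]
    return total


TEST_FORMULAS = [
    "H2O", "CO2", "CH4", "C6H12O6", "C8H10N4O2", "C5H5N5", "C2H5OH",
    "NaCl", "KBr", "H2SO4", "H3PO4", "C27H46O", "C10H16N5O13P3",
    "C37H67NO13", "FeS", "CaCO3", "MgSO4", "SiO2", "C6H5I", "CHCl3",
    "C19H19N7O6", "LiAlH4", "CuSO4", "C2F6",
]


class TestFormulas:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
            ("H2O", {"H": 2, "O": 1}),
            ("NaCl", {"Na": 1, "Cl": 1}),
            ("CHCl3", {"C": 1, "H": 1, "Cl": 3}),
        ],
    )
    def test_parse(self, text, expected):
        assert chem.parse_formula(text) == expected

    @pytest.mark.parametrize("bad", ["C6H12O6X", "", "12C", "C0", "(CH3)2", "Xx"])
    def test_parse_errors(self, bad):
        with pytest.raises(chem.FormulaError):
            chem.parse_formula(bad)

    def test_carbon_is_exactly_twelve(self):
        assert chem.monoisotopic_mass({"C": 1}) == 12.0

    @pytest.mark.parametrize(
        "formula,expected,tol",
        [
            ({"H": 2, "O": 1}, 18.010565, 1e-4),
            ({"C": 6, "H": 12, "O": 6}, 180.063388, 1e-4),
        ],
    )
    def test_monoisotopic_reference_values(self, formula, expected, tol):
        assert chem.monoisotopic_mass(formula) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize(
        "formula,expected,tol",
        [
            ({"C": 6, "H": 12, "O": 6}, 180.156, 0.01),
            ({"C": 1}, 12.011, 0.001),
            ({"H": 1}, 1.008, 0.001),
        ],
    )
    def test_average_reference_values(self, formula, expected, tol):
        assert chem.average_mass(formula) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("text", TEST_FORMULAS)
    def test_monoisotopic_matches_independent_oracle(self, text):
        ours = chem.monoisotopic_mass(chem.parse_formula(text))
        assert ours == pytest.approx(oracle_monoisotopic(text), abs=1e-4)


class TestAdducts:
    def test_protonation(self):
        adduct = chem.parse_adduct("M+H")
        assert adduct.name == "[M+H]+"
        assert adduct.charge == 1 and adduct.multiplier == 1
        assert adduct.mass_shift == pytest.approx(1.007276, abs=1e-5)

    def test_deprotonation_with_unicode_minus(self):
        adduct = chem.parse_adduct("[M−H]−")
        assert adduct.charge == -1
        assert adduct.mass_shift == pytest.approx(-1.007276, abs=1e-5)

    def test_sodiated_dimer(self):
        adduct = chem.parse_adduct("[2M+Na]+")
        assert adduct.multiplier == 2 and adduct.charge == 1
        # Na monoisotopic minus one electron
        assert adduct.mass_shift == pytest.approx(22.98922, abs=1e-4)

    def test_doubly_charged(self):
        adduct = chem.parse_adduct("[M+2H]2+")
        assert adduct.charge == 2
        assert adduct.mass_shift == pytest.approx(2 * 1.007276, abs=1e-5)

    @pytest.mark.parametrize("bad", ["not_a_smiles", "", "H+", "[M+Xx]+", "M+H2O"])
    def test_unparseable_raises(self, bad):
        with pytest.raises(chem.AdductParseError):
            chem.parse_adduct(bad)

    def test_unknown_but_grammatical_gets_computed_shift(self):
        adduct = chem.parse_adduct("[M+C6H12O6+H]+")  # glucose cluster ion
        expected = 180.063388 + 1.007276
        assert adduct.mass_shift == pytest.approx(expected, abs=1e-4)

    def test_canonicalization_round_trip_for_all_table_entries(self):
        for adduct in chem.known_adducts():
            assert chem.parse_adduct(adduct.name) == adduct

    def test_surface_form_tolerance(self):
        for text in ["[M+H]1+", "M +H", "[m+h]+", "M+H"]:
            assert chem.parse_adduct(text).name == "[M+H]+"

    def test_ionmode_follows_charge_sign(self):
        assert chem.parse_adduct("[M+Cl]-").ionmode == "negative"
        assert chem.parse_adduct("[M+NH4]+").ionmode == "positive"


class TestAdductAlgebra:
    def test_glucose_protonated(self):
        adduct = chem.parse_adduct("[M+H]+")
        parent = chem.parent_mass_from_precursor(181.070664, adduct)
        assert parent == pytest.approx(180.063388, abs=1e-5)

    def test_forward_then_inverse_doubly_charged(self):
        adduct = chem.parse_adduct("[M+2H]2+")
        precursor = chem.precursor_from_parent(178.062887, adduct)
        assert precursor == pytest.approx(90.038720, abs=1e-4)
        assert chem.parent_mass_from_precursor(precursor, adduct) == pytest.approx(
            178.062887, abs=1e-6
        )

    def test_nonsensical_combination_rejected(self):
        with pytest.raises(ValueError):
            chem.parent_mass_from_precursor(10.0, chem.parse_adduct("[M+Na]+"))

    @given(st.floats(min_value=50, max_value=2000))
    def test_round_trip_property_over_all_adducts(self, parent):
        for adduct in chem.known_adducts():
            precursor = chem.precursor_from_parent(parent, adduct)
            assert chem.parent_mass_from_precursor(precursor, adduct) == pytest.approx(
                parent, abs=1e-6
            )


class TestStructures:
    def test_water_from_implicit_hydrogens(self):
        assert chem.structure_monoisotopic_mass("O") == pytest.approx(
            18.010565, abs=1e-4
        )

    def test_adenine(self):
        assert chem.structure_monoisotopic_mass(ADENINE_SMILES) == pytest.approx(
            135.054495, abs=1e-4
        )

    def test_unparseable_structure_raises(self):
        with pytest.raises(chem.StructureParseError):
            chem.structure_monoisotopic_mass("not_a_smiles")

    def test_structure_mass_matches_rdkit_descriptor(self, compound_table):
        from rdkit import Chem as RDChem
        from rdkit.Chem import Descriptors

        for entry in compound_table[:10]:
            ours = chem.structure_monoisotopic_mass(entry.smiles)
            rdkit_value = Descriptors.ExactMolWt(RDChem.MolFromSmiles(entry.smiles))
            assert ours == pytest.approx(rdkit_value, abs=1e-3)

    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("C1=NC2=NC=NC(=C2N1)N.Cl", ["C1=NC2=NC=NC(=C2N1)N", "Cl"]),
            ("CCO", ["CCO"]),
            ("[Na+].[Cl-]", ["[Na+]", "[Cl-]"]),
        ],
    )
    def test_split_components(self, smiles, expected):
        assert chem.split_components(smiles) == expected

    def test_component_additivity(self):
        combined = chem.structure_monoisotopic_mass(f"{ADENINE_SMILES}.O")
        parts = chem.structure_monoisotopic_mass(
            ADENINE_SMILES
        ) + chem.structure_monoisotopic_mass("O")
        assert combined == pytest.approx(parts, abs=1e-6)


class TestConsistency2D:
    def test_matching_smiles_and_inchi(self, compounds):
        entry = compounds["adenine"]
        assert chem.consistent_2d(
            chem.Annotation(smiles=entry.smiles, inchi=entry.inchi)
        )

    def test_full_consistent_annotation(self, compounds):
        entry = compounds["caffeine"]
        assert chem.consistent_2d(
            chem.Annotation(
                smiles=entry.smiles, inchi=entry.inchi, inchikey=entry.inchikey
            )
        )

    def test_mismatching_inchikey(self, compounds):
        assert not chem.consistent_2d(
            chem.Annotation(
                smiles=compounds["adenine"].smiles,
                inchikey=compounds["caffeine"].inchikey,
            )
        )

    def test_single_parseable_field_is_vacuously_consistent(self, compounds):
        assert chem.consistent_2d(chem.Annotation(smiles=compounds["glucose"].smiles))

    def test_unparseable_field_is_false_not_an_exception(self):
        assert not chem.consistent_2d(chem.Annotation(smiles="not_a_smiles"))

    def test_malformed_inchikey_is_false(self):
        assert not chem.consistent_2d(chem.Annotation(inchikey="TOO-SHORT"))

    def test_no_fields_raises(self):
        with pytest.raises(ValueError):
            chem.consistent_2d(chem.Annotation())
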