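"""Annotation-repair filters: evidence-gated corrections, never removals."""

import itertools

import pytest

from speclean import chem, repair
from speclean.spectrum import make_spectrum

ADENINE = "C1=NC2=NC=NC(=C2N1)N"


def spectrum(metadata, mz=(100.0, 110.0), intensities=(1.0, 2.0)):
    return make_spectrum(metadata, list(mz), list(intensities))


class TestDeriveAnnotationFromName:
    def test_accepts_mass_matching_candidate(self, resolver, compounds):
        s = spectrum({"compound_name": "adenine", "parent_mass": 135.0545})
        out = repair.derive_annotation_from_compound_name(s, resolver)
        assert out.get("smiles") == compounds["adenine"].smiles
        assert out.get("inchikey") == compounds["adenine"].inchikey
        assert chem.consistent_2d(repair.annotation_of(out))

    def test_mass_veto_blocks_wrong_candidate(self, resolver):
        s = spectrum({"compound_name": "adenine", "parent_mass": 194.08})
        assert repair.derive_annotation_from_compound_name(s, resolver) is s

    def test_present_structure_blocks_derivation(self, resolver, compounds):
        s = spectrum(
            {
                "compound_name": "adenine",
                "parent_mass": 135.0545,
                "smiles": compounds["glucose"].smiles,
            }
        )
        assert repair.derive_annotation_from_compound_name(s, resolver) is s

    def test_unresolvable_name_unchanged(self, resolver):
        s = spectrum({"compound_name": "unobtainium", "parent_mass": 135.0545})
        assert repair.derive_annotation_from_compound_name(s, resolver) is s

    def test_failing_resolver_never_removes(self):
        class Broken:
            def resolve(self, name):
                raise OSError("service down")

        s = spectrum({"compound_name": "adenine", "parent_mass": 135.0545})
        assert repair.derive_annotation_from_compound_name(s, Broken()) is s


class TestNameResolverCache:
    def test_cache_round_trip_and_short_circuit(self, tmp_path, resolver):
        calls = []

        class Counting:
            def resolve(self, name):
                calls.append(name)
                return resolver.resolve(name)

        cache_file = str(tmp_path / "names.tsv")
        cached = repair.CachedNameResolver(Counting(), cache_file)
        first = cached.resolve("adenine")
        again = cached.resolve("adenine")
        assert calls == ["adenine"] and first == again
        # a fresh instance reloads the cache file and never hits the backend
        reloaded = repair.CachedNameResolver(Counting(), cache_file)
        assert reloaded.resolve("adenine") == first
        assert calls == ["adenine"]

    def test_misses_are_cached_too(self, tmp_path, resolver):
        cache_file = str(tmp_path / "names.tsv")
        cached = repair.CachedNameResolver(resolver, cache_file)
        assert cached.resolve("unobtainium") == []
        reloaded = repair.CachedNameResolver(resolver, cache_file)
        assert reloaded.resolve("unobtainium") == []


class TestRepairSmilesOfSalts:
    def test_counterion_dropped_when_parent_matches_main_component(self):
        s = spectrum({"smiles": f"{ADENINE}.Cl", "parent_mass": 135.0545})
        out = repair.repair_smiles_of_salts(s)
        assert chem.split_components(out.get("smiles")) == [ADENINE]
        assert chem.consistent_2d(repair.annotation_of(out))

    def test_charged_component_selected(self):
        s = spectrum({"smiles": "[Na+].[Cl-]", "parent_mass": 22.9898})
        out = repair.repair_smiles_of_salts(s)
        assert out.get("smiles") == "[Na+]"

    def test_single_component_untouched(self):
        s = spectrum({"smiles": "CCO", "parent_mass": 46.0419})
        assert repair.repair_smiles_of_salts(s) is s

    def test_full_structure_match_untouched(self):
        mass = chem.structure_monoisotopic_mass(f"{ADENINE}.O")
        s = spectrum({"smiles": f"{ADENINE}.O", "parent_mass": round(mass, 4)})
        assert repair.repair_smiles_of_salts(s) is s

    def test_no_matching_subset_untouched(self):
        s = spectrum({"smiles": f"{ADENINE}.Cl", "parent_mass": 500.0})
        assert repair.repair_smiles_of_salts(s) is s

    def test_component_cap(self):
        many = ".".join(["O"] * 9)
        s = spectrum({"smiles": many, "parent_mass": 18.0106})
        assert repair.repair_smiles_of_salts(s) is s

    def test_repaired_smiles_mass_matches_parent(self, compound_table):
        for entry in compound_table[:5]:
            s = spectrum(
                {
                    "smiles": f"{entry.smiles}.Cl.O",
                    "parent_mass": round(entry.monoisotopic_mass, 4),
                }
            )
            out = repair.repair_smiles_of_salts(s)
            mass = chem.structure_monoisotopic_mass(out.get("smiles"))
            assert abs(mass - entry.monoisotopic_mass) <= repair.DEFAULT_MASS_TOLERANCE


def brute_force_salt_subsets(components, parent, tolerance, backend):
    """Independent powerset oracle for the salt subset search."""
    masses = [chem.structure_monoisotopic_mass(c, backend) for c in components]
    heavies = [chem.heavy_atom_count(backend.formula(c, "smiles")) for c in components]
    candidates = []
    n = len(components)
    for size in range(1, n):
        for indices in itertools.combinations(range(n), size):
            mass = sum(masses[i] for i in indices)
            error = abs(mass - parent)
            if error <= tolerance:
                heavy = sum(heavies[i] for i in indices)
                mask = sum(1 << i for i in indices)
                candidates.append((error, -heavy, mask))
    if not candidates:
        return None
    _, _, mask = min(candidates)
    return [components[i] for i in range(n) if mask >> i & 1]


class TestSaltSubsetOracle:
    @pytest.mark.parametrize("extras", [["Cl"], ["Cl", "O"], ["O", "O", "Br"], ["OC=O", "O", "Cl", "Br"]])
    def test_matches_powerset_brute_force(self, extras, compound_table, stub_backend):
        for entry in compound_table[:8]:
            components = [entry.smiles] + extras
            for target in (
                entry.monoisotopic_mass,
                entry.monoisotopic_mass + 18.010565,  # main + hydrate
                10_000.0,  # nothing matches
            ):
                s = spectrum(
                    {"smiles": ".".join(components), "parent_mass": round(target, 6)}
                )
                expected = brute_force_salt_subsets(
                    components, target, repair.DEFAULT_MASS_TOLERANCE, stub_backend
                )
                proposal = repair.propose_salt_component_subset(
                    s, backend=stub_backend
                )
                if expected is None:
                    assert proposal is None
                else:
                    assert proposal is not None
                    assert chem.split_components(str(proposal.changes["smiles"])) == expected


class TestRepairParentMassIsMolarMass:
    def test_molar_mass_replaced_by_monoisotopic(self, compounds):
        caffeine = compounds["caffeine"]
        s = spectrum({"smiles": caffeine.smiles, "parent_mass": 194.19})
        out = repair.repair_parent_mass_is_molar_mass(s)
        assert out.get("parent_mass") == pytest.approx(194.080376, abs=1e-4)

    def test_correct_parent_mass_untouched(self, compounds):
        s = spectrum({"smiles": compounds["caffeine"].smiles, "parent_mass": 194.0804})
        assert repair.repair_parent_mass_is_molar_mass(s) is s

    def test_unrelated_parent_mass_untouched(self, compounds):
        s = spectrum({"smiles": compounds["caffeine"].smiles, "parent_mass": 300.0})
        assert repair.repair_parent_mass_is_molar_mass(s) is s

    def test_unparseable_smiles_untouched(self):
        s = spectrum({"smiles": "not_a_smiles", "parent_mass": 194.19})
        assert repair.repair_parent_mass_is_molar_mass(s) is s


class TestRepairAdductFromSmiles:
    def test_default_proton_adduct_corrected_to_sodium(self, compounds):
        glucose = compounds["glucose"]
        precursor = chem.precursor_from_parent(
            glucose.monoisotopic_mass, chem.parse_adduct("[M+Na]+")
        )
        s = spectrum(
            {
                "smiles": glucose.smiles,
                "precursor_mz": round(precursor, 6),
                "adduct": "[M+H]+",
                "ionmode": "positive",
            }
        )
        out = repair.repair_adduct_and_parent_mass_based_on_smiles(s)
        assert out.get("adduct") == "[M+Na]+"
        assert out.get("parent_mass") == pytest.approx(180.063388, abs=1e-5)

    def test_consistent_spectrum_untouched(self, compounds):
        glucose = compounds["glucose"]
        s = spectrum(
            {
                "smiles": glucose.smiles,
                "precursor_mz": 181.070664,
                "adduct": "[M+H]+",
            }
        )
        assert repair.repair_adduct_and_parent_mass_based_on_smiles(s) is s

    def test_inexplicable_precursor_untouched(self, compounds):
        s = spectrum(
            {
                "smiles": compounds["glucose"].smiles,
                "precursor_mz": 500.0,
                "adduct": "[M+H]+",
            }
        )
        assert repair.repair_adduct_and_parent_mass_based_on_smiles(s) is s

    def test_candidates_respect_ionmode(self, compounds):
        glucose = compounds["glucose"]
        precursor = chem.precursor_from_parent(
            glucose.monoisotopic_mass, chem.parse_adduct("[M+Na]+")
        )
        s = spectrum(
            {
                "smiles": glucose.smiles,
                "precursor_mz": round(precursor, 6),
                "adduct": "[M-H]-",
                "ionmode": "negative",
            }
        )
        # the only explaining adduct is positive; a negative-mode spectrum
        # must not adopt it
        assert repair.repair_adduct_and_parent_mass_based_on_smiles(s) is s


class TestRepairNotMatchingAnnotation:
    def test_conflicting_inchi_rederived_from_mass_matching_smiles(self, compounds):
        adenine, caffeine = compounds["adenine"], compounds["caffeine"]
        s = spectrum(
            {
                "smiles": adenine.smiles,
                "inchi": caffeine.inchi,
                "inchikey": caffeine.inchikey,
                "parent_mass": 135.0545,
            }
        )
        out = repair.repair_not_matching_annotation(s)
        assert out.get("inchi") == adenine.inchi
        assert out.get("inchikey") == adenine.inchikey
        assert chem.consistent_2d(repair.annotation_of(out))

    def test_consistent_annotation_untouched(self, compounds):
        adenine = compounds["adenine"]
        s = spectrum(
            {
                "smiles": adenine.smiles,
                "inchi": adenine.inchi,
                "parent_mass": 135.0545,
            }
        )
        assert repair.repair_not_matching_annotation(s) is s

    def test_ambiguous_when_nothing_matches_parent(self, compounds):
        s = spectrum(
            {
                "smiles": compounds["adenine"].smiles,
                "inchi": compounds["caffeine"].inchi,
                "parent_mass": 500.0,
            }
        )
        assert repair.repair_not_matching_annotation(s) is s

    def test_single_field_out_of_scope(self, compounds):
        s = spectrum({"smiles": compounds["adenine"].smiles, "parent_mass": 135.0545})
        assert repair.repair_not_matching_annotation(s) is s


class TestRepairInvariants:
    def test_repairs_never_remove(self, mixed_library, resolver):
        spectra, _ = mixed_library
        filters = [
            lambda s: repair.derive_annotation_from_compound_name(s, resolver),
            repair.repair_smiles_of_salts,
            repair.repair_parent_mass_is_molar_mass,
            repair.repair_adduct_and_parent_mass_based_on_smiles,
            repair.repair_not_matching_annotation,
        ]
        for s in spectra[:60]:
            for fn in filters:
                result = fn(s)
                assert result is not None

    def test_propose_does_not_modify(self, compounds):
        caffeine = compounds["caffeine"]
        s = spectrum({"smiles": caffeine.smiles, "parent_mass": 194.19})
        proposal = repair.propose_parent_mass_from_molar_mass(s)
        assert proposal is not None
        assert s.get("parent_mass") == 194.19
        assert proposal.changes["parent_mass"] == pytest.approx(194.080376, abs=1e-4)
        assert "molar mass" in proposal.evidence
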