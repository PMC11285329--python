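"""Require filters: pure predicates, removal rules, order independence."""

import itertools

import pytest

from speclean import require
from speclean.spectrum import make_spectrum


def spectrum(metadata, mz=(100.0,) * 6, intensities=(1.0,) * 6):
    return make_spectrum(metadata, list(mz), list(intensities))


def full_annotation(entry, **extra):
    metadata = {
        "smiles": entry.smiles,
        "inchi": entry.inchi,
        "inchikey": entry.inchikey,
    }
    metadata.update(extra)
    return metadata


class TestRequireValidAnnotation:
    def test_complete_consistent_annotation_kept(self, compounds):
        s = spectrum(full_annotation(compounds["adenine"]))
        assert require.require_valid_annotation(s) is s

    def test_missing_inchi_removed(self, compounds):
        entry = compounds["adenine"]
        s = spectrum({"smiles": entry.smiles, "inchikey": entry.inchikey})
        assert require.require_valid_annotation(s) is None

    def test_cross_compound_mismatch_removed(self, compounds):
        metadata = full_annotation(compounds["adenine"])
        metadata["inchikey"] = compounds["caffeine"].inchikey
        assert require.require_valid_annotation(spectrum(metadata)) is None

    def test_unparseable_smiles_removed(self, compounds):
        metadata = full_annotation(compounds["adenine"])
        metadata["smiles"] = "not_a_smiles"
        assert require.require_valid_annotation(spectrum(metadata)) is None


class TestRequireParentMassMatchSmiles:
    def test_matching_kept(self, compounds):
        s = spectrum({"smiles": compounds["glucose"].smiles, "parent_mass": 180.0634})
        assert require.require_parent_mass_match_smiles(s) is s

    def test_average_mass_within_default_tolerance_for_small_molecule(self, compounds):
        # glucose: |average - monoisotopic| ~ 0.093 Da sits inside the 0.1 Da
        # default, a documented blind spot for very small molecules; a
        # tighter tolerance removes it
        s = spectrum({"smiles": compounds["glucose"].smiles, "parent_mass": 180.156})
        assert require.require_parent_mass_match_smiles(s) is s
        assert require.require_parent_mass_match_smiles(s, mass_tolerance=0.05) is None

    def test_wrong_mass_removed(self, compounds):
        s = spectrum({"smiles": compounds["glucose"].smiles, "parent_mass": 185.0})
        assert require.require_parent_mass_match_smiles(s) is None

    def test_missing_parent_mass_removed(self, compounds):
        s = spectrum({"smiles": compounds["glucose"].smiles})
        assert require.require_parent_mass_match_smiles(s) is None


class TestRequireMatchingAdductPrecursorParent:
    def test_closing_algebra_kept(self):
        s = spectrum(
            {
                "precursor_mz": 181.070664,
                "adduct": "[M+H]+",
                "parent_mass": 180.063388,
            }
        )
        assert require.require_matching_adduct_precursor_parent(s) is s

    def test_parent_equal_to_precursor_removed(self):
        s = spectrum(
            {"precursor_mz": 181.070664, "adduct": "[M+H]+", "parent_mass": 181.0707}
        )
        assert require.require_matching_adduct_precursor_parent(s) is None

    def test_unparseable_adduct_removed(self):
        s = spectrum(
            {"precursor_mz": 181.070664, "adduct": "???", "parent_mass": 180.063388}
        )
        assert require.require_matching_adduct_precursor_parent(s) is None


class TestRequireMatchingAdductAndIonmode:
    def test_agreeing_polarity_kept(self):
        s = spectrum({"adduct": "[M-H]-", "ionmode": "negative"})
        assert require.require_matching_adduct_and_ionmode(s) is s

    def test_contradiction_removed(self):
        s = spectrum({"adduct": "[M+H]+", "ionmode": "negative"})
        assert require.require_matching_adduct_and_ionmode(s) is None

    def test_missing_ionmode_out_of_scope(self):
        s = spectrum({"adduct": "[M+H]+"})
        assert require.require_matching_adduct_and_ionmode(s) is s


class TestRequireMinimumNumberOfHighPeaks:
    def test_enough_high_peaks_kept(self):
        mz = [float(50 + i) for i in range(10)]
        intensities = [1000.0] * 6 + [1.0] * 4
        s = spectrum({}, mz, intensities)
        assert require.require_minimum_number_of_high_peaks(s) is s

    def test_too_few_peaks_removed(self):
        s = spectrum({}, [50.0, 60.0, 70.0], [1.0, 1.0, 1.0])
        assert require.require_minimum_number_of_high_peaks(s) is None

    def test_low_relative_intensities_do_not_count(self):
        mz = [float(50 + i) for i in range(10)]
        intensities = [1000.0] + [1.0] * 9  # only the base peak clears 2%
        s = spectrum({}, mz, intensities)
        assert require.require_minimum_number_of_high_peaks(s) is None

    def test_zero_minimum_always_keeps(self):
        s = spectrum({}, [], [])
        assert require.require_minimum_number_of_high_peaks(s, n_min=0) is s

    def test_works_on_raw_and_normalized_alike(self):
        mz = [float(50 + i) for i in range(8)]
        raw = spectrum({}, mz, [500.0, 400, 300, 200, 100, 5, 4, 3])
        normalized = raw.replace(intensities=raw.intensities / 500.0)
        assert require.require_minimum_number_of_high_peaks(raw) is raw
        assert require.require_minimum_number_of_high_peaks(normalized) is normalized


ALL_REQUIRES = [
    require.require_valid_annotation,
    require.require_parent_mass_match_smiles,
    require.require_matching_adduct_precursor_parent,
    require.require_matching_adduct_and_ionmode,
    require.require_minimum_number_of_high_peaks,
]


def test_require_filters_return_the_same_object_or_none(mixed_library):
    spectra, _ = mixed_library
    for s in spectra[:60]:
        for fn in ALL_REQUIRES:
            result = fn(s)
            assert result is s or result is None


def test_surviving_set_is_order_independent(mixed_library):
    spectra, _ = mixed_library
    subset = spectra[:80]

    def survivors(order):
        kept = []
        for s in subset:
            if all(fn(s) is s for fn in order):
                kept.append(s.get("spectrum_id"))
        return kept

    reference = survivors(ALL_REQUIRES)
    for order in itertools.islice(itertools.permutations(ALL_REQUIRES), 1, 8):
        assert survivors(list(order)) == reference
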