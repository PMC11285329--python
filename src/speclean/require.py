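"""Requirement filters: pure predicates that remove spectra.

Each filter inspects a spectrum and either returns it untouched (the very
same object) or returns ``None`` to mark removal. They run after all
repairs, so only spectra that could not be repaired are discarded. Because
every filter is a pure predicate, the surviving set is independent of the
order in which require filters are applied; the processing report
attributes a removal to the first failing predicate in canonical order.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import chem
from .repair import DEFAULT_MASS_TOLERANCE, annotation_of
from .spectrum import Spectrum

__all__ = [
    "require_valid_annotation",
    "require_parent_mass_match_smiles",
    "require_matching_adduct_precursor_parent",
    "require_matching_adduct_and_ionmode",
    "require_minimum_number_of_high_peaks",
]


def require_valid_annotation(
    spectrum: Spectrum, backend: Optional[chem.StructureBackend] = None
) -> Optional[Spectrum]:
    """Keep only complete, mutually consistent structure annotations.

    SMILES, InChI and InChIKey must all be present, individually
    well-formed/parseable, and agree on one 2D skeleton (equal InChIKey
    first blocks).
    """
    annotation = annotation_of(spectrum)
    if not (annotation.smiles and annotation.inchi and annotation.inchikey):
        return None
    if not chem.consistent_2d(annotation, backend):
        return None
    return spectrum


def require_parent_mass_match_smiles(
    spectrum: Spectrum,
    mass_tolerance: float = DEFAULT_MASS_TOLERANCE,
    backend: Optional[chem.StructureBackend] = None,
) -> Optional[Spectrum]:
    """Keep spectra whose SMILES monoisotopic mass matches the parent mass."""
    smiles = spectrum.get("smiles")
    parent = spectrum.get("parent_mass")
    if not isinstance(smiles, str) or not isinstance(parent, (int, float)):
        return None
    try:
        monoisotopic = chem.structure_monoisotopic_mass(smiles, backend)
    except chem.StructureParseError:
        return None
    if abs(monoisotopic - float(parent)) > mass_tolerance:
        return None
    return spectrum


def require_matching_adduct_precursor_parent(
    spectrum: Spectrum, mass_tolerance: float = DEFAULT_MASS_TOLERANCE
) -> Optional[Spectrum]:
    """Keep spectra whose adduct algebra closes.

    The parent mass calculated from precursor m/z and adduct must match
    the stored parent mass; an unparseable adduct or a missing operand
    means the calculation cannot be checked and the spectrum is removed.
    """
    precursor = spectrum.get("precursor_mz")
    parent = spectrum.get("parent_mass")
    adduct_text = spectrum.get("adduct")
    if not isinstance(precursor, (int, float)) or not isinstance(parent, (int, float)):
        return None
    if adduct_text is None:
        return None
    try:
        adduct = chem.parse_adduct(str(adduct_text))
        calculated = chem.parent_mass_from_precursor(float(precursor), adduct)
    except (chem.AdductParseError, ValueError):
        return None
    if abs(calculated - float(parent)) > mass_tolerance:
        return None
    return spectrum


def require_matching_adduct_and_ionmode(spectrum: Spectrum) -> Optional[Spectrum]:
    """Remove spectra whose adduct polarity contradicts the ion mode field.

    Only contradictions remove: a missing ion mode or an unparseable
    adduct is out of this predicate's scope (completeness requirements are
    enforced by other filters in the preset).
    """
    ionmode = spectrum.get("ionmode")
    adduct_text = spectrum.get("adduct")
    if ionmode not in ("positive", "negative") or adduct_text is None:
        return spectrum
    try:
        adduct = chem.parse_adduct(str(adduct_text))
    except chem.AdductParseError:
        return spectrum
    if adduct.ionmode != ionmode:
        return None
    return spectrum


def require_minimum_number_of_high_peaks(
    spectrum: Spectrum, n_min: int = 5, intensity_fraction: float = 0.02
) -> Optional[Spectrum]:
    """Keep spectra with enough informative fragments.

    At least ``n_min`` fragments must reach ``intensity_fraction`` of the
    base-peak intensity; barely-fragmented spectra carry too little
    information for reliable library matching. Works on raw or normalized
    intensities (the threshold is relative to the maximum).
    """
    if n_min <= 0:
        return spectrum
    if spectrum.n_peaks == 0:
        return None
    maximum = float(spectrum.intensities.max())
    if maximum <= 0:
        return None
    count = int(np.count_nonzero(spectrum.intensities >= intensity_fraction * maximum))
    if count < n_min:
        return None
    return spectrum
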