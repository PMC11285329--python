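"""Metadata harmonization and derivation filters, plus peak normalization.

These are the "basic" and "default" layers of a cleaning pipeline: they
standardize spellings (ion mode variants, adduct surface forms, metadata
keys), fill in missing fields that can be computed from others (ion mode
from the adduct sign, the adduct from a token embedded in the compound
name, the parent mass from precursor m/z + adduct), and rescale fragment
intensities to the base peak.

Derivation never overwrites a value that is already present: explicitly
stored metadata wins, and only the repair filters (which demand support
from multiple other fields) may replace an existing value. All filters are
idempotent — a second application is a no-op — and return the *same*
object when nothing changed, so change tracking is exact.
"""

from __future__ import annotations

import re
from typing import Optional

from . import chem
from .spectrum import Spectrum, make_spectrum

__all__ = [
    "harmonize_metadata_keys",
    "harmonize_ionmode",
    "harmonize_adduct",
    "derive_ionmode_from_adduct",
    "derive_adduct_from_name_or_comment",
    "derive_parent_mass",
    "normalize_intensities",
    "require_precursor_mz",
]

_POSITIVE_ALIASES = {"positive", "pos", "p", "+", "positive ion", "1", "+1"}
_NEGATIVE_ALIASES = {"negative", "neg", "n", "-", "negative ion", "-1"}


def harmonize_metadata_keys(spectrum: Spectrum) -> Spectrum:
    """Re-apply key harmonization; a fixpoint for already-built spectra.

    Spectra constructed through :func:`speclean.spectrum.make_spectrum` are
    harmonized on entry, so this filter usually returns its input; it
    exists so a pipeline is explicit about the guarantee.
    """
    rebuilt = make_spectrum(spectrum.metadata, spectrum.mz, spectrum.intensities)
    return rebuilt if not rebuilt == spectrum else spectrum


def harmonize_ionmode(spectrum: Spectrum) -> Spectrum:
    """Map ion mode spellings onto {positive, negative}; unknown -> absent."""
    value = spectrum.get("ionmode")
    if value is None:
        return spectrum
    text = str(value).strip().lower()
    if text in _POSITIVE_ALIASES:
        harmonized: Optional[str] = "positive"
    elif text in _NEGATIVE_ALIASES:
        harmonized = "negative"
    else:
        harmonized = None
    if harmonized == value:
        return spectrum
    return spectrum.with_metadata(ionmode=harmonized)


def harmonize_adduct(spectrum: Spectrum) -> Spectrum:
    """Rewrite a parseable adduct to its canonical bracket notation."""
    value = spectrum.get("adduct")
    if value is None:
        return spectrum
    try:
        canonical = chem.parse_adduct(str(value)).name
    except chem.AdductParseError:
        return spectrum
    if canonical == value:
        return spectrum
    return spectrum.with_metadata(adduct=canonical)


def derive_ionmode_from_adduct(spectrum: Spectrum) -> Spectrum:
    """Fill a missing ion mode from the adduct's charge sign."""
    if spectrum.get("ionmode") is not None:
        return spectrum
    adduct = spectrum.get("adduct")
    if adduct is None:
        return spectrum
    try:
        spec = chem.parse_adduct(str(adduct))
    except chem.AdductParseError:
        return spectrum
    return spectrum.with_metadata(ionmode=spec.ionmode)


_ADDUCT_TOKEN = re.compile(
    r"\[\d?M(?:[+-][A-Za-z0-9]+)+\]\d?[+-−]|\[\d?M(?:[+-−][A-Za-z0-9]+)+\]"
)


def derive_adduct_from_name_or_comment(spectrum: Spectrum) -> Spectrum:
    """Move an adduct token out of the compound name (or comment).

    If the name or comment contains a grammatical adduct such as
    ``"Glucose [M+H]+"``, the token is stripped from the text and, when the
    adduct field is still empty, stored there in canonical form. An already
    present adduct is never overwritten.
    """
    updates: dict[str, object] = {}
    found: Optional[str] = None
    for field in ("compound_name", "comment"):
        value = spectrum.get(field)
        if value is None or not isinstance(value, str):
            continue
        match = _ADDUCT_TOKEN.search(value)
        if match is None:
            continue
        token = match.group(0)
        try:
            canonical = chem.parse_adduct(token).name
        except chem.AdductParseError:
            continue
        stripped = (value[: match.start()] + value[match.end() :]).strip()
        stripped = re.sub(r"\s{2,}", " ", stripped)
        updates[field] = stripped if stripped else None
        if found is None:
            found = canonical
    if not updates:
        return spectrum
    if found is not None and spectrum.get("adduct") is None:
        updates["adduct"] = found
    return spectrum.with_metadata(**updates)


def derive_parent_mass(spectrum: Spectrum, allow_default_adduct: bool = False) -> Spectrum:
    """Fill a missing parent mass from precursor m/z and adduct algebra.

    With ``allow_default_adduct`` a spectrum without an adduct falls back
    to [M+H]+ / [M-H]- according to its ion mode; this is off by default in
    the library-cleaning preset because an assumed protonation is exactly
    the error class the repair filters exist to fix.
    """
    if spectrum.get("parent_mass") is not None:
        return spectrum
    precursor = spectrum.get("precursor_mz")
    if not isinstance(precursor, (int, float)) or precursor <= 0:
        return spectrum
    adduct_text = spectrum.get("adduct")
    adduct: Optional[chem.AdductSpec] = None
    if adduct_text is not None:
        try:
            adduct = chem.parse_adduct(str(adduct_text))
        except chem.AdductParseError:
            adduct = None
    if adduct is None and allow_default_adduct:
        ionmode = spectrum.get("ionmode")
        if ionmode == "positive":
            adduct = chem.parse_adduct("[M+H]+")
        elif ionmode == "negative":
            adduct = chem.parse_adduct("[M-H]-")
    if adduct is None:
        return spectrum
    try:
        parent = chem.parent_mass_from_precursor(float(precursor), adduct)
    except ValueError:
        return spectrum
    return spectrum.with_metadata(parent_mass=parent)


def normalize_intensities(spectrum: Spectrum) -> Spectrum:
    """Scale fragment intensities so the base peak is exactly 1.0.

    Peak count and m/z values are untouched. Empty or all-zero spectra are
    returned unchanged (removal decisions belong to require filters).
    """
    if spectrum.n_peaks == 0:
        return spectrum
    maximum = float(spectrum.intensities.max())
    if maximum <= 0:
        return spectrum
    if maximum == 1.0:
        return spectrum
    return spectrum.replace(intensities=spectrum.intensities / maximum)


def require_precursor_mz(spectrum: Spectrum, maximum_mz: float = 5000.0) -> Optional[Spectrum]:
    """Remove spectra without a usable precursor m/z in (0, maximum_mz]."""
    precursor = spectrum.get("precursor_mz")
    if not isinstance(precursor, (int, float)):
        return None
    if not (0 < float(precursor) <= maximum_mz):
        return None
    return spectrum
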