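"""Annotation-repair filters.

Instead of discarding every spectrum whose annotation metadata is wrong or
incomplete, these filters recover, correct or complete annotations —
always requiring corroboration from at least two metadata fields (the
field being changed plus mass/precursor evidence), so a repair is never a
guess from a single value:

* :func:`derive_annotation_from_compound_name` — look the compound name up
  in a resolver (an offline table or a PubChem-style service, behind a
  cache file) and adopt the structure only if its monoisotopic mass
  matches the stored parent mass.
* :func:`repair_smiles_of_salts` — a salt's SMILES lists several
  components joined by ``.``, but the spectrometer usually measured only a
  sub-set of them; keep the component subset whose summed mass matches the
  parent mass.
* :func:`repair_parent_mass_is_molar_mass` — a parent mass computed from
  standard atomic weights instead of monoisotopic masses is a classic
  annotation mistake; detect it against the SMILES and replace it with the
  monoisotopic value.
* :func:`repair_adduct_and_parent_mass_based_on_smiles` — a stored default
  adduct (typically [M+H]+) that does not explain precursor m/z + SMILES
  is replaced by the common adduct that does.
* :func:`repair_not_matching_annotation` — when SMILES/InChI/InChIKey
  disagree, keep the field(s) whose mass matches the parent mass and
  rederive the rest.

Every repair exists in two forms: ``propose_*`` returns the change and its
evidence without touching the spectrum (audit mode, used to estimate
error rates by stripping a field and re-deriving it), and the filter
itself applies the proposal. Repair filters never remove a spectrum.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

from . import chem
from .spectrum import Spectrum

__all__ = [
    "DEFAULT_MASS_TOLERANCE",
    "Candidate",
    "NameResolver",
    "TableNameResolver",
    "CachedNameResolver",
    "PubChemNameResolver",
    "RepairProposal",
    "propose_annotation_from_compound_name",
    "propose_salt_component_subset",
    "propose_parent_mass_from_molar_mass",
    "propose_adduct_from_smiles",
    "propose_annotation_conflict_resolution",
    "derive_annotation_from_compound_name",
    "repair_smiles_of_salts",
    "repair_parent_mass_is_molar_mass",
    "repair_adduct_and_parent_mass_based_on_smiles",
    "repair_not_matching_annotation",
    "annotation_of",
    "SALT_COMPONENT_CAP",
]

logger = logging.getLogger(__name__)

#: Da; the paper-silent default for every "mass matches" decision. Wide
#: enough for unit-resolution library metadata, narrow enough to reject a
#: different molecule.
DEFAULT_MASS_TOLERANCE = 0.1

#: salt SMILES with more components than this are left untouched
#: (the subset search is a powerset, <= 255 candidates at the cap)
SALT_COMPONENT_CAP = 8


def annotation_of(spectrum: Spectrum) -> chem.Annotation:
    return chem.Annotation(
        smiles=spectrum.get("smiles"),
        inchi=spectrum.get("inchi"),
        inchikey=spectrum.get("inchikey"),
        compound_name=spectrum.get("compound_name"),
    )


def _parent_mass(spectrum: Spectrum) -> Optional[float]:
    value = spectrum.get("parent_mass")
    return float(value) if isinstance(value, (int, float)) else None


# --- name resolution --------------------------------------------------------


@dataclass(frozen=True)
class Candidate:
    """One structure candidate for a compound name."""

    smiles: str
    inchi: str = ""
    inchikey: str = ""
    monoisotopic_mass: float = 0.0


class NameResolver(Protocol):
    """Contract: compound name -> ordered candidates (canonical first)."""

    def resolve(self, name: str) -> Sequence[Candidate]: ...


class TableNameResolver:
    """Offline resolver over (name, smiles, inchi, inchikey, mass) rows.

    Lookup is case-insensitive on the name. Used for tests and for the
    synthetic-library validation replication; also the natural adapter for
    any pre-downloaded name->structure dump.
    """

    def __init__(self, rows: Sequence[tuple[str, Candidate]]):
        self._table: dict[str, list[Candidate]] = {}
        for name, candidate in rows:
            self._table.setdefault(name.strip().lower(), []).append(candidate)

    def resolve(self, name: str) -> Sequence[Candidate]:
        return list(self._table.get(name.strip().lower(), []))


class CachedNameResolver:
    """File-backed cache in front of another resolver.

    The cache is a TSV of ``name<TAB>smiles<TAB>inchi<TAB>inchikey<TAB>mass``
    rows (a row with empty structure fields records a miss). A cache hit
    short-circuits the backend; new lookups are appended within the run and
    reloadable across runs, so repeated cleanings of large libraries do not
    repeat lookups.
    """

    def __init__(self, backend: NameResolver, cache_path: str):
        self._backend = backend
        self._path = cache_path
        self._cache: dict[str, list[Candidate]] = {}
        if os.path.exists(cache_path):
            with open(cache_path, "r", encoding="utf-8") as handle:
                for line in handle:
                    parts = line.rstrip("\n").split("\t")
                    if len(parts) != 5:
                        continue
                    name, smiles, inchi, inchikey, mass = parts
                    entry = self._cache.setdefault(name, [])
                    if smiles:
                        entry.append(Candidate(smiles, inchi, inchikey, float(mass or 0.0)))

    def resolve(self, name: str) -> Sequence[Candidate]:
        key = name.strip().lower()
        if key in self._cache:
            return list(self._cache[key])
        candidates = list(self._backend.resolve(name))
        self._cache[key] = candidates
        with open(self._path, "a", encoding="utf-8") as handle:
            if candidates:
                for c in candidates:
                    handle.write(
                        f"{key}\t{c.smiles}\t{c.inchi}\t{c.inchikey}"
                        f"\t{c.monoisotopic_mass:.6f}\n"
                    )
            else:
                handle.write(f"{key}\t\t\t\t\n")
        return candidates


class PubChemNameResolver:
    """Live PubChem-style REST resolver (PUG REST) behind the same contract.

    Network-dependent; intended for real cleaning runs, never used by the
    test suite. Failures resolve to "no candidates" so a flaky service can
    only leave spectra unrepaired, never break a run.
    """

    URL = (
        "https://pubchem.ncbi.nlm.nih.gov/rest/pug/compound/name/{}/property/"
        "CanonicalSMILES,InChI,InChIKey,MonoisotopicMass/JSON"
    )

    def __init__(self, timeout: float = 10.0):
        self._timeout = timeout

    def resolve(self, name: str) -> Sequence[Candidate]:
        import json
        import urllib.parse
        import urllib.request

        url = self.URL.format(urllib.parse.quote(name))
        try:
            with urllib.request.urlopen(url, timeout=self._timeout) as response:
                payload = json.load(response)
        except Exception as exc:  # pragma: no cover - network path
            logger.warning("name lookup failed for %r: %s", name, exc)
            return []
        candidates = []
        for row in payload.get("PropertyTable", {}).get("Properties", []):
            candidates.append(
                Candidate(
                    smiles=row.get("CanonicalSMILES", ""),
                    inchi=row.get("InChI", ""),
                    inchikey=row.get("InChIKey", ""),
                    monoisotopic_mass=float(row.get("MonoisotopicMass", 0.0)),
                )
            )
        return candidates


# --- proposals --------------------------------------------------------------


@dataclass(frozen=True)
class RepairProposal:
    """A repair that could be applied: field updates plus their evidence."""

    filter_name: str
    changes: dict[str, object] = field(default_factory=dict)
    evidence: str = ""

    def apply(self, spectrum: Spectrum) -> Spectrum:
        return spectrum.with_metadata(**self.changes)


def _apply(spectrum: Spectrum, proposal: Optional[RepairProposal]) -> Spectrum:
    if proposal is None:
        return spectrum
    return proposal.apply(spectrum)


# --- derive annotation from compound name -----------------------------------


def propose_annotation_from_compound_name(
    spectrum: Spectrum,
    resolver: NameResolver,
    mass_tolerance: float = DEFAULT_MASS_TOLERANCE,
    backend: Optional[chem.StructureBackend] = None,
) -> Optional[RepairProposal]:
    """Structure fields for an annotation that is only a compound name.

    Applies when both SMILES and InChI are missing, a compound name and a
    parent mass are present. The first resolver candidate whose
    monoisotopic mass is within ``mass_tolerance`` of the parent mass is
    adopted; without a mass match, no annotation is added.
    """
    if spectrum.get("smiles") is not None or spectrum.get("inchi") is not None:
        return None
    name = spectrum.get("compound_name")
    parent = _parent_mass(spectrum)
    if not isinstance(name, str) or not name.strip() or parent is None:
        return None
    try:
        candidates = resolver.resolve(name)
    except Exception as exc:
        logger.warning("name resolver unavailable for %r: %s", name, exc)
        return None
    for candidate in candidates:
        if abs(candidate.monoisotopic_mass - parent) <= mass_tolerance:
            backend = backend or chem.default_backend()
            inchi = candidate.inchi
            inchikey = candidate.inchikey
            try:
                if not inchi:
                    inchi = backend.convert(candidate.smiles, "smiles", "inchi")
                if not inchikey:
                    inchikey = backend.convert(candidate.smiles, "smiles", "inchikey")
            except chem.StructureParseError:
                continue
            return RepairProposal(
                "derive_annotation_from_compound_name",
                {"smiles": candidate.smiles, "inchi": inchi, "inchikey": inchikey},
                evidence=(
                    f"name {name!r} resolved to mass "
                    f"{candidate.monoisotopic_mass:.4f} Da, parent mass {parent:.4f} Da"
                ),
            )
    return None


def derive_annotation_from_compound_name(
    spectrum: Spectrum,
    resolver: NameResolver,
    mass_tolerance: float = DEFAULT_MASS_TOLERANCE,
    backend: Optional[chem.StructureBackend] = None,
) -> Spectrum:
    return _apply(
        spectrum,
        propose_annotation_from_compound_name(spectrum, resolver, mass_tolerance, backend),
    )


# --- repair SMILES of salts -------------------------------------------------


def propose_salt_component_subset(
    spectrum: Spectrum,
    mass_tolerance: float = DEFAULT_MASS_TOLERANCE,
    backend: Optional[chem.StructureBackend] = None,
) -> Optional[RepairProposal]:
    """The component subset of a salt SMILES that explains the parent mass.

    All non-empty proper subsets of the ``.``-separated components are
    scored (component count capped at :data:`SALT_COMPONENT_CAP`); the
    subset with the smallest mass error wins, ties broken by more heavy
    atoms, then by enumeration order. The surviving components keep their
    original order and InChI/InChIKey are rederived from the new SMILES.
    """
    smiles = spectrum.get("smiles")
    parent = _parent_mass(spectrum)
    if not isinstance(smiles, str) or parent is None:
        return None
    components = chem.split_components(smiles)
    if len(components) < 2 or len(components) > SALT_COMPONENT_CAP:
        return None
    backend = backend or chem.default_backend()
    try:
        masses = [chem.structure_monoisotopic_mass(c, backend) for c in components]
        heavies = [chem.heavy_atom_count(backend.formula(c, "smiles")) for c in components]
    except chem.StructureParseError:
        return None
    if abs(sum(masses) - parent) <= mass_tolerance:
        return None  # full structure already explains the parent mass
    best: Optional[tuple[float, int, int]] = None  # (|error|, -heavy, mask)
    n = len(components)
    for mask in range(1, (1 << n) - 1):
        subset_mass = sum(masses[i] for i in range(n) if mask >> i & 1)
        error = abs(subset_mass - parent)
        if error > mass_tolerance:
            continue
        heavy = sum(heavies[i] for i in range(n) if mask >> i & 1)
        key = (error, -heavy, mask)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    mask = best[2]
    kept = [components[i] for i in range(n) if mask >> i & 1]
    new_smiles = ".".join(kept)
    try:
        inchi = backend.convert(new_smiles, "smiles", "inchi")
        inchikey = backend.convert(new_smiles, "smiles", "inchikey")
    except chem.StructureParseError:
        inchi = None
        inchikey = None
    changes: dict[str, object] = {"smiles": new_smiles}
    if inchi and inchikey:
        changes["inchi"] = inchi
        changes["inchikey"] = inchikey
    return RepairProposal(
        "repair_smiles_of_salts",
        changes,
        evidence=(
            f"components {kept} sum to within {best[0]:.4f} Da of "
            f"parent mass {parent:.4f} Da"
        ),
    )


def repair_smiles_of_salts(
    spectrum: Spectrum,
    mass_tolerance: float = DEFAULT_MASS_TOLERANCE,
    backend: Optional[chem.StructureBackend] = None,
) -> Spectrum:
    return _apply(spectrum, propose_salt_component_subset(spectrum, mass_tolerance, backend))


# --- repair parent mass is molar mass ---------------------------------------


def propose_parent_mass_from_molar_mass(
    spectrum: Spectrum,
    mass_tolerance: float = DEFAULT_MASS_TOLERANCE,
    backend: Optional[chem.StructureBackend] = None,
) -> Optional[RepairProposal]:
    """Replace an average-mass parent mass with the monoisotopic mass.

    Fires only when the stored parent mass disagrees with the SMILES
    monoisotopic mass but agrees with its average (molar) mass — the
    signature of a parent mass computed from standard atomic weights.
    """
    smiles = spectrum.get("smiles")
    parent = _parent_mass(spectrum)
    if not isinstance(smiles, str) or parent is None:
        return None
    backend = backend or chem.default_backend()
    try:
        formula = backend.formula(smiles, "smiles")
    except chem.StructureParseError:
        return None
    monoisotopic = chem.monoisotopic_mass(formula)
    if abs(parent - monoisotopic) <= mass_tolerance:
        return None
    average = chem.average_mass(formula)
    if abs(parent - average) > mass_tolerance:
        return None
    return RepairProposal(
        "repair_parent_mass_is_molar_mass",
        {"parent_mass": monoisotopic},
        evidence=(
            f"parent mass {parent:.4f} Da matches molar mass {average:.4f} Da; "
            f"monoisotopic mass is {monoisotopic:.4f} Da"
        ),
    )


def repair_parent_mass_is_molar_mass(
    spectrum: Spectrum,
    mass_tolerance: float = DEFAULT_MASS_TOLERANCE,
    backend: Optional[chem.StructureBackend] = None,
) -> Spectrum:
    return _apply(
        spectrum, propose_parent_mass_from_molar_mass(spectrum, mass_tolerance, backend)
    )


# --- repair adduct and parent mass based on SMILES --------------------------


def propose_adduct_from_smiles(
    spectrum: Spectrum,
    mass_tolerance: float = DEFAULT_MASS_TOLERANCE,
    backend: Optional[chem.StructureBackend] = None,
) -> Optional[RepairProposal]:
    """The common adduct that explains SMILES + precursor m/z.

    Fires when the stored adduct (often an unedited default [M+H]+) does
    not link precursor m/z to the SMILES monoisotopic mass. Candidate
    adducts are restricted to the spectrum's ion mode (both polarities if
    unknown); the best mass agreement wins, ties broken by table priority
    ([M+H]+ / [M-H]- first). Parent mass is set to the SMILES monoisotopic
    mass alongside the corrected adduct.
    """
    smiles = spectrum.get("smiles")
    precursor = spectrum.get("precursor_mz")
    if not isinstance(smiles, str) or not isinstance(precursor, (int, float)):
        return None
    if precursor <= 0:
        return None
    backend = backend or chem.default_backend()
    try:
        monoisotopic = chem.structure_monoisotopic_mass(smiles, backend)
    except chem.StructureParseError:
        return None
    stored = spectrum.get("adduct")
    if stored is not None:
        try:
            current = chem.parse_adduct(str(stored))
            implied = chem.parent_mass_from_precursor(float(precursor), current)
            if abs(implied - monoisotopic) <= mass_tolerance:
                return None  # already consistent
        except (chem.AdductParseError, ValueError):
            pass
    ionmode = spectrum.get("ionmode")
    ionmode = ionmode if ionmode in ("positive", "negative") else None
    best: Optional[tuple[float, int, chem.AdductSpec]] = None
    for priority, adduct in enumerate(chem.known_adducts(ionmode)):
        try:
            implied = chem.parent_mass_from_precursor(float(precursor), adduct)
        except ValueError:
            continue
        error = abs(implied - monoisotopic)
        if error > mass_tolerance:
            continue
        key = (error, priority)
        if best is None or key < (best[0], best[1]):
            best = (error, priority, adduct)
    if best is None:
        return None
    adduct = best[2]
    return RepairProposal(
        "repair_adduct_and_parent_mass_based_on_smiles",
        {"adduct": adduct.name, "parent_mass": monoisotopic},
        evidence=(
            f"adduct {adduct.name} links precursor m/z {float(precursor):.4f} to "
            f"SMILES monoisotopic mass {monoisotopic:.4f} Da "
            f"(error {best[0]:.4f} Da)"
        ),
    )


def repair_adduct_and_parent_mass_based_on_smiles(
    spectrum: Spectrum,
    mass_tolerance: float = DEFAULT_MASS_TOLERANCE,
    backend: Optional[chem.StructureBackend] = None,
) -> Spectrum:
    return _apply(spectrum, propose_adduct_from_smiles(spectrum, mass_tolerance, backend))


# --- repair not matching annotation -----------------------------------------


def propose_annotation_conflict_resolution(
    spectrum: Spectrum,
    mass_tolerance: float = DEFAULT_MASS_TOLERANCE,
    backend: Optional[chem.StructureBackend] = None,
) -> Optional[RepairProposal]:
    """Resolve SMILES/InChI/InChIKey that describe different compounds.

    Each mass-carrying field (SMILES, InChI) is judged by whether its
    monoisotopic mass matches the parent mass; an InChIKey, which carries
    no computable mass, is judged by 2D agreement with a mass-matching
    field. If the mass-matching fields single out one structure, the
    conflicting fields are cleared and rederived from it; if zero or
    several conflicting structures match the parent mass, nothing is
    changed and the require filters decide the spectrum's fate.
    """
    annotation = annotation_of(spectrum)
    fields = annotation.structure_fields()
    if len(fields) < 2:
        return None
    backend = backend or chem.default_backend()
    try:
        if chem.consistent_2d(annotation, backend):
            return None
    except ValueError:
        return None

    parent = _parent_mass(spectrum)
    if parent is None:
        return None
    matching: dict[str, str] = {}  # field kind -> first block
    for kind in ("smiles", "inchi"):
        value = fields.get(kind)
        if value is None:
            continue
        try:
            mass = chem.monoisotopic_mass(backend.formula(value, kind))
            block = chem.first_block(backend.inchikey(value, kind))
        except chem.StructureParseError:
            continue
        if abs(mass - parent) <= mass_tolerance:
            matching[kind] = block
    if not matching or len(set(matching.values())) > 1:
        return None  # nothing matches, or two different structures both match
    block = next(iter(matching.values()))
    source_kind = next(iter(matching))
    source_value = fields[source_kind]

    inchikey = fields.get("inchikey")
    inchikey_ok = inchikey is not None and chem.first_block(inchikey) == block
    changes: dict[str, object] = {}
    try:
        for kind in ("smiles", "inchi"):
            if kind not in matching and fields.get(kind) is not None:
                changes[kind] = backend.convert(source_value, source_kind, kind)
            elif kind not in matching and fields.get(kind) is None:
                pass
        if inchikey is not None and not inchikey_ok:
            changes["inchikey"] = backend.convert(source_value, source_kind, "inchikey")
    except chem.StructureParseError:
        return None
    if not changes:
        return None
    return RepairProposal(
        "repair_not_matching_annotation",
        changes,
        evidence=(
            f"{source_kind} matches parent mass {parent:.4f} Da; "
            f"conflicting fields {sorted(changes)} rederived from it"
        ),
    )


def repair_not_matching_annotation(
    spectrum: Spectrum,
    mass_tolerance: float = DEFAULT_MASS_TOLERANCE,
    backend: Optional[chem.StructureBackend] = None,
) -> Spectrum:
    return _apply(
        spectrum, propose_annotation_conflict_resolution(spectrum, mass_tolerance, backend)
    )
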