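"""Chemistry arithmetic for spectral-library curation.

Everything mass-related lives here: molecular-formula parsing, monoisotopic
and average (molar) mass, the adduct grammar with precursor <-> parent-mass
algebra, and 2D structure-consistency checks over SMILES / InChI / InChIKey.

Two mass scales matter throughout:

* **monoisotopic mass** — sum of the masses of the most abundant isotope of
  each element; this is what "parent mass" means for MS/MS library spectra.
* **average (molar) mass** — sum of standard atomic weights; a frequent
  source of wrong parent-mass metadata, which the repair filters detect by
  comparing a stored parent mass against both scales.

Adduct algebra follows the usual convention: for an adduct with multiplier
``x`` (count of neutral molecules M), charge ``z`` and mass shift ``delta``
(which includes the electron-mass book-keeping for the charge carriers),

    precursor_mz = (x * M + delta) / |z|

and the inverse recovers the neutral monoisotopic mass M.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Protocol

__all__ = [
    "MONOISOTOPIC_MASS",
    "AVERAGE_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "FormulaError",
    "AdductParseError",
    "StructureParseError",
    "AdductSpec",
    "Annotation",
    "INCHIKEY_PATTERN",
    "parse_formula",
    "formula_to_string",
    "monoisotopic_mass",
    "average_mass",
    "heavy_atom_count",
    "parse_adduct",
    "known_adducts",
    "parent_mass_from_precursor",
    "precursor_from_parent",
    "StructureBackend",
    "RDKitBackend",
    "StubBackend",
    "default_backend",
    "structure_monoisotopic_mass",
    "structure_average_mass",
    "split_components",
    "consistent_2d",
    "first_block",
]

# --- element mass tables ---------------------------------------------------
# Monoisotopic: mass of the most abundant isotope (12C defines the scale).
# Average: IUPAC standard atomic weight. Note Se: average < monoisotopic,
# so no ordering between the two columns is assumed anywhere.

MONOISOTOPIC_MASS: Mapping[str, float] = {
    "H": 1.00782503,
    "C": 12.0,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376163,
    "S": 31.97207100,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Br": 78.91833710,
    "I": 126.90447300,
    "Na": 22.98976928,
    "K": 38.96370668,
    "Ca": 39.96259098,
    "Mg": 23.98504170,
    "Fe": 55.93493750,
    "Zn": 63.92914220,
    "Si": 27.97692653,
    "Se": 79.91652130,
    "B": 11.00930540,
    "Li": 7.01600450,
    "Al": 26.98153863,
    "Cu": 62.92959750,
}

AVERAGE_MASS: Mapping[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.067,
    "F": 18.998,
    "Cl": 35.453,
    "Br": 79.904,
    "I": 126.904,
    "Na": 22.990,
    "K": 39.098,
    "Ca": 40.078,
    "Mg": 24.305,
    "Fe": 55.845,
    "Zn": 65.390,
    "Si": 28.086,
    "Se": 78.960,
    "B": 10.812,
    "Li": 6.941,
    "Al": 26.982,
    "Cu": 63.546,
}

PROTON_MASS = 1.00727646  # Da, H+ (H minus one electron)
ELECTRON_MASS = 0.00054858  # Da


class FormulaError(ValueError):
    """Raised for text that is not a valid molecular formula."""


class AdductParseError(ValueError):
    """Raised for text that is not grammatical adduct notation.

    Distinct from an adduct that parses but is not in the built-in table:
    such adducts are returned with a mass shift computed from their
    gain/loss formulas, not rejected.
    """


class StructureParseError(ValueError):
    """Raised by a structure backend for an uninterpretable SMILES/InChI."""


# --- molecular formulas ----------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula into an element -> count map.

    Isotope labels, charges and parentheses are rejected; every element
    symbol must be in the mass tables.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError(f"not a molecular formula: {text!r}")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        match = _FORMULA_TOKEN.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        symbol, digits = match.group(1), match.group(2)
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {symbol!r} in formula {text!r}")
        count = int(digits) if digits else 1
        pos = match.end()
        if count < 1:
            raise FormulaError(f"zero count for {symbol!r} in formula {text!r}")
        counts[symbol] = counts.get(symbol, 0) + count
    if not counts:
        raise FormulaError(f"empty formula {text!r}")
    return counts


def formula_to_string(formula: Mapping[str, int]) -> str:
    """Render a formula map in Hill order (C, H, then alphabetical)."""
    symbols = sorted(formula, key=lambda s: (s != "C", s != "H", s))
    return "".join(f"{s}{formula[s] if formula[s] != 1 else ''}" for s in symbols)


def _mass(formula: Mapping[str, int], table: Mapping[str, float]) -> float:
    total = 0.0
    for symbol, count in formula.items():
        if symbol not in table:
            raise FormulaError(f"unknown element {symbol!r}")
        if count < 1:
            raise FormulaError(f"invalid count {count} for element {symbol!r}")
        total += count * table[symbol]
    return total


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of a formula: most-abundant-isotope masses."""
    return _mass(formula, MONOISOTOPIC_MASS)


def average_mass(formula: Mapping[str, int]) -> float:
    """Average (molar) mass (Da) of a formula: standard atomic weights."""
    return _mass(formula, AVERAGE_MASS)


def heavy_atom_count(formula: Mapping[str, int]) -> int:
    return sum(count for symbol, count in formula.items() if symbol != "H")


# --- adducts ---------------------------------------------------------------


@dataclass(frozen=True)
class AdductSpec:
    """A parsed adduct: ``precursor_mz = (multiplier * M + mass_shift) / |charge|``.

    ``mass_shift`` carries the full charge-carrier book-keeping including
    electron masses, so [M+H]+ shifts by the proton mass (1.00727646 Da),
    not the hydrogen-atom mass.
    """

    name: str
    charge: int
    multiplier: int = 1
    mass_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")
        if self.multiplier < 1:
            raise ValueError("adduct multiplier must be >= 1")

    @property
    def ionmode(self) -> str:
        return "positive" if self.charge > 0 else "negative"


# neutral-species aliases accepted inside adduct terms
_SPECIES_ALIASES = {
    "FA": "CH2O2",  # formic acid
    "HAC": "C2H4O2",  # acetic acid
    "ACN": "C2H3N",  # acetonitrile
    "MEOH": "CH4O",
    "DMSO": "C2H6OS",
    "NH4": "NH4",
    "H2O": "H2O",
}

# species whose presence implies the charge sign when none is written
_CATION_SPECIES = {"H", "NA", "K", "NH4", "LI"}
_ANION_GAIN_SPECIES = {"CL", "BR", "I"}

_ADDUCT_RE = re.compile(
    r"^\[?(?P<mult>\d*)M(?P<terms>(?:[+-][A-Za-z0-9]+)*)\]?(?P<zmag>\d*)(?P<zsign>[+-]?)$"
)
_TERM_RE = re.compile(r"([+-])(\d*)([A-Za-z][A-Za-z0-9]*)")


def _species_formula(token: str) -> dict[str, int]:
    alias = _SPECIES_ALIASES.get(token.upper())
    if alias is not None:
        return parse_formula(alias)
    try:
        return parse_formula(token)
    except FormulaError:
        # tolerate all-lower/upper library spellings such as "na" or "CL"
        fixed = token.capitalize()
        return parse_formula(fixed)


def _canonical_token(token: str) -> str:
    upper = token.upper()
    if upper in _SPECIES_ALIASES:
        return "FA" if upper == "FA" else upper if upper in {"NH4", "H2O"} else token
    try:
        return formula_to_string(parse_formula(token))
    except FormulaError:
        return token.capitalize()


def parse_adduct(text: str) -> AdductSpec:
    """Parse adduct notation such as ``[M+H]+``, ``M-H``, ``[2M+Na]+``.

    Surface-form tolerance: optional brackets, unicode minus signs,
    whitespace, an explicit ``1`` charge, lower-case species tokens and an
    omitted charge sign (inferred from the charge-carrying species). The
    mass shift is computed from the gained/lost formulas with proton and
    electron accounting, so unknown-but-grammatical adducts are supported.
    """
    if not isinstance(text, str):
        raise AdductParseError(f"not an adduct: {text!r}")
    cleaned = (
        text.strip()
        .replace("−", "-")
        .replace("–", "-")
        .replace("—", "-")
        .replace(" ", "")
    )
    if not cleaned:
        raise AdductParseError("empty adduct string")
    match = _ADDUCT_RE.match(cleaned)
    if match is None and "m" in cleaned:
        # tolerate a lower-case molecule marker, e.g. "[m+h]+"
        cleaned = cleaned.replace("m", "M", 1)
        match = _ADDUCT_RE.match(cleaned)
    if match is None:
        raise AdductParseError(f"cannot parse adduct {text!r}")
    multiplier = int(match.group("mult") or "1")

    terms: list[tuple[int, int, str]] = []  # (sign, count, canonical token)
    consumed = 0
    raw_terms = match.group("terms") or ""
    for term in _TERM_RE.finditer(raw_terms):
        sign = 1 if term.group(1) == "+" else -1
        count = int(term.group(2) or "1")
        token = term.group(3)
        try:
            _species_formula(token)
        except FormulaError as exc:
            raise AdductParseError(f"unknown species {token!r} in adduct {text!r}") from exc
        terms.append((sign, count, _canonical_token(token)))
        consumed = term.end()
    if consumed != len(raw_terms):
        raise AdductParseError(f"cannot parse adduct {text!r}")

    zsign, zmag = match.group("zsign"), match.group("zmag")
    if zsign:
        charge = (1 if zsign == "+" else -1) * int(zmag or "1")
    else:
        if zmag:
            raise AdductParseError(f"charge magnitude without sign in {text!r}")
        hint = 0
        for sign, count, token in terms:
            upper = token.upper()
            if upper in _CATION_SPECIES:
                hint += sign * count
            elif upper in _ANION_GAIN_SPECIES:
                hint -= sign * count
        if hint == 0:
            raise AdductParseError(f"cannot infer charge of adduct {text!r}")
        charge = hint
    if charge == 0:
        raise AdductParseError(f"adduct {text!r} has zero charge")

    shift = -charge * ELECTRON_MASS
    for sign, count, token in terms:
        shift += sign * count * monoisotopic_mass(_species_formula(token))

    term_text = "".join(
        f"{'+' if sign > 0 else '-'}{count if count > 1 else ''}{token}"
        for sign, count, token in terms
    )
    name = (
        f"[{multiplier if multiplier > 1 else ''}M{term_text}]"
        f"{abs(charge) if abs(charge) > 1 else ''}{'+' if charge > 0 else '-'}"
    )
    spec = AdductSpec(name=name, charge=charge, multiplier=multiplier, mass_shift=shift)
    return _ADDUCT_TABLE.get(name, spec)


def _build_table(names: Iterable[str]) -> dict[str, AdductSpec]:
    table: dict[str, AdductSpec] = {}
    for name in names:
        spec = parse_adduct(name)
        table[spec.name] = spec
    return table


# Common adducts, in repair-priority order ([M+H]+ / [M-H]- first).
_COMMON_ADDUCT_NAMES = [
    "[M+H]+",
    "[M-H]-",
    "[M+Na]+",
    "[M+K]+",
    "[M+NH4]+",
    "[M+H-H2O]+",
    "[2M+H]+",
    "[M+2H]2+",
    "[M+Cl]-",
    "[M+FA-H]-",
    "[2M-H]-",
    "[M-2H]2-",
]

_ADDUCT_TABLE: dict[str, AdductSpec] = {}
_ADDUCT_TABLE.update(_build_table(_COMMON_ADDUCT_NAMES))


def known_adducts(ionmode: Optional[str] = None) -> list[AdductSpec]:
    """Built-in common adducts in priority order, optionally one polarity."""
    specs = [_ADDUCT_TABLE[name] for name in _COMMON_ADDUCT_NAMES]
    if ionmode is None:
        return specs
    return [a for a in specs if a.ionmode == ionmode]


def parent_mass_from_precursor(precursor_mz: float, adduct: AdductSpec) -> float:
    """Neutral monoisotopic mass implied by a precursor m/z and adduct."""
    if precursor_mz <= 0:
        raise ValueError(f"precursor m/z must be positive, got {precursor_mz}")
    parent = (precursor_mz * abs(adduct.charge) - adduct.mass_shift) / adduct.multiplier
    if parent <= 0:
        raise ValueError(
            f"adduct {adduct.name} gives non-physical parent mass {parent:.6f} "
            f"for precursor m/z {precursor_mz:.6f}"
        )
    return parent


def precursor_from_parent(parent_mass: float, adduct: AdductSpec) -> float:
    """Precursor m/z of a neutral molecule ionized as the given adduct."""
    if parent_mass <= 0:
        raise ValueError(f"parent mass must be positive, got {parent_mass}")
    return (adduct.multiplier * parent_mass + adduct.mass_shift) / abs(adduct.charge)


# --- structure annotations -------------------------------------------------

INCHIKEY_PATTERN = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z0-9]$")


@dataclass(frozen=True)
class Annotation:
    """The structure fields of a library spectrum's annotation."""

    smiles: Optional[str] = None
    inchi: Optional[str] = None
    inchikey: Optional[str] = None
    compound_name: Optional[str] = None

    def structure_fields(self) -> dict[str, str]:
        present = {}
        if self.smiles:
            present["smiles"] = self.smiles
        if self.inchi:
            present["inchi"] = self.inchi
        if self.inchikey:
            present["inchikey"] = self.inchikey
        return present


class StructureBackend(Protocol):
    """Minimal contract a structure toolkit must satisfy.

    ``kind`` is ``"smiles"`` or ``"inchi"``. Implementations raise
    :class:`StructureParseError` for uninterpretable input.
    """

    def formula(self, structure: str, kind: str) -> dict[str, int]: ...

    def inchikey(self, structure: str, kind: str) -> str: ...

    def convert(self, structure: str, kind: str, to: str) -> str: ...


def _require_rdkit():
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.*")
    return Chem


@lru_cache(maxsize=200_000)
def _rdkit_mol_data(structure: str, kind: str) -> tuple[tuple[tuple[str, int], ...], str, str, str]:
    """(formula items, inchikey, smiles, inchi) for a structure, via RDKit."""
    Chem = _require_rdkit()
    if kind == "smiles":
        mol = Chem.MolFromSmiles(structure, sanitize=True)
    elif kind == "inchi":
        mol = Chem.MolFromInchi(structure, sanitize=True, treatWarningAsError=False)
    else:
        raise ValueError(f"unknown structure kind {kind!r}")
    if mol is None:
        raise StructureParseError(f"cannot parse {kind} {structure!r}")
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        counts[symbol] = counts.get(symbol, 0) + 1
        hydrogens = atom.GetTotalNumHs()
        if hydrogens:
            counts["H"] = counts.get("H", 0) + hydrogens
    inchi = Chem.MolToInchi(mol)
    if not inchi:
        raise StructureParseError(f"cannot derive InChI for {kind} {structure!r}")
    key = Chem.MolToInchiKey(mol)
    smiles = Chem.MolToSmiles(mol)
    return tuple(sorted(counts.items())), key, smiles, inchi


class RDKitBackend:
    """Default structure backend; wraps RDKit with per-string caching."""

    def formula(self, structure: str, kind: str) -> dict[str, int]:
        items, _, _, _ = _rdkit_mol_data(structure, kind)
        return dict(items)

    def inchikey(self, structure: str, kind: str) -> str:
        _, key, _, _ = _rdkit_mol_data(structure, kind)
        return key

    def convert(self, structure: str, kind: str, to: str) -> str:
        items, key, smiles, inchi = _rdkit_mol_data(structure, kind)
        if to == "smiles":
            return smiles
        if to == "inchi":
            return inchi
        if to == "inchikey":
            return key
        raise ValueError(f"unknown conversion target {to!r}")


class StubBackend:
    """Table-driven backend for toolkit-free tests.

    Knows only the structures it was given: each entry maps both its SMILES
    and InChI spelling to a (formula, inchikey, smiles, inchi) record.
    Multi-component SMILES are resolved component-wise when the composite
    string itself is unknown (formulas merge; identity fields unavailable).
    """

    def __init__(self, entries: Iterable[tuple[str, str, str, str]]):
        # entries: (smiles, inchi, inchikey, formula string)
        self._by_string: dict[str, tuple[dict[str, int], str, str, str]] = {}
        for smiles, inchi, inchikey, formula in entries:
            record = (parse_formula(formula), inchikey, smiles, inchi)
            self._by_string[smiles] = record
            if inchi:
                self._by_string[inchi] = record

    def _lookup(self, structure: str, kind: str) -> tuple[dict[str, int], str, str, str]:
        record = self._by_string.get(structure)
        if record is not None:
            return record
        if kind == "smiles" and "." in structure:
            merged: dict[str, int] = {}
            for component in split_components(structure):
                part = self._by_string.get(component)
                if part is None:
                    raise StructureParseError(f"stub backend: unknown component {component!r}")
                for symbol, count in part[0].items():
                    merged[symbol] = merged.get(symbol, 0) + count
            return merged, "", structure, ""
        raise StructureParseError(f"stub backend: unknown {kind} {structure!r}")

    def formula(self, structure: str, kind: str) -> dict[str, int]:
        return dict(self._lookup(structure, kind)[0])

    def inchikey(self, structure: str, kind: str) -> str:
        key = self._lookup(structure, kind)[1]
        if not key:
            raise StructureParseError(f"stub backend: no inchikey for {structure!r}")
        return key

    def convert(self, structure: str, kind: str, to: str) -> str:
        formula, key, smiles, inchi = self._lookup(structure, kind)
        value = {"smiles": smiles, "inchi": inchi, "inchikey": key}[to]
        if not value:
            raise StructureParseError(f"stub backend: cannot convert {structure!r} to {to}")
        return value


_DEFAULT_BACKEND: Optional[StructureBackend] = None


def default_backend() -> StructureBackend:
    global _DEFAULT_BACKEND
    if _DEFAULT_BACKEND is None:
        _DEFAULT_BACKEND = RDKitBackend()
    return _DEFAULT_BACKEND


def split_components(smiles: str) -> list[str]:
    """Split a SMILES on the component separator ``.``, order preserved."""
    return smiles.split(".") if smiles else [smiles]


def structure_monoisotopic_mass(smiles: str, backend: Optional[StructureBackend] = None) -> float:
    """Monoisotopic mass (Da) of a possibly multi-component structure."""
    backend = backend or default_backend()
    return monoisotopic_mass(backend.formula(smiles, "smiles"))


def structure_average_mass(smiles: str, backend: Optional[StructureBackend] = None) -> float:
    """Average (molar) mass (Da) of a possibly multi-component structure."""
    backend = backend or default_backend()
    return average_mass(backend.formula(smiles, "smiles"))


def first_block(inchikey: str) -> str:
    """First 14 characters of an InChIKey: the 2D-skeleton hash block."""
    return inchikey[:14]


def consistent_2d(annotation: Annotation, backend: Optional[StructureBackend] = None) -> bool:
    """True iff all present structure fields share one 2D skeleton.

    Each SMILES/InChI is hashed to an InChIKey and compared by its first
    block; an explicit InChIKey field contributes its own first block. An
    unparseable or ill-formed field yields ``False``, never an exception.
    """
    backend = backend or default_backend()
    fields = annotation.structure_fields()
    if not fields:
        raise ValueError("consistent_2d needs at least one structure field")
    blocks = set()
    for kind, value in fields.items():
        if kind == "inchikey":
            if not INCHIKEY_PATTERN.match(value):
                return False
            blocks.add(first_block(value))
        else:
            try:
                blocks.add(first_block(backend.inchikey(value, kind)))
            except StructureParseError:
                return False
    return len(blocks) == 1
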