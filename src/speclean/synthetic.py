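"""Synthetic dirty spectral libraries with ground-truth error ledgers.

Real library cleaning is validated against enormous public libraries; for
testing the pipeline itself we instead *generate* libraries in which every
spectrum carries exactly one known error class (or none), together with a
ledger stating what a correct cleaning run must do to it. The generator
covers the error classes the repair filters target:

====================== ====================================================
class                   injected defect
====================== ====================================================
none                    fully consistent spectrum
wrong_default_adduct    measured as [M+Na]+ but annotated with the unedited
                        default "[M+H]+" (precursor m/z is the sodium one)
molar_parent_mass       parent mass computed from standard atomic weights
                        instead of monoisotopic masses
salt_counterion         SMILES keeps a salt counterion the spectrometer
                        never measured; parent mass fits the main component
name_only_annotation    annotation is just a compound name; structure
                        fields missing
inconsistent_inchi      InChI (and InChIKey) belong to a different compound
                        than the mass-matching SMILES
too_few_peaks           barely fragmented: under five usable fragments
ionmode_adduct_conflict ion mode field contradicts the adduct polarity
unrepairable_garbage    parent mass is simply wrong; no field supports a
                        repair
====================== ====================================================

The first six classes after ``none`` are repairable; the last three must
be removed. Peak positions are random within the precursor range — the
filters under test only look at peak counts and relative intensities, so
no fragmentation chemistry is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np

from . import chem, repair
from .pipeline import ProcessingReport
from .spectrum import Spectrum, make_spectrum

__all__ = [
    "ERROR_CLASSES",
    "REPAIRABLE_CLASSES",
    "REMOVED_CLASSES",
    "MIXED_PROFILE",
    "EXPECTED_FATE",
    "CompoundEntry",
    "LedgerEntry",
    "ErrorLedger",
    "load_compound_table",
    "table_resolver",
    "stub_backend",
    "generate_library",
    "observed_fates",
    "score_cleaning",
    "replicate_name_annotation_validation",
]

ERROR_CLASSES = (
    "none",
    "wrong_default_adduct",
    "molar_parent_mass",
    "salt_counterion",
    "name_only_annotation",
    "inconsistent_inchi",
    "too_few_peaks",
    "ionmode_adduct_conflict",
    "unrepairable_garbage",
)

REPAIRABLE_CLASSES = frozenset(
    {
        "wrong_default_adduct",
        "molar_parent_mass",
        "salt_counterion",
        "name_only_annotation",
        "inconsistent_inchi",
    }
)
REMOVED_CLASSES = frozenset(
    {"too_few_peaks", "ionmode_adduct_conflict", "unrepairable_garbage"}
)

EXPECTED_FATE: Mapping[str, str] = {
    "none": "kept_unchanged",
    **{cls: "repaired_then_kept" for cls in REPAIRABLE_CLASSES},
    **{cls: "removed" for cls in REMOVED_CLASSES},
}

#: default class mix; the real-world frequencies of these error classes in
#: public libraries are unknown, so this mix is simply a broad exercise of
#: every pipeline path with a clean majority.
MIXED_PROFILE: Mapping[str, float] = {
    "none": 0.40,
    "wrong_default_adduct": 0.10,
    "molar_parent_mass": 0.08,
    "salt_counterion": 0.08,
    "name_only_annotation": 0.10,
    "inconsistent_inchi": 0.08,
    "too_few_peaks": 0.06,
    "ionmode_adduct_conflict": 0.05,
    "unrepairable_garbage": 0.05,
}


@dataclass(frozen=True)
class CompoundEntry:
    """One compound of the curated universe, all fields mutually consistent."""

    name: str
    formula: dict[str, int]
    smiles: str
    inchi: str
    inchikey: str
    monoisotopic_mass: float
    average_mass: float


@lru_cache(maxsize=1)
def load_compound_table() -> tuple[CompoundEntry, ...]:
    """The packaged compound table (~30 entries spanning 100-900 Da)."""
    text = resources.files("speclean.data").joinpath("compounds.tsv").read_text("utf-8")
    entries = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, formula, smiles, inchi, inchikey, mono, avg = line.split("\t")
        entries.append(
            CompoundEntry(
                name=name,
                formula=chem.parse_formula(formula),
                smiles=smiles,
                inchi=inchi,
                inchikey=inchikey,
                monoisotopic_mass=float(mono),
                average_mass=float(avg),
            )
        )
    return tuple(entries)


def table_resolver() -> repair.TableNameResolver:
    """A name resolver over the packaged compound table."""
    rows = [
        (
            entry.name,
            repair.Candidate(
                smiles=entry.smiles,
                inchi=entry.inchi,
                inchikey=entry.inchikey,
                monoisotopic_mass=entry.monoisotopic_mass,
            ),
        )
        for entry in load_compound_table()
    ]
    return repair.TableNameResolver(rows)


# salt counterions paired with their SMILES spelling and neutral formula
_COUNTERIONS = [
    ("Cl", "HCl"),  # hydrochloride
    ("Br", "HBr"),  # hydrobromide
    ("O", "H2O"),  # hydrate
    ("OC=O", "CH2O2"),  # formate
]


def stub_backend() -> chem.StubBackend:
    """Structure backend that knows the packaged compounds and counterions."""
    entries = [
        (e.smiles, e.inchi, e.inchikey, chem.formula_to_string(e.formula))
        for e in load_compound_table()
    ]
    entries.extend((smiles, "", "", formula) for smiles, formula in _COUNTERIONS)
    return chem.StubBackend(entries)


# --- ledger -----------------------------------------------------------------


@dataclass(frozen=True)
class LedgerEntry:
    spectrum_id: str
    error_class: str
    expected_fate: str
    compound_name: str


class ErrorLedger:
    """Ground truth for one generated library, in generation order."""

    def __init__(self, entries: Sequence[LedgerEntry], seed: int):
        self.entries = list(entries)
        self.seed = seed

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_id(self) -> dict[str, LedgerEntry]:
        return {entry.spectrum_id: entry for entry in self.entries}

    def count(self, *classes: str) -> int:
        wanted = set(classes)
        return sum(1 for entry in self.entries if entry.error_class in wanted)

    @property
    def repairable_count(self) -> int:
        return sum(1 for e in self.entries if e.error_class in REPAIRABLE_CLASSES)

    def to_tsv(self) -> str:
        lines = [f"# speclean synthetic ledger (seed {self.seed})"]
        lines.append("spectrum_id\terror_class\texpected_fate\tcompound_name")
        for entry in self.entries:
            lines.append(
                f"{entry.spectrum_id}\t{entry.error_class}"
                f"\t{entry.expected_fate}\t{entry.compound_name}"
            )
        return "\n".join(lines) + "\n"

    def write(self, path: str) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as handle:
            handle.write(self.to_tsv())


# --- generation -------------------------------------------------------------

_POSITIVE_ADDUCTS = ["[M+H]+", "[M+Na]+", "[M+NH4]+"]
_NEGATIVE_ADDUCTS = ["[M-H]-", "[M+Cl]-"]

# surface-form variants exercising value harmonization
_IONMODE_SPELLINGS = {"positive": ["positive", "Positive", "POS", "pos"],
                      "negative": ["negative", "Negative", "NEG", "neg"]}


@lru_cache(maxsize=None)
def _salt_identity(salt_smiles: str) -> tuple[str, str]:
    """InChI and InChIKey of a salted SMILES (internally consistent salt)."""
    backend = chem.default_backend()
    return (
        backend.convert(salt_smiles, "smiles", "inchi"),
        backend.convert(salt_smiles, "smiles", "inchikey"),
    )


def _peaks(rng: np.random.Generator, precursor: float, n_peaks: int):
    mz = np.sort(rng.uniform(50.0, max(60.0, precursor - 1.0), size=n_peaks))
    mz = np.round(mz, 4)
    while len(np.unique(mz)) < n_peaks:  # m/z must be ascending and distinct
        mz = np.sort(np.round(rng.uniform(50.0, max(60.0, precursor - 1.0), n_peaks), 4))
    intensities = np.round(rng.uniform(1.0, 1000.0, size=n_peaks), 3)
    if n_peaks >= 6:
        # guarantee >= 6 fragments above 2% of the base peak
        top = rng.choice(n_peaks, size=6, replace=False)
        intensities[top] = np.round(rng.uniform(50.0, 1000.0, size=6), 3)
    return mz, intensities


def _molar_eligible(entry: CompoundEntry) -> bool:
    # the average/monoisotopic gap must clear the 0.1 Da tolerance with margin
    return entry.average_mass - entry.monoisotopic_mass > 0.15


def generate_library(
    n: int,
    class_probabilities: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> tuple[list[Spectrum], ErrorLedger]:
    """Generate ``n`` spectra with exactly one error class each.

    Deterministic for a given seed. Clean fields are exact: the adduct is
    drawn from the common-adduct table, the precursor m/z follows from the
    parent mass by exact adduct algebra, and every injected error perturbs
    only the fields its repair filter targets.
    """
    profile = dict(class_probabilities or MIXED_PROFILE)
    unknown = set(profile) - set(ERROR_CLASSES)
    if unknown:
        raise ValueError(f"unknown error class(es): {sorted(unknown)}")
    classes = [cls for cls in ERROR_CLASSES if profile.get(cls, 0.0) > 0]
    weights = np.array([profile[cls] for cls in classes], dtype=float)
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0, atol=1e-9):
        raise ValueError("class probabilities must be non-negative and sum to 1")
    weights = weights / weights.sum()

    table = load_compound_table()
    if len(table) < 20:
        raise ValueError("compound table too small for generation")
    molar_pool = [e for e in table if _molar_eligible(e)]

    rng = np.random.default_rng(seed)
    spectra: list[Spectrum] = []
    ledger: list[LedgerEntry] = []
    for index in range(n):
        error_class = classes[int(rng.choice(len(classes), p=weights))]
        pool = molar_pool if error_class == "molar_parent_mass" else table
        entry = pool[int(rng.integers(len(pool)))]
        spectrum_id = f"SYN-{index:06d}"

        true_adduct_name = (
            "[M+Na]+"
            if error_class == "wrong_default_adduct"
            else (_POSITIVE_ADDUCTS + _NEGATIVE_ADDUCTS)[int(rng.integers(5))]
        )
        adduct = chem.parse_adduct(true_adduct_name)
        parent = entry.monoisotopic_mass
        precursor = chem.precursor_from_parent(parent, adduct)
        ionmode = adduct.ionmode

        metadata: dict[str, object] = {
            "spectrum_id": spectrum_id,
            "compound_name": entry.name,
            "adduct": adduct.name,
            "ionmode": _IONMODE_SPELLINGS[ionmode][int(rng.integers(4))],
            "charge": adduct.charge,
            "precursor_mz": round(precursor, 6),
            "parent_mass": round(parent, 6),
            "smiles": entry.smiles,
            "inchi": entry.inchi,
            "inchikey": entry.inchikey,
        }
        n_peaks = int(rng.integers(8, 41))

        if error_class == "wrong_default_adduct":
            # unedited default adduct: the measured ion was [M+Na]+, the
            # metadata claims [M+H]+ and a parent mass derived from it
            metadata["adduct"] = "[M+H]+"
            metadata["parent_mass"] = round(
                chem.parent_mass_from_precursor(precursor, chem.parse_adduct("[M+H]+")), 6
            )
        elif error_class == "molar_parent_mass":
            metadata["parent_mass"] = round(entry.average_mass, 6)
        elif error_class == "salt_counterion":
            counterion = _COUNTERIONS[int(rng.integers(len(_COUNTERIONS)))][0]
            salt_smiles = f"{entry.smiles}.{counterion}"
            inchi, inchikey = _salt_identity(salt_smiles)
            metadata["smiles"] = salt_smiles
            metadata["inchi"] = inchi
            metadata["inchikey"] = inchikey
        elif error_class == "name_only_annotation":
            del metadata["smiles"], metadata["inchi"], metadata["inchikey"]
        elif error_class == "inconsistent_inchi":
            # InChI/InChIKey copied from a clearly different compound
            other = table[int(rng.integers(len(table)))]
            while abs(other.monoisotopic_mass - entry.monoisotopic_mass) < 0.5:
                other = table[int(rng.integers(len(table)))]
            metadata["inchi"] = other.inchi
            metadata["inchikey"] = other.inchikey
        elif error_class == "too_few_peaks":
            n_peaks = int(rng.integers(1, 4))
        elif error_class == "ionmode_adduct_conflict":
            flipped = "negative" if ionmode == "positive" else "positive"
            metadata["ionmode"] = _IONMODE_SPELLINGS[flipped][int(rng.integers(4))]
        elif error_class == "unrepairable_garbage":
            # a parent mass that nothing supports: offset 5.5-7.5 Da, clear
            # of the molar-mass gap and of every common-adduct shift difference
            offset = 5.0 + float(rng.uniform(0.5, 2.5))
            wrong_parent = parent + offset
            metadata["parent_mass"] = round(wrong_parent, 6)
            metadata["precursor_mz"] = round(
                chem.precursor_from_parent(wrong_parent, adduct), 6
            )

        mz, intensities = _peaks(rng, float(metadata["precursor_mz"]), n_peaks)
        spectra.append(make_spectrum(metadata, mz, intensities))
        ledger.append(
            LedgerEntry(
                spectrum_id=spectrum_id,
                error_class=error_class,
                expected_fate=EXPECTED_FATE[error_class],
                compound_name=entry.name,
            )
        )
    return spectra, ErrorLedger(ledger, seed)


# --- scoring ----------------------------------------------------------------


def observed_fates(
    ledger: ErrorLedger, report: ProcessingReport, cleaned: Sequence[Spectrum]
) -> dict[str, str]:
    """Per-spectrum fate actually produced by a run, keyed by spectrum id."""
    if report.spectra_in != len(ledger):
        raise ValueError(
            f"report covers {report.spectra_in} spectra but ledger has {len(ledger)}"
        )
    kept_ids = {s.get("spectrum_id") for s in cleaned}
    ledger_ids = {entry.spectrum_id for entry in ledger}
    if not kept_ids <= ledger_ids:
        raise ValueError("cleaned spectra do not belong to this ledger's run")
    fates: dict[str, str] = {}
    for index, entry in enumerate(ledger):
        events = report.per_spectrum[index]
        if entry.spectrum_id not in kept_ids:
            fates[entry.spectrum_id] = "removed"
        elif ProcessingReport.is_repaired(events):
            fates[entry.spectrum_id] = "repaired_then_kept"
        else:
            fates[entry.spectrum_id] = "kept_unchanged"
    return fates


def score_cleaning(
    ledger: ErrorLedger, report: ProcessingReport, cleaned: Sequence[Spectrum]
) -> dict[str, object]:
    """Compare a cleaning run against the generator's ground truth.

    Returns fate agreement, the false-repair rate on clean spectra, repair
    recall per repairable class, removal recall/precision, and the overall
    repaired/removed fractions.
    """
    fates = observed_fates(ledger, report, cleaned)
    n = len(ledger)
    agree = sum(1 for e in ledger if fates[e.spectrum_id] == e.expected_fate)

    clean_entries = [e for e in ledger if e.error_class == "none"]
    false_repairs = sum(
        1 for e in clean_entries if fates[e.spectrum_id] == "repaired_then_kept"
    )

    per_class_recall: dict[str, float] = {}
    for cls in sorted(REPAIRABLE_CLASSES):
        members = [e for e in ledger if e.error_class == cls]
        if members:
            repaired = sum(
                1 for e in members if fates[e.spectrum_id] == "repaired_then_kept"
            )
            per_class_recall[cls] = repaired / len(members)

    should_remove = [e for e in ledger if e.expected_fate == "removed"]
    removed_ids = {sid for sid, fate in fates.items() if fate == "removed"}
    removal_recall = (
        sum(1 for e in should_remove if e.spectrum_id in removed_ids) / len(should_remove)
        if should_remove
        else 1.0
    )
    removal_precision = (
        sum(1 for e in should_remove if e.spectrum_id in removed_ids) / len(removed_ids)
        if removed_ids
        else 1.0
    )

    return {
        "n": n,
        "fate_agreement": agree / n if n else 1.0,
        "false_repair_rate": false_repairs / len(clean_entries) if clean_entries else 0.0,
        "repair_recall": per_class_recall,
        "removal_recall": removal_recall,
        "removal_precision": removal_precision,
        "fraction_repaired": sum(
            1 for fate in fates.values() if fate == "repaired_then_kept"
        )
        / n
        if n
        else 0.0,
        "fraction_removed": len(removed_ids) / n if n else 0.0,
    }


def replicate_name_annotation_validation(
    spectra: Sequence[Spectrum],
    resolver: Optional[repair.NameResolver] = None,
    mass_tolerance: float = repair.DEFAULT_MASS_TOLERANCE,
    backend: Optional[chem.StructureBackend] = None,
) -> dict[str, float]:
    """Audit the name-derivation repair by strip-and-rederive.

    Mirrors the error-rate estimation protocol for "derive annotation from
    compound name": take spectra with a complete, consistent annotation
    and a compound name, strip the structure fields, re-derive them from
    the name alone, and compare the recovered 2D skeleton (InChIKey first
    block) with the original. On the synthetic universe with the packaged
    resolver this recovers 100% with zero mismatches — the upper bound a
    real-world resolver is measured against.
    """
    resolver = resolver or table_resolver()
    backend = backend or chem.default_backend()
    selected = 0
    derived = 0
    mismatched = 0
    for spectrum in spectra:
        annotation = repair.annotation_of(spectrum)
        if not (annotation.smiles and annotation.inchikey and annotation.compound_name):
            continue
        if spectrum.get("parent_mass") is None:
            continue
        try:
            if not chem.consistent_2d(annotation, backend):
                continue
        except ValueError:
            continue
        selected += 1
        stripped = spectrum.with_metadata(smiles=None, inchi=None, inchikey=None)
        proposal = repair.propose_annotation_from_compound_name(
            stripped, resolver, mass_tolerance, backend
        )
        if proposal is None:
            continue
        derived += 1
        recovered_key = str(proposal.changes.get("inchikey", ""))
        if chem.first_block(recovered_key) != chem.first_block(annotation.inchikey):
            mismatched += 1
    return {
        "selected": float(selected),
        "derived_fraction": derived / selected if selected else 0.0,
        "mismatch_fraction": mismatched / derived if derived else 0.0,
    }
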