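"""Pipeline assembly: ordered filters, presets, reports, YAML workflows.

A workflow is an ordered, parameterized list of registered filters. The
order is not free: many filters depend on earlier ones (an adduct consumer
must run after the filter that extracts an adduct from the compound name),
so declared filters are automatically arranged into a predefined global
order — harmonization, then derivation, then intensity normalization, then
repairs, then requirements. Declaring the same filter set in any order
therefore yields identical results.

Running a pipeline produces the cleaned library plus a
:class:`ProcessingReport` that tallies, per filter, how many spectra were
removed, had metadata changed, or had peak data changed. The whole
configuration round-trips through a human-readable YAML file, so any
cleaning run can be rerun exactly from the file it wrote.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import yaml

from . import __version__, chem, harmonize, repair, require
from .spectrum import ChangeStatus, FilterOutcome, Spectrum, diff_spectra

__all__ = [
    "FilterStep",
    "WorkflowConfig",
    "WorkflowError",
    "ProcessingReport",
    "REPAIR_FILTERS",
    "REQUIRE_FILTERS",
    "registered_filters",
    "canonical_order",
    "build_preset",
    "run_pipeline",
    "write_workflow_yaml",
    "read_workflow_yaml",
    "write_report",
]

logger = logging.getLogger(__name__)


class WorkflowError(ValueError):
    """Raised for unknown filter ids or malformed workflow files."""


# --- filter registry --------------------------------------------------------
# Global order: key harmonization -> ionmode/adduct harmonization -> derive
# filters (adduct-from-name before any adduct consumer) -> intensity
# normalization -> repairs (name-derivation, salts, molar-mass,
# adduct-from-smiles, annotation conflicts) -> require filters.

_GLOBAL_ORDER = [
    "harmonize_metadata_keys",
    "harmonize_ionmode",
    "derive_adduct_from_name_or_comment",
    "harmonize_adduct",
    "derive_ionmode_from_adduct",
    "derive_parent_mass",
    "normalize_intensities",
    "derive_annotation_from_compound_name",
    "repair_smiles_of_salts",
    "repair_parent_mass_is_molar_mass",
    "repair_adduct_and_parent_mass_based_on_smiles",
    "repair_not_matching_annotation",
    "require_precursor_mz",
    "require_valid_annotation",
    "require_parent_mass_match_smiles",
    "require_matching_adduct_precursor_parent",
    "require_matching_adduct_and_ionmode",
    "require_minimum_number_of_high_peaks",
]
_ORDER_INDEX = {name: index for index, name in enumerate(_GLOBAL_ORDER)}

REPAIR_FILTERS = frozenset(
    {
        "derive_annotation_from_compound_name",
        "repair_smiles_of_salts",
        "repair_parent_mass_is_molar_mass",
        "repair_adduct_and_parent_mass_based_on_smiles",
        "repair_not_matching_annotation",
    }
)
REQUIRE_FILTERS = frozenset(name for name in _GLOBAL_ORDER if name.startswith("require_"))


@dataclass(frozen=True)
class RunContext:
    """Shared run-time services handed to filter factories."""

    resolver: Optional[repair.NameResolver] = None
    backend: Optional[chem.StructureBackend] = None
    mass_tolerance: float = repair.DEFAULT_MASS_TOLERANCE


def _tol(params: dict, context: RunContext) -> float:
    return float(params.get("mass_tolerance", context.mass_tolerance))


def _build_filter(name: str, params: dict, context: RunContext) -> Callable:
    if name == "harmonize_metadata_keys":
        return harmonize.harmonize_metadata_keys
    if name == "harmonize_ionmode":
        return harmonize.harmonize_ionmode
    if name == "harmonize_adduct":
        return harmonize.harmonize_adduct
    if name == "derive_adduct_from_name_or_comment":
        return harmonize.derive_adduct_from_name_or_comment
    if name == "derive_ionmode_from_adduct":
        return harmonize.derive_ionmode_from_adduct
    if name == "derive_parent_mass":
        allow_default = bool(params.get("allow_default_adduct", False))
        return lambda s: harmonize.derive_parent_mass(s, allow_default)
    if name == "normalize_intensities":
        return harmonize.normalize_intensities
    if name == "require_precursor_mz":
        maximum = float(params.get("maximum_mz", 5000.0))
        return lambda s: harmonize.require_precursor_mz(s, maximum)
    if name == "derive_annotation_from_compound_name":
        tolerance = _tol(params, context)
        resolver = context.resolver
        if resolver is None:
            logger.warning(
                "derive_annotation_from_compound_name has no name resolver; "
                "it will leave all spectra unchanged"
            )
            return lambda s: s
        return lambda s: repair.derive_annotation_from_compound_name(
            s, resolver, tolerance, context.backend
        )
    if name == "repair_smiles_of_salts":
        tolerance = _tol(params, context)
        return lambda s: repair.repair_smiles_of_salts(s, tolerance, context.backend)
    if name == "repair_parent_mass_is_molar_mass":
        tolerance = _tol(params, context)
        return lambda s: repair.repair_parent_mass_is_molar_mass(
            s, tolerance, context.backend
        )
    if name == "repair_adduct_and_parent_mass_based_on_smiles":
        tolerance = _tol(params, context)
        return lambda s: repair.repair_adduct_and_parent_mass_based_on_smiles(
            s, tolerance, context.backend
        )
    if name == "repair_not_matching_annotation":
        tolerance = _tol(params, context)
        return lambda s: repair.repair_not_matching_annotation(
            s, tolerance, context.backend
        )
    if name == "require_valid_annotation":
        return lambda s: require.require_valid_annotation(s, context.backend)
    if name == "require_parent_mass_match_smiles":
        tolerance = _tol(params, context)
        return lambda s: require.require_parent_mass_match_smiles(
            s, tolerance, context.backend
        )
    if name == "require_matching_adduct_precursor_parent":
        tolerance = _tol(params, context)
        return lambda s: require.require_matching_adduct_precursor_parent(s, tolerance)
    if name == "require_matching_adduct_and_ionmode":
        return require.require_matching_adduct_and_ionmode
    if name == "require_minimum_number_of_high_peaks":
        n_min = int(params.get("n_min", 5))
        fraction = float(params.get("intensity_fraction", 0.02))
        return lambda s: require.require_minimum_number_of_high_peaks(s, n_min, fraction)
    raise WorkflowError(f"unknown filter id {name!r}")


def registered_filters() -> list[str]:
    """All filter ids, in global (canonical) order."""
    return list(_GLOBAL_ORDER)


def canonical_order(filter_names: Sequence[str]) -> list[str]:
    """Arrange filter ids into the predefined global order.

    The sort is stable, duplicates collapse to one occurrence (with a
    warning) and unknown ids raise :class:`WorkflowError`.
    """
    unknown = [name for name in filter_names if name not in _ORDER_INDEX]
    if unknown:
        raise WorkflowError(f"unknown filter id(s): {', '.join(sorted(unknown))}")
    seen = set()
    unique: list[str] = []
    for name in filter_names:
        if name in seen:
            logger.warning("duplicate filter %r collapsed to one occurrence", name)
            continue
        seen.add(name)
        unique.append(name)
    return sorted(unique, key=_ORDER_INDEX.__getitem__)


# --- workflow configuration -------------------------------------------------


@dataclass(frozen=True)
class FilterStep:
    name: str
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class WorkflowConfig:
    """An ordered, parameterized filter list; round-trips through YAML."""

    filters: tuple[FilterStep, ...]
    preset: str = "custom"
    mass_tolerance: float = repair.DEFAULT_MASS_TOLERANCE
    tool_version: str = __version__

    def __post_init__(self) -> None:
        by_name = {step.name: step for step in self.filters}
        ordered = canonical_order([step.name for step in self.filters])
        object.__setattr__(
            self, "filters", tuple(by_name[name] for name in ordered)
        )

    def filter_names(self) -> list[str]:
        return [step.name for step in self.filters]


_PRESETS: dict[str, list[str]] = {
    "basic": [
        "harmonize_metadata_keys",
        "harmonize_ionmode",
        "harmonize_adduct",
    ],
    "default": [],
    "library_cleaning": [],
}
_PRESETS["default"] = _PRESETS["basic"] + [
    "derive_adduct_from_name_or_comment",
    "derive_ionmode_from_adduct",
    "derive_parent_mass",
    "normalize_intensities",
    "require_precursor_mz",
]
_PRESETS["library_cleaning"] = _PRESETS["default"] + sorted(
    REPAIR_FILTERS | (REQUIRE_FILTERS - {"require_precursor_mz"}),
    key=_ORDER_INDEX.__getitem__,
)


def build_preset(
    name: str,
    mass_tolerance: float = repair.DEFAULT_MASS_TOLERANCE,
    include_repairs: bool = True,
) -> WorkflowConfig:
    """One of the nested presets: basic ⊂ default ⊂ library_cleaning.

    ``basic`` harmonizes metadata only; ``default`` additionally derives
    missing fields, requires a precursor m/z and normalizes intensities;
    ``library_cleaning`` adds all repair filters and, after them, all
    requirement filters. ``include_repairs=False`` drops the repair
    filters (the with/without-repairs contrast used to quantify how many
    spectra the repairs rescue).
    """
    if name not in _PRESETS:
        raise WorkflowError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    filter_names = [
        fid for fid in _PRESETS[name] if include_repairs or fid not in REPAIR_FILTERS
    ]
    return WorkflowConfig(
        filters=tuple(FilterStep(fid) for fid in filter_names),
        preset=name if include_repairs else "custom",
        mass_tolerance=mass_tolerance,
    )


# --- processing report ------------------------------------------------------


@dataclass
class FilterCounters:
    removed: int = 0
    metadata_changed: int = 0
    peaks_changed: int = 0


class ProcessingReport:
    """Per-filter change tally over one pipeline run.

    Counts how many spectra each filter removed, metadata-changed or
    peaks-changed; a spectrum may appear under several filters' change
    counters but is counted removed exactly once, at the first filter that
    rejected it. ``per_spectrum`` keeps the event list of every input
    spectrum (by input position) for ground-truth scoring.
    """

    def __init__(self, filter_names: Sequence[str], tool_version: str = __version__):
        self.filter_names = list(filter_names)
        self.tool_version = tool_version
        self.counters: dict[str, FilterCounters] = {
            name: FilterCounters() for name in self.filter_names
        }
        self.spectra_in = 0
        self.spectra_out = 0
        self.per_spectrum: list[list[FilterOutcome]] = []

    # -- tallying

    def record(self, outcomes: list[FilterOutcome], kept: bool) -> None:
        self.spectra_in += 1
        self.spectra_out += int(kept)
        self.per_spectrum.append(outcomes)
        for outcome in outcomes:
            counter = self.counters[outcome.filter_name]
            for status in outcome.statuses:
                if status is ChangeStatus.REMOVED:
                    counter.removed += 1
                elif status is ChangeStatus.METADATA_CHANGED:
                    counter.metadata_changed += 1
                elif status is ChangeStatus.PEAKS_CHANGED:
                    counter.peaks_changed += 1

    # -- totals

    @property
    def spectra_removed(self) -> int:
        return self.spectra_in - self.spectra_out

    @property
    def spectra_with_any_repair(self) -> int:
        return sum(1 for events in self.per_spectrum if self.is_repaired(events))

    @staticmethod
    def is_repaired(events: Sequence[FilterOutcome]) -> bool:
        return any(
            outcome.filter_name in REPAIR_FILTERS and outcome.changed
            for outcome in events
        )

    def removing_filter(self, index: int) -> Optional[str]:
        for outcome in self.per_spectrum[index]:
            if outcome.removed:
                return outcome.filter_name
        return None

    def totals(self) -> dict[str, int]:
        return {
            "spectra_in": self.spectra_in,
            "spectra_out": self.spectra_out,
            "spectra_removed": self.spectra_removed,
            "spectra_with_any_repair": self.spectra_with_any_repair,
        }

    # -- rendering

    def rows(self) -> list[tuple[str, int, int, int]]:
        return [
            (
                name,
                self.counters[name].removed,
                self.counters[name].metadata_changed,
                self.counters[name].peaks_changed,
            )
            for name in self.filter_names
        ]

    def to_tsv(self) -> str:
        lines = [f"# speclean processing report (version {self.tool_version})"]
        lines.append("filter\tremoved\tmetadata_changed\tpeaks_changed")
        for name, removed, meta, peaks in self.rows():
            lines.append(f"{name}\t{removed}\t{meta}\t{peaks}")
        for key, value in self.totals().items():
            lines.append(f"{key}\t{value}")
        return "\n".join(lines) + "\n"

    def to_markdown(self) -> str:
        lines = [f"# Processing report (speclean {self.tool_version})", ""]
        lines.append("| filter | removed | metadata changed | peaks changed |")
        lines.append("| --- | ---: | ---: | ---: |")
        for name, removed, meta, peaks in self.rows():
            lines.append(f"| {name} | {removed} | {meta} | {peaks} |")
        lines.append("")
        for key, value in self.totals().items():
            lines.append(f"- {key}: {value}")
        return "\n".join(lines) + "\n"


def write_report(report: ProcessingReport, path: str, format: str = "tsv") -> None:
    """Write a processing report as TSV or Markdown (same numbers)."""
    if format == "tsv":
        text = report.to_tsv()
    elif format == "markdown":
        text = report.to_markdown()
    else:
        raise ValueError(f"unknown report format {format!r}")
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write(text)


# --- running ----------------------------------------------------------------


def run_pipeline(
    spectra: Sequence[Spectrum],
    config: WorkflowConfig,
    resolver: Optional[repair.NameResolver] = None,
    backend: Optional[chem.StructureBackend] = None,
) -> tuple[list[Spectrum], ProcessingReport]:
    """Apply a workflow's filters, in canonical order, to every spectrum.

    Removed spectra are excluded from the output; the report tallies every
    change. Deterministic: identical inputs and configuration give
    identical outputs and report. A filter exception aborts the run naming
    the spectrum index and filter id.
    """
    context = RunContext(
        resolver=resolver, backend=backend, mass_tolerance=config.mass_tolerance
    )
    steps = [
        (step.name, _build_filter(step.name, dict(step.params), context))
        for step in config.filters
    ]
    report = ProcessingReport([name for name, _ in steps])
    cleaned: list[Spectrum] = []
    for index, spectrum in enumerate(spectra):
        current = spectrum
        outcomes: list[FilterOutcome] = []
        for name, fn in steps:
            try:
                result = fn(current)
            except Exception as exc:
                raise RuntimeError(
                    f"filter {name!r} failed on spectrum {index}: {exc}"
                ) from exc
            outcome = diff_spectra(current, result, name)
            if outcome.changed:
                outcomes.append(outcome)
                logger.debug("spectrum %d: %s -> %s", index, name, outcome.statuses)
            if result is None:
                current = None
                break
            current = result
        kept = current is not None
        if kept:
            cleaned.append(current)
        report.record(outcomes, kept)
    for name, counter in report.counters.items():
        logger.info(
            "%s: removed=%d metadata_changed=%d peaks_changed=%d",
            name,
            counter.removed,
            counter.metadata_changed,
            counter.peaks_changed,
        )
    return cleaned, report


# --- YAML workflows ---------------------------------------------------------


def write_workflow_yaml(config: WorkflowConfig, path: str) -> None:
    """Serialize a workflow so the run can be repeated exactly."""
    document = {
        "tool": "speclean",
        "tool_version": config.tool_version,
        "preset": config.preset,
        "mass_tolerance": config.mass_tolerance,
        "filters": [
            {"name": step.name, "params": dict(step.params)} for step in config.filters
        ],
    }
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        yaml.safe_dump(document, handle, sort_keys=False)


def read_workflow_yaml(path: str) -> WorkflowConfig:
    """Load a workflow file; filters are re-canonicalized on load.

    A version mismatch warns but proceeds as long as every filter id still
    resolves; an unknown filter id is an error.
    """
    with open(path, "r", encoding="utf-8") as handle:
        document = yaml.safe_load(handle)
    if not isinstance(document, dict) or "filters" not in document:
        raise WorkflowError(f"not a workflow file: {path}")
    version = str(document.get("tool_version", ""))
    if version and version != __version__:
        logger.warning(
            "workflow %s was written by version %s; this is version %s",
            path,
            version,
            __version__,
        )
    steps = []
    for entry in document["filters"]:
        if not isinstance(entry, dict) or "name" not in entry:
            raise WorkflowError(f"malformed filter entry {entry!r} in {path}")
        steps.append(FilterStep(entry["name"], dict(entry.get("params") or {})))
    config = WorkflowConfig(
        filters=tuple(steps),
        preset=str(document.get("preset", "custom")),
        mass_tolerance=float(
            document.get("mass_tolerance", repair.DEFAULT_MASS_TOLERANCE)
        ),
        tool_version=version or __version__,
    )
    return config
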