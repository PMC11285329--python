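"""Core data model: an annotated MS/MS spectrum and change tracking.

A :class:`Spectrum` couples a harmonized metadata map (lowercase,
underscore-separated keys; numeric values parsed) with sorted fragment
arrays. Filters never mutate a spectrum in place — they return a new
spectrum, the same object (meaning "unchanged"), or ``None`` (removal) —
and :func:`diff_spectra` classifies what a filter did for the processing
report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "SpectrumError",
    "ChangeStatus",
    "FilterOutcome",
    "make_spectrum",
    "diff_spectra",
    "harmonize_key",
    "key_alias_table",
]


class SpectrumError(ValueError):
    """Raised when spectrum construction preconditions are violated."""


# --- metadata key harmonization --------------------------------------------

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def key_alias_table() -> dict[str, str]:
    """The packaged raw-key -> harmonized-key alias table."""
    table: dict[str, str] = {}
    text = resources.files("speclean.data").joinpath("key_aliases.tsv").read_text("utf-8")
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        raw, harmonized = line.split("\t")
        table[raw] = harmonized
    return table


_ALIASES: Optional[dict[str, str]] = None


def harmonize_key(raw_key: str) -> str:
    """Lowercase, normalize punctuation to underscores, then alias-map."""
    global _ALIASES
    if _ALIASES is None:
        _ALIASES = key_alias_table()
    key = _NON_ALNUM.sub("_", str(raw_key).strip().lower()).strip("_")
    return _ALIASES.get(key, key)


_CHARGE_RE = re.compile(r"^\s*([+-]?)(\d+)\s*([+-]?)\s*$")
_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _parse_charge(value) -> Optional[int]:
    """Parse charge spellings like ``1+``, ``2-``, ``-2``, ``+1``, ``1``."""
    if isinstance(value, (int, np.integer)):
        return int(value)
    if isinstance(value, float) and value == int(value):
        return int(value)
    match = _CHARGE_RE.match(str(value))
    if not match:
        return None
    lead, digits, trail = match.groups()
    if lead and trail:
        return None
    sign = -1 if "-" in (lead, trail) else 1
    return sign * int(digits)


def _parse_value(key: str, value):
    """Parse metadata values: numeric strings to numbers, charge to int."""
    if value is None:
        return None
    if key == "charge":
        charge = _parse_charge(value)
        return charge if charge is not None else str(value).strip()
    if isinstance(value, (int, float, np.integer, np.floating)):
        return int(value) if isinstance(value, (int, np.integer)) else float(value)
    text = str(value).strip()
    if not text or text.lower() in {"none", "n/a", "na", "nan", ""}:
        return None
    if key == "precursor_mz" and " " in text:
        # tolerate MGF-style "mz intensity" tuples; the m/z is the first token
        text = text.split()[0]
    if _NUMBER_RE.match(text):
        number = float(text)
        if re.match(r"^[+-]?\d+$", text):
            return int(text)
        return number
    return text


# --- spectrum ---------------------------------------------------------------


@dataclass(frozen=True)
class Spectrum:
    """An annotated MS/MS spectrum.

    ``metadata`` maps harmonized keys to parsed values; ``mz`` is ascending
    (ties keep input order) and ``intensities`` is non-negative with the
    same length. Treated as immutable: arrays are write-locked and filters
    produce new instances via :meth:`replace`.
    """

    metadata: Mapping[str, object]
    mz: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        if mz.ndim != 1 or intensities.ndim != 1 or len(mz) != len(intensities):
            raise SpectrumError(
                f"m/z and intensity arrays must be 1-D and equal length, "
                f"got {mz.shape} and {intensities.shape}"
            )
        if len(intensities) and float(intensities.min()) < 0:
            raise SpectrumError("negative fragment intensity")
        if len(mz) > 1 and np.any(np.diff(mz) < 0):
            raise SpectrumError("fragment m/z values must be ascending")
        mz.setflags(write=False)
        intensities.setflags(write=False)
        object.__setattr__(self, "metadata", dict(self.metadata))
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensities", intensities)

    def get(self, key: str, default=None):
        return self.metadata.get(key, default)

    @property
    def n_peaks(self) -> int:
        return len(self.mz)

    def replace(
        self,
        metadata: Optional[Mapping[str, object]] = None,
        mz: Optional[np.ndarray] = None,
        intensities: Optional[np.ndarray] = None,
    ) -> "Spectrum":
        """A copy with the given parts substituted (the rest shared)."""
        return Spectrum(
            metadata=dict(self.metadata if metadata is None else metadata),
            mz=self.mz if mz is None else mz,
            intensities=self.intensities if intensities is None else intensities,
        )

    def with_metadata(self, **updates) -> "Spectrum":
        """A copy with metadata keys set (``None`` deletes a key)."""
        metadata = dict(self.metadata)
        for key, value in updates.items():
            if value is None:
                metadata.pop(key, None)
            else:
                metadata[key] = value
        return self.replace(metadata=metadata)

    def metadata_equal(self, other: "Spectrum") -> bool:
        return dict(self.metadata) == dict(other.metadata)

    def peaks_equal(self, other: "Spectrum") -> bool:
        return (
            self.n_peaks == other.n_peaks
            and bool(np.array_equal(self.mz, other.mz))
            and bool(np.array_equal(self.intensities, other.intensities))
        )

    def __eq__(self, other) -> bool:  # value equality, for round-trip tests
        if not isinstance(other, Spectrum):
            return NotImplemented
        return self.metadata_equal(other) and self.peaks_equal(other)


def make_spectrum(
    raw_metadata: Mapping[str, object],
    mz: Sequence[float],
    intensities: Sequence[float],
) -> Spectrum:
    """Build a :class:`Spectrum` from raw metadata and peak arrays.

    Keys are lowercased and alias-mapped (first occurrence wins on alias
    collisions), numeric values are parsed, empty values dropped, and peaks
    are stably sorted by m/z so ties keep their input order.
    """
    metadata: dict[str, object] = {}
    for raw_key, raw_value in raw_metadata.items():
        key = harmonize_key(raw_key)
        if not key:
            continue
        value = _parse_value(key, raw_value)
        if value is None:
            continue
        if key not in metadata:
            metadata[key] = value

    mz_arr = np.asarray(mz, dtype=float)
    int_arr = np.asarray(intensities, dtype=float)
    if mz_arr.ndim != 1 or int_arr.ndim != 1 or len(mz_arr) != len(int_arr):
        raise SpectrumError(
            f"m/z and intensity arrays must be 1-D and equal length, "
            f"got {mz_arr.shape} and {int_arr.shape}"
        )
    if len(mz_arr):
        order = np.argsort(mz_arr, kind="stable")
        mz_arr = mz_arr[order]
        int_arr = int_arr[order]
    return Spectrum(metadata=metadata, mz=mz_arr, intensities=int_arr)


# --- change tracking --------------------------------------------------------


class ChangeStatus(str, Enum):
    UNCHANGED = "unchanged"
    METADATA_CHANGED = "metadata_changed"
    PEAKS_CHANGED = "peaks_changed"
    REMOVED = "removed"


@dataclass(frozen=True)
class FilterOutcome:
    """What one filter did to one spectrum.

    A filter that changes both metadata and peaks carries both statuses;
    the processing report counts each category independently.
    """

    filter_name: str
    statuses: tuple[ChangeStatus, ...]
    detail: Optional[str] = None

    @property
    def status(self) -> ChangeStatus:
        return self.statuses[0]

    @property
    def removed(self) -> bool:
        return ChangeStatus.REMOVED in self.statuses

    @property
    def changed(self) -> bool:
        return self.statuses != (ChangeStatus.UNCHANGED,)


def diff_spectra(
    before: Spectrum,
    after: Optional[Spectrum],
    filter_name: str,
    detail: Optional[str] = None,
) -> FilterOutcome:
    """Classify a filter application for the processing report."""
    if after is None:
        return FilterOutcome(filter_name, (ChangeStatus.REMOVED,), detail)
    if after is before:
        return FilterOutcome(filter_name, (ChangeStatus.UNCHANGED,), detail)
    statuses: list[ChangeStatus] = []
    if not before.metadata_equal(after):
        statuses.append(ChangeStatus.METADATA_CHANGED)
    if not before.peaks_equal(after):
        statuses.append(ChangeStatus.PEAKS_CHANGED)
    if not statuses:
        statuses.append(ChangeStatus.UNCHANGED)
    return FilterOutcome(filter_name, tuple(statuses), detail)
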