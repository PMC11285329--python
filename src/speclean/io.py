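"""Reading and writing spectral libraries in MGF, MSP and JSON.

The three formats are the common library-exchange trio:

* **MGF** (Mascot generic format): ``BEGIN IONS``/``END IONS`` blocks with
  ``KEY=value`` metadata lines; read through :mod:`pyteomics.mgf`.
* **MSP** (NIST text records): ``Key: value`` lines followed by
  ``Num Peaks: n`` and n peak lines.
* **JSON**: an array of ``{"metadata": {...}, "mz": [...], "intensities": [...]}``
  records holding harmonized metadata directly.

All metadata keys are preserved (lowercased and alias-harmonized by
:func:`speclean.spectrum.make_spectrum`). Writing is deterministic —
canonical key order, fixed float precision, UTF-8, ``\\n`` line endings —
so two writes of the same library are byte-identical and a cleaning run
can be reproduced byte-for-byte from its workflow file.
"""

from __future__ import annotations

import json
import math
import os
import re
from typing import Iterable, Optional, Sequence

from .spectrum import Spectrum, make_spectrum

__all__ = [
    "LibraryFormatError",
    "detect_format",
    "read_library",
    "write_library",
]


class LibraryFormatError(ValueError):
    """Raised for malformed library files, naming the offending record."""


_EXTENSIONS = {".mgf": "mgf", ".msp": "msp", ".json": "json"}

#: metadata keys written first, in this order; the rest follow alphabetically
CANONICAL_KEY_ORDER = [
    "compound_name",
    "precursor_mz",
    "charge",
    "ionmode",
    "adduct",
    "parent_mass",
    "formula",
    "smiles",
    "inchi",
    "inchikey",
    "comment",
    "spectrum_id",
]

#: metadata keys rendered with fixed 6-decimal precision (mass-like values)
_MASS_KEYS = {"precursor_mz", "parent_mass"}


def detect_format(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in _EXTENSIONS:
        raise LibraryFormatError(f"cannot detect library format from extension {ext!r}")
    return _EXTENSIONS[ext]


# --- reading ----------------------------------------------------------------


def _read_mgf(path: str) -> list[Spectrum]:
    from pyteomics import mgf

    spectra: list[Spectrum] = []
    try:
        with mgf.MGF(str(path), convert_arrays=1) as reader:
            for index, entry in enumerate(reader):
                try:
                    params = dict(entry.get("params", {}))
                    if "pepmass" in params:
                        pepmass = params.pop("pepmass")
                        if isinstance(pepmass, (tuple, list)):
                            pepmass = pepmass[0]
                        params["pepmass"] = pepmass
                    if "charge" in params:
                        charge = params["charge"]
                        if isinstance(charge, (tuple, list)) and len(charge):
                            charge = charge[0]
                        params["charge"] = int(charge)
                    spectra.append(
                        make_spectrum(params, entry["m/z array"], entry["intensity array"])
                    )
                except Exception as exc:
                    raise LibraryFormatError(
                        f"malformed MGF record {index} in {path}: {exc}"
                    ) from exc
    except LibraryFormatError:
        raise
    except Exception as exc:
        raise LibraryFormatError(f"cannot parse MGF file {path}: {exc}") from exc
    return spectra


_MSP_KV = re.compile(r"^([^:]+):\s?(.*)$")
_MSP_PEAK = re.compile(r"^\s*([0-9.eE+-]+)[\s;,\t]+([0-9.eE+-]+)")


def _read_msp(path: str) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    with open(path, "r", encoding="utf-8") as handle:
        lines = handle.read().splitlines()
    index = 0
    record = 0
    n_lines = len(lines)
    while index < n_lines:
        if not lines[index].strip():
            index += 1
            continue
        metadata: dict[str, object] = {}
        n_peaks: Optional[int] = None
        record_label = f"MSP record {record}"
        while index < n_lines and lines[index].strip():
            match = _MSP_KV.match(lines[index])
            if match is None:
                raise LibraryFormatError(
                    f"{record_label} in {path}: expected 'Key: value', got {lines[index]!r}"
                )
            key, value = match.group(1).strip(), match.group(2).strip()
            index += 1
            if key.lower().replace(" ", "_") in {"num_peaks", "numpeaks"}:
                try:
                    n_peaks = int(value)
                except ValueError as exc:
                    raise LibraryFormatError(
                        f"{record_label} in {path}: bad peak count {value!r}"
                    ) from exc
                break
            metadata[key] = value
            if key.lower() == "name":
                record_label = f"MSP record {record} ({value!r})"
        if n_peaks is None:
            raise LibraryFormatError(f"{record_label} in {path}: missing 'Num Peaks'")
        mz: list[float] = []
        intensities: list[float] = []
        while index < n_lines and lines[index].strip() and len(mz) < n_peaks:
            peak = _MSP_PEAK.match(lines[index])
            if peak is None:
                raise LibraryFormatError(
                    f"{record_label} in {path}: expected peak line, got {lines[index]!r}"
                )
            mz.append(float(peak.group(1)))
            intensities.append(float(peak.group(2)))
            index += 1
        if len(mz) != n_peaks:
            raise LibraryFormatError(
                f"{record_label} in {path}: 'Num Peaks: {n_peaks}' but only "
                f"{len(mz)} peak lines"
            )
        try:
            spectra.append(make_spectrum(metadata, mz, intensities))
        except Exception as exc:
            raise LibraryFormatError(f"{record_label} in {path}: {exc}") from exc
        record += 1
    return spectra


def _read_json(path: str) -> list[Spectrum]:
    with open(path, "r", encoding="utf-8") as handle:
        try:
            records = json.load(handle)
        except json.JSONDecodeError as exc:
            raise LibraryFormatError(f"cannot parse JSON library {path}: {exc}") from exc
    if not isinstance(records, list):
        raise LibraryFormatError(f"JSON library {path} must be an array of records")
    spectra: list[Spectrum] = []
    for index, record in enumerate(records):
        try:
            spectra.append(
                make_spectrum(
                    record.get("metadata", {}),
                    record.get("mz", []),
                    record.get("intensities", []),
                )
            )
        except Exception as exc:
            raise LibraryFormatError(
                f"malformed JSON record {index} in {path}: {exc}"
            ) from exc
    return spectra


def read_library(path: str, format: str = "auto") -> list[Spectrum]:
    """Read a spectral library; one :class:`Spectrum` per record.

    ``format`` is ``"mgf"``, ``"msp"``, ``"json"`` or ``"auto"`` (detected
    from the file extension). An empty file yields an empty list; a
    malformed record raises :class:`LibraryFormatError` naming it.
    """
    if format == "auto":
        format = detect_format(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "mgf":
        return _read_mgf(path)
    if format == "msp":
        return _read_msp(path)
    if format == "json":
        return _read_json(path)
    raise LibraryFormatError(f"unknown library format {format!r}")


# --- writing ----------------------------------------------------------------


def _ordered_keys(metadata: dict) -> list[str]:
    head = [key for key in CANONICAL_KEY_ORDER if key in metadata]
    tail = sorted(key for key in metadata if key not in CANONICAL_KEY_ORDER)
    return head + tail


def _format_value(key: str, value) -> str:
    if key == "charge" and isinstance(value, int):
        return f"{abs(value)}{'+' if value >= 0 else '-'}"
    if isinstance(value, float):
        if key in _MASS_KEYS or not math.isfinite(value):
            return f"{value:.6f}"
        if value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return f"{value:.6f}"
    return str(value)


def _format_peaks(spectrum: Spectrum, separator: str) -> list[str]:
    return [
        f"{mz:.6f}{separator}{intensity:.6f}"
        for mz, intensity in zip(spectrum.mz, spectrum.intensities)
    ]


_MGF_KEY = {"precursor_mz": "PEPMASS", "compound_name": "NAME"}


def _write_mgf(spectra: Sequence[Spectrum], path: str) -> None:
    lines: list[str] = []
    for spectrum in spectra:
        lines.append("BEGIN IONS")
        for key in _ordered_keys(dict(spectrum.metadata)):
            mgf_key = _MGF_KEY.get(key, key.upper())
            lines.append(f"{mgf_key}={_format_value(key, spectrum.metadata[key])}")
        lines.extend(_format_peaks(spectrum, " "))
        lines.append("END IONS")
        lines.append("")
    _write_text(path, lines)


def _msp_key(key: str) -> str:
    return "Name" if key == "compound_name" else key.capitalize()


def _write_msp(spectra: Sequence[Spectrum], path: str) -> None:
    lines: list[str] = []
    for spectrum in spectra:
        metadata = dict(spectrum.metadata)
        keys = _ordered_keys(metadata)
        if "compound_name" in metadata:  # MSP records conventionally start with Name:
            keys = ["compound_name"] + [k for k in keys if k != "compound_name"]
        for key in keys:
            lines.append(f"{_msp_key(key)}: {_format_value(key, metadata[key])}")
        lines.append(f"Num Peaks: {spectrum.n_peaks}")
        lines.extend(_format_peaks(spectrum, "\t"))
        lines.append("")
    _write_text(path, lines)


def _json_value(key: str, value):
    if isinstance(value, float):
        return float(f"{value:.6f}") if key in _MASS_KEYS else value
    return value


def _write_json(spectra: Sequence[Spectrum], path: str) -> None:
    records = []
    for spectrum in spectra:
        metadata = dict(spectrum.metadata)
        records.append(
            {
                "metadata": {
                    key: _json_value(key, metadata[key]) for key in _ordered_keys(metadata)
                },
                "mz": [round(float(v), 6) for v in spectrum.mz],
                "intensities": [round(float(v), 6) for v in spectrum.intensities],
            }
        )
    text = json.dumps(records, indent=2, ensure_ascii=False)
    _write_text(path, [text])


def _write_text(path: str, lines: Iterable[str]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\n".join(lines))
        handle.write("\n")


def write_library(spectra: Sequence[Spectrum], path: str, format: str = "auto") -> None:
    """Write a library deterministically (byte-identical on rewrite).

    Metadata keys appear in canonical order; m/z, intensities and mass-like
    metadata are rendered with 6 decimals; absent fields are omitted rather
    than written as a ``None`` placeholder.
    """
    if format == "auto":
        format = detect_format(path)
    if format == "mgf":
        _write_mgf(spectra, path)
    elif format == "msp":
        _write_msp(spectra, path)
    elif format == "json":
        _write_json(spectra, path)
    else:
        raise LibraryFormatError(f"unknown library format {format!r}")
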