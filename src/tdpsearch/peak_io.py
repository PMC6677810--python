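"""Reading deconvolved peak lists and writing ranked search results.

Input spectra are *deconvolved* MS2 peak lists: each peak is a neutral
monoisotopic fragment mass with a relative intensity.  Four container formats
are supported (MGF, mzML, mzXML and two-column flat text), in single-file and
batch (directory) modes.  Charge annotations, if present, are ignored — the
numbers in the m/z column are taken to already be neutral masses, as produced
by upstream deconvolution tools.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, FormatError

log = logging.getLogger(__name__)

FRAGMENTATION_MODES = (
    "CID", "HCD", "ECD", "ETD", "EDD", "UVPD", "SID", "BIRD", "IRMPD",
)

_EXTENSIONS = {
    ".mgf": "mgf",
    ".mzml": "mzml",
    ".mzxml": "mzxml",
    ".txt": "flat_text",
    ".tsv": "flat_text",
    ".dat": "flat_text",
    ".peaks": "flat_text",
}

#: merge tolerance for duplicate peak masses (Da)
DUPLICATE_TOL = 1e-6


@dataclass(frozen=True)
class Peak:
    """One deconvolved fragment observation."""

    mass: float       # neutral monoisotopic mass, Da
    intensity: float  # relative abundance, arbitrary units

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"peak mass must be positive, got {self.mass}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class SpectrumRecord:
    """One MS2 scan: precursor intact mass plus its sorted fragment peak list."""

    spectrum_id: str
    precursor_mass: float
    peaks: tuple[Peak, ...]
    fragmentation_mode: str = "CID"
    source_file: str = ""
    scan_number: int | None = None

    def __post_init__(self) -> None:
        if self.precursor_mass <= 0:
            raise ValueError("precursor mass must be positive")
        if self.fragmentation_mode not in FRAGMENTATION_MODES:
            raise ValueError(f"unknown fragmentation mode {self.fragmentation_mode!r}")

    @property
    def masses(self) -> np.ndarray:
        return np.array([p.mass for p in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)


def make_record(
    spectrum_id: str,
    precursor_mass: float,
    masses: Sequence[float],
    intensities: Sequence[float],
    **kwargs,
) -> SpectrumRecord:
    """Build a record with peaks sorted ascending and near-duplicate masses merged.

    Masses closer than ``DUPLICATE_TOL`` are merged by summing their
    intensities, so a fragment-match count is well defined.  Zero-intensity
    peaks are retained.
    """
    order = np.argsort(np.asarray(masses, dtype=float), kind="stable")
    merged: list[list[float]] = []
    for idx in order:
        m, i = float(masses[idx]), float(intensities[idx])
        if merged and m - merged[-1][0] <= DUPLICATE_TOL:
            merged[-1][1] += i
        else:
            merged.append([m, i])
    peaks = tuple(Peak(m, i) for m, i in merged)
    return SpectrumRecord(spectrum_id, float(precursor_mass), peaks, **kwargs)


def _detect_format(path: Path) -> str:
    fmt = _EXTENSIONS.get(path.suffix.lower())
    if fmt is None:
        raise FormatError(f"cannot infer format from extension of {path.name!r}")
    return fmt


def read_spectra(
    path: str | os.PathLike,
    format: str = "auto",
    precursor_mass: float | None = None,
    fragmentation_mode: str = "CID",
) -> list[SpectrumRecord]:
    """Read all MS2 spectra from one file into :class:`SpectrumRecord` objects.

    ``precursor_mass`` is required for flat-text input (the format carries no
    precursor); for the other formats it is ignored in favor of the value
    embedded in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _detect_format(path)
    reader = {
        "mgf": _read_mgf,
        "mzml": _read_mzml,
        "mzxml": _read_mzxml,
        "flat_text": _read_flat_text,
    }.get(format)
    if reader is None:
        raise ConfigurationError(f"unknown spectrum format {format!r}")
    return reader(path, precursor_mass, fragmentation_mode)


def _read_mgf(path: Path, precursor: float | None, mode: str) -> list[SpectrumRecord]:
    from pyteomics import mgf

    records = []
    with mgf.MGF(str(path)) as reader:
        for n, spec in enumerate(reader):
            params = spec.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise FormatError(f"{path.name}: spectrum {n} has no PEPMASS")
            if params.get("charge"):
                log.info("%s: ignoring CHARGE field (deconvolved neutral masses assumed)", path.name)
            title = str(params.get("title", "")) or f"scan={n + 1}"
            records.append(
                make_record(
                    f"{path.name}:{title}",
                    float(pepmass[0]),
                    spec["m/z array"],
                    spec["intensity array"],
                    fragmentation_mode=mode,
                    source_file=str(path),
                    scan_number=n + 1,
                )
            )
    return records


def _decode_binary(text: str, dtype: str, compressed: bool, byte_order: str = "<") -> np.ndarray:
    import base64
    import zlib

    raw = base64.b64decode(text.strip())
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=np.dtype(byte_order + dtype))


def _read_mzml(path: Path, precursor: float | None, mode: str) -> list[SpectrumRecord]:
    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    records = []
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path.name}: {exc}") from exc
    for spec in tree.iter(f"{ns}spectrum"):
        params = {
            cv.get("accession"): cv.get("value")
            for cv in spec.iter(f"{ns}cvParam")
        }
        if params.get("MS:1000511", "2") != "2":  # ms level
            continue
        ion = spec.find(f".//{ns}selectedIon")
        if ion is None:
            raise FormatError(f"{path.name}: spectrum {spec.get('id')!r} lacks a precursor element")
        prec = None
        for cv in ion.iter(f"{ns}cvParam"):
            if cv.get("accession") == "MS:1000744":  # selected ion m/z
                prec = float(cv.get("value"))
        if prec is None:
            raise FormatError(f"{path.name}: spectrum {spec.get('id')!r} lacks a selected ion m/z")
        arrays = {}
        for arr in spec.iter(f"{ns}binaryDataArray"):
            acc = {cv.get("accession") for cv in arr.iter(f"{ns}cvParam")}
            dtype = "f4" if "MS:1000521" in acc else "f8"
            compressed = "MS:1000574" in acc
            name = "mz" if "MS:1000514" in acc else "intensity" if "MS:1000515" in acc else None
            binary = arr.find(f"{ns}binary")
            if name and binary is not None and binary.text:
                arrays[name] = _decode_binary(binary.text, dtype, compressed)
        if "mz" not in arrays or "intensity" not in arrays:
            raise FormatError(f"{path.name}: spectrum {spec.get('id')!r} lacks m/z or intensity arrays")
        sid = str(spec.get("id", ""))
        scan = None
        for token in sid.split():
            if token.startswith("scan="):
                scan = int(token.split("=", 1)[1])
        records.append(
            make_record(
                f"{path.name}:{sid}",
                prec,
                arrays["mz"],
                arrays["intensity"],
                fragmentation_mode=mode,
                source_file=str(path),
                scan_number=scan,
            )
        )
    return records


def _read_mzxml(path: Path, precursor: float | None, mode: str) -> list[SpectrumRecord]:
    from lxml import etree

    ns = "{http://sashimi.sourceforge.net/schema_revision/mzXML_3.2}"
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path.name}: {exc}") from exc
    root_tag = tree.getroot().tag
    if root_tag.startswith("{"):
        ns = root_tag.split("}")[0] + "}"
    else:
        ns = ""
    records = []
    for scan in tree.iter(f"{ns}scan"):
        if scan.get("msLevel", "2") != "2":
            continue
        prec_el = scan.find(f"{ns}precursorMz")
        if prec_el is None or not prec_el.text:
            raise FormatError(f"{path.name}: scan {scan.get('num')!r} lacks a precursorMz element")
        prec = float(prec_el.text)
        peaks_el = scan.find(f"{ns}peaks")
        if peaks_el is None or peaks_el.text is None:
            raise FormatError(f"{path.name}: scan {scan.get('num')!r} lacks a peaks element")
        dtype = "f8" if peaks_el.get("precision", "32") == "64" else "f4"
        compressed = peaks_el.get("compressionType", "none") == "zlib"
        data = _decode_binary(peaks_el.text, dtype, compressed, byte_order=">")
        num = int(scan.get("num")) if scan.get("num") else None
        records.append(
            make_record(
                f"{path.name}:scan={num}",
                prec,
                data[0::2],
                data[1::2],
                fragmentation_mode=mode,
                source_file=str(path),
                scan_number=num,
            )
        )
    return records


def _read_flat_text(path: Path, precursor: float | None, mode: str) -> list[SpectrumRecord]:
    if precursor is None:
        raise ConfigurationError(
            f"{path.name}: flat-text input carries no precursor mass; "
            "supply one via precursor_mass / --precursor-mass"
        )
    masses, intensities = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise FormatError(f"{path.name}:{lineno}: expected two numeric columns, got {line!r}")
        try:
            masses.append(float(parts[0]))
            intensities.append(float(parts[1]))
        except ValueError as exc:
            raise FormatError(f"{path.name}:{lineno}: non-numeric value in {line!r}") from exc
    return [
        make_record(
            f"{path.name}",
            precursor,
            masses,
            intensities,
            fragmentation_mode=mode,
            source_file=str(path),
        )
    ]


def read_batch(
    dir_path: str | os.PathLike,
    format: str,
    precursor_mass: float | None = None,
    fragmentation_mode: str = "CID",
) -> list[SpectrumRecord]:
    """Read every matching file in a directory, sorted by filename."""
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise FileNotFoundError(dir_path)
    wanted = {ext for ext, fmt in _EXTENSIONS.items() if format in (fmt, "auto")}
    files = sorted(p for p in dir_path.iterdir() if p.suffix.lower() in wanted)
    if not files:
        log.warning("batch directory %s contains no %s files", dir_path, format)
        return []
    records: list[SpectrumRecord] = []
    for f in files:
        records.extend(
            read_spectra(f, "auto" if format == "auto" else format, precursor_mass, fragmentation_mode)
        )
    return records


RESULT_COLUMNS = (
    "spectrum_id",
    "accession",
    "is_decoy",
    "modifications",
    "truncation",
    "unexplained_shift",
    "score_mass",
    "score_pst",
    "score_insilico",
    "score_final",
    "n_matched",
    "e_value",
    "q_value",
)


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_results(prsms: Iterable, path: str | os.PathLike) -> None:
    """Write proteoform-spectrum matches to a TSV, sorted by final score descending."""
    rows = sorted(prsms, key=lambda p: (-p.score_final, p.accession, p.spectrum_id))
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for p in rows:
            pf = p.proteoform
            mods = ";".join(f"{s.ptm.name}@{s.position}" for s in pf.modifications) or "-"
            trunc = f"{pf.truncation[0]}:{pf.truncation[1]}" if pf.truncation else "-"
            fh.write(
                "\t".join(
                    _fmt(v)
                    for v in (
                        p.spectrum_id,
                        p.accession,
                        p.is_decoy,
                        mods,
                        trunc,
                        pf.unexplained_shift,
                        p.score_mass,
                        p.score_pst,
                        p.score_insilico,
                        p.score_final,
                        p.n_matched,
                        p.e_value,
                        p.q_value,
                    )
                )
                + "\n"
            )
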