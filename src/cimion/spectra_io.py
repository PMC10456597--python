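"""Spectral format I/O: MSP in; MSP/CSV/MGF/SIRIUS-MS out.

All writers are deterministic byte-for-byte for a fixed input and emit
UTF-8 text with '.' decimal points. The MSP reader accepts NIST-style
records with space- or semicolon-delimited peak pairs and preserves
unknown header fields verbatim.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import IO, Dict, Iterable, List, Optional, Sequence, Tuple

__all__ = [
    "Spectrum",
    "MspParseError",
    "read_msp",
    "write_msp",
    "write_csv",
    "write_mgf",
    "write_sirius_ms",
]


@dataclass
class Spectrum:
    """A centroided peak list with free-form metadata.

    Peaks are kept sorted ascending by m/z; intensities must be >= 0.
    """

    peaks: List[Tuple[float, float]]
    metadata: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("negative peak intensity")
        self.peaks = sorted(self.peaks, key=lambda p: p[0])

    @property
    def name(self) -> str:
        return self.metadata.get("Name", "")

    @property
    def base_peak(self) -> Tuple[float, float]:
        if not self.peaks:
            raise ValueError("spectrum has no peaks")
        return max(self.peaks, key=lambda p: p[1])

    def normalized(self) -> "Spectrum":
        """Copy with intensities scaled so the base peak is 1."""
        bp = self.base_peak[1]
        if bp <= 0:
            raise ValueError("base peak intensity is zero")
        return Spectrum([(mz, i / bp) for mz, i in self.peaks], dict(self.metadata))


class MspParseError(ValueError):
    """Malformed MSP input; message carries record name / line number."""


_PAIR = re.compile(r"([0-9.eE+-]+)[\s:]+([0-9.eE+-]+)")


def read_msp(stream: IO[str]) -> List[Spectrum]:
    """Parse NIST-style MSP records from a text stream.

    Each record: ``Name:`` line, optional ``Key: value`` header lines, a
    ``Num Peaks: N`` line, then N m/z-intensity pairs separated by
    whitespace or semicolons, possibly several pairs per line. Records are
    separated by blank lines.
    """
    spectra: List[Spectrum] = []
    metadata: Dict[str, str] = {}
    peaks: List[Tuple[float, float]] = []
    expected: Optional[int] = None

    def flush(lineno: int) -> None:
        nonlocal metadata, peaks, expected
        if not metadata and not peaks:
            return
        name = metadata.get("Name", "<unnamed>")
        if expected is None:
            raise MspParseError(f"record {name!r}: missing 'Num Peaks' header")
        if len(peaks) != expected:
            raise MspParseError(
                f"record {name!r}: declared Num Peaks: {expected} "
                f"but parsed {len(peaks)} (near line {lineno})"
            )
        spectra.append(Spectrum(peaks, metadata))
        metadata, peaks, expected = {}, [], None

    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            flush(lineno)
            continue
        if expected is None:
            if ":" not in line:
                raise MspParseError(f"line {lineno}: expected 'Key: value' header, got {line!r}")
            key, _, value = line.partition(":")
            key, value = key.strip(), value.strip()
            if key.lower() == "num peaks":
                try:
                    expected = int(value)
                except ValueError:
                    raise MspParseError(f"line {lineno}: bad Num Peaks value {value!r}") from None
            else:
                metadata[key] = value
        else:
            for chunk in line.split(";"):
                chunk = chunk.strip()
                if not chunk:
                    continue
                m = _PAIR.fullmatch(chunk)
                if m is None:
                    raise MspParseError(f"line {lineno}: unparseable peak pair {chunk!r}")
                try:
                    peaks.append((float(m.group(1)), float(m.group(2))))
                except ValueError:
                    raise MspParseError(f"line {lineno}: unparseable peak pair {chunk!r}") from None
    flush(lineno=-1)
    return spectra


def _fmt(x: float) -> str:
    """Compact decimal rendering without float repr noise."""
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


def write_msp(spectra: Iterable[Spectrum], stream: IO[str]) -> None:
    """Write NIST-style MSP records; metadata written verbatim, then peaks."""
    for spec in spectra:
        meta = dict(spec.metadata)
        if "Name" in meta:
            stream.write(f"Name: {meta.pop('Name')}\n")
        for key, value in meta.items():
            stream.write(f"{key}: {value}\n")
        stream.write(f"Num Peaks: {len(spec.peaks)}\n")
        for mz, inten in spec.peaks:
            stream.write(f"{_fmt(mz)} {_fmt(inten)}\n")
        stream.write("\n")


def write_csv(spectra: Iterable[Spectrum], stream: IO[str]) -> None:
    """Long-format CSV: one row per peak, columns name, mz, intensity."""
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(["name", "mz", "intensity"])
    for spec in spectra:
        for mz, inten in spec.peaks:
            writer.writerow([spec.name, _fmt(mz), _fmt(inten)])


def write_mgf(
    spectra_with_assignment: Sequence[Tuple[Spectrum, "MolecularIonAssignment"]],
    stream: IO[str],
) -> None:
    """Mascot generic format, one BEGIN IONS block per assigned spectrum.

    PEPMASS is the precursor m/z of the detector assignment; charge is 1+.
    """
    for spec, assignment in spectra_with_assignment:
        if assignment is None or assignment.precursor_mz is None:
            raise ValueError(f"spectrum {spec.name!r} has no molecular-ion assignment")
        stream.write("BEGIN IONS\n")
        stream.write(f"TITLE={spec.name}\n")
        stream.write(f"PEPMASS={assignment.precursor_mz:.4f}\n")
        stream.write("CHARGE=1+\n")
        for mz, inten in spec.peaks:
            stream.write(f"{_fmt(mz)} {_fmt(inten)}\n")
        stream.write("END IONS\n")


def write_sirius_ms(
    spectrum: Spectrum,
    assignment: "MolecularIonAssignment",
    stream: IO[str],
    formula_hint: Optional[str] = None,
) -> None:
    """SIRIUS .ms input file: compound header plus an ms1 peak block."""
    if assignment is None or assignment.precursor_mz is None:
        raise ValueError(f"spectrum {spectrum.name!r} has no molecular-ion assignment")
    name = spectrum.name or "unknown"
    stream.write(f">compound {name}\n")
    stream.write(f">parentmass {assignment.precursor_mz:.4f}\n")
    stream.write(f">ionization {assignment.base_species.label}\n")
    if formula_hint:
        stream.write(f">formula {formula_hint}\n")
    stream.write(">ms1\n")
    for mz, inten in spectrum.peaks:
        stream.write(f"{_fmt(mz)} {_fmt(inten)}\n")


def to_string(writer, *args) -> str:
    """Run any of the write_* functions into a string."""
    buf = io.StringIO()
    writer(*args, buf)
    return buf.getvalue()
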