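"""Emission-spectrum data model and parameter extraction.

A fluorometer scan is represented as an :class:`EmissionSpectrum`: a strictly
increasing wavelength grid (nm) with non-negative intensity counts.  Two scalar
parameters are extracted from each scan:

* the peak emission intensity ``I_E`` — the number of counts at the spectral
  maximum (for Nile Red stained cells excited at 488 nm the maximum sits near
  570 nm, but the peak is located on the data, not assumed);
* the emission area ``A_E`` — the trapezoidal integral of the spectrum over
  its recorded wavelength range, in counts·nm.

Both quantities are *relative*: they scale with excitation-lamp intensity and
instrument gain, which is exactly why the quantum-yield route in
:mod:`lipidqy.photophysics` exists.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SpectrumValidationError

__all__ = [
    "EmissionSpectrum",
    "AbsorbanceReading",
    "FluorescenceReading",
    "validate_spectrum",
    "peak_intensity",
    "emission_area",
    "read_spectrum_file",
    "write_spectrum_file",
    "read_manifest",
]


@dataclass(frozen=True)
class EmissionSpectrum:
    """One fluorometer emission scan.

    Attributes
    ----------
    wavelengths : ndarray
        Strictly increasing wavelength grid in nm, length >= 3.
    intensities : ndarray
        Non-negative, finite fluorescence counts, same length as the grid.
    excitation_wavelength : float
        Excitation wavelength in nm (488 for Nile Red work here).
    diagnostics : tuple of str
        Non-fatal warnings recorded at validation time.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    excitation_wavelength: float = 488.0
    diagnostics: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise SpectrumValidationError(
                "wavelengths and intensities must be 1-D sequences of equal length"
            )
        if wl.size < 3:
            raise SpectrumValidationError(
                f"spectrum needs at least 3 points, got {wl.size}"
            )
        if not np.all(np.isfinite(wl)):
            raise SpectrumValidationError("non-finite wavelength value")
        if np.any(np.diff(wl) <= 0):
            raise SpectrumValidationError("wavelength grid is not strictly increasing")
        if not np.all(np.isfinite(it)):
            raise SpectrumValidationError("non-finite intensity value")
        if np.any(it < 0):
            raise SpectrumValidationError("negative intensity value")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    def scaled(self, factor: float) -> "EmissionSpectrum":
        """Return a copy with all intensities multiplied by ``factor`` (>= 0)."""
        if factor < 0:
            raise SpectrumValidationError("scaling factor must be non-negative")
        return EmissionSpectrum(
            self.wavelengths.copy(),
            self.intensities * factor,
            self.excitation_wavelength,
            self.diagnostics,
        )


@dataclass(frozen=True)
class AbsorbanceReading:
    """Optical densities for one sample: OD at the exciting wavelength (488 nm)
    plus the OD_600 cell-density proxy used for dilution bookkeeping."""

    od_488: float
    od_600: float | None = None

    def __post_init__(self) -> None:
        if self.od_488 < 0:
            raise SpectrumValidationError("od_488 must be >= 0")
        if self.od_600 is not None and self.od_600 < 0:
            raise SpectrumValidationError("od_600 must be >= 0 when present")


@dataclass(frozen=True)
class FluorescenceReading:
    """One stained-cell measurement: spectrum, absorbances and the derived
    relative parameters I_E (peak counts) and A_E (counts·nm)."""

    spectrum: EmissionSpectrum
    absorbance: AbsorbanceReading
    i_e: float
    a_e: float
    peak_wavelength: float
    label: str = ""

    @classmethod
    def from_measurements(
        cls,
        spectrum: EmissionSpectrum,
        absorbance: AbsorbanceReading,
        label: str = "",
    ) -> "FluorescenceReading":
        """Extract I_E and A_E from a spectrum and bundle the reading."""
        i_e, peak_wl = peak_intensity(spectrum)
        a_e = emission_area(spectrum)
        return cls(spectrum, absorbance, i_e, a_e, peak_wl, label)


def validate_spectrum(
    wavelengths: Sequence[float],
    intensities: Sequence[float],
    excitation: float = 488.0,
) -> EmissionSpectrum:
    """Validate raw wavelength/intensity columns into an :class:`EmissionSpectrum`.

    Raises :class:`SpectrumValidationError` on a non-increasing grid, negative
    or non-finite intensities, or fewer than 3 points.  An excitation
    wavelength at or below the start of the emission grid is legal but unusual
    (the scan would not bracket scattered excitation light), so it is recorded
    as a diagnostic rather than an error.
    """
    spec = EmissionSpectrum(np.asarray(wavelengths, dtype=float),
                            np.asarray(intensities, dtype=float),
                            float(excitation))
    diags = []
    if excitation <= spec.wavelengths[0]:
        diags.append(
            f"excitation wavelength {excitation} nm is at or below the start "
            f"of the emission grid ({spec.wavelengths[0]} nm)"
        )
    if diags:
        spec = EmissionSpectrum(spec.wavelengths, spec.intensities,
                                spec.excitation_wavelength, tuple(diags))
    return spec


def peak_intensity(spectrum: EmissionSpectrum) -> tuple[float, float]:
    """Peak emission intensity I_E and the wavelength at which it occurs.

    The peak is the global maximum over the recorded grid; ties are broken
    toward the lowest wavelength so the result is deterministic.

    Returns
    -------
    (i_e, peak_wavelength)
    """
    idx = int(np.argmax(spectrum.intensities))  # argmax returns first maximum
    return float(spectrum.intensities[idx]), float(spectrum.wavelengths[idx])


def emission_area(
    spectrum: EmissionSpectrum,
    window: tuple[float, float] | None = None,
    baseline: float = 0.0,
) -> float:
    """Emission area A_E: trapezoidal integral of intensity over wavelength.

    By default the full recorded grid is integrated with no baseline
    correction.  ``window=(lo, hi)`` restricts integration to grid points in
    [lo, hi]; ``baseline`` subtracts a constant before integrating (negative
    excursions are clipped to zero so the area stays non-negative).
    """
    wl, it = spectrum.wavelengths, spectrum.intensities
    if window is not None:
        lo, hi = window
        mask = (wl >= lo) & (wl <= hi)
        if mask.sum() < 2:
            raise SpectrumValidationError(
                f"integration window [{lo}, {hi}] contains fewer than 2 grid points"
            )
        wl, it = wl[mask], it[mask]
    if baseline:
        it = np.clip(it - baseline, 0.0, None)
    return float(np.trapezoid(it, wl))


# ---------------------------------------------------------------------------
# plain-text I/O

def read_spectrum_file(path: str | os.PathLike, excitation: float = 488.0) -> EmissionSpectrum:
    """Read a two-column delimited spectrum file (CSV or TSV, auto-detected).

    Column 1 is wavelength in nm, column 2 intensity in counts.  A single
    header line is tolerated; lines beginning with '#' are comments.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise SpectrumValidationError(f"{path}: no data lines")
    sep = "\t" if "\t" in lines[0] else ","
    # drop a header line if its first field is not numeric
    first = lines[0].split(sep)[0].strip()
    try:
        float(first)
    except ValueError:
        lines = lines[1:]
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep=sep, header=None,
                     usecols=[0, 1], names=["wavelength_nm", "intensity"])
    return validate_spectrum(df["wavelength_nm"].to_numpy(),
                             df["intensity"].to_numpy(), excitation)


def write_spectrum_file(spectrum: EmissionSpectrum, path: str | os.PathLike) -> None:
    """Write a spectrum as CSV with a header line and a '#' metadata comment."""
    p = Path(path)
    with p.open("w", encoding="utf-8") as fh:
        fh.write(f"# excitation_nm={spectrum.excitation_wavelength:g}\n")
        fh.write("wavelength_nm,intensity\n")
        for wl, it in zip(spectrum.wavelengths, spectrum.intensities):
            fh.write(f"{wl:.10g},{it:.10g}\n")


MANIFEST_COLUMNS = [
    "sample_id", "spectrum_path", "od_488", "od_600",
    "strain", "medium", "month", "replicate",
]


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read an experiment manifest (one row per reading).

    Required columns: sample_id, spectrum_path, od_488, od_600, strain,
    medium, month, replicate.  spectrum_path is resolved relative to the
    manifest's directory.
    """
    p = Path(path)
    sep = "\t" if p.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(p, sep=sep, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SpectrumValidationError(f"{path}: manifest missing columns {missing}")
    df["spectrum_path"] = [str((p.parent / sp).resolve()) for sp in df["spectrum_path"]]
    return df
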