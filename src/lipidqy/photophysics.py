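"""Comparative fluorescence quantum-yield computation.

The fluorescence quantum yield ``phi_fl`` — photons emitted per photon
absorbed — is an absolute photophysical property, independent of lamp
intensity, lamp age and fluorometer gain.  It is obtained here by the
comparative (relative) method against a reference dye of known yield, Nile
Red dissolved in acetone with ``phi(s) = 0.32``:

    phi_fl = [I_A(s) * A_E * eta**2] / [I_A * A_E(s) * eta(s)**2] * phi(s)

where ``I_A = 1 - 10**(-OD_488)`` is the fraction of 488 nm excitation light
absorbed (Beer–Lambert), ``A_E`` the integrated emission area, and ``eta`` the
refractive index of each solvent (aqueous PBS for the stained-cell suspension,
acetone for the standard).

Because the standard is re-measured in the same session as the samples, any
multiplicative lamp factor applied to every emission intensity cancels in the
``A_E / A_E(s)`` ratio — the mechanism that makes phi_fl-based lipid
calibration robust to lamp aging, unlike raw peak intensity or area.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError, DomainError, UndefinedRatioError
from .spectra import EmissionSpectrum, FluorescenceReading, emission_area, peak_intensity

__all__ = [
    "PHI_STANDARD_NILE_RED_ACETONE",
    "ETA_ACETONE",
    "ETA_AQUEOUS",
    "ReferenceStandard",
    "QuantumYieldResult",
    "absorbed_fraction",
    "quantum_yield",
    "quantum_yield_for_reading",
    "InstrumentConfig",
    "load_instrument_config",
]

#: Literature quantum yield of Nile Red dissolved in acetone.
PHI_STANDARD_NILE_RED_ACETONE = 0.32
#: Handbook refractive index of acetone (sodium D line, 20 C).
ETA_ACETONE = 1.359
#: Handbook refractive index of water / dilute PBS.
ETA_AQUEOUS = 1.333


@dataclass(frozen=True)
class ReferenceStandard:
    """Reference-dye measurement for one session.

    phi_s is the known quantum yield of the standard solution, eta_s its
    solvent's refractive index, od_488_s its optical density at the exciting
    wavelength and a_e_s its integrated emission area measured in the same
    session as the samples.  The standard's peak intensity i_e_s is recorded
    for completeness but does not enter the quantum-yield formula, which uses
    areas.
    """

    phi_s: float = PHI_STANDARD_NILE_RED_ACETONE
    eta_s: float = ETA_ACETONE
    od_488_s: float = 0.30
    a_e_s: float = 1.0
    i_e_s: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.phi_s <= 1.0):
            raise ConfigurationError(f"phi_s must be in (0, 1], got {self.phi_s}")
        if self.eta_s <= 1.0:
            raise ConfigurationError(f"eta_s must exceed 1 (vacuum), got {self.eta_s}")
        if self.od_488_s <= 0:
            raise ConfigurationError(f"od_488_s must be > 0, got {self.od_488_s}")
        if self.a_e_s <= 0:
            raise ConfigurationError(f"a_e_s must be > 0, got {self.a_e_s}")

    @classmethod
    def from_spectrum(
        cls,
        spectrum: EmissionSpectrum,
        od_488_s: float,
        phi_s: float = PHI_STANDARD_NILE_RED_ACETONE,
        eta_s: float = ETA_ACETONE,
    ) -> "ReferenceStandard":
        """Build a session standard from its measured emission spectrum."""
        i_e, _ = peak_intensity(spectrum)
        return cls(phi_s=phi_s, eta_s=eta_s, od_488_s=od_488_s,
                   a_e_s=emission_area(spectrum), i_e_s=i_e)


@dataclass(frozen=True)
class QuantumYieldResult:
    """Outcome of one comparative quantum-yield computation."""

    phi_fl: float
    i_a: float
    i_a_s: float
    eta: float
    #: set when phi_fl > 1, which is unphysical and signals bad inputs
    warning: str | None = None


def absorbed_fraction(od_488: float) -> float:
    """Fraction of incident excitation light absorbed: ``1 - 10**(-OD_488)``.

    Strictly increasing in OD and confined to [0, 1).  Negative optical
    densities are rejected.
    """
    if od_488 < 0:
        raise DomainError(f"optical density must be >= 0, got {od_488}")
    return 1.0 - 10.0 ** (-od_488)


def quantum_yield(
    sample_area: float,
    sample_od488: float,
    eta: float,
    standard: ReferenceStandard,
) -> QuantumYieldResult:
    """Sample fluorescence quantum yield by the comparative method.

    Parameters
    ----------
    sample_area : float
        Integrated emission area A_E of the sample, counts*nm (>= 0).
    sample_od488 : float
        Optical density of the sample at the exciting wavelength (> 0; a zero
        absorbed fraction makes the ratio undefined).
    eta : float
        Refractive index of the sample's solvent (> 1).
    standard : ReferenceStandard
        Same-session reference measurement supplying phi_s, eta_s, OD and area.

    Returns
    -------
    QuantumYieldResult
        phi_fl together with the absorbed fractions used.  phi_fl > 1 is
        reported with a warning flag rather than raised: it indicates noisy or
        inconsistent inputs that the caller should inspect, not a programming
        error.
    """
    if sample_area < 0:
        raise DomainError(f"sample_area must be >= 0, got {sample_area}")
    if sample_od488 <= 0:
        raise UndefinedRatioError(
            "sample OD_488 must be > 0: a zero absorbed fraction makes the "
            "comparative ratio undefined"
        )
    if eta <= 1.0:
        raise DomainError(f"eta must exceed 1 (vacuum), got {eta}")
    i_a = absorbed_fraction(sample_od488)
    i_a_s = absorbed_fraction(standard.od_488_s)
    phi = (i_a_s * sample_area * eta**2) / (i_a * standard.a_e_s * standard.eta_s**2) * standard.phi_s
    warning = None
    if phi > 1.0:
        warning = f"phi_fl = {phi:.4g} exceeds 1; inputs are likely inconsistent"
    return QuantumYieldResult(phi_fl=phi, i_a=i_a, i_a_s=i_a_s, eta=eta, warning=warning)


def quantum_yield_for_reading(
    reading: FluorescenceReading,
    standard: ReferenceStandard,
    eta: float = ETA_AQUEOUS,
) -> QuantumYieldResult:
    """Convenience wrapper: quantum yield of a bundled fluorescence reading."""
    return quantum_yield(reading.a_e, reading.absorbance.od_488, eta, standard)


@dataclass(frozen=True)
class InstrumentConfig:
    """Standard/instrument constants, loadable from YAML."""

    phi_s: float = PHI_STANDARD_NILE_RED_ACETONE
    eta_s: float = ETA_ACETONE
    eta_sample: float = ETA_AQUEOUS
    excitation_nm: float = 488.0


def load_instrument_config(path: str | os.PathLike | None) -> InstrumentConfig:
    """Load an :class:`InstrumentConfig` from a YAML file; defaults if None."""
    if path is None:
        return InstrumentConfig()
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    known = {k: float(v) for k, v in data.items()
             if k in {"phi_s", "eta_s", "eta_sample", "excitation_nm"}}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigurationError(f"unknown instrument-config keys: {sorted(unknown)}")
    return InstrumentConfig(**known)
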