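"""Synthetic fluorometry campaigns with lamp aging.

This module generates the full data a fluorometric lipid-quantification
campaign produces — emission spectra, OD_488 absorbances and gravimetric
lipid truths over an OD_600 dilution series, across measurement sessions
months apart — with the statistical structure the analysis assumes:

* a single-Gaussian Nile Red emission band centred near 570 nm (488 nm
  excitation), whose noise-free integral is the sample's true emission area;
* true lipid content proportional to dilution: at OD_600 = d the diluted
  sample carries ``d * lipid_at_od1`` % w/w;
* a sample's intrinsic quantum yield proportional to its lipid content, so
  its true emission area is ``emission_per_lipid * lipid * I_A`` where
  ``I_A`` is the absorbed fraction at 488 nm — emission scales with both how
  much light is absorbed and how lipid-rich the cells are;
* a session-level multiplicative lamp factor ``L = exp(-decay_rate * hours)``
  applied to every emission intensity in the session (samples and reference
  standard alike), emulating xenon-lamp intensity loss with cumulative use;
* multiplicative log-normal measurement noise with a stated coefficient of
  variation, drawn once per scan (fluorometric repeatability is dominated by
  scan-to-scan factors — alignment, source flicker — common to all points of
  one scan).

All randomness flows from the explicit per-session seed, so a campaign is
bit-reproducible.  Count magnitudes are arbitrary instrument units; only
ratios and calibrated quantities are meaningful.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, DomainError
from .photophysics import (
    ETA_ACETONE,
    PHI_STANDARD_NILE_RED_ACETONE,
    ReferenceStandard,
    absorbed_fraction,
)
from .spectra import (
    AbsorbanceReading,
    EmissionSpectrum,
    FluorescenceReading,
    write_spectrum_file,
)

__all__ = [
    "SCAN_START_NM",
    "SCAN_STOP_NM",
    "SCAN_STEP_NM",
    "DEFAULT_LAMP_DECAY_RATE",
    "StrainProfile",
    "SessionConfig",
    "SessionResult",
    "SyntheticCampaign",
    "generate_spectrum",
    "generate_session",
    "generate_campaign",
    "default_campaign_configs",
    "write_campaign",
]

# Emission scan window and step (nm).  The acquisition range of the original
# instrument is not documented; these are conventional values for Nile Red
# emission under 488 nm excitation and are configuration, not inference.
SCAN_START_NM = 500.0
SCAN_STOP_NM = 700.0
SCAN_STEP_NM = 0.5

# Fractional lamp-intensity loss per hour of use.  Chosen so that six months
# of use at 70 h/month (420 h) costs 30% of intensity; xenon-lamp aging is
# approximated as exponential in cumulative hours.
DEFAULT_LAMP_DECAY_RATE = math.log(1.0 / 0.7) / 420.0

# Reference standard (Nile Red in acetone): session-invariant true emission
# area and absorbance; fresh dye is assumed each session, so session-to-session
# variation in the *measured* standard area isolates the lamp factor.
STANDARD_TRUE_AREA = 50_000.0
STANDARD_OD488 = 0.30
STANDARD_PEAK_CENTER_NM = 565.0
STANDARD_PEAK_WIDTH_NM = 20.0


@dataclass(frozen=True)
class StrainProfile:
    """Emission and lipid characteristics of one yeast strain in one medium.

    emission_per_lipid is the true emission area (counts*nm) produced per
    % w/w of lipid per unit absorbed fraction; together with lipid_at_od1 and
    od488_per_od600 it sets the overall signal scale, which is arbitrary.
    """

    name: str = "C.curvatum"
    medium: str = "VFA"
    peak_center: float = 570.0  # nm
    peak_width: float = 15.0  # nm, Gaussian sigma
    lipid_at_od1: float = 30.0  # % w/w at OD_600 = 1.0
    emission_per_lipid: float = 2500.0  # counts*nm per (% w/w * absorbed fraction)
    od488_per_od600: float = 0.35

    def __post_init__(self) -> None:
        for f in ("peak_center", "peak_width", "lipid_at_od1",
                  "emission_per_lipid", "od488_per_od600"):
            if getattr(self, f) <= 0:
                raise ConfigurationError(f"StrainProfile.{f} must be positive")
        if not (SCAN_START_NM <= self.peak_center <= SCAN_STOP_NM):
            raise ConfigurationError(
                f"peak_center {self.peak_center} nm outside the simulated scan "
                f"range [{SCAN_START_NM}, {SCAN_STOP_NM}] nm"
            )


#: OD_600 dilution levels of the standard-curve series.
DEFAULT_DILUTIONS = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class SessionConfig:
    """One measurement session of a simulated campaign."""

    lamp_hours: float = 70.0
    lamp_decay_rate: float = DEFAULT_LAMP_DECAY_RATE
    strain_profile: StrainProfile = field(default_factory=StrainProfile)
    dilution_ods: tuple = DEFAULT_DILUTIONS
    noise_cv: float = 0.03
    seed: int = 0
    month: str = "month-1"

    def __post_init__(self) -> None:
        if self.lamp_hours < 0 or self.lamp_decay_rate < 0:
            raise ConfigurationError("lamp_hours and lamp_decay_rate must be >= 0")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if len(self.dilution_ods) == 0:
            raise ConfigurationError("dilution_ods must not be empty")
        if any(d <= 0 for d in self.dilution_ods):
            raise ConfigurationError("dilution OD_600 levels must all be > 0")

    @property
    def lamp_factor(self) -> float:
        """Session lamp intensity relative to a fresh lamp, in (0, 1]."""
        return math.exp(-self.lamp_decay_rate * self.lamp_hours)


@dataclass(frozen=True)
class SessionResult:
    """Generated data for one session."""

    config: SessionConfig
    lamp_factor: float
    standard: ReferenceStandard
    standard_spectrum: EmissionSpectrum
    readings: tuple  # of FluorescenceReading
    truths: tuple  # true lipid % w/w, aligned with readings


@dataclass(frozen=True)
class SyntheticCampaign:
    """A multi-session campaign: every reading is paired with the reference
    standard measured in its own session, under the same lamp factor."""

    sessions: tuple  # of SessionResult

    @property
    def readings(self) -> list:
        return [r for s in self.sessions for r in s.readings]

    @property
    def standard_readings(self) -> list:
        return [s.standard for s in self.sessions]

    @property
    def truths(self) -> list:
        return [t for s in self.sessions for t in s.truths]

    @property
    def configs(self) -> list:
        return [s.config for s in self.sessions]


def _scan_grid() -> np.ndarray:
    n = int(round((SCAN_STOP_NM - SCAN_START_NM) / SCAN_STEP_NM)) + 1
    return np.linspace(SCAN_START_NM, SCAN_STOP_NM, n)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    # mean-1 log-normal with coefficient of variation cv
    if cv == 0.0:
        return 1.0
    s2 = math.log1p(cv * cv)
    return float(np.exp(rng.normal(-0.5 * s2, math.sqrt(s2))))


def generate_spectrum(
    profile: StrainProfile,
    true_area: float,
    lamp_factor: float,
    noise_cv: float,
    rng: np.random.Generator,
    center: float | None = None,
    width: float | None = None,
) -> EmissionSpectrum:
    """Generate one Gaussian-band emission scan.

    The noise-free spectrum integrates to ``lamp_factor * true_area``; the
    whole scan is then multiplied by one mean-1 log-normal factor with the
    given coefficient of variation.  Deterministic for a fixed generator
    state.
    """
    if true_area < 0:
        raise DomainError(f"true_area must be >= 0, got {true_area}")
    if not (0.0 < lamp_factor <= 1.0):
        raise DomainError(f"lamp_factor must be in (0, 1], got {lamp_factor}")
    c = profile.peak_center if center is None else center
    w = profile.peak_width if width is None else width
    grid = _scan_grid()
    amplitude = lamp_factor * true_area / (w * math.sqrt(2.0 * math.pi))
    shape = np.exp(-0.5 * ((grid - c) / w) ** 2)
    factor = _lognormal_factor(rng, noise_cv)
    return EmissionSpectrum(grid, amplitude * factor * shape, 488.0)


def generate_session(config: SessionConfig) -> SessionResult:
    """Generate all measurements of one session.

    Emits one reading per OD_600 dilution plus a same-session measurement of
    the reference standard, all under the session's lamp factor.
    """
    rng = np.random.default_rng(config.seed)
    profile = config.strain_profile
    lamp = config.lamp_factor

    std_spectrum = generate_spectrum(
        profile, STANDARD_TRUE_AREA, lamp, config.noise_cv, rng,
        center=STANDARD_PEAK_CENTER_NM, width=STANDARD_PEAK_WIDTH_NM,
    )
    standard = ReferenceStandard.from_spectrum(
        std_spectrum, od_488_s=STANDARD_OD488,
        phi_s=PHI_STANDARD_NILE_RED_ACETONE, eta_s=ETA_ACETONE,
    )

    readings, truths = [], []
    for d in config.dilution_ods:
        lipid = d * profile.lipid_at_od1
        od488 = profile.od488_per_od600 * d
        true_area = profile.emission_per_lipid * lipid * absorbed_fraction(od488)
        spec = generate_spectrum(profile, true_area, lamp, config.noise_cv, rng)
        reading = FluorescenceReading.from_measurements(
            spec,
            AbsorbanceReading(od_488=od488, od_600=d),
            label=f"{profile.name}/{profile.medium}/{config.month}/od{d:g}",
        )
        readings.append(reading)
        truths.append(lipid)
    return SessionResult(
        config=config,
        lamp_factor=lamp,
        standard=standard,
        standard_spectrum=std_spectrum,
        readings=tuple(readings),
        truths=tuple(truths),
    )


def generate_campaign(
    config_month1: SessionConfig,
    config_month7: SessionConfig,
) -> SyntheticCampaign:
    """Generate a two-session campaign (the month-1 / month-7 design).

    Both sessions must share a strain profile, and the later session must
    have accumulated more lamp hours than the earlier one.
    """
    if config_month1.strain_profile != config_month7.strain_profile:
        raise ConfigurationError("both sessions must share a strain profile")
    if config_month7.lamp_hours <= config_month1.lamp_hours:
        raise ConfigurationError(
            "the later session must have more cumulative lamp hours than the earlier"
        )
    return SyntheticCampaign(
        sessions=(generate_session(config_month1), generate_session(config_month7))
    )


def default_campaign_configs(
    seed: int = 0,
    noise_cv: float = 0.03,
    profile: StrainProfile | None = None,
    lamp_decay_rate: float = DEFAULT_LAMP_DECAY_RATE,
) -> tuple[SessionConfig, SessionConfig]:
    """Month-1 / month-7 session configs for the default campaign.

    Lamp use accrues at 70 h/month, so month-1 has 70 h and month-7 has
    490 h on the lamp; with the default decay rate the month-7 lamp factor is
    exactly 0.7x the month-1 factor.  The two sessions draw from independent
    seeded streams derived from ``seed``.
    """
    profile = profile or StrainProfile()
    base = SessionConfig(
        lamp_hours=70.0, lamp_decay_rate=lamp_decay_rate,
        strain_profile=profile, noise_cv=noise_cv,
        seed=seed * 2 + 1, month="month-1",
    )
    later = replace(base, lamp_hours=490.0, seed=seed * 2 + 2, month="month-7")
    return base, later


# ---------------------------------------------------------------------------
# campaign writer: emits the manifest + spectrum-file layout the spectra
# module reads, so the full pipeline runs end-to-end on generated data.

def write_campaign(campaign: SyntheticCampaign, outdir: str | os.PathLike) -> Path:
    """Write a campaign to disk as plain-text artifacts.

    Layout::

        outdir/
          manifest.csv      one row per sample reading
          truths.csv        sample_id, true lipid % w/w
          standards.csv     per-session standard scalars (od_488_s, phi_s, ...)
          spectra/*.csv     two-column spectrum files (samples and standards)
          campaign.yaml     the generating configuration, seeds included

    Returns the output directory path.
    """
    out = Path(outdir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)

    manifest_rows, truth_rows, standard_rows, config_docs = [], [], [], []
    for s in campaign.sessions:
        month = s.config.month
        prof = s.config.strain_profile
        std_name = f"spectra/standard_{month}.csv"
        write_spectrum_file(s.standard_spectrum, out / std_name)
        standard_rows.append(
            f"{month},{std_name},{s.standard.od_488_s:.10g},"
            f"{s.standard.phi_s:.10g},{s.standard.eta_s:.10g}"
        )
        for i, (reading, truth) in enumerate(zip(s.readings, s.truths)):
            d = reading.absorbance.od_600
            sample_id = f"{prof.name}_{prof.medium}_{month}_od{d:g}"
            spec_name = f"spectra/{sample_id}.csv"
            write_spectrum_file(reading.spectrum, out / spec_name)
            manifest_rows.append(
                f"{sample_id},{spec_name},{reading.absorbance.od_488:.10g},"
                f"{d:.10g},{prof.name},{prof.medium},{month},1"
            )
            truth_rows.append(f"{sample_id},{truth:.10g}")
        config_docs.append({
            "month": month,
            "seed": s.config.seed,
            "lamp_hours": s.config.lamp_hours,
            "lamp_decay_rate": s.config.lamp_decay_rate,
            "lamp_factor": s.lamp_factor,
            "noise_cv": s.config.noise_cv,
            "dilution_ods": list(s.config.dilution_ods),
            "strain_profile": {
                "name": prof.name, "medium": prof.medium,
                "peak_center": prof.peak_center, "peak_width": prof.peak_width,
                "lipid_at_od1": prof.lipid_at_od1,
                "emission_per_lipid": prof.emission_per_lipid,
                "od488_per_od600": prof.od488_per_od600,
            },
        })

    (out / "manifest.csv").write_text(
        "sample_id,spectrum_path,od_488,od_600,strain,medium,month,replicate\n"
        + "\n".join(manifest_rows) + "\n", encoding="utf-8")
    (out / "truths.csv").write_text(
        "sample_id,lipid_pct_ww\n" + "\n".join(truth_rows) + "\n", encoding="utf-8")
    (out / "standards.csv").write_text(
        "month,spectrum_path,od_488_s,phi_s,eta_s\n" + "\n".join(standard_rows) + "\n",
        encoding="utf-8")
    (out / "campaign.yaml").write_text(
        yaml.safe_dump({"sessions": config_docs}, sort_keys=False), encoding="utf-8")
    return out
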