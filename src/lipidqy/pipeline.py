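"""End-to-end analysis steps: extract parameters, calibrate, quantify, drift report.

This layer connects the data model to the study design: per measurement
session it extracts the three fluorescence readouts (I_E, A_E, phi_fl) from
each reading, fits one standard curve per readout against gravimetric lipid
truth, quantifies unknowns, and compares sessions to expose instrument drift.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationPoint,
    CurveComparison,
    CurveRegistry,
    FluorescenceParameter,
    StandardCurve,
    compare_curves,
    estimate_lipid,
    fit_standard_curve,
)
from .errors import ConfigurationError, UndefinedStatisticError
from .photophysics import ETA_AQUEOUS, ReferenceStandard, quantum_yield
from .spectra import emission_area, peak_intensity, read_manifest, read_spectrum_file
from .stats import GroupedMeasurements, TestResult, one_way_anova, variance_f_test
from .synthdata import SessionResult, SyntheticCampaign

__all__ = [
    "session_parameter_table",
    "campaign_parameter_table",
    "fit_session_curves",
    "fit_campaign_curves",
    "quantify_table",
    "ParameterDrift",
    "DriftReport",
    "drift_report",
    "load_campaign",
]

PARAMETERS = (FluorescenceParameter.I_E, FluorescenceParameter.A_E,
              FluorescenceParameter.PHI_FL)


def session_parameter_table(session: SessionResult, eta: float = ETA_AQUEOUS) -> pd.DataFrame:
    """Per-reading fluorescence parameters for one generated session.

    Columns: sample_id, strain, medium, month, od_600, od_488, I_E, A_E,
    PHI_FL, lipid_true.
    """
    prof = session.config.strain_profile
    rows = []
    for reading, truth in zip(session.readings, session.truths):
        qy = quantum_yield(reading.a_e, reading.absorbance.od_488, eta,
                           session.standard)
        rows.append({
            "sample_id": reading.label,
            "strain": prof.name,
            "medium": prof.medium,
            "month": session.config.month,
            "od_600": reading.absorbance.od_600,
            "od_488": reading.absorbance.od_488,
            "I_E": reading.i_e,
            "A_E": reading.a_e,
            "PHI_FL": qy.phi_fl,
            "lipid_true": truth,
        })
    return pd.DataFrame(rows)


def campaign_parameter_table(campaign: SyntheticCampaign, eta: float = ETA_AQUEOUS) -> pd.DataFrame:
    return pd.concat([session_parameter_table(s, eta) for s in campaign.sessions],
                     ignore_index=True)


def fit_session_curves(session: SessionResult, eta: float = ETA_AQUEOUS) -> dict:
    """Fit one standard curve per fluorescence parameter for a session."""
    table = session_parameter_table(session, eta)
    prof = session.config.strain_profile
    curves = {}
    for param in PARAMETERS:
        points = [
            CalibrationPoint(fluorescence_value=row[param.value],
                             lipid_content=row["lipid_true"],
                             od_600=row["od_600"], sample_id=row["sample_id"])
            for _, row in table.iterrows()
        ]
        curves[param] = fit_standard_curve(points, param, strain=prof.name,
                                           medium=prof.medium,
                                           month=session.config.month)
    return curves


def fit_campaign_curves(campaign: SyntheticCampaign, eta: float = ETA_AQUEOUS) -> CurveRegistry:
    registry = CurveRegistry()
    for session in campaign.sessions:
        for curve in fit_session_curves(session, eta).values():
            registry.add(curve)
    return registry


def quantify_table(table: pd.DataFrame, curve: StandardCurve,
                   parameter: FluorescenceParameter | str) -> pd.DataFrame:
    """Apply a standard curve to a parameter table; returns estimates."""
    parameter = FluorescenceParameter(parameter)
    out = table.copy()
    ests = [estimate_lipid(curve, x) for x in table[parameter.value]]
    out["lipid_est"] = [e.lipid_pct for e in ests]
    out["lipid_half_width"] = [e.half_width for e in ests]
    out["below_zero"] = [e.below_zero for e in ests]
    out["curve_month"] = curve.month
    out["parameter"] = parameter.value
    return out


@dataclass(frozen=True)
class ParameterDrift:
    """Cross-session behaviour of one fluorescence readout."""

    parameter: FluorescenceParameter
    curve_early: StandardCurve
    curve_late: StandardCurve
    comparison: CurveComparison
    #: SD of (estimate - truth) for late-session readings quantified with the
    #: late curve (same-session, the intended use)
    same_session_error_sd: float
    #: same, but quantified with the early curve (cross-session use)
    cross_session_error_sd: float
    #: SD of the pooled same+cross session errors — the dispersion a user sees
    #: when curve vintage is not controlled
    pooled_error_sd: float
    anova: TestResult | None
    variance_test: TestResult | None
    #: True when the slope ratio deviates from 1 by more than its sampling
    #: uncertainty allows (see drift_report)
    slope_drifted: bool = False


@dataclass(frozen=True)
class DriftReport:
    """Per-parameter drift diagnostics plus the most stable readout, if any."""

    drifts: tuple  # of ParameterDrift
    flagged: FluorescenceParameter | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.drifts:
            rows.append({
                "parameter": d.parameter.value,
                "slope_early": d.curve_early.slope,
                "slope_late": d.curve_late.slope,
                "slope_ratio": d.comparison.slope_ratio,
                "intercept_difference": d.comparison.intercept_difference,
                "max_prediction_discrepancy": d.comparison.max_prediction_discrepancy,
                "same_session_error_sd": d.same_session_error_sd,
                "cross_session_error_sd": d.cross_session_error_sd,
                "pooled_error_sd": d.pooled_error_sd,
                "anova_p": d.anova.p_value if d.anova else float("nan"),
                "variance_test_p": d.variance_test.p_value if d.variance_test else float("nan"),
                "slope_drifted": d.slope_drifted,
                "flagged_most_stable": d.parameter == self.flagged,
            })
        return pd.DataFrame(rows)


def _errors(session: SessionResult, curve: StandardCurve,
            param: FluorescenceParameter, eta: float) -> np.ndarray:
    table = session_parameter_table(session, eta)
    est = quantify_table(table, curve, param)
    return (est["lipid_est"] - est["lipid_true"]).to_numpy()


def _slope_drifted(c_early, c_late, z: float = 2.0) -> bool:
    """Does the late/early slope ratio deviate from 1 beyond sampling noise?

    Uses the OLS slope standard errors of both curves, propagated to the
    ratio on the relative scale.  Noise-free drifted campaigns give SE = 0
    with ratio != 1 (drifted); noise-only campaigns stay within ~2 combined
    SEs of ratio 1.
    """
    ratio = c_late.slope / c_early.slope
    rel_se = math.hypot(c_early.slope_se / abs(c_early.slope),
                        c_late.slope_se / abs(c_late.slope))
    return abs(ratio - 1.0) > z * rel_se


def drift_report(campaign: SyntheticCampaign, eta: float = ETA_AQUEOUS,
                 level: float = 0.05) -> DriftReport:
    """Compare the earliest and latest sessions of a campaign per readout.

    For each parameter, the late session's readings are quantified twice —
    with the late-session curve (intended use) and with the early-session
    curve (what a user does when reusing an old calibration) — and the
    estimation errors are compared by ANOVA (means) and the variance F-test.
    A readout's calibration is considered drifted when its late/early slope
    ratio deviates from 1 by more than twice the propagated slope standard
    error.  The readout with the smallest cross-session prediction
    discrepancy is flagged as most stable only when it is itself undrifted
    while at least one other readout drifted; with no drift anywhere,
    nothing is flagged.
    """
    if len(campaign.sessions) < 2:
        raise ConfigurationError("drift report needs at least 2 sessions")
    early, late = campaign.sessions[0], campaign.sessions[-1]
    curves_early = fit_session_curves(early, eta)
    curves_late = fit_session_curves(late, eta)

    drifts = []
    for param in PARAMETERS:
        c_early, c_late = curves_early[param], curves_late[param]
        comparison = compare_curves(c_early, c_late)
        err_same = _errors(late, c_late, param, eta)
        err_cross = _errors(late, c_early, param, eta)
        anova = variance = None
        try:
            anova = one_way_anova(
                GroupedMeasurements.from_lists(
                    [err_same.tolist(), err_cross.tolist()],
                    ["same-session-curve", "cross-session-curve"]),
                level=level)
        except UndefinedStatisticError:
            pass
        try:
            variance = variance_f_test(err_same, err_cross, level=0.10)
        except UndefinedStatisticError:
            pass
        pooled = float(np.std(np.concatenate([err_same, err_cross]), ddof=1))
        drifts.append(ParameterDrift(
            parameter=param, curve_early=c_early, curve_late=c_late,
            comparison=comparison,
            same_session_error_sd=float(np.std(err_same, ddof=1)),
            cross_session_error_sd=float(np.std(err_cross, ddof=1)),
            pooled_error_sd=pooled,
            anova=anova, variance_test=variance,
            slope_drifted=_slope_drifted(c_early, c_late),
        ))

    best = min(drifts, key=lambda d: d.comparison.max_prediction_discrepancy)
    others_drifted = any(d.slope_drifted for d in drifts if d.parameter != best.parameter)
    flagged = best.parameter if (others_drifted and not best.slope_drifted) else None
    return DriftReport(drifts=tuple(drifts), flagged=flagged)


# ---------------------------------------------------------------------------
# on-disk campaigns (as written by synthdata.write_campaign)

def load_campaign(campaign_dir: str | os.PathLike, eta: float = ETA_AQUEOUS) -> pd.DataFrame:
    """Load a written campaign and extract all fluorescence parameters.

    Reads manifest.csv, the per-session standards and every spectrum file,
    recomputes I_E, A_E and phi_fl from the on-disk data, and joins the
    gravimetric truths.  This is the same computation the in-memory path
    performs, run from plain-text artifacts.
    """
    campaign_dir = Path(campaign_dir)
    manifest = read_manifest(campaign_dir / "manifest.csv")
    standards_df = pd.read_csv(campaign_dir / "standards.csv")
    truths = pd.read_csv(campaign_dir / "truths.csv")

    standards = {}
    for _, row in standards_df.iterrows():
        spec = read_spectrum_file(campaign_dir / row["spectrum_path"])
        standards[str(row["month"])] = ReferenceStandard.from_spectrum(
            spec, od_488_s=float(row["od_488_s"]),
            phi_s=float(row["phi_s"]), eta_s=float(row["eta_s"]))

    rows = []
    for _, row in manifest.iterrows():
        spec = read_spectrum_file(row["spectrum_path"])
        i_e, _peak = peak_intensity(spec)
        a_e = emission_area(spec)
        month = str(row["month"])
        if month not in standards:
            raise ConfigurationError(f"no reference standard for session {month!r}")
        qy = quantum_yield(a_e, float(row["od_488"]), eta, standards[month])
        rows.append({
            "sample_id": row["sample_id"], "strain": row["strain"],
            "medium": row["medium"], "month": month,
            "od_600": float(row["od_600"]), "od_488": float(row["od_488"]),
            "I_E": i_e, "A_E": a_e, "PHI_FL": qy.phi_fl,
        })
    table = pd.DataFrame(rows)
    return table.merge(truths.rename(columns={"lipid_pct_ww": "lipid_true"}),
                       on="sample_id", how="left")
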