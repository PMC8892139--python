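"""Assembly of the 34-feature vector per subject, with all unit conversions.

The feature set combines anthropometrics, curve statistics (means, AUCs,
peaks, disappearance rates), minimal-model indexes, secretion indexes from
C-peptide deconvolution, and clearance indexes.  Missing component results
propagate as missing features (NaN / empty CSV cells), never as silent zeros
and never imputed.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import (
    CPEPTIDE_NGDL_PER_PMOLL,
    FIT_START_MIN,
    GLUCOSE_DOSE_MG_PER_KG,
    GLUCOSE_MGDL_PER_MMOLL,
    INSULIN_PMOL_PER_UU_ML,
    INSULIN_VOLUME_L_PER_KG,
    DECONV_LAMBDA_DEFAULT,
    PHASE_SPLIT_MIN,
    TEST_DURATION_MIN,
)
from .glucose_model import (
    disposition_index,
    fit_minimal_model,
    glucose_disappearance_rate,
    sg_components,
)
from .secretion_model import (
    acute_response,
    cpeptide_kinetics_from_anthropometrics,
    deconvolve_isr,
    phi_1c,
    secretion_aucs,
)
from .clearance_model import clearance_estimates

__all__ = [
    "FEATURE_COLUMNS",
    "FEATURE_UNITS",
    "mean_curve",
    "curve_auc",
    "peaks",
    "glucose_dose",
    "assemble_features",
    "extract_features",
    "extract_feature_matrix",
    "write_feature_matrix",
    "read_feature_matrix",
]

#: the 34 features, in canonical table order
FEATURE_UNITS: dict[str, str] = {
    "age": "years",
    "BW": "kg",
    "h": "cm",
    "BMI": "kg/m2",
    "g_b": "mg/dL",
    "G_MEAN": "mmol/L",
    "I_MEAN": "pmol/L",
    "Cp_MEAN": "pmol/L",
    "AUC_INS_1P": "pmol*min/L",
    "AUC_INS_2P": "pmol*min/L",
    "K_G1": "%/min",
    "K_G2": "%/min",
    "S_I": "1e-4/min per uU/mL",
    "S_G": "1/min",
    "V": "L",
    "BIE": "1e-3/min",
    "GEZI": "1e-2/min",
    "AIR": "pmol/L",
    "ACPR": "pmol/L",
    "DI": "1e-2/min",
    "BSR": "pmol/L/min",
    "Phi_1c": "(pmol/L/min)/(mg/dL)",
    "AUC_SECR": "pmol",
    "AUC_SECR_1P": "pmol",
    "AUC_SECR_2P": "pmol",
    "CL_MEAN": "L/min",
    "CL_MEAN_1P": "L/min",
    "CL_MEAN_2P": "L/min",
    "CL_P": "L/min",
    "FE_L": "fraction",
    "I_PEAK_FIRST": "uU/mL",
    "I_PEAK_INJECT": "uU/mL",
    "C_PEAK": "ng/dL",
    "DOSE": "g",
}
FEATURE_COLUMNS: tuple[str, ...] = tuple(FEATURE_UNITS)


def mean_curve(times, series, duration: float = TEST_DURATION_MIN) -> float:
    """Mean curve level: trapezoidal AUC over [0, duration] divided by duration.

    The fasting sample anchors the curve at t = 0.  If the samples do not
    reach ``duration`` the last sample is extended (nearest-sample, with a
    warning).
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    if times[0] > 0.0 or times[-1] < duration:
        warnings.warn("samples do not span the full test; extending nearest sample")
        if times[0] > 0.0:
            times = np.concatenate([[0.0], times])
            series = np.concatenate([[series[0]], series])
        if times[-1] < duration:
            times = np.concatenate([times, [duration]])
            series = np.concatenate([series, [series[-1]]])
    mask = (times >= 0.0) & (times <= duration)
    return float(np.trapezoid(series[mask], times[mask])) / duration


def curve_auc(times, series, window: tuple[float, float]) -> float:
    """Trapezoidal AUC of a sampled curve over a window (endpoints interpolated)."""
    lo, hi = window
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    if hi <= lo:
        raise ValueError(f"empty window {window}")
    inner = (times > lo) & (times < hi)
    w_times = np.concatenate([[lo], times[inner], [hi]])
    w_series = np.concatenate(
        [[np.interp(lo, times, series)], series[inner], [np.interp(hi, times, series)]]
    )
    return float(np.trapezoid(w_series, w_times))


def peaks(record, split: float = PHASE_SPLIT_MIN) -> dict[str, float]:
    """Sample peaks: insulin per phase (uU/mL) and C-peptide (ng/dL).

    Measured samples only, no interpolation; ties resolve to the earliest
    sample.  I_PEAK_FIRST is the maximum insulin over (0, split], I_PEAK_INJECT
    over (split, 180]; C_PEAK the maximum C-peptide over (0, 180].
    """
    times = np.asarray(record.times, dtype=float)
    ins = np.asarray(record.insulin, dtype=float)
    cp = np.asarray(record.cpeptide, dtype=float)

    def _max(series, lo, hi):
        mask = (times > lo) & (times <= hi)
        vals = series[mask]
        return float(vals[np.argmax(vals)])  # argmax -> earliest on ties

    return {
        "I_PEAK_FIRST": _max(ins, 0.0, split) / INSULIN_PMOL_PER_UU_ML,
        "I_PEAK_INJECT": _max(ins, split, TEST_DURATION_MIN) / INSULIN_PMOL_PER_UU_ML,
        "C_PEAK": _max(cp, 0.0, TEST_DURATION_MIN) * CPEPTIDE_NGDL_PER_PMOLL,
    }


def glucose_dose(body_weight_kg: float) -> float:
    """Injected glucose dose in grams (300 mg per kg body weight)."""
    if body_weight_kg < 0:
        raise ValueError("body weight must be non-negative")
    return GLUCOSE_DOSE_MG_PER_KG * body_weight_kg / 1e3


def assemble_features(record, mm_fit, secretion, clearances) -> dict[str, float]:
    """Assemble the full 34-entry feature dict for one subject.

    ``secretion`` is a dict holding the SecretionProfile under ``"profile"``
    and the scalar indexes (AIR, ACPR, Phi_1c, AUCs); any component passed as
    ``None`` leaves its features missing (NaN).  Deterministic.
    """
    times = np.asarray(record.times, dtype=float)
    g_b_mmol = float(record.glucose[times == 0.0][0])
    i_b = float(record.insulin[times == 0.0][0])

    feats: dict[str, float] = {name: float("nan") for name in FEATURE_COLUMNS}
    feats.update(
        {
            "age": record.age,
            "BW": record.body_weight,
            "h": record.height,
            "BMI": record.BMI,
            "g_b": g_b_mmol * GLUCOSE_MGDL_PER_MMOLL,
            "G_MEAN": mean_curve(times, record.glucose),
            "I_MEAN": mean_curve(times, record.insulin),
            "Cp_MEAN": mean_curve(times, record.cpeptide),
            "AUC_INS_1P": curve_auc(times, record.insulin, (0.0, PHASE_SPLIT_MIN)),
            "AUC_INS_2P": curve_auc(
                times, record.insulin, (PHASE_SPLIT_MIN, TEST_DURATION_MIN)
            ),
            "K_G1": glucose_disappearance_rate(record, 10.0, 20.0),
            "K_G2": glucose_disappearance_rate(record, 20.0, 40.0),
            "DOSE": glucose_dose(record.body_weight),
        }
    )
    feats.update(peaks(record))

    air = float("nan")
    if secretion is not None:
        air = secretion.get("AIR", float("nan"))
        for name in ("AIR", "ACPR", "BSR", "Phi_1c",
                     "AUC_SECR", "AUC_SECR_1P", "AUC_SECR_2P"):
            if name in secretion:
                feats[name] = secretion[name]

    if mm_fit is not None and mm_fit.converged:
        comps = sg_components(mm_fit, i_b)
        feats.update(
            {
                "S_I": mm_fit.S_I * 1e4,
                "S_G": mm_fit.S_G,
                "V": mm_fit.V,
                "BIE": comps["BIE"] * 1e3,
                "GEZI": comps["GEZI"] * 1e2,
            }
        )
        if np.isfinite(air):
            feats["DI"] = disposition_index(mm_fit.S_I, air)

    if clearances is not None:
        feats.update(
            {
                "CL_MEAN": clearances.CL_MEAN,
                "CL_MEAN_1P": clearances.CL_MEAN_1P,
                "CL_MEAN_2P": clearances.CL_MEAN_2P,
                "CL_P": clearances.CL_P,
                "FE_L": clearances.FE_L,
            }
        )
    return feats


def extract_features(
    record,
    fit_start: float = FIT_START_MIN,
    deconv_lambda: float = DECONV_LAMBDA_DEFAULT,
) -> dict[str, float]:
    """Run the full extraction stack on one record and assemble its features."""
    from .synth_cohort import tolerance_status_for  # avoid import cycle

    times = np.asarray(record.times, dtype=float)
    i_b = float(record.insulin[times == 0.0][0])
    cp_b = float(record.cpeptide[times == 0.0][0])

    kin = cpeptide_kinetics_from_anthropometrics(
        record.age, record.sex, record.body_weight, record.height,
        tolerance_status_for(record.BMI),
    )
    profile = deconvolve_isr(record, kin, deconv_lambda)
    secretion = {
        "profile": profile,
        "BSR": profile.BSR,
        "AIR": acute_response(times, record.insulin, i_b),
        "ACPR": acute_response(times, record.cpeptide, cp_b),
        "Phi_1c": phi_1c(profile, record),
    }
    secretion.update(secretion_aucs(profile))

    try:
        mm_fit = fit_minimal_model(record, fit_start=fit_start)
    except ValueError:
        mm_fit = None
    v_i = INSULIN_VOLUME_L_PER_KG * record.body_weight
    clearances = clearance_estimates(record, profile, v_i)
    return assemble_features(record, mm_fit, secretion, clearances)


def extract_feature_matrix(records, **kwargs) -> pd.DataFrame:
    """Feature matrix for a list of records: id index, label + 34 feature columns."""
    rows = []
    for record in records:
        feats = extract_features(record, **kwargs)
        rows.append({"id": record.id, "label": record.group, **feats})
    return pd.DataFrame(rows).set_index("id")


def _suffixed(name: str) -> str:
    return f"{name} [{FEATURE_UNITS[name]}]"


def write_feature_matrix(matrix: pd.DataFrame, path) -> None:
    """Write ``features.csv`` with unit-suffixed column headers."""
    out = matrix.reset_index()
    out.columns = [
        _suffixed(c) if c in FEATURE_UNITS else c for c in out.columns
    ]
    out.to_csv(path, index=False, na_rep="")


def read_feature_matrix(path) -> pd.DataFrame:
    """Read a ``features.csv`` written by :func:`write_feature_matrix`."""
    df = pd.read_csv(path)
    df.columns = [c.split(" [")[0] for c in df.columns]
    return df.set_index("id")
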