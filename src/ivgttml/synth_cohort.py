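"""Synthetic insulin-modified IVGTT cohorts with known physiology.

The clinical cohort this pipeline was designed around (78 women with prior
gestational diabetes, 59 non-progressors and 19 progressors to type 2
diabetes) is not publicly available, so this module generates surrogate
cohorts from a mechanistic forward model with per-subject ground truth:

* glucose follows the minimal model of glucose kinetics (states G, X) with the
  intravenous bolus raising G instantaneously at t = 0;
* insulin secretion is basal + a first-phase raised-cosine pulse over 0-8 min
  + a second-phase component proportional to suprabasal glucose;
* C-peptide follows population two-compartment kinetics driven by secretion;
* plasma insulin follows a one-compartment balance receiving the post-hepatic
  fraction (1 - FE_L) of secretion plus the exogenous infusion (20-25 min),
  cleared at the extra-hepatic rate CL_P.

Group-level parameter distributions are log-normal, with per-group medians
calibrated to the published cohort description (progressors: lower insulin
sensitivity and first-phase secretion, higher BMI, fasting glucose and basal
secretion) and scales set from the reported IQR/median ratios.  Basal insulin
is derived from the other parameters so every subject starts at an exact
steady state.
"""

from __future__ import annotations

import io
import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .constants import (
    GLUCOSE_DOSE_MG_PER_KG,
    GLUCOSE_MGDL_PER_MMOLL,
    GLUCOSE_MG_PER_MMOL,
    GRID_STEP_MIN,
    INFUSION_DURATION_MIN,
    INFUSION_START_MIN,
    INSULIN_DOSE_IU_PER_KG,
    INSULIN_NMOL_PER_IU,
    INSULIN_PMOL_PER_UU_ML,
    INSULIN_VOLUME_L_PER_KG,
    SAMPLE_SCHEDULE_MIN,
    TEST_DURATION_MIN,
)
from .secretion_model import CPeptideKinetics, cpeptide_kinetics_from_anthropometrics

__all__ = [
    "ConfigurationError",
    "SimulationError",
    "SubjectTruth",
    "SimulationConfig",
    "IVGTTRecord",
    "sample_cohort",
    "simulate_ivgtt",
    "simulate_dense",
    "simulate_cohort",
    "inject_outliers",
    "write_cohort",
    "read_cohort",
    "tolerance_status_for",
]


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


class SimulationError(RuntimeError):
    """Forward integration failed or produced a non-physical state."""


FIRST_PHASE_WINDOW_MIN = 8.0  # first-phase pulse support, min


@dataclass(frozen=True)
class SubjectTruth:
    """Ground-truth physiology of one simulated subject."""

    id: str
    group: str  #: "PROG" or "NON-PROG"
    age: float  #: years
    body_weight: float  #: kg
    height: float  #: cm
    S_I_true: float  #: insulin sensitivity, min^-1 per (uU/mL)
    S_G_true: float  #: glucose effectiveness, min^-1
    V_true: float  #: glucose distribution volume, L
    p2_true: float  #: remote insulin action rate constant, min^-1
    G_b: float  #: basal glucose, mmol/L
    Cp_b: float  #: basal C-peptide, pmol/L
    first_phase_amp: float  #: first-phase secreted amount, pmol (0-8 min)
    second_phase_gain: float  #: pmol/min per mmol/L suprabasal glucose
    FE_L_true: float  #: hepatic fractional extraction, in [0, 1]
    CL_P_true: float  #: extra-hepatic insulin clearance, L/min
    cpep_kinetics: CPeptideKinetics
    sex: str = "F"

    def __post_init__(self) -> None:
        if self.group not in ("PROG", "NON-PROG"):
            raise ValueError(f"group must be PROG or NON-PROG, got {self.group!r}")
        if not (0.0 <= self.FE_L_true <= 1.0):
            raise ValueError("FE_L_true must lie in [0, 1]")
        positive = (
            self.age, self.body_weight, self.height, self.S_G_true, self.V_true,
            self.p2_true, self.G_b, self.Cp_b, self.CL_P_true,
        )
        if any(v <= 0 for v in positive) or self.S_I_true < 0:
            raise ValueError(f"non-positive physiological parameter for {self.id}")

    @property
    def BSR(self) -> float:
        """Basal secretion rate, pmol L^-1 min^-1 (per V_C)."""
        return self.cpep_kinetics.k01 * self.Cp_b

    @property
    def I_b(self) -> float:
        """Basal insulin (pmol/L) at the exact pre-test steady state."""
        s_basal = self.BSR * self.cpep_kinetics.V_C  # pmol/min
        return (1.0 - self.FE_L_true) * s_basal / self.CL_P_true

    @property
    def V_I(self) -> float:
        """Insulin distribution volume, L."""
        return INSULIN_VOLUME_L_PER_KG * self.body_weight


# Per-group log-normal calibration: {param: (median, sigma_log)}.  Medians
# follow the published group characteristics (units as in SubjectTruth);
# sigmas follow the reported IQR/median ratios where available.
GROUP_CALIBRATION: dict[str, dict[str, tuple[float, float]]] = {
    "NON-PROG": {
        "age": (33.3, 0.12),
        "body_weight": (65.8, 0.17),
        "height": (164.0, 0.054),
        "G_b": (84.0 / GLUCOSE_MGDL_PER_MMOLL, 0.071),
        "S_I_true": (4.7e-4, 0.43),
        "S_G_true": (0.022, 0.17),
        "V_true": (13.4, 0.075),
        "p2_true": (0.030, 0.20),
        "Cp_b": (545.0, 0.24),
        "first_phase_amp": (4000.0, 0.45),
        "second_phase_gain": (10.0, 0.40),
        "FE_L_true": (0.53, 0.20),
        "CL_P_true": (0.39, 0.50),
    },
    "PROG": {
        "age": (36.6, 0.12),
        "body_weight": (75.0, 0.19),
        "height": (158.0, 0.056),
        "G_b": (96.0 / GLUCOSE_MGDL_PER_MMOLL, 0.089),
        "S_I_true": (3.1e-4, 0.48),
        "S_G_true": (0.018, 0.33),
        "V_true": (13.9, 0.053),
        "p2_true": (0.030, 0.20),
        "Cp_b": (680.0, 0.20),
        "first_phase_amp": (2800.0, 0.55),
        "second_phase_gain": (14.0, 0.40),
        "FE_L_true": (0.50, 0.19),
        "CL_P_true": (0.56, 0.50),
    },
}


@dataclass
class SimulationConfig:
    """Cohort-level settings: counts, distributions, protocol and noise."""

    n_nonprog: int = 59
    n_prog: int = 19
    group_params: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in GROUP_CALIBRATION.items()}
    )
    noise_cv: dict = field(
        default_factory=lambda: {"glucose": 0.015, "insulin": 0.06, "cpeptide": 0.05}
    )
    schedule: tuple = SAMPLE_SCHEDULE_MIN
    glucose_dose_per_kg: float = GLUCOSE_DOSE_MG_PER_KG  # mg/kg
    insulin_dose_per_kg: float = INSULIN_DOSE_IU_PER_KG  # IU/kg
    infusion_start: float = INFUSION_START_MIN
    infusion_duration: float = INFUSION_DURATION_MIN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nonprog < 1 or self.n_prog < 1:
            raise ConfigurationError("both group counts must be >= 1")
        sched = np.asarray(self.schedule, dtype=float)
        if sched[0] != 0.0 or np.any(np.diff(sched) <= 0):
            raise ConfigurationError(
                "schedule must start at 0 (fasting) and be strictly increasing"
            )
        for group, params in self.group_params.items():
            for name, (median, sigma) in params.items():
                if median <= 0 or sigma < 0:
                    raise ConfigurationError(
                        f"invalid log-normal parameters for {group}/{name}"
                    )


@dataclass
class IVGTTRecord:
    """One subject's anthropometrics, protocol doses and sampled curves."""

    id: str
    group: str
    age: float
    body_weight: float  #: kg
    height: float  #: cm
    times: np.ndarray  #: min
    glucose: np.ndarray  #: mmol/L
    insulin: np.ndarray  #: pmol/L
    cpeptide: np.ndarray  #: pmol/L
    glucose_dose: float  #: g
    exo_insulin: float  #: IU
    infusion_start: float = INFUSION_START_MIN
    infusion_duration: float = INFUSION_DURATION_MIN
    sex: str = "F"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("glucose", "insulin", "cpeptide"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} series not aligned to times for {self.id}")
            if np.any(arr <= 0):
                raise ValueError(f"non-positive {name} value for {self.id}")

    @property
    def BMI(self) -> float:
        """Body mass index, kg/m^2."""
        return self.body_weight / (self.height / 100.0) ** 2


def tolerance_status_for(bmi: float) -> str:
    """Glucose-tolerance class used for population C-peptide kinetics."""
    return "obese" if bmi >= 30.0 else "normal"


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(subject_id.encode())])


def sample_cohort(config: SimulationConfig) -> list[SubjectTruth]:
    """Draw a cohort of :class:`SubjectTruth` from the configured distributions.

    Reproducible given ``config.seed``; subjects are drawn group by group
    (NON-PROG first) with ids ``S001`` ... ``S{n}``.
    """
    rng = np.random.default_rng(config.seed)
    truths: list[SubjectTruth] = []
    counter = 0
    for group, count in (("NON-PROG", config.n_nonprog), ("PROG", config.n_prog)):
        params = config.group_params[group]
        for _ in range(count):
            counter += 1
            draw = {
                name: median * math.exp(sigma * rng.standard_normal())
                for name, (median, sigma) in params.items()
            }
            draw["FE_L_true"] = min(draw["FE_L_true"], 0.95)
            bmi = draw["body_weight"] / (draw["height"] / 100.0) ** 2
            kin = cpeptide_kinetics_from_anthropometrics(
                draw["age"], "F", draw["body_weight"], draw["height"],
                tolerance_status_for(bmi),
            )
            truths.append(
                SubjectTruth(
                    id=f"S{counter:03d}", group=group, cpep_kinetics=kin, **draw
                )
            )
    return truths


def _first_phase_rate(t: float, amp: float) -> float:
    """Raised-cosine secretion pulse on [0, 8] min with unit area times amp."""
    if t < 0.0 or t > FIRST_PHASE_WINDOW_MIN or amp == 0.0:
        return 0.0
    w = FIRST_PHASE_WINDOW_MIN
    return amp * (1.0 - math.cos(2.0 * math.pi * t / w)) / w


def simulate_dense(
    truth: SubjectTruth,
    config: SimulationConfig,
    duration: float = TEST_DURATION_MIN,
):
    """Integrate the forward model and return the full state on a 1-min grid.

    Returns a dict with arrays ``t, glucose, X, insulin, cpeptide, S_pre,
    R_exo`` (plus scalars for doses); used by :func:`simulate_ivgtt` and by
    round-trip oracles that need the exact internal flows.
    """
    kin = truth.cpep_kinetics
    dose_mg = config.glucose_dose_per_kg * truth.body_weight
    dose_mmol = dose_mg / GLUCOSE_MG_PER_MMOL
    exo_iu = config.insulin_dose_per_kg * truth.body_weight
    exo_rate = (
        exo_iu * INSULIN_NMOL_PER_IU * 1e3 / config.infusion_duration
        if exo_iu > 0
        else 0.0
    )  # pmol/min during the infusion window
    t_on, t_off = config.infusion_start, config.infusion_start + config.infusion_duration
    s_basal = truth.BSR * kin.V_C  # pmol/min
    amp = truth.first_phase_amp if dose_mmol > 0 else 0.0
    i_b, v_i = truth.I_b, truth.V_I

    def s_pre(t: float, g: float) -> float:
        return (
            s_basal
            + _first_phase_rate(t, amp)
            + truth.second_phase_gain * max(g - truth.G_b, 0.0)
        )

    def rhs(t: float, y: np.ndarray) -> list[float]:
        g, x, cp1, cp2, ins = y
        s = s_pre(t, g)
        r_exo = exo_rate if t_on <= t < t_off else 0.0
        return [
            -(truth.S_G_true + x) * g + truth.S_G_true * truth.G_b,
            -truth.p2_true * x
            + truth.p2_true * truth.S_I_true * (ins - i_b) / INSULIN_PMOL_PER_UU_ML,
            -(kin.k01 + kin.k21) * cp1 + kin.k12 * cp2 + s / kin.V_C,
            kin.k21 * cp1 - kin.k12 * cp2,
            ((1.0 - truth.FE_L_true) * s + r_exo - truth.CL_P_true * ins) / v_i,
        ]

    g0 = truth.G_b + dose_mmol / truth.V_true
    y = np.array([g0, 0.0, truth.Cp_b, (kin.k21 / kin.k12) * truth.Cp_b, i_b])
    grid = np.arange(0.0, duration + GRID_STEP_MIN / 2, GRID_STEP_MIN)
    eval_times = np.unique(np.concatenate([grid, np.asarray(config.schedule)]))
    eval_times = eval_times[eval_times <= duration]

    breakpoints = sorted(
        {0.0, duration}
        | {t for t in (FIRST_PHASE_WINDOW_MIN, t_on, t_off) if 0.0 < t < duration}
    )
    ts, ys = [], []
    for lo, hi in zip(breakpoints[:-1], breakpoints[1:]):
        seg = eval_times[(eval_times >= lo) & (eval_times <= hi)]
        seg = np.unique(np.concatenate([[lo], seg, [hi]]))
        sol = solve_ivp(
            rhs, (lo, hi), y, t_eval=seg, method="LSODA", rtol=1e-8, atol=1e-10
        )
        if not sol.success:
            raise SimulationError(f"integration failed for subject {truth.id}")
        y = sol.y[:, -1]
        keep = slice(0, None) if not ts else slice(1, None)
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])
    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    if np.any(y_all[[0, 2, 3, 4], :] < -1e-9):
        raise SimulationError(f"negative state encountered for subject {truth.id}")

    s_vals = np.array([s_pre(t, g) for t, g in zip(t_all, y_all[0])])
    r_vals = np.where((t_all >= t_on) & (t_all < t_off), exo_rate, 0.0)
    return {
        "t": t_all,
        "glucose": y_all[0],
        "X": y_all[1],
        "cpeptide": y_all[2],
        "cpeptide_peripheral": y_all[3],
        "insulin": y_all[4],
        "S_pre": s_vals,
        "R_exo": r_vals,
        "glucose_dose_g": dose_mg / 1e3,
        "exo_insulin_iu": exo_iu,
    }


def simulate_ivgtt(truth: SubjectTruth, config: SimulationConfig) -> IVGTTRecord:
    """Simulate one IM-IVGTT and sample it on the configured schedule.

    Multiplicative Gaussian measurement noise is applied per analyte at the
    configured coefficients of variation; with all CVs at 0 the record is the
    exact model output (noise-free mode).  The per-subject noise stream is
    derived from ``config.seed`` and the subject id, so cohorts are
    reproducible regardless of simulation order.
    """
    dense = simulate_dense(truth, config)
    sched = np.asarray(config.schedule, dtype=float)
    idx = np.searchsorted(dense["t"], sched)
    if not np.allclose(dense["t"][idx], sched):
        raise SimulationError(f"schedule times missing from grid for {truth.id}")
    series = {k: dense[k][idx] for k in ("glucose", "insulin", "cpeptide")}
    # the t=0 sample is drawn before the bolus: report fasting values there
    at_zero = sched == 0.0
    series["glucose"][at_zero] = truth.G_b
    series["insulin"][at_zero] = truth.I_b
    series["cpeptide"][at_zero] = truth.Cp_b

    rng = _subject_rng(config.seed, truth.id)
    for name in ("glucose", "insulin", "cpeptide"):
        cv = float(config.noise_cv.get(name, 0.0))
        if cv > 0:
            noisy = series[name] * (1.0 + cv * rng.standard_normal(sched.size))
            series[name] = np.maximum(noisy, 1e-3 * series[name])

    return IVGTTRecord(
        id=truth.id,
        group=truth.group,
        age=truth.age,
        body_weight=truth.body_weight,
        height=truth.height,
        times=sched,
        glucose=series["glucose"],
        insulin=series["insulin"],
        cpeptide=series["cpeptide"],
        glucose_dose=dense["glucose_dose_g"],
        exo_insulin=dense["exo_insulin_iu"],
        infusion_start=config.infusion_start,
        infusion_duration=config.infusion_duration,
        sex=truth.sex,
    )


def simulate_cohort(
    truths: list[SubjectTruth], config: SimulationConfig
) -> list[IVGTTRecord]:
    """Simulate every subject in a cohort."""
    return [simulate_ivgtt(t, config) for t in truths]


def inject_outliers(
    features: pd.DataFrame, k: int, magnitude: float, seed: int
) -> tuple[pd.DataFrame, list]:
    """Displace ``k`` random rows by ``magnitude`` SDs in random directions.

    Only numeric feature columns are displaced (id/label-like columns are left
    untouched).  Returns the modified copy and the ids (index values) of the
    displaced rows.  Used to plant recoverable outliers for testing the LOF
    preprocessing stage.
    """
    n = len(features)
    if k >= n:
        raise ValueError(f"cannot displace k={k} rows out of n={n}")
    out = features.copy()
    if k == 0:
        return out, []
    rng = np.random.default_rng(seed)
    numeric = out.select_dtypes(include=[np.number]).columns
    sds = out[numeric].std(ddof=0).to_numpy()
    sds = np.where(sds > 0, sds, 1.0)
    rows = rng.choice(n, size=k, replace=False)
    for row in rows:
        direction = rng.standard_normal(len(numeric))
        direction /= np.linalg.norm(direction)
        out.iloc[row, out.columns.get_indexer(numeric)] += magnitude * sds * direction
    return out, list(features.index[rows])


# --- cohort I/O ---------------------------------------------------------------

def write_cohort(
    directory, records: list[IVGTTRecord], truths: list[SubjectTruth] | None = None
) -> None:
    """Write ``subjects.csv`` + ``timeseries.csv`` (and ``truth.csv``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    subjects = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "group": [r.group for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "weight_kg": [r.body_weight for r in records],
            "height_cm": [r.height for r in records],
        }
    )
    subjects.to_csv(directory / "subjects.csv", index=False)
    frames = [
        pd.DataFrame(
            {
                "id": r.id,
                "time_min": r.times,
                "glucose_mmol_l": r.glucose,
                "insulin_pmol_l": r.insulin,
                "cpeptide_pmol_l": r.cpeptide,
            }
        )
        for r in records
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        directory / "timeseries.csv", index=False
    )
    if truths is not None:
        rows = []
        for t in truths:
            rows.append(
                {
                    "id": t.id, "group": t.group, "age": t.age,
                    "body_weight": t.body_weight, "height": t.height,
                    "S_I_true": t.S_I_true, "S_G_true": t.S_G_true,
                    "V_true": t.V_true, "p2_true": t.p2_true, "G_b": t.G_b,
                    "Cp_b": t.Cp_b, "I_b": t.I_b,
                    "first_phase_amp": t.first_phase_amp,
                    "second_phase_gain": t.second_phase_gain,
                    "FE_L_true": t.FE_L_true, "CL_P_true": t.CL_P_true,
                }
            )
        pd.DataFrame(rows).to_csv(directory / "truth.csv", index=False)


def read_cohort(directory) -> list[IVGTTRecord]:
    """Read records written by :func:`write_cohort`."""
    directory = Path(directory)
    subjects = pd.read_csv(directory / "subjects.csv")
    series = pd.read_csv(directory / "timeseries.csv")
    records = []
    for _, row in subjects.iterrows():
        sub = series[series["id"] == row["id"]].sort_values("time_min")
        weight = float(row["weight_kg"])
        records.append(
            IVGTTRecord(
                id=str(row["id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                body_weight=weight,
                height=float(row["height_cm"]),
                times=sub["time_min"].to_numpy(),
                glucose=sub["glucose_mmol_l"].to_numpy(),
                insulin=sub["insulin_pmol_l"].to_numpy(),
                cpeptide=sub["cpeptide_pmol_l"].to_numpy(),
                glucose_dose=GLUCOSE_DOSE_MG_PER_KG * weight / 1e3,
                exo_insulin=INSULIN_DOSE_IU_PER_KG * weight,
                sex=str(row.get("sex", "F")),
            )
        )
    return records
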