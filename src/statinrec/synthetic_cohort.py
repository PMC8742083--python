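"""Synthetic longitudinal EHR cohort generator with known ground truth.

Emulates the schema of a lipid-management EHR extract — demographics, long-form
laboratory results and vitals, prescriptions, diagnoses, visits and
census-block socioeconomic indicators — together with a four-arm statin
decision (none / low / moderate / high intensity) and a heterogeneous 1-year
relative LDL-C response.  Because the generating model is known, every
downstream stage (cohort filters, metric learning, neighbor matching, policy
recovery) is testable against ground truth.

The response model for patient ``i`` under arm ``t`` is

    mu_t(x_i) = base_t + c_t . z_i          (percent LDL-C reduction)

where ``z_i`` is the heterogeneity basis (standardized age, standardized
baseline LDL-C, then the binary condition flags) and ``c_t`` the per-arm
heterogeneity coefficients.  An efficacy-effectiveness gap is modeled by
multiplicatively attenuating the high-intensity effect in the subgroup carrying
condition flag ``cond_01`` (prevalence = ``gap_fraction``).  The realized
follow-up LDL-C is ``baseline * (1 - (mu_arm + eps) / 100)`` with
``eps ~ Normal(0, noise_sd)``, measured at index + 365 +/- 30 days.

Treatment assignment is confounded with observables: arm logits are the log
prevalences tilted by a linear score in standardized age, standardized
baseline LDL-C and the diabetes flag, scaled by ``confounding_strength`` —
older, higher-LDL, diabetic patients are pushed toward more intense therapy,
mirroring real prescribing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .defaults import ANTIHYPERTENSIVE_AGENTS, ARMS
from .errors import ConfigurationError, ParseError

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "EHRTables",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "write_ground_truth",
    "read_ground_truth",
]

# age drawn Uniform(40, 80): mean and sd used to standardize the basis
_AGE_MEAN, _AGE_SD = 60.0, 40.0 / np.sqrt(12.0)
_LDL_MEAN, _LDL_SD = 121.0, 30.0

_STATIN_MENU = {
    "low": [("pravastatin", 20.0), ("lovastatin", 20.0), ("simvastatin", 10.0)],
    "moderate": [
        ("atorvastatin", 10.0),
        ("atorvastatin", 20.0),
        ("rosuvastatin", 10.0),
        ("simvastatin", 20.0),
    ],
    "high": [("atorvastatin", 40.0), ("atorvastatin", 80.0), ("rosuvastatin", 20.0)],
}

_OTHER_AGENTS = ("omeprazole", "levothyroxine", "sertraline", "albuterol", "ibuprofen")

_RACE_LEVELS = ("white", "asian", "hispanic", "black", "other", "unknown")
_RACE_PROBS = (0.48, 0.32, 0.074, 0.017, 0.019, 0.09)

TABLE_COLUMNS = {
    "patients": ["patient_id", "birth_date", "sex", "race", "smoker", "index_date"],
    "labs": ["patient_id", "date", "test_code", "value", "unit"],
    "prescriptions": ["patient_id", "start_date", "end_date", "agent", "dose_mg"],
    "diagnoses": ["patient_id", "date", "code", "code_system"],
    "visits": ["patient_id", "date", "visit_type"],
    "socioeconomics": ["patient_id", "median_income", "pct_bachelors"],
}
_DATE_COLUMNS = {
    "patients": ["birth_date", "index_date"],
    "labs": ["date"],
    "prescriptions": ["start_date", "end_date"],
    "diagnoses": ["date"],
    "visits": ["date"],
    "socioeconomics": [],
}


def _default_base_effects() -> dict[str, float]:
    return {"none": 0.0, "low": 15.0, "moderate": 25.0, "high": 35.0}


def _default_prevalence() -> dict[str, float]:
    # mirrors the real-world composition: ~92% untreated, rare high intensity
    return {"none": 0.917, "low": 0.026, "moderate": 0.05, "high": 0.007}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    ``heterogeneity_coefs[arm]`` is a vector over the basis
    ``[age_std, ldl_std, cond_00, ..., cond_{n-1}]`` in percent reduction per
    standardized unit; omitted arms default to zeros.  ``flag_prevalences``
    optionally overrides per-flag Bernoulli rates (index 0 is the diabetes
    flag, index 1 the efficacy-gap subgroup flag whose rate is always
    ``gap_fraction``).
    """

    n_patients: int = 1000
    seed: int = 0
    n_condition_flags: int = 20
    arm_base_effects: dict[str, float] = field(default_factory=_default_base_effects)
    heterogeneity_coefs: dict[str, np.ndarray] = field(default_factory=dict)
    noise_sd: float = 10.0
    confounding_strength: float = 0.0
    gap_fraction: float = 0.3
    gap_attenuation: float = 0.4
    arm_prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    missing_lab_rate: float = 0.05
    flag_prevalences: list[float] | None = None

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if self.n_condition_flags < 2:
            raise ConfigurationError("n_condition_flags must be >= 2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for name in ("confounding_strength", "gap_fraction", "missing_lab_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if set(self.arm_prevalence) != set(ARMS):
            raise ConfigurationError("arm_prevalence must cover exactly the four arms")
        if any(p < 0 or p > 1 for p in self.arm_prevalence.values()):
            raise ConfigurationError("arm_prevalence entries must lie in [0, 1]")
        if abs(sum(self.arm_prevalence.values()) - 1.0) > 1e-9:
            raise ConfigurationError("arm_prevalence must sum to 1 within 1e-9")
        if not set(self.arm_base_effects) >= set(ARMS):
            raise ConfigurationError("arm_base_effects must cover the four arms")
        dim = self.basis_dim
        coefs = {}
        for arm in ARMS:
            c = np.asarray(self.heterogeneity_coefs.get(arm, np.zeros(dim)), dtype=float)
            if c.shape != (dim,):
                raise ConfigurationError(
                    f"heterogeneity_coefs[{arm}] must have length {dim} "
                    f"(age_std, ldl_std, then {self.n_condition_flags} flags)"
                )
            coefs[arm] = c
        self.heterogeneity_coefs = coefs
        if self.flag_prevalences is not None:
            if len(self.flag_prevalences) != self.n_condition_flags:
                raise ConfigurationError(
                    "flag_prevalences must have one entry per condition flag"
                )
            if any(p < 0 or p > 1 for p in self.flag_prevalences):
                raise ConfigurationError("flag_prevalences entries must lie in [0, 1]")

    @property
    def basis_dim(self) -> int:
        return 2 + self.n_condition_flags

    @property
    def basis_names(self) -> list[str]:
        return ["age_std", "ldl_std"] + [
            f"cond_{i:02d}" for i in range(self.n_condition_flags)
        ]


@dataclass
class GroundTruth:
    """True per-arm expected reductions and the implied best arm per patient.

    ``expectations`` has columns ``patient_id, mu_none, mu_low, mu_moderate,
    mu_high, best_arm``; ``active_features`` flags which basis features truly
    modify some arm's response.
    """

    expectations: pd.DataFrame
    active_features: pd.Series

    def best_arm(self) -> pd.Series:
        return self.expectations.set_index("patient_id")["best_arm"]


@dataclass
class EHRTables:
    """The six-file raw EHR extract (long-format labs include vitals)."""

    patients: pd.DataFrame
    labs: pd.DataFrame
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame
    visits: pd.DataFrame
    socioeconomics: pd.DataFrame

    def table_dict(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_COLUMNS}

    @classmethod
    def empty(cls) -> "EHRTables":
        frames = {}
        for name, cols in TABLE_COLUMNS.items():
            df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
            for c in _DATE_COLUMNS[name]:
                df[c] = pd.Series(dtype="datetime64[ns]")
            frames[name] = df
        return cls(**frames)

    @classmethod
    def from_rows(cls, rows: dict[str, list[dict]]) -> "EHRTables":
        """Build tables from per-table lists of row dicts (test fixtures)."""
        base = cls.empty().table_dict()
        frames = {}
        for name, cols in TABLE_COLUMNS.items():
            recs = rows.get(name, [])
            df = pd.DataFrame(recs, columns=cols) if recs else base[name]
            for c in _DATE_COLUMNS[name]:
                df[c] = pd.to_datetime(df[c])
            frames[name] = df
        return cls(**frames)


def _flag_prevalences(config: GeneratorConfig) -> np.ndarray:
    if config.flag_prevalences is not None:
        p = np.asarray(config.flag_prevalences, dtype=float).copy()
    else:
        p = np.full(config.n_condition_flags, 0.08)
        p[0] = 0.10  # diabetes
    p[1] = config.gap_fraction  # efficacy-gap subgroup flag
    return p


def generate_cohort(config: GeneratorConfig) -> tuple[EHRTables, GroundTruth]:
    """Draw a cohort and its ground truth; byte-deterministic in (config, seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pid = np.array([f"P{i:07d}" for i in range(n)])

    # --- patient-level covariates -------------------------------------------
    age = np.floor(rng.uniform(40.0, 80.0, n))
    sex = np.where(rng.random(n) < 0.55, "F", "M")
    race = rng.choice(_RACE_LEVELS, size=n, p=_RACE_PROBS)
    smoker = (rng.random(n) < 0.042).astype(int)

    ldl = rng.normal(_LDL_MEAN, _LDL_SD, n)
    ldl = np.where(ldl < 40.0, 40.0 + (40.0 - ldl) % 40.0, ldl)  # reflect at floor
    # total cholesterol correlated with LDL-C (rho = 0.7)
    tc = 200.0 + 0.7 * (34.0 / _LDL_SD) * (ldl - _LDL_MEAN) + rng.normal(
        0.0, 34.0 * np.sqrt(1 - 0.7**2), n
    )
    hdl = np.clip(rng.normal(55.0, 15.0, n), 20.0, None)
    sbp = rng.normal(124.0, 16.6, n)
    dbp = rng.normal(77.0, 10.3, n)
    height = np.where(sex == "F", rng.normal(162.0, 7.0, n), rng.normal(176.0, 7.5, n))
    weight = np.clip(rng.normal(78.0, 17.0, n), 40.0, None)

    pflag = _flag_prevalences(config)
    flags = (rng.random((n, config.n_condition_flags)) < pflag).astype(int)

    income = np.clip(rng.lognormal(np.log(85_000), 0.5, n), 15_000, 400_000)
    pct_bach = np.clip(rng.normal(68.0, 28.0, n), 0.0, 100.0)

    index_offset = rng.integers(0, 2557, n)  # 2010-01-01 .. 2016-12-31
    index_date = pd.Timestamp("2010-01-01") + pd.to_timedelta(index_offset, unit="D")
    birth_date = index_date - pd.to_timedelta(
        (age * 365.25 + rng.integers(0, 365, n)).astype(int), unit="D"
    )

    # --- heterogeneity basis and true response surface ----------------------
    age_std = (age - _AGE_MEAN) / _AGE_SD
    ldl_std = (ldl - _LDL_MEAN) / _LDL_SD
    basis = np.column_stack([age_std, ldl_std, flags])
    diabetes = flags[:, 0]
    gap_flag = flags[:, 1]

    mu = {}
    for arm in ARMS:
        mu[arm] = config.arm_base_effects[arm] + basis @ config.heterogeneity_coefs[arm]
    mu["high"] = np.where(gap_flag == 1, mu["high"] * config.gap_attenuation, mu["high"])
    mu_mat = np.column_stack([mu[a] for a in ARMS])
    best_arm = np.array(ARMS)[np.argmax(mu_mat, axis=1)]

    # --- confounded arm assignment ------------------------------------------
    score = 0.6 * age_std + 0.6 * ldl_std + 0.8 * diabetes
    tilt = np.array([0.0, 0.5, 0.75, 1.0])  # more intense arms attract higher scores
    logits = np.log(np.array([config.arm_prevalence[a] for a in ARMS]) + 1e-300)
    logits = logits[None, :] + config.confounding_strength * score[:, None] * tilt[None, :]
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    arm_idx = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
    arm = np.array(ARMS)[arm_idx]

    # --- realized follow-up LDL-C -------------------------------------------
    eps = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    mu_assigned = mu_mat[np.arange(n), arm_idx]
    followup_ldl = np.maximum(ldl * (1.0 - (mu_assigned + eps) / 100.0), 5.0)
    followup_offset = 365 + rng.integers(-30, 31, n)
    followup_missing = rng.random(n) < config.missing_lab_rate

    # --- assemble the six tables --------------------------------------------
    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "birth_date": birth_date,
            "sex": sex,
            "race": race,
            "smoker": smoker,
            "index_date": index_date,
        }
    )
    socio = pd.DataFrame(
        {
            "patient_id": pid,
            "median_income": np.round(income, 2),
            "pct_bachelors": np.round(pct_bach, 2),
        }
    )

    lab_parts = []

    def add_lab(code, values, day_offset, unit):
        lab_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "date": index_date + pd.to_timedelta(day_offset, unit="D"),
                    "test_code": code,
                    "value": np.round(values, 2),
                    "unit": unit,
                }
            )
        )

    add_lab("LDL", ldl, -10, "mg/dL")
    add_lab("TC", tc, -10, "mg/dL")
    add_lab("HDL", hdl, -10, "mg/dL")
    add_lab("SBP", sbp, -30, "mmHg")
    add_lab("DBP", dbp, -30, "mmHg")
    add_lab("HEIGHT", height, -30, "cm")
    add_lab("WEIGHT", weight, -30, "kg")
    fup = pd.DataFrame(
        {
            "patient_id": pid,
            "date": index_date + pd.to_timedelta(followup_offset, unit="D"),
            "test_code": "LDL",
            "value": np.round(followup_ldl, 2),
            "unit": "mg/dL",
        }
    )[~followup_missing]
    lab_parts.append(fup)
    labs = pd.concat(lab_parts, ignore_index=True)

    # diagnoses: one CCS-coded row per active flag, dated inside the 1y lookback
    pat_idx, flag_idx = np.nonzero(flags)
    diag_days = rng.integers(20, 360, pat_idx.size)
    diagnoses = pd.DataFrame(
        {
            "patient_id": pid[pat_idx],
            "date": index_date[pat_idx] - pd.to_timedelta(diag_days, unit="D"),
            "code": np.array([f"CCS_{j:02d}" for j in flag_idx]),
            "code_system": "CCS",
        }
    )

    # prescriptions: statin per assigned arm (started shortly post-index),
    # antihypertensives, diabetes agents, assorted other agents in lookback
    rx_parts = []
    for arm_name, menu in _STATIN_MENU.items():
        mask = arm == arm_name
        m = int(mask.sum())
        if m == 0:
            continue
        pick = rng.integers(0, len(menu), m)
        agents = np.array([menu[k][0] for k in pick])
        doses = np.array([menu[k][1] for k in pick])
        start = index_date[mask] + pd.to_timedelta(rng.integers(1, 45, m), unit="D")
        rx_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pid[mask],
                    "start_date": start,
                    "end_date": start + pd.Timedelta(days=365),
                    "agent": agents,
                    "dose_mg": doses,
                }
            )
        )

    antihtn = rng.random(n) < 0.28
    for mask, agent_pool, dose in (
        (antihtn, sorted(ANTIHYPERTENSIVE_AGENTS), 10.0),
        (diabetes == 1, ["metformin"], 500.0),
    ):
        m = int(mask.sum())
        if m == 0:
            continue
        agents = rng.choice(agent_pool, m)
        start = index_date[mask] - pd.to_timedelta(rng.integers(30, 360, m), unit="D")
        rx_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pid[mask],
                    "start_date": start,
                    "end_date": start + pd.Timedelta(days=365),
                    "agent": agents,
                    "dose_mg": dose,
                }
            )
        )

    n_other = rng.poisson(1.5, n)
    rep = np.repeat(np.arange(n), n_other)
    if rep.size:
        start = index_date[rep] - pd.to_timedelta(rng.integers(10, 360, rep.size), unit="D")
        rx_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pid[rep],
                    "start_date": start,
                    "end_date": start + pd.Timedelta(days=90),
                    "agent": rng.choice(_OTHER_AGENTS, rep.size),
                    "dose_mg": 10.0,
                }
            )
        )
    prescriptions = pd.concat(rx_parts, ignore_index=True)

    # visits: two anchors >= 1 year apart plus utilization draws in lookback
    visit_parts = [
        pd.DataFrame(
            {"patient_id": pid, "date": index_date - pd.Timedelta(days=380),
             "visit_type": "primary_care"}
        ),
        pd.DataFrame({"patient_id": pid, "date": index_date, "visit_type": "primary_care"}),
    ]
    for vtype, lam in (
        ("primary_care", 0.5),
        ("urgent_care", 0.3),
        ("specialty", 0.8),
        ("other", 0.5),
    ):
        counts = rng.poisson(lam, n)
        rep = np.repeat(np.arange(n), counts)
        if rep.size:
            visit_parts.append(
                pd.DataFrame(
                    {
                        "patient_id": pid[rep],
                        "date": index_date[rep]
                        - pd.to_timedelta(rng.integers(1, 360, rep.size), unit="D"),
                        "visit_type": vtype,
                    }
                )
            )
    visits = pd.concat(visit_parts, ignore_index=True)

    tables = EHRTables(
        patients=patients,
        labs=_sorted(labs, ["patient_id", "date", "test_code"]),
        prescriptions=_sorted(prescriptions, ["patient_id", "start_date", "agent"]),
        diagnoses=_sorted(diagnoses, ["patient_id", "date", "code"]),
        visits=_sorted(visits, ["patient_id", "date", "visit_type"]),
        socioeconomics=socio,
    )

    expectations = pd.DataFrame({"patient_id": pid})
    for a in ARMS:
        expectations[f"mu_{a}"] = mu[a] if a != "high" else mu_mat[:, ARMS.index("high")]
    expectations["best_arm"] = best_arm
    active = pd.Series(False, index=config.basis_names)
    for a in ARMS:
        active |= pd.Series(config.heterogeneity_coefs[a] != 0, index=config.basis_names)
    if config.gap_fraction > 0 and config.gap_attenuation != 1.0:
        active["cond_01"] = True
    truth = GroundTruth(expectations=expectations, active_features=active)
    return tables, truth


def _sorted(df: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    return df.sort_values(by, kind="mergesort").reset_index(drop=True)


# --- file round-trip ---------------------------------------------------------

def write_cohort(tables: EHRTables, path: str | Path) -> None:
    """Write the six tables as UTF-8 CSV files under ``path`` (a directory)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, df in tables.table_dict().items():
        out = df.copy()
        for col in _DATE_COLUMNS[name]:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        out.to_csv(path / f"{name}.csv", index=False)


def read_cohort(path: str | Path) -> EHRTables:
    """Read a cohort directory written by :func:`write_cohort`.

    Raises :class:`ParseError` naming the file and column when a required
    column is absent.
    """
    path = Path(path)
    loaded = {}
    for name, required in TABLE_COLUMNS.items():
        fname = path / f"{name}.csv"
        if not fname.exists():
            raise ParseError(f"missing table file: {fname.name}")
        df = pd.read_csv(fname, dtype={"patient_id": str})
        for col in required:
            if col not in df.columns:
                raise ParseError(f"{fname.name}: missing required column '{col}'")
        for col in _DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
        loaded[name] = df[required]
    return EHRTables(**loaded)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    truth.expectations.to_csv(path / "ground_truth.csv", index=False)
    truth.active_features.rename("active").rename_axis("feature").to_csv(
        path / "active_features.csv"
    )


def read_ground_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    exp = pd.read_csv(path / "ground_truth.csv", dtype={"patient_id": str})
    active = pd.read_csv(path / "active_features.csv", index_col="feature")["active"]
    return GroundTruth(expectations=exp, active_features=active)


def config_to_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["heterogeneity_coefs"] = {
        a: list(map(float, v)) for a, v in config.heterogeneity_coefs.items()
    }
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "heterogeneity_coefs" in d and d["heterogeneity_coefs"]:
        d["heterogeneity_coefs"] = {
            a: np.asarray(v, dtype=float) for a, v in d["heterogeneity_coefs"].items()
        }
    return GeneratorConfig(**d)
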