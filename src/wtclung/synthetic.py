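"""Synthetic responder-cohort generator with a planted outcome hazard.

The real surveillance cohort is restricted, so every downstream stage is
exercised on synthetic cohorts that reproduce its published marginal
covariate structure: median enrollment age 44 (IQR 38-51), 15.9% female,
smoking status 13.8% current / 24.4% former / 61.8% never, median smoker
pack-years 7.5 (exponential), median BMI 29.1 (IQR 26.4-32.4), 6.7% COPD,
the twelve occupational-exposure prevalences, and median follow-up 11.1
years (IQR 6.3-14.3).  Continuous covariates use log-normals fitted to the
printed median/IQR; pack-years use an exponential whose mean is set so the
median equals 7.5 (mean 7.5/ln 2).  Joint structure beyond these marginals
is NOT emulated: occupational flags are drawn independently by default.

Outcomes are planted with a known multiplicative monthly hazard
(``plant_outcomes``) so that parameter-recovery and null-calibration tests
have a ground truth, or directly from a logistic risk model
(``plant_outcomes_from_model``) so the planted hazard can equal the
microsimulation comparator's exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import COLUMNS, OCC_EXPOSURES, DAYS_PER_YEAR
from .errors import ConfigError, ValidationError

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal

#: Race/ethnicity distribution (non-case column of the published cohort table).
RACE_PROBS = {"nl_white": 9125, "nl_black": 2072, "latino": 2003,
              "asian": 209, "multiracial": 2515, "other": 1674}
EDUCATION_PROBS = {"lt_hs": 1442, "hs_grad": 3630, "some_college": 6741,
                   "college_grad": 3467, "grad_school": 1683, "unknown": 635}
SMOKING_PROBS = {"never": 10878, "former": 4300, "current": 2420}
WTC_LEVEL_PROBS = {"low": 2469, "intermediate": 10949, "high": 3737,
                   "missing": 443}
#: Pre-enrollment occupational exposure prevalences (non-case column).
OCC_PREVS = {"any_moderate_significant": 12509 / 17598, "asbestos": 2239 / 17598,
             "cadmium": 359 / 17598, "diesel": 5523 / 17598,
             "nondiesel_fumes": 4203 / 17598, "general_dust": 10897 / 17598,
             "mineral_dust": 1200 / 17598, "wood_dust": 3113 / 17598,
             "silica": 2730 / 17598, "fiberglass": 1918 / 17598,
             "industrial_solutions": 2807 / 17598, "welding": 1648 / 17598}


def _norm(counts: dict) -> dict:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def lognormal_from_median_iqr(median: float, q1: float, q3: float):
    """(mu, sigma) of the log-normal matching the given median and IQR."""
    if not (0 < q1 < median < q3):
        raise ConfigError("need 0 < q1 < median < q3")
    return math.log(median), math.log(q3 / q1) / (2.0 * _Z75)


@dataclass
class GeneratorConfig:
    """Marginal distributions for the synthetic cohort.

    Defaults are the published cohort's marginals; probability vectors are
    validated to sum to 1.
    """

    n: int = 1000
    seed: int = 0
    age_median_iqr: tuple = (44.0, 38.0, 51.0)
    frac_female: float = 2805 / 17598  # 15.9%
    race_probs: dict = field(default_factory=lambda: _norm(RACE_PROBS))
    education_probs: dict = field(default_factory=lambda: _norm(EDUCATION_PROBS))
    smoking_probs: dict = field(default_factory=lambda: _norm(SMOKING_PROBS))
    pack_year_mean: float = 7.5 / math.log(2)  # median 7.5
    bmi_median_iqr: tuple = (29.1, 26.4, 32.4)
    copd_prev: float = 0.067
    prior_cancer_prev: float = 0.03
    spirometry_missing_frac: float = 1090 / 17668
    fev1_fvc_mean_sd: tuple = (0.78, 0.055)
    occ_exposure_prevs: dict = field(default_factory=lambda: dict(OCC_PREVS))
    wtc_level_probs: dict = field(default_factory=lambda: _norm(WTC_LEVEL_PROBS))
    wtc_arrival_48h_prev: float = 11172 / 17598
    wtc_duration_gt60d_prev: float = 10992 / 16758
    followup_median_iqr: tuple = (11.1, 6.3, 14.3)
    followup_max: float = 17.0  # surveillance window cap
    enrollment_window: tuple = ("2002-01-01", "2004-12-31")
    missing_fracs: dict = field(default_factory=lambda: {
        "bmi": 0.011, "pack_years": 0.05, "education": 0.03})

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigError("n must be non-negative")
        for name in ("race_probs", "education_probs", "smoking_probs",
                     "wtc_level_probs"):
            probs = getattr(self, name)
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1")
            if any(p < 0 for p in probs.values()):
                raise ConfigError(f"{name} has negative entries")
        for k, p in {**self.occ_exposure_prevs,
                     "female": self.frac_female, "copd": self.copd_prev,
                     **self.missing_fracs}.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"prevalence {k}={p} outside [0,1]")


@dataclass
class PlantedHazard:
    """Ground-truth multiplicative monthly hazard for planted outcomes.

    Per-person monthly event probability is
    ``baseline_monthly_rate × exp(Σ log_irr · covariate)``.  Recognised
    covariate keys: ``age_per_year`` (age − 45), ``pack_year``, ``female``,
    ``copd``, ``prior_cancer``, ``current_smoker``, ``former_smoker`` and any
    occupational exposure name (e.g. ``mineral_dust``).
    """

    baseline_monthly_rate: float = 39.5e-5 / 12.0  # matches the observed crude rate
    log_irrs: dict = field(default_factory=dict)

    AGE_CENTER = 45.0

    def monthly_probs(self, cohort: pd.DataFrame) -> np.ndarray:
        if not 0.0 < self.baseline_monthly_rate < 1.0 and self.baseline_monthly_rate != 0.0:
            raise ConfigError("baseline_monthly_rate must be in [0, 1)")
        lp = np.zeros(len(cohort))
        for key, beta in self.log_irrs.items():
            lp += beta * self._covariate(cohort, key)
        p = self.baseline_monthly_rate * np.exp(lp)
        if (p >= 1.0).any():
            raise ValidationError("planted monthly probability reached 1; "
                                  "reduce baseline or effect sizes")
        return p

    @staticmethod
    def _covariate(cohort: pd.DataFrame, key: str) -> np.ndarray:
        if key == "age_per_year":
            return cohort["age_at_enrollment"].to_numpy(float) - PlantedHazard.AGE_CENTER
        if key == "pack_year":
            return cohort["pack_years"].fillna(0.0).to_numpy(float)
        if key == "female":
            return (cohort["sex"] == "female").to_numpy(float)
        if key in ("current_smoker", "former_smoker"):
            return (cohort["smoking_status"] == key.split("_")[0]).to_numpy(float)
        if key in ("copd", "prior_cancer"):
            return cohort[key].to_numpy(bool).astype(float)
        if key in OCC_EXPOSURES:
            return cohort[f"occ_{key}"].to_numpy(bool).astype(float)
        raise ConfigError(f"unknown planted-hazard covariate {key!r}")


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic cohort (outcome columns unset) in the canonical schema.

    Reproducible given ``config.seed``; marginals match the configuration up
    to sampling error; missingness injected at the configured fractions.
    """
    config.validate()
    n = config.n
    rng = np.random.default_rng(config.seed)
    df = pd.DataFrame(index=range(n))
    df["id"] = [f"S{i:06d}" for i in range(n)]

    mu, sig = lognormal_from_median_iqr(*config.age_median_iqr)
    df["age_at_enrollment"] = np.clip(rng.lognormal(mu, sig, n), 18.0, 85.0).round(1)
    df["sex"] = np.where(rng.random(n) < config.frac_female, "female", "male")
    for col, probs in (("race_ethnicity", config.race_probs),
                       ("education", config.education_probs),
                       ("smoking_status", config.smoking_probs),
                       ("wtc_exposure_level", config.wtc_level_probs)):
        df[col] = rng.choice(list(probs), size=n, p=list(probs.values()))

    smoker = df["smoking_status"].isin(["former", "current"]).to_numpy()
    py = np.where(smoker, rng.exponential(config.pack_year_mean, n), 0.0)
    # Decompose pack-years into intensity x duration: smoking is assumed to
    # start at 18 and occupy a random 30-90% span of adult life (convention;
    # the source tables report only pack-years).
    adult = np.maximum(df["age_at_enrollment"].to_numpy() - 18.0, 1.5)
    duration = np.where(smoker, np.maximum(rng.uniform(0.3, 0.9, n) * adult, 1.0), 0.0)
    cpd = np.where(smoker, py * 20.0 / np.maximum(duration, 1e-9), 0.0)
    former = (df["smoking_status"] == "former").to_numpy()
    quit_gap = np.maximum(adult - duration, 0.0)
    ysq = np.where(former, rng.uniform(0.0, 1.0, n) * quit_gap, np.nan)
    df["pack_years"] = np.round(py, 3)
    df["smoking_duration"] = np.round(duration, 2)
    df["cigarettes_per_day"] = np.round(cpd, 2)
    # keep the pack-year identity exact after rounding
    df.loc[smoker, "pack_years"] = (df.loc[smoker, "cigarettes_per_day"] / 20.0
                                    * df.loc[smoker, "smoking_duration"])
    df["years_since_quit"] = np.round(ysq, 2)

    mu, sig = lognormal_from_median_iqr(*config.bmi_median_iqr)
    df["bmi"] = np.clip(rng.lognormal(mu, sig, n), 15.0, 60.0).round(1)
    df["copd"] = rng.random(n) < config.copd_prev
    df["prior_cancer"] = rng.random(n) < config.prior_cancer_prev
    df["family_history_lung_cancer"] = pd.array([pd.NA] * n, dtype="boolean")

    spiro_missing = rng.random(n) < config.spirometry_missing_frac
    fvc = np.clip(rng.normal(4.1, 0.8, n), 2.0, 7.0)
    ratio = np.clip(rng.normal(*config.fev1_fvc_mean_sd, n), 0.35, 0.95)
    df["fvc"] = np.where(spiro_missing, np.nan, fvc.round(2))
    df["fev1"] = np.where(spiro_missing, np.nan, (ratio * fvc).round(2))

    for e in OCC_EXPOSURES:
        df[f"occ_{e}"] = rng.random(n) < config.occ_exposure_prevs[e]
    df["wtc_arrival_48h"] = rng.random(n) < config.wtc_arrival_48h_prev
    df["wtc_duration_gt60d"] = rng.random(n) < config.wtc_duration_gt60d_prev

    start, end = (pd.Timestamp(d) for d in config.enrollment_window)
    window_days = (end - start).days
    enroll = start + pd.to_timedelta(
        rng.integers(0, window_days + 1, n), unit="D")
    mu, sig = lognormal_from_median_iqr(*config.followup_median_iqr)
    fu_years = np.clip(rng.lognormal(mu, sig, n), 0.3, config.followup_max)
    df["enrollment_date"] = enroll
    df["last_encounter_date"] = enroll + pd.to_timedelta(
        np.round(fu_years * DAYS_PER_YEAR).astype(int), unit="D")

    df["lung_cancer"] = False
    df["lung_cancer_date"] = pd.NaT

    # Missingness injection (observed values untouched elsewhere).
    miss = config.missing_fracs
    df.loc[rng.random(n) < miss.get("bmi", 0.0), "bmi"] = np.nan
    # smoking dose is missing as a block: pack-years derive from intensity
    # and duration, so the three are unobserved together
    py_miss = (rng.random(n) < miss.get("pack_years", 0.0)) & smoker
    df.loc[py_miss, ["pack_years", "cigarettes_per_day",
                     "smoking_duration"]] = np.nan
    df.loc[rng.random(n) < miss.get("education", 0.0), "education"] = pd.NA

    return df[list(COLUMNS)]


def plant_outcomes(cohort: pd.DataFrame, hazard: PlantedHazard,
                   seed: int) -> pd.DataFrame:
    """Plant lung-cancer outcomes under a constant per-person monthly hazard.

    Each person's event month is geometric with their monthly probability;
    events beyond the last encounter are censored.  Returns a copy.
    """
    df = cohort.copy()
    n = len(df)
    if n == 0:
        return df
    p = hazard.monthly_probs(df)
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        month = np.where(p > 0, np.ceil(np.log(u) / np.log1p(-p)), np.inf)
    fu_days = (df["last_encounter_date"] - df["enrollment_date"]).dt.days.to_numpy()
    n_months = np.ceil(fu_days / (DAYS_PER_YEAR / 12.0))
    event = month <= n_months
    df["lung_cancer"] = event
    days = np.where(event, np.minimum(month * (DAYS_PER_YEAR / 12.0), fu_days), 0)
    dates = df["enrollment_date"] + pd.to_timedelta(np.round(days), unit="D")
    df["lung_cancer_date"] = dates.where(event, pd.NaT)
    return df


def plant_outcomes_from_model(cohort: pd.DataFrame, model, seed: int) -> pd.DataFrame:
    """Plant outcomes whose hazard is exactly a logistic risk model's schedule.

    Builds the same monthly schedules the microsimulation comparator uses
    (6/12/18-year windows, constant monthly rate within each) and draws each
    person's event month from them, so observed and simulated cohorts share
    the same ground-truth hazard.  The cohort must carry complete risk-model
    inputs (run imputation first).
    """
    from . import microsim
    from .cohort import apply_eligibility

    df = cohort.copy()
    analytic = apply_eligibility(df)
    schedules = microsim.build_schedules(analytic, model)
    rng = np.random.default_rng(seed)
    months = microsim.draw_event_months(schedules, rng)
    by_id = dict(zip(analytic.participants["id"], zip(
        months, analytic.participants["entry_date"],
        analytic.participants["last_encounter_date"])))
    event, dates = [], []
    for pid in df["id"]:
        m, entry, last = by_id.get(pid, (0, None, None))
        if m > 0:
            event.append(True)
            dates.append(min(entry + pd.to_timedelta(round(m * DAYS_PER_YEAR / 12.0),
                                                     unit="D"), last))
        else:
            event.append(False)
            dates.append(pd.NaT)
    df["lung_cancer"] = event
    df["lung_cancer_date"] = pd.to_datetime(dates)
    return df
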