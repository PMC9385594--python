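"""Cohort data model: schema, derived covariates, eligibility, person-time.

The analytic design follows the standard occupational-surveillance layout:
participants enroll in a monitoring program, undergo a baseline exam
(demographics, smoking history, spirometry, exposure questionnaires) and are
followed through clinic encounters until their last visit.  Because a cancer
diagnosed immediately after joining is more plausibly prevalent disease that
motivated enrollment than incident disease, entry into the analytic cohort is
deferred by three months and cancers dated before that entry are excluded.

Person-time runs from the deferred entry date to the last clinical encounter.
"Three months" is implemented as exactly 0.25 Julian years (91.3125 days) so
that person-time arithmetic is exact and testable; no calendar-month
convention is assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
#: Deferred-entry lag: exactly 0.25 Julian years.
THREE_MONTHS_DAYS = DAYS_PER_YEAR / 4.0  # 91.3125

SEX_LEVELS = ("female", "male")
RACE_LEVELS = ("nl_white", "nl_black", "latino", "asian", "multiracial", "other")
EDUCATION_LEVELS = ("lt_hs", "hs_grad", "some_college", "college_grad",
                    "grad_school", "unknown")
SMOKING_LEVELS = ("never", "former", "current")
WTC_EXPOSURE_LEVELS = ("low", "intermediate", "high", "missing")

#: The twelve self-reported pre-enrollment occupational exposure flags.
OCC_EXPOSURES = (
    "asbestos", "cadmium", "diesel", "nondiesel_fumes", "general_dust",
    "mineral_dust", "wood_dust", "silica", "fiberglass",
    "industrial_solutions", "welding", "any_moderate_significant",
)
OCC_COLUMNS = tuple(f"occ_{e}" for e in OCC_EXPOSURES)

#: Canonical CSV column order.
COLUMNS = (
    "id", "enrollment_date", "age_at_enrollment", "sex", "race_ethnicity",
    "education", "bmi", "copd", "fev1", "fvc", "smoking_status",
    "cigarettes_per_day", "smoking_duration", "pack_years",
    "years_since_quit", "family_history_lung_cancer", "prior_cancer",
    "wtc_exposure_level", "wtc_arrival_48h", "wtc_duration_gt60d",
    *OCC_COLUMNS,
    "last_encounter_date", "lung_cancer", "lung_cancer_date",
)

_DATE_COLUMNS = ("enrollment_date", "last_encounter_date", "lung_cancer_date")
_BOOL_COLUMNS = ("copd", "family_history_lung_cancer", "prior_cancer",
                 "wtc_arrival_48h", "wtc_duration_gt60d", *OCC_COLUMNS,
                 "lung_cancer")


def classify_smoking(lifetime_packs: float, cigarettes_per_day: float,
                     duration_years: float, currently_smoking: bool) -> str:
    """Classify smoking status from lifetime exposure.

    A participant counts as a never smoker if they smoked fewer than 20
    lifetime packs, or smoked less than one cigarette per day for at most one
    year.  Both thresholds are strict ("less than"), so exactly 20 packs or
    exactly 1 cigarette/day qualifies as a smoker.  Otherwise the participant
    is a current smoker if still smoking, former if not.
    """
    if lifetime_packs < 0 or cigarettes_per_day < 0 or duration_years < 0:
        raise ValidationError("smoking quantities must be non-negative")
    if lifetime_packs < 20 or (cigarettes_per_day < 1 and duration_years <= 1):
        return "never"
    return "current" if currently_smoking else "former"


def derive_obstruction(fev1: float | None, fvc: float | None) -> bool | None:
    """Airway obstruction from spirometry: FEV1/FVC of 0.70 or less.

    Missing spirometry returns ``None`` (a distinct missing state, never
    coerced to ``False``): participants without spirometry are excluded from
    obstruction-stratified models rather than treated as unobstructed.
    """
    if fev1 is None or fvc is None or (isinstance(fev1, float) and np.isnan(fev1)) \
            or (isinstance(fvc, float) and np.isnan(fvc)):
        return None
    if fvc == 0:
        raise ValidationError("FVC must be positive")
    if fvc < 0 or fev1 < 0 or fev1 > fvc:
        raise ValidationError(f"implausible spirometry: FEV1={fev1}, FVC={fvc}")
    # tolerate float representation at the 0.70 boundary (e.g. 2.1/3.0)
    return fev1 / fvc <= 0.70 * (1.0 + 1e-9)


def pack_years(cigarettes_per_day: float, duration_years: float) -> float:
    """Cumulative dose in pack-years: (cigarettes/day ÷ 20) × years smoked."""
    return cigarettes_per_day / 20.0 * duration_years


@dataclass
class AnalyticCohort:
    """Eligibility-filtered participants with person-time and event status.

    ``participants`` carries the cohort schema plus three derived columns:
    ``entry_date`` (enrollment + 3 months), ``person_years`` and ``event``.
    """

    participants: pd.DataFrame
    n_dropped_early_cancer: int = 0
    n_dropped_short_followup: int = 0
    end_at_diagnosis: bool = False

    @property
    def n(self) -> int:
        return len(self.participants)

    @property
    def total_person_years(self) -> float:
        return float(self.participants["person_years"].sum())

    @property
    def n_events(self) -> int:
        return int(self.participants["event"].sum())

    def summary(self) -> dict:
        return {"n": self.n, "events": self.n_events,
                "person_years": self.total_person_years,
                "dropped_early_cancer": self.n_dropped_early_cancer,
                "dropped_short_followup": self.n_dropped_short_followup}


def _validate_outcomes(df: pd.DataFrame) -> None:
    lc = df["lung_cancer"].fillna(False).astype(bool)
    has_date = df["lung_cancer_date"].notna()
    if (lc & ~has_date).any():
        bad = df.loc[lc & ~has_date, "id"].tolist()[:5]
        raise ValidationError(f"lung_cancer flagged without a date: {bad}")
    dated = df.loc[lc & has_date]
    late = dated["lung_cancer_date"] > dated["last_encounter_date"]
    if late.any():
        bad = dated.loc[late, "id"].tolist()[:5]
        raise ValidationError(
            f"lung_cancer_date after last encounter (linkage error): {bad}")
    if (df["last_encounter_date"] < df["enrollment_date"]).any():
        raise ValidationError("last_encounter_date precedes enrollment_date")


def apply_eligibility(participants: pd.DataFrame, *,
                      end_at_diagnosis: bool = False) -> AnalyticCohort:
    """Filter to the analytic cohort and accrue person-time.

    Drops (1) cancers dated before the deferred entry date (enrollment + 3
    months) — these are prevalent, not incident — and (2) participants whose
    last encounter precedes entry (no at-risk time); the second count is
    logged.  Retained participants get ``entry_date``, ``person_years``
    (entry to last encounter, or to diagnosis when ``end_at_diagnosis``) and
    ``event``.

    Idempotent: re-applying to the result changes neither membership nor
    person-time.
    """
    df = participants.copy()
    _validate_outcomes(df)

    entry = df["enrollment_date"] + pd.to_timedelta(THREE_MONTHS_DAYS, unit="D")
    lc = df["lung_cancer"].fillna(False).astype(bool)
    early = lc & (df["lung_cancer_date"] < entry)
    df, entry, lc = df[~early], entry[~early], lc[~early]
    n_early = int(early.sum())

    short = df["last_encounter_date"] < entry
    n_short = int(short.sum())
    if n_short:
        logger.info("dropping %d participants with no follow-up after entry",
                    n_short)
    df, entry, lc = df[~short], entry[~short], lc[~short]

    df = df.assign(entry_date=entry, event=lc)
    end = df["last_encounter_date"].copy()
    if end_at_diagnosis:
        end[df["event"]] = df.loc[df["event"], "lung_cancer_date"]
    df["person_years"] = (end - df["entry_date"]).dt.total_seconds() \
        / (86400.0 * DAYS_PER_YEAR)
    return AnalyticCohort(df.reset_index(drop=True),
                          n_dropped_early_cancer=n_early,
                          n_dropped_short_followup=n_short,
                          end_at_diagnosis=end_at_diagnosis)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV (ISO dates, {0,1} booleans, empty cells missing)."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing columns: {missing}")
    for c in _DATE_COLUMNS:
        df[c] = pd.to_datetime(df[c], format="ISO8601")
    for c in _BOOL_COLUMNS:
        df[c] = df[c].map({0: False, 1: True, 0.0: False, 1.0: True,
                           "0": False, "1": True, False: False, True: True})
    return df[list(COLUMNS)]


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV in the canonical schema."""
    out = df.copy()
    for c in _DATE_COLUMNS:
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    for c in _BOOL_COLUMNS:
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else str(int(bool(v))))
    cols = [c for c in COLUMNS if c in out.columns]
    # full-precision floats: keeps the pack-year identity exact on roundtrip
    out[cols].to_csv(path, index=False)


def validate_cohort(df: pd.DataFrame) -> list[str]:
    """Return a list of human-readable schema problems (empty = valid)."""
    problems: list[str] = []
    for col, levels in (("sex", SEX_LEVELS), ("race_ethnicity", RACE_LEVELS),
                        ("education", EDUCATION_LEVELS),
                        ("smoking_status", SMOKING_LEVELS),
                        ("wtc_exposure_level", WTC_EXPOSURE_LEVELS)):
        bad = set(df[col].dropna().unique()) - set(levels)
        if bad:
            problems.append(f"{col}: unexpected levels {sorted(bad)}")
    former = df["smoking_status"] == "former"
    if df.loc[~former, "years_since_quit"].notna().any() and \
            (df.loc[~former, "years_since_quit"].fillna(0) > 0).any():
        problems.append("years_since_quit set for non-former smokers")
    if former.any() and df.loc[former, "years_since_quit"].isna().any():
        problems.append("former smokers missing years_since_quit")
    ok = df[["cigarettes_per_day", "smoking_duration", "pack_years"]].notna().all(axis=1)
    if ok.any():
        expected = df.loc[ok, "cigarettes_per_day"] / 20.0 * df.loc[ok, "smoking_duration"]
        if (np.abs(df.loc[ok, "pack_years"] - expected) > 1e-9).any():
            problems.append("pack_years inconsistent with cigarettes_per_day × duration / 20")
    if (df["last_encounter_date"] < df["enrollment_date"]).any():
        problems.append("last_encounter_date precedes enrollment_date")
    lc = df["lung_cancer"].fillna(False).astype(bool)
    if (lc & df["lung_cancer_date"].isna()).any():
        problems.append("lung_cancer flagged without lung_cancer_date")
    dated = df[lc & df["lung_cancer_date"].notna()]
    if ((dated["lung_cancer_date"] < dated["enrollment_date"]) |
            (dated["lung_cancer_date"] > dated["last_encounter_date"])).any():
        problems.append("lung_cancer_date outside [enrollment, last encounter]")
    return problems
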