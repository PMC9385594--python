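"""Risk-model microsimulation comparator.

The comparator cohort is a replica of the observed cohort — same covariates,
same per-person follow-up — whose lung-cancer hazard comes from a published
6-year logistic risk model (the PLCOm2012 family) rather than from observed
events, i.e. a cohort with the same individual risk profiles but no WTC or
other occupational exposure contribution.

Per person the pipeline is:

1. evaluate the 6-year lung-cancer probability at baseline;
2. time-update the profile by 6 and 12 years (age advances; current smokers
   keep smoking at the same intensity so duration grows; former smokers stay
   quit so quit-time grows) and re-evaluate, giving 12- and 18-year window
   probabilities;
3. convert each window probability P to a constant monthly probability p with
   (1 - p)^72 = 1 - P;
4. lay the three windows along the person's actual follow-up (months 1-72,
   73-144, 145-216; follow-up beyond 216 months reuses the last window);
5. draw monthly Bernoulli trials until first success or end of follow-up.

The cohort is replicated ``n_reps`` times (default 30) with independent RNG
streams and the mean case count converted to an expected incidence rate on
the observed person-time denominator.  ``analytic_expected`` gives the exact
expectation of one replicate and serves as the engine's oracle.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .cohort import AnalyticCohort
from .errors import ConfigError, ValidationError

WINDOW_MONTHS = 72

#: Ordinal coding of educational attainment on the risk model's 1-6 scale.
#: "unknown" maps to the scale midpoint (documented convention).
EDUCATION_ORDINAL = {"lt_hs": 1, "hs_grad": 2, "some_college": 4,
                     "college_grad": 5, "grad_school": 6, "unknown": 3}

_TRANSFORMS = {
    "identity": lambda x: x,
    # smoking-intensity transform of the source model: (cigs/day ÷ 10)^-1
    "inverse_div10": lambda x: (x / 10.0) ** -1,
}


@dataclass(frozen=True)
class RiskModelTerm:
    """One term of the logistic risk model: coef × (transform(var) − center)."""

    name: str
    coef: float
    var: str
    center: float = 0.0
    transform: str = "identity"
    #: smoker-only terms contribute 0 for never smokers (reference level).
    smoker_only: bool = False


@dataclass(frozen=True)
class RiskModelCoefficients:
    """Named logistic coefficients + intercept for the 6-year risk model."""

    intercept: float
    terms: tuple[RiskModelTerm, ...]
    name: str = "unnamed"

    def __post_init__(self):
        for t in self.terms:
            if not math.isfinite(t.coef):
                raise ConfigError(f"non-finite coefficient for {t.name}")
            if t.transform not in _TRANSFORMS:
                raise ConfigError(f"unknown transform {t.transform!r}")
            if t.var not in _PROFILE_VARS:
                raise ConfigError(f"term {t.name!r} references unknown "
                                  f"covariate {t.var!r}")

    @classmethod
    def from_yaml(cls, path_or_stream) -> "RiskModelCoefficients":
        """Load a coefficient file, verifying its checksum when present.

        The optional top-level ``sha256`` field is the SHA-256 of the
        canonical JSON serialization of intercept + terms; a mismatch raises,
        guarding the transcription against silent edits.
        """
        if hasattr(path_or_stream, "read"):
            doc = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                doc = yaml.safe_load(fh)
        terms = tuple(RiskModelTerm(**t) for t in doc["terms"])
        model = cls(intercept=float(doc["intercept"]), terms=terms,
                    name=doc.get("name", "unnamed"))
        declared = doc.get("sha256")
        if declared and declared != model.checksum():
            raise ConfigError(f"coefficient checksum mismatch for "
                              f"{model.name}: file edited or corrupted?")
        return model

    def checksum(self) -> str:
        payload = json.dumps(
            {"intercept": self.intercept,
             "terms": [vars(t) if not hasattr(t, "__dict__") else
                       {f: getattr(t, f) for f in
                        ("name", "coef", "var", "center", "transform",
                         "smoker_only")} for t in self.terms]},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def load_bundled_model(name: str = "plco2012") -> RiskModelCoefficients:
    """Load a coefficient set shipped with the package (``plco2012``, ``toy``)."""
    ref = resources.files("wtclung.data") / f"{name}.yaml"
    with ref.open() as fh:
        return RiskModelCoefficients.from_yaml(fh)


@dataclass
class RiskProfile:
    """Covariate snapshot for one person at one horizon start."""

    age: float
    education_ord: float
    bmi: float
    copd: bool
    prior_cancer: bool
    family_history: bool
    race: str
    smoking_status: str
    intensity: float  # cigarettes/day
    duration: float   # years smoked
    quit_years: float  # former smokers; 0 otherwise

    def __post_init__(self):
        if self.age is not None and not (self.age != self.age) and self.age <= 0:
            raise ValidationError("age must be positive")
        if self.smoking_status == "never" and (self.intensity or self.duration):
            raise ValidationError("never smokers must have zero intensity "
                                  "and duration")


_PROFILE_VARS = {
    "age": lambda p: p.age,
    "education": lambda p: p.education_ord,
    "bmi": lambda p: p.bmi,
    "copd": lambda p: float(p.copd),
    "prior_cancer": lambda p: float(p.prior_cancer),
    "family_history": lambda p: float(p.family_history),
    "race_black": lambda p: float(p.race == "nl_black"),
    "race_hispanic": lambda p: float(p.race == "latino"),
    "race_asian": lambda p: float(p.race == "asian"),
    "female": lambda p: float(getattr(p, "sex", "") == "female"),
    "current_smoker": lambda p: float(p.smoking_status == "current"),
    "cigs_per_day": lambda p: p.intensity,
    "smoking_duration": lambda p: p.duration,
    "quit_years": lambda p: p.quit_years,
}


def profile_from_row(row) -> RiskProfile:
    """Build a baseline risk profile from a cohort-schema row."""
    status = row["smoking_status"]
    edu = row["education"]
    edu_ord = EDUCATION_ORDINAL["unknown" if pd.isna(edu) else edu]
    quit = row.get("years_since_quit", float("nan"))
    return RiskProfile(
        age=float(row["age_at_enrollment"]),
        education_ord=float(edu_ord),
        bmi=float(row["bmi"]),
        copd=bool(row["copd"]),
        prior_cancer=bool(row["prior_cancer"]),
        family_history=bool(row["family_history_lung_cancer"]),
        race=row["race_ethnicity"],
        smoking_status=status,
        intensity=float(row["cigarettes_per_day"]) if status != "never" else 0.0,
        duration=float(row["smoking_duration"]) if status != "never" else 0.0,
        quit_years=float(quit) if status == "former" and not pd.isna(quit) else 0.0,
    )


def six_year_prob(profile: RiskProfile,
                  coeffs: RiskModelCoefficients) -> float:
    """6-year lung-cancer probability: inverse-logit of the linear predictor.

    Never smokers are scored with all smoker-only terms at their reference
    (zero-contribution) level — the model was derived in ever-smokers and
    this is the minimal literal extension (see the methods note).
    """
    lp = coeffs.intercept
    never = profile.smoking_status == "never"
    for t in coeffs.terms:
        if t.smoker_only and never:
            continue
        x = _PROFILE_VARS[t.var](profile)
        if x is None or (isinstance(x, float) and math.isnan(x)):
            raise ValidationError(f"missing covariate {t.var!r} "
                                  f"required by term {t.name!r}")
        lp += t.coef * (_TRANSFORMS[t.transform](x) - t.center)
    return 1.0 / (1.0 + math.exp(-lp))


def update_profile(profile: RiskProfile, years: float = 6.0) -> RiskProfile:
    """Advance a profile in time: everyone ages; smoking evolves in kind.

    Current smokers continue at the same intensity (duration grows); former
    smokers continue cessation (quit-time grows); never smokers only age.
    All other covariates are held fixed.
    """
    kw = {"age": profile.age + years}
    if profile.smoking_status == "current":
        kw["duration"] = profile.duration + years
    elif profile.smoking_status == "former":
        kw["quit_years"] = profile.quit_years + years
    return replace(profile, **kw)


def monthly_prob(p6: float) -> float:
    """Constant-rate conversion of a 72-month window probability to monthly.

    Solves (1 - p)^72 = 1 - P6, i.e. p = 1 - (1 - P6)^(1/72).
    """
    if not 0.0 <= p6 <= 1.0:
        raise ValidationError(f"window probability {p6} outside [0,1]")
    if p6 == 1.0:
        return 1.0
    return -math.expm1(math.log1p(-p6) / WINDOW_MONTHS)


@dataclass
class MonthlySchedule:
    """Per-person monthly event probabilities spanning their follow-up."""

    person_id: str
    monthly_probs: np.ndarray
    window_probs: tuple[float, float, float]

    @property
    def n_months(self) -> int:
        return len(self.monthly_probs)


def build_schedule(row, coeffs: RiskModelCoefficients) -> MonthlySchedule:
    """Monthly schedule for one eligible participant (needs person_years).

    Months 1-72 use the baseline 6-year window probability, 73-144 the
    12-year window, 145-216 the 18-year window; any follow-up beyond 216
    months conservatively reuses the last window's monthly probability.
    """
    person_years = float(row["person_years"])
    window_p, p_month = [], []
    prof = profile_from_row(row)
    for _ in range(3):
        p6 = six_year_prob(prof, coeffs)
        window_p.append(p6)
        p_month.append(monthly_prob(p6))
        prof = update_profile(prof, 6.0)
    if person_years <= 0:
        return MonthlySchedule(row["id"], np.empty(0), tuple(window_p))
    n_months = math.ceil(person_years * 12.0)
    reps = [min(n_months, WINDOW_MONTHS),
            min(max(n_months - WINDOW_MONTHS, 0), WINDOW_MONTHS),
            max(n_months - 2 * WINDOW_MONTHS, 0)]
    probs = np.repeat(p_month, reps)
    return MonthlySchedule(row["id"], probs, tuple(window_p))


def build_schedules(cohort: AnalyticCohort,
                    coeffs: RiskModelCoefficients) -> list[MonthlySchedule]:
    return [build_schedule(row, coeffs)
            for _, row in cohort.participants.iterrows()]


def _event_prob_matrix(schedules) -> np.ndarray:
    """Padded (n_person, max_months) matrix of cumulative event probability."""
    if not schedules:
        return np.empty((0, 0))
    max_m = max(s.n_months for s in schedules)
    log_surv = np.zeros((len(schedules), max(max_m, 1)))
    for i, s in enumerate(schedules):
        if s.n_months:
            log_surv[i, :s.n_months] = np.log1p(-np.minimum(s.monthly_probs, 1 - 1e-15))
            log_surv[i, s.n_months:] = 0.0
    cum = np.cumsum(log_surv, axis=1)
    return 1.0 - np.exp(cum)


def simulate_replicate(schedules: list[MonthlySchedule],
                       rng: np.random.Generator) -> int:
    """One replica cohort: monthly Bernoulli draws to first success per person.

    Implemented by inverse-CDF sampling of the first-success month, which is
    distributionally identical to sequential monthly draws.
    """
    if not schedules:
        return 0
    E = _event_prob_matrix(schedules)
    u = rng.random(len(schedules))
    total = E[:, -1] if E.size else np.zeros(len(schedules))
    return int((u < total).sum())


def draw_event_months(schedules: list[MonthlySchedule],
                      rng: np.random.Generator) -> np.ndarray:
    """First-success month per person (1-based; 0 = censored)."""
    if not schedules:
        return np.zeros(0, dtype=int)
    E = _event_prob_matrix(schedules)
    u = rng.random(len(schedules))
    event = u < E[:, -1]
    month = (E >= u[:, None]).argmax(axis=1) + 1
    # guard padded tails: month cannot exceed the person's own schedule
    own = np.array([s.n_months for s in schedules])
    month = np.minimum(month, np.maximum(own, 1))
    return np.where(event, month, 0)


def analytic_expected(schedules: list[MonthlySchedule]) -> float:
    """Exact expected case count of one replicate: Σ_i [1 − Π_m (1 − p_im)]."""
    total = 0.0
    for s in schedules:
        if s.n_months:
            total += -math.expm1(float(np.log1p(-s.monthly_probs).sum()))
    return total


@dataclass
class SimSummary:
    """Replicate case counts and the implied expected incidence rate."""

    replicate_counts: np.ndarray
    mean_cases: float
    expected_rate: float  # cases per 100,000 person-years
    person_years: float
    n_reps: int
    seed: int | None

    def to_dict(self) -> dict:
        return {"replicate_counts": [int(c) for c in self.replicate_counts],
                "mean_cases": self.mean_cases,
                "expected_rate": self.expected_rate,
                "person_years": self.person_years,
                "n_reps": self.n_reps, "seed": self.seed}


def run_microsim(cohort: AnalyticCohort, coeffs: RiskModelCoefficients,
                 n_reps: int = 30, seed: int | None = None) -> SimSummary:
    """Replicate the cohort ``n_reps`` times and average the case counts.

    Each replicate uses an independently spawned RNG stream from one master
    seed, so results are reproducible and replicates are independent.  The
    expected rate divides mean cases by the *observed* person-time (simulated
    events do not truncate the denominator, keeping the comparator's
    denominator identical to the observed cohort's).
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be at least 1")
    schedules = build_schedules(cohort, coeffs)
    E = _event_prob_matrix(schedules)
    total = E[:, -1] if E.size else np.zeros(len(schedules))
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    counts = np.array([
        int((np.random.default_rng(s).random(len(schedules)) < total).sum())
        for s in streams])
    py = cohort.total_person_years
    mean_cases = float(counts.mean())
    rate = mean_cases / py * 1e5 if py > 0 else 0.0
    return SimSummary(counts, mean_cases, rate, py, n_reps, seed)
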