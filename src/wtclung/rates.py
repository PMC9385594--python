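"""Incidence rates with exact Poisson and gamma confidence intervals.

Crude rates use the Garwood exact interval (chi-square quantiles at 2x and
2x+2 degrees of freedom), the classical "Poisson method" that reproduces
published exact bounds where a normal approximation does not.  Directly
age-standardized rates weight stratum rates by the year-2000 US standard
population and use the Fay-Feuer gamma interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AnalyticCohort
from .errors import ValidationError

RATE_SCALE = 1e5  # rates reported per 100,000 person-years


@dataclass
class RateEstimate:
    """An incidence rate per 100,000 person-years with a 95% (or alpha) CI."""

    cases: int
    person_years: float
    rate: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    method: str = "exact_poisson"

    def to_dict(self) -> dict:
        return {"cases": self.cases, "person_years": self.person_years,
                "rate": self.rate, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "alpha": self.alpha,
                "method": self.method}


def poisson_exact_ci(cases: int, alpha: float = 0.05) -> tuple[float, float]:
    """Garwood exact CI for a Poisson count (on the count scale)."""
    if cases < 0:
        raise ValidationError("cases must be non-negative")
    low = 0.0 if cases == 0 else stats.chi2.ppf(alpha / 2.0, 2 * cases) / 2.0
    high = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * cases + 2) / 2.0
    return low, high


def crude_rate(cases: int, person_years: float,
               alpha: float = 0.05) -> RateEstimate:
    """Crude incidence rate with Garwood exact Poisson CI."""
    if person_years <= 0:
        raise ValidationError("person_years must be positive")
    low, high = poisson_exact_ci(cases, alpha)
    scale = RATE_SCALE / person_years
    return RateEstimate(cases=int(cases), person_years=float(person_years),
                        rate=cases * scale, ci_low=low * scale,
                        ci_high=high * scale, alpha=alpha)


def cohort_crude_rate(cohort: AnalyticCohort, alpha: float = 0.05) -> RateEstimate:
    return crude_rate(cohort.n_events, cohort.total_person_years, alpha)


def stratified_rates(cohort: AnalyticCohort, by: str = "smoking_status",
                     alpha: float = 0.05) -> dict[str, RateEstimate]:
    """Crude rates by stratum (default: baseline smoking status).

    Strata are disjoint and exhaustive; their person-years sum to the total.
    """
    df = cohort.participants
    if df[by].isna().any():
        raise ValidationError(f"stratifier {by!r} has missing values")
    out = {}
    for level, grp in df.groupby(by, observed=True):
        out[str(level)] = crude_rate(int(grp["event"].sum()),
                                     float(grp["person_years"].sum()), alpha)
    return out


@dataclass
class StandardPopulation:
    """Age bands (closed-open year intervals) with standardization weights."""

    bands: tuple  # ((low, high), ...) with high = inf on the last band
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValidationError("standard-population weights must sum to 1")
        lows = [b[0] for b in self.bands]
        highs = [b[1] for b in self.bands]
        if lows[0] != 0 or highs[-1] != np.inf or \
                any(h != l for h, l in zip(highs[:-1], lows[1:])):
            raise ValidationError("bands must partition [0, inf)")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def band_index(self, age) -> np.ndarray:
        edges = np.array([b[0] for b in self.bands[1:]])
        return np.searchsorted(edges, np.asarray(age, dtype=float), side="right")


def load_us_standard_2000() -> StandardPopulation:
    """Year-2000 US standard population (11 bands, census standard million)."""
    ref = resources.files("wtclung.data") / "us_std_2000.csv"
    with ref.open() as fh:
        tbl = pd.read_csv(fh)
    bands = tuple((float(l), float(h)) for l, h in
                  zip(tbl["age_low"], tbl["age_high"]))
    return StandardPopulation(bands=bands, weights=tbl["weight"].to_numpy())


US_STANDARD_2000 = load_us_standard_2000()


def age_standardized_rate(stratum_cases, stratum_py, std: StandardPopulation,
                          alpha: float = 0.05) -> RateEstimate:
    """Directly standardized rate with the Fay-Feuer gamma CI.

    ``stratum_cases`` and ``stratum_py`` are aligned with ``std.bands``.
    Bands with zero person-years must have zero cases; they are dropped from
    the weighted sum (their weight contributes no rate, the convention used
    when a standard band is empty in the study population).
    """
    cases = np.asarray(stratum_cases, dtype=float)
    py = np.asarray(stratum_py, dtype=float)
    if len(cases) != std.n_bands or len(py) != std.n_bands:
        raise ValidationError(
            f"expected {std.n_bands} bands, got {len(cases)} cases / "
            f"{len(py)} person-year entries")
    if ((py <= 0) & (cases > 0)).any():
        raise ValidationError("band has cases but no person-years")
    keep = py > 0
    w, c, n = std.weights[keep], cases[keep], py[keep]
    x = float(np.sum(w * c / n))          # standardized rate (per 1 p-y)
    v = float(np.sum(w ** 2 * c / n ** 2))  # its variance estimate
    wmax = float(np.max(w / n)) if keep.any() else 0.0
    if x > 0:
        low = stats.gamma.ppf(alpha / 2.0, x ** 2 / v, scale=v / x)
    else:
        low = 0.0
    xu, vu = x + wmax, v + wmax ** 2
    high = stats.gamma.ppf(1.0 - alpha / 2.0, xu ** 2 / vu, scale=vu / xu) \
        if xu > 0 else 0.0
    return RateEstimate(cases=int(cases.sum()), person_years=float(py.sum()),
                        rate=x * RATE_SCALE, ci_low=low * RATE_SCALE,
                        ci_high=high * RATE_SCALE, alpha=alpha,
                        method="gamma_standardized")


def cohort_age_standardized_rate(cohort: AnalyticCohort,
                                 std: StandardPopulation = US_STANDARD_2000,
                                 alpha: float = 0.05) -> RateEstimate:
    """Age-standardized rate with all of a person's time in their entry-age band."""
    df = cohort.participants
    entry_age = df["age_at_enrollment"].to_numpy(float) + 0.25
    idx = std.band_index(entry_age)
    cases = np.bincount(idx, weights=df["event"].to_numpy(float),
                        minlength=std.n_bands)
    py = np.bincount(idx, weights=df["person_years"].to_numpy(float),
                     minlength=std.n_bands)
    return age_standardized_rate(cases, py, std, alpha)
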