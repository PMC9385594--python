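"""Observed-vs-expected rate comparison and Poisson risk-factor regression.

``compare_rates`` forms the incidence rate ratio of the observed cohort
against the microsimulation comparator.  Its default CI is the exact
conditional method: on matched person-time, the observed count given the
total is binomial, so a Clopper-Pearson interval on the binomial proportion
transforms to the odds (= rate-ratio) scale.  The simulated expected count
is treated as fixed (rounded to a count); a Wald alternative on log-IRR is
available, optionally propagating replicate variance.

``fit_poisson`` fits the multivariable Poisson log-linear model of lung
cancer counts with a log person-years offset, using the risk-factor coding
of the primary analysis (age and BMI continuous, sex, race/ethnicity vs
non-Latino White, education vs less-than-high-school, pack-years continuous,
former-smoker quit-time categories, prior cancer, any moderate/significant
occupational exposure, WTC exposure level vs low).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import AnalyticCohort, OCC_EXPOSURES, derive_obstruction
from .errors import ModelFitError, ValidationError
from .rates import RATE_SCALE, RateEstimate

Z975 = stats.norm.ppf(0.975)


def _safe_exp(x: float) -> float:
    try:
        return math.exp(x)
    except OverflowError:
        return math.inf


@dataclass
class RateComparison:
    """Observed vs expected incidence: IRR with CI."""

    observed: RateEstimate
    expected_rate: float
    irr: float
    ci_low: float
    ci_high: float
    method: str
    observed_cases: int = 0
    expected_cases: float = 0.0
    infinite: bool = False

    def to_dict(self) -> dict:
        return {"irr": self.irr, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "method": self.method,
                "observed_rate": self.observed.rate,
                "expected_rate": self.expected_rate,
                "observed_cases": self.observed_cases,
                "expected_cases": self.expected_cases,
                "infinite": self.infinite}


def compare_rates(observed: RateEstimate, expected_rate: float,
                  method: str = "exact_conditional", alpha: float = 0.05,
                  sim_rate_variance: float | None = None) -> RateComparison:
    """Observed-vs-expected IRR on matched person-time.

    The expected count is ``expected_rate × person_years``; for the exact
    conditional method it is rounded to the nearest count and held fixed.
    ``sim_rate_variance`` (variance of the expected rate across simulation
    replicates, per-100k² units) optionally widens the Wald interval.
    A zero expected rate with observed cases yields an infinite-IRR flag
    rather than an exception.
    """
    x_obs = observed.cases
    if expected_rate <= 0:
        inf = x_obs > 0
        return RateComparison(observed, expected_rate,
                              irr=math.inf if inf else math.nan,
                              ci_low=math.nan, ci_high=math.nan,
                              method=method, observed_cases=x_obs,
                              infinite=inf)
    irr = observed.rate / expected_rate
    x_exp = expected_rate * observed.person_years / RATE_SCALE
    if method == "exact_conditional":
        k, m = x_obs, int(round(x_exp))
        n = k + m
        p_low = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
        p_high = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
        lo = p_low / (1 - p_low)
        hi = p_high / (1 - p_high) if p_high < 1 else math.inf
        return RateComparison(observed, expected_rate, irr, lo, hi, method,
                              observed_cases=k, expected_cases=float(m))
    if method == "wald":
        if x_obs == 0:
            return RateComparison(observed, expected_rate, 0.0, 0.0,
                                  math.nan, method, observed_cases=0,
                                  expected_cases=x_exp)
        var_log = 1.0 / x_obs
        if sim_rate_variance is not None:
            var_log += sim_rate_variance / expected_rate ** 2
        half = Z975 * math.sqrt(var_log)
        return RateComparison(observed, expected_rate, irr,
                              irr * math.exp(-half), irr * math.exp(half),
                              method, observed_cases=x_obs,
                              expected_cases=x_exp)
    raise ValidationError(f"unknown method {method!r}")


@dataclass
class TermResult:
    name: str
    coef: float
    se: float
    irr: float
    ci_low: float
    ci_high: float
    flagged: bool = False  # possible separation / unstable estimate


@dataclass
class RegressionResult:
    """Fitted Poisson model: per-term IRRs with Wald CIs on the log scale."""

    terms: list[TermResult]
    converged: bool
    n_obs: int
    n_events: int
    offset: str = "log person-years"
    llf: float = float("nan")

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]


def _table4_design(df: pd.DataFrame) -> pd.DataFrame:
    """Risk-factor coding of the primary multivariable model."""
    X = pd.DataFrame(index=df.index)
    X["age"] = df["age_at_enrollment"].astype(float) + 0.25  # age at entry
    X["female"] = (df["sex"] == "female").astype(float)
    for level in ("nl_black", "latino", "asian", "multiracial", "other"):
        X[f"race_{level}"] = (df["race_ethnicity"] == level).astype(float)
    edu = df["education"].fillna("unknown")
    for level in ("hs_grad", "some_college", "college_grad", "grad_school",
                  "unknown"):
        X[f"edu_{level}"] = (edu == level).astype(float)
    if df["pack_years"].isna().any():
        raise ValidationError("pack_years has missing values; impute first")
    X["pack_years"] = df["pack_years"].astype(float)
    former = df["smoking_status"] == "former"
    ysq = df["years_since_quit"].fillna(0.0)
    X["former_quit_0_14"] = (former & (ysq < 15)).astype(float)
    X["former_quit_15plus"] = (former & (ysq >= 15)).astype(float)
    X["prior_cancer"] = df["prior_cancer"].astype(float)
    if df["bmi"].isna().any():
        raise ValidationError("bmi has missing values; impute first")
    X["bmi"] = df["bmi"].astype(float)
    X["occ_any_moderate_significant"] = \
        df["occ_any_moderate_significant"].astype(float)
    X["wtc_intermediate"] = (df["wtc_exposure_level"] == "intermediate").astype(float)
    X["wtc_high"] = (df["wtc_exposure_level"] == "high").astype(float)
    X["wtc_missing"] = (df["wtc_exposure_level"] == "missing").astype(float)
    return X


def _drop_constant(X: pd.DataFrame) -> pd.DataFrame:
    # empty categorical levels (e.g. no Asian participants) carry no information
    keep = [c for c in X.columns if X[c].nunique() > 1]
    return X[keep]


def _check_rank(X: pd.DataFrame) -> None:
    M = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    if np.linalg.matrix_rank(M) < M.shape[1]:
        names = ["const"] + list(X.columns)
        kept, dropped = [], []
        for j in range(M.shape[1]):
            if np.linalg.matrix_rank(M[:, kept + [j]]) == len(kept) + 1:
                kept.append(j)
            else:
                dropped.append(names[j])
        raise ModelFitError(f"design matrix rank-deficient; collinear "
                            f"columns: {dropped}")


_SEPARATION_SE = 50.0


def fit_poisson(cohort: AnalyticCohort, term_spec="table4",
                extra_columns: pd.DataFrame | None = None,
                maxiter: int = 100) -> RegressionResult:
    """Poisson log-linear fit of events with a log person-years offset (IRLS).

    ``term_spec`` is ``"table4"`` for the primary risk-factor coding or a
    list of cohort-schema column names used as numeric terms.
    ``extra_columns`` appends prebuilt design columns (used for the
    single-exposure adjusted models).
    """
    df = cohort.participants
    if int(df["event"].sum()) < 1:
        raise ModelFitError("no events; Poisson model undefined")
    if isinstance(term_spec, str) and term_spec == "table4":
        X = _table4_design(df)
    else:
        X = df[list(term_spec)].astype(float).copy()
    if extra_columns is not None:
        X = pd.concat([X, extra_columns.astype(float)], axis=1)
    X = _drop_constant(X)
    _check_rank(X)
    y = df["event"].astype(float).to_numpy()
    offset = np.log(df["person_years"].to_numpy(float))
    model = sm.GLM(y, sm.add_constant(X, has_constant="add"),
                   family=sm.families.Poisson(), offset=offset)
    try:
        fit = model.fit(maxiter=maxiter)
    except Exception as exc:  # pragma: no cover - statsmodels internals
        raise ModelFitError(f"Poisson fit failed: {exc}") from exc
    if not fit.converged:
        raise ModelFitError(f"IRLS did not converge in {maxiter} iterations")
    terms = []
    for name, coef, se in zip(fit.params.index, fit.params, fit.bse):
        flagged = bool(se > _SEPARATION_SE or abs(coef) > 15.0)
        half = Z975 * se
        terms.append(TermResult(name=name, coef=float(coef), se=float(se),
                                irr=_safe_exp(coef),
                                ci_low=_safe_exp(coef - half),
                                ci_high=_safe_exp(coef + half),
                                flagged=flagged))
    return RegressionResult(terms=terms, converged=True, n_obs=len(df),
                            n_events=int(df["event"].sum()), llf=float(fit.llf))


def fit_adjusted_single_exposure(cohort: AnalyticCohort,
                                 exposure_name: str) -> RegressionResult:
    """Primary adjustment set plus one exposure term.

    ``exposure_name`` is an occupational exposure (e.g. ``mineral_dust``) or
    ``airway_obstruction`` (spirometric FEV1/FVC ≤ 0.70; participants with
    missing spirometry are excluded — complete-case analysis).
    """
    df = cohort.participants
    if exposure_name == "airway_obstruction":
        obstruction = df.apply(
            lambda r: derive_obstruction(r["fev1"], r["fvc"]), axis=1)
        keep = obstruction.notna()
        sub = AnalyticCohort(df[keep].reset_index(drop=True))
        extra = pd.DataFrame({"airway_obstruction":
                              obstruction[keep].astype(float).to_numpy()})
        return fit_poisson(sub, "table4", extra_columns=extra)
    if exposure_name not in OCC_EXPOSURES:
        raise ValidationError(f"unknown exposure {exposure_name!r}")
    col = f"occ_{exposure_name}"
    exposed = df[col].astype(bool)
    if exposed.all() or not exposed.any():
        raise ModelFitError(f"{exposure_name}: all-exposed or none-exposed "
                            f"(separation)")
    extra = pd.DataFrame({exposure_name: exposed.astype(float).to_numpy()},
                         index=df.index)
    return fit_poisson(cohort, "table4", extra_columns=extra)


def pool_rubin(results: list[RegressionResult]) -> RegressionResult:
    """Pool m ≥ 2 fits on multiply-imputed data by Rubin's rules.

    Coefficients are averaged; total variance is the mean within-imputation
    variance plus (1 + 1/m) times the between-imputation variance; CIs use a
    t reference with the Rubin degrees of freedom (normal when the
    between-variance is zero).
    """
    m = len(results)
    if m < 2:
        raise ValidationError("Rubin pooling needs at least 2 results")
    names = results[0].term_names
    for r in results[1:]:
        if r.term_names != names:
            raise ValidationError("mismatched term sets across imputations")
    terms = []
    for name in names:
        coefs = np.array([r.term(name).coef for r in results])
        ses = np.array([r.term(name).se for r in results])
        qbar = float(coefs.mean())
        w = float((ses ** 2).mean())
        b = float(coefs.var(ddof=1))
        total = w + (1.0 + 1.0 / m) * b
        se = math.sqrt(total)
        if b > 0:
            dof = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
            tcrit = stats.t.ppf(0.975, dof)
        else:
            tcrit = Z975
        terms.append(TermResult(name=name, coef=qbar, se=se,
                                irr=math.exp(qbar),
                                ci_low=math.exp(qbar - tcrit * se),
                                ci_high=math.exp(qbar + tcrit * se)))
    return RegressionResult(terms=terms, converged=all(r.converged for r in results),
                            n_obs=results[0].n_obs,
                            n_events=results[0].n_events)
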