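"""Imputation of missing risk-model inputs.

Three procedures, one per missing variable class:

* family history of lung cancer — absent from the surveillance data
  altogether, filled by Bernoulli draws at a literature prevalence
  (mandatory configuration, never defaulted);
* pack-years — missing for some smokers, drawn from an exponential fitted
  to the observed smokers (method of moments);
* BMI — missing for ~1%, filled by an OLS regression on demographic
  covariates plus a Gaussian residual draw.

Observed values are never altered; a fixed RNG yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ModelFitError

DEFAULT_BMI_COVARIATES = ("age_at_enrollment", "sex", "race_ethnicity",
                          "education", "smoking_status")
_CATEGORICAL = {"sex", "race_ethnicity", "education", "smoking_status"}


@dataclass
class ImputationConfig:
    """Settings for the three imputation procedures.

    ``family_history_prevalence`` has no default: the published estimate must
    be supplied explicitly by the analyst.
    """

    family_history_prevalence: float | None = None
    pack_year_exponential_mean: float | None = None
    bmi_model_covariates: tuple = DEFAULT_BMI_COVARIATES

    def validate_family_history(self) -> float:
        p = self.family_history_prevalence
        if p is None:
            raise ConfigError("family_history_prevalence must be configured "
                              "(published estimate; no default)")
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"family_history_prevalence={p} outside [0,1]")
        return p


def impute_family_history(cohort: pd.DataFrame, config: ImputationConfig,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Fill missing family-history flags with Bernoulli(prevalence) draws."""
    p = config.validate_family_history()
    df = cohort.copy()
    col = df["family_history_lung_cancer"].astype("boolean")
    missing = col.isna().to_numpy()
    draws = rng.random(int(missing.sum())) < p
    col[missing] = draws
    df["family_history_lung_cancer"] = col.astype(bool)
    return df


def impute_pack_years(cohort: pd.DataFrame, config: ImputationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Fill missing pack-years: 0 for never smokers, exponential for smokers.

    The exponential mean is the configured value or, failing that, the sample
    mean of observed smoker pack-years (the exponential MLE).
    """
    df = cohort.copy()
    smoker = df["smoking_status"].isin(["former", "current"])
    missing = df["pack_years"].isna()
    df.loc[missing & ~smoker, "pack_years"] = 0.0
    target = (missing & smoker).to_numpy()
    if target.any():
        mean = config.pack_year_exponential_mean
        if mean is None:
            observed = df.loc[smoker & ~missing, "pack_years"]
            if observed.empty:
                raise ConfigError("no observed smoker pack-years to fit and "
                                  "no configured exponential mean")
            mean = float(observed.mean())
        if mean <= 0:
            raise ConfigError("pack-year exponential mean must be positive")
        draws = rng.exponential(mean, int(target.sum()))
        df.loc[target, "pack_years"] = draws
        # reconstruct intensity/duration where the whole dose block was
        # missing, keeping the pack-year identity exact: duration spans 60%
        # of adult life (convention), intensity follows
        fix = target & df["smoking_duration"].isna().to_numpy()
        if fix.any():
            dur = np.maximum(
                0.6 * (df.loc[fix, "age_at_enrollment"].to_numpy(float) - 18.0),
                1.0)
            df.loc[fix, "smoking_duration"] = dur
            df.loc[fix, "cigarettes_per_day"] = \
                df.loc[fix, "pack_years"].to_numpy(float) * 20.0 / dur
    return df


def _bmi_design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    for cov in covariates:
        if cov in _CATEGORICAL:
            series = df[cov].fillna("unknown") if cov == "education" else df[cov]
            dummies = pd.get_dummies(series, prefix=cov, drop_first=True)
            X = pd.concat([X, dummies.astype(float)], axis=1)
        else:
            X[cov] = df[cov].astype(float)
    X.insert(0, "const", 1.0)
    return X


def impute_bmi(cohort: pd.DataFrame, config: ImputationConfig,
               rng: np.random.Generator) -> pd.DataFrame:
    """Fill missing BMI by OLS prediction plus a Gaussian residual draw."""
    df = cohort.copy()
    missing = df["bmi"].isna()
    if not missing.any():
        return df
    X_all = _bmi_design(df, config.bmi_model_covariates)
    complete = ~missing
    X, y = X_all[complete].to_numpy(), df.loc[complete, "bmi"].to_numpy(float)
    if X.shape[0] < X.shape[1] + 2:
        raise ModelFitError("too few complete cases for the BMI model")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_columns(X, list(X_all.columns))
        raise ModelFitError(f"BMI design rank-deficient; collinear columns: "
                            f"{collinear}")
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    dof = X.shape[0] - X.shape[1]
    resid_sd = float(np.sqrt(((y - X @ beta) ** 2).sum() / dof))
    pred = X_all[missing].to_numpy() @ beta
    df.loc[missing, "bmi"] = pred + rng.normal(0.0, resid_sd, missing.sum())
    return df


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    kept: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        cols = kept + [j]
        if np.linalg.matrix_rank(X[:, cols]) == len(cols):
            kept.append(j)
        else:
            dropped.append(names[j])
    return dropped


def impute_all(cohort: pd.DataFrame, config: ImputationConfig,
               seed: int) -> pd.DataFrame:
    """Run all three procedures; returns a cohort with complete model inputs."""
    rng = np.random.default_rng(seed)
    df = impute_family_history(cohort, config, rng)
    df = impute_pack_years(df, config, rng)
    df = impute_bmi(df, config, rng)
    return df
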