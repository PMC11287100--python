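"""Constrained-regression test of which anchor a behavior measure tracks.

For one behavior measure (the response) and one self-reported outcome, two
Gaussian linear models are compared:

* unconstrained — response ~ outcome + fitness (VO2) + age + sex + BMI +
  months since diagnosis + stage + intercept, all continuous columns
  z-scored on the model's complete cases, sex sum-coded (+1 female / -1
  male), stage treated as ordinal 0-4 then z-scored;
* constrained — identical except the outcome and VO2 coefficients are
  forced equal, implemented by replacing the two columns with their sum
  (one fewer free parameter).

The fits are compared with the nested-model F statistic

    F = (RSS_c - RSS_u) / (RSS_u / df2),   df1 = 1,  df2 = n - p_free,

whose p-value is the upper tail of F(1, df2).  For Gaussian least squares
this ordering agrees with the likelihood-ratio ordering, and F equals the
squared Wald t for the contrast beta_outcome - beta_vo2 = 0 from the
unconstrained fit; the Gaussian log-likelihood difference is reported
alongside.  A significant F with |beta_vo2| > |beta_outcome| says the
behavior measure is more strongly associated with aerobic fitness than with
the self-reported outcome.

Each comparison standardizes within its own complete-case set, mirroring
an analysis that restricts to participants with no missing values for the
specific measures being compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_COVARIATES = ("age", "sex", "bmi", "months_since_dx", "stage")
STAGE_ORDINAL = {"0": 0.0, "I": 1.0, "II": 2.0, "III": 3.0, "IV": 4.0}


class DegenerateDesignError(ValueError):
    """A design column has zero variance, or n <= number of parameters."""


@dataclass(frozen=True)
class ModelSpec:
    response: str
    outcome: str
    fitness: str = "vo2"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    stage_as_categories: bool = False  # ordinal 0-4 by default

    @property
    def predictors(self) -> tuple[str, ...]:
        return (self.outcome, self.fitness, *self.covariates)

    @property
    def constrained_pair(self) -> tuple[str, str]:
        return (self.outcome, self.fitness)


@dataclass
class OlsFit:
    params: dict[str, float]
    rss: float
    loglik: float
    n: int
    p_free: int


@dataclass
class CoefficientEqualityTest:
    F: float
    df1: int
    df2: int
    p: float
    beta_outcome: float
    beta_vo2: float
    delta_loglik: float
    n: int

    @property
    def direction(self) -> str:
        """Which anchor the behavior measure is more strongly tied to."""
        return "vo2" if abs(self.beta_vo2) > abs(self.beta_outcome) else "outcome"


def _encode_stage(col: pd.Series) -> pd.Series:
    def conv(v):
        if pd.isna(v):
            return np.nan
        s = str(v).strip()
        if s in STAGE_ORDINAL:
            return STAGE_ORDINAL[s]
        try:
            x = float(s)
        except ValueError:
            return np.nan  # "Unsure" and friends -> complete-case exclusion
        return x if 0 <= x <= 4 else np.nan

    return col.map(conv)


def _encode_sex(col: pd.Series) -> pd.Series:
    mapping = {"female": 1.0, "male": -1.0}
    return col.map(lambda v: mapping.get(str(v).strip().lower(), np.nan))


def build_design(
    cohort: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, pd.DataFrame, list]:
    """Response vector, standardized design matrix, and retained case ids.

    Complete cases across the response and every predictor; continuous
    columns (response included) z-scored on those cases; sex sum-coded;
    stage ordinal (or one-hot when ``stage_as_categories``); intercept
    column appended last.
    """
    cols = [spec.response, *spec.predictors]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table lacks columns {missing}")

    work = pd.DataFrame(index=cohort.index)
    sum_coded: list[str] = []
    for c in cols:
        if c == "sex":
            work[c] = _encode_sex(cohort[c])
            sum_coded.append(c)
        elif c == "stage":
            work[c] = _encode_stage(cohort[c])
        else:
            work[c] = pd.to_numeric(cohort[c], errors="coerce")

    complete = work.notna().all(axis=1)
    work = work.loc[complete]
    ids = (
        cohort.loc[complete, "subject_id"].tolist()
        if "subject_id" in cohort.columns
        else work.index.tolist()
    )
    n = len(work)

    if spec.stage_as_categories and "stage" in work.columns:
        dummies = pd.get_dummies(work["stage"].astype(int), prefix="stage")
        # sum-to-zero style: drop the first level
        dummies = dummies.iloc[:, 1:].astype(float)
        work = pd.concat([work.drop(columns="stage"), dummies], axis=1)

    X = pd.DataFrame(index=work.index)
    for c in work.columns:
        if c == spec.response:
            continue
        v = work[c].to_numpy(dtype=float)
        sd = v.std(ddof=1) if n > 1 else 0.0
        if sd == 0:
            raise DegenerateDesignError(f"column {c!r} has zero variance")
        X[c] = v if c in sum_coded else (v - v.mean()) / sd
    X["const"] = 1.0

    yv = work[spec.response].to_numpy(dtype=float)
    sd = yv.std(ddof=1) if n > 1 else 0.0
    if sd == 0:
        raise DegenerateDesignError(f"response {spec.response!r} has zero variance")
    y = (yv - yv.mean()) / sd

    if n <= X.shape[1]:
        raise DegenerateDesignError(
            f"underdetermined design: n={n} cases for {X.shape[1]} parameters"
        )
    return y, X, ids


def _gaussian_loglik(rss: float, n: int) -> float:
    if rss <= 0:
        return math.inf
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


def fit_ols(y: np.ndarray, X: pd.DataFrame) -> OlsFit:
    """Least-squares fit; errors on rank deficiency."""
    A = X.to_numpy(dtype=float)
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        raise DegenerateDesignError("design matrix is rank-deficient")
    resid = y - A @ beta
    rss = float(resid @ resid)
    n = len(y)
    return OlsFit(
        params=dict(zip(X.columns, map(float, beta))),
        rss=rss,
        loglik=_gaussian_loglik(rss, n),
        n=n,
        p_free=A.shape[1],
    )


def fit_constrained(
    y: np.ndarray, X: pd.DataFrame, pair: Sequence[str]
) -> OlsFit:
    """Fit with the two named columns sharing a single coefficient."""
    a, b = pair
    if a not in X.columns or b not in X.columns:
        raise KeyError(f"constrained pair {pair!r} not in design columns")
    merged = X.drop(columns=[a, b]).copy()
    merged.insert(0, f"{a}+{b}", X[a] + X[b])
    return fit_ols(y, merged)


def compare_coefficient_equality(
    cohort: pd.DataFrame, spec: ModelSpec
) -> CoefficientEqualityTest:
    """Nested-model F test of beta_outcome = beta_fitness."""
    y, X, _ids = build_design(cohort, spec)
    unconstrained = fit_ols(y, X)
    constrained = fit_constrained(y, X, spec.constrained_pair)
    df2 = unconstrained.n - unconstrained.p_free
    F = max(0.0, (constrained.rss - unconstrained.rss) / (unconstrained.rss / df2))
    p = float(sps.f.sf(F, 1, df2))
    return CoefficientEqualityTest(
        F=float(F),
        df1=1,
        df2=df2,
        p=p,
        beta_outcome=unconstrained.params[spec.outcome],
        beta_vo2=unconstrained.params[spec.fitness],
        delta_loglik=unconstrained.loglik - constrained.loglik,
        n=unconstrained.n,
    )
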