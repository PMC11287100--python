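"""Rank-based association statistics, splits, and gated group tests.

Spearman correlations use average ranks for ties, with the two-sided p-value
from the t approximation t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of
freedom.  The partial Spearman residualizes the ranks of x and y on the
ranks of the covariates (plus intercept) by least squares and correlates the
residuals, with n - 2 - k degrees of freedom.

Tertile and median splits assign tied values by stable input order so that
group sizes stay balanced to within one subject.  Two-sample comparisons
are gated on per-group Shapiro-Wilk normality tests: a two-tailed Welch t
test when neither group deviates from normality at the gate alpha,
otherwise a two-tailed Mann-Whitney U test (tie-corrected).  Families of
pairwise split comparisons are adjusted with the step-down Holm method.

Missing values (NaN) propagate pairwise-complete throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class CollinearityError(ValueError):
    """Covariate matrix is rank-deficient."""


@dataclass
class AssociationResult:
    rho: float
    n: int
    p: float
    covariates: tuple[str, ...] = ()


@dataclass
class SplitAssignment:
    """Group labels aligned with the input; missing values get None."""

    labels: list[str | None]
    cutpoints: tuple[float, ...]

    def group(self, label: str) -> np.ndarray:
        return np.array([lab == label for lab in self.labels])


@dataclass
class GroupComparisonResult:
    test: str  # "welch_t" or "mann_whitney"
    statistic: float
    df: float  # Welch-Satterthwaite df; NaN for Mann-Whitney
    p_raw: float
    p_holm: float = math.nan
    normality_gate: tuple[float, float] = (math.nan, math.nan)


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def _rank_p_value(rho: float, df: int) -> float:
    if not math.isfinite(rho) or df <= 0:
        return math.nan
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt(df / (1.0 - rho * rho))
    return 2.0 * sps.t.sf(abs(t), df)


def spearman(x: Sequence[float], y: Sequence[float]) -> AssociationResult:
    """Spearman rank correlation on pairwise-complete observations."""
    xv, yv = _pairwise_complete(x, y)
    n = xv.size
    if n < 3:
        return AssociationResult(math.nan, n, math.nan)
    rx, ry = sps.rankdata(xv), sps.rankdata(yv)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return AssociationResult(math.nan, n, math.nan)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return AssociationResult(rho, n, _rank_p_value(rho, n - 2))


def partial_spearman(
    x: Sequence[float], y: Sequence[float], covariates: pd.DataFrame | None
) -> AssociationResult:
    """Spearman correlation of x and y adjusted for covariates.

    All variables are rank-transformed (average ranks); the x and y ranks
    are residualized on the covariate ranks plus an intercept and the
    residuals are correlated.  Complete cases across x, y and every
    covariate; p uses n - 2 - k degrees of freedom.
    """
    if covariates is None or covariates.shape[1] == 0:
        return spearman(x, y)
    cov = covariates.apply(pd.to_numeric, errors="coerce")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y) & cov.notna().all(axis=1).to_numpy()
    n = int(mask.sum())
    k = cov.shape[1]
    if n <= k + 2:
        return AssociationResult(math.nan, n, math.nan, tuple(cov.columns))

    rx = sps.rankdata(x[mask])
    ry = sps.rankdata(y[mask])
    rz = np.column_stack(
        [sps.rankdata(cov.loc[mask, c].to_numpy()) for c in cov.columns]
    )
    design = np.column_stack([np.ones(n), rz])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        for j, name in enumerate(cov.columns):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise CollinearityError(
                    f"covariate {name!r} is collinear with the others"
                )
        raise CollinearityError("covariate matrix is rank-deficient")

    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    if np.std(res_x) == 0 or np.std(res_y) == 0:
        return AssociationResult(math.nan, n, math.nan, tuple(cov.columns))
    rho = float(np.corrcoef(res_x, res_y)[0, 1])
    return AssociationResult(rho, n, _rank_p_value(rho, n - 2 - k), tuple(cov.columns))


def _stable_order(values: np.ndarray, present: np.ndarray) -> np.ndarray:
    idx = np.flatnonzero(present)
    return idx[np.argsort(values[idx], kind="stable")]


def tertile_split(values: Sequence[float]) -> SplitAssignment:
    """Split into low/medium/high thirds, balanced to within one subject.

    Values are ordered (stable input order breaks ties) and assigned by rank
    into three contiguous groups; the lower groups absorb the remainder.
    """
    v = np.asarray(values, dtype=float)
    present = np.isfinite(v)
    n = int(present.sum())
    if n < 3:
        raise ValueError(f"tertile split needs at least 3 values, got {n}")
    order = _stable_order(v, present)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if g < rem else 0) for g in range(3)]
    labels: list[str | None] = [None] * v.size
    names = ["low", "medium", "high"]
    pos = 0
    for g, size in enumerate(sizes):
        for i in order[pos : pos + size]:
            labels[i] = names[g]
        pos += size
    q1, q2 = np.quantile(v[present], [1 / 3, 2 / 3])
    return SplitAssignment(labels, (float(q1), float(q2)))


def median_split(values: Sequence[float]) -> SplitAssignment:
    """Split into low/high halves; ties at the median fall by stable order."""
    v = np.asarray(values, dtype=float)
    present = np.isfinite(v)
    n = int(present.sum())
    if n < 2:
        raise ValueError(f"median split needs at least 2 values, got {n}")
    order = _stable_order(v, present)
    n_low = n // 2
    labels: list[str | None] = [None] * v.size
    for pos, i in enumerate(order):
        labels[i] = "low" if pos < n_low else "high"
    return SplitAssignment(labels, (float(np.median(v[present])),))


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston's approximation), 3 <= n <= 5000."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if not 3 <= v.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {v.size}")
    if np.ptp(v) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(v)
    return float(w), float(p)


def compare_groups(
    a: Sequence[float], b: Sequence[float], alpha_gate: float = 0.05
) -> GroupComparisonResult:
    """Two-sample comparison with a per-group Shapiro-Wilk normality gate.

    Both groups normal at ``alpha_gate``: two-tailed Welch t test
    (Welch-Satterthwaite df).  Either group non-normal: two-tailed
    Mann-Whitney U (exact where SciPy can, tie-corrected normal
    approximation otherwise).  ``p_holm`` is filled by the caller once the
    comparison's family is complete.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    av, bv = av[np.isfinite(av)], bv[np.isfinite(bv)]
    if av.size < 3 or bv.size < 3:
        raise ValueError("each group needs at least 3 observations")
    try:
        pa = shapiro_wilk(av)[1]
        pb = shapiro_wilk(bv)[1]
    except ValueError:
        # constant group: treat as a (maximal) deviation from normality
        pa = pb = 0.0
    if pa >= alpha_gate and pb >= alpha_gate:
        res = sps.ttest_ind(av, bv, equal_var=False)
        return GroupComparisonResult(
            "welch_t", float(res.statistic), float(res.df), float(res.pvalue),
            normality_gate=(pa, pb),
        )
    res = sps.mannwhitneyu(av, bv, alternative="two-sided")
    return GroupComparisonResult(
        "mann_whitney", float(res.statistic), math.nan, float(res.pvalue),
        normality_gate=(pa, pb),
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm adjustment, returned in the input order.

    Sorted ascending, adjusted_(i) = max_{j<=i} (m-j+1) * p_(j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = np.maximum.accumulate((m - np.arange(m)) * p[order])
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(stepped, 1.0)
    return adjusted


def adjust_family(results: Sequence[GroupComparisonResult]) -> None:
    """Fill ``p_holm`` across one family of group comparisons, in place."""
    adjusted = holm_adjust([r.p_raw for r in results])
    for r, p in zip(results, adjusted):
        r.p_holm = float(p)


@dataclass
class DistributionSummary:
    mean: float
    sd: float
    min: float
    max: float
    skewness: float  # adjusted Fisher-Pearson g1
    kurtosis: float  # excess kurtosis g2
    ceiling_percent: float = math.nan
    n: int = 0


def describe_distribution(
    values: Sequence[float], max_possible: float | None = None
) -> DistributionSummary:
    """Mean/SD/range, bias-adjusted skewness and excess kurtosis, ceiling."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError(f"need at least 3 observations, got {v.size}")
    sd = float(np.std(v, ddof=1))
    if sd == 0:
        skew = kurt = math.nan
    else:
        skew = float(sps.skew(v, bias=False))
        kurt = float(sps.kurtosis(v, fisher=True, bias=False))
    ceiling = math.nan
    if max_possible is not None:
        from .scores import ceiling_effect

        ceiling = ceiling_effect(v, max_possible).percent
    return DistributionSummary(
        mean=float(np.mean(v)), sd=sd, min=float(v.min()), max=float(v.max()),
        skewness=skew, kurtosis=kurt, ceiling_percent=ceiling, n=int(v.size),
    )


def rin_transform(values: Sequence[float]) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Phi^{-1}((r - 3/8) / (n + 1/4)) on average ranks; NaNs stay NaN.
    Used in reporting to linearize heavily skewed measures (e.g. MVPA time)
    for plotting.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    mask = np.isfinite(v)
    n = int(mask.sum())
    if n == 0:
        return out
    r = sps.rankdata(v[mask])
    out[mask] = sps.norm.ppf((r - 3.0 / 8.0) / (n + 0.25))
    return out
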