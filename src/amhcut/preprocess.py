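"""Cohort preprocessing: outlier fences, descriptives, group tests.

Implements the descriptive half of the analysis: Tukey outlier fences on
the biomarker (applied within each group), mean/SD and median/IQR
summaries, the standard two-group comparisons (Welch t, Mann-Whitney U
with tie correction, chi-square), Pearson/Spearman correlation,
fractional-polynomial exploration of the AMH-age trend, and the Gen II
to picoAMH assay conversion.

Quantiles throughout use linear interpolation between order statistics
(the "type 7" convention) — fences and IQRs depend on this choice, so it
is fixed here and documented.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TukeyFences",
    "DescriptiveSummary",
    "GroupComparison",
    "FPFit",
    "FilterResult",
    "tukey_fences",
    "filter_outliers",
    "describe",
    "compare_groups",
    "chi_square_test",
    "correlate",
    "fit_fractional_polynomial",
    "genII_to_picoAMH",
]

#: Royston-Altman candidate powers; 0 denotes log(x).
FP_POWERS: Tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class TukeyFences:
    """Quartiles and the 1.5*IQR outlier fences for one set of values."""

    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float
    n_excluded: int


@dataclass(frozen=True)
class DescriptiveSummary:
    variable: str
    group: str
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test: str
    statistic: float
    p_value: float


@dataclass(frozen=True)
class FPFit:
    """A fractional-polynomial least-squares fit.

    ``powers`` are drawn from :data:`FP_POWERS`; a repeated power (p, p)
    denotes the basis (x^p, x^p log x).  ``deviance`` is the residual sum
    of squares of the selected model.
    """

    powers: Tuple[float, ...]
    coefficients: np.ndarray
    deviance: float


@dataclass(frozen=True)
class FilterResult:
    """Outcome of per-group outlier filtering."""

    cohort: pd.DataFrame
    fences: Dict[str, TukeyFences]
    excluded: pd.DataFrame

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def tukey_fences(values: Iterable[float]) -> TukeyFences:
    """Quartiles (linear interpolation) and Tukey 1.5*IQR fences.

    ``n_excluded`` counts values strictly outside [lower, upper]; values
    exactly on a fence are kept.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 4:
        raise ValueError(f"need at least 4 values for Tukey fences, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in input")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    lower = q1 - 1.5 * iqr
    upper = q3 + 1.5 * iqr
    n_excluded = int(np.sum((v < lower) | (v > upper)))
    return TukeyFences(float(q1), float(q3), float(iqr), float(lower), float(upper), n_excluded)


def filter_outliers(
    cohort: pd.DataFrame, variable: str = "amh", group_col: str = "group"
) -> FilterResult:
    """Remove Tukey outliers of ``variable`` within each group.

    Fences are computed separately per group (case and control have very
    different biomarker distributions, so pooled fences would mostly
    flag healthy-range values in the higher group).  Survivor order is
    preserved; excluded rows are returned and logged by id.
    """
    if variable not in cohort.columns:
        raise KeyError(f"unknown variable {variable!r}")
    if group_col not in cohort.columns:
        raise KeyError(f"unknown group column {group_col!r}")
    keep = np.ones(len(cohort), dtype=bool)
    fences: Dict[str, TukeyFences] = {}
    values = cohort[variable].to_numpy(dtype=float)
    for g in cohort[group_col].unique():
        idx = (cohort[group_col] == g).to_numpy()
        f = tukey_fences(values[idx])
        fences[g] = f
        keep[idx] = (values[idx] >= f.lower) & (values[idx] <= f.upper)
    excluded = cohort.loc[~keep]
    if len(excluded) and "id" in excluded.columns:
        logger.info(
            "excluded %d outlier record(s) on %s: ids %s",
            len(excluded), variable, list(excluded["id"]),
        )
    return FilterResult(cohort.loc[keep].copy(), fences, excluded.copy())


def describe(
    cohort: pd.DataFrame,
    variables: Sequence[str] = ("age", "amh", "bmi"),
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group descriptive summaries (n, mean, SD, median, Q1, Q3)."""
    rows = []
    for g, sub in cohort.groupby(group_col, sort=True):
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        for var in variables:
            if var not in cohort.columns:
                raise KeyError(f"unknown variable {var!r}")
            v = sub[var].dropna().to_numpy(dtype=float)
            if v.size == 0:
                raise ValueError(f"no observations for {var!r} in group {g!r}")
            q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
            rows.append(
                DescriptiveSummary(
                    variable=var,
                    group=str(g),
                    n=int(v.size),
                    mean=float(np.mean(v)),
                    sd=float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
                    median=float(med),
                    q1=float(q1),
                    q3=float(q3),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def chi_square_test(table: np.ndarray, variable: str = "table") -> GroupComparison:
    """Pearson chi-square test of independence on a contingency table."""
    res = stats.chi2_contingency(np.asarray(table), correction=False)
    return GroupComparison(variable, "chi_square", float(res.statistic), float(res.pvalue))


def compare_groups(
    cohort: pd.DataFrame,
    variable: str,
    test: str = "mann_whitney",
    group_col: str = "group",
) -> GroupComparison:
    """Two-sided two-group comparison of ``variable``.

    ``test`` is one of ``t`` (Welch), ``mann_whitney`` (normal
    approximation with tie correction), or ``chi_square`` (on the
    group-by-category contingency table).
    """
    groups = sorted(cohort[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    a = cohort.loc[cohort[group_col] == groups[0], variable].dropna()
    b = cohort.loc[cohort[group_col] == groups[1], variable].dropna()
    if test == "chi_square":
        table = pd.crosstab(cohort[group_col], cohort[variable]).to_numpy()
        return chi_square_test(table, variable)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
        return GroupComparison(variable, "t", float(res.statistic), float(res.pvalue))
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return GroupComparison(
            variable, "mann_whitney", float(res.statistic), float(res.pvalue)
        )
    raise ValueError(f"unknown test {test!r}")


def correlate(
    x: Iterable[float], y: Iterable[float], method: str = "pearson"
) -> Tuple[float, float]:
    """Pearson or Spearman correlation with two-sided p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def _fp_basis(x: np.ndarray, powers: Sequence[float]) -> np.ndarray:
    """Design matrix for an FP model: intercept plus one column per term.

    Power 0 denotes log(x); a repeated power (p, p) gives x^p and
    x^p * log(x).
    """
    cols = [np.ones_like(x)]
    seen: Dict[float, int] = {}
    for p in powers:
        base = np.log(x) if p == 0 else x ** p
        if p in seen:
            cols.append(base * np.log(x))
        else:
            cols.append(base)
            seen[p] = 1
    return np.column_stack(cols)


def fit_fractional_polynomial(
    x: Iterable[float], y: Iterable[float], degree: int = 2
) -> FPFit:
    """Best-fitting fractional polynomial of ``y`` on ``x``.

    Exhaustive search over the candidate power set; least squares with a
    Gaussian working model, deviance = residual sum of squares.  Ties in
    deviance resolve to the first candidate in enumeration order.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if np.any(x <= 0):
        raise ValueError("fractional polynomials require strictly positive x")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if degree == 1:
        candidates = [(p,) for p in FP_POWERS]
    else:
        candidates = [
            tuple(c) for c in itertools.combinations_with_replacement(FP_POWERS, 2)
        ]
    if x.size <= degree + 1:
        raise ValueError("need more observations than parameters")
    best: FPFit | None = None
    for powers in candidates:
        X = _fp_basis(x, powers)
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coef) ** 2))
        if best is None or rss < best.deviance - 1e-12:
            best = FPFit(powers, coef, rss)
    assert best is not None
    return best


def genII_to_picoAMH(value: float) -> float:
    """Convert a Gen II assay AMH value (ng/mL) to the picoAMH scale."""
    if np.any(np.asarray(value) < 0):
        raise ValueError("AMH cannot be negative")
    return 0.01 + 1.69 * value
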