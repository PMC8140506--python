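"""Data-driven age categorization by AUC maximization.

Fits a logit-link GAM of disease status on smooth(age) + smooth(AMH)
(penalized B-splines, statsmodels), then searches age cut-point tuples
on a half-year grid: for each candidate tuple a logistic working model
with categorized age (plus a spline basis in AMH when the biomarker is
available) is fitted and scored by its in-sample empirical AUC; the
maximizing tuple is returned.

Conventions: bands are left-closed/right-open except the last
(``[20, c1), [c1, c2), ..., [c_k, 40]``); the empirical AUC is the
rank-based Mann-Whitney statistic with ties counted one half.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

logger = logging.getLogger(__name__)

__all__ = ["AgePartition", "GamFit", "auc", "fit_logit_gam", "optimal_cutpoints"]


@dataclass(frozen=True)
class AgePartition:
    """An ordered set of age cut-points and the AUC it achieves."""

    cutpoints: Tuple[float, ...]
    auc: float
    age_range: Tuple[float, float] = (20.0, 40.0)
    band_counts: Tuple[int, ...] = ()

    @property
    def k(self) -> int:
        return len(self.cutpoints)

    @property
    def intervals(self) -> Tuple[str, ...]:
        edges = [self.age_range[0], *self.cutpoints, self.age_range[1]]
        labels = [
            f"{edges[i]:g} to < {edges[i + 1]:g}" for i in range(len(edges) - 2)
        ]
        labels.append(f"{edges[-2]:g} to {edges[-1]:g}")
        return tuple(labels)

    def assign_bands(self, ages: Iterable[float]) -> np.ndarray:
        """Band index (0-based) per age; last band is closed on the right."""
        return np.searchsorted(
            np.asarray(self.cutpoints, dtype=float),
            np.asarray(list(ages), dtype=float),
            side="right",
        )


@dataclass
class GamFit:
    """A fitted binomial GAM of disease on smooth(age) + smooth(AMH)."""

    result: object
    smoother: BSplines
    alpha: Sequence[float]
    fitted: np.ndarray
    labels: np.ndarray
    edf: Tuple[float, ...]

    @property
    def auc(self) -> float:
        return auc(self.fitted, self.labels)

    def predict(self, age: Iterable[float], amh: Iterable[float]) -> np.ndarray:
        exog = pd.DataFrame({"age": list(age), "amh": list(amh)})
        x_spline = self.smoother.transform(exog[["age", "amh"]].to_numpy())
        return np.asarray(
            self.result.predict(
                np.ones((len(exog), 1)), exog_smooth=exog[["age", "amh"]].to_numpy()
            )
        )


def auc(scores: Iterable[float], labels: Iterable[float]) -> float:
    """Empirical AUC: P(random case outscores random control), ties half.

    Computed as the normalized Mann-Whitney rank statistic.
    """
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels))
    pos = s[y == 1]
    neg = s[y != 1]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both outcome classes must be present")
    ranks = pd.Series(s).rank(method="average").to_numpy()
    r_pos = ranks[y == 1].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _gcv_score(res, n: int) -> float:
    """Generalized cross-validation: deviance / (1 - edf/n)^2."""
    edf = float(np.sum(res.edf)) if hasattr(res, "edf") else res.df_model + 1
    denom = max(1.0 - edf / n, 1e-3)
    return float(res.deviance) / (n * denom**2)


def fit_logit_gam(
    cohort: pd.DataFrame,
    age_col: str = "age",
    amh_col: str = "amh",
    label_col: str = "label",
    df: int = 10,
    alphas: Sequence[float] | None = None,
) -> GamFit:
    """Binomial (logit) GAM of disease status on smooth(age) + smooth(AMH).

    Smoothing penalties are chosen by a small generalized-cross-validation
    grid over ``alphas`` (shared across both terms); if every penalized
    fit fails, an unpenalized moderate-df fit is used as fallback.
    ``label_col`` must be 0/1; if absent, a ``group`` column with
    case/control labels is used instead.
    """
    y = _labels(cohort, label_col)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("outcome has a single class; GAM is not identifiable")
    if len(cohort) < 50:
        raise ValueError("need at least 50 subjects to fit the GAM")
    x = cohort[[age_col, amh_col]].to_numpy(dtype=float)
    smoother = BSplines(x, df=[df, df], degree=[3, 3])
    if alphas is None:
        alphas = [0.1, 1.0, 10.0, 100.0, 1000.0]
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for a in alphas:
            try:
                model = GLMGam(
                    y, np.ones((len(y), 1)), smoother=smoother,
                    alpha=[a, a], family=sm.families.Binomial(),
                )
                res = model.fit()
            except Exception:  # singular/separation failures: try next alpha
                continue
            score = _gcv_score(res, len(y))
            if best is None or score < best[0]:
                best = (score, a, res)
        if best is None:
            model = GLMGam(
                y, np.ones((len(y), 1)), smoother=smoother,
                alpha=[1e4, 1e4], family=sm.families.Binomial(),
            )
            res = model.fit()
            best = (_gcv_score(res, len(y)), 1e4, res)
    _, a, res = best
    fitted = np.asarray(res.fittedvalues)
    if not np.all((fitted > 0) & (fitted < 1)):
        raise RuntimeError("GAM produced degenerate fitted probabilities (separation?)")
    edf = _term_edf(res, smoother)
    return GamFit(res, smoother, [a, a], fitted, y, edf)


def _term_edf(res, smoother: BSplines) -> Tuple[float, ...]:
    """Approximate per-term effective degrees of freedom."""
    try:
        edf_all = np.asarray(res.edf)
        out = []
        start = 1  # skip intercept
        for size in smoother.dim_basis:
            out.append(float(np.sum(edf_all[start : start + size])))
            start += size
        return tuple(out)
    except Exception:
        return ()


def _labels(cohort: pd.DataFrame, label_col: str) -> np.ndarray:
    if label_col in cohort.columns:
        return cohort[label_col].to_numpy(dtype=int)
    if "group" in cohort.columns:
        return (cohort["group"] == "case").to_numpy(dtype=int)
    if "d" in cohort.columns:
        return cohort["d"].to_numpy(dtype=int)
    raise KeyError(f"no outcome column found (tried {label_col!r}, 'group', 'd')")


def _amh_spline(amh: np.ndarray, df: int = 5) -> np.ndarray:
    """Fixed B-spline basis for the biomarker term of the working model."""
    sm_b = BSplines(amh.reshape(-1, 1), df=[df], degree=[3], include_intercept=False)
    return sm_b.basis


def optimal_cutpoints(
    cohort: pd.DataFrame,
    k: int = 2,
    grid_step: float = 0.5,
    age_col: str = "age",
    amh_col: str | None = None,
    label_col: str = "label",
    age_range: Tuple[float, float] = (20.0, 40.0),
    min_band_frac: float = 0.05,
    cv_folds: int = 0,
) -> AgePartition:
    """AUC-maximizing age cut-points for categorized-age prediction.

    Exhaustive search over k-tuples from a ``grid_step``-year grid
    strictly inside ``age_range``.  Each tuple is scored by the in-sample
    AUC of a logistic model with the categorized age factor — the
    univariate categorization the bands exist to provide.  Passing
    ``amh_col`` additionally conditions the working model on a fixed
    B-spline basis in the biomarker; this is off by default because a
    flexible biomarker term absorbs the very age-specific diagnostic
    signal the bands are meant to stratify.  Tuples leaving any band
    below ``min_band_frac`` of subjects are skipped.  Ties break toward
    the most balanced band sizes, then toward smaller cut-points.

    ``cv_folds > 0`` scores tuples by K-fold cross-validated AUC instead
    of the default in-sample AUC (bands-only models only); off by
    default, matching in-sample usage.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    y = _labels(cohort, label_col)
    if np.unique(y).size < 2:
        raise ValueError("outcome has a single class")
    ages = cohort[age_col].to_numpy(dtype=float)
    n = len(ages)
    lo, hi = age_range
    grid = np.arange(lo + 1.0, hi - 1.0 + 1e-9, grid_step)

    use_amh = amh_col is not None and amh_col in cohort.columns
    if use_amh:
        if cv_folds:
            raise ValueError("cv_folds is only supported for bands-only models")
        amh_basis = _amh_spline(cohort[amh_col].to_numpy(dtype=float))
    folds = None
    if cv_folds:
        folds = np.arange(n) % cv_folds  # ages arrive in arbitrary order

    min_count = max(int(np.ceil(min_band_frac * n)), 1)
    order = np.argsort(ages, kind="mergesort")
    ages_sorted = ages[order]

    best = None  # (auc, balance_key, cutpoints, band_counts)
    n_evaluated = 0
    for tup in itertools.combinations(grid, k):
        cps = np.asarray(tup)
        # band occupancy via binary search on the sorted ages
        idx = np.searchsorted(ages_sorted, cps, side="left")
        counts = np.diff(np.concatenate([[0], idx, [n]]))
        if np.any(counts < min_count):
            continue
        band = np.searchsorted(cps, ages, side="right")
        if folds is not None:
            scores = _cv_scores(y, band, k + 1, folds)
        else:
            scores = _categorized_scores(y, band, k + 1, amh_basis if use_amh else None)
        if scores is None:
            continue
        n_evaluated += 1
        a = auc(scores, y)
        balance = -float(np.var(counts))  # higher = more balanced
        key = (a, balance, tuple(-c for c in cps))
        if best is None or key > best[0]:
            best = (key, tuple(float(c) for c in cps), tuple(int(c) for c in counts))
    if best is None:
        raise ValueError("no admissible cut-point tuple (all bands too small)")
    logger.debug("evaluated %d candidate tuples", n_evaluated)
    (a, _, _), cps, counts = best
    return AgePartition(cps, float(a), age_range, counts)


def _cv_scores(
    y: np.ndarray, band: np.ndarray, n_bands: int, folds: np.ndarray
) -> np.ndarray:
    """Out-of-fold band-prevalence predictions (bands-only model)."""
    scores = np.empty(len(y), dtype=float)
    overall = y.mean()
    for f in np.unique(folds):
        test = folds == f
        train_y, train_band = y[~test], band[~test]
        prev = np.array([
            train_y[train_band == b].mean() if np.any(train_band == b) else overall
            for b in range(n_bands)
        ])
        scores[test] = prev[band[test]]
    return scores


def _categorized_scores(
    y: np.ndarray, band: np.ndarray, n_bands: int, amh_basis: np.ndarray | None
) -> np.ndarray | None:
    """Fitted probabilities of the categorized-age logistic working model.

    Without a biomarker term the MLE fitted value in each band is the
    band prevalence, so no iterative fit is needed.
    """
    if amh_basis is None:
        prev = np.array([y[band == b].mean() if np.any(band == b) else 0.0
                         for b in range(n_bands)])
        return prev[band]
    dummies = np.eye(n_bands)[band]  # one column per band, no intercept
    X = np.column_stack([dummies, amh_basis])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
        return np.asarray(res.fittedvalues)
    except Exception:
        return None
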