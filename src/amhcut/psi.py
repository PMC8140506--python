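"""Predictive summary index (PSI) cut-off estimation.

The PSI is the predictive-value analogue of the Youden index:

    PSI = max over cut-offs of (PPV + NPV - 1)

with test-positivity defined as x >= c.  The maximizer over the observed
values is the frequentist cut-off estimate; confidence intervals come
from a nonparametric case-resampling bootstrap (percentile method).

Candidate cut-offs are the sorted unique observed values; a candidate is
admissible only if both sides of the split are non-empty.  Ties in PSI
break toward the smallest cut-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PsiResult", "predictive_values", "psi_optimize", "bootstrap_ci"]


@dataclass(frozen=True)
class PsiResult:
    """PSI-maximizing cut-off with predictive values and bootstrap CIs."""

    cutoff: float
    ppv: float
    npv: float
    psi: float
    ci_cutoff: Optional[Tuple[float, float]] = None
    ci_ppv: Optional[Tuple[float, float]] = None
    ci_npv: Optional[Tuple[float, float]] = None
    ci_psi: Optional[Tuple[float, float]] = None
    n_boot: int = 0
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}


def predictive_values(
    x: np.ndarray, d: np.ndarray, c: float
) -> Tuple[float, float]:
    """PPV and NPV of the test "x >= c".

    Raises if either side of the split is empty (the predictive value is
    undefined there); the cut-off search skips such candidates.
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d)
    pos = x >= c
    n_pos = int(pos.sum())
    n_neg = x.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"cut-off {c} leaves an empty side; predictive values undefined")
    ppv = float(d[pos].mean())
    npv = float(1.0 - d[~pos].mean())
    return ppv, npv


def psi_optimize(x: np.ndarray, d: np.ndarray) -> PsiResult:
    """PSI-maximizing cut-off over the observed biomarker values.

    Vectorized over all admissible candidates (each unique value above
    the minimum); ties break toward the smallest cut-off.
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d).astype(float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.unique(d).size < 2:
        raise ValueError("both outcome classes must be present")
    order = np.argsort(x, kind="mergesort")
    xs, ds = x[order], d[order]
    # first index of each unique value
    uniq_first = np.flatnonzero(np.concatenate([[True], np.diff(xs) > 0]))
    cum = np.concatenate([[0.0], np.cumsum(ds)])
    total = cum[-1]
    n = xs.size
    # candidate c = xs[i] for i in uniq_first[1:]: below side has i points
    idx = uniq_first[1:]
    if idx.size == 0:
        raise ValueError("no admissible cut-off candidate (all values tied)")
    s_below = cum[idx]
    ppv = (total - s_below) / (n - idx)
    npv = 1.0 - s_below / idx
    psi = ppv + npv - 1.0
    # smallest cut-off among ties (tolerance guards float noise between
    # mathematically equal candidates)
    best = int(np.flatnonzero(psi >= psi.max() - 1e-12)[0])
    return PsiResult(
        cutoff=float(xs[idx[best]]),
        ppv=float(ppv[best]),
        npv=float(npv[best]),
        psi=float(psi[best]),
    )


def bootstrap_ci(
    x: np.ndarray,
    d: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> PsiResult:
    """Percentile bootstrap intervals around the PSI point estimate.

    Case resampling with a per-replicate seed stream spawned from the
    master seed (so extending ``n_boot`` keeps earlier replicates
    identical).  Replicates where the optimization is undefined (single
    class or all values tied) are dropped and counted in ``n_failed``.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for stable percentile intervals")
    x = np.asarray(x, dtype=float)
    d = np.asarray(d).astype(int)
    point = psi_optimize(x, d)
    n = x.size
    children = np.random.SeedSequence(seed).spawn(n_boot)
    cuts, ppvs, npvs, psis = [], [], [], []
    n_failed = 0
    for ss in children:
        rng = np.random.default_rng(ss)
        idx = rng.integers(0, n, size=n)
        try:
            r = psi_optimize(x[idx], d[idx])
        except ValueError:
            n_failed += 1
            continue
        cuts.append(r.cutoff)
        ppvs.append(r.ppv)
        npvs.append(r.npv)
        psis.append(r.psi)
    if not cuts:
        raise RuntimeError("every bootstrap replicate failed")
    if n_failed:
        logger.info("dropped %d failed bootstrap replicate(s)", n_failed)
    q = lambda v: tuple(float(t) for t in np.quantile(v, [0.025, 0.975]))
    return PsiResult(
        cutoff=point.cutoff,
        ppv=point.ppv,
        npv=point.npv,
        psi=point.psi,
        ci_cutoff=q(cuts),
        ci_ppv=q(ppvs),
        ci_npv=q(npvs),
        ci_psi=q(psis),
        n_boot=n_boot,
        n_failed=n_failed,
    )
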