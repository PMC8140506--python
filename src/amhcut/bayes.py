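"""Bayesian cut-off estimation for a predictive-value step model.

The disease probability is modeled as a step function of the biomarker:

    P(d = 1 | x) = theta_pos   if x >= c   (theta_pos is the PPV)
    P(d = 1 | x) = theta_neg   if x <  c   (NPV = 1 - theta_neg)

The likelihood conditions on x, so the marginal distribution of the
biomarker drops out and the two Bernoulli rates are literally the
positive and negative predictive values of the test "x >= c".  The
cut-off c is itself a parameter, supported on the observed biomarker
range.

Sampling is Metropolis-within-Gibbs with the rates collapsed out of the
cut-off move: c moves by a Gaussian random walk (reflection at the
support bounds) mixed with occasional uniform independence proposals,
accepted by the Beta-binomial marginal likelihood times the cut-off
prior ratio; the rates are then drawn from their exact conjugate Beta
conditionals (also exact under Beta-mixture priors, via recomputed
posterior mixture weights).  Collapsing is what lets chains cross
between well-separated likelihood modes in c.  The likelihood is
piecewise constant in c between order statistics, so per-iteration cost
is O(log n) using a precomputed cumulative disease count.

Three prior families are provided: uninformative (Beta(1,1) rates,
uniform cut-off), informative (Beta with user-centered means at a fixed
effective sample size; truncated-normal cut-off, by default centered at
the 4.7 ng/mL literature threshold), and an equal-weight mixture of the
two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "StepModelParams",
    "CutoffPrior",
    "PriorSpec",
    "McmcConfig",
    "Chains",
    "PosteriorSummary",
    "log_likelihood",
    "sample_posterior",
    "summarize_posterior",
    "gelman_rubin",
]


@dataclass(frozen=True)
class StepModelParams:
    """Step-model parameters: cut-off and the two Bernoulli rates."""

    c: float
    theta_pos: float  # P(disease | x >= c) == PPV
    theta_neg: float  # P(disease | x < c)  == 1 - NPV

    @property
    def ppv(self) -> float:
        return self.theta_pos

    @property
    def npv(self) -> float:
        return 1.0 - self.theta_neg

    def validate(self) -> None:
        for name in ("theta_pos", "theta_neg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class CutoffPrior:
    """Prior for the cut-off on the observed biomarker range.

    ``uniform``: flat on [min x, max x].  ``truncnorm``: Normal(mean, sd)
    truncated to the same range.  ``fixed``: degenerate at ``mean``
    (used for conjugacy validation).
    """

    kind: str = "uniform"
    mean: float = 4.7
    sd: float = 1.0

    def logpdf(self, c: float, lo: float, hi: float) -> float:
        if self.kind == "uniform":
            return -np.log(hi - lo) if lo <= c <= hi else -np.inf
        if self.kind == "truncnorm":
            if not lo <= c <= hi:
                return -np.inf
            # closed form (no scipy frozen-dist overhead: this sits in
            # the MCMC inner loop)
            z = (c - self.mean) / self.sd
            a, b = (lo - self.mean) / self.sd, (hi - self.mean) / self.sd
            log_norm = np.log(max(special.ndtr(b) - special.ndtr(a), 1e-300))
            return float(
                -0.5 * z * z - 0.5 * np.log(2 * np.pi) - np.log(self.sd) - log_norm
            )
        if self.kind == "fixed":
            return 0.0
        raise ValueError(f"unknown cutoff prior kind {self.kind!r}")


@dataclass(frozen=True)
class PriorSpec:
    """Prior specification: Beta shapes for the rates, cut-off prior.

    ``kind`` is ``uninformative``, ``informative`` or ``mixture``; for a
    mixture, ``components`` holds the two component specs and
    ``mixture_weight`` the weight of the first.
    """

    kind: str = "uninformative"
    beta_pos: Tuple[float, float] = (1.0, 1.0)
    beta_neg: Tuple[float, float] = (1.0, 1.0)
    cutoff_prior: CutoffPrior = field(default_factory=CutoffPrior)
    mixture_weight: float = 0.5
    components: Optional[Tuple["PriorSpec", "PriorSpec"]] = None

    @staticmethod
    def uninformative() -> "PriorSpec":
        return PriorSpec(
            kind="uninformative",
            beta_pos=(1.0, 1.0),
            beta_neg=(1.0, 1.0),
            cutoff_prior=CutoffPrior("uniform"),
        )

    @staticmethod
    def informative(
        ppv: float = 0.95,
        npv: float = 0.85,
        cutoff: float = 4.7,
        cutoff_sd: float = 1.0,
        ess: float = 20.0,
    ) -> "PriorSpec":
        """Beta priors with the given means at effective sample size ``ess``.

        The cut-off prior is truncated-normal centered at ``cutoff`` —
        by default the ~4.7 ng/mL single-threshold value reported in the
        AMH/PCOS literature.
        """
        t_neg = 1.0 - npv  # prior mean for theta_neg
        return PriorSpec(
            kind="informative",
            beta_pos=(ppv * ess, (1.0 - ppv) * ess),
            beta_neg=(t_neg * ess, (1.0 - t_neg) * ess),
            cutoff_prior=CutoffPrior("truncnorm", mean=cutoff, sd=cutoff_sd),
        )

    @staticmethod
    def mixture(
        weight: float = 0.5, informative: Optional["PriorSpec"] = None
    ) -> "PriorSpec":
        """Equal-weight (by default) mixture of uninformative and informative."""
        if not 0.0 < weight < 1.0:
            raise ValueError("mixture weight must be in (0, 1)")
        comp = (PriorSpec.uninformative(), informative or PriorSpec.informative())
        return PriorSpec(kind="mixture", mixture_weight=weight, components=comp)

    def validate(self) -> None:
        if self.kind == "mixture":
            if self.components is None or len(self.components) != 2:
                raise ValueError("mixture prior needs exactly 2 components")
            for c in self.components:
                c.validate()
            return
        for a, b in (self.beta_pos, self.beta_neg):
            if a <= 0 or b <= 0:
                raise ValueError("Beta shape parameters must be > 0")

    def cutoff_logpdf(self, c: float, lo: float, hi: float) -> float:
        if self.kind == "mixture":
            assert self.components is not None
            w = self.mixture_weight
            l1 = self.components[0].cutoff_logpdf(c, lo, hi)
            l2 = self.components[1].cutoff_logpdf(c, lo, hi)
            return float(np.logaddexp(np.log(w) + l1, np.log1p(-w) + l2))
        return self.cutoff_prior.logpdf(c, lo, hi)


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    ``proposal_sd=None`` starts the random walk at 0.25 * IQR(x); with
    ``adapt=True`` (default) the step size is tuned during burn-in
    toward ~30% acceptance and then frozen, so the post-burn-in kernel
    is fixed.  With probability ``jump_prob`` the cut-off move is an
    independence proposal uniform over the support instead of a local
    step — the step likelihood can have well-separated local modes in c,
    which a pure random walk cannot cross.
    """

    n_chains: int = 3
    n_iter: int = 20_000
    n_burnin: int = 5_000
    proposal_sd: Optional[float] = None
    adapt: bool = True
    jump_prob: float = 0.1
    thin: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.proposal_sd is not None and self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be > 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class Chains:
    """Post-burn-in draws, one row per chain."""

    c: np.ndarray          # (n_chains, n_draws)
    theta_pos: np.ndarray
    theta_neg: np.ndarray
    acceptance_rate: Tuple[float, ...]
    x_range: Tuple[float, float]

    @property
    def n_draws(self) -> int:
        return self.c.shape[0] * self.c.shape[1]


@dataclass(frozen=True)
class ParamSummary:
    mean: float
    median: float
    ci_lower: float
    ci_upper: float
    rhat: float


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior summaries for cut-off, PPV and NPV.

    Equal-tailed 95% credible intervals; NPV is reported on the NPV
    scale (1 - theta_neg).  ``converged`` flags all split-chain R-hat
    below 1.1.
    """

    cutoff: ParamSummary
    ppv: ParamSummary
    npv: ParamSummary
    acceptance_rate: float
    n_draws: int

    @property
    def converged(self) -> bool:
        return all(
            s.rhat < 1.1 for s in (self.cutoff, self.ppv, self.npv)
        )

    def table(self) -> pd.DataFrame:
        rows = []
        for name, s in (("cutoff", self.cutoff), ("ppv", self.ppv), ("npv", self.npv)):
            rows.append(
                dict(parameter=name, mean=s.mean, median=s.median,
                     ci_lower=s.ci_lower, ci_upper=s.ci_upper, rhat=s.rhat)
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> Dict:
        return {
            name: vars(s)
            for name, s in (("cutoff", self.cutoff), ("ppv", self.ppv), ("npv", self.npv))
        } | {"acceptance_rate": self.acceptance_rate, "n_draws": self.n_draws}


def log_likelihood(
    x: np.ndarray, d: np.ndarray, params: StepModelParams
) -> float:
    """Bernoulli step-model log-likelihood, conditioning on x.

    Impossible outcomes under degenerate rates return -inf rather than
    raising.
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d)
    if x.size == 0:
        raise ValueError("empty data")
    params.validate()
    theta = np.where(x >= params.c, params.theta_pos, params.theta_neg)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(d == 1, np.log(theta), np.log1p(-theta))
    if np.any(np.isnan(ll)):
        # 0 * log(0) style cases resolve to -inf (impossible outcome)
        ll = np.where(np.isnan(ll), -np.inf, ll)
    return float(np.sum(ll))


def _counts(xs: np.ndarray, cum_d: np.ndarray, c: float) -> Tuple[int, int, int, int]:
    """(s+, f+, s-, f-): disease successes/failures above/below c.

    ``xs`` sorted ascending, ``cum_d`` its cumulative disease count.
    Points with x >= c are test-positive.
    """
    n = xs.size
    idx = int(np.searchsorted(xs, c, side="left"))
    total = int(cum_d[-1]) if n else 0
    s_minus = int(cum_d[idx - 1]) if idx > 0 else 0
    s_plus = total - s_minus
    n_plus = n - idx
    return s_plus, n_plus - s_plus, s_minus, idx - s_minus


def _beta_draw(
    rng: np.random.Generator,
    prior: PriorSpec,
    which: str,
    s: int,
    f: int,
) -> float:
    """Conjugate (or mixture-conjugate) update for one rate parameter."""
    if prior.kind != "mixture":
        a, b = getattr(prior, which)
        return float(rng.beta(a + s, b + f))
    assert prior.components is not None
    w = np.array([prior.mixture_weight, 1.0 - prior.mixture_weight])
    logw = np.log(w)
    for i, comp in enumerate(prior.components):
        a, b = getattr(comp, which)
        logw[i] += special.betaln(a + s, b + f) - special.betaln(a, b)
    logw -= np.logaddexp(logw[0], logw[1])
    pick = prior.components[int(rng.random() > np.exp(logw[0]))]
    a, b = getattr(pick, which)
    return float(rng.beta(a + s, b + f))


def _marginal_side(prior: PriorSpec, which: str, s: int, f: int) -> float:
    """Log Beta-binomial marginal likelihood of one side's counts."""
    if prior.kind != "mixture":
        a, b = getattr(prior, which)
        return float(special.betaln(a + s, b + f) - special.betaln(a, b))
    assert prior.components is not None
    w = (prior.mixture_weight, 1.0 - prior.mixture_weight)
    t0 = np.log(w[0]) + _marginal_side(prior.components[0], which, s, f)
    t1 = np.log(w[1]) + _marginal_side(prior.components[1], which, s, f)
    return float(np.logaddexp(t0, t1))


def _marginal_loglik(
    counts: Tuple[int, int, int, int], prior: PriorSpec
) -> float:
    """Log-likelihood of a cut-off with the conjugate rates integrated out.

    Collapsing theta_pos/theta_neg makes the Metropolis update target
    the exact marginal posterior of c, so chains cannot get trapped in a
    local mode by rates adapted to the current split.
    """
    sp, fp, sn, fn = counts
    return _marginal_side(prior, "beta_pos", sp, fp) + _marginal_side(
        prior, "beta_neg", sn, fn
    )


def _reflect(c: float, lo: float, hi: float) -> float:
    width = hi - lo
    if width <= 0:
        return lo
    # reflect into [lo, hi]; at most a few bounces for reasonable steps
    c = (c - lo) % (2 * width)
    return lo + (c if c <= width else 2 * width - c)


def sample_posterior(
    x: np.ndarray,
    d: np.ndarray,
    prior: PriorSpec | None = None,
    config: McmcConfig | None = None,
    fixed_cutoff: Optional[float] = None,
    prior_only: bool = False,
) -> Chains:
    """Metropolis-within-Gibbs sampler for the step model.

    ``fixed_cutoff`` freezes c (degenerate cut-off prior), leaving pure
    conjugate Gibbs for the rates — used to validate the sampler against
    the closed-form Beta posteriors.  ``prior_only`` switches the
    likelihood off, so the sampler should reproduce the prior (a sampler
    self-check).
    """
    prior = prior or PriorSpec.uninformative()
    config = config or McmcConfig()
    prior.validate()
    config.validate()
    x = np.asarray(x, dtype=float)
    d = np.asarray(d).astype(int)
    if x.size == 0:
        raise ValueError("empty data")
    if np.unique(d).size < 2 and not prior_only:
        raise ValueError("both outcome classes must be present")

    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    cum_d = np.cumsum(d[order])
    lo, hi = float(xs[0]), float(xs[-1])
    if hi <= lo:
        raise ValueError("degenerate biomarker range")
    iqr = float(np.subtract(*np.quantile(xs, [0.75, 0.25])))
    step = config.proposal_sd if config.proposal_sd is not None else max(0.25 * iqr, 1e-3 * (hi - lo))

    n_kept = (config.n_iter - config.n_burnin) // config.thin
    out_c = np.empty((config.n_chains, n_kept))
    out_tp = np.empty_like(out_c)
    out_tn = np.empty_like(out_c)
    acc_rates = []

    for chain in range(config.n_chains):
        rng = np.random.default_rng([config.seed, chain])
        c = fixed_cutoff if fixed_cutoff is not None else rng.uniform(lo, hi)
        counts = _counts(xs, cum_d, c)
        chain_step = step
        n_acc = 0
        n_prop = 0
        win_acc = 0
        win_prop = 0
        kept = 0
        cur_post = prior.cutoff_logpdf(c, lo, hi)
        if not prior_only:
            cur_post += _marginal_loglik(counts, prior)
        for it in range(config.n_iter):
            if fixed_cutoff is None:
                is_jump = rng.random() < config.jump_prob
                if is_jump:
                    # independence proposal: q is constant, so the
                    # acceptance ratio reduces to the posterior ratio
                    c_new = rng.uniform(lo, hi)
                else:
                    c_new = _reflect(c + rng.normal(0.0, chain_step), lo, hi)
                counts_new = _counts(xs, cum_d, c_new)
                new_post = prior.cutoff_logpdf(c_new, lo, hi)
                if not prior_only:
                    new_post += _marginal_loglik(counts_new, prior)
                n_prop += 1
                if not is_jump:
                    win_prop += 1
                if np.log(rng.random()) < new_post - cur_post:
                    c, counts, cur_post = c_new, counts_new, new_post
                    n_acc += 1
                    if not is_jump:
                        win_acc += 1
                # step-size adaptation, burn-in only: the kernel is
                # frozen after warm-up
                if config.adapt and it < config.n_burnin and win_prop == 50:
                    rate = win_acc / win_prop
                    chain_step *= float(np.exp(1.2 * (rate - 0.3)))
                    chain_step = float(np.clip(chain_step, 1e-6 * (hi - lo), hi - lo))
                    win_acc = win_prop = 0
            if prior_only:
                sp = fp = sn = fn = 0
            else:
                sp, fp, sn, fn = counts
            tp = _beta_draw(rng, prior, "beta_pos", sp, fp)
            tn = _beta_draw(rng, prior, "beta_neg", sn, fn)
            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
                out_c[chain, kept] = c
                out_tp[chain, kept] = tp
                out_tn[chain, kept] = tn
                kept += 1
        rate = n_acc / n_prop if n_prop else 1.0
        acc_rates.append(rate)
        if n_prop and n_acc == 0:
            raise RuntimeError(
                f"chain {chain}: zero acceptance for the cut-off update; "
                f"proposal sd {step:.3g} is unusable on range [{lo:.3g}, {hi:.3g}]"
            )
        if fixed_cutoff is None and not 0.1 <= rate <= 0.6:
            logger.warning(
                "chain %d acceptance rate %.2f outside [0.1, 0.6]; "
                "consider tuning proposal_sd", chain, rate,
            )
    return Chains(out_c, out_tp, out_tn, tuple(acc_rates), (lo, hi))


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (R-hat).

    ``chains`` has shape (n_chains, n_draws).  Constant chains return
    1.0 by convention.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (n_chains >= 2, n_draws) array")
    half = chains.shape[1] // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain")
    split = np.vstack([chains[:, :half], chains[:, half : 2 * half]])
    m, n = split.shape
    means = split.mean(axis=1)
    w = split.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 1e-14 * max(1.0, float(np.mean(means**2))):
        # (numerically) constant chains: 1.0 by convention
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def _summarize(draws: np.ndarray) -> ParamSummary:
    flat = draws.ravel()
    lo, hi = np.quantile(flat, [0.025, 0.975])
    return ParamSummary(
        mean=float(flat.mean()),
        median=float(np.median(flat)),
        ci_lower=float(lo),
        ci_upper=float(hi),
        rhat=gelman_rubin(draws),
    )


def summarize_posterior(chains: Chains, min_draws: int = 1000) -> PosteriorSummary:
    """Posterior means/medians/95% equal-tailed intervals with R-hat."""
    if chains.n_draws < min_draws:
        raise ValueError(
            f"need at least {min_draws} post-burn-in draws, got {chains.n_draws}"
        )
    summ = PosteriorSummary(
        cutoff=_summarize(chains.c),
        ppv=_summarize(chains.theta_pos),
        npv=_summarize(1.0 - chains.theta_neg),
        acceptance_rate=float(np.mean(chains.acceptance_rate)),
        n_draws=chains.n_draws,
    )
    if not summ.converged:
        logger.warning(
            "convergence warning: split-chain R-hat above 1.1 "
            "(cutoff %.3f, ppv %.3f, npv %.3f)",
            summ.cutoff.rhat, summ.ppv.rhat, summ.npv.rhat,
        )
    return summ
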