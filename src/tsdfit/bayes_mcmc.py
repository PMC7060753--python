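"""Bayesian fitting of TSD reaction norms by adaptive Metropolis-Hastings.

A component-wise Gaussian random-walk Metropolis-Hastings sampler targets the
posterior proportional to (binomial likelihood) x (prior). Each parameter
carries its own prior specification in the style of the classical TSD
toolkits: a density (uniform or normal) with its two shape values, hard
support bounds, a starting value, and an initial proposal standard
deviation. Proposals landing outside the support are rejected outright.

During the first part of the run the proposal standard deviations are tuned
by a Robbins-Monro schedule toward the optimal random-walk acceptance rate
of 0.234, then frozen so that the summarized part of the chain is a proper
Markov chain. Posterior summaries use empirical quantiles, which accommodate
the asymmetric posteriors typical of the S (and K) parameters; derived
quantities such as the TRT are computed from every retained parameter vector
so their posterior needs no distributional assumption. Unlike maximum
likelihood, the sampler remains usable on datasets without any mixed-sex
group — the posterior then simply reflects the prior where the data are
uninformative, which the prior-overlap diagnostic flags.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import TSDDataset
from .mle_fit import FitResult, make_nll
from .reaction_norms import ModelParams, TRTSpec, trt

__all__ = ["PriorSpec", "MCMCResult", "default_priors", "mh_mcmc", "posterior_summaries"]

TARGET_ACCEPTANCE = 0.234
ADAPT_ITERATIONS = 10_000
ADAPT_BATCH = 100

_SUPPORT = {
    "P": (25.0, 35.0),
    "S": (-2.0, 2.0),
    "K1": (-500.0, 500.0),
    "K2": (-500.0, 500.0),
}
_PRIOR_SD = {"P": 2.0, "S": 1.0, "K1": 100.0, "K2": 100.0}
_SD_PROP = {"P": 2.0, "S": 0.5, "K1": 0.5, "K2": 0.5}


@dataclass(frozen=True)
class PriorSpec:
    """Prior, support, start and proposal scale for one parameter."""

    name: str
    density: str  # "uniform" | "normal"
    prior1: float  # min (uniform) or mean (normal)
    prior2: float  # max (uniform) or sd (normal)
    min: float
    max: float
    init: float
    sd_prop: float

    def __post_init__(self) -> None:
        if self.density not in ("uniform", "normal"):
            raise ValueError(f"unknown prior density {self.density!r}")
        if not self.min < self.max:
            raise ValueError(f"{self.name}: min must be < max")
        if not self.min <= self.init <= self.max:
            raise ValueError(f"{self.name}: init {self.init} outside [{self.min}, {self.max}]")
        if self.sd_prop <= 0:
            raise ValueError(f"{self.name}: sd_prop must be positive")

    def log_density(self, x: float) -> float:
        if x < self.min or x > self.max:
            return -math.inf
        if self.density == "uniform":
            return -math.log(self.prior2 - self.prior1) if self.prior1 <= x <= self.prior2 else -math.inf
        z = (x - self.prior1) / self.prior2
        return -0.5 * z * z - math.log(self.prior2) - 0.5 * math.log(2.0 * math.pi)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draws from the prior truncated to the support (for diagnostics)."""
        out = np.empty(size)
        filled = 0
        while filled < size:
            if self.density == "uniform":
                cand = rng.uniform(self.prior1, self.prior2, size - filled)
            else:
                cand = rng.normal(self.prior1, self.prior2, size - filled)
            cand = cand[(cand >= self.min) & (cand <= self.max)]
            out[filled : filled + cand.size] = cand
            filled += cand.size
        return out


@dataclass
class MCMCResult:
    """Chain, acceptance history and posterior summaries of one MCMC run."""

    chain: np.ndarray  # (n_iter, n_params)
    log_posterior: np.ndarray
    param_names: tuple[str, ...]
    family: str
    burn_in: int
    seed: int | None
    acceptance_rate: float
    acceptance_rate_post_adaptation: float
    sd_prop_final: np.ndarray
    priors: tuple[PriorSpec, ...]
    thinning: int = 1
    summaries: pd.DataFrame | None = None

    @property
    def posterior(self) -> np.ndarray:
        return self.chain[self.burn_in :]

    def to_frame(self) -> pd.DataFrame:
        f = pd.DataFrame(self.chain, columns=list(self.param_names))
        f["log_posterior"] = self.log_posterior
        f.index.name = "iteration"
        return f

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def default_priors(
    family: str, mle: FitResult | None = None
) -> tuple[PriorSpec, ...]:
    """Standard prior set for a family, optionally informed by an ML fit.

    With an ML fit available: normal priors centered at the estimates
    (sd 2 for P, 1 for S, 100 for K1/K2), initialized at the estimates —
    which also makes a short burn-in adequate. Without one: uniform priors
    over the support, initialized at mid-support. Supports are P in
    [25, 35] degrees C, S in [-2, 2], K in [-500, 500]; initial proposal
    sd 2 for P and 0.5 for S, K1, K2.
    """
    names = ("P", "S") if family == "logistic" else ("P", "S", "K1", "K2")
    if mle is not None and mle.params.family != family:
        raise ValueError("MLE family does not match requested family")
    specs = []
    for i, name in enumerate(names):
        lo, hi = _SUPPORT[name]
        if mle is not None:
            center = float(np.clip(mle.params.to_array()[i], lo, hi))
            specs.append(
                PriorSpec(name, "normal", center, _PRIOR_SD[name], lo, hi, center, _SD_PROP[name])
            )
        else:
            init = 1.0 if name in ("K1", "K2") else (lo + hi) / 2.0
            if name == "S":
                init = -0.3  # male-at-cool orientation is the common TSD Ia case
            specs.append(PriorSpec(name, "uniform", lo, hi, lo, hi, init, _SD_PROP[name]))
    return tuple(specs)


def mh_mcmc(
    ds: TSDDataset,
    family: str = "logistic",
    priors: tuple[PriorSpec, ...] | None = None,
    n_iter: int = 100_000,
    seed: int | None = None,
    adapt: bool = True,
    burn_in: int | None = None,
) -> MCMCResult:
    """Component-wise adaptive random-walk Metropolis-Hastings sampler.

    One sub-step per parameter per iteration; the recorded chain state is the
    vector after all sub-steps. During the first ``ADAPT_ITERATIONS``
    iterations each proposal sd is rescaled every ``ADAPT_BATCH`` iterations
    by ``exp(kappa * (acc - 0.234))`` with ``kappa = 1/sqrt(batch index)``,
    then frozen. ``burn_in`` defaults to 10,000 (the adaptation span) for
    prior starts; pass a small value (the classical choice is ~10) when the
    chain starts at the maximum-likelihood estimates.

    Datasets without sexed embryos are allowed: the likelihood is then
    constant and the chain samples the prior.
    """
    if family not in ("logistic", "flexit"):
        raise ValueError(f"unknown family {family!r}")
    if priors is None:
        priors = default_priors(family)
    names = tuple(s.name for s in priors)
    k = len(priors)

    if ds.has_sexed_embryos():
        nll = make_nll(ds, family)
        log_lik = lambda th: -nll(th)
    else:
        log_lik = lambda th: 0.0

    def log_post(theta: np.ndarray) -> float:
        lp = sum(s.log_density(x) for s, x in zip(priors, theta))
        if not math.isfinite(lp):
            return -math.inf
        return lp + log_lik(theta)

    theta = np.array([s.init for s in priors], float)
    lp = log_post(theta)
    if not math.isfinite(lp):
        raise ValueError("initial state has zero posterior probability (outside prior support)")

    if burn_in is None:
        burn_in = min(ADAPT_ITERATIONS, n_iter // 2)
    rng = np.random.default_rng(seed)
    sd = np.array([s.sd_prop for s in priors], float)
    lo = np.array([s.min for s in priors])
    hi = np.array([s.max for s in priors])

    chain = np.empty((n_iter, k))
    lps = np.empty(n_iter)
    accepted = np.zeros(k, dtype=np.int64)
    accepted_post = 0
    proposals_post = 0
    batch_accept = np.zeros(k)
    batch = 0

    for it in range(n_iter):
        for j in range(k):
            prop = theta.copy()
            prop[j] = theta[j] + sd[j] * rng.standard_normal()
            if prop[j] < lo[j] or prop[j] > hi[j]:
                lp_prop = -math.inf
            else:
                lp_prop = log_post(prop)
            if math.log(rng.random()) < lp_prop - lp:
                theta, lp = prop, lp_prop
                accepted[j] += 1
                batch_accept[j] += 1
                if it >= burn_in:
                    accepted_post += 1
            if it >= burn_in:
                proposals_post += 1
        chain[it] = theta
        lps[it] = lp
        if adapt and it < ADAPT_ITERATIONS and (it + 1) % ADAPT_BATCH == 0:
            batch += 1
            kappa = 1.0 / math.sqrt(batch)
            acc = batch_accept / ADAPT_BATCH
            sd *= np.exp(kappa * (acc - TARGET_ACCEPTANCE))
            batch_accept[:] = 0.0

    overall = float(accepted.sum()) / (n_iter * k)
    post = accepted_post / proposals_post if proposals_post else float("nan")
    return MCMCResult(
        chain=chain,
        log_posterior=lps,
        param_names=names,
        family=family,
        burn_in=burn_in,
        seed=seed,
        acceptance_rate=overall,
        acceptance_rate_post_adaptation=float(post),
        sd_prop_final=sd,
        priors=tuple(priors),
    )


def posterior_summaries(
    result: MCMCResult,
    spec: TRTSpec = TRTSpec(),
    overlap_warn: float = 0.9,
) -> pd.DataFrame:
    """Mean, sd and (0.025, 0.5, 0.975) quantiles of parameters and the TRT.

    The sd of the chain is the standard error of the corresponding
    parameter. The TRT is computed from every post-burn-in parameter vector.
    A per-parameter prior-vs-posterior overlap diagnostic (1 minus the total
    variation distance between binned prior and posterior samples) is
    attached; overlap close to 1 means the data did not update the prior and
    the estimate should not be used, or used with caution.
    """
    if result.burn_in >= len(result.chain):
        raise ValueError("burn-in is not shorter than the chain")
    post = result.posterior
    rng = np.random.default_rng(result.seed)
    rows = []
    for i, name in enumerate(result.param_names):
        vals = post[:, i]
        prior_draws = result.priors[i].sample(rng, min(len(vals), 20_000))
        edges = np.histogram_bin_edges(np.concatenate([vals, prior_draws]), bins=50)
        p_hist, _ = np.histogram(vals, bins=edges, density=False)
        q_hist, _ = np.histogram(prior_draws, bins=edges, density=False)
        p_hist = p_hist / p_hist.sum()
        q_hist = q_hist / q_hist.sum()
        overlap = 1.0 - 0.5 * np.abs(p_hist - q_hist).sum()
        if overlap > overlap_warn:
            warnings.warn(
                f"posterior of {name} closely matches its prior (overlap {overlap:.2f}); "
                "the data did not inform this parameter — use with caution",
                stacklevel=2,
            )
        rows.append(_summary_row(name, vals, overlap))
    trt_vals = np.array(
        [trt(ModelParams.from_array(result.family, th), spec).width for th in post]
    )
    rows.append(_summary_row("TRT", trt_vals, np.nan))
    return pd.DataFrame(rows).set_index("quantity")


def _summary_row(name: str, vals: np.ndarray, overlap: float) -> dict:
    qs = np.quantile(vals, [0.025, 0.5, 0.975])  # numpy default = type-7
    return {
        "quantity": name,
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        "q0.025": qs[0],
        "q0.5": qs[1],
        "q0.975": qs[2],
        "prior_overlap": overlap,
    }
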