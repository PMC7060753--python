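"""Confidence intervals by resampling the asymptotic covariance of the MLE.

Draws are taken from a multivariate normal centered at the point estimates
with the Hessian-derived covariance (Cholesky factorization, falling back to
an eigenvalue factorization when the matrix is not positive definite). Each
draw is screened for sign coherence: S must keep the sign of the estimate,
and for the flexit family K1 - 1 and K2 - 1 must not change sign either —
a sign flip in S reverses the entire TSD pattern, and a K crossing 1 flips
the asymmetry of the corresponding asymptote. Screening discards divergent
draws and therefore *artificially narrows* the interval; the rejection log
records how much was discarded, and a Bayesian MCMC fit avoids the problem
altogether. Quantiles of the retained draws (and of derived quantities such
as the TRT computed per draw) give the reported intervals.

The delta method is deliberately not implemented: it assumes an untruncated
normal distribution for the estimator, which fails for the sign-constrained
S of a TSD pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mle_fit import FitResult
from .reaction_norms import ModelParams, TRTSpec, sex_ratio, trt

__all__ = [
    "ResampleDraws",
    "resample_parameters",
    "ci_curve",
    "ci_derived",
    "delta_method",
]

_QS = (0.025, 0.5, 0.975)


@dataclass
class ResampleDraws:
    """Retained parameter draws from the asymptotic covariance."""

    draws: np.ndarray  # (n_retained, n_params)
    family: str
    param_names: tuple[str, ...]
    n_requested: int
    n_retained: int
    rejection_log: dict = field(default_factory=dict)
    seed: int | None = None
    screened: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=list(self.param_names))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _mvn_factor(cov: np.ndarray) -> np.ndarray:
    """Matrix A with A A' = cov; Cholesky, or eigen fallback for PSD matrices."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        return V * np.sqrt(w)


def resample_parameters(
    fit: FitResult,
    n: int = 10_000,
    seed: int | None = None,
    screen: bool = True,
) -> ResampleDraws:
    """Draw parameter vectors from the fit's asymptotic covariance.

    ``screen`` enables the sign-coherence rules described in the module
    docstring (opt-out to quantify the narrowing bias they introduce).
    A warning recommends the MCMC route when more than 90% of the draws
    are rejected.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not np.all(np.isfinite(fit.covariance)):
        raise ValueError("fit covariance is not finite; cannot resample")
    est = fit.params.to_array()
    A = _mvn_factor(fit.covariance)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=(n, est.size))
    draws = est + z @ A.T

    log: dict[str, int] = {}
    if screen:
        keep = np.ones(n, dtype=bool)
        s_idx = 1
        bad_s = np.sign(draws[:, s_idx]) != np.sign(est[s_idx])
        log["S sign flip"] = int(bad_s.sum())
        keep &= ~bad_s
        if fit.params.family == "flexit":
            for idx, name in ((2, "K1"), (3, "K2")):
                bad = np.sign(draws[:, idx] - 1.0) != np.sign(est[idx] - 1.0)
                log[f"{name} - 1 sign flip"] = int((bad & keep).sum())
                keep &= ~bad
        draws = draws[keep]
    n_retained = draws.shape[0]
    if screen and n_retained < 0.1 * n:
        warnings.warn(
            "more than 90% of resampled parameter sets were rejected by the "
            "sign-coherence screen; the interval is unreliable — use the "
            "Bayesian MCMC procedure instead (tsdfit.bayes_mcmc.mh_mcmc)",
            stacklevel=2,
        )
    return ResampleDraws(
        draws=draws,
        family=fit.params.family,
        param_names=fit.params.names,
        n_requested=n,
        n_retained=n_retained,
        rejection_log=log,
        seed=seed,
        screened=screen,
    )


def ci_curve(
    fit: FitResult,
    draws: ResampleDraws,
    temps,
    level: float = 0.95,
) -> pd.DataFrame:
    """Pointwise quantile band of the sex-ratio curve over the draws.

    Returns a frame with the lower, median and upper sex-ratio quantiles at
    each temperature of ``temps``; the band is contained in [0, 1] by
    construction.
    """
    if draws.n_retained == 0:
        raise ValueError("no retained draws; cannot build a confidence band")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    temps = np.atleast_1d(np.asarray(temps, float))
    curves = np.empty((draws.n_retained, temps.size))
    for i, theta in enumerate(draws.draws):
        curves[i] = sex_ratio(temps, ModelParams.from_array(draws.family, theta))
    alpha = (1.0 - level) / 2.0
    lo, med, hi = np.quantile(curves, [alpha, 0.5, 1.0 - alpha], axis=0)
    return pd.DataFrame(
        {"temperature": temps, "lower": lo, "median": med, "upper": hi}
    )


def ci_derived(
    fit: FitResult,
    draws: ResampleDraws,
    spec: TRTSpec = TRTSpec(),
) -> pd.DataFrame:
    """(0.025, 0.5, 0.975) quantiles of P and of the TRT computed per draw."""
    if draws.n_retained == 0:
        raise ValueError("no retained draws; cannot summarize derived quantities")
    P_draws = draws.draws[:, 0]
    trt_draws = np.array(
        [trt(ModelParams.from_array(draws.family, th), spec).width for th in draws.draws]
    )
    rows = []
    for name, vals in (("P", P_draws), ("TRT", trt_draws)):
        qs = np.quantile(vals, _QS)
        rows.append({"quantity": name, "q0.025": qs[0], "q0.5": qs[1], "q0.975": qs[2]})
    return pd.DataFrame(rows).set_index("quantity")


def delta_method(*args, **kwargs):
    """Reserved: not implemented.

    The delta method assumes an untruncated asymptotically normal estimator,
    which does not hold for the sign-constrained S (and K) parameters of a
    TSD reaction norm. Use :func:`resample_parameters` with
    :func:`ci_derived`, or the Bayesian route in :mod:`tsdfit.bayes_mcmc`.
    """
    raise NotImplementedError(delta_method.__doc__)
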