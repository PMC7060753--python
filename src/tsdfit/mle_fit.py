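"""Binomial likelihood and maximum-likelihood estimation of TSD reaction norms.

The sex of each embryo is treated as an independent Bernoulli draw whose
success probability is the model's male frequency at that group's incubation
temperature, so each group contributes a binomial term

    L_i = C(M_i + F_i, M_i) * sr(t_i)^M_i * (1 - sr(t_i))^F_i

and the dataset log-likelihood is the sum over groups *as listed* (duplicate
temperatures are not pooled; the binomial coefficient is included so that
-ln L values are comparable across software). Intersex counts never enter
the binomial total.

Standard errors come from the inverse of the numerical Hessian of -ln L at
the optimum (central finite differences). When the Hessian is singular a
pseudo-inverse is reported with a flag instead of raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, xlogy

from .data_io import TSDDataset
from .reaction_norms import ModelParams, sex_ratio

__all__ = [
    "FitResult",
    "FitError",
    "neg_log_likelihood",
    "fit_mle",
    "hessian_covariance",
    "numeric_hessian",
]

DEFAULT_BOUNDS = {
    "P": (20.0, 40.0),
    "S": (-2.0, 2.0),
    "K1": (-1000.0, 1000.0),
    "K2": (-1000.0, 1000.0),
}

_P_CLIP = 1e-15  # probability guard against log(0) at saturated predictions


class FitError(RuntimeError):
    """The dataset cannot support a maximum-likelihood fit."""


@dataclass
class FitResult:
    """Maximum-likelihood fit of a reaction norm to one dataset."""

    params: ModelParams
    neg_ln_L: float
    covariance: np.ndarray
    se: np.ndarray
    cv: np.ndarray
    n_groups: int
    converged: bool
    dataset_label: str = ""
    hessian_invertible: bool = True
    warnings: list[str] = field(default_factory=list)
    n_starts: int = 0

    @property
    def aic(self) -> float:
        return 2.0 * self.neg_ln_L + 2.0 * self.params.n_params

    def aicc(self, n: int | None = None) -> float:
        """Small-sample corrected AIC; ``n`` defaults to the group count."""
        n = self.n_groups if n is None else n
        p = self.params.n_params
        if n - p - 1 <= 0:
            return np.nan
        return self.aic + 2.0 * p * (p + 1) / (n - p - 1)

    def bic(self, n: int) -> float:
        return 2.0 * self.neg_ln_L + self.params.n_params * np.log(n)

    def summary_row(self) -> dict:
        d = {"model": self.params.family}
        for name, est, se, cv in zip(self.params.names, self.params.to_array(), self.se, self.cv):
            d[name] = est
            d[f"SE({name})"] = se
            d[f"CV({name})"] = cv
        d["-lnL"] = self.neg_ln_L
        d["n_groups"] = self.n_groups
        d["converged"] = self.converged
        return d


def _arrays(ds: TSDDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.array([g.temperature for g in ds.groups], float)
    M = np.array([g.males for g in ds.groups], float)
    F = np.array([g.females for g in ds.groups], float)
    return t, M, F


def _ln_binom_coef(M: np.ndarray, F: np.ndarray) -> np.ndarray:
    return gammaln(M + F + 1.0) - gammaln(M + 1.0) - gammaln(F + 1.0)


def binomial_neg_ln_L(p: np.ndarray, M: np.ndarray, F: np.ndarray) -> float:
    """-ln of a product of binomial terms, coefficients included."""
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    return float(-(_ln_binom_coef(M, F) + xlogy(M, p) + xlogy(F, 1.0 - p)).sum())


def neg_log_likelihood(ds: TSDDataset, params: ModelParams) -> float:
    """-ln L of the dataset under a reaction norm, summed over groups as listed."""
    if not ds.has_sexed_embryos():
        raise FitError("dataset has no sexed embryos")
    t, M, F = _arrays(ds)
    return binomial_neg_ln_L(sex_ratio(t, params), M, F)


def make_nll(ds: TSDDataset, family: str) -> Callable[[np.ndarray], float]:
    """Fast closure over the dataset arrays for optimizers and MCMC."""
    t, M, F = _arrays(ds)
    lcoef = float(_ln_binom_coef(M, F).sum())

    if family == "logistic":

        def nll(theta: np.ndarray) -> float:
            P, S = theta
            if S == 0.0:
                return np.inf
            with np.errstate(over="ignore"):
                p = 1.0 / (1.0 + np.exp((P - t) / S))
            p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
            return float(-(lcoef + (xlogy(M, p) + xlogy(F, 1.0 - p)).sum()))

    else:

        def nll(theta: np.ndarray) -> float:
            params = ModelParams.from_array("flexit", theta)
            p = np.clip(sex_ratio(t, params), _P_CLIP, 1.0 - _P_CLIP)
            return float(-(lcoef + (xlogy(M, p) + xlogy(F, 1.0 - p)).sum()))

    return nll


def _default_starts(ds: TSDDataset, family: str) -> list[np.ndarray]:
    t, M, F = _arrays(ds)
    mixed = (M > 0) & (F > 0)
    if mixed.any():
        w = (M + F)[mixed]
        P0 = float(np.average(t[mixed], weights=w))
    else:
        P0 = float((t.min() + t.max()) / 2.0)
    starts = []
    for S0 in (-0.3, -0.1, -1.0, 0.3):  # TSD Ia default first, sign flip last
        for dP in (0.0, -1.0, 1.0):
            starts.append(np.array([P0 + dP, S0]))
    if family == "flexit":
        flex_starts = []
        for base in starts:
            flex_starts.append(np.array([base[0], 1.0 / (4.0 * base[1]), 1.0, 1.0]))
        return flex_starts
    return starts


def fit_mle(
    ds: TSDDataset,
    family: str = "logistic",
    init: ModelParams | None = None,
    bounds: Sequence[tuple[float, float]] | None = None,
    compute_covariance: bool = True,
    multi_start: bool = True,
) -> FitResult:
    """Maximum-likelihood fit of a logistic or flexit reaction norm.

    Strategy: box-bounded quasi-Newton (L-BFGS-B) from a multi-start grid,
    with the best candidates refined by Nelder-Mead polish passes. For the
    flexit family the logistic fit always runs first and seeds the start
    ``(P, 1/(4 S), 1, 1)``, because the flexit likelihood is nearly flat in
    K2 and a good start is essential. Ties between starts are broken by
    smallest -ln L, then smallest |K1| + |K2|. ``multi_start=False`` with an
    explicit ``init`` is the fast path used by bootstrap refits.

    Raises :class:`FitError` when the dataset is all-one-sex (use the
    Bayesian path, :func:`tsdfit.bayes_mcmc.mh_mcmc`, which remains able to
    describe a credibility interval there). Emits a warning when the number
    of mixed-sex groups is below the parameter count.
    """
    if family not in ("logistic", "flexit"):
        raise ValueError(f"unknown family {family!r}")
    if not ds.has_sexed_embryos():
        raise FitError("dataset has no sexed embryos; nothing to fit")
    notes: list[str] = []
    if ds.n_mixed == 0:
        raise FitError(
            "dataset has no mixed sex ratio; maximum likelihood cannot identify "
            "the parameters. A Bayesian MCMC fit can still describe the "
            "credibility interval (tsdfit.bayes_mcmc.mh_mcmc)."
        )
    p_count = 2 if family == "logistic" else 4
    if ds.n_mixed < p_count:
        msg = (
            f"only {ds.n_mixed} mixed-sex group(s) for a {p_count}-parameter model; "
            "standard errors will be unreliable"
        )
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)

    nll = make_nll(ds, family)
    names = ("P", "S") if family == "logistic" else ("P", "S", "K1", "K2")
    box = list(bounds) if bounds is not None else [DEFAULT_BOUNDS[n] for n in names]

    starts: list[np.ndarray] = []
    if init is not None:
        if init.family != family:
            raise ValueError("init family does not match requested family")
        starts.append(init.to_array())
    if multi_start:
        if family == "flexit":
            logi = fit_mle(ds, "logistic", compute_covariance=False)
            seed = np.array([logi.params.P, 1.0 / (4.0 * logi.params.S), 1.0, 1.0])
            starts.append(seed)
            for K1x in (0.5, -1.0, -2.0, 2.0):
                for K2x in (1.0, 10.0, 200.0):
                    starts.append(np.array([seed[0], seed[1], K1x, K2x]))
        starts.extend(_default_starts(ds, family))
    elif not starts:
        starts.extend(_default_starts(ds, family)[:1])

    lo_box = np.array([b[0] for b in box])
    hi_box = np.array([b[1] for b in box])
    stage1: list[tuple[float, np.ndarray, bool]] = []
    for x0 in starts:
        x0 = np.clip(x0, lo_box, hi_box)
        try:
            res = minimize(nll, x0, method="L-BFGS-B", bounds=box)
        except (ValueError, FloatingPointError):
            continue
        stage1.append((float(res.fun), res.x, bool(res.success)))
    if not stage1:
        raise FitError("all optimizer starts failed")
    stage1.sort(key=lambda c: c[0])

    best_x, best_f, best_ok = None, np.inf, False
    n_top = 3 if multi_start else 1
    for f1, x1, ok in stage1[:n_top]:
        x, f = x1, f1
        for _ in range(2):  # Nelder-Mead polish to likelihood tolerance 1e-8
            res2 = minimize(
                nll,
                x,
                method="Nelder-Mead",
                options=dict(xatol=1e-10, fatol=1e-12, maxiter=20000, maxfev=20000),
            )
            if res2.fun <= f:
                x, f = res2.x, res2.fun
        x = np.clip(x, lo_box, hi_box)
        f = nll(x)
        better = f < best_f - 1e-8
        tie = abs(f - best_f) <= 1e-8 and best_x is not None
        if tie and family == "flexit":
            better = abs(x[2]) + abs(x[3]) < abs(best_x[2]) + abs(best_x[3])
        if best_x is None or better:
            best_x, best_f, best_ok = x, f, ok

    if best_x is None or not np.isfinite(best_f):
        raise FitError("all optimizer starts failed")
    params = ModelParams.from_array(family, best_x)

    k = len(best_x)
    if compute_covariance:
        cov, invertible = hessian_covariance(ds, params, return_flag=True)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = se / np.abs(best_x)
        for name, c in zip(names, cv):
            if np.isfinite(c) and c > 1.0:
                notes.append(f"high coefficient of variation for {name}: CV = {c:.2f}")
    else:
        cov = np.full((k, k), np.nan)
        se = np.full(k, np.nan)
        cv = np.full(k, np.nan)
        invertible = False

    return FitResult(
        params=params,
        neg_ln_L=float(best_f),
        covariance=cov,
        se=se,
        cv=cv,
        n_groups=len(ds),
        converged=best_ok,
        dataset_label=ds.label,
        hessian_invertible=invertible,
        warnings=notes,
        n_starts=len(starts),
    )


def numeric_hessian(
    f: Callable[[np.ndarray], float], x: np.ndarray, rel_step: float = 1e-4
) -> np.ndarray:
    """Central-difference Hessian with per-parameter relative steps.

    Steps are halved (up to 10 times) on non-finite entries.
    """
    x = np.asarray(x, float)
    n = x.size
    h = np.array([rel_step * max(abs(v), 1e-3) for v in x])
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            hi, hj = h[i], h[j]
            for _ in range(10):
                ei = np.zeros(n)
                ej = np.zeros(n)
                ei[i], ej[j] = hi, hj
                if i == j:
                    val = (f(x + ei) - 2.0 * f0 + f(x - ei)) / hi**2
                else:
                    val = (
                        f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                    ) / (4.0 * hi * hj)
                if np.isfinite(val):
                    break
                hi, hj = hi / 2.0, hj / 2.0
            H[i, j] = H[j, i] = val
    return H


def hessian_covariance(
    ds: TSDDataset, params: ModelParams, return_flag: bool = False
):
    """Asymptotic covariance of the estimates: inverse Hessian of -ln L.

    A singular Hessian is reported through the Moore-Penrose pseudo-inverse
    together with ``invertible = False`` rather than as an exception.
    """
    nll = make_nll(ds, params.family)
    H = numeric_hessian(nll, params.to_array())
    try:
        cov = np.linalg.inv(H)
        invertible = True
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        invertible = False
    cov = (cov + cov.T) / 2.0
    return (cov, invertible) if return_flag else cov
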