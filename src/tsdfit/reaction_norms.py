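"""Sigmoid thermal reaction norms for sex ratio and their transitional range.

Two model families are supported, both mapping a constant incubation
temperature ``t`` to the expected male relative frequency:

``logistic``
    ``sr(t) = 1 / (1 + exp((P - t) / S))`` with pivotal temperature ``P``
    (where ``sr = 0.5``) and shape parameter ``S``, one fourth of the inverse
    of the slope at ``P``. Negative ``S`` gives the male-at-cool /
    female-at-warm orientation (TSD Ia); positive ``S`` the reverse (TSD Ib).

``flexit``
    A flexible logistic with independent shape parameters ``K1`` and ``K2``
    for the transitions toward the lower and upper asymptotes (acute for
    positive values, obtuse for negative values)::

        t <  P:  sr = (1 + (2^K1 - 1) exp(4 S1 (P - t)))^(-1/K1)
        t >= P:  sr = 1 - (1 + (2^K2 - 1) exp(4 S2 (t - P)))^(-1/K2)

    with ``S1 = 2^(K1-1) S K1 / (2^K1 - 1)`` and likewise for ``S2``. Here
    ``S`` is the slope (first derivative) of the curve at ``P`` itself, so a
    logistic with shape ``S_logistic`` corresponds to a flexit with
    ``K1 = K2 = 1`` and ``S = 1/(4 S_logistic)`` — the two families
    parameterize slope differently and are never converted silently.
    ``K = 0`` is undefined and is replaced by ``1e-9`` (sign preserved).

The transitional range of temperatures (TRT) is the width of the temperature
interval producing sex ratios between ``l`` and ``1 - l`` (default
``l = 0.05``, i.e. the 5%-95% male frequency window).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "ModelParams",
    "TRTSpec",
    "TRTResult",
    "logistic_sr",
    "flexit_sr",
    "sex_ratio",
    "trt",
    "logistic_to_flexit",
]

_LN2 = math.log(2.0)
_K_FLOOR = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Parameters of a sex-ratio reaction norm.

    ``family`` selects the functional form; ``K1``/``K2`` are present for
    flexit only. ``S`` carries the TSD orientation in its sign and means a
    different thing in the two families (see module docstring).
    """

    family: Literal["logistic", "flexit"]
    P: float
    S: float
    K1: float | None = None
    K2: float | None = None

    def __post_init__(self) -> None:
        if self.family == "logistic":
            if self.K1 is not None or self.K2 is not None:
                raise ValueError("logistic parameters take no K1/K2")
        elif self.family == "flexit":
            if self.K1 is None or self.K2 is None:
                raise ValueError("flexit parameters require K1 and K2")
        else:
            raise ValueError(f"unknown family {self.family!r}")
        for name in ("P", "S") + (("K1", "K2") if self.family == "flexit" else ()):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")

    @property
    def n_params(self) -> int:
        return 2 if self.family == "logistic" else 4

    def to_array(self) -> np.ndarray:
        if self.family == "logistic":
            return np.array([self.P, self.S], float)
        return np.array([self.P, self.S, self.K1, self.K2], float)

    @classmethod
    def from_array(cls, family: str, theta) -> "ModelParams":
        theta = np.asarray(theta, float)
        if family == "logistic":
            return cls("logistic", float(theta[0]), float(theta[1]))
        return cls("flexit", float(theta[0]), float(theta[1]), float(theta[2]), float(theta[3]))

    @property
    def names(self) -> tuple[str, ...]:
        return ("P", "S") if self.family == "logistic" else ("P", "S", "K1", "K2")

    def to_json(self) -> str:
        d = {"family": self.family, "P": self.P, "S": self.S}
        if self.family == "flexit":
            d.update(K1=self.K1, K2=self.K2)
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        d = json.loads(text)
        return cls(d["family"], d["P"], d["S"], d.get("K1"), d.get("K2"))


@dataclass(frozen=True)
class TRTSpec:
    """Sex-ratio limit defining the transitional range (default 5%-95%)."""

    l: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.l < 0.5:
            raise ValueError(f"TRT limit l must lie in (0, 0.5), got {self.l}")

    @property
    def K_l(self) -> float:
        """The logistic TRT constant |2 ln(l/(1-l))|."""
        return abs(2.0 * math.log(self.l / (1.0 - self.l)))


@dataclass(frozen=True)
class TRTResult:
    """TRT width plus the two bounding temperatures (lower < upper)."""

    width: float
    lower: float
    upper: float


def logistic_to_flexit(params: ModelParams) -> ModelParams:
    """Explicit conversion of a logistic parameter set to the equivalent flexit."""
    if params.family != "logistic":
        raise ValueError("expected logistic parameters")
    return ModelParams("flexit", params.P, 1.0 / (4.0 * params.S), 1.0, 1.0)


def logistic_sr(t, params: ModelParams) -> np.ndarray:
    """Male frequency of the logistic reaction norm; vectorized over ``t``."""
    if params.family != "logistic":
        raise ValueError(f"logistic_sr needs logistic parameters, got {params.family}")
    if params.S == 0:
        raise ValueError("S = 0 leaves the logistic model undefined")
    t = np.asarray(t, float)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp((params.P - t) / params.S))
    return out


def _guard_K(K: float) -> float:
    if abs(K) < _K_FLOOR:
        return _K_FLOOR if K >= 0 else -_K_FLOOR
    return K


def _half_slope_ratio(K: float) -> float:
    """``2^(K-1) / (2^K - 1)``, evaluated in log space for large |K|."""
    z = K * _LN2
    if K > 0:
        # ratio -> 1/2 as K -> +inf
        return math.exp(-_LN2 - (math.log1p(-math.exp(-z)) if z < 700 else 0.0))
    # denominator negative: ratio = -2^(K-1) / (1 - 2^K) -> 0- as K -> -inf
    return -math.exp(z - _LN2 - math.log1p(-math.exp(z)))


def _branch(u: np.ndarray, K: float) -> np.ndarray:
    """``(1 + (2^K - 1) e^u)^(-1/K)`` for vector ``u``; 0.5 at ``u = 0``.

    Log-space evaluation keeps the expression finite for K as large as the
    box bound used in fitting (|K| up to ~1000). For K < 0 the base reaches
    zero at finite ``u`` and the curve attains its asymptote exactly; the
    value is clamped to 0 there.
    """
    z = K * _LN2
    if K > 0:
        a = z if z > 30 else math.log(math.expm1(z))
        return np.exp(-np.logaddexp(0.0, a + u) / K)
    c = -math.expm1(z)  # 1 - 2^K in (0, 1)
    with np.errstate(over="ignore"):
        base = 1.0 - c * np.exp(u)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(base > 0.0, np.exp(np.log(np.where(base > 0.0, base, 1.0)) / (-K)), 0.0)
    return out


def flexit_sr(t, params: ModelParams) -> np.ndarray:
    """Male frequency of the flexit reaction norm; vectorized over ``t``.

    Both branches meet at ``sr(P) = 0.5`` for every K1, K2.
    """
    if params.family != "flexit":
        raise ValueError(f"flexit_sr needs flexit parameters, got {params.family}")
    P, S = params.P, params.S
    K1 = _guard_K(params.K1)
    K2 = _guard_K(params.K2)
    S1 = _half_slope_ratio(K1) * S * K1
    S2 = _half_slope_ratio(K2) * S * K2
    t = np.asarray(t, float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.empty_like(t)
    lo = t < P
    out[lo] = _branch(4.0 * S1 * (P - t[lo]), K1)
    out[~lo] = 1.0 - _branch(4.0 * S2 * (t[~lo] - P), K2)
    return out[0] if scalar else out


def sex_ratio(t, params: ModelParams) -> np.ndarray:
    """Dispatch to the reaction norm of ``params.family``."""
    return logistic_sr(t, params) if params.family == "logistic" else flexit_sr(t, params)


def _flexit_branch_offset(q: float, S_branch: float, K: float) -> float:
    """Distance from P at which a flexit branch value equals ``q``.

    Inverts ``(1 + (2^K - 1) e^u)^(-1/K) = q`` for ``u`` and converts to a
    temperature offset ``u / (4 S_branch)``; log-space throughout.
    """
    z = K * _LN2
    w = -K * math.log(q)  # ln(q^-K)
    if K > 0:
        num = w if w > 30 else math.log(math.expm1(w))
        den = z if z > 30 else math.log(math.expm1(z))
    else:
        num = math.log(-math.expm1(w))
        den = math.log(-math.expm1(z))
    return (num - den) / (4.0 * S_branch)


def trt(params: ModelParams, spec: TRTSpec = TRTSpec()) -> TRTResult:
    """Transitional range of temperatures and its bounding temperatures.

    The width is reported as an absolute value; the bounds are the
    temperatures where the curve crosses ``l`` and ``1 - l``. Closed forms
    are used for both families (branch inversion for flexit).
    """
    if params.S == 0:
        raise ValueError("S = 0 leaves the TRT undefined")
    l = spec.l
    if params.family == "logistic":
        # t(q) = P - S ln((1-q)/q)
        t_l = params.P - params.S * math.log((1.0 - l) / l)
        t_u = params.P - params.S * math.log(l / (1.0 - l))
        lower, upper = sorted((t_l, t_u))
        return TRTResult(abs(params.S) * spec.K_l, lower, upper)

    K1 = _guard_K(params.K1)
    K2 = _guard_K(params.K2)
    S1 = _half_slope_ratio(K1) * params.S * K1
    S2 = _half_slope_ratio(K2) * params.S * K2
    if params.S < 0:
        # decreasing curve: branch 1 (t < P) crosses 1-l, branch 2 crosses l
        t_lo = params.P - _flexit_branch_offset(1.0 - l, S1, K1)
        t_hi = params.P + _flexit_branch_offset(1.0 - l, S2, K2)
    else:
        # increasing curve: branch 1 crosses l, branch 2 crosses 1-l
        t_lo = params.P - _flexit_branch_offset(l, S1, K1)
        t_hi = params.P + _flexit_branch_offset(l, S2, K2)
    return TRTResult(abs(t_hi - t_lo), min(t_lo, t_hi), max(t_lo, t_hi))
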