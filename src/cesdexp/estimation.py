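"""Estimating (P, r) from observed category counts.

Two estimators are provided.  The *ratio* estimator is the descriptive one
used in the age-trajectory analysis: P-hat is the relative frequency of
"some", and r-hat is the mean of the two successive frequency ratios
much/some and most/much.  The *MLE* maximizes the multinomial likelihood of
the exponential model over its validity region; it is the model-consistent
alternative and is used for cross-checking.

Zero-count conventions for the ratio estimator:

* ``n_some == 0`` — both parameters undefined.
* ``n_much == 0`` with ``n_most > 0`` — r undefined (a ratio through an
  empty middle category is meaningless).
* ``n_much == 0`` and ``n_most == 0`` — r-hat = 0 (empty upper tail).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .core_model import ModelParams, category_probabilities

__all__ = [
    "CategoryCounts",
    "ParamEstimate",
    "estimate_ratio",
    "estimate_mle",
    "aggregate_params",
    "loglinear_slope",
    "parallelism_check",
    "log_likelihood",
]

#: Default verdict threshold for slope spread, in natural-log units.
DEFAULT_PARALLEL_THRESHOLD = 0.15


@dataclass(frozen=True)
class CategoryCounts:
    """Observed counts over the four ordered categories of one item."""

    n_rarely: int
    n_some: int
    n_much: int
    n_most: int

    def __post_init__(self) -> None:
        for name in ("n_rarely", "n_some", "n_much", "n_most"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.n_total == 0:
            raise ValueError("empty counts: n_total must be >= 1")

    @property
    def n_total(self) -> int:
        return self.n_rarely + self.n_some + self.n_much + self.n_most

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.n_rarely, self.n_some, self.n_much, self.n_most], dtype=float
        )


@dataclass(frozen=True)
class ParamEstimate:
    """Result of fitting (P, r) to one item's counts.

    ``defined`` is False when the counts do not identify the parameters
    (e.g. no "some" responses); then ``P_hat``/``r_hat`` are NaN.
    """

    P_hat: float
    r_hat: float
    method: str
    n_total: int
    defined: bool

    @property
    def params(self) -> ModelParams:
        if not self.defined:
            raise ValueError("estimate is undefined; no ModelParams available")
        return ModelParams(self.P_hat, max(self.r_hat, 1e-12))


def estimate_ratio(counts: CategoryCounts) -> ParamEstimate:
    """Ratio estimator: P-hat = f_some; r-hat = (much/some + most/much) / 2.

    Examples
    --------
    >>> est = estimate_ratio(CategoryCounts(650, 200, 100, 50))
    >>> (est.P_hat, est.r_hat)
    (0.2, 0.5)
    """
    n = counts.n_total
    if counts.n_some == 0:
        return ParamEstimate(math.nan, math.nan, "ratio", n, defined=False)
    P_hat = counts.n_some / n
    if counts.n_much == 0:
        if counts.n_most > 0:
            # mass beyond an empty middle category: no common-ratio reading
            return ParamEstimate(math.nan, math.nan, "ratio", n, defined=False)
        r_hat = 0.0
    else:
        r_hat = (counts.n_much / counts.n_some + counts.n_most / counts.n_much) / 2.0
    return ParamEstimate(P_hat, r_hat, "ratio", n, defined=True)


def log_likelihood(counts: CategoryCounts, params: ModelParams) -> float:
    """Multinomial log-likelihood of the exponential model at (P, r).

    Categories with zero observed count contribute nothing even when their
    model probability is zero; a zero probability with a positive count
    gives ``-inf``.
    """
    probs = np.asarray(category_probabilities(params).as_tuple())
    cnts = counts.as_array()
    ll = 0.0
    for c, p in zip(cnts, probs):
        if c > 0:
            if p <= 0.0:
                return -math.inf
            ll += c * math.log(p)
    return ll


def _nll_transformed(z: np.ndarray, cnts: np.ndarray) -> float:
    """Negative log-likelihood in an unconstrained parameterization.

    z = (logit u, log r) with P = u / (r^2 + r + 1), u in (0, 1), keeps the
    optimizer strictly inside the validity region.
    """
    u = 1.0 / (1.0 + math.exp(-z[0]))
    r = math.exp(z[1])
    s = r * r + r + 1.0
    P = u / s
    probs = np.array([1.0 - u, P, P * r, P * r * r])
    ll = 0.0
    for c, p in zip(cnts, probs):
        if c > 0:
            if p <= 0.0:
                return 1e300
            ll += c * math.log(p)
    return -ll


def estimate_mle(counts: CategoryCounts, tol: float = 1e-9) -> ParamEstimate:
    """Maximum-likelihood estimate of (P, r) under the exponential model.

    Optimizes the multinomial log-likelihood over the validity region
    ``P (r^2 + r + 1) <= 1`` via an unconstrained reparameterization, with
    multi-start from the ratio estimate and from (P, r) = (0.1, 0.5).
    Undefined when all mass sits in "rarely" (P unidentified).
    """
    n = counts.n_total
    n_upper = counts.n_some + counts.n_much + counts.n_most
    if n_upper == 0:
        return ParamEstimate(math.nan, math.nan, "mle", n, defined=False)

    cnts = counts.as_array()
    starts: list[tuple[float, float]] = [(0.1, 0.5)]
    ratio = estimate_ratio(counts)
    if ratio.defined and ratio.r_hat > 0:
        starts.insert(0, (ratio.P_hat, ratio.r_hat))

    best = None
    for P0, r0 in starts:
        r0 = min(max(r0, 1e-6), 1e6)
        s0 = r0 * r0 + r0 + 1.0
        u0 = min(max(P0 * s0, 1e-9), 1.0 - 1e-9)
        z0 = np.array([math.log(u0 / (1.0 - u0)), math.log(r0)])
        res = minimize(
            _nll_transformed,
            z0,
            args=(cnts,),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": min(tol, 1e-12), "maxiter": 10000},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    # stationarity polish: in the (u, r) parameterization with u = P(r^2+r+1)
    # the score equations separate — u* = (n1+n2+n3)/n and r* solves
    # (2-q) r^2 + (1-q) r - q = 0, q = (n2+2n3)/(n1+n2+n3).  When that
    # interior root exists and beats the numeric optimum, take it.
    q = (counts.n_much + 2 * counts.n_most) / n_upper
    if 0.0 < q < 2.0:
        disc = (1.0 - q) ** 2 + 4.0 * q * (2.0 - q)
        r_star = (-(1.0 - q) + math.sqrt(disc)) / (2.0 * (2.0 - q))
        if r_star > 0.0:
            u_star = n_upper / n
            z_star = np.array(
                [math.log(u_star / (1.0 - u_star)) if u_star < 1.0 else 35.0,
                 math.log(r_star)]
            )
            f_star = _nll_transformed(z_star, cnts)
            # unique interior critical point; accept within float noise
            if f_star <= best.fun + 1e-8 * (1.0 + abs(best.fun)):
                best.x, best.fun = z_star, f_star
    if not best.success and not math.isfinite(best.fun):
        raise RuntimeError(f"MLE optimization failed: {best.message}")
    u = 1.0 / (1.0 + math.exp(-best.x[0]))
    r = math.exp(best.x[1])
    P = u / (r * r + r + 1.0)
    return ParamEstimate(P, r, "mle", n, defined=True)


def aggregate_params(
    estimates: Iterable[ParamEstimate],
) -> tuple[float, float, int]:
    """Unweighted means of P-hat and r-hat over the defined estimates.

    Returns ``(mean_P, mean_r, n_skipped)`` where ``n_skipped`` counts the
    undefined estimates that were excluded.  Raises if none are defined.
    """
    ps, rs, skipped = [], [], 0
    for est in estimates:
        if est.defined:
            ps.append(est.P_hat)
            rs.append(est.r_hat)
        else:
            skipped += 1
    if not ps:
        raise ValueError("all estimates undefined; nothing to aggregate")
    return (float(np.mean(ps)), float(np.mean(rs)), skipped)


def loglinear_slope(counts: CategoryCounts) -> float:
    """OLS slope of log frequency vs category index over (some, much, most).

    With three equally spaced abscissae the OLS slope reduces to
    ``(log f_most - log f_some) / 2``.  On exact model frequencies it
    equals ``log r``.  NaN when any of the three upper counts is zero.
    """
    if min(counts.n_some, counts.n_much, counts.n_most) == 0:
        return math.nan
    return (math.log(counts.n_most) - math.log(counts.n_some)) / 2.0


@dataclass(frozen=True)
class ParallelismResult:
    slopes: tuple[float, ...]
    spread: float  # max - min over defined slopes
    sd: float
    n_undefined: int
    parallel: bool
    threshold: float


def parallelism_check(
    counts_by_item: Sequence[CategoryCounts],
    threshold: float = DEFAULT_PARALLEL_THRESHOLD,
) -> ParallelismResult:
    """Spread of per-item log-linear slopes; "parallel" when max-min <= threshold."""
    slopes = [loglinear_slope(c) for c in counts_by_item]
    defined = [s for s in slopes if not math.isnan(s)]
    if len(defined) < 2:
        raise ValueError("need at least 2 items with defined slopes")
    spread = max(defined) - min(defined)
    sd = float(np.std(defined, ddof=0))
    return ParallelismResult(
        slopes=tuple(slopes),
        spread=spread,
        sd=sd,
        n_undefined=len(slopes) - len(defined),
        parallel=spread <= threshold,
        threshold=threshold,
    )
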