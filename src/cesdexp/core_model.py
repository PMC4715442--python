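"""Closed-form exponential (geometric) model for 4-category ordinal items.

An item rated on the four ordered frequency categories *rarely*, *some*,
*much*, *most* is modelled by two parameters: ``P``, the probability of the
"some" category, and ``r``, a common ratio linking the three upper
categories.  The category probabilities are

    p_rarely = 1 - P (r^2 + r + 1)
    p_some   = P
    p_much   = P r
    p_most   = P r^2

so the upper three categories form a geometric progression with ratio ``r``
and the "rarely" category absorbs the remaining mass.  The model is valid
only while ``P (r^2 + r + 1) <= 1``; otherwise the implied "rarely"
probability would be negative.

Everything here is pure arithmetic; estimation from data lives in
:mod:`cesdexp.estimation`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ModelParams",
    "ResponseDistribution",
    "CrossingPoint",
    "InvalidParamsError",
    "category_probabilities",
    "expected_item_score",
    "validity_bound",
    "crossing_point",
    "CATEGORY_LABELS",
    "LIKERT_WEIGHTS",
    "BINARY_WEIGHTS",
]

#: Category labels in axis order; index 0..3 doubles as the Likert score.
CATEGORY_LABELS = ("rarely", "some", "much", "most")

#: Score assigned to each category under the two scoring methods.
LIKERT_WEIGHTS = (0.0, 1.0, 2.0, 3.0)
BINARY_WEIGHTS = (0.0, 1.0, 1.0, 1.0)


class InvalidParamsError(ValueError):
    """Raised when (P, r) lies outside the model's admissible region."""


@dataclass(frozen=True)
class ModelParams:
    """Parameter pair (P, r) of one item's category distribution.

    Parameters
    ----------
    P : float
        Probability of the "some" category; must satisfy ``0 < P`` and the
        validity constraint ``P (r^2 + r + 1) <= 1``.
    r : float
        Common ratio between successive upper-category probabilities;
        must be positive.
    """

    P: float
    r: float

    def __post_init__(self) -> None:
        if not (self.P > 0.0):
            raise InvalidParamsError(f"P must be positive, got {self.P}")
        if not (self.r > 0.0):
            raise InvalidParamsError(f"r must be positive, got {self.r}")
        s = self.r * self.r + self.r + 1.0
        if self.P * s > 1.0 + 1e-15:
            raise InvalidParamsError(
                f"invalid parameters: P*(r^2+r+1) = {self.P * s:.6g} > 1 "
                f"(P={self.P}, r={self.r})"
            )


@dataclass(frozen=True)
class ResponseDistribution:
    """Probabilities of the four ordered categories (sums to 1)."""

    p_rarely: float
    p_some: float
    p_much: float
    p_most: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p_rarely, self.p_some, self.p_much, self.p_most)


@dataclass(frozen=True)
class CrossingPoint:
    """Intersection of the rarely-to-some frequency segments.

    For a fixed ratio ``r``, the line segments joining
    (category 0, p_rarely) to (category 1, p_some) for *every* admissible
    ``P`` pass through one common point with ``0 < x < 1``.
    """

    x: float
    y: float


def category_probabilities(params: ModelParams) -> ResponseDistribution:
    """Category probabilities (rarely, some, much, most) implied by (P, r).

    Returns ``(1 - P(r^2+r+1), P, Pr, Pr^2)``.

    Examples
    --------
    >>> category_probabilities(ModelParams(0.2, 0.5)).as_tuple()
    (0.65, 0.2, 0.1, 0.05)
    """
    P, r = params.P, params.r
    p_some = P
    p_much = P * r
    p_most = P * r * r
    p_rarely = 1.0 - (p_some + p_much + p_most)
    # validity was checked at construction; clip the float dust at the boundary
    if p_rarely < 0.0:
        p_rarely = 0.0
    return ResponseDistribution(p_rarely, p_some, p_much, p_most)


def expected_item_score(params: ModelParams, method: str = "likert") -> float:
    """Expected score of one item under Likert (0-1-2-3) or binary (0-1-1-1).

    Likert expectation is ``P (3 r^2 + 2 r + 1)``; binary expectation is
    ``P (r^2 + r + 1)``, the probability of any non-"rarely" response.
    The Likert value always dominates: the difference is ``P (2 r^2 + r) >= 0``.
    """
    P, r = params.P, params.r
    if method == "likert":
        return P * (3.0 * r * r + 2.0 * r + 1.0)
    if method == "binary":
        return P * (r * r + r + 1.0)
    raise ValueError(f"unknown scoring method {method!r}; use 'likert' or 'binary'")


def validity_bound(r: float) -> float:
    """Largest admissible P for a given ratio r, i.e. ``1 / (r^2 + r + 1)``.

    At this bound the "rarely" probability is exactly zero.
    """
    if not (r > 0.0):
        raise InvalidParamsError(f"r must be positive, got {r}")
    return 1.0 / (r * r + r + 1.0)


def crossing_point(r: float) -> CrossingPoint:
    """Common intersection of all rarely-to-some segments sharing ratio r.

    On the category axis (rarely at 0, some at 1) the segment for a given P
    is the line ``y(x) = (1 - P s) + x (P - (1 - P s))`` with
    ``s = r^2 + r + 1``.  Setting the P-derivative to zero gives the point
    shared by all P::

        x = (r^2 + r + 1) / (r^2 + r + 2),   y = 1 / (r^2 + r + 2)

    so that ``x + y = 1``.
    """
    if not (r > 0.0):
        raise InvalidParamsError(f"r must be positive, got {r}")
    s = r * r + r + 1.0
    return CrossingPoint(x=s / (s + 1.0), y=1.0 / (s + 1.0))


def log_upper_probabilities(params: ModelParams) -> tuple[float, float, float]:
    """Natural logs of (p_some, p_much, p_most); collinear with slope log r."""
    P, r = params.P, params.r
    lp = math.log(P)
    lr = math.log(r)
    return (lp, lp + lr, lp + 2.0 * lr)
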