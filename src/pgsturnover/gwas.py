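"""Threshold model of GWA effect estimation.

A locus with true additive effect beta is assigned the estimate beta-hat =
beta when its allele count D in the GWA sample of n diploids falls strictly
inside the detection interval (d1, 2n - d2), and beta-hat = 0 otherwise.
Under the stationary Beta(a, a) law the allele count is beta-binomial, which
gives closed-form detection probabilities; the detection threshold itself
comes from the standard two-sided GWA power condition for an additive test
on a continuous trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import betaln, gammaln

from .wright_fisher import PopGenParams

__all__ = [
    "GwasDesign",
    "detection_prob",
    "prob_effect_detected",
    "effect_estimate",
    "miss_weight",
    "detected_weight",
    "solve_threshold",
    "NoSolutionError",
]


class NoSolutionError(ValueError):
    """The GWA study is underpowered for the requested effect at any frequency."""


@dataclass(frozen=True)
class GwasDesign:
    """GWA study design: size, per-locus detection thresholds, significance.

    ``d1`` and ``d2`` are allele-count thresholds (lower and upper side); a
    locus is detected iff its trait-increasing allele count D satisfies
    d1 < D < 2n - d2.  Scalars broadcast to all loci.
    """

    n: int
    d1: np.ndarray
    d2: np.ndarray
    alpha: float = 1e-8
    Vp: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "d1", np.atleast_1d(np.asarray(self.d1, dtype=int)))
        object.__setattr__(self, "d2", np.atleast_1d(np.asarray(self.d2, dtype=int)))
        if self.n <= 0:
            raise ValueError("study size n must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.Vp <= 0:
            raise ValueError("phenotypic variance must be positive")
        for d in (self.d1, self.d2):
            if np.any(d < 0) or np.any(d > self.n):
                raise ValueError("thresholds must be allele counts in [0, n]")

    @classmethod
    def symmetric(cls, n: int, d: int, **kwargs) -> "GwasDesign":
        return cls(n=n, d1=d, d2=d, **kwargs)

    @property
    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self.d1, self.d2))

    def thresholds(self, locus: int = 0) -> tuple[int, int]:
        d1 = int(self.d1[locus % self.d1.size] if self.d1.size > 1 else self.d1[0])
        d2 = int(self.d2[locus % self.d2.size] if self.d2.size > 1 else self.d2[0])
        return d1, d2


def detection_prob(params: PopGenParams, design: GwasDesign, d: int) -> float:
    """Lower-tail beta-binomial probability P^(d) = P(D < d) at stationarity.

    P^(d) = sum_{i=0}^{d-1} C(2n, i) B(a+i, a+2n-i) / B(a, a).
    """
    a = params.a
    two_n = 2 * design.n
    if d < 0 or d > two_n + 1:
        raise ValueError(f"d must lie in [0, 2n+1], got {d}")
    if d == 0:
        return 0.0
    i = np.arange(d, dtype=float)
    log_terms = (
        gammaln(two_n + 1)
        - gammaln(i + 1)
        - gammaln(two_n - i + 1)
        + betaln(a + i, a + two_n - i)
        - betaln(a, a)
    )
    return float(min(np.sum(np.exp(log_terms)), 1.0))


def prob_effect_detected(
    params: PopGenParams, design: GwasDesign, locus: int = 0
) -> float:
    """Probability the effect estimate is non-zero: P(d1 < D < 2n - d2).

    Equals 1 - P^(d1) - P^(d2) up to the boundary point masses at d1 and
    2n - d2 (negligible for the large-n regimes of interest, but the exact
    open-interval form is used so that d1 = d2 = n gives exactly 0).
    """
    d1, d2 = design.thresholds(locus)
    two_n = 2 * design.n
    lo, hi = d1 + 1, two_n - d2 - 1  # inclusive detected range
    if lo > hi:
        return 0.0
    return float(
        max(
            detection_prob(params, design, hi + 1)
            - detection_prob(params, design, lo),
            0.0,
        )
    )


def effect_estimate(D: int, design: GwasDesign, beta: float, locus: int = 0) -> float:
    """Threshold rule: beta if D in the open interval (d1, 2n - d2), else 0."""
    d1, d2 = design.thresholds(locus)
    return beta if d1 < D < 2 * design.n - d2 else 0.0


def miss_weight(design: GwasDesign, locus: int = 0) -> np.ndarray:
    """Indicator over D in {0..2n} that the locus is NOT detected."""
    two_n = 2 * design.n
    d1, d2 = design.thresholds(locus)
    w = np.zeros(two_n + 1)
    w[: d1 + 1] = 1.0
    w[two_n - d2 :] = 1.0
    return np.clip(w, 0.0, 1.0)


def detected_weight(design: GwasDesign, locus: int = 0) -> np.ndarray:
    """Indicator over D in {0..2n} that the locus IS detected."""
    return 1.0 - miss_weight(design, locus)


def solve_threshold(n: int, beta_sq: float, Vp: float = 1.0, alpha: float = 1e-8) -> int:
    """Allele-count detection threshold from the two-sided power condition.

    The additive association test on a continuous trait reaches two-sided
    significance alpha at the smallest sample frequency p satisfying
    ``2 n p (1 - p) beta^2 / Vp = z^2`` with z the standard-normal quantile
    at alpha / 2; the lower root is taken and d = round(2 n p).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if beta_sq <= 0 or Vp <= 0:
        raise ValueError("beta_sq and Vp must be positive")
    z = stats.norm.isf(alpha / 2.0)
    q = z * z * Vp / (2.0 * n * beta_sq)
    disc = 1.0 - 4.0 * q
    if disc < 0:
        raise NoSolutionError(
            f"study underpowered: 2n*p*(1-p)*beta^2/Vp < z^2 = {z * z:.3f} "
            f"for every frequency (n = {n}, beta^2 = {beta_sq}, Vp = {Vp}, "
            f"alpha = {alpha})"
        )
    p = 0.5 * (1.0 - np.sqrt(disc))
    return int(round(2.0 * n * p))
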