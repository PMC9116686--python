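"""Analytic error curves for out-of-sample polygenic scores under neutrality.

For a stationary neutral locus with symmetric recurrent mutation, every
statistic of the score of an individual sampled ``tau`` coalescent units in
the past reduces to a joint expectation of (i) an indicator on the GWA-sample
allele count D (whether the threshold estimator detects the locus) and
(ii) a polynomial of degree <= 2 in the ancient frequency Z_tau.  The exact
per-locus integrands follow from Hardy-Weinberg sampling with the symmetric
{-1, 0, 1} genotype encoding:

    E[X | Z = z]   = 2 z - 1
    Var[X | Z = z] = 2 z (1 - z)
    X-bar          = D / n - 1   (GWA-sample mean genotype)

so that, with ``miss = 1{beta-hat = 0}`` and ``det = 1 - miss``:

    bias_l(tau)  = beta   E[ miss * (D/n - 2 Z_tau) ]
    mse_l(tau)   = beta^2 E[ miss * (2 Z_tau (1 - Z_tau) + (2 Z_tau - D/n)^2) ]
    VA-hat_l(tau)= 2 (2 n_a - 1)/(2 n_a) beta^2 E[ det * Z_tau (1 - Z_tau) ]
    rho^2(tau)   = 2 E[ det * Z_tau (1 - Z_tau) ] / ( a/(2a+1) + sigma_e'^2 )

with sigma_e'^2 = sigma_e^2 / (L beta^2) the compound environmental variance
and a/(2a+1) = E[2 Z (1 - Z)] the stationary per-unit-effect additive
genetic variance.  Linear (small-tau) approximations and the e^(-tau)
relative-accuracy approximation are provided as explicit curve variants.
Each exact integrand is validated against Monte-Carlo and discrete-chain
oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gwas import GwasDesign, detected_weight, detection_prob, miss_weight
from .wright_fisher import PopGenParams, joint_expectation, stationary_moment

__all__ = [
    "TraitModel",
    "MetricCurve",
    "bias_curve",
    "mse_curve",
    "va_hat_curve",
    "rho2_curve",
    "relative_accuracy_curve",
    "heritability_to_sigma",
    "sigma_to_heritability",
    "expected_va_per_locus",
    "two_pop_to_tau",
]

METRICS = ("bias", "mse", "va_hat", "rho2", "relative_accuracy")
VARIANTS = ("exact", "linear_approx", "e_minus_tau")


@dataclass(frozen=True)
class TraitModel:
    """Additive trait: L iid loci of effect beta plus environmental noise.

    Exactly one of ``sigma_e_sq``, ``sigma_e_prime_sq`` or ``h2`` fixes the
    environmental variance; the others are derived.  ``sigma_e_prime_sq =
    sigma_e_sq / (L beta^2)`` and, at stationarity with scaled mutation rate
    a, ``h2 = (a/(2a+1)) / (a/(2a+1) + sigma_e_prime_sq)``.
    """

    L: int
    beta: float
    sigma_e_prime_sq: float

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.beta < 0:
            raise ValueError("beta must be >= 0 (trait-increasing allele is A2)")
        if self.sigma_e_prime_sq < 0:
            raise ValueError("environmental variance must be >= 0")

    @classmethod
    def from_h2(cls, L: int, beta: float, h2: float, a: float) -> "TraitModel":
        return cls(L=L, beta=beta, sigma_e_prime_sq=heritability_to_sigma(a, h2))

    @classmethod
    def from_sigma_e_sq(cls, L: int, beta: float, sigma_e_sq: float) -> "TraitModel":
        if beta == 0:
            raise ValueError("beta must be > 0 to normalize the environmental variance")
        return cls(L=L, beta=beta, sigma_e_prime_sq=sigma_e_sq / (L * beta**2))

    @property
    def sigma_e_sq(self) -> float:
        return self.sigma_e_prime_sq * self.L * self.beta**2

    def h2(self, a: float) -> float:
        return sigma_to_heritability(a, self.sigma_e_prime_sq)


@dataclass(frozen=True)
class MetricCurve:
    """A metric evaluated on a grid of ancient sampling times."""

    tau_grid: np.ndarray
    values: np.ndarray
    metric: str
    variant: str
    per_locus: bool
    params_snapshot: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau_grid, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if tau.shape != val.shape:
            raise ValueError("tau_grid and values must have equal length")
        if np.any(np.diff(tau) < 0):
            raise ValueError("tau_grid must be sorted ascending")
        if np.any(tau < 0):
            raise ValueError("sampling times must be >= 0")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        object.__setattr__(self, "tau_grid", tau)
        object.__setattr__(self, "values", val)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau": self.tau_grid,
                "metric": self.metric,
                "variant": self.variant,
                "per_locus": self.per_locus,
                "value": self.values,
            }
        )


def expected_va_per_locus(a: float, beta: float = 1.0) -> float:
    """Stationary expected per-locus additive genetic variance.

    E[V_Al] = E[2 beta^2 Z (1 - Z)] = beta^2 a / (2a + 1).
    """
    return beta**2 * a / (2.0 * a + 1.0)


def heritability_to_sigma(a: float, h2: float) -> float:
    """Compound environmental variance from narrow-sense heritability.

    sigma_e'^2 = (a / (2a + 1)) (1 - h2) / h2.
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError(f"h2 must lie in (0, 1], got {h2}")
    return (a / (2.0 * a + 1.0)) * (1.0 - h2) / h2


def sigma_to_heritability(a: float, sigma_e_prime_sq: float) -> float:
    """Inverse of :func:`heritability_to_sigma`; round-trips exactly."""
    va = a / (2.0 * a + 1.0)
    return va / (va + sigma_e_prime_sq)


def two_pop_to_tau(tau_split: float, tau_prime: float) -> float:
    """Map the two-population scenario onto a single ancient sampling time.

    A sample taken ``tau_prime`` before present from a population that split
    from the GWA population ``tau_split`` ago is equivalent to an ancient
    sample from the GWA population at ``tau = 2 tau_split - tau_prime``.
    """
    if tau_split < 0:
        raise ValueError("tau_split must be >= 0")
    tau = 2.0 * tau_split - tau_prime
    if tau < 0:
        raise ValueError(
            "tau_prime may not exceed 2 * tau_split (sample older than the split path)"
        )
    return tau


def _snapshot(params, design, trait, **extra) -> dict:
    snap = {
        "a": params.a,
        "two_N": params.two_N,
        "n": design.n,
        "d1": int(design.d1[0]),
        "d2": int(design.d2[0]),
        "L": trait.L if trait is not None else None,
        "beta": trait.beta if trait is not None else None,
        "sigma_e_prime_sq": trait.sigma_e_prime_sq if trait is not None else None,
    }
    snap.update(extra)
    return snap


def _require_symmetric_design(design: GwasDesign, what: str) -> int:
    if not design.is_symmetric:
        raise ValueError(f"the {what} approximation assumes symmetric thresholds")
    return int(design.d1[0])


def bias_curve(
    params: PopGenParams,
    design: GwasDesign,
    trait: TraitModel,
    tau_grid: Sequence[float],
    variant: str = "exact",
    per_locus: bool = True,
    locus: int = 0,
) -> MetricCurve:
    """Expected score-minus-phenotype difference as a function of tau.

    Exact: beta * E[(X-bar - X(tau)) 1{beta-hat = 0}] evaluated via the
    spectral joint expectation with X-bar = D/n - 1.  Approximation:
    beta (e^(-a tau) - 1)(P^(d1) - P^(d2)); identically zero for symmetric
    thresholds.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    beta = trait.beta
    n = design.n
    if variant == "exact":
        w_miss = miss_weight(design, locus)
        D = np.arange(2 * n + 1)
        w_miss_D = w_miss * D / n
        vals = np.array(
            [
                beta
                * (
                    joint_expectation(params, n, w_miss_D, [1.0], tau)
                    - joint_expectation(params, n, w_miss, [0.0, 2.0], tau)
                )
                for tau in tau_grid
            ]
        )
    elif variant == "linear_approx":
        d1, d2 = design.thresholds(locus)
        gap = detection_prob(params, design, d1) - detection_prob(params, design, d2)
        vals = beta * (np.exp(-params.a * tau_grid) - 1.0) * gap
    else:
        raise ValueError(f"bias has no {variant!r} variant")
    if not per_locus:
        vals = trait.L * vals
    return MetricCurve(
        tau_grid, vals, "bias", variant, per_locus, _snapshot(params, design, trait)
    )


def mse_curve(
    params: PopGenParams,
    design: GwasDesign,
    trait: TraitModel,
    tau_grid: Sequence[float],
    variant: str = "exact",
    per_locus: bool = True,
    locus: int = 0,
) -> MetricCurve:
    """Mean-squared prediction error as a function of tau.

    Exact per-locus form: beta^2 E[1{miss} ((X(tau) - X-bar)^2)], with the
    inner genotype expectation marginalized to 2 Z_tau (1 - Z_tau) +
    (2 Z_tau - D/n)^2.  The trait-wide curve adds ((n-1)/n) sigma_e^2.
    Linear approximation (symmetric d): mse_l(0) + 2 beta^2 a P^(d) tau.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    beta2 = trait.beta**2
    n = design.n

    def exact_at(tau: float) -> float:
        w_miss = miss_weight(design, locus)
        D = np.arange(2 * n + 1)
        # integrand in z: 2 z + 2 z^2 - (4 D / n) z + (D/n)^2
        t_poly = joint_expectation(params, n, w_miss, [0.0, 2.0, 2.0], tau)
        t_cross = joint_expectation(params, n, w_miss * 4.0 * D / n, [0.0, 1.0], tau)
        t_const = joint_expectation(params, n, w_miss * (D / n) ** 2, [1.0], tau)
        return beta2 * (t_poly - t_cross + t_const)

    if variant == "exact":
        vals = np.array([exact_at(tau) for tau in tau_grid])
    elif variant == "linear_approx":
        d = _require_symmetric_design(design, "mse linear")
        p_d = detection_prob(params, design, d)
        vals = exact_at(0.0) + 2.0 * beta2 * params.a * p_d * tau_grid
    else:
        raise ValueError(f"mse has no {variant!r} variant")
    if not per_locus:
        vals = trait.L * vals + ((n - 1) / n) * trait.sigma_e_sq
    return MetricCurve(
        tau_grid, vals, "mse", variant, per_locus, _snapshot(params, design, trait)
    )


def _detected_het_expectation(
    params: PopGenParams, design: GwasDesign, tau: float, locus: int = 0
) -> float:
    """E[1{detected} Z_tau (1 - Z_tau)], the kernel shared by va_hat and rho2.

    Computed via the complement so the beta-binomial sum runs over the small
    miss set: E[Z(1-Z)] at stationarity minus the miss-weighted expectation.
    """
    w_miss = miss_weight(design, locus)
    stat = stationary_moment(params, 1, 1)
    # E[g_tau(Z0)] over the full law is tau-independent (stationarity).
    return stat - joint_expectation(params, design.n, w_miss, [0.0, 1.0, -1.0], tau)


def va_hat_curve(
    params: PopGenParams,
    design: GwasDesign,
    trait: TraitModel,
    n_a: int,
    tau_grid: Sequence[float],
    variant: str = "exact",
    per_locus: bool = True,
    locus: int = 0,
) -> MetricCurve:
    """Expected estimated additive genetic variance in an ancient sample.

    Exact: 2 ((2 n_a - 1) / (2 n_a)) beta^2 E[1{detected} Z_tau (1 - Z_tau)],
    the finite-sample factor coming from estimating the ancient frequency
    from n_a diploids.  Approximation: VA-hat_l(0) - 2 ((2 n_a - 1)/(2 n_a))
    beta^2 a P^(d) tau.
    """
    if n_a < 2:
        raise ValueError("ancient sample size n_a must be >= 2")
    tau_grid = np.asarray(tau_grid, dtype=float)
    factor = 2.0 * (2 * n_a - 1) / (2 * n_a) * trait.beta**2
    if variant == "exact":
        vals = np.array(
            [factor * _detected_het_expectation(params, design, tau, locus) for tau in tau_grid]
        )
    elif variant == "linear_approx":
        d = _require_symmetric_design(design, "va_hat linear")
        p_d = detection_prob(params, design, d)
        v0 = factor * _detected_het_expectation(params, design, 0.0, locus)
        vals = v0 - factor * params.a * p_d * tau_grid
    else:
        raise ValueError(f"va_hat has no {variant!r} variant")
    if not per_locus:
        vals = trait.L * vals
    return MetricCurve(
        tau_grid, vals, "va_hat", variant, per_locus,
        _snapshot(params, design, trait, n_a=n_a),
    )


def rho2_curve(
    params: PopGenParams,
    design: GwasDesign,
    trait: TraitModel,
    tau_grid: Sequence[float],
    variant: str = "exact",
    locus: int = 0,
) -> MetricCurve:
    """Polygenic score accuracy rho^2(tau) (approximate expected sample r^2).

    Exact: rho^2(tau) = 2 E[1{detected} Z_tau (1 - Z_tau)] /
    (a/(2a+1) + sigma_e'^2); equal to h2 at tau = 0 under full detection.
    Linear approximation: rho^2(0) - 2 a P^(d) tau / (a/(2a+1) + sigma_e'^2).
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    denom = params.a / (2.0 * params.a + 1.0) + trait.sigma_e_prime_sq
    if denom <= 0.0:
        raise ValueError("degenerate trait: zero genetic and environmental variance")
    if variant == "exact":
        vals = np.array(
            [
                2.0 * _detected_het_expectation(params, design, tau, locus) / denom
                for tau in tau_grid
            ]
        )
    elif variant == "linear_approx":
        d = _require_symmetric_design(design, "accuracy linear")
        p_d = detection_prob(params, design, d)
        rho0 = 2.0 * _detected_het_expectation(params, design, 0.0, locus) / denom
        vals = rho0 - 2.0 * params.a * p_d * tau_grid / denom
    else:
        raise ValueError(f"rho2 has no {variant!r} variant")
    return MetricCurve(
        tau_grid, vals, "rho2", variant, False, _snapshot(params, design, trait)
    )


def relative_accuracy_curve(
    params: PopGenParams,
    design: GwasDesign,
    trait: TraitModel,
    tau_grid: Sequence[float],
    variant: str = "exact",
    locus: int = 0,
) -> MetricCurve:
    """Relative accuracy rho^2(tau) / rho^2(0).

    Insensitive to heritability (the tau-independent denominator cancels)
    and, for small mutation rates, well approximated by e^(-tau) — available
    as the ``e_minus_tau`` variant.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    if variant == "e_minus_tau":
        vals = np.exp(-tau_grid)
    elif variant == "exact":
        e0 = _detected_het_expectation(params, design, 0.0, locus)
        if e0 <= 0.0:
            raise ValueError("no detectable variance at tau = 0")
        vals = np.array(
            [_detected_het_expectation(params, design, tau, locus) / e0 for tau in tau_grid]
        )
    else:
        raise ValueError(f"relative accuracy has no {variant!r} variant")
    return MetricCurve(
        tau_grid, vals, "relative_accuracy", variant, False,
        _snapshot(params, design, trait),
    )
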