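"""Wright-Fisher diffusion machinery under symmetric recurrent mutation.

At stationarity the population allele frequency Z of a neutral bi-allelic
locus subject to recurrent mutation (rate ``mu`` per site per generation in
each direction) is Beta(a, a)-distributed, with ``a = 4*N*mu`` the
population-scaled mutation rate.  Time is measured in coalescent units
throughout: one unit equals ``2N`` generations, so a sampling time ``tau``
corresponds to ``round(tau * two_N)`` discrete generations.

Everything the error metrics of this package need reduces to expectations of
polynomials of degree <= 2 in the ancient frequency ``Z_tau``, jointly with a
weight on the present-day GWA-sample allele count ``D | Z_0 ~ Binom(2n, Z_0)``.
The transition density of the diffusion has a spectral representation in
polynomials orthonormal under the stationary beta law; projecting a
degree-<= 2 polynomial onto the first three eigenfunctions and scaling the
k-th coefficient by ``exp(-lambda_k * tau)`` therefore evaluates
``E[f(Z_tau) | Z_0]`` *exactly* (no series truncation).  The outer
expectation against the beta-binomially distributed allele count is a finite
sum of beta-function ratios, computed in log space.

A dense discrete Wright-Fisher chain (:class:`DiscreteWrightFisher`) serves
as the brute-force oracle for every analytic quantity in this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.special import betaln, gammaln

__all__ = [
    "PopGenParams",
    "SpectralTerm",
    "stationary_moment",
    "eigenvalue",
    "orthonormal_polynomials",
    "conditional_poly_moment",
    "propagate_polynomial",
    "joint_expectation",
    "weighted_frequency_moment",
    "DiscreteWrightFisher",
]

#: Largest chromosome count for which the dense oracle matrix is built.
MAX_ORACLE_TWO_N = 4000

#: Maximum polynomial degree handled by the finite spectral sum.  Every
#: metric in this package needs degree <= 2 only; this is an extension
#: point, not a tuning knob.
MAX_DEGREE = 2


class UnsupportedConfigurationError(ValueError):
    """Raised when an analytic routine is asked for an unsupported regime."""


@dataclass(frozen=True)
class PopGenParams:
    """Population-genetic parameters of a single neutral locus.

    Parameters
    ----------
    two_N
        Number of chromosomes (twice the diploid population size N).
    mu, nu
        Per-site per-generation mutation rates A1->A2 and A2->A1.  The
        analytic machinery requires ``mu == nu``; the discrete oracle and
        the forward simulator accept asymmetric rates.
    """

    two_N: int
    mu: float
    nu: float

    def __post_init__(self) -> None:
        if self.two_N <= 0:
            raise ValueError(f"two_N must be positive, got {self.two_N}")
        if not (0.0 <= self.mu <= 1.0 and 0.0 <= self.nu <= 1.0):
            raise ValueError("mutation rates must lie in [0, 1]")

    @classmethod
    def from_scaled(cls, a: float, two_N: int = 2000) -> "PopGenParams":
        """Construct symmetric-mutation parameters from ``a = 4*N*mu``."""
        if a <= 0:
            raise ValueError(f"scaled mutation rate a must be > 0, got {a}")
        mu = a / (2.0 * two_N)
        return cls(two_N=two_N, mu=mu, nu=mu)

    @property
    def symmetric(self) -> bool:
        return self.mu == self.nu

    @property
    def a(self) -> float:
        """Population-scaled mutation rate 4*N*mu (symmetric case only)."""
        if not self.symmetric:
            raise UnsupportedConfigurationError(
                "scaled rate a is defined for symmetric mutation (mu == nu)"
            )
        a = 2.0 * self.two_N * self.mu
        if a <= 0:
            raise ValueError("a must be > 0 for a proper stationary law")
        return a

    def _require_symmetric(self) -> float:
        if not self.symmetric:
            raise UnsupportedConfigurationError(
                "analytic results require equal mutation rates (mu == nu)"
            )
        return self.a


@dataclass(frozen=True)
class SpectralTerm:
    """One component of the spectral expansion.

    ``poly_coeffs`` are monomial coefficients (ascending powers of z) of the
    k-th polynomial orthonormal under the Beta(a, a) stationary weight;
    ``eigenvalue`` is its decay rate lambda_k in coalescent time units.
    """

    k: int
    eigenvalue: float
    poly_coeffs: np.ndarray


def stationary_moment(params: PopGenParams, j: int, k: int = 0) -> float:
    """E[Z^j (1-Z)^k] under the symmetric Beta(a, a) stationary law.

    Closed form via beta-function ratios: B(a+j, a+k) / B(a, a).
    """
    a = params._require_symmetric()
    if j < 0 or k < 0:
        raise ValueError("moment orders must be non-negative")
    return float(np.exp(betaln(a + j, a + k) - betaln(a, a)))


def eigenvalue(params: PopGenParams, k: int) -> float:
    """Decay rate lambda_k = k (k - 1 + 2a) / 2 of the k-th eigenfunction.

    Time unit: 2N generations.  lambda_0 = 0 (stationarity), lambda_1 = a
    (decay of E[Z] - 1/2), lambda_2 = 1 + 2a (heterozygosity-type decay).
    Validated against the discrete-chain oracle in the test suite.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    a = params._require_symmetric()
    return 0.5 * k * (k - 1 + 2.0 * a)


def _moment_vector(params: PopGenParams, max_order: int) -> np.ndarray:
    """Raw stationary moments E[Z^j] for j = 0..max_order."""
    return np.array([stationary_moment(params, j) for j in range(max_order + 1)])


def orthonormal_polynomials(params: PopGenParams) -> list[SpectralTerm]:
    """Polynomials of degree 0..2 orthonormal under the stationary law.

    Built by Gram-Schmidt on the monomial basis using the closed-form beta
    moments; exact up to floating point.
    """
    m = _moment_vector(params, 2 * MAX_DEGREE)
    basis: list[np.ndarray] = []  # monomial coeff arrays, length MAX_DEGREE+1

    def inner(p: np.ndarray, q: np.ndarray) -> float:
        # <p, q> = sum_{i,j} p_i q_j E[Z^{i+j}]
        prod = np.outer(p, q)
        idx = np.add.outer(np.arange(p.size), np.arange(q.size))
        return float(np.sum(prod * m[idx]))

    terms = []
    for k in range(MAX_DEGREE + 1):
        p = np.zeros(MAX_DEGREE + 1)
        p[k] = 1.0
        for q in basis:
            p = p - inner(p, q) * q
        norm = np.sqrt(inner(p, p))
        p = p / norm
        basis.append(p)
        terms.append(SpectralTerm(k=k, eigenvalue=eigenvalue(params, k), poly_coeffs=p))
    return terms


def _as_coeffs(poly) -> np.ndarray:
    """Coerce a polynomial spec (scalar, sequence, np.polynomial) to monomial coeffs."""
    if np.isscalar(poly):
        coeffs = np.array([float(poly)])
    elif isinstance(poly, np.polynomial.Polynomial):
        coeffs = np.asarray(poly.coef, dtype=float)
    else:
        coeffs = np.asarray(poly, dtype=float)
    if coeffs.ndim != 1 or coeffs.size == 0:
        raise ValueError("polynomial must be a 1-D coefficient sequence")
    coeffs = np.trim_zeros(coeffs, "b")
    if coeffs.size == 0:
        coeffs = np.zeros(1)
    if coeffs.size - 1 > MAX_DEGREE:
        raise UnsupportedConfigurationError(
            f"polynomials of degree > {MAX_DEGREE} are not supported"
        )
    out = np.zeros(MAX_DEGREE + 1)
    out[: coeffs.size] = coeffs
    return out


def propagate_polynomial(params: PopGenParams, poly, tau: float) -> np.ndarray:
    """Monomial coefficients of z0 -> E[f(Z_tau) | Z_0 = z0].

    Projects ``f`` onto the orthonormal polynomials, scales the k-th
    coefficient by exp(-lambda_k * tau), and re-expands in the monomial
    basis.  Exact for deg(f) <= 2.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    coeffs = _as_coeffs(poly)
    m = _moment_vector(params, 2 * MAX_DEGREE)
    out = np.zeros(MAX_DEGREE + 1)
    for term in orthonormal_polynomials(params):
        prod = np.outer(coeffs, term.poly_coeffs)
        idx = np.add.outer(np.arange(coeffs.size), np.arange(term.poly_coeffs.size))
        c_k = float(np.sum(prod * m[idx]))
        out += c_k * np.exp(-term.eigenvalue * tau) * term.poly_coeffs
    return out


def conditional_poly_moment(params: PopGenParams, poly, z0: float, tau: float) -> float:
    """E[f(Z_tau) | Z_0 = z0] for a polynomial f of degree <= 2."""
    if not (0.0 <= z0 <= 1.0):
        raise ValueError("z0 must lie in [0, 1]")
    g = propagate_polynomial(params, poly, tau)
    return float(np.polynomial.polynomial.polyval(z0, g))


def weighted_frequency_moment(
    params: PopGenParams, n: int, weight: np.ndarray, j: int
) -> float:
    """E[w(D) * Z_0^j] with D | Z_0 ~ Binomial(2n, Z_0) at stationarity.

    Each term is a beta-binomial probability with the first shape parameter
    shifted by j: w_D * C(2n, D) * B(a + D + j, a + 2n - D) / B(a, a).
    Computed in log space over the support of ``weight`` only.
    """
    a = params._require_symmetric()
    two_n = 2 * n
    weight = np.asarray(weight, dtype=float)
    if weight.shape != (two_n + 1,):
        raise ValueError(
            f"weight must have length 2n+1 = {two_n + 1}, got {weight.shape}"
        )
    support = np.nonzero(weight)[0]
    if support.size == 0:
        return 0.0
    d = support.astype(float)
    log_terms = (
        gammaln(two_n + 1)
        - gammaln(d + 1)
        - gammaln(two_n - d + 1)
        + betaln(a + d + j, a + two_n - d)
        - betaln(a, a)
    )
    return float(np.sum(weight[support] * np.exp(log_terms)))


def joint_expectation(
    params: PopGenParams, n: int, weight: np.ndarray, poly, tau: float
) -> float:
    """E[w(D) * f(Z_tau)] for the stationary reversible diffusion.

    ``D`` is the allele count in a present-day sample of ``n`` diploids
    (binomial given Z_0); ``Z_tau`` is the frequency ``tau`` coalescent
    units in the past.  ``D`` and ``Z_tau`` are conditionally independent
    given Z_0, so the inner expectation reduces to a degree-<= 2 polynomial
    in Z_0 with tau-dependent coefficients, and the outer expectation is a
    finite beta-binomial sum.  Closed form; no numerical integration.
    """
    g = propagate_polynomial(params, poly, tau)
    return float(
        sum(
            g[j] * weighted_frequency_moment(params, n, weight, j)
            for j in range(g.size)
            if g[j] != 0.0
        )
    )


# ---------------------------------------------------------------------------
# Discrete-chain brute-force oracle
# ---------------------------------------------------------------------------


class DiscreteWrightFisher:
    """Dense discrete Wright-Fisher chain: the ground-truth oracle.

    One generation = deterministic genic selection (genotypic fitnesses
    1 : 1+s : 1+2s) and mutation applied to the allele frequency, followed
    by binomial resampling of ``two_N`` chromosomes.  All analytic spectral
    results are validated against matrix computations on this chain.
    """

    def __init__(self, two_N: int, mu: float, nu: float, s: float = 0.0):
        if two_N > MAX_ORACLE_TWO_N:
            raise ValueError(
                f"two_N = {two_N} exceeds the dense-oracle guard "
                f"({MAX_ORACLE_TWO_N}); use the forward simulator instead"
            )
        self.two_N = int(two_N)
        self.mu = float(mu)
        self.nu = float(nu)
        self.s = float(s)
        self.grid = np.arange(self.two_N + 1) / self.two_N
        self._T: np.ndarray | None = None

    def expected_offspring_frequency(self, z: np.ndarray) -> np.ndarray:
        """Deterministic selection + mutation update of the frequency."""
        z = np.asarray(z, dtype=float)
        if self.s != 0.0:
            s = self.s
            w_bar = z**2 * (1 + 2 * s) + 2 * z * (1 - z) * (1 + s) + (1 - z) ** 2
            z = (z**2 * (1 + 2 * s) + z * (1 - z) * (1 + s)) / w_bar
        return z * (1.0 - self.nu) + (1.0 - z) * self.mu

    @property
    def transition_matrix(self) -> np.ndarray:
        """(two_N+1) x (two_N+1) one-generation transition matrix (rows sum to 1)."""
        if self._T is None:
            from scipy.stats import binom

            p_star = self.expected_offspring_frequency(self.grid)
            counts = np.arange(self.two_N + 1)
            # row i: Binomial(two_N, p_star[i]) pmf over counts
            self._T = binom.pmf(counts[None, :], self.two_N, p_star[:, None])
        return self._T

    def matrix_power(self, generations: int) -> np.ndarray:
        if generations < 0:
            raise ValueError("generations must be >= 0")
        return np.linalg.matrix_power(self.transition_matrix, generations)

    def evolve_distribution(self, dist: np.ndarray, generations: int) -> np.ndarray:
        """Push a distribution over allele counts forward ``generations`` steps."""
        v = np.asarray(dist, dtype=float)
        T = self.transition_matrix
        for _ in range(generations):
            v = v @ T
        return v

    def conditional_expectation(self, fvals: np.ndarray, generations: int) -> np.ndarray:
        """E[f(Z_g) | Z_0 = grid] for every starting state, by backward iteration."""
        u = np.asarray(fvals, dtype=float)
        T = self.transition_matrix
        for _ in range(generations):
            u = T @ u
        return u

    def stationary_distribution(self) -> np.ndarray:
        """Stationary law of the chain via a dense linear solve.

        Solves pi (T - I) = 0 with the normalization sum(pi) = 1 replacing
        one equation.  Requires mutation in both directions (irreducibility).
        """
        if self.mu <= 0.0 or self.nu <= 0.0:
            raise ValueError("stationary distribution requires mu, nu > 0")
        K = self.two_N + 1
        A = self.transition_matrix.T - np.eye(K)
        A[-1, :] = 1.0
        b = np.zeros(K)
        b[-1] = 1.0
        pi = lu_solve(lu_factor(A), b)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def generations_for_tau(self, tau: float) -> int:
        """Coalescent time -> generations: one unit is two_N generations.

        Calibrated by the k = 1 spectral mode: the chain's per-generation
        decay of E[Z] - 1/2 is (1 - mu - nu), and (1 - 2 mu)^(tau * two_N)
        ~= exp(-a tau) for a = 2 * two_N * mu.
        """
        if tau < 0:
            raise ValueError("tau must be >= 0")
        return int(round(tau * self.two_N))
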