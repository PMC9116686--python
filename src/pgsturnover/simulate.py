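"""Forward Wright-Fisher simulator with genic selection and a threshold GWA study.

Each replicate simulates L unlinked loci of a fully additive trait through
discrete Wright-Fisher dynamics: frequencies start at the neutral stationary
law, evolve neutrally, and — if selection is configured — evolve under genic
selection (genotypic fitnesses 1 : 1+s : 1+2s per copy of the
trait-increasing allele) for the final ``tau_s`` coalescent units before the
present.  A GWA study of n diploids is conducted on the present-day
frequencies using the threshold estimator; samples of n_a diploids are drawn
at each requested ancient time, scored with the estimated effects, and the
replicate-level bias, mse, sample r^2 and estimated additive genetic
variance are recorded.

One coalescent unit is ``two_N`` generations; a sampling time tau maps to
``round(tau * two_N)`` generations before present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import heritability_to_sigma
from .wright_fisher import DiscreteWrightFisher, MAX_ORACLE_TWO_N

__all__ = [
    "SimConfig",
    "SimReplicate",
    "stationary_initial_frequencies",
    "simulate_trajectories",
    "run_gwas",
    "sample_ancient",
    "replicate_stats",
    "simulate_replicate",
    "run_study",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation study.

    ``sigma = 4 N s = 2 * two_N * s`` is the population-scaled selection
    coefficient of the trait-increasing allele; ``tau_s`` is the onset of
    selection (coalescent units before present, 0 = never under selection
    when sigma = 0).  ``beneficial_increases_trait=False`` flips which
    allele is favoured, changing only the sign of the bias.
    """

    two_N: int = 2000
    L: int = 5000
    a: float = 1e-3
    sigma: float = 0.0
    tau_s: float = 0.5
    span: float = 1.0
    tau_grid: tuple = (0.0, 0.2, 0.5, 1.0)
    n: int = 100_000
    n_a: int = 100
    d1: int = 10_000
    d2: int = 10_000
    beta: float = 0.1
    h2: float = 0.5
    K: int = 5000
    seed: int = 0
    beneficial_increases_trait: bool = True

    def __post_init__(self) -> None:
        if self.two_N <= 0 or self.L <= 0 or self.K <= 0:
            raise ValueError("two_N, L and K must be positive")
        if self.a <= 0:
            raise ValueError("scaled mutation rate a must be > 0")
        if not (0.0 <= self.tau_s <= self.span):
            raise ValueError("selection onset tau_s must lie in [0, span]")
        if any(t < 0 or t > self.span for t in self.tau_grid):
            raise ValueError("tau_grid must lie within [0, span]")
        if self.n_a < 2:
            raise ValueError("ancient sample size n_a must be >= 2")
        if not (0 <= self.d1 <= self.n and 0 <= self.d2 <= self.n):
            raise ValueError("detection thresholds must be allele counts in [0, n]")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("h2 must lie in (0, 1]")
        object.__setattr__(self, "tau_grid", tuple(sorted(self.tau_grid)))

    @property
    def mu(self) -> float:
        return self.a / (2.0 * self.two_N)

    @property
    def s(self) -> float:
        """Per-copy fitness advantage: sigma = 2 * two_N * s."""
        return self.sigma / (2.0 * self.two_N)

    @property
    def sigma_e_sq(self) -> float:
        """Environmental variance implied by h2 at neutral stationarity."""
        return heritability_to_sigma(self.a, self.h2) * self.L * self.beta**2


@dataclass
class SimReplicate:
    """Outputs of a single replicate."""

    freq_paths: dict  # tau -> (L,) frequencies (tau = 0.0 is the present)
    D: np.ndarray  # (L,) GWA allele counts
    beta_hat: np.ndarray  # (L,) estimated effects
    C_hat: float
    ancient_genotypes: dict  # tau -> (n_a, L) in {-1, 0, 1}
    phenotypes: dict  # tau -> (n_a,)
    scores: dict  # tau -> (n_a,)
    stats: pd.DataFrame  # one row per tau: bias, mse, r2, va_hat


def stationary_initial_frequencies(
    config: SimConfig, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Draw initial allele counts / two_N from the neutral stationary law.

    For populations small enough for the dense chain, the exact discrete
    stationary distribution is used (removes O(1/N) initialization bias in
    oracle comparisons); otherwise frequencies are drawn from Beta(a, a),
    rounded to the frequency grid, and burned in for min(10/a, 20*two_N)
    neutral generations.
    """
    if config.two_N <= MAX_ORACLE_TWO_N:
        chain = DiscreteWrightFisher(config.two_N, config.mu, config.mu)
        pi = chain.stationary_distribution()
        counts = rng.choice(config.two_N + 1, p=pi, size=size)
        return counts / config.two_N
    z = rng.beta(config.a, config.a, size=size)
    counts = np.round(z * config.two_N).astype(np.int64)
    burn = int(min(10.0 / config.a, 20.0 * config.two_N))
    for _ in range(burn):
        p_star = counts / config.two_N * (1 - config.mu) + (
            1 - counts / config.two_N
        ) * config.mu
        counts = rng.binomial(config.two_N, p_star)
    return counts / config.two_N


def _one_generation(
    counts: np.ndarray, config: SimConfig, with_selection: bool, rng: np.random.Generator
) -> np.ndarray:
    """Selection -> mutation -> binomial drift on an array of allele counts."""
    z = counts / config.two_N
    if with_selection and config.s != 0.0:
        s = config.s
        w_bar = z**2 * (1 + 2 * s) + 2 * z * (1 - z) * (1 + s) + (1 - z) ** 2
        z = (z**2 * (1 + 2 * s) + z * (1 - z) * (1 + s)) / w_bar
    z = z * (1.0 - config.mu) + (1.0 - z) * config.mu
    return rng.binomial(config.two_N, z)


def simulate_trajectories(
    config: SimConfig, rng: np.random.Generator, z0: np.ndarray | None = None
) -> dict:
    """Simulate L loci over ``span`` coalescent units; record at each tau.

    The population evolves neutrally from stationarity until the onset of
    selection at ``tau_s`` before present, then under genic selection with
    the configured ``sigma``.  Returns {tau: frequencies at tau}, including
    tau = 0.0 (the present).
    """
    total_gen = int(round(config.span * config.two_N))
    sel_gen = int(round(config.tau_s * config.two_N)) if config.sigma != 0.0 else 0
    record_at = {int(round(t * config.two_N)): float(t) for t in set(config.tau_grid) | {0.0}}
    if z0 is None:
        z0 = stationary_initial_frequencies(config, rng, config.L)
    counts = np.round(np.asarray(z0) * config.two_N).astype(np.int64)

    paths: dict = {}
    for gen_before_present in range(total_gen, -1, -1):
        if gen_before_present in record_at:
            paths[record_at[gen_before_present]] = counts / config.two_N
        if gen_before_present == 0:
            break
        with_selection = gen_before_present <= sel_gen
        counts = _one_generation(counts, config, with_selection, rng)
    return paths


def run_gwas(
    freqs_at_present: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Threshold-model GWA study on the present-day frequencies.

    The allele count of a Hardy-Weinberg sample of n diploids is
    D ~ Binomial(2n, z) per locus; the mean genotype is X-bar = D/n - 1
    exactly, and the mean phenotype needs only X-bar and the mean
    environmental noise ~ N(0, sigma_e^2 / n).  Returns
    (D, beta_hat, X_bar, C_hat).
    """
    z = np.asarray(freqs_at_present, dtype=float)
    two_n = 2 * config.n
    D = rng.binomial(two_n, z)
    X_bar = D / config.n - 1.0
    detected = (D > config.d1) & (D < two_n - config.d2)
    beta_signed = config.beta if config.beneficial_increases_trait else -config.beta
    beta_vec = np.full(config.L, beta_signed)
    beta_hat = np.where(detected, beta_vec, 0.0)
    eps_bar = rng.normal(0.0, np.sqrt(config.sigma_e_sq / config.n))
    Y_bar = float(beta_vec @ X_bar) + eps_bar  # C = 0
    C_hat = Y_bar - float(beta_hat @ X_bar)
    return D, beta_hat, X_bar, C_hat


def sample_ancient(
    freqs_at_tau: np.ndarray,
    config: SimConfig,
    beta_hat: np.ndarray,
    C_hat: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hardy-Weinberg sample of n_a ancient diploids, phenotyped and scored."""
    z = np.asarray(freqs_at_tau, dtype=float)
    X = rng.binomial(2, z, size=(config.n_a, config.L)) - 1
    beta_signed = config.beta if config.beneficial_increases_trait else -config.beta
    eps = rng.normal(0.0, np.sqrt(config.sigma_e_sq), size=config.n_a)
    phenotypes = X @ np.full(config.L, beta_signed) + eps  # C = 0
    scores = C_hat + X @ beta_hat
    return X, phenotypes, scores


def replicate_stats(
    scores: np.ndarray, phenotypes: np.ndarray, genotypes: np.ndarray, beta_hat: np.ndarray
) -> dict:
    """Per-replicate (bias, mse, r2, va_hat) for one ancient sample.

    r2 is the squared Pearson correlation of scores and phenotypes over the
    n_a individuals (NaN when the score has zero variance — e.g., no locus
    detected); va_hat = 2 sum beta_hat^2 Z-hat (1 - Z-hat) with Z-hat the
    ancient-sample allele frequency.
    """
    err = scores - phenotypes
    z_hat = (genotypes + 1).mean(axis=0) / 2.0
    va_hat = float(2.0 * np.sum(beta_hat**2 * z_hat * (1.0 - z_hat)))
    if np.ptp(scores) == 0.0 or np.ptp(phenotypes) == 0.0:
        r2 = np.nan
    else:
        r2 = float(np.corrcoef(scores, phenotypes)[0, 1] ** 2)
    return {
        "bias": float(err.mean()),
        "mse": float((err**2).mean()),
        "r2": r2,
        "va_hat": va_hat,
    }


def simulate_replicate(config: SimConfig, rng: np.random.Generator) -> SimReplicate:
    """One full replicate: trajectories, GWA study, ancient samples, stats."""
    paths = simulate_trajectories(config, rng)
    D, beta_hat, X_bar, C_hat = run_gwas(paths[0.0], config, rng)
    genotypes, phenotypes, scores = {}, {}, {}
    rows = []
    for tau in config.tau_grid:
        X, phen, sc = sample_ancient(paths[float(tau)], config, beta_hat, C_hat, rng)
        genotypes[tau], phenotypes[tau], scores[tau] = X, phen, sc
        rows.append({"tau": tau, **replicate_stats(sc, phen, X, beta_hat)})
    return SimReplicate(
        freq_paths=paths,
        D=D,
        beta_hat=beta_hat,
        C_hat=C_hat,
        ancient_genotypes=genotypes,
        phenotypes=phenotypes,
        scores=scores,
        stats=pd.DataFrame(rows),
    )


def run_study(config: SimConfig, progress: bool = False) -> pd.DataFrame:
    """K replicates, averaged: one row per tau with means and standard errors.

    All randomness flows from ``config.seed`` through per-replicate spawned
    generators, so identical configs give bit-identical results.  Replicates
    with undefined r2 (zero score variance) are excluded from the r2 average
    and counted in ``r2_excluded``.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.K)
    frames = []
    for k, ss in enumerate(seeds):
        rep = simulate_replicate(config, np.random.default_rng(ss))
        frames.append(rep.stats.assign(replicate=k))
        if progress and (k + 1) % 50 == 0:
            print(f"  replicate {k + 1}/{config.K}", flush=True)
    all_stats = pd.concat(frames, ignore_index=True)

    def agg(group: pd.DataFrame) -> pd.Series:
        out = {}
        for stat in ("bias", "mse", "r2", "va_hat"):
            vals = group[stat].to_numpy()
            ok = ~np.isnan(vals)
            out[f"{stat}_mean"] = vals[ok].mean() if ok.any() else np.nan
            out[f"{stat}_se"] = (
                vals[ok].std(ddof=1) / np.sqrt(ok.sum()) if ok.sum() > 1 else np.nan
            )
        out["r2_excluded"] = int(np.isnan(group["r2"].to_numpy()).sum())
        out["K"] = len(group)
        return pd.Series(out)

    summary = (
        all_stats.groupby("tau", sort=True).apply(agg, include_groups=False).reset_index()
    )
    summary.insert(1, "sigma", config.sigma)
    summary.insert(2, "d", config.d1)
    return summary
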