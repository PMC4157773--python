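"""Synthetic metapopulation data with recorded ground truth.

Generates census histories, inter-site distances, demographic factors and
microsatellite genotypes with exactly the statistical structure the F-model
assumes, so that every pipeline stage can be tested end-to-end with known
generating parameters:

* occupancy flips by annual extinction/colonisation Bernoulli events (the
  study system turns over at roughly 5-20% of sites per year);
* occupied-site counts are shifted-Poisson (>= 1 plant);
* sites sit on a line network (roadside habitat) with configurable spacing;
* each population's logit differentiation is a linear function of its
  factors plus Gaussian noise, ``y_j = alpha0 + G_j beta + N(0, sigma2)``,
  ``F_ST,j = logistic(y_j)``, ``theta_j = (1 - F_ST,j)/F_ST,j``;
* genotypes follow the Balding-Nichols construction: ancestral frequencies
  ``p_i ~ Dirichlet(1, ..., 1)``, population frequencies
  ``~ Dirichlet(theta_j p_i)``, and diploid individuals are random unions
  of two gene copies.

Default dimensions mirror the study: 33 populations, 8 loci, about 730
diploid plants, a 21-year census.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .census import CensusTable, ConnectivityConfig, DistanceSource, feature_table
from .fmodel import FactorMatrix
from .genepop import GenotypeTable


@dataclass
class SyntheticTruth:
    """Generating parameters recorded for parameter-recovery tests."""

    seed: int
    alpha0: float
    beta: list
    sigma2: float
    theta: list
    fst: list
    factor_names: list
    p_colonize: float
    p_extinct: float
    growth_mean: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def simulate_census(
    n_sites: int = 100,
    n_years: int = 21,
    p_colonize: float = 0.1,
    p_extinct: float = 0.1,
    growth_mean: float = 8.0,
    seed: int = 0,
    first_year: int = 1988,
    p_initial: float | None = None,
) -> CensusTable:
    """Simulate an annual census with extinction/colonisation turnover.

    Each empty site colonises with probability ``p_colonize`` per year and
    each occupied site goes extinct with probability ``p_extinct``; occupied
    sites hold ``1 + Poisson(growth_mean - 1)`` plants.  ``p_initial``
    defaults to the stationary occupancy ``p_colonize / (p_colonize +
    p_extinct)``.
    """
    for name, v in (("p_colonize", p_colonize), ("p_extinct", p_extinct)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if n_years < 2:
        raise ValueError("need at least 2 census years")
    if growth_mean < 1:
        raise ValueError("growth_mean must be >= 1 plant")
    rng = np.random.default_rng(seed)
    if p_initial is None:
        denom = p_colonize + p_extinct
        p_initial = p_colonize / denom if denom > 0 else 0.0
    occupied = rng.uniform(size=n_sites) < p_initial
    counts = np.zeros((n_sites, n_years), dtype=np.int64)
    for t in range(n_years):
        if t > 0:
            flip = rng.uniform(size=n_sites)
            occupied = np.where(occupied, flip >= p_extinct, flip < p_colonize)
        counts[occupied, t] = 1 + rng.poisson(growth_mean - 1.0, size=int(occupied.sum()))
    return CensusTable(
        [f"site_{i + 1}" for i in range(n_sites)],
        list(range(first_year, first_year + n_years)),
        counts,
    )


def line_network_distances(site_ids, spacing: float = 250.0, seed: int = 0) -> DistanceSource:
    """Place sites along a line (roadside habitat) with jittered spacing."""
    rng = np.random.default_rng(seed)
    gaps = spacing * (0.5 + rng.uniform(size=len(site_ids)))
    pos = np.cumsum(gaps)
    d = np.abs(pos[:, None] - pos[None, :])
    return DistanceSource(list(site_ids), matrix=d)


def simulate_factors_and_theta(
    factors: FactorMatrix,
    alpha0: float,
    beta,
    sigma2: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-population theta from the logit-linear factor model.

    Returns ``(y, theta)`` where ``y_j = alpha0 + G_j beta + N(0, sigma2)``
    is the logit F_ST and ``theta_j = (1 - F_ST,j) / F_ST,j = exp(-y_j)``.
    """
    beta = np.asarray(beta, dtype=float)
    if factors.values.shape[1] != len(beta):
        raise ValueError("beta length must match factor count")
    rng = np.random.default_rng(seed)
    y = (
        alpha0
        + factors.values @ beta
        + np.sqrt(sigma2) * rng.standard_normal(len(factors.populations))
    )
    return y, np.exp(-y)


def simulate_genotypes(
    theta,
    n_loci: int = 8,
    alleles_per_locus=None,
    diploids_per_pop: int = 22,
    seed: int = 0,
    population_ids=None,
) -> GenotypeTable:
    """Balding-Nichols genotypes for populations with given theta.

    ``alleles_per_locus`` may be an int, a sequence of length ``n_loci``,
    or None (default: drawn uniformly from 2-16, mimicking typical
    microsatellite allele counts).  ``diploids_per_pop`` may be an int or a
    per-population sequence.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("all theta must be positive")
    J = len(theta)
    rng = np.random.default_rng(seed)
    if alleles_per_locus is None:
        alleles_per_locus = rng.integers(2, 17, size=n_loci)
    elif np.isscalar(alleles_per_locus):
        alleles_per_locus = np.full(n_loci, int(alleles_per_locus))
    else:
        alleles_per_locus = np.asarray(alleles_per_locus, dtype=int)
        if len(alleles_per_locus) != n_loci:
            raise ValueError("alleles_per_locus length must equal n_loci")
    if np.isscalar(diploids_per_pop):
        n_ind = np.full(J, int(diploids_per_pop))
    else:
        n_ind = np.asarray(diploids_per_pop, dtype=int)
    if population_ids is None:
        population_ids = [f"pop_{j + 1}" for j in range(J)]

    total = int(n_ind.sum())
    calls = np.zeros((total, n_loci, 2), dtype=np.int64)
    for li in range(n_loci):
        K = int(alleles_per_locus[li])
        p_anc = rng.dirichlet(np.ones(K))
        row = 0
        for j in range(J):
            p_pop = rng.dirichlet(theta[j] * p_anc)
            draws = rng.choice(K, size=(n_ind[j], 2), p=p_pop) + 1
            calls[row : row + n_ind[j], li, :] = draws
            row += n_ind[j]
    ids, pops = [], []
    for j in range(J):
        for k in range(n_ind[j]):
            ids.append(f"{population_ids[j]}_ind{k + 1}")
            pops.append(population_ids[j])
    loci = [f"locus_{i + 1}" for i in range(n_loci)]
    return GenotypeTable(ids, pops, loci, calls)


@dataclass
class BundleConfig:
    """Dimensions and generating parameters for a full synthetic study."""

    n_populations: int = 33
    n_loci: int = 8
    diploids_per_pop: int = 22
    n_years: int = 21
    n_sites: int = 100
    p_colonize: float = 0.1
    p_extinct: float = 0.1
    growth_mean: float = 8.0
    alpha0: float = -2.2
    beta: tuple = (-0.5, 0.3)
    sigma2: float = 0.1
    alleles_per_locus: object = None
    alpha_dispersal: float = 0.05
    site_spacing: float = 250.0


@dataclass
class RecoveryBundle:
    """A complete synthetic input set with its generating truth."""

    census: CensusTable
    distances: DistanceSource
    genotypes: GenotypeTable
    factors: FactorMatrix
    features: object  # pandas DataFrame from feature_table
    truth: SyntheticTruth


def make_recovery_bundle(config: BundleConfig | None = None, seed: int = 0) -> RecoveryBundle:
    """Generate census, distances, factors and genotypes with known truth.

    A census larger than the target study is simulated; the first
    ``n_populations`` sites extant in the final year become the sampled
    populations.  Their demographic features are computed exactly as for
    real data, the first ``len(beta)`` feature columns (standardized) form
    the factor matrix, and theta/genotypes are drawn from the logit-linear
    F-model around those factors.
    """
    config = config or BundleConfig()
    rng = np.random.default_rng(seed)
    sub = rng.integers(2**31, size=4)
    census = simulate_census(
        config.n_sites,
        config.n_years,
        config.p_colonize,
        config.p_extinct,
        config.growth_mean,
        seed=int(sub[0]),
    )
    ref_year = census.years[-1]
    j = census.years.index(ref_year)
    extant = [s for s, c in zip(census.site_ids, census.counts[:, j]) if c >= 1]
    if len(extant) < config.n_populations:
        raise ValueError(
            f"only {len(extant)} extant sites at {ref_year}; increase n_sites"
        )
    sites = extant[: config.n_populations]
    distances = line_network_distances(census.site_ids, config.site_spacing, seed=int(sub[1]))
    features = feature_table(
        census,
        distances,
        ConnectivityConfig(alpha=config.alpha_dispersal),
        ref_year,
        sites,
    )
    feature_cols = ["age", "harmonic_size", "s_t", "s_s"][: len(config.beta)]
    factors = FactorMatrix.from_dataframe(
        features.set_index("site_id")[feature_cols], standardize=True
    )
    y, theta = simulate_factors_and_theta(
        factors, config.alpha0, config.beta, config.sigma2, seed=int(sub[2])
    )
    genotypes = simulate_genotypes(
        theta,
        config.n_loci,
        config.alleles_per_locus,
        config.diploids_per_pop,
        seed=int(sub[3]),
        population_ids=sites,
    )
    truth = SyntheticTruth(
        seed=seed,
        alpha0=config.alpha0,
        beta=list(config.beta),
        sigma2=config.sigma2,
        theta=[float(t) for t in theta],
        fst=[float(f) for f in 1.0 / (1.0 + theta)],
        factor_names=feature_cols,
        p_colonize=config.p_colonize,
        p_extinct=config.p_extinct,
        growth_mean=config.growth_mean,
    )
    return RecoveryBundle(census, distances, genotypes, factors, features, truth)
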