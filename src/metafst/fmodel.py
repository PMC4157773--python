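"""Hierarchical Bayesian F-model with reversible-jump model selection.

The F-model treats each local population's allele frequencies at locus *i*
as a Dirichlet draw around shared ancestral frequencies ``p_i`` with
population-specific concentration ``theta_j``; integrating the local
frequencies out of the multinomial sample leaves a Dirichlet-multinomial
(Pólya) likelihood with parameters ``theta_j * p_i``.  The differentiation
of population *j* is ``F_ST,j = 1 / (1 + theta_j)``.

A regression layer links differentiation to demographic factors on the
logit scale::

    y_j = ln(F_ST,j / (1 - F_ST,j)) = -ln(theta_j) ~ Normal(eta_j, sigma^2)
    eta_j = alpha0 + sum_g m_g * beta_g * G_jg

where ``m`` is a binary inclusion vector ranging over all ``2^G`` factor
subsets.  A reversible-jump MCMC samples jointly over ``(p, theta, alpha0,
beta, sigma^2, m)``; posterior model probabilities are the empirical visit
frequencies of the chain, and factor importances are sums of probabilities
of the models containing each factor.

Priors (all configurable): flat Dirichlet on each ``p_i``; ``alpha0, beta_g
~ Normal(0, tau^2)`` with ``tau^2 = 10``; ``sigma^2 ~ InvGamma(2, 1)``;
uniform over the model space.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import gaussian_kde


# --------------------------------------------------------------------------
# small posterior-summary utilities


def hpdi(samples, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(level * n)`` samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 samples for an HPDI")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    m = int(np.ceil(level * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + m - 1])


def posterior_mode(samples) -> float:
    """Mode of an MCMC sample: argmax of a Gaussian KDE (Silverman bandwidth)
    on a 512-point grid."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 100:
        raise ValueError("need at least 100 samples for a mode estimate")
    if np.ptp(x) == 0:
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def enumerate_models(n_factors: int) -> np.ndarray:
    """All ``2^n`` factor-inclusion vectors, null model first, full model last.

    The regression constant is always included and is not part of the
    inclusion vector.
    """
    if n_factors < 0:
        raise ValueError("n_factors must be >= 0")
    rows = sorted(
        itertools.product([0, 1], repeat=n_factors), key=lambda r: (sum(r), r)
    )
    return np.array(rows, dtype=bool).reshape(2**n_factors, n_factors)


def factor_inclusion_probs(model_probs: pd.Series | dict) -> pd.Series:
    """Per-factor summed posterior probability over models containing it.

    ``model_probs`` maps inclusion tuples (e.g. ``(0, 1, 1, 0)``) to
    posterior probabilities.
    """
    items = list(model_probs.items())
    total = sum(p for _, p in items)
    if not np.isclose(total, 1.0, atol=0.01):
        raise ValueError(f"model probabilities sum to {total:.3f}, expected 1")
    G = len(items[0][0])
    out = np.zeros(G)
    for m, p in items:
        out += np.asarray(m, dtype=float) * p
    return pd.Series(out, index=[f"factor_{g + 1}" for g in range(G)])


# --------------------------------------------------------------------------
# likelihood


def dirichlet_multinomial_loglik(counts, p, theta: float) -> float:
    """Log probability of an allele-count vector under the F-model.

    ``counts`` are gene-copy counts for one population at one locus, ``p``
    the ancestral frequencies and ``theta`` the concentration; the density
    is the Pólya / Dirichlet-multinomial::

        C(n; counts) * Gamma(theta)/Gamma(theta + n)
                     * prod_a Gamma(theta p_a + n_a)/Gamma(theta p_a)

    including the multinomial coefficient (counts are unordered).
    """
    n_a = np.asarray(counts, dtype=float)
    p = np.asarray(p, dtype=float)
    if n_a.shape != p.shape:
        raise ValueError("counts and p must have the same length")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if np.any(p <= 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("p must be a strictly positive simplex vector")
    if np.any(n_a < 0):
        raise ValueError("counts must be non-negative")
    n = n_a.sum()
    log_multinom = gammaln(n + 1) - gammaln(n_a + 1).sum()
    return float(
        log_multinom
        + gammaln(theta)
        - gammaln(theta + n)
        + (gammaln(theta * p + n_a) - gammaln(theta * p)).sum()
    )


def regression_mean(factor_row, alpha0: float, beta, m) -> float:
    """Linear predictor ``eta_j = alpha0 + sum_g m_g beta_g G_jg``."""
    G = np.asarray(factor_row, dtype=float)
    b = np.asarray(beta, dtype=float)
    mask = np.asarray(m, dtype=bool)
    return float(alpha0 + (G[mask] * b[mask]).sum())


# --------------------------------------------------------------------------
# containers


@dataclass
class FactorMatrix:
    """Population-by-factor design matrix with a standardization record.

    ``values`` holds the (possibly standardized) factor values; ``means``
    and ``sds`` record the transformation so coefficients can be mapped back
    to the raw scale.
    """

    populations: list
    names: list
    values: np.ndarray
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.populations), len(self.names)):
            raise ValueError("factor matrix shape mismatch")
        if np.isnan(self.values).any():
            raise ValueError("factor matrix has missing cells")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, standardize: bool = True) -> "FactorMatrix":
        vals = df.to_numpy(dtype=float)
        means = sds = None
        if standardize:
            means = vals.mean(axis=0)
            sds = vals.std(axis=0, ddof=1)
            if np.any(sds == 0):
                raise ValueError("constant factor column cannot be standardized")
            vals = (vals - means) / sds
        return cls(list(df.index), list(df.columns), vals, means, sds)

    def subset(self, names) -> "FactorMatrix":
        idx = [self.names.index(n) for n in names]
        return FactorMatrix(
            self.populations,
            [self.names[i] for i in idx],
            self.values[:, idx],
            None if self.means is None else self.means[idx],
            None if self.sds is None else self.sds[idx],
        )


@dataclass
class FModelConfig:
    """MCMC schedule and priors.

    The ``desk`` preset (the default) runs in seconds-to-minutes on one
    core; the ``paper`` preset is the published GESTE schedule (5e6 burn-in,
    thinning 50, 60,000 retained) and takes hours.
    """

    pilot_runs: int = 10
    pilot_length: int = 1000
    burn_in: int = 10_000
    thinning: int = 10
    retained: int = 5_000
    seed: int = 0
    tau2: float = 10.0
    sigma2_shape: float = 2.0
    sigma2_scale: float = 1.0
    target_accept: float = 0.3

    def __post_init__(self) -> None:
        for name in ("pilot_runs", "pilot_length", "burn_in", "thinning", "retained"):
            if getattr(self, name) < 1 and name not in ("burn_in",):
                raise ValueError(f"{name} must be positive")

    @classmethod
    def preset(cls, name: str, **overrides) -> "FModelConfig":
        presets = {
            "desk": dict(),
            "paper": dict(burn_in=5_000_000, thinning=50, retained=60_000),
        }
        if name not in presets:
            raise ValueError(f"unknown preset {name!r} (desk | paper)")
        return cls(**{**presets[name], **overrides})


@dataclass
class FModelPosterior:
    """Retained MCMC samples plus derived summaries.

    ``fst`` has shape (samples, populations); ``models`` is the boolean
    inclusion matrix per retained sample; ``beta`` holds NaN where a factor
    was excluded at that iteration.
    """

    populations: list
    factor_names: list
    fst: np.ndarray
    models: np.ndarray
    alpha0: np.ndarray
    beta: np.ndarray
    sigma2: np.ndarray
    config: FModelConfig
    acceptance: dict = field(default_factory=dict)

    def model_probs(self) -> pd.DataFrame:
        """Posterior probability of every model (empirical chain frequency).

        Probabilities sum to exactly 1; unvisited models get 0.
        """
        space = enumerate_models(len(self.factor_names))
        S = len(self.models)
        keys = [tuple(int(v) for v in row) for row in space]
        visits = {k: 0 for k in keys}
        for row in self.models:
            visits[tuple(int(v) for v in row)] += 1
        rows = []
        for k in keys:
            label = " + ".join(
                ["constant"] + [n for n, inc in zip(self.factor_names, k) if inc]
            )
            rows.append((k, label, visits[k] / S))
        return pd.DataFrame(rows, columns=["model", "label", "probability"])

    def model_prob_se(self, n_batches: int = 25) -> pd.Series:
        """Batch-means Monte-Carlo standard error of each model probability."""
        probs = self.model_probs()
        S = len(self.models)
        bounds = np.linspace(0, S, n_batches + 1).astype(int)
        out = []
        for key in probs["model"]:
            ind = np.all(self.models == np.array(key, dtype=bool), axis=1).astype(float)
            bm = [ind[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
            out.append(np.std(bm, ddof=1) / np.sqrt(n_batches))
        return pd.Series(out, index=[str(k) for k in probs["model"]])

    def factor_inclusion(self) -> pd.Series:
        """Summed posterior probability of models containing each factor."""
        return pd.Series(self.models.mean(axis=0), index=self.factor_names)

    def population_summary(self, level: float = 0.95) -> pd.DataFrame:
        rows = []
        for j, pop in enumerate(self.populations):
            s = self.fst[:, j]
            lo, hi = hpdi(s, level)
            rows.append((pop, s.mean(), posterior_mode(s), lo, hi))
        return pd.DataFrame(
            rows, columns=["population", "fst_mean", "fst_mode", "hpdi_low", "hpdi_high"]
        ).set_index("population")

    def coefficient_summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior summaries of alpha0 and each beta_g conditional on the
        factor being included in the model."""
        rows = [
            (
                "constant",
                1.0,
                self.alpha0.mean(),
                posterior_mode(self.alpha0),
                *hpdi(self.alpha0, level),
            )
        ]
        for g, name in enumerate(self.factor_names):
            b = self.beta[:, g]
            b = b[~np.isnan(b)]
            if len(b) >= 100:
                rows.append((name, len(b) / len(self.beta), b.mean(),
                             posterior_mode(b), *hpdi(b, level)))
            else:
                rows.append((name, len(b) / len(self.beta), np.nan, np.nan, np.nan, np.nan))
        return pd.DataFrame(
            rows, columns=["term", "inclusion", "mean", "mode", "hpdi_low", "hpdi_high"]
        ).set_index("term")


# --------------------------------------------------------------------------
# the sampler


def _prepare_counts(counts) -> tuple[np.ndarray, np.ndarray]:
    """Padded count tensor and allele-validity mask from an AlleleCounts."""
    c = np.asarray(counts.counts, dtype=float)
    L = len(counts.loci)
    A = c.shape[2]
    mask = np.zeros((L, A), dtype=bool)
    for li in range(L):
        mask[li, : len(counts.alleles[li])] = True
    return c, mask


def _dm_core(counts, mask, tp):
    """p- and theta-dependent part of the DM log-likelihood, (J, L, A) -> (J, L)."""
    tp_safe = np.where(mask[None, :, :], tp, 1.0)
    return np.where(
        mask[None, :, :], gammaln(tp_safe + counts) - gammaln(tp_safe), 0.0
    ).sum(axis=2)


def _dm_loglik_pops(counts, mask, n_jl, p, theta) -> np.ndarray:
    """Unnormalised DM log-likelihood per population, summed over loci."""
    tp = theta[:, None, None] * p[None, :, :]
    per_jl = gammaln(theta)[:, None] - gammaln(theta[:, None] + n_jl)
    return (per_jl + _dm_core(counts, mask, tp)).sum(axis=1)


def _dirichlet_logpdf_flat(x, alpha, seg, L):
    """Per-locus Dirichlet log-density for flat column vectors grouped by
    the segment labels ``seg``."""
    t = np.bincount(seg, weights=(alpha - 1.0) * np.log(x), minlength=L)
    t += gammaln(np.bincount(seg, weights=alpha, minlength=L))
    t -= np.bincount(seg, weights=gammaln(alpha), minlength=L)
    return t


class _Chain:
    """Mutable MCMC state and update kernels (internal).

    Count cells with zero copies contribute nothing to the
    Dirichlet-multinomial log-likelihood, so the chain stores only the
    nonzero (population, locus, allele) cells in flat arrays and forms the
    per-population / per-locus sums it needs with ``bincount``.  The
    ancestral frequencies live in a flat vector ``p_flat`` over the valid
    (locus, allele) columns.
    """

    def __init__(self, counts, factors: FactorMatrix, config: FModelConfig, rng):
        self.cfg = config
        self.rng = rng
        cnt, mask = _prepare_counts(counts)
        self.n_jl = cnt.sum(axis=2)
        self.J, self.L, self.A = cnt.shape
        self.G = len(factors.names)
        self.X = factors.values
        # flat column layout over valid (locus, allele) pairs
        loc_of_col, all_of_col = np.nonzero(mask)
        self.col_locus = loc_of_col
        self.C = len(loc_of_col)
        col_index = np.full((self.L, self.A), -1, dtype=np.int64)
        col_index[loc_of_col, all_of_col] = np.arange(self.C)
        # flat nonzero cells
        jj, ll, aa = np.nonzero(cnt)
        self.nz_j = jj
        self.nz_col = col_index[ll, aa]
        self.nz_cnt = cnt[jj, ll, aa]
        self.nz_locus = ll
        # initial ancestral frequencies: pooled empirical with pseudocount
        pooled = cnt.sum(axis=0)[loc_of_col, all_of_col] + 1.0
        sums = np.bincount(self.col_locus, weights=pooled, minlength=self.L)
        self.p_flat = pooled / sums[self.col_locus]
        self.y = np.full(self.J, np.log(0.1 / 0.9))
        self.theta = np.exp(-self.y)
        self.alpha0 = 0.0
        self.beta = np.zeros(self.G)
        self.m = np.ones(self.G, dtype=bool)
        self.sigma2 = 0.5
        self.core_cells = self._cells(self.p_flat, self.theta)
        self.core_j = np.bincount(self.nz_j, weights=self.core_cells, minlength=self.J)
        self.th_j = self._th(self.theta)
        # adaptive proposal scales
        self.scale_y = np.full(self.J, 0.3)
        self.conc_p = np.full(self.L, 200.0)
        self.acc_y = np.zeros(self.J)
        self.acc_p = np.zeros(self.L)
        self.try_count = 0
        # RJ proposal (tuned from pilot betas)
        self.rj_mu = np.zeros(self.G)
        self.rj_sd = np.full(self.G, 1.0)
        self.acc_rj = 0
        self.try_rj = 0

    # -- kernels ----------------------------------------------------------

    def _cells(self, p_flat, theta) -> np.ndarray:
        tp = theta[self.nz_j] * p_flat[self.nz_col]
        return gammaln(tp + self.nz_cnt) - gammaln(tp)

    def _th(self, theta) -> np.ndarray:
        return (gammaln(theta)[:, None] - gammaln(theta[:, None] + self.n_jl)).sum(axis=1)

    @property
    def p(self) -> np.ndarray:
        """Padded (L, A) ancestral-frequency matrix (for inspection)."""
        out = np.zeros((self.L, self.A))
        cols = np.zeros(self.L, dtype=int)
        for c in range(self.C):
            l = self.col_locus[c]
            out[l, cols[l]] = self.p_flat[c]
            cols[l] += 1
        return out

    def eta(self) -> np.ndarray:
        return self.alpha0 + self.X[:, self.m] @ self.beta[self.m]

    def update_theta(self) -> None:
        yp = self.y + self.scale_y * self.rng.standard_normal(self.J)
        thp = np.exp(-yp)
        cells_p = self._cells(self.p_flat, thp)
        core_pj = np.bincount(self.nz_j, weights=cells_p, minlength=self.J)
        th_pj = self._th(thp)
        eta = self.eta()
        logr = (
            core_pj + th_pj - self.core_j - self.th_j
            + ((self.y - eta) ** 2 - (yp - eta) ** 2) / (2.0 * self.sigma2)
        )
        acc = np.log(self.rng.uniform(size=self.J)) < logr
        self.y[acc] = yp[acc]
        self.theta[acc] = thp[acc]
        self.core_j[acc] = core_pj[acc]
        self.th_j[acc] = th_pj[acc]
        sel = acc[self.nz_j]
        self.core_cells[sel] = cells_p[sel]
        self.acc_y += acc

    def update_p(self) -> None:
        shift = 0.5
        a_fwd = self.conc_p[self.col_locus] * self.p_flat + shift
        g = self.rng.gamma(a_fwd)
        sums = np.bincount(self.col_locus, weights=g, minlength=self.L)
        pp = g / sums[self.col_locus]
        degenerate = np.bincount(
            self.col_locus, weights=(pp <= 1e-12), minlength=self.L
        ) > 0
        if degenerate.any():
            sel = degenerate[self.col_locus]
            pp[sel] = self.p_flat[sel]  # no-op proposal, always accepted
        cells_p = self._cells(pp, self.theta)
        prop_l = np.bincount(self.nz_locus, weights=cells_p, minlength=self.L)
        cur_l = np.bincount(self.nz_locus, weights=self.core_cells, minlength=self.L)
        a_rev = self.conc_p[self.col_locus] * pp + shift
        logq_fwd = _dirichlet_logpdf_flat(pp, a_fwd, self.col_locus, self.L)
        logq_rev = _dirichlet_logpdf_flat(self.p_flat, a_rev, self.col_locus, self.L)
        logr = prop_l - cur_l + logq_rev - logq_fwd
        acc = np.log(self.rng.uniform(size=self.L)) < logr
        if acc.any():
            colsel = acc[self.col_locus]
            self.p_flat[colsel] = pp[colsel]
            sel = acc[self.nz_locus]
            delta = cells_p[sel] - self.core_cells[sel]
            self.core_j += np.bincount(self.nz_j[sel], weights=delta, minlength=self.J)
            self.core_cells[sel] = cells_p[sel]
        self.acc_p += acc

    def update_regression(self) -> None:
        k = 1 + int(self.m.sum())
        X = np.column_stack([np.ones(self.J), self.X[:, self.m]])
        prec = X.T @ X / self.sigma2 + np.eye(k) / self.cfg.tau2
        cov = np.linalg.inv(prec)
        mean = cov @ (X.T @ self.y) / self.sigma2
        draw = mean + np.linalg.cholesky(cov) @ self.rng.standard_normal(k)
        self.alpha0 = draw[0]
        self.beta[self.m] = draw[1:]
        resid = self.y - X @ draw
        shape = self.cfg.sigma2_shape + self.J / 2.0
        scale = self.cfg.sigma2_scale + 0.5 * float(resid @ resid)
        self.sigma2 = scale / self.rng.gamma(shape)

    def _reg_loglik(self, m, beta) -> float:
        eta = self.alpha0 + self.X[:, m] @ beta[m]
        r = self.y - eta
        return float(-0.5 * (r @ r) / self.sigma2)

    def update_model(self) -> None:
        if self.G == 0:
            return
        self.try_rj += 1
        g = int(self.rng.integers(self.G))
        tau = np.sqrt(self.cfg.tau2)
        ll_cur = self._reg_loglik(self.m, self.beta)
        if self.m[g]:  # propose removal
            m_new = self.m.copy()
            m_new[g] = False
            ll_new = self._reg_loglik(m_new, self.beta)
            bg = self.beta[g]
            logr = (
                ll_new
                - ll_cur
                - _norm_logpdf(bg, 0.0, tau)
                + _norm_logpdf(bg, self.rj_mu[g], self.rj_sd[g])
            )
            if np.log(self.rng.uniform()) < logr:
                self.m = m_new
                self.acc_rj += 1
        else:  # propose addition
            bstar = self.rj_mu[g] + self.rj_sd[g] * self.rng.standard_normal()
            m_new = self.m.copy()
            m_new[g] = True
            b_new = self.beta.copy()
            b_new[g] = bstar
            ll_new = self._reg_loglik(m_new, b_new)
            logr = (
                ll_new
                - ll_cur
                + _norm_logpdf(bstar, 0.0, tau)
                - _norm_logpdf(bstar, self.rj_mu[g], self.rj_sd[g])
            )
            if np.log(self.rng.uniform()) < logr:
                self.m = m_new
                self.beta[g] = bstar
                self.acc_rj += 1

    def sweep(self, with_rj: bool = True) -> None:
        self.update_theta()
        self.update_p()
        self.update_regression()
        if with_rj:
            self.update_model()
        self.try_count += 1

    def adapt(self) -> tuple[np.ndarray, np.ndarray]:
        """Rescale proposals toward the target acceptance rate; reset counters."""
        ry = self.acc_y / max(self.try_count, 1)
        rp = self.acc_p / max(self.try_count, 1)
        t = self.cfg.target_accept
        self.scale_y *= np.clip(np.exp(ry - t), 0.5, 2.0)
        # larger concentration = smaller Dirichlet steps, so invert the ratio
        self.conc_p *= np.clip(np.exp(t - rp), 0.5, 2.0)
        self.conc_p = np.clip(self.conc_p, 10.0, 1e6)
        self.acc_y[:] = 0
        self.acc_p[:] = 0
        self.try_count = 0
        return ry, rp


def _norm_logpdf(x, mu, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def mcmc_run(counts, factors: FactorMatrix, config: FModelConfig | None = None) -> FModelPosterior:
    """Fit the F-model by reversible-jump MCMC.

    Parameters
    ----------
    counts
        :class:`~metafst.diversity.AlleleCounts` for the included populations.
    factors
        Standardized population-by-factor design matrix; its row order must
        match ``counts.populations``.
    config
        MCMC schedule; defaults to the desk preset.

    Returns
    -------
    FModelPosterior with ``config.retained`` thinned samples.
    """
    config = config or FModelConfig()
    if len(factors.populations) != len(counts.populations):
        raise ValueError("factor rows must match populations in the count tensor")
    rng = np.random.default_rng(config.seed)
    chain = _Chain(counts, factors, config, rng)

    # pilot phase: full model, adapt proposal scales, collect beta samples
    pilot_betas = []
    rates = None
    for run in range(config.pilot_runs):
        for _ in range(config.pilot_length):
            chain.sweep(with_rj=False)
            if run >= config.pilot_runs // 2:
                pilot_betas.append(chain.beta.copy())
        rates = chain.adapt()
    if rates is not None:
        ry, rp = rates
        bad = ((ry < 0.10) | (ry > 0.60)).sum() + ((rp < 0.10) | (rp > 0.60)).sum()
        if bad:
            warnings.warn(
                f"pilot adaptation left {bad} proposal(s) outside the 10-60% "
                f"acceptance band (theta: {np.round(ry, 2)}, p: {np.round(rp, 2)})"
            )
    if pilot_betas and chain.G:
        pb = np.asarray(pilot_betas)
        chain.rj_mu = pb.mean(axis=0)
        chain.rj_sd = np.maximum(1.5 * pb.std(axis=0), 0.05)

    for _ in range(config.burn_in):
        chain.sweep()

    S = config.retained
    fst = np.empty((S, chain.J))
    models = np.empty((S, chain.G), dtype=bool)
    alpha0 = np.empty(S)
    beta = np.full((S, chain.G), np.nan)
    sigma2 = np.empty(S)
    for s in range(S):
        for _ in range(config.thinning):
            chain.sweep()
        fst[s] = 1.0 / (1.0 + chain.theta)
        models[s] = chain.m
        alpha0[s] = chain.alpha0
        beta[s, chain.m] = chain.beta[chain.m]
        sigma2[s] = chain.sigma2

    acceptance = {
        "theta": chain.acc_y / max(chain.try_count, 1),
        "p": chain.acc_p / max(chain.try_count, 1),
        "rj": chain.acc_rj / max(chain.try_rj, 1),
    }
    return FModelPosterior(
        populations=list(counts.populations),
        factor_names=list(factors.names),
        fst=fst,
        models=models,
        alpha0=alpha0,
        beta=beta,
        sigma2=sigma2,
        config=config,
        acceptance=acceptance,
    )
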