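"""Brute-force cross-checks for the analytic machinery.

Small, deliberately naive reference computations — sequence enumeration,
exhaustive subsampling, dense numerical quadrature — that are tractable
only on tiny inputs.  They share no code with the production paths and
exist so tests (and the reproducibility script) can verify the fast
implementations against first principles.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import invgamma


def all_count_vectors(n: int, K: int):
    """Every way to distribute ``n`` gene copies over ``K`` alleles."""
    if K == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in all_count_vectors(n - first, K - 1):
            yield (first, *rest)


def polya_loglik_enum(counts, p, theta: float) -> float:
    """Dirichlet-multinomial log-probability by explicit Pólya-urn enumeration.

    Sums the probabilities of every ordered draw sequence consistent with
    the unordered counts: draw ``t`` of allele ``a`` has probability
    ``(theta p_a + c_a) / (theta + t)`` given ``c_a`` prior draws of ``a``.
    Exponential in ``n`` — use only for n <= ~8.
    """
    counts = [int(c) for c in counts]
    n = sum(counts)
    base = []
    for a, c in enumerate(counts):
        base.extend([a] * c)
    total = 0.0
    for seq in set(itertools.permutations(base)):
        prob = 1.0
        seen = [0] * len(counts)
        for t, a in enumerate(seq):
            prob *= (theta * p[a] + seen[a]) / (theta + t)
            seen[a] += 1
        total += prob
    return float(np.log(total))


def rarefaction_enum(counts, g: int) -> float:
    """Expected distinct alleles in a ``g``-copy subsample, by enumerating
    all C(N, g) subsets of the gene copies."""
    copies = []
    for a, c in enumerate(counts):
        copies.extend([a] * int(c))
    subsets = list(itertools.combinations(range(len(copies)), g))
    richness = [len({copies[i] for i in sub}) for sub in subsets]
    return float(np.mean(richness))


def _dm_prob(n_a, p, theta) -> float:
    """Direct (gamma-function-free) DM probability via the urn product over
    one canonical ordering times the multinomial count of orderings."""
    from math import comb, factorial

    n = int(sum(n_a))
    orderings = factorial(n)
    for c in n_a:
        orderings //= factorial(int(c))
    seq = []
    for a, c in enumerate(n_a):
        seq.extend([a] * int(c))
    prob = 1.0
    seen = [0] * len(n_a)
    for t, a in enumerate(seq):
        prob *= (theta * p[a] + seen[a]) / (theta + t)
        seen[a] += 1
    return orderings * prob


def tiny_model_evidence(
    counts1,
    counts2,
    factor,
    tau2: float = 10.0,
    sigma2_shape: float = 2.0,
    sigma2_scale: float = 1.0,
    n_p: int = 64,
    n_y: int = 400,
    n_s: int = 200,
    y_range: tuple = (-28.0, 28.0),
) -> dict:
    """Posterior model probabilities for the 2-population, 1-locus,
    2-allele, 1-factor instance by dense numerical quadrature.

    The regression coefficients are integrated analytically: given sigma^2
    and the design X, the logit differentiations are jointly Gaussian,
    ``y ~ N(0, sigma^2 I + tau^2 X X')``.  sigma^2 is integrated by
    Gauss-Legendre on the log scale against its inverse-gamma prior, and
    (p, y1, y2) on Gauss-Legendre grids (the wide y-range covers the
    diffuse tau^2 prior, under which the likelihood does not vanish).

    Returns ``{"null": P(null | data), "factor": P(factor model | data)}``.
    """
    counts1 = np.asarray(counts1, dtype=float)
    counts2 = np.asarray(counts2, dtype=float)
    if counts1.shape != (2,) or counts2.shape != (2,):
        raise ValueError("tiny instance requires exactly 2 alleles per population")
    G = np.asarray(factor, dtype=float)
    if G.shape != (2,):
        raise ValueError("one factor value per population required")

    # nodes
    xp, wp = np.polynomial.legendre.leggauss(n_p)
    p_nodes = 0.5 * (xp + 1.0)          # p of allele 1 on (0, 1)
    p_w = 0.5 * wp                      # flat Dirichlet(1,1) density = 1
    xy, wy = np.polynomial.legendre.leggauss(n_y)
    y_lo, y_hi = y_range
    y_nodes = 0.5 * (xy + 1.0) * (y_hi - y_lo) + y_lo
    y_w = 0.5 * wy * (y_hi - y_lo)
    # sigma^2 on the log scale against the inverse-gamma prior
    xs, ws = np.polynomial.legendre.leggauss(n_s)
    t_lo, t_hi = np.log(1e-4), np.log(5e3)
    t_nodes = 0.5 * (xs + 1.0) * (t_hi - t_lo) + t_lo
    s2_nodes = np.exp(t_nodes)
    s2_w = 0.5 * ws * (t_hi - t_lo) * invgamma.pdf(
        s2_nodes, a=sigma2_shape, scale=sigma2_scale
    ) * s2_nodes  # Jacobian d sigma^2 / d log sigma^2

    # DM likelihood of each population's counts on the (p, y) grid
    def dm_grid(n_a):
        out = np.empty((n_p, n_y))
        for i, pv in enumerate(p_nodes):
            p_vec = (pv, 1.0 - pv)
            for k, yv in enumerate(y_nodes):
                out[i, k] = _dm_prob(n_a, p_vec, np.exp(-yv))
        return out

    D1 = dm_grid(counts1)
    D2 = dm_grid(counts2)

    # regression-layer density f_m(y1, y2) with coefficients integrated out
    Y1 = y_nodes[:, None]
    Y2 = y_nodes[None, :]
    designs = {"null": np.ones((2, 1)), "factor": np.column_stack([np.ones(2), G])}
    evidence = {}
    for name, X in designs.items():
        B = tau2 * (X @ X.T)
        f = np.zeros((n_y, n_y))
        for s2, w in zip(s2_nodes, s2_w):
            v1, v2 = s2 + B[0, 0], s2 + B[1, 1]
            c = B[0, 1]
            det = v1 * v2 - c * c
            quad = (v2 * Y1**2 - 2 * c * Y1 * Y2 + v1 * Y2**2) / det
            f += w * np.exp(-0.5 * quad) / (2 * np.pi * np.sqrt(det))
        total = 0.0
        for i in range(n_p):
            total += p_w[i] * (D1[i] * y_w) @ f @ (D2[i] * y_w)
        evidence[name] = total
    z = sum(evidence.values())
    return {k: v / z for k, v in evidence.items()}
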