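"""Recompute the package's desk-scale validation numbers from scratch.

Every quantity is produced by running the actual pipeline components at the
study's dimensions (or at the tiny sizes where exhaustive cross-checks are
tractable); nothing is looked up.  Used by ``metafst reproduce`` and the
repository's acceptance script.
"""

from __future__ import annotations

import itertools

import numpy as np

from .census import correlate
from .diversity import AlleleCounts, fst_gst, jost_d, rarefied_allelic_richness
from .fmodel import (
    FactorMatrix,
    FModelConfig,
    dirichlet_multinomial_loglik,
    enumerate_models,
    hpdi,
    mcmc_run,
)
from .genepop import tally_counts
from .io import load_table1
from .simulate import BundleConfig, make_recovery_bundle, simulate_genotypes
from .validate import (
    all_count_vectors,
    polya_loglik_enum,
    rarefaction_enum,
    tiny_model_evidence,
)


def table1_correlations() -> dict:
    t = load_table1()
    r_conn, _ = correlate(t["s_t"], t["s_s"])
    r_age_size, _ = correlate(t["age"], t["size"])
    n = len(t)
    return {
        "pearson_r_connectivity_st_ss": {"value": round(r_conn, 4), "n": n},
        "pearson_r_age_size": {"value": round(r_age_size, 4), "n": n},
    }


def model_space_size(n_factors: int = 4) -> dict:
    models = enumerate_models(n_factors)
    return {"n_models_four_factors": {"value": len(models), "n": n_factors}}


def likelihood_oracle_error(max_n: int = 4, max_k: int = 3) -> dict:
    """Max |analytic - Pólya-enumeration| log-likelihood and worst deviation
    of the summed probability from 1, over all count vectors."""
    rng = np.random.default_rng(7)
    worst_ll = 0.0
    worst_sum = 0.0
    n_checked = 0
    for K in range(1, max_k + 1):
        p = rng.dirichlet(np.ones(K) * 2.0)
        theta = float(rng.uniform(0.5, 10.0))
        for n in range(1, max_n + 1):
            total = 0.0
            for counts in all_count_vectors(n, K):
                ll = dirichlet_multinomial_loglik(counts, p, theta)
                ll_enum = polya_loglik_enum(counts, p, theta)
                worst_ll = max(worst_ll, abs(ll - ll_enum))
                total += np.exp(ll)
                n_checked += 1
            worst_sum = max(worst_sum, abs(total - 1.0))
    return {
        "dm_loglik_oracle_max_abs_err": {"value": worst_ll, "n": n_checked},
        "dm_total_prob_max_dev_from_1": {"value": worst_sum, "n": n_checked},
    }


def rarefaction_oracle_error(max_copies: int = 6) -> dict:
    """Max |combinatorial - exhaustive-subsampling| rarefied richness over
    all count vectors with <= ``max_copies`` gene copies (K <= 3)."""
    worst = 0.0
    n_checked = 0
    for K in (1, 2, 3):
        for counts in itertools.product(range(max_copies + 1), repeat=K):
            N = sum(counts)
            if N < 1 or N > max_copies:
                continue
            for g in range(1, N + 1):
                tensor = AlleleCounts(
                    ["popA"], ["L1"], [list(range(1, K + 1))], np.array([[counts]])
                )
                got = float(rarefied_allelic_richness(tensor, g).iloc[0, 0])
                want = rarefaction_enum(counts, g)
                worst = max(worst, abs(got - want))
                n_checked += 1
    return {"rarefaction_oracle_max_abs_err": {"value": worst, "n": n_checked}}


def fixed_difference_differentiation(n_copies: int = 40) -> dict:
    """G_ST and Jost's D for two populations fixed for different alleles."""
    counts = AlleleCounts(
        ["popA", "popB"],
        ["L1"],
        [[1, 2]],
        np.array([[[n_copies, 0]], [[0, n_copies]]]),
    )
    _, gst = fst_gst(counts)
    _, d_mean, _ = jost_d(counts)
    return {
        "gst_fixed_difference": {"value": gst, "n": n_copies},
        "jost_d_fixed_difference": {"value": d_mean, "n": n_copies},
    }


def quadrature_check(seed: int = 1) -> dict:
    """RJ-MCMC vs numerical quadrature on the 2-population, 1-locus,
    2-allele, 1-factor instance.

    Reports the largest |MCMC - quadrature| model-probability discrepancy
    in units of the Monte-Carlo standard error.
    """
    counts = AlleleCounts(
        ["popA", "popB"],
        ["L1"],
        [[1, 2]],
        np.array([[[11, 5]], [[3, 13]]]),
    )
    g = np.array([-1.0, 1.0])
    factors = FactorMatrix(["popA", "popB"], ["factor"], g[:, None])
    cfg = FModelConfig(seed=seed)
    post = mcmc_run(counts, factors, cfg)
    probs = post.model_probs()
    se = post.model_prob_se()
    oracle = tiny_model_evidence(counts.counts[0, 0], counts.counts[1, 0], g,
                                 tau2=cfg.tau2, sigma2_shape=cfg.sigma2_shape,
                                 sigma2_scale=cfg.sigma2_scale)
    want = {(0,): oracle["null"], (1,): oracle["factor"]}
    worst = 0.0
    for _, row in probs.iterrows():
        key = row["model"]
        diff = abs(row["probability"] - want[key])
        s = max(float(se[str(key)]), 1e-3)
        worst = max(worst, diff / s)
    return {
        "tiny_instance_prob_discrepancy_mcse_units": {
            "value": worst,
            "n": cfg.retained,
        },
        "tiny_instance_factor_model_prob": {
            "value": float(
                probs.set_index("model")["probability"][(1,)]
            ),
            "n": cfg.retained,
        },
    }


def recovery_experiment(seed: int = 1, n_replicates: int = 20) -> dict:
    """Parameter recovery on synthetic bundles at the study's dimensions.

    For each replicate, a 33-population, 8-locus, ~20-diploid bundle is
    generated at beta = (-0.5, +0.3), sigma^2 = 0.1, fitted with the desk
    MCMC preset, and the 95% HPDIs of the coefficients (conditional on
    inclusion) are checked against the generating values.
    """
    beta_true = (-0.5, 0.3)
    rng = np.random.default_rng(seed)
    cover = np.zeros(2)
    both_signs = 0
    used = 0
    for rep in range(n_replicates):
        bseed = int(rng.integers(2**31))
        bundle = make_recovery_bundle(
            BundleConfig(diploids_per_pop=20, beta=beta_true, sigma2=0.1), seed=bseed
        )
        counts = tally_counts(bundle.genotypes)
        post = mcmc_run(
            counts, bundle.factors, FModelConfig(seed=int(rng.integers(2**31)))
        )
        used += 1
        rep_signs = 0
        for gi in range(2):
            b = post.beta[:, gi]
            b = b[~np.isnan(b)]
            if len(b) < 100:  # factor almost never included: no interval
                continue
            lo, hi = hpdi(b, 0.95)
            if lo <= beta_true[gi] <= hi:
                cover[gi] += 1
            if np.sign(np.mean(b)) == np.sign(beta_true[gi]):
                rep_signs += 1
        if rep_signs == 2:
            both_signs += 1
    return {
        "recovery_beta1_hpdi_coverage_pct": {"value": 100.0 * cover[0] / used, "n": used},
        "recovery_beta2_hpdi_coverage_pct": {"value": 100.0 * cover[1] / used, "n": used},
        "recovery_sign_correct_replicates": {"value": float(both_signs), "n": used},
    }


def bn_calibration(seed: int = 1, n_replicates: int = 50) -> dict:
    """Balding-Nichols generator calibration: mean Nei F_ST over replicates
    against the target 1/(1+theta), at 8 loci x 25 diploids x 2 populations."""
    rng = np.random.default_rng(seed)
    out = {}
    for theta in (3.0, 9.0, 19.0):
        target = 1.0 / (1.0 + theta)
        vals = []
        for _ in range(n_replicates):
            table = simulate_genotypes(
                np.full(8, theta),
                n_loci=8,
                alleles_per_locus=8,
                diploids_per_pop=25,
                seed=int(rng.integers(2**31)),
            )
            _, overall = fst_gst(tally_counts(table))
            vals.append(overall)
        out[f"bn_calibration_ratio_theta_{int(theta)}"] = {
            "value": float(np.mean(vals) / target),
            "n": n_replicates,
        }
    return out


def determinism_check(seed: int = 1) -> dict:
    """Same seed twice: identical genotypes, identical posterior samples."""
    b1 = make_recovery_bundle(BundleConfig(n_populations=8, diploids_per_pop=10,
                                           n_sites=40), seed=seed)
    b2 = make_recovery_bundle(BundleConfig(n_populations=8, diploids_per_pop=10,
                                           n_sites=40), seed=seed)
    same = np.array_equal(b1.genotypes.calls, b2.genotypes.calls)
    cfg = FModelConfig(seed=seed, pilot_runs=2, pilot_length=200,
                       burn_in=500, thinning=2, retained=200)
    c = tally_counts(b1.genotypes)
    p1 = mcmc_run(c, b1.factors, cfg)
    p2 = mcmc_run(c, b2.factors, cfg)
    same = same and np.array_equal(p1.fst, p2.fst) and np.array_equal(p1.models, p2.models)
    return {"determinism_identical": {"value": float(same), "n": 2}}


def run_all(seed: int = 1) -> dict:
    results = {}
    results.update(table1_correlations())
    results.update(model_space_size())
    results.update(likelihood_oracle_error())
    results.update(rarefaction_oracle_error())
    results.update(fixed_difference_differentiation())
    results.update(determinism_check(seed))
    results.update(bn_calibration(seed))
    results.update(quadrature_check(seed))
    results.update(recovery_experiment(seed))
    return results
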