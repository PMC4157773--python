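"""End-to-end pipeline: census -> factors -> diversity -> F-model -> reports."""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .census import ConnectivityConfig, feature_table
from .diversity import diversity_summary
from .fmodel import FactorMatrix, FModelConfig, mcmc_run
from .genepop import read_genepop, tally_counts
from .io import (
    apply_inclusion_rule,
    read_census_csv,
    read_distance_matrix_csv,
    read_edge_list_csv,
    write_posterior_outputs,
)

log = logging.getLogger("metafst")


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    genotypes: str
    census: str | None = None
    distances: str | None = None
    distance_edges: str | None = None
    distance_attachments: str | None = None
    factors: str | None = None
    ref_year: int | None = None
    alpha: float = 0.05
    sample_floor: int = 4
    preset: str = "desk"
    seed: int = 0
    outdir: str = "metafst_out"
    factor_columns: list = field(default_factory=lambda: ["age", "harmonic_size", "s_t", "s_s"])
    mcmc_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a JSON (or JSON-compatible YAML) config file."""
        text = open(path).read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml  # optional; only needed for YAML configs

            data = yaml.safe_load(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def pipeline_run(config: RunConfig):
    """Run the full analysis and write all outputs plus a manifest.

    Stages: read genotypes, apply the sample-size floor, derive demographic
    factors (from a census + distances, or read a pre-built factor table),
    compute diversity summaries, fit the F-model, and plot logit-F_ST
    against each factor.  Returns a dict with the in-memory results and
    output paths.
    """
    t0 = time.time()
    os.makedirs(config.outdir, exist_ok=True)
    stage = "read genotypes"
    try:
        genotypes = read_genepop(config.genotypes)
        stage = "inclusion rule"
        genotypes, excluded = apply_inclusion_rule(genotypes, config.sample_floor)
        if excluded:
            log.info("excluded %d population(s) below floor: %s", len(excluded), excluded)

        stage = "factors"
        if config.factors is not None:
            factor_df = pd.read_csv(config.factors, index_col=0)
            features = None
        elif config.census is not None:
            census = read_census_csv(config.census)
            if config.distance_edges is not None:
                distances = read_edge_list_csv(
                    config.distance_edges, config.distance_attachments
                )
            else:
                distances = read_distance_matrix_csv(config.distances)
            ref_year = config.ref_year or census.years[-1]
            features = feature_table(
                census,
                distances,
                ConnectivityConfig(alpha=config.alpha),
                ref_year,
                sites=genotypes.populations,
            )
            factor_df = features.set_index("site_id")[config.factor_columns]
        else:
            raise ValueError("provide either a factor table or a census + distances")
        factor_df = factor_df.loc[genotypes.populations]
        factors = FactorMatrix.from_dataframe(factor_df, standardize=True)

        stage = "diversity summary"
        summary = diversity_summary(genotypes)

        stage = "f-model"
        mcmc = FModelConfig.preset(config.preset, seed=config.seed, **config.mcmc_overrides)
        counts = tally_counts(genotypes)
        posterior = mcmc_run(counts, factors, mcmc)

        stage = "outputs"
        paths = write_posterior_outputs(posterior, config.outdir)
        summary_path = os.path.join(config.outdir, "diversity_summary.csv")
        summary.to_csv(summary_path, float_format="%.6g")
        paths["diversity_summary"] = summary_path
        if features is not None:
            fpath = os.path.join(config.outdir, "features.csv")
            features.to_csv(fpath, index=False, float_format="%.6g")
            paths["features"] = fpath
        paths["plots"] = plot_logit_fst(posterior, factors, config.outdir)

        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "mcmc": asdict(mcmc),
            "excluded_populations": excluded,
            "n_populations": len(genotypes.populations),
            "n_loci": len(genotypes.loci),
            "n_individuals": len(genotypes.individual_ids),
            "config_hash": hashlib.sha256(
                json.dumps(asdict(config), sort_keys=True).encode()
            ).hexdigest(),
            "wall_time_s": round(time.time() - t0, 2),
            "outputs": paths,
        }
        mpath = os.path.join(config.outdir, "manifest.json")
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        paths["manifest"] = mpath
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err
    return {
        "genotypes": genotypes,
        "factors": factors,
        "diversity": summary,
        "posterior": posterior,
        "paths": paths,
        "manifest": manifest,
    }


def plot_logit_fst(posterior, factors: FactorMatrix, outdir) -> str:
    """Scatter of posterior-mean logit F_ST against each factor."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fst = posterior.fst.mean(axis=0)
    logit = np.log(fst / (1.0 - fst))
    G = len(factors.names)
    fig, axes = plt.subplots(1, max(G, 1), figsize=(4 * max(G, 1), 3.5), squeeze=False)
    for g, name in enumerate(factors.names):
        ax = axes[0, g]
        ax.plot(factors.values[:, g], logit, "+", color="k")
        ax.set_xlabel(f"{name} (standardized)")
        ax.set_ylabel(r"$\ln(F_{ST}/(1-F_{ST}))$" if g == 0 else "")
    fig.tight_layout()
    path = os.path.join(outdir, "logit_fst_vs_factors.png")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
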