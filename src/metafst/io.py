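"""CSV readers/writers, the packaged factor table, and the inclusion rule."""

from __future__ import annotations

from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd

from .census import CensusTable, DistanceSource
from .genepop import GenotypeTable


def read_census_csv(path) -> CensusTable:
    """Wide-format census: first column site id, one column per calendar year."""
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    return CensusTable(list(df.index), [int(c) for c in df.columns], df.to_numpy())


def write_census_csv(census: CensusTable, path) -> None:
    census.to_frame().to_csv(path)


def read_distance_matrix_csv(path) -> DistanceSource:
    """Square symmetric distance matrix with site ids as header row/column."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValueError("distance matrix row and column ids differ")
    return DistanceSource(list(df.index), matrix=df.to_numpy(dtype=float))


def write_distance_matrix_csv(source: DistanceSource, path) -> None:
    from .census import shortest_path_distances

    shortest_path_distances(source).to_csv(path)


def read_edge_list_csv(edges_path, attachments_path) -> DistanceSource:
    """Road-network edge list (node_a, node_b, length_m) plus a site
    attachment table (site_id, node)."""
    edges = pd.read_csv(edges_path)
    attach = pd.read_csv(attachments_path)
    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row.iloc[0], row.iloc[1], length=float(row.iloc[2]))
    attachments = dict(zip(attach.iloc[:, 0], attach.iloc[:, 1]))
    return DistanceSource(list(attach.iloc[:, 0]), graph=g, attachments=attachments)


def read_factors_csv(path) -> pd.DataFrame:
    """Per-population factor table; first column is the population id."""
    df = pd.read_csv(path)
    return df.set_index(df.columns[0])


def load_table1() -> pd.DataFrame:
    """The published per-population table for the 33-population plant study.

    Columns: sample size, per-population F_ST posterior summaries (mean,
    mode, 95% HPDI bounds) and the four demographic factors (age, harmonic
    mean size, occupancy-weighted connectivity ``s_t``, size-weighted
    connectivity ``s_s``).
    """
    with resources.files("metafst.data").joinpath("table1_factors.csv").open() as fh:
        return pd.read_csv(fh).set_index("population_id")


def apply_inclusion_rule(table: GenotypeTable, floor: int = 4):
    """Drop populations sampled below the size floor.

    Populations with fewer than ``floor`` individuals cannot support
    reliable allele-frequency estimates; the study used a floor of 4
    plants.  Returns ``(filtered_table, report)`` where the report lists
    ``(population, size)`` for each exclusion.
    """
    if floor < 1:
        raise ValueError("floor must be >= 1")
    sizes = table.population_sizes()
    excluded = [(p, n) for p, n in sizes.items() if n < floor]
    keep = [p for p, n in sizes.items() if n >= floor]
    if not keep:
        raise ValueError("inclusion rule excluded every population")
    if not excluded:
        return table, []
    return table.subset_populations(keep), excluded


def write_posterior_outputs(posterior, outdir) -> dict:
    """Write Table-1/4/5-style summary CSVs plus raw thinned samples.

    Returns a dict of the file paths written.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    pop = posterior.population_summary()
    paths["population_summary"] = os.path.join(outdir, "population_fst.csv")
    pop.to_csv(paths["population_summary"], float_format="%.6g")

    mp = posterior.model_probs().copy()
    mp["model"] = mp["model"].astype(str)
    paths["model_probs"] = os.path.join(outdir, "model_probabilities.csv")
    mp.to_csv(paths["model_probs"], index=False, float_format="%.6g")

    paths["factor_inclusion"] = os.path.join(outdir, "factor_inclusion.csv")
    posterior.factor_inclusion().rename("summed_probability").to_csv(
        paths["factor_inclusion"], float_format="%.6g"
    )

    paths["coefficients"] = os.path.join(outdir, "coefficients.csv")
    posterior.coefficient_summary().to_csv(paths["coefficients"], float_format="%.6g")

    samples = pd.DataFrame(
        np.column_stack([posterior.alpha0, posterior.beta, posterior.sigma2, posterior.fst]),
        columns=(
            ["alpha0"]
            + [f"beta_{n}" for n in posterior.factor_names]
            + ["sigma2"]
            + [f"fst_{p}" for p in posterior.populations]
        ),
    )
    samples.insert(
        0, "model", ["".join(str(int(v)) for v in row) for row in posterior.models]
    )
    paths["samples"] = os.path.join(outdir, "samples.tsv")
    samples.to_csv(paths["samples"], sep="\t", index=False, float_format="%.6g")
    return paths
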