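"""Classical diversity and differentiation statistics for microsatellite data.

Implements the per-locus and overall summaries typically reported for a
multi-population microsatellite survey: number of alleles, observed
heterozygosity H_O, within-population gene diversity H_S, total diversity
H_T, Nei-style G_ST-type F_ST, Jost's D, and rarefied allelic richness.

Conventions (documented because programs differ):

* populations are weighted equally, not by sample size;
* H_S uses the unbiased per-population estimator ``(1 - sum p^2) * n/(n-1)``
  with ``n`` gene copies, averaged over populations;
* H_T applies the Nei & Chesser small-sample correction
  ``1 - sum(pbar^2) + H_S / (n_harm * s)`` with ``n_harm`` the harmonic mean
  gene-copy count and ``s`` the number of populations;
* F_ST is ``(H_T - H_S)/H_T`` per locus and a ratio of across-locus sums
  overall; exact agreement with other estimators (e.g. Weir-Cockerham) is
  not claimed;
* Jost's D is ``[(H_T - H_S)/(1 - H_S)] * s/(s-1)``; the overall value is
  reported both as the across-locus mean and as the sums ratio;
* the unbiased estimators can fall marginally below zero by sampling noise;
  F_ST and D are floored at 0 (no differentiation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln


@dataclass
class AlleleCounts:
    """Gene-copy counts per population, locus and allele.

    ``counts`` has shape ``(n_pops, n_loci, max_alleles)``; rows are padded
    with zeros beyond ``len(alleles[locus])``.
    """

    populations: list
    loci: list
    alleles: list  # per locus, the allele labels in column order
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("allele counts must be non-negative")
        J, L = len(self.populations), len(self.loci)
        if self.counts.shape[:2] != (J, L):
            raise ValueError("counts shape does not match populations x loci")

    @property
    def n_copies(self) -> np.ndarray:
        """Gene copies per population and locus, shape (n_pops, n_loci)."""
        return self.counts.sum(axis=2)

    def locus_counts(self, li: int) -> np.ndarray:
        """Counts for one locus restricted to its real alleles."""
        return self.counts[:, li, : len(self.alleles[li])]


def observed_heterozygosity(table) -> pd.Series:
    """Per-locus H_O: fraction of heterozygous individuals, populations
    weighted equally."""
    pops = table.populations
    out = []
    for li in range(len(table.loci)):
        per_pop = []
        for p in pops:
            idx = [i for i, q in enumerate(table.population_of) if q == p]
            calls = table.calls[idx, li, :]
            ok = calls[:, 0] != 0
            if ok.sum() == 0:
                continue
            per_pop.append(float(np.mean(calls[ok, 0] != calls[ok, 1])))
        out.append(np.mean(per_pop) if per_pop else np.nan)
    return pd.Series(out, index=table.loci, name="H_O")


def _locus_diversities(counts_l: np.ndarray, min_copies: int = 2):
    """Unbiased H_S and corrected H_T for one locus.

    Populations with fewer than ``min_copies`` gene copies are dropped from
    the locus.  Returns (H_S, H_T, n_pops_used).
    """
    n = counts_l.sum(axis=1)
    keep = n >= min_copies
    if keep.sum() < counts_l.shape[0]:
        warnings.warn("population(s) with < 2 gene copies dropped from a locus")
    counts_l = counts_l[keep]
    n = n[keep]
    s = counts_l.shape[0]
    if s == 0:
        return np.nan, np.nan, 0
    p = counts_l / n[:, None]
    hs_pop = (1.0 - (p**2).sum(axis=1)) * n / (n - 1.0)
    hs = float(hs_pop.mean())
    pbar = p.mean(axis=0)  # populations weighted equally
    ht = 1.0 - float((pbar**2).sum())
    if s > 1:
        n_harm = stats.hmean(n)
        ht += hs / (n_harm * s)
    return hs, min(ht, 1.0), s


def gene_diversity(counts: AlleleCounts) -> pd.DataFrame:
    """Per-locus H_S and H_T (equal population weights, unbiased)."""
    rows = []
    for li in range(len(counts.loci)):
        hs, ht, _ = _locus_diversities(counts.locus_counts(li))
        rows.append((hs, ht))
    return pd.DataFrame(rows, index=counts.loci, columns=["H_S", "H_T"])


def fst_gst(counts: AlleleCounts) -> tuple[pd.Series, float]:
    """Nei-style F_ST (G_ST form): per-locus ``(H_T - H_S)/H_T`` and the
    overall ratio of across-locus sums.

    Monomorphic loci (H_T == 0) are reported as NaN and excluded from the
    overall sums.
    """
    div = gene_diversity(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = ((div.H_T - div.H_S) / div.H_T).clip(lower=0.0)
    per_locus[div.H_T == 0] = np.nan
    ok = div.H_T > 0
    overall = (
        max(float((div.H_T[ok] - div.H_S[ok]).sum() / div.H_T[ok].sum()), 0.0)
        if ok.any()
        else np.nan
    )
    per_locus.name = "F_ST"
    return per_locus, overall


def jost_d(counts: AlleleCounts) -> tuple[pd.Series, float, float]:
    """Jost's D per locus and overall.

    Returns ``(per_locus, overall_mean, overall_sums_ratio)``; the two
    overall conventions both circulate, so both are reported.
    """
    div = gene_diversity(counts)
    s = len(counts.populations)
    if s < 2:
        raise ValueError("Jost's D requires at least 2 populations")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = (
            ((div.H_T - div.H_S) / (1.0 - div.H_S) * s / (s - 1.0)).clip(0.0, 1.0)
        )
    per_locus[div.H_S >= 1.0] = np.nan
    ok = per_locus.notna()
    mean_d = float(per_locus[ok].mean()) if ok.any() else np.nan
    denom = ((1.0 - div.H_S[ok]) * (s - 1.0) / s).sum()
    ratio_d = (
        float(np.clip((div.H_T[ok] - div.H_S[ok]).sum() / denom, 0.0, 1.0))
        if ok.any()
        else np.nan
    )
    per_locus.name = "D"
    return per_locus, mean_d, ratio_d


def rarefied_allelic_richness(counts: AlleleCounts, g: int | None = None) -> pd.DataFrame:
    """Expected number of distinct alleles in a subsample of ``g`` gene copies.

    ``A_g = sum_a [1 - C(N - N_a, g) / C(N, g)]`` for a population with
    ``N`` copies of which ``N_a`` carry allele ``a``.  Default ``g`` is the
    smallest per-population per-locus gene-copy count (so every population
    is comparable).  Computed in log space to stay exact for large samples.
    """
    n = counts.n_copies
    if g is None:
        g = int(n[n > 0].min())
    if g < 1:
        raise ValueError("rarefaction depth must be >= 1")
    if g > n.min():
        raise ValueError(f"rarefaction depth {g} exceeds smallest sample ({int(n.min())} copies)")

    def log_comb(N, k):
        return gammaln(N + 1) - gammaln(k + 1) - gammaln(N - k + 1)

    J, L = n.shape
    out = np.zeros((J, L))
    for li in range(L):
        c = counts.locus_counts(li)
        N = c.sum(axis=1)[:, None].astype(float)
        with np.errstate(invalid="ignore"):
            miss = np.where(N - c >= g, np.exp(log_comb(N - c, g) - log_comb(N, g)), 0.0)
        out[:, li] = ((1.0 - miss) * (c > 0)).sum(axis=1)
    return pd.DataFrame(out, index=counts.populations, columns=counts.loci)


def diversity_summary(table) -> pd.DataFrame:
    """Per-locus summary table (alleles, H_O, H_S, H_T, F_ST, Jost's D) with
    an across-locus ``overall`` row."""
    from .genepop import tally_counts

    counts = tally_counts(table)
    n_alleles = pd.Series([len(a) for a in counts.alleles], index=counts.loci, name="N")
    ho = observed_heterozygosity(table)
    div = gene_diversity(counts)
    fst, fst_all = fst_gst(counts)
    d, d_mean, d_ratio = jost_d(counts)
    out = pd.concat([n_alleles, ho, div.H_S, div.H_T, d, fst], axis=1)
    overall = {
        "N": n_alleles.mean(),
        "H_O": ho.mean(),
        "H_S": div.H_S.mean(),
        "H_T": div.H_T.mean(),
        "D": d_mean,
        "F_ST": fst_all,
    }
    out.loc["overall"] = overall
    out.attrs["jost_d_overall_mean"] = d_mean
    out.attrs["jost_d_overall_ratio"] = d_ratio
    return out
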