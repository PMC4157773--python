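"""Diversity and differentiation statistics against direct-definition oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hmean

from metafst import (
    AlleleCounts,
    GenotypeTable,
    diversity_summary,
    fst_gst,
    gene_diversity,
    jost_d,
    observed_heterozygosity,
    rarefied_allelic_richness,
    tally_counts,
)
from metafst.validate import rarefaction_enum


def _counts(arr, pops=None):
    arr = np.asarray(arr)
    J, L, A = arr.shape
    return AlleleCounts(
        pops or [f"p{j}" for j in range(J)],
        [f"L{i}" for i in range(L)],
        [list(range(1, A + 1))] * L,
        arr,
    )


def _direct_hs_ht(counts_l):
    """Spreadsheet-style H_S / H_T for one locus (independent of module code)."""
    n = counts_l.sum(axis=1)
    p = counts_l / n[:, None]
    hs_each = [(1 - (pi**2).sum()) * ni / (ni - 1) for pi, ni in zip(p, n)]
    hs = float(np.mean(hs_each))
    pbar = p.mean(axis=0)
    ht = 1 - (pbar**2).sum() + hs / (hmean(n) * len(n))
    return hs, float(ht)


class TestTally:
    def test_small_example(self):
        t = GenotypeTable(
            ["i1", "i2"], ["p1", "p1"], ["L1"], np.array([[[1, 1]], [[1, 2]]])
        )
        c = tally_counts(t)
        assert c.counts[0, 0, :2].tolist() == [3, 1]

    def test_all_missing_locus_gives_zero_counts(self):
        t = GenotypeTable(
            ["i1"], ["p1"], ["L1", "L2"], np.array([[[1, 2], [0, 0]]])
        )
        c = tally_counts(t)
        assert c.counts[0, 1].sum() == 0

    def test_conserves_gene_copies_against_double_loop(self):
        rng = np.random.default_rng(3)
        n, L = 20, 3
        calls = rng.integers(1, 4, size=(n, L, 2))
        miss = rng.uniform(size=(n, L)) < 0.2
        calls[miss] = 0
        pops = [f"p{j}" for j in rng.integers(0, 3, size=n)]
        t = GenotypeTable([f"i{k}" for k in range(n)], pops, ["a", "b", "c"], calls)
        c = tally_counts(t)
        for j, pop in enumerate(c.populations):
            for li in range(L):
                # naive per-individual accumulation
                naive = {}
                for i in range(n):
                    if pops[i] != pop or calls[i, li, 0] == 0:
                        continue
                    for a in calls[i, li]:
                        naive[a] = naive.get(a, 0) + 1
                got = {
                    c.alleles[li][k]: int(v)
                    for k, v in enumerate(c.locus_counts(li)[j])
                    if v
                }
                assert got == naive
                assert c.counts[j, li].sum() == 2 * sum(
                    1
                    for i in range(n)
                    if pops[i] == pop and calls[i, li, 0] != 0
                )

    def test_rejects_half_missing_calls(self):
        with pytest.raises(ValueError, match="diploid"):
            GenotypeTable(["i1"], ["p1"], ["L1"], np.array([[[1, 0]]]))


class TestHeterozygosityAndDiversity:
    def test_all_heterozygous_and_all_homozygous(self):
        t = GenotypeTable(
            ["i1", "i2"], ["p1", "p1"], ["L1", "L2"],
            np.array([[[1, 2], [1, 1]], [[1, 2], [2, 2]]]),
        )
        ho = observed_heterozygosity(t)
        assert ho["L1"] == 1.0 and ho["L2"] == 0.0

    def test_ho_averages_populations_equally(self):
        # pop1: 1 het of 3; pop2: 1 het of 1 -> mean(1/3, 1) = 2/3
        t = GenotypeTable(
            ["a", "b", "c", "d"],
            ["p1", "p1", "p1", "p2"],
            ["L1"],
            np.array([[[1, 2]], [[1, 1]], [[2, 2]], [[1, 2]]]),
        )
        assert observed_heterozygosity(t)["L1"] == pytest.approx(2 / 3)

    def test_fixed_population_has_zero_hs(self):
        c = _counts([[[10, 0]]])
        assert gene_diversity(c).H_S.iloc[0] == 0.0

    def test_two_equal_alleles_approach_half(self):
        c = _counts([[[5000, 5000]]])
        assert gene_diversity(c).H_S.iloc[0] == pytest.approx(0.5, abs=1e-3)

    def test_matches_direct_definition_on_random_tensors(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            arr = rng.integers(0, 6, size=(3, 2, 3))
            arr[arr.sum(axis=2) < 2] += 2  # keep >= 2 copies everywhere
            c = _counts(arr)
            div = gene_diversity(c)
            for li in range(2):
                hs, ht = _direct_hs_ht(c.locus_counts(li).astype(float))
                assert div.H_S.iloc[li] == pytest.approx(hs)
                assert div.H_T.iloc[li] == pytest.approx(min(ht, 1.0))

    def test_small_population_dropped_with_warning(self):
        arr = np.array([[[4, 4]], [[1, 0]]])
        with pytest.warns(UserWarning, match="dropped"):
            div = gene_diversity(_counts(arr))
        assert np.isfinite(div.H_S.iloc[0])


class TestDifferentiation:
    def test_identical_frequencies_give_near_zero(self):
        c = _counts([[[500, 500]], [[500, 500]]])
        per, overall = fst_gst(c)
        assert overall == pytest.approx(0.0, abs=1e-3)
        _, d_mean, _ = jost_d(c)
        assert d_mean == pytest.approx(0.0, abs=1e-3)

    def test_fixed_differences_give_one(self):
        c = _counts([[[40, 0]], [[0, 40]]])
        _, overall = fst_gst(c)
        assert overall == pytest.approx(1.0)
        _, d_mean, _ = jost_d(c)
        assert d_mean == pytest.approx(1.0)

    def test_monomorphic_locus_reported_missing(self):
        c = _counts([[[6, 0], [3, 3]], [[6, 0], [2, 4]]])
        per, overall = fst_gst(c)
        assert np.isnan(per.iloc[0]) and np.isfinite(per.iloc[1])

    def test_statistics_in_unit_interval_on_random_tensors(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            arr = rng.integers(0, 5, size=(3, 3, 3))
            arr[..., 0] += 2
            c = _counts(arr)
            div = gene_diversity(c)
            per_f, overall_f = fst_gst(c)
            per_d, d_mean, d_ratio = jost_d(c)
            assert ((div >= 0) & (div <= 1)).all().all()
            ok = per_f.dropna()
            assert ((ok >= -1e-9) & (ok <= 1)).all()
            okd = per_d.dropna()
            assert (okd <= 1 + 1e-9).all()

    def test_matches_direct_definitions_on_small_tensors(self):
        # exhaustive over tiny tensors: 2 pops x 1 locus, <= 3 alleles, <= 6 copies
        for a1 in itertools.product(range(4), repeat=2):
            for a2 in itertools.product(range(4), repeat=2):
                if not (2 <= sum(a1) <= 6 and 2 <= sum(a2) <= 6):
                    continue
                c = _counts(np.array([[list(a1)], [list(a2)]]))
                hs, ht = _direct_hs_ht(c.locus_counts(0).astype(float))
                ht = min(ht, 1.0)
                per_f, _ = fst_gst(c)
                per_d, _, _ = jost_d(c)
                if ht > 0:
                    assert per_f.iloc[0] == pytest.approx(max((ht - hs) / ht, 0.0))
                if hs < 1:
                    want_d = float(np.clip(2 * (ht - hs) / (1 - hs), 0.0, 1.0))
                    assert per_d.iloc[0] == pytest.approx(want_d)


class TestRarefaction:
    def test_full_sample_returns_observed_alleles(self):
        c = _counts([[[3, 2, 1]]])
        assert rarefied_allelic_richness(c, 6).iloc[0, 0] == pytest.approx(3.0)

    def test_two_plus_two_at_depth_two(self):
        c = _counts([[[2, 2, 0]]])
        assert rarefied_allelic_richness(c, 2).iloc[0, 0] == pytest.approx(5 / 3)

    def test_single_allele_always_one(self):
        c = _counts([[[8, 0, 0]]])
        for g in (1, 3, 8):
            assert rarefied_allelic_richness(c, g).iloc[0, 0] == pytest.approx(1.0)

    def test_non_decreasing_in_depth(self):
        c = _counts([[[5, 3, 2]]])
        vals = [rarefied_allelic_richness(c, g).iloc[0, 0] for g in range(1, 11)]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_matches_exhaustive_subsampling(self):
        for counts in itertools.product(range(7), repeat=3):
            N = sum(counts)
            if not 1 <= N <= 6:
                continue
            c = _counts([[list(counts)]])
            for g in range(1, N + 1):
                got = rarefied_allelic_richness(c, g).iloc[0, 0]
                assert got == pytest.approx(rarefaction_enum(counts, g))

    def test_depth_beyond_sample_rejected(self):
        c = _counts([[[2, 2, 0]]])
        with pytest.raises(ValueError):
            rarefied_allelic_richness(c, 7)


def test_summary_table_shape_and_overall_row(small_bundle):
    summary = diversity_summary(small_bundle.genotypes)
    assert list(summary.columns) == ["N", "H_O", "H_S", "H_T", "D", "F_ST"]
    assert summary.index[-1] == "overall"
    body = summary.iloc[:-1]
    assert ((body[["H_O", "H_S", "H_T"]] >= 0) & (body[["H_O", "H_S", "H_T"]] <= 1)).all().all()
    assert 0 <= summary.loc["overall", "F_ST"] <= 1
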