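"""Census-derived demographic factors: age, harmonic size, connectivity."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metafst import (
    CensusTable,
    ConnectivityConfig,
    DistanceSource,
    compute_age,
    connectivity_score,
    correlate,
    feature_table,
    harmonic_mean_size,
    load_table1,
    shortest_path_distances,
)
from metafst.census import NotExtantError


class TestComputeAge:
    def test_always_occupied_site_has_age_equal_to_census_span(self):
        c = CensusTable(["s"], range(1988, 2009), np.ones((1, 21), dtype=int))
        assert compute_age(c, "s", 2008) == 21

    @pytest.mark.parametrize(
        "pattern, ref_idx, expected",
        [
            ((0, 1), 1, 1),                  # first-year colonist
            ((1, 1, 0, 0, 1, 1, 1), 6, 3),   # run restarts after the gap
            ((1, 0, 1, 1), 3, 2),
        ],
    )
    def test_single_gap_resets_the_run(self, pattern, ref_idx, expected):
        c = CensusTable(["s"], range(2000, 2000 + len(pattern)), [list(pattern)])
        assert compute_age(c, "s", 2000 + ref_idx) == expected

    def test_unoccupied_reference_year_is_an_error(self, toy_census):
        with pytest.raises(NotExtantError):
            compute_age(toy_census, "b", 2002)

    def test_unknown_site_and_year_raise_lookup_errors(self, toy_census):
        with pytest.raises(KeyError):
            compute_age(toy_census, "zz", 2003)
        with pytest.raises(KeyError):
            compute_age(toy_census, "a", 1900)

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=25))
    @settings(deadline=None, derandomize=True)
    def test_matches_backwards_scan_oracle(self, pattern):
        c = CensusTable(["s"], range(2000, 2000 + len(pattern)), [pattern])
        occupied = [i for i, n in enumerate(pattern) if n >= 1]
        if not occupied:
            return
        ref = occupied[-1]
        want = 0
        for k in range(ref, -1, -1):
            if pattern[k] == 0:
                break
            want += 1
        assert compute_age(c, "s", 2000 + ref) == want


class TestHarmonicMeanSize:
    def test_hand_computed_values(self, toy_census):
        # counts (1, 10, 0, 10) -> 3 / (1 + 0.1 + 0.1) = 2.5
        c = CensusTable(["s"], range(2000, 2004), [[1, 10, 0, 10]])
        assert harmonic_mean_size(c, "s") == pytest.approx(2.5)

    def test_constant_count_is_identity(self):
        c = CensusTable(["s"], range(2000, 2005), [[7] * 5])
        assert harmonic_mean_size(c, "s") == pytest.approx(7.0)

    def test_never_occupied_is_an_error(self):
        c = CensusTable(["s"], range(2000, 2003), [[0, 0, 0]])
        with pytest.raises(NotExtantError):
            harmonic_mean_size(c, "s")

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=21))
    @settings(deadline=None, derandomize=True)
    def test_bounded_by_arithmetic_mean(self, counts):
        occ = [n for n in counts if n >= 1]
        if not occ:
            return
        c = CensusTable(["s"], range(2000, 2000 + len(counts)), [counts])
        h = harmonic_mean_size(c, "s")
        assert h <= np.mean(occ) + 1e-12
        assert h <= max(occ)
        if len(set(occ)) > 1:
            assert h < np.mean(occ)


class TestShortestPaths:
    def test_path_graph(self):
        g = nx.Graph()
        g.add_edge("u", "v", length=1.0)
        g.add_edge("v", "w", length=2.0)
        src = DistanceSource(
            ["a", "b", "c"], graph=g, attachments={"a": "u", "b": "v", "c": "w"}
        )
        d = shortest_path_distances(src)
        assert d.loc["a", "c"] == pytest.approx(3.0)
        assert (np.diag(d) == 0).all()

    def test_disconnected_pair_is_inf_with_warning(self):
        g = nx.Graph()
        g.add_edge("u", "v", length=1.0)
        g.add_node("w")
        src = DistanceSource(["a", "b"], graph=g, attachments={"a": "u", "b": "w"})
        with pytest.warns(UserWarning, match="disconnected"):
            d = shortest_path_distances(src)
        assert np.isinf(d.loc["a", "b"])

    def test_matches_brute_force_path_enumeration(self):
        rng = np.random.default_rng(5)
        g = nx.Graph()
        nodes = list("abcde")
        for i, u in enumerate(nodes):
            for v in nodes[i + 1 :]:
                if rng.uniform() < 0.7:
                    g.add_edge(u, v, length=float(rng.integers(1, 20)))
        if not nx.is_connected(g):
            g.add_edge("a", "e", length=30.0)
        src = DistanceSource(nodes, graph=g, attachments={n: n for n in nodes})
        d = shortest_path_distances(src)

        def brute(u, v):
            best = np.inf
            for path in nx.all_simple_paths(g, u, v):
                w = sum(g[a][b]["length"] for a, b in zip(path, path[1:]))
                best = min(best, w)
            return 0.0 if u == v else best

        for u in nodes:
            for v in nodes:
                assert d.loc[u, v] == pytest.approx(brute(u, v))

    def test_triangle_inequality(self):
        src = DistanceSource(
            ["a", "b", "c", "d"],
            matrix=np.array(
                [[0, 3, 5, 9], [3, 0, 4, 7], [5, 4, 0, 6], [9, 7, 6, 0.0]]
            ),
        )
        d = shortest_path_distances(src).to_numpy()
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestConnectivity:
    dmat = None

    def _distances(self, pairs):
        import pandas as pd

        ids = sorted({a for a, _ in pairs} | {b for _, b in pairs} | {"f"})
        m = np.zeros((len(ids), len(ids)))
        df = __import__("pandas").DataFrame(m, index=ids, columns=ids)
        for (a, b), d in pairs.items():
            df.loc[a, b] = df.loc[b, a] = d
        return df

    def test_direct_evaluation(self):
        # neighbors (w=2, d=ln2), (w=4, d=2 ln2), alpha=1 -> 2*0.5 + 4*0.25 = 2
        df = self._distances({("f", "n1"): np.log(2), ("f", "n2"): 2 * np.log(2)})
        s = connectivity_score({"n1": 2.0, "n2": 4.0}, df, "f", alpha=1.0)
        assert s == pytest.approx(2.0)

    def test_alpha_zero_degenerates_to_weight_sum(self):
        df = self._distances({("f", "n1"): 100.0, ("f", "n2"): 5000.0})
        s = connectivity_score({"n1": 2.0, "n2": 4.0}, df, "f", alpha=0.0)
        assert s == pytest.approx(6.0)

    def test_focal_excluded_and_zero_distance_neighbor(self):
        df = self._distances({("f", "n1"): 0.0})
        s = connectivity_score({"n1": 1.0, "f": 99.0}, df, "f", alpha=0.7)
        assert s == pytest.approx(1.0)

    def test_negative_weight_rejected(self):
        df = self._distances({("f", "n1"): 1.0})
        with pytest.raises(ValueError):
            connectivity_score({"n1": -1.0}, df, "f", alpha=0.1)

    def test_monotone_decreasing_in_alpha(self):
        rng = np.random.default_rng(0)
        pairs = {("f", f"n{i}"): float(rng.uniform(10, 500)) for i in range(6)}
        df = self._distances(pairs)
        w = {f"n{i}": float(rng.uniform(0.1, 5)) for i in range(6)}
        scores = [
            connectivity_score(w, df, "f", alpha=a)
            for a in np.linspace(0.0, 0.2, 15)
        ]
        assert all(s1 >= s2 - 1e-12 for s1, s2 in zip(scores, scores[1:]))

    def test_invariant_under_neighbor_permutation(self):
        rng = np.random.default_rng(1)
        pairs = {("f", f"n{i}"): float(rng.uniform(10, 500)) for i in range(5)}
        df = self._distances(pairs)
        w = {f"n{i}": float(rng.uniform(0.1, 5)) for i in range(5)}
        s1 = connectivity_score(w, df, "f", alpha=0.05)
        s2 = connectivity_score(dict(reversed(list(w.items()))), df, "f", alpha=0.05)
        assert s1 == pytest.approx(s2)


class TestFeatureTable:
    def test_composition_matches_per_site_calls(self, small_bundle):
        feats = small_bundle.features
        census = small_bundle.census
        dmat = shortest_path_distances(small_bundle.distances)
        ref = census.years[-1]
        j = census.years.index(ref)
        extant = [
            s for s, c in zip(census.site_ids, census.counts[:, j]) if c >= 1
        ]
        occ = {s: census.occupancy(s).mean() for s in extant}
        hs = {s: harmonic_mean_size(census, s) for s in extant}
        for _, row in feats.iterrows():
            s = row.site_id
            assert row.age == compute_age(census, s, ref)
            assert row.harmonic_size == pytest.approx(harmonic_mean_size(census, s))
            assert row.s_t == pytest.approx(
                connectivity_score(occ, dmat, s, row.alpha)
            )
            assert row.s_s == pytest.approx(
                connectivity_score(hs, dmat, s, row.alpha)
            )

    def test_isolated_site_has_zero_connectivity(self):
        c = CensusTable(["a"], range(2000, 2003), [[2, 2, 2]])
        src = DistanceSource(["a"], matrix=np.zeros((1, 1)))
        out = feature_table(c, src, ConnectivityConfig(alpha=0.05), 2002)
        assert out.s_t.iloc[0] == 0.0 and out.s_s.iloc[0] == 0.0

    def test_packaged_study_table_has_33_populations(self):
        t = load_table1()
        assert len(t) == 33
        assert t.age.between(1, 21).all()
        assert (t["size"] > 0).all()


class TestCorrelate:
    def test_perfect_correlation(self):
        r, p = correlate([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_study_connectivity_correlation(self):
        t = load_table1()
        r, p = correlate(t.s_t, t.s_s)
        assert r == pytest.approx(0.6141, abs=1e-3)
        assert p < 0.001

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])
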