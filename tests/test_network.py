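"""Correlation, adjacency, scale-free fit, TOM, aggregation, extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dmrnetwork as dn
from dmrnetwork.io import ValidationError
from dmrnetwork.network import DegenerateDegreeError, SoftThresholdError

from conftest import (
    dmr_avg_nested_loops,
    pcc_textbook,
    random_adjacency,
    tom_triple_loop,
)


def matrix_from(values, probe_prefix="cg"):
    values = np.asarray(values, dtype=float)
    return dn.MethylationMatrix(
        [f"{probe_prefix}{i}" for i in range(values.shape[0])],
        [f"S{j}" for j in range(values.shape[1])],
        values,
    )


class TestCorrelation:
    def test_perfect_linear(self):
        m = matrix_from([[0.1, 0.2, 0.3], [0.2, 0.4, 0.6]])
        c = dn.compute_correlation(m, min_overlap=3)
        assert c.values[0, 1] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        m = matrix_from([[0.1, 0.2, 0.3], [0.3, 0.2, 0.1]])
        c = dn.compute_correlation(m, min_overlap=3)
        assert c.values[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        vals = rng.random((20, 15))
        c = dn.compute_correlation(matrix_from(vals))
        for i in range(20):
            for j in range(i + 1, 20):
                assert c.values[i, j] == pytest.approx(
                    pcc_textbook(vals[i], vals[j]), abs=1e-12
                )

    def test_pairwise_complete_with_missing(self, rng):
        vals = rng.random((4, 30))
        vals[0, :5] = np.nan
        c = dn.compute_correlation(matrix_from(vals))
        obs = ~np.isnan(vals[0]) & ~np.isnan(vals[1])
        assert c.n_obs[0, 1] == obs.sum() == 25
        assert c.values[0, 1] == pytest.approx(
            pcc_textbook(vals[0, obs], vals[1, obs]), abs=1e-12
        )

    def test_all_missing_probe_is_named(self):
        vals = np.full((2, 12), 0.4)
        vals[1] = np.nan
        with pytest.raises(ValidationError, match="cg1"):
            dn.compute_correlation(matrix_from(vals))

    def test_constant_probe_zeroed_and_counted(self, rng):
        vals = rng.random((3, 15))
        vals[0] = 0.5
        c = dn.compute_correlation(matrix_from(vals))
        assert c.values[0, 1] == 0.0 and c.values[0, 2] == 0.0
        assert c.n_constant_pairs == 2
        assert np.isfinite(c.values).all()

    def test_low_overlap_error_and_flag(self, rng):
        vals = rng.random((3, 12))
        vals[0, :8] = np.nan  # only 4 shared samples with the others
        m = matrix_from(vals)
        with pytest.raises(ValidationError, match="fewer than 10"):
            dn.compute_correlation(m, min_overlap=10)
        c = dn.compute_correlation(m, min_overlap=10, on_low_overlap="flag")
        assert c.values[0, 1] == 0.0 and c.n_low_overlap_pairs == 2


class TestAdjacency:
    @pytest.mark.parametrize(
        "pcc,beta,expected", [(1.0, 5, 1.0), (0.0, 3, 0.0), (-0.5, 2, 0.25)]
    )
    def test_power_examples(self, pcc, beta, expected):
        c = dn.CorrelationMatrix(
            ["a", "b"], np.array([[1.0, pcc], [pcc, 1.0]]), np.full((2, 2), 30)
        )
        assert dn.adjacency(c, beta).values[0, 1] == pytest.approx(expected)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 19))
    def test_raising_beta_never_increases_offdiag(self, seed, b):
        rng = np.random.default_rng(seed)
        r = rng.uniform(-1, 1, size=(6, 6))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        c = dn.CorrelationMatrix([f"p{i}" for i in range(6)], r, np.full((6, 6), 30))
        a1, a2 = dn.adjacency(c, b).values, dn.adjacency(c, b + 1).values
        off = ~np.eye(6, dtype=bool)
        assert np.all(a2[off] <= a1[off] + 1e-15)
        fixed = np.isin(np.abs(r), (0.0, 1.0)) & off
        assert np.array_equal(a1[fixed], a2[fixed])


class TestScaleFreeFit:
    def test_power_law_connectivity_sequence(self):
        """Connectivity k ∝ rank^(-1) implies p(k) ∝ k^(-2); the binned
        log-log fit must be close to linear (independent OLS agrees)."""
        n = 200
        c = 0.9 / np.arange(1, n + 1)
        a = np.outer(c, c)
        np.fill_diagonal(a, 1.0)
        adj = dn.AdjacencyMatrix([f"p{i}" for i in range(n)], a, beta=1.0)
        fit = dn.scale_free_fit(adj)
        assert fit.r_squared >= 0.9
        assert fit.slope < 0
        # independent oracle: rebuild the binned points and OLS them
        from scipy.stats import linregress

        k = a.sum(axis=1) - 1.0
        counts, edges = np.histogram(k, bins=10)
        mids = []
        for lo, hi, cnt in zip(edges[:-1], edges[1:], counts):
            if cnt:
                in_bin = (k >= lo) & (k < hi if hi < edges[-1] else k <= hi)
                mids.append((k[in_bin].mean(), cnt / n))
        res = linregress(np.log10([m for m, _ in mids]), np.log10([p for _, p in mids]))
        assert fit.r_squared == pytest.approx(res.rvalue**2, abs=1e-12)
        assert fit.slope == pytest.approx(res.slope, abs=1e-12)

    def test_complete_graph_degenerate(self):
        a = np.ones((8, 8))
        adj = dn.AdjacencyMatrix([f"p{i}" for i in range(8)], a, beta=1.0)
        with pytest.raises(DegenerateDegreeError, match="degenerate"):
            dn.scale_free_fit(adj)

    def test_two_points_always_collinear(self):
        # two non-empty bins fit exactly: documents why n_bins must be > 2
        a = np.eye(5)
        for i, j, w in [(0, 1, 0.2), (2, 3, 0.5), (2, 4, 0.3), (3, 4, 0.3)]:
            a[i, j] = a[j, i] = w
        adj = dn.AdjacencyMatrix(list("abcde"), a, beta=1.0)
        fit = dn.scale_free_fit(adj, n_bins=2)
        assert fit.n_bins_used == 2
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


class TestSoftThresholdSelection:
    def test_blocks_selection_is_exhaustive_minimum(self, blocks):
        matrix, *_ = blocks
        corr = dn.compute_correlation(matrix)
        params = dn.NetworkParams()
        beta, table = dn.select_soft_threshold(corr, params)
        qualifying = []
        for b in params.beta_grid:  # brute-force scan
            try:
                f = dn.scale_free_fit(dn.adjacency(corr, b))
            except DegenerateDegreeError:
                continue
            if f.r_squared > params.r2_threshold and f.slope < 0:
                qualifying.append(b)
        assert qualifying and beta == min(qualifying)
        row = table.loc[table.beta == beta].iloc[0]
        assert row.r_squared > 0.70 and row.slope < 0

    def test_threshold_near_zero_returns_first_negative_slope(self, blocks):
        matrix, *_ = blocks
        corr = dn.compute_correlation(matrix)
        params = dn.NetworkParams(r2_threshold=1e-9)
        beta, table = dn.select_soft_threshold(corr, params)
        slopes = table.set_index("beta").slope
        first_negative = next(b for b in params.beta_grid if slopes[b] < 0)
        assert beta == first_negative

    def test_no_qualifier_raises_with_diagnostics(self, rng):
        vals = rng.random((30, 20))
        corr = dn.compute_correlation(matrix_from(vals))
        with pytest.raises(SoftThresholdError) as err:
            dn.select_soft_threshold(corr, dn.NetworkParams(r2_threshold=0.9999))
        assert isinstance(err.value.diagnostics, pd.DataFrame)
        assert len(err.value.diagnostics) == 20


class TestTOM:
    def test_complete_unit_graph(self):
        a = np.ones((5, 5))
        tom = dn.compute_tom(dn.AdjacencyMatrix([f"p{i}" for i in range(5)], a, 1.0))
        assert np.allclose(tom.values, 1.0)

    def test_star_leaf_leaf_is_half(self):
        # L_ij = 1, k_i = k_j = 1, a_ij = 0  =>  1 / (1 + 1 - 0) = 1/2
        a = np.eye(3)
        a[0, 1] = a[1, 0] = a[0, 2] = a[2, 0] = 1.0
        tom = dn.compute_tom(dn.AdjacencyMatrix(["c", "l1", "l2"], a, 1.0))
        assert tom.values[1, 2] == pytest.approx(0.5)
        assert np.array_equal(tom.values, tom_triple_loop(a))

    @pytest.mark.parametrize("seed", range(20))
    def test_matrix_product_equals_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 61))
        adj = random_adjacency(rng, n)
        tom = dn.compute_tom(adj)
        assert np.abs(tom.values - tom_triple_loop(adj.values)).max() < 1e-10

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_on_random_adjacency(self, seed):
        rng = np.random.default_rng(seed)
        tom = dn.compute_tom(random_adjacency(rng, int(rng.integers(3, 40))))
        assert tom.values.min() >= 0.0 and tom.values.max() <= 1.0
        assert np.allclose(tom.values, tom.values.T)

    def test_entries_outside_unit_interval_rejected(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 1.5
        with pytest.raises(ValidationError):
            dn.compute_tom(dn.AdjacencyMatrix(list("abc"), a, 1.0))


class TestDMRAverageTOM:
    def _dmrs(self, spec):
        return dn.DMRSet(
            [
                dn.DMR(f"D{i}", "chr1", 100 * i + 1, 100 * i + 50, f"G{i}", probes)
                for i, probes in enumerate(spec)
            ]
        )

    def _tom(self, values, ids):
        a = np.asarray(values, dtype=float)
        adj = dn.AdjacencyMatrix(ids, np.eye(len(ids)), 1.0)
        return dn.TOMResult(ids, a, adj)

    def test_singleton_pair_is_tom_entry(self):
        tom = self._tom([[1.0, 0.37], [0.37, 1.0]], ["p1", "p2"])
        dt = dn.dmr_average_tom(tom, self._dmrs([["p1"], ["p2"]]))
        assert dt.values[0, 1] == pytest.approx(0.37)

    def test_cross_pair_arithmetic_mean(self):
        vals = np.eye(3)
        vals[0, 2] = vals[2, 0] = 0.2
        vals[1, 2] = vals[2, 1] = 0.4
        tom = self._tom(vals, ["p1", "p2", "p3"])
        dt = dn.dmr_average_tom(tom, self._dmrs([["p1", "p2"], ["p3"]]))
        assert dt.values[0, 1] == pytest.approx(0.3)
        assert dt.pair_counts[0, 1] == 2

    def test_blocks_matches_nested_loop_oracle(self, blocks, blocks_tom):
        _, dmrs, _, _ = blocks
        dt = dn.dmr_average_tom(blocks_tom, dmrs)
        oracle = dmr_avg_nested_loops(blocks_tom.values, blocks_tom.probe_ids, dmrs)
        assert np.abs(dt.values - oracle).max() < 1e-12

    def test_all_singletons_reduce_to_probe_tom(self, rng):
        adj = random_adjacency(rng, 12)
        tom = dn.compute_tom(adj)
        dmrs = self._dmrs([[p] for p in adj.probe_ids])
        dt = dn.dmr_average_tom(tom, dmrs)
        assert np.allclose(dt.values, tom.values, atol=1e-15)

    def test_union_mean_variant(self):
        vals = np.eye(3)
        vals[0, 1] = vals[1, 0] = 0.6  # within DMR A
        vals[0, 2] = vals[2, 0] = 0.2
        vals[1, 2] = vals[2, 1] = 0.4
        tom = self._tom(vals, ["p1", "p2", "p3"])
        dt = dn.dmr_average_tom(
            tom, self._dmrs([["p1", "p2"], ["p3"]]), include_within_dmr=True
        )
        # union of 3 probes: pairs (1,2)x2, (1,3)x2, (2,3)x2 -> mean of 6 entries
        assert dt.values[0, 1] == pytest.approx((0.6 + 0.2 + 0.4) * 2 / 6)

    def test_unresolvable_probe_raises(self, blocks_tom):
        dmrs = self._dmrs([["nope1"], ["nope2"]])
        with pytest.raises(ValidationError, match="nope1"):
            dn.dmr_average_tom(blocks_tom, dmrs)


class TestExtractionAndHubs:
    def _dt(self, values, ids):
        v = np.asarray(values, dtype=float)
        return dn.DMRTomMatrix(ids, v, np.ones_like(v))

    def _dmrs(self, ids):
        return dn.DMRSet(
            [dn.DMR(i, "chr1", 1 + k * 100, 50 + k * 100, f"G_{i}", [f"{i}_p"])
             for k, i in enumerate(ids)]
        )

    def test_cutoff_zero_complete_graph(self, rng):
        n = 7
        v = rng.uniform(0.01, 1.0, (n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        ids = [f"D{i}" for i in range(n)]
        net = dn.extract_network(self._dt(v, ids), self._dmrs(ids), 0.0)
        assert net.n_edges == n * (n - 1) // 2

    def test_cutoff_above_max_gives_isolates(self, rng):
        ids = [f"D{i}" for i in range(5)]
        v = rng.uniform(0.0, 0.3, (5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        net = dn.extract_network(self._dt(v, ids), self._dmrs(ids), 0.9)
        assert net.n_edges == 0
        assert set(net.components.values()) == set(range(1, 6))

    @pytest.mark.parametrize("seed", range(10))
    def test_edge_sets_nested_under_increasing_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        ids = [f"D{i}" for i in range(n)]
        dmrs = self._dmrs(ids)
        dt = self._dt(v, ids)
        prev = None
        for cut in (0.1, 0.3, 0.5, 0.7, 0.9):
            edges = dn.extract_network(dt, dmrs, cut).edge_set()
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_diagonal_never_thresholded(self):
        ids = ["D0", "D1"]
        v = np.array([[1.0, 0.05], [0.05, 1.0]])
        net = dn.extract_network(self._dt(v, ids), self._dmrs(ids), 0.5)
        assert net.n_edges == 0  # the unit diagonal creates no self-edges

    def test_component_labels_by_descending_size(self):
        ids = [f"D{i}" for i in range(5)]
        v = np.eye(5)
        for i, j in [(0, 1), (1, 2), (3, 4)]:
            v[i, j] = v[j, i] = 0.8
        net = dn.extract_network(self._dt(v, ids), self._dmrs(ids), 0.5)
        assert net.components["D0"] == net.components["D1"] == net.components["D2"] == 1
        assert net.components["D3"] == net.components["D4"] == 2

    def test_star_hub_table(self):
        ids = [f"D{i}" for i in range(10)]
        edges = [("D0", f"D{i}", 0.9) for i in range(1, 10)]
        net = dn.DMRNetwork(ids, {i: f"G_{i}" for i in ids}, edges, 0.5)
        tab = dn.hub_table(net)
        assert tab.iloc[0].dmr_id == "D0"
        assert tab.iloc[0].edge_count == 9
        assert tab.iloc[0].percent_of_total_edges == pytest.approx(100.0)
        assert tab.iloc[-1].dmr_id == "Total" and tab.iloc[-1].edge_count == 9

    def test_hub_percentages_against_degree_oracle(self, rng):
        import networkx as nx

        g = nx.gnp_random_graph(25, 0.25, seed=4)
        ids = [f"D{i}" for i in range(25)]
        edges = [(ids[u], ids[v], 0.6) for u, v in g.edges]
        net = dn.DMRNetwork(ids, {i: "" for i in ids}, edges, 0.5)
        tab = dn.hub_table(net, top_n=25)
        total = g.number_of_edges()
        degs = dict(g.degree)
        for row in tab.itertuples():
            if row.dmr_id == "Total":
                continue
            d = degs[int(row.dmr_id[1:])]
            assert row.edge_count == d
            assert row.percent_of_total_edges == pytest.approx(100.0 * d / total)

    def test_empty_network_hub_table(self):
        net = dn.DMRNetwork(["D0", "D1"], {}, [], 0.9)
        tab = dn.hub_table(net)
        assert len(tab) == 1 and tab.iloc[0].edge_count == 0

    def test_hub_tie_break_by_gene_then_id(self):
        ids = ["D2", "D1", "D3"]
        edges = [("D1", "D2", 0.9), ("D2", "D3", 0.9), ("D1", "D3", 0.9)]
        net = dn.DMRNetwork(ids, {"D1": "B", "D2": "A", "D3": "A"}, edges, 0.5)
        tab = dn.hub_table(net)
        assert list(tab.dmr_id[:3]) == ["D2", "D3", "D1"]  # A before B, then id
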