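"""Graphical-lasso networks, Delaunay neighbors, synchrony indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clocksync.errors import (
    ClockSyncError,
    ConstantSeriesError,
    DegenerateGeometryError,
)
from clocksync.synchrony import (
    CorrelationNetwork,
    NeighborGraph,
    SeriesMatrix,
    delaunay_graph,
    index_time_course,
    kkt_residual,
    sparse_network,
    synchrony_indices,
)
from clocksync.synth import TimelapseScenario, gen_timelapse


def _noise_series(rng, n=40, T=41, sd=0.05, mean=0.4):
    """Independent cells at the natural rel_nuc intensity scale."""
    return mean + sd * rng.standard_normal((n, T))


class TestSparseNetwork:
    def test_solution_satisfies_stationarity(self, rng):
        X = _noise_series(rng, n=30, sd=1.0)   # standardized-scale instance
        net = sparse_network(X, rho=0.1, tol=1e-12)
        assert kkt_residual(net.sample_cov, net.precision, net.rho) < 1e-6

    def test_large_rho_gives_empty_network(self, rng):
        X = _noise_series(rng, n=20)
        Xc = X - X.mean(1, keepdims=True)
        S = Xc @ Xc.T / Xc.shape[1]
        rho = np.abs(S - np.diag(np.diag(S))).max() * 1.001
        net = sparse_network(X, rho=rho)
        assert net.edges == set()

    def test_independent_cells_give_sparse_network_at_default_rho(self, rng):
        X = _noise_series(rng, n=40, sd=0.05)
        net = sparse_network(X)
        assert len(net.edges) < 0.05 * (40 * 39 / 2)

    def test_constant_series_rejected_by_cell_id(self, rng):
        X = _noise_series(rng, n=5)
        X[3] = 0.7
        ids = np.array([10, 11, 12, 13, 14])
        sm = SeriesMatrix(X, rng.uniform(0, 10, (5, 2)),
                          np.arange(X.shape[1], dtype=float), ids)
        with pytest.raises(ConstantSeriesError, match="13"):
            sparse_network(sm)

    def test_near_identical_cells_stabilized_with_jitter_warning(self, rng):
        # perfect synchrony: correlation matrix is numerically rank one
        base = 0.5 + 0.45 * np.sin(np.linspace(0, 12, 41))
        X = np.tile(base, (10, 1)) + 1e-4 * rng.standard_normal((10, 41))
        with pytest.warns(RuntimeWarning, match="jitter"):
            net = sparse_network(X, standardize=True)
        assert net.jitter > 0


class TestDelaunay:
    def test_triangle_has_three_edges(self):
        g = delaunay_graph(np.array([[0, 0], [1, 0], [0, 1.0]]))
        assert g.edges == {(0, 1), (0, 2), (1, 2)}

    def test_four_points_in_general_position_have_five_edges(self):
        # convex quadrilateral: 4 hull edges + 1 diagonal
        g = delaunay_graph(np.array([[0, 0], [2, 0], [2.1, 1.9], [0, 2.0]]))
        assert len(g.edges) == 5

    def test_collinear_points_are_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            delaunay_graph(np.array([[0, 0], [1, 1], [2, 2.0], [3, 3.0]]))

    @given(st.integers(4, 40), st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_planar_edge_bound(self, n, seed):
        pts = np.random.default_rng(seed).uniform(0, 100, (n, 2))
        g = delaunay_graph(pts)
        assert len(g.edges) <= 3 * n - 6


def _net(n, edges):
    return CorrelationNetwork(
        precision=np.eye(n), covariance=np.eye(n), sample_cov=np.eye(n),
        rho=0.013, edges=set(edges), n=n,
    )


class TestIndices:
    def test_empty_network_scores_zero(self):
        neigh = NeighborGraph({(0, 1), (1, 2)}, 4)
        idx = synchrony_indices(_net(4, []), neigh)
        assert idx.local_index == 0.0 and idx.global_index == 0.0

    def test_network_covering_neighbors_scores_local_one(self):
        neigh = NeighborGraph({(0, 1), (1, 2)}, 4)
        idx = synchrony_indices(_net(4, [(0, 1), (1, 2), (0, 3)]), neigh)
        assert idx.local_index == 1.0

    def test_complete_network_scores_global_one(self):
        n = 5
        allpairs = {(i, j) for i in range(n) for j in range(i + 1, n)}
        idx = synchrony_indices(_net(n, allpairs), NeighborGraph({(0, 1)}, n))
        assert idx.global_index == 1.0

    def test_node_mismatch_rejected(self):
        with pytest.raises(ClockSyncError):
            synchrony_indices(_net(4, []), NeighborGraph({(0, 1)}, 5))

    @given(st.integers(4, 15), st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone_under_edge_addition(self, n, seed):
        rng = np.random.default_rng(seed)
        allpairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        neigh_edges = {e for e in allpairs if rng.random() < 0.4} or {allpairs[0]}
        net_edges = {e for e in allpairs if rng.random() < 0.3}
        neigh = NeighborGraph(neigh_edges, n)
        idx = synchrony_indices(_net(n, net_edges), neigh)
        assert 0.0 <= idx.local_index <= 1.0
        assert 0.0 <= idx.global_index <= 1.0
        remaining = [e for e in allpairs if e not in net_edges]
        if remaining:
            extra = remaining[rng.integers(len(remaining))]
            idx2 = synchrony_indices(_net(n, net_edges | {extra}), neigh)
            assert idx2.local_index >= idx.local_index
            assert idx2.global_index > idx.global_index


class TestTimeCourse:
    def test_windows_below_minimum_marked_unavailable(self, rng):
        X = _noise_series(rng, n=10, T=10)
        sm = SeriesMatrix(X, rng.uniform(0, 100, (10, 2)), np.arange(10.0) * 3)
        df = index_time_course(sm, eval_times=np.array([0.0, 3.0, 9.0, 27.0]))
        assert not df["available"].iloc[0] and not df["available"].iloc[1]
        assert df["available"].iloc[2] and df["available"].iloc[3]
        assert np.isnan(df.loc[0, "local_index"])

    def test_local_index_rises_after_synchronized_stimulus(self):
        tl = gen_timelapse(
            TimelapseScenario(n_cells=40, spatial_correlation=True, seed=31),
            render=False,
        )
        sm = tl.series_matrix()
        df = index_time_course(
            sm, eval_times=np.array([15.0, 120.0]), tol=1e-7
        )
        early, late = df["local_index"].to_numpy()
        assert late > early

    def test_stationary_independent_cells_stay_near_zero(self, rng):
        X = _noise_series(rng, n=30, T=41)
        sm = SeriesMatrix(X, rng.uniform(0, 400, (30, 2)), np.arange(41.0) * 3)
        df = index_time_course(sm, eval_times=np.array([60.0, 120.0]), tol=1e-7)
        assert (df["local_index"] < 0.1).all()


class TestDiscrimination:
    def test_spatially_correlated_latencies_raise_local_index(self):
        on = gen_timelapse(
            TimelapseScenario(spatial_correlation=True, seed=101), render=False
        )
        off = gen_timelapse(
            TimelapseScenario(spatial_correlation=False, seed=201), render=False
        )
        net_on = sparse_network(on.series_matrix(), tol=1e-7)
        net_off = sparse_network(off.series_matrix(), tol=1e-7)
        li_on = synchrony_indices(net_on, delaunay_graph(on.coords)).local_index
        li_off = synchrony_indices(net_off, delaunay_graph(off.coords)).local_index
        assert li_on > li_off
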