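"""Cell-to-cell synchrony of translocation dynamics.

Which cells move together?  An L1-penalized Gaussian graphical model
(graphical lasso, penalty ρ = 0.013 following the original analysis) is fit
to the cells' translocation series; nonzero off-diagonal precision entries
define "correlated" edges.  Spatial neighbors are the edges of the Delaunay
triangulation of mean cell positions.  Two summary indices follow:

* local index  = |E_net ∩ E_delaunay| / |E_delaunay|  — fraction of
  neighboring cell pairs that are also correlated;
* global index = |E_net| / C(n, 2) — correlated fraction of all pairs.

The series enter the covariance *centered but on their natural intensity
scale* (relative nuclear intensity, variance ~1e-3..1e-2): the fixed penalty
0.013 is only meaningfully selective on that scale.  ``standardize=True``
switches to per-cell z-scoring.

The fitted precision matrix is always verified against the stationarity
(KKT) conditions of the penalized log-likelihood — the check is computed
here, independently of the solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .errors import (
    ClockSyncError,
    ConstantSeriesError,
    DegenerateGeometryError,
    NetworkConvergenceError,
)

__all__ = [
    "SeriesMatrix",
    "CorrelationNetwork",
    "NeighborGraph",
    "SynchronyIndices",
    "sparse_network",
    "delaunay_graph",
    "synchrony_indices",
    "index_time_course",
    "kkt_residual",
    "DEFAULT_RHO",
    "EDGE_EPS",
]

DEFAULT_RHO = 0.013
EDGE_EPS = 1e-8
_JITTER_LADDER = (0.0, 1e-6, 1e-4, 1e-2, 5e-2)


@dataclass
class SeriesMatrix:
    """Cells x timepoints translocation signal plus mean cell coordinates."""

    data: np.ndarray            # (n_cells, n_times)
    coords: np.ndarray          # (n_cells, 2)
    times: np.ndarray           # (n_times,), minutes
    cell_ids: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.coords = np.asarray(self.coords, float)
        self.times = np.asarray(self.times, float)
        n, t = self.data.shape
        if self.coords.shape != (n, 2):
            raise ClockSyncError("coords must be (n_cells, 2) matching data rows")
        if len(self.times) != t:
            raise ClockSyncError("times length must match data columns")
        if n < 2 or t < 3:
            raise ClockSyncError("need >= 2 cells and >= 3 timepoints")
        if self.cell_ids is None:
            self.cell_ids = np.arange(n)

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @classmethod
    def from_tracks(cls, tracks) -> "SeriesMatrix":
        """Build from complete, frame-aligned tracks (gap-free common grid)."""
        from .tracking import relative_nuclear_series

        series = [relative_nuclear_series(tr) for tr in tracks]
        common = series[0].index
        for s in series[1:]:
            common = common.intersection(s.index)
        if len(common) < 3:
            raise ClockSyncError("tracks share fewer than 3 timepoints")
        data = np.stack([s.loc[common].to_numpy() for s in series])
        coords = np.array([
            [tr.frames["x"].mean(), tr.frames["y"].mean()] for tr in tracks
        ])
        return cls(data, coords, np.asarray(common, float),
                   np.array([tr.cell_id for tr in tracks]))


@dataclass
class CorrelationNetwork:
    """Sparse inverse-covariance network over cells."""

    precision: np.ndarray
    covariance: np.ndarray           # fitted covariance (precision^{-1})
    sample_cov: np.ndarray           # empirical covariance the fit saw
    rho: float
    edges: set[tuple[int, int]]
    n: int
    jitter: float = 0.0
    kkt: float = np.nan


@dataclass
class NeighborGraph:
    """Delaunay edge set over cell coordinates."""

    edges: set[tuple[int, int]]
    n: int


@dataclass
class SynchronyIndices:
    local_index: float
    global_index: float
    n_net_edges: int
    n_neighbor_edges: int
    n_shared_edges: int


def kkt_residual(sample_cov: np.ndarray, precision: np.ndarray, rho: float,
                 edge_eps: float = EDGE_EPS) -> float:
    """Stationarity residual of the off-diagonal-penalized graphical lasso.

    At the optimum W = Θ⁻¹ satisfies, elementwise off the diagonal,
    W_ij − S_ij = ρ·sign(Θ_ij) where Θ_ij ≠ 0 and |W_ij − S_ij| ≤ ρ where
    Θ_ij = 0, with W_ii = S_ii.  Returns the largest violation.
    """
    W = np.linalg.inv(precision)
    G = W - sample_cov
    off = ~np.eye(len(W), dtype=bool)
    nz = off & (np.abs(precision) > edge_eps)
    z = off & ~nz
    res = np.abs(np.diag(G)).max() if len(W) else 0.0
    if nz.any():
        res = max(res, np.abs(G[nz] - rho * np.sign(precision[nz])).max())
    if z.any():
        res = max(res, max(0.0, np.abs(G[z]).max() - rho))
    return float(res)


def sparse_network(
    series: SeriesMatrix | np.ndarray,
    rho: float = DEFAULT_RHO,
    edge_eps: float = EDGE_EPS,
    standardize: bool = False,
    tol: float = 1e-9,
    enet_tol: float | None = None,
    max_iter: int = 500,
    kkt_tol: float = 1e-4,
) -> CorrelationNetwork:
    """Graphical-lasso network over cells at penalty ``rho``.

    Constant series are rejected (by cell id).  A near-singular covariance
    (nearly identical cells) is stabilized by the smallest diagonal jitter
    from a fixed ladder that lets the solver converge; the jitter used is
    recorded on the result and warned about.  The returned precision matrix
    has passed the KKT stationarity check within ``kkt_tol``.
    """
    X = series.data if isinstance(series, SeriesMatrix) else np.asarray(series, float)
    ids = (series.cell_ids if isinstance(series, SeriesMatrix)
           else np.arange(X.shape[0]))
    if X.shape[1] < 3:
        raise ClockSyncError("need >= 3 timepoints")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = ids[np.flatnonzero(sd == 0)[0]]
        raise ConstantSeriesError(f"cell {bad} has a constant series")
    Xc = X - X.mean(axis=1, keepdims=True)
    if standardize:
        Xc = Xc / sd[:, None]
    S = Xc @ Xc.T / Xc.shape[1]

    n = S.shape[0]
    if enet_tol is None:
        enet_tol = min(1e-6, tol)
    last_err: str | None = None
    for jit in _JITTER_LADDER:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cov, prec = _sk_graphical_lasso(
                    S + jit * np.eye(n), alpha=rho, tol=tol,
                    enet_tol=enet_tol, max_iter=max_iter,
                )
        except (FloatingPointError, np.linalg.LinAlgError) as e:
            last_err = f"{type(e).__name__}: {e}"
            continue
        res = kkt_residual(S + jit * np.eye(n), prec, rho, edge_eps)
        if res > kkt_tol:
            last_err = f"KKT residual {res:.3e} > {kkt_tol:g}"
            continue
        if jit > 0:
            warnings.warn(
                f"covariance near-singular: added {jit:g} diagonal jitter",
                RuntimeWarning, stacklevel=2,
            )
        edges = {
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if abs(prec[i, j]) > edge_eps
        }
        return CorrelationNetwork(
            precision=prec, covariance=cov, sample_cov=S + jit * np.eye(n),
            rho=rho, edges=edges, n=n, jitter=jit, kkt=res,
        )
    raise NetworkConvergenceError(
        f"graphical lasso failed to converge (last: {last_err})"
    )


def delaunay_graph(coords: np.ndarray) -> NeighborGraph:
    """Delaunay neighbor edges over cell coordinates.

    Requires >= 3 points not all collinear.  Degenerate (co-circular)
    configurations are resolved deterministically by Qhull's tie handling;
    identical input always yields an identical edge set.
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) < 3:
        raise DegenerateGeometryError("need >= 3 planar points")
    try:
        tri = Delaunay(coords)
    except QhullError as e:
        raise DegenerateGeometryError(f"degenerate geometry: {e}") from e
    if tri.simplices.size == 0:
        raise DegenerateGeometryError("degenerate geometry: no triangles (collinear points?)")
    edges: set[tuple[int, int]] = set()
    for s in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = int(s[a]), int(s[b])
                edges.add((min(i, j), max(i, j)))
    return NeighborGraph(edges=edges, n=len(coords))


def synchrony_indices(net: CorrelationNetwork, neigh: NeighborGraph) -> SynchronyIndices:
    """Local and global correlation indices from the two edge sets."""
    if net.n != neigh.n:
        raise ClockSyncError(f"node mismatch: network has {net.n}, neighbors {neigh.n}")
    if not neigh.edges:
        raise ClockSyncError("neighbor graph has no edges")
    shared = net.edges & neigh.edges
    n_pairs = net.n * (net.n - 1) // 2
    return SynchronyIndices(
        local_index=len(shared) / len(neigh.edges),
        global_index=len(net.edges) / n_pairs,
        n_net_edges=len(net.edges),
        n_neighbor_edges=len(neigh.edges),
        n_shared_edges=len(shared),
    )


def index_time_course(
    series: SeriesMatrix,
    eval_times: np.ndarray | None = None,
    rho: float = DEFAULT_RHO,
    min_timepoints: int = 3,
    **network_kw,
) -> pd.DataFrame:
    """Expanding-window time evolution of the synchrony indices.

    For each evaluation time t the window [first frame, t] feeds the
    network; the neighbor graph is fixed (coordinates are per-track means).
    Windows shorter than ``min_timepoints`` frames yield a row flagged
    unavailable rather than fabricated indices.
    """
    neigh = delaunay_graph(series.coords)
    if eval_times is None:
        eval_times = series.times
    rows = []
    for t in np.asarray(eval_times, float):
        m = series.times <= t
        row = {"t_min": t, "available": False,
               "local_index": np.nan, "global_index": np.nan}
        if m.sum() >= min_timepoints:
            sub = SeriesMatrix(series.data[:, m], series.coords,
                               series.times[m], series.cell_ids)
            try:
                net = sparse_network(sub, rho=rho, **network_kw)
            except (ConstantSeriesError, NetworkConvergenceError):
                rows.append(row)
                continue
            idx = synchrony_indices(net, neigh)
            row.update(available=True, local_index=idx.local_index,
                       global_index=idx.global_index)
        rows.append(row)
    return pd.DataFrame(rows)
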