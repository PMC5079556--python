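"""Fire-spread network construction and node centralities.

The lattice is recast as a directed weighted graph: the weight of edge
``l -> k`` is the one-step probability that fire spreads from cell ``l`` into
cell ``k``.  High-probability routes are short "distances", so shortest-path
centralities use the reciprocal transform ``d = 1/p`` (configurable to
``-ln p``, which induces the same rankings on uniform-structure lattices).

Measures:

* betweenness — fraction of weighted geodesics through a node, exact path
  multiplicities (Brandes), paths followed in the flow direction;
* closeness — inverse summed geodesic out-distance;
* eigencentrality — principal eigenvector of ``A^T`` (fire flowing *into* a
  node), nonnegative, normalized to unit sum;
* Bonacich — ``x = (I - (beta/lambda_max) A^T)^(-1) e``, the attenuated
  influence measure interpolating between weighted in-degree (beta -> 0) and
  eigencentrality (beta -> 1).

Shortest-path computations are delegated to igraph's C core so that
2500-node campaign lattices stay fast; the module surface hides the backend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .landscape import CAParams, LandscapeGrid
from .spread import MOORE_OFFSETS, ignition_probability_fields

logger = logging.getLogger("firebreaks")

#: Iterative eigen/linear solves: relative tolerance and iteration cap factor.
SOLVER_TOL = 1e-8
SOLVER_MAXITER_PER_NODE = 10


class CentralityError(ValueError):
    """Invalid centrality input."""


class ConvergenceError(RuntimeError):
    """An iterative solver failed to converge within its iteration budget."""


@dataclass
class FireSpreadNetwork:
    """Sparse directed weighted adjacency over lattice nodes.

    ``adjacency[l, k]`` is the spread probability ``p(l -> k)``; zero-
    probability pairs are absent from the sparse structure and non-fuel nodes
    are fully isolated.  Node ``k`` maps to cell ``divmod(k, n_cols)``.
    """

    adjacency: sp.csr_matrix
    n_rows: int
    n_cols: int
    _lambda_max: float | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def lambda_max(self) -> float:
        """Largest eigenvalue of A (computed once, then cached)."""
        if self._lambda_max is None:
            self._lambda_max = _principal_eigenpair(self.adjacency)[0]
        return self._lambda_max


@dataclass
class CentralityScores:
    """Per-node scores for one centrality measure."""

    measure: str  # betweenness | closeness | eigen | bonacich | degree
    scores: np.ndarray
    beta: float | None = None  # Bonacich attenuation, if applicable

    def ranking(self) -> np.ndarray:
        """Node indices sorted by descending score, ties by ascending index."""
        return rank_nodes(self.scores)


def rank_nodes(scores: np.ndarray) -> np.ndarray:
    """Descending-score order with deterministic ascending-index tie-break."""
    scores = np.asarray(scores)
    return np.lexsort((np.arange(scores.size), -scores))


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


def build_network(
    grid: LandscapeGrid, params: CAParams | None = None
) -> FireSpreadNetwork:
    """Build the directed weighted fire-spread network of a landscape.

    One edge per ordered Moore-neighbor pair with positive spread
    probability; weights come from the simple or full CA kernel.  Edges out
    of non-fuel cells are dropped too (a break can neither ignite nor burn).
    """
    prob = ignition_probability_fields(grid, params)  # (8, R, C), entry = p into (r,c)
    periodic = grid.boundary == "periodic"
    n_rows, n_cols = grid.shape
    rows_idx, cols_idx = np.meshgrid(
        np.arange(n_rows), np.arange(n_cols), indexing="ij"
    )
    flammable = grid.flammable
    src_list, dst_list, w_list = [], [], []
    for d, (dr, dc) in enumerate(MOORE_OFFSETS):
        src_r = rows_idx + dr
        src_c = cols_idx + dc
        if periodic:
            src_r %= n_rows
            src_c %= n_cols
            valid = np.ones(grid.shape, dtype=bool)
        else:
            valid = (src_r >= 0) & (src_r < n_rows) & (src_c >= 0) & (src_c < n_cols)
            src_r = np.clip(src_r, 0, n_rows - 1)
            src_c = np.clip(src_c, 0, n_cols - 1)
        w = prob[d]
        keep = valid & (w > 0) & flammable[src_r, src_c]
        src_list.append((src_r * n_cols + src_c)[keep])
        dst_list.append((rows_idx * n_cols + cols_idx)[keep])
        w_list.append(w[keep])
    n = grid.n_nodes
    adj = sp.coo_matrix(
        (np.concatenate(w_list), (np.concatenate(src_list), np.concatenate(dst_list))),
        shape=(n, n),
    ).tocsr()
    adj.eliminate_zeros()
    return FireSpreadNetwork(adjacency=adj, n_rows=n_rows, n_cols=n_cols)


def edge_distance(weight, transform: str = "reciprocal"):
    """Map a spread probability to a shortest-path distance.

    High probability = short distance.  ``reciprocal`` (default) is ``1/p``;
    ``neglog`` is ``-ln p`` (additive along paths of multiplied
    probabilities).  Both are monotone decreasing in ``p``.
    """
    w = np.asarray(weight, dtype=float)
    if (w <= 0).any():
        raise CentralityError("edge weights must be positive probabilities")
    if transform == "reciprocal":
        out = 1.0 / w
    elif transform == "neglog":
        out = -np.log(w)
    else:
        raise CentralityError(f"unknown distance transform {transform!r}")
    return float(out) if out.ndim == 0 else out


def _distance_matrix_sparse(
    network: FireSpreadNetwork, transform: str
) -> sp.csr_matrix:
    adj = network.adjacency.tocsr(copy=True)
    adj.data = edge_distance(adj.data, transform)
    return adj


def _to_igraph(network: FireSpreadNetwork, transform: str) -> igraph.Graph:
    coo = network.adjacency.tocoo()
    g = igraph.Graph(
        n=network.n_nodes,
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        directed=True,
    )
    g.es["distance"] = edge_distance(coo.data, transform).tolist()
    return g


# ---------------------------------------------------------------------------
# Centrality measures
# ---------------------------------------------------------------------------


def betweenness(
    network: FireSpreadNetwork, transform: str = "reciprocal"
) -> CentralityScores:
    """Weighted-geodesic betweenness with exact path multiplicities.

    ``BC(v) = sum over ordered pairs (l, m), l != v != m, of the fraction of
    shortest l->m paths through v``; distances are ``edge_distance`` of the
    spread probabilities, so nodes on many high-probability routes score
    high.  Unnormalized, as defined.
    """
    if network.n_nodes < 3:
        raise CentralityError("betweenness needs at least 3 nodes")
    g = _to_igraph(network, transform)
    scores = np.asarray(g.betweenness(weights="distance", directed=True), dtype=float)
    return CentralityScores(measure="betweenness", scores=scores)


def closeness(
    network: FireSpreadNetwork, transform: str = "reciprocal"
) -> CentralityScores:
    """Inverse summed geodesic out-distance per node.

    With unreachable targets the sum runs over reachable targets only and is
    multiplied by ``reached / (N - 1)`` before inverting; on a strongly
    connected graph this is exactly ``1 / sum(d)``.  Nodes reaching no other
    node score 0.
    """
    dist = csgraph.dijkstra(
        _distance_matrix_sparse(network, transform), directed=True
    )
    n = network.n_nodes
    np.fill_diagonal(dist, np.inf)
    finite = np.isfinite(dist)
    reached = finite.sum(axis=1)
    sums = np.where(finite, dist, 0.0).sum(axis=1)
    scores = np.zeros(n)
    ok = reached > 0
    scores[ok] = 1.0 / (sums[ok] * (reached[ok] / (n - 1)))
    return CentralityScores(measure="closeness", scores=scores)


def _principal_eigenpair(adj: sp.spmatrix) -> tuple[float, np.ndarray]:
    """(lambda_max, principal eigenvector of A^T), Perron-normalized."""
    at = sp.csr_matrix(adj).T.astype(float)
    n = at.shape[0]
    if n <= 16:  # ARPACK needs k < n - 1; small cases go dense
        vals, vecs = np.linalg.eig(at.toarray())
        i = int(np.argmax(np.abs(vals)))
        lam, vec = vals[i], vecs[:, i]
    else:
        try:
            # fixed start vector: ARPACK's default draw from the global RNG
            # would make scores (and campaigns) irreproducible
            vals, vecs = spla.eigs(
                at,
                k=1,
                which="LM",
                tol=SOLVER_TOL,
                maxiter=SOLVER_MAXITER_PER_NODE * n,
                v0=np.ones(n),
            )
        except spla.ArpackNoConvergence as exc:  # pragma: no cover
            raise ConvergenceError("eigencentrality iteration did not converge") from exc
        lam, vec = vals[0], vecs[:, 0]
    lam = float(np.real(lam))
    vec = np.real(vec)
    if vec.sum() < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)  # Perron vector is nonnegative up to round-off
    total = vec.sum()
    if total <= 0:
        raise ConvergenceError("degenerate principal eigenvector")
    return lam, vec / total


def eigencentrality(network: FireSpreadNetwork) -> CentralityScores:
    """Principal-eigenvector centrality (unit-sum, nonnegative).

    Uses the eigenvector of ``A^T`` for the largest eigenvalue, i.e. a node
    is central when fire flows into it from central nodes — the beta -> 1
    limit of the Bonacich measure.  Invariant to scaling all weights.
    """
    if network.n_nodes == 0:
        raise CentralityError("empty network")
    lam, vec = _principal_eigenpair(network.adjacency)
    network._lambda_max = lam
    return CentralityScores(measure="eigen", scores=vec)


def bonacich(network: FireSpreadNetwork, beta: float) -> CentralityScores:
    """Bonacich power centrality with attenuation ``beta / lambda_max``.

    Solves ``(I - (beta/lambda_max) A^T) x = e`` (sparse direct solve),
    convergent for ``0 <= beta < 1``.  At exactly beta = 0 the solve returns
    the uninformative constant vector, so the degenerate-limit convention
    reports the weighted in-degree ``A^T e`` — the degree centrality the
    measure reduces to.
    """
    if not 0.0 <= beta:
        raise CentralityError(f"beta must be >= 0, got {beta}")
    if beta >= 1.0:
        raise CentralityError(
            f"beta={beta} >= 1 makes (I - (beta/lambda_max) A^T) singular or divergent"
        )
    n = network.n_nodes
    ones = np.ones(n)
    if beta == 0.0:
        scores = np.asarray(network.adjacency.T @ ones).ravel()
        return CentralityScores(measure="bonacich", scores=scores, beta=0.0)
    lam = network.lambda_max
    if lam <= 0:
        raise CentralityError("network has no positive spectral radius")
    system = sp.eye(n, format="csc") - (beta / lam) * network.adjacency.T.tocsc()
    x = spla.spsolve(system, ones)
    if not np.all(np.isfinite(x)):
        raise ConvergenceError("Bonacich linear solve produced non-finite scores")
    return CentralityScores(measure="bonacich", scores=np.asarray(x), beta=beta)


def compute_centrality(
    network: FireSpreadNetwork,
    measure: str,
    beta: float | None = None,
    transform: str = "reciprocal",
) -> CentralityScores:
    """Dispatch a measure by name (betweenness/closeness/eigen/bonacich)."""
    if measure == "betweenness":
        return betweenness(network, transform)
    if measure == "closeness":
        return closeness(network, transform)
    if measure == "eigen":
        return eigencentrality(network)
    if measure == "bonacich":
        if beta is None:
            raise CentralityError("bonacich requires a beta")
        return bonacich(network, beta)
    raise CentralityError(f"unknown centrality measure {measure!r}")


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def scores_to_frame(scores: CentralityScores, n_cols: int):
    """Scores as a DataFrame (node, row, col, score) for CSV export."""
    import pandas as pd

    nodes = np.arange(scores.scores.size)
    return pd.DataFrame(
        {
            "node": nodes,
            "row": nodes // n_cols,
            "col": nodes % n_cols,
            "score": scores.scores,
        }
    )


def write_adjacency_mtx(network: FireSpreadNetwork, path) -> None:
    """Export the adjacency matrix in Matrix Market format."""
    import scipy.io as sio

    sio.mmwrite(str(path), network.adjacency)
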