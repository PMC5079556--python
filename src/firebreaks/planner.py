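"""Fire-break placement strategies under a break-density budget.

A fire-break plan removes (clears of fuel) a set of cells whose size is a
fraction ``d_f`` of the landscape's flammable nodes.  Three strategies:

* ``centrality`` — sweep a centrality ranking from the highest score down;
* ``random`` — sweep a seeded uniform random permutation of flammable nodes;
* ``conventional`` — sweep the density/flammability priority classes used in
  practical fuel-reduction planning (dense pine first, agricultural last).

Ranked placements (centrality, conventional) obey a non-adjacency
constraint: no two breaks may be orthogonally adjacent (4-neighborhood),
which stops the top-ranked — and therefore spatially clustered — cells from
merging into contiguous cleared zones.  Diagonal contact is allowed (a
diagonal chain of breaks does not wall off a Moore-neighborhood fire, so
breaks act statistically, not as solid barriers); a stricter full-Moore
exclusion is available via ``adjacency="moore"``.  The random benchmark is
by default an *unconstrained* uniform random subset (``adjacency="none"``),
the percolation-style null model: random picks rarely cluster, and any
non-adjacency rule would jam random sequential placement near density 0.36,
capping the reachable break densities well below a half.

The ranking is computed once on the intact landscape; plans for nested
budgets are prefixes of one greedy sweep, so growing ``d_f`` only adds
breaks (never moves them).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .landscape import LandscapeGrid
from .netcent import CentralityScores, rank_nodes

logger = logging.getLogger("firebreaks")

ORTHOGONAL_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))
MOORE_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)
)

#: Conventional fuel-reduction priority: (density, type) class rank, low = first.
CONVENTIONAL_PRIORITY: dict[tuple[str, str], int] = {
    ("dense", "pine"): 0,
    ("dense", "other"): 1,
    ("moderate", "pine"): 2,
    ("moderate", "other"): 3,
    ("sparse", "pine"): 4,
    ("sparse", "other"): 5,
}
_AGRICULTURAL_RANK = 6  # ranked last regardless of density


class PlannerError(ValueError):
    """Invalid planning input."""


@dataclass
class FireBreakPlan:
    """An ordered set of removed nodes and how it was produced."""

    strategy: str  # centrality | random | conventional
    removed: list[int]
    d_f_target: float
    d_f_achieved: float
    n_v: int  # flammable nodes of the intact landscape
    adjacency: str = "orthogonal"
    measure: str | None = None
    beta: float | None = None
    seed: int | None = None

    @property
    def n_breaks(self) -> int:
        return len(self.removed)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "strategy": self.strategy,
                "removed": list(map(int, self.removed)),
                "d_f_target": self.d_f_target,
                "d_f_achieved": self.d_f_achieved,
                "n_v": self.n_v,
                "adjacency": self.adjacency,
                "measure": self.measure,
                "beta": self.beta,
                "seed": self.seed,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "FireBreakPlan":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls(**json.loads(text))

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """0/1 break mask on the grid."""
        out = np.zeros(shape, dtype=int)
        rows, cols = np.divmod(np.asarray(self.removed, dtype=int), shape[1])
        out[rows, cols] = 1
        return out


# ---------------------------------------------------------------------------
# Greedy non-adjacent selection
# ---------------------------------------------------------------------------


def _neighbor_indices(
    k: int, shape: tuple[int, int], periodic: bool, adjacency: str
) -> list[int]:
    if adjacency == "none":
        return []
    offsets = ORTHOGONAL_OFFSETS if adjacency == "orthogonal" else MOORE_OFFSETS
    n_rows, n_cols = shape
    r, c = divmod(k, n_cols)
    out = []
    for dr, dc in offsets:
        rr, cc = r + dr, c + dc
        if periodic:
            rr %= n_rows
            cc %= n_cols
        elif not (0 <= rr < n_rows and 0 <= cc < n_cols):
            continue
        out.append(rr * n_cols + cc)
    return out


def greedy_nonadjacent_selection(
    order: np.ndarray,
    grid: LandscapeGrid,
    forbidden: frozenset[int] | set[int] = frozenset(),
    adjacency: str = "orthogonal",
) -> list[int]:
    """Maximal selection sweeping ``order``, skipping ineligible nodes.

    A node is skipped when it carries no fuel, is forbidden (e.g. the planned
    ignition cell), or neighbors an already-selected break (``adjacency``
    ``"orthogonal"``/``"moore"``; ``"none"`` disables the constraint).  The
    full sweep is returned; a budget plan is its prefix, so nested budgets
    yield nested plans (greedy correctness: every selected node outranks
    every eligible node skipped after it).
    """
    if adjacency not in ("orthogonal", "moore", "none"):
        raise PlannerError(f"unknown adjacency constraint {adjacency!r}")
    periodic = grid.boundary == "periodic"
    flammable = grid.flammable.ravel()
    blocked = np.zeros(grid.n_nodes, dtype=bool)
    selected: list[int] = []
    forbidden = set(forbidden)
    for k in map(int, order):
        if not flammable[k] or blocked[k] or k in forbidden:
            continue
        selected.append(k)
        blocked[k] = True
        for nb in _neighbor_indices(k, grid.shape, periodic, adjacency):
            blocked[nb] = True
    return selected


def _budget(d_f: float, n_v: int) -> int:
    """Number of breaks for density d_f: round half away from zero."""
    if not 0.0 <= d_f <= 1.0:
        raise PlannerError(f"d_f must lie in [0, 1], got {d_f}")
    return int(np.floor(d_f * n_v + 0.5))


def _make_plan(
    strategy: str,
    sweep: list[int],
    d_f: float,
    n_v: int,
    adjacency: str,
    **meta,
) -> FireBreakPlan:
    n_fb = min(_budget(d_f, n_v), len(sweep))
    return FireBreakPlan(
        strategy=strategy,
        removed=sweep[:n_fb],
        d_f_target=d_f,
        d_f_achieved=n_fb / n_v,
        n_v=n_v,
        adjacency=adjacency,
        **meta,
    )


# ---------------------------------------------------------------------------
# Strategies
# ---------------------------------------------------------------------------


def place_by_centrality(
    grid: LandscapeGrid,
    scores: CentralityScores | np.ndarray,
    d_f: float,
    forbidden: set[int] = frozenset(),
    adjacency: str = "orthogonal",
) -> FireBreakPlan:
    """Break plan from a descending-centrality sweep (ties by node index)."""
    if isinstance(scores, CentralityScores):
        measure, beta, values = scores.measure, scores.beta, scores.scores
    else:
        measure, beta, values = None, None, np.asarray(scores)
    if values.size != grid.n_nodes:
        raise PlannerError("scores must cover every node")
    n_v = int(grid.flammable.sum())
    sweep = greedy_nonadjacent_selection(rank_nodes(values), grid, forbidden, adjacency)
    return _make_plan(
        "centrality", sweep, d_f, n_v, adjacency, measure=measure, beta=beta
    )


def place_random(
    grid: LandscapeGrid,
    d_f: float,
    rng: np.random.Generator | int,
    forbidden: set[int] = frozenset(),
    adjacency: str = "none",
) -> FireBreakPlan:
    """Break plan from a seeded uniform random permutation of flammable nodes.

    Unconstrained by default (the percolation-style null benchmark); pass
    ``adjacency="orthogonal"`` or ``"moore"`` to enforce spacing.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if seed is not None:
        rng = np.random.default_rng(seed)
    n_v = int(grid.flammable.sum())
    candidates = np.flatnonzero(grid.flammable.ravel())
    order = rng.permutation(candidates)
    sweep = greedy_nonadjacent_selection(order, grid, forbidden, adjacency)
    return _make_plan(
        "random", sweep, d_f, n_v, adjacency, seed=None if seed is None else int(seed)
    )


def conventional_ranking(grid: LandscapeGrid) -> np.ndarray:
    """Fuel-reduction priority order by vegetation density and flammability.

    Dense pine > dense other > moderate pine > moderate other > sparse pine >
    sparse other; agricultural cells rank last at any density (the practical
    sort targets forest fuels).  Ties within a class break by ascending node
    index.  Requires a full-model grid with retained category labels.
    """
    if grid.model_kind != "full" or grid.type_label is None:
        raise PlannerError("conventional ranking needs a full-model grid with labels")
    ranks = np.full(grid.n_nodes, _AGRICULTURAL_RANK + 1, dtype=int)
    dens = grid.density_label.ravel()
    typ = grid.type_label.ravel()
    for (d, t), r in CONVENTIONAL_PRIORITY.items():
        ranks[(dens == d) & (typ == t)] = r
    ranks[typ == "agricultural"] = _AGRICULTURAL_RANK
    return np.lexsort((np.arange(grid.n_nodes), ranks))


def place_conventional(
    grid: LandscapeGrid,
    d_f: float,
    forbidden: set[int] = frozenset(),
    adjacency: str = "orthogonal",
) -> FireBreakPlan:
    """Break plan sweeping the conventional density/flammability ranking."""
    n_v = int(grid.flammable.sum())
    sweep = greedy_nonadjacent_selection(
        conventional_ranking(grid), grid, forbidden, adjacency
    )
    return _make_plan("conventional", sweep, d_f, n_v, adjacency)


def apply_breaks(grid: LandscapeGrid, plan: FireBreakPlan) -> LandscapeGrid:
    """Clear the plan's cells of fuel; burn states are untouched.

    Simple model: emptiness set to 1.  Full model: fuel mask cleared.
    Returns a new grid; the input is not modified.
    """
    removed = np.asarray(plan.removed, dtype=int)
    if removed.size and (removed.min() < 0 or removed.max() >= grid.n_nodes):
        raise PlannerError("plan contains node indices outside the grid")
    out = grid.copy()
    if removed.size == 0:
        return out
    rows, cols = np.divmod(removed, grid.n_cols)
    if grid.model_kind == "simple":
        out.emptiness[rows, cols] = 1.0
    else:
        out.fuel_mask[rows, cols] = False
    return out


def plan_is_valid(plan: FireBreakPlan, grid: LandscapeGrid) -> bool:
    """Check the non-adjacency invariant and fuel membership of a plan."""
    removed = set(plan.removed)
    if len(removed) != len(plan.removed):
        return False
    flammable = grid.flammable.ravel()
    periodic = grid.boundary == "periodic"
    for k in plan.removed:
        if not flammable[k]:
            return False
        for nb in _neighbor_indices(k, grid.shape, periodic, plan.adjacency):
            if nb in removed:
                return False
    return True
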