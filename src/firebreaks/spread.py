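"""Stochastic cellular-automata fire-spread kernels and the simulation loop.

The dynamics are a Markov random field on the lattice, second order in space
(Moore neighborhood) and first order in time, advanced synchronously:

* a burning cell becomes burned at the next step with probability 1;
* a susceptible cell with at least one burning Moore neighbor at time ``t``
  ignites at ``t+1``; each burning neighbor contributes one independent
  Bernoulli trial, so the combined ignition probability is
  ``1 - prod_l (1 - p_{l->k})``.

Per-pair spread probabilities:

* simple model: ``p = 1 - s2_k`` (emptiness of the target cell);
* full model: ``p = p0 * (1 + s2_k) * (1 + s3_k) * exp(a * theta_s)`` with
  the slope angle ``theta_s = atan((z_l - z_k) / d)``, ``d`` the cell side
  for orthogonally adjacent pairs and ``side * sqrt(2)`` for diagonal pairs;
  the product is clamped to [0, 1].

An optional wind hook multiplies the full-model probability by a
per-direction gain (default 1, i.e. no wind).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .landscape import BURNED, BURNING, SUSCEPTIBLE, CAParams, LandscapeGrid

logger = logging.getLogger("firebreaks")

#: Moore-neighborhood offsets (row, col); orthogonal pairs have dr*dc == 0.
MOORE_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

#: Wind hook signature: offset (dr, dc) -> multiplicative gain.
WindGain = Callable[[tuple[int, int]], float]


class SpreadError(ValueError):
    """Invalid kernel input."""


@dataclass
class SimulationResult:
    """Outcome of a single fire-spread run."""

    burned_mask: np.ndarray  # bool, cells burned by the end (incl. ignition)
    n_burned: int
    n_steps: int
    ignition: int  # node index
    seed: int | None = None

    def burned_fraction(self, n_v: int) -> float:
        """Fraction of the ``n_v`` flammable nodes burned in this run."""
        return self.n_burned / n_v


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------


def simple_spread_prob(emptiness):
    """Ignition probability of a cell in the simple model: ``1 - s2``."""
    emptiness = np.asarray(emptiness, dtype=float)
    if (emptiness < 0).any() or (emptiness > 1).any():
        raise SpreadError("emptiness must lie in [0, 1]")
    out = 1.0 - emptiness
    return float(out) if out.ndim == 0 else out


def slope_angle(elev_from, elev_to, cell_side: float, kind: str = "adjacent"):
    """Slope angle (radians) seen by fire moving from one cell to a neighbor.

    ``atan((z_from - z_to) / cell_side)`` for orthogonally adjacent pairs;
    the horizontal run is ``cell_side * sqrt(2)`` for diagonal pairs.
    """
    if cell_side <= 0:
        raise SpreadError("cell_side must be > 0")
    if kind not in ("adjacent", "diagonal"):
        raise SpreadError(f"unknown neighbor kind {kind!r}")
    run = cell_side * (math.sqrt(2.0) if kind == "diagonal" else 1.0)
    return np.arctan((np.asarray(elev_from, dtype=float) - elev_to) / run)


def slope_gain(theta_s, slope_coeff: float):
    """Exponential slope gain ``exp(a * theta_s)``; may exceed 1."""
    if slope_coeff <= 0:
        raise SpreadError("slope coefficient must be > 0")
    return np.exp(slope_coeff * np.asarray(theta_s, dtype=float))


def transition_prob(
    params: CAParams,
    type_effect,
    density_effect,
    elev_from=0.0,
    elev_to=0.0,
    kind: str = "adjacent",
    flammable=True,
    wind_gain: float = 1.0,
):
    """Full-model spread probability from a burning cell into a neighbor.

    ``p0 * (1 + s2_k) * (1 + s3_k) * exp(a * theta_s) * wind_gain`` clamped
    to [0, 1]; 0 when the target cell carries no fuel.  ``type_effect`` /
    ``density_effect`` / elevations refer to the target (``_k``) and source
    (``_from``) cells as indicated.
    """
    theta = slope_angle(elev_from, elev_to, params.cell_side, kind)
    p = (
        params.p0
        * (1.0 + np.asarray(type_effect, dtype=float))
        * (1.0 + np.asarray(density_effect, dtype=float))
        * slope_gain(theta, params.slope_coeff)
        * wind_gain
    )
    p = np.clip(p, 0.0, 1.0) * np.asarray(flammable, dtype=float)
    return float(p) if p.ndim == 0 else p


# ---------------------------------------------------------------------------
# Per-direction ignition-probability fields
# ---------------------------------------------------------------------------


def _shift(field: np.ndarray, dr: int, dc: int, periodic: bool) -> np.ndarray:
    """``out[r, c] = field[r + dr, c + dc]`` with wrap or zero fill."""
    if periodic:
        return np.roll(field, (-dr, -dc), axis=(0, 1))
    out = np.zeros_like(field)
    rows_src = slice(max(dr, 0), field.shape[0] + min(dr, 0))
    rows_dst = slice(max(-dr, 0), field.shape[0] + min(-dr, 0))
    cols_src = slice(max(dc, 0), field.shape[1] + min(dc, 0))
    cols_dst = slice(max(-dc, 0), field.shape[1] + min(-dc, 0))
    out[rows_dst, cols_dst] = field[rows_src, cols_src]
    return out


def ignition_probability_fields(
    grid: LandscapeGrid,
    params: CAParams | None = None,
    wind: WindGain | None = None,
) -> np.ndarray:
    """Stack ``P[d, r, c]``: probability that a burning neighbor at Moore
    offset ``d`` ignites cell ``(r, c)`` in one step.

    For the simple model all eight directions share ``1 - s2`` of the target;
    for the full model each direction carries its own slope gain.  Entries
    into non-fuel cells, and (absorbing boundary) from outside the grid, are 0.
    """
    periodic = grid.boundary == "periodic"
    if grid.model_kind == "simple":
        base = simple_spread_prob(grid.emptiness)
        stack = np.broadcast_to(base, (8,) + grid.shape).copy()
    else:
        params = params or CAParams()
        stack = np.empty((8,) + grid.shape)
        for d, (dr, dc) in enumerate(MOORE_OFFSETS):
            kind = "diagonal" if dr * dc != 0 else "adjacent"
            elev_from = _shift(grid.elevation, dr, dc, periodic)
            gain = float(wind((dr, dc))) if wind is not None else 1.0
            stack[d] = transition_prob(
                params,
                grid.type_effect,
                grid.density_effect,
                elev_from=elev_from,
                elev_to=grid.elevation,
                kind=kind,
                flammable=grid.fuel_mask,
                wind_gain=gain,
            )
    flammable = grid.flammable
    stack *= flammable  # no ignition of non-fuel / break cells
    if not periodic:
        # edges from outside the grid do not exist
        ones = np.ones(grid.shape)
        for d, (dr, dc) in enumerate(MOORE_OFFSETS):
            stack[d] *= _shift(ones, dr, dc, periodic=False)
    return stack


def _combined_ignition_prob(
    prob_fields: np.ndarray, burning: np.ndarray, periodic: bool
) -> np.ndarray:
    """``1 - prod_d (1 - P_d * [neighbor d burning])`` per cell."""
    one_minus = np.ones(burning.shape)
    for d, (dr, dc) in enumerate(MOORE_OFFSETS):
        b = _shift(burning, dr, dc, periodic)
        one_minus *= 1.0 - prob_fields[d] * b
    return 1.0 - one_minus


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def step(
    grid: LandscapeGrid,
    rng: np.random.Generator,
    params: CAParams | None = None,
    prob_fields: np.ndarray | None = None,
    wind: WindGain | None = None,
) -> LandscapeGrid:
    """One synchronous update: burning -> burned; susceptible cells with
    burning neighbors run their Bernoulli ignition trials.

    Time-``t`` states alone drive time ``t+1`` (double buffering).  A full
    grid of uniforms is drawn every step so that runs sharing a seed are
    coupled cell-for-cell across different break plans (common random
    numbers).
    """
    if prob_fields is None:
        prob_fields = ignition_probability_fields(grid, params, wind)
    periodic = grid.boundary == "periodic"
    burning = grid.burn_state == BURNING
    p_ign = _combined_ignition_prob(prob_fields, burning, periodic)
    draws = rng.random(grid.shape)
    new_fire = (grid.burn_state == SUSCEPTIBLE) & (draws < p_ign)
    out = grid.copy()
    out.burn_state[burning] = BURNED
    out.burn_state[new_fire] = BURNING
    return out


def run_simulation(
    grid: LandscapeGrid,
    ignition: int,
    rng: np.random.Generator | int,
    params: CAParams | None = None,
    prob_fields: np.ndarray | None = None,
    wind: WindGain | None = None,
) -> SimulationResult:
    """Ignite one cell and iterate the CA until no cell is burning.

    The ignition cell is set burning at t=0 (and counts as burned); if it
    carries no fuel the fire cannot start and ``n_burned = 0``.  Terminates
    in at most ``N`` steps: each step either ignites a new cell or ends the
    fire.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if seed is not None:
        rng = np.random.default_rng(seed)
    if not (0 <= ignition < grid.n_nodes):
        raise IndexError(f"ignition node {ignition} out of bounds")
    if prob_fields is None:
        prob_fields = ignition_probability_fields(grid, params, wind)
    periodic = grid.boundary == "periodic"
    r0, c0 = grid.node_coords(ignition)
    flammable = grid.flammable

    burn = grid.burn_state.astype(np.int8).copy()
    if not flammable[r0, c0]:
        return SimulationResult(
            burned_mask=np.zeros(grid.shape, dtype=bool),
            n_burned=0,
            n_steps=0,
            ignition=ignition,
            seed=seed,
        )
    burn[r0, c0] = BURNING
    burning = burn == BURNING
    n_steps = 0
    while burning.any():
        p_ign = _combined_ignition_prob(prob_fields, burning, periodic)
        draws = rng.random(grid.shape)
        new_fire = (burn == SUSCEPTIBLE) & (draws < p_ign)
        burn[burning] = BURNED
        burn[new_fire] = BURNING
        burning = new_fire
        n_steps += 1
        if n_steps > grid.n_nodes:  # unreachable; guards the invariant
            raise RuntimeError("simulation failed to terminate")
    burned_mask = burn == BURNED
    return SimulationResult(
        burned_mask=burned_mask,
        n_burned=int(burned_mask.sum()),
        n_steps=n_steps,
        ignition=ignition,
        seed=seed,
    )
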