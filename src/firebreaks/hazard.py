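"""Monte-Carlo hazard evaluation: R(d_f) curves, strategy comparison,
burning-frequency maps and transition detection.

The hazard intensity at break density ``d_f`` is

    R(d_f) = (1 / n_r) * sum_i  n_b(i) / n_v,

the mean fraction of flammable nodes burned per run.  Two campaign modes:

* ``ensemble`` — n_r independent landscape realizations, a fresh break plan
  per realization, one run each from a fixed (central) ignition;
* ``multi_ignition`` — one landscape, one plan per (strategy, d_f), n_r runs
  from uniformly random flammable ignition cells.

Seed discipline (documented splitting scheme): landscape realization ``i``
of a campaign with base seed ``s`` is generated from seed ``s + i``; all
other generators are ``np.random.default_rng([stream, s, i])`` with fixed
per-purpose stream constants.  The simulation stream for realization ``i``
is *reused across the d_f sweep*, coupling runs cell-for-cell (common random
numbers), which makes curves comparable across strategies and densities and
campaigns bit-reproducible from the base seed alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import CAParams, LandscapeGrid, generate_artificial_forest
from .netcent import build_network, compute_centrality, rank_nodes
from .planner import (
    FireBreakPlan,
    _make_plan,
    conventional_ranking,
    greedy_nonadjacent_selection,
)
from .spread import ignition_probability_fields, run_simulation

logger = logging.getLogger("firebreaks")

# Per-purpose RNG stream constants for the seed-splitting scheme.
_SIM_STREAM = 1
_PLACE_STREAM = 2
_IGNITION_STREAM = 3

#: Default artificial-forest sweep: fine enough to localize transitions to ±0.01.
DEFAULT_DF_GRID: np.ndarray = np.round(np.arange(0.0, 0.5001, 0.02), 10)


class HazardError(ValueError):
    """Invalid campaign input."""


class NoTransitionError(RuntimeError):
    """The hazard curve never crosses its high/low midpoint."""


@dataclass
class HazardCurve:
    """Per-run burned fractions over a d_f sweep for one strategy."""

    strategy: str
    d_f_grid: np.ndarray  # (n_d,) target break densities
    fractions: np.ndarray  # (n_d, n_r) burned fraction n_b / n_v per run
    d_f_achieved: np.ndarray  # (n_d, n_r) realized break densities
    base_seed: int
    mode: str = "ensemble"

    @property
    def n_runs(self) -> int:
        return self.fractions.shape[1]

    @property
    def mean(self) -> np.ndarray:
        """R(d_f): arithmetic mean of per-run burned fractions."""
        return self.fractions.mean(axis=1)

    def percentile(self, q: float = 90.0) -> np.ndarray:
        return np.percentile(self.fractions, q, axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": self.strategy,
                "d_f": self.d_f_grid,
                "d_f_achieved_mean": self.d_f_achieved.mean(axis=1),
                "mean_R": self.mean,
                "p90": self.percentile(90.0),
                "n_runs": self.n_runs,
            }
        )


@dataclass
class FrequencyMap:
    """Per-cell burn statistics over repeated same-ignition runs."""

    counts: np.ndarray  # int, burns per cell over n_runs
    frequency: np.ndarray  # counts / n_runs
    gray: np.ndarray  # nominal gray level per cell (16, 32, ..., 256; 0 = never)
    n_runs: int
    bin_edges: np.ndarray


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def hazard_intensity(burned_counts, n_v: int) -> float:
    """Mean burned fraction over runs: ``mean(n_b / n_v)``."""
    counts = np.asarray(burned_counts, dtype=float)
    if counts.size == 0:
        raise HazardError("hazard intensity of an empty run list is undefined")
    if n_v <= 0:
        raise HazardError("n_v must be positive")
    if (counts < 0).any():
        raise HazardError("burned counts must be non-negative")
    return float(np.mean(counts / n_v))


def compare_strategies(
    curve_a: HazardCurve,
    curve_b: HazardCurve,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-d_f two-sample t-test on burned fractions (Welch by default).

    Returns a frame with the t statistic, p value and a ``significant`` flag
    (p < alpha) at each d_f.
    """
    if curve_a.d_f_grid.shape != curve_b.d_f_grid.shape or not np.allclose(
        curve_a.d_f_grid, curve_b.d_f_grid
    ):
        raise HazardError("hazard curves were sampled on different d_f grids")
    t, p = stats.ttest_ind(
        curve_a.fractions, curve_b.fractions, axis=1, equal_var=equal_var
    )
    return pd.DataFrame(
        {
            "d_f": curve_a.d_f_grid,
            "t": t,
            "p_value": p,
            "significant": p < alpha,
        }
    )


def detect_transition(curve: HazardCurve | tuple[np.ndarray, np.ndarray]) -> float:
    """Locate the high-to-low transition of a hazard curve.

    The high plateau is the mean R over the first two grid points, the low
    plateau the mean over the last two; the transition point is the smallest
    d_f where R first drops below the midpoint of the two plateaus, linearly
    interpolated between the bracketing grid points.
    """
    if isinstance(curve, HazardCurve):
        d_f, mean_r = curve.d_f_grid, curve.mean
    else:
        d_f, mean_r = map(np.asarray, curve)
    if d_f.size < 4:
        raise HazardError("transition detection needs at least 4 grid points")
    r_high = mean_r[:2].mean()
    r_low = mean_r[-2:].mean()
    threshold = (r_high + r_low) / 2.0
    below = np.flatnonzero(mean_r < threshold)
    if below.size == 0 or below[0] == 0:
        raise NoTransitionError(
            f"curve never crosses its plateau midpoint {threshold:.4f}"
        )
    i = below[0]
    r0, r1 = mean_r[i - 1], mean_r[i]
    frac = (r0 - threshold) / (r0 - r1)
    return float(d_f[i - 1] + frac * (d_f[i] - d_f[i - 1]))


# ---------------------------------------------------------------------------
# Campaigns
# ---------------------------------------------------------------------------


def _strategy_sweep(
    spec: dict,
    grid: LandscapeGrid,
    net,
    score_cache: dict,
    forbidden: set[int],
    adjacency: str,
    rng_place: np.random.Generator,
) -> tuple[list[int], dict]:
    """Full greedy selection order for one strategy on one landscape."""
    kind = spec["kind"]
    # random benchmark is unconstrained unless the spec says otherwise
    adjacency = spec.get("adjacency", "none" if kind == "random" else adjacency)
    if kind == "centrality":
        key = (spec["measure"], spec.get("beta"))
        if key not in score_cache:
            score_cache[key] = compute_centrality(
                net, spec["measure"], spec.get("beta")
            )
        scores = score_cache[key]
        order = rank_nodes(scores.scores)
        meta = {"measure": scores.measure, "beta": scores.beta}
        label = "centrality"
    elif kind == "random":
        candidates = np.flatnonzero(grid.flammable.ravel())
        order = rng_place.permutation(candidates)
        meta = {}
        label = "random"
    elif kind == "conventional":
        order = conventional_ranking(grid)
        meta = {}
        label = "conventional"
    else:
        raise HazardError(f"unknown strategy kind {kind!r}")
    sweep = greedy_nonadjacent_selection(order, grid, forbidden, adjacency)
    return sweep, {"label": label, "adjacency": adjacency, **meta}


def run_ensemble_campaign(
    grid_size: int,
    strategies: dict[str, dict],
    d_f_grid=DEFAULT_DF_GRID,
    n_realizations: int = 100,
    base_seed: int = 0,
    adjacency: str = "orthogonal",
    params: CAParams | None = None,
) -> dict[str, HazardCurve]:
    """Ensemble-mode campaign over independent artificial forests.

    For each realization: generate a forest, build its fire-spread network,
    compute each strategy's break sweep once, then for every d_f apply the
    prefix plan, ignite the lattice center and run the CA to extinction.
    Returns one :class:`HazardCurve` per strategy, all sharing forests,
    ignitions and simulation random numbers (paired comparisons).
    """
    d_f_grid = np.asarray(d_f_grid, dtype=float)
    curves = {
        name: np.zeros((d_f_grid.size, n_realizations)) for name in strategies
    }
    achieved = {
        name: np.zeros((d_f_grid.size, n_realizations)) for name in strategies
    }
    for i in range(n_realizations):
        forest = generate_artificial_forest(grid_size, base_seed + i)
        net = build_network(forest, params)
        n_v = int(forest.flammable.sum())
        center = forest.node_index(grid_size // 2, grid_size // 2)
        score_cache: dict = {}
        for s_idx, (name, spec) in enumerate(strategies.items()):
            rng_place = np.random.default_rng([_PLACE_STREAM, base_seed, i, s_idx])
            sweep, meta = _strategy_sweep(
                spec, forest, net, score_cache, {center}, adjacency, rng_place
            )
            for j, d_f in enumerate(d_f_grid):
                plan = _make_plan(meta["label"], sweep, float(d_f), n_v, meta["adjacency"])
                broken = _apply_removed(forest, plan.removed)
                rng_sim = np.random.default_rng([_SIM_STREAM, base_seed, i])
                result = run_simulation(broken, center, rng_sim, params)
                curves[name][j, i] = result.n_burned / n_v
                achieved[name][j, i] = plan.d_f_achieved
        if (i + 1) % 10 == 0:
            logger.info("ensemble campaign: %d/%d realizations", i + 1, n_realizations)
    return {
        name: HazardCurve(
            strategy=name,
            d_f_grid=d_f_grid,
            fractions=curves[name],
            d_f_achieved=achieved[name],
            base_seed=base_seed,
            mode="ensemble",
        )
        for name in strategies
    }


def run_multi_ignition_campaign(
    grid: LandscapeGrid,
    strategies: dict[str, dict],
    d_f_grid,
    n_runs: int,
    base_seed: int = 0,
    adjacency: str = "orthogonal",
    params: CAParams | None = None,
) -> dict[str, HazardCurve]:
    """Multi-ignition campaign on a single (typically full-model) landscape.

    One plan per (strategy, d_f); ``n_runs`` ignition cells drawn uniformly
    from the intact landscape's flammable nodes, shared across strategies and
    densities (paired seeds).  An ignition landing on a break yields a dead
    run (fraction 0) for that strategy.
    """
    d_f_grid = np.asarray(d_f_grid, dtype=float)
    n_v = int(grid.flammable.sum())
    if n_v == 0:
        raise HazardError("landscape has no flammable ignition candidates")
    candidates = np.flatnonzero(grid.flammable.ravel())
    rng_ign = np.random.default_rng([_IGNITION_STREAM, base_seed])
    ignitions = rng_ign.choice(candidates, size=n_runs, replace=True)

    net = build_network(grid, params)
    score_cache: dict = {}
    out: dict[str, HazardCurve] = {}
    for s_idx, (name, spec) in enumerate(strategies.items()):
        rng_place = np.random.default_rng([_PLACE_STREAM, base_seed, 0, s_idx])
        sweep, meta = _strategy_sweep(
            spec, grid, net, score_cache, set(), adjacency, rng_place
        )
        fractions = np.zeros((d_f_grid.size, n_runs))
        achieved = np.zeros((d_f_grid.size, n_runs))
        for j, d_f in enumerate(d_f_grid):
            plan = _make_plan(meta["label"], sweep, float(d_f), n_v, meta["adjacency"])
            broken = _apply_removed(grid, plan.removed)
            fields = ignition_probability_fields(broken, params)
            for r, ignition in enumerate(ignitions):
                rng_sim = np.random.default_rng([_SIM_STREAM, base_seed, r])
                result = run_simulation(
                    broken, int(ignition), rng_sim, params, prob_fields=fields
                )
                fractions[j, r] = result.n_burned / n_v
                achieved[j, r] = plan.d_f_achieved
            logger.info(
                "multi-ignition campaign [%s]: d_f=%.3f done (mean R=%.3f)",
                name,
                d_f,
                fractions[j].mean(),
            )
        out[name] = HazardCurve(
            strategy=name,
            d_f_grid=d_f_grid,
            fractions=fractions,
            d_f_achieved=achieved,
            base_seed=base_seed,
            mode="multi_ignition",
        )
    return out


def run_campaign(
    grid_or_size,
    strategy: dict,
    d_f_grid,
    ignition: str = "center",
    n_r: int = 100,
    base_seed: int = 0,
    mode: str = "ensemble",
    adjacency: str = "orthogonal",
    params: CAParams | None = None,
) -> HazardCurve:
    """Single-strategy campaign wrapper; see the two mode-specific drivers."""
    strategies = {"campaign": strategy}
    if mode == "ensemble":
        if ignition != "center":
            raise HazardError("ensemble mode ignites the lattice center")
        curves = run_ensemble_campaign(
            int(grid_or_size), strategies, d_f_grid, n_r, base_seed, adjacency, params
        )
    elif mode == "multi_ignition":
        if ignition != "random":
            raise HazardError("multi-ignition mode draws random ignitions")
        curves = run_multi_ignition_campaign(
            grid_or_size, strategies, d_f_grid, n_r, base_seed, adjacency, params
        )
    else:
        raise HazardError(f"unknown campaign mode {mode!r}")
    curve = curves["campaign"]
    curve.strategy = strategy.get("kind", "campaign")
    return curve


def _apply_removed(grid: LandscapeGrid, removed: list[int]) -> LandscapeGrid:
    """apply_breaks without constructing an intermediate plan object."""
    out = grid.copy()
    if removed:
        rows, cols = np.divmod(np.asarray(removed, dtype=int), grid.n_cols)
        if grid.model_kind == "simple":
            out.emptiness[rows, cols] = 1.0
        else:
            out.fuel_mask[rows, cols] = False
    return out


# ---------------------------------------------------------------------------
# Burning-frequency maps
# ---------------------------------------------------------------------------


def quantize_frequencies(frequency: np.ndarray, n_bins: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Quantize positive burn frequencies into equal-width bins and gray levels.

    Bins span (0, max frequency]; bin ``b`` (1 = least frequent) receives the
    nominal gray level ``256 - 16*(b-1)``, i.e. levels descend 256, 240, ...,
    16 as frequency rises — the most frequently burned cells are darkest.
    Zero-frequency cells get background level 0, outside the bins.
    """
    freq = np.asarray(frequency, dtype=float)
    gray = np.zeros(freq.shape, dtype=int)
    positive = freq > 0
    if not positive.any():
        return gray, np.array([0.0])
    fmax = freq[positive].max()
    edges = np.linspace(0.0, fmax, n_bins + 1)
    # right-closed bins so freq == fmax lands in the top bin
    bins = np.digitize(freq[positive], edges[1:-1], right=True) + 1
    gray[positive] = 16 * n_bins - 16 * (bins - 1)
    return gray, edges


def burning_frequency_map(
    grid: LandscapeGrid,
    plan: FireBreakPlan | None,
    ignition: int,
    n_runs: int,
    base_seed: int = 0,
    params: CAParams | None = None,
) -> FrequencyMap:
    """Per-cell burn frequency over repeated runs from one ignition point."""
    if n_runs < 1:
        raise HazardError("frequency map needs at least one run")
    working = _apply_removed(grid, plan.removed) if plan is not None else grid
    fields = ignition_probability_fields(working, params)
    counts = np.zeros(grid.shape, dtype=int)
    for r in range(n_runs):
        rng = np.random.default_rng([_SIM_STREAM, base_seed, r])
        result = run_simulation(working, ignition, rng, params, prob_fields=fields)
        counts += result.burned_mask
    frequency = counts / n_runs
    gray, edges = quantize_frequencies(frequency)
    return FrequencyMap(
        counts=counts,
        frequency=frequency,
        gray=gray,
        n_runs=n_runs,
        bin_edges=edges,
    )
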