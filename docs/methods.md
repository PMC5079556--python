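# Methods

## Model

Fire spread is modeled as a stochastic cellular automaton on a square
lattice with a Moore (8-cell) neighborhood, advanced synchronously in
discrete time.  Each cell (node `k`) carries a burn state `s1 ∈ {0, 1, −1}`
(susceptible, burning, burned) plus landscape state.  Two rules drive the
dynamics:

1. a burning cell becomes burned at the next step with probability 1
   (burning lasts exactly one step);
2. a susceptible cell with at least one burning Moore neighbor at time `t`
   ignites at `t+1`; each burning neighbor contributes an independent
   Bernoulli trial with its pairwise spread probability `p(l→k)`, so the
   combined per-step ignition probability is `1 − Π_l (1 − p(l→k))`.

The combination rule is a modeling choice: the pairwise probability is
defined per neighbor, and independent trials are the standard convention
for lattice contact processes.  The update is double-buffered — only
time-`t` states drive time `t+1`.

Two spread kernels:

* **simple model** (artificial forest): flat terrain, one vegetation type;
  the only per-cell property is emptiness `s2 ∈ [0, 1]` (0 = very dense
  vegetation, 1 = empty/burned) and `p(l→k) = 1 − s2_k`.  A cell's
  emptiness does not decay before it burns; burned cells are treated as
  empty thereafter (equivalently, their burn state blocks re-ignition).
* **full model** (heterogeneous landscape):
  `p(l→k) = p0 · (1 + s2_k) · (1 + s3_k) · exp(a·θs)`, clamped to [0, 1],
  where `s2_k` is the vegetation-type effect of the target cell
  (agricultural −0.3, other/shrubs 0, pines +0.4), `s3_k` the density
  effect (sparse −0.4, moderate 0, dense +0.3), and
  `θs = atan((z_l − z_k)/d)` the slope angle with horizontal run `d` equal
  to the cell side for orthogonal neighbor pairs and `side·√2` for diagonal
  pairs.  Defaults `p0 = 0.58` and `a = 0.078` are field-calibrated values
  for Aegean pine landscapes; the cell side defaults to 10 m.  The slope
  sign convention is taken exactly as written above (source minus target).
  An optional per-direction wind gain multiplies the product; no wind
  formula is shipped (the default gain is 1).

The simple model carries no length scale (flat terrain), so its cell side
is left unset.

## Network recasting and centralities

The lattice is a directed weighted graph: `A[l, k] = p(l→k)`.  Out-degree
is at most 8, the diagonal is zero, zero-probability edges are absent, and
non-fuel cells are fully isolated (a cleared cell can neither ignite nor
transmit).  Because high spread probability means short effective distance,
shortest-path measures use `d = 1/p` (the literal "inversely proportional"
reading; `−ln p` is available and induces the same rankings on lattices of
uniform structure, since both transforms are monotone).

* **Betweenness**: unnormalized directed weighted betweenness with exact
  shortest-path multiplicities (Brandes), paths in the flow direction.
* **Closeness**: inverse summed geodesic out-distance.  With unreachable
  targets the sum runs over reached targets and is multiplied by
  `reached/(N−1)` before inverting; closeness is not used in any campaign
  and ships for completeness.
* **Eigencentrality**: principal eigenvector of `Aᵀ` (fire flowing into a
  node), nonnegative and normalized to unit sum.  `Aᵀ` is chosen so that
  the measure is the β→1 limit of the Bonacich solve below; for directed
  graphs the untransposed choice is equally defensible but would not
  connect to that limit.
* **Bonacich**: `x = (I − (β/λmax)·Aᵀ)⁻¹ e`, with `λmax` the largest
  eigenvalue of `A`.  The attenuation is read as `β/λmax` — the standard
  Katz/Bonacich scaling, and the only reading under which β < 1 guarantees
  convergence and β→1 recovers eigencentrality.  At exactly β = 0 the solve
  returns the constant vector, so the implementation reports the weighted
  in-degree `Aᵀe` (the degree centrality the measure reduces to in that
  limit).

Numerical choices: ARPACK for `λmax` and the principal eigenvector
(tolerance 1e-8, iteration cap 10·N, fixed all-ones start vector — the
default random start would make scores and campaigns irreproducible; dense
fallback below 17 nodes where ARPACK cannot run), sparse direct solve for
the Bonacich system.  Ranking
ties break by ascending node index, making every downstream placement
deterministic.  Shortest-path computations are delegated to igraph's C
core; a 2500-node campaign betweenness takes ~1.5 s.

## Fire-break placement

A plan removes a budget of `round(d_f · n_v)` cells (half-away-from-zero;
`n_v` = flammable nodes of the intact landscape) by sweeping a ranking from
the top, skipping non-fuel cells, forbidden cells (the planned ignition
point in single-ignition studies), and — for ranked strategies — any cell
orthogonally adjacent to an already-selected break.  The ranking is
computed once on the intact landscape; plans for nested budgets are
prefixes of one sweep.

The non-adjacency constraint prevents the spatially clustered top-ranked
cells from merging into contiguous cleared zones.  "Adjacent" means the 4
orthogonal neighbors (the same sense in which the slope formulas
distinguish adjacent from diagonal pairs); a stricter full-Moore exclusion
is available but caps achievable break densities at 1/4 by packing alone.
The **random benchmark is unconstrained by default**: it is the
percolation-style null of removing a uniform random subset, and uniform
random picks are not spatially clustered to begin with.  Any sequential
non-adjacency rule jams random placement near density 0.36, making break
densities above that unreachable; the unconstrained null keeps the whole
0–0.5 sweep meaningful.  The constraint can still be imposed per strategy.

The conventional benchmark ranks cells by fuel-reduction practice: dense
pine > dense other > moderate pine > moderate other > sparse pine > sparse
other, with agricultural cells last at any density (the practical sort
targets forest fuels; ranking them last, rather than omitting them, keeps
the sweep total).

## Hazard evaluation

Hazard intensity `R(d_f)` is the mean over runs of the burned fraction
`n_b/n_v`.  Two campaign modes:

* **ensemble** — independent landscape realizations (default 100), a fresh
  plan per realization, one run each from the lattice center;
* **multi-ignition** — one landscape, one plan per strategy and density,
  runs from ignition cells drawn uniformly from the intact landscape's
  flammable nodes and shared across strategies (paired comparisons; an
  ignition landing on a break is a dead run for that strategy).

Seed discipline: realization `i` of a campaign with base seed `s` draws its
landscape from seed `s + i`; placement, ignition and simulation generators
are `default_rng([stream, s, i])` with fixed per-purpose stream constants.
The simulation stream is deliberately reused across the d_f sweep and
across strategies, and each step draws a full grid of uniforms, so runs are
coupled cell-for-cell (common random numbers): denser nested plans see the
same fire, which sharpens strategy contrasts and yields the statistical
monotonicity of `R` in `d_f`.  Campaigns are bit-reproducible from the base
seed.

Strategy comparison uses a two-sample t-test on per-run burned fractions at
each `d_f`, Welch (unequal-variance) by default — safer than the pooled
variant near the transition where variances differ strongly; the pooled
test is a switch away.  The significance threshold is 0.05.

The transition detector defines "where the curve drops": the high plateau
is the mean `R` of the first two grid points, the low plateau the mean of
the last two, and the transition is the first crossing of their midpoint,
linearly interpolated between bracketing grid points.  The default sweep is
0 to 0.5 in steps of 0.02, fine enough to localize transitions to ±0.01.

Burning-frequency maps quantize per-cell burn frequencies (over repeated
same-ignition runs) into 16 equal-width bins spanning (0, max frequency];
bin `b` in ascending frequency order receives nominal gray `256 − 16(b−1)`,
so the most frequently burned cells are darkest.  Never-burned cells get a
background level of 0 outside the bins (zeros would otherwise swamp the
lowest bin).  The nominal level 256 exceeds the 8-bit range and clamps to
255 on image export only; the numeric map keeps exact levels.

## Synthetic landscapes

`generate_artificial_forest` draws per-cell emptiness iid Uniform(0,1) on
an n×n torus — the study condition for all simple-model campaigns (default
50×50, 100 realizations, central ignition).  Periodic boundaries remove
edge effects at this size; real landscapes use absorbing boundaries since
a coastline cannot wrap.

`generate_heterogeneous_landscape` is a synthetic stand-in for a real
co-registered raster stack: iid categorical vegetation type (pine 0.45,
other 0.35, agricultural 0.2) and density (uniform over the three classes),
plus a smooth relief from random low-order cosine modes (default amplitude
120 m over a 300 m domain, i.e. realistic hillslope angles at 10 m cells).
What it deliberately lacks: spatial autocorrelation of vegetation classes,
valley/ridge drainage structure, roads and settlements, and wind.  Tests
passing on it show the machinery is correct and that centrality-guided
placement is not worse than the conventional ranking under heterogeneity
and slope; they do not validate hazard numbers for any real landscape.

## Degenerate inputs and edge cases

Igniting a non-fuel cell yields an empty fire (zero burned, zero steps).
Plans whose constraint exhausts candidates before the budget report the
shortfall in `d_f_achieved` instead of raising.  Budget rounding can
overshoot the target density by up to half a node.  Simulations terminate
in at most N steps (each step ignites a new cell or ends the fire); this is
asserted, not assumed.

## Problem sizes

The shipped study sizes — 50×50 lattices, 100 realizations, 26-point
density sweeps, 200-run multi-ignition campaigns on 30×30 landscapes — are
the package's reference experiment scale: large enough for the transition
estimates to stabilize well inside the ±0.04 bands quoted in the tests,
small enough to run on a laptop in minutes.  The architecture (sparse
matrices, vectorized CA steps, C-core shortest paths) scales to
megapixel-class rasters for everything except exact betweenness, whose
all-pairs cost is the known bottleneck on very large lattices.

## Known limitations

No wind formula (hook only), no fuel moisture, no spotting/ember transport,
no continuous-time front propagation.  Exact betweenness on production-size
rasters is impractical; approximate betweenness is deliberately out of
scope.  Closeness on graphs with unreachable pairs uses the documented
correction and should not be compared across graphs of different
connectivity.
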