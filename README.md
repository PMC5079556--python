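# firebreaks

Where should fuel breaks go so that a wildfire cannot sweep a landscape?
`firebreaks` answers this with a two-level approach aimed at landscape
ecologists and fire-management modelers:

1. **Spread model.** Fire spread is a stochastic cellular automaton on a
   square lattice (Moore neighborhood, synchronous update): a burning cell
   burns down in one step, and ignites each susceptible neighbor `k` with a
   pairwise probability — `1 − s2_k` (vegetation emptiness) in the simple
   single-fuel model, or `p0(1+s2_k)(1+s3_k)·exp(a·θs)` in the full model
   with vegetation-type effect, density effect and slope angle `θs`
   (defaults `p0 = 0.58`, `a = 0.078`, clamped to [0,1]).
2. **Network placement.** Those probabilities are the edge weights of a
   directed lattice network, so "where does fire flow" becomes a network
   centrality question.  Cells are ranked by Bonacich power centrality
   `x = (I − (β/λmax)Aᵀ)⁻¹e`, betweenness on inverse-probability distances,
   eigencentrality or closeness, and the top-ranked cells (no two
   orthogonally adjacent) are cleared of fuel as breaks.

Placements are evaluated by Monte-Carlo campaigns: the hazard intensity
`R(d_f)` — the mean burned fraction at break density `d_f` — drops sharply
from a high to a low plateau at a critical density, and a good placement
moves that transition to much sparser (cheaper) break networks.  Campaigns
against the random and conventional (density/flammability-sorted)
benchmarks come with Welch t-tests per density and per-cell
burning-frequency maps.

## Worked example

```python
import firebreaks as fb

forest = fb.generate_artificial_forest(50, seed=7)   # emptiness ~ U(0,1), torus
net = fb.build_network(forest)
scores = fb.bonacich(net, beta=0.5)
plan = fb.place_by_centrality(forest, scores, d_f=0.24,
                              forbidden={forest.node_index(25, 25)})
print(f"breaks placed: {plan.n_breaks} (d_f achieved {plan.d_f_achieved:.3f})")

before = fb.run_simulation(forest, forest.node_index(25, 25), rng=11)
after = fb.run_simulation(fb.apply_breaks(forest, plan),
                          forest.node_index(25, 25), rng=11)
print(f"burned without breaks: {before.n_burned}/2500 "
      f"({before.n_burned / 2500:.1%}) in {before.n_steps} steps")
print(f"burned with breaks:    {after.n_burned}/2500 "
      f"({after.n_burned / 2500:.1%}) in {after.n_steps} steps")
```

prints

```
breaks placed: 600 (d_f achieved 0.240)
burned without breaks: 2169/2500 (86.8%) in 37 steps
burned with breaks:    5/2500 (0.2%) in 3 steps
```

Clearing 24% of cells — chosen by Bonacich centrality — cuts this fire from
87% of the forest to 5 cells: the break density sits just above the
centrality placement's percolation-style transition (≈ 0.21), so the fire
dies immediately.  The same budget placed at random would leave the forest
well above its own transition (≈ 0.29) and still burning at large scale.

A command-line interface mirrors the library
(`firebreaks generate | simulate | centrality | plan | campaign | freqmap`);
campaign runs are driven by a YAML config and write CSV hazard curves plus
a JSON manifest of all resolved parameters and seeds.  Real landscapes
enter as three co-registered ESRI ASCII rasters (elevation, vegetation-type
codes, density codes); frequency maps export as plain PGM images.

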