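# gridpop

Population-autocorrelation analysis of grid-cell lattices in undersampled
environments.

## The problem

Grid cells in the medial entorhinal cortex fire on the vertices of a
hexagonal lattice that tiles an open environment.  When an animal is
confined to a circular track, its trajectory samples only a thin annular
slice of the underlying 2D pattern: most firing fields are "missing" from
the rate map, and the 2D autocorrelogram of any single cell no longer shows
the diagnostic ring of six peaks — it becomes indistinguishable from that of
a field-shuffled surrogate.

`gridpop` implements the population-level remedy.  Because a spatial
autocorrelogram is independent of the lattice *phase*, the autocorrelograms
of comodular cells (same spacing λ and orientation θ, different phases) can
be summed:

```
P(Δ) = Σ_c  r_c(Δ),        r_c(Δ) = corr( λ_c(x), λ_c(x+Δ) )
```

Each cell contributes the subset of lattice peaks its own slice happens to
sample, and the **population autocorrelation** `P` recovers the full
six-peak hexagonal signature that no individual correlogram shows.  From the
inner peak ring the module's spacing (ring radius λ), orientation (peak
angles θ, θ+60°, θ+120°) and a sixfold-symmetry **gridness score**

```
g = min{ρ(60°), ρ(120°)} − max{ρ(30°), ρ(90°), ρ(150°)}
```

are inferred, where ρ(φ) is the correlation of the extracted peak-ring
annulus with itself rotated by φ.  Significance is assessed against
field-shuffle surrogates that preserve field number, sizes and value
statistics while randomizing field locations, and lap-stability of the code
is tested on the 1D linearized track, where allocentric (world-anchored)
fields produce an autocorrelation peak at the track circumference
(2π·75 cm = 471 cm).

The package is aimed at systems neuroscientists analyzing grid-cell
recordings from tracks or other undersampled environments, and ships the
idealized grid-cell simulator (three summed cosine gratings, Poisson
spiking along a generated trajectory) used to validate every stage.

## Worked example

Simulate 20 comodular grid cells (λ = 45 cm, θ = 14.9°, random phases)
confined to a circular track (outer diameter 150 cm, width 15 cm), sum
their autocorrelograms and infer the lattice:

```python
from gridpop.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(environment="track", n_cells=20, seed=1))
print(report["population_gridness"])        # 1.8277742174059513
print(report["inferred_spacing_cm"])        # 41.24272886345981
print(report["inferred_orientations_deg"])  # [14.04, 74.62, 135.0]
```

The population gridness of 1.83 (range −2…2) says the summed correlogram is
strongly sixfold-symmetric even though the cells only ever fired on the
annulus.  The inferred orientations sit within a degree of the generative
14.9°/74.9°/134.9°, pairwise 60° apart; the spacing is recovered slightly
low (41.2 vs 45 cm) because the peak-ring annulus clips the ring on a
track — in the open arena (`environment="arena"`) the same module yields
44.85 cm and gridness 1.45.

The same pipeline is scriptable from the shell (`gridpop simulate`,
`gridpop autocorr`, `gridpop popcorr`, `gridpop gridness`,
`gridpop controls`, `gridpop linearize`, `gridpop cluster`, `gridpop xenv`,
`gridpop run`); all stages are seeded and rerunning a configuration
reproduces its outputs exactly.

## Layout

- `src/gridpop/synthetic.py` — idealized grid-cell maps, modules,
  trajectories, Poisson spikes
- `src/gridpop/ratemaps.py` — smoothed occupancy-normalized rate maps,
  track linearization
- `src/gridpop/correlograms.py` — 2D/1D autocorrelograms, population sums
- `src/gridpop/gridness.py` — annulus extraction, gridness, lattice
  spacing/orientation inference
- `src/gridpop/null_models.py` — field-shuffle surrogates, permutation
  significance
- `src/gridpop/module_partition.py` — module clustering on lattice features
- `src/gridpop/cross_env.py` — cross-environment annulus correlations
- `src/gridpop/io.py`, `pipeline.py`, `cli.py` — text formats, run
  configuration, command line

See `docs/methods.md` for the model, the estimators and the numerical
choices.
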