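# phyloturn

Phylogenetic turnover of species assemblages, mapped into environmental
space and explained by macroecological characteristics.

The package implements a complete, reproducible pipeline:

1. **Environmental layers** — Turc potential evapotranspiration, a summer
   moisture index, equal-width stratification of two environmental rasters
   into a combined k×k stratification layer, and stratified random site
   sampling with per-stratum counts proportional to the log of the
   stratum's pixel count (min 1, max 10).
2. **Geographic land distance** — least-cost paths over the study grid with
   sea cells penalized (default 10×; 100× and straight-line Euclidean
   available), 8-connected with average-of-endpoints edge costs.
3. **Phylogenetic turnover** — the true-turnover (Simpson) component
   `min(b,c)/(a + min(b,c))` computed on shared vs unique rooted branch
   lengths, averaged over a set of trees (default 20); Pagel-δ depth
   rescaling (δ ∈ {0.1, 0.3, 1, 3, 10}) and depth truncation with clade
   collapsing are supported tree transforms.
4. **Distance removal** — OLS of logit-turnover on land distance (linear +
   quadratic terms); residuals are the distance-independent turnover.
5. **Macroecology** — species richness, Faith's PD, relative PD (residual
   of PD ~ SR + SR²) and niche size (95% bivariate data ellipse area of a
   species' occupied cells in environmental space).
6. **Mapping & importance** — neighboring-strata mean residual turnover
   interpolated onto a regular grid over (env1, env2), and LMG (Shapley)
   decomposition of the R² of a standardized regression of residual
   turnover on SR, relPD and NS (linear + quadratic terms).
7. **Synthetic data** — Yule trees, Brownian-motion niche evolution and
   Gaussian-suitability ranges over generated land/sea grids with two
   correlated gradients, including planted-barrier scenarios with known
   turnover structure.

## CLI

```bash
# generate a synthetic study system
phyloturn simulate -o inputs/ --rows 40 --cols 40 --n-species 40 --seed 1

# run the full pipeline from a YAML config
phyloturn run -c config.yaml -o runs/demo --seed 1

# recompute variable importance from run artifacts
phyloturn importance --pairs runs/demo/delta_1/stratum_pairs.csv \
    --macro runs/demo/delta_1/macroeco.csv --sites runs/demo/sites.csv

# render an environmental-space surface
phyloturn plot --surface runs/demo/delta_1/surface_residual.csv -o surface.png
```

A minimal config:

```yaml
synthetic: {rows: 40, cols: 40, n_species: 40, n_trees: 5, seed: 1}
k: 9
deltas: [0.1, 0.3, 1.0, 3.0, 10.0]
sea_penalty: 10
seed: 1
```

Real inputs are supplied instead of `synthetic` via `env1_path` /
`env2_path` (ESRI ASCII grids), `trees_path` (one Newick per line) and
`occurrence_path` (wide CSV of 0/1 per cell and species).

Depth conventions: branch rescaling and truncation measure depth from the
root; for an ultrametric tree of height *h*, a cut at depth *d*
corresponds to age *h − d*.

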