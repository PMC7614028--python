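# narweb

Network–area relationships (NARs) for trophic metawebs on gridded species
ranges. Given a species-level metaweb of potential feeding links, per-cell
presence/absence of each species on a regular grid, and a partition of the
grid into regions, `narweb`:

1. aggregates cells outward from random start points in a deterministic
   spiral, producing nested, spatially coherent areas;
2. induces the local food web at every area from the metaweb and computes
   its structure (S, L, L/S, generality/vulnerability means and SDs,
   basal/intermediate/top fractions, consumers' diet overlap);
3. fits power laws `y = c·A^z` to each property–area relationship by
   nonlinear least squares, giving per-region scaling exponents;
4. compares observed curves with two richness-matched null models
   (metaweb-subsampled webs and fully random webs at matched S and L);
5. summarises each region's environment (Bray–Curtis habitat dissimilarity,
   Moran's I habitat clustering, climate means/SDs) and links those
   predictors to the scaling exponents via commonality analysis and OLS.

A synthetic-data module generates every input — a niche-model metaweb with
a tunable basal fraction, contiguous heavy-tailed species ranges, clustered
habitat mosaics, smooth-plus-noise climate fields and contiguous region
partitions — so the whole pipeline runs at desk scale with no downloads.

## CLI

All stages are subcommands of `narweb`; each takes `--seed` and `--out`,
and every output CSV carries a provenance header comment.

```sh
# generate a synthetic scenario (five input CSVs)
narweb simulate --seed 1 --out data/

# build curves and fits for every region
narweb build-nar --species data/species.csv --links data/links.csv \
    --presence data/presence.csv --regions data/regions.csv \
    --rows 30 --cols 30 --replicates 100 --seed 1 --out run/

# richness-matched null models + z-ratio table
narweb nullmodel --model subsampled --curves run/curves.csv \
    --species data/species.csv --links data/links.csv --seed 1 --out run/null/

# per-region environmental predictors
narweb env --habitat data/habitat.csv --climate data/climate.csv \
    --regions data/regions.csv --rows 30 --cols 30 --out run/env_summary.csv

# regress z-exponents on selected predictors (also emits commonality.csv)
narweb regress --fits run/fits.csv --env run/env_summary.csv \
    --property S --out run/regression.csv

# or everything at once from a YAML config
narweb run --config scenario.yaml --seed 1 --out run/
```

`scenario.yaml` keys mirror `narweb.synthetic_data.ScenarioConfig`
(`s_pool`, `c_target`, `basal_fraction`, `n_rows`, `n_cols`, `n_regions`,
`range_median`, `range_sigma`, `habitat_k`, `habitat_clustering`, ...) plus
`replicates` and `null_model`.

## Input formats

Plain UTF-8 CSVs with header rows; `#` lines are comments. Grids are
0-based `(row, col)`, row-major cell ids.

| file | columns |
|---|---|
| species table | `species_id,name,group` |
| edge list | `consumer_id,resource_id` (consumer eats resource) |
| presence | `species_id,row,col` |
| habitat | `row,col,class_id,proportion` (per-cell sums ≈ 1) |
| climate | `row,col,variable,value` |
| region map | `row,col,region` (unlisted cells are `outside`) |

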