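# ifpmap

Inverse Frobenius–Perron inference for marker-expression dynamics: infer a
one-dimensional piecewise-linear map from a time series of per-cell
fluorescence density functions, analyze its equilibria, invariant density
and chaotic character, and simulate the cell-sorting experiments that
generate such density series.

The pipeline treats daily flow-cytometry distributions of sorted
subpopulations as successive probability density functions on a shared
log10-intensity partition. One step of the hidden deterministic map
`x(k+1) = S(x(k))` acts on densities as a row-stochastic transfer matrix
`Q`; the package estimates `Q` from consecutive-day density pairs by
simplex-constrained least squares, realizes it as a canonical
piecewise-linear semi-Markov map, and analyzes / iterates the result. An
augmented fit co-estimates the scale of additive Gaussian noise
(`x(k+1) = S(x(k)) + eta(k)`) by modeling each step as transport followed
by a Gaussian blur and grid-searching the blur scale.

## Layout

| module                 | what it does |
|------------------------|--------------|
| `ifpmap.partition`     | ordered cell partitions of the log10-intensity domain `[lo, hi)` |
| `ifpmap.density`       | event-table ingestion, log transform, histogram densities, density-series CSV round-trip |
| `ifpmap.transfer`      | piecewise-linear maps, exact transfer matrices, density evolution, invariant densities, map JSON |
| `ifpmap.inference`     | transition-matrix estimation, semi-Markov map construction, end-to-end fits, noise-scale grid search |
| `ifpmap.dynamics`      | closed-form fixed points, Lyapunov exponent, one-parameter bifurcation scans |
| `ifpmap.ensemble`      | Monte-Carlo iteration of cell populations, with or without additive noise |
| `ifpmap.synthetic`     | ground-truth maps and a full synthetic sorting-experiment simulator |
| `ifpmap.cli` / config  | `ifpmap` command: `synth`, `infer`, `analyze`, `simulate`, `plot`, `pipeline` |

## CLI

Everything runs from a single JSON/YAML config (all keys optional; see
`ifpmap.config.RunConfig` for the full list):

```sh
cat > config.json <<'EOF'
{"lo": 0.0, "hi": 4.0, "n_cells": 16,
 "map_kind": "random_semi_markov",
 "n_cells_per_day": 20000, "days": 5, "seed": 1}
EOF

ifpmap pipeline --config config.json --out-dir out
```

writes a ground-truth map, the simulated sorted-fraction density series,
the fitted map and fit report, a dynamics analysis, predicted densities
and a recovery report, plus a manifest with per-artifact SHA-256 hashes
(identical config + seed gives identical hashes). Stages can also be run
individually:

```sh
ifpmap synth    --config config.json --out-dir out
ifpmap infer    --config config.json --densities out/densities.csv --out-dir out
ifpmap analyze  --map out/fitted_map.json --out-dir out --bifurcation --plot
ifpmap simulate --config config.json --map out/fitted_map.json \
                --initial out/densities.csv --out-dir out
ifpmap plot     --config config.json --map out/fitted_map.json \
                --observed out/densities.csv \
                --predicted out/predicted_densities.csv --out-dir out/figs
```

Real measurements enter through per-event CSV/TSV tables (one row per
event, channel column named in the call), `ifpmap.density.load_intensity_table`
plus `log10_transform` and `estimate_density`; density series travel as a
long-format CSV with columns `fraction, day, cell_index, height`.

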