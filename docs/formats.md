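# File formats

All artifacts are plain text.  Time is in seconds, lengths in µm, counts
are photons per bin.  Correlation values use the "+1" offset convention:
an uncorrelated signal gives G ≈ 1 and the zero-lag excess amplitude is
G(0) − 1 = 1/N.

## Trace (`*.csv` + `*.meta.yaml`)

CSV with header `bin_index,counts_green,counts_red`; counts are
non-negative integers, one row per time bin.  A YAML sidecar named
`<stem>.meta.yaml` is required and carries at least `bin_time` (s); the
simulator also records the seed, optics, box, and realized particle counts
per species.  Readers reject non-integer or negative counts and malformed
headers, naming the offending line.

## Correlation curve (`*.csv`)

Comment header lines `# key: value` (`kind` ∈ {gg, rr, gr} is mandatory;
`source_bin_time`, `n_segments`, `estimator` are recorded), then
`lag_s,value,stderr` rows.  Lags are strictly increasing and may start at
0 (the zero lag of autocorrelations carries shot noise; fits skip it).
Floats are written with full `repr` precision, so write→read round-trips
exactly.

## Fit result (`*.json`)

One JSON object: `model` (n_particles, components as [fraction,
diffusion_time_s] pairs sorted by increasing time, structure_parameter,
triplet_fraction, triplet_time), `stderr` per free parameter, `fixed`
parameters, `reduced_chi_square`, `residuals`, `lags`, `converged`,
`n_function_evals`, `weighted`, `warnings`.

## Pipeline config (`*.yaml`)

Mapping with `optics`, `box_edge_lengths`, `duration`, `time_step`,
`bin_time`, `rng_seed`, `conditions` (name, n_cells, species list),
optional `correlator` / `fit` / `rca` blocks and `compare` pairs.
`PipelineConfig.from_yaml(PipelineConfig.to_yaml(c)) == c` holds exactly.
Simulation-only configs for `fccs simulate` use the same species/optics
schema without the condition layer.

## Pipeline output directory

```
out/
  config.yaml               # the exact config that ran
  traces/<cell>.csv(+meta)  # stage 1
  curves/<cell>_<kind>.csv  # stage 2
  fits/<cell>_<kind>.json   # stage 3
  interaction_table.csv     # cell_id,condition,rca,nc_over_ng,normalization
  comparison_<a>_vs_<b>.json
  manifest.json             # SHA-256 checksums, per-cell seeds, status
  pipeline.log              # wall times; removing it changes nothing
```

## CLI exit codes

0 success · 2 configuration error · 3 data-format error · 4 numerical
failure (non-convergent fit, no correlated signal).
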