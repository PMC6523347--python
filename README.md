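# tmsmap

Accuracy assessment for grid-based navigated-TMS motor maps.

The package computes eight muscle-representation parameters from per-cell
MEP amplitude samples (three thresholded areas, amplitude- and
probability-weighted areas, and three center-of-gravity variants), and uses
bootstrap resampling of each cell's amplitudes to estimate how the accuracy
of every parameter depends on the number of stimuli delivered per grid
cell:

- **normalized bias** `(mean(P) − P0) / P0` over bootstrap replicate maps,
- **within-session CV** `std(P) / mean(P)`,
- **between-session variability** `mean over triples of (Pmax − Pmin) / (Pmax + Pmin)`,
- **COG error**: mean distance between the observed COG and bootstrap COGs.

Sub-threshold responses (below 50 µV by default) are left-censored, so
cell-wise session comparisons use Gehan's generalization of the
Mann–Whitney test with permutation p-values, visualized as signed
significance diagrams. Session discrimination is quantified by histogram
overlaps of bootstrap parameter distributions and a one-way random-effects
intraclass correlation on them (BICC). Page's trend test backs the
ordered-alternative claims (accuracy improving with stimulus count), and a
coverage module scores candidate grid sizes against gridless point-cloud
maps. A synthetic generator (censored lognormal amplitudes on a Gaussian
excitability surface, with optional between-session drift) makes every
stage runnable without any external data.

## Package layout

| module | contents |
| --- | --- |
| `tmsmap.map_model` | `GridSpec`, `TMSMap`, `PointMap`, `SessionSet`, CSV I/O, per-cell summaries |
| `tmsmap.map_parameters` | the eight representation parameters |
| `tmsmap.bootstrap_engine` | resampling, bias/CV/V/COG-error, accuracy profiles |
| `tmsmap.session_stats` | Gehan test, significance diagrams, histogram overlap, BICC, Page trend test |
| `tmsmap.grid_coverage` | coverage fractions/curves for candidate grid sizes |
| `tmsmap.synthetic_data` | excitability surfaces, session/point-map simulators |
| `tmsmap.cli_report` | `tmsmap` CLI and the end-to-end pipeline with a run manifest |

## CLI

```sh
tmsmap simulate --seed 1 --out maps.csv --points points.csv
tmsmap params   --map maps.csv --threshold 50 --out params.csv
tmsmap accuracy --maps maps.csv --k 1..10 --boot 1000 --seed 1 --out accuracy.csv
tmsmap compare  --maps maps.csv --subject sub01 --alpha 0.05 --out-dir cmp/
tmsmap coverage --points points.csv --sides 38,46,53,61,69 --out coverage.csv
tmsmap run      --config config.yaml --out-dir out/
```

`tmsmap run` executes simulate → params → accuracy → compare from a YAML
config (`sim:` block for the generator, `analysis:` block mirroring
`AnalysisConfig`) and writes a `manifest.json` recording the seed, config
and outputs; re-running a manifest reproduces all CSVs byte-for-byte.

## Map table format

CSV with columns `subject, session, row, col, x_mm, y_mm, stim_index,
amplitude_uV, censored` (censored = 1 means the response was below the
detection threshold; its amplitude is stored as 0). Point clouds use
`subject, muscle, x_mm, y_mm, amplitude_uV, censored`.

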