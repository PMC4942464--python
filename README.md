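# p2ensemble

Analysis of ATP dose-dependent calcium responses shaped by an ensemble of
P2 purinergic receptors. The package provides:

- **`hill_core`** — Hill-equation evaluation and nonlinear least-squares
  fitting (optional constant offset, 95% confidence intervals, R²).
- **`receptor_catalog`** — an embedded, versioned catalog of per-receptor
  Hill parameters (K½, Hill coefficient, provenance) for human and rodent
  P2X1–7 / P2Y1–14, and assembly of evaluable basis-function sets
  (e.g. the ATP-responsive osteoblast receptors P2X2, P2X5, P2X7, P2Y1,
  P2Y2, P2Y4).
- **`trace_features`** — single-cell fluorescence trace metrics: baseline
  normalization (F/F₀)−1, peak amplitude, width at half maximum, area under
  the curve; single-pass mean ± 2 SD outlier removal and per-experiment
  normalization of condition summaries.
- **`ensemble_model`** — fitting ensemble dose-response curves as *signed*
  linear combinations of receptor basis functions (negative weights mark
  inhibitory contributions), model comparison by R², and landmark (two-peak)
  analysis of non-monotone amplitude curves.
- **`synthetic_data`** — fully seeded generators for dose-response tables
  and multi-experiment single-cell trace ensembles with ground-truth
  manifests, so the entire pipeline is testable without external data.
- **`cli_io`** — CSV/JSON readers and writers plus the command-line
  interface.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle agreement,
recovery rates, end-to-end two-peak detection); the other files are unit and
property tests per module.

## CLI

```sh
# generate a synthetic dataset (traces.csv, stimuli.csv, manifest.json)
p2ensemble simulate --preset fig6 --seed 1 --out data/

# per-cell features and per-condition summaries
p2ensemble extract-features data/traces.csv data/stimuli.csv \
    --out-features features.csv --out-summary summary.csv --normalize

# fit a single Hill curve to a dose-response CSV
p2ensemble fit-hill dose_response.csv --include-offset --out fit.json

# decompose a dose-response curve into receptor basis functions
p2ensemble decompose curve.csv --basis "P2Y1,P2Y4,P2X7" --species rodent \
    --drop-top-concentration --out model.json

# export the embedded receptor catalog
p2ensemble catalog export --out catalog.json
```

Concentrations are molar throughout; the CLI also accepts unit-suffixed
values such as `1uM` or `100 nM`. Dose-response CSVs use columns
`concentration_M, response[, dispersion, n]`; trace CSVs are long-form
`experiment_id, cell_id, concentration_M, time_s, fluorescence` with a
separate `experiment_id, stimulus_time_s` stimulus table.

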