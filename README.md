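# synchrospread

Timescale-specific spatial synchrony in invasion-front spread rates, and
how much of it is explained by synchronous climate fluctuations.

The package turns annual trap-catch point data at a species' range edge
into per-transect spread rates (indicator kriging → 0.5-probability
isocline → radial boundary displacement), normalises the resulting
location × year matrices (Box-Cox, linear detrend, demean, unit
variance), and then quantifies synchrony with Morlet-wavelet tools:

- **WMF / WPMF** — wavelet mean field and wavelet phasor mean field,
  with a Monte-Carlo phasor null for the WPMF significance contour;
- **spatial wavelet coherence** — band-level (2–4 yr and > 4 yr)
  surrogate tests using synchrony-preserving Fourier surrogates, with
  mean phase reported in units of π (positive = response leads);
- **wavelet Moran decomposition** — percent of synchrony explained by a
  predictor field, with cross-term diagnostics (|cross| > 10 % flags a
  violated independence assumption).

A built-in simulator generates synthetic invasion-front worlds (direct
spread/climate series, or full trap grids with negative-binomial catches
around a logistic front) with known ground truth, so every stage is
testable without external data.

## CLI

```sh
# synthetic world (series mode writes spread.csv / climate.csv)
synchrospread simulate --config sim.yaml --out world/ --mode series

# trap CSVs -> crossings + spread-rate matrix
synchrospread spread --traps 'world/traps_*.csv' --out rates/

# normalise a locations x years matrix
synchrospread clean --in rates/spread.csv --out clean.csv --params params.csv

# mean fields + WPMF significance level
synchrospread synchrony --in clean.csv --out sync/

# band coherence test and Moran decomposition
synchrospread coherence --response clean.csv --predictor climate.csv \
    --band short --n-surrog 2000 --seed 1 --out coh.csv
synchrospread moran --response clean.csv --predictor climate.csv \
    --band short --out moran.csv

# config-driven end-to-end run on prepared matrices
synchrospread all --config analysis.yaml --spread clean_spread.csv \
    --climate prcp=clean_prcp.csv --out results/
```

A simulation YAML holds `SimulationConfig` fields plus a `driver:`
block (`components: [[period, amplitude, phase], ...]`, `ar1_phi`,
`ar1_sigma`); an analysis YAML holds `AnalysisConfig` fields plus
optional `regions:` / `bands:` lists (see `tests/test_pipeline.py`).

## Layout

| module | contents |
| --- | --- |
| `simulate` | driver process, series bundles, trap-grid worlds, ground truth |
| `geometry` | treatment masking, indicator kriging/IDW, transect crossings, spread rates, buffer means |
| `clean` | rectangularisation (≥ 20-yr, ≥ 10-location rules), Box-Cox/detrend/standardise |
| `wavelet` | Morlet CWT, power normalisation, WMF, WPMF, phasor null threshold |
| `coherence` | spatial coherence, Fourier surrogates, band tests, index coherence |
| `moran` | per-timescale wavelet regression and synchrony decomposition |
| `pipeline` | region orchestration, seasonal index windows, result tables |
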