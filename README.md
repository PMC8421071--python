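# titerflow

Quantitative characterization of inducible transcriptional controllers from
flow-cytometry data. The package provides, as reusable and tested pieces:

- **Event-table I/O** (`titerflow.flow_events`): FCS 3.0/3.1 (linear-scaled,
  list-mode) and a plain CSV event-table dialect with `#key=value` metadata
  comments; minimal quantile-based debris gating (off by default — data are
  analyzed ungated).
- **Synthetic populations** (`titerflow.synthetic_flow`): seeded generators
  for single-cell populations with lognormal volume, volume-coupled scatter
  channels, additive lognormal autofluorescence, volume-scaled reporter
  expression with a known volume-independent noise term, dose-dependent
  medians from a ground-truth dose-response model, and 1n/2n/>2n DNA-content
  mixtures. Every population comes with its ground truth for recovery tests.
- **Population metrics** (`titerflow.expression_metrics`): medians, fold
  difference, fold over autofluorescence, percent-of-reference, CoV, and
  0–100 curve normalization.
- **Volume-independent variation** (`titerflow.variation`): the
  `sqrt(FSC-W^2 + SSC-H^2)` volume proxy, Huber M-estimator robust regression
  (IRLS, k = 1.345, MAD-based scale), the VIV statistic (robust residual
  standard deviation of log reporter vs log proxy), percentile bootstrap
  confidence intervals, and rank-matching calibration of the proxy against
  Coulter-counter volumes.
- **Dose-response fitting** (`titerflow.dose_response`): the
  fractional-polynomial logistic model
  `f(x) = c + (d-c)/(1 + exp(b*ln(x+1)^p1 + e*ln(x+1)^p2))` with fixed
  powers `p1`, `p2`, multi-start least squares, analytic slopes, input
  dynamic range extraction, and the CI-based induction threshold.
- **DNA-content analysis** (`titerflow.ploidy`): constrained two-component
  EM mixture fitting of 1n/2n peaks (constant-CV widths, optional
  `mean_2n = 2*mean_1n` constraint), >2n tail quantification, and
  arrest/release time-course summaries.
- **Pipeline + CLI** (`titerflow.pipeline`, `titerflow.cli`): YAML-configured
  end-to-end runs emitting a tidy metrics CSV, a dose-response JSON report,
  and a fully seeded run log. Reports are byte-identical across reruns.

## CLI

```sh
# synthesize a 12-dose experiment with ground-truth sidecars
titerflow simulate --config examples/characterize.yaml --out out/sim

# end-to-end characterization (metrics.csv, dose_response.json, run_log.json)
titerflow characterize --config examples/characterize.yaml --out out/run

# one-off analyses on event CSV/FCS files
titerflow viv --events events.csv --reporter FL1
titerflow ploidy --events dna.csv --seed 1
titerflow calibrate --proxy proxy.csv --coulter volumes.csv --seed 1
```

Every stochastic command requires a seed (in the config or via `--seed`);
all randomness is driven by NumPy's PCG64 generator, so outputs are
reproducible bit for bit.

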