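# ncctrials

Simulation and analysis of adaptive platform trials that reuse
**non-concurrent controls (NCC)** — control patients randomized before the
evaluated experimental arm entered the platform — under systematic drifts
("time trends") in the mean response.

The package provides:

- **`ncctrials.design`** — staggered-entry trial structure: entry schedules
  `d_k = d·(k−1)`, a deterministic equal-allocation recruitment plan with
  exit times and total sample size, the *period* partition (cut at every arm
  entry/exit), fixed-length *calendar* intervals, and the analysis window
  containing all data up to the evaluated arm's exit.
- **`ncctrials.simulate`** — patient-level data generation: permuted-block
  randomization with block size `2·(active arms + 1)`, Gaussian outcomes,
  and four trend patterns (linear, stepwise, inverted-U, seasonal) with
  per-arm strengths.
- **`ncctrials.models`** — one-sided inference on the evaluated arm's
  effect via: fixed-effect regression with period or calendar adjustment,
  B-spline time adjustment (degree 1–3, knots at period starts or on an
  equidistant grid), linear mixed models with iid or AR(1) random time
  effects (custom REML engine in `ncctrials.lmm`), mixed models with a
  random treatment×time interaction (evaluated arm excluded), and
  pooled/separate t-test comparators.
- **`ncctrials.study`** — Monte-Carlo operating characteristics (type I
  error, power, bias, MC error) over scenario grids with per-replicate
  seed derivation (order-independent, individually reproducible).
- **`ncctrials.cli` / `ncctrials.config`** — YAML/JSON configuration,
  CSV I/O, and a reproducibility manifest.

## CLI

```sh
# one simulated trial -> CSV (columns j,t,arm,y,period,calendar; arm 0 = control)
ncctrials simulate --config config.yaml --seed 1 --out trial.csv

# fit one model to a trial file
ncctrials fit --data trial.csv --config config.yaml --model fixed-period --arm 3

# operating-characteristics study + manifest; replay reproduces it byte-identically
ncctrials study --config config.yaml --reps 2000 --out summary.csv [--plot rates.png]
ncctrials study --replay summary.csv.manifest.json --out summary2.csv
```

Minimal config:

```yaml
K: 4          # experimental arms
d: 250        # entry spacing (or schedule: [0, 250, 500, 750])
n_arm: 250    # patients per experimental arm
clength: 100  # calendar-interval length
pattern: linear
lam: 0.5      # scalar -> equal strength in all arms; or list of K+1 values
M: 3          # evaluated arm
models: [fixed-period, spline-period-q3, mixed-period-ar1, ttest-separate]
```

Model labels: `fixed-{period,calendar}`, `spline-{period,calendar}-q{1,2,3}`,
`mixed-{period,calendar}-{iid,ar1}`, `interaction-{period,calendar}`,
`ttest-{pooled,separate}`.

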