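# gtpkin

Analysis toolkit for fluorescent GTPase assays: closed-form kinetic models
and nonlinear fitters for plate-reader fluorescence traces, screening-plate
hit calling against vehicle controls, dose-dependence ANOVA, and
dual-channel BRET (resonance-energy-transfer) quantification — plus seeded
synthetic-data generators so every stage is testable without external data.

## What it does

* **`gtpkin.kinetic_models`** — forward models for three assay geometries:
  single-exponential probe association (`k_bind`), a sequential
  binding-then-hydrolysis scheme (`k_bind`, `k_hydr`, with the analytic
  equal-rates limit and a brightness factor `rho` for the hydrolyzed
  product), and post-challenge displacement decay (`k_diss`, with optional
  injection dilution). Every closed form is backed by an independent
  numerical-ODE route (`ode_signal`) for verification.
* **`gtpkin.trace_fitting`** — multi-start bounded least-squares fitters
  (`fit_k_bind`, `fit_k_hydr`, `fit_k_diss`) with endpoint/initial baseline
  conventions, curvature-based standard errors, Welch-style rate comparison
  (`compare_rates`) and fold changes with propagated errors (`fold_change`).
* **`gtpkin.hts_screen`** — per-well screening metrics (windowed `k_bind`
  fit and maximal uptake), per-plate DMSO control statistics, two-sided
  hit calling at 2 SD (`k_bind`) / 3 SD (`max_uptake`) with inclusive
  boundaries, and one-way ANOVA dose-dependence testing (`dose_response`).
* **`gtpkin.bret_analysis`** — acceptor/donor ratio series, basal level
  (mean of the 10 readings before agonist injection), plateau-to-basal
  ratio of the last 10 stimulated readings, and antagonist-recovery flag.
* **`gtpkin.synthetic_data`** — deterministic, seeded generators for
  traces, 384-well plates (controls, neutral wells, spiked wells in
  control-SD units) and BRET series.
* **`gtpkin.cli`** — `simulate`, `fit`, `screen`, `bret` subcommands.

## CLI

```sh
# synthesize a plate and screen it
gtpkin simulate --kind plate --seed 1 --out sim/
gtpkin screen --plate-map sim/plate_map.csv --traces sim/traces.csv --out screen/

# synthesize and fit a single association trace
gtpkin simulate --kind trace --assay association --seed 1 --out sim_trace/
gtpkin fit --traces sim_trace/traces.csv --assay association --out fits/

# BRET summary
gtpkin simulate --kind bret --seed 1 --out sim_bret/
gtpkin bret --series sim_bret/bret.csv --injections sim_bret/bret_injections.json --out bret/
```

Every command writes a `manifest.json` (options, inputs, package version)
next to its outputs and is byte-identical under a fixed `--seed`.

File formats: traces as long-format CSV (`well,time_s,signal`), plate maps
as `well,role,compound_id,concentration_uM` CSV, hit calls as TSV, BRET
series as `time_s,donor,acceptor` CSV plus a JSON sidecar with injection
indices, parameter sets and summaries as JSON.

## Conventions

* Time is in seconds and rates in s^-1 throughout; fluorescence is in
  arbitrary units (AU).
* Rates are bounded to [1e-8, 10] s^-1 so that hydrolysis-dead fits stay
  finite and reportable.
* Hit calling is two-sided and per plate; wells whose `k_bind` fit fails
  are still scored on `max_uptake`.
* `fit_k_hydr` supports pinning `k_bind` (measured separately in the
  association assay) and `rho` (probe calibration) — recommended for
  slow-decay traces where `k_hydr` and `rho` are otherwise degenerate.
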