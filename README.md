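# plastisim

An individual-based, forward-time simulator of reaction-norm evolution in a
metapopulation on a linear environmental gradient, with temporally
fluctuating deme environments. It is built to study when adaptation proceeds
by phenotypic plasticity (environment-responsive loci) versus genetic
differentiation (fixed loci), as a function of:

- the **timing of temporal variation** relative to development and selection
  (patterns: none, before selection only, before development only, both —
  with a tunable within-generation correlation, including perfect carry-over),
- among-generation **AR(1) autocorrelation** of the environment and optional
  spatial **synchronization** across demes,
- the **life-history order** of dispersal and selection (select-first vs
  move-first),
- the **migration pattern** (Gaussian stepping-stone vs island) and dispersal
  rate.

## Model in brief

Fifty demes carry linearly varying trait optima (step 0.4, endpoints ±9.8).
Each diploid individual has 5 nonplastic and 5 plastic loci; its phenotype is
`ΣN + multiplier(deme) × ΣP`, fixed at development, where the expression
multiplier varies linearly across demes (step 0.04) and tracks temporal
perturbations of the development environment. Survival is Gaussian in the
distance between phenotype and the local selection-stage optimum (σ = 2).
Reproduction is soft-selective: any deme with at least one survivor is
refilled to carrying capacity (100; 1,000 in single-deme mode) by random
mating with replacement, with 10% per-allele mutation (Normal, SD 0.1).
The reported outcome is **relative plasticity**: the population mean plastic
allelic sum standardized so 1 = the optimum-matching reaction-norm slope and
0 = flat norms (values outside [0, 1] indicate hyperplastic or reversed
norms). Replicates are run until 20 succeed or 60 attempts are exhausted;
extinct runs are excluded from averages.

## CLI

```sh
# one parameter combination (YAML config and/or overrides)
plastisim simulate --config run.yaml --seed 42 --out results/
plastisim simulate --preset fig3a --generations 2000 --replicates 5 --out results/
plastisim simulate --set pattern=p1 --set tau_pct=10 --set dispersal_rate=0.64 --out results/

# a Cartesian parameter grid (figure-style presets or a YAML grid file)
plastisim sweep --preset fig2b --generations 2000 --replicates 5 --out sweep_out/
plastisim sweep --grid grid.yaml --out sweep_out/

# collect per-run summaries into one table
plastisim summarize sweep_out/ --out summary.csv
```

Each run directory gets per-replicate trajectory CSVs (`generation,
mean_plasticity, relative_plasticity, pop_size`), a `manifest.json` with the
full config and extinction bookkeeping, and a one-row `summary.csv`.
Presets (`fig1a` … `fig5`) encode the captioned parameter points and sweep
axes of the standard experiment panels; see `plastisim.config.PRESETS`.

Config keys (YAML or `--set`): `n_demes, optimum_slope, expression_slope,
pattern {none|p1|p2|p3}, tau_pct, rho_among, corr_within, synchronized,
sigma, migration {stepping_stone|island}, dispersal_rate, order
{select_first|move_first}, n_generations, deme_capacity, single_deme,
mutation_rate, mutation_sd, master_seed, n_success, max_attempts,
end_window`.

## Package layout

- `plastisim.environment` — gradient construction, AR(1) temporal variation,
  expression multipliers
- `plastisim.genome` — genotypes, development, inheritance, mutation,
  founding populations
- `plastisim.selection` — Gaussian viability selection
- `plastisim.dispersal` — stepping-stone and island kernels, rate↔kernel-SD
  calibration
- `plastisim.engine` — generation loop, soft-selection reproduction,
  replicate protocol
- `plastisim.metrics` — mean/relative plasticity, replicate aggregation,
  equilibrium checks
- `plastisim.config`, `plastisim.cli` — validated run configs, sweeps,
  presets, command line
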