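# viralwf

Agent-based Wright–Fisher simulation of deleterious mutation accumulation in
viral populations with cellular coinfection, reassortment, and heterogeneous
cellular output.

RNA viruses mutate fast, and most mutations are deleterious. Unlike cellular
organisms, viruses replicate *through cells*: when several virions coinfect a
cell they pool their protein products, so a genome loaded with deleterious
mutations can ride on the fitness of its cellmates ("phenotypic hiding"),
decoupling progeny genotype from phenotype and relaxing purifying selection.
Coinfection simultaneously enables reassortment in segmented viruses, which
re-creates high-fitness genotypes and slows Muller's ratchet. This package
simulates those opposing forces explicitly, for modellers and experimentalists
studying within-host viral evolution.

## Model

Each generation, `V` virions infect `C` cells (constant sizes; mean MOI =
`V/C`). A genome has `g` genes on `y` freely reassorting segments and is
summarized by its per-gene deleterious mutation counts `n_i` (infinite sites).
Within a cell infected by `m` virions:

- per-copy gene fitness: `w_ij = (1 − s)^(n_ij)`
- per-gene group fitness: `w̄_i = (1/m) Σ_j w_ij` (incomplete dominance;
  `max`/`min` variants model fully recessive / fully dominant mutations)
- cellular fitness: `W_c = Π_i w̄_i`

Exactly `V` progeny are drawn, each choosing a source cell with probability
proportional to the cell's *output weight* `W′_c`, then drawing each of its
`y` segments uniformly among the cell's `m` parents. The output weight is
`W_c` (base model), `W_c · m_c` (input-dependent production), or a gamma
random variable with mean `W_c` and shape `k` (stochastic cellular
heterogeneity; small `k` = strong heterogeneity, predicted effective size
`V_e = V/(1 + 1/k)` at low MOI). Finally each gene gains Poisson(`U/g`) new
mutations, `U` per genome per generation.

## Worked example

Mutation–selection balance at low MOI: `V = 1000` virions on `C = 10000`
cells (MOI 0.1), influenza-like defaults `U = 1`, `s = 0.2`, `g = 8`, `y = 1`,
for `t = 20` generations:

```bash
$ viralwf run --V 1000 --C 10000 --t 20 --reps 5 --seed 7 --out demo_out
mean final load 5.231 (+/- 0.152 SE, 5 replicates) -> demo_out/
```

`demo_out/summary.csv` holds one row per replicate:

```
 replicate  final_mean_load  final_min_load  clicks  neutral_Ut  balance_Us
         0            5.408               1       1        20.0         5.0
         1            5.016               0       0        20.0         5.0
         2            4.737               0       0        20.0         5.0
         3            5.501               0       0        20.0         5.0
         4            5.492               0       0        20.0         5.0
```

The population equilibrates near the infinite-population balance `U/s = 5`
(column `balance_Us`), far below the neutral expectation `Ut = 20`
(`neutral_Ut`): at MOI 0.1 coinfection is rare and selection purges mutations
efficiently. `final_min_load` is the least-loaded genome's mutation count and
`clicks` counts the generations in which that minimum increased — the clicks
of Muller's ratchet. `demo_out/trajectories.csv` has the full per-generation
trajectories and `params.json` the exact resolved parameters and seed, so
every run is bit-reproducible.

The same interface drives the library (`SimParams`, `run_simulation`,
`run_experiment`), config-file sweeps (`viralwf sweep --config sweep.yaml`)
and named experimental designs (`viralwf figures fig3d`), which scan MOI,
population size, segment number, dispersion `k`, output model and dominance
form.

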