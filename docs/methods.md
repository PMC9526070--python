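# Methods

## Model

`viralwf` implements a discrete-generation, intercellular Wright–Fisher model
of a viral population. Census sizes are fixed: `V` virions and `C` target
cells per generation, so the mean multiplicity of infection MOI = `V/C` is a
derived quantity and never a free parameter. One generation consists of:

1. **Assignment.** Each virion independently picks a uniform cell.
   Occupancy is therefore multinomial with Σm = V exactly; for large `C`
   the per-cell MOI `m_c` is Poisson(V/C) to excellent approximation.
   Uninfected cells play no further role.
2. **Cellular fitness.** A genome carries `n_i` deleterious mutations on
   each of `g` genes (infinite sites: mutations never revert and never
   collide, so counts are a sufficient description). Per-copy gene fitness
   is `w_ij = (1−s)^(n_ij)`; the `m` copies of gene `i` delivered to a cell
   combine into a group fitness `w̄_i` (arithmetic mean by default); cellular
   fitness is `W_c = Π_i w̄_i`. The mean rule encodes the biology of shared
   protein products: every delivered copy contributes to the common pool, so
   a cell's output depends on its aggregate genetic cargo, not on any single
   genome — this is what lets deleterious mutations hide phenotypically in
   coinfected cells.
3. **Realized output.** The weight `W′_c` that determines a cell's share of
   the next generation is `W_c` (base), `W_c·m_c` (input-dependent
   production, the simplest linear input–output relationship), or one fresh
   draw from Gamma(shape `k`, mean `W_c`) per infected cell per generation
   (stochastic cellular heterogeneity). Cells have no identity across
   generations, so gamma draws are never persisted.
4. **Progeny and reassortment.** Exactly `V` progeny are drawn
   independently; each picks a source cell with probability `W′_c / Σ W′`,
   then draws each of its `y` segments uniformly among the cell's `m`
   parents. Segments reassort freely; there is no recombination within a
   segment. Crucially the within-cell draw ignores genotype: a low-fitness
   segment is as likely to be exported as a high-fitness one.
5. **Mutation.** Each progeny gene gains Poisson(`U/g`) new mutations, for
   a genomic rate of `U` per generation. A Poisson count (rather than a
   Bernoulli trial per gene) is the natural infinite-sites choice and
   matters at the default `U = 1`, where multiple hits per gene per
   generation are not rare.

Runs start from `V` mutation-free genomes, so "mutations accumulated by
generation t" is measured against zero and against the neutral reference
`U·t` and the infinite-population mutation–selection balance `U/s`.

## Parameters

| name | meaning | units | default |
|---|---|---|---|
| `V` | virion census size | count | 1000 |
| `C` | cell census size | count | 1000 |
| `U` | genomic deleterious mutation rate | mutations/genome/generation | 1.0 |
| `s` | fitness cost per mutation | – (0 ≤ s < 1) | 0.2 |
| `g` | genes per genome | count | 8 |
| `y` | reassorting segments (divides `g`) | count | 1 |
| `t` | horizon | generations | 20 |
| `k` | gamma dispersion (stochastic model) | – (> 0) | required iff stochastic |
| `fitness_function` | mean / max_fit (recessive) / min_fit (dominant) | – | mean |

Defaults are loosely influenza-like: `g = 8` genes lets `y` range over
{1, 2, 4, 8} with equal blocks, `U = 1` reflects a high RNA-virus genomic
deleterious rate, and `s = 0.2` a strongly deleterious typical effect. The
two standard horizons are `t = 20` (time to approach mutation–selection
balance at these rates) and `t = 150` (long enough to separate fast from
slow Muller's ratchets). Genes are assigned to segments in contiguous equal
blocks (`y = 4` ⇒ {1,2},{3,4},{5,6},{7,8}); genes are statistically
exchangeable, so the partition convention is inconsequential and contiguity
is simply reproducible.

## What the simulator emulates, and what it does not

The model deliberately isolates three forces — phenotypic hiding,
reassortment, and fitness-independent heterogeneity in cellular output —
from everything else in a real infection. It omits spatial structure (and
hence fitness correlations between coinfecting virions), time-varying
population sizes, superinfection exclusion as a mechanism, epistasis,
back-mutation and beneficial mutation, and within-segment recombination.
Agreement of simulated load trajectories with the closed-form limits and
with each other therefore demonstrates internal correctness of the
mechanism, not quantitative realism for any particular virus: real
infections should show the same qualitative trade-offs (hiding vs. sex vs.
drift) with different magnitudes.

## Numerical and design choices

- **Log-space fitness.** `(1−s)^n` underflows near `n ≈ 3300` at `s = 0.2`.
  Per-copy log-fitnesses are accumulated in log space; the grouped mean
  exponentiates after subtracting the per-gene population maximum
  (logsumexp-style), and sampling probabilities are normalized from shifted
  logs. Within-population per-gene spreads large enough to defeat the shift
  (> ~3000 mutations) are unreachable at the supported scales.
- **Vectorized update.** `step_generation` executes the whole generation as
  grouped array operations (sort/bincount/gather) over all cells at once;
  the per-cell reference functions implement the identical contracts one
  cell at a time, and the test suite asserts the two paths agree exactly.
  An exhaustive one-generation enumeration (`viralwf.oracle`) independently
  validates assignment weights, selection and reassortment on tiny
  populations, and closed-form gamma/Poisson moments validate the
  stochastic pieces.
- **Degenerate weights.** If every `W′_c` is zero (impossible for `s < 1`
  and `k > 0`, but reachable under future extensions) the step raises an
  explicit error rather than silently sampling uniformly.
- **No tie-breaking is needed** in sampling: all weights are continuous.
  The one discrete tie rule is in sweep analysis: when two grid points have
  equal mean load, the optimum is reported at the smaller MOI, and boundary
  minima are flagged as unbracketed.
- **Seeding.** Every replicate's generator derives from
  `SeedSequence((root_seed, grid_point, replicate))`, so sweep results are
  independent of execution order and reproduce bit-identically; CSVs from
  `run_experiment` are byte-stable across re-runs.
- **Clicks.** A "click" of Muller's ratchet is counted whenever the
  population minimum total load strictly increases between generations
  (event count; the total magnitude is reported separately). This is the
  standard usage for unsegmented genomes; for `y > 1` the minimum-load
  trajectory is still recorded but reassortment can reassemble low-load
  genotypes, so increments lack click semantics.
- **Offspring variance.** Measured from neutral (`U = 0`, `s = 0`)
  lineage-tagged single generations at low MOI, crediting each progeny to
  the parent its segment came from. At MOI ≪ 1 the base model gives
  variance ≈ 1 − 1/V (multinomial) and the stochastic model ≈ 1 + 1/k
  (gamma–Poisson, i.e. negative binomial), the basis of the effective-size
  prediction `V_e = V/(1 + 1/k)`; above MOI 0.1 the function warns that the
  prediction overestimates the variance because output noise is shared
  among coinfecting virions.
- **Sweep scale.** Experiment presets default to 20 replicates per grid
  point with standard errors across replicates; grid points with
  `V > 10^5` drop to single replicates. Default MOI grids are logarithmic
  over {0.01 … 100}, clipped so that `V` and `C` stay ≥ 10.

## Limitations

- The location of the optimum MOI in fixed-`C` sweeps (where low-MOI grid
  points have small `V` and therefore strong drift) is sensitive to the
  horizon `t` and to the drift cost at the small-`V` end of the grid; the
  fixed-`V` design separates the hiding/reassortment trade-off from drift
  and localizes the optimum more robustly.
- The gamma heterogeneity model draws output weights independently each
  generation; persistent cell-type differences would induce temporal
  correlations the model does not represent.
- At very high load and very small `s` the infinite-sites assumption keeps
  genomes viable (`W > 0` always for `s < 1`); lethal mutation classes are
  not modelled.
- Enumeration in `viralwf.oracle` covers the base and input-dependent
  models only; the stochastic model mixes over a continuous gamma weight
  and is validated by moment identities instead.
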