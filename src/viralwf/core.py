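"""Per-generation update loop of the intercellular Wright-Fisher model.

Each generation:

1. the V virions are assigned independently and uniformly at random to
   the C cells (multinomial assignment; Poisson occupancy in the
   large-C limit);
2. within each infected cell, per-copy gene fitnesses w = (1-s)^n are
   combined per gene (mean / max / min across the m delivered copies)
   and multiplied across the g genes to give the cellular fitness W;
3. each cell's realized output weight W' is derived from W according to
   the chosen output model (identity, gamma-distributed with mean W, or
   W * m);
4. exactly V progeny are drawn, each independently choosing a source
   cell with probability proportional to W', then drawing each of its
   y segments uniformly among that cell's m parents (free reassortment,
   no within-segment recombination);
5. each progeny gene gains Poisson(U/g) new deleterious mutations
   (infinite sites, no back mutation).

Populations are plain ``(V, g)`` integer arrays of per-gene mutation
counts wrapped in :class:`PopulationState`.  ``step_generation`` runs
the whole update as vectorized array operations; the per-cell functions
(:func:`cellular_fitness`, :func:`realized_output`, ...) implement the
same contracts one cell at a time and are cross-checked against the
vectorized pass in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import FitnessFunction, OutputModel, ParameterError, SimParams

__all__ = [
    "Genome",
    "CellState",
    "PopulationState",
    "DegeneratePopulationError",
    "segment_map",
    "gene_fitness",
    "group_gene_fitness",
    "cellular_fitness",
    "realized_output",
    "assign_virions",
    "sample_progeny",
    "mutate",
    "step_generation",
    "run_simulation",
    "RunResult",
    "replicate_rng",
]


class DegeneratePopulationError(RuntimeError):
    """All cellular output weights are zero: no progeny can be drawn."""


def segment_map(g: int, y: int) -> np.ndarray:
    """Segment index of each gene: g genes in y contiguous equal blocks.

    >>> segment_map(8, 4)
    array([0, 0, 1, 1, 2, 2, 3, 3])
    """
    if g % y != 0:
        raise ParameterError(f"y={y} must divide g={g}")
    return np.repeat(np.arange(y), g // y)


@dataclass(frozen=True)
class Genome:
    """A virion's genome: per-gene deleterious mutation counts.

    Under the infinite-sites assumption a genome is fully characterized
    by how many deleterious mutations it carries at each of its g genes.
    """

    mutation_counts: np.ndarray
    y: int = 1

    def __post_init__(self):
        counts = np.asarray(self.mutation_counts, dtype=np.int64)
        if counts.ndim != 1:
            raise ParameterError("mutation_counts must be a 1-D vector")
        if (counts < 0).any():
            raise ParameterError("mutation counts must be non-negative")
        if len(counts) % self.y != 0:
            raise ParameterError(f"y={self.y} must divide g={len(counts)}")
        object.__setattr__(self, "mutation_counts", counts)

    @property
    def g(self) -> int:
        return len(self.mutation_counts)

    @property
    def total_load(self) -> int:
        return int(self.mutation_counts.sum())

    @property
    def segment_map(self) -> np.ndarray:
        return segment_map(self.g, self.y)


@dataclass
class PopulationState:
    """Exactly V genomes, stored as a (V, g) array of mutation counts."""

    counts: np.ndarray
    generation: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ParameterError("counts must be a (V, g) array")

    @property
    def V(self) -> int:
        return self.counts.shape[0]

    @property
    def g(self) -> int:
        return self.counts.shape[1]

    @property
    def total_loads(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @classmethod
    def founding(cls, params: SimParams) -> "PopulationState":
        """Mutation-free founding population of V genomes."""
        return cls(np.zeros((params.V, params.g), dtype=np.int64), generation=0)


@dataclass
class CellState:
    """One infected cell: the m parental genomes it received and its
    derived fitness and realized output weight."""

    parents: np.ndarray  # (m, g) mutation counts of the infecting virions
    gene_group_fitness: np.ndarray | None = None  # (g,) omega-bar values
    W: float | None = None  # cellular fitness, product of omega-bar
    W_out: float | None = None  # realized output weight W'

    def __post_init__(self):
        self.parents = np.atleast_2d(np.asarray(self.parents, dtype=np.int64))
        if self.m < 1:
            raise ParameterError("a CellState must contain at least one genome")

    @property
    def m(self) -> int:
        """Cellular multiplicity of infection."""
        return self.parents.shape[0]


# ---------------------------------------------------------------------------
# per-cell operations (reference semantics; vectorized fast path below)
# ---------------------------------------------------------------------------

def gene_fitness(n, s: float):
    """Fitness of a single gene copy carrying n deleterious mutations.

    Multiplicative cost per mutation: w = (1 - s)^n.
    """
    n = np.asarray(n)
    if (n < 0).any():
        raise ParameterError("mutation count must be non-negative")
    if not 0.0 <= s < 1.0:
        raise ParameterError(f"s must be in [0, 1), got {s}")
    out = (1.0 - s) ** n
    return out if out.ndim else float(out)


def group_gene_fitness(copy_fitnesses, fitness_function=FitnessFunction.MEAN) -> float:
    """Combine the m per-copy fitnesses of one gene into its group fitness.

    ``mean`` models incomplete dominance (every delivered copy contributes
    equally via shared protein products); ``max_fit`` makes deleterious
    mutations fully recessive (the fittest copy sets the phenotype);
    ``min_fit`` makes them fully dominant.  For m = 1 all three coincide.
    """
    w = np.asarray(copy_fitnesses, dtype=float)
    if w.size == 0:
        raise ParameterError("group fitness of an empty cell is undefined (m=0)")
    fitness_function = FitnessFunction(fitness_function)
    if fitness_function is FitnessFunction.MEAN:
        return float(w.mean())
    if fitness_function is FitnessFunction.MAX_FIT:
        return float(w.max())
    return float(w.min())


def cellular_fitness(cell: CellState, params: SimParams) -> float:
    """Cellular fitness W: product over genes of the per-gene group fitness.

    Also fills ``cell.gene_group_fitness`` and ``cell.W``.
    """
    w_copies = gene_fitness(cell.parents, params.s)  # (m, g)
    omega_bar = np.array(
        [group_gene_fitness(w_copies[:, i], params.fitness_function)
         for i in range(cell.parents.shape[1])]
    )
    cell.gene_group_fitness = omega_bar
    # accumulate in log space; exponentiate once
    cell.W = float(np.exp(np.log(omega_bar).sum()))
    return cell.W


def realized_output(cell: CellState, params: SimParams,
                    rng: np.random.Generator | None = None) -> float:
    """Realized output weight W' of a cell with known fitness W.

    base: W' = W;  input-dependent: W' = W * m;  stochastic: one fresh
    gamma draw with shape k and mean W (scale W/k).
    """
    if cell.W is None:
        cellular_fitness(cell, params)
    if params.output_model is OutputModel.BASE:
        cell.W_out = cell.W
    elif params.output_model is OutputModel.INPUT_DEPENDENT:
        cell.W_out = cell.W * cell.m
    else:
        if params.k is None or params.k <= 0:
            raise ParameterError("stochastic output requires k > 0")
        if rng is None:
            raise ParameterError("stochastic output requires an RNG")
        cell.W_out = float(rng.gamma(params.k, cell.W / params.k))
    return cell.W_out


def assign_virions(pop: PopulationState, params: SimParams,
                   rng: np.random.Generator) -> list[CellState]:
    """Randomly assign the V virions to the C cells.

    Each virion independently picks a uniform cell, giving multinomial
    cell occupancy (Poisson in the large-C limit) with sum of m exactly V.
    Only infected cells (m >= 1) are returned.
    """
    cell_of = rng.integers(0, params.C, size=pop.V)
    order = np.argsort(cell_of, kind="stable")
    cells = []
    for block in np.split(order, np.flatnonzero(np.diff(cell_of[order])) + 1):
        cells.append(CellState(parents=pop.counts[block]))
    return cells


def sample_progeny(cells: list[CellState], params: SimParams,
                   rng: np.random.Generator) -> PopulationState:
    """Draw exactly V progeny from the infected cells.

    Each progeny independently picks a source cell with probability
    proportional to W', then draws each of its y segments uniformly
    among that cell's m parents.  A high-fitness segment is as likely
    to be drawn as a low-fitness one: cellular fitness reflects the
    pooled protein products, not the genotype of the chosen segment.
    Mutation is NOT applied here.
    """
    weights = np.array([c.W_out for c in cells], dtype=float)
    total = weights.sum()
    if not total > 0:
        raise DegeneratePopulationError("all cellular output weights are zero")
    chosen = rng.choice(len(cells), size=params.V, p=weights / total)
    seg_of_gene = segment_map(params.g, params.y)
    counts = np.empty((params.V, params.g), dtype=np.int64)
    for i, c in enumerate(chosen):
        cell = cells[c]
        picks = rng.integers(0, cell.m, size=params.y)  # parent per segment
        counts[i] = cell.parents[picks[seg_of_gene], np.arange(params.g)]
    return PopulationState(counts)


def mutate(pop: PopulationState, params: SimParams,
           rng: np.random.Generator) -> PopulationState:
    """Add Poisson(U/g) new deleterious mutations per gene per genome.

    Infinite sites: counts only ever increase (no back mutation); the
    expected number of new mutations per genome is U.
    """
    if params.U > 0:
        pop.counts = pop.counts + rng.poisson(params.U / params.g, size=pop.counts.shape)
    return pop


# ---------------------------------------------------------------------------
# vectorized generation step
# ---------------------------------------------------------------------------

def _grouped_log_omega_bar(log_w: np.ndarray, inv: np.ndarray, m: np.ndarray,
                           fitness_function: FitnessFunction) -> np.ndarray:
    """log omega-bar per (cell, gene), grouped by the compressed cell
    index ``inv`` of each virion.

    log_w is (V, g); returns (n_cells, g).  The mean variant shifts by
    the per-gene maximum before exponentiating so that uniformly huge
    loads cannot underflow the grouped sums.
    """
    n_cells = len(m)
    V, g = log_w.shape
    if fitness_function is FitnessFunction.MEAN:
        shift = log_w.max(axis=0)  # (g,)
        w = np.exp(log_w - shift)
        flat_idx = inv[:, None] * g + np.arange(g)
        sums = np.bincount(flat_idx.ravel(), weights=w.ravel(),
                           minlength=n_cells * g).reshape(n_cells, g)
        return shift + np.log(sums / m[:, None])
    op = np.maximum if fitness_function is FitnessFunction.MAX_FIT else np.minimum
    init = -np.inf if fitness_function is FitnessFunction.MAX_FIT else np.inf
    out = np.full((n_cells, g), init)
    op.at(out, inv, log_w)
    return out


def step_generation(pop: PopulationState, params: SimParams,
                    rng: np.random.Generator) -> PopulationState:
    """One full generation: assignment, fitness, output, progeny, mutation.

    Returns a new population of exactly V genomes with the generation
    counter incremented.  All randomness is drawn from ``rng`` in a fixed
    order, so runs are bit-reproducible given (params, seed).
    """
    V, g, y = params.V, params.g, params.y
    cell_of = rng.integers(0, params.C, size=V)
    _, inv = np.unique(cell_of, return_inverse=True)
    m = np.bincount(inv)  # (n_occupied,)
    n_occ = len(m)

    log_w = pop.counts * math.log1p(-params.s) if params.s > 0 else np.zeros_like(
        pop.counts, dtype=float)
    log_omega = _grouped_log_omega_bar(log_w, inv, m, params.fitness_function)
    log_W = log_omega.sum(axis=1)  # (n_occ,)

    if params.output_model is OutputModel.BASE:
        log_W_out = log_W
    elif params.output_model is OutputModel.INPUT_DEPENDENT:
        log_W_out = log_W + np.log(m)
    else:
        # W' = W * Gamma(k, scale=1/k); one fresh draw per infected cell
        draws = rng.gamma(params.k, 1.0 / params.k, size=n_occ)
        with np.errstate(divide="ignore"):
            log_W_out = log_W + np.log(draws)

    top = log_W_out.max()
    if not np.isfinite(top):
        raise DegeneratePopulationError("all cellular output weights are zero")
    p = np.exp(log_W_out - top)
    p /= p.sum()
    chosen = rng.choice(n_occ, size=V, p=p)

    # per-cell parent lists via a stable sort of virions by cell
    order = np.argsort(inv, kind="stable")
    starts = np.concatenate(([0], np.cumsum(m)[:-1]))
    picks = np.minimum((rng.random((V, y)) * m[chosen, None]).astype(np.int64),
                       m[chosen, None] - 1)
    parent = order[starts[chosen, None] + picks]  # (V, y) global virion index
    seg_of_gene = segment_map(g, y)
    counts = pop.counts[parent[:, seg_of_gene], np.arange(g)]

    if params.U > 0:
        counts = counts + rng.poisson(params.U / g, size=(V, g))
    return PopulationState(counts, generation=pop.generation + 1)


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Trajectory of one replicate: per-generation summaries plus the
    final population and the exact parameters used."""

    params: SimParams
    trajectory: list  # list[GenerationSummary], generation 0 .. t
    final_population: PopulationState

    @property
    def final_summary(self):
        return self.trajectory[-1]

    def to_frame(self):
        """Tidy per-generation DataFrame (one row per generation)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": [s.generation for s in self.trajectory],
                "mean_load": [s.mean_load for s in self.trajectory],
                "min_load": [s.min_load for s in self.trajectory],
                "mean_fitness": [s.mean_fitness for s in self.trajectory],
            }
        )


def replicate_rng(seed: int, rep: int = 0, point: int | None = None) -> np.random.Generator:
    """Deterministic, order-independent RNG for replicate ``rep`` (and
    optionally sweep grid point ``point``) of root ``seed``."""
    entropy = (seed, rep) if point is None else (seed, point, rep)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def run_simulation(params: SimParams,
                   rng: np.random.Generator | None = None) -> RunResult:
    """Run one replicate for t generations from a mutation-free founding
    population, recording a summary at every generation including 0.

    Deterministic given (params, params.seed): two runs with identical
    inputs produce bit-identical trajectories.
    """
    from .summaries import summarize

    if rng is None:
        rng = replicate_rng(params.seed)
    pop = PopulationState.founding(params)
    trajectory = [summarize(pop, params.s)]
    for _ in range(params.t):
        pop = step_generation(pop, params, rng)
        trajectory.append(summarize(pop, params.s))
    return RunResult(params=params, trajectory=trajectory, final_population=pop)
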