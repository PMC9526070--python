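"""Unit tests for the per-generation update loop and its component operations."""

import numpy as np
import pytest

from viralwf import (
    CellState,
    ParameterError,
    PopulationState,
    SimParams,
    run_simulation,
    step_generation,
)
from viralwf.core import (
    DegeneratePopulationError,
    _grouped_log_omega_bar,
    assign_virions,
    cellular_fitness,
    gene_fitness,
    group_gene_fitness,
    mutate,
    realized_output,
    sample_progeny,
    segment_map,
)
from viralwf.params import FitnessFunction


# ---------------------------------------------------------------------------
# parameter validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "bad",
    [
        dict(V=0, C=1),
        dict(V=1, C=0),
        dict(V=1, C=1, s=1.0),
        dict(V=1, C=1, s=-0.1),
        dict(V=1, C=1, U=-1.0),
        dict(V=1, C=1, t=-1),
        dict(V=1, C=1, g=8, y=3),  # y must divide g
        dict(V=1, C=1, output_model="stochastic"),  # missing k
        dict(V=1, C=1, output_model="stochastic", k=0.0),
        dict(V=1, C=1, output_model="martian"),
        dict(V=1, C=1, fitness_function="median"),
    ],
)
def test_invalid_params_rejected(bad):
    with pytest.raises(ParameterError):
        SimParams(**bad)


def test_moi_is_derived():
    assert SimParams(V=300, C=1000).moi == pytest.approx(0.3)


def test_param_aliases():
    p = SimParams(V=1, C=1, output_model="input-dependent", fitness_function="recessive")
    assert p.output_model.value == "input_dependent"
    assert p.fitness_function is FitnessFunction.MAX_FIT


# ---------------------------------------------------------------------------
# fitness operations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n, s, expected",
    [(0, 0.2, 1.0), (1, 0.2, 0.8), (3, 0.2, 0.8 * 0.8 * 0.8), (5, 0.0, 1.0)],
)
def test_gene_fitness(n, s, expected):
    assert gene_fitness(n, s) == pytest.approx(expected)


def test_gene_fitness_strictly_decreasing():
    w = gene_fitness(np.arange(10), 0.2)
    assert (np.diff(w) < 0).all()


def test_gene_fitness_rejects_bad_input():
    with pytest.raises(ParameterError):
        gene_fitness(-1, 0.2)
    with pytest.raises(ParameterError):
        gene_fitness(1, 1.0)


@pytest.mark.parametrize(
    "copies, fn, expected",
    [
        ([1.0, 0.8], "mean", 0.9),
        ([1.0, 0.8], "max_fit", 1.0),
        ([1.0, 0.8], "min_fit", 0.8),
        ([0.64], "mean", 0.64),
        ([0.64], "max_fit", 0.64),
        ([0.64], "min_fit", 0.64),
    ],
)
def test_group_gene_fitness(copies, fn, expected):
    assert group_gene_fitness(copies, fn) == pytest.approx(expected)


def test_group_gene_fitness_empty_cell():
    with pytest.raises(ParameterError):
        group_gene_fitness([], "mean")


def test_cellular_fitness_examples():
    params = SimParams(V=10, C=10, s=0.2, g=8)
    # single mutation-free parent: product of ones
    cell = CellState(parents=np.zeros((1, 8), dtype=int))
    assert cellular_fitness(cell, params) == pytest.approx(1.0)
    # one mutation on each of 8 genes
    cell = CellState(parents=np.ones((1, 8), dtype=int))
    assert cellular_fitness(cell, params) == pytest.approx(0.8**8)
    # two parents: mutation-free + single mutant on gene 1 -> omega_bar_1 = 0.9
    parents = np.zeros((2, 8), dtype=int)
    parents[1, 0] = 1
    cell = CellState(parents=parents)
    assert cellular_fitness(cell, params) == pytest.approx(0.9)
    assert cell.gene_group_fitness[0] == pytest.approx(0.9)
    assert cell.gene_group_fitness[1:] == pytest.approx(np.ones(7))


def test_cellular_fitness_matches_per_gene_brute_force(rng):
    """Product form checked against a direct per-gene computation."""
    for fn in ("mean", "max_fit", "min_fit"):
        params = SimParams(V=10, C=10, s=0.3, g=8, fitness_function=fn)
        parents = rng.integers(0, 4, size=(3, 8))
        cell = CellState(parents=parents)
        w = (1 - params.s) ** parents.astype(float)
        agg = {"mean": np.mean, "max_fit": np.max, "min_fit": np.min}[fn]
        expected = np.prod([agg(w[:, i]) for i in range(8)])
        assert cellular_fitness(cell, params) == pytest.approx(expected)


def test_realized_output_deterministic_variants():
    parents = np.zeros((3, 8), dtype=int)
    cell = CellState(parents=parents)
    cell.W = 0.5
    assert realized_output(cell, SimParams(V=3, C=1)) == pytest.approx(0.5)
    cell.W_out = None
    out = realized_output(cell, SimParams(V=3, C=1, output_model="input_dependent"))
    assert out == pytest.approx(1.5)  # W * m = 0.5 * 3


def test_realized_output_gamma_moments(rng):
    """Stochastic output: mean W and variance W^2/k (gamma moments)."""
    params = SimParams(V=1, C=1, output_model="stochastic", k=2.0)
    n = 10**5
    draws = np.empty(n)
    cell = CellState(parents=np.zeros((1, 8), dtype=int))
    cell.W = 0.5
    for i in range(n):
        draws[i] = realized_output(cell, params, rng)
    se_mean = draws.std() / np.sqrt(n)
    assert abs(draws.mean() - 0.5) < 3 * se_mean
    expected_var = 0.5**2 / params.k
    assert draws.var() == pytest.approx(expected_var, rel=0.05)


def test_realized_output_stochastic_needs_rng():
    cell = CellState(parents=np.zeros((1, 8), dtype=int))
    cell.W = 0.5
    with pytest.raises(ParameterError):
        realized_output(cell, SimParams(V=1, C=1, output_model="stochastic", k=1.0))


# ---------------------------------------------------------------------------
# assignment, progeny sampling, mutation
# ---------------------------------------------------------------------------

def test_assign_virions_forced_cases(rng):
    pop = PopulationState(np.zeros((1, 8), dtype=int))
    cells = assign_virions(pop, SimParams(V=1, C=1), rng)
    assert len(cells) == 1 and cells[0].m == 1

    pop = PopulationState(np.zeros((100, 8), dtype=int))
    cells = assign_virions(pop, SimParams(V=100, C=1), rng)
    assert len(cells) == 1 and cells[0].m == 100


def test_assign_virions_poisson_occupancy(rng):
    """At V = C = 1000 the occupied fraction is ~ 1 - exp(-1)."""
    params = SimParams(V=1000, C=1000)
    pop = PopulationState(np.zeros((1000, 8), dtype=int))
    n_draws = 200
    fractions = np.empty(n_draws)
    for i in range(n_draws):
        cells = assign_virions(pop, params, rng)
        assert sum(c.m for c in cells) == 1000
        fractions[i] = len(cells) / params.C
    expected = 1 - np.exp(-1)
    se = fractions.std() / np.sqrt(n_draws)
    assert abs(fractions.mean() - expected) < max(3 * se, 0.005)


def test_sample_progeny_single_parent_copies(rng):
    params = SimParams(V=5, C=1, y=1)
    parent = np.arange(8, dtype=np.int64).reshape(1, 8)
    cell = CellState(parents=parent)
    cell.W_out = 1.0
    pop = sample_progeny([cell], params, rng)
    assert pop.counts.shape == (5, 8)
    assert (pop.counts == parent).all()


def test_sample_progeny_full_reassortment_fraction(rng):
    """Two parents, y=8: P(progeny identical to parent A) = 2^-8."""
    params = SimParams(V=2000, C=1, g=8, y=8)
    parents = np.stack([np.zeros(8, dtype=np.int64), np.ones(8, dtype=np.int64)])
    cell = CellState(parents=parents)
    cell.W_out = 1.0
    n_rounds = 20
    frac = np.empty(n_rounds)
    for i in range(n_rounds):
        pop = sample_progeny([cell], params, rng)
        frac[i] = (pop.counts.sum(axis=1) == 0).mean()
    p = 2.0**-8
    se = np.sqrt(p * (1 - p) / (params.V * n_rounds))
    assert abs(frac.mean() - p) < 4 * se


def test_sample_progeny_cell_weights(rng):
    """Cell choice proportional to W_out."""
    params = SimParams(V=10**4, C=2, y=1)
    a = CellState(parents=np.zeros((1, 8), dtype=np.int64))
    b = CellState(parents=np.full((1, 8), 5, dtype=np.int64))
    a.W_out, b.W_out = 0.9, 0.1
    pop = sample_progeny([a, b], params, rng)
    frac_a = (pop.counts.sum(axis=1) == 0).mean()
    se = np.sqrt(0.9 * 0.1 / params.V)
    assert abs(frac_a - 0.9) < 4 * se


def test_sample_progeny_degenerate_weights():
    cell = CellState(parents=np.zeros((1, 8), dtype=np.int64))
    cell.W_out = 0.0
    with pytest.raises(DegeneratePopulationError):
        sample_progeny([cell], SimParams(V=1, C=1), np.random.default_rng(0))


def test_mutate_zero_rate_is_identity(rng):
    counts = np.array([[5, 0, 0, 0, 0, 0, 0, 0]], dtype=np.int64)
    pop = PopulationState(counts.copy())
    mutate(pop, SimParams(V=1, C=1, U=0.0), rng)
    assert (pop.counts == counts).all()


def test_mutate_poisson_rate(rng):
    """New mutations per gene ~ Poisson(U/g): mean checked to 3 SE."""
    n = 10**5
    params = SimParams(V=n, C=1, U=1.0, g=8)
    pop = PopulationState(np.zeros((n, 8), dtype=np.int64))
    mutate(pop, params, rng)
    per_gene = pop.counts.mean(axis=0)
    se = np.sqrt(0.125 / n)
    assert np.abs(per_gene - 0.125).max() < 4 * se
    se_tot = np.sqrt(1.0 / n)
    assert abs(pop.counts.sum(axis=1).mean() - 1.0) < 3 * se_tot


# ---------------------------------------------------------------------------
# the composed generation step
# ---------------------------------------------------------------------------

def test_vectorized_fitness_matches_per_cell_ops(rng):
    """The grouped log omega-bar used by step_generation equals the
    composition of the per-cell reference operations, for every fitness
    function, on a random population and assignment."""
    import math

    for fn in ("mean", "max_fit", "min_fit"):
        params = SimParams(V=60, C=15, s=0.25, g=8, fitness_function=fn)
        counts = rng.integers(0, 5, size=(60, 8)).astype(np.int64)
        cell_of = rng.integers(0, 15, size=60)
        _, inv = np.unique(cell_of, return_inverse=True)
        m = np.bincount(inv)
        log_w = counts * math.log1p(-params.s)
        log_W_vec = _grouped_log_omega_bar(log_w, inv, m, params.fitness_function).sum(axis=1)

        order = np.argsort(cell_of, kind="stable")
        expected = []
        for block in np.split(order, np.flatnonzero(np.diff(cell_of[order])) + 1):
            cell = CellState(parents=counts[block])
            expected.append(np.log(cellular_fitness(cell, params)))
        assert log_W_vec == pytest.approx(np.array(expected), abs=1e-10)


@pytest.mark.parametrize("model, k", [("base", None), ("stochastic", 0.5),
                                      ("input_dependent", None)])
def test_population_size_conserved(rng, model, k):
    params = SimParams(V=137, C=23, U=1.0, s=0.2, g=8, y=4,
                       output_model=model, k=k)
    pop = PopulationState.founding(params)
    for _ in range(5):
        pop = step_generation(pop, params, rng)
        assert pop.counts.shape == (137, 8)
        assert (pop.counts >= 0).all()
    assert pop.generation == 5


def test_step_pergene_min_never_decreases(rng):
    """No back mutation: the population minimum count of each gene can
    never drop below the parental per-gene minimum."""
    params = SimParams(V=50, C=10, U=0.5, s=0.2, g=8, y=4)
    counts = rng.integers(0, 6, size=(50, 8)).astype(np.int64)
    pop = PopulationState(counts)
    floor = counts.min(axis=0)
    for _ in range(10):
        pop = step_generation(pop, params, rng)
        assert (pop.counts.min(axis=0) >= floor).all()
        floor = pop.counts.min(axis=0)


def test_zero_generations_returns_founding_population():
    result = run_simulation(SimParams(V=20, C=5, t=0, seed=3))
    assert len(result.trajectory) == 1
    assert result.trajectory[0].mean_load == 0.0
    assert result.final_population.generation == 0


def test_run_simulation_deterministic():
    params = SimParams(V=100, C=50, U=1.0, s=0.2, y=2, t=10, seed=42)
    a, b = run_simulation(params), run_simulation(params)
    assert a.to_frame().equals(b.to_frame())
    assert (a.final_population.counts == b.final_population.counts).all()


def test_neutral_accumulation_rate():
    """With s = 0 the mean load grows at U per generation (U*t)."""
    params = SimParams(V=500, C=500, U=1.0, s=0.0, t=10)
    loads = [run_simulation(params, rng=np.random.default_rng((9, r)))
             .final_summary.mean_load for r in range(10)]
    loads = np.array(loads)
    se = loads.std(ddof=1) / np.sqrt(len(loads))
    assert abs(loads.mean() - 10.0) < 3 * max(se, 1e-9) + 0.05


def test_segment_map_blocks():
    assert segment_map(8, 4).tolist() == [0, 0, 1, 1, 2, 2, 3, 3]
    assert segment_map(8, 1).tolist() == [0] * 8
    assert segment_map(8, 8).tolist() == list(range(8))
    with pytest.raises(ParameterError):
        segment_map(8, 3)
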