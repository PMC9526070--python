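"""Independent brute-force and closed-form references.

These are deliberately written as direct, slow enumerations of the model
definition — independent of the array code in :mod:`viralwf.core` — so
the test suite can check the simulator against them.

:func:`enumerate_one_generation` sums over every virion-to-cell
assignment (each with probability C^-V) and, within each assignment,
over every per-progeny cell choice (probability proportional to the
cell's output weight) and per-segment parent choice (uniform), yielding
the exact marginal genotype distribution of a single progeny and hence
the exact expected mean load after one generation.  Mutation is
excluded (U = 0); the mutation process is validated separately against
its Poisson moments.  Because progeny are exchangeable and drawn
independently given the assignment, the per-progeny marginal suffices
for expected-load validation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .params import FitnessFunction, OutputModel, ParameterError, SimParams

__all__ = [
    "TinyScenario",
    "enumerate_one_generation",
    "neutral_expectation",
    "balance_expectation",
]

_MAX_OUTCOMES = 10**6


@dataclass(frozen=True)
class TinyScenario:
    """An explicitly listed tiny population (V <= 3 genomes, C <= 3 cells)
    small enough for exhaustive one-generation enumeration."""

    genomes: tuple  # tuple of per-gene count tuples, one per virion
    params: SimParams

    def __post_init__(self):
        if self.params.U != 0:
            raise ParameterError("enumeration requires U = 0")
        if self.params.output_model is OutputModel.STOCHASTIC:
            raise ParameterError(
                "the stochastic output model mixes over a continuous gamma "
                "weight and cannot be enumerated exactly"
            )
        V, C = len(self.genomes), self.params.C
        if V != self.params.V:
            raise ParameterError("number of genomes must equal params.V")
        for gen in self.genomes:
            if len(gen) != self.params.g:
                raise ParameterError("every genome must have g genes")
            if any(n < 0 for n in gen):
                raise ParameterError("mutation counts must be non-negative")
        m_max = V
        outcomes = C**V * V * m_max**self.params.y
        if outcomes > _MAX_OUTCOMES:
            raise ParameterError(f"enumeration space too large ({outcomes})")


def _cell_fitness(genomes, s, fitness_function):
    """Direct evaluation of the per-gene group fitness and its product."""
    w = (1.0 - s) ** np.asarray(genomes, dtype=float)  # (m, g)
    if fitness_function is FitnessFunction.MEAN:
        omega_bar = w.mean(axis=0)
    elif fitness_function is FitnessFunction.MAX_FIT:
        omega_bar = w.max(axis=0)
    else:
        omega_bar = w.min(axis=0)
    return float(np.prod(omega_bar))


def enumerate_one_generation(scn: TinyScenario):
    """Exact expected mean load and marginal genotype distribution of a
    progeny virion after one generation, by full enumeration.

    Returns ``(expected_mean_load, dist)`` where ``dist`` maps genotype
    tuples (per-gene counts) to exact probabilities summing to 1.
    """
    params = scn.params
    V, C, g, y = params.V, params.C, params.g, params.y
    width = g // y
    dist: dict[tuple, float] = {}

    for assignment in itertools.product(range(C), repeat=V):
        p_assign = C ** (-float(V))
        cells = {}
        for virion, cell in enumerate(assignment):
            cells.setdefault(cell, []).append(virion)
        weights = {}
        for cell, members in cells.items():
            W = _cell_fitness([scn.genomes[v] for v in members], params.s,
                              params.fitness_function)
            if params.output_model is OutputModel.INPUT_DEPENDENT:
                W *= len(members)
            weights[cell] = W
        total = sum(weights.values())
        if not total > 0:
            raise ParameterError("degenerate assignment: all weights zero")
        for cell, members in cells.items():
            p_cell = p_assign * weights[cell] / total
            m = len(members)
            p_seg = m ** (-float(y))
            for picks in itertools.product(range(m), repeat=y):
                genotype = tuple(
                    scn.genomes[members[picks[seg]]][seg * width + j]
                    for seg in range(y)
                    for j in range(width)
                )
                dist[genotype] = dist.get(genotype, 0.0) + p_cell * p_seg

    expected_load = sum(p * sum(geno) for geno, p in dist.items())
    return expected_load, dist


def neutral_expectation(U: float, t: int) -> float:
    """Mean load accumulated by generation t under selective neutrality: U*t."""
    if U < 0 or t < 0:
        raise ParameterError("U and t must be non-negative")
    return U * t


def balance_expectation(U: float, s: float) -> float:
    """Mutation-selection balance mean load for an infinite population: U/s."""
    if U < 0:
        raise ParameterError("U must be non-negative")
    if s <= 0:
        raise ParameterError("the balance U/s is undefined for s <= 0")
    return U / s
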