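"""Population statistics: mutation load, ratchet clicks, effective size.

The quantities reported by the simulator are per-generation summaries
of the deleterious mutation load (mean, minimum, full histogram), the
click count of Muller's ratchet (increments of the population minimum
load), the offspring-number variance measured from lineage-tagged
one-generation runs, and the effective population size Ve = V / sigma^2
predicted for gamma-distributed cellular output (sigma^2 = 1 + 1/k at
low MOI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import OutputModel, ParameterError, SimParams
from .core import PopulationState

__all__ = [
    "GenerationSummary",
    "summarize",
    "effective_population_size",
    "offspring_variance",
    "click_count",
    "click_magnitude",
    "aggregate_sweep",
]


@dataclass(frozen=True)
class GenerationSummary:
    """Per-generation population statistics.

    ``load_histogram`` maps total load -> number of virions (sparse);
    its counts sum to V.  ``mean_fitness`` is the mean of
    (1 - s)^(total load) over virions.
    """

    generation: int
    mean_load: float
    min_load: int
    load_histogram: dict
    mean_fitness: float


def summarize(pop: PopulationState, s: float) -> GenerationSummary:
    """Summarize a population: exact integer arithmetic for loads."""
    loads = pop.total_loads
    values, counts = np.unique(loads, return_counts=True)
    mean_fitness = float(np.mean((1.0 - s) ** loads.astype(float)))
    return GenerationSummary(
        generation=pop.generation,
        mean_load=float(loads.sum()) / pop.V,
        min_load=int(loads.min()),
        load_histogram={int(v): int(c) for v, c in zip(values, counts)},
        mean_fitness=mean_fitness,
    )


def effective_population_size(V: int, k: float) -> float:
    """Predicted effective viral population size Ve = V / (1 + 1/k).

    Under gamma-distributed cellular output with shape k at low MOI the
    offspring distribution is negative binomial with variance
    sigma^2 = 1 + 1/k, so Ve = V / sigma^2.  Monotone increasing in k;
    tends to V as k -> infinity.  Values below 1 are returned as-is
    (they remain useful for collapsing load curves even though they are
    biologically unrealistic).
    """
    if V < 1:
        raise ParameterError(f"V must be >= 1, got {V}")
    if k <= 0:
        raise ParameterError(f"k must be > 0, got {k}")
    return V / (1.0 + 1.0 / k)


def offspring_variance(params: SimParams, n_generations: int = 100,
                       rng: np.random.Generator | None = None) -> float:
    """Empirical variance of per-virion offspring number.

    Runs ``n_generations`` independent one-generation trials with every
    virion lineage-tagged and counts how many progeny each parent
    contributes.  Requires a neutral setting (U = 0, s = 0) so that the
    measured variance isolates the demographic noise: expected about
    1 - 1/V for the base model (multinomial) and 1 + 1/k for the
    stochastic model at low MOI.  Single-segment attribution: each
    progeny is credited to the parent its (single) segment came from,
    so the measurement is intended for y = 1.

    The 1 + 1/k prediction assumes MOI << 1 (cells carry 0 or 1
    virion); at MOI > 0.1 it overestimates the variance because output
    noise is shared among coinfecting virions, so a warning is issued.
    """
    if params.U != 0 or params.s != 0:
        raise ParameterError("offspring variance requires U = 0 and s = 0")
    if params.moi > 0.1:
        warnings.warn(
            f"offspring variance measured at MOI {params.moi:.3g} > 0.1: "
            "the negative-binomial prediction 1 + 1/k overestimates the "
            "variance when coinfection is common",
            stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(params.seed)
    V, C = params.V, params.C
    stochastic = params.output_model is OutputModel.STOCHASTIC
    counts = np.empty((n_generations, V), dtype=np.int64)
    for gen in range(n_generations):
        cell_of = rng.integers(0, C, size=V)
        _, inv = np.unique(cell_of, return_inverse=True)
        m = np.bincount(inv)
        n_occ = len(m)
        if stochastic:
            w = rng.gamma(params.k, 1.0 / params.k, size=n_occ)
            total = w.sum()
            if not total > 0:
                raise ParameterError("all gamma output weights are zero")
            p = w / total
        else:
            p = np.full(n_occ, 1.0 / n_occ)
        chosen_cell = rng.choice(n_occ, size=V, p=p)
        order = np.argsort(inv, kind="stable")
        starts = np.concatenate(([0], np.cumsum(m)[:-1]))
        picks = np.minimum((rng.random(V) * m[chosen_cell]).astype(np.int64),
                           m[chosen_cell] - 1)
        parent = order[starts[chosen_cell] + picks]
        counts[gen] = np.bincount(parent, minlength=V)
    return float(counts.var(ddof=1))


def click_count(trajectory) -> int:
    """Number of ratchet clicks: generations at which the population
    minimum total load strictly increased.

    Meaningful for y = 1 (no reassortment), where the loss of the
    least-loaded class is effectively irreversible; for y > 1 the
    min-load trajectory can move without click semantics.
    """
    mins = np.asarray([s.min_load for s in trajectory])
    return int(np.count_nonzero(np.diff(mins) > 0))


def click_magnitude(trajectory) -> int:
    """Total increase of the minimum load over the trajectory."""
    mins = [s.min_load for s in trajectory]
    return int(mins[-1] - mins[0])


def aggregate_sweep(table, by=("point",)):
    """Replicate-averaged sweep: mean and standard error per grid point.

    ``table`` is a tidy per-point-per-replicate DataFrame as produced by
    :func:`viralwf.experiments.run_experiment`; the standard error is
    the sample SD divided by sqrt(n_reps).
    """
    import pandas as pd

    by = list(by)
    grouped = table.groupby(by, sort=False)["final_mean_load"]
    out = grouped.agg(
        mean_final_load="mean",
        sd_final_load="std",
        n_reps="count",
    ).reset_index()
    out["se_final_load"] = out["sd_final_load"] / np.sqrt(out["n_reps"])
    keep = [c for c in ("moi", "V", "C", "y", "k", "output_model",
                        "fitness_function") if c in table.columns]
    meta = table.groupby(by, sort=False)[keep].first().reset_index()
    return meta.merge(out, on=by)
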