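"""Simulation parameterization.

A single :class:`SimParams` instance fully describes one simulation
scenario: the census sizes of the virion and cell populations, the
genetics (mutation rate, selection coefficient, genome organization),
the cellular-output model, the dominance form of the within-cell fitness
function, the horizon and the RNG seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from enum import Enum


class OutputModel(str, Enum):
    """How a cell's realized output weight relates to its fitness.

    - ``BASE``: output weight equals cellular fitness, W' = W.
    - ``STOCHASTIC``: W' is gamma-distributed with mean W and shape k,
      modelling intrinsic cell-to-cell heterogeneity in virion production.
    - ``INPUT_DEPENDENT``: W' = W * m, so cells infected by more virions
      produce proportionally more progeny.
    """

    BASE = "base"
    STOCHASTIC = "stochastic"
    INPUT_DEPENDENT = "input_dependent"


class FitnessFunction(str, Enum):
    """Dominance form of the per-gene group fitness among the m copies
    delivered to a cell.

    - ``MEAN``: incomplete dominance, arithmetic mean of copy fitnesses.
    - ``MAX_FIT``: fully recessive deleterious mutations (fittest copy wins).
    - ``MIN_FIT``: fully dominant deleterious mutations (least-fit copy wins).
    """

    MEAN = "mean"
    MAX_FIT = "max_fit"
    MIN_FIT = "min_fit"


# accepted spellings on the CLI / in config files
_OUTPUT_ALIASES = {
    "base": OutputModel.BASE,
    "stochastic": OutputModel.STOCHASTIC,
    "input_dependent": OutputModel.INPUT_DEPENDENT,
    "input-dependent": OutputModel.INPUT_DEPENDENT,
}
_FITNESS_ALIASES = {
    "mean": FitnessFunction.MEAN,
    "max_fit": FitnessFunction.MAX_FIT,
    "recessive": FitnessFunction.MAX_FIT,
    "min_fit": FitnessFunction.MIN_FIT,
    "dominant": FitnessFunction.MIN_FIT,
}


class ParameterError(ValueError):
    """Raised when a SimParams field violates its invariants."""


@dataclass(frozen=True)
class SimParams:
    """Full parameterization of one simulation scenario.

    Parameters
    ----------
    V : int
        Virion population size; constant over generations.
    C : int
        Cell population size; constant over generations.  The mean
        multiplicity of infection is the derived quantity ``V / C``.
    U : float
        Genomic deleterious mutation rate (mutations per genome per
        generation).  Each gene mutates at rate ``U / g``.
    s : float
        Selection coefficient per deleterious mutation, ``0 <= s < 1``.
    g : int
        Number of genes per genome.
    y : int
        Number of freely reassorting segments; must divide ``g``.
    t : int
        Number of generations to simulate.
    output_model : OutputModel
        Cellular-output variant (see :class:`OutputModel`).
    k : float or None
        Gamma shape (dispersion) parameter; required iff
        ``output_model == STOCHASTIC``.  Small k means strong
        heterogeneity; k -> infinity recovers the base model.
    fitness_function : FitnessFunction
        Dominance form of the per-gene group fitness.
    seed : int
        Root RNG seed.
    n_reps : int
        Replicate count for multi-replicate runs.
    """

    V: int
    C: int
    U: float = 1.0
    s: float = 0.2
    g: int = 8
    y: int = 1
    t: int = 20
    output_model: OutputModel = OutputModel.BASE
    k: float | None = None
    fitness_function: FitnessFunction = FitnessFunction.MEAN
    seed: int = 0
    n_reps: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "output_model", _OUTPUT_ALIASES.get(str(self.output_model), self.output_model)
        )
        object.__setattr__(
            self,
            "fitness_function",
            _FITNESS_ALIASES.get(str(self.fitness_function), self.fitness_function),
        )
        if not isinstance(self.output_model, OutputModel):
            raise ParameterError(f"unknown output model {self.output_model!r}")
        if not isinstance(self.fitness_function, FitnessFunction):
            raise ParameterError(f"unknown fitness function {self.fitness_function!r}")
        if self.V < 1:
            raise ParameterError(f"V must be >= 1, got {self.V}")
        if self.C < 1:
            raise ParameterError(f"C must be >= 1, got {self.C}")
        if self.g < 1:
            raise ParameterError(f"g must be >= 1, got {self.g}")
        if self.y < 1:
            raise ParameterError(f"y must be >= 1, got {self.y}")
        if self.g % self.y != 0:
            raise ParameterError(f"y={self.y} must divide g={self.g}")
        if self.t < 0:
            raise ParameterError(f"t must be >= 0, got {self.t}")
        if self.U < 0:
            raise ParameterError(f"U must be >= 0, got {self.U}")
        if not 0.0 <= self.s < 1.0:
            raise ParameterError(f"s must be in [0, 1), got {self.s}")
        if self.n_reps < 1:
            raise ParameterError(f"n_reps must be >= 1, got {self.n_reps}")
        if self.output_model is OutputModel.STOCHASTIC:
            if self.k is None or self.k <= 0:
                raise ParameterError(
                    "stochastic output model requires dispersion k > 0, "
                    f"got {self.k}"
                )

    @property
    def moi(self) -> float:
        """Mean multiplicity of infection V/C (derived, never stored)."""
        return self.V / self.C

    def replace(self, **changes) -> "SimParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["output_model"] = self.output_model.value
        d["fitness_function"] = self.fitness_function.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        return cls(**d)
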