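"""Config-driven experiment runners.

An :class:`ExperimentSpec` is a base parameter set plus a grid of
parameter overrides; :func:`run_experiment` runs every grid point for
``n_reps`` replicates with seeds derived deterministically from
(root seed, grid point index, replicate), so replicate order and
execution order never affect the results.  Named presets reproduce the
published experimental designs (MOI sweeps at fixed V or fixed C,
segment sweeps, heterogeneity sweeps, input dependence and dominance
comparisons) at configurable replicate counts.

Outputs serialize to tidy CSV (one row per point x replicate in
``summary.csv``, one row per generation in ``trajectories.csv``) with a
``params.json`` sidecar recording the exact resolved parameters.
"""

from __future__ import annotations

import json
from collections import namedtuple
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .params import ParameterError, SimParams
from .core import replicate_rng, run_simulation
from .oracle import balance_expectation, neutral_expectation
from .summaries import aggregate_sweep, click_count

__all__ = [
    "ExperimentSpec",
    "run_experiment",
    "locate_optimum_moi",
    "OptimumMOI",
    "figure_preset",
    "FIGURE_PRESETS",
    "write_outputs",
    "load_spec",
    "DEFAULT_MOI_GRID",
]

#: Default logarithmic MOI grid spanning all published sweep ranges and
#: containing the reported optimum near 0.3.
DEFAULT_MOI_GRID = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)

#: Above this population size sweeps default to a single replicate.
SINGLE_REP_THRESHOLD = 10**5


@dataclass(frozen=True)
class ExperimentSpec:
    """One experimental design: defaults + a grid of overrides.

    ``grid`` is a list of dicts of :class:`SimParams` field overrides;
    each grid point must resolve to a valid SimParams.  ``horizon``
    overrides ``t`` for every point (20 targets mutation-selection
    balance, 150 the ratchet regime).
    """

    design: str
    grid: tuple = ()
    base_params: SimParams = field(
        default_factory=lambda: SimParams(V=1000, C=1000, U=1.0, s=0.2, g=8, y=1)
    )
    n_reps: int = 20
    horizon: int | None = None
    seed: int = 0

    def resolve_point(self, i: int) -> SimParams:
        overrides = dict(self.grid[i])
        if self.horizon is not None:
            overrides.setdefault("t", self.horizon)
        try:
            return self.base_params.replace(**overrides)
        except (ParameterError, TypeError) as exc:
            raise ParameterError(f"invalid grid point {i} ({overrides}): {exc}") from exc

    def reps_for_point(self, i: int) -> int:
        params = self.resolve_point(i)
        if params.V > SINGLE_REP_THRESHOLD:
            return 1
        return self.n_reps

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "grid": [dict(p) for p in self.grid],
            "base_params": self.base_params.to_dict(),
            "n_reps": self.n_reps,
            "horizon": self.horizon,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentSpec":
        d = dict(d)
        if "base_params" in d and not isinstance(d["base_params"], SimParams):
            d["base_params"] = SimParams.from_dict(d["base_params"])
        if "grid" in d:
            d["grid"] = tuple(dict(p) for p in d["grid"])
        return cls(**d)


def run_experiment(spec: ExperimentSpec, keep_trajectories: bool = True):
    """Run every grid point for its replicate count.

    Returns ``(summary, trajectories)``: tidy DataFrames with one row
    per point x replicate (final-generation statistics, plus the
    neutral U*t and balance U/s reference columns) and one row per
    generation per replicate.  An empty grid yields empty frames.
    """
    summary_rows = []
    traj_frames = []
    for i in range(len(spec.grid)):
        params = spec.resolve_point(i)
        for rep in range(spec.reps_for_point(i)):
            rng = replicate_rng(spec.seed, rep=rep, point=i)
            result = run_simulation(params, rng=rng)
            final = result.final_summary
            summary_rows.append(
                {
                    "design": spec.design,
                    "point": i,
                    "replicate": rep,
                    "moi": params.moi,
                    "V": params.V,
                    "C": params.C,
                    "U": params.U,
                    "s": params.s,
                    "g": params.g,
                    "y": params.y,
                    "t": params.t,
                    "output_model": params.output_model.value,
                    "k": params.k,
                    "fitness_function": params.fitness_function.value,
                    "final_mean_load": final.mean_load,
                    "final_min_load": final.min_load,
                    "final_mean_fitness": final.mean_fitness,
                    "clicks": click_count(result.trajectory),
                    "neutral_Ut": neutral_expectation(params.U, params.t),
                    "balance_Us": (
                        balance_expectation(params.U, params.s)
                        if params.s > 0 else np.nan
                    ),
                    "final_load_histogram": json.dumps(final.load_histogram),
                }
            )
            if keep_trajectories:
                tf = result.to_frame()
                tf.insert(0, "replicate", rep)
                tf.insert(0, "point", i)
                traj_frames.append(tf)
    columns = [
        "design", "point", "replicate", "moi", "V", "C", "U", "s", "g", "y",
        "t", "output_model", "k", "fitness_function", "final_mean_load",
        "final_min_load", "final_mean_fitness", "clicks", "neutral_Ut",
        "balance_Us", "final_load_histogram",
    ]
    summary = pd.DataFrame(summary_rows, columns=columns)
    trajectories = (
        pd.concat(traj_frames, ignore_index=True)
        if traj_frames
        else pd.DataFrame(columns=["point", "replicate", "generation",
                                   "mean_load", "min_load", "mean_fitness"])
    )
    return summary, trajectories


OptimumMOI = namedtuple("OptimumMOI", ["moi", "boundary"])


def locate_optimum_moi(table: pd.DataFrame) -> OptimumMOI:
    """Grid MOI minimizing the replicate-averaged final mean load.

    ``table`` is a tidy sweep summary with ``moi`` and
    ``final_mean_load`` columns.  Ties break toward the smaller MOI.
    ``boundary`` is True when the minimum sits at an end of the grid,
    meaning the optimum was not bracketed.
    """
    agg = (
        table.groupby("moi", sort=True)["final_mean_load"].mean().reset_index()
    )
    if len(agg) < 3:
        raise ParameterError(
            f"need at least 3 MOI grid points to locate an optimum, got {len(agg)}"
        )
    best = int(np.argmin(agg["final_mean_load"].to_numpy()))  # first min: smaller MOI
    return OptimumMOI(
        moi=float(agg["moi"].iloc[best]),
        boundary=best in (0, len(agg) - 1),
    )


# ---------------------------------------------------------------------------
# named presets for the published experimental designs
# ---------------------------------------------------------------------------

def _moi_grid_fixed_V(V: int, mois, extra=None) -> tuple:
    # C varied; keep C >= 10
    pts = []
    for moi in mois:
        C = max(10, round(V / moi))
        pts.append({"C": C, **(extra or {})})
    return tuple(pts)


def _moi_grid_fixed_C(C: int, mois, extra=None) -> tuple:
    # V varied; keep V >= 10
    pts = []
    for moi in mois:
        V = max(10, round(moi * C))
        pts.append({"V": V, **(extra or {})})
    return tuple(pts)


def _presets(n_reps: int, seed: int) -> dict:
    base = SimParams(V=1000, C=1000, U=1.0, s=0.2, g=8, y=1)
    V_grid = (100, 300, 1000, 3000, 10000)
    moi5 = (0.01, 0.1, 1.0, 10.0, 100.0)
    k_grid = (0.1, 1.0, 10.0)
    return {
        # mutation accumulation vs population size at fixed MOI 0.1
        "fig2a": ExperimentSpec(
            design="vary_V_fixed_MOI",
            grid=tuple({"V": V, "C": 10 * V} for V in V_grid),
            base_params=base, n_reps=n_reps, horizon=20, seed=seed,
        ),
        # phenotypic hiding: V fixed, C varied to change MOI
        "fig2b": ExperimentSpec(
            design="vary_C_fixed_V",
            grid=_moi_grid_fixed_V(1000, moi5),
            base_params=base, n_reps=n_reps, horizon=20, seed=seed,
        ),
        # drift vs hiding: C fixed, V varied to change MOI
        "fig2c": ExperimentSpec(
            design="vary_V_fixed_C",
            grid=_moi_grid_fixed_C(1000, DEFAULT_MOI_GRID),
            base_params=base, n_reps=n_reps, horizon=20, seed=seed,
        ),
        # segment sweep time series at V=1000, C=10000
        "fig3a": ExperimentSpec(
            design="segment_sweep",
            grid=tuple({"y": y} for y in (1, 2, 4, 8)),
            base_params=base.replace(C=10000), n_reps=n_reps, horizon=150,
            seed=seed,
        ),
        # segment sweep across V at fixed MOI 0.1
        "fig3b": ExperimentSpec(
            design="segment_sweep",
            grid=tuple({"V": V, "C": 10 * V, "y": y}
                       for y in (1, 2, 4, 8) for V in V_grid),
            base_params=base, n_reps=n_reps, horizon=150, seed=seed,
        ),
        # segmented vs unsegmented across MOI, V fixed
        "fig3c": ExperimentSpec(
            design="vary_C_fixed_V",
            grid=tuple(p | {"y": y} for y in (1, 2, 4, 8)
                       for p in _moi_grid_fixed_V(1000, DEFAULT_MOI_GRID[:7])),
            base_params=base, n_reps=n_reps, horizon=150, seed=seed,
        ),
        # segmented genome MOI sweep at fixed C: optimum near MOI 0.3
        "fig3d": ExperimentSpec(
            design="vary_V_fixed_C",
            grid=_moi_grid_fixed_C(1000, (0.03, 0.1, 0.3, 1.0, 3.0, 10.0),
                                   extra={"y": 8}),
            base_params=base, n_reps=n_reps, horizon=150, seed=seed,
        ),
        # stochastic heterogeneity across MOI at fixed C
        "fig4a": ExperimentSpec(
            design="heterogeneity_sweep",
            grid=tuple(
                p | ({"output_model": "stochastic", "k": k} if k is not None else {})
                for k in (None, *k_grid)
                for p in _moi_grid_fixed_C(1000, DEFAULT_MOI_GRID[:7])
            ),
            base_params=base, n_reps=n_reps, horizon=20, seed=seed,
        ),
        # effective-size collapse: V x k grid at MOI 0.1
        "fig4b": ExperimentSpec(
            design="heterogeneity_sweep",
            grid=tuple(
                {"V": V, "C": 10 * V}
                | ({"output_model": "stochastic", "k": k} if k is not None else {})
                for k in (None, *k_grid)
                for V in V_grid
            ),
            base_params=base, n_reps=n_reps, horizon=20, seed=seed,
        ),
        # input-dependent output vs base across MOI at fixed C
        "fig5": ExperimentSpec(
            design="input_dependence",
            grid=tuple(p | {"output_model": om}
                       for om in ("base", "input_dependent")
                       for p in _moi_grid_fixed_C(1000, DEFAULT_MOI_GRID[:7])),
            base_params=base, n_reps=n_reps, horizon=20, seed=seed,
        ),
        # dominance forms across MOI, V fixed
        "fig6a": ExperimentSpec(
            design="fitness_functions",
            grid=tuple(p | {"fitness_function": ff}
                       for ff in ("mean", "max_fit", "min_fit")
                       for p in _moi_grid_fixed_V(1000, DEFAULT_MOI_GRID[:7])),
            base_params=base, n_reps=n_reps, horizon=20, seed=seed,
        ),
        # dominance forms across MOI, C fixed
        "fig6b": ExperimentSpec(
            design="fitness_functions",
            grid=tuple(p | {"fitness_function": ff}
                       for ff in ("mean", "max_fit", "min_fit")
                       for p in _moi_grid_fixed_C(1000, DEFAULT_MOI_GRID[:7])),
            base_params=base, n_reps=n_reps, horizon=20, seed=seed,
        ),
        # per-virion load distributions at V=1668, C=1000
        "fig6c": ExperimentSpec(
            design="fitness_functions",
            grid=tuple({"V": 1668, "fitness_function": ff}
                       for ff in ("mean", "max_fit", "min_fit")),
            base_params=base, n_reps=max(1, n_reps // 4), horizon=20, seed=seed,
        ),
    }


FIGURE_PRESETS = tuple(_presets(20, 0).keys())


def figure_preset(name: str, n_reps: int = 20, seed: int = 0) -> ExperimentSpec:
    """Named experiment preset (``fig2a`` .. ``fig6c``)."""
    presets = _presets(n_reps, seed)
    if name not in presets:
        raise ParameterError(
            f"unknown preset {name!r}; choose from {sorted(presets)}"
        )
    return presets[name]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_outputs(out_dir, spec: ExperimentSpec, summary: pd.DataFrame,
                  trajectories: pd.DataFrame) -> None:
    """Write ``summary.csv``, ``trajectories.csv`` and ``params.json``.

    Re-running the same spec reproduces the CSVs bit-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out / "summary.csv", index=False)
    trajectories.to_csv(out / "trajectories.csv", index=False)
    meta = spec.to_dict()
    meta["code_version"] = __version__
    (out / "params.json").write_text(json.dumps(meta, indent=2) + "\n")


def load_spec(path) -> ExperimentSpec:
    """Load an ExperimentSpec from a YAML or JSON config file."""
    import yaml

    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    return ExperimentSpec.from_dict(data)
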