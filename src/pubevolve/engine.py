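"""Seeded run loop, trajectory recording, ensembles and experiment presets.

A :class:`Trajectory` is a per-run time series of population summaries (mean
power, mean effort, mean replication rate, mean false positive rate, the
cumulative false discovery rate of the literature, and literature size),
recorded every ``record_every`` steps. :func:`run_simulation` executes one
seeded run; :func:`run_ensemble` runs several with deterministically derived
seeds and also returns the pointwise mean trajectory, mirroring the
convention of averaging results over many runs.

Two engines are available: the default compiled kernel (fast, used for
million-step horizons) and the pure-Python reference engine built from the
object-level stage functions (slow; supports event logs and is the ground
truth the kernel is checked against). Each engine is deterministic given
(params, seed); the kernel uses numba's Mersenne Twister, the reference
engine a ``numpy.random.Generator`` (PCG64).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import _kernel
from .model_core import (
    EFFORT_HIGH,
    EFFORT_LOW,
    LabState,
    ModelParams,
    OrderMode,
    ParentSelection,
    false_positive_rate,
)
from .science_stage import Literature, step_science
from .evolution_stage import step_evolution

__all__ = [
    "Trajectory",
    "ExperimentSpec",
    "run_simulation",
    "run_ensemble",
    "peak_statistics",
    "preset_coevolution",
    "preset_effort_evolution",
    "preset_power_evolution",
    "preset_effort_competition",
    "list_presets",
]

METRIC_COLUMNS = [
    "step",
    "mean_power",
    "mean_effort",
    "mean_replication_rate",
    "mean_alpha",
    "fdr",
    "literature_size",
    "mean_payoff",
]


@dataclass
class Trajectory:
    """Recorded time series of one simulation run plus its provenance."""

    data: pd.DataFrame
    seed: int
    params_digest: str
    engine: str = "kernel"

    def final(self) -> pd.Series:
        """The last recorded row."""
        return self.data.iloc[-1]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = -1,
                 params_digest: str = "", engine: str = "") -> "Trajectory":
        return cls(pd.read_csv(path), seed=seed, params_digest=params_digest,
                   engine=engine)


def _run_kernel(params: ModelParams, seed: int, record_every: int,
                check_every: int) -> pd.DataFrame:
    order = (_kernel.DEATH_FIRST if params.order_mode == OrderMode.death_first
             else _kernel.REPRODUCE_FIRST)
    psel = {
        ParentSelection.tournament: _kernel.TOURNAMENT,
        ParentSelection.payoff_proportional: _kernel.PROPORTIONAL,
        ParentSelection.uniform: _kernel.UNIFORM,
    }[params.parent_selection]
    init_effort = np.asarray(params.initial_efforts(), dtype=np.float64)
    out = _kernel.simulate_kernel(
        seed,
        params.n_steps,
        params.n_labs,
        params.base_rate,
        params.e_min,
        params.e_max,
        params.w_init,
        params.r_init,
        init_effort,
        params.evolve_power,
        params.evolve_effort,
        params.evolve_replication,
        params.mu,
        params.mutation_scale_power,
        params.mutation_scale_effort,
        params.mutation_scale_replication,
        params.tournament_size,
        params.payoff_novel_pos,
        params.payoff_novel_neg,
        params.payoff_replication,
        params.payoff_original_confirmed,
        params.payoff_original_failed,
        params.publish_prob_novel_neg,
        params.publish_prob_replication,
        params.eta,
        params.bug_mode,
        order,
        psel,
        record_every,
        check_every,
    )
    (steps, w, e, r, a, fdr, lit, pay, ok) = out
    if ok != 0:
        raise RuntimeError(f"invariant violation detected at step {ok}")
    df = pd.DataFrame(
        {
            "step": steps,
            "mean_power": w,
            "mean_effort": e,
            "mean_replication_rate": r,
            "mean_alpha": a,
            "fdr": fdr,
            "literature_size": lit,
            "mean_payoff": pay,
        }
    )
    for col in ("mean_power", "mean_effort", "mean_replication_rate",
                "mean_alpha", "mean_payoff"):
        if not np.all(np.isfinite(df[col].to_numpy())):
            raise RuntimeError(f"non-finite metric in column {col}")
    return df


def _initial_population(params: ModelParams) -> list[LabState]:
    efforts = params.initial_efforts()
    return [
        LabState(lab_id=i, power=params.w_init, effort=efforts[i],
                 replication_rate=params.r_init)
        for i in range(params.n_labs)
    ]


def _population_row(step: int, population: list[LabState],
                    literature: Literature) -> dict[str, Any]:
    n = len(population)
    return {
        "step": step,
        "mean_power": sum(l.power for l in population) / n,
        "mean_effort": sum(l.effort for l in population) / n,
        "mean_replication_rate": sum(l.replication_rate for l in population) / n,
        "mean_alpha": sum(
            false_positive_rate(l.power, l.effort) for l in population
        ) / n,
        "fdr": literature.fdr,
        "literature_size": len(literature),
        "mean_payoff": sum(l.payoff for l in population) / n,
    }


def _run_reference(params: ModelParams, seed: int, record_every: int,
                   event_log: Optional[list[dict]] = None) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    population = _initial_population(params)
    literature = Literature()
    next_id = params.n_labs
    rows = [_population_row(0, population, literature)]
    for step in range(1, params.n_steps + 1):
        step_science(population, literature, params, rng, step=step,
                     event_log=event_log)
        population = step_evolution(population, params, rng, next_lab_id=next_id)
        next_id += 1
        assert len(population) == params.n_labs
        if step % record_every == 0 or step == params.n_steps:
            rows.append(_population_row(step, population, literature))
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def run_simulation(
    params: ModelParams,
    seed: Optional[int] = None,
    record_every: int = 1000,
    engine: str = "kernel",
    check_every: int = 10_000,
    event_log: Optional[list[dict]] = None,
) -> Trajectory:
    """Execute one seeded run of ``n_steps`` (science stage then evolution
    stage) and return its :class:`Trajectory`.

    The initial state is always recorded as the step-0 row; afterwards
    metrics are recorded every ``record_every`` steps and at the final step.
    Identical (params, seed, engine) give bit-identical trajectories.
    ``event_log``, if supplied, collects one record per publication and
    forces the reference engine.
    """
    if seed is None:
        seed = params.seed
    seed = int(seed) % (2**31)
    if record_every <= 0:
        raise ValueError("record_every must be positive")
    if event_log is not None:
        engine = "reference"
    if engine == "kernel":
        df = _run_kernel(params, seed, record_every, check_every)
    elif engine == "reference":
        df = _run_reference(params, seed, record_every, event_log=event_log)
    else:
        raise ValueError(f"unknown engine {engine!r} (use 'kernel' or 'reference')")
    return Trajectory(df, seed=seed, params_digest=params.digest(), engine=engine)


@dataclass
class ExperimentSpec:
    """A named, resolvable experiment: parameters, ensemble size, cadence."""

    name: str
    params: ModelParams
    n_runs: int = 50
    record_every: int = 1000
    description: str = ""

    def resolve(self) -> ModelParams:
        """Concrete :class:`ModelParams` for one run of this experiment."""
        return self.params.model_copy(update={"n_runs": self.n_runs})


@dataclass
class EnsembleResult:
    """Per-run trajectories plus their pointwise mean."""

    runs: list[Trajectory]
    mean: pd.DataFrame
    spec_name: str = ""

    def __iter__(self):
        return iter(self.runs)


def mean_trajectory(runs: list[Trajectory]) -> pd.DataFrame:
    """Pointwise mean of per-run metrics (NaN-aware for the FDR column)."""
    stacked = pd.concat([t.data for t in runs])
    return stacked.groupby("step", as_index=False).mean().sort_values(
        "step", ignore_index=True
    )


def run_ensemble(
    spec: ExperimentSpec,
    base_seed: Optional[int] = None,
    engine: str = "kernel",
    out_dir: Optional[str | Path] = None,
) -> EnsembleResult:
    """Run ``spec.n_runs`` independent simulations with seeds
    ``base_seed + run_index`` and return all runs plus the pointwise mean.

    With ``out_dir`` set, per-run CSVs (``runs/run_###.csv``), the mean
    trajectory (``mean.csv``) and a metadata sidecar are written as the runs
    complete, so partial results survive an aborted ensemble.
    """
    params = spec.resolve()
    if base_seed is None:
        base_seed = params.seed
    runs: list[Trajectory] = []
    run_dir = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        run_dir = out_dir / "runs"
        run_dir.mkdir(parents=True, exist_ok=True)
        write_metadata(out_dir / "metadata.json", params, base_seed,
                       engine=engine, extra={"experiment": spec.name,
                                             "n_runs": spec.n_runs,
                                             "record_every": spec.record_every})
    for k in range(spec.n_runs):
        traj = run_simulation(params, seed=(int(base_seed) + k) % (2**31),
                              record_every=spec.record_every, engine=engine)
        runs.append(traj)
        if run_dir is not None:
            traj.to_csv(run_dir / f"run_{k:03d}.csv")
    mean = mean_trajectory(runs)
    if out_dir is not None:
        mean.to_csv(out_dir / "mean.csv", index=False, float_format="%.10g")
    return EnsembleResult(runs=runs, mean=mean, spec_name=spec.name)


def peak_statistics(trajectory: pd.DataFrame | Trajectory,
                    column: str) -> tuple[float, int]:
    """Maximum of ``column`` and the first recorded step attaining it."""
    df = trajectory.data if isinstance(trajectory, Trajectory) else trajectory
    if column not in df.columns:
        valid = [c for c in df.columns if c != "step"]
        raise ValueError(f"unknown field {column!r}; valid fields: {valid}")
    values = df[column].to_numpy()
    steps = df["step"].to_numpy()
    i = int(np.nanargmax(values))
    return float(values[i]), int(steps[i])


def write_metadata(path: str | Path, params: ModelParams, seed: int,
                   engine: str = "kernel",
                   extra: Optional[dict[str, Any]] = None) -> None:
    """JSON sidecar sufficient to reproduce a run exactly."""
    from . import __version__

    meta = {
        "params": params.to_dict(),
        "params_digest": params.digest(),
        "seed": int(seed),
        "engine": engine,
        "rng": ("numba internal MT19937" if engine == "kernel"
                else "numpy PCG64 (default_rng)"),
        "version": __version__,
    }
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset_coevolution(extend: float = 1.0, **overrides: Any) -> ExperimentSpec:
    """Coevolution of effort and replication rate with power fixed at 0.8.

    Effort starts high (75) and replication rate low (0.01); both mutate
    while power stays fixed. Corrected hypothesis selection by default; set
    ``bug_mode=True`` to reproduce the original implementation's erroneous
    neutral-drift variant. ``extend`` multiplies the million-step horizon.
    """
    params = ModelParams(
        evolve_power=False,
        evolve_effort=True,
        evolve_replication=True,
        w_init=0.8,
        e_init=EFFORT_HIGH,
        r_init=0.01,
        bug_mode=False,
        n_steps=int(1_000_000 * extend),
        n_runs=50,
    )
    params = params.model_copy(update=overrides)
    return ExperimentSpec(
        name="coevolution",
        params=ModelParams(**params.to_dict()),
        n_runs=params.n_runs,
        description="effort + replication rate evolving, power fixed at 0.8",
    )


def preset_effort_evolution(**overrides: Any) -> ExperimentSpec:
    """Evolution of effort alone (replication rate fixed at 0).

    Settings not pinned by the constants above are best-effort; verify
    against the original model publication before claiming figure-level
    reproduction.
    """
    params = ModelParams(
        evolve_power=False,
        evolve_effort=True,
        evolve_replication=False,
        w_init=0.8,
        e_init=EFFORT_HIGH,
        r_init=0.0,
        n_steps=1_000_000,
        n_runs=50,
    ).model_copy(update=overrides)
    return ExperimentSpec(
        name="effort_evolution",
        params=ModelParams(**params.to_dict()),
        n_runs=params.n_runs,
        description="effort evolving alone, no replication",
    )


def preset_power_evolution(**overrides: Any) -> ExperimentSpec:
    """Joint evolution of power and effort (replication rate fixed at 0).

    Best-effort configuration; verify against the original model
    publication before claiming figure-level reproduction.
    """
    params = ModelParams(
        evolve_power=True,
        evolve_effort=True,
        evolve_replication=False,
        w_init=0.8,
        e_init=EFFORT_HIGH,
        r_init=0.0,
        n_steps=1_000_000,
        n_runs=50,
    ).model_copy(update=overrides)
    return ExperimentSpec(
        name="power_evolution",
        params=ModelParams(**params.to_dict()),
        n_runs=params.n_runs,
        description="power and effort evolving, no replication",
    )


def preset_effort_competition(**overrides: Any) -> ExperimentSpec:
    """Competition between fixed high-effort (75) and low-effort (15) labs.

    Half the population starts at e_H = 75, half at e_L = 15; no mutation,
    so the outcome is pure selection between the two strategies.
    """
    params = ModelParams(
        evolve_power=False,
        evolve_effort=False,
        evolve_replication=False,
        w_init=0.8,
        e_init=EFFORT_HIGH,
        e_init_low=EFFORT_LOW,
        frac_low=0.5,
        r_init=0.01,
        n_steps=1_000_000,
        n_runs=50,
    ).model_copy(update=overrides)
    return ExperimentSpec(
        name="effort_competition",
        params=ModelParams(**params.to_dict()),
        n_runs=params.n_runs,
        description="high-effort (75) vs low-effort (15) labs, no mutation",
    )


_PRESETS = {
    "coevolution": preset_coevolution,
    "effort_evolution": preset_effort_evolution,
    "power_evolution": preset_power_evolution,
    "effort_competition": preset_effort_competition,
}


def list_presets() -> dict[str, str]:
    """Mapping of preset name to one-line description."""
    return {name: fn().description for name, fn in _PRESETS.items()}


def get_preset(name: str, **overrides: Any) -> ExperimentSpec:
    if name not in _PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        )
    return _PRESETS[name](**overrides)
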