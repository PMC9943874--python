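"""Core trait mathematics and shared state types.

The model describes a population of laboratories characterised by three
heritable traits:

* **power** ``W`` — probability of a positive result when the investigated
  hypothesis is true,
* **effort** ``e`` — costly methodological rigour; it lowers the false
  positive rate but also lowers productivity (the probability of
  investigating a hypothesis in a given step),
* **replication rate** ``r`` — probability of re-testing an already
  published finding instead of formulating a novel hypothesis.

This module holds the trait-level functions (false positive rate,
productivity, bounded mutation), the per-laboratory state record, and the
full parameter object shared by every simulation stage.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "EFFORT_HIGH",
    "EFFORT_LOW",
    "LabState",
    "ModelParams",
    "OrderMode",
    "ParentSelection",
    "false_positive_rate",
    "productivity",
    "mutate_trait",
]

#: Canonical "high" and "low" effort values used by the competition presets.
EFFORT_HIGH = 75.0
EFFORT_LOW = 15.0


def false_positive_rate(power: float, effort: float) -> float:
    """Probability of a positive result for a *false* hypothesis.

    .. math:: \\alpha(W, e) = \\frac{W}{1 + (1 - W)\\,e}

    The rate equals ``power`` at zero effort and decreases strictly with
    effort whenever ``0 < power < 1``; perfect power (``W = 1``) pins
    ``alpha`` to 1 regardless of effort.

    Parameters
    ----------
    power : float
        Statistical power ``W`` in ``[0, 1]``.
    effort : float
        Methodological effort ``e >= 0``.

    Returns
    -------
    float
        ``alpha`` in ``[0, power]``.
    """
    if not 0.0 <= power <= 1.0:
        raise ValueError(f"power must be in [0, 1], got {power}")
    if effort < 0.0:
        raise ValueError(f"effort must be non-negative, got {effort}")
    return power / (1.0 + (1.0 - power) * effort)


_PRODUCTIVITY_WARNED: set[tuple[float, float]] = set()


def productivity(effort: float, eta: float = 0.2) -> float:
    """Probability that a lab investigates a hypothesis in one step.

    Default form ``h(e) = 1 - eta * log10(e)``, clipped to ``[0, 1]``:
    effort buys rigour at the price of throughput. ``h`` is monotonically
    non-increasing in effort, with the maximum at the lower effort bound.

    A parameter combination that would fall outside ``[0, 1]`` before
    clipping is reported once per (effort, eta) pair via ``warnings``.
    """
    if effort <= 0.0:
        raise ValueError(f"effort must be positive, got {effort}")
    h = 1.0 - eta * math.log10(effort)
    if not 0.0 <= h <= 1.0:
        key = (effort, eta)
        if key not in _PRODUCTIVITY_WARNED:
            _PRODUCTIVITY_WARNED.add(key)
            warnings.warn(
                f"productivity h({effort}, eta={eta}) = {h:.4g} outside [0, 1]; "
                "clipping",
                RuntimeWarning,
                stacklevel=2,
            )
        h = min(1.0, max(0.0, h))
    return h


def mutate_trait(
    value: float,
    lower: float,
    upper: float,
    mu: float,
    scale: float,
    rng: Any,
) -> float:
    """Bounded additive mutation of a single trait value.

    With probability ``1 - mu`` the value is returned unchanged. With
    probability ``mu`` a zero-mean increment drawn uniformly from
    ``[-scale, +scale]`` is added and the result is *truncated* (not
    reflected) to ``[lower, upper]``. Truncation after the addition means
    increments are asymmetrically censored near a bound — the source of the
    spurious upward drift of a neutral trait sitting just above its lower
    bound.

    ``rng`` needs ``random()`` and ``uniform(a, b)`` methods
    (``numpy.random.Generator`` qualifies, as do scripted test doubles).
    """
    if lower > upper:
        raise ValueError(f"lower bound {lower} exceeds upper bound {upper}")
    if not lower <= value <= upper:
        raise ValueError(f"value {value} outside [{lower}, {upper}]")
    if mu > 0.0 and rng.random() < mu:
        value = value + rng.uniform(-scale, scale)
        value = min(upper, max(lower, value))
    return value


@dataclass
class LabState:
    """One laboratory: heritable traits plus accumulated bookkeeping.

    ``payoff`` and ``n_publications`` start at 0; ``age`` increases by one
    per simulation step while the lab is alive.
    """

    lab_id: int
    power: float
    effort: float
    replication_rate: float
    payoff: float = 0.0
    age: int = 0
    n_publications: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.power <= 1.0:
            raise ValueError(f"power {self.power} outside [0, 1]")
        if not 0.0 <= self.replication_rate <= 1.0:
            raise ValueError(
                f"replication_rate {self.replication_rate} outside [0, 1]"
            )


class OrderMode(str, Enum):
    """Ordering of death and reproduction within one evolution step."""

    death_first = "death_first"
    reproduce_first = "reproduce_first"


class ParentSelection(str, Enum):
    """How the reproducing laboratory is chosen."""

    tournament = "tournament"
    payoff_proportional = "payoff_proportional"
    uniform = "uniform"


class ModelParams(BaseModel):
    """Every constant and mode switch of the model.

    All fields have defaults; unknown keys raise a validation error so that
    typos in experiment configs fail loudly. The object round-trips
    losslessly through YAML and JSON.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # population / hypothesis space
    n_labs: int = Field(100, gt=0, description="population size N")
    base_rate: float = Field(0.1, ge=0.0, le=1.0,
                             description="prior probability b that a novel hypothesis is true")

    # trait bounds and initial values
    e_min: float = Field(1.0, ge=0.0)
    e_max: float = Field(100.0)
    w_init: float = Field(0.8, ge=0.0, le=1.0)
    e_init: float = Field(EFFORT_HIGH)
    r_init: float = Field(0.01, ge=0.0, le=1.0)
    # optional heterogeneous start: a fraction of labs begin at e_init_low
    # (high-vs-low effort competition configs)
    e_init_low: float | None = Field(None)
    frac_low: float = Field(0.0, ge=0.0, le=1.0)

    # evolution switches and mutation
    evolve_power: bool = False
    evolve_effort: bool = True
    evolve_replication: bool = True
    mu: float = Field(0.01, ge=0.0, le=1.0,
                      description="per-trait mutation probability at birth")
    mutation_scale_power: float = Field(0.01, gt=0.0)
    mutation_scale_effort: float = Field(2.0, gt=0.0)
    mutation_scale_replication: float = Field(0.025, gt=0.0)
    tournament_size: int = Field(20, gt=0, description="tournament size d")

    # pay-offs and publication probabilities
    payoff_novel_pos: float = 1.0
    payoff_novel_neg: float = 0.0
    payoff_replication: float = 0.5
    payoff_original_confirmed: float = 0.1
    payoff_original_failed: float = -100.0
    publish_prob_novel_neg: float = Field(0.0, ge=0.0, le=1.0)
    publish_prob_replication: float = Field(1.0, ge=0.0, le=1.0)

    # productivity
    eta: float = Field(0.2, ge=0.0)

    # mode switches
    bug_mode: bool = Field(
        False,
        description="reproduce the original implementation's error of using "
                    "the initial replication rate for every lab",
    )
    order_mode: OrderMode = OrderMode.death_first
    parent_selection: ParentSelection = ParentSelection.tournament

    # run control
    n_steps: int = Field(1_000_000, ge=0)
    n_runs: int = Field(50, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_consistency(self) -> "ModelParams":
        if self.e_min > self.e_max:
            raise ValueError(f"e_min {self.e_min} > e_max {self.e_max}")
        if not self.e_min <= self.e_init <= self.e_max:
            raise ValueError(
                f"e_init {self.e_init} outside [{self.e_min}, {self.e_max}]"
            )
        if self.e_init_low is not None and not (
            self.e_min <= self.e_init_low <= self.e_max
        ):
            raise ValueError(
                f"e_init_low {self.e_init_low} outside [{self.e_min}, {self.e_max}]"
            )
        if self.tournament_size > self.n_labs:
            raise ValueError(
                f"tournament_size {self.tournament_size} exceeds n_labs {self.n_labs}"
            )
        return self

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = self.model_dump()
        d["order_mode"] = self.order_mode.value
        d["parent_selection"] = self.parent_selection.value
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelParams":
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        """Load from a YAML or JSON config file (by extension, YAML default)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable content hash identifying this parameter set."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def initial_efforts(self) -> list[float]:
        """Per-lab initial efforts, honouring a high/low competition split.

        The first ``floor(frac_low * n_labs)`` labs start at ``e_init_low``,
        the rest at ``e_init``.
        """
        n_low = int(self.frac_low * self.n_labs) if self.e_init_low is not None else 0
        low = self.e_init_low if self.e_init_low is not None else self.e_init
        return [low] * n_low + [self.e_init] * (self.n_labs - n_low)
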