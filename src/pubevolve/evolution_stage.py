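"""The birth–death selection step.

Once per time step a laboratory dies and another reproduces, holding the
population size constant. Death removes the oldest lab from a random
tournament sample; reproduction copies the traits of the highest-pay-off lab
from another sample (or, in the pay-off-proportional variant, a lab drawn
with probability proportional to its shifted pay-off), mutating each
evolving trait. Two orderings are supported: removing the dying lab before
choosing a parent (the written model description) and choosing the parent
first, so that a lab may reproduce immediately before being eliminated (the
original implementation's behaviour).
"""

from __future__ import annotations

from typing import Any, Optional, Sequence

from .model_core import LabState, ModelParams, OrderMode, ParentSelection, mutate_trait

__all__ = ["select_dying", "select_parent", "reproduce", "step_evolution"]


def _tournament(
    population: Sequence[LabState], d: int, key, rng: Any
) -> LabState:
    """Best-of-d tournament: sample d distinct labs, return the one maximising
    ``key``; ties broken uniformly at random."""
    if d > len(population):
        raise ValueError(
            f"tournament size {d} exceeds eligible population {len(population)}"
        )
    idx = rng.choice(len(population), size=d, replace=False)
    best = max(key(population[i]) for i in idx)
    winners = [i for i in idx if key(population[i]) == best]
    pick = winners[int(rng.integers(len(winners)))] if len(winners) > 1 else winners[0]
    return population[pick]


def select_dying(population: Sequence[LabState], d: int, rng: Any) -> int:
    """Identifier of the dying lab: the oldest of ``d`` sampled labs."""
    return _tournament(population, d, lambda lab: lab.age, rng).lab_id


def select_parent(
    population: Sequence[LabState],
    params: ModelParams,
    rng: Any,
    excluded: Optional[int] = None,
) -> int:
    """Identifier of the reproducing lab.

    Tournament mode picks the highest pay-off of ``d`` sampled labs.
    Proportional mode picks lab ``i`` with probability proportional to its
    pay-off after shifting all pay-offs to be non-negative (origin-lab
    penalties can drive pay-offs negative); if every shifted pay-off is zero
    the draw falls back to uniform. Uniform mode ignores pay-offs entirely
    (selection switched off). ``excluded`` removes the already-dead lab in
    death-first ordering.
    """
    eligible = [lab for lab in population if lab.lab_id != excluded]
    if not eligible:
        raise ValueError("no eligible parent laboratories")
    mode = params.parent_selection
    if mode == ParentSelection.tournament:
        d = min(params.tournament_size, len(eligible))
        return _tournament(eligible, d, lambda lab: lab.payoff, rng).lab_id
    if mode == ParentSelection.payoff_proportional:
        shift = min(0.0, min(lab.payoff for lab in eligible))
        weights = [lab.payoff - shift for lab in eligible]
        total = sum(weights)
        if total <= 0.0:
            return eligible[int(rng.integers(len(eligible)))].lab_id
        u = rng.random() * total
        acc = 0.0
        for lab, w in zip(eligible, weights):
            acc += w
            if u < acc:
                return lab.lab_id
        return eligible[-1].lab_id
    # uniform
    return eligible[int(rng.integers(len(eligible)))].lab_id


def reproduce(
    parent: LabState, params: ModelParams, rng: Any, lab_id: Optional[int] = None
) -> LabState:
    """Create a child lab from a parent.

    Traits are copied; each trait flagged ``evolve_*`` passes through
    :func:`mutate_trait` with its own scale and bounds. The child starts
    with zero pay-off, age and publications; the parent is unchanged.
    """
    power = parent.power
    effort = parent.effort
    rep = parent.replication_rate
    if params.evolve_power:
        power = mutate_trait(power, 0.0, 1.0, params.mu,
                             params.mutation_scale_power, rng)
    if params.evolve_effort:
        effort = mutate_trait(effort, params.e_min, params.e_max, params.mu,
                              params.mutation_scale_effort, rng)
    if params.evolve_replication:
        rep = mutate_trait(rep, 0.0, 1.0, params.mu,
                           params.mutation_scale_replication, rng)
    return LabState(
        lab_id=parent.lab_id if lab_id is None else lab_id,
        power=power,
        effort=effort,
        replication_rate=rep,
    )


def step_evolution(
    population: list[LabState],
    params: ModelParams,
    rng: Any,
    next_lab_id: Optional[int] = None,
) -> list[LabState]:
    """One birth–death event; returns the new population of identical size.

    ``death_first``: the dying lab is removed before the parent is chosen
    among the survivors. ``reproduce_first``: the parent is chosen among all
    N labs (so a lab may reproduce immediately before dying), then the dying
    lab is picked among the original N — never the newborn.
    """
    if next_lab_id is None:
        next_lab_id = max(lab.lab_id for lab in population) + 1
    d = params.tournament_size
    if params.order_mode == OrderMode.death_first:
        dying = select_dying(population, d, rng)
        survivors = [lab for lab in population if lab.lab_id != dying]
        parent_id = select_parent(survivors, params, rng)
        parent = next(lab for lab in survivors if lab.lab_id == parent_id)
    else:
        parent_id = select_parent(population, params, rng)
        parent = next(lab for lab in population if lab.lab_id == parent_id)
        dying = select_dying(population, d, rng)
    child = reproduce(parent, params, rng, lab_id=next_lab_id)
    return [lab for lab in population if lab.lab_id != dying] + [child]
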