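"""Tiny deterministic populations and scripted RNGs for unit testing.

Every fixture is a fully constructed population plus a parameter set; tests
across all modules build on these instead of ad hoc setups. The
:class:`ScriptedRNG` replays a documented stream of numbers so that
single-step traces can be checked against hand-derived event logs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .model_core import LabState, ModelParams

__all__ = ["ScriptedRNG", "make_fixture", "FIXTURE_NAMES"]


class ScriptedRNG:
    """Replays a fixed stream of floats.

    ``random()`` pops the next value; ``uniform(a, b)`` maps the next value
    from [0, 1) onto [a, b); ``integers(n)`` maps it onto {0..n-1};
    ``choice(n, size=d, replace=False)`` consumes one value per pick using a
    partial Fisher–Yates walk. Exhausting the script raises, so a test knows
    exactly how many draws an operation consumed.
    """

    def __init__(self, stream: Sequence[float]):
        self._stream = list(stream)
        self._pos = 0

    def _next(self) -> float:
        if self._pos >= len(self._stream):
            raise RuntimeError("scripted RNG stream exhausted")
        v = self._stream[self._pos]
        self._pos += 1
        return v

    @property
    def consumed(self) -> int:
        return self._pos

    def random(self) -> float:
        return self._next()

    def uniform(self, a: float, b: float) -> float:
        return a + (b - a) * self._next()

    def integers(self, n: int) -> int:
        return min(int(self._next() * n), n - 1)

    def choice(self, n: int, size: int = 1, replace: bool = False):
        assert not replace
        pool = list(range(n))
        picks = []
        for k in range(size):
            j = min(int(self._next() * (n - k)), n - k - 1)
            picks.append(pool.pop(j))
        return np.array(picks)


def _fixture_two_lab_tournament():
    """Two labs with pay-offs {5, 3} and ages {10, 2}: tournament arithmetic."""
    params = ModelParams(n_labs=2, tournament_size=2, evolve_power=False,
                         evolve_effort=False, evolve_replication=False,
                         n_steps=10, n_runs=1)
    population = [
        LabState(lab_id=0, power=0.8, effort=75.0, replication_rate=0.01,
                 payoff=5.0, age=10),
        LabState(lab_id=1, power=0.8, effort=75.0, replication_rate=0.01,
                 payoff=3.0, age=2),
    ]
    return population, params


def _fixture_three_lab():
    """Three heterogeneous labs for hand-traced science steps."""
    params = ModelParams(n_labs=3, tournament_size=3, n_steps=10, n_runs=1,
                         base_rate=0.1)
    population = [
        LabState(lab_id=0, power=0.8, effort=75.0, replication_rate=0.0),
        LabState(lab_id=1, power=0.8, effort=15.0, replication_rate=0.5),
        LabState(lab_id=2, power=1.0, effort=1.0, replication_rate=1.0),
    ]
    return population, params


def _fixture_static_fdr():
    """Homogeneous population driving the closed-form FDR check.

    W=0.8, e=75, r=0, b=0.1, evolution off: the cumulative FDR converges to
    (1-b)*alpha / ((1-b)*alpha + b*W) = 0.36.
    """
    params = ModelParams(n_labs=100, w_init=0.8, e_init=75.0, r_init=0.0,
                         base_rate=0.1, evolve_power=False,
                         evolve_effort=False, evolve_replication=False,
                         n_steps=100_000, n_runs=1)
    population = [
        LabState(lab_id=i, power=0.8, effort=75.0, replication_rate=0.0)
        for i in range(params.n_labs)
    ]
    return population, params


def _fixture_two_lab_bugmode():
    """Labs with replication rates 0.0 and 0.9 under bug mode.

    In bug mode both replicate at the initial rate, so realized replication
    frequency is independent of the trait.
    """
    params = ModelParams(n_labs=2, tournament_size=2, bug_mode=True,
                         r_init=0.01, evolve_power=False, evolve_effort=False,
                         evolve_replication=False, n_steps=10, n_runs=1)
    population = [
        LabState(lab_id=0, power=0.8, effort=15.0, replication_rate=0.0),
        LabState(lab_id=1, power=0.8, effort=15.0, replication_rate=0.9),
    ]
    return population, params


_FIXTURES = {
    "two-lab-tournament": _fixture_two_lab_tournament,
    "three-lab": _fixture_three_lab,
    "static-fdr": _fixture_static_fdr,
    "two-lab-bugmode": _fixture_two_lab_bugmode,
}

FIXTURE_NAMES = sorted(_FIXTURES)


def make_fixture(name: str):
    """Return (population, params) for a named deterministic fixture."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return _FIXTURES[name]()
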