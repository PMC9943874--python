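"""One time step of science for every living laboratory.

Each step a lab may investigate a hypothesis (with probability given by its
productivity), choose between a novel hypothesis and the replication of a
published finding (according to its replication rate — or, in bug mode, the
population's *initial* replication rate), run the experiment, and attempt to
publish. Pay-offs are assigned on publication: novel positives pay most,
replications pay less, and the originator of a replicated finding is
rewarded when confirmed and heavily penalised when contradicted.

This module is the object-level reference implementation; the compiled
kernel in :mod:`pubevolve._kernel` mirrors its semantics for long runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Optional, Union

from .model_core import LabState, ModelParams, false_positive_rate, productivity

__all__ = [
    "Finding",
    "Literature",
    "NovelHypothesis",
    "ReplicationTarget",
    "ExperimentResult",
    "decide_investigates",
    "choose_hypothesis",
    "run_experiment_outcome",
    "publish_and_pay",
    "step_science",
]


@dataclass(frozen=True)
class Finding:
    """One published result."""

    finding_id: int
    hypothesis_true: bool
    positive: bool
    is_replication: bool
    origin_lab: int  # lab that first published the hypothesis
    author_lab: int
    step: int


class Literature:
    """The growing set of published findings.

    Keeps the ordered collection, an index of replication-eligible findings
    (published *novel* findings), and running counts of published positives
    and false positives from which the cumulative false discovery rate is
    derived.
    """

    def __init__(self) -> None:
        self.findings: list[Finding] = []
        self.eligible: list[Finding] = []
        self._eligible_ids: set[int] = set()
        self.n_published_positive = 0
        self.n_false_positive = 0
        self._next_id = 0

    def __len__(self) -> int:
        return len(self.findings)

    def add(self, *, hypothesis_true: bool, positive: bool, is_replication: bool,
            origin_lab: int, author_lab: int, step: int) -> Finding:
        f = Finding(
            finding_id=self._next_id,
            hypothesis_true=hypothesis_true,
            positive=positive,
            is_replication=is_replication,
            origin_lab=origin_lab,
            author_lab=author_lab,
            step=step,
        )
        self._next_id += 1
        self.findings.append(f)
        if not is_replication:
            self.eligible.append(f)
            self._eligible_ids.add(f.finding_id)
        if positive:
            self.n_published_positive += 1
            if not hypothesis_true:
                self.n_false_positive += 1
        return f

    @property
    def fdr(self) -> float:
        """Cumulative fraction of published positives that are false (NaN if none)."""
        if self.n_published_positive == 0:
            return float("nan")
        return self.n_false_positive / self.n_published_positive

    def recount(self) -> tuple[int, int]:
        """Full recount of (published positives, false positives) for audits."""
        pos = sum(1 for f in self.findings if f.positive)
        fp = sum(1 for f in self.findings if f.positive and not f.hypothesis_true)
        return pos, fp


@dataclass(frozen=True)
class NovelHypothesis:
    hypothesis_true: bool


@dataclass(frozen=True)
class ReplicationTarget:
    finding: Finding

    @property
    def hypothesis_true(self) -> bool:
        return self.finding.hypothesis_true


@dataclass(frozen=True)
class ExperimentResult:
    """Outcome of one investigation, before the publication attempt."""

    hypothesis_true: bool
    positive: bool
    is_replication: bool
    target: Optional[Finding]  # origin finding for replications


def decide_investigates(lab: LabState, params: ModelParams, rng: Any) -> bool:
    """True when the lab investigates a hypothesis this step.

    The probability is the lab's productivity ``h(e)``; higher effort means
    fewer investigations.
    """
    h = productivity(lab.effort, params.eta)
    if h >= 1.0:
        return True
    return bool(rng.random() < h)


def choose_hypothesis(
    lab: LabState,
    literature: Literature,
    params: ModelParams,
    rng: Any,
    eligible_snapshot: Optional[list[Finding]] = None,
) -> Union[NovelHypothesis, ReplicationTarget]:
    """Pick a novel hypothesis or a replication target.

    Replication is chosen with probability equal to the lab's own
    replication rate — except in bug mode, which reproduces the original
    implementation's error of always using the *initial* replication rate,
    making the trait selectively neutral. Targets are drawn uniformly from
    the replication-eligible findings; with an empty eligible set the lab
    falls back to a novel hypothesis. A novel hypothesis is true with the
    base rate ``b``.
    """
    eligible = literature.eligible if eligible_snapshot is None else eligible_snapshot
    p_rep = params.r_init if params.bug_mode else lab.replication_rate
    if len(eligible) > 0 and rng.random() < p_rep:
        target = eligible[int(rng.integers(len(eligible)))]
        return ReplicationTarget(target)
    return NovelHypothesis(hypothesis_true=bool(rng.random() < params.base_rate))


def run_experiment_outcome(hypothesis_true: bool, lab: LabState, rng: Any) -> bool:
    """Draw the experiment's sign: power for true hypotheses, alpha for false."""
    p = lab.power if hypothesis_true else false_positive_rate(lab.power, lab.effort)
    return bool(rng.random() < p)


def publish_and_pay(
    result: ExperimentResult,
    lab: LabState,
    population: Iterable[LabState],
    literature: Literature,
    params: ModelParams,
    rng: Any,
    step: int = 0,
) -> Optional[Finding]:
    """Attempt publication and assign pay-offs.

    Novel positives always publish; novel negatives publish with
    ``publish_prob_novel_neg`` (default 0, mirroring the file-drawer
    asymmetry); replications publish with ``publish_prob_replication``
    regardless of sign. On a published replication the origin lab — if still
    alive — is additionally paid ``payoff_original_confirmed`` on a positive
    outcome or ``payoff_original_failed`` on a negative one.

    Returns the published :class:`Finding`, or None if unpublished.
    """
    if result.is_replication:
        if result.target is None or result.target.finding_id not in literature._eligible_ids:
            raise RuntimeError(
                "replication result references a finding absent from the literature"
            )
        p_pub = params.publish_prob_replication
        if p_pub < 1.0 and not rng.random() < p_pub:
            return None
        finding = literature.add(
            hypothesis_true=result.hypothesis_true,
            positive=result.positive,
            is_replication=True,
            origin_lab=result.target.origin_lab,
            author_lab=lab.lab_id,
            step=step,
        )
        lab.payoff += params.payoff_replication
        lab.n_publications += 1
        origin = next(
            (l for l in population if l.lab_id == result.target.origin_lab), None
        )
        if origin is not None:
            origin.payoff += (
                params.payoff_original_confirmed
                if result.positive
                else params.payoff_original_failed
            )
        return finding

    # novel result
    if result.positive:
        pay = params.payoff_novel_pos
    else:
        p_pub = params.publish_prob_novel_neg
        if p_pub <= 0.0 or not rng.random() < p_pub:
            return None
        pay = params.payoff_novel_neg
    finding = literature.add(
        hypothesis_true=result.hypothesis_true,
        positive=result.positive,
        is_replication=False,
        origin_lab=lab.lab_id,
        author_lab=lab.lab_id,
        step=step,
    )
    lab.payoff += pay
    lab.n_publications += 1
    return finding


def step_science(
    population: list[LabState],
    literature: Literature,
    params: ModelParams,
    rng: Any,
    step: int = 0,
    event_log: Optional[list[dict]] = None,
) -> None:
    """Run one science step for every living lab, in stable id order.

    Replication targets are drawn from the start-of-step literature
    snapshot, so a finding published this step cannot be replicated within
    the same step. Every lab ages by one step.
    """
    snapshot = list(literature.eligible)
    for lab in sorted(population, key=lambda l: l.lab_id):
        lab.age += 1
        if not decide_investigates(lab, params, rng):
            continue
        hypothesis = choose_hypothesis(
            lab, literature, params, rng, eligible_snapshot=snapshot
        )
        is_rep = isinstance(hypothesis, ReplicationTarget)
        positive = run_experiment_outcome(hypothesis.hypothesis_true, lab, rng)
        result = ExperimentResult(
            hypothesis_true=hypothesis.hypothesis_true,
            positive=positive,
            is_replication=is_rep,
            target=hypothesis.finding if is_rep else None,
        )
        published = publish_and_pay(
            result, lab, population, literature, params, rng, step=step
        )
        if event_log is not None and published is not None:
            event_log.append(
                {
                    "step": step,
                    "finding_id": published.finding_id,
                    "author_lab": published.author_lab,
                    "origin_lab": published.origin_lab,
                    "hypothesis_true": published.hypothesis_true,
                    "positive": published.positive,
                    "is_replication": published.is_replication,
                }
            )
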