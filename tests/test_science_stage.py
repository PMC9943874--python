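"""The science step: hypothesis choice, experiments, publication, pay-offs."""

import numpy as np
import pytest
from scipy import stats

from pubevolve import (
    ExperimentResult,
    LabState,
    Literature,
    ModelParams,
    NovelHypothesis,
    ReplicationTarget,
    ScriptedRNG,
    choose_hypothesis,
    decide_investigates,
    make_fixture,
    publish_and_pay,
    run_experiment_outcome,
    step_science,
)


def _seed_literature(lit: Literature, origin: int = 0, true: bool = True, k: int = 1):
    for _ in range(k):
        lit.add(hypothesis_true=true, positive=True, is_replication=False,
                origin_lab=origin, author_lab=origin, step=0)


class TestDecideInvestigates:
    def test_minimum_effort_always_investigates(self, rng):
        lab = LabState(lab_id=0, power=0.8, effort=1.0, replication_rate=0.0)
        params = ModelParams()
        assert all(decide_investigates(lab, params, rng) for _ in range(50))

    def test_eta_zero_always_investigates(self, rng):
        lab = LabState(lab_id=0, power=0.8, effort=100.0, replication_rate=0.0)
        params = ModelParams(eta=0.0)
        assert all(decide_investigates(lab, params, rng) for _ in range(50))

    def test_frequency_matches_closed_form(self, rng):
        # h(100, 0.2) = 0.6; 1e5 draws within 3 standard errors
        lab = LabState(lab_id=0, power=0.8, effort=100.0, replication_rate=0.0)
        params = ModelParams()
        n = 100_000
        freq = sum(decide_investigates(lab, params, rng) for _ in range(n)) / n
        se = np.sqrt(0.6 * 0.4 / n)
        assert abs(freq - 0.6) < 3 * se


class TestChooseHypothesis:
    def test_zero_replication_rate_always_novel(self, rng):
        lab = LabState(lab_id=0, power=0.8, effort=75.0, replication_rate=0.0)
        params = ModelParams()
        lit = Literature()
        _seed_literature(lit, k=5)
        for _ in range(50):
            assert isinstance(choose_hypothesis(lab, lit, params, rng),
                              NovelHypothesis)

    def test_full_replication_rate_always_replicates(self, rng):
        lab = LabState(lab_id=0, power=0.8, effort=75.0, replication_rate=1.0)
        params = ModelParams()
        lit = Literature()
        _seed_literature(lit, k=5)
        for _ in range(50):
            assert isinstance(choose_hypothesis(lab, lit, params, rng),
                              ReplicationTarget)

    def test_empty_literature_falls_back_to_novel(self, rng):
        lab = LabState(lab_id=0, power=0.8, effort=75.0, replication_rate=1.0)
        params = ModelParams()
        assert isinstance(choose_hypothesis(lab, Literature(), params, rng),
                          NovelHypothesis)

    def test_bug_mode_ignores_own_trait(self, rng):
        # lab trait 0.9 but bug mode uses r_init = 0.01
        lab = LabState(lab_id=0, power=0.8, effort=75.0, replication_rate=0.9)
        params = ModelParams(bug_mode=True, r_init=0.01)
        lit = Literature()
        _seed_literature(lit, k=3)
        n = 20_000
        reps = sum(
            isinstance(choose_hypothesis(lab, lit, params, rng), ReplicationTarget)
            for _ in range(n)
        )
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(reps / n - 0.01) < 4 * se

    def test_novel_truth_frequency_matches_base_rate(self, rng):
        lab = LabState(lab_id=0, power=0.8, effort=75.0, replication_rate=0.0)
        params = ModelParams(base_rate=0.1)
        lit = Literature()
        n = 20_000
        true = sum(
            choose_hypothesis(lab, lit, params, rng).hypothesis_true
            for _ in range(n)
        )
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(true / n - 0.1) < 4 * se


class TestRunExperimentOutcome:
    def test_perfect_power_true_hypothesis_always_positive(self, rng):
        lab = LabState(lab_id=0, power=1.0, effort=1.0, replication_rate=0.0)
        assert all(run_experiment_outcome(True, lab, rng) for _ in range(50))

    def test_zero_power_true_hypothesis_never_positive(self, rng):
        lab = LabState(lab_id=0, power=0.0, effort=1.0, replication_rate=0.0)
        assert not any(run_experiment_outcome(True, lab, rng) for _ in range(50))

    def test_false_positive_frequency_matches_alpha(self, rng):
        # alpha(0.8, 75) = 0.05 over 1e5 draws
        lab = LabState(lab_id=0, power=0.8, effort=75.0, replication_rate=0.0)
        n = 100_000
        pos = sum(run_experiment_outcome(False, lab, rng) for _ in range(n))
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(pos / n - 0.05) < 3 * se


class TestPublishAndPay:
    def _population(self):
        pop, params = make_fixture("three-lab")
        return pop, params

    def test_novel_positive_pays_and_grows_literature(self, rng):
        pop, params = self._population()
        lit = Literature()
        result = ExperimentResult(hypothesis_true=True, positive=True,
                                  is_replication=False, target=None)
        publish_and_pay(result, pop[0], pop, lit, params, rng)
        assert pop[0].payoff == params.payoff_novel_pos == 1.0
        assert pop[0].n_publications == 1
        assert len(lit) == 1

    def test_novel_negative_unpublished_by_default(self, rng):
        pop, params = self._population()
        lit = Literature()
        result = ExperimentResult(hypothesis_true=False, positive=False,
                                  is_replication=False, target=None)
        assert publish_and_pay(result, pop[0], pop, lit, params, rng) is None
        assert pop[0].payoff == 0.0 and len(lit) == 0

    @pytest.mark.parametrize("positive", [True, False])
    @pytest.mark.parametrize("origin_alive", [True, False])
    def test_replication_payoff_four_cases(self, rng, positive, origin_alive):
        """Enumerate (sign x origin-alive): author always paid on a published
        replication; origin paid/penalised only while alive."""
        pop, params = self._population()
        lit = Literature()
        target = lit.add(hypothesis_true=True, positive=True,
                         is_replication=False, origin_lab=0, author_lab=0,
                         step=0)
        population = pop if origin_alive else pop[1:]  # lab 0 dead
        author = pop[1]
        result = ExperimentResult(hypothesis_true=True, positive=positive,
                                  is_replication=True, target=target)
        publish_and_pay(result, author, population, lit, params, rng)
        assert author.payoff == params.payoff_replication == 0.5
        expected_origin = 0.0
        if origin_alive:
            expected_origin = (params.payoff_original_confirmed if positive
                               else params.payoff_original_failed)
        assert pop[0].payoff == expected_origin

    def test_replication_of_unknown_finding_is_an_error(self, rng):
        from pubevolve.science_stage import Finding

        pop, params = self._population()
        lit = Literature()
        ghost = Finding(finding_id=999, hypothesis_true=True, positive=True,
                        is_replication=False, origin_lab=0, author_lab=0, step=0)
        result = ExperimentResult(hypothesis_true=True, positive=True,
                                  is_replication=True, target=ghost)
        with pytest.raises(RuntimeError):
            publish_and_pay(result, pop[1], pop, lit, params, rng)

    def test_replication_pays_less_than_novel_in_all_presets(self):
        from pubevolve.engine import _PRESETS

        for fn in _PRESETS.values():
            p = fn().resolve()
            assert p.payoff_replication < p.payoff_novel_pos


class TestStepScience:
    def test_idle_step_changes_only_ages(self, rng):
        # eta = 0.5 makes h(100) = 0: nobody investigates
        params = ModelParams(n_labs=2, eta=0.5, tournament_size=2)
        pop = [LabState(lab_id=i, power=0.8, effort=100.0, replication_rate=0.0)
               for i in range(2)]
        lit = Literature()
        step_science(pop, lit, params, rng, step=1)
        assert len(lit) == 0
        assert all(lab.payoff == 0.0 for lab in pop)
        assert all(lab.age == 1 for lab in pop)

    def test_forced_path_publishes_exactly_once_per_step(self, rng):
        # N=1, r=0, W=1, b=1, e=1 (h=1): one novel positive per step
        params = ModelParams(n_labs=1, base_rate=1.0, tournament_size=1)
        pop = [LabState(lab_id=0, power=1.0, effort=1.0, replication_rate=0.0)]
        lit = Literature()
        for step in range(1, 11):
            step_science(pop, lit, params, rng, step=step)
            assert len(lit) == step
        assert pop[0].payoff == 10.0 and pop[0].n_publications == 10

    def test_hand_traced_two_steps(self):
        """A fully scripted RNG stream against a hand-derived event log."""
        pop, params = make_fixture("three-lab")
        lit = Literature()
        events: list[dict] = []
        # step 1: lab0 idle (0.9 >= h=0.625); lab1 investigates (0.1),
        # novel true (0.05 < b=0.1), positive (0.5 < W=0.8); lab2 h=1 (no
        # draw), empty snapshot -> novel, false (0.95), positive (0.3 < alpha=1)
        rng1 = ScriptedRNG([0.9, 0.1, 0.05, 0.5, 0.95, 0.3])
        step_science(pop, lit, params, rng1, step=1, event_log=events)
        assert rng1.consumed == 6
        assert [e["author_lab"] for e in events] == [1, 2]
        assert [e["hypothesis_true"] for e in events] == [True, False]
        assert lit.n_published_positive == 2 and lit.n_false_positive == 1
        assert pop[1].payoff == 1.0 and pop[2].payoff == 1.0

        # step 2: lab0 investigates (0.5 < 0.625), replication draw 0.99
        # fails (r=0), novel false (0.5), positive (0.02 < alpha=0.05);
        # lab1 idle (0.8 >= h=0.765); lab2 replicates (0.3 < r=1), target
        # index int(0.6*2)=1 (lab2's own false finding), positive (0.7 < 1),
        # published with prob 1 -> +0.5 author and +0.1 origin (itself)
        events2: list[dict] = []
        rng2 = ScriptedRNG([0.5, 0.99, 0.5, 0.02, 0.8, 0.3, 0.6, 0.7])
        step_science(pop, lit, params, rng2, step=2, event_log=events2)
        assert rng2.consumed == 8
        assert [e["author_lab"] for e in events2] == [0, 2]
        assert events2[1]["is_replication"] is True
        assert events2[1]["origin_lab"] == 2
        assert pop[0].payoff == 1.0
        assert pop[2].payoff == pytest.approx(1.6)
        assert lit.n_published_positive == 4 and lit.n_false_positive == 3
        assert all(lab.age == 2 for lab in pop)

    def test_same_step_findings_not_replicable(self, rng):
        # r=1 labs with an empty start-of-step literature all go novel even
        # though earlier labs publish within the step
        params = ModelParams(n_labs=5, base_rate=1.0, tournament_size=5)
        pop = [LabState(lab_id=i, power=1.0, effort=1.0, replication_rate=1.0)
               for i in range(5)]
        lit = Literature()
        step_science(pop, lit, params, rng, step=1)
        assert len(lit) == 5
        assert all(not f.is_replication for f in lit.findings)

    def test_payoff_conservation(self, rng):
        """Total pay-off change equals the sum of per-publication pay-offs."""
        pop, params = make_fixture("three-lab")
        lit = Literature()
        for step in range(1, 30):
            before = sum(lab.payoff for lab in pop)
            events: list[dict] = []
            step_science(pop, lit, params, rng, step=step, event_log=events)
            issued = 0.0
            for ev in events:
                if ev["is_replication"]:
                    issued += params.payoff_replication
                    # all origins alive in this fixture (no evolution)
                    issued += (params.payoff_original_confirmed if ev["positive"]
                               else params.payoff_original_failed)
                elif ev["positive"]:
                    issued += params.payoff_novel_pos
                else:
                    issued += params.payoff_novel_neg
            after = sum(lab.payoff for lab in pop)
            assert after - before == pytest.approx(issued)


class TestLiterature:
    def test_counts_match_full_recount(self, rng):
        pop, params = make_fixture("three-lab")
        lit = Literature()
        sizes = []
        for step in range(1, 50):
            step_science(pop, lit, params, rng, step=step)
            pos, fp = lit.recount()
            assert (pos, fp) == (lit.n_published_positive, lit.n_false_positive)
            sizes.append(len(lit))
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_no_published_negatives_when_probability_zero(self, rng):
        pop, params = make_fixture("three-lab")
        assert params.publish_prob_novel_neg == 0.0
        lit = Literature()
        for step in range(1, 50):
            step_science(pop, lit, params, rng, step=step)
        novel = [f for f in lit.findings if not f.is_replication]
        assert all(f.positive for f in novel)


class TestBugModeIndependence:
    def _replication_counts(self, bug_mode, rng, n_steps=400):
        pop, params = make_fixture("two-lab-bugmode")
        params = params.model_copy(update={"bug_mode": bug_mode})
        # keep traits but use corrected/bug switch; r_init = 0.01
        lit = Literature()
        _seed_literature(lit, origin=0, k=3)
        events: list[dict] = []
        for step in range(1, n_steps + 1):
            step_science(pop, lit, params, rng, step=step, event_log=events)
        reps = {0: 0, 1: 0}
        total = {0: 0, 1: 0}
        for ev in events:
            total[ev["author_lab"]] += 1
            if ev["is_replication"]:
                reps[ev["author_lab"]] += 1
        return reps, total

    def test_bug_mode_replication_independent_of_trait(self, rng):
        """chi-square: labs with r=0.0 and r=0.9 replicate at the same
        (initial) rate under the bug."""
        reps, total = self._replication_counts(True, rng, n_steps=3000)
        table = np.array([
            [reps[0], total[0] - reps[0]],
            [reps[1], total[1] - reps[1]],
        ])
        if table[:, 0].sum() == 0:  # no replications at all: independent
            return
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_corrected_mode_matches_each_lab_rate(self, rng):
        reps, total = self._replication_counts(False, rng, n_steps=1500)
        # lab 0 (r=0) never replicates; lab 1 (r=0.9) mostly does
        assert reps[0] == 0
        f1 = reps[1] / total[1]
        assert f1 > 0.75


class TestSpearmanReplicationCorrelation:
    def _realized(self, bug_mode, seed=3, n_steps=400):
        params = ModelParams(n_labs=10, tournament_size=5, bug_mode=bug_mode,
                             r_init=0.01)
        r_values = np.linspace(0.0, 0.9, 10)
        pop = [LabState(lab_id=i, power=0.8, effort=15.0,
                        replication_rate=float(r_values[i])) for i in range(10)]
        rng = np.random.default_rng(seed)
        lit = Literature()
        _seed_literature(lit, origin=0, k=5)
        events: list[dict] = []
        for step in range(1, n_steps + 1):
            step_science(pop, lit, params, rng, step=step, event_log=events)
        counts = np.zeros(10)
        for ev in events:
            if ev["is_replication"]:
                counts[ev["author_lab"]] += 1
        return r_values, counts

    def test_corrected_mode_positive_correlation(self):
        r_values, counts = self._realized(False)
        rho, _ = stats.spearmanr(r_values, counts)
        assert rho > 0.8

    def test_bug_mode_correlation_within_permutation_null(self):
        r_values, counts = self._realized(True, n_steps=2000)
        rho, _ = stats.spearmanr(r_values, counts)
        null_rng = np.random.default_rng(99)
        null = [
            abs(stats.spearmanr(r_values, null_rng.permutation(counts))[0])
            for _ in range(500)
        ]
        assert abs(rho) <= np.quantile(null, 0.95)
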