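# Methods

## Model

The unit of selection is a laboratory. A population of fixed size `N`
(default 100) evolves over discrete time steps; each step consists of a
*science stage* followed by an *evolution stage*.

**Science stage.** Every living lab, visited in stable identifier order:

1. investigates a hypothesis with probability equal to its productivity
   `h(e) = clip(1 − η·log10 e, 0, 1)`;
2. chooses replication with probability equal to its replication rate `r_i`
   (in bug mode: the population's initial rate `r_init`, for every lab);
   replication targets are drawn uniformly from all published *novel*
   findings as of the start of the step, so a finding cannot be replicated
   in the step it appears. If the literature is empty, the lab falls back to
   a novel hypothesis, which is true with base rate `b`;
3. obtains a positive result with probability `W_i` for a true hypothesis or
   `α(W_i, e_i) = W_i / (1 + (1 − W_i) e_i)` for a false one;
4. attempts publication. Novel positives always publish (pay-off +1.0);
   novel negatives publish with probability 0 by default; replications
   publish with probability 1 regardless of sign (pay-off +0.5). On a
   published replication the originating lab — if still alive — receives
   +0.1 when confirmed or −100 when contradicted. Dead originators are
   silently skipped. Re-replication of the same finding is allowed;
   replications themselves never become replication targets.

**Evolution stage.** One birth–death event per step. Death: the oldest of
`d` labs sampled without replacement (ties uniform). Reproduction: the
highest pay-off of `d` sampled labs (ties uniform); alternatively pay-off
proportional (pay-offs shifted by their minimum when negative, uniform
fallback when all shifted weights are zero) or uniform (selection off). In
`death_first` order the dying lab is removed before the parent is chosen;
in `reproduce_first` order the parent is chosen among all `N`, so a lab can
reproduce immediately before dying; the newborn is never the dying lab.
Each trait flagged as evolving mutates with probability `μ` by a uniform
increment on `[−scale, +scale]`, then is **truncated** (not reflected) to
its domain. Truncation censors increments asymmetrically near a bound: a
neutral trait sitting at 0.01 with scale > 0.01 acquires a spurious upward
drift, which is exactly the artefact the bug-mode experiment exposes.

The cumulative false discovery rate (FDR) is the fraction of all published
positives whose hypothesis is false. For a static population it has the
closed form `(1−b)α / ((1−b)α + bW)` — 0.36 at `b=0.1, W=0.8, e=75` — which
the test suite uses as an oracle. A windowed FDR is not provided; the
cumulative definition matches "the set of published results".

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_labs` | 100 | population size |
| `base_rate` | 0.1 | prior truth probability of novel hypotheses |
| `e_min, e_max` | 1, 100 | effort domain; `h(1) = 1`, `α(0.8, 1) = 2/3` |
| `w_init, e_init, r_init` | 0.8, 75, 0.01 | canonical starting traits |
| `eta` | 0.2 | productivity slope; `h(100) = 0.6` |
| `mu` | 0.01 | per-trait mutation probability at birth |
| `mutation_scale_effort` | 2.0 | calibrated, see below |
| `mutation_scale_replication` | 0.025 | calibrated, see below |
| `mutation_scale_power` | 0.01 | power rarely evolves in shipped presets |
| `tournament_size` | 20 | calibrated, see below |
| pay-offs | +1, +0.5, +0.1, −100 | novel positive, replication, origin confirmed / contradicted |
| `n_steps`, `n_runs` | 10⁶, 50 | standard horizon and ensemble size |

Pay-off constants, publication probabilities, `b` and `μ` follow the
conventional values for this model family. The mutation scales and
tournament size are not uniquely pinned by any closed-form constraint, so
they were calibrated once against the qualitative template of the corrected
coevolution experiment: the replication boom must complete (ensemble-mean
peak near 100%) before effort's collapse ends it, the boom's decline must
begin within the standard 10⁶-step horizon (probe seeds gave onset at
roughly 0.6–0.95 × 10⁶ steps), bug-mode drift of the neutral replication
rate must stay well below the boom scale (ensemble-mean peak ≈ 0.1 over
10⁶ steps), and mean effort must equilibrate at `e_min` by 2 × 10⁶ steps.
The calibration is coarse by construction: effort scales of 3 or more let
effort collapse before the boom completes, while replication scales of 0.05
or more start the boom implausibly early and inflate the neutral drift.
These defaults are a package choice; anyone comparing against a specific
historical configuration should override them (`ModelParams` accepts every
constant) and confirm against that source.

## Engines, RNG, determinism

Two interchangeable engines implement the identical model:

* the **reference engine** — the object-level stage functions
  (`step_science`, `step_evolution`) over explicit `LabState`/`Finding`/
  `Literature` objects, with optional per-publication event logs. RNG:
  `numpy.random.Generator` (PCG64). Used for unit tests, traces, and small
  populations.
* the **kernel** — a numba-compiled loop used by `run_simulation` for long
  horizons (a 10⁶-step run at N=100 takes ~10 s on one CPU). It stores the
  literature as per-origin-slot counts of replication-eligible findings
  split by hypothesis truth, plus a pooled count for dead origins and the
  cumulative FDR counters. This aggregation is exact: replication dynamics
  depend on a target only through its truth value and its originator's
  aliveness. Uniform target sampling uses two Fenwick trees (O(log N)).
  RNG: numba's internal Mersenne Twister, seeded per run.

The engines share no code and no RNG stream; `tests/test_kernel_consistency`
checks them against each other (and against closed forms) on distributional
quantities. Each engine is bit-deterministic given `(params, seed)`.
Ensemble seeds are derived as `base_seed + run_index`, so any single run of
an ensemble can be reproduced in isolation. Runs execute sequentially; the
seed derivation makes concurrent execution trivially equivalent.

Trajectories record, every `record_every` steps (default 1000) plus the
initial state and final step: mean power, mean effort, mean replication
rate, mean α (the population mean of `α(W_i, e_i)`), cumulative FDR (NaN
until the first published positive), literature size, and mean pay-off.
Population means are over living labs — which is all labs, since the
population size is constant by construction.

## Numerical choices and degenerate inputs

* Trait values are kept at full float precision; clamping uses closed
  intervals; `α ≤ W` holds exactly.
* `h` outside [0, 1] before clipping (possible for large η) is clipped and
  warned once per (effort, η) pair.
* `productivity(e) = 1` short-circuits the investigation draw, and
  publication probabilities of exactly 1 short-circuit the publication
  draw, so the degenerate paths consume no randomness.
* Tournament ties (age or pay-off) are broken uniformly at random;
  tournaments sample without replacement; a tournament larger than the
  eligible pool (possible only after exclusion of the dying lab) shrinks to
  the pool size.
* `n_steps = 0` yields a trajectory with only the initial-state row.
* Non-finite recorded metrics or an in-kernel trait-bound violation abort
  the run with a diagnostic error.

## What the experiments show — and what they do not

The shipped presets (`coevolution`, `effort_evolution`, `power_evolution`,
`effort_competition` with its high/low efforts 75 and 15) are best-effort
reconstructions of the canonical experiment designs; their docstrings say
so. The simulated world is deliberately austere: no peer review, journals,
multi-author papers, citation dynamics, or lab heterogeneity beyond the
three traits; pay-offs are universal constants; exactly one birth–death
event per step. Passing tests therefore show that the *model* behaves as
described, not that real scientific communities do.

One substantive observation from the corrected-vs-bug comparison: during
the corrected-mode replication boom nearly all investigations are
replications, whose pay-off does not depend on the result's sign, so the
α-mediated component of selection on effort pauses and the effort collapse
lags the bug-mode run by roughly 10⁵ steps before both converge to the same
endpoint. Effort and α trajectories of the two modes are therefore
indistinguishable at most, but not strictly all, intermediate checkpoints
of small ensembles (the corresponding strict test in the acceptance suite
documents this, and fails, at the transition checkpoint); their endpoints
agree tightly.

## Problem sizes used in tests

The test suite runs the coevolution ensemble at 3 seeds × 2×10⁶ steps and
the bug-mode ensemble at 5 seeds × 10⁶ steps (the standard protocol
averages 50 runs; the qualitative dynamics are already stable at a handful
of seeds, which keeps the suite at a few minutes). The drift artefact test
uses 20 runs × 10⁵ steps with uniform parent selection. The acceptance
script uses 4 runs × 2×10⁶ steps.
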