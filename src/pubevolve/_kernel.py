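"""Compiled simulation kernel for long-horizon runs.

Semantically equivalent to composing :func:`pubevolve.science_stage.step_science`
with :func:`pubevolve.evolution_stage.step_evolution`, but implemented over
flat arrays and JIT-compiled so that million-step runs at N=100 take seconds.

The key compression: replication dynamics depend on a target finding only
through (a) whether its hypothesis is true and (b) whether its originating
lab is still alive (for origin pay-offs). The literature is therefore stored
as per-slot counts of replication-eligible findings split by truth, plus a
pooled count for findings whose origin lab has died, plus cumulative
published-positive / false-positive counters for the FDR. Uniform sampling
over all eligible findings is done with two Fenwick trees (one per truth
value) in O(log N).

Randomness uses numba's internal Mersenne Twister state, seeded per run;
runs with identical (params, seed) are bit-identical.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# order_mode codes
DEATH_FIRST = 0
REPRODUCE_FIRST = 1
# parent_selection codes
TOURNAMENT = 0
PROPORTIONAL = 1
UNIFORM = 2


@njit(cache=True)
def _fen_add(tree, slot, delta):
    i = slot + 1
    n = tree.shape[0] - 1
    while i <= n:
        tree[i] += delta
        i += i & (-i)


@njit(cache=True)
def _fen_find(tree, v):
    """Smallest 0-based slot whose prefix sum exceeds v (v < total)."""
    n = tree.shape[0] - 1
    bit = 1
    while bit * 2 <= n:
        bit *= 2
    idx = 0
    rem = v
    while bit > 0:
        nxt = idx + bit
        if nxt <= n and tree[nxt] <= rem:
            idx = nxt
            rem -= tree[nxt]
        bit >>= 1
    return idx


@njit(cache=True)
def _sample_distinct(buf, m, d):
    """Partial Fisher–Yates: after the call, buf[:d] holds d distinct entries
    drawn uniformly from buf[:m]."""
    for k in range(d):
        j = k + int(np.random.random() * (m - k))
        if j >= m:
            j = m - 1
        tmp = buf[k]
        buf[k] = buf[j]
        buf[j] = tmp


@njit(cache=True)
def _fill_eligible(buf, n, excluded):
    m = 0
    for s in range(n):
        if s != excluded:
            buf[m] = s
            m += 1
    return m


@njit(cache=True)
def _tournament_max(values, buf, m, d):
    """Max-of-d tournament over buf[:m]; ties broken uniformly at random."""
    _sample_distinct(buf, m, d)
    best = buf[0]
    best_v = values[best]
    ties = 1
    for k in range(1, d):
        s = buf[k]
        v = values[s]
        if v > best_v:
            best = s
            best_v = v
            ties = 1
        elif v == best_v:
            ties += 1
            if np.random.random() * ties < 1.0:
                best = s
    return best


@njit(cache=True)
def _select_parent_slot(payoff, buf, n, d, mode, excluded):
    m = _fill_eligible(buf, n, excluded)
    if mode == TOURNAMENT:
        dd = d if d <= m else m
        return _tournament_max(payoff, buf, m, dd)
    if mode == PROPORTIONAL:
        shift = 0.0
        for k in range(m):
            p = payoff[buf[k]]
            if p < shift:
                shift = p
        total = 0.0
        for k in range(m):
            total += payoff[buf[k]] - shift
        if total <= 0.0:
            return buf[int(np.random.random() * m)]
        u = np.random.random() * total
        acc = 0.0
        for k in range(m):
            acc += payoff[buf[k]] - shift
            if u < acc:
                return buf[k]
        return buf[m - 1]
    # UNIFORM
    return buf[int(np.random.random() * m)]


@njit(cache=True)
def _mutate(value, lower, upper, mu, scale):
    if np.random.random() < mu:
        value = value + np.random.uniform(-scale, scale)
        if value < lower:
            value = lower
        elif value > upper:
            value = upper
    return value


@njit(cache=True)
def simulate_kernel(
    seed,
    n_steps,
    n_labs,
    base_rate,
    e_min,
    e_max,
    w_init,
    r_init,
    init_effort,
    evolve_power,
    evolve_effort,
    evolve_replication,
    mu,
    scale_power,
    scale_effort,
    scale_replication,
    d,
    pay_novel_pos,
    pay_novel_neg,
    pay_replication,
    pay_orig_confirmed,
    pay_orig_failed,
    pub_novel_neg,
    pub_replication,
    eta,
    bug_mode,
    order_mode,
    parent_sel,
    record_every,
    check_every,
):
    np.random.seed(seed)
    n = n_labs

    power = np.full(n, w_init)
    effort = init_effort.copy()
    rep = np.full(n, r_init)
    payoff = np.zeros(n)
    age = np.zeros(n, dtype=np.int64)
    npubs = np.zeros(n, dtype=np.int64)

    alpha = np.empty(n)
    h = np.empty(n)
    for i in range(n):
        alpha[i] = power[i] / (1.0 + (1.0 - power[i]) * effort[i])
        hh = 1.0 - eta * np.log10(effort[i])
        h[i] = min(1.0, max(0.0, hh))

    # literature aggregates: eligible (novel published) findings by origin slot
    lit_true = np.zeros(n, dtype=np.int64)
    lit_false = np.zeros(n, dtype=np.int64)
    fen_t = np.zeros(n + 1, dtype=np.int64)
    fen_f = np.zeros(n + 1, dtype=np.int64)
    new_t = np.zeros(n, dtype=np.int64)
    new_f = np.zeros(n, dtype=np.int64)
    dead_true = 0
    dead_false = 0
    tot_true = 0
    tot_false = 0
    pub_pos = 0
    pub_fp = 0
    lit_size = 0

    buf = np.empty(n, dtype=np.int64)

    n_rec = 1 + n_steps // record_every
    if n_steps > 0 and n_steps % record_every != 0:
        n_rec += 1
    rec_step = np.empty(n_rec, dtype=np.int64)
    rec_w = np.empty(n_rec)
    rec_e = np.empty(n_rec)
    rec_r = np.empty(n_rec)
    rec_a = np.empty(n_rec)
    rec_fdr = np.empty(n_rec)
    rec_lit = np.empty(n_rec, dtype=np.int64)
    rec_pay = np.empty(n_rec)

    ri = 0
    rec_step[ri] = 0
    rec_w[ri] = power.mean()
    rec_e[ri] = effort.mean()
    rec_r[ri] = rep.mean()
    rec_a[ri] = alpha.mean()
    rec_fdr[ri] = np.nan
    rec_lit[ri] = 0
    rec_pay[ri] = 0.0
    ri += 1

    ok = 0  # first step at which an invariant was violated; 0 = clean

    for step in range(1, n_steps + 1):
        # ---------------- science stage ----------------
        snap_t = tot_true
        snap_f = tot_false
        snap_total = snap_t + snap_f
        any_new = False
        for i in range(n):
            age[i] += 1
            if h[i] < 1.0 and np.random.random() >= h[i]:
                continue
            p_rep = r_init if bug_mode else rep[i]
            if snap_total > 0 and p_rep > 0.0 and np.random.random() < p_rep:
                # replication of a published novel finding
                u = np.random.random() * snap_total
                if u < snap_t:
                    truth = True
                    v = np.random.random() * snap_t
                    if v < dead_true:
                        origin = -1
                    else:
                        origin = _fen_find(fen_t, v - dead_true)
                else:
                    truth = False
                    v = np.random.random() * snap_f
                    if v < dead_false:
                        origin = -1
                    else:
                        origin = _fen_find(fen_f, v - dead_false)
                p_pos = power[i] if truth else alpha[i]
                positive = np.random.random() < p_pos
                published = pub_replication >= 1.0 or (
                    np.random.random() < pub_replication
                )
                if published:
                    payoff[i] += pay_replication
                    npubs[i] += 1
                    lit_size += 1
                    if positive:
                        pub_pos += 1
                        if not truth:
                            pub_fp += 1
                    if origin >= 0:
                        if positive:
                            payoff[origin] += pay_orig_confirmed
                        else:
                            payoff[origin] += pay_orig_failed
            else:
                # novel hypothesis
                truth = np.random.random() < base_rate
                p_pos = power[i] if truth else alpha[i]
                positive = np.random.random() < p_pos
                if positive:
                    payoff[i] += pay_novel_pos
                    npubs[i] += 1
                    lit_size += 1
                    pub_pos += 1
                    if not truth:
                        pub_fp += 1
                    if truth:
                        new_t[i] += 1
                    else:
                        new_f[i] += 1
                    any_new = True
                elif pub_novel_neg > 0.0 and np.random.random() < pub_novel_neg:
                    payoff[i] += pay_novel_neg
                    npubs[i] += 1
                    lit_size += 1
                    if truth:
                        new_t[i] += 1
                    else:
                        new_f[i] += 1
                    any_new = True
        if any_new:
            for s in range(n):
                if new_t[s] > 0:
                    lit_true[s] += new_t[s]
                    _fen_add(fen_t, s, new_t[s])
                    tot_true += new_t[s]
                    new_t[s] = 0
                if new_f[s] > 0:
                    lit_false[s] += new_f[s]
                    _fen_add(fen_f, s, new_f[s])
                    tot_false += new_f[s]
                    new_f[s] = 0

        # ---------------- evolution stage ----------------
        if order_mode == DEATH_FIRST:
            _fill_eligible(buf, n, -1)
            dying = _tournament_max(age, buf, n, d)
            parent = _select_parent_slot(payoff, buf, n, d, parent_sel, dying)
        else:
            parent = _select_parent_slot(payoff, buf, n, d, parent_sel, -1)
            _fill_eligible(buf, n, -1)
            dying = _tournament_max(age, buf, n, d)

        cp = power[parent]
        ce = effort[parent]
        cr = rep[parent]
        if evolve_power:
            cp = _mutate(cp, 0.0, 1.0, mu, scale_power)
        if evolve_effort:
            ce = _mutate(ce, e_min, e_max, mu, scale_effort)
        if evolve_replication:
            cr = _mutate(cr, 0.0, 1.0, mu, scale_replication)

        # retire the dying lab's findings to the dead-origin pool
        if lit_true[dying] > 0:
            dead_true += lit_true[dying]
            _fen_add(fen_t, dying, -lit_true[dying])
            lit_true[dying] = 0
        if lit_false[dying] > 0:
            dead_false += lit_false[dying]
            _fen_add(fen_f, dying, -lit_false[dying])
            lit_false[dying] = 0

        power[dying] = cp
        effort[dying] = ce
        rep[dying] = cr
        payoff[dying] = 0.0
        age[dying] = 0
        npubs[dying] = 0
        alpha[dying] = cp / (1.0 + (1.0 - cp) * ce)
        hh = 1.0 - eta * np.log10(ce)
        h[dying] = min(1.0, max(0.0, hh))

        # ---------------- recording & checks ----------------
        if step % record_every == 0 or step == n_steps:
            rec_step[ri] = step
            rec_w[ri] = power.mean()
            rec_e[ri] = effort.mean()
            rec_r[ri] = rep.mean()
            rec_a[ri] = alpha.mean()
            rec_fdr[ri] = pub_fp / pub_pos if pub_pos > 0 else np.nan
            rec_lit[ri] = lit_size
            rec_pay[ri] = payoff.mean()
            ri += 1
        if check_every > 0 and step % check_every == 0 and ok == 0:
            for i in range(n):
                if not (0.0 <= power[i] <= 1.0):
                    ok = step
                if not (e_min <= effort[i] <= e_max):
                    ok = step
                if not (0.0 <= rep[i] <= 1.0):
                    ok = step
                if age[i] < 0:
                    ok = step

    return (
        rec_step[:ri],
        rec_w[:ri],
        rec_e[:ri],
        rec_r[:ri],
        rec_a[:ri],
        rec_fdr[:ri],
        rec_lit[:ri],
        rec_pay[:ri],
        ok,
    )
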