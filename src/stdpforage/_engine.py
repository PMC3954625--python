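"""Compiled simulation core: the epoch loop and its pieces.

Everything here operates on flat numpy arrays so that the whole
epoch protocol — visual-field encoding, the 600-step network simulation,
the move decision, food relocation, trace bookkeeping, reward/punishment,
balancing and homeostasis — runs inside numba-compiled code.  The public,
documented surface for each of these operations lives in :mod:`env`,
:mod:`circuit`, :mod:`plasticity` and :mod:`experiments`; the functions
there call the same kernels, so a run stepped one epoch at a time from
Python is bit-identical to a run driven by :func:`run_epochs_kernel`.

Layer index layout (156 cells): input 0..48, excitatory hidden 49..97,
inhibitory hidden 98..146, output 147..155.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._rng import (
    STREAM_DECISION,
    STREAM_PERTURB,
    STREAM_RELEASE,
    random_below,
    random_float,
    random_uniform,
)
from .config import (
    P_ALPHA, P_BETA_E, P_DECISION_STEPS, P_EMA_A, P_EMA_RATE, P_EPOCH_STEPS,
    P_ETA_HOMEO, P_F_TARGET, P_FORCE_REWARD, P_GAMMA, P_HUNGER_CONT,
    P_HUNGER_THRESH, P_INBAL_ON, P_K_MINUS, P_K_PLUS, P_LEARNING_ON, P_MU,
    P_OUTBAL_ON, P_PULSE_AMP, P_PULSE_STEPS, P_PUNISH_FRAC, P_PUNISH_ON,
    P_RELEASE_R, P_REVERSED, P_RUNAWAY_FACTOR, P_SC, P_SIGMA, P_SIGMA_E,
    P_TC_STEPS, P_TRACE_EPOCHS, P_TURN_PROB, P_VALIDATE, P_VBIAS, P_VREV_EXC,
    P_VREV_INH, P_W_INPUT, P_WJ0_MAX, P_WJ0_MIN,
)
from .env import move_entity_kernel, visual_field_kernel

N_INPUT = 49
N_HIDDEN = 49
N_OUTPUT = 9
N_CELLS = 156
I0, H0, HI0, O0 = 0, 49, 98, 147
CENTER_INPUT = 24          # visual-field centre: never stimulated

TRACE_RING = 6             # current epoch + trace_epochs past epochs
TRACE_CAP = 1792           # 2 kinds x 49 x 9 pairs: hard upper bound per epoch
MAX_H_SPIKES = 32
MAX_O_SPIKES = 64

GATE_SNAP = 1e-30          # gating below this is flushed to exact zero
QUIET_GATE = 1e-6          # gating this small cannot move a cell toward threshold
QUIET_MARGIN = 1e-4        # x/y distance to rest that precludes further spikes
CURRENT_EPS = 1e-9         # currents below this are flushed to exact zero: keeps
                           # the balanced E/I state exactly balanced in floating
                           # point (real synaptic events are >= 1e-3)

# Output cell (3x3, row-major) -> compass direction; centre (-1) = continue.
OUT_TO_DIR = np.array([7, 0, 1, 6, -1, 2, 5, 4, 3], dtype=np.int64)

# state_i layout
SI_ROW, SI_COL, SI_HEADING, SI_SINCE_FOOD, SI_HUNGER, SI_EPOCH, SI_HALTED = range(7)

# counters layout
C_DEGENERATE, C_VIOLATIONS, C_TRACE_DROPS = range(3)


# ---------------------------------------------------------------------------
# Network simulation for one decision window
# ---------------------------------------------------------------------------
@njit(cache=True)
def simulate_decision_window(
    p, rng, x, y, xp, active, spk, s1, s2, sE, sI, W, WI, stim,
    h_times, h_n, o_times, o_n,
):
    """Simulate the first half-epoch; record hidden/output spike times.

    Stimulated input cells receive the calibrated current pulse on the first
    ``input_pulse_steps`` steps.  The loop exits early once no spike can
    occur any more (all gating decayed, every cell at or below rest); at the
    end all cells are reset to the exact resting fixed point and gating is
    cleared — the idealised cooling-off period.  Returns the total number of
    output-layer spikes.
    """
    alpha = p[P_ALPHA]
    mu = p[P_MU]
    sigma = p[P_SIGMA]
    beta_e = p[P_BETA_E]
    sigma_e = p[P_SIGMA_E]
    gamma = p[P_GAMMA]
    R = p[P_RELEASE_R]
    v_exc = p[P_VREV_EXC]
    v_inh = p[P_VREV_INH]
    steps = int(p[P_DECISION_STEPS])
    pulse = p[P_PULSE_AMP]
    pulse_steps = int(p[P_PULSE_STEPS])
    w_in = p[P_W_INPUT]
    x_rest = sigma - 1.0
    y_rest = x_rest - alpha / (1.0 - x_rest)

    for i in range(N_HIDDEN):
        h_n[i] = 0
    for j in range(N_OUTPUT):
        o_n[j] = 0
    total_o = 0

    for t in range(steps):
        any_event = False
        for n in range(N_CELLS):
            if not active[n]:
                spk[n] = False
                continue
            if n < H0:
                i_ext = pulse if (t < pulse_steps and stim[n]) else 0.0
            elif n < HI0:
                i_ext = -s1[n - H0] * (x[n] - v_exc)
            elif n < O0:
                i_ext = -s2[n - HI0] * (x[n] - v_exc)
            else:
                j = n - O0
                i_ext = -sE[j] * (x[n] - v_exc) - sI[j] * (x[n] - v_inh)
            if n >= H0 and -CURRENT_EPS < i_ext < CURRENT_EPS:
                i_ext = 0.0
            u = y[n] + beta_e * i_ext
            xc = x[n]
            sp = False
            if xc <= 0.0:
                xn = alpha / (1.0 - xc) + u
            elif xc < alpha + u and xp[n] <= 0.0:
                xn = alpha + u
            else:
                xn = -1.0
                sp = True
            y[n] = y[n] - mu * (xc + 1.0) + mu * sigma + mu * sigma_e * i_ext
            xp[n] = xc
            x[n] = xn
            spk[n] = sp
            if sp:
                any_event = True
                if H0 <= n < HI0:
                    k = n - H0
                    if h_n[k] < MAX_H_SPIKES:
                        h_times[k, h_n[k]] = t
                        h_n[k] += 1
                elif n >= O0:
                    j = n - O0
                    if o_n[j] < MAX_O_SPIKES:
                        o_times[j, o_n[j]] = t
                        o_n[j] += 1
                    total_o += 1

        # First-order kinetics: geometric decay, then spike-triggered jumps
        # with multiplicative release noise.
        for i in range(N_HIDDEN):
            if s1[i] != 0.0:
                s1[i] *= gamma
                if s1[i] < GATE_SNAP:
                    s1[i] = 0.0
            if s2[i] != 0.0:
                s2[i] *= gamma
                if s2[i] < GATE_SNAP:
                    s2[i] = 0.0
        for j in range(N_OUTPUT):
            if sE[j] != 0.0:
                sE[j] *= gamma
                if sE[j] < GATE_SNAP:
                    sE[j] = 0.0
            if sI[j] != 0.0:
                sI[j] *= gamma
                if sI[j] < GATE_SNAP:
                    sI[j] = 0.0
        for n in range(N_CELLS):
            if spk[n]:
                if n < H0:
                    a1 = 1.0 if R == 0.0 else random_uniform(rng, STREAM_RELEASE, 1.0 - R, 1.0 + R)
                    a2 = 1.0 if R == 0.0 else random_uniform(rng, STREAM_RELEASE, 1.0 - R, 1.0 + R)
                    s1[n] += w_in * a1
                    s2[n] += w_in * a2
                    active[H0 + n] = True
                    active[HI0 + n] = True
                elif n < HI0:
                    i = n - H0
                    for j in range(N_OUTPUT):
                        a = 1.0 if R == 0.0 else random_uniform(rng, STREAM_RELEASE, 1.0 - R, 1.0 + R)
                        sE[j] += W[i, j] * a
                        active[O0 + j] = True
                elif n < O0:
                    i = n - HI0
                    for j in range(N_OUTPUT):
                        a = 1.0 if R == 0.0 else random_uniform(rng, STREAM_RELEASE, 1.0 - R, 1.0 + R)
                        sI[j] += WI[i, j] * a
                        active[O0 + j] = True

        # Early exit: once gating is negligible and every active cell sits at
        # or below rest (x and y within QUIET_MARGIN, far less than the
        # distance from rest to the spiking bifurcation), no further spike is
        # possible and the remaining steps are inert.
        if t >= pulse_steps and not any_event:
            quiet = True
            for i in range(N_HIDDEN):
                if s1[i] > QUIET_GATE or s2[i] > QUIET_GATE:
                    quiet = False
                    break
            if quiet:
                for j in range(N_OUTPUT):
                    if sE[j] > QUIET_GATE or sI[j] > QUIET_GATE:
                        quiet = False
                        break
            if quiet:
                for n in range(N_CELLS):
                    if active[n] and (
                        x[n] > x_rest + QUIET_MARGIN
                        or y[n] > y_rest + QUIET_MARGIN
                        or xp[n] > 0.0
                    ):
                        quiet = False
                        break
            if quiet:
                break

    # Idealised cooling-off: the epoch is long enough for the network to
    # return to rest, so the boundary state is the exact resting fixed point.
    for n in range(N_CELLS):
        if active[n]:
            x[n] = x_rest
            y[n] = y_rest
            xp[n] = x_rest
            active[n] = False
    for i in range(N_HIDDEN):
        s1[i] = 0.0
        s2[i] = 0.0
    for j in range(N_OUTPUT):
        sE[j] = 0.0
        sI[j] = 0.0
    return total_o


# ---------------------------------------------------------------------------
# STDP trace detection (nearest pairing with suppression)
# ---------------------------------------------------------------------------
@njit(cache=True)
def detect_traces_kernel(
    p, W, h_times, h_n, o_times, o_n, epoch_start,
    tr_pre, tr_post, tr_val, tr_time, tr_count, slot, counters,
):
    """Scan each (hidden, output) spike-train pair and store traces.

    A post spike that directly follows a pre spike creates one
    pre-before-post event with vE = k_plus * S * exp(-dt / T_c); further
    post spikes create nothing until a new pre spike re-arms the pair
    (symmetrically for post-before-pre with k_minus).  Simultaneous spikes
    count as pre-before-post with dt = 0.  ``S`` is the current weight.
    Trace creation time is the (global) time of the second spike of the pair.
    """
    k_plus = p[P_K_PLUS]
    k_minus = p[P_K_MINUS]
    tc = p[P_TC_STEPS]
    cnt = 0
    for i in range(N_HIDDEN):
        ni = h_n[i]
        if ni == 0:
            continue
        for j in range(N_OUTPUT):
            nj = o_n[j]
            if nj == 0:
                continue
            S = W[i, j]
            a = 0
            b = 0
            armed_pre = False
            armed_post = False
            t_pre = 0
            t_post = 0
            while a < ni or b < nj:
                if b >= nj or (a < ni and h_times[i, a] <= o_times[j, b]):
                    t = h_times[i, a]
                    a += 1
                    if armed_post:
                        if cnt < TRACE_CAP:
                            tr_pre[slot, cnt] = i
                            tr_post[slot, cnt] = j
                            tr_val[slot, cnt] = k_minus * S * np.exp(-(t - t_post) / tc)
                            tr_time[slot, cnt] = epoch_start + t
                            cnt += 1
                        else:
                            counters[C_TRACE_DROPS] += 1
                        armed_post = False
                    armed_pre = True
                    t_pre = t
                else:
                    t = o_times[j, b]
                    b += 1
                    if armed_pre:
                        if cnt < TRACE_CAP:
                            tr_pre[slot, cnt] = i
                            tr_post[slot, cnt] = j
                            tr_val[slot, cnt] = k_plus * S * np.exp(-(t - t_pre) / tc)
                            tr_time[slot, cnt] = epoch_start + t
                            cnt += 1
                        else:
                            counters[C_TRACE_DROPS] += 1
                        armed_pre = False
                    armed_post = True
                    t_post = t
    tr_count[slot] = cnt


# ---------------------------------------------------------------------------
# Balancing primitives
# ---------------------------------------------------------------------------
@njit(cache=True)
def rebalance_column_kernel(W, j, target, counters):
    """Multiplicatively rescale column j so its sum equals ``target``.

    A column whose weights all reached zero cannot be rescaled; it is reset
    to uniform target/49 and counted as a degenerate event.
    """
    total = 0.0
    for i in range(N_HIDDEN):
        total += W[i, j]
    if total > 0.0:
        f = target / total
        for i in range(N_HIDDEN):
            W[i, j] *= f
    else:
        counters[C_DEGENERATE] += 1
        for i in range(N_HIDDEN):
            W[i, j] = target / N_HIDDEN


@njit(cache=True)
def balance_inhibition_column_kernel(W, WI, j):
    """Set the uniform inhibitory column so its sum equals the excitatory sum."""
    total = 0.0
    for i in range(N_HIDDEN):
        total += W[i, j]
    u = total / N_HIDDEN
    for i in range(N_HIDDEN):
        WI[i, j] = u


@njit(cache=True)
def refresh_row_sums(W, row_sum):
    for i in range(N_HIDDEN):
        t = 0.0
        for j in range(N_OUTPUT):
            t += W[i, j]
        row_sum[i] = t


# ---------------------------------------------------------------------------
# Reward / punishment application
# ---------------------------------------------------------------------------
@njit(cache=True)
def apply_reward_kernel(
    p, W, WI, Wj0, w_io, row_sum,
    tr_pre, tr_post, tr_val, tr_time, tr_count, slot_epoch,
    epoch_idx, reward, dW, touched, counters,
):
    """Commit all live traces to the weights at a reward/punishment event.

    Each live trace contributes S_rp * vE * exp(-age / T_e).  Reward is
    scaled per presynaptic cell by S_c * W_io / W_i (output balancing);
    punishment applies the sign-flipped trace at the constant reduced scale
    punish_fraction * S_c.  Deltas are accumulated and applied
    simultaneously, weights are floored at zero, and every touched output
    column is rebalanced to its homeostatic target with the inhibitory
    column tracking the excitatory sum.
    """
    Te = p[P_EPOCH_STEPS]
    Sc = p[P_SC]
    out_bal = p[P_OUTBAL_ON] > 0.5
    in_bal = p[P_INBAL_ON] > 0.5
    life = int(p[P_TRACE_EPOCHS])
    t_re = epoch_idx * Te + p[P_DECISION_STEPS]

    for i in range(N_HIDDEN):
        for j in range(N_OUTPUT):
            dW[i, j] = 0.0
    for j in range(N_OUTPUT):
        touched[j] = False

    any_trace = False
    for s in range(TRACE_RING):
        se = slot_epoch[s]
        if se < 0:
            continue
        age = epoch_idx - se
        if age < 0 or age > life:
            continue
        for k in range(tr_count[s]):
            i = tr_pre[s, k]
            j = tr_post[s, k]
            decay = np.exp(-(t_re - tr_time[s, k]) / Te)
            if reward:
                if out_bal and row_sum[i] > 0.0:
                    s_rp = Sc * (w_io[i] / row_sum[i])
                else:
                    s_rp = Sc
            else:
                s_rp = -p[P_PUNISH_FRAC] * Sc
            dW[i, j] += s_rp * tr_val[s, k] * decay
            touched[j] = True
            any_trace = True
    if not any_trace:
        return

    for j in range(N_OUTPUT):
        if not touched[j]:
            continue
        for i in range(N_HIDDEN):
            w = W[i, j] + dW[i, j]
            W[i, j] = w if w > 0.0 else 0.0
        if in_bal:
            rebalance_column_kernel(W, j, Wj0[j], counters)
        balance_inhibition_column_kernel(W, WI, j)
    refresh_row_sums(W, row_sum)


@njit(cache=True)
def homeostasis_kernel(p, W, WI, Wj0, F_est, o_n, wj0_init, counters):
    """Per-epoch homeostatic scaling of each output cell's input target.

    The firing-rate estimate is an exponential average of spikes/epoch; the
    target total input W_j0 moves opposite to the rate error (silent cells
    grow their target, over-active cells shrink it) and the excitatory
    column is rescaled to the new target, inhibition tracking it.
    """
    ema = p[P_EMA_RATE]
    eta = p[P_ETA_HOMEO]
    f_target = p[P_F_TARGET]
    in_bal = p[P_INBAL_ON] > 0.5
    floor = p[P_WJ0_MIN] * wj0_init
    cap = p[P_WJ0_MAX] * wj0_init
    for j in range(N_OUTPUT):
        F_est[j] = (1.0 - ema) * F_est[j] + ema * o_n[j]
        Wj0[j] += eta * wj0_init * (f_target - F_est[j])
        if Wj0[j] < floor:
            Wj0[j] = floor
        elif Wj0[j] > cap:
            Wj0[j] = cap
        if in_bal:
            rebalance_column_kernel(W, j, Wj0[j], counters)
        balance_inhibition_column_kernel(W, WI, j)


# ---------------------------------------------------------------------------
# Move decision
# ---------------------------------------------------------------------------
@njit(cache=True)
def decide_move_kernel(p, rng, o_counts, o_first, prev_heading, hunger_active):
    """Turn output spike counts into one of the 8 compass directions.

    Winner = most spikes in the decision window; ties go to the earliest
    first spike, residual ties are broken uniformly.  No spikes (or a win by
    the centre cell, which maps to no direction) continues the previous
    heading.  Active hunger ignores the outputs entirely: continue with
    probability hunger_continue_prob, else a uniformly random new direction.
    Independently, with probability turn_prob the final choice is replaced
    by a 45-degree turn off the previous heading (left/right equiprobable).
    Returns (direction, winner_cell) with winner_cell = -1 if no cell won.
    """
    winner = -1
    if hunger_active:
        if random_float(rng, STREAM_DECISION) < p[P_HUNGER_CONT]:
            direction = prev_heading
        else:
            direction = random_below(rng, STREAM_DECISION, 8)
    else:
        best_count = 0
        best_first = 1 << 30
        n_tied = 0
        for j in range(N_OUTPUT):
            c = o_counts[j]
            if c == 0:
                continue
            f = o_first[j]
            if c > best_count or (c == best_count and f < best_first):
                best_count = c
                best_first = f
                winner = j
                n_tied = 1
            elif c == best_count and f == best_first:
                n_tied += 1
        if n_tied > 1:
            # residual tie: identical count and first-spike step
            pick = random_below(rng, STREAM_DECISION, n_tied)
            for j in range(N_OUTPUT):
                if o_counts[j] == best_count and o_first[j] == best_first:
                    if pick == 0:
                        winner = j
                        break
                    pick -= 1
        if winner >= 0 and OUT_TO_DIR[winner] >= 0:
            direction = OUT_TO_DIR[winner]
        else:
            direction = prev_heading
    if random_float(rng, STREAM_DECISION) < p[P_TURN_PROB]:
        if random_float(rng, STREAM_DECISION) < 0.5:
            direction = (prev_heading + 1) % 8
        else:
            direction = (prev_heading + 7) % 8
    return direction, winner


@njit(cache=True)
def perturb_weights_kernel(p, rng, W, WI, Wj0, row_sum, level, counters):
    """Multiply each excitatory weight by U[1-level, 1+level]; rebalance."""
    in_bal = p[P_INBAL_ON] > 0.5
    for i in range(N_HIDDEN):
        for j in range(N_OUTPUT):
            W[i, j] *= random_uniform(rng, STREAM_PERTURB, 1.0 - level, 1.0 + level)
    for j in range(N_OUTPUT):
        if in_bal:
            rebalance_column_kernel(W, j, Wj0[j], counters)
        balance_inhibition_column_kernel(W, WI, j)
    refresh_row_sums(W, row_sum)


# ---------------------------------------------------------------------------
# The full epoch loop
# ---------------------------------------------------------------------------
@njit(cache=True)
def run_epochs_kernel(
    n_epochs, p, rng, food, state_i,
    x, y, xp, active, spk, s1, s2, sE, sI,
    W, WI, Wj0, w_io, row_sum, F_est, wj0_init,
    h_times, h_n, o_times, o_n,
    tr_pre, tr_post, tr_val, tr_time, tr_count, slot_epoch,
    stim, dW, touched, counters, fmetrics,
    freeze_start, freeze_end, perf,
    log_perf, log_ate, log_dir, log_nsp, log_row, log_col,
):
    """Run ``n_epochs`` full epochs; returns the number actually completed.

    Stops early (returning fewer) when the runaway-weight detector trips.
    Logs are filled per epoch from index 0.
    """
    vf = np.empty((7, 7), dtype=np.uint8)
    o_counts = np.empty(N_OUTPUT, dtype=np.int64)
    o_first = np.empty(N_OUTPUT, dtype=np.int64)
    decision_steps = int(p[P_DECISION_STEPS])
    validate = p[P_VALIDATE] > 0.5
    in_bal = p[P_INBAL_ON] > 0.5
    runaway_factor = p[P_RUNAWAY_FACTOR]

    for n in range(n_epochs):
        if state_i[SI_HALTED] == 1:
            return n
        ep = state_i[SI_EPOCH]
        frozen = False
        for fw in range(freeze_start.shape[0]):
            if freeze_start[fw] <= ep < freeze_end[fw]:
                frozen = True
        learning = (p[P_LEARNING_ON] > 0.5) and not frozen

        # --- encode: stimulate the input cells whose visual-field cell has food
        visual_field_kernel(food, state_i[SI_ROW], state_i[SI_COL], vf)
        for ii in range(N_INPUT):
            stim[ii] = False
        for r7 in range(7):
            for c7 in range(7):
                idx = r7 * 7 + c7
                if idx != CENTER_INPUT and vf[r7, c7] == 1:
                    stim[idx] = True
                    active[idx] = True

        # --- simulate the decision window
        total_o = simulate_decision_window(
            p, rng, x, y, xp, active, spk, s1, s2, sE, sI, W, WI, stim,
            h_times, h_n, o_times, o_n,
        )

        # --- store this epoch's STDP traces
        slot = ep % TRACE_RING
        if learning:
            tr_count[slot] = 0
            slot_epoch[slot] = ep
            if total_o > 0:
                detect_traces_kernel(
                    p, W, h_times, h_n, o_times, o_n, ep * p[P_EPOCH_STEPS],
                    tr_pre, tr_post, tr_val, tr_time, tr_count, slot, counters,
                )
        else:
            tr_count[slot] = 0
            slot_epoch[slot] = -1

        # --- decide and move
        for j in range(N_OUTPUT):
            o_counts[j] = o_n[j]
            o_first[j] = o_times[j, 0] if o_n[j] > 0 else (1 << 30)
        direction, _ = decide_move_kernel(
            p, rng, o_counts, o_first, state_i[SI_HEADING], state_i[SI_HUNGER] == 1
        )
        r, c, ate = move_entity_kernel(
            food, state_i[SI_ROW], state_i[SI_COL], direction, p[P_VBIAS], rng
        )
        state_i[SI_ROW] = r
        state_i[SI_COL] = c
        state_i[SI_HEADING] = direction

        # --- hunger bookkeeping
        if ate:
            state_i[SI_SINCE_FOOD] = 0
            state_i[SI_HUNGER] = 0
        else:
            state_i[SI_SINCE_FOOD] += 1
            if state_i[SI_SINCE_FOOD] >= int(p[P_HUNGER_THRESH]):
                state_i[SI_HUNGER] = 1

        # --- performance EMA
        A = p[P_EMA_A]
        perf[0] = (1.0 - A) * perf[0] + (A if ate else 0.0)

        # --- plasticity
        if learning:
            reward = ate
            if p[P_REVERSED] > 0.5:
                reward = not ate
            if p[P_FORCE_REWARD] > 0.5:
                reward = True
            if reward or p[P_PUNISH_ON] > 0.5:
                apply_reward_kernel(
                    p, W, WI, Wj0, w_io, row_sum,
                    tr_pre, tr_post, tr_val, tr_time, tr_count, slot_epoch,
                    ep, reward, dW, touched, counters,
                )
            homeostasis_kernel(p, W, WI, Wj0, F_est, o_n, wj0_init, counters)
            # Runaway guard: with input balancing a weight can never exceed its
            # column target, so crossing runaway_factor x W_j0 flags the
            # unstable (unbalanced) regime.
            for j in range(N_OUTPUT):
                limit = runaway_factor * Wj0[j]
                for i in range(N_HIDDEN):
                    if W[i, j] > limit:
                        state_i[SI_HALTED] = 1
            if validate:
                for j in range(N_OUTPUT):
                    col = 0.0
                    coli = 0.0
                    for i in range(N_HIDDEN):
                        col += W[i, j]
                        coli += WI[i, j]
                    if in_bal:
                        dev = abs(col - Wj0[j]) / Wj0[j]
                        if dev > fmetrics[0]:
                            fmetrics[0] = dev
                        if dev > 1e-9:
                            counters[C_VIOLATIONS] += 1
                    if col > 0.0:
                        devi = abs(coli - col) / col
                        if devi > fmetrics[1]:
                            fmetrics[1] = devi
                        if devi > 1e-9:
                            counters[C_VIOLATIONS] += 1

        # --- logs
        log_perf[n] = perf[0]
        log_ate[n] = 1 if ate else 0
        log_dir[n] = direction
        log_nsp[n] = total_o
        log_row[n] = r
        log_col[n] = c
        state_i[SI_EPOCH] = ep + 1
    return n_epochs
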