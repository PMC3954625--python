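"""The four non-learning reference foraging strategies.

These are pre-programmed yardsticks against which the learning network's
food-acquisition rate is compared; they share the environment, movement
rules and logging with the neural agent but never learn:

1. **Blind** — move in a straight line; each epoch there is a 2% chance the
   heading rotates 45 degrees (left/right equiprobable).
2. **Adjacent** — if any of the 8 neighbouring cells holds food, move onto
   one of them (uniformly); otherwise behave as Strategy 1.
3. **Nearest** — if food is visible in the 7x7 field, step toward one of
   the closest particles (Chebyshev distance, ties uniform); otherwise
   Strategy 1.
4. **Planner** — if food is visible, exhaustively evaluate all length-5
   move sequences confined to the visual field (food is consumed along the
   simulated path), and make the first move of a sequence collecting the
   most food, preferring earlier pickups; ties among optimal sequences are
   broken uniformly.  Otherwise Strategy 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._rng import STREAM_INIT, STREAM_STRATEGY, make_state, random_below, random_float
from .env import DIR_DC, DIR_DR, GridWorld, FoodDistribution, init_food, move_entity_kernel

VISUAL_RADIUS = 3
PLAN_DEPTH = 5


@dataclass
class StrategyState:
    """Heading memory of a reference-strategy agent."""

    heading: int = 0


# ---------------------------------------------------------------------------
# Per-step direction kernels
# ---------------------------------------------------------------------------
@njit(cache=True)
def strategy1_kernel(heading, turn_prob, rng):
    """Straight-line motion with an occasional 45-degree turn."""
    if random_float(rng, STREAM_STRATEGY) < turn_prob:
        if random_float(rng, STREAM_STRATEGY) < 0.5:
            return (heading + 1) % 8
        return (heading + 7) % 8
    return heading


@njit(cache=True)
def strategy2_kernel(food, row, col, heading, turn_prob, rng):
    """Move onto an adjacent food cell when one exists, else Strategy 1."""
    height, width = food.shape
    n_adj = 0
    for d in range(8):
        r = (row + DIR_DR[d]) % height
        c = (col + DIR_DC[d]) % width
        if food[r, c] > 0:
            n_adj += 1
    if n_adj > 0:
        k = random_below(rng, STREAM_STRATEGY, n_adj)
        for d in range(8):
            r = (row + DIR_DR[d]) % height
            c = (col + DIR_DC[d]) % width
            if food[r, c] > 0:
                if k == 0:
                    return d
                k -= 1
    return strategy1_kernel(heading, turn_prob, rng)


@njit(cache=True)
def strategy3_kernel(food, row, col, heading, turn_prob, rng):
    """Step toward one of the closest visible food cells, else Strategy 1.

    Closeness is Chebyshev distance (matching 8-way moves); the target among
    equally close particles, and the step among equally reducing directions,
    are chosen uniformly.
    """
    height, width = food.shape
    best = 99
    n_best = 0
    for dr in range(-VISUAL_RADIUS, VISUAL_RADIUS + 1):
        for dc in range(-VISUAL_RADIUS, VISUAL_RADIUS + 1):
            if dr == 0 and dc == 0:
                continue
            if food[(row + dr) % height, (col + dc) % width] > 0:
                dist = max(abs(dr), abs(dc))
                if dist < best:
                    best = dist
                    n_best = 1
                elif dist == best:
                    n_best += 1
    if n_best == 0:
        return strategy1_kernel(heading, turn_prob, rng)
    k = random_below(rng, STREAM_STRATEGY, n_best)
    tr = 0
    tc = 0
    for dr in range(-VISUAL_RADIUS, VISUAL_RADIUS + 1):
        for dc in range(-VISUAL_RADIUS, VISUAL_RADIUS + 1):
            if dr == 0 and dc == 0:
                continue
            if food[(row + dr) % height, (col + dc) % width] > 0:
                if max(abs(dr), abs(dc)) == best:
                    if k == 0:
                        tr = dr
                        tc = dc
                        k = -1
                    else:
                        k -= 1
    # 8-way step minimising the remaining Chebyshev distance to the target.
    best_rem = 99
    n_dirs = 0
    for d in range(8):
        rem = max(abs(tr - DIR_DR[d]), abs(tc - DIR_DC[d]))
        if rem < best_rem:
            best_rem = rem
            n_dirs = 1
        elif rem == best_rem:
            n_dirs += 1
    k = random_below(rng, STREAM_STRATEGY, n_dirs)
    for d in range(8):
        if max(abs(tr - DIR_DR[d]), abs(tc - DIR_DC[d])) == best_rem:
            if k == 0:
                return d
            k -= 1
    return heading  # unreachable


@njit(cache=True)
def _plan_better(count_a, times_a, count_b, times_b):
    """True if plan A beats plan B: more food, then earlier pickups."""
    if count_a != count_b:
        return count_a > count_b
    for k in range(count_a):
        if times_a[k] != times_b[k]:
            return times_a[k] < times_b[k]
    return False


@njit(cache=True)
def strategy4_plan(local, first_counts):
    """Exhaustive depth-5 search over the 7x7 window with incremental eating.

    ``local`` is the 7x7 food window (centre = entity, no food) and is
    restored on exit.  ``first_counts[d]`` receives the number of optimal
    sequences starting with move ``d``; the return value is the food count
    of an optimal sequence (-1 if no valid sequence exists, which cannot
    happen from the centre).  Sequences that would leave the window are
    disallowed.  Subtrees that cannot reach the current best count are
    pruned, which never affects the set of optimal sequences.
    """
    for d in range(8):
        first_counts[d] = 0
    best_count = -1
    best_times = np.zeros(PLAN_DEPTH, dtype=np.int64)
    times = np.zeros(PLAN_DEPTH, dtype=np.int64)
    pos_r = np.zeros(PLAN_DEPTH + 1, dtype=np.int64)
    pos_c = np.zeros(PLAN_DEPTH + 1, dtype=np.int64)
    ate = np.zeros(PLAN_DEPTH, dtype=np.bool_)
    moves = np.zeros(PLAN_DEPTH, dtype=np.int64)
    pos_r[0] = VISUAL_RADIUS
    pos_c[0] = VISUAL_RADIUS
    depth = 0
    n_eaten = 0
    moves[0] = 0
    while depth >= 0:
        if moves[depth] >= 8:
            # backtrack
            depth -= 1
            if depth >= 0:
                if ate[depth]:
                    local[pos_r[depth + 1], pos_c[depth + 1]] = 1
                    n_eaten -= 1
                moves[depth] += 1
            continue
        d = moves[depth]
        r = pos_r[depth] + DIR_DR[d]
        c = pos_c[depth] + DIR_DC[d]
        if r < 0 or r > 6 or c < 0 or c > 6:
            moves[depth] += 1
            continue
        # prune: even eating on every remaining step cannot beat the best
        if n_eaten + (PLAN_DEPTH - depth) < best_count:
            moves[depth] += 1
            continue
        got = local[r, c] == 1
        if got:
            local[r, c] = 0
            times[n_eaten] = depth
            n_eaten += 1
        ate[depth] = got
        pos_r[depth + 1] = r
        pos_c[depth + 1] = c
        if depth == PLAN_DEPTH - 1:
            # leaf: compare with the best plan so far
            if best_count < 0 or _plan_better(n_eaten, times, best_count, best_times):
                best_count = n_eaten
                for k in range(n_eaten):
                    best_times[k] = times[k]
                for dd in range(8):
                    first_counts[dd] = 0
                first_counts[moves[0]] = 1
            elif n_eaten == best_count and not _plan_better(
                best_count, best_times, n_eaten, times
            ):
                first_counts[moves[0]] += 1
            if got:
                local[r, c] = 1
                n_eaten -= 1
            moves[depth] += 1
        else:
            depth += 1
            moves[depth] = 0
    return best_count


@njit(cache=True)
def strategy4_kernel(food, row, col, heading, turn_prob, rng, local, first_counts):
    """First move of an optimal 5-step plan, else Strategy 1 when no food seen."""
    height, width = food.shape
    seen = False
    for i in range(7):
        for j in range(7):
            v = 1 if food[(row + i - VISUAL_RADIUS) % height, (col + j - VISUAL_RADIUS) % width] > 0 else 0
            if i == VISUAL_RADIUS and j == VISUAL_RADIUS:
                v = 0
            local[i, j] = v
            if v == 1:
                seen = True
    if not seen:
        return strategy1_kernel(heading, turn_prob, rng)
    strategy4_plan(local, first_counts)
    total = 0
    for d in range(8):
        total += first_counts[d]
    k = random_below(rng, STREAM_STRATEGY, total)
    for d in range(8):
        if k < first_counts[d]:
            return d
        k -= first_counts[d]
    return heading  # unreachable


# ---------------------------------------------------------------------------
# Long-run driver
# ---------------------------------------------------------------------------
@njit(cache=True)
def run_strategy_kernel(
    strategy, n_moves, food, start_row, start_col, start_heading,
    turn_prob, override_prob, vertical_bias, ema_a, rng, log_ate, log_perf,
):
    """Run one strategy for ``n_moves`` moves; returns total food eaten.

    On top of the strategy's own choice, every move carries the global
    ``override_prob`` chance (present in all conditions, learning or not)
    that the move is replaced by a 45-degree turn off the previous heading.
    """
    row = start_row
    col = start_col
    heading = start_heading
    local = np.zeros((7, 7), dtype=np.uint8)
    first_counts = np.zeros(8, dtype=np.int64)
    perf = 0.0
    eaten = 0
    for n in range(n_moves):
        if strategy == 1:
            d = strategy1_kernel(heading, turn_prob, rng)
        elif strategy == 2:
            d = strategy2_kernel(food, row, col, heading, turn_prob, rng)
        elif strategy == 3:
            d = strategy3_kernel(food, row, col, heading, turn_prob, rng)
        else:
            d = strategy4_kernel(food, row, col, heading, turn_prob, rng, local, first_counts)
        if random_float(rng, STREAM_STRATEGY) < override_prob:
            if random_float(rng, STREAM_STRATEGY) < 0.5:
                d = (heading + 1) % 8
            else:
                d = (heading + 7) % 8
        row, col, ate = move_entity_kernel(food, row, col, d, vertical_bias, rng)
        heading = d
        if ate:
            eaten += 1
        perf = (1.0 - ema_a) * perf + (ema_a if ate else 0.0)
        log_ate[n] = 1 if ate else 0
        log_perf[n] = perf
    return eaten


# ---------------------------------------------------------------------------
# Python surface
# ---------------------------------------------------------------------------
def _step(world: GridWorld, state: StrategyState, rng_state, strategy: int,
          turn_prob: float = 0.02) -> int:
    scratch = np.zeros((7, 7), dtype=np.uint8)
    counts = np.zeros(8, dtype=np.int64)
    if strategy == 1:
        d = strategy1_kernel(state.heading, turn_prob, rng_state)
    elif strategy == 2:
        d = strategy2_kernel(world.food, world.entity_row, world.entity_col,
                             state.heading, turn_prob, rng_state)
    elif strategy == 3:
        d = strategy3_kernel(world.food, world.entity_row, world.entity_col,
                             state.heading, turn_prob, rng_state)
    elif strategy == 4:
        d = strategy4_kernel(world.food, world.entity_row, world.entity_col,
                             state.heading, turn_prob, rng_state, scratch, counts)
    else:
        raise ValueError(f"strategy must be 1..4, got {strategy}")
    return int(d)


def strategy1_step(world, state, rng_state, turn_prob: float = 0.02) -> int:
    return _step(world, state, rng_state, 1, turn_prob)


def strategy2_step(world, state, rng_state, turn_prob: float = 0.02) -> int:
    return _step(world, state, rng_state, 2, turn_prob)


def strategy3_step(world, state, rng_state, turn_prob: float = 0.02) -> int:
    return _step(world, state, rng_state, 3, turn_prob)


def strategy4_step(world, state, rng_state, turn_prob: float = 0.02) -> int:
    return _step(world, state, rng_state, 4, turn_prob)


def run_strategy(
    strategy: int,
    n_moves: int,
    seed: int,
    dist: FoodDistribution | None = None,
    width: int = 50,
    height: int = 50,
    turn_prob: float = 0.02,
    override_prob: float = 0.02,
    ema_a: float = 0.00001,
) -> dict:
    """Simulate one reference strategy in a fresh environment.

    ``override_prob`` is the global random-turn chance applied after the
    strategy's choice on every move, exactly as for the neural agent.
    Returns a dict with the per-move ``ate`` flags, the performance EMA
    trace, the total eaten and the mean acquisition rate per move.
    """
    if strategy not in (1, 2, 3, 4):
        raise ValueError(f"strategy must be 1..4, got {strategy}")
    dist = dist or FoodDistribution()
    rng = make_state(seed)
    world = GridWorld(width=width, height=height)
    init_food(world, dist, rng)
    row = random_below(rng, STREAM_INIT, height)
    col = random_below(rng, STREAM_INIT, width)
    heading = random_below(rng, STREAM_INIT, 8)
    log_ate = np.zeros(n_moves, dtype=np.uint8)
    log_perf = np.zeros(n_moves, dtype=np.float64)
    eaten = run_strategy_kernel(
        strategy, n_moves, world.food, row, col, heading,
        turn_prob, override_prob, dist.vertical_bias, ema_a, rng, log_ate, log_perf,
    )
    return {
        "strategy": strategy,
        "ate": log_ate,
        "performance": log_perf,
        "eaten": int(eaten),
        "rate": float(eaten) / n_moves,
    }
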