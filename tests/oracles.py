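"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's algorithms: the visual field is a
literal 49-offset scan, STDP pairing is a per-event eligibility scan, and
the 5-move planner re-simulates every one of the 8^5 sequences from scratch.
"""

from itertools import product

import numpy as np

DIRS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
# order: N NE E SE S SW W NW (matches the package's direction indices)


def brute_visual_field(food, row, col):
    """Scan all 49 offsets with explicit toroidal wrapping."""
    h, w = food.shape
    out = np.zeros((7, 7), dtype=bool)
    for i in range(7):
        for j in range(7):
            if i == 3 and j == 3:
                continue
            out[i, j] = food[(row + i - 3) % h, (col + j - 3) % w] > 0
    return out


def naive_stdp_pairs(pre, post):
    """All (kind, t_first, t_second) pairings under nearest-with-suppression.

    A post spike at tp creates a pre-before-post event with the latest pre
    at t_r <= tp, provided no other post occurred in [t_r, tp) (i.e. tp is
    the first post at or after that pre).  Symmetrically, a pre spike at t_r
    creates a post-before-pre event with the latest post at t_p < t_r,
    provided no other pre occurred in (t_p, t_r).  Simultaneous spikes count
    as pre-before-post.
    """
    pre = sorted(pre)
    post = sorted(post)
    events = []
    for tp in post:
        cands = [t for t in pre if t <= tp]
        if not cands:
            continue
        tr = max(cands)
        if any(tr <= q < tp for q in post):
            continue
        events.append(("pre_before_post", tr, tp))
    for tr in pre:
        cands = [t for t in post if t < tr]
        if not cands:
            continue
        tp = max(cands)
        if any(tp < q < tr for q in pre):
            continue
        events.append(("post_before_pre", tp, tr))
    return sorted(events, key=lambda e: (e[2], e[0]))


def brute_force_plans(local):
    """Evaluate all 8^5 move sequences on a 7x7 field by full re-simulation.

    Returns (best_count, best_times, first_counts) where first_counts[d] is
    the number of optimal sequences whose first move is d.  Sequences
    leaving the 7x7 window are invalid.
    """
    best_key = None
    firsts = np.zeros(8, dtype=np.int64)
    for seq in product(range(8), repeat=5):
        grid = local.copy()
        r = c = 3
        times = []
        ok = True
        for step, d in enumerate(seq):
            r += DIRS[d][0]
            c += DIRS[d][1]
            if not (0 <= r <= 6 and 0 <= c <= 6):
                ok = False
                break
            if grid[r, c]:
                grid[r, c] = 0
                times.append(step)
        if not ok:
            continue
        key = (-len(times), tuple(times))
        if best_key is None or key < best_key:
            best_key = key
            firsts[:] = 0
            firsts[seq[0]] = 1
        elif key == best_key:
            firsts[seq[0]] += 1
    return -best_key[0], list(best_key[1]), firsts
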