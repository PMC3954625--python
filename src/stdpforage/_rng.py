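"""Deterministic counter-based random streams usable inside numba kernels.

The simulation keeps several named, mutually independent random streams
(environment, synaptic release noise, decision tie-breaks, weight
perturbations, ...) so that switching one model feature on or off never
shifts the random draws consumed by the others.  numpy ``Generator`` objects
cannot be used inside ``nopython`` kernels, so the streams are built on
splitmix64, a well-studied 64-bit mixing function; each stream is a single
``uint64`` counter cell in a shared state array.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Stream indices into the shared state vector.
STREAM_ENV = 0        # food placement and relocation
STREAM_RELEASE = 1    # synaptic release noise
STREAM_DECISION = 2   # tie-breaks, random turns, hunger turns
STREAM_PERTURB = 3    # weight perturbation experiments
STREAM_INIT = 4       # initial position / heading
STREAM_STRATEGY = 5   # reference-strategy choices
N_STREAMS = 6

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)
_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True)
def next_uint64(state: np.ndarray, stream: int) -> np.uint64:
    """Advance ``stream`` and return a mixed 64-bit word (splitmix64)."""
    state[stream] = state[stream] + _GOLDEN
    z = state[stream]
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def random_float(state: np.ndarray, stream: int) -> float:
    """Uniform double in [0, 1)."""
    return float(next_uint64(state, stream) >> np.uint64(11)) * _INV53


@njit(cache=True)
def random_below(state: np.ndarray, stream: int, n: int) -> int:
    """Uniform integer in [0, n).  n must be positive and small (<< 2**32)."""
    return np.int64(next_uint64(state, stream) % np.uint64(n))


@njit(cache=True)
def random_uniform(state: np.ndarray, stream: int, lo: float, hi: float) -> float:
    return lo + (hi - lo) * random_float(state, stream)


def make_state(seed: int) -> np.ndarray:
    """Seed all named streams from one master seed.

    Each stream starts from an independent splitmix64 trajectory obtained by
    mixing the master seed with the stream index, so streams never overlap.
    """
    if not 0 <= int(seed) < 2**63:
        raise ValueError(f"seed must be a non-negative 63-bit integer, got {seed}")
    mask = (1 << 64) - 1
    state = np.empty(N_STREAMS, dtype=np.uint64)
    for i in range(N_STREAMS):
        z = (int(seed) + (i + 1) * 0x9E3779B97F4A7C15 * 0x5851F42D) & mask
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        state[i] = z ^ (z >> 31)
    return state
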