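"""Map-based spiking neuron and first-order synapse kinetics.

The neuron is the two-dimensional difference-equation (map) model with a
fast membrane variable ``x`` and a slow variable ``y``; one iteration
represents ~0.5 ms.  The fast equation applies a piecewise nonlinearity with
an explicit reset branch (the spike), and the slow variable drifts with a
small rate ``mu``:

    x[n+1] = f(x[n], x[n-1], y[n] + beta_e * I[n])
    y[n+1] = y[n] - mu * (x[n] + 1) + mu * sigma + mu * sigma_e * I[n]

    f(x, x_prev, u) = alpha / (1 - x) + u      if x <= 0
                      alpha + u                if 0 < x < alpha + u and x_prev <= 0
                      -1  (reset; spike)       otherwise

With ``sigma`` below the spiking threshold the model rests at the stable
fixed point x* = sigma - 1; above it, it fires tonically at a rate that
grows with the resting level and with injected current.

Synapses follow first-order kinetics in difference form: the gating variable
``s`` relaxes geometrically (factor ``gamma`` per step) and, on a
presynaptic spike, jumps by weight x a where the amplitude factor ``a`` is
drawn uniformly from [1 - R, 1 + R] (release noise, standard R = 0.16).  The
synaptic current is -s * (v_post - v_rev); the reversal potential ``v_rev``
alone distinguishes excitatory from inhibitory synapses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._rng import STREAM_RELEASE, random_uniform
from .config import NeuronConfig

NeuronParams = NeuronConfig  # the config section doubles as the parameter record


@dataclass
class NeuronState:
    """Fast/slow map variables of one spiking unit.

    ``x_prev`` is carried because the middle branch of the nonlinearity
    depends on the previous fast value; ``spiked`` flags the reset branch.
    """

    x: float
    y: float
    x_prev: float = 0.0
    spiked: bool = False

    @classmethod
    def resting(cls, params: NeuronParams) -> "NeuronState":
        return cls(x=params.x_rest, y=params.y_rest, x_prev=params.x_rest)


@dataclass
class SynapseState:
    """Weight, gating variable and kinetic constants of one synapse."""

    weight: float
    gamma: float = 0.8
    v_rev: float = 0.0
    release_noise: float = 0.16
    s: float = 0.0


@njit(cache=True)
def step_neuron_kernel(x, y, x_prev, alpha, mu, sigma, beta_e, sigma_e, i_ext):
    """One map iteration.  Returns (x_new, y_new, spiked)."""
    u = y + beta_e * i_ext
    spiked = False
    if x <= 0.0:
        x_new = alpha / (1.0 - x) + u
    elif x < alpha + u and x_prev <= 0.0:
        x_new = alpha + u
    else:
        x_new = -1.0
        spiked = True
    y_new = y - mu * (x + 1.0) + mu * sigma + mu * sigma_e * i_ext
    return x_new, y_new, spiked


def step_neuron(state: NeuronState, params: NeuronParams, i_ext: float = 0.0) -> NeuronState:
    """Advance one neuron one time step under summed synaptic current ``i_ext``."""
    x_new, y_new, spiked = step_neuron_kernel(
        state.x, state.y, state.x_prev,
        params.alpha, params.mu, params.sigma, params.beta_e, params.sigma_e,
        i_ext,
    )
    return NeuronState(x=x_new, y=y_new, x_prev=state.x, spiked=spiked)


def step_synapse(syn: SynapseState, pre_spiked: bool, rng_state: np.ndarray) -> SynapseState:
    """Advance the gating variable: jump on a presynaptic spike, else decay."""
    if pre_spiked:
        r = syn.release_noise
        a = random_uniform(rng_state, STREAM_RELEASE, 1.0 - r, 1.0 + r) if r > 0 else 1.0
        s_new = syn.s + syn.weight * a
    else:
        s_new = syn.gamma * syn.s
    return SynapseState(
        weight=syn.weight, gamma=syn.gamma, v_rev=syn.v_rev,
        release_noise=syn.release_noise, s=s_new,
    )


def synaptic_current(syn: SynapseState, v_post: float) -> float:
    """Current injected into the postsynaptic cell: -s * (v_post - v_rev)."""
    return -syn.s * (v_post - syn.v_rev)


def to_millivolts(x: float | np.ndarray, params: NeuronParams):
    """Affine map from the dimensionless membrane variable to physiological mV."""
    return params.v_scale * x + params.v_offset


def simulate_neuron(
    params: NeuronParams,
    n_steps: int,
    i_ext: float | np.ndarray = 0.0,
    state: NeuronState | None = None,
):
    """Run an isolated neuron; returns (x trace, spike-step indices).

    ``i_ext`` may be a scalar (constant current) or a per-step array.
    """
    if state is None:
        state = NeuronState.resting(params)
    drive = np.broadcast_to(np.asarray(i_ext, dtype=np.float64), (n_steps,))
    xs = np.empty(n_steps, dtype=np.float64)
    spikes = []
    for n in range(n_steps):
        state = step_neuron(state, params, drive[n])
        xs[n] = state.x
        if state.spiked:
            spikes.append(n)
    return xs, np.array(spikes, dtype=np.int64)
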