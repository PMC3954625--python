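"""Rewarded STDP with synaptic balancing and homeostatic scaling.

The learning rule operates on the dense excitatory projection from the 49
hidden cells onto the 9 output cells.  It has five interacting parts:

* **Trace creation** — a pre/post spike pairing between hidden cell ``i``
  and output cell ``j`` creates an eligibility trace with value
  ``vE = k * S * exp(-dt / T_c)`` where ``S`` is the current weight,
  ``k = k_plus`` for pre-before-post and ``k_minus`` for post-before-pre,
  under a nearest-pairing rule with suppression: after a pre spike only the
  first following post spike creates an event (and symmetrically).
* **Reward / punishment** — traces are stored, not applied.  Every move
  triggers either a reward (food obtained) or a punishment; each trace that
  is at most ``trace_epochs`` epochs old then contributes
  ``S_rp * vE * exp(-(t_re - t_created) / T_e)`` to its weight.
* **Output balancing** — the reward scale of presynaptic cell ``i`` is
  ``S_c * W_io / W_i``, inversely proportional to its current total
  outgoing strength, creating competition among a cell's outputs.  The
  punishment scale is the constant ``punish_fraction * S_c`` and applies the
  sign-flipped trace.
* **Input balancing** — after any weight change, all 49 excitatory weights
  into the touched output cell are multiplied by a common scale factor so
  their sum equals the homeostatic target ``W_j0``.
* **Homeostatic scaling** — once per epoch, ``W_j0`` moves opposite to the
  error between an exponential estimate of the cell's firing rate and the
  target rate, and the inhibitory column (uniform by construction) is set so
  its sum equals the excitatory sum.

These functions are straightforward numpy implementations of the rule; the
training engine applies the identical arithmetic inside compiled kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .config import PlasticityConfig

PlasticityParams = PlasticityConfig  # the config section is the parameter record


class TraceKind(Enum):
    PRE_BEFORE_POST = "pre_before_post"
    POST_BEFORE_PRE = "post_before_pre"


@dataclass(frozen=True)
class StdpTrace:
    """One stored pre/post pairing event awaiting reward or expiry."""

    pre_index: int
    post_index: int
    value: float          # vE, weight-delta units
    created_at: float     # global time step of the second spike of the pair
    kind: TraceKind


@dataclass
class HomeostasisState:
    """Per-output-cell input target and firing-rate estimate."""

    w_j0: np.ndarray                      # target total excitatory input
    f_est: np.ndarray = field(default=None)  # spikes/epoch, exponential average

    def __post_init__(self) -> None:
        self.w_j0 = np.asarray(self.w_j0, dtype=np.float64)
        if self.f_est is None:
            self.f_est = np.zeros_like(self.w_j0)
        if np.any(self.w_j0 <= 0):
            raise ValueError("homeostatic targets W_j0 must be positive")


def detect_stdp_events(
    pre_spikes,
    post_spikes,
    weight: float,
    params: PlasticityParams,
    pre_index: int = 0,
    post_index: int = 0,
    epoch_start: float = 0.0,
) -> list[StdpTrace]:
    """Pair one pre and one post spike train into eligibility traces.

    Spike times are in steps within one epoch window.  Simultaneous spikes
    count as a pre-before-post pairing with dt = 0.
    """
    pre = sorted(int(t) for t in pre_spikes)
    post = sorted(int(t) for t in post_spikes)
    traces: list[StdpTrace] = []
    a = b = 0
    armed_pre = armed_post = False
    t_pre = t_post = 0
    while a < len(pre) or b < len(post):
        if b >= len(post) or (a < len(pre) and pre[a] <= post[b]):
            t = pre[a]
            a += 1
            if armed_post:
                v = params.k_minus * weight * np.exp(-(t - t_post) / params.tc_steps)
                traces.append(StdpTrace(pre_index, post_index, v, epoch_start + t,
                                        TraceKind.POST_BEFORE_PRE))
                armed_post = False
            armed_pre = True
            t_pre = t
        else:
            t = post[b]
            b += 1
            if armed_pre:
                v = params.k_plus * weight * np.exp(-(t - t_pre) / params.tc_steps)
                traces.append(StdpTrace(pre_index, post_index, v, epoch_start + t,
                                        TraceKind.PRE_BEFORE_POST))
                armed_pre = False
            armed_post = True
            t_post = t
    return traces


def output_balancing_scale(w_i: float, w_io: float, params: PlasticityParams) -> float:
    """Reward scale for a presynaptic cell with outgoing total ``w_i``.

    S_rp = S_c * W_io / W_i: cells whose outputs already grew strong are
    rewarded proportionally less.  The punishment scale is not computed here
    because it is constant (``punish_fraction * S_c``) by construction.
    """
    if w_i <= 0:
        raise ValueError(f"total outgoing weight must be positive, got {w_i}")
    return params.stdp_strength * w_io / w_i


def apply_reward_or_punish(
    traces,
    W: np.ndarray,
    reward: bool,
    t_re: float,
    params: PlasticityParams,
    homeo: HomeostasisState,
    w_io: np.ndarray,
    epoch_steps: int = 600,
    input_balancing: bool = True,
    output_balancing: bool = True,
) -> np.ndarray:
    """Commit live traces to a copy of the weight matrix and rebalance.

    ``traces`` must already be restricted to those younger than
    ``params.trace_epochs`` epochs.  Deltas are accumulated simultaneously,
    weights floored at zero, and each touched column rebalanced to its
    homeostatic target.  Returns the new weight matrix.
    """
    W = np.array(W, dtype=np.float64, copy=True)
    row_sum = W.sum(axis=1)
    dW = np.zeros_like(W)
    touched = np.zeros(W.shape[1], dtype=bool)
    for tr in traces:
        decay = np.exp(-(t_re - tr.created_at) / epoch_steps)
        if reward:
            if output_balancing:
                s_rp = output_balancing_scale(row_sum[tr.pre_index], w_io[tr.pre_index], params)
            else:
                s_rp = params.stdp_strength
        else:
            s_rp = -params.punish_fraction * params.stdp_strength
        dW[tr.pre_index, tr.post_index] += s_rp * tr.value * decay
        touched[tr.post_index] = True
    W = np.clip(W + dW, 0.0, None)
    for j in np.flatnonzero(touched):
        if input_balancing:
            W[:, j] = rebalance_inputs(W[:, j], homeo.w_j0[j])
    return W


def homeostatic_update(
    homeo: HomeostasisState,
    spikes_this_epoch: np.ndarray,
    params: PlasticityParams,
    w_j0_init: float,
) -> HomeostasisState:
    """Once-per-epoch update of the firing estimate and the input target.

    Cells firing below target grow their target total input; cells firing
    above it shrink it.  The target is floored at a small fraction of its
    initial value.
    """
    f = (1.0 - params.ema_rate) * homeo.f_est + params.ema_rate * np.asarray(spikes_this_epoch)
    w = homeo.w_j0 + params.eta_homeo * w_j0_init * (params.f_target - f)
    w = np.maximum(w, params.w_j0_min_fraction * w_j0_init)
    return HomeostasisState(w_j0=w, f_est=f)


def rebalance_inputs(column: np.ndarray, w_j0: float) -> np.ndarray:
    """Multiplicatively rescale an excitatory input column to sum to ``w_j0``.

    The common scale factor S_f = W_j0 / sum preserves the ratios among all
    49 incoming weights.
    """
    column = np.asarray(column, dtype=np.float64)
    total = column.sum()
    if total <= 0:
        raise ValueError("cannot rebalance a column with non-positive sum")
    return column * (w_j0 / total)


def balance_inhibition(wi_column: np.ndarray, w_column: np.ndarray) -> np.ndarray:
    """Uniform inhibitory column whose sum equals the excitatory column sum."""
    n = len(wi_column)
    return np.full(n, np.asarray(w_column, dtype=np.float64).sum() / n)
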