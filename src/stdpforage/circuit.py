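"""Network architecture, epoch protocol, input encoding and move decoding.

The network has 156 map-based cells in three feedforward layers: a 7x7
input layer, one excitatory and one inhibitory 7x7 hidden layer, and a 3x3
output layer.  Input cells connect one-to-one to their excitatory and
inhibitory hidden counterparts; both hidden populations project densely
(49 x 9) onto the output layer, giving each output cell balanced
feedforward excitation and inhibition.  Each output cell maps to one of the
8 compass directions; the centre cell maps to "continue current heading".

An epoch is 600 time steps (~300 ms): stimulated input cells receive a
suprathreshold current pulse at the start, output spikes are counted over
the first half, the move is executed at the half-epoch point, and the rest
is a cooling-off period returning the network to rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine as eng
from ._rng import make_state
from .config import RunConfig, pack_params
from .env import DIRECTION_NAMES  # noqa: F401  (re-export for decoding logs)

CENTER_INPUT = eng.CENTER_INPUT
CENTER_OUTPUT = 4
OUT_TO_DIR = eng.OUT_TO_DIR


@dataclass
class HungerState:
    """Tracks the foodless-epoch count and the hunger override flag.

    Hunger activates after ``threshold`` consecutive epochs without food and
    persists until the entity next eats; while active, movement ignores the
    network outputs (continue heading with high probability, occasionally a
    random new direction).
    """

    threshold: int = 100
    epochs_since_food: int = 0
    active: bool = False

    def update(self, ate: bool) -> None:
        if ate:
            self.epochs_since_food = 0
            self.active = False
        else:
            self.epochs_since_food += 1
            if self.epochs_since_food >= self.threshold:
                self.active = True


@dataclass
class EpochResult:
    """Output-layer activity summary for one epoch."""

    spike_counts: np.ndarray       # spikes per output cell, decision window
    first_spike_step: np.ndarray   # step of first spike, -1 if silent
    total_spikes: int
    hidden_spike_times: list       # per hidden cell, spike steps (for plasticity)
    output_spike_times: list


@dataclass
class NetworkState:
    """All mutable state of the 156-cell network plus its weights.

    ``W`` is the plastic excitatory hidden->output matrix (49 x 9, always
    non-negative); ``WI`` the inhibitory matrix, uniform within each column
    with column sums tied to ``W``.  ``w_j0`` holds the homeostatic input
    targets and ``w_io`` the fixed initial outgoing totals used by output
    balancing.
    """

    config: RunConfig
    params: np.ndarray = field(default=None)
    rng: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        cfg = self.config
        if self.params is None:
            self.params = pack_params(cfg)
        if self.rng is None:
            self.rng = make_state(cfg.seed)
        x_rest = cfg.neuron.x_rest
        y_rest = cfg.neuron.y_rest
        self.x = np.full(eng.N_CELLS, x_rest)
        self.y = np.full(eng.N_CELLS, y_rest)
        self.xp = np.full(eng.N_CELLS, x_rest)
        self.active = np.zeros(eng.N_CELLS, dtype=np.bool_)
        self.spk = np.zeros(eng.N_CELLS, dtype=np.bool_)
        self.s1 = np.zeros(eng.N_HIDDEN)
        self.s2 = np.zeros(eng.N_HIDDEN)
        self.sE = np.zeros(eng.N_OUTPUT)
        self.sI = np.zeros(eng.N_OUTPUT)
        w0 = cfg.circuit.w_init
        self.W = np.full((eng.N_HIDDEN, eng.N_OUTPUT), w0)
        self.WI = np.full((eng.N_HIDDEN, eng.N_OUTPUT), w0)
        self.w_j0_init = float(eng.N_HIDDEN * w0)
        self.w_j0 = np.full(eng.N_OUTPUT, self.w_j0_init)
        self.w_io = self.W.sum(axis=1).copy()      # fixed at initial values
        self.row_sum = self.W.sum(axis=1)
        self.f_est = np.zeros(eng.N_OUTPUT)
        self.h_times = np.zeros((eng.N_HIDDEN, eng.MAX_H_SPIKES), dtype=np.int64)
        self.h_n = np.zeros(eng.N_HIDDEN, dtype=np.int64)
        self.o_times = np.zeros((eng.N_OUTPUT, eng.MAX_O_SPIKES), dtype=np.int64)
        self.o_n = np.zeros(eng.N_OUTPUT, dtype=np.int64)
        self.tr_pre = np.zeros((eng.TRACE_RING, eng.TRACE_CAP), dtype=np.int64)
        self.tr_post = np.zeros((eng.TRACE_RING, eng.TRACE_CAP), dtype=np.int64)
        self.tr_val = np.zeros((eng.TRACE_RING, eng.TRACE_CAP))
        self.tr_time = np.zeros((eng.TRACE_RING, eng.TRACE_CAP))
        self.tr_count = np.zeros(eng.TRACE_RING, dtype=np.int64)
        self.slot_epoch = np.full(eng.TRACE_RING, -1, dtype=np.int64)
        self.stim = np.zeros(eng.N_INPUT, dtype=np.bool_)
        self.dW = np.zeros((eng.N_HIDDEN, eng.N_OUTPUT))
        self.touched = np.zeros(eng.N_OUTPUT, dtype=np.bool_)
        self.counters = np.zeros(8, dtype=np.int64)
        self.fmetrics = np.zeros(4)

    @property
    def n_cells(self) -> int:
        return eng.N_CELLS


def encode_input(field_7x7: np.ndarray) -> np.ndarray:
    """Map a 7x7 visual field to the 49-cell stimulation plan.

    Input cell ``i = r*7 + c`` is stimulated iff the visual-field cell at
    relative offset ``(r-3, c-3)`` contains food.  The centre input cell
    (the entity's own position) is never stimulated, so 48 of the 49 cells
    carry a unique offset.
    """
    f = np.asarray(field_7x7)
    if f.shape != (7, 7):
        raise ValueError(f"visual field must be 7x7, got {f.shape}")
    plan = f.astype(bool).ravel().copy()
    plan[CENTER_INPUT] = False
    return plan


def run_epoch(net: NetworkState, plan: np.ndarray) -> EpochResult:
    """Simulate one epoch under the given stimulation plan.

    Output spikes are counted over the first half-epoch; by the epoch
    boundary the network is back at rest.  Spike times are returned for
    trace detection.
    """
    net.stim[:] = np.asarray(plan, dtype=bool)
    net.stim[CENTER_INPUT] = False
    net.active[: eng.N_INPUT] |= net.stim
    total = eng.simulate_decision_window(
        net.params, net.rng, net.x, net.y, net.xp, net.active, net.spk,
        net.s1, net.s2, net.sE, net.sI, net.W, net.WI, net.stim,
        net.h_times, net.h_n, net.o_times, net.o_n,
    )
    counts = net.o_n.copy()
    first = np.where(counts > 0, net.o_times[:, 0], -1)
    h_spikes = [net.h_times[i, : net.h_n[i]].copy() for i in range(eng.N_HIDDEN)]
    o_spikes = [net.o_times[j, : net.o_n[j]].copy() for j in range(eng.N_OUTPUT)]
    return EpochResult(
        spike_counts=counts,
        first_spike_step=first,
        total_spikes=int(total),
        hidden_spike_times=h_spikes,
        output_spike_times=o_spikes,
    )


def decide_move(
    res: EpochResult,
    prev_heading: int,
    hunger: HungerState,
    net: NetworkState,
) -> int:
    """Choose the move direction from an epoch's output activity.

    The cell with the most decision-window spikes wins; ties go to the
    earliest first spike (residual ties uniform).  All-silent epochs — and
    wins by the centre cell — continue the previous heading.  Active hunger
    ignores the outputs.  Independently, with the configured probability the
    final choice is replaced by a 45-degree turn.
    """
    o_first = np.where(res.spike_counts > 0, res.first_spike_step, 1 << 30).astype(np.int64)
    direction, _ = eng.decide_move_kernel(
        net.params, net.rng, res.spike_counts.astype(np.int64), o_first,
        prev_heading, hunger.active,
    )
    return int(direction)
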