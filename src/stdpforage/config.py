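"""Run configuration: every model constant in one validated, serialisable record.

The configuration is organised in sections mirroring the model components
(environment, neuron, synapse, circuit, plasticity, experiment).  A
``RunConfig`` can be round-tripped through YAML, and is flattened into a
single float64 parameter vector (:func:`pack_params`) for the compiled
simulation kernels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

# ---------------------------------------------------------------------------
# Parameter-vector layout used by the numba kernels.
# ---------------------------------------------------------------------------
(
    P_WIDTH, P_HEIGHT, P_DENSITY, P_VBIAS,
    P_ALPHA, P_MU, P_SIGMA, P_BETA_E, P_SIGMA_E,
    P_GAMMA, P_RELEASE_R, P_VREV_EXC, P_VREV_INH,
    P_EPOCH_STEPS, P_DECISION_STEPS, P_PULSE_AMP, P_PULSE_STEPS,
    P_W_INPUT, P_W_INIT, P_HUNGER_THRESH, P_TURN_PROB, P_HUNGER_CONT,
    P_K_PLUS, P_K_MINUS, P_TC_STEPS, P_TRACE_EPOCHS, P_SC, P_PUNISH_FRAC,
    P_F_TARGET, P_EMA_RATE, P_ETA_HOMEO, P_EMA_A,
    P_RUNAWAY_FACTOR, P_WJ0_MIN, P_WJ0_MAX,
    P_PUNISH_ON, P_OUTBAL_ON, P_INBAL_ON, P_LEARNING_ON, P_REVERSED,
    P_FORCE_REWARD, P_VALIDATE,
) = range(42)
N_PARAMS = 42


@dataclass
class EnvironmentConfig:
    """Grid world geometry and food distribution."""

    width: int = 50
    height: int = 50
    density: float = 0.10          # fraction of cells holding food
    vertical_bias: float = 0.0     # probability mass favouring above/below placement

    def __post_init__(self) -> None:
        if self.width < 7 or self.height < 7:
            raise ValueError("grid must be at least 7x7 to hold the visual field")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError(f"density must lie in [0, 1], got {self.density}")
        if not 0.0 <= self.vertical_bias < 1.0:
            raise ValueError(f"vertical_bias must lie in [0, 1), got {self.vertical_bias}")


@dataclass
class NeuronConfig:
    """Two-dimensional map (Rulkov) fast-spiking neuron parameters.

    ``x`` is the dimensionless membrane variable, ``y`` the slow variable;
    one map iteration represents ~0.5 ms.  ``sigma`` sets the resting level
    (rest at x* = sigma - 1 in the silent regime); ``beta_e`` and ``sigma_e``
    couple external current into the fast and slow equations.  ``v_offset``
    and ``v_scale`` give the affine map to physiological millivolts and are
    used for display only.
    """

    alpha: float = 3.65
    mu: float = 0.0005
    sigma: float = 0.06
    beta_e: float = 0.133
    sigma_e: float = 1.0
    v_scale: float = 50.0
    v_offset: float = -18.0

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu must lie in (0, 1), got {self.mu}")
        if self.alpha <= 0.0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")

    @property
    def x_rest(self) -> float:
        """Resting fixed point of the silent regime."""
        return self.sigma - 1.0

    @property
    def y_rest(self) -> float:
        return self.x_rest - self.alpha / (1.0 - self.x_rest)


@dataclass
class SynapseConfig:
    """First-order synaptic kinetics with multiplicative release noise.

    The gating variable relaxes geometrically with factor ``gamma`` per step
    and jumps by weight x a on a presynaptic spike, with the amplitude factor
    a drawn uniformly from [1 - R, 1 + R] (release noise).  ``v_rev_inh``
    defaults to the mirror image of the excitatory reversal about the resting
    potential, which makes equal excitatory and inhibitory conductance sums
    cancel exactly at rest.
    """

    gamma: float = 0.8
    release_noise: float = 0.16    # R, half-width of the amplitude jitter
    v_rev_exc: float = 0.0
    v_rev_inh: float | None = None  # None -> 2 * x_rest - v_rev_exc

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError(f"gamma must lie in [0, 1), got {self.gamma}")
        if self.release_noise < 0.0:
            raise ValueError(f"release_noise must be >= 0, got {self.release_noise}")

    def resolved_v_rev_inh(self, neuron: NeuronConfig) -> float:
        if self.v_rev_inh is not None:
            return self.v_rev_inh
        return 2.0 * neuron.x_rest - self.v_rev_exc


@dataclass
class CircuitConfig:
    """Network architecture and the epoch protocol.

    49 input cells map one-to-one onto 49 excitatory and 49 inhibitory hidden
    cells; both hidden populations project densely onto the 3x3 output layer.
    Each epoch lasts ``epoch_steps`` map iterations (~300 ms); output spikes
    are counted over the first ``decision_steps`` and the move is executed at
    that point, the remainder being a cooling-off period.
    """

    epoch_steps: int = 600
    decision_steps: int = 300
    input_pulse_amplitude: float = 1.0   # current injected into stimulated inputs
    input_pulse_steps: int = 3           # duration of the stimulation pulse
    w_input: float = 0.5                 # one-to-one I->H and I->HI weight
    w_init: float = 2.0                  # initial uniform H->O weight
    hunger_threshold: int = 100          # foodless epochs before hunger activates
    hunger_continue_prob: float = 0.98
    turn_prob: float = 0.02              # chance the decision is replaced by a 45-deg turn

    def __post_init__(self) -> None:
        if not 0 < self.decision_steps <= self.epoch_steps:
            raise ValueError("decision_steps must lie in (0, epoch_steps]")
        if not 0.0 <= self.turn_prob <= 1.0:
            raise ValueError(f"turn_prob must lie in [0, 1], got {self.turn_prob}")
        if self.w_input <= 0 or self.w_init <= 0:
            raise ValueError("synaptic weights must be positive")


@dataclass
class PlasticityConfig:
    """Rewarded STDP with output balancing, input balancing and homeostasis.

    A pre/post pairing between a hidden cell and an output cell creates a
    trace vE = k * S * exp(-dt / tc_steps) (k = +k_plus for pre-before-post,
    k_minus for post-before-pre, S the current weight).  Traces live for
    ``trace_epochs`` epochs; every reward or punishment applies each live
    trace scaled by exp(-age / epoch_steps).  Reward is scaled per presynaptic
    cell by stdp_strength * W_io / W_i (output balancing); punishment applies
    the sign-flipped traces at the constant scale punish_fraction *
    stdp_strength.  After every weight change the excitatory inputs of each
    output cell are rescaled to the homeostatic target W_j0, and the uniform
    inhibitory inputs are set so their sum matches the excitatory sum.
    """

    k_plus: float = 0.025
    k_minus: float = -0.025
    tc_steps: float = 20.0          # STDP time constant: 10 ms at 0.5 ms/step
    trace_epochs: int = 5
    stdp_strength: float = 1.0      # S_c, the sweep variable
    punish_fraction: float = 0.5
    f_target: float = 1.0           # target output firing, spikes/epoch
    ema_rate: float = 0.01          # firing-rate estimator rate
    eta_homeo: float = 0.01         # homeostatic rate, fraction of initial W_j0
    w_j0_min_fraction: float = 0.01  # floor on W_j0, fraction of initial
    w_j0_max_fraction: float = 20.0  # cap on W_j0, fraction of initial

    def __post_init__(self) -> None:
        if self.stdp_strength <= 0:
            raise ValueError(f"stdp_strength must be positive, got {self.stdp_strength}")
        if not 0.0 < self.punish_fraction <= 1.0:
            raise ValueError(f"punish_fraction must lie in (0, 1], got {self.punish_fraction}")
        if self.f_target <= 0:
            raise ValueError(f"f_target must be positive, got {self.f_target}")
        if self.k_minus > 0:
            raise ValueError("k_minus must be non-positive (post-before-pre depresses)")


@dataclass
class ExperimentConfig:
    """Performance metric, feature switches and safety rails.

    Every Fig-4-style ablation is a switch here; no code changes are needed
    to run any of the experiment battery.
    """

    ema_a: float = 0.00001          # A of the food-rate exponential moving average
    punishment_on: bool = True
    output_balancing_on: bool = True
    input_balancing_on: bool = True
    learning_on: bool = True
    reward_reversed: bool = False
    force_reward: bool = False       # testing fixture: reward every move
    runaway_factor: float = 10.0     # halt when any weight exceeds this x initial column sum
    validate: bool = False           # assert conservation invariants every epoch

    def __post_init__(self) -> None:
        if not 0.0 < self.ema_a <= 1.0:
            raise ValueError(f"ema_a must lie in (0, 1], got {self.ema_a}")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: constants, switches and the seed."""

    env: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    neuron: NeuronConfig = field(default_factory=NeuronConfig)
    synapse: SynapseConfig = field(default_factory=SynapseConfig)
    circuit: CircuitConfig = field(default_factory=CircuitConfig)
    plasticity: PlasticityConfig = field(default_factory=PlasticityConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    seed: int = 0
    n_epochs: int = 10_000

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        sections = {
            "env": EnvironmentConfig,
            "neuron": NeuronConfig,
            "synapse": SynapseConfig,
            "circuit": CircuitConfig,
            "plasticity": PlasticityConfig,
            "experiment": ExperimentConfig,
        }
        kwargs: dict[str, Any] = {}
        for key, val in d.items():
            if key in sections:
                kwargs[key] = sections[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))


def pack_params(cfg: RunConfig) -> np.ndarray:
    """Flatten a RunConfig into the float64 vector consumed by the kernels."""
    p = np.zeros(N_PARAMS, dtype=np.float64)
    p[P_WIDTH] = cfg.env.width
    p[P_HEIGHT] = cfg.env.height
    p[P_DENSITY] = cfg.env.density
    p[P_VBIAS] = cfg.env.vertical_bias
    p[P_ALPHA] = cfg.neuron.alpha
    p[P_MU] = cfg.neuron.mu
    p[P_SIGMA] = cfg.neuron.sigma
    p[P_BETA_E] = cfg.neuron.beta_e
    p[P_SIGMA_E] = cfg.neuron.sigma_e
    p[P_GAMMA] = cfg.synapse.gamma
    p[P_RELEASE_R] = cfg.synapse.release_noise
    p[P_VREV_EXC] = cfg.synapse.v_rev_exc
    p[P_VREV_INH] = cfg.synapse.resolved_v_rev_inh(cfg.neuron)
    p[P_EPOCH_STEPS] = cfg.circuit.epoch_steps
    p[P_DECISION_STEPS] = cfg.circuit.decision_steps
    p[P_PULSE_AMP] = cfg.circuit.input_pulse_amplitude
    p[P_PULSE_STEPS] = cfg.circuit.input_pulse_steps
    p[P_W_INPUT] = cfg.circuit.w_input
    p[P_W_INIT] = cfg.circuit.w_init
    p[P_HUNGER_THRESH] = cfg.circuit.hunger_threshold
    p[P_TURN_PROB] = cfg.circuit.turn_prob
    p[P_HUNGER_CONT] = cfg.circuit.hunger_continue_prob
    p[P_K_PLUS] = cfg.plasticity.k_plus
    p[P_K_MINUS] = cfg.plasticity.k_minus
    p[P_TC_STEPS] = cfg.plasticity.tc_steps
    p[P_TRACE_EPOCHS] = cfg.plasticity.trace_epochs
    p[P_SC] = cfg.plasticity.stdp_strength
    p[P_PUNISH_FRAC] = cfg.plasticity.punish_fraction
    p[P_F_TARGET] = cfg.plasticity.f_target
    p[P_EMA_RATE] = cfg.plasticity.ema_rate
    p[P_ETA_HOMEO] = cfg.plasticity.eta_homeo
    p[P_EMA_A] = cfg.experiment.ema_a
    p[P_RUNAWAY_FACTOR] = cfg.experiment.runaway_factor
    p[P_WJ0_MIN] = cfg.plasticity.w_j0_min_fraction
    p[P_WJ0_MAX] = cfg.plasticity.w_j0_max_fraction
    p[P_PUNISH_ON] = float(cfg.experiment.punishment_on)
    p[P_OUTBAL_ON] = float(cfg.experiment.output_balancing_on)
    p[P_INBAL_ON] = float(cfg.experiment.input_balancing_on)
    p[P_LEARNING_ON] = float(cfg.experiment.learning_on)
    p[P_REVERSED] = float(cfg.experiment.reward_reversed)
    p[P_FORCE_REWARD] = float(cfg.experiment.force_reward)
    p[P_VALIDATE] = float(cfg.experiment.validate)
    return p
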