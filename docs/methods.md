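# Methods

## The model in brief

A virtual entity forages on a 50x50 toroidal grid in which 10% of cells
initially hold a "food" particle.  Its behaviour is controlled by a
feedforward network of 156 map-based (difference-equation) spiking neurons:
a 7x7 input layer representing the visual field, a 7x7 excitatory and a 7x7
inhibitory hidden layer (one-to-one relays of the input), and a 3x3 output
layer receiving dense excitation from the excitatory hidden cells and
matched feedforward inhibition from the inhibitory ones.  Each output cell
codes one of the 8 compass moves; the centre cell codes "continue".

Time is organised in epochs of 600 map steps (~300 ms at ~0.5 ms/step).
Input cells whose visual-field cell holds food receive a suprathreshold
current pulse at epoch start; output spikes are counted over the first 300
steps; the entity moves at the half-epoch point; the remaining steps are a
cooling-off period.  Learning is rewarded STDP between the excitatory
hidden layer and the output layer: spike pairings are stored as eligibility
traces for 5 epochs and are committed to the weights at every subsequent
reward (food obtained) or punishment (no food), stabilised by three
balancing mechanisms (below).

## Neuron and synapse

The neuron is the two-dimensional map with fast variable `x` and slow
variable `y`:

    x[n+1] = f(x[n], x[n-1], y[n] + beta_e * I[n])
    y[n+1] = y[n] - mu (x[n] + 1) + mu sigma + mu sigma_e * I[n]

with the piecewise nonlinearity `f(x, x_prev, u) = alpha/(1-x) + u` for
`x <= 0`, `alpha + u` for `0 < x < alpha + u` (rising phase), and `-1`
(reset = spike) otherwise.  All 156 cells use the fast-spiking parameter
set `alpha = 3.65`, `mu = 5e-4`, `sigma = 0.06`, `beta_e = 0.133`,
`sigma_e = 1`.  At `sigma = 0.06` the cell is silent with a stable rest at
`x* = sigma - 1 = -0.94`; raising the resting level or injecting current
produces tonic firing whose rate grows monotonically with drive.  The
affine map to physiological units (`v_scale = 50`, `v_offset = -18`,
rest about -65 mV) is used for display only.

Synapses are first-order kinetics in difference form: the gating variable
decays geometrically (`gamma = 0.8`, time constant about 2 ms) and jumps by
`weight x a` on each presynaptic spike, with `a ~ U[1-R, 1+R]`.  The release
noise `R` (standard value 0.16) is the model's only source of synaptic
variability and is what breaks the excitation/inhibition symmetry at the
output layer.  The synaptic current is `-s (v_post - v_rev)`.

**Choice of the inhibitory reversal potential.**  The model requires that
with `R = 0` the matched excitatory and inhibitory conductance sums cancel
exactly at the output cells, leaving them silent.  With driving forces
evaluated at rest this requires `|x* - v_rev_inh| = |x* - v_rev_exc|`, so
the default inhibitory reversal is the mirror image of the excitatory one
about the resting potential: `v_rev_inh = 2 x* - v_rev_exc = -1.88`.  Both
reversals are configurable.

**Calibrated couplings.**  The input pulse (amplitude 1.0 for 3 steps)
fires a resting cell at step ~7; the relay weight `w_input = 0.5` makes a
hidden cell fire exactly one spike ~13 steps after its input spikes.  The
initial hidden-to-output weight is uniform `w_init = 2.0`, at which the
balanced output layer spikes only occasionally, from release-noise
fluctuations.  These three constants were calibrated once against those
target behaviours and are pinned in the configuration.

## Plasticity

A pre/post pairing creates a trace `vE = k S exp(-dt / T_c)` with
`k = +-0.025` (sign by pairing order), `S` the current weight and
`T_c = 10 ms` (20 steps), under nearest-pairing with suppression: after a
pre spike only the first following post spike creates an event, and
symmetrically.  Traces live for 5 epochs; each reward or punishment applies
every live trace as `S_rp * vE * exp(-age / T_e)` with `T_e` one epoch —
the exponential age kernel is chosen to be consistent with the 5-epoch
storage horizon (residual `e^-5 < 1%`).

* **Output balancing** scales reward per presynaptic cell:
  `S_rp = S_c * W_io / W_i`, the pure inverse-proportion form, with `W_io`
  the cell's initial outgoing total.  Punishment is constant at
  `punish_fraction * S_c` (default 0.5) and applies the sign-flipped trace.
* **Input balancing** multiplicatively rescales the 49 excitatory inputs of
  a touched output cell so their sum equals the homeostatic target `W_j0`
  (the simplest rule satisfying the sum constraint; it preserves weight
  ratios).  Deltas within one event are applied simultaneously; weights are
  floored at zero.
* **Homeostatic scaling** updates `W_j0` once per epoch:
  `F_est <- (1-ema) F_est + ema * spikes`, `W_j0 <- W_j0 + eta * W_j0_init
  * (F_target - F_est)`, with `F_target = 1` spike/epoch, `ema = 0.01`,
  `eta = 0.01`, clipped to `[0.01, 20] x W_j0_init`.  The constants were
  chosen so the untrained network reaches its operating point within a few
  thousand epochs and then holds output firing near target.
* **Inhibitory balancing** keeps each output cell's 49 uniform inhibitory
  weights summing to its excitatory column sum, every epoch.  There is no
  inhibitory plasticity.

The decision rule is argmax of output spike counts over the first
half-epoch, ties to the earliest first spike, residual ties uniform; a
silent epoch (or a win by the centre cell) continues the previous heading.
Independently of everything, 2% of moves are replaced by a 45-degree turn
off the previous heading; this override exists in all conditions, including
the non-learning reference strategies.  A hunger override (after 100
foodless epochs, until food is next obtained) ignores the outputs and
continues the heading with probability 0.98, else picks a random direction.

## Environment semantics

Movement, vision and placement wrap toroidally; this keeps the environment
statistically homogeneous and avoids wall artefacts.  Initialisation places
exactly `round(density x cells)` particles on distinct cells (exact count,
for reproducibility).  When the entity moves onto food, the cell's entire
content is relocated, each particle landing on an independently chosen
random square — any square except the entity's own, occupied allowed, so
particles can stack (cells store counts; vision reports occupancy).  This
literal "randomly selected new square" rule, together with applying the
global 2% override to the reference strategies, is what reproduces all four
published baseline rates simultaneously (blind 8.7%, adjacent 32.3%,
nearest 53.1%, planner 56.0%); empty-cell-only relocation overshoots the
food-seeking baselines by 2-3 points and undershoots the blind one.
The vertically biased environment places each new particle, with
probability `vertical_bias`, on an empty cell directly above or below
existing food (uniform fallback).

The planner strategy's 5-move search is confined to the 7x7 window (plans
may not leave it; food outside is invisible), simulates pickups along the
path, maximises food collected with earlier pickups preferred
(lexicographic on the pickup-time sequence), and breaks ties uniformly over
optimal sequences.  "Closest" for the nearest-food strategy is Chebyshev
distance, matching 8-way movement.

## Numerical choices

* **Idealised cooling-off.**  Each epoch is long enough for the network to
  return to rest, and input only arrives at epoch start.  The engine
  therefore simulates the decision window (with an early exit once all
  gating has decayed below 1e-6 and every cell sits within 1e-4 of rest —
  both far below the distance from rest to the spiking bifurcation) and
  then sets the state to the exact resting fixed point at the epoch
  boundary.  Spike counts and times are unaffected; epoch boundaries are
  bit-reproducible.
* **Current flushing.**  Synaptic currents smaller than 1e-9 are flushed to
  exact zero.  At the operating point the balanced conductance makes the
  discrete map locally expansive, so otherwise even ulp-level rounding
  differences between the excitatory and inhibitory sums would be amplified
  into spurious spikes in the noise-free (`R = 0`) condition.  Real
  synaptic events produce currents at least six orders of magnitude above
  the threshold.
* **Runaway guard.**  With input balancing, no weight can exceed its
  column's target `W_j0`; a weight crossing `10 x W_j0` therefore
  unambiguously signals the unbalanced runaway regime, and the run halts
  with a flag rather than overflowing.
* **RNG.**  All stochasticity flows through named splitmix64 counter
  streams (environment, release noise, decisions, perturbations,
  initialisation, strategies) seeded from one master seed, so ablating one
  mechanism never shifts the draws of another, and every run replays
  bit-identically from (config, seed).

## Scaled-down protocol

Published learning curves span 4-8 million epochs with a metric rate
`A = 1e-5`.  The package's scaled protocol uses `A = 1e-3`, STDP strength
`S_c = 4` and 3e5 epochs (about 10 s per run), at which the default
configuration reliably reaches a food-acquisition EMA of ~0.2 — well above
the blind-strategy baseline (~0.08) though far below the published trained
performance (~0.5 at millions of epochs).  Higher `S_c` trades final
performance for learning speed, so all tests assert orderings (default
beats blind; no-output-balancing trails default; reversed reward falls
below blind), never absolute published curves.

## What the tests do and do not show

The synthetic environment is the study system itself, so there is no
real-data gap in the usual sense; the scaled-down protocol, however, means
the learned weight structure is coarser than in full-length runs, and
slow phenomena (late-stage local maxima, the long-run failure mode of one
trial in six) are out of reach at this scale.  The exact-count food
initialisation and count-based relocation are modelling choices pinned for
reproducibility; both conserve the particle total, which the tests assert
throughout.

## Known limitations

* The map parameters and couplings are one calibrated operating point, not
  a fit to the published voltage traces; only qualitative single-cell
  behaviour (silent rest, tonic firing, rate growing with drive) is
  matched.
* At high homeostatic targets the balanced-conductance dynamics are locally
  chaotic within the decision window; decisions remain well defined via
  spike counts, but per-step membrane trajectories should not be
  interpreted quantitatively in that regime.
* The no-output-balancing ablation lands slightly below the blind baseline
  at desk scale, whereas the published full-length runs stay somewhat
  above it; the qualitative signature (large, stable performance loss) is
  reproduced.
* Only one entity, binary food, and a single food type are supported.
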