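# stdpforage

A tested simulator of reward-modulated spike-timing-dependent plasticity
(STDP) learning a foraging task.  A virtual entity lives on a 50x50
toroidal grid where 10% of cells hold "food"; a 156-cell feedforward
network of map-based (difference-equation) spiking neurons — a 7x7 visual
input layer, matched excitatory and inhibitory 7x7 hidden layers, and a
3x3 motor output layer — turns each visual snapshot into one of 8 compass
moves.  The package is for computational neuroscientists who want to run,
ablate and extend this class of reinforcement-learning spiking model
without re-deriving its many stabilising mechanisms.

## The learning rule

Spike pairings between hidden cell *i* and output cell *j* create
eligibility traces

    vE = k · S · exp(−Δt / T_c),   k = ±0.025,  T_c = 10 ms,

stored for 5 epochs (an epoch is 600 map steps ≈ 300 ms, one move).  Every
move triggers a global reward (food) or punishment (no food) that commits
each live trace as

    ΔW_ij = S_rp · vE · exp(−(t_re − t_trace) / T_e),

solving the distal-reward problem by construction.  Three mechanisms keep
the weights bounded and competitive:

* **output balancing** — reward scale `S_rp = S_c · W_io / W_i`, inversely
  proportional to the presynaptic cell's total outgoing strength
  (punishment stays constant at `0.5 · S_c`);
* **input balancing** — after every change, the 49 excitatory inputs of an
  output cell are rescaled so their sum equals a homeostatic target `W_j0`;
* **homeostatic scaling** — `W_j0` drifts opposite to the error between the
  cell's firing-rate estimate and a 1 spike/epoch target, and the uniform
  feedforward inhibition is held equal in total to the excitation.

Multiplicative synaptic release noise (`a ~ U[1−R, 1+R]`, standard
`R = 0.16`) is the sole symmetry breaker: with `R = 0` excitation and
inhibition cancel exactly and the network never acts.

## Worked example

```python
import stdpforage as sf

# scaled-down training: faster metric (A = 1e-3) and STDP strength 4
d = sf.RunConfig(seed=7).to_dict()
d["plasticity"]["stdp_strength"] = 4.0
d["experiment"]["ema_a"] = 1e-3
cfg = sf.RunConfig.from_dict(d)

logs = sf.run_training(cfg, n_epochs=300_000)
print(f"final EMA      {logs.final_performance:.3f}")
print(f"food per move  {logs.ate[-50_000:].mean():.3f}")

blind = sf.run_strategy(1, 1_000_000, seed=7)
print(f"blind baseline {blind['rate']:.3f}")
```

prints (seed 7, ~10 s after compilation):

```
final EMA      0.221
food per move  0.220
blind baseline 0.079
```

The exponential moving average `X ← (1−A)·X + A·S` of the per-move food
flag rises from the blind-walk level (~0.08) to ~0.22 as the network learns
to steer toward visible food — at desk scale; published multi-million-epoch
runs approach the strongest heuristics.  The same config surface drives the
experiment battery: `sf.run_ablation(cfg, "release_noise")`,
`sf.reversed_reward_run(cfg)`, `sf.switch_environment(...)`,
`sf.Simulation(cfg).perturb(0.2)`.

A CLI mirrors the library:

```bash
stdpforage run --seed 1 --epochs 100000 --out runs/demo
stdpforage strategies --seed 1
stdpforage ablate release_noise --seed 1 --epochs 10000 --out runs/ablate
stdpforage sweep --parameter synapse.release_noise --values 0.02,0.08,0.16,0.32
```

## Layout

| module | contents |
|---|---|
| `stdpforage.env` | grid world, food placement/relocation, visual field |
| `stdpforage.neuron` | map neuron, synapse kinetics, release noise |
| `stdpforage.circuit` | network state, epoch protocol, move decoding, hunger |
| `stdpforage.plasticity` | traces, reward/punishment, the three balancing rules |
| `stdpforage.strategies` | the four reference strategies |
| `stdpforage.experiments` | training loop, metric, ablations, perturbations, switches |

`docs/methods.md` documents the model, every default constant, and the
numerical choices.
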