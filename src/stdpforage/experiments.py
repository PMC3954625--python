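"""Training orchestration, the performance metric and the experiment battery.

The performance score is an exponential moving average of the per-move food
flag: X[n] = (1 - A) X[n-1] + A S[n] with S = 1 on a move that obtains food
(A = 1e-5 in the full-scale protocol; scaled-down runs use a larger A so the
estimate settles within the shorter run).

Every experiment — baseline training, feature ablations, weight
perturbations, environment switches and reward reversal — is driven by one
configuration surface (:class:`~stdpforage.config.RunConfig`), runs through
the same compiled epoch loop, and is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _engine as eng
from . import __version__
from ._rng import STREAM_INIT, make_state, random_below
from .circuit import NetworkState
from .config import N_PARAMS, P_INBAL_ON, P_VBIAS, RunConfig
from .env import FoodDistribution, GridWorld, init_food

ABLATABLE_FEATURES = ("punishment", "output_balancing", "release_noise", "input_balancing")


@dataclass
class PerformanceTracker:
    """Exponential-moving-average estimate of the food-acquisition rate."""

    a: float = 0.00001
    x: float = 0.0

    def update(self, ate: bool) -> None:
        self.x = (1.0 - self.a) * self.x + (self.a if ate else 0.0)


def update_performance(tracker: PerformanceTracker, ate: bool) -> PerformanceTracker:
    """Functional form of the per-move metric update."""
    out = PerformanceTracker(a=tracker.a, x=tracker.x)
    out.update(ate)
    return out


@dataclass
class RunLogs:
    """Per-epoch logs and end state of one training run."""

    config: RunConfig
    performance: np.ndarray      # EMA after each move
    ate: np.ndarray
    direction: np.ndarray
    n_output_spikes: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    epochs_run: int
    halted: bool
    W: np.ndarray
    WI: np.ndarray
    w_j0: np.ndarray
    f_est: np.ndarray
    counters: np.ndarray
    fmetrics: np.ndarray
    snapshots: list = field(default_factory=list)  # (epoch, W copy)

    @property
    def final_performance(self) -> float:
        return float(self.performance[self.epochs_run - 1]) if self.epochs_run else 0.0

    @property
    def food_rate(self) -> float:
        n = self.epochs_run
        return float(self.ate[:n].sum()) / n if n else 0.0


class Simulation:
    """A live training run: environment + network + logs, steppable in chunks.

    All state mutation happens inside the compiled epoch loop; stepping one
    epoch at a time (:meth:`step`) or in chunks (:meth:`run`) follows the
    identical code path, so the two are bit-identical for the same seed.
    """

    def __init__(self, config: RunConfig, freeze_windows=()):
        self.config = config
        self.net = NetworkState(config)
        self.world = GridWorld(width=config.env.width, height=config.env.height)
        self.dist = FoodDistribution(
            density=config.env.density, vertical_bias=config.env.vertical_bias
        )
        init_food(self.world, self.dist, self.net.rng)
        self.state_i = np.zeros(7, dtype=np.int64)
        self.state_i[eng.SI_ROW] = random_below(self.net.rng, STREAM_INIT, config.env.height)
        self.state_i[eng.SI_COL] = random_below(self.net.rng, STREAM_INIT, config.env.width)
        self.state_i[eng.SI_HEADING] = random_below(self.net.rng, STREAM_INIT, 8)
        self.perf = np.zeros(1)
        self.set_freeze_windows(freeze_windows)
        self._logs: list[dict] = []

    # ------------------------------------------------------------- control
    def set_freeze_windows(self, windows) -> None:
        """Plasticity-freeze intervals [start, end) in epochs; must not overlap."""
        windows = sorted(tuple(w) for w in windows)
        for (a0, b0), (a1, _) in zip(windows, windows[1:]):
            if a1 < b0:
                raise ValueError(f"overlapping freeze windows: {(a0, b0)} and {(a1, _)}")
        self.freeze_start = np.array([w[0] for w in windows], dtype=np.int64)
        self.freeze_end = np.array([w[1] for w in windows], dtype=np.int64)

    @property
    def epoch(self) -> int:
        return int(self.state_i[eng.SI_EPOCH])

    @property
    def halted(self) -> bool:
        return bool(self.state_i[eng.SI_HALTED])

    @property
    def performance(self) -> float:
        return float(self.perf[0])

    def run(self, n_epochs: int, chunk: int = 50_000) -> int:
        """Advance ``n_epochs`` epochs (or fewer if the runaway guard trips)."""
        done = 0
        while done < n_epochs and not self.halted:
            n = min(chunk, n_epochs - done)
            log = {
                "performance": np.zeros(n),
                "ate": np.zeros(n, dtype=np.uint8),
                "direction": np.zeros(n, dtype=np.int8),
                "n_output_spikes": np.zeros(n, dtype=np.int16),
                "rows": np.zeros(n, dtype=np.int16),
                "cols": np.zeros(n, dtype=np.int16),
            }
            net = self.net
            ran = eng.run_epochs_kernel(
                n, net.params, net.rng, self.world.food, self.state_i,
                net.x, net.y, net.xp, net.active, net.spk,
                net.s1, net.s2, net.sE, net.sI,
                net.W, net.WI, net.w_j0, net.w_io, net.row_sum, net.f_est,
                net.w_j0_init,
                net.h_times, net.h_n, net.o_times, net.o_n,
                net.tr_pre, net.tr_post, net.tr_val, net.tr_time,
                net.tr_count, net.slot_epoch,
                net.stim, net.dW, net.touched, net.counters, net.fmetrics,
                self.freeze_start, self.freeze_end, self.perf,
                log["performance"], log["ate"], log["direction"],
                log["n_output_spikes"], log["rows"], log["cols"],
            )
            ran = int(ran)
            for k in log:
                log[k] = log[k][:ran]
            self._logs.append(log)
            done += ran
            if ran < n:
                break
        return done

    def step(self) -> None:
        """Advance exactly one epoch."""
        self.run(1, chunk=1)

    def switch_environment(self, new_dist: FoodDistribution) -> None:
        """Replace the food distribution mid-run (food is re-scattered)."""
        self.world.food[:] = 0
        init_food(self.world, new_dist, self.net.rng)
        self.dist = new_dist
        self.net.params[P_VBIAS] = new_dist.vertical_bias

    def perturb(self, level: float) -> None:
        """Randomise every excitatory weight by U[1-level, 1+level].

        Input balancing restores each output cell's total afferent weight,
        so only the distribution within columns changes.
        """
        if level < 0:
            raise ValueError(f"perturbation level must be >= 0, got {level}")
        if level >= 1:
            raise ValueError("perturbation level must be < 1 (factors must stay positive)")
        net = self.net
        eng.perturb_weights_kernel(
            net.params, net.rng, net.W, net.WI, net.w_j0, net.row_sum, level, net.counters
        )

    # ------------------------------------------------------------- results
    def collect(self) -> RunLogs:
        cat = {}
        keys = ("performance", "ate", "direction", "n_output_spikes", "rows", "cols")
        for k in keys:
            parts = [log[k] for log in self._logs]
            cat[k] = np.concatenate(parts) if parts else np.zeros(0)
        net = self.net
        return RunLogs(
            config=self.config,
            performance=cat["performance"], ate=cat["ate"], direction=cat["direction"],
            n_output_spikes=cat["n_output_spikes"], rows=cat["rows"], cols=cat["cols"],
            epochs_run=len(cat["ate"]), halted=self.halted,
            W=net.W.copy(), WI=net.WI.copy(), w_j0=net.w_j0.copy(), f_est=net.f_est.copy(),
            counters=net.counters.copy(), fmetrics=net.fmetrics.copy(),
        )


# ---------------------------------------------------------------------------
# The experiment battery
# ---------------------------------------------------------------------------
def _with(config: RunConfig, **overrides) -> RunConfig:
    """Copy a config, overriding dotted section fields (e.g. experiment.ema_a)."""
    d = config.to_dict()
    for key, val in overrides.items():
        section, _, name = key.partition(".")
        if name:
            d[section][name] = val
        else:
            d[section] = val
    return RunConfig.from_dict(d)


def run_training(
    config: RunConfig,
    n_epochs: int | None = None,
    snapshot_every: int | None = None,
    freeze_windows=(),
) -> RunLogs:
    """The full training loop: encode -> simulate -> decide -> move -> learn."""
    n_epochs = n_epochs if n_epochs is not None else config.n_epochs
    sim = Simulation(config, freeze_windows=freeze_windows)
    snapshots = []
    if snapshot_every:
        while sim.epoch < n_epochs and not sim.halted:
            sim.run(min(snapshot_every, n_epochs - sim.epoch))
            snapshots.append((sim.epoch, sim.net.W.copy()))
    else:
        sim.run(n_epochs)
    logs = sim.collect()
    logs.snapshots = snapshots
    return logs


def run_ablation(config: RunConfig, feature: str, n_epochs: int | None = None) -> RunLogs:
    """Re-run training with one model feature removed.

    ``feature`` is one of "punishment", "output_balancing", "release_noise"
    (R = 0), "input_balancing".
    """
    if feature == "punishment":
        cfg = _with(config, **{"experiment.punishment_on": False})
    elif feature == "output_balancing":
        cfg = _with(config, **{"experiment.output_balancing_on": False})
    elif feature == "release_noise":
        cfg = _with(config, **{"synapse.release_noise": 0.0})
    elif feature == "input_balancing":
        cfg = _with(config, **{"experiment.input_balancing_on": False})
    else:
        raise ValueError(f"unknown feature {feature!r}; expected one of {ABLATABLE_FEATURES}")
    return run_training(cfg, n_epochs=n_epochs)


def reversed_reward_run(config: RunConfig, n_epochs: int | None = None) -> RunLogs:
    """Train with reward and punishment exchanged (reward for NOT eating)."""
    return run_training(_with(config, **{"experiment.reward_reversed": True}), n_epochs=n_epochs)


def perturb_weights(W: np.ndarray, level: float, rng_state: np.ndarray,
                    w_j0: np.ndarray | None = None) -> np.ndarray:
    """Scale each weight by U[1-level, 1+level]; restore column sums.

    Standalone form of :meth:`Simulation.perturb` acting on a copied matrix.
    When ``w_j0`` is omitted the original column sums are restored.
    """
    if level < 0:
        raise ValueError(f"perturbation level must be >= 0, got {level}")
    if level >= 1:
        raise ValueError("perturbation level must be < 1 (factors must stay positive)")
    W = np.array(W, dtype=np.float64, copy=True)
    targets = W.sum(axis=0) if w_j0 is None else np.asarray(w_j0, dtype=np.float64)
    WI = np.zeros_like(W)
    row_sum = np.zeros(W.shape[0])
    counters = np.zeros(8, dtype=np.int64)
    params = np.zeros(N_PARAMS)
    params[P_INBAL_ON] = 1.0
    eng.perturb_weights_kernel(params, rng_state, W, WI, targets, row_sum, level, counters)
    return W


def switch_environment(
    config: RunConfig,
    at_epoch: int,
    new_dist: FoodDistribution,
    n_epochs: int | None = None,
    freeze_window: tuple[int, int] | None = None,
) -> RunLogs:
    """Train, swap the food distribution at ``at_epoch``, continue.

    ``freeze_window`` optionally freezes all plasticity over [t1, t2)
    (weights held constant while the entity forages in the new world).
    """
    n_epochs = n_epochs if n_epochs is not None else config.n_epochs
    if not 0 < at_epoch < n_epochs:
        raise ValueError("at_epoch must lie inside the run")
    windows = [freeze_window] if freeze_window else []
    sim = Simulation(config, freeze_windows=windows)
    sim.run(at_epoch)
    if not sim.halted:
        sim.switch_environment(new_dist)
        sim.run(n_epochs - at_epoch)
    return sim.collect()


# ---------------------------------------------------------------------------
# Output files
# ---------------------------------------------------------------------------
def write_run_outputs(logs: RunLogs, out_dir: str | Path, every: int = 1) -> None:
    """Write performance/trajectory CSVs, weight arrays and the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = logs.epochs_run
    idx = np.arange(0, n, every)
    pd.DataFrame({"epoch": idx, "performance": logs.performance[idx]}).to_csv(
        out / "performance.csv", index=False
    )
    pd.DataFrame({
        "epoch": np.arange(n), "row": logs.rows[:n], "col": logs.cols[:n],
        "ate": logs.ate[:n],
    }).to_csv(out / "trajectory.csv", index=False)
    np.savez(out / "weights.npz", W=logs.W, WI=logs.WI, w_j0=logs.w_j0, f_est=logs.f_est,
             **{f"W_epoch_{e}": w for e, w in logs.snapshots})
    manifest = {
        "config": logs.config.to_dict(),
        "code_version": __version__,
        "epochs_run": int(logs.epochs_run),
        "halted": bool(logs.halted),
        "final_performance": logs.final_performance,
        "food_rate": logs.food_rate,
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
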