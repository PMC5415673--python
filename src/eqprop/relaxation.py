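"""Fixed-point relaxation: discretized gradient descent on the total energy.

Each free unit follows the leaky-integrator update

    s_i <- 0 v (s_i - eps * dF/ds_i) ^ 1        (clipped rule)

applied synchronously over the whole free-state vector. Inputs stay clamped
throughout. With ``beta = 0`` this is the free phase whose endpoint carries
the prediction; with small ``beta != 0`` it is the nudged (weakly clamped)
phase whose endpoint feeds the contrastive update.

Stopping is governed either by a fixed iteration count (the practice used
for training) or by a tolerance on the max-norm state change (used by the
gradient-validation suites, which need accurate fixed points). The clip to
[0, 1] can be disabled for smooth-activation analyses whose stationary
points may fall outside the box.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .energy import (
    NetworkParams,
    NetworkState,
    WorldInput,
    state_gradient,
    total_energy,
)

__all__ = [
    "RelaxationConfig",
    "Trajectory",
    "ConvergenceError",
    "init_state",
    "relax_step",
    "relax",
    "free_phase",
    "nudged_phase",
    "predict",
]


class ConvergenceError(RuntimeError):
    """Tolerance-mode relaxation failed to converge within the iteration cap."""


@dataclass
class RelaxationConfig:
    """How long and how finely to relax.

    Exactly one of ``n_iter`` (fixed duration) and ``tolerance`` (max-norm
    state change threshold) must be set. ``max_iter`` caps tolerance mode
    (default ``10 * 1000``); ``clip`` applies the [0, 1] box of the clipped
    update rule.
    """

    epsilon: float = 0.5
    n_iter: int | None = None
    tolerance: float | None = None
    max_iter: int | None = None
    record_trajectory: bool = False
    clip: bool = True

    def __post_init__(self):
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError("epsilon must lie in (0, 1)")
        if (self.n_iter is None) == (self.tolerance is None):
            raise ValueError("set exactly one of n_iter and tolerance")
        if self.n_iter is not None and self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.tolerance is not None and self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class Trajectory:
    """Ordered record of the states and total energies visited."""

    states: list = field(default_factory=list)
    energies: list = field(default_factory=list)
    beta: float = 0.0

    def append(self, state: NetworkState, energy) -> None:
        self.states.append(state)
        self.energies.append(energy)

    def __len__(self) -> int:
        return len(self.states)

    def to_csv(self, path) -> None:
        """One row per iteration: index, every unit value, total energy F."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            n = self.states[0].n_units
            writer.writerow(["iteration", *(f"u{i}" for i in range(n)), "F"])
            for t, (s, e) in enumerate(zip(self.states, self.energies)):
                writer.writerow([t, *np.ravel(s.values).tolist(), float(e)])


def init_state(x: np.ndarray, n_hidden: int, n_output: int,
               fill: float = 0.0) -> NetworkState:
    """Build a state with inputs clamped to ``x`` and free units at ``fill``.

    ``x`` may carry a leading batch axis.
    """
    x = np.asarray(x, dtype=float)
    n_in = x.shape[-1]
    n = n_in + n_hidden + n_output
    values = np.full(x.shape[:-1] + (n,), fill, dtype=float)
    values[..., :n_in] = x
    return NetworkState(
        values,
        input_idx=np.arange(n_in),
        hidden_idx=np.arange(n_in, n_in + n_hidden),
        output_idx=np.arange(n_in + n_hidden, n),
    )


def relax_step(p: NetworkParams, w: WorldInput, beta: float, u: NetworkState,
               activation: str, epsilon: float, clip: bool = True) -> NetworkState:
    """One synchronous update of all free units; inputs untouched."""
    g = state_gradient(p, w, beta, u, activation)
    free = u.free_idx
    new = u.values[..., free] - epsilon * g
    if clip:
        new = np.clip(new, 0.0, 1.0)
    values = u.values.copy()
    values[..., free] = new
    return u.with_values(values)


def relax(p: NetworkParams, w: WorldInput, beta: float, u0: NetworkState,
          activation: str, cfg: RelaxationConfig
          ) -> tuple[NetworkState, Trajectory | None]:
    """Iterate :func:`relax_step` to an (approximate) fixed point.

    Returns the final state and, when requested, the trajectory whose first
    entry is the initial state.
    """
    traj = None
    if cfg.record_trajectory:
        traj = Trajectory(beta=beta)
        traj.append(u0, total_energy(p, w, beta, u0, activation))
    u = u0
    if cfg.n_iter is not None:
        for _ in range(cfg.n_iter):
            u = relax_step(p, w, beta, u, activation, cfg.epsilon, cfg.clip)
            if traj is not None:
                traj.append(u, total_energy(p, w, beta, u, activation))
        return u, traj
    cap = cfg.max_iter if cfg.max_iter is not None else 10_000
    for _ in range(cap):
        nxt = relax_step(p, w, beta, u, activation, cfg.epsilon, cfg.clip)
        delta = np.max(np.abs(nxt.values - u.values))
        u = nxt
        if traj is not None:
            traj.append(u, total_energy(p, w, beta, u, activation))
        if delta < cfg.tolerance:
            return u, traj
    raise ConvergenceError(
        f"relaxation did not reach tolerance {cfg.tolerance} in {cap} steps"
    )


def free_phase(p: NetworkParams, w: WorldInput, u0: NetworkState,
               activation: str, cfg: RelaxationConfig):
    """Relax with beta = 0; the endpoint is the free fixed point u^0."""
    return relax(p, w, 0.0, u0, activation, cfg)


def nudged_phase(p: NetworkParams, w: WorldInput, beta: float,
                 u_free: NetworkState, activation: str, cfg: RelaxationConfig):
    """Relax with beta != 0, starting from the free fixed point.

    The default duration heuristic (when callers build the config) is
    ``N / epsilon`` iterations, N the number of non-input layers: the time
    a perturbation needs to travel back across the network.
    """
    if beta == 0.0:
        raise ValueError("nudged phase requires beta != 0")
    return relax(p, w, beta, u_free, activation, cfg)


def default_nudged_iters(n_free_layers: int, epsilon: float) -> int:
    """N / epsilon iterations for a net with N non-input layers."""
    return int(round(n_free_layers / epsilon))


def predict(p: NetworkParams, x: np.ndarray, activation: str,
            cfg: RelaxationConfig, n_hidden: int | None = None,
            n_output: int | None = None, u0: NetworkState | None = None):
    """Free-phase prediction: argmax over output-unit values at the free
    fixed point; ties break toward the lowest class index.

    Layer counts are taken from ``p.layer_sizes`` unless given explicitly.
    Accepts a batch of inputs (leading axis).
    """
    if u0 is None:
        if n_hidden is None or n_output is None:
            if p.layer_sizes is None:
                raise ValueError("need n_hidden/n_output or layered parameters")
            n_output = p.layer_sizes[-1]
            n_hidden = p.n_units - p.layer_sizes[0] - n_output
        u0 = init_state(x, n_hidden, n_output)
    w = WorldInput(x=np.asarray(x, dtype=float),
                   d=np.zeros(u0.output_idx.size))
    u, _ = free_phase(p, w, u0, activation, cfg)
    return np.argmax(u.values[..., u0.output_idx], axis=-1)
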