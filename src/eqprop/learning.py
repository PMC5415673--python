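"""Equilibrium Propagation training: the contrastive two-point estimator,
per-layer learning rates, persistent particles, random-sign nudging, and
minibatch SGD.

The estimator compares the parameter gradient of the total energy at two
fixed points of the same network — the free fixed point (beta = 0) and a
weakly nudged one (small beta != 0) — and scales the difference by 1/beta:

    Delta W_ij = (1/beta) (rho(u_i^b) rho(u_j^b) - rho(u_i^0) rho(u_j^0))
    Delta b_i  = (1/beta) (rho(u_i^b) - rho(u_i^0))

As beta -> 0 this converges to minus the gradient of the squared prediction
error at the free fixed point, so applying it is stochastic gradient
descent without a separate backward circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import Dataset, glorot_weights, layered_mask
from .energy import (
    GradientEstimate,
    NetworkParams,
    NetworkState,
    WorldInput,
    cost_param_gradient,
    param_gradient,
    quadratic_cost,
    total_energy,
)
from .relaxation import (
    RelaxationConfig,
    default_nudged_iters,
    free_phase,
    init_state,
    nudged_phase,
)

__all__ = [
    "TrainConfig",
    "ParticleStore",
    "eqprop_gradient",
    "apply_update",
    "train_minibatch",
    "fit",
]


@dataclass
class TrainConfig:
    """Hyperparameters of a training run.

    ``layer_rates`` holds one learning rate per inter-layer weight matrix
    (the biases of the downstream layer share its rate). ``beta_magnitude``
    is |beta| for the nudged phase; with ``random_beta_sign`` the sign is
    drawn once per minibatch, which regularizes without biasing the update
    (the 1/beta factor keeps both signs consistent).
    """

    beta_magnitude: float = 1.0
    random_beta_sign: bool = False
    layer_rates: tuple = (0.1, 0.05)
    minibatch_size: int = 20
    n_epochs: int = 25
    seed: int = 0
    persistent_particles: bool = True
    free_config: RelaxationConfig = field(
        default_factory=lambda: RelaxationConfig(epsilon=0.5, n_iter=20))
    nudged_config: RelaxationConfig | None = None
    l2_penalty: float = 0.0
    activation: str = "hard_sigmoid"

    def __post_init__(self):
        if self.beta_magnitude <= 0:
            raise ValueError("beta_magnitude must be positive")
        if any(r <= 0 for r in np.atleast_1d(self.layer_rates)):
            raise ValueError("learning rates must be positive")
        if self.minibatch_size < 1:
            raise ValueError("minibatch_size must be >= 1")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be >= 0")

    def resolved_nudged_config(self, n_free_layers: int) -> RelaxationConfig:
        """Default second-phase duration: N / epsilon steps, N the number
        of non-input layers (the time an output perturbation needs to
        propagate back through the net)."""
        if self.nudged_config is not None:
            return self.nudged_config
        eps = self.free_config.epsilon
        return replace(self.free_config, n_iter=default_nudged_iters(
            n_free_layers, eps), tolerance=None, record_trajectory=False)


class ParticleStore:
    """Persistent particles: each training example's free-unit state at the
    end of its last free phase, used to warm-start the next one."""

    def __init__(self):
        self._store: dict[int, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self._store)

    def __contains__(self, key) -> bool:
        return int(key) in self._store

    def get_batch(self, ids, n_free: int) -> np.ndarray:
        """Stacked free-unit states for ``ids``; zeros where unseen."""
        out = np.zeros((len(ids), n_free))
        for row, key in enumerate(ids):
            v = self._store.get(int(key))
            if v is not None:
                out[row] = v
        return out

    def put_batch(self, ids, free_values: np.ndarray) -> None:
        for row, key in enumerate(ids):
            self._store[int(key)] = free_values[row].copy()

    def state_dict(self) -> dict:
        return {str(k): v for k, v in self._store.items()}

    @classmethod
    def from_state_dict(cls, d: dict) -> "ParticleStore":
        store = cls()
        store._store = {int(k): np.asarray(v, dtype=float) for k, v in d.items()}
        return store


def eqprop_gradient(p: NetworkParams, w: WorldInput, beta: float,
                    u_free: NetworkState, u_nudged: NetworkState,
                    activation: str, form: str = "total_energy"
                    ) -> GradientEstimate:
    """Two-point contrastive estimate; an ASCENT direction on -J (callers
    add it scaled by a positive rate, subtracting nothing further).

    ``form`` selects between two algebraically equivalent expressions:
    ``"total_energy"`` differences dF/dtheta between the two fixed points;
    ``"free_cost"`` adds dC/dtheta at the free point to the dE/dtheta
    difference. They coincide whenever the cost carries no explicit
    parameter dependence (the quadratic cost here).

    Batched states yield the batch-mean estimate.
    """
    if beta == 0.0:
        raise ValueError("eqprop estimate requires beta != 0")
    gE_nudged = param_gradient(p, u_nudged, activation)
    gE_free = param_gradient(p, u_free, activation)
    if form == "total_energy":
        # -(1/beta) (dF/dtheta|_beta - dF/dtheta|_0) with
        # dF/dtheta = dE/dtheta + beta * dC/dtheta
        gC_nudged = cost_param_gradient(p, u_nudged, w)
        dW = -((gE_nudged.dW + beta * gC_nudged.dW) - gE_free.dW) / beta
        db = -((gE_nudged.db + beta * gC_nudged.db) - gE_free.db) / beta
    elif form == "free_cost":
        # -dC/dtheta(free) - (1/beta)(dE/dtheta(nudged) - dE/dtheta(free))
        gC_free = cost_param_gradient(p, u_free, w)
        dW = -gC_free.dW - (gE_nudged.dW - gE_free.dW) / beta
        db = -gC_free.db - (gE_nudged.db - gE_free.db) / beta
    else:
        raise ValueError(f"unknown estimator form {form!r}")
    return GradientEstimate(dW, db)


def _rate_arrays(p: NetworkParams, rates) -> tuple[np.ndarray, np.ndarray]:
    """Expand per-layer rates to per-entry arrays (alpha_W, alpha_b)."""
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    n = p.n_units
    if p.layer_sizes is None or rates.size == 1:
        if rates.size != 1:
            raise ValueError("per-layer rates need layered parameters")
        return np.full((n, n), rates[0]), np.full(n, rates[0])
    slices = p.layer_slices()
    if rates.size != len(slices) - 1:
        raise ValueError(
            f"got {rates.size} rates for {len(slices) - 1} weight matrices")
    aW = np.zeros((n, n))
    ab = np.zeros(n)
    for k, (lo, hi) in enumerate(zip(slices[:-1], slices[1:])):
        aW[lo, hi] = rates[k]
        aW[hi, lo] = rates[k]
        ab[hi] = rates[k]
    ab[slices[0]] = rates[0]  # input biases never move (zero gradient)
    return aW, ab


def apply_update(p: NetworkParams, g: GradientEstimate, rates,
                 l2_penalty: float = 0.0) -> NetworkParams:
    """W <- W + alpha_k * dW (biases likewise), preserving exact symmetry,
    the zero diagonal, and mask sparsity; optional L2 weight shrinkage."""
    aW, ab = _rate_arrays(p, rates)
    upper = np.triu(g.dW, k=1)           # mirror the upper triangle so the
    dW = upper + upper.T                 # update is exactly symmetric
    step = aW * dW
    if l2_penalty:
        step = step - aW * l2_penalty * p.weights
    W = np.where(p.mask, p.weights + step, 0.0)
    b = p.biases + ab * g.db
    return NetworkParams(W, b, p.mask, p.layer_sizes)


def _free_layer_count(p: NetworkParams) -> int:
    if p.layer_sizes is None:
        raise ValueError("training requires layered parameters")
    return len(p.layer_sizes) - 1


def train_minibatch(p: NetworkParams, X: np.ndarray, D: np.ndarray, ids,
                    cfg: TrainConfig, store: ParticleStore | None,
                    rng: np.random.Generator) -> tuple[NetworkParams, dict]:
    """One SGD step: batched free phase (warm-started from particles), save
    particles, nudged phase with beta = +-beta_magnitude, batch-mean
    contrastive estimate, single parameter update.

    Returns the new parameters and batch metrics (mean cost, error rate,
    the beta used, per-layer relative update norms).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = np.atleast_2d(np.asarray(D, dtype=float))
    n_out = p.layer_sizes[-1]
    n_hidden = p.n_units - p.layer_sizes[0] - n_out
    u0 = init_state(X, n_hidden, n_out)
    if store is not None:
        u0.values[..., u0.free_idx] = store.get_batch(ids, n_hidden + n_out)
    w = WorldInput(x=X, d=D)

    u_free, _ = free_phase(p, w, u0, cfg.activation, cfg.free_config)
    if store is not None:
        store.put_batch(ids, u_free.values[..., u_free.free_idx])

    beta = cfg.beta_magnitude
    if cfg.random_beta_sign and rng.random() < 0.5:
        beta = -beta
    nudged_cfg = cfg.resolved_nudged_config(_free_layer_count(p))
    u_nudged, _ = nudged_phase(p, w, beta, u_free, cfg.activation, nudged_cfg)

    g = eqprop_gradient(p, w, beta, u_free, u_nudged, cfg.activation)
    p_new = apply_update(p, g, cfg.layer_rates, cfg.l2_penalty)

    costs = quadratic_cost(u_free, w)
    preds = np.argmax(u_free.values[..., u_free.output_idx], axis=-1)
    truth = np.argmax(D, axis=-1)
    metrics = {
        "cost": float(np.mean(costs)),
        "error": float(np.mean(preds != truth)),
        "energy": float(np.mean(total_energy(p, w, 0.0, u_free,
                                             cfg.activation))),
        "beta": float(beta),
        "rel_update": _layer_update_norms(p, p_new),
    }
    return p_new, metrics


def _layer_update_norms(p_old: NetworkParams, p_new: NetworkParams) -> list:
    """Diagnostic ||Delta W_k|| / ||W_k|| per weight matrix (reported so the
    per-layer rates can be studied; no automatic adaptation is attempted)."""
    out = []
    slices = p_old.layer_slices()
    for lo, hi in zip(slices[:-1], slices[1:]):
        Wk = p_old.weights[lo, hi]
        dWk = p_new.weights[lo, hi] - Wk
        denom = np.linalg.norm(Wk)
        out.append(float(np.linalg.norm(dWk) / denom) if denom else float("nan"))
    return out


def evaluate(p: NetworkParams, ds: Dataset, activation: str,
             cfg: RelaxationConfig, batch_size: int = 500) -> tuple[float, float]:
    """Stateless free-phase evaluation (fresh zero starts, no particles):
    returns (error rate, mean cost)."""
    if len(ds) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    n_out = p.layer_sizes[-1]
    n_hidden = p.n_units - p.layer_sizes[0] - n_out
    errs, costs = [], []
    for lo in range(0, len(ds), batch_size):
        X = ds.features[lo:lo + batch_size]
        D = ds.one_hot[lo:lo + batch_size]
        u0 = init_state(X, n_hidden, n_out)
        w = WorldInput(x=X, d=D)
        u, _ = free_phase(p, w, u0, activation, cfg)
        preds = np.argmax(u.values[..., u.output_idx], axis=-1)
        errs.append(preds != ds.labels[lo:lo + batch_size])
        costs.append(quadratic_cost(u, w))
    return float(np.mean(np.concatenate(errs))), float(
        np.mean(np.concatenate(costs)))


def init_network(layer_sizes, seed: int = 0) -> NetworkParams:
    """Layered network with fan-based uniform weights and zero biases."""
    layer_sizes = tuple(int(s) for s in layer_sizes)
    if any(s < 1 for s in layer_sizes) or len(layer_sizes) < 2:
        raise ValueError("every layer needs at least one unit")
    rng = np.random.default_rng(seed)
    W = glorot_weights(layer_sizes, rng)
    return NetworkParams(W, np.zeros(int(sum(layer_sizes))),
                         layered_mask(layer_sizes), layer_sizes)


def fit(dataset: Dataset, layer_sizes, cfg: TrainConfig,
        init_params: NetworkParams | None = None,
        store: ParticleStore | None = None, start_epoch: int = 0,
        ) -> tuple[NetworkParams, pd.DataFrame, ParticleStore]:
    """Epochs of minibatch SGD on the training split; per-epoch metrics on
    train and validation splits.

    Epoch-level randomness (shuffling, beta signs) is drawn from a
    generator seeded by (seed, epoch), so a run resumed from a checkpoint
    at epoch k reproduces the original epochs k, k+1, ... exactly.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    train = dataset.subset("train")
    valid = dataset.subset("valid")
    if init_params is None:
        p = init_network(layer_sizes, seed=cfg.seed)
    else:
        p = init_params.copy()
    if store is None:
        store = ParticleStore() if cfg.persistent_particles else None

    rows = []
    for epoch in range(start_epoch, start_epoch + cfg.n_epochs):
        rng = np.random.default_rng([cfg.seed, epoch])
        order = rng.permutation(len(train))
        batch_costs, batch_errs, batch_energy, rel_updates = [], [], [], []
        for lo in range(0, len(train), cfg.minibatch_size):
            ids = order[lo:lo + cfg.minibatch_size]
            p, m = train_minibatch(
                p, train.features[ids], train.one_hot[ids], ids, cfg,
                store, rng)
            batch_costs.append(m["cost"])
            batch_errs.append(m["error"])
            batch_energy.append(m["energy"])
            rel_updates.append(m["rel_update"])
        if len(valid):
            valid_err, _ = evaluate(p, valid, cfg.activation, cfg.free_config)
        else:
            valid_err = float("nan")
        row = {
            "epoch": epoch,
            "train_error": float(np.mean(batch_errs)),
            "valid_error": valid_err,
            "mean_cost": float(np.mean(batch_costs)),
            "mean_energy": float(np.mean(batch_energy)),
        }
        for k, v in enumerate(np.nanmean(np.array(rel_updates), axis=0)):
            row[f"rel_update_W{k + 1}"] = float(v)
        rows.append(row)
    history = pd.DataFrame(rows)
    return p, history, store if store is not None else ParticleStore()
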