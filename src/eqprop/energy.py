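"""Hopfield-style energy model: state containers, activations, energies and
their analytic derivatives.

The network is a recurrently connected rate model with symmetric synapses.
A unit ``i`` carries a real-valued potential ``u_i``; its firing rate is
``rho(u_i)``. The internal energy is

    E(u) = 1/2 sum_i u_i^2 - 1/2 sum_{i != j} W_ij rho(u_i) rho(u_j)
           - sum_i b_i rho(u_i),

with ``W`` symmetric and zero on the diagonal. Output units are compared to
a target ``d`` through the quadratic cost ``C = 1/2 ||y - d||^2``, and the
total energy ``F = E + beta * C`` couples the two with the clamping factor
``beta`` (which may be negative).

All state-carrying arrays accept an optional leading batch axis: a state of
shape ``(n_units,)`` is a single network, ``(B, n_units)`` is a batch of B
networks sharing one parameter set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HARD_SIGMOID",
    "LOGISTIC",
    "rho",
    "rho_prime",
    "rho_double_prime",
    "NetworkParams",
    "NetworkState",
    "WorldInput",
    "GradientEstimate",
    "hopfield_energy",
    "quadratic_cost",
    "total_energy",
    "state_gradient",
    "param_gradient",
    "save_params",
    "load_params",
]

HARD_SIGMOID = "hard_sigmoid"
LOGISTIC = "logistic_sigmoid"
_KNOWN_ACTIVATIONS = (HARD_SIGMOID, LOGISTIC)


def _check_activation(kind: str) -> None:
    if kind not in _KNOWN_ACTIVATIONS:
        raise ValueError(
            f"unknown activation {kind!r}; expected one of {_KNOWN_ACTIVATIONS}"
        )


def rho(kind: str, v):
    """Firing-rate nonlinearity, elementwise, mapping into [0, 1]."""
    _check_activation(kind)
    v = np.asarray(v, dtype=float)
    if kind == HARD_SIGMOID:
        return np.clip(v, 0.0, 1.0)
    return 1.0 / (1.0 + np.exp(-v))


def rho_prime(kind: str, v):
    """Derivative of :func:`rho`.

    For the hard sigmoid the derivative is taken to be 1 on the closed
    interval [0, 1] and 0 outside: a clipped unit sitting exactly on a
    boundary stays responsive, so the relaxation dynamics can pull it back
    into the interior.
    """
    _check_activation(kind)
    v = np.asarray(v, dtype=float)
    if kind == HARD_SIGMOID:
        return ((v >= 0.0) & (v <= 1.0)).astype(float)
    r = 1.0 / (1.0 + np.exp(-v))
    return r * (1.0 - r)


def rho_double_prime(kind: str, v):
    """Second derivative of :func:`rho` (zero a.e. for the hard sigmoid)."""
    _check_activation(kind)
    v = np.asarray(v, dtype=float)
    if kind == HARD_SIGMOID:
        return np.zeros_like(v)
    r = 1.0 / (1.0 + np.exp(-v))
    return r * (1.0 - r) * (1.0 - 2.0 * r)


@dataclass
class NetworkParams:
    """Learnable parameters theta = (W, b) plus the connectivity mask.

    ``weights`` is symmetric with zero diagonal and vanishes wherever
    ``mask`` is False. ``layer_sizes``, when present, records the layered
    architecture (inputs first, hidden layers in order, outputs last) used
    for per-layer learning rates.
    """

    weights: np.ndarray
    biases: np.ndarray
    mask: np.ndarray
    layer_sizes: tuple | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.layer_sizes is not None:
            self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        self.validate()

    @property
    def n_units(self) -> int:
        return self.biases.shape[0]

    def validate(self) -> None:
        n = self.n_units
        if self.weights.shape != (n, n) or self.mask.shape != (n, n):
            raise ValueError("weights/mask shape inconsistent with biases")
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("connectivity mask must be symmetric")
        if np.any(np.diag(self.mask)):
            raise ValueError("mask diagonal must be False (no self-connections)")
        if np.max(np.abs(self.weights - self.weights.T), initial=0.0) != 0.0:
            raise ValueError("weights must be exactly symmetric")
        if np.any(self.weights[~self.mask] != 0.0):
            raise ValueError("weights must be zero outside the mask")
        if self.layer_sizes is not None and sum(self.layer_sizes) != n:
            raise ValueError("layer_sizes do not sum to the number of units")

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.weights.copy(), self.biases.copy(), self.mask.copy(),
            self.layer_sizes,
        )

    def layer_slices(self) -> list[slice]:
        """Unit index ranges per layer (requires ``layer_sizes``)."""
        if self.layer_sizes is None:
            raise ValueError("parameters carry no layered structure")
        edges = np.cumsum((0,) + self.layer_sizes)
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class NetworkState:
    """Full unit vector u plus the index sets identifying x, h and y.

    ``values`` has shape ``(..., n_units)``; the free state s = {h, y} is
    ``values[..., free_idx]``. Input units are clamped: relaxation never
    touches them.
    """

    values: np.ndarray
    input_idx: np.ndarray
    hidden_idx: np.ndarray
    output_idx: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.input_idx = np.asarray(self.input_idx, dtype=int)
        self.hidden_idx = np.asarray(self.hidden_idx, dtype=int)
        self.output_idx = np.asarray(self.output_idx, dtype=int)
        n = self.values.shape[-1]
        all_idx = np.concatenate([self.input_idx, self.hidden_idx, self.output_idx])
        if len(np.unique(all_idx)) != n or all_idx.size != n:
            raise ValueError("index sets must be disjoint and cover all units")

    @property
    def n_units(self) -> int:
        return self.values.shape[-1]

    @property
    def free_idx(self) -> np.ndarray:
        """Indices of the free units s = {h, y} (hidden first, then output)."""
        return np.concatenate([self.hidden_idx, self.output_idx])

    @property
    def x(self) -> np.ndarray:
        return self.values[..., self.input_idx]

    @property
    def y(self) -> np.ndarray:
        return self.values[..., self.output_idx]

    def with_values(self, values: np.ndarray) -> "NetworkState":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class WorldInput:
    """The state of the outside world v = (x, d): clamped input and target."""

    x: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.d = np.asarray(self.d, dtype=float)


@dataclass
class GradientEstimate:
    """Per-parameter direction (dW symmetric, db), produced by the two-phase
    rule or by an oracle. Sign convention is context-dependent: oracles
    return gradients, the learning rule returns an ascent direction on -J.
    """

    dW: np.ndarray
    db: np.ndarray

    def flatten(self, mask: np.ndarray) -> np.ndarray:
        """Concatenate the independent parameters: masked upper-triangular
        weights (each symmetric pair is one parameter) plus all biases."""
        iu = np.triu_indices(mask.shape[0], k=1)
        keep = mask[iu]
        return np.concatenate([self.dW[iu][keep], self.db])

    def __neg__(self) -> "GradientEstimate":
        return GradientEstimate(-self.dW, -self.db)


def _check_state_shapes(p: NetworkParams, u: NetworkState) -> None:
    if u.n_units != p.n_units:
        raise ValueError(
            f"state has {u.n_units} units but parameters have {p.n_units}"
        )


def hopfield_energy(p: NetworkParams, u: NetworkState, activation: str):
    """Internal energy E(u); each unordered connected pair counts once."""
    _check_state_shapes(p, u)
    v = u.values
    r = rho(activation, v)
    quad = 0.5 * np.einsum("...i,ij,...j->...", r, p.weights, r)
    leak = 0.5 * np.sum(v * v, axis=-1)
    return leak - quad - r @ p.biases


def quadratic_cost(u: NetworkState, w: WorldInput):
    """Prediction error C = 1/2 ||y - d||^2 at the output units."""
    y = u.values[..., u.output_idx]
    if w.d.shape[-1] != y.shape[-1]:
        raise ValueError("target length does not match the number of output units")
    diff = y - w.d
    return 0.5 * np.sum(diff * diff, axis=-1)


def total_energy(p: NetworkParams, w: WorldInput, beta: float, u: NetworkState,
                 activation: str):
    """Total energy F = E + beta * C; beta may be negative."""
    return hopfield_energy(p, u, activation) + beta * quadratic_cost(u, w)


def state_gradient(p: NetworkParams, w: WorldInput, beta: float,
                   u: NetworkState, activation: str) -> np.ndarray:
    """dF/ds over the free units (hidden entries first, outputs last).

    For a free unit: ``s_i - rho'(s_i) (sum_j W_ij rho(u_j) + b_i)``, plus
    ``beta (y_i - d_i)`` on the output units. No entries are produced for
    the clamped inputs.
    """
    _check_state_shapes(p, u)
    v = u.values
    r = rho(activation, v)
    drive = r @ p.weights + p.biases  # symmetric W: row == column sums
    grad_full = v - rho_prime(activation, v) * drive
    free = u.free_idx
    g = grad_full[..., free]
    if beta != 0.0:
        n_out = u.output_idx.size
        g = g.copy()
        g[..., g.shape[-1] - n_out:] += beta * (v[..., u.output_idx] - w.d)
    return g


def param_gradient(p: NetworkParams, u: NetworkState,
                   activation: str) -> GradientEstimate:
    """dE/dtheta at a state: dE/dW_ij = -rho(u_i) rho(u_j) on masked pairs
    (a symmetric pair is one parameter), dE/db_i = -rho(u_i).

    For a batched state the gradient is averaged over the batch.
    """
    _check_state_shapes(p, u)
    r = rho(activation, u.values)
    if r.ndim == 1:
        dW = -np.outer(r, r)
        db = -r
    else:
        flat = r.reshape(-1, r.shape[-1])
        dW = -(flat.T @ flat) / flat.shape[0]
        db = -flat.mean(axis=0)
    dW = np.where(p.mask, dW, 0.0)
    return GradientEstimate(dW, db)


def cost_param_gradient(p: NetworkParams, u: NetworkState,
                        w: WorldInput) -> GradientEstimate:
    """dC/dtheta. The quadratic cost depends on the state only, so this is
    identically zero; it exists so the contrastive estimator is written for
    a general energy/cost pair."""
    return GradientEstimate(np.zeros_like(p.weights), np.zeros_like(p.biases))


def save_params(path, p: NetworkParams, state_template: NetworkState | None = None,
                activation: str | None = None, extra: dict | None = None,
                **arrays) -> None:
    """Serialize parameters (and optional metadata) to a single .npz archive
    with a JSON header."""
    header = {
        "layer_sizes": list(p.layer_sizes) if p.layer_sizes else None,
        "activation": activation,
    }
    if extra:
        header.update(extra)
    payload = dict(weights=p.weights, biases=p.biases, mask=p.mask, **arrays)
    if state_template is not None:
        payload.update(
            input_idx=state_template.input_idx,
            hidden_idx=state_template.hidden_idx,
            output_idx=state_template.output_idx,
        )
    np.savez(path, header=np.array(json.dumps(header)), **payload)


def load_params(path) -> tuple[NetworkParams, dict]:
    """Inverse of :func:`save_params`; returns the parameters and the full
    archive contents (header decoded) for the caller to interpret."""
    with np.load(path, allow_pickle=False) as z:
        data = {k: z[k] for k in z.files}
    header = json.loads(str(data.pop("header")))
    ls = header.get("layer_sizes")
    p = NetworkParams(
        data.pop("weights"), data.pop("biases"), data.pop("mask"),
        tuple(ls) if ls else None,
    )
    data["header"] = header
    return p, data
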