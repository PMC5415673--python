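"""Ground-truth gradients of the fixed-point objective J for validating the
contrastive estimator.

J(theta) is the quadratic cost evaluated at the free fixed point, which is
an implicit function of the parameters. Two independent oracles compute its
exact gradient:

* brute-force centered finite differences, re-relaxing the network for each
  perturbed parameter; and
* the implicit-function-theorem linear solve (the recurrent-backprop view):
  solve (d2E/ds2) lambda = dC/ds at the free fixed point, then
  dJ/dtheta = dC/dtheta - lambda^T d2E/(ds dtheta).

Both require a smooth activation and tolerance-mode relaxation without the
[0, 1] clip, so the fixed point satisfies dE/ds = 0 exactly in the reals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import fixture_state, make_fixture_network
from .energy import (
    LOGISTIC,
    GradientEstimate,
    NetworkParams,
    NetworkState,
    WorldInput,
    quadratic_cost,
    rho,
    rho_double_prime,
    rho_prime,
    state_gradient,
)
from .learning import eqprop_gradient
from .relaxation import RelaxationConfig, free_phase, init_state, nudged_phase

__all__ = [
    "ORACLE_RELAXATION",
    "GradCheckReport",
    "objective",
    "fd_param_gradient",
    "implicit_param_gradient",
    "state_hessian",
    "theorem1_check",
    "proposition2_check",
]

# Relaxation used by every oracle computation: smooth-activation fixed
# points located to near machine precision, no box clip.
ORACLE_RELAXATION = RelaxationConfig(
    epsilon=0.5, tolerance=1e-13, max_iter=200_000, clip=False)


def _zero_start(p: NetworkParams, w: WorldInput) -> NetworkState:
    n_out = w.d.shape[-1]
    n_hidden = p.n_units - w.x.shape[-1] - n_out
    return init_state(w.x, n_hidden, n_out)


def objective(p: NetworkParams, w: WorldInput, activation: str,
              cfg: RelaxationConfig = ORACLE_RELAXATION,
              u0: NetworkState | None = None) -> float:
    """J = 1/2 ||y^0 - d||^2 at the tolerance-converged free fixed point."""
    if u0 is None:
        u0 = _zero_start(p, w)
    u, _ = free_phase(p, w, u0, activation, cfg)
    return float(quadratic_cost(u, w))


def fd_param_gradient(p: NetworkParams, w: WorldInput, activation: str,
                      cfg: RelaxationConfig = ORACLE_RELAXATION,
                      delta: float = 1e-5,
                      u_free: NetworkState | None = None) -> GradientEstimate:
    """Centered finite differences of J over every independent parameter.

    A symmetric pair (W_ij, W_ji) is one parameter: both entries are
    perturbed together. Each evaluation re-relaxes the network, warm-started
    from the unperturbed fixed point.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if u_free is None:
        u_free, _ = free_phase(p, w, _zero_start(p, w), activation, cfg)

    def J(params: NetworkParams) -> float:
        return objective(params, w, activation, cfg, u0=u_free)

    dW = np.zeros_like(p.weights)
    iu, ju = np.triu_indices(p.n_units, k=1)
    for i, j in zip(iu, ju):
        if not p.mask[i, j]:
            continue
        Wp, Wm = p.weights.copy(), p.weights.copy()
        Wp[i, j] = Wp[j, i] = Wp[i, j] + delta
        Wm[i, j] = Wm[j, i] = Wm[i, j] - delta
        g = (J(NetworkParams(Wp, p.biases, p.mask, p.layer_sizes))
             - J(NetworkParams(Wm, p.biases, p.mask, p.layer_sizes))) / (2 * delta)
        dW[i, j] = dW[j, i] = g
    db = np.zeros_like(p.biases)
    for i in range(p.n_units):
        bp, bm = p.biases.copy(), p.biases.copy()
        bp[i] += delta
        bm[i] -= delta
        db[i] = (J(NetworkParams(p.weights, bp, p.mask, p.layer_sizes))
                 - J(NetworkParams(p.weights, bm, p.mask, p.layer_sizes))
                 ) / (2 * delta)
    return GradientEstimate(dW, db)


def state_hessian(p: NetworkParams, u: NetworkState,
                  activation: str) -> np.ndarray:
    """d2E/ds2 over the free units at a state (analytic)."""
    v = u.values
    if v.ndim != 1:
        raise ValueError("hessian is defined for a single (unbatched) state")
    r = rho(activation, v)
    rp = rho_prime(activation, v)
    rpp = rho_double_prime(activation, v)
    drive = p.weights @ r + p.biases
    free = u.free_idx
    H = -(rp[free, None] * p.weights[np.ix_(free, free)] * rp[None, free])
    np.fill_diagonal(H, 1.0 - rpp[free] * drive[free])
    return H


def implicit_param_gradient(p: NetworkParams, w: WorldInput, activation: str,
                            cfg: RelaxationConfig = ORACLE_RELAXATION,
                            u_free: NetworkState | None = None,
                            cond_limit: float = 1e12) -> GradientEstimate:
    """Exact dJ/dtheta by implicit differentiation through the free fixed
    point: solve H lambda = dC/ds, return dC/dtheta - lambda^T d2E/(ds dtheta).

    Requires an interior fixed point (no unit pinned at a box boundary) and
    a positive-definite, well-conditioned state Hessian; violations raise.
    """
    if u_free is None:
        u_free, _ = free_phase(p, w, _zero_start(p, w), activation, cfg)
    v = u_free.values
    free = u_free.free_idx
    if cfg.clip:
        on_boundary = np.where((v[free] == 0.0) | (v[free] == 1.0))[0]
        if on_boundary.size:
            raise ValueError(
                "free fixed point has clipped units at the box boundary "
                f"(free positions {on_boundary.tolist()}); the implicit "
                "solve needs an interior fixed point")
    H = state_hessian(p, u_free, activation)
    cond = np.linalg.cond(H)
    if not np.isfinite(cond) or cond > cond_limit:
        raise np.linalg.LinAlgError(
            f"state Hessian is singular or ill-conditioned (cond={cond:.3g}); "
            "the fixed point does not satisfy the minimum condition")
    dC_ds = np.zeros(free.size)
    n_out = u_free.output_idx.size
    dC_ds[free.size - n_out:] = v[u_free.output_idx] - w.d
    lam = np.linalg.solve(H, dC_ds)

    t = np.zeros(p.n_units)
    t[free] = lam * rho_prime(activation, v[free])
    r = rho(activation, v)
    dW = np.where(p.mask, np.outer(t, r) + np.outer(r, t), 0.0)
    db = t
    return GradientEstimate(dW, db)


@dataclass
class GradCheckReport:
    """Outcome of a Theorem-1 beta sweep on one seeded instance."""

    seed: int
    layer_sizes: tuple
    betas: list
    one_sided_errors: list
    two_sided_errors: list
    oracle_rel_error: float
    oracle_agreement: bool

    @property
    def errors_monotone(self) -> bool:
        e = self.one_sided_errors
        return all(a > b for a, b in zip(e, e[1:]))

    @property
    def two_sided_beats_one_sided(self) -> bool:
        return all(t < o for t, o in zip(self.two_sided_errors,
                                         self.one_sided_errors))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "layer_sizes": list(self.layer_sizes),
            "betas": list(self.betas),
            "one_sided_errors": list(self.one_sided_errors),
            "two_sided_errors": list(self.two_sided_errors),
            "oracle_rel_error": self.oracle_rel_error,
            "oracle_agreement": self.oracle_agreement,
            "errors_monotone": self.errors_monotone,
            "two_sided_beats_one_sided": self.two_sided_beats_one_sided,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _rel_l2(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))


def theorem1_check(layer_sizes=(5, 8, 3), seed: int = 0,
                   betas=(0.1, 0.01, 0.001), activation: str = LOGISTIC,
                   cfg: RelaxationConfig = ORACLE_RELAXATION,
                   fd_delta: float = 1e-5) -> GradCheckReport:
    """Build a seeded random instance and compare the contrastive estimate
    at each beta (one- and two-sided) against both exact-gradient oracles.

    Errors are relative L2 over the whole independent-parameter vector; the
    update direction is compared against minus the oracle gradient.
    """
    betas = list(betas)
    if any(b == 0 for b in betas):
        raise ValueError("betas must be nonzero")
    p, w = make_fixture_network(layer_sizes, seed=seed)
    u_free, _ = free_phase(p, w, fixture_state(p, w), activation, cfg)

    g_imp = implicit_param_gradient(p, w, activation, cfg, u_free=u_free)
    g_fd = fd_param_gradient(p, w, activation, cfg, delta=fd_delta,
                             u_free=u_free)
    imp_vec = g_imp.flatten(p.mask)
    fd_vec = g_fd.flatten(p.mask)
    oracle_rel = _rel_l2(fd_vec, imp_vec)
    target = -imp_vec  # estimator returns the ascent direction on -J

    one_sided, two_sided = [], []
    for beta in betas:
        u_plus, _ = nudged_phase(p, w, beta, u_free, activation, cfg)
        u_minus, _ = nudged_phase(p, w, -beta, u_free, activation, cfg)
        est_plus = eqprop_gradient(p, w, beta, u_free, u_plus,
                                   activation).flatten(p.mask)
        est_minus = eqprop_gradient(p, w, -beta, u_free, u_minus,
                                    activation).flatten(p.mask)
        one_sided.append(_rel_l2(est_plus, target))
        two_sided.append(_rel_l2(0.5 * (est_plus + est_minus), target))
    return GradCheckReport(
        seed=seed, layer_sizes=tuple(layer_sizes), betas=betas,
        one_sided_errors=one_sided, two_sided_errors=two_sided,
        oracle_rel_error=oracle_rel, oracle_agreement=oracle_rel < 1e-4)


def proposition2_check(p: NetworkParams, w: WorldInput, activation: str,
                       cfg: RelaxationConfig = ORACLE_RELAXATION,
                       beta: float = 0.01) -> tuple[float, float]:
    """Cost at the free fixed point and at the fully converged nudged fixed
    point for beta > 0; nudging can only reduce the cost (up to numerics)."""
    if beta <= 0:
        raise ValueError("proposition-2 check requires beta > 0")
    u_free, _ = free_phase(p, w, _zero_start(p, w), activation, cfg)
    u_nudged, _ = nudged_phase(p, w, beta, u_free, activation, cfg)
    return float(quadratic_cost(u_free, w)), float(quadratic_cost(u_nudged, w))
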