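"""Rate-level STDP reading of the contrastive update.

The continuous-time plasticity rule dW_ij/dt ∝ rho(u_i) d rho(u_j)/dt,
symmetrized for tied weights, integrates along the second-phase path from
the free fixed point to the nudged fixed point into exactly the contrastive
endpoint update rho(u_i^b) rho(u_j^b) - rho(u_i^0) rho(u_j^0). This module
performs that integration on recorded trajectories and reports the
discrepancy against the endpoint rule, at the rate-model level (no spike
trains are simulated).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .energy import NetworkParams, WorldInput, rho
from .relaxation import RelaxationConfig, Trajectory, free_phase, init_state, nudged_phase

__all__ = ["stdp_integrated_update", "stdp_equivalence_report",
           "StdpEquivalenceReport"]


def stdp_integrated_update(traj: Trajectory, p: NetworkParams,
                           activation: str,
                           method: str = "telescoping") -> np.ndarray:
    """Accumulate the symmetrized plasticity rule along a trajectory.

    ``"telescoping"`` sums exact increments of rho(u_i) rho(u_j) and so
    collapses to the endpoint difference; ``"product_rule"`` sums the
    discretization rho_i drho_j + rho_j drho_i (left endpoints), which
    approaches the telescoping value as the step size shrinks (O(epsilon)).
    Returns the masked symmetric update matrix.
    """
    if len(traj) < 2:
        raise ValueError("need at least two states to integrate")
    rhos = [rho(activation, s.values) for s in traj.states]
    if any(r.ndim != 1 for r in rhos):
        raise ValueError("trajectory integration expects unbatched states")
    if method == "telescoping":
        total = np.outer(rhos[-1], rhos[-1]) - np.outer(rhos[0], rhos[0])
    elif method == "product_rule":
        total = np.zeros((p.n_units, p.n_units))
        for r_now, r_next in zip(rhos[:-1], rhos[1:]):
            dr = r_next - r_now
            total += np.outer(r_now, dr) + np.outer(dr, r_now)
    else:
        raise ValueError(f"unknown integration method {method!r}")
    return np.where(p.mask, total, 0.0)


@dataclass
class StdpEquivalenceReport:
    """Integrated second-phase updates vs. the contrastive endpoint update
    (beta * Delta W of the two-point rule)."""

    endpoint: np.ndarray
    telescoping: np.ndarray
    product_rule: np.ndarray
    mask: np.ndarray

    @property
    def telescoping_max_discrepancy(self) -> float:
        return float(np.max(np.abs(self.telescoping - self.endpoint)))

    @property
    def product_rule_max_discrepancy(self) -> float:
        return float(np.max(np.abs(self.product_rule - self.endpoint)))

    def to_frame(self) -> pd.DataFrame:
        """Per-synapse table: one row per masked upper-triangular pair."""
        i, j = np.where(np.triu(self.mask, k=1))
        return pd.DataFrame({
            "pre": i, "post": j,
            "endpoint": self.endpoint[i, j],
            "telescoping": self.telescoping[i, j],
            "product_rule": self.product_rule[i, j],
            "telescoping_discrepancy":
                self.telescoping[i, j] - self.endpoint[i, j],
            "product_rule_discrepancy":
                self.product_rule[i, j] - self.endpoint[i, j],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def stdp_equivalence_report(p: NetworkParams, w: WorldInput, beta: float,
                            activation: str, cfg: RelaxationConfig,
                            ) -> StdpEquivalenceReport:
    """Run a free phase and a fully converged, recorded nudged phase, then
    integrate the plasticity rule along the second-phase path and compare
    both discretizations against the contrastive endpoint update."""
    if beta == 0.0:
        raise ValueError("the second phase requires beta != 0")
    n_out = w.d.shape[-1]
    n_hidden = p.n_units - w.x.shape[-1] - n_out
    u0 = init_state(w.x, n_hidden, n_out)
    u_free, _ = free_phase(p, w, u0, activation, cfg)
    rec_cfg = replace(cfg, record_trajectory=True)
    u_nudged, traj = nudged_phase(p, w, beta, u_free, activation, rec_cfg)

    r_free = rho(activation, u_free.values)
    r_nudged = rho(activation, u_nudged.values)
    endpoint = np.where(p.mask, np.outer(r_nudged, r_nudged)
                        - np.outer(r_free, r_free), 0.0)
    return StdpEquivalenceReport(
        endpoint=endpoint,
        telescoping=stdp_integrated_update(traj, p, activation, "telescoping"),
        product_rule=stdp_integrated_update(traj, p, activation,
                                            "product_rule"),
        mask=p.mask,
    )
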