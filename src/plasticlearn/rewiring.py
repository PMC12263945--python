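"""Structural plasticity: distance-dependent growth, pruning, homeostatic cap.

Topology changes are distinct from weight changes.  Candidate connections
form with a logistic probability of the Euclidean distance between neuron
positions,

    P(e_ij) = α / (1 + e^{−κ(d_ij − d0)}),

either deterministically (every absent pair with P > θ is added) or
stochastically (Bernoulli with intensity λ·a_i·a_j·P·dt, an activity-driven
Hebbian growth rule).  Weak synapses (w < ε) are pruned, and a homeostatic
cap removes weakest-first until at most E_max synapses remain.

As written, P is monotone increasing in distance.  The probability function
is a named, swappable component (``probability_fn`` argument of
:func:`grow_edges`) so a unimodal variant can be configured without touching
callers.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from pydantic import BaseModel, model_validator

from .network import PlasticNetwork

__all__ = [
    "RewireParams",
    "connection_probability",
    "grow_edges",
    "prune_edges",
    "enforce_cap",
]


class RewireParams(BaseModel):
    """Structural-plasticity parameters.

    alpha_grow — maximum growth probability α ∈ [0, 1];
    kappa — distance sensitivity κ > 0;
    d0 — connectivity threshold distance (sigmoid midpoint);
    theta_add — addition threshold θ for deterministic growth;
    epsilon_prune — minimum surviving weight ε;
    lambda_growth — activity-growth intensity λ;
    E_max — homeostatic cap on total synapse count;
    growth_mode — ``threshold`` (deterministic) or ``activity`` (Bernoulli);
    new_weight — initial weight of formed synapses; defaults to
    1.1·epsilon_prune so a new synapse survives the pruning that follows in
    the same step.
    """

    alpha_grow: float = 0.3
    kappa: float = 8.0
    d0: float = 0.5
    theta_add: float = 0.25
    epsilon_prune: float = 0.01
    lambda_growth: float = 0.5
    E_max: int = 400
    growth_mode: str = "activity"
    new_weight: float | None = None

    @model_validator(mode="after")
    def _check(self):
        if not 0.0 <= self.alpha_grow <= 1.0:
            raise ValueError("alpha_grow must lie in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.d0 < 0 or self.epsilon_prune < 0 or self.E_max < 0:
            raise ValueError("d0, epsilon_prune and E_max must be nonnegative")
        if not 0.0 <= self.theta_add <= 1.0:
            raise ValueError("theta_add must lie in [0, 1]")
        if self.lambda_growth < 0:
            raise ValueError("lambda_growth must be nonnegative")
        if self.growth_mode not in ("threshold", "activity"):
            raise ValueError("growth_mode must be 'threshold' or 'activity'")
        return self

    @property
    def formed_weight(self) -> float:
        return 1.1 * self.epsilon_prune if self.new_weight is None else self.new_weight


def connection_probability(d, params: RewireParams):
    """Logistic formation probability α/(1 + e^{−κ(d − d0)}), in (0, α).

    Accepts scalars or arrays.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    out = params.alpha_grow / (1.0 + np.exp(-params.kappa * (d - params.d0)))
    return float(out) if out.ndim == 0 else out


def grow_edges(
    network: PlasticNetwork,
    params: RewireParams,
    activations: np.ndarray,
    dt: float,
    rng: np.random.Generator | None = None,
    probability_fn: Callable[[np.ndarray, RewireParams], np.ndarray] | None = None,
) -> int:
    """Add new synapses to absent ordered non-self pairs, in place.

    threshold mode — every absent pair with P(d_ij) > θ is added
    deterministically (hence idempotent).  activity mode — each absent pair
    is added with Bernoulli probability min(1, λ·a_i·a_j·P(d_ij)·dt) drawn
    from the supplied seeded generator.  Existing synapses are never
    modified.  Returns the number of synapses added.
    """
    if probability_fn is None:
        probability_fn = connection_probability
    P = probability_fn(network.distance_matrix(), params)
    absent = ~network.mask
    np.fill_diagonal(absent, False)
    if params.growth_mode == "threshold":
        add = absent & (P > params.theta_add)
    else:
        if dt <= 0:
            raise ValueError("dt must be positive in activity mode")
        if rng is None:
            raise ValueError("activity-mode growth requires a random generator")
        a = np.asarray(activations, dtype=float)
        intensity = params.lambda_growth * np.outer(a, a) * P * dt
        p = np.minimum(1.0, intensity)
        draws = rng.uniform(size=p.shape)
        add = absent & (draws < p)
    network.mask[add] = True
    network.weights[add] = params.formed_weight
    return int(add.sum())


def prune_edges(network: PlasticNetwork, epsilon_prune: float) -> int:
    """Remove every synapse whose weight is strictly below ε, in place.

    Returns the number removed.
    """
    if epsilon_prune < 0:
        raise ValueError("epsilon_prune must be nonnegative")
    drop = network.mask & (network.weights < epsilon_prune)
    network.mask[drop] = False
    network.weights[drop] = 0.0
    network.last_drive[drop] = 0.0
    return int(drop.sum())


def enforce_cap(network: PlasticNetwork, E_max: int) -> int:
    """Enforce the homeostatic cap Σ e_ij ≤ E_max, in place.

    If the synapse count exceeds E_max, synapses are removed in ascending
    weight order, ties broken by (pre, post) lexicographic order, until the
    count equals E_max.  Returns the number removed.
    """
    if E_max < 0:
        raise ValueError("E_max must be nonnegative")
    excess = network.n_synapses - E_max
    if excess <= 0:
        return 0
    pre, post = np.nonzero(network.mask)  # row-major: (pre, post) lexicographic
    w = network.weights[pre, post]
    # stable sort on weight keeps lexicographic order among ties
    order = np.argsort(w, kind="stable")[:excess]
    network.mask[pre[order], post[order]] = False
    network.weights[pre[order], post[order]] = 0.0
    network.last_drive[pre[order], post[order]] = 0.0
    return int(excess)
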