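"""Synaptic weight dynamics: Hebbian and timing-dependent drives, the weight
ODE with decay, the decaying learning-rate schedule, and multiplicative
weight normalization.

Each synaptic weight obeys, in continuous time,

    dw_ij/dt = η(t) · F(a_i, a_j) − β · w_ij,

where F is the plasticity drive (activity product or pair-based STDP), η(t)
the learning rate and β a passive decay that stabilizes weights.  The
simulator integrates this by forward Euler with a global step dt; the
closed-form solutions for constant drive serve as test oracles.

The model is rate-based and has no spikes: "event times" for the
timing-dependent rules are defined as the most recent upward crossing of an
activation threshold (default 0.5), a deterministic, rate-compatible event
definition.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, model_validator

from .network import PlasticNetwork

__all__ = [
    "PlasticityParams",
    "EventTimes",
    "hebbian_drive",
    "stdp_delta",
    "stdp_pair_drive",
    "drive_matrix",
    "step_weights",
    "decayed_eta",
    "normalize_weights",
]


class PlasticityParams(BaseModel):
    """Parameters of the synaptic weight dynamics.

    Attributes
    ----------
    eta0 : baseline learning rate η0 (≥ 0; zero freezes learning).
    lr_time_decay : λ of the decaying schedule η(t) = η0·e^{−λt}; 0 keeps
        the baseline constant.
    weight_decay : passive decay coefficient β (≥ 0) of the weight ODE.
    A_plus, A_minus : potentiation / depression magnitudes of the
        timing-dependent rules (≥ 0).
    tau_plus, tau_minus : time constants of the two branches of the
        asymmetric timing rule (> 0).
    tau_pair : shared time constant τ of the pair-based drive (> 0).
    gamma_norm : γ of the multiplicative outgoing-weight normalization (≥ 0).
    rule : which drive F feeds the weight ODE, ``hebbian`` (activity
        product) or ``stdp_pair``.
    w_min, w_max : clamp bounds applied after every Euler step; weights are
        nonnegative by default (w_min = 0).
    event_threshold : activation level whose upward crossing defines an
        event time.
    """

    eta0: float = 0.05
    lr_time_decay: float = 0.0
    weight_decay: float = 0.1
    A_plus: float = 1.0
    A_minus: float = 0.5
    tau_plus: float = 1.0
    tau_minus: float = 1.0
    tau_pair: float = 1.0
    gamma_norm: float = 0.1
    rule: str = "hebbian"
    w_min: float = 0.0
    w_max: float = 5.0
    event_threshold: float = 0.5

    @model_validator(mode="after")
    def _check(self):
        if self.eta0 < 0:
            raise ValueError("eta0 must be nonnegative")
        if self.weight_decay < 0 or self.gamma_norm < 0:
            raise ValueError("weight_decay and gamma_norm must be nonnegative")
        if min(self.tau_plus, self.tau_minus, self.tau_pair) <= 0:
            raise ValueError("time constants must be positive")
        if self.A_plus < 0 or self.A_minus < 0:
            raise ValueError("A_plus and A_minus must be nonnegative")
        if not self.w_min <= self.w_max:
            raise ValueError("w_min must not exceed w_max")
        if self.rule not in ("hebbian", "stdp_pair"):
            raise ValueError("rule must be 'hebbian' or 'stdp_pair'")
        return self


class EventTimes:
    """Most recent event time per neuron (NaN = no event yet).

    An event is an upward crossing of the activation threshold: the previous
    activation was below the threshold and the current one is at or above it.
    """

    def __init__(self, n_neurons: int):
        self.times = np.full(n_neurons, np.nan)

    def update(
        self,
        prev_activations: np.ndarray,
        new_activations: np.ndarray,
        t: float,
        threshold: float = 0.5,
    ) -> None:
        crossed = (prev_activations < threshold) & (new_activations >= threshold)
        self.times[crossed] = t


def hebbian_drive(a_pre: float, a_post: float) -> float:
    """Activity-product Hebbian drive F = a_pre · a_post."""
    return a_pre * a_post


def stdp_delta(delta_t: float, params: PlasticityParams) -> float:
    """Asymmetric timing-dependent weight change for Δt = t_post − t_pre.

    Potentiation A₊·e^{−Δt/τ₊} when the presynaptic event precedes the
    postsynaptic one (Δt > 0); depression −A₋·e^{Δt/τ₋} when it follows
    (Δt < 0).  Δt = 0 returns 0 (midpoint of the antisymmetric limit).
    """
    if delta_t > 0:
        return params.A_plus * math.exp(-delta_t / params.tau_plus)
    if delta_t < 0:
        return -params.A_minus * math.exp(delta_t / params.tau_minus)
    return 0.0


def stdp_pair_drive(
    a_pre: float,
    a_post: float,
    t_pre: float,
    t_post: float,
    params: PlasticityParams,
) -> float:
    """Pair-based drive combining activity levels with event-time proximity.

    F = A₊·a_pre·a_post·e^{−|t_pre−t_post|/τ} − A₋·a_pre·a_post·e^{−|t_post−t_pre|/τ}.

    Both exponents share the same |Δt|, so the expression reduces to
    (A₊ − A₋)·a_pre·a_post·e^{−|Δt|/τ}; it is implemented term by term as
    written, with the reduction serving as an independent test oracle.
    Missing event times (NaN) yield drive 0 — no event pair has occurred.
    """
    if math.isnan(t_pre) or math.isnan(t_post):
        return 0.0
    prod = a_pre * a_post
    gap = math.exp(-abs(t_pre - t_post) / params.tau_pair)
    return params.A_plus * prod * gap - params.A_minus * prod * gap


def drive_matrix(
    network: PlasticNetwork,
    params: PlasticityParams,
    event_times: EventTimes | None = None,
) -> np.ndarray:
    """Plasticity drive F for every existing synapse, as an (n, n) matrix.

    The per-synapse rule selected by ``params.rule`` is applied elementwise
    across the weight matrix; entries off the adjacency mask are zero.
    """
    a = network.activations
    prod = np.outer(a, a)
    if params.rule == "hebbian":
        F = prod
    else:
        if event_times is None:
            F = np.zeros_like(prod)
        else:
            t = event_times.times
            gap = np.abs(t[:, None] - t[None, :])  # NaN where either is missing
            kernel = np.exp(-gap / params.tau_pair)
            F = params.A_plus * prod * kernel - params.A_minus * prod * kernel
            F = np.where(np.isnan(F), 0.0, F)
    F = np.where(network.mask, F, 0.0)
    return F


def step_weights(
    network: PlasticNetwork,
    eta_t: float,
    params: PlasticityParams,
    dt: float,
    event_times: EventTimes | None = None,
) -> PlasticNetwork:
    """One forward-Euler step of the weight ODE for every synapse, in place.

    w ← clamp(w + dt·(η(t)·F − β·w), w_min, w_max).  No synapse is added or
    removed here; structural change is the rewiring stage's job.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if eta_t < 0:
        raise ValueError("eta_t must be nonnegative")
    F = drive_matrix(network, params, event_times)
    with np.errstate(over="ignore", invalid="ignore"):  # caught explicitly below
        new_w = network.weights + dt * (
            eta_t * F - params.weight_decay * network.weights
        )
    if not np.all(np.isfinite(new_w[network.mask])):
        bad = np.argwhere(~np.isfinite(new_w) & network.mask)[0]
        raise FloatingPointError(
            f"non-finite weight at synapse ({bad[0]}, {bad[1]}) during step_weights"
        )
    new_w = np.clip(new_w, params.w_min, params.w_max)
    new_w[~network.mask] = 0.0
    network.weights = new_w
    network.last_drive = F
    return network


def decayed_eta(t: float, params: PlasticityParams) -> float:
    """Time-decayed baseline learning rate η(t) = η0·e^{−λt}."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    return params.eta0 * math.exp(-params.lr_time_decay * t)


def normalize_weights(network: PlasticNetwork, gamma_norm: float) -> PlasticNetwork:
    """Multiplicative normalization of each neuron's outgoing weights, in place.

    Every outgoing weight w_ik is divided by (1 + γ·Σ_k w_ik) using the
    pre-update row sum, which bounds each post-normalization row sum strictly
    below 1/γ and prevents runaway growth.
    """
    if gamma_norm < 0:
        raise ValueError("gamma_norm must be nonnegative")
    if gamma_norm == 0:
        return network
    row_sums = network.weights.sum(axis=1, keepdims=True)
    network.weights = network.weights / (1.0 + gamma_norm * row_sums)
    network.weights[~network.mask] = 0.0
    return network
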