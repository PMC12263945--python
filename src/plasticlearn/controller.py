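"""Adaptive-instruction control layer.

Closes the loop between the plastic network and the "curriculum": the total
absolute synaptic change per unit time, P_learn = Σ|dw/dt|, serves as an
engagement signal that drives

* curriculum difficulty D, nudged toward a target plasticity rate and
  clamped to [D_min, D_max] (first-order), or tracking the change in
  plasticity (second-order);
* spaced-repetition review intervals, which expand as plasticity falls and
  knowledge stabilizes: R_next = R·(1 + γ·e^{−β·P_learn});
* multisensory modality weights w_m (probability simplex), updated
  multiplicatively by per-modality learning success;
* neural fatigue F, the running time-integral of total activation, which
  triggers a recovery break of duration T0 + μ·(F − F_max) once it
  surpasses F_max.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, model_validator

__all__ = [
    "ControllerParams",
    "ControllerState",
    "plasticity_rate",
    "update_difficulty",
    "next_review_interval",
    "multisensory_score",
    "update_modality_weights",
    "accumulate_fatigue",
    "maybe_break",
    "tick_break",
]


class ControllerParams(BaseModel):
    """Controller parameters; see the module docstring for roles."""

    P_target: float = 0.5
    alpha_diff: float = 0.2
    beta_diff2: float = 0.2
    D_min: float = 0.5
    D_max: float = 2.0
    gamma_rep: float = 0.5
    beta_rep: float = 1.0
    R_init: float = 5.0
    T0: float = 2.0
    mu_break: float = 0.5
    F_max: float = 100.0
    n_modalities: int = 2
    modality_gain: float = 0.1
    difficulty_mode: str = "first_order"

    @model_validator(mode="after")
    def _check(self):
        if self.D_min > self.D_max:
            raise ValueError("D_min must not exceed D_max")
        if min(self.gamma_rep, self.beta_rep, self.T0, self.mu_break) < 0:
            raise ValueError("gamma_rep, beta_rep, T0 and mu_break must be nonnegative")
        if self.F_max <= 0:
            raise ValueError("F_max must be positive")
        if self.R_init <= 0:
            raise ValueError("R_init must be positive")
        if self.n_modalities < 1:
            raise ValueError("n_modalities must be at least 1")
        if self.difficulty_mode not in ("first_order", "second_order"):
            raise ValueError("difficulty_mode must be 'first_order' or 'second_order'")
        return self


@dataclass
class ControllerState:
    """Mutable controller bookkeeping carried across steps."""

    D: float
    P_learn: float = 0.0
    P_learn_prev: float = 0.0
    R_interval: float = 5.0
    modality_weights: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    A_multi: float = 0.0
    fatigue: float = 0.0
    on_break: bool = False
    break_remaining: float = 0.0

    @classmethod
    def initial(cls, params: ControllerParams) -> "ControllerState":
        """Fresh state: difficulty at the midpoint of its bounds, uniform
        modality weights, first review after R_init."""
        return cls(
            D=0.5 * (params.D_min + params.D_max),
            R_interval=params.R_init,
            modality_weights=np.full(
                params.n_modalities, 1.0 / params.n_modalities
            ),
        )


def plasticity_rate(
    weights_prev: np.ndarray, weights_new: np.ndarray, dt: float
) -> float:
    """Total absolute synaptic change per unit time, Σ|Δw| / dt.

    The two snapshots are aligned over the union of synapses present in
    either (absent = 0), so structural change contributes |w| for a pruned
    synapse and |w_new| for a grown one.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    wp = np.asarray(weights_prev, dtype=float)
    wn = np.asarray(weights_new, dtype=float)
    if wp.shape != wn.shape:
        raise ValueError("weight snapshots must have equal shape")
    return float(np.abs(wn - wp).sum() / dt)


def update_difficulty(
    state: ControllerState, params: ControllerParams, hold: bool = False
) -> ControllerState:
    """Adapt curriculum difficulty toward the plasticity target, in place.

    first_order: D ← clamp(D + α·(P_learn − P_target)); second_order:
    D ← clamp(D + β·(P_learn − P_learn_prev)).  Skipped while an
    intervention hold (or break) is active.
    """
    if hold:
        return state
    if params.difficulty_mode == "first_order":
        raw = state.D + params.alpha_diff * (state.P_learn - params.P_target)
    else:
        raw = state.D + params.beta_diff2 * (state.P_learn - state.P_learn_prev)
    state.D = min(params.D_max, max(params.D_min, raw))
    return state


def next_review_interval(
    R_current: float, P_learn: float, params: ControllerParams
) -> float:
    """Spaced-repetition expansion R_next = R·(1 + γ·e^{−β·P_learn}).

    Strictly decreasing in P_learn and bounded in (R, R·(1 + γ)]: intervals
    lengthen as plasticity (hence forgetting-prone change) subsides.
    """
    if R_current <= 0:
        raise ValueError("R_current must be positive")
    return R_current * (1.0 + params.gamma_rep * math.exp(-params.beta_rep * P_learn))


def multisensory_score(
    modality_weights: np.ndarray, modality_activations: np.ndarray
) -> float:
    """Weighted multisensory engagement A_multi = Σ_m w_m·a_m."""
    w = np.asarray(modality_weights, dtype=float)
    a = np.asarray(modality_activations, dtype=float)
    if w.shape != a.shape:
        raise ValueError("modality weights and activations must have equal length")
    return float(w @ a)


def update_modality_weights(
    weights: np.ndarray, per_modality_plasticity: np.ndarray, modality_gain: float
) -> np.ndarray:
    """Multiplicative-weights update on the modality simplex.

    w_m ← w_m·e^{gain·p_m}, renormalized to sum 1: modalities with greater
    recent learning success gain influence.  Exponents are centred on their
    maximum before exponentiation for numerical stability (the shift cancels
    in the normalization).
    """
    w = np.asarray(weights, dtype=float)
    p = np.asarray(per_modality_plasticity, dtype=float)
    if np.any(w < 0) or np.any(p < 0):
        raise ValueError("weights and plasticity values must be nonnegative")
    z = modality_gain * p
    mult = np.exp(z - z.max())
    new = w * mult
    total = new.sum()
    if total <= 0:
        raise ValueError("modality weights collapsed to zero")
    return new / total


def accumulate_fatigue(fatigue: float, activation_sum: float, dt: float) -> float:
    """Left-rectangle accumulation of the fatigue integral F(t) = ∫ Σ a_i dτ.

    Only the positive part of the activation sum accumulates, so fatigue is
    nondecreasing between breaks even under signed activation functions.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    return fatigue + max(0.0, activation_sum) * dt


def maybe_break(state: ControllerState, params: ControllerParams) -> ControllerState:
    """Start a recovery break when fatigue strictly surpasses F_max, in place.

    Break duration is T_break = T0 + μ·(F − F_max).  While on a break,
    plasticity and difficulty updates are suspended by the simulation loop.
    """
    if state.fatigue > params.F_max and not state.on_break:
        state.on_break = True
        state.break_remaining = params.T0 + params.mu_break * (
            state.fatigue - params.F_max
        )
    return state


def tick_break(state: ControllerState, dt: float) -> ControllerState:
    """Advance break countdown by dt; on completion fatigue resets to 0."""
    if state.on_break:
        state.break_remaining -= dt
        if state.break_remaining <= 0:
            state.on_break = False
            state.break_remaining = 0.0
            state.fatigue = 0.0
    return state
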