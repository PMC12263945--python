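"""Cognitive load, the effective learning state, and adaptive learning-rate laws.

Cognitive load is the scalar functional

    C(t) = γ · Σ_i a_i(t) − δ · Σ_ij w_ij(t),

total activation (processing demand) minus weighted synaptic mass (prior
consolidation).  Three learning-rate laws throttle plasticity by load:

* ``exp``   — η = η0 · e^{−C/C_max}, exponential suppression;
* ``tanh``  — η = η0 · (1 + tanh(−(C − C_θ)/C_s)), sigmoidal overload gate;
* ``state`` — η tracks η0 · S(C), where S = 1/(1 + e^{−λ(C_opt − C)}) is the
  effective learning state, with first-order smoothing
  η ← η + ρ·(η0·S − η) to damp oscillation.

A Heaviside trigger fires an intervention when load deviates from its
optimum by more than a tolerance margin: Θ(|C − C_opt| − ΔC), with the
Θ(0) = 0 convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, model_validator
from scipy.special import expit

__all__ = [
    "LoadParams",
    "LoadState",
    "cognitive_load",
    "eta_exp",
    "eta_tanh",
    "load_rate",
    "effective_state",
    "eta_from_state",
    "smooth_eta",
    "intervention_trigger",
]


class LoadParams(BaseModel):
    """Parameters of the load functional and the η laws.

    gamma_act / delta_syn weight activations and synaptic mass in C(t);
    C_max normalizes the exponential law; (C_theta, C_s) locate and smooth
    the tanh overload gate; (C_opt, lambda_sens) define the effective
    learning state; rho_smooth is the smoothing gain; Delta_C the
    intervention tolerance; (alpha_rate, beta_rate) weight the finite-
    difference load-rate estimate.  ``eta_mode`` selects which law governs a
    closed-loop run.  Raw C may be negative; by default it is clamped at 0
    before entering the η laws, with the raw value logged.
    """

    gamma_act: float = 1.0
    delta_syn: float = 0.5
    C_max: float = 20.0
    C_theta: float = 18.0
    C_s: float = 2.0
    C_opt: float = 16.0
    lambda_sens: float = 1.0
    rho_smooth: float = 0.3
    Delta_C: float = 3.0
    alpha_rate: float = 1.0
    beta_rate: float = 1.0
    eta_mode: str = "state"
    clamp_load_at_zero: bool = True

    @model_validator(mode="after")
    def _check(self):
        if self.C_max <= 0 or self.C_s <= 0 or self.lambda_sens <= 0:
            raise ValueError("C_max, C_s and lambda_sens must be positive")
        if not 0.0 <= self.rho_smooth <= 1.0:
            raise ValueError("rho_smooth must lie in [0, 1]")
        if self.Delta_C < 0:
            raise ValueError("Delta_C must be nonnegative")
        if self.eta_mode not in ("exp", "tanh", "state"):
            raise ValueError("eta_mode must be 'exp', 'tanh' or 'state'")
        return self


@dataclass
class LoadState:
    """Instantaneous load bookkeeping carried between steps."""

    C: float = 0.0  # raw load, may be negative
    dC: float = 0.0  # finite-difference load rate
    S: float = 0.5  # effective learning state, in (0, 1)
    eta: float = 0.0  # current learning rate
    intervene: int = 0  # Heaviside trigger flag


def cognitive_load(
    activations: np.ndarray, weights: np.ndarray, params: LoadParams
) -> float:
    """C = γ·Σ a_i − δ·Σ w_ij over the supplied activation and weight values."""
    return float(
        params.gamma_act * np.sum(activations) - params.delta_syn * np.sum(weights)
    )


def eta_exp(C: float, eta0: float, C_max: float) -> float:
    """Exponential load suppression η = η0·e^{−C/C_max}."""
    if C_max <= 0:
        raise ValueError("C_max must be positive")
    return eta0 * math.exp(-C / C_max)


def eta_tanh(C: float, eta0: float, C_theta: float, C_s: float) -> float:
    """Sigmoidal overload gate η = η0·(1 + tanh(−(C − C_θ)/C_s)).

    Monotone decreasing in C with range (0, 2·η0): below the overload
    threshold the rate can exceed its baseline, above it the rate vanishes.
    """
    if C_s <= 0:
        raise ValueError("C_s must be positive")
    return eta0 * (1.0 + math.tanh(-(C - C_theta) / C_s))


def load_rate(
    delta_activations: np.ndarray,
    delta_weights: np.ndarray,
    dt: float,
    params: LoadParams,
) -> float:
    """Finite-difference estimate dC/dt = α·Σ Δa_i/dt − β·Σ Δw_ij/dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return float(
        params.alpha_rate * np.sum(delta_activations) / dt
        - params.beta_rate * np.sum(delta_weights) / dt
    )


def effective_state(C: float, params: LoadParams) -> float:
    """Effective learning state S = 1/(1 + e^{−λ(C_opt − C)}), in (0, 1).

    Near-optimal load gives S ≈ 1 (efficient learning); overload drives
    S toward 0.  The result is kept strictly inside (0, 1) even where the
    sigmoid saturates at float precision.
    """
    s = float(expit(params.lambda_sens * (params.C_opt - C)))
    return min(max(s, np.nextafter(0.0, 1.0)), np.nextafter(1.0, 0.0))


def eta_from_state(S: float, eta0: float) -> float:
    """State-gated learning rate η = η0·S."""
    return eta0 * S


def smooth_eta(eta_prev: float, S: float, eta0: float, rho_smooth: float) -> float:
    """First-order smoothing η ← η_prev + ρ·(η0·S − η_prev).

    Iterated with constant S this converges geometrically to η0·S at rate
    (1 − ρ) per step.
    """
    if not 0.0 <= rho_smooth <= 1.0:
        raise ValueError("rho_smooth must lie in [0, 1]")
    return eta_prev + rho_smooth * (eta0 * S - eta_prev)


def intervention_trigger(C: float, params: LoadParams) -> int:
    """Heaviside intervention flag Θ(|C − C_opt| − ΔC), with Θ(0) = 0."""
    return 1 if abs(C - params.C_opt) - params.Delta_C > 0 else 0
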