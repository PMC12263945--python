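"""Synthetic multimodal stimulus generation.

All external input to the network is synthetic: a stimulus vector of
``n_modalities × channels_per_modality`` nonnegative channels whose
amplitude scales with the current curriculum difficulty D through

    amplitude = base_amplitude · (1 + difficulty_coupling · D),

so harder material drives the network harder.  Patterns:

* ``constant``    — the difficulty-scaled amplitude on every channel;
* ``ramp``        — amplitude grows linearly with simulation time t;
* ``event_train`` — per-channel Bernoulli events at rate ``event_rate``
  per unit time (a discretized Poisson train), each event carrying the
  difficulty-scaled amplitude;
* ``replay``      — a fixed pattern stored per spec seed, used by
  spaced-repetition review events.

Channel c of the vector feeds neuron c; modality m owns the contiguous
channel block [m·K, (m+1)·K).  Modality activation a_m is the mean input
over that block.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, model_validator

__all__ = ["StimulusSpec", "generate_stimulus", "replay_pattern", "modality_means"]

PATTERNS = ("constant", "ramp", "event_train", "replay")


class StimulusSpec(BaseModel):
    n_modalities: int = 2
    channels_per_modality: int = 4
    pattern: str = "constant"
    base_amplitude: float = 1.0
    difficulty_coupling: float = 0.5
    event_rate: float = 2.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.n_modalities < 1 or self.channels_per_modality < 1:
            raise ValueError("n_modalities and channels_per_modality must be >= 1")
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.base_amplitude < 0 or self.difficulty_coupling < 0:
            raise ValueError("base_amplitude and difficulty_coupling must be >= 0")
        if self.event_rate < 0:
            raise ValueError("event_rate must be nonnegative")
        return self

    @property
    def n_channels(self) -> int:
        return self.n_modalities * self.channels_per_modality


def replay_pattern(spec: StimulusSpec) -> np.ndarray:
    """The stored review pattern: a fixed seeded draw in [0, base_amplitude]."""
    rng = np.random.default_rng(spec.seed)
    return rng.uniform(0.0, max(spec.base_amplitude, 1e-12), size=spec.n_channels)


def generate_stimulus(
    spec: StimulusSpec,
    D: float,
    t: float,
    rng: np.random.Generator | None = None,
    dt: float = 1.0,
) -> np.ndarray:
    """One stimulus vector for difficulty D at time t.

    ``dt`` scales the event probability of the ``event_train`` pattern
    (events per step = event_rate·dt).  Deterministic given (spec, D, t) and
    the generator state.
    """
    amp = spec.base_amplitude * (1.0 + spec.difficulty_coupling * D)
    if spec.pattern == "constant":
        return np.full(spec.n_channels, amp)
    if spec.pattern == "ramp":
        return np.full(spec.n_channels, amp * t)
    if spec.pattern == "event_train":
        if rng is None:
            raise ValueError("event_train pattern requires a random generator")
        p = min(1.0, spec.event_rate * dt)
        events = rng.uniform(size=spec.n_channels) < p
        return np.where(events, amp, 0.0)
    if spec.pattern == "replay":
        return replay_pattern(spec)
    raise ValueError(f"unknown pattern {spec.pattern!r}")


def modality_means(spec: StimulusSpec, stimulus: np.ndarray) -> np.ndarray:
    """Per-modality mean input a_m over each modality's channel block."""
    return stimulus.reshape(spec.n_modalities, spec.channels_per_modality).mean(axis=1)
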