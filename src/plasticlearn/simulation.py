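"""Closed-loop simulation: the fixed-order step, run orchestration, sweeps.

Each discrete step of size dt applies, in a fixed, normative order:

1.  stimulus generation (or replay, on a spaced-repetition review event);
2.  synchronous neuron activation;
3.  cognitive load C(t) and its finite-difference rate;
4.  learning-rate update per the configured η law (with smoothing in
    ``state`` mode);
5.  the Heaviside intervention trigger (starts a difficulty-freeze hold);
6.  forward-Euler synaptic weight update;
7.  multiplicative weight normalization;
8.  structural rewiring — grow, prune, homeostatic cap;
9.  plasticity-rate measurement from weight snapshots taken before stage 6
    and after stage 8, so structural change contributes to P_learn;
10. controller updates — difficulty, review scheduling, modality weights,
    fatigue accumulation, break triggering.

Stages 6–10 are suspended while a recovery break is in progress (only the
break countdown advances).  Invariant-restoring stages (prune, cap) run
last within rewiring.

Randomness is a single seeded source with named substreams (neuron
placement, stimulus events, rewiring draws), so disabling one stochastic
component does not shift another's draws.  Identical config + seed gives
byte-identical trajectory CSVs; floats are serialized with 17 significant
digits.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cognitive_load import (
    LoadState,
    cognitive_load,
    effective_state,
    eta_exp,
    eta_tanh,
    intervention_trigger,
    load_rate,
    smooth_eta,
)
from .config import SimulationConfig
from .controller import (
    ControllerState,
    accumulate_fatigue,
    maybe_break,
    multisensory_score,
    next_review_interval,
    plasticity_rate,
    tick_break,
    update_difficulty,
    update_modality_weights,
)
from .network import PlasticNetwork, activate, build_network, write_network
from .plasticity import EventTimes, decayed_eta, normalize_weights, step_weights
from .rewiring import enforce_cap, grow_edges, prune_edges
from .stimulus import generate_stimulus, modality_means, replay_pattern

__all__ = ["Simulator", "run", "sweep", "TRAJECTORY_COLUMNS"]

TRAJECTORY_COLUMNS = [
    "t",
    "C_raw",
    "C_clamped",
    "S",
    "eta",
    "intervene",
    "P_learn",
    "D",
    "R_interval",
    "A_multi",
    "fatigue",
    "on_break",
    "edge_count",
    "edges_added",
    "edges_pruned",
    "edges_capped",
    "mean_weight",
    "sum_activation",
]


class Simulator:
    """Stateful closed-loop simulator for one configuration.

    Parameters
    ----------
    config : validated simulation configuration.
    network : optional pre-built network; by default one is constructed from
        the ``network`` section using the placement substream.
    """

    def __init__(self, config: SimulationConfig, network: PlasticNetwork | None = None):
        self.config = config
        if config.controller.n_modalities != config.stimulus.n_modalities:
            raise ValueError(
                "controller.n_modalities must equal stimulus.n_modalities"
            )
        ss = np.random.SeedSequence(config.run.seed)
        placement_ss, stimulus_ss, rewiring_ss = ss.spawn(3)
        self.stimulus_rng = np.random.default_rng(stimulus_ss)
        self.rewiring_rng = np.random.default_rng(rewiring_ss)
        if network is None:
            nc = config.network
            network = build_network(
                nc.n_neurons,
                nc.edge_density,
                rng=np.random.default_rng(placement_ss),
                weight_init=(nc.weight_init_low, nc.weight_init_high),
                bias=nc.bias,
            )
        self.network = network
        self.event_times = EventTimes(network.n_neurons)
        self.load_state = LoadState(eta=config.plasticity.eta0)
        self.controller_state = ControllerState.initial(config.controller)
        self.step_index = 0
        self.hold_remaining = 0  # intervention difficulty freeze, in steps
        self.total_breaks = 0
        self.prev_sum_a = float(network.activations.sum())
        self.prev_sum_w = float(network.weights.sum())
        self.steps_to_review = self._review_steps(self.controller_state.R_interval)
        # modality m owns input channels / neurons [m*K, (m+1)*K)
        k = config.stimulus.channels_per_modality
        n = network.n_neurons
        self._modality_blocks = [
            np.arange(m * k, min((m + 1) * k, n))
            for m in range(config.stimulus.n_modalities)
        ]

    def _review_steps(self, R_interval: float) -> int:
        return max(1, math.ceil(R_interval / self.config.run.dt))

    def _input_vector(self, stim: np.ndarray) -> np.ndarray:
        """Map stimulus channels onto neurons: channel c feeds neuron c."""
        x = np.zeros(self.network.n_neurons)
        m = min(stim.size, x.size)
        x[:m] = stim[:m]
        return x

    def step(self) -> dict:
        """Advance one step; returns the trajectory row as a dict."""
        cfg = self.config
        dt = cfg.run.dt
        net = self.network
        load = self.load_state
        ctrl = self.controller_state
        t = self.step_index * dt
        on_break = ctrl.on_break

        # review scheduling pauses during breaks
        review_event = False
        if not on_break:
            self.steps_to_review -= 1
            review_event = self.steps_to_review <= 0

        # (1) stimulus
        if review_event:
            stim = replay_pattern(cfg.stimulus)
        else:
            stim = generate_stimulus(
                cfg.stimulus, ctrl.D, t, self.stimulus_rng, dt=dt
            )

        # (2) synchronous activation
        a_prev = net.activations.copy()
        activate(net, self._input_vector(stim), cfg.network.activation_fn,
                 cfg.network.convention)

        # (3) cognitive load and its rate
        sum_a = float(net.activations.sum())
        sum_w = float(net.weights.sum())
        C_raw = cognitive_load(net.activations, net.weights, cfg.load)
        C_used = max(0.0, C_raw) if cfg.load.clamp_load_at_zero else C_raw
        dC = load_rate(
            np.array([sum_a - self.prev_sum_a]),
            np.array([sum_w - self.prev_sum_w]),
            dt,
            cfg.load,
        )

        # (4) learning rate per the configured law
        eta_base = decayed_eta(t, cfg.plasticity)
        S = effective_state(C_used, cfg.load)
        if cfg.load.eta_mode == "exp":
            eta = eta_exp(C_used, eta_base, cfg.load.C_max)
        elif cfg.load.eta_mode == "tanh":
            eta = eta_tanh(C_used, eta_base, cfg.load.C_theta, cfg.load.C_s)
        else:
            eta = smooth_eta(load.eta, S, eta_base, cfg.load.rho_smooth)

        # (5) intervention trigger on the raw (unclamped) load deviation
        intervene = intervention_trigger(C_raw, cfg.load)
        if intervene:
            self.hold_remaining = cfg.run.intervention_hold_steps

        load.C, load.dC, load.S, load.eta, load.intervene = C_raw, dC, S, eta, intervene

        edges_added = edges_pruned = edges_capped = 0
        P_learn_step = 0.0
        if not on_break:
            # (6-8) plasticity and structural rewiring
            w_before = net.weights.copy()
            self.event_times.update(
                a_prev, net.activations, t, cfg.plasticity.event_threshold
            )
            step_weights(net, eta, cfg.plasticity, dt, self.event_times)
            normalize_weights(net, cfg.plasticity.gamma_norm)
            if cfg.run.rewiring_enabled:
                edges_added = grow_edges(
                    net, cfg.rewiring, net.activations, dt, self.rewiring_rng
                )
                edges_pruned = prune_edges(net, cfg.rewiring.epsilon_prune)
                edges_capped = enforce_cap(net, cfg.rewiring.E_max)

            # (9) plasticity rate over the union of synapses (absent = 0)
            P_learn_step = plasticity_rate(w_before, net.weights, dt)
            ctrl.P_learn_prev = ctrl.P_learn
            ctrl.P_learn = P_learn_step

            # (10) controller
            update_difficulty(ctrl, cfg.controller, hold=self.hold_remaining > 0)
            if review_event:
                ctrl.R_interval = next_review_interval(
                    ctrl.R_interval, ctrl.P_learn, cfg.controller
                )
                self.steps_to_review = self._review_steps(ctrl.R_interval)
            abs_dw = np.abs(net.weights - w_before)
            p_m = np.array(
                [abs_dw[block, :].sum() / dt for block in self._modality_blocks]
            )
            ctrl.modality_weights = update_modality_weights(
                ctrl.modality_weights, p_m, cfg.controller.modality_gain
            )
            ctrl.A_multi = multisensory_score(
                ctrl.modality_weights, modality_means(cfg.stimulus, stim)
            )
            ctrl.fatigue = accumulate_fatigue(ctrl.fatigue, sum_a, dt)
            maybe_break(ctrl, cfg.controller)
            if ctrl.on_break:
                self.total_breaks += 1
        else:
            tick_break(ctrl, dt)

        if self.hold_remaining > 0:
            self.hold_remaining -= 1
        self.prev_sum_a, self.prev_sum_w = sum_a, sum_w
        self.step_index += 1
        net.time = self.step_index * dt

        n_edges = net.n_synapses
        return {
            "t": t,
            "C_raw": C_raw,
            "C_clamped": C_used,
            "S": S,
            "eta": eta,
            "intervene": int(intervene),
            "P_learn": P_learn_step,
            "D": ctrl.D,
            "R_interval": ctrl.R_interval,
            "A_multi": ctrl.A_multi,
            "fatigue": ctrl.fatigue,
            "on_break": int(on_break),
            "edge_count": n_edges,
            "edges_added": edges_added,
            "edges_pruned": edges_pruned,
            "edges_capped": edges_capped,
            "mean_weight": sum_w / n_edges if n_edges else 0.0,
            "sum_activation": sum_a,
        }


def run(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    network: PlasticNetwork | None = None,
) -> tuple[pd.DataFrame, PlasticNetwork]:
    """Run ``n_steps`` closed-loop steps; return (trajectory, final network).

    With ``out_dir`` set, writes ``trajectory.csv`` (floats at 17 significant
    digits), periodic network snapshots as edge-list/neuron TSV pairs, and a
    ``run_meta.json`` sidecar echoing the configuration and versions.
    """
    sim = Simulator(config, network=network)
    rows = [sim.step() for _ in range(config.run.n_steps)]
    trajectory = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trajectory.to_csv(out / "trajectory.csv", index=False, float_format="%.17g")
        write_network(sim.network, str(out / "network_final"))
        meta = {
            "config": config.model_dump(),
            "seed": config.run.seed,
            "plasticlearn_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "total_breaks": sim.total_breaks,
        }
        (out / "run_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return trajectory, sim.network


def run_with_snapshots(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[pd.DataFrame, PlasticNetwork]:
    """Like :func:`run` but also writes a snapshot every ``snapshot_every`` steps."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = Simulator(config)
    rows = []
    for i in range(config.run.n_steps):
        rows.append(sim.step())
        if (i + 1) % config.run.snapshot_every == 0:
            write_network(sim.network, str(out / f"snapshot_{i + 1:05d}"))
    trajectory = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    trajectory.to_csv(out / "trajectory.csv", index=False, float_format="%.17g")
    write_network(sim.network, str(out / "network_final"))
    meta = {
        "config": config.model_dump(),
        "seed": config.run.seed,
        "plasticlearn_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "total_breaks": sim.total_breaks,
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return trajectory, sim.network


def summarize(trajectory: pd.DataFrame) -> dict:
    """Headline summary statistics of one run's trajectory."""
    breaks = int((trajectory["on_break"].diff().fillna(trajectory["on_break"]) > 0).sum())
    return {
        "mean_eta": float(trajectory["eta"].mean()),
        "mean_C": float(trajectory["C_clamped"].mean()),
        "final_D": float(trajectory["D"].iloc[-1]),
        "final_edge_count": int(trajectory["edge_count"].iloc[-1]),
        "total_breaks": breaks,
    }


def sweep(config: SimulationConfig, parameter_grid: dict[str, list]) -> pd.DataFrame:
    """One run per point of the cartesian grid over dotted config fields.

    Seeds are offset deterministically (base seed + run index).  Returns one
    summary row per run: the grid values plus mean η, mean clamped C, final
    D, final edge count and total breaks.
    """
    import itertools

    names = list(parameter_grid)
    records = []
    for idx, values in enumerate(itertools.product(*(parameter_grid[n] for n in names))):
        overrides = dict(zip(names, values))
        cfg = config.with_overrides(overrides)
        cfg = cfg.with_overrides({"run.seed": config.run.seed + idx})
        trajectory, _ = run(cfg)
        rec = {"run_index": idx, **overrides, **summarize(trajectory)}
        records.append(rec)
    return pd.DataFrame(records)
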