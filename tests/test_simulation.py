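import math

import numpy as np
import pandas as pd
import pytest

from plasticlearn import SimulationConfig, Simulator, StimulusSpec, demo_config, run, sweep
from plasticlearn.cognitive_load import (
    cognitive_load,
    effective_state,
    intervention_trigger,
    smooth_eta,
)
from plasticlearn.controller import (
    multisensory_score,
    plasticity_rate,
    update_modality_weights,
)
from plasticlearn.network import activate
from plasticlearn.plasticity import normalize_weights, step_weights
from plasticlearn.stimulus import generate_stimulus, modality_means, replay_pattern

from conftest import make_network


class TestStimulus:
    def test_zero_base_amplitude_gives_zero_vector(self):
        spec = StimulusSpec(pattern="constant", base_amplitude=0.0)
        assert np.all(generate_stimulus(spec, D=3.0, t=5.0) == 0.0)

    def test_difficulty_coupling_scales_amplitude(self):
        spec = StimulusSpec(pattern="constant", base_amplitude=1.0,
                            difficulty_coupling=0.5)
        stim = generate_stimulus(spec, D=2.0, t=0.0)
        assert np.all(stim == pytest.approx(2.0))

    def test_ramp_is_linear_in_time(self):
        spec = StimulusSpec(pattern="ramp", base_amplitude=0.5,
                            difficulty_coupling=0.0)
        s1 = generate_stimulus(spec, D=1.0, t=2.0)
        s2 = generate_stimulus(spec, D=1.0, t=4.0)
        assert np.all(s2 == pytest.approx(2 * s1))

    def test_event_train_deterministic_under_same_seed(self):
        spec = StimulusSpec(pattern="event_train", event_rate=5.0)
        seqs = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            seqs.append(
                np.concatenate(
                    [generate_stimulus(spec, 1.0, t, rng, dt=0.1) for t in range(20)]
                )
            )
        assert np.array_equal(seqs[0], seqs[1])

    def test_replay_pattern_is_stable_per_spec_seed(self):
        spec = StimulusSpec(seed=5)
        assert np.array_equal(replay_pattern(spec), replay_pattern(spec))
        other = StimulusSpec(seed=6)
        assert not np.array_equal(replay_pattern(spec), replay_pattern(other))

    def test_modality_means_average_channel_blocks(self):
        spec = StimulusSpec(n_modalities=2, channels_per_modality=2)
        means = modality_means(spec, np.array([1.0, 3.0, 0.0, 4.0]))
        assert means == pytest.approx([2.0, 2.0])


def frozen_config(n_steps=30):
    cfg = SimulationConfig()
    return cfg.with_overrides({
        "plasticity.eta0": 0.0,
        "plasticity.weight_decay": 0.0,
        "plasticity.gamma_norm": 0.0,
        "run.rewiring_enabled": False,
        "run.n_steps": n_steps,
        "network.n_neurons": 12,
    })


class TestClosedLoop:
    def test_frozen_dynamics_leave_weights_and_topology_unchanged(self):
        sim = Simulator(frozen_config())
        w0, m0 = sim.network.weights.copy(), sim.network.mask.copy()
        for _ in range(30):
            row = sim.step()
            assert row["P_learn"] == 0.0
        assert np.array_equal(sim.network.weights, w0)
        assert np.array_equal(sim.network.mask, m0)

    def test_single_step_run_has_one_row_and_time_grid_is_exact(self):
        cfg = demo_config(seed=3).with_overrides({"run.n_steps": 1})
        traj, _ = run(cfg)
        assert len(traj) == 1
        cfg = demo_config(seed=3).with_overrides({"run.n_steps": 40})
        traj, _ = run(cfg)
        assert len(traj) == 40
        assert np.allclose(np.diff(traj["t"]), cfg.run.dt)

    def test_trajectory_csv_round_trip_is_lossless(self, tmp_path):
        cfg = demo_config(seed=4).with_overrides({"run.n_steps": 25})
        traj, _ = run(cfg, out_dir=tmp_path)
        back = pd.read_csv(tmp_path / "trajectory.csv", float_precision="round_trip")
        assert list(back.columns) == list(traj.columns)
        for col in traj.columns:
            np.testing.assert_array_equal(back[col].to_numpy(), traj[col].to_numpy())

    def test_same_config_and_seed_give_byte_identical_csvs(self, tmp_path):
        for d in ("a", "b"):
            run(demo_config(seed=8).with_overrides({"run.n_steps": 60}),
                out_dir=tmp_path / d)
        a = (tmp_path / "a" / "trajectory.csv").read_bytes()
        b = (tmp_path / "b" / "trajectory.csv").read_bytes()
        assert a == b

    def test_demo_run_completes_with_edge_count_under_cap(self):
        cfg = demo_config(seed=1)
        traj, net = run(cfg)
        assert len(traj) == 200
        assert net.n_synapses <= cfg.rewiring.E_max
        assert (traj["edge_count"] <= cfg.rewiring.E_max).all()

    def test_one_step_matches_manual_composition_of_stage_order(self):
        """A single closed-loop step equals the module operations applied by
        hand in the documented stage order, on a hand-set 2-neuron state."""
        cfg = SimulationConfig.model_validate({
            "network": {"n_neurons": 2},
            "stimulus": {"n_modalities": 2, "channels_per_modality": 1,
                         "pattern": "constant", "base_amplitude": 0.8,
                         "difficulty_coupling": 0.5},
            "controller": {"n_modalities": 2, "D_min": 1.0, "D_max": 1.0},
            "run": {"rewiring_enabled": False, "dt": 0.1, "n_steps": 1},
        })
        w = np.array([[0.0, 0.6], [0.3, 0.0]])
        net = make_network(w, positions=np.array([[0.2, 0.2], [0.8, 0.8]]))
        sim = Simulator(cfg, network=net.copy())
        row = sim.step()

        # manual composition
        p, lp, cp = cfg.plasticity, cfg.load, cfg.controller
        man = net.copy()
        stim = generate_stimulus(cfg.stimulus, D=1.0, t=0.0)
        a = activate(man, stim, "logistic", "incoming")
        C_raw = cognitive_load(a, man.weights, lp)
        C_used = max(0.0, C_raw)
        S = effective_state(C_used, lp)
        eta = smooth_eta(p.eta0, S, p.eta0, lp.rho_smooth)
        intervene = intervention_trigger(C_raw, lp)
        w_before = man.weights.copy()
        step_weights(man, eta, p, cfg.run.dt)
        normalize_weights(man, p.gamma_norm)
        P_learn = plasticity_rate(w_before, man.weights, cfg.run.dt)
        abs_dw = np.abs(man.weights - w_before)
        p_m = np.array([abs_dw[0, :].sum(), abs_dw[1, :].sum()]) / cfg.run.dt
        mw = update_modality_weights(np.array([0.5, 0.5]), p_m, cp.modality_gain)
        A_multi = multisensory_score(mw, modality_means(cfg.stimulus, stim))

        assert row["C_raw"] == pytest.approx(C_raw, rel=1e-12)
        assert row["S"] == pytest.approx(S, rel=1e-12)
        assert row["eta"] == pytest.approx(eta, rel=1e-12)
        assert row["intervene"] == intervene
        assert row["P_learn"] == pytest.approx(P_learn, rel=1e-12)
        assert row["A_multi"] == pytest.approx(A_multi, rel=1e-12)
        assert row["D"] == 1.0
        assert row["fatigue"] == pytest.approx(a.sum() * cfg.run.dt, rel=1e-12)
        np.testing.assert_allclose(sim.network.weights, man.weights, rtol=1e-12)


class TestSweep:
    def test_degenerate_grid_equals_single_run_summary(self):
        from plasticlearn.simulation import summarize

        cfg = demo_config(seed=2).with_overrides({"run.n_steps": 40})
        table = sweep(cfg, {"plasticity.eta0": [0.05]})
        direct = summarize(run(cfg)[0])
        assert len(table) == 1
        for key, val in direct.items():
            assert table.iloc[0][key] == pytest.approx(val)

    def test_zero_eta_row_has_no_plasticity(self):
        cfg = frozen_config(n_steps=40)
        traj, _ = run(cfg)
        assert (traj["P_learn"] == 0.0).all()
        live = cfg.with_overrides({"plasticity.eta0": 0.05})
        traj_live, _ = run(live)
        assert traj_live["P_learn"].max() > 0

    def test_higher_stimulus_amplitude_raises_mean_load(self):
        base = demo_config(seed=6).with_overrides({"run.n_steps": 80})
        lo, _ = run(base.with_overrides({"stimulus.base_amplitude": 0.2}))
        hi, _ = run(base.with_overrides({"stimulus.base_amplitude": 2.5}))
        assert hi["C_clamped"].mean() > lo["C_clamped"].mean()

    def test_unknown_grid_field_rejected(self):
        cfg = demo_config(seed=0)
        with pytest.raises(KeyError):
            sweep(cfg, {"plasticity.not_a_field": [1]})
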