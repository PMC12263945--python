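# plasticlearn

A seeded, discrete-time simulator of a **plastic neural graph coupled to an
adaptive-instruction control loop**, for researchers studying
neuroplasticity-inspired models of learning: how synaptic-level adaptation
(Hebbian/STDP weight dynamics, structural rewiring) can drive — and be driven
by — instructional control signals such as curriculum difficulty, spaced
repetition, and fatigue-aware breaks.

The model is a functional control architecture, not a biophysical one: it has
no spikes, membrane potentials, or physiological data. Continuous-valued
rate neurons and scalar control laws capture the directional tendencies of
plasticity (potentiation, depression, growth, pruning, homeostasis).

## The model

A learner's network is a directed weighted graph N = (V, E). Neuron
activations update synchronously, a_i = σ(Σ_j w_ji a_j + b_i + I_i), with a
configurable nonlinearity σ (logistic by default) and external stimulus I.
Each synaptic weight follows

```
dw_ij/dt = η(t) · F(a_i, a_j) − β · w_ij
```

integrated by forward Euler with step dt, where F is the plasticity drive
(activity product, or a pair-based STDP form using activation-threshold
event times) and β a stabilizing decay; outgoing weights are normalized
multiplicatively, w_ik ← w_ik / (1 + γ Σ_k w_ik).

The learning rate is throttled by **cognitive load**
C(t) = γ Σ_i a_i − δ Σ_ij w_ij through one of three laws: exponential
(η0·e^{−C/C_max}), a tanh overload gate, or the **effective learning state**
S = 1/(1 + e^{−λ(C_opt − C)}) with first-order smoothing
η ← η + ρ(η0·S − η). Deviations |C − C_opt| > ΔC fire a Heaviside
intervention trigger that freezes difficulty updates.

**Structural rewiring**: absent connections form with logistic
distance-dependent probability P(e_ij) = α/(1 + e^{−κ(d_ij − d0)}) — either
deterministically when P > θ or stochastically at Bernoulli intensity
λ a_i a_j P(e_ij) dt; weights below ε are pruned, and a homeostatic cap
removes weakest-first synapses beyond E_max.

**The controller** measures the plasticity rate P_learn = Σ|dw/dt| and
adapts: curriculum difficulty D ← clamp(D + α(P_learn − P_target)); review
intervals R ← R(1 + γ e^{−β·P_learn}); modality weights (multiplicative
update on the simplex, scored by A_multi = Σ_m w_m a_m); and fatigue
F = ∫ Σ a_i dτ, which above F_max triggers a break of length
T0 + μ(F − F_max).

## Worked example

Run the packaged 200-step demo (30 logistic neurons, density 0.15, cap
E_max = 120, state-mode learning rate, constant difficulty-coupled
stimulus):

```bash
plasticlearn demo --out demo_out --seed 0
```

which prints

```json
{
  "mean_eta": 0.02252919769182447,
  "mean_C": 16.186161120038495,
  "final_D": 0.5,
  "final_edge_count": 120,
  "total_breaks": 1
}
```

Read: the network settles near its optimal load (C ≈ 16.2 against
C_opt = 16), so the smoothed learning rate averages ≈ 0.45·η0; synaptic
turnover keeps the edge count pinned at the homeostatic cap (120); measured
plasticity stays below the controller's target, so difficulty relaxes to its
floor D_min = 0.5; and accumulated activation crosses F_max = 100 once,
triggering one recovery break. `demo_out/` contains the per-step trajectory
CSV, edge-list/neuron TSV snapshots, the echoed config, and a run-metadata
sidecar.

The same loop is scriptable:

```python
import plasticlearn as pl

cfg = pl.demo_config(seed=0)
trajectory, network = pl.run(cfg, out_dir="demo_out")
print(trajectory[["t", "C_clamped", "eta", "D", "edge_count"]].tail())
```

`plasticlearn simulate --config cfg.yaml --out DIR`,
`plasticlearn sweep --config cfg.yaml --grid grid.json --out DIR` and
`plasticlearn report --trajectory FILE` run custom configs, parameter
grids, and trajectory summaries.

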