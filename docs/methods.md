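# Methods

## Scope and modeling stance

`plasticlearn` simulates a rate-based plastic neural graph under closed-loop
adaptive instruction. It is a functionally inspired control model: neurons
are continuous-valued units, "spike times" are threshold-crossing events of
those rates, and cognitive constructs (load, fatigue, difficulty) are scalar
functionals of network state. Nothing is calibrated to neural recordings or
human data, and no claim of biological realism is made beyond directional
correspondence (potentiation/depression, growth/pruning, homeostasis,
overload-throttled learning).

## State and dynamics

A network holds n neurons with fixed positions in the unit square (used only
to define the Euclidean inter-neuron distance d_ij for rewiring), biases,
activations, and a dense weight matrix w[pre, post] masked by the adjacency.
Time is dimensionless and advances in fixed steps dt; all differential
equations are integrated by forward Euler. This is the simplest scheme whose
global first-order error can be verified against closed forms, and the test
suite checks both the 10·dt error bound on the linear weight ODE and the
error-halving behavior under dt-halving.

Activation updates are synchronous: every neuron reads the previous step's
activation vector, making the update a pure, order-independent function of
state. A neuron's drive sums over its *incoming* synapses (the standard
rate-network convention); the transpose convention is available as a config
switch because the summation index order is genuinely ambiguous in this
model family.

### Plasticity drives

Two drives F(a_pre, a_post) feed the weight equation
dw/dt = η·F − β·w:

* `hebbian` — the activity product a_pre·a_post (default);
* `stdp_pair` — A₊·a_pre·a_post·e^{−|Δt|/τ} − A₋·a_pre·a_post·e^{−|Δt|/τ},
  where Δt is the difference of the two neurons' most recent *event times*.

An event is defined as the upward crossing of an activation threshold
(default 0.5): deterministic, and the natural analog of a spike for a rate
unit. The pair form is implemented term by term as stated, even though the
two terms share |Δt| and therefore cancel exactly when A₊ = A₋; the
algebraic reduction to (A₊ − A₋)·a·a·e^{−|Δt|/τ} is used as an independent
test oracle, not as the implementation. The separate asymmetric kernel
(A₊e^{−Δt/τ₊} for Δt > 0, −A₋e^{Δt/τ₋} for Δt < 0) is exposed as
`stdp_delta`, with the Δt = 0 value set to 0 — the midpoint of the
antisymmetric limit. Weights are clamped to [w_min, w_max] after every
step; w_min = 0 by default, since pruning on w < ε presumes a nonnegative
magnitude scale.

A global linear filter dW/dt = αW + βI is *not* implemented as a separate
state: its decay role is played by β in the per-synapse equation and its
stimulus term enters through the activations, so a second copy would be
redundant.

### Stabilization

Two mechanisms bound weight growth: the decay β and multiplicative
normalization of each neuron's outgoing row by (1 + γ·Σ_k w_ik), computed
from pre-update row sums, which bounds every row sum strictly below 1/γ.
The acceptance suite demonstrates both directions: with the stabilizers
disabled and a constant positive drive, the maximum weight grows without
bound (monotone, linear); enabled, it remains bounded over long runs.

## Cognitive load and learning-rate laws

C(t) = γ_act·Σa − δ_syn·Σw may be negative when synaptic mass dominates.
Because none of the η laws is specified for negative load (η > η0 under
"negative effort" has no meaning here), the default clamps C at 0 before
the η laws while logging the raw value; the intervention trigger uses the
raw value, since a large *negative* deviation from C_opt is exactly what it
should detect. dC/dt is a finite difference of the logged sums rather than
an independently integrated state — the model provides no separate dynamics
for it.

`eta_mode` selects the governing law per run; the three laws are presented
as alternatives, not composed. The default for closed-loop runs is `state`
(S-gated with smoothing), which is the only law with an explicit smoothing
dynamic; `exp` and `tanh` are memoryless maps of C and are applied directly.
The time-decayed baseline η0·e^{−λt} composes with whichever law is active
(λ = 0 by default, i.e. a constant baseline).

## Structural rewiring

The formation probability α/(1 + e^{−κ(d − d0)}) is monotone *increasing*
in distance, which favors long-range connection formation. A unimodal
("not too close, not too far") variant is sometimes the intended reading of
such rules; the probability function is therefore a swappable component of
`grow_edges` so a variant can be injected without changing callers, but the
printed logistic form is the implemented default.

For a binary edge variable in discrete time, the activity-driven growth
intensity λ·a_i·a_j·P(e_ij) is converted to a per-step Bernoulli
probability min(1, intensity·dt) — the only consistent discrete reading of
a formation rate. New synapses start at 1.1·ε so they survive the pruning
pass of the same step (no initial weight is otherwise implied by the
model). The stage order within rewiring is grow → prune → cap, so the two
invariant-restoring operations always run last; the cap removes weakest
synapses first, ties broken lexicographically by (pre, post) for
determinism.

## Controller

P_learn = Σ|Δw|/dt is measured between a snapshot taken before the weight
update and one taken after rewiring, over the union of synapses present in
either (absent = 0): pruning contributes |w| and growth |w_new|, so
structural plasticity counts as plasticity. Difficulty adaptation is
first-order (toward P_target) or second-order (tracking ΔP_learn), never
both summed — the two rules are alternatives selected by `difficulty_mode`.
Difficulty updates freeze during an intervention hold (a configurable
number of steps after the Heaviside trigger fires) and during breaks; the
two suspensions are independent mechanisms that may co-occur.

Review events fire every ⌈R/dt⌉ steps; at each review the stimulus replays
a stored pattern and the interval expands by (1 + γ_rep·e^{−β_rep·P_learn}).
Modality attribution, absent any stated rule, assigns modality m the
contiguous block of input channels (hence neurons) [m·K, (m+1)·K); its
per-modality plasticity is Σ|Δw| over synapses presynaptic to that block,
and modality weights follow a multiplicative-weights update on the simplex.
Fatigue accumulates the positive part of Σa by the left rectangle rule; a
break starts when it strictly exceeds F_max, suspends plasticity, rewiring
and control (stages 6–10), pauses fatigue accumulation and review
countdowns, and on completion resets fatigue to 0 — recovery is modeled as
complete, there being no stated partial-recovery law.

## Simulation loop

The stage order is fixed and normative for reproducibility: stimulus →
activation → load/load-rate → η → trigger → weight update → normalization →
rewiring → plasticity measurement → controller. One seed feeds three named
substreams (placement, stimulus, rewiring) via `numpy` SeedSequence
spawning, so toggling one stochastic component never shifts another's
draws. Identical config + seed yields byte-identical trajectory CSVs;
floats are serialized at 17 significant digits (lossless for float64 —
note that re-reading with pandas requires `float_precision="round_trip"`).
Any non-finite intermediate aborts the run naming the offending synapse.

## Synthetic stimuli

The generator emulates difficulty-graded multimodal instruction: channel
amplitudes scale as base·(1 + coupling·D), in constant, time-ramped, or
Bernoulli event-train form, plus the stored replay pattern for reviews. It
does **not** emulate structured content (correlated channels, temporal
motifs, curriculum semantics), sensory noise statistics, or any property of
real learner data. Passing tests therefore certify the mathematical
behavior of the dynamics and control laws under controlled synthetic input
— self-regulation, boundedness, calibration, determinism — not predictive
validity for human learning.

## Default parameters

Defaults define a self-regulating 30-neuron demo; all are configurable.

| group | values | rationale |
|---|---|---|
| network | n = 30, density 0.15, weights U(0.05, 0.15), logistic σ, bias 0 | sparse graph well under the cap; an initialization is needed and none is implied by the model, so a narrow positive band above the prune floor |
| plasticity | η0 = 0.05, λ = 0, β = 0.1, A₊ = 1, A₋ = 0.5, τ = 1, γ_norm = 0.1, w ∈ [0, 5] | decay and normalization both active so the stabilization properties are exercised; potentiation-dominant STDP |
| load | γ_act = 1, δ_syn = 0.5, C_max = 20, C_θ = 18, C_opt = 16, λ_sens = 1, ρ = 0.3, ΔC = 3 | scaled once to the default network's operating range — total logistic activation sits near 15–18, so the optimum is reachable from both sides |
| rewiring | α = 0.3, κ = 8, d0 = 0.5, θ = 0.25, ε = 0.01, λ_growth = 0.5, E_max = 4n | moderate turnover; cap just below the initial edge count so homeostasis is active |
| controller | P_target = 0.5, α_diff = 0.2, D ∈ [0.5, 2], D(0) = 1.25, γ_rep = 0.5, β_rep = 1, R_init = 5, F_max = 100, T0 = 2, μ = 0.5, M = 2 | difficulty starts at the midpoint of its bounds; F_max chosen so a multi-hundred-step run crosses it at least once |
| run | dt = 0.05, 200 steps (demo), hold 10 steps | dt small enough that Euler error is far below the dynamics' scale |

Long-horizon checks (structural invariants, divergence/boundedness) use
2,000-step runs of the same 30-neuron configuration, sized to exercise
every mechanism — reviews, interventions, at least one break — while the
whole suite stays fast.

## Known limitations

* Euler integration only; no adaptive or higher-order stepping.
* The load functional is global — no per-subnetwork or per-task load.
* Modality attribution by contiguous channel blocks is a convention, not a
  learned mapping.
* The distance-increasing growth probability is kept as stated; swap in a
  unimodal probability function if "intermediate-distance" rewiring is
  intended.
* Event times are rate-threshold crossings; networks whose activations
  never cross the threshold produce zero pair-STDP drive.
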