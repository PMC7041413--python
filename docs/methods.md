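# Methods

## Model

Two populations of binary neurons on d-dimensional grids encode input and
output of a mapping f: [0,1]^{d_A} → [0,1]^{d_B}.  Neuron i = (i₁, …, i_d),
with every component in 1..n, prefers the value (i₁/n, …, i_d/n).  A value is
represented by a bump of width k: the Cartesian product of the per-axis
integer intervals Int_k(a) = [a − k/2, a + k/2] ∩ ℤ, clamped to [1, n] on
bounded grids and wrapped modulo n on circular ones.  Following the
closed-interval definition, a bump spans k+1 integers per axis for even k
and k for odd k (fewer near a bounded edge).  Continuous values map to
center neurons by nearest-index rounding (half up); the quantization error
is at most 1/(2n) per axis except below the first neuron, where clamping
allows 1/n.

Synapses are all-to-all, weight 1, with plastic transmission probabilities
p_ij ∈ [0, 1].  Activating input bump I draws each synapse independently
(Bernoulli(p_ij)), scores every candidate output bump J of width k_B by its
total synaptic input s(I, J), and activates an argmax bump, ties uniform at
random.  One draw is shared by all candidates, so candidate scores are
dependent; an all-zero draw is a global tie and yields a uniform random
bump.  Scores are computed by a separable box-sum (prefix sums per axis with
clamped or wrapped windows), which is bit-exact equal to the naive double
sum; the test suite checks this against brute-force enumeration on random
small grids.

The error of a learned network is E[L(x, y)] for uniform x, estimated by
Monte Carlo with fresh activations (default 1000 evaluation samples) and
reported with its standard error.

## Learning rules

**Counter-based static rule.**  Width k_A fixed, k_B = ⌈C·k_A⌉ with C the
Lipschitz constant, a single error threshold L̂ (default the bound scale
3k/n), and M = ⌈c (n/k)^{d_A+d_B} ln n⌉ samples with
c = (d_A+d_B+1)(2C)^{d_A}(d_A+d_B)^{d_A+d_B}.  Each sample increments the
counters of all synapses between the co-active bumps when L(x, y) ≤ L̂ and
decrements them otherwise; at the end every synapse with a non-positive
counter is pruned (p = 0).  Initial probabilities default to p_init = 0.5
(symmetric exploration; the biologically typical release-probability range
is 0.1–0.9).

**Phase-halving dynamic rule.**  Starts at k₀ = ⌊c_k n⌋ with
0 < c_k ≤ 2/(3(d_A+d_B)) and repeats the static rule, halving k and L̂ each
phase, until 3k/n reaches the target precision ℓ.  Counters reset at phase
boundaries; exploration is automatically confined to surviving synapses
because pruned synapses never transmit.  The per-phase sample count keeps
the static formula's (n/k_A)^{d_A} input factor but replaces the
(n/k_B)^{d_B} output-candidate factor by (b/k_B)^{d_B}, where b is the mean
per-axis extent of the surviving synapses of an input row (capped by n/k_B;
the first phase reduces to the printed static formula).  After a phase with
threshold L̂ an input row's survivors span ~2L̂n ∝ k outputs, so b/k_B is an
O(1) constant from the second phase on and the cumulative sample count to
reach error ε scales as ε^{−d_A} ln n, which is what the scaling check
measures (log-log slope of samples-to-ε against 1/ε over
ε ∈ {0.1, 0.05, 0.025} at n = 256).  That check sets c_k = 0.25 so the
width sequence 64, 32, …, 2 halves exactly; with a non-power-of-two start
the integer floor (e.g. 5 → 2) distorts the schedule and inflates the
measured slope.

**Adaptive simulation rule.**  Handles feedback whose scale varies across
inputs.  Per sample, with input bump I (center x) and activated output bump
J (center y), in order: (1) widths — static variant: k fixed; dynamic
variant: k_A = max(1, ⌊c_A·s^{1/d_B}⌋) and k_B likewise with c_B, where s is
the surviving-synapse count of the center neuron (the d_B-th root keeps the
width a per-axis quantity; d_B = 1 is the plain constant-fraction rule);
(2) error pruning — every i ∈ I with L ≥ L̂_i prunes its synapses into J,
compared against the threshold *before* this sample's update (the
comparison reads as against the running estimate, not one contaminated by
the current L); (3) threshold update L̂_i ← αL + (1−α)L̂_i for all i ∈ I;
(4) inactivity — d_ij grows for live synapses of I-rows outside J, resets
inside J, and d_ij ≥ θ_prune prunes; (5) consolidation — an input neuron
whose surviving count drops below θ_syn has its survivors set to p = 1 and
is frozen.  Training stops when mean_i L̂_i < ℓ (or at a sample cap, with
the convergence flag false).

Degenerate rows (every synapse pruned before consolidation — possible when
an error-pruned output bump covers the whole surviving band) are re-seeded
with p_init on a band of width θ_syn centered on the row's most recent
co-active output center.  Centering on a fixed grid point instead would
lock rows whose target is far from it into a permanent re-seed/prune cycle;
the recent center keeps re-exploration where the attractor currently sends
that row.  Re-seeds are counted in the per-step record.

## Hyperparameters

Defaults were fixed once by a coarse grid search on the 1-D mapping tasks
(α ∈ {0.05, 0.1, 0.3}, θ_prune ∈ {3, 10, 30, 60}, θ_syn ∈ {2, 3, 4, 5, 10},
L̂_init ∈ {1, 10}×bound, c_A ∈ {0.05, 0.1, 0.15, 0.2, 0.3}):

| parameter | default | role |
| --- | --- | --- |
| α | 0.1 | threshold EMA decay; sets how many activations a threshold needs to become informative (~ln(L̂_init/L)/α) |
| c_A | 0.15 | width fraction of the surviving count (dynamic variant); c_B defaults to C·c_A |
| θ_prune | 30 | inactivity limit, in co-activations of the row |
| θ_syn | 10 | consolidation threshold, surviving synapses per row |
| L̂_init | feedback bound | thresholds start at the worst feedback: no pruning on first contact, decay toward the running error |
| p_init | 0.5 | initial transmission probability |

The balance that matters: inactivity pruning must not collapse a row onto
its few most recent output bands before the error threshold can
discriminate, which requires θ_prune ≫ ln(L̂_init/L_typ)/α.  (θ_prune = 3
with L̂_init = 10×bound, a combination that superficially looks safe,
consolidates rows onto essentially random bands.)  The polynomial-endpoint
run uses the per-task setting c_A = 0.05, c_B = 3c_A (output bump three
times the input bump), θ_syn = 3, θ_prune = 60: the larger width ratio makes
error pruning coarse, so later consolidation (smaller θ_syn) and slower
inactivity pruning are needed for clean bands.

**RL agent.**  The policy is a static-width bump map from the (clamped,
box-normalized) environment state to the action box; a tabular value
function on a 50-bins-per-dimension state grid supplies the baseline.  The
k-step return G_t = R_{t+1} + … + R_{t+k} + v(S_{t+k}) − v(S_t) (bootstrap
0 and truncated sum at episode end, undiscounted) updates
v(S_t) ← v(S_t) + α_v G_t and nudges the probabilities of the co-active
bump pair: p ← p + (0.9 − p)·min(βG, 1) for G ≥ 0, else
p ← p + (p − 0.1)·max(βG, −1), so p stays in [0.1, 0.9] and exploration
(probabilistic transmission plus tie-breaking) never dies.  Defaults
td_k = 10, α_v = 0.5, β = 0.1, k_policy = 5, k_action = 10, n_state = 30,
n_action = 100 were fixed by a coarse search on mountain car.  The fast
value step is essential there: frequently visited valley states accumulate
negative value, making returns positive for actions that leave them — the
pressure that first pushes the car out of the valley despite the fuel
penalty.

## Tasks

All tasks are closed-form; nothing is downloaded.  Mapping tasks use
absolute-distance feedback |f(x) − y|.  The polynomial x² − 3x + 1 maps
[0,1] onto [−1,1], outside the coded interval, so it is rescaled affinely by
(g+1)/2 (Lipschitz bound 1.5).  Ball throwing uses drag-free ballistics on
flat ground (g = 9.81, launch height 0): the output decodes to angle
θ ∈ (0, π/2) and speed v ∈ (0, √g], giving range v² sin 2θ / g with maximum
exactly 1; feedback is |range − d|.  The speed cap means very flat or very
steep angles cannot reach distant targets; within the reachable angle
interval the zero-feedback set is a curve (underdetermined optimum).  The
two-link arm has links 0.5/0.5 anchored at the origin; positions live in the
radius-1 disc mapped to [0,1]² by (e+1)/2, outputs decode to joint angles in
(−π, π]², and feedback is the Euclidean distance in workspace coordinates
(closed-form inverse kinematics serves as the test oracle).  Mountain car
follows the published continuous-control constants (position −1.2..0.6,
velocity ±0.07, velocity += 0.0015a − 0.0025 cos 3x, goal at 0.45 with
+100, fuel −0.1a² per step, 999-step cap).  The inverted pendulum is a
classical continuous-action cart-pole (Euler at dt = 0.02, force ±10,
failure at |θ| > 0.2095 or |x| > 2.4, +1 per step, 1000-step cap) — a
qualitative stand-in, not a rigid-body-engine reproduction, so claims about
it are qualitative only.

## What the synthetic setup does and does not show

The task generators produce exactly the study conditions: uniform input
sampling, noiseless closed-form feedback, stationary targets.  Passing
tests therefore demonstrate the coding-scheme and plasticity results under
ideal feedback; they do not probe sensor noise, non-stationary targets,
non-uniform input distributions, or model mismatch in the feedback channel.
Circular topology is implemented and tested at the coding/attractor level
but the learning experiments all run on bounded grids.

## Numerics and problem sizes

Synaptic state is dense (≤10⁷ entries enforced), float64 probabilities,
int32 counters.  In the training loops and batched evaluation, probabilities
only take the values {0, p_init, 1}, so per-column synaptic input is drawn
as n_consolidated + Binomial(n_live, p_init) — identical in distribution to
per-synapse Bernoulli draws and far cheaper; `network.activate` keeps the
generic per-synapse path, and a test checks the two paths agree.  Uniform
tie-breaking is realised either by collecting the argmax set or by adding
i.i.d. uniform keys to integer scores; both give the uniform-over-maximizers
rule.  Learning curves are recorded at log-spaced sample counts;
samples-to-threshold metrics interpolate linearly between recorded points.

Problem sizes in the test suite and acceptance script: counter-rule bound at
n = 100, k = 10 with the full formula sample count (11053) over 10 (tests)
or 5 (script) seeds; scaling at n = 256 over 3/2 seeds; width trade-off at
n = 1000 over 10/3 seeds with sample caps 15k/45k/40k (all three arms
plateau well before their caps); polynomial endpoint at n = 100, 100k
samples; mountain car over 10/3 seeds at 300 episodes.

## Known limitations

Consolidation is irreversible, so a row frozen onto a wrong or fragmented
band cannot recover; at the polynomial task's settings this leaves roughly
0–7% of rows with a non-contiguous surviving set.  The dense synapse matrix
caps population sizes (no sparse connectivity).  The RL agent has no
discounting, eligibility traces, or action-noise schedule, and its
computational cost grows with the full candidate-bump scan, so
high-dimensional state spaces are out of reach.  The phase-halving rule's
per-phase sample formula is exact only in its first phase; later phases use
the measured surviving band, which is a modelling choice rather than a
printed formula.
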