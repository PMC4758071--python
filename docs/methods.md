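# Methods

## Model

The planner is a discrete-time stochastic recurrent network.  State
neurons $V$ (one per discrete state, or one per place field for
continuous state) are driven by their own previous spikes through fixed
recurrent weights $W$ and by context neurons $Y$ through learnable
weights $\Theta$:

    u_{t,k} = Σ_i W[k,i] ν_{t-1,i} + Σ_j Θ[k,j] y_{t,j}

Two firing regimes are supported.

* **Hard winner-take-all (`softmax_wta`)** — exactly one state neuron
  fires per step, drawn from softmax(u).  With `W = log P^T` for a
  stochastic matrix `P`, the input-free network *is* a Markov chain
  with transition matrix `P`; context input tilts each transition by
  `exp(Θ y)` and renormalises.  All discrete planning tasks use this
  regime.
* **Sigmoid** — each neuron fires an independent Bernoulli with
  probability `expit(u_k)`.  The sweep simulation additionally applies
  divisive normalisation (see below).

The postsynaptic-potential window is a single time step (only
$v_{t-1}$ enters $u_t$); extended PSP kernels are out of scope.  Time
is unitless; durations quoted in milliseconds map through
`MS_PER_STEP = 20 ms` per step.

The initial state is drawn from `softmax(theta0)`; a strongly peaked
`theta0` pins the start state, a zero vector gives the uniform initial
distribution used for exploratory offline learning.

## Learning

Only $\Theta$ is learned.  The per-step gradient contribution is the
three-factor Hebbian term `G_t[k,j] = (ν_{t,k} − ρ_{t,k}) y_{t,j}`,
which is the exact derivative of the step log-likelihood for both the
softmax and sigmoid activations; `step_gradient` exposes a hook for
other differentiable activations (supply the derivative of the step
log-likelihood with respect to the membrane potential).

* **Online (finite horizon)**: after each episode,
  `Θ += η r Σ_t G_t` with the binary terminal return `r`.
* **Offline (finite horizon)**: `Θ += (η/L) Σ_l r_l Σ_t G_t^(l)` over a
  batch of `L` episodes drawn from the *fixed* input-free random walk
  with uniform start.  Because the sampling distribution is fixed, the
  batch can be drawn vectorised (`train_finite_offline`); the test
  suite verifies bit-level equivalence with the generic per-episode
  rule.
* **Infinite horizon**: per-synapse eligibility trace
  `e_t = λ e_{t-1} + G_t`, with `Θ += η r_t e_t` applied only at steps
  where reward arrives.  `λ` defaults to the discount factor γ —
  the geometric prior over trajectory lengths that the discounted
  objective induces — and the raw (undiscounted) reward is used, the
  discount being carried entirely by the trace.
* The maze trains on-policy (episodes drawn from the current model);
  its optimised loop exploits that Θ is constant within an episode, so
  the tilted transition matrix is built once per episode.  Equivalence
  with the generic operations is again covered by a test.

No baseline subtraction or other variance reduction is applied;
unrewarded episodes change nothing (zero-reward neutrality is a tested
invariant).

### Learning rates

The published experiments state training budgets (5000 online episodes;
10000 maze trials) but no step sizes, so η is calibrated to those
budgets: η = 0.2 for the online track task and η = 1.0 with L = 10 for
the maze (η ≲ 0.2 leaves the maze walk nearly untrained within 10000
trials).  The KL-convergence study uses the offline rule with a
Robbins–Monro decay `η(i) = 300/(1 + i/300)` and L = 2000: the plain
rule's gradient is scaled by the reward probability of the exploration
walk (~0.025 on the toy task), so order-hundreds step sizes are simply
the natural scale, and the decay removes the sampling-noise floor that
a constant step leaves (~0.05–0.1 nats).

## Tasks

**Linear track.** K = 9 states, moves restricted to |Δ| ≤ 1 by the
transition model (uniform over stay/left/right with an `eps = 1e-3`
leak to forbidden states, row-normalised).  Reward 1 iff the agent
occupies the mid passage at step T/2 and the end passage at step T.
Defaults: T = 10, passages at states 2 and 6, start at state 4 — the
smallest horizon exhibiting the plan-ahead structure; the acceptance
behaviour is insensitive to the passage placement.  One context neuron
per time step (temporal one-hot code).

**Grid maze.** 15 × 20 cells (K = 300), uniform 4-neighbour walk with
illegal moves redistributed to legal ones (keeps the walk irreducible
on free cells), reward 1 at the target only, episodes end at the target
or after T = 300 steps, γ = 0.98.  The shipped obstacle layout is a
vertical wall with symmetric top and bottom openings, so exactly two
globally optimal routes connect the default start (7,2) and target
(7,17).  A single always-on context neuron makes Θ a per-state bias
field; after learning it forms a gradient decreasing towards the target
(negative rank correlation with breadth-first-search distance, tested).

The maze is sampled with WTA dynamics even though the infinite-horizon
learning rule is usually written for sigmoid units: the stated
transition model (exactly one occupied cell, equal-probability
4-neighbour moves) is only realisable with a winner-take-all step, and
the Hebbian learning term is identical in both regimes.

## Population code and the sweep simulation

Place cells own preferred positions on a grid; a spike vector decodes
to the spike-weighted centroid, `None` marking spike-free steps (the
decoder carries the last defined position forward and the very first
step must be seeded).  Cell indexing is row-major and 0-based
everywhere, so place cells are bijective with maze cells.

The sweep experiment drives 100 place cells (10 × 10 over a 2 × 2 m
arena) with 20 context neurons and no learning: ten encode the current
location, active only during a 200 ms initialisation window; ten encode
home and fire as stationary Bernoulli(0.5) processes.  Context weights
are affine decreasing in distance to the respective anchor
(`θ = a − b‖p − anchor‖`, a = 1, b = 0.5): drive must be *largest* near
the anchor, so the distance-proportional magnitude is given a negative
slope.  Recurrent weights are a Gaussian kernel
(`σ = 0.25 m`), which forbids teleports and forces the activity bump to
drift.  The state layer is a soft WTA: `ρ = n_active · softmax(u)`
clipped below 1, with `n_active = 3` expected spikes per step; on
spike-free steps the previous activity pattern persists in the
recurrent term, otherwise the bump would re-seed at the goal.

Numerical balance: the summed home drive across ~5 active context
neurons changes by `5 b Δd` per cell step while the recurrent penalty
grows quadratically, `Δd²/(2σ²)`; with b = 0.5 the gain exceeds the
penalty only within ≲ 0.6 m, so the bump hops a fraction of that per
step but cannot jump to the goal.  The default geometry rests the
animal at the arena centre (1, 1) with home at (1.7, 1.7): diffusion at
the centre is isotropic, making the silenced-goal control (no
systematic drift without home input) interpretable.

What the simulation does *not* capture: real place-field shapes and
sizes, theta/ripple temporal structure, and the recorded-data
comparison — a green sweep test establishes goal-directed, continuous,
horizon-sensitive drift of a simulated activity bump, nothing about
rodent physiology.

## Transition learning from demonstrations

`transition_cd` fits the recurrent weights when no analytic model
exists.  The conditional formulation is used — the planner only ever
consumes `p(v_t | v_{t-1})` — so CD-k reduces to: sample a
reconstruction of the next state from the current conditional for every
demonstrated previous state and move `W` along data-minus-model
statistics, normalised per presynaptic state so all visited states
converge at the same rate.  The fixed point is the empirical
conditional frequency table (tested on tiny chains).  An optional
geometric step-size anneal suppresses the reconstruction-sampling noise
floor.  Demonstrations are synthetic stand-ins for kinesthetic
teaching: Gaussian-increment walks reflected at the arena bounds and
discretised to the nearest place cell.  Robot-workspace defaults:
15 × 15 place cells over 70 × 70 cm; obstacles enter at planning time
as a fixed −10 context bias on overlapped cells, not through learning.

## Exact baselines

`evaluation` enumerates the reward-conditioned posterior outright for
instances up to 10^6 trajectories.  Two conditionings are offered:
joint (reward conditioning may reshape the start-state marginal) and
per-start (`condition_on_init=True`), which conditions within each
start state.  The per-start form is the correct target for the KL
study: the network's initial state is pinned by `theta0`, not learned,
so only the per-start posterior lies in its model class — against the
joint posterior the divergence plateaus at the (irreducible) KL of the
start marginals.  With one context neuron per step the model class
contains the per-start posterior exactly (the optimal context bias is
the log backward message), so KL → 0 is attainable and observed
(< 0.05 nats, typically ~0.02).

Monte-Carlo policy evaluation is first-visit (the variant is not
dictated by anything upstream; first-visit gives unbiased per-cell
estimates), and success rates carry 95% Wilson intervals
(statsmodels).  The infinite mixture over trajectory lengths implied by
the discount is truncated at T = 300 wherever it appears.

## Numerical choices

- Softmax always computed with max-subtraction (via `scipy.special`);
  log-probabilities via `log_softmax` / `log_expit`.
- Categorical draws by inverse-CDF on the rng's uniform; no argmax
  tie-breaking anywhere in sampling.
- Maze log-transition weights floor exact zeros at `log(1e-300)` to
  keep all weights finite.
- Zero-probability trajectories yield `-inf` log-probability (flagged
  by value, not by exception); a model assigning zero mass to a
  supported trajectory yields KL = +inf.
- Enumeration guardrail: 10^6 trajectories.
- CD aborts when any |w| exceeds 1e3.

## Known limitations

- Only the one-step ideal model: no extended PSPs, no
  integrate-and-fire variant, no continuous time.
- Actions are never represented; plans are state sequences.
- The recurrent weights are fixed during planning; reward never adapts
  them.
- Offline maze learning uses on-policy samples without importance
  correction; it optimises expected discounted reward rather than
  matching the full posterior (by design — the finite-horizon offline
  rule is the posterior-matching one).
- The sweep module's divisive normalisation is a mechanism choice; any
  circuit producing a normalised multi-spike bump would do.
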