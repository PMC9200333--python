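# Methods

## Setting and model

The optimizer treats one DBTL round as a contextual-bandit interaction:
an agent holding strain design e (enzyme levels in transformed space)
runs a cultivation, observes a state vector s (normalized
metabolite/enzyme readouts at pseudo-steady state) and a scalar response y
(for enzyme-tuning problems, specific production × growth relative to wild
type; for library problems, a biosensor readout), and receives the reward
r = y_t − y_{t−1}, the improvement over its own previous round. No value
function is learned — with a drifting, unknown simulator there is no
stationary model to bootstrap from, so only immediate rewards and the
history of (s, a, r) triplets drive the policy.

### Enzyme-level transform

Raw enzyme pools live in [0.1, 10] (10-fold down- to up-regulation; gene
deletions are excluded as they cause discontinuous responses). All
optimization happens in the transform f(ê) = (ê − 1)/(ê + 1), which maps
[0.1, 10] to the nearly symmetric interval [−9/11, 9/11] ≈ [−0.818, 0.818]
with f(1) = 0 at wild type. The inverse (1 + y)/(1 − y) converts designs
back for the simulator. Round-trip accuracy is better than 1e−12 across
the range. Combinatorial-library environments use coded promoter strengths
on [0, 1] directly (identity transform).

### Policy: maximum margin regression

Each agent group fits, every round, the dual QP

    min ½ βᵀ(K_S ∘ K_A)β − Mᵀβ,   0 ≤ β_i ≤ C_ξ,

with Gaussian kernels K(x, x′) = exp(−‖x − x′‖²/σ²) (bandwidth enters
un-squared: σ², not 2σ²), margins M_i = log₂(r_i + 1) clamped at
r ≥ −1 + 1e−6 (rewards are deltas and can reach −1 and below; the clamp
keeps the log defined while preserving monotonicity), and the Hadamard
kernel product, PSD by the Schur product theorem. Triplets with
non-positive margin get β = 0 — only rewarded experiments become support
vectors. Predictions are the pre-image sum π(s) = Σ β_i a_i K_S(s, s_i).
An optional Nadaraya–Watson normalization (divide by Σ β_i K_S) is
available behind `normalize_prediction` but off by default.

### QP solver

No dedicated QP library is assumed: the box QP is solved by L-BFGS-B
(analytic gradient) followed by cyclic coordinate descent — each update is
the exact one-dimensional minimizer, well-posed because K_SA has unit
diagonal even when globally singular — plus one exact line minimization
per sweep along (e_i − e_j) for the worst-KKT coordinate i and the partner
j giving the largest decrease. The pair step matters: histories routinely
contain near-duplicate triplets whose kernel columns differ by ~1e−6,
creating valleys that coordinate-wise descent traverses at a rate of
(1 − K_ij) per sweep. Convergence is certified by the natural-map residual
‖Π_box(β − ∇) − β‖_∞ ≤ 1e−8 (10× relaxation on one retry); the fitted
objective matches an independent projected-gradient oracle to 1e−6 in the
test suite. Everything is deterministic: fixed sweep order, no randomized
pivoting.

### Exploration: why the pre-image prediction alone is not enough

Two failure modes of the raw prediction surfaced during development and
shape the defaults:

1. **Magnitude collapse.** β scales with the margins, and margins scale
   with local reward deltas, so near an optimum (or on any plateau) the
   predicted action norm decays to ~1e−2 while its *direction* stays
   informative. Left alone, agents freeze: tiny actions produce tiny
   rewards produce tiny replayed actions.
2. **Global averaging.** With the plain median-heuristic bandwidth the
   state kernel is nearly flat over the whole design box, and the
   prediction degenerates into one global "central pull" vector that
   perpetually overshoots the optimum into the nearest box corner.

The remedies are (a) sharper kernels — bandwidths default to
`bandwidth_scale` = 0.125 × the median pairwise distance of the pooled
warm-up data, restoring locality of the policy — and (b) an
**exploration step** (`exploration_kick`, default 0.1 transformed units):
where the prediction is backed by local evidence (the fraction of dual
mass Σβ_iK_S(s, s_i)/Σβ_i within a bandwidth of the current state exceeds
`kick_confidence` = 0.02) its direction is kept and its length stretched
to at least the exploration step; elsewhere the agent takes a random step
of that length. Large supported predictions pass through unchanged. These
defaults were calibrated on the surface testbed and validated on held-out
landscape seeds and run-seed sets.

### Multi-agent loop

Agents (default 4) are split into contiguous groups (default 2 — the
mixed centralized/decentralized scheme outperformed both one fully shared
policy and per-agent policies in our benchmarks). Per round and group:
query the environment for every member, append the causally aligned
triplet (state before acting, executed action, resulting reward delta) to
the group history, refit the policy, predict member actions, apply the
exploration rule, diversify with Gram-Schmidt perturbation (c = 0.8;
renormalization to the original action length makes the perturbation a
pure rotation toward an orthogonal direction, and the spanned Gram volume
cannot shrink), and update designs with clipping to the transformed box.
Every `replace_every_k` rounds (default 2) the agent with the lowest
median response is overwritten — design only, histories kept — by a copy
of a uniformly chosen other agent; frequent replacement spreads good
positions through the population quickly and costs nothing when all
agents perform equally.

Initialization: a Latin-hypercube warm-up of τ = 5 rounds per agent (one
sample per equiprobable stratum per dimension); the first agent then
starts from the coordinate-wise median of the designs in the top
(1 − 0.75) response quantile of the warm-up, all others from fresh LHS
draws. The first reward of each agent is measured against the wild-type
baseline response.

The iteration budget is fixed (default 40 rounds, so 4 × (5 + 40) = 180
cultivations); an optional plateau stop (`plateau_patience`) can end runs
early but is off by default so that budgets stay comparable.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `n_agents` | 4 | – | parallel cultivations per round |
| `n_groups` | 2 | – | mixed centralized/decentralized training |
| `tau` | 5 | rounds/agent | LHS warm-up length |
| `n_iterations` | 40 | rounds | fixed experiment budget |
| `perturb_c` | 0.8 | – | Gram-Schmidt perturbation coefficient |
| `replace_every_k` | 2 | rounds | worst-agent replacement cadence |
| `upper_quantile` | 0.75 | – | warm-up quantile for the first agent's start |
| `c_xi` | 1.0 | – | dual box bound (slack trade-off) |
| `sigma_s`, `sigma_a` | median × scale | state/action units | kernel bandwidths; `None` → heuristic |
| `bandwidth_scale` | 0.125 | – | locality of the policy (see above) |
| `exploration_kick` | 0.1 | transformed units | minimum step length |
| `kick_confidence` | 0.02 | – | support-mass gate for trusting directions |
| `max_step` | off | transformed units | optional action-norm cap |
| `qp_tol` | 1e−8 | – | certified KKT residual |

`library_run_config()` adapts three of these to coded-strength libraries:
kick = 0.2 (the grid spacing — within-cell moves carry no signal on a
piecewise-constant response), `bandwidth_scale` = 0.25 (the 5-gene box is
small and smooth) and k = 1.

Baselines: RAND draws uniform batches from the same transformed box;
BO-GP fits a squared-exponential GP (fixed length scale by the median
heuristic, observation noise 1e−6) and proposes batches by maximizing
expected improvement sequentially with the constant-liar strategy, each
proposal optimized from 64 seeded LHS starts. Both share the warm-up
cultivations and the exact call budget of the multi-agent loop.

## Synthetic testbeds — what they emulate, what they do not

**Surface environment**: a seeded Gaussian response bump
y = 10·exp(−(f(ê) − f*)ᵀQ(f(ê) − f*)) with f* uniform in [−0.6, 0.6]ⁿ,
SPD curvature Q (eigenvalues 0.5–2) and state readout tanh(B f(ê)),
n_state = 2n. It gives a smooth landscape with a certifiable interior
optimum and nontrivial state–design coupling. It does **not** reproduce a
kinetic model's stiff nonlinearities, flux plateaus, multimodality, or
boundary optima; passing the recovery test shows the loop can home in on
a smooth interior optimum within a 180-call budget, not that it would
match wet-lab performance. A real simulator attaches through the same
`Environment` contract.

**Library environment**: the full 6⁵ grid of five-gene coded designs,
subsampled to a coverage fraction; responses follow a quadratic landscape
(seeded curvature 1–2 per gene, pairwise interactions ±0.2) around a
designed optimum, times multiplicative log-normal noise (σ_log = 0.1);
states are the design columns plus three correlated covariates. The
designed optimum is *planted*: always retained in the sample, and lifted
just above the runner-up (× 1.02) if a noise draw would displace it, so
the benchmark has a known ground truth. Matching uses the strict < 0.2
element-wise rule with Euclidean/lowest-index tie-breaks and returns zero
on no match. Real combinatorial libraries have correlated measurement
error, batch effects and non-numeric annotations, none of which are
modelled.

**Noise wrapper**: seeded Gaussian noise per channel — action sd =
m%·min|a_i| (floored at 1e−8·‖a‖ when a coordinate is exactly zero, since
the literal rule would disable the channel), state sd = m%·median(state)
(absolute-value median if the signed median is ≤ 0), response sd =
m%·|y|. A channel at m = 0 draws nothing.

## Evaluation statistics

Best-found trajectories are pooled per round across agents × seeds and
summarized as median with 25th/75th percentiles (linear interpolation).
Stability is RSD = σ/μ (population σ by default; `ddof=1` available) of
the responses at 10 neighbours drawn by multiplying each raw enzyme level
with an independent uniform factor in [0.5, 1.5] — the multiplicative
reading of "within 0.5-fold change", the natural one on the [0.1, 10]
scale — clipped to the valid range; a mean ≤ 1e−12 is flagged undefined
instead of divided by. Noise degradation is the percentage drop of the
final-round pooled median versus the noiseless protocol; improvements
appear as negative decrements.

## Numerical and design notes

* The Gaussian kernel is implemented with the negative exponent;
  kernels must be bounded by 1 for the dual to be bounded.
* Histories store the causally aligned triplet (state observed before
  acting, executed action after perturbation and clipping, resulting
  reward delta), which is what the margin constraint semantically binds.
* Clipping to the design box happens after perturbation; the logged
  executed action is the post-clip delta.
* Worst-agent replacement copies the design only; the replaced agent's
  reward continuity is preserved by keeping its own previous response.
* Gram-Schmidt outputs unit vectors; numerically dependent inputs
  (residual < 1e−10) are substituted by random orthogonalized unit
  vectors, inputs beyond the space dimension by plain random unit vectors,
  both flagged. Zero actions entering the perturbation are replaced by
  random vectors of norm 1e−3.
* All randomness flows from one root seed through named CRC-32
  substreams (warm-up, init, perturbation, replacement, environment
  noise), so adding a consumer never shifts existing streams and every
  command is bit-reproducible.
* Policies serialize to JSON and round-trip exactly.

## Known limitations

* Performance on the surface testbed depends on the exploration defaults;
  on landscapes much flatter or sharper than the bundled one the kick and
  bandwidth scale may need retuning. The 5-seed medians of the study
  protocols carry noticeable seed-to-seed spread (≈ ±0.3 on a 10-point
  response scale).
* On the library benchmark, multiplicative 10% noise makes near-optimal
  strains statistically indistinguishable without repeated queries; the
  planted-optimum recovery test passes at the default protocol but the
  margin is modest, and roughly half of alternative seed sets land below
  the 95% bar — an intrinsic limit of a 180-query budget under that noise,
  not specific to this optimizer (BO-GP shows the same ceiling).
* The MMR policy replays rewarded actions; it cannot extrapolate reversed
  actions from penalized ones, and on plateaus it is a guided random walk.
* Groups never communicate; learned group assignment, asynchronous agents
  and value-function methods are out of scope.
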