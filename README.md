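# strainrl

Multi-agent, max-margin reinforcement learning for microbial strain design
optimization.

Engineering a microbe to overproduce a target compound means tuning the
expression of a handful of metabolic enzymes, but each Design-Build-Test-Learn
(DBTL) round of cultivations is slow and expensive, and the cellular
regulation connecting enzyme levels to yield is largely unknown. `strainrl`
automates the Design and Learn phases with a model-free contextual-bandit
optimizer: several agents propose strain designs in parallel (matching
multi-well plates or parallel bioreactors), observe the culture's state
(metabolite/enzyme readouts) and response (e.g. production × growth), and
learn from the accumulated history which enzyme-level changes pay off.

## The method

A strain design is a vector of normalized total enzyme pools ê ∈ [0.1, 10]
(10-fold down- to 10-fold up-regulation), worked with in the symmetrizing
transform f(ê) = (ê − 1)/(ê + 1), so f(1) = 0 is wild type, f(0) = −1
knock-out and f(10) ≈ 0.82 maximal up-regulation.

The policy learner is **Maximum Margin Regression (MMR)**, an SVM-style
learner for vector-valued outputs. For each observed triplet
(state sᵢ, action aᵢ, reward rᵢ = yᵢ − yᵢ₋₁) it asks the predicted reward
⟨ψ(a), W φ(s)⟩ to clear a margin M(r) = log₂(r + 1), so profitable
experiments become support vectors. With Gaussian kernels
K(x, x′) = exp(−‖x − x′‖²/σ²) the dual is a box-constrained QP over
coefficients β with the Hadamard product K_S ∘ K_A as its quadratic term:

    min ½ βᵀ(K_S ∘ K_A)β − Mᵀβ   s.t.  0 ≤ β ≤ C_ξ,

and the recommended action in state s is the pre-image sum
π(s) = Σᵢ βᵢ aᵢ K_S(s, sᵢ) — a kernel-weighted recombination of past
successful moves, stretched to a minimum exploration step where it is
backed by nearby support vectors and replaced by a random exploration step
where it is not.

Agents are split into groups: each group pools its history and learns a
joint policy (centralized training), groups stay independent so they can
specialize (decentralized across groups). Before execution the group's
actions are diversified by Gram-Schmidt perturbation — ãⁱ = (1−c)aⁱ + c vⁱ
with c = 0.8, renormalized to the original length — which provably does
not shrink the volume (Gram determinant) spanned by the group's actions.
Every k rounds the agent with the lowest median response is replaced by a
copy of a random other agent. Runs start with a Latin-hypercube warm-up.

Bundled, behind one `Environment` step contract:

* a smooth **surface testbed** (seeded Gaussian response bump with a known
  optimum and a nonlinear state readout) standing in for a kinetic-model
  simulator — an external simulator plugs into the same contract;
* a **combinatorial strain library** testbed: five genes at six coded
  promoter strengths {0, 0.2, …, 1}, nearest-neighbour matching (< 0.2
  element-wise, zero response on no match) and a planted known optimum;
* a three-channel **noise wrapper** (action, state, response) for
  robustness studies;
* baselines under the identical budget: random search (RAND) and Bayesian
  optimization with a GP surrogate and expected improvement (BO-GP);
* evaluation statistics: pooled best-found trajectories with percentile
  bands, the relative-standard-deviation (RSD = σ/μ) stability of a design
  under ±50% enzyme-level perturbations, and noise-degradation summaries.

## Worked example

```python
import numpy as np
import strainrl as sr

env = sr.make_surface_env(6, seed=0)          # 6-enzyme surrogate testbed
result = sr.run_marl(env, sr.RunConfig(seed=1))
print(f"wild-type response : {env.baseline_response:.3f}")
print(f"best response found: {result.best_response:.3f}  (optimum {env.meta['y_max']:.1f})")
print(f"best enzyme levels : {np.round(result.best_design_raw, 2)}")
print(f"environment calls  : {result.n_env_calls}")
stab = sr.rsd_stability(env, result.best_design_raw, rng=np.random.default_rng(0))
print(f"design stability   : RSD = {stab.rsd:.3f} over 10 neighbours")
```

prints

```
wild-type response : 2.091
best response found: 9.261  (optimum 10.0)
best enzyme levels : [1.35 0.57 0.3  0.14 3.44 2.23]
environment calls  : 180
design stability   : RSD = 0.093 over 10 neighbours
```

Four agents spent 180 cultivations (5 warm-up + 40 optimization rounds
each) and improved the response from the wild type's 2.09 to 9.26 — 93% of
the landscape's true optimum of 10 — with a design whose response varies by
only 9.3% (RSD) when every enzyme level is independently perturbed within
±50%, i.e. a design robust to imprecise promoter tuning.

The same protocols are scriptable from the shell:

```bash
strainrl fixtures --out fixtures            # example configs + library CSV
strainrl run     --config fixtures/succinic_acid.yaml --seed 1 --out out/
strainrl compare --config my_comparison.yaml --out out/   # marl vs bogp vs rand
strainrl stability --config fixtures/succinic_acid.yaml --out out/
strainrl noise     --config fixtures/succinic_acid.yaml --out out/
```

All commands are bit-reproducible given the same config and seed.

## Documentation

See `docs/methods.md` for the model, its assumptions, every tunable
parameter with its default and rationale, what the synthetic testbeds do
and do not emulate, and known limitations.
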