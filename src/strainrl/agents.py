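"""Grouped multi-agent optimization loop with MMR policies.

Several agents run cultivations in parallel (one strain each per round).
Agents are partitioned into groups; within a group the agents pool their
state–action–reward history and learn a joint MMR policy (centralized
training), while groups stay independent so each can specialize to its own
region of the design space (decentralized across groups).

Each round, per group: every member queries the environment at its current
design, the resulting (previous state, executed action, response delta)
triplet is appended to the group history, the group policy is refit, new
actions are predicted, diversified by a Gram-Schmidt perturbation (so the
parallelotope spanned by the group's actions — measured by the Gram
determinant — does not shrink), and applied with clipping to the valid
transformed design box. Every k rounds the agent with the lowest median
response is replaced by a copy of a randomly chosen other agent's design.

The loop starts with a Latin-hypercube warm-up of τ rounds per agent; the
first agent then starts from the coordinate-wise median of the designs in
the upper response quantile of the warm-up, the others from fresh LHS
draws.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from ._rng import substream
from .environments import Environment
from .mmr import (
    History,
    MMRFitError,
    MMRHyperParams,
    fit,
    median_heuristic_bandwidth,
    predict_action,
)

__all__ = [
    "RunConfig",
    "RunResult",
    "WarmupData",
    "gram_schmidt",
    "init_enzyme_levels",
    "latin_hypercube",
    "perturb_agents",
    "replace_worst",
    "run_marl",
    "warmup",
]


@dataclass
class RunConfig:
    """Configuration of one multi-agent optimization run.

    Defaults: 4 agents in 2 groups, τ = 5 warm-up rounds per agent, 40
    optimization rounds, perturbation coefficient c = 0.8, worst-agent
    replacement every 2 rounds, upper response quantile 0.75 for the first
    agent's start. Kernel bandwidths default to a scaled median heuristic
    over the warm-up data (``None``); C_ξ defaults to 1.
    """

    n_agents: int = 4
    n_groups: int = 2
    tau: int = 5
    n_iterations: int = 40
    perturb_c: float = 0.8
    replace_every_k: int = 2
    upper_quantile: float = 0.75
    seed: int = 0
    sigma_s: float | None = None
    sigma_a: float | None = None
    #: bandwidths default to bandwidth_scale × the median pairwise distance
    #: of the warm-up data; the plain median is far wider than the
    #: within-run step scale and washes out the policy's locality.
    bandwidth_scale: float = 0.125
    c_xi: float = 1.0
    normalize_prediction: bool = False
    #: exploration step size (transformed design units). Predictions backed
    #: by local support evidence are stretched to at least this length;
    #: unsupported predictions are replaced by a random step of this length.
    exploration_kick: float = 0.1
    #: minimum fraction of support mass (MMRPolicy.support_weight) near the
    #: current state for the predicted direction to be trusted.
    kick_confidence: float = 0.02
    #: optional cap on the predicted action norm before perturbation; off by
    #: default (the pre-image sum is used verbatim).
    max_step: float | None = None
    #: optional early stop: quit when the best-found response has not
    #: improved for this many rounds. None = fixed budget.
    plateau_patience: int | None = None
    qp_tol: float = 1e-8

    def __post_init__(self):
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if not 1 <= self.n_groups <= self.n_agents:
            raise ValueError("need 1 <= n_groups <= n_agents")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if not 0.0 <= self.perturb_c <= 1.0:
            raise ValueError("perturb_c must be in [0, 1]")
        if self.replace_every_k < 1:
            raise ValueError("replace_every_k must be >= 1")
        if not 0.0 < self.upper_quantile < 1.0:
            raise ValueError("upper_quantile must be in (0, 1)")
        if self.c_xi <= 0:
            raise ValueError("c_xi must be positive")
        if self.bandwidth_scale <= 0:
            raise ValueError("bandwidth_scale must be positive")
        if self.exploration_kick < 0:
            raise ValueError("exploration_kick must be >= 0")
        if not 0.0 <= self.kick_confidence <= 1.0:
            raise ValueError("kick_confidence must be in [0, 1]")


@dataclass
class WarmupData:
    """Per-agent warm-up records, all in transformed design space."""

    designs: np.ndarray  # (n_agents, tau, n_design)
    actions: np.ndarray  # (n_agents, tau, n_design)
    states: np.ndarray  # (n_agents, tau, n_state)
    responses: np.ndarray  # (n_agents, tau)
    rewards: np.ndarray  # (n_agents, tau)

    @property
    def n_agents(self) -> int:
        return self.designs.shape[0]

    @property
    def tau(self) -> int:
        return self.designs.shape[1]


@dataclass
class RunResult:
    """Full log of one optimization run.

    ``log`` has one row per (round, agent) with the design (transformed and
    raw), flattened state, response and reward; ``policy_log`` tracks the
    per-round support size and norm of each group's dual coefficients.
    """

    method: str
    env_name: str
    config: object
    log: pd.DataFrame
    policy_log: pd.DataFrame | None
    best_design_raw: np.ndarray
    best_response: float
    n_env_calls: int
    meta: dict = field(default_factory=dict)

    def best_found(self) -> pd.DataFrame:
        """Per-(agent, round) running best response — non-decreasing by construction."""
        df = self.log.sort_values(["agent", "round"])
        best = df.groupby("agent")["response"].cummax()
        out = df[["round", "agent"]].copy()
        out["best"] = best
        return out.reset_index(drop=True)


def latin_hypercube(n: int, bounds, rng: np.random.Generator) -> np.ndarray:
    """n Latin-hypercube samples within per-dimension ``bounds`` (d × 2).

    Each dimension's range is split into n equiprobable strata and every
    stratum receives exactly one sample. Deterministic given the generator
    state. Degenerate bounds (lo == hi) yield a constant dimension with a
    warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    if bounds.shape[1] != 2 or not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be a finite (d, 2) array")
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(hi < lo):
        raise ValueError("bounds must satisfy lo <= hi")
    if np.any(hi == lo):
        warnings.warn("degenerate bounds: some dimensions are constant", stacklevel=2)
    sampler = qmc.LatinHypercube(d=len(lo), seed=rng)
    u = sampler.random(n)
    return lo + u * (hi - lo)


def warmup(env: Environment, config, rng: np.random.Generator) -> WarmupData:
    """τ seeded LHS cultivations per agent, with within-agent reward deltas.

    The first reward of each agent is taken against the environment's
    wild-type baseline response, and the first action against the wild-type
    design, so every triplet has a well-defined predecessor.
    """
    n_agents = getattr(config, "n_agents", None) or config.n_parallel
    tau = config.tau
    d = env.n_enzymes
    lo_t, hi_t = env.transformed_bounds
    bounds = np.column_stack([np.full(d, lo_t), np.full(d, hi_t)])
    rows = latin_hypercube(n_agents * tau, bounds, rng)

    base_t = np.asarray(env.transform(env.baseline_design), dtype=float)
    designs = np.empty((n_agents, tau, d))
    actions = np.empty((n_agents, tau, d))
    states = np.empty((n_agents, tau, env.n_state))
    responses = np.empty((n_agents, tau))
    rewards = np.empty((n_agents, tau))

    for i in range(n_agents):
        prev_t, prev_raw = base_t, env.baseline_design
        prev_y = env.baseline_response
        for j in range(tau):
            d_t = rows[i * tau + j]
            raw = np.asarray(env.inverse(d_t), dtype=float)
            try:
                s, y = env.step(raw, prev_design=prev_raw)
            except Exception as exc:
                raise RuntimeError(
                    f"environment failed during warm-up (agent {i}, round {j + 1})"
                ) from exc
            designs[i, j] = d_t
            actions[i, j] = d_t - prev_t
            states[i, j] = s
            responses[i, j] = y
            rewards[i, j] = y - prev_y
            prev_t, prev_raw, prev_y = d_t, raw, y
    return WarmupData(designs, actions, states, responses, rewards)


def init_enzyme_levels(
    wd: WarmupData, config, env: Environment, rng: np.random.Generator
) -> list[np.ndarray]:
    """Starting designs after the warm-up, in transformed space.

    Agent 0 starts at the coordinate-wise median of the warm-up designs
    whose responses fall in the top (1 − upper_quantile) fraction; the
    remaining agents get fresh LHS draws to keep exploring other subspaces.
    """
    designs = wd.designs.reshape(-1, wd.designs.shape[-1])
    responses = wd.responses.ravel()
    if len(responses) == 0:
        raise ValueError("warm-up is empty")
    q = getattr(config, "upper_quantile", 0.75)
    n_top = max(1, int(np.ceil(len(responses) * (1.0 - q))))
    top = np.argsort(responses)[::-1][:n_top]
    first = np.median(designs[top], axis=0)

    n_agents = getattr(config, "n_agents", None) or config.n_parallel
    levels = [first]
    if n_agents > 1:
        d = designs.shape[1]
        lo_t, hi_t = env.transformed_bounds
        bounds = np.column_stack([np.full(d, lo_t), np.full(d, hi_t)])
        levels.extend(latin_hypercube(n_agents - 1, bounds, rng))
    return [np.asarray(v, dtype=float) for v in levels]


def gram_schmidt(
    vectors, rng: np.random.Generator, dependent_tol: float = 1e-10
) -> tuple[list[np.ndarray], list[bool]]:
    """Orthonormalize a list of vectors, substituting random directions as needed.

    The i-th output spans inputs 1..i when they are independent. A
    (numerically) dependent input is replaced by a random unit vector
    orthogonalized against the previous outputs; inputs beyond the space
    dimension d cannot be orthogonalized and become plain random unit
    vectors. The second return value flags every substituted position.
    """
    vs = [np.asarray(v, dtype=float) for v in vectors]
    if not vs or vs[0].ndim != 1 or vs[0].size == 0:
        raise ValueError("need non-empty vectors of dimension >= 1")
    d = vs[0].size
    out: list[np.ndarray] = []
    flags: list[bool] = []

    def orthogonalize(w):
        for u in out[: min(len(out), d)]:
            w = w - (w @ u) * u
        return w

    for i, v in enumerate(vs):
        if v.shape != (d,):
            raise ValueError("vectors must share a common dimension")
        substituted = False
        if i < d:
            w = orthogonalize(v.copy())
            if np.linalg.norm(w) < dependent_tol:
                substituted = True
                while True:
                    w = orthogonalize(rng.standard_normal(d))
                    if np.linalg.norm(w) >= dependent_tol:
                        break
        else:
            substituted = True
            w = rng.standard_normal(d)
        out.append(w / np.linalg.norm(w))
        flags.append(substituted)
    return out, flags


def perturb_agents(actions, c: float, rng: np.random.Generator) -> list[np.ndarray]:
    """Diversify a group's actions: ã = (1−c)a + c·v, renormalized to ‖a‖.

    v are the Gram-Schmidt directions of the actions, so the perturbed set
    spans a parallelotope of no smaller volume (Gram determinant) while
    every action keeps its original length. Zero actions are replaced by a
    small random vector (norm 1e−3) so they can still be diversified.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError("c must be in [0, 1]")
    acts = [np.asarray(a, dtype=float) for a in actions]
    if not acts:
        raise ValueError("actions must be non-empty")
    d = acts[0].size
    for i, a in enumerate(acts):
        if np.linalg.norm(a) < 1e-12:
            u = rng.standard_normal(d)
            acts[i] = 1e-3 * u / np.linalg.norm(u)
    vs, _ = gram_schmidt(acts, rng)
    out = []
    for a, v in zip(acts, vs):
        t = (1.0 - c) * a + c * v
        nt = np.linalg.norm(t)
        out.append(a if nt < 1e-12 else t * (np.linalg.norm(a) / nt))
    return out


def replace_worst(
    levels: list[np.ndarray], response_series: list, rng: np.random.Generator
) -> tuple[list[np.ndarray], int, int]:
    """Overwrite the worst agent's design with a copy of a random other agent's.

    The worst agent minimizes the median of its recorded responses; ties go
    to the lowest agent index. Only the design is copied — histories are
    untouched. Returns (new levels, worst index, donor index).
    """
    if len(levels) < 2:
        raise ValueError("need at least two agents")
    medians = [float(np.median(s)) for s in response_series]
    worst = int(np.argmin(medians))
    donor = int(rng.choice([i for i in range(len(levels)) if i != worst]))
    new_levels = [v.copy() for v in levels]
    new_levels[worst] = new_levels[donor].copy()
    return new_levels, worst, donor


def _assign_groups(n_agents: int, n_groups: int) -> list[np.ndarray]:
    return [np.asarray(g) for g in np.array_split(np.arange(n_agents), n_groups)]


def run_marl(
    env: Environment, config: RunConfig, warmup_data: WarmupData | None = None
) -> RunResult:
    """Run the full grouped multi-agent optimization loop.

    Deterministic given ``config.seed``; consumes exactly
    n_agents × (τ + n_iterations) environment calls (fewer only when the
    optional plateau stop is enabled). A pre-generated ``warmup_data`` may
    be passed so several methods can share the same warm-up cultivations.
    """
    cfg = config
    rng_warm = substream(cfg.seed, "warmup")
    rng_init = substream(cfg.seed, "init")
    rng_pert = substream(cfg.seed, "perturb")
    rng_repl = substream(cfg.seed, "replace")

    wd = warmup_data if warmup_data is not None else warmup(env, cfg, rng_warm)
    if wd.n_agents != cfg.n_agents or wd.tau != cfg.tau:
        raise ValueError("warm-up data does not match the configuration")
    groups = _assign_groups(cfg.n_agents, cfg.n_groups)
    group_of = np.empty(cfg.n_agents, dtype=int)
    for g, members in enumerate(groups):
        group_of[members] = g

    lo_t, hi_t = env.transformed_bounds
    d = env.n_enzymes

    # group histories; bandwidths from the pooled warm-up (scaled median heuristic)
    hists = [History() for _ in groups]
    sig_s = cfg.sigma_s or cfg.bandwidth_scale * median_heuristic_bandwidth(
        wd.states.reshape(-1, env.n_state)
    )
    sig_a = cfg.sigma_a or cfg.bandwidth_scale * median_heuristic_bandwidth(
        wd.actions.reshape(-1, d)
    )
    mmr_params = MMRHyperParams(sig_s, sig_a, cfg.c_xi, normalize=cfg.normalize_prediction)
    for g, members in enumerate(groups):
        for i in members:
            for j in range(cfg.tau):
                hists[g].append(wd.states[i, j], wd.actions[i, j], wd.rewards[i, j])

    levels = init_enzyme_levels(wd, cfg, env, rng_init)
    levels = [np.clip(v, lo_t, hi_t) for v in levels]
    last_queried = [wd.designs[i, -1].copy() for i in range(cfg.n_agents)]
    raw_prev = [np.asarray(env.inverse(wd.designs[i, -1]), dtype=float) for i in range(cfg.n_agents)]
    s_prev = [wd.states[i, -1].copy() for i in range(cfg.n_agents)]
    y_prev = [float(wd.responses[i, -1]) for i in range(cfg.n_agents)]
    response_series = [list(wd.responses[i]) for i in range(cfg.n_agents)]

    rows: list[dict] = []
    policy_rows: list[dict] = []
    n_env_calls = cfg.n_agents * cfg.tau

    def log_row(rnd, agent, phase, d_t, raw, state, response, reward):
        row = {
            "round": rnd,
            "agent": agent,
            "group": int(group_of[agent]),
            "phase": phase,
        }
        row.update({f"design_t_{j + 1}": d_t[j] for j in range(d)})
        row.update({f"design_raw_{j + 1}": raw[j] for j in range(d)})
        row.update({f"state_{j + 1}": state[j] for j in range(env.n_state)})
        row["response"] = response
        row["reward"] = reward
        rows.append(row)

    for i in range(cfg.n_agents):
        for j in range(cfg.tau):
            log_row(
                j + 1,
                i,
                "warmup",
                wd.designs[i, j],
                np.asarray(env.inverse(wd.designs[i, j]), dtype=float),
                wd.states[i, j],
                float(wd.responses[i, j]),
                float(wd.rewards[i, j]),
            )

    best_so_far = float(np.max(wd.responses))
    rounds_since_improvement = 0

    for t in range(1, cfg.n_iterations + 1):
        rnd = cfg.tau + t
        for g, members in enumerate(groups):
            for i in members:
                a_exec = levels[i] - last_queried[i]
                raw = np.asarray(env.inverse(levels[i]), dtype=float)
                try:
                    s, y = env.step(raw, prev_design=raw_prev[i])
                except Exception as exc:
                    raise RuntimeError(
                        f"environment failed at round {rnd}, agent {i}"
                    ) from exc
                n_env_calls += 1
                r = y - y_prev[i]
                hists[g].append(s_prev[i], a_exec, r)
                log_row(rnd, i, "optimize", levels[i], raw, s, y, r)
                last_queried[i] = levels[i].copy()
                raw_prev[i] = raw
                s_prev[i] = s
                y_prev[i] = y
                response_series[i].append(y)
                if y > best_so_far:
                    best_so_far = y
                    rounds_since_improvement = -1  # reset below

            try:
                policy = fit(hists[g], mmr_params, tol=cfg.qp_tol)
            except MMRFitError:
                policy = fit(hists[g], mmr_params, tol=cfg.qp_tol * 10.0)
            policy_rows.append(
                {
                    "round": rnd,
                    "group": g,
                    "n_support": int(np.sum(policy.beta > 1e-8)),
                    "beta_norm": float(np.linalg.norm(policy.beta)),
                }
            )
            acts = []
            for i in members:
                a = predict_action(policy, s_prev[i])
                # exploration kick: the pre-image prediction carries a
                # reliable direction only where support vectors lie nearby,
                # and its magnitude shrinks with the local reward deltas —
                # left alone, agents freeze. Stretch supported directions to
                # the exploration step; elsewhere take a random step.
                if cfg.exploration_kick > 0:
                    norm_a = float(np.linalg.norm(a))
                    conf = policy.support_weight(s_prev[i])
                    if conf >= cfg.kick_confidence and norm_a > 1e-12:
                        a = a * (max(norm_a, cfg.exploration_kick) / norm_a)
                    else:
                        u = rng_pert.standard_normal(d)
                        a = u * (cfg.exploration_kick / np.linalg.norm(u))
                if cfg.max_step is not None and (n := np.linalg.norm(a)) > cfg.max_step:
                    a = a * (cfg.max_step / n)
                acts.append(a)
            acts = perturb_agents(acts, cfg.perturb_c, rng_pert)
            for i, a in zip(members, acts):
                levels[i] = np.clip(levels[i] + a, lo_t, hi_t)

        if cfg.n_agents >= 2 and t % cfg.replace_every_k == 0:
            levels, _, _ = replace_worst(levels, response_series, rng_repl)

        rounds_since_improvement += 1
        if (
            cfg.plateau_patience is not None
            and rounds_since_improvement >= cfg.plateau_patience
        ):
            break

    log = pd.DataFrame(rows)
    best_idx = int(log["response"].idxmax())
    best_raw = log.loc[best_idx, [f"design_raw_{j + 1}" for j in range(d)]].to_numpy(
        dtype=float
    )
    return RunResult(
        method="marl",
        env_name=env.name,
        config=cfg,
        log=log,
        policy_log=pd.DataFrame(policy_rows) if policy_rows else None,
        best_design_raw=best_raw,
        best_response=float(log.loc[best_idx, "response"]),
        n_env_calls=n_env_calls,
    )
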