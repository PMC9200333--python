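"""Comparison optimizers run under the identical experiment budget.

* RAND: pure random search — each round draws the parallel batch uniformly
  from the transformed design box.
* BO-GP: Bayesian optimization with a Gaussian-process surrogate (squared
  exponential kernel, fixed length scale by default via the median
  heuristic) and expected-improvement acquisition; parallel batches are
  built sequentially with the constant-liar strategy.

Both share the Latin-hypercube warm-up protocol of the multi-agent loop,
consume exactly n_parallel × (τ + n_iterations) environment calls, and log
the same tidy schema, so trajectories are directly comparable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF

from ._rng import substream
from .agents import RunResult, WarmupData, latin_hypercube, warmup
from .environments import Environment
from .mmr import median_heuristic_bandwidth

__all__ = [
    "BaselineConfig",
    "GPConfig",
    "bo_gp",
    "expected_improvement",
    "random_search",
]


@dataclass
class GPConfig:
    """Surrogate hyper-parameters for BO-GP."""

    length_scale: float | str = "median"  # "median" → median heuristic per refit
    noise_var: float = 1e-6
    xi: float = 0.0  # EI exploration offset
    n_restarts: int = 64  # LHS multi-starts for the acquisition maximization

    def __post_init__(self):
        if self.length_scale != "median" and not float(self.length_scale) > 0:
            raise ValueError("length_scale must be positive or 'median'")
        if self.noise_var <= 0:
            raise ValueError("noise_var must be positive")
        if self.xi < 0:
            raise ValueError("xi must be >= 0")


@dataclass
class BaselineConfig:
    """Budget protocol shared with the multi-agent method."""

    n_parallel: int = 4
    tau: int = 5
    n_iterations: int = 40
    seed: int = 0
    gp: GPConfig = field(default_factory=GPConfig)

    def __post_init__(self):
        if self.n_parallel < 1:
            raise ValueError("n_parallel must be >= 1")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")


def expected_improvement(mu, sigma, best: float, xi: float = 0.0):
    """Closed-form EI for a Gaussian posterior: (μ−b−ξ)Φ(z) + σφ(z)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    imp = mu - best - xi
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, imp / np.where(sigma > 0, sigma, 1.0), 0.0)
        ei = np.where(sigma > 0, imp * norm.cdf(z) + sigma * norm.pdf(z), 0.0)
    return ei if ei.ndim else float(ei)


def _make_log(env, rows, method, config, n_env_calls):
    log = pd.DataFrame(rows)
    d = env.n_enzymes
    best_idx = int(log["response"].idxmax())
    return RunResult(
        method=method,
        env_name=env.name,
        config=config,
        log=log,
        policy_log=None,
        best_design_raw=log.loc[best_idx, [f"design_raw_{j + 1}" for j in range(d)]].to_numpy(dtype=float),
        best_response=float(log.loc[best_idx, "response"]),
        n_env_calls=n_env_calls,
    )


def _warmup_rows(env, wd: WarmupData):
    d = env.n_enzymes
    rows = []
    for i in range(wd.n_agents):
        for j in range(wd.tau):
            raw = np.asarray(env.inverse(wd.designs[i, j]), dtype=float)
            row = {"round": j + 1, "agent": i, "group": 0, "phase": "warmup"}
            row.update({f"design_t_{k + 1}": wd.designs[i, j, k] for k in range(d)})
            row.update({f"design_raw_{k + 1}": raw[k] for k in range(d)})
            row.update({f"state_{k + 1}": wd.states[i, j, k] for k in range(env.n_state)})
            row["response"] = float(wd.responses[i, j])
            row["reward"] = float(wd.rewards[i, j])
            rows.append(row)
    return rows


def random_search(
    env: Environment, config: BaselineConfig, warmup_data: WarmupData | None = None
) -> RunResult:
    """RAND: uniform draws from the transformed design box, batch per round."""
    cfg = config
    rng_warm = substream(cfg.seed, "warmup")
    rng_draw = substream(cfg.seed, "rand")
    wd = warmup_data if warmup_data is not None else warmup(env, cfg, rng_warm)
    d = env.n_enzymes
    lo_t, hi_t = env.transformed_bounds

    rows = _warmup_rows(env, wd)
    raw_prev = [np.asarray(env.inverse(wd.designs[i, -1]), dtype=float) for i in range(cfg.n_parallel)]
    y_prev = [float(wd.responses[i, -1]) for i in range(cfg.n_parallel)]
    n_env_calls = cfg.n_parallel * cfg.tau

    for t in range(1, cfg.n_iterations + 1):
        batch = rng_draw.uniform(lo_t, hi_t, size=(cfg.n_parallel, d))
        for i in range(cfg.n_parallel):
            d_t = batch[i]
            raw = np.asarray(env.inverse(d_t), dtype=float)
            s, y = env.step(raw, prev_design=raw_prev[i])
            n_env_calls += 1
            row = {"round": cfg.tau + t, "agent": i, "group": 0, "phase": "optimize"}
            row.update({f"design_t_{k + 1}": d_t[k] for k in range(d)})
            row.update({f"design_raw_{k + 1}": raw[k] for k in range(d)})
            row.update({f"state_{k + 1}": s[k] for k in range(env.n_state)})
            row["response"] = y
            row["reward"] = y - y_prev[i]
            rows.append(row)
            raw_prev[i], y_prev[i] = raw, y

    return _make_log(env, rows, "rand", cfg, n_env_calls)


def _fit_gp(x, y, gp_cfg: GPConfig) -> GaussianProcessRegressor:
    if gp_cfg.length_scale == "median":
        ls = median_heuristic_bandwidth(x) if len(x) >= 2 else 1.0
    else:
        ls = float(gp_cfg.length_scale)
    for alpha in (gp_cfg.noise_var, gp_cfg.noise_var + 1e-8):
        gp = GaussianProcessRegressor(
            kernel=RBF(length_scale=ls, length_scale_bounds="fixed"),
            alpha=alpha,
            optimizer=None,
            normalize_y=True,
        )
        try:
            gp.fit(np.asarray(x), np.asarray(y))
            return gp
        except np.linalg.LinAlgError:  # singular covariance → jitter once
            continue
    raise RuntimeError("GP fit failed even with jitter")


def _maximize_ei(gp, best, bounds, gp_cfg: GPConfig, rng) -> np.ndarray:
    def neg_ei(x):
        mu, sd = gp.predict(x.reshape(1, -1), return_std=True)
        return -expected_improvement(mu[0], sd[0], best, gp_cfg.xi)

    starts = latin_hypercube(gp_cfg.n_restarts, bounds, rng)
    best_x, best_val = None, np.inf
    for x0 in starts:
        res = minimize(
            neg_ei, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": 50}
        )
        if res.fun < best_val:
            best_x, best_val = res.x, res.fun
    return np.clip(best_x, bounds[:, 0], bounds[:, 1])


def bo_gp(
    env: Environment, config: BaselineConfig, warmup_data: WarmupData | None = None
) -> RunResult:
    """BO-GP: GP surrogate on (design → response), EI batches via constant liar.

    Each accepted proposal is temporarily assigned the current best observed
    response ("constant liar") so the next proposal in the batch avoids it;
    real responses replace the lies when the batch is executed.
    """
    cfg = config
    rng_warm = substream(cfg.seed, "warmup")
    rng_prop = substream(cfg.seed, "bogp")
    wd = warmup_data if warmup_data is not None else warmup(env, cfg, rng_warm)
    d = env.n_enzymes
    lo_t, hi_t = env.transformed_bounds
    bounds = np.column_stack([np.full(d, lo_t), np.full(d, hi_t)])

    x_train = [wd.designs[i, j] for i in range(cfg.n_parallel) for j in range(cfg.tau)]
    y_train = [float(wd.responses[i, j]) for i in range(cfg.n_parallel) for j in range(cfg.tau)]

    rows = _warmup_rows(env, wd)
    raw_prev = [np.asarray(env.inverse(wd.designs[i, -1]), dtype=float) for i in range(cfg.n_parallel)]
    y_prev = [float(wd.responses[i, -1]) for i in range(cfg.n_parallel)]
    n_env_calls = cfg.n_parallel * cfg.tau

    for t in range(1, cfg.n_iterations + 1):
        best = float(np.max(y_train))
        x_tmp, y_tmp = list(x_train), list(y_train)
        proposals = []
        for _ in range(cfg.n_parallel):
            gp = _fit_gp(x_tmp, y_tmp, cfg.gp)
            x_new = _maximize_ei(gp, float(np.max(y_tmp)), bounds, cfg.gp, rng_prop)
            proposals.append(x_new)
            x_tmp.append(x_new)
            y_tmp.append(best)  # the lie

        for i, d_t in enumerate(proposals):
            raw = np.asarray(env.inverse(d_t), dtype=float)
            s, y = env.step(raw, prev_design=raw_prev[i])
            n_env_calls += 1
            row = {"round": cfg.tau + t, "agent": i, "group": 0, "phase": "optimize"}
            row.update({f"design_t_{k + 1}": d_t[k] for k in range(d)})
            row.update({f"design_raw_{k + 1}": raw[k] for k in range(d)})
            row.update({f"state_{k + 1}": s[k] for k in range(env.n_state)})
            row["response"] = y
            row["reward"] = y - y_prev[i]
            rows.append(row)
            raw_prev[i], y_prev[i] = raw, y
            x_train.append(np.asarray(d_t, dtype=float))
            y_train.append(y)

    return _make_log(env, rows, "bogp", cfg, n_env_calls)
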