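"""Evaluation statistics: best-found trajectories, RSD stability, noise robustness.

Three summaries are computed from run logs:

* best-found trajectories pooled across agents and seeds, reported as the
  median with the 25th–75th percentile band per round;
* the statistical stability of a strain design, measured as the relative
  standard deviation (RSD = σ/μ, the coefficient of variation) of the
  responses in a multiplicative neighborhood of the design — a robust
  design keeps its response under small implementation errors of the
  enzyme levels;
* the degradation of the final-round median best-found response under
  increasing noise, relative to the noiseless protocol.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._rng import substream
from .agents import RunConfig, RunResult, run_marl
from .environments import Environment, NoiseSpec, with_noise

__all__ = [
    "StabilityResult",
    "aggregate_trajectories",
    "final_round_median",
    "noise_degradation",
    "rsd_stability",
    "stability_table",
]


def aggregate_trajectories(runs: list[RunResult]) -> pd.DataFrame:
    """Pool per-agent best-found series across runs; summarize per round.

    Returns a frame with columns round, median, q25, q75, mean where the
    percentiles use linear interpolation. All runs must share their round
    count.
    """
    if not runs:
        raise ValueError("no runs to aggregate")
    tables = [r.best_found() for r in runs]
    n_rounds = {int(t["round"].max()) for t in tables}
    if len(n_rounds) != 1:
        raise ValueError("runs disagree on round count")
    pooled = pd.concat(tables, ignore_index=True)
    out = (
        pooled.groupby("round")["best"]
        .agg(
            median="median",
            q25=lambda v: np.percentile(v, 25),
            q75=lambda v: np.percentile(v, 75),
            mean="mean",
        )
        .reset_index()
    )
    return out


def final_round_median(runs: list[RunResult]) -> float:
    """Median of the final-round best-found values pooled over agents × runs."""
    agg = aggregate_trajectories(runs)
    return float(agg.loc[agg["round"].idxmax(), "median"])


@dataclass
class StabilityResult:
    """RSD of the responses in a perturbed neighborhood of one design."""

    rsd: float
    responses: np.ndarray
    undefined: bool = False  # mean response ≈ 0: σ/μ not meaningful


def rsd_stability(
    env: Environment,
    design,
    n_neighbors: int = 10,
    fold: float = 0.5,
    rng: np.random.Generator | None = None,
    ddof: int = 0,
) -> StabilityResult:
    """σ/μ of responses within a ``fold``-change neighborhood of ``design``.

    Each neighbor multiplies every raw enzyme level by an independent factor
    uniform in [1 − fold, 1 + fold] (a multiplicative reading of
    "fold change"), clipped to the environment's raw bounds. Population
    standard deviation by default (``ddof=0``); set ``ddof=1`` for the
    sample convention.
    """
    if n_neighbors < 2:
        raise ValueError("n_neighbors must be >= 2")
    if not 0.0 < fold < 1.0:
        raise ValueError("fold must be in (0, 1)")
    rng = rng if rng is not None else np.random.default_rng(0)
    design = np.asarray(design, dtype=float)
    lo, hi = env.raw_bounds
    responses = np.empty(n_neighbors)
    for i in range(n_neighbors):
        factors = rng.uniform(1.0 - fold, 1.0 + fold, size=design.shape)
        neighbor = np.clip(design * factors, lo, hi)
        _, responses[i] = env.step(neighbor)
    mu = float(np.mean(responses))
    if mu <= 1e-12:
        return StabilityResult(rsd=float("nan"), responses=responses, undefined=True)
    sigma = float(np.std(responses, ddof=ddof))
    return StabilityResult(rsd=sigma / mu, responses=responses)


def stability_table(
    env: Environment,
    runs: list[RunResult],
    n_neighbors: int = 10,
    fold: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """One RSD per (run, agent) trajectory at that agent's best design.

    Mirrors the mean ± sd summary over 20 trajectories (4 agents × 5 seeds)
    used to compare methods' stability.
    """
    records = []
    for run_idx, run in enumerate(runs):
        d = env.n_enzymes
        for agent, sub in run.log.groupby("agent"):
            best_row = sub.loc[sub["response"].idxmax()]
            design = best_row[[f"design_raw_{j + 1}" for j in range(d)]].to_numpy(dtype=float)
            res = rsd_stability(
                env,
                design,
                n_neighbors=n_neighbors,
                fold=fold,
                rng=substream(seed, "stability", f"{run_idx}-{agent}"),
            )
            records.append(
                {
                    "method": run.method,
                    "env": run.env_name,
                    "run": run_idx,
                    "agent": int(agent),
                    "rsd": res.rsd,
                    "undefined": res.undefined,
                    "best_response": float(best_row["response"]),
                }
            )
    return pd.DataFrame(records)


def noise_degradation(
    env: Environment,
    config: RunConfig,
    noise_grid: list[NoiseSpec],
    seeds: list[int],
) -> pd.DataFrame:
    """Median best-found decrement (%) at the final round vs the noiseless run.

    For each noise spec, the multi-agent loop is run once per seed on the
    noise-wrapped environment; decrement = 100·(median₀ − median_spec)/median₀,
    where the medians pool final-round best-found values over agents × seeds.
    The grid must include the zero spec (the baseline). Negative decrements
    (improvements under noise) are reported as-is.
    """
    if not any(s.is_zero for s in noise_grid):
        raise ValueError("noise_grid must include the zero (noiseless) spec")

    medians: dict[NoiseSpec, float] = {}
    for spec in noise_grid:
        runs = []
        for seed in seeds:
            if spec.is_zero:
                wrapped = env
            else:
                rng = substream(
                    seed,
                    "noise-env",
                    f"{spec.m_state}-{spec.m_action}-{spec.m_response}",
                )
                wrapped = with_noise(env, spec, rng)
            runs.append(run_marl(wrapped, replace(config, seed=seed)))
        medians[spec] = final_round_median(runs)

    base = medians[next(s for s in noise_grid if s.is_zero)]
    records = []
    for spec in noise_grid:
        dec = 0.0 if spec.is_zero else 100.0 * (base - medians[spec]) / base
        records.append(
            {
                "m_state": spec.m_state,
                "m_action": spec.m_action,
                "m_response": spec.m_response,
                "median_best": medians[spec],
                "decrement_pct": dec,
            }
        )
    return pd.DataFrame(records)
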