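"""Experiment orchestration: config files, method comparison, fixture generation.

A run configuration is a YAML or JSON file; unknown keys are rejected so
typos fail loudly. All defaults live in one place (``DEFAULTS``): τ = 5
warm-up rounds, 40 iterations, 4 agents in 2 groups, perturbation
coefficient c = 0.8, worst-agent replacement every 2 rounds, C_ξ = 1.0,
upper quantile 0.75.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .agents import RunConfig, RunResult, run_marl, warmup
from .baselines import BaselineConfig, GPConfig, bo_gp, random_search
from .environments import (
    Environment,
    NoiseSpec,
    make_library_env,
    make_surface_env,
    make_synthetic_library,
)
from .evaluation import aggregate_trajectories

__all__ = [
    "ConfigError",
    "DEFAULTS",
    "ExperimentSpec",
    "build_environment",
    "compare_methods",
    "library_run_config",
    "load_config",
    "make_fixtures",
    "run_experiment",
    "save_config",
]

METHODS = ("marl", "bogp", "rand")
ENVS = ("surface", "library")

DEFAULTS: dict = {
    "methods": ["marl"],
    "env": "surface",
    "env_params": {
        "n_enzymes": 6,
        "env_seed": 0,
        "library_path": None,
        "coverage": 1.0,
        "tolerance": 0.2,
    },
    "run": {
        "n_agents": 4,
        "n_groups": 2,
        "tau": 5,
        "n_iterations": 40,
        "perturb_c": 0.8,
        "replace_every_k": 2,
        "upper_quantile": 0.75,
        "sigma_s": None,
        "sigma_a": None,
        "bandwidth_scale": 0.125,
        "c_xi": 1.0,
        "normalize_prediction": False,
        "exploration_kick": 0.1,
        "kick_confidence": 0.02,
        "max_step": None,
        "plateau_patience": None,
    },
    "baseline": {
        "n_parallel": 4,
        "gp": {"length_scale": "median", "noise_var": 1e-6, "xi": 0.0, "n_restarts": 64},
    },
    "noise": {"m_state": 0.0, "m_action": 0.0, "m_response": 0.0},
    "seeds": [0, 1, 2, 3, 4],
}


class ConfigError(ValueError):
    """Invalid experiment configuration (every offence listed)."""


@dataclass
class ExperimentSpec:
    """A validated experiment: methods × environment × seeds."""

    methods: list[str]
    env: str
    env_params: dict
    run: RunConfig
    baseline: BaselineConfig
    noise: NoiseSpec
    seeds: list[int]
    out_dir: Path | None = None
    #: a programmatically supplied Environment (env == "custom")
    custom_env: Environment | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        run = dataclasses.asdict(self.run)
        run.pop("seed", None)
        run.pop("qp_tol", None)
        baseline = {
            "n_parallel": self.baseline.n_parallel,
            "gp": dataclasses.asdict(self.baseline.gp),
        }
        return {
            "methods": list(self.methods),
            "env": self.env,
            "env_params": dict(self.env_params),
            "run": run,
            "baseline": baseline,
            "noise": dataclasses.asdict(self.noise),
            "seeds": list(self.seeds),
        }


def _merge(defaults: dict, user: dict, prefix: str, errors: list[str]) -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in user and isinstance(dval, dict) and isinstance(user[key], dict):
            out[key] = _merge(dval, user[key], f"{prefix}{key}.", errors)
        elif key in user:
            out[key] = user[key]
        else:
            out[key] = dval
    for key in user:
        if key not in defaults:
            errors.append(f"unknown key: {prefix}{key}")
    return out


def _validate(cfg: dict) -> ExperimentSpec:
    errors: list[str] = []
    methods = cfg["methods"]
    if isinstance(methods, str):
        methods = [methods]
    for m in methods:
        if m not in METHODS:
            errors.append(f"methods: unknown method {m!r} (choose from {METHODS})")
    if cfg["env"] not in ENVS + ("custom",):
        errors.append(f"env: unknown environment {cfg['env']!r}")
    seeds = list(cfg["seeds"])
    if len(set(seeds)) != len(seeds):
        errors.append("seeds: must be distinct")
    r = cfg["run"]
    if not 0.0 <= r["perturb_c"] <= 1.0:
        errors.append("run.perturb_c: must be in [0, 1]")
    if not 0.0 < r["upper_quantile"] < 1.0:
        errors.append("run.upper_quantile: must be in (0, 1)")
    if r["tau"] < 1:
        errors.append("run.tau: must be >= 1")
    if r["n_groups"] > r["n_agents"]:
        errors.append("run.n_groups: must be <= n_agents")
    if r["c_xi"] <= 0:
        errors.append("run.c_xi: must be positive")
    n = cfg["noise"]
    for ch in ("m_state", "m_action", "m_response"):
        if n[ch] < 0:
            errors.append(f"noise.{ch}: must be >= 0")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))

    gp = cfg["baseline"]["gp"]
    return ExperimentSpec(
        methods=methods,
        env=cfg["env"],
        env_params=dict(cfg["env_params"]),
        run=RunConfig(seed=seeds[0], **r),
        baseline=BaselineConfig(
            n_parallel=cfg["baseline"]["n_parallel"],
            tau=r["tau"],
            n_iterations=r["n_iterations"],
            seed=seeds[0],
            gp=GPConfig(**gp),
        ),
        noise=NoiseSpec(**n),
        seeds=seeds,
    )


def load_config(path) -> ExperimentSpec:
    """Parse and validate a YAML/JSON experiment file, filling defaults."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    errors: list[str] = []
    merged = _merge(DEFAULTS, raw, "", errors)
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return _validate(merged)


def save_config(spec: ExperimentSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=True))


def build_environment(spec: ExperimentSpec) -> Environment:
    """Instantiate the environment an ExperimentSpec asks for."""
    p = spec.env_params
    if spec.env == "surface":
        return make_surface_env(int(p["n_enzymes"]), seed=int(p["env_seed"]))
    if spec.env == "library":
        if p.get("library_path"):
            table = pd.read_csv(p["library_path"])
            meta = None
        else:
            table, meta = make_synthetic_library(
                coverage=float(p["coverage"]), seed=int(p["env_seed"])
            )
        return make_library_env(table, tolerance=float(p["tolerance"]), meta=meta)
    if spec.env == "custom":
        if spec.custom_env is None:
            raise ConfigError("env 'custom' needs a programmatically supplied Environment")
        return spec.custom_env
    raise ConfigError(f"unknown environment {spec.env!r}")


def _run_method(method: str, env, spec: ExperimentSpec, seed: int, shared_warmup=None) -> RunResult:
    if method == "marl":
        return run_marl(env, replace(spec.run, seed=seed), warmup_data=shared_warmup)
    if method == "rand":
        return random_search(env, replace(spec.baseline, seed=seed), warmup_data=shared_warmup)
    if method == "bogp":
        return bo_gp(env, replace(spec.baseline, seed=seed), warmup_data=shared_warmup)
    raise ConfigError(f"unknown method {method!r}")


def run_experiment(spec: ExperimentSpec) -> dict[str, list[RunResult]]:
    """Run every (method, seed) combination; write logs when out_dir is set."""
    env = build_environment(spec)
    results: dict[str, list[RunResult]] = {m: [] for m in spec.methods}
    for method in spec.methods:
        for seed in spec.seeds:
            res = _run_method(method, env, spec, seed)
            results[method].append(res)
            if spec.out_dir is not None:
                out = Path(spec.out_dir)
                out.mkdir(parents=True, exist_ok=True)
                res.log.to_csv(out / f"{method}_seed{seed}_log.csv", index=False)
    if spec.out_dir is not None:
        _write_summary(spec, results)
    return results


def compare_methods(spec: ExperimentSpec) -> dict:
    """Run ≥ 2 methods under the identical budget with a shared warm-up.

    For each seed a single warm-up dataset is generated once and handed to
    every method, and all methods see the same environment. Raises when the
    methods' budgets differ (comparisons must be call-for-call fair).
    """
    if len(spec.methods) < 2:
        raise ConfigError("compare needs at least two methods")
    marl_budget = spec.run.n_agents * (spec.run.tau + spec.run.n_iterations)
    base_budget = spec.baseline.n_parallel * (spec.baseline.tau + spec.baseline.n_iterations)
    uses_marl = "marl" in spec.methods
    uses_base = any(m in ("rand", "bogp") for m in spec.methods)
    if uses_marl and uses_base and marl_budget != base_budget:
        raise ConfigError(
            f"budget mismatch: marl uses {marl_budget} environment calls, "
            f"baselines use {base_budget}"
        )

    env = build_environment(spec)
    results: dict[str, list[RunResult]] = {m: [] for m in spec.methods}
    for seed in spec.seeds:
        wcfg = replace(spec.run, seed=seed)
        shared = warmup(env, wcfg, substream(seed, "warmup"))
        for method in spec.methods:
            results[method].append(_run_method(method, env, spec, seed, shared_warmup=shared))

    trajectories = {m: aggregate_trajectories(rs) for m, rs in results.items()}
    if spec.out_dir is not None:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frames = []
        for m, tr in trajectories.items():
            tr = tr.copy()
            tr.insert(0, "method", m)
            frames.append(tr)
        pd.concat(frames, ignore_index=True).to_csv(out / "comparison.csv", index=False)
        for m, rs in results.items():
            for seed, res in zip(spec.seeds, rs):
                res.log.to_csv(out / f"{m}_seed{seed}_log.csv", index=False)
        _write_summary(spec, results)
    return {"results": results, "trajectories": trajectories}


def _write_summary(spec: ExperimentSpec, results: dict[str, list[RunResult]]) -> None:
    summary = {"config": spec.to_dict(), "methods": {}}
    for m, rs in results.items():
        best = max(rs, key=lambda r: r.best_response)
        summary["methods"][m] = {
            "best_response": best.best_response,
            "best_design_raw": [float(v) for v in best.best_design_raw],
            "final_best_per_seed": [float(r.best_response) for r in rs],
        }
    out = Path(spec.out_dir)
    (out / "summary.json").write_text(json.dumps(summary, indent=2))


def library_run_config(seed: int = 0, **overrides) -> RunConfig:
    """Run configuration adapted to coded-strength strain libraries.

    Promoter libraries code gene strength on a 0.2-spaced grid and match
    queries to the nearest strain, so the response surface is piecewise
    constant: within-cell moves carry no signal. The exploration step is
    therefore set to the grid spacing (one coded level per move), the
    kernel bandwidth is left wider than the continuous-surface default
    (the 5-gene box is small and smooth), and the worst agent is replaced
    every round to spread hits quickly across the small grid.
    """
    cfg = dict(
        seed=seed, exploration_kick=0.2, bandwidth_scale=0.25, replace_every_k=1
    )
    cfg.update(overrides)
    return RunConfig(**cfg)


# Named surface testbeds: three products with their perturbed-enzyme counts
# (6 enzymes for succinic acid; 13 each for acetate and ethanol).
PRODUCT_FIXTURES = {"succinic_acid": 6, "acetate": 13, "ethanol": 13}


def make_fixtures(out_dir, seed: int = 0) -> list[Path]:
    """Write the bundled example configurations and data files.

    Produces one surface-environment config per named product, a synthetic
    strain-library CSV at coverage 0.1, and a JSON bundle of small
    hand-computed worked examples (dual QP and perturbation) that double as
    documentation of the core formulas. Regeneration with the same seed is
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for product, n_enzymes in PRODUCT_FIXTURES.items():
        cfg = {
            "methods": ["marl"],
            "env": "surface",
            "env_params": {"n_enzymes": n_enzymes, "env_seed": int(seed)},
        }
        path = out / f"{product}.yaml"
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
        written.append(path)

    table, _ = make_synthetic_library(coverage=0.1, seed=seed)
    lib_path = out / "library.csv"
    table.to_csv(lib_path, index=False)
    written.append(lib_path)

    # c = 0.8 on the pair (1,0), (1/sqrt2, 1/sqrt2): Gram-Schmidt gives
    # e1, e2; the second action becomes 0.2*a2 + 0.8*e2 renormalized to 1.
    sq = float(1.0 / np.sqrt(2.0))
    t2 = np.array([0.2 * sq, 0.2 * sq + 0.8])
    t2 = t2 / np.linalg.norm(t2)
    examples = {
        "dual_qp_scalar": {
            "K": [[1.0]],
            "M": [1.0],
            "c_xi": 10.0,
            "beta": [1.0],
            "note": "min 1/2 b^2 - b over [0, 10] has the closed-form optimum b = 1",
        },
        "perturbation_pair": {
            "actions": [[1.0, 0.0], [sq, sq]],
            "c": 0.8,
            "perturbed": [[1.0, 0.0], [float(t2[0]), float(t2[1])]],
            "gram_det_before": 0.5,
            "gram_det_after": float(1.0 - t2[0] ** 2),
        },
    }
    ex_path = out / "worked_examples.json"
    ex_path.write_text(json.dumps(examples, indent=2, sort_keys=True))
    written.append(ex_path)
    return written
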