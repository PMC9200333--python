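"""Environments: the step contract, the enzyme-level transform, and synthetic testbeds.

An environment maps a strain design (a vector of normalized total enzyme
pools, each in [0.1, 10] for enzyme-tuning problems, or coded promoter
strengths in [0, 1] for combinatorial-library problems) to an observed
state vector and a scalar response (e.g. production × growth).

Two synthetic testbeds are bundled:

* a smooth "kinetic surrogate" surface with a certifiable optimum, standing
  in for an external kinetic-model simulator (which plugs in through the
  same :class:`Environment` contract);
* a combinatorial strain-library lookup emulating a five-gene promoter
  library at six coded strengths, with the nearest-neighbour (< 0.2
  element-wise) matching rule and zero response on no-match.

A noise wrapper adds seeded Gaussian noise on three channels (action,
state, response) to emulate measurement error and biological variability.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "RAW_LO",
    "RAW_HI",
    "Environment",
    "NoiseSpec",
    "transform_enzyme",
    "inverse_transform",
    "identity_transform",
    "make_surface_env",
    "make_library_env",
    "make_synthetic_library",
    "with_noise",
]

#: Valid raw enzyme-level range: 10-fold down- to 10-fold up-regulation.
RAW_LO, RAW_HI = 0.1, 10.0


def transform_enzyme(e_hat):
    """Map enzyme levels ê ≥ 0 to (ê − 1)/(ê + 1) ∈ [−1, 1).

    Induces nearly symmetric ranges for down- and up-regulation:
    f(0) = −1 (knock-out), f(1) = 0 (wild type), f(10) ≈ 0.82.
    Strictly increasing; accepts scalars or arrays.
    """
    e = np.asarray(e_hat, dtype=float)
    if not np.all(np.isfinite(e)) or np.any(e < 0):
        raise ValueError(f"enzyme levels must be finite and >= 0, got {e_hat!r}")
    out = (e - 1.0) / (e + 1.0)
    return float(out) if np.isscalar(e_hat) or out.ndim == 0 else out


def inverse_transform(y):
    """Inverse of :func:`transform_enzyme`: y ∈ (−1, 1) ↦ (1 + y)/(1 − y)."""
    yv = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(yv)) or np.any(np.abs(yv) >= 1.0):
        raise ValueError(f"transformed levels must lie in (-1, 1), got {y!r}")
    out = (1.0 + yv) / (1.0 - yv)
    return float(out) if np.isscalar(y) or out.ndim == 0 else out


def _identity(x):
    return np.asarray(x, dtype=float)


#: (transform, inverse) pair for environments whose design space needs no
#: warping, e.g. coded promoter strengths on [0, 1].
identity_transform = (_identity, _identity)


class Environment:
    """The step contract: design vector in → (state vector, response) out.

    ``step`` is a pure function of the design (and, for noise wrappers, of
    the wrapper's seeded stream). ``baseline_*`` hold the wild-type point —
    the all-ones design — used as the y_{t−1} of each agent's first reward.

    External simulators (e.g. a published kinetic model run out of process)
    attach by constructing an ``Environment`` with their own ``step_fn``.
    """

    def __init__(
        self,
        name: str,
        n_enzymes: int,
        n_state: int,
        step_fn: Callable[[np.ndarray, np.ndarray | None], tuple[np.ndarray, float]],
        raw_bounds: tuple[float, float] = (RAW_LO, RAW_HI),
        transform: Callable = transform_enzyme,
        inverse: Callable = inverse_transform,
        meta: dict | None = None,
        baseline: tuple[np.ndarray, float] | None = None,
    ):
        if n_enzymes < 1:
            raise ValueError("n_enzymes must be >= 1")
        self.name = name
        self.n_enzymes = int(n_enzymes)
        self.n_state = int(n_state)
        self._step_fn = step_fn
        self.raw_bounds = (float(raw_bounds[0]), float(raw_bounds[1]))
        self.transform = transform
        self.inverse = inverse
        self.meta = dict(meta or {})
        self.baseline_design = np.ones(self.n_enzymes)
        if baseline is None:
            self.baseline_state, self.baseline_response = self.step(
                self.baseline_design
            )
        else:
            self.baseline_state = np.asarray(baseline[0], dtype=float)
            self.baseline_response = float(baseline[1])

    @property
    def transformed_bounds(self) -> tuple[float, float]:
        """Design box in transformed space, as (lo, hi) scalars."""
        lo, hi = self.raw_bounds
        return float(self.transform(lo)), float(self.transform(hi))

    def step(self, design, prev_design=None) -> tuple[np.ndarray, float]:
        """Run one cultivation at ``design``; return (state, response).

        ``prev_design`` is the previously executed design of the same
        experiment line; base environments ignore it, the noise wrapper uses
        it to reconstruct the executed action for the action-noise channel.
        """
        design = np.asarray(design, dtype=float)
        if design.shape != (self.n_enzymes,):
            raise ValueError(
                f"design must have shape ({self.n_enzymes},), got {design.shape}"
            )
        lo, hi = self.raw_bounds
        if not np.all(np.isfinite(design)):
            raise ValueError("design must be finite")
        if np.any(design < lo - 1e-9) or np.any(design > hi + 1e-9):
            raise ValueError(f"design outside bounds [{lo}, {hi}]: {design}")
        design = np.clip(design, lo, hi)
        state, y = self._step_fn(design, None if prev_design is None else np.asarray(prev_design, dtype=float))
        return np.asarray(state, dtype=float), float(y)


def make_surface_env(n_enzymes: int, seed: int, y_max: float = 10.0) -> Environment:
    """A smooth response surface with a certifiable optimum ("kinetic surrogate").

    The response is a Gaussian bump in transformed design space,
    y(ê) = y_max · exp(−(f(ê) − f*)ᵀ Q (f(ê) − f*)), with a seeded optimum
    f* ∈ U[−0.6, 0.6]^n and a random SPD curvature Q (eigenvalues in
    [0.5, 2]). The state is a nonlinear readout s = tanh(B f(ê)) with a
    random map B (n_state = 2·n_enzymes), giving nontrivial state–design
    coupling. ``meta`` exposes f*, Q, B and y_max for test oracles.
    """
    if n_enzymes < 2:
        raise ValueError("n_enzymes must be >= 2")
    rng = np.random.default_rng(seed)
    f_star = rng.uniform(-0.6, 0.6, size=n_enzymes)
    h = rng.standard_normal((n_enzymes, n_enzymes))
    q_basis, _ = np.linalg.qr(h)
    eigs = rng.uniform(0.5, 2.0, size=n_enzymes)
    q = (q_basis * eigs) @ q_basis.T
    b = rng.standard_normal((2 * n_enzymes, n_enzymes))

    def step_fn(design, prev):
        z = transform_enzyme(design)
        d = z - f_star
        y = y_max * np.exp(-float(d @ q @ d))
        return np.tanh(b @ z), y

    return Environment(
        name=f"surface-{n_enzymes}",
        n_enzymes=n_enzymes,
        n_state=2 * n_enzymes,
        step_fn=step_fn,
        meta={"f_star": f_star, "y_max": y_max, "Q": q, "B": b, "seed": seed},
    )


def make_synthetic_library(
    n_genes: int = 5,
    strengths: tuple = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    coverage: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Generate a synthetic combinatorial strain library.

    Emulates a five-gene promoter-strength library: the full
    len(strengths)^n_genes grid of coded designs is enumerated, a
    ``coverage`` fraction of rows is sampled (seeded), and each retained
    strain gets a response from a smooth quadratic landscape with one
    designed grid argmax and pairwise gene–gene interactions, times
    multiplicative log-normal measurement noise (σ_log = 0.1). State
    columns are the design columns plus 3 seeded correlated covariates.

    The designed optimum is planted: its row is always retained in the
    sample and, when a lucky noise draw would push another strain past it,
    its response is lifted just above the runner-up so the designed argmax
    is the table maximum by construction (a benchmark with a known ground
    truth, as is standard for synthetic test problems).

    Returns ``(table, meta)``; ``meta`` exposes the planted optimum
    ``x_star`` with its table row and response for test oracles.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    strengths = tuple(float(s) for s in strengths)
    rng = substream(seed, "library")
    grid = np.array(list(itertools.product(strengths, repeat=n_genes)))
    n_rows = max(1, int(round(coverage * len(grid))))
    idx = np.sort(rng.choice(len(grid), size=n_rows, replace=False))

    x_star = np.array(
        [strengths[i] for i in rng.integers(0, len(strengths), size=n_genes)]
    )
    star_grid_idx = int(np.nonzero(np.all(grid == x_star, axis=1))[0][0])
    if star_grid_idx not in idx:  # plant the designed optimum in the sample
        idx[np.argmax(np.sum(np.abs(grid[idx] - x_star), axis=1))] = star_grid_idx
        idx = np.sort(idx)
    designs = grid[idx]

    curvature = np.diag(rng.uniform(1.0, 2.0, size=n_genes))
    inter = rng.uniform(-0.2, 0.2, size=(n_genes, n_genes))
    inter = (inter + inter.T) / 2.0
    np.fill_diagonal(inter, 0.0)
    a_mat = curvature + inter

    diff = designs - x_star
    quad = np.einsum("ij,jk,ik->i", diff, a_mat, diff)
    y0 = 10.0
    noiseless = np.maximum(y0 - quad, 0.1)
    noise = np.exp(rng.normal(0.0, 0.1, size=n_rows))
    response = noiseless * noise

    star_row = int(np.nonzero(idx == star_grid_idx)[0][0])
    runner_up = np.max(np.delete(response, star_row)) if n_rows > 1 else 0.0
    response[star_row] = max(response[star_row], 1.02 * runner_up)

    w_cov = rng.standard_normal((n_genes, 3))
    covariates = designs @ w_cov + 0.1 * rng.standard_normal((n_rows, 3))

    cols = {f"gene_{j + 1}": designs[:, j] for j in range(n_genes)}
    cols["response"] = response
    for j in range(n_genes):
        cols[f"state_{j + 1}"] = designs[:, j]
    for j in range(3):
        cols[f"state_{n_genes + j + 1}"] = covariates[:, j]
    table = pd.DataFrame(cols)

    meta = {
        "x_star": x_star,
        "A": a_mat,
        "y0": y0,
        "argmax_index": star_row,
        "argmax_design": designs[star_row].copy(),
        "max_response": float(response[star_row]),
        "seed": seed,
        "coverage": coverage,
    }
    return table, meta


def make_library_env(
    library: pd.DataFrame, tolerance: float = 0.2, meta: dict | None = None
) -> Environment:
    """Strain-library lookup environment with nearest-neighbour matching.

    A query matches a library row when every coordinate's absolute
    difference is strictly below ``tolerance``; among matches, the row with
    the smallest Euclidean distance wins (ties → lowest row index). With no
    match the response is 0 and the state a zero vector — the design could
    not be built from the library.

    The table needs ``gene_*`` design columns, a ``response`` column, and
    optionally ``state_*`` columns (design columns double as the state when
    absent). Designs are coded promoter strengths on [0, 1]; no enzyme
    transform is applied.
    """
    gene_cols = sorted(
        (c for c in library.columns if c.startswith("gene_")),
        key=lambda c: int(c.split("_")[1]),
    )
    state_cols = sorted(
        (c for c in library.columns if c.startswith("state_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not gene_cols or "response" not in library.columns:
        raise ValueError("library needs gene_* columns and a response column")
    try:
        designs = library[gene_cols].to_numpy(dtype=float)
        responses = library["response"].to_numpy(dtype=float)
        states = (
            library[state_cols].to_numpy(dtype=float) if state_cols else designs
        )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"malformed library table: {exc}") from exc
    if not (np.all(np.isfinite(designs)) and np.all(np.isfinite(responses))):
        raise ValueError("malformed library table: non-finite entries")
    n_genes = designs.shape[1]
    n_state = states.shape[1]

    # Strict "< tolerance" with a guard against float representation noise:
    # a printed-decimal difference of exactly 0.2 must be a non-match even
    # when binary arithmetic lands a hair below 0.2.
    tol_eff = tolerance - 1e-9

    def step_fn(design, prev):
        diff = np.abs(designs - design)
        matched = np.all(diff < tol_eff, axis=1)
        if not matched.any():
            return np.zeros(n_state), 0.0
        rows = np.nonzero(matched)[0]
        d2 = np.sum((designs[rows] - design) ** 2, axis=1)
        winner = rows[int(np.argmin(d2))]  # argmin keeps lowest index on ties
        return states[winner].copy(), float(responses[winner])

    return Environment(
        name="library",
        n_enzymes=n_genes,
        n_state=n_state,
        step_fn=step_fn,
        raw_bounds=(0.0, 1.0),
        transform=identity_transform[0],
        inverse=identity_transform[1],
        meta={"tolerance": tolerance, "n_rows": len(library), **(meta or {})},
    )


@dataclass(frozen=True)
class NoiseSpec:
    """Noise levels, in percent, for the three channels of the wrapper."""

    m_state: float = 0.0
    m_action: float = 0.0
    m_response: float = 0.0

    def __post_init__(self):
        for name in ("m_state", "m_action", "m_response"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def is_zero(self) -> bool:
        return self.m_state == self.m_action == self.m_response == 0


def with_noise(env: Environment, spec: NoiseSpec, rng: np.random.Generator) -> Environment:
    """Wrap an environment with seeded Gaussian noise on three channels.

    * action: the executed design delta (design − prev_design, wild type
      when no prev is given) is perturbed with sd = (m_action/100)·min_i|a_i|
      before application. When an action coordinate is exactly zero the
      literal rule would disable the channel, so the sd is floored at
      1e−8·‖a‖.
    * state: additive noise with sd = (m_state/100)·median(state); when the
      signed median is ≤ 0 the median of absolute values is used instead.
    * response: additive noise with sd = (m_response/100)·|y|.

    A channel at m = 0 draws nothing, so it is disabled exactly. The
    baseline is copied from the wrapped environment noise-free.
    """

    def step_fn(design, prev):
        prev_d = env.baseline_design if prev is None else prev
        executed = design
        if spec.m_action > 0:
            a = design - prev_d
            sd = spec.m_action / 100.0 * float(np.min(np.abs(a)))
            if sd <= 0.0:
                sd = 1e-8 * float(np.linalg.norm(a))
            if sd > 0.0:
                noisy = prev_d + a + rng.normal(0.0, sd, size=a.shape)
                executed = np.clip(noisy, env.raw_bounds[0], env.raw_bounds[1])
        state, y = env.step(executed, prev_design=prev_d)
        if spec.m_state > 0:
            med = float(np.median(state))
            if med <= 0.0:
                med = float(np.median(np.abs(state)))
            if med > 0.0:
                state = state + rng.normal(0.0, spec.m_state / 100.0 * med, size=state.shape)
        if spec.m_response > 0:
            sd = spec.m_response / 100.0 * abs(y)
            if sd > 0.0:
                y = y + rng.normal(0.0, sd)
        return state, y

    return Environment(
        name=f"{env.name}+noise",
        n_enzymes=env.n_enzymes,
        n_state=env.n_state,
        step_fn=step_fn,
        raw_bounds=env.raw_bounds,
        transform=env.transform,
        inverse=env.inverse,
        meta={**env.meta, "noise": spec},
        baseline=(env.baseline_state, env.baseline_response),
    )
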