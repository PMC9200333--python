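"""Maximum Margin Regression (MMR) policy learner.

MMR is an SVM-style learner for vector-valued outputs: a linear operator
W between a state feature space and an action feature space is trained so
that the predicted "reward" ⟨ψ(a), Wφ(s)⟩ of every observed state–action
pair exceeds a margin M(r) that grows with the observed reward r. High-reward
experiments therefore become support vectors, and the learned policy
recommends actions resembling the ones that paid off in similar states.

All of the machinery reduces, through the Lagrangian dual, to a convex
box-constrained quadratic program over coefficients β (one per training
triplet) with the Hadamard product of the state and action Gram matrices
as its quadratic term. The policy prediction is the pre-image solution

    π(s) = Σ_i β_i a_i K_S(s, s_i),

a kernel-weighted recombination of past actions.

The kernels are Gaussian, K(x, x') = exp(−‖x − x'‖² / σ²); note the
bandwidth enters un-squared in the denominator exponent convention used
throughout this package.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "REWARD_FLOOR",
    "History",
    "MMRFitError",
    "MMRHyperParams",
    "MMRPolicy",
    "fit",
    "gaussian_kernel",
    "joint_kernel_matrix",
    "margin_transform",
    "median_heuristic_bandwidth",
    "predict_action",
]

#: Lower clamp applied to rewards before the log margin. Rewards are response
#: deltas y_t − y_{t−1} and can fall at or below −1, outside the domain of
#: log2(r + 1); the clamp preserves monotonicity wherever the log is defined.
REWARD_FLOOR = -1.0 + 1e-6


class MMRFitError(RuntimeError):
    """The dual QP solver failed to reach the requested KKT tolerance."""

    def __init__(self, message: str, status: object = None):
        super().__init__(message)
        self.status = status


def margin_transform(r: float) -> float:
    """Margin M(r) = log2(r + 1) of a reward, clamped at the log-domain edge.

    Strictly increasing on the unclamped range, with M(0) = 0: a no-change
    round asks for zero margin, improvements ask for positive margin.
    """
    r = float(r)
    if not math.isfinite(r):
        raise ValueError(f"reward must be finite, got {r!r}")
    return math.log2(max(r, REWARD_FLOOR) + 1.0)


def gaussian_kernel(x, x2, sigma: float) -> float:
    """Gaussian kernel exp(−‖x − x2‖² / σ²) between two vectors."""
    x = np.asarray(x, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x.shape != x2.shape:
        raise ValueError(f"vector shapes differ: {x.shape} vs {x2.shape}")
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return float(np.exp(-float(np.sum((x - x2) ** 2)) / sigma**2))


def _gaussian_gram(X: np.ndarray, sigma: float) -> np.ndarray:
    d2 = cdist(X, X, metric="sqeuclidean")
    return np.exp(-d2 / sigma**2)


def _gaussian_cross(X: np.ndarray, s: np.ndarray, sigma: float) -> np.ndarray:
    d2 = np.sum((X - s[None, :]) ** 2, axis=1)
    return np.exp(-d2 / sigma**2)


@dataclass
class History:
    """Aligned state–action–reward triplets for one agent group.

    This is the MMR training set: ``states[i]`` is the state observed before
    acting, ``actions[i]`` the executed action (delta in transformed design
    space), and ``rewards[i]`` the resulting change of the response.
    """

    states: list = field(default_factory=list)
    actions: list = field(default_factory=list)
    rewards: list = field(default_factory=list)

    def __post_init__(self):
        if not (len(self.states) == len(self.actions) == len(self.rewards)):
            raise ValueError("states, actions, rewards must have equal length")
        self.states = [np.asarray(s, dtype=float) for s in self.states]
        self.actions = [np.asarray(a, dtype=float) for a in self.actions]
        self.rewards = [float(r) for r in self.rewards]

    def __len__(self) -> int:
        return len(self.rewards)

    def append(self, state, action, reward: float) -> None:
        state = np.asarray(state, dtype=float)
        action = np.asarray(action, dtype=float)
        if not (np.all(np.isfinite(state)) and np.all(np.isfinite(action))):
            raise ValueError("state and action must be finite")
        if self.states and state.shape != self.states[0].shape:
            raise ValueError("state dimension changed within a run")
        if self.actions and action.shape != self.actions[0].shape:
            raise ValueError("action dimension changed within a run")
        self.states.append(state)
        self.actions.append(action)
        self.rewards.append(float(reward))

    def state_matrix(self) -> np.ndarray:
        return np.asarray(self.states, dtype=float)

    def action_matrix(self) -> np.ndarray:
        return np.asarray(self.actions, dtype=float)

    def reward_array(self) -> np.ndarray:
        return np.asarray(self.rewards, dtype=float)

    def copy(self) -> "History":
        return History(
            [s.copy() for s in self.states],
            [a.copy() for a in self.actions],
            list(self.rewards),
        )


@dataclass(frozen=True)
class MMRHyperParams:
    """Kernel bandwidths and the slack trade-off of the dual QP.

    ``c_xi`` is the box bound on the dual coefficients: triplets whose margin
    constraint is violated (slack active) sit at β = c_xi. The slack variables
    and the operator W are never materialized.
    """

    sigma_s: float
    sigma_a: float
    c_xi: float = 1.0
    #: divide the predicted action by Σ β_i K_S (Nadaraya–Watson style);
    #: off by default — the plain pre-image sum is the canonical prediction.
    normalize: bool = False

    def __post_init__(self):
        if not self.sigma_s > 0:
            raise ValueError(f"sigma_s must be positive, got {self.sigma_s}")
        if not self.sigma_a > 0:
            raise ValueError(f"sigma_a must be positive, got {self.sigma_a}")
        if not self.c_xi > 0:
            raise ValueError(f"c_xi must be positive, got {self.c_xi}")


def joint_kernel_matrix(h: History, params: MMRHyperParams) -> np.ndarray:
    """Joint Gram matrix K_SA = K_S ∘ K_A (Hadamard product).

    The element-wise product of two PSD Gram matrices is PSD by the Schur
    product theorem, and has unit diagonal since both factors do.
    """
    if len(h) == 0:
        raise ValueError("history is empty")
    ks = _gaussian_gram(h.state_matrix(), params.sigma_s)
    ka = _gaussian_gram(h.action_matrix(), params.sigma_a)
    return ks * ka


@dataclass
class MMRPolicy:
    """A fitted policy: dual coefficients plus its training triplets."""

    beta: np.ndarray
    train: History
    params: MMRHyperParams

    def predict(self, s) -> np.ndarray:
        return predict_action(self, s)

    def support_weight(self, s) -> float:
        """Fraction of total support mass near ``s``: Σ_i β_i K_S(s, s_i) / Σ_i β_i.

        In (0, 1]; ≈ 0 when no support vector lies within a bandwidth of
        ``s``, i.e. the prediction there extrapolates without local
        evidence. Returns 0 for an all-zero β.
        """
        s = np.asarray(s, dtype=float)
        total = float(self.beta.sum())
        if total <= 0.0:
            return 0.0
        w = self.beta * _gaussian_cross(self.train.state_matrix(), s, self.params.sigma_s)
        return float(w.sum() / total)

    def dual_objective(self) -> float:
        k = joint_kernel_matrix(self.train, self.params)
        m = np.array([margin_transform(r) for r in self.train.rewards])
        return float(0.5 * self.beta @ k @ self.beta - m @ self.beta)

    def to_dict(self) -> dict:
        return {
            "beta": [float(b) for b in self.beta],
            "states": [list(map(float, s)) for s in self.train.states],
            "actions": [list(map(float, a)) for a in self.train.actions],
            "rewards": [float(r) for r in self.train.rewards],
            "sigma_s": self.params.sigma_s,
            "sigma_a": self.params.sigma_a,
            "c_xi": self.params.c_xi,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "MMRPolicy":
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            train=History(d["states"], d["actions"], d["rewards"]),
            params=MMRHyperParams(d["sigma_s"], d["sigma_a"], d["c_xi"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "MMRPolicy":
        return cls.from_dict(json.loads(s))


def _kkt_residual(beta: np.ndarray, grad: np.ndarray, c: float) -> float:
    """Natural-map residual ‖Π_box(β − ∇) − β‖_∞; zero exactly at a KKT point."""
    return float(np.max(np.abs(np.clip(beta - grad, 0.0, c) - beta)))


def _solve_box_qp(k: np.ndarray, m: np.ndarray, c: float, tol: float) -> np.ndarray:
    """Minimize ½βᵀKβ − mᵀβ over the box [0, c]^n to KKT residual ≤ tol.

    L-BFGS-B provides a warm start; cyclic coordinate descent then polishes
    to a certified KKT residual. Each coordinate update is the exact
    one-dimensional minimizer clipped to the box (K has unit diagonal, so
    the sub-problems are strictly convex even when K itself is singular,
    e.g. under duplicated triplets). Deterministic: fixed sweep order, no
    randomized pivoting.
    """
    n = len(m)
    res = minimize(
        lambda b: 0.5 * b @ k @ b - m @ b,
        np.zeros(n),
        jac=lambda b: k @ b - m,
        method="L-BFGS-B",
        bounds=[(0.0, c)] * n,
        options={"maxiter": 1000, "ftol": 1e-15, "gtol": 1e-12},
    )
    beta = np.clip(res.x, 0.0, c)
    for _ in range(10_000):
        grad = k @ beta - m  # recomputed per sweep: incremental updates drift
        if _kkt_residual(beta, grad, c) <= tol:
            return beta
        for i in range(n):
            new = min(max(beta[i] - grad[i] / k[i, i], 0.0), c)
            delta = new - beta[i]
            if delta != 0.0:
                grad += delta * k[:, i]
                beta[i] = new
        if n >= 2:
            # pair step: near-duplicate triplets give K columns with
            # K_ij ≈ 1, a flat valley along e_i − e_j that single-coordinate
            # sweeps traverse at rate (1 − K_ij) per sweep; one exact line
            # minimization along the valley clears it
            i = int(np.argmax(np.abs(np.clip(beta - grad, 0.0, c) - beta)))
            slope = grad[i] - grad
            curv = 2.0 * (k[i, i] - k[i, :])
            t_lo = np.maximum(-beta[i], beta - c)
            t_hi = np.minimum(c - beta[i], beta)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(curv > 1e-15, -slope / np.where(curv > 0, curv, 1.0), np.where(slope > 0, t_lo, t_hi))
            t = np.clip(t, t_lo, t_hi)
            gain = -(slope * t + 0.5 * curv * t * t)
            gain[i] = -np.inf
            j = int(np.argmax(gain))
            if gain[j] > 0 and t[j] != 0.0:
                grad += t[j] * (k[:, i] - k[:, j])
                beta[i] += t[j]
                beta[j] -= t[j]
    raise MMRFitError(
        f"box QP did not reach KKT tolerance {tol:g} "
        f"(residual {_kkt_residual(beta, grad, c):g}, n={n})",
        status=res,
    )


def fit(h: History, params: MMRHyperParams, tol: float = 1e-8) -> MMRPolicy:
    """Fit the MMR dual: β* = argmin ½βᵀK_SA β − Mᵀβ s.t. 0 ≤ β ≤ C_ξ.

    M_i = margin_transform(r_i). Triplets with non-positive margin cannot
    contribute (their optimal β is 0 for PSD K and β ≥ 0), so only rewarded
    experiments become support vectors.
    """
    k = joint_kernel_matrix(h, params)
    m = np.array([margin_transform(r) for r in h.rewards])
    beta = _solve_box_qp(k, m, params.c_xi, tol)
    return MMRPolicy(beta=beta, train=h.copy(), params=params)


def predict_action(p: MMRPolicy, s) -> np.ndarray:
    """Pre-image prediction π(s) = Σ_i β_i a_i K_S(s, s_i)."""
    s = np.asarray(s, dtype=float)
    states = p.train.state_matrix()
    if s.shape != states[0].shape:
        raise ValueError(
            f"state has dimension {s.shape}, policy expects {states[0].shape}"
        )
    w = p.beta * _gaussian_cross(states, s, p.params.sigma_s)
    action = w @ p.train.action_matrix()
    if p.params.normalize:
        total = float(w.sum())
        if total > 1e-12:
            action = action / total
    return action


def median_heuristic_bandwidth(vectors) -> float:
    """Median pairwise Euclidean distance — the default kernel bandwidth.

    Falls back to 1.0 with a warning when all vectors coincide.
    """
    x = np.atleast_2d(np.asarray(vectors, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("need at least two vectors for the median heuristic")
    med = float(np.median(pdist(x)))
    if med <= 0.0:
        warnings.warn(
            "all vectors identical; median-heuristic bandwidth falls back to 1.0",
            stacklevel=2,
        )
        return 1.0
    return med
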