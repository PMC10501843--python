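"""Extreme learning machine trained by norm-constrained least squares.

A single-hidden-layer network whose hidden weights and biases are drawn
once at random and frozen; only the output weight ``w`` is learned.  With
hidden-layer output matrix ``H`` (rows = samples, columns = hidden nodes)
and target vector ``R``, the fit is the constrained least-squares problem

    min_w  0.5 * ||H w - R||^2   subject to  w in C,

where C is an L1 ball (``||w||_1 <= gamma``) or an L2 ball
(``||w||_2^2 <= gamma``) — the norm budget regularizes in place of the
usual Moore-Penrose pseudoinverse solve and guards against overfitting.
The problem is posed as a split feasibility problem with operator ``H``
and target set ``Q = {R}`` and handed to any solver from
:mod:`relaxedcq.solvers`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import (
    SFPInstance,
    l1_ball_constraint,
    l2_ball_constraint,
    singleton_constraint,
)
from .solvers import Method, SolverConfig, SolverRun, solve

__all__ = ["ELMModel", "TrainingSet", "sigmoid", "hidden_matrix", "train", "predict"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically symmetric form; clamped so outputs stay strictly inside (0, 1)
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return np.clip(out, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))


@dataclass
class TrainingSet:
    """Feature matrix (N x d) with binary 0/1 targets (N,)."""

    features: np.ndarray
    targets: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float).ravel()
        if self.features.ndim != 2 or self.features.shape[0] == 0:
            raise ValueError("features must be a nonempty N x d matrix")
        if self.targets.shape[0] != self.features.shape[0]:
            raise ValueError("features and targets disagree on sample count")
        if np.isnan(self.features).any() or np.isnan(self.targets).any():
            raise ValueError("training data must not contain missing values")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass
class ELMModel:
    """Hidden-layer parameters plus the trained output weight.

    Hidden weights (M x d) and biases (M,) are drawn uniformly on [-1, 1]
    from the stated seed, so a model is fully reproducible from
    ``(n_hidden, n_features, seed)``.  ``standardize=True`` (the default)
    z-scores features with moments learned at training time before they
    reach the hidden layer.
    """

    n_hidden: int
    n_features: int
    seed: int = 0
    activation: str = "sigmoid"
    standardize: bool = True
    hidden_weights: np.ndarray = field(init=False)
    hidden_bias: np.ndarray = field(init=False)
    out_weight: Optional[np.ndarray] = None
    feat_mean: Optional[np.ndarray] = None
    feat_scale: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.activation != "sigmoid":
            raise ValueError("only the sigmoid activation is supported")
        if self.n_hidden < 1 or self.n_features < 1:
            raise ValueError("n_hidden and n_features must be positive")
        rng = np.random.default_rng(self.seed)
        self.hidden_weights = rng.uniform(-1.0, 1.0, size=(self.n_hidden, self.n_features))
        self.hidden_bias = rng.uniform(-1.0, 1.0, size=self.n_hidden)

    # -- feature scaling -----------------------------------------------------

    def fit_scaler(self, features: np.ndarray) -> None:
        features = np.asarray(features, dtype=float)
        if self.standardize:
            self.feat_mean = features.mean(axis=0)
            sd = features.std(axis=0)
            sd[sd == 0] = 1.0  # constant columns pass through unscaled
            self.feat_scale = sd
        else:
            self.feat_mean = np.zeros(features.shape[1])
            self.feat_scale = np.ones(features.shape[1])

    def _scale(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if self.feat_mean is None:
            self.fit_scaler(features)
        return (features - self.feat_mean) / self.feat_scale

    # -- forward pass --------------------------------------------------------

    def raw_output(self, features: np.ndarray) -> np.ndarray:
        if self.out_weight is None:
            raise ValueError("model is untrained: out_weight is not set")
        return hidden_matrix(self, features) @ self.out_weight


def hidden_matrix(model: ELMModel, features: np.ndarray) -> np.ndarray:
    """Hidden-layer output matrix: entry (s, i) = sigmoid(<c_i, mu_s> + e_i)."""
    X = model._scale(features)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.n_features})"
        )
    return sigmoid(X @ model.hidden_weights.T + model.hidden_bias)


def train(
    model: ELMModel,
    data: TrainingSet,
    constraint: str = "l2_ball",
    gamma: float = 17.0,
    method: Method | str = Method.IMRCQM,
    config: Optional[SolverConfig] = None,
    keep_iterates: bool = True,
) -> tuple[ELMModel, SolverRun]:
    """Fit the output weight by solving the norm-constrained least-squares SFP.

    The split feasibility encoding: operator A = H (the hidden matrix),
    C = the chosen norm ball (``l1_ball``: ||w||_1 <= gamma, ``l2_ball``:
    ||w||_2^2 <= gamma), Q = {R} the singleton of the target vector with
    q(v) = 0.5*||v - R||^2.  The final iterate receives one exact
    projection onto C before being stored, so the returned weight is
    feasible at any stopping iteration, not only in the limit.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    model.fit_scaler(data.features)
    H = hidden_matrix(model, data.features)
    R = data.targets
    if constraint == "l1_ball":
        Cset = l1_ball_constraint(gamma)
    elif constraint == "l2_ball":
        Cset = l2_ball_constraint(gamma)
    else:
        raise ValueError("constraint must be 'l1_ball' or 'l2_ball'")
    problem = SFPInstance(A=H, Cset=Cset, Qset=singleton_constraint(R))
    if config is None:
        config = SolverConfig(max_iter=500, tol=1e-10)
    run = solve(problem, method=method, config=config, keep_iterates=keep_iterates)
    model.out_weight = Cset.project(run.final)
    return model, run


def predict(
    model: ELMModel, features: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Binary labels from the raw network output: 1 where output >= threshold."""
    return (model.raw_output(features) >= threshold).astype(int)
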