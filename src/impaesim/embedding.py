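"""Disease embeddings: classic autoencoder and its constraint-regularized form.

Each network's diffusion profile matrix X (one row per disease) is compressed
by a single-hidden-layer autoencoder with logistic-sigmoid activations,

    h_i = sigmoid(W x_i + b),    y_i = sigmoid(W' h_i + d),

trained by full-batch gradient descent (Adam) on the summed squared
reconstruction error  sum_i ||y_i - x_i||^2.  The per-network hidden vectors
are concatenated row-wise and fed, together with mined link constraints, to
the constraint-regularized autoencoder, which minimizes

    sum_i ||y_i - x_i||^2
        + gamma * ( gamma1 * sum_{(i,j) in P} ||h_i - h_j||^2
                    - gamma2 * sum_{(i,j) in N} ||h_i - h_j||^2 ),

pulling positive-link pairs together in the hidden space and pushing
negative-link pairs apart.  The reward (negative) term is unbounded below,
so each negative pair's squared distance is capped at a margin ``neg_cap``
before subtraction; within the cap the loss is exactly the raw form, and
``neg_cap=inf`` recovers the literal objective.  All gradients are analytic
(plain backprop plus the quadratic constraint terms); with gamma = 0 the
training loop is bit-for-bit the classic autoencoder.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .constraints import ConstraintSet
from .network_io import NodeIndex

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AeParams:
    """Classic autoencoder hyperparameters (single sigmoid hidden layer)."""

    hidden_dim: int
    learning_rate: float = 1e-3
    epochs: int = 200
    seed: int = 42

    def __post_init__(self) -> None:
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (self.learning_rate > 0):
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class ImpAeParams:
    """Constraint-regularized autoencoder hyperparameters.

    gamma weights the whole constraint loss against reconstruction; gamma1 /
    gamma2 weight the positive (penalty) and negative (reward) sums inside
    it.  The reconstruction term sums O(1) errors over every coordinate of
    every disease while the constraint sums cover a few dozen near-coincident
    pairs, so commensurate defaults must be large: gamma=1000 with
    gamma1=100, gamma2=1 makes both constraint terms actually shape the
    hidden geometry at realistic data scales.  ``neg_cap`` is the margin
    capping each negative pair's squared hidden distance so the reward term
    cannot diverge to -inf.
    """

    final_dim: int
    gamma1: float = 100.0
    gamma2: float = 1.0
    gamma: float = 1000.0
    neg_cap: float = 1.0
    learning_rate: float = 1e-3
    epochs: int = 200
    seed: int = 42

    def __post_init__(self) -> None:
        if self.final_dim < 1:
            raise ValueError("final_dim must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        for name in ("gamma1", "gamma2", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.neg_cap > 0):
            raise ValueError("neg_cap must be positive (use inf for no cap)")


@dataclass
class AeModel:
    """Encoder/decoder weights: h = sigmoid(W x + b), y = sigmoid(W_out h + d)."""

    W: np.ndarray
    b: np.ndarray
    W_out: np.ndarray
    d: np.ndarray

    def encode(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.W.T + self.b)

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        H = self.encode(X)
        return H, expit(H @ self.W_out.T + self.d)


@dataclass
class DiseaseEmbedding:
    """Final low-dimensional feature vector per disease (rows align with index)."""

    disease_index: NodeIndex
    vectors: np.ndarray

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.disease_index):
            raise ValueError("vector row count must match disease index size")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains non-finite entries")
        if np.any(np.all(self.vectors == 0, axis=1)):
            warnings.warn("embedding contains all-zero rows", RuntimeWarning,
                          stacklevel=2)


def init_model(n_in: int, n_hidden: int, seed: int) -> AeModel:
    """Glorot-style uniform initialization from a seeded generator; zero biases."""
    rng = np.random.default_rng(seed)
    lim_enc = math.sqrt(6.0 / (n_in + n_hidden))
    lim_dec = math.sqrt(6.0 / (n_hidden + n_in))
    return AeModel(
        W=rng.uniform(-lim_enc, lim_enc, size=(n_hidden, n_in)),
        b=np.zeros(n_hidden),
        W_out=rng.uniform(-lim_dec, lim_dec, size=(n_in, n_hidden)),
        d=np.zeros(n_in),
    )


def _pairs_to_indices(
    pairs: Sequence[tuple[str, str]], index: NodeIndex
) -> tuple[np.ndarray, np.ndarray]:
    if not pairs:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    ii, jj = [], []
    for a, b in sorted(pairs):
        ii.append(index.position(a))
        jj.append(index.position(b))
    return np.array(ii), np.array(jj)


def loss_and_grad(
    model: AeModel,
    X: np.ndarray,
    pos_idx: tuple[np.ndarray, np.ndarray] | None = None,
    neg_idx: tuple[np.ndarray, np.ndarray] | None = None,
    gamma: float = 0.0,
    gamma1: float = 1.0,
    gamma2: float = 1.0,
    neg_cap: float = math.inf,
) -> tuple[float, AeModel]:
    """Joint loss and its analytic gradient with respect to all parameters.

    Returns the scalar loss and an :class:`AeModel` holding the gradient
    arrays in the corresponding slots.  With ``gamma == 0`` (or empty
    constraint index arrays) this is exactly the reconstruction objective.
    """
    Z1 = X @ model.W.T + model.b
    H = expit(Z1)
    Z2 = H @ model.W_out.T + model.d
    Y = expit(Z2)

    R = Y - X
    loss = float((R * R).sum())
    Gc = np.zeros_like(H)

    use_constraints = gamma != 0.0
    if use_constraints and pos_idx is not None and pos_idx[0].size:
        pi, pj = pos_idx
        diff = H[pi] - H[pj]
        loss += gamma * gamma1 * float((diff * diff).sum())
        scaled = (2.0 * gamma * gamma1) * diff
        np.add.at(Gc, pi, scaled)
        np.add.at(Gc, pj, -scaled)
    if use_constraints and neg_idx is not None and neg_idx[0].size:
        ni, nj = neg_idx
        diff = H[ni] - H[nj]
        d2 = (diff * diff).sum(axis=1)
        loss -= gamma * gamma2 * float(np.minimum(d2, neg_cap).sum())
        active = d2 < neg_cap  # capped pairs contribute zero gradient
        scaled = (-2.0 * gamma * gamma2) * diff[active]
        np.add.at(Gc, ni[active], scaled)
        np.add.at(Gc, nj[active], -scaled)

    dZ2 = (2.0 * R) * Y * (1.0 - Y)
    gW_out = dZ2.T @ H
    gd = dZ2.sum(axis=0)
    dH = dZ2 @ model.W_out + Gc
    dZ1 = dH * H * (1.0 - H)
    gW = dZ1.T @ X
    gb = dZ1.sum(axis=0)
    return loss, AeModel(W=gW, b=gb, W_out=gW_out, d=gd)


def _train(
    X: np.ndarray,
    hidden_dim: int,
    learning_rate: float,
    epochs: int,
    seed: int,
    pos_idx: tuple[np.ndarray, np.ndarray] | None = None,
    neg_idx: tuple[np.ndarray, np.ndarray] | None = None,
    gamma: float = 0.0,
    gamma1: float = 1.0,
    gamma2: float = 1.0,
    neg_cap: float = math.inf,
) -> tuple[AeModel, np.ndarray, list[float]]:
    """Full-batch Adam on the (possibly constraint-regularized) AE objective."""
    X = np.asarray(X, dtype=float)
    n, n_in = X.shape
    if n < 2:
        raise ValueError("need at least 2 input rows")
    if hidden_dim >= n_in:
        raise ValueError(
            f"hidden_dim ({hidden_dim}) must be smaller than input dim ({n_in})"
        )
    model = init_model(n_in, hidden_dim, seed)
    params = [model.W, model.b, model.W_out, model.d]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    history: list[float] = []
    has_negatives = neg_idx is not None and neg_idx[0].size > 0
    for epoch in range(1, epochs + 1):
        loss, grad = loss_and_grad(
            model, X, pos_idx, neg_idx, gamma, gamma1, gamma2, neg_cap
        )
        if not np.isfinite(loss):
            hint = (
                " (the negative-link reward term may be diverging; reduce "
                "gamma2 or the neg_cap margin)"
                if gamma != 0.0 and has_negatives
                else ""
            )
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}{hint}"
            )
        history.append(loss)
        grads = [grad.W, grad.b, grad.W_out, grad.d]
        for k, (p, g) in enumerate(zip(params, grads)):
            m[k] = beta1 * m[k] + (1 - beta1) * g
            v[k] = beta2 * v[k] + (1 - beta2) * g * g
            m_hat = m[k] / (1 - beta1**epoch)
            v_hat = v[k] / (1 - beta2**epoch)
            p -= learning_rate * m_hat / (np.sqrt(v_hat) + eps)
    H = model.encode(X)
    logger.info(
        "trained AE (%d->%d, gamma=%g): loss %.5g -> %.5g over %d epochs",
        n_in, hidden_dim, gamma, history[0], history[-1], epochs,
    )
    return model, H, history


def train_classic_ae(
    profiles, params: AeParams
) -> tuple[AeModel, np.ndarray]:
    """Train the plain reconstruction autoencoder on diffusion profiles.

    ``profiles`` may be a :class:`~impaesim.diffusion.DiffusionProfile` or a
    raw (n_diseases x n_features) array.
    """
    X = profiles.profiles if hasattr(profiles, "profiles") else np.asarray(profiles)
    model, H, _ = _train(
        X, params.hidden_dim, params.learning_rate, params.epochs, params.seed
    )
    return model, H


def concatenate_hidden(
    hidden_list: Sequence[np.ndarray], index: NodeIndex
) -> np.ndarray:
    """Row-wise concatenation of per-network hidden matrices (aligned rows)."""
    if not hidden_list:
        raise ValueError("need at least one hidden matrix")
    n = len(index)
    for k, h in enumerate(hidden_list):
        if h.shape[0] != n:
            raise ValueError(
                f"hidden matrix {k} has {h.shape[0]} rows, index has {n}"
            )
    return np.hstack([np.asarray(h, dtype=float) for h in hidden_list])


def constraint_loss(
    hidden: np.ndarray,
    index: NodeIndex,
    constraints: ConstraintSet,
    gamma1: float = 1.0,
    gamma2: float = 1.0,
    neg_cap: float = math.inf,
) -> float:
    """Constraint loss gamma1 * sum_P ||h_i-h_j||^2 - gamma2 * sum_N ||h_i-h_j||^2.

    Negative-pair squared distances are capped at ``neg_cap`` (default inf,
    i.e. the raw objective).
    """
    hidden = np.asarray(hidden, dtype=float)
    total = 0.0
    for a, b in constraints.positives:
        diff = hidden[index.position(a)] - hidden[index.position(b)]
        total += gamma1 * float(diff @ diff)
    for a, b in constraints.negatives:
        diff = hidden[index.position(a)] - hidden[index.position(b)]
        total -= gamma2 * min(float(diff @ diff), neg_cap)
    return total


def train_impae(
    concat: np.ndarray,
    constraints: ConstraintSet,
    params: ImpAeParams,
    index: NodeIndex,
) -> DiseaseEmbedding:
    """Train the constraint-regularized autoencoder; hidden layer is the embedding."""
    pos_idx = _pairs_to_indices(sorted(constraints.positives), index)
    neg_idx = _pairs_to_indices(sorted(constraints.negatives), index)
    _, H, history = _train(
        concat,
        params.final_dim,
        params.learning_rate,
        params.epochs,
        params.seed,
        pos_idx=pos_idx,
        neg_idx=neg_idx,
        gamma=params.gamma,
        gamma1=params.gamma1,
        gamma2=params.gamma2,
        neg_cap=params.neg_cap,
    )
    return DiseaseEmbedding(index, H)


def save_embedding(embedding: DiseaseEmbedding, path: Union[str, Path]) -> None:
    """Write embedding vectors as a TSV matrix keyed by disease id."""
    df = pd.DataFrame(
        embedding.vectors,
        index=list(embedding.disease_index),
        columns=[f"dim_{k}" for k in range(embedding.vectors.shape[1])],
    )
    df.to_csv(path, sep="\t", index_label="disease")


def load_embedding(path: Union[str, Path]) -> DiseaseEmbedding:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DiseaseEmbedding(
        NodeIndex(tuple(df.index), "disease"), df.to_numpy(dtype=float)
    )
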