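"""Random walk with restart (RWR) on the bipartite disease networks.

The walk runs on the full bipartite graph (diseases + partner nodes).  With
row-stochastic transition matrix B, mass-conserving propagation is

    p^{t+1} = (1 - u_r) * B.T @ p^t + u_r * e_source

iterated from p^0 = e_source to an L1 tolerance.  The stationary vector is
then restricted to the shared disease coordinates and renormalized to give a
per-disease diffusion profile; stacking profiles over all shared diseases
yields the n x n feature matrix downstream embedding consumes.

Note: left-multiplying p by a row-stochastic B (instead of B.T) does not
conserve probability mass; the transpose convention used here is the
standard one that keeps p a distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network_io import DiseaseNetwork, NodeIndex

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RwrParams:
    """Restart probability u_r, L1 convergence tolerance and iteration cap."""

    restart_prob: float = 0.5
    tol: float = 1e-6
    max_iter: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.restart_prob <= 1.0):
            raise ValueError(f"restart_prob must be in (0, 1], got {self.restart_prob}")
        if not (self.tol > 0):
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass
class DiffusionProfile:
    """Stationary RWR vectors restricted to the shared disease coordinates.

    Row i of ``profiles`` is the renormalized stationary distribution of the
    walk restarted at ``disease_index.ids[i]``; every row is non-negative and
    sums to 1.
    """

    network_name: str
    disease_index: NodeIndex
    profiles: np.ndarray

    def __post_init__(self) -> None:
        if self.profiles.shape[0] != len(self.disease_index):
            raise ValueError("profile row count must match disease index size")


def transition_matrix(
    network: DiseaseNetwork,
) -> Union[np.ndarray, sp.csr_array]:
    """Row-normalize the adjacency: B[i, j] = A[i, j] / sum_j' A[i, j']."""
    A = network.adjacency
    if sp.issparse(A):
        row_sums = np.asarray(A.sum(axis=1)).ravel()
        if np.any(row_sums <= 0):
            raise ValueError("zero-degree node found; filter isolated nodes first")
        inv = sp.diags_array(1.0 / row_sums)
        return sp.csr_array(inv @ A)
    row_sums = A.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValueError("zero-degree node found; filter isolated nodes first")
    return A / row_sums[:, None]


def rwr(network: DiseaseNetwork, source: str, params: RwrParams) -> np.ndarray:
    """Stationary RWR distribution over all nodes, restarted at ``source``.

    Iterates p <- (1 - u_r) B.T p + u_r e_source until the L1 change drops
    below ``params.tol``; warns and returns the last iterate if the cap is
    hit first.
    """
    B = transition_matrix(network)
    BT = B.T if not sp.issparse(B) else sp.csr_array(B.T)
    idx = network.node_position(source)
    n = network.n_nodes
    e = np.zeros(n)
    e[idx] = 1.0
    u = params.restart_prob
    p = e.copy()
    for _ in range(params.max_iter):
        p_next = (1.0 - u) * (BT @ p) + u * e
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < params.tol:
            break
    else:
        warnings.warn(
            f"RWR from {source!r} on {network.name} did not converge to "
            f"{params.tol} within {params.max_iter} iterations "
            f"(last L1 change {delta:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return p


def rwr_closed_form(
    network: DiseaseNetwork, source: str, params: RwrParams
) -> np.ndarray:
    """Exact stationary vector u_r (I - (1-u_r) B.T)^{-1} e_source (dense solve)."""
    B = transition_matrix(network)
    Bd = np.asarray(B.todense()) if sp.issparse(B) else B
    n = network.n_nodes
    e = np.zeros(n)
    e[network.node_position(source)] = 1.0
    u = params.restart_prob
    return u * np.linalg.solve(np.eye(n) - (1.0 - u) * Bd.T, e)


def diffusion_profiles(
    network: DiseaseNetwork, params: RwrParams, shared: NodeIndex
) -> DiffusionProfile:
    """Run RWR from every shared disease and restrict to shared coordinates.

    Each stationary vector is cut down to the shared-disease entries and
    renormalized to sum 1 (uniform fallback for an all-zero restriction,
    which can only happen numerically).
    """
    missing = [d for d in shared if d not in network.disease_index]
    if missing:
        raise ValueError(
            f"shared diseases absent from network {network.name}: {missing[:5]}"
        )
    coords = np.array([network.node_position(d) for d in shared])
    n = len(shared)
    profiles = np.empty((n, n))
    for i, disease in enumerate(shared):
        p = rwr(network, disease, params)
        row = p[coords]
        total = row.sum()
        if total <= 0:
            row = np.full(n, 1.0 / n)
        else:
            row = row / total
        profiles[i] = row
    logger.info("diffusion profiles on %s: %d x %d", network.name, n, n)
    return DiffusionProfile(network.name, shared, profiles)


def exclude_self_mass(profile: DiffusionProfile) -> DiffusionProfile:
    """Drop each row's own-disease coordinate and renormalize.

    The restart term concentrates most of a stationary vector's restricted
    mass on the source disease itself (for u_r = 0.5 typically well over
    half), a feature that encodes identity rather than relatedness and
    swamps downstream feature learning.  Zeroing the diagonal and
    renormalizing keeps only the informative cross-disease mass; an all-zero
    row (possible only in degenerate walks, e.g. u_r = 1) falls back to
    uniform.
    """
    P = profile.profiles.copy()
    np.fill_diagonal(P, 0.0)
    totals = P.sum(axis=1)
    n = P.shape[1]
    for i, total in enumerate(totals):
        if total <= 0:
            P[i] = np.full(n, 1.0 / n)
        else:
            P[i] /= total
    return DiffusionProfile(profile.network_name, profile.disease_index, P)


def save_profiles(profile: DiffusionProfile, path: Union[str, Path]) -> None:
    """Write profiles as a TSV matrix with disease ids as row/column headers."""
    df = pd.DataFrame(
        profile.profiles,
        index=list(profile.disease_index),
        columns=list(profile.disease_index),
    )
    df.to_csv(path, sep="\t", index_label="disease")


def load_profiles(path: Union[str, Path], network_name: str) -> DiffusionProfile:
    df = pd.read_csv(path, sep="\t", index_col=0)
    index = NodeIndex(tuple(df.index), "disease")
    return DiffusionProfile(network_name, index, df.to_numpy(dtype=float))
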