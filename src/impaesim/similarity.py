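"""Cosine disease-similarity scoring, ranking and score-distribution summaries.

The similarity of two diseases is the cosine of their embedding vectors,
Sim(d1, d2) = <v1, v2> / (||v1|| ||v2||).  Optionally the off-diagonal scores
are min-max rescaled to [0, 1] (the diagonal stays at the maximum), which
makes score densities across methods comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .embedding import DiseaseEmbedding
from .network_io import NodeIndex

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    """Symmetric all-pairs disease similarity scores.

    ``normalized`` records whether off-diagonal entries were min-max rescaled
    to [0, 1]; raw cosine entries lie in [-1, 1].
    """

    disease_index: NodeIndex
    scores: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        n = len(self.disease_index)
        if self.scores.shape != (n, n):
            raise ValueError(f"score matrix shape {self.scores.shape} != ({n},{n})")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of two vectors; 0.0 with a warning if either is the zero vector."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        warnings.warn("zero vector in cosine similarity; returning 0.0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def similarity_matrix(
    embedding: DiseaseEmbedding, normalize: bool = True
) -> SimilarityMatrix:
    """All-pairs cosine similarity, optionally min-max normalized off-diagonal.

    Zero-vector rows score 0 against everything.  Under normalization the
    smallest off-diagonal score maps to 0 and the largest to 1; the diagonal
    is set to 1.  A constant off-diagonal (degenerate) maps to all zeros
    with a warning.
    """
    n = len(embedding.disease_index)
    if n < 2:
        raise ValueError("need at least 2 diseases")
    V = embedding.vectors
    zero_rows = np.linalg.norm(V, axis=1) == 0
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} zero-vector embeddings score 0 everywhere",
            RuntimeWarning, stacklevel=2,
        )
    S = _sk_cosine(V)
    S = np.clip(S, -1.0, 1.0)
    S[zero_rows, :] = 0.0
    S[:, zero_rows] = 0.0
    np.fill_diagonal(S, np.where(zero_rows, 0.0, 1.0))
    S = np.triu(S) + np.triu(S, 1).T  # exact symmetry
    if normalize:
        iu, ju = np.triu_indices(n, k=1)
        vals = S[iu, ju]
        lo, hi = vals.min(), vals.max()
        if hi > lo:
            scaled = (vals - lo) / (hi - lo)
        else:
            warnings.warn("constant off-diagonal scores; normalized to 0",
                          RuntimeWarning, stacklevel=2)
            scaled = np.zeros_like(vals)
        S = np.zeros_like(S)
        S[iu, ju] = scaled
        S = S + S.T
        np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(embedding.disease_index, S, normalized=normalize)


def top_k(
    matrix: SimilarityMatrix, query: str, k: int
) -> list[tuple[str, float]]:
    """The k most similar diseases to ``query`` (ties broken lexicographically)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    idx = matrix.disease_index.position(query)  # raises on unknown id
    ids = matrix.disease_index.ids
    scored = [
        (ids[j], float(matrix.scores[idx, j]))
        for j in range(len(ids))
        if j != idx
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:k]


def score_density_summary(matrix: SimilarityMatrix, bins: int) -> pd.DataFrame:
    """Histogram of off-diagonal scores over the natural score range.

    Bins span [0, 1] for normalized scores and [-1, 1] for raw cosines;
    counts sum to n(n-1)/2.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    n = len(matrix.disease_index)
    iu, ju = np.triu_indices(n, k=1)
    vals = matrix.scores[iu, ju]
    lo, hi = (0.0, 1.0) if matrix.normalized else (-1.0, 1.0)
    counts, edges = np.histogram(np.clip(vals, lo, hi), bins=bins, range=(lo, hi))
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def interval_count(matrix: SimilarityMatrix, low: float, high: float) -> int:
    """Number of off-diagonal pairs with score in the closed interval [low, high]."""
    n = len(matrix.disease_index)
    iu, ju = np.triu_indices(n, k=1)
    vals = matrix.scores[iu, ju]
    return int(((vals >= low) & (vals <= high)).sum())


def save_similarity(matrix: SimilarityMatrix, path: Union[str, Path]) -> None:
    """Write the long-format pair table (disease_a, disease_b, score) as TSV."""
    n = len(matrix.disease_index)
    ids = matrix.disease_index.ids
    iu, ju = np.triu_indices(n, k=1)
    df = pd.DataFrame(
        {
            "disease_a": [ids[i] for i in iu],
            "disease_b": [ids[j] for j in ju],
            "score": matrix.scores[iu, ju],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def save_similarity_matrix(matrix: SimilarityMatrix, path: Union[str, Path]) -> None:
    """Write the full square score matrix as TSV with disease-id headers."""
    df = pd.DataFrame(
        matrix.scores,
        index=list(matrix.disease_index),
        columns=list(matrix.disease_index),
    )
    df.to_csv(path, sep="\t", index_label="disease")


def load_similarity_matrix(
    path: Union[str, Path], normalized: bool = True
) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(
        NodeIndex(tuple(df.index), "disease"),
        df.to_numpy(dtype=float),
        normalized=normalized,
    )
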