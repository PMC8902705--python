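"""Positive/negative link constraints from per-network Pearson correlation.

For each network, pairwise disease similarity is the Pearson correlation
coefficient (PCC) of per-disease feature vectors (by default the classic-AE
hidden vectors).  Two thresholds T1 > T2 carve out a small set of
positive-link pairs (PCC > T1, must be close after embedding) and
negative-link pairs (PCC < T2, must be far).  Constraints mined per network
are merged before being handed to the constraint-regularized autoencoder;
because the three networks can disagree, the default merge unions each
polarity and drops any pair claimed by both polarities, while strict
intersection is available as the conservative alternative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .network_io import NodeIndex

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Unordered pair stored as a lexicographically sorted tuple."""
    if a == b:
        raise ValueError(f"self-pair {a!r} is not a valid constraint")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class ConstraintParams:
    """Thresholding and merging policy for constraint extraction.

    In ``absolute`` mode the thresholds are raw PCC cutoffs with
    -1 <= negative < positive <= 1.  In ``quantile`` mode (default) they are
    empirical quantiles of the off-diagonal PCC distribution, so the sizes
    of the extracted sets track the data rather than a fixed scale: the
    defaults keep roughly the top 0.5% of pairs as positive links and the
    bottom 0.5% as negative links.
    """

    positive_threshold: float = 0.995
    negative_threshold: float = 0.005
    mode: str = "quantile"
    merge: str = "union_drop_conflicts"

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "quantile"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.merge not in ("intersection", "union_drop_conflicts"):
            raise ValueError(f"unknown merge {self.merge!r}")
        t1, t2 = self.positive_threshold, self.negative_threshold
        if self.mode == "absolute":
            if not (-1.0 <= t2 < t1 <= 1.0):
                raise ValueError(
                    f"absolute mode requires -1 <= T2 < T1 <= 1, got T1={t1}, T2={t2}"
                )
        else:
            if not (0.0 < t2 < t1 < 1.0):
                raise ValueError(
                    "quantile mode requires 0 < negative < positive < 1, "
                    f"got positive={t1}, negative={t2}"
                )


@dataclass
class ConstraintSet:
    """Disjoint sets of positive-link (P) and negative-link (N) disease pairs."""

    positives: set[Pair] = field(default_factory=set)
    negatives: set[Pair] = field(default_factory=set)

    def __post_init__(self) -> None:
        for pair in list(self.positives) + list(self.negatives):
            if pair != canonical_pair(*pair):
                raise ValueError(f"pair {pair} not stored canonically")
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"P and N overlap on {len(overlap)} pairs")

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient of two equal-length vectors.

    Returns 0.0 with a warning when either vector has zero variance, where
    the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            "zero-variance vector in PCC; returning 0.0", RuntimeWarning, stacklevel=2
        )
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def pairwise_pcc(hidden: np.ndarray, index: NodeIndex) -> np.ndarray:
    """All-pairs PCC of the rows of ``hidden``; symmetric with unit diagonal.

    Rows with zero variance correlate 0 with everything (their diagonal
    entry is also 0, flagging the degenerate row).
    """
    hidden = np.asarray(hidden, dtype=float)
    if hidden.shape[0] != len(index):
        raise ValueError(
            f"hidden has {hidden.shape[0]} rows but index has {len(index)} diseases"
        )
    stds = hidden.std(axis=1)
    constant = stds == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance rows in pairwise PCC",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(hidden)
    mat = np.nan_to_num(mat, nan=0.0)
    mat[constant, :] = 0.0
    mat[:, constant] = 0.0
    mat = np.clip(mat, -1.0, 1.0)
    mat = np.triu(mat) + np.triu(mat, 1).T  # exact symmetry
    return mat


def _offdiag_upper(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(matrix.shape[0], k=1)
    return iu, ju, matrix[iu, ju]


def extract_constraints(
    pcc_matrix: np.ndarray, index: NodeIndex, params: ConstraintParams
) -> ConstraintSet:
    """Threshold a PCC matrix into positive- and negative-link pair sets."""
    n = len(index)
    if pcc_matrix.shape != (n, n):
        raise ValueError(f"matrix shape {pcc_matrix.shape} does not match index ({n})")
    iu, ju, vals = _offdiag_upper(np.asarray(pcc_matrix, dtype=float))
    if params.mode == "quantile":
        t1 = float(np.quantile(vals, params.positive_threshold))
        t2 = float(np.quantile(vals, params.negative_threshold))
        if t2 > t1:  # heavy ties can invert empirical quantiles
            t2 = t1
    else:
        t1, t2 = params.positive_threshold, params.negative_threshold
    ids = index.ids
    positives = {
        canonical_pair(ids[i], ids[j]) for i, j, v in zip(iu, ju, vals) if v > t1
    }
    negatives = {
        canonical_pair(ids[i], ids[j]) for i, j, v in zip(iu, ju, vals) if v < t2
    }
    logger.info(
        "extracted constraints (T1=%.4f, T2=%.4f): |P|=%d, |N|=%d of %d pairs",
        t1, t2, len(positives), len(negatives), len(vals),
    )
    return ConstraintSet(positives, negatives)


def merge_constraints(
    sets: Sequence[ConstraintSet], merge: str = "union_drop_conflicts"
) -> ConstraintSet:
    """Combine per-network constraint sets into one disjoint pair of sets.

    ``intersection``: keep only pairs every network agrees on, per polarity.
    ``union_drop_conflicts``: pool each polarity across networks, then drop
    any pair that some network assigned to the opposite polarity.
    """
    if not sets:
        raise ValueError("need at least one constraint set")
    if merge == "intersection":
        positives = set.intersection(*(s.positives for s in sets))
        negatives = set.intersection(*(s.negatives for s in sets))
    elif merge == "union_drop_conflicts":
        all_pos = set.union(*(s.positives for s in sets))
        all_neg = set.union(*(s.negatives for s in sets))
        positives = all_pos - all_neg
        negatives = all_neg - all_pos
    else:
        raise ValueError(f"unknown merge mode {merge!r}")
    merged = ConstraintSet(positives, negatives)
    logger.info("merged %d sets (%s): |P|=%d, |N|=%d",
                len(sets), merge, len(positives), len(negatives))
    return merged


def save_constraints(cs: ConstraintSet, prefix: Union[str, Path]) -> None:
    """Write one two-column pair-list file per polarity."""
    for polarity, pairs in (("positive", cs.positives), ("negative", cs.negatives)):
        with open(f"{prefix}.{polarity}.tsv", "w") as fh:
            for a, b in sorted(pairs):
                fh.write(f"{a}\t{b}\n")


def load_constraints(prefix: Union[str, Path]) -> ConstraintSet:
    def read(path: str) -> set[Pair]:
        pairs: set[Pair] = set()
        with open(path) as fh:
            for line in fh:
                a, b = line.rstrip("\n").split("\t")
                pairs.add(canonical_pair(a, b))
        return pairs

    return ConstraintSet(
        read(f"{prefix}.positive.tsv"), read(f"{prefix}.negative.tsv")
    )
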