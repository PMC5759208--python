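"""Outlier detection from the lengths of PCA loading vectors.

Every object contributes a weight to each principal component; restricted to
the first D components those weights form the object's *loading vector*, and
its Euclidean length Delta summarises how much the object participates in the
structure the components capture.  Objects with short loading vectors
(Delta < 0.3 by default) are flagged as outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import DataMatrix

__all__ = ["LoadingSet", "object_loadings", "flag_outliers", "roc_over_cutoffs"]

DEFAULT_CUTOFF = 0.3


@dataclass(frozen=True)
class LoadingSet:
    """Per-object loading vectors, their lengths and outlier flags."""

    loadings: np.ndarray          # P objects x D components
    delta: np.ndarray             # Euclidean norm of each loading row
    object_ids: tuple[str, ...]
    scale: str
    cutoff: float | None = None
    is_outlier: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"object_id": self.object_ids, "delta": self.delta})
        if self.is_outlier is not None:
            frame["is_outlier"] = self.is_outlier
        return frame


def object_loadings(data: DataMatrix, d: int, scale: str = "eigen") -> LoadingSet:
    """Loading vectors of all objects on the first ``d`` components.

    The components are the unit-norm eigenvectors of the objects' Pearson
    correlation matrix (right-singular vectors of the object-standardized
    matrix).  ``scale`` controls the length scale of the loading entries:

    ``"eigen"`` (default)
        Eigenvector entries multiplied by the square root of their
        eigenvalue.  Entry ``(j, k)`` is then the correlation between object
        ``j`` and the k-th principal component score, so Delta^2 is the
        communality — the fraction of the object's variance captured by the
        first ``d`` components.  This bounds Delta in [0, 1] and makes a
        fixed absolute cutoff comparable across datasets of any size.
    ``"unit"``
        Raw eigenvector entries; the rows of an orthonormal matrix, so
        ``sum_j Delta_j^2 = d``.
    """
    if d < 0:
        raise ValueError("d must be nonnegative")
    if scale not in ("eigen", "unit"):
        raise ValueError(f"unknown loading scale: {scale!r}")
    from .pca import object_corr_svd

    _, s, vt = object_corr_svd(data)
    rank = int(np.sum(s > s[0] * 1e-9)) if s.size else 0
    if d > rank:
        raise ValueError(f"d={d} exceeds matrix rank {rank}")
    v = vt.T[:, :d]  # P x d, unit columns
    if scale == "eigen":
        n = data.n_variables
        loadings = v * (s[:d] / np.sqrt(n - 1))  # = v * sqrt(eigenvalue)
    else:
        loadings = v
    delta = np.linalg.norm(loadings, axis=1)
    return LoadingSet(
        loadings=loadings,
        delta=delta,
        object_ids=data.object_ids,
        scale=scale,
    )


def flag_outliers(loadings: LoadingSet, cutoff: float = DEFAULT_CUTOFF) -> LoadingSet:
    """Flag objects with Delta strictly below the cutoff as outliers."""
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    return replace(
        loadings, cutoff=float(cutoff), is_outlier=loadings.delta < cutoff
    )


def roc_over_cutoffs(
    deltas: np.ndarray,
    truth_good: np.ndarray,
    cutoffs: np.ndarray,
) -> pd.DataFrame:
    """TPR/FPR of *retaining* objects, over a grid of Delta cutoffs.

    An object is retained ("called good") when its Delta is at least the
    cutoff.  TPR is the fraction of genuinely good objects retained; FPR is
    the fraction of noise objects retained.  Both are nonincreasing in the
    cutoff.
    """
    deltas = np.asarray(deltas, dtype=float)
    truth_good = np.asarray(truth_good, dtype=bool)
    if deltas.shape != truth_good.shape:
        raise ValueError("deltas and truth must have equal length")
    good = deltas[truth_good]
    bad = deltas[~truth_good]
    if good.size == 0 or bad.size == 0:
        warnings.warn("degenerate truth: some rates are undefined", stacklevel=2)
    rows = []
    for c in np.asarray(cutoffs, dtype=float):
        tpr = float(np.mean(good >= c)) if good.size else float("nan")
        fpr = float(np.mean(bad >= c)) if bad.size else float("nan")
        rows.append((c, fpr, tpr))
    return pd.DataFrame(rows, columns=["cutoff", "fpr", "tpr"])
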