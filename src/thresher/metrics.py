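"""Scoring outlier detection and cluster-number estimation on simulations.

Conventions: for the confusion summary the *positive class is the "bad"
(noise) objects* — sensitivity is the fraction of truly bad objects called
bad, specificity the fraction of truly good objects called good, and the FDR
is the fraction of good objects among those called bad.  The AUC treats a
*small* loading length Delta as evidence of badness: it is the probability
that a random bad object has smaller Delta than a random good one (ties
count one half, the Mann-Whitney convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .outliers import flag_outliers, object_loadings, roc_over_cutoffs
from .pca import pc_dimension
from .simulate import PROTOCOL_KINDS, cutoff_protocol_dataset

__all__ = [
    "ConfusionSummary",
    "outlier_confusion",
    "abs_diff_score",
    "protocol_deltas",
    "cutoff_calibration_curve",
    "CALIBRATION_CUTOFFS",
]

#: the Delta grid of the published calibration table
CALIBRATION_CUTOFFS = np.array(
    [0.20, 0.25, 0.26, 0.27, 0.28, 0.29, 0.30, 0.31, 0.32, 0.33, 0.34,
     0.35, 0.40, 0.45, 0.50, 0.55, 0.60]
)


@dataclass(frozen=True)
class ConfusionSummary:
    sensitivity: float
    specificity: float
    fdr: float
    auc: float
    n_good: int
    n_bad: int


def outlier_confusion(
    called_bad: np.ndarray,
    truth_bad: np.ndarray,
    deltas: np.ndarray,
) -> ConfusionSummary:
    """Confusion rates and rank-sum AUC for one batch of outlier calls."""
    called_bad = np.asarray(called_bad, dtype=bool)
    truth_bad = np.asarray(truth_bad, dtype=bool)
    deltas = np.asarray(deltas, dtype=float)
    if not (called_bad.shape == truth_bad.shape == deltas.shape):
        raise ValueError("inputs must have equal length")
    n_bad = int(truth_bad.sum())
    n_good = int((~truth_bad).sum())
    if n_bad == 0 or n_good == 0:
        warnings.warn("degenerate truth: some rates are undefined", stacklevel=2)
    nan = float("nan")
    sensitivity = float(called_bad[truth_bad].mean()) if n_bad else nan
    specificity = float((~called_bad)[~truth_bad].mean()) if n_good else nan
    n_called = int(called_bad.sum())
    fdr = float(called_bad[~truth_bad].sum() / n_called) if n_called else nan
    if n_bad and n_good:
        bad_d = deltas[truth_bad]
        good_d = deltas[~truth_bad]
        wins = (bad_d[:, None] < good_d[None, :]).sum()
        ties = (bad_d[:, None] == good_d[None, :]).sum()
        auc = float((wins + 0.5 * ties) / (n_bad * n_good))
    else:
        auc = nan
    return ConfusionSummary(sensitivity, specificity, fdr, auc, n_good, n_bad)


def abs_diff_score(estimated_k, true_k) -> float:
    """Mean absolute difference between estimated and true cluster counts."""
    est = np.asarray(estimated_k, dtype=float)
    true = np.asarray(true_k, dtype=float)
    if est.shape != true.shape:
        raise ValueError("estimate and truth must have equal length")
    if est.size == 0:
        raise ValueError("empty input")
    return float(np.abs(est - true).mean())


def protocol_deltas(
    reps: int,
    seed: int | np.random.Generator | None = None,
    criterion: str = "twicemean",
) -> pd.DataFrame:
    """Loading lengths with truth labels over the calibration protocol.

    Generates ``reps`` datasets for each of the five signal kinds, runs the
    PC-dimension and loading steps on each, and pools every object's Delta
    with its good/noise truth label.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        for kind in PROTOCOL_KINDS:
            ds = cutoff_protocol_dataset(kind, seed=rng)
            fit = pc_dimension(ds.data, criterion=criterion)
            ls = object_loadings(ds.data, fit.dimension)
            for delta, good in zip(ls.delta, ds.truth_good):
                rows.append((kind, rep, float(delta), bool(good)))
    return pd.DataFrame(rows, columns=["kind", "rep", "delta", "truth_good"])


def cutoff_calibration_curve(
    reps: int,
    seed: int | np.random.Generator | None = None,
    cutoffs: np.ndarray = CALIBRATION_CUTOFFS,
    criterion: str = "twicemean",
) -> pd.DataFrame:
    """Pooled retain-TPR/FPR over a Delta-cutoff grid (calibration table)."""
    pooled = protocol_deltas(reps, seed=seed, criterion=criterion)
    return roc_over_cutoffs(
        pooled["delta"].to_numpy(), pooled["truth_good"].to_numpy(), cutoffs
    )
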