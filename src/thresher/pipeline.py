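"""End-to-end Thresher run: PC dimension, outlier filtering, vMF clustering.

The three stages are: (1) standardize the data and estimate the number D of
significant principal components; (2) map each object to its D-dimensional
loading vector and flag objects whose length Delta falls below the cutoff as
outliers; (3) on the retained objects, re-estimate the dimension D0, map the
objects' D0-dimensional loading directions onto the unit hypersphere, and
choose the number of clusters N in D0..2*D0+1 by minimum BIC of a von
Mises-Fisher mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .data import DataMatrix
from .outliers import DEFAULT_CUTOFF, flag_outliers, object_loadings
from .pca import pc_dimension
from .vmf import VmfMixtureFit, choose_n_clusters

__all__ = ["ThresherResult", "run_thresher"]

OUTLIER_LABEL = "outlier"


@dataclass(frozen=True)
class ThresherResult:
    """Complete record of one Thresher run."""

    dimension: int                     # D, before outlier removal
    outliers: tuple[str, ...]          # object ids flagged at stage 2
    dimension_retained: int            # D0, after outlier removal
    n_clusters: int
    labels: dict[str, int | str]       # per object: cluster id or "outlier"
    deltas: dict[str, float]
    diagnostics: dict[str, Any] = field(default_factory=dict)
    fits: dict[int, VmfMixtureFit] = field(default_factory=dict)

    @property
    def retained(self) -> tuple[str, ...]:
        return tuple(k for k, v in self.labels.items() if v != OUTLIER_LABEL)

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "outliers": list(self.outliers),
            "dimension_retained": self.dimension_retained,
            "n_clusters": self.n_clusters,
            "labels": dict(self.labels),
            "deltas": {k: float(v) for k, v in self.deltas.items()},
            "diagnostics": self.diagnostics,
            "bic_by_n": {n: fit.bic for n, fit in self.fits.items()},
        }


def run_thresher(
    data: DataMatrix,
    cutoff: float = DEFAULT_CUTOFF,
    criterion: str = "twicemean",
    seed: int | None = None,
    n_starts: int = 10,
) -> ThresherResult:
    """Run the full pipeline on a variables-by-objects matrix.

    Objects are compared on their Pearson correlations, so each object is
    standardized across the variables inside the PCA steps; no further
    normalisation of the input is required (or applied).
    """
    fit = pc_dimension(data, criterion=criterion)
    d = fit.dimension

    loadings = flag_outliers(object_loadings(data, d), cutoff=cutoff)
    is_out = loadings.is_outlier
    outlier_ids = tuple(str(x) for x in np.asarray(data.object_ids)[is_out])
    deltas = dict(zip(data.object_ids, map(float, loadings.delta)))
    diagnostics: dict[str, Any] = {
        "criterion": criterion,
        "cutoff": cutoff,
        "seed": seed,
        "step_lengths": fit.step_lengths.tolist(),
        "eigenvalues": fit.eigenvalues.tolist(),
    }
    labels: dict[str, int | str] = {oid: OUTLIER_LABEL for oid in outlier_ids}

    retained = ~is_out
    n_retained = int(retained.sum())
    if n_retained == 0:
        warnings.warn("all objects were flagged as outliers", stacklevel=2)
        return ThresherResult(d, outlier_ids, 0, 0, labels, deltas, diagnostics)

    if n_retained < 3:
        warnings.warn(
            f"only {n_retained} retained object(s); skipping mixture fitting",
            stacklevel=2,
        )
        for oid in np.asarray(data.object_ids)[retained]:
            labels[str(oid)] = 0
        return ThresherResult(
            d, outlier_ids, 0, min(n_retained, 1), labels, deltas, diagnostics
        )

    sub = data.subset_objects(retained)
    fit0 = pc_dimension(sub, criterion=criterion)
    d0 = fit0.dimension
    diagnostics["step_lengths_retained"] = fit0.step_lengths.tolist()

    if d0 == 0:
        n_clusters, fits = 1, {}
        for oid in sub.object_ids:
            labels[oid] = 0
    else:
        # vMF mixtures need at least a circle to live on: with D0 = 1 the
        # "sphere" would degenerate to two points, so the mapping keeps a
        # second component while the BIC search range stays D0..2*D0+1
        rank = int(np.sum(fit0.eigenvalues > fit0.eigenvalues[0] * 1e-9))
        sphere_dim = min(max(d0, 2), rank)
        ls0 = object_loadings(sub, sphere_dim)
        norms = np.linalg.norm(ls0.loadings, axis=1)
        on_sphere = norms > 1e-12
        if not on_sphere.all():
            warnings.warn(
                f"{int((~on_sphere).sum())} retained object(s) have zero-length "
                "loadings and are left unclustered",
                stacklevel=2,
            )
        points = ls0.loadings[on_sphere] / norms[on_sphere, None]
        sphere_ids = [str(x) for x in np.asarray(sub.object_ids)[on_sphere]]
        for oid in np.asarray(sub.object_ids)[~on_sphere]:
            labels[str(oid)] = -1  # degenerate direction, left unclustered
        n_clusters, fits = choose_n_clusters(points, d0, seed=seed, n_starts=n_starts)
        best = fits.get(n_clusters)
        if best is None:  # D0 handled without fitting
            for oid in sphere_ids:
                labels[oid] = 0
        else:
            for oid, lab in zip(sphere_ids, best.labels):
                labels[oid] = int(lab)
    diagnostics["bic_by_n"] = {n: f.bic for n, f in fits.items()}

    return ThresherResult(
        dimension=d,
        outliers=outlier_ids,
        dimension_retained=d0,
        n_clusters=n_clusters,
        labels=labels,
        deltas=deltas,
        diagnostics=diagnostics,
        fits=fits,
    )
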