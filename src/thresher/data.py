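"""Numeric data matrices for clustering.

Terminology follows the directional-clustering convention: the *objects* are
the things we want to cluster (columns), and the *variables* are the
measurements used to cluster them (rows).  A gene-expression study clustering
patients by their expression profiles has genes as variables and patients as
objects; clustering genes by their behaviour across samples swaps the roles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["DataMatrix", "standardize", "read_matrix"]


@dataclass(frozen=True)
class DataMatrix:
    """A variables-by-objects numeric matrix with string labels.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_variables, n_objects)``; must be finite.
    object_ids
        Labels for the columns (the things to be clustered).
    variable_ids
        Labels for the rows (the measurements used for clustering).
    """

    values: np.ndarray
    object_ids: tuple[str, ...] = field(default=())
    variable_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        n, p = values.shape
        if n < 2 or p < 2:
            raise ValueError(
                f"need at least 2 variables and 2 objects, got {n}x{p}"
            )
        if not np.isfinite(values).all():
            raise ValueError("values contain missing or non-finite entries")
        object.__setattr__(self, "values", values)
        oid = tuple(self.object_ids) or tuple(f"obj{i}" for i in range(p))
        vid = tuple(self.variable_ids) or tuple(f"var{i}" for i in range(n))
        if len(oid) != p:
            raise ValueError(f"got {len(oid)} object ids for {p} objects")
        if len(vid) != n:
            raise ValueError(f"got {len(vid)} variable ids for {n} variables")
        object.__setattr__(self, "object_ids", oid)
        object.__setattr__(self, "variable_ids", vid)

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_objects(self) -> int:
        return self.values.shape[1]

    def transpose(self) -> "DataMatrix":
        """Swap the roles of objects and variables."""
        return DataMatrix(self.values.T, self.variable_ids, self.object_ids)

    def subset_objects(self, keep: np.ndarray) -> "DataMatrix":
        """Restrict to a boolean or index selection of objects (columns)."""
        keep = np.asarray(keep)
        ids = np.asarray(self.object_ids)[keep]
        return DataMatrix(self.values[:, keep], tuple(ids), self.variable_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=list(self.variable_ids),
            columns=list(self.object_ids),
        )


def standardize(data: DataMatrix) -> DataMatrix:
    """Centre and scale each variable (row) to mean 0 and unit sd.

    The sample standard deviation (``ddof=1``) is used; a constant row has no
    scale and raises a ``ValueError`` naming the offending variable.
    """
    values = data.values
    sd = values.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            "zero-variance variable(s): "
            + ", ".join(data.variable_ids[i] for i in bad[:5])
        )
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return replace(data, values=z)


def read_matrix(path, objects_in: str = "columns", sep: str | None = None) -> DataMatrix:
    """Read a CSV/TSV matrix: first column holds ids, header holds the rest.

    ``objects_in`` says whether the objects to be clustered live in the file's
    columns (default) or rows; the returned matrix always has objects in
    columns.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if frame.isna().any().any():
        raise ValueError(f"{path}: matrix contains missing values")
    dm = DataMatrix(
        frame.to_numpy(dtype=float),
        tuple(map(str, frame.columns)),
        tuple(map(str, frame.index)),
    )
    if objects_in == "rows":
        dm = dm.transpose()
    elif objects_in != "columns":
        raise ValueError("objects_in must be 'columns' or 'rows'")
    return dm
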