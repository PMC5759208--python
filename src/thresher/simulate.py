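"""Synthetic data with block-correlation structure among objects.

Datasets are drawn as ``n_variables`` i.i.d. rows from a multivariate normal
over the objects, MVN(mu, Sigma) with Sigma = sigma^2 * corr and sigma^2 = 1.
The correlation matrix groups the objects into blocks; a *signed* block
splits its members into anticorrelated halves, so its within-block
correlations are ``+rho`` inside a half and ``-rho`` across halves.  Noise
objects are uncorrelated with everything.

Two generators are provided: the cutoff-calibration protocol (five signal
kinds with randomly drawn sizes and correlation strength, plus two noise
objects per dataset), and sixteen fixed block-layout presets spanning
noise-only, unsigned, signed and mixed structures with varying between-block
correlation and noise fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DataMatrix

__all__ = [
    "CorrelationSpec",
    "SimulatedDataset",
    "sample_mvn",
    "cutoff_protocol_dataset",
    "PROTOCOL_KINDS",
    "preset_structure",
]

#: the five signal configurations of the cutoff-calibration protocol: one or
#: two independent signals, each either all positively correlated (unsigned)
#: or split into anticorrelated halves (signed)
PROTOCOL_KINDS = (
    "1-unsigned",
    "1-signed",
    "2-unsigned",
    "2-signed",
    "2-mixed",
)


@dataclass(frozen=True)
class CorrelationSpec:
    """Block-correlation structure over the objects of one dataset."""

    block_sizes: tuple[int, ...]
    within_corr: tuple[float, ...]
    sign_pattern: tuple[str, ...]           # "unsigned" or "signed" per block
    between_corr: float = 0.0
    n_noise: int = 0
    n_variables: int = 96
    sigma2: float = 1.0
    approximate: bool = False               # layout not fully pinned down

    def __post_init__(self) -> None:
        if len(self.within_corr) != len(self.block_sizes):
            raise ValueError("one within_corr per block required")
        if len(self.sign_pattern) != len(self.block_sizes):
            raise ValueError("one sign_pattern per block required")
        for s in self.sign_pattern:
            if s not in ("unsigned", "signed"):
                raise ValueError(f"bad sign_pattern {s!r}")
        if any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if self.n_noise < 0 or self.n_variables < 1 or self.sigma2 <= 0:
            raise ValueError("invalid spec")

    @property
    def n_objects(self) -> int:
        return sum(self.block_sizes) + self.n_noise

    def object_signs(self) -> np.ndarray:
        """+/-1 per object; the first ceil(size/2) members of a signed block
        keep the positive orientation."""
        signs = []
        for size, pattern in zip(self.block_sizes, self.sign_pattern):
            if pattern == "signed":
                half = (size + 1) // 2
                signs.extend([1.0] * half + [-1.0] * (size - half))
            else:
                signs.extend([1.0] * size)
        signs.extend([1.0] * self.n_noise)
        return np.asarray(signs)

    def truth_cluster(self) -> np.ndarray:
        """Directional cluster id per object; noise objects get -1.

        Each unsigned block is one cluster; each signed block contributes two
        (its anticorrelated halves point in opposite directions).
        """
        labels = []
        next_id = 0
        for size, pattern in zip(self.block_sizes, self.sign_pattern):
            if pattern == "signed":
                half = (size + 1) // 2
                labels.extend([next_id] * half + [next_id + 1] * (size - half))
                next_id += 2
            else:
                labels.extend([next_id] * size)
                next_id += 1
        labels.extend([-1] * self.n_noise)
        return np.asarray(labels, dtype=int)

    def correlation_matrix(self) -> np.ndarray:
        p = self.n_objects
        signs = self.object_signs()
        corr = np.zeros((p, p))
        starts = np.cumsum((0,) + self.block_sizes)
        n_signal = starts[-1]
        for b, (lo, hi) in enumerate(zip(starts[:-1], starts[1:])):
            corr[lo:hi, lo:hi] = self.within_corr[b]
        if self.between_corr and len(self.block_sizes) > 1:
            between = np.ones((n_signal, n_signal), dtype=bool)
            for lo, hi in zip(starts[:-1], starts[1:]):
                between[lo:hi, lo:hi] = False
            corr[:n_signal, :n_signal][between] = self.between_corr
        corr *= np.outer(signs, signs)
        np.fill_diagonal(corr, 1.0)
        evals = np.linalg.eigvalsh(corr)
        if evals.min() < -1e-8:
            raise ValueError(
                f"implied correlation matrix is not PSD (min eig {evals.min():.3g})"
            )
        return corr


@dataclass(frozen=True)
class SimulatedDataset:
    data: DataMatrix
    truth_good: np.ndarray
    truth_cluster: np.ndarray
    k_true: int = field(default=0)

    def __post_init__(self) -> None:
        good_ids = set(self.truth_cluster[self.truth_good]) - {-1}
        object.__setattr__(self, "k_true", len(good_ids))


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_mvn(
    spec: CorrelationSpec,
    n_variables: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> SimulatedDataset:
    """Draw one dataset: i.i.d. variable rows from MVN(mu, sigma^2 * corr).

    The mean vector mu is drawn once per dataset, standard normal per object
    coordinate.  Sampling goes through the eigendecomposition of Sigma with
    negative eigenvalues clipped at zero (the spec is PSD-checked first).
    """
    rng = _as_rng(seed)
    n_vars = int(n_variables if n_variables is not None else spec.n_variables)
    corr = spec.correlation_matrix()
    p = spec.n_objects
    mu = rng.standard_normal(p)
    evals, evecs = np.linalg.eigh(spec.sigma2 * corr)
    scale = evecs * np.sqrt(np.clip(evals, 0.0, None))
    z = rng.standard_normal((n_vars, p))
    values = mu + z @ scale.T
    truth_cluster = spec.truth_cluster()
    data = DataMatrix(
        values,
        object_ids=tuple(
            f"noise{j}" if truth_cluster[j] < 0 else f"obj{j}" for j in range(p)
        ),
    )
    return SimulatedDataset(
        data=data,
        truth_good=truth_cluster >= 0,
        truth_cluster=truth_cluster,
    )


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    while True:
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)


def cutoff_protocol_dataset(
    kind: str,
    seed: int | np.random.Generator | None = None,
) -> SimulatedDataset:
    """One dataset of the cutoff-calibration protocol.

    Per dataset: the number of variables is drawn from Normal(300, 60)
    (rounded, floored at 30); an even number of objects is drawn uniformly
    from {10, 12, ..., 20}; the objects are split roughly in half into two
    groups, and independently in half into sign halves, as the kind requires;
    a single correlation strength is drawn from Normal(0.5, 0.1) truncated to
    (0.05, 0.95); finally two uncorrelated standard-normal noise objects are
    appended to play the role of outliers.
    """
    if kind not in PROTOCOL_KINDS:
        raise ValueError(f"kind must be one of {PROTOCOL_KINDS}")
    rng = _as_rng(seed)
    n_vars = max(30, int(round(rng.normal(300.0, 60.0))))
    p = int(2 * rng.integers(5, 11))  # even, 10..20
    rho = _truncated_normal(rng, 0.5, 0.1, 0.05, 0.95)

    n_signals = 1 if kind.startswith("1") else 2
    if n_signals == 1:
        sizes = (p,)
        patterns = ("signed",) if kind == "1-signed" else ("unsigned",)
    else:
        sizes = ((p + 1) // 2, p // 2)
        patterns = {
            "2-unsigned": ("unsigned", "unsigned"),
            "2-signed": ("signed", "signed"),
            "2-mixed": ("unsigned", "signed"),
        }[kind]
    spec = CorrelationSpec(
        block_sizes=sizes,
        within_corr=(rho,) * n_signals,
        sign_pattern=patterns,
        between_corr=0.0,
        n_noise=2,
        n_variables=n_vars,
    )
    # signal objects carry a random mean vector; the appended noise objects
    # are plain standard normals (mean zero)
    base = sample_mvn(spec, seed=rng)
    values = base.data.values.copy()
    values[:, -2:] = rng.standard_normal((n_vars, 2))
    data = DataMatrix(values, base.data.object_ids, base.data.variable_ids)
    return SimulatedDataset(data, base.truth_good, base.truth_cluster)


# block layouts at 24 objects for the sixteen preset correlation structures;
# (sizes, within, patterns, between, n_noise).  Structures 1-3 are exact by
# construction; 4-16 are documented approximations (equal-size blocks) of
# layouts whose exact partitions are configurable.
_PRESET_LAYOUTS: dict[int, tuple] = {
    1: ((), (), (), 0.0, 24),
    2: ((24,), (0.3,), ("unsigned",), 0.0, 0),
    3: ((24,), (0.8,), ("unsigned",), 0.0, 0),
    4: ((12, 12), (0.8, 0.8), ("unsigned",) * 2, 0.3, 0),
    5: ((12, 12), (0.8, 0.8), ("unsigned",) * 2, 0.1, 0),
    6: ((12, 12), (0.8, 0.8), ("unsigned",) * 2, 0.0, 0),
    7: ((7, 7, 6), (0.3, 0.3, 0.3), ("unsigned",) * 3, 0.1, 4),
    8: ((7, 7, 6), (0.8, 0.8, 0.8), ("unsigned",) * 3, 0.3, 4),
    9: ((6,), (0.8,), ("unsigned",), 0.0, 18),
    10: ((5, 5), (0.8, 0.8), ("unsigned",) * 2, 0.0, 14),
    11: ((24,), (0.8,), ("signed",), 0.0, 0),
    12: ((24,), (0.3,), ("signed",), 0.0, 0),
    13: ((12, 12), (0.8, 0.8), ("signed",) * 2, 0.0, 0),
    14: ((12, 12), (0.3, 0.3), ("signed",) * 2, 0.0, 0),
    15: ((12, 12), (0.8, 0.8), ("unsigned", "signed"), 0.0, 0),
    16: ((12, 12), (0.3, 0.3), ("unsigned", "signed"), 0.0, 0),
}


def preset_structure(
    index: int,
    n_objects: int = 24,
    n_variables: int = 96,
) -> CorrelationSpec:
    """One of the sixteen preset block-correlation structures.

    ``n_objects`` must be a multiple of 24; block sizes and noise counts
    scale proportionally.  Presets 4-16 carry ``approximate=True`` because
    only their qualitative layout (block count, correlation strengths, noise
    fraction) is pinned down, not the exact partition.
    """
    if index not in _PRESET_LAYOUTS:
        raise ValueError("preset index must be in 1..16")
    if n_objects % 24:
        raise ValueError("n_objects must be a multiple of 24")
    factor = n_objects // 24
    sizes, within, patterns, between, n_noise = _PRESET_LAYOUTS[index]
    return CorrelationSpec(
        block_sizes=tuple(s * factor for s in sizes),
        within_corr=within,
        sign_pattern=patterns,
        between_corr=between,
        n_noise=n_noise * factor,
        n_variables=n_variables,
        approximate=index >= 4,
    )
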