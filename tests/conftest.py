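import numpy as np
import pytest

from thresher.data import DataMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_matrix(rng):
    """A small unstructured matrix (pure noise)."""
    return DataMatrix(rng.standard_normal((40, 12)))


def orthogonal_columns(n: int, p: int) -> DataMatrix:
    """Columns that are exactly mean-zero, mutually orthogonal, equal norm.

    Built from a Helmert basis of the subspace orthogonal to the constant
    vector, so object standardization leaves them orthonormal and the
    objects' correlation matrix is exactly the identity.
    """
    from scipy.linalg import helmert

    if p > n - 1:
        raise ValueError("need p <= n-1 orthogonal mean-zero columns")
    basis = helmert(n).T[:, :p]  # n x p, orthonormal, each col sums to 0
    return DataMatrix(basis)
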