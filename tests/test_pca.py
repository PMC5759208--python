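import numpy as np
import pytest

from thresher.data import DataMatrix
from thresher.pca import (
    AuerGerviniFit,
    auer_gervini_steps,
    eigen_spectrum,
    pc_dimension,
    select_dimension,
)
from thresher.simulate import preset_structure, sample_mvn

from conftest import orthogonal_columns


def brute_force_map_dimension(loglik, n_obs, thetas):
    """Independent oracle: argmax of L(d) - theta*n*d on a theta grid."""
    d = np.arange(len(loglik))
    return np.array(
        [int(np.argmax(loglik - theta * n_obs * d)) for theta in thetas]
    )


class TestEigenSpectrum:
    def test_orthogonal_equal_norm_columns_isotropic(self):
        dm = orthogonal_columns(30, 8)
        lam = eigen_spectrum(dm)
        np.testing.assert_allclose(lam, 1.0, atol=1e-10)

    def test_rank_one_matrix(self, rng):
        col = rng.standard_normal(25)
        values = np.outer(col, rng.uniform(0.5, 2.0, 6))
        lam = eigen_spectrum(DataMatrix(values))
        assert lam[0] == pytest.approx(6.0, abs=1e-8)  # trace = n_objects
        np.testing.assert_allclose(lam[1:], 0.0, atol=1e-8)

    def test_matches_dense_eigendecomposition(self, rng):
        values = rng.standard_normal((20, 10))
        lam = eigen_spectrum(DataMatrix(values))
        corr = np.corrcoef(values.T)
        expected = np.sort(np.linalg.eigvalsh(corr))[::-1]
        np.testing.assert_allclose(lam, expected, atol=1e-8)


class TestAuerGerviniSteps:
    def test_isotropic_only_dimension_zero(self):
        fit = auer_gervini_steps(np.ones(6), n_obs=50)
        assert fit.dims_path.tolist() == [0]
        assert fit.step_lengths[0] > 0
        assert np.all(fit.step_lengths[1:] == 0)

    def test_single_spike_dominates_higher_dims(self):
        lam = np.array([10.0, 1.0, 1.0, 1.0, 1.0])
        fit = auer_gervini_steps(lam, n_obs=50)
        assert fit.step_lengths[1] > fit.step_lengths[2:].max()

    def test_breakpoints_match_theta_grid_brute_force(self, rng):
        for _ in range(5):
            lam = np.sort(rng.uniform(0.2, 8.0, 7))[::-1]
            fit = auer_gervini_steps(lam, n_obs=40)
            grid = np.linspace(0, fit.theta_breakpoints[-1] * 1.2, 4001)
            oracle = brute_force_map_dimension(fit.profile_loglik, 40, grid)
            ours = np.array([fit.map_dimension(t) for t in grid])
            # agreement except within grid resolution of a breakpoint
            near_break = np.zeros_like(grid, dtype=bool)
            res = grid[1] - grid[0]
            for b in fit.theta_breakpoints:
                near_break |= np.abs(grid - b) <= res
            assert np.array_equal(oracle[~near_break], ours[~near_break])

    def test_map_dimension_nonincreasing_in_theta(self, rng):
        lam = np.sort(rng.uniform(0.1, 5.0, 10))[::-1]
        fit = auer_gervini_steps(lam, n_obs=30)
        grid = np.linspace(0, fit.theta_breakpoints[-1] * 2 + 1, 500)
        dims = [fit.map_dimension(t) for t in grid]
        assert np.all(np.diff(dims) <= 0)

    def test_increasing_eigenvalues_rejected(self):
        with pytest.raises(ValueError, match="nonincreasing"):
            auer_gervini_steps(np.array([1.0, 2.0]), n_obs=10)


def make_fit(step_lengths):
    """Fit object with hand-set step lengths (all candidates on the path)."""
    lengths = np.asarray(step_lengths, dtype=float)
    k = lengths.size
    return AuerGerviniFit(
        eigenvalues=np.sort(lengths)[::-1] + 1,
        profile_loglik=np.zeros(k),
        theta_breakpoints=np.cumsum(lengths[::-1])[:-1],
        step_lengths=lengths,
        dims_path=np.arange(k - 1, -1, -1),
        n_obs=50,
    )


class TestSelectDimension:
    def test_noise_like_steps_give_zero(self):
        fit = select_dimension(make_fit([100.0, 1.0, 1.0]), "twicemean")
        assert fit.dimension == 0

    def test_twicemean_hand_computed_cutoff(self):
        # steps {0: 2, 1: 50, 2: 1, 3: 1}: cutoff 2*13.5 = 27, long = {1}
        fit = select_dimension(make_fit([2.0, 50.0, 1.0, 1.0]), "twicemean")
        assert fit.dimension == 1

    def test_identical_steps_no_long_set(self):
        fit = select_dimension(make_fit([5.0, 5.0, 5.0, 5.0]), "twicemean")
        assert fit.dimension == 0

    def test_cpt_detects_clear_change(self):
        fit = select_dimension(
            make_fit([40.0, 35.0, 0.5, 0.4, 0.3, 0.2, 0.4, 0.3]), "cpt"
        )
        assert fit.dimension == 1

    def test_cpt_flat_steps_give_zero(self):
        fit = select_dimension(make_fit([1.0, 1.1, 0.9, 1.05, 0.95]), "cpt")
        assert fit.dimension == 0

    def test_single_step_warns_and_returns_zero(self):
        fit = auer_gervini_steps(np.ones(4), n_obs=20)
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert select_dimension(fit, "twicemean").dimension == 0

    def test_unknown_criterion(self):
        with pytest.raises(ValueError, match="criterion"):
            select_dimension(make_fit([1.0, 2.0]), "brokenstick")


class TestPcDimensionBehaviour:
    @pytest.mark.parametrize("criterion", ["twicemean", "cpt"])
    def test_transpose_invariance_on_random_matrices(self, rng, criterion):
        """D is the same for a matrix and its transpose."""
        for _ in range(20):
            n = int(rng.integers(10, 97))
            p = int(rng.integers(8, 25))
            dm = DataMatrix(rng.standard_normal((n, p)))
            d1 = pc_dimension(dm, criterion).dimension
            d2 = pc_dimension(dm.transpose(), criterion).dimension
            assert d1 == d2

    def test_pure_noise_selects_zero(self):
        rng = np.random.default_rng(11)
        spec = preset_structure(1, 24, 96)
        hits = sum(
            pc_dimension(sample_mvn(spec, seed=rng).data).dimension == 0
            for _ in range(200)
        )
        assert hits >= 180

    def test_rank_one_signal_selects_one(self):
        rng = np.random.default_rng(13)
        spec = preset_structure(3, 24, 96)  # one block, within-corr 0.8
        hits = sum(
            pc_dimension(sample_mvn(spec, seed=rng).data).dimension == 1
            for _ in range(200)
        )
        assert hits >= 180
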