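import numpy as np
import pytest
from scipy.integrate import quad

from thresher.vmf import (
    KAPPA_MAX,
    choose_n_clusters,
    fit_movMF,
    sample_vmf,
    vmf_logpdf,
    vmf_mixture_bic,
)


def random_direction(rng, d):
    v = rng.standard_normal(d)
    return v / np.linalg.norm(v)


class TestLogpdf:
    def test_uniform_at_kappa_zero(self, rng):
        mu = random_direction(rng, 3)
        xs = np.array([random_direction(rng, 3) for _ in range(10)])
        vals = vmf_logpdf(xs, mu, 0.0)
        np.testing.assert_allclose(vals, vals[0])
        # density equals 1 / surface area of the 2-sphere
        assert vals[0] == pytest.approx(-np.log(4 * np.pi), abs=1e-12)

    @pytest.mark.parametrize("kappa", [0.5, 5.0, 50.0])
    def test_integrates_to_one_on_circle(self, kappa):
        mu = np.array([1.0, 0.0])

        def density(angle):
            x = np.array([np.cos(angle), np.sin(angle)])
            return np.exp(vmf_logpdf(x, mu, kappa))

        total, _ = quad(density, -np.pi, np.pi, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_maximised_at_mu(self, rng):
        mu = random_direction(rng, 4)
        at_mu = vmf_logpdf(mu, mu, 3.0)
        for _ in range(20):
            x = random_direction(rng, 4)
            assert vmf_logpdf(x, mu, 3.0) <= at_mu + 1e-12

    def test_negative_kappa_errors(self):
        with pytest.raises(ValueError):
            vmf_logpdf(np.array([1.0, 0.0]), np.array([1.0, 0.0]), -1.0)


class TestFit:
    def test_point_mass_hits_kappa_ceiling(self):
        pts = np.tile([0.0, 1.0, 0.0], (8, 1))
        fit = fit_movMF(pts, 1, n_starts=2, seed=0)
        np.testing.assert_allclose(fit.components[0].mu, [0, 1, 0], atol=1e-9)
        assert fit.components[0].kappa == KAPPA_MAX

    def test_antipodal_bundles_recovered(self):
        rng = np.random.default_rng(7)
        mu = random_direction(rng, 3)
        pts = np.vstack(
            [sample_vmf(mu, 50.0, 50, rng), sample_vmf(-mu, 50.0, 50, rng)]
        )
        fit = fit_movMF(pts, 2, n_starts=5, seed=1)
        found = np.array([c.mu for c in fit.components])
        cos = np.abs(found @ mu)
        assert np.all(cos > np.cos(np.radians(5.0)))

    def test_restarts_never_hurt(self):
        rng = np.random.default_rng(3)
        pts = np.vstack(
            [sample_vmf(np.array([1.0, 0.0]), 5.0, 30, rng),
             sample_vmf(np.array([0.0, 1.0]), 5.0, 30, rng)]
        )
        single = fit_movMF(pts, 2, n_starts=1, seed=11)
        multi = fit_movMF(pts, 2, n_starts=5, seed=11)
        assert multi.loglik >= single.loglik - 1e-9

    def test_em_loglik_monotone(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pts = np.vstack(
                [sample_vmf(np.array([0.0, 0.0, 1.0]), 10.0, 40, rng),
                 sample_vmf(np.array([1.0, 0.0, 0.0]), 10.0, 40, rng)]
            )
            fit = fit_movMF(pts, 2, n_starts=3, seed=seed)
            assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_rotation_invariance(self, rng):
        pts = np.vstack(
            [sample_vmf(np.array([0.0, 1.0, 0.0]), 20.0, 30, rng),
             sample_vmf(np.array([1.0, 0.0, 0.0]), 20.0, 30, rng)]
        )
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        base = fit_movMF(pts, 2, n_starts=3, seed=5)
        rotated = fit_movMF(pts @ q.T, 2, n_starts=3, seed=5)
        assert rotated.loglik == pytest.approx(base.loglik, abs=1e-6)
        assert np.array_equal(rotated.labels, base.labels)

    def test_responsibility_rows_sum_to_one(self, rng):
        pts = sample_vmf(np.array([0.0, 0.0, 1.0]), 5.0, 25, rng)
        fit = fit_movMF(pts, 3, n_starts=3, seed=2)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0)
        assert np.array_equal(fit.labels, fit.responsibilities.argmax(axis=1))

    def test_bic_identity(self, rng):
        pts = sample_vmf(np.array([0.0, 0.0, 1.0]), 5.0, 25, rng)
        fit = fit_movMF(pts, 2, n_starts=3, seed=2)
        expected = -2 * fit.loglik + (2 * 3 + 1) * np.log(25)
        assert fit.bic == pytest.approx(expected, rel=1e-12)
        assert vmf_mixture_bic(fit.loglik, 2, 3, 25) == pytest.approx(expected)

    def test_n_larger_than_points_errors(self, rng):
        pts = sample_vmf(np.array([1.0, 0.0]), 5.0, 4, rng)
        with pytest.raises(ValueError, match="N"):
            fit_movMF(pts, 5, seed=0)

    def test_non_unit_points_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            fit_movMF(np.ones((5, 2)), 1, seed=0)

    def test_parameter_recovery_single_component(self):
        """mu and kappa recovered for one vMF component (d=3, kappa=20)."""
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            mu = random_direction(rng, 3)
            pts = sample_vmf(mu, 20.0, 200, rng)
            fit = fit_movMF(pts, 1, n_starts=3, seed=seed)
            comp = fit.components[0]
            assert float(comp.mu @ mu) > 0.99
            assert abs(comp.kappa - 20.0) / 20.0 < 0.25


class TestChooseN:
    def test_d0_zero_shortcircuits_to_one_cluster(self):
        n, fits = choose_n_clusters(np.zeros((0, 2)), 0, seed=0)
        assert n == 1 and fits == {}

    def test_search_range_is_d0_to_2d0_plus_1(self, rng):
        pts = sample_vmf(np.array([0.0, 1.0]), 10.0, 30, rng)
        n, fits = choose_n_clusters(pts, 1, seed=0, n_starts=3)
        assert set(fits) == {1, 2, 3}
        assert n == min(fits, key=lambda k: fits[k].bic)

    def test_antipodal_circle_selects_two(self):
        rng = np.random.default_rng(41)
        mu = np.array([np.cos(0.7), np.sin(0.7)])
        pts = np.vstack(
            [sample_vmf(mu, 50.0, 40, rng), sample_vmf(-mu, 50.0, 40, rng)]
        )
        n, _ = choose_n_clusters(pts, 1, seed=3, n_starts=5)
        assert n == 2
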