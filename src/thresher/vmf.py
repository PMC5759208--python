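"""Mixtures of von Mises-Fisher distributions on the unit hypersphere.

The von Mises-Fisher (vMF) distribution is the spherical analogue of an
isotropic Gaussian: density proportional to ``exp(kappa * <mu, x>)`` on the
unit sphere in R^d, with mean direction ``mu`` and concentration ``kappa``.
Mixtures are fitted by expectation-maximisation; the concentration update
starts from the Banerjee et al. closed form and is refined by a few Newton
steps to the exact M-step optimum, so the log-likelihood is monotone.  The
number of components is chosen by minimum BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, ive

__all__ = [
    "VmfComponent",
    "VmfMixtureFit",
    "vmf_logpdf",
    "sample_vmf",
    "fit_movMF",
    "choose_n_clusters",
]

KAPPA_MAX = 1e5
MAX_ITER = 200
REL_TOL = 1e-8


@dataclass(frozen=True)
class VmfComponent:
    mu: np.ndarray
    kappa: float
    weight: float


@dataclass(frozen=True)
class VmfMixtureFit:
    components: tuple[VmfComponent, ...]
    loglik: float
    bic: float
    responsibilities: np.ndarray  # P0 x N, rows sum to 1
    labels: np.ndarray            # argmax of responsibilities
    loglik_trace: tuple[float, ...] = ()  # per-iteration, for the best start

    @property
    def n_components(self) -> int:
        return len(self.components)

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "loglik": self.loglik,
            "bic": self.bic,
            "components": [
                {"mu": c.mu.tolist(), "kappa": c.kappa, "weight": c.weight}
                for c in self.components
            ],
        }


def _log_norm_const(d: int, kappa: float) -> float:
    """log C_d(kappa) such that the vMF density is C_d * exp(kappa <mu,x>)."""
    if kappa < 1e-12:
        # uniform on the sphere: inverse surface area of S^{d-1}
        return float(gammaln(d / 2.0) - np.log(2.0) - (d / 2.0) * np.log(np.pi))
    nu = d / 2.0 - 1.0
    # ive is exponentially scaled: I_nu(k) = ive(nu, k) * exp(k)
    log_iv = np.log(ive(nu, kappa)) + kappa
    return float(nu * np.log(kappa) - (d / 2.0) * np.log(2.0 * np.pi) - log_iv)


def vmf_logpdf(x: np.ndarray, mu: np.ndarray, kappa: float) -> np.ndarray:
    """Log density of vMF(mu, kappa) at unit vector(s) ``x``."""
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    mu = np.asarray(mu, dtype=float)
    x = np.asarray(x, dtype=float)
    return _log_norm_const(mu.size, kappa) + kappa * (x @ mu)


def sample_vmf(mu: np.ndarray, kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` unit vectors from vMF(mu, kappa) (Wood's 1994 sampler)."""
    mu = np.asarray(mu, dtype=float)
    d = mu.size
    if d == 1:
        p = 1.0 / (1.0 + np.exp(-2.0 * kappa))  # P(x = sign(mu))
        signs = np.where(rng.random(n) < p, 1.0, -1.0) * np.sign(mu[0])
        return signs[:, None]
    if kappa < 1e-12:
        z = rng.standard_normal((n, d))
        return z / np.linalg.norm(z, axis=1, keepdims=True)
    b = (-2.0 * kappa + np.sqrt(4.0 * kappa**2 + (d - 1.0) ** 2)) / (d - 1.0)
    x0 = (1.0 - b) / (1.0 + b)
    c = kappa * x0 + (d - 1.0) * np.log(1.0 - x0**2)
    out = np.empty((n, d))
    for i in range(n):
        while True:
            z = rng.beta((d - 1.0) / 2.0, (d - 1.0) / 2.0)
            w = (1.0 - (1.0 + b) * z) / (1.0 - (1.0 - b) * z)
            u = rng.random()
            if kappa * w + (d - 1.0) * np.log(1.0 - x0 * w) - c >= np.log(u):
                break
        v = rng.standard_normal(d - 1)
        v /= np.linalg.norm(v)
        out[i, 0] = w
        out[i, 1:] = np.sqrt(max(1.0 - w**2, 0.0)) * v
    # rotate the north pole onto mu via Householder reflection
    e = np.zeros(d)
    e[0] = 1.0
    u = e - mu
    norm = np.linalg.norm(u)
    if norm > 1e-12:
        u /= norm
        out = out - 2.0 * np.outer(out @ u, u)
    return out


def _banerjee_kappa(rbar: float, d: int) -> float:
    """Closed-form concentration estimate from the mean resultant length."""
    rbar = min(max(rbar, 0.0), 1.0 - 1e-12)
    kappa = (rbar * d - rbar**3) / (1.0 - rbar**2)
    return float(np.clip(kappa, 0.0, KAPPA_MAX))


def _solve_kappa(rbar: float, d: int) -> float:
    """Exact concentration M-step: solve A_d(kappa) = rbar.

    ``A_d(kappa) = I_{d/2}(kappa) / I_{d/2-1}(kappa)`` is the mean resultant
    length of a vMF distribution.  The Banerjee closed form is an excellent
    starting point; a few Newton steps make the M-step an exact maximiser,
    which keeps the EM log-likelihood monotone to machine precision.
    """
    if rbar <= 1e-12:
        return 0.0
    if rbar >= 1.0 - 1e-12:
        return KAPPA_MAX
    nu = d / 2.0 - 1.0
    kappa = max(_banerjee_kappa(rbar, d), 1e-8)
    for _ in range(25):
        a = float(ive(nu + 1.0, kappa) / ive(nu, kappa))
        # dA/dkappa for the Bessel ratio
        da = 1.0 - a * a - (d - 1.0) / kappa * a
        if abs(da) < 1e-300:
            break
        step = (a - rbar) / da
        new = min(max(kappa - step, kappa / 10.0), KAPPA_MAX)
        if abs(new - kappa) <= 1e-12 * max(kappa, 1.0):
            kappa = new
            break
        kappa = new
        if kappa >= KAPPA_MAX:
            break
    return float(np.clip(kappa, 0.0, KAPPA_MAX))


def _seed_directions(points: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Spherical k-means++-style seeding: spread the initial directions."""
    p0 = points.shape[0]
    centers = [points[rng.integers(p0)]]
    for _ in range(1, n):
        sim = points @ np.column_stack(centers)
        dist = np.clip(1.0 - sim.max(axis=1), 0.0, None)
        total = dist.sum()
        if total <= 1e-12:
            centers.append(points[rng.integers(p0)])
        else:
            centers.append(points[rng.choice(p0, p=dist / total)])
    return np.asarray(centers)


def _em_once(
    points: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray, list[float]]:
    p0, d = points.shape
    mus = _seed_directions(points, n, rng)
    kappas = np.full(n, 1.0)
    weights = np.full(n, 1.0 / n)
    loglik = -np.inf
    log_resp = None
    trace: list[float] = []
    for _ in range(MAX_ITER):
        # E-step
        log_dens = np.empty((p0, n))
        for k in range(n):
            log_dens[:, k] = vmf_logpdf(points, mus[k], kappas[k])
        log_joint = log_dens + np.log(weights)
        log_marg = np.logaddexp.reduce(log_joint, axis=1)
        new_loglik = float(log_marg.sum())
        trace.append(new_loglik)
        log_resp = log_joint - log_marg[:, None]
        resp = np.exp(log_resp)
        # M-step
        counts = resp.sum(axis=0)
        if np.any(counts < 1e-8):
            raise _DegenerateComponent()
        weights = counts / p0
        for k in range(n):
            r = resp[:, k] @ points
            r_norm = float(np.linalg.norm(r))
            if r_norm > 1e-12:
                mus[k] = r / r_norm
            kappas[k] = _solve_kappa(r_norm / counts[k], d)
        if new_loglik - loglik < REL_TOL * max(abs(new_loglik), 1.0):
            loglik = new_loglik
            break
        loglik = new_loglik
    return mus, kappas, weights, loglik, np.exp(log_resp), trace


class _DegenerateComponent(Exception):
    pass


def vmf_mixture_bic(loglik: float, n: int, d: int, p0: int) -> float:
    """BIC with ``n*d + (n-1)`` free parameters and sample size ``p0``."""
    n_params = n * d + (n - 1)
    return -2.0 * loglik + n_params * np.log(p0)


def fit_movMF(
    points: np.ndarray,
    n: int,
    n_starts: int = 10,
    seed: int | np.random.Generator | None = None,
) -> VmfMixtureFit:
    """Fit an N-component vMF mixture by EM, best of ``n_starts`` runs.

    E-step: soft responsibilities from the current parameters.  M-step: each
    mean direction is the normalised responsibility-weighted resultant; the
    concentration starts from the Banerjee approximation
    ``kappa = (rbar*d - rbar^3) / (1 - rbar^2)``, is Newton-refined to the
    exact root of ``A_d(kappa) = rbar`` and capped at 1e5; weights are
    responsibility mass fractions.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array of unit vectors")
    p0, d = points.shape
    if not (1 <= n <= p0):
        raise ValueError(f"need 1 <= N <= {p0} points, got N={n}")
    norms = np.linalg.norm(points, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("points must be unit vectors")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    best = None
    failures = 0
    for _ in range(n_starts):
        try:
            result = _em_once(points, n, rng)
        except _DegenerateComponent:
            failures += 1
            continue
        if best is None or result[3] > best[3]:
            best = result
    if best is None:
        raise RuntimeError(
            f"all {n_starts} EM starts collapsed a component for N={n}"
        )
    if failures:
        warnings.warn(
            f"{failures}/{n_starts} EM starts collapsed a component (N={n})",
            stacklevel=2,
        )
    mus, kappas, weights, loglik, resp, trace = best
    return VmfMixtureFit(
        components=tuple(
            VmfComponent(mu=mus[k].copy(), kappa=float(kappas[k]), weight=float(weights[k]))
            for k in range(n)
        ),
        loglik=loglik,
        bic=float(vmf_mixture_bic(loglik, n, d, p0)),
        responsibilities=resp,
        labels=resp.argmax(axis=1),
        loglik_trace=tuple(trace),
    )


def choose_n_clusters(
    points: np.ndarray,
    d0: int,
    seed: int | np.random.Generator | None = None,
    n_starts: int = 10,
) -> tuple[int, dict[int, VmfMixtureFit]]:
    """Pick the number of clusters by minimum BIC over N = D0 .. 2*D0 + 1.

    A PC dimension of D0 needs at least one cluster of directions per
    dimension, while anticorrelated (antipodal) halves of a signal form
    separate clusters, roughly doubling the ceiling; the extra +1 covers the
    degenerate D0 = 0 case, which short-circuits to a single cluster without
    fitting anything.
    """
    if d0 < 0:
        raise ValueError("d0 must be nonnegative")
    if d0 == 0:
        return 1, {}
    points = np.asarray(points, dtype=float)
    p0 = points.shape[0]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fits: dict[int, VmfMixtureFit] = {}
    errors: dict[int, str] = {}
    for n in range(max(1, d0), min(2 * d0 + 1, p0) + 1):
        try:
            fits[n] = fit_movMF(points, n, n_starts=n_starts, seed=rng)
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            errors[n] = str(exc)
    if not fits:
        raise RuntimeError(f"every mixture fit failed: {errors}")
    best_n = min(fits, key=lambda n: (fits[n].bic, n))
    return best_n, fits
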