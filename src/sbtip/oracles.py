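"""Closed-form references for validating the bridge machinery.

Three independent routes are provided:

* :func:`bures_w2` — the exact squared 2-Wasserstein distance between
  Gaussian measures,
  ||mu_a - mu_b||^2 + tr(Sa + Sb - 2 (Sb^{1/2} Sa Sb^{1/2})^{1/2}).

* :func:`gaussian_sb_closed_form` — time marginals of the 1-D entropic
  interpolation (zero base drift, constant noise g over horizon T).  The
  static entropic coupling of N(m0, s0^2) and N(m1, s1^2) at regularisation
  eps = g^2 T is Gaussian with cross-covariance

      c = ( -eps + sqrt(eps^2 + 4 s0^2 s1^2) ) / 2,

  which contracts to the monotone coupling c -> s0 s1 as g -> 0 and to
  independence as g -> inf.  Conditioned on its endpoints the reference
  path is a Brownian bridge, so the time-tau marginal is Gaussian with

      mean(tau) = (1-tau) m0 + tau m1
      var(tau)  = (1-tau)^2 s0^2 + tau^2 s1^2 + tau(1-tau) (2c + eps).

  At g -> 0 the variance tends to the displacement-interpolation value
  ((1-tau) s0 + tau s1)^2.

* :func:`grid_sinkhorn` — a brute-force log-domain Sinkhorn solution of
  the same static problem on a fine 1-D grid, used to cross-check the
  closed form without sharing any code with it.

:func:`gaussian_bridge_score` converts the closed-form marginal flow into
the forward score field Z(tau, x) = (alpha(tau) + beta(tau) x) / sg that
reproduces it under Euler propagation, by matching the first two moment
ODEs m' = alpha + beta m and v' = 2 beta v + sg^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import sqrtm
from scipy.special import logsumexp

__all__ = ["GaussianSpec", "bures_w2", "gaussian_sb_closed_form",
           "gaussian_bridge_score", "grid_sinkhorn"]


@dataclass(frozen=True)
class GaussianSpec:
    """A Gaussian measure given by mean and covariance (variance in 1-D)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        m = np.atleast_1d(np.asarray(self.mean, dtype=float))
        C = np.atleast_2d(np.asarray(self.cov, dtype=float))
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "cov", C)
        if C.shape != (m.size, m.size):
            raise ValueError("covariance shape does not match the mean")
        if not np.allclose(C, C.T):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(C) <= 0):
            raise ValueError("covariance must be positive definite")

    @property
    def dim(self):
        return self.mean.size

    @property
    def sd(self):
        if self.dim != 1:
            raise ValueError("sd is defined for 1-D specs")
        return float(np.sqrt(self.cov[0, 0]))


def bures_w2(a: GaussianSpec, b: GaussianSpec) -> float:
    """Squared Bures–Wasserstein distance W2^2 between two Gaussians."""
    if a.dim != b.dim:
        raise ValueError("dimension mismatch")
    dm = a.mean - b.mean
    rb = np.real(sqrtm(b.cov))
    cross = np.real(sqrtm(rb @ a.cov @ rb))
    return float(dm @ dm + np.trace(a.cov + b.cov - 2.0 * cross))


def _entropic_cross_cov(s0, s1, eps):
    return 0.5 * (-eps + np.sqrt(eps * eps + 4.0 * s0 * s0 * s1 * s1))


def gaussian_sb_closed_form(a: GaussianSpec, b: GaussianSpec, g, t_grid, T=1.0):
    """Per-time mean and variance of the 1-D Gaussian bridge marginals.

    ``t_grid`` is on the unit clock.  Returns (means, variances) arrays.
    """
    if a.dim != 1 or b.dim != 1:
        raise ValueError("the closed form covers 1-D specs only")
    if g <= 0:
        raise ValueError("g must be positive (use bures_w2 / displacement "
                         "interpolation for the zero-noise limit)")
    tau = np.asarray(t_grid, dtype=float)
    eps = g * g * T
    s0, s1 = a.sd, b.sd
    m0, m1 = float(a.mean[0]), float(b.mean[0])
    c = _entropic_cross_cov(s0, s1, eps)
    mean = (1 - tau) * m0 + tau * m1
    var = ((1 - tau) ** 2 * s0 ** 2 + tau ** 2 * s1 ** 2
           + tau * (1 - tau) * (2 * c + eps))
    return mean, var


class _AffineScore:
    """Time-dependent affine field Z(tau, x) = (alpha + beta x) / sg."""

    def __init__(self, a, b, g, T):
        self.a, self.b, self.g, self.T = a, b, float(g), float(T)
        self.sg = np.sqrt(T) * float(g)
        self.dim = 1

    def _coeffs(self, tau):
        tau = np.asarray(tau, dtype=float)
        mean, var = gaussian_sb_closed_form(self.a, self.b, self.g, tau, self.T)
        eps = self.sg ** 2
        s0, s1 = self.a.sd, self.b.sd
        c = _entropic_cross_cov(s0, s1, eps)
        dvar = (-2 * (1 - tau) * s0 ** 2 + 2 * tau * s1 ** 2
                + (1 - 2 * tau) * (2 * c + eps))
        dmean = float(self.b.mean[0] - self.a.mean[0])
        beta = (dvar - eps) / (2.0 * var)
        alpha = dmean - beta * mean
        return alpha, beta

    def __call__(self, t, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        alpha, beta = self._coeffs(np.broadcast_to(np.asarray(t, float), (x.shape[0],)))
        return ((alpha + beta * x[:, 0]) / self.sg)[:, None]

    def divergence(self, t, x, weights=None):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        _, beta = self._coeffs(np.broadcast_to(np.asarray(t, float), (x.shape[0],)))
        w = 1.0 if weights is None else float(np.asarray(weights).ravel()[0])
        return w * beta / self.sg


def gaussian_bridge_score(a: GaussianSpec, b: GaussianSpec, g, T=1.0):
    """Exact forward score field of the 1-D Gaussian bridge.

    Plugging it into :func:`sbtip.bridge.propagate_forward` (zero drift,
    constant schedule g, horizon T) reproduces the closed-form marginals.
    """
    if a.dim != 1 or b.dim != 1:
        raise ValueError("1-D only")
    return _AffineScore(a, b, g, T)


@dataclass
class SinkhornResult:
    xa: np.ndarray
    xb: np.ndarray
    pa: np.ndarray
    pb: np.ndarray
    plan: np.ndarray
    eps: float

    @property
    def cross_cov(self):
        ma = float(self.pa @ self.xa)
        mb = float(self.pb @ self.xb)
        return float(self.xa @ self.plan @ self.xb - ma * mb)

    def marginal_moments(self, t_grid):
        """Bridge-time moments implied by the discrete plan."""
        tau = np.asarray(t_grid, dtype=float)[:, None, None]
        mid = (1 - tau) * self.xa[None, :, None] + tau * self.xb[None, None, :]
        w = self.plan[None, :, :]
        mean = (w * mid).sum(axis=(1, 2))
        var_cond = self.eps * (tau * (1 - tau)).ravel()
        second = (w * mid * mid).sum(axis=(1, 2))
        return mean, second - mean ** 2 + var_cond


def grid_sinkhorn(a: GaussianSpec, b: GaussianSpec, g, T=1.0,
                  n_grid=400, n_sd=6.0, max_iter=5000, tol=1e-12):
    """Log-domain Sinkhorn on a fine 1-D grid (brute-force oracle)."""
    if a.dim != 1 or b.dim != 1:
        raise ValueError("1-D only")
    eps = g * g * T
    xa = np.linspace(a.mean[0] - n_sd * a.sd, a.mean[0] + n_sd * a.sd, n_grid)
    xb = np.linspace(b.mean[0] - n_sd * b.sd, b.mean[0] + n_sd * b.sd, n_grid)
    pa = np.exp(-0.5 * ((xa - a.mean[0]) / a.sd) ** 2)
    pa /= pa.sum()
    pb = np.exp(-0.5 * ((xb - b.mean[0]) / b.sd) ** 2)
    pb /= pb.sum()
    C = 0.5 * (xa[:, None] - xb[None, :]) ** 2
    logK = -C / eps
    lpa, lpb = np.log(pa), np.log(pb)
    f = np.zeros(n_grid)
    gpot = np.zeros(n_grid)
    for _ in range(max_iter):
        f_new = lpa - logsumexp(logK + gpot[None, :], axis=1)
        g_new = lpb - logsumexp(logK + f_new[:, None], axis=0)
        delta = np.max(np.abs(g_new - gpot)) if np.all(np.isfinite(gpot)) else np.inf
        f, gpot = f_new, g_new
        if delta < tol:
            break
    plan = np.exp(f[:, None] + logK + gpot[None, :])
    plan /= plan.sum()
    return SinkhornResult(xa, xb, pa, pb, plan, eps)
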