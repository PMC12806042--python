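"""Trainable score fields.

A score field approximates sigma_t * grad ln(phi_t) (forward potential) or
sigma_t * grad ln(phihat_t) (backward potential) of the Schrödinger system.
It is a map (t, x) -> R^d, with t on the internal unit clock.

The network is a single-hidden-layer tanh perceptron written directly in
numpy.  Because the likelihood loss needs both the field value and its
spatial divergence — and the gradient of *both* with respect to the
parameters — we derive those quantities in closed form rather than relying
on an autodiff framework.  With

    u = [t, (x - loc)/scale]          (features, F = 1 + d)
    z = u W1^T + b1,  a = tanh(z)     (hidden, H units)
    y = a W2^T + b2                   (output, d)

the spatial Jacobian is dy_i/dx_j = sum_h W2[i,h] (1-a_h^2) W1[h,1+j]/scale_j,
so the divergence is sum_h (1-a_h^2) s_h with
s_h = sum_i W2[i,h] W1[h,1+i] / scale_i.  Parameter gradients of a loss of
the form  sum_b gy[b]·y[b] + sum_b c[b]·div[b]  follow by the chain rule and
are implemented in :meth:`ScoreMLP.loss_grads`; they are verified against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ScoreMLP", "ZeroField", "ConstantField", "LinearField", "Adam"]


def _as_batch(t, x):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    t = np.broadcast_to(np.asarray(t, dtype=float), (x.shape[0],))
    return t, x


class ZeroField:
    """The trivial score field Z == 0 (reference process)."""

    def __init__(self, dim: int):
        self.dim = dim

    def __call__(self, t, x):
        _, x = _as_batch(t, x)
        return np.zeros_like(x)

    def divergence(self, t, x, weights=None):
        _, x = _as_batch(t, x)
        return np.zeros(x.shape[0])


class ConstantField:
    """A constant vector field; handy for engineered-transport tests."""

    def __init__(self, value):
        self.value = np.atleast_1d(np.asarray(value, dtype=float))
        self.dim = self.value.size

    def __call__(self, t, x):
        _, x = _as_batch(t, x)
        return np.broadcast_to(self.value, x.shape).copy()

    def divergence(self, t, x, weights=None):
        _, x = _as_batch(t, x)
        return np.zeros(x.shape[0])


class LinearField:
    """x -> A x + b, with exact divergence trace(A)."""

    def __init__(self, A, b=None):
        self.A = np.atleast_2d(np.asarray(A, dtype=float))
        self.b = np.zeros(self.A.shape[0]) if b is None else np.asarray(b, float)
        self.dim = self.A.shape[0]

    def __call__(self, t, x):
        _, x = _as_batch(t, x)
        return x @ self.A.T + self.b

    def divergence(self, t, x, weights=None):
        _, x = _as_batch(t, x)
        w = np.ones(self.dim) if weights is None else np.asarray(weights, float)
        return np.full(x.shape[0], float(np.sum(w * np.diag(self.A))))


class ScoreMLP:
    """One-hidden-layer tanh network for a time-dependent vector field.

    The output layer is initialised to zero so a freshly built field is the
    zero field: the associated bridge then starts exactly at the reference
    process, which is the natural initialisation of the alternating scheme.

    Parameters
    ----------
    dim : state dimension d.
    hidden : number of hidden units.
    x_loc, x_scale : per-coordinate affine input normalisation.
    seed : seed for the (first-layer) weight initialisation.
    """

    def __init__(self, dim, hidden=64, x_loc=None, x_scale=None, seed=0):
        self.dim = int(dim)
        self.hidden = int(hidden)
        self.x_loc = np.zeros(dim) if x_loc is None else np.asarray(x_loc, float) + 0.0
        self.x_scale = np.ones(dim) if x_scale is None else np.asarray(x_scale, float) + 0.0
        if np.any(self.x_scale <= 0):
            raise ValueError("x_scale must be positive")
        rng = np.random.default_rng(seed)
        F = 1 + self.dim
        self.params = {
            "W1": rng.normal(0.0, 1.0, size=(self.hidden, F)) / np.sqrt(F),
            "b1": rng.normal(0.0, 0.3, size=self.hidden),
            "W2": np.zeros((self.dim, self.hidden)),
            "b2": np.zeros(self.dim),
        }

    # -- evaluation ---------------------------------------------------------
    def _features(self, t, x):
        t, x = _as_batch(t, x)
        return np.concatenate([t[:, None], (x - self.x_loc) / self.x_scale], axis=1)

    def _hidden(self, u):
        return np.tanh(u @ self.params["W1"].T + self.params["b1"])

    def __call__(self, t, x):
        u = self._features(t, x)
        a = self._hidden(u)
        return a @ self.params["W2"].T + self.params["b2"]

    def divergence(self, t, x, weights=None):
        """(Weighted) divergence sum_i w_i dy_i/dx_i at each batch point."""
        u = self._features(t, x)
        a = self._hidden(u)
        s = self._plane_sums(weights)
        return (1.0 - a * a) @ s

    def _plane_sums(self, weights=None):
        # s_h = sum_i w_i * W2[i,h] * W1[h, 1+i] / scale_i
        W1x = self.params["W1"][:, 1:] / self.x_scale  # (H, d)
        W2 = self.params["W2"]
        if weights is not None:
            W2 = W2 * np.asarray(weights, float)[:, None]
        return np.einsum("ih,hi->h", W2, W1x)

    # -- gradients ----------------------------------------------------------
    def loss_grads(self, t, x, gy=None, gdiv=None, div_weights=None):
        """Parameter gradients of
        sum_b gy[b]·y[b] + sum_b gdiv[b] * div_w[b], where div_w is the
        divergence weighted per-coordinate by ``div_weights`` (default 1).

        gy : (B, d) upstream gradient on the field value (or None).
        gdiv : (B,) upstream gradient on the (weighted) divergence (or None).
        """
        u = self._features(t, x)
        a = self._hidden(u)
        W1, W2 = self.params["W1"], self.params["W2"]
        g = {k: np.zeros_like(v) for k, v in self.params.items()}
        if gy is not None:
            gy = np.asarray(gy, dtype=float)
            g["W2"] += gy.T @ a
            g["b2"] += gy.sum(axis=0)
            dz = (gy @ W2) * (1.0 - a * a)
            g["W1"] += dz.T @ u
            g["b1"] += dz.sum(axis=0)
        if gdiv is not None:
            c = np.asarray(gdiv, dtype=float)
            w = np.ones(self.dim) if div_weights is None else np.asarray(div_weights, float)
            D = 1.0 - a * a
            cD = c[:, None] * D                       # (B, H)
            colsum = cD.sum(axis=0)                   # (H,)
            W1x = W1[:, 1:] / self.x_scale            # (H, d)
            g["W2"] += colsum[None, :] * (W1x * w[None, :]).T
            g["W1"][:, 1:] += colsum[:, None] * (W2.T * w[None, :] / self.x_scale[None, :])
            s = self._plane_sums(w)
            dz = cD * (-2.0 * a) * s[None, :]
            g["W1"] += dz.T @ u
            g["b1"] += dz.sum(axis=0)
        return g

    # -- (de)serialisation --------------------------------------------------
    def state_dict(self):
        out = {k: v.copy() for k, v in self.params.items()}
        out["x_loc"] = self.x_loc.copy()
        out["x_scale"] = self.x_scale.copy()
        return out

    @classmethod
    def from_state(cls, state):
        W1 = np.asarray(state["W1"])
        obj = cls(dim=W1.shape[1] - 1, hidden=W1.shape[0],
                  x_loc=np.asarray(state["x_loc"]), x_scale=np.asarray(state["x_scale"]))
        for k in ("W1", "b1", "W2", "b2"):
            obj.params[k] = np.asarray(state[k]).copy()
        return obj


class Adam:
    """Plain Adam on a dict of parameter arrays."""

    def __init__(self, params, lr=1e-2, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads):
        self.t += 1
        corr1 = 1.0 - self.b1 ** self.t
        corr2 = 1.0 - self.b2 ** self.t
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            mhat = self.m[k] / corr1
            vhat = self.v[k] / corr2
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
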