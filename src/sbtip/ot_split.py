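"""Semi-discrete optimal transport via the discrete Brenier potential.

The target measure is a weighted atom set nu = sum_i nu_i delta_{y_i}.
Each atom carries a support plane pi_i(x) = <x, y_i> + h_i of the
piecewise-linear convex Brenier potential max_i pi_i(x); the induced cell
decomposition W_i(h) = {x : pi_i(x) >= pi_j(x) for all j} partitions the
source, and the height vector h is chosen so that each cell carries
exactly its atom's mass: omega_i(h) = nu_i.  That h is the unique (up to
an additive constant) minimiser of the convex energy

    E(h) = int_0^h sum_i omega_i(eta) d eta_i  -  sum_i h_i nu_i,

whose gradient is omega(h) - nu.  Source masses omega are estimated by
Monte Carlo over the empirical source samples.

For a non-convex, multi-component target, the induced map is used to
split the *source* into parts matched one-to-one with the target
components (each part carrying its component's mass); each matched pair
can then be bridged separately, avoiding the discontinuity a single
continuous transport map cannot represent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.cluster import KMeans

__all__ = ["TargetAtoms", "cell_assign", "cell_masses", "ot_energy_grad",
           "solve_heights", "split_by_target_clusters", "cluster_terminal_loss",
           "SplitResult"]


@dataclass(frozen=True)
class TargetAtoms:
    """Discrete target: atom locations Y (n, d) and positive weights nu."""

    Y: np.ndarray
    nu: np.ndarray

    def __post_init__(self):
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        nu = np.atleast_1d(np.asarray(self.nu, dtype=float))
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "nu", nu)
        if Y.shape[0] != nu.size:
            raise ValueError("one weight per atom is required")
        if np.any(nu <= 0):
            raise ValueError("atom weights must be positive")
        if not np.isclose(nu.sum(), 1.0, atol=1e-8):
            raise ValueError("atom weights must sum to 1")

    @property
    def n(self):
        return self.nu.size


def _check_h(atoms, h):
    h = np.atleast_1d(np.asarray(h, dtype=float))
    if h.size != atoms.n:
        raise ValueError("one height per atom is required")
    if not np.all(np.isfinite(h)):
        raise ValueError("heights must be finite")
    return h


def cell_assign(x, atoms: TargetAtoms, h):
    """Index of the maximising support plane argmax_i <x, y_i> + h_i.

    Ties break to the lowest index.  ``x`` may be a point or a batch; the
    assignment is invariant under h -> h + c 1.
    """
    h = _check_h(atoms, h)
    xb = np.atleast_2d(np.asarray(x, dtype=float))
    idx = np.argmax(xb @ atoms.Y.T + h, axis=1)
    return int(idx[0]) if np.asarray(x).ndim == 1 else idx


def cell_masses(source_samples, atoms: TargetAtoms, h):
    """Monte-Carlo cell masses omega_i = #{x in W_i} / n (sums to 1)."""
    X = np.atleast_2d(np.asarray(source_samples, dtype=float))
    if X.size == 0:
        raise ValueError("empty source sample set")
    idx = cell_assign(X, atoms, h)
    return np.bincount(idx, minlength=atoms.n) / X.shape[0]


def ot_energy_grad(source_samples, atoms: TargetAtoms, h, n_quad=64):
    """Energy E(h) and its exact gradient omega(h) - nu.

    E is evaluated by midpoint quadrature of sum_i omega_i(eta) d eta_i
    along the straight path 0 -> h (only the gradient matters for the
    optimisation; E is reported for monitoring).
    """
    h = _check_h(atoms, h)
    X = np.atleast_2d(np.asarray(source_samples, dtype=float))
    if X.size == 0:
        raise ValueError("empty source sample set")
    svals = (np.arange(n_quad) + 0.5) / n_quad
    E = 0.0
    for s in svals:
        om = cell_masses(X, atoms, s * h)
        E += float(om @ h) / n_quad
    E -= float(h @ atoms.nu)
    grad = cell_masses(X, atoms, h) - atoms.nu
    return E, grad


def solve_heights(source_samples, atoms: TargetAtoms, tol=0.01,
                  max_iters=5000, step=None, verbose=False):
    """Gradient descent on E(h) until max_i |omega_i - nu_i| < tol.

    The gauge h_n = 0 is fixed after every step.  The step size adapts by
    halving whenever the best residual has not improved for 100 iterations.
    Raises on non-convergence, carrying the final residual.
    """
    X = np.atleast_2d(np.asarray(source_samples, dtype=float))
    if step is None:
        # natural scale of the support-plane scores
        step = max(float(np.std(X @ atoms.Y.T)), 1e-3)
    h = np.zeros(atoms.n)
    best = np.inf
    since_best = 0
    for it in range(max_iters):
        om = cell_masses(X, atoms, h)
        res = float(np.max(np.abs(om - atoms.nu)))
        if res < best - 1e-12:
            best, since_best = res, 0
        else:
            since_best += 1
            if since_best >= 100:
                step *= 0.5
                since_best = 0
        if res < tol:
            return h - h[-1]
        h = h - step * (om - atoms.nu)
        h = h - h[-1]
    raise RuntimeError(
        f"height optimisation did not converge (residual {best:.4f} > tol {tol})")


@dataclass
class SplitResult:
    """Matched (source part, target component) decomposition."""

    atoms: TargetAtoms
    heights: np.ndarray
    atom_cluster: np.ndarray      # cluster id per atom
    labels0: np.ndarray           # cluster id per source sample
    labels1: np.ndarray           # cluster id per target sample
    pairs: list                   # [(source_indices, target_indices), ...]

    @property
    def source_masses(self):
        n = self.labels0.size
        k = int(self.atom_cluster.max()) + 1
        return np.bincount(self.labels0, minlength=k) / n


def split_by_target_clusters(rho0_samples, rho1_samples, n_clusters,
                             atoms_per_cluster=16, tol=0.01, max_iters=5000,
                             seed=0, labels1=None):
    """Partition the source to mirror the target's connected components.

    The target is clustered (k-means, or caller-supplied ``labels1``);
    each cluster is summarised by a small k-means codebook of weighted
    atoms; the heights are solved on the pooled atom set; and every source
    sample inherits the cluster of its assigned atom.  Mass preservation
    of the semi-discrete map makes each source part carry (up to the
    Monte-Carlo tolerance) the sample weight of its target component.
    """
    X0 = np.atleast_2d(np.asarray(rho0_samples, dtype=float))
    X1 = np.atleast_2d(np.asarray(rho1_samples, dtype=float))
    n1 = X1.shape[0]
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if labels1 is None:
        if n_clusters == 1:
            labels1 = np.zeros(n1, dtype=int)
        else:
            km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
            labels1 = km.fit_predict(X1)
    labels1 = np.asarray(labels1, dtype=int)
    Ys, nus, atom_cluster = [], [], []
    for c in range(n_clusters):
        pts = X1[labels1 == c]
        if pts.shape[0] == 0:
            raise ValueError(f"target cluster {c} has zero weight")
        m = min(atoms_per_cluster, pts.shape[0])
        if m == 1:
            centers = pts.mean(axis=0, keepdims=True)
            counts = np.array([pts.shape[0]])
        else:
            km = KMeans(n_clusters=m, n_init=4, random_state=seed + 1 + c)
            sub = km.fit_predict(pts)
            centers = km.cluster_centers_
            counts = np.bincount(sub, minlength=m)
        Ys.append(centers)
        nus.append(counts / n1)
        atom_cluster.extend([c] * centers.shape[0])
    atoms = TargetAtoms(np.vstack(Ys), np.concatenate(nus))
    atom_cluster = np.asarray(atom_cluster, dtype=int)
    h = solve_heights(X0, atoms, tol=tol, max_iters=max_iters)
    labels0 = atom_cluster[cell_assign(X0, atoms, h)]
    pairs = [(np.flatnonzero(labels0 == c), np.flatnonzero(labels1 == c))
             for c in range(n_clusters)]
    return SplitResult(atoms, h, atom_cluster, labels0, labels1, pairs)


def cluster_terminal_loss(X1_batch, assigned_targets):
    """Quadratic terminal attachment E ||X_1 - y_i||^2 over a path batch."""
    X = np.atleast_2d(np.asarray(X1_batch, dtype=float))
    Y = np.atleast_2d(np.asarray(assigned_targets, dtype=float))
    if X.shape != Y.shape:
        raise ValueError("terminal states and targets must align")
    return float(np.mean(np.sum((X - Y) ** 2, axis=1)))
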