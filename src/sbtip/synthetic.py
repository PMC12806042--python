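"""Seeded generators for test fixtures and demonstration inputs.

``make_nonconvex_target`` emulates the geometry of a 2-D embedding of a
cohort study: one connected initial cluster (e.g. healthy scans) and a
target split into two disjoint components (e.g. two disease subtypes),
whose convex hull contains a near-empty region — the configuration under
which a single continuous transport map breaks down and the measure flow
of the bridge visibly splits.  Coordinates are unit-scale, as in
scale-free low-dimensional embeddings.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .indicator import IndicatorSeries

__all__ = ["GaussianPairConfig", "NonconvexConfig", "JumpSeriesConfig",
           "make_gaussian_pair", "make_nonconvex_target", "make_jump_series"]


@dataclass(frozen=True)
class GaussianPairConfig:
    n: int = 1000
    dim: int = 1
    mean0: Sequence[float] = (-2.0,)
    mean1: Sequence[float] = (2.0,)
    std0: Sequence[float] = (0.3162,)      # variance 0.1
    std1: Sequence[float] = (0.3162,)
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class NonconvexConfig:
    """One initial blob, two disjoint target components."""

    n: int = 2000
    center0: Tuple[float, float] = (-3.0, 0.0)
    spread0: float = 0.8
    centers: Tuple[Tuple[float, float], Tuple[float, float]] = ((3.0, 1.8), (3.0, -1.8))
    spreads: Tuple[float, float] = (0.45, 0.45)
    weights: Tuple[float, float] = (0.5, 0.5)
    shape: str = "blobs"                   # "blobs" | "crescents"
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("component weights must sum to 1")
        if min(self.weights) <= 0:
            raise ValueError("component weights must be positive")
        if self.shape not in ("blobs", "crescents"):
            raise ValueError("shape must be 'blobs' or 'crescents'")
        gap = float(np.linalg.norm(np.subtract(*self.centers)))
        if gap < 3.0 * sum(self.spreads):
            raise ValueError("components not disjoint")


@dataclass(frozen=True)
class JumpSeriesConfig:
    n: int = 40
    jump_index: int = 7
    height: float = 1.0
    base: float = 1.0
    slope: float = 0.01
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.jump_index < self.n:
            raise ValueError("jump index out of range")


def _pervec(x, dim):
    v = np.atleast_1d(np.asarray(x, dtype=float))
    if v.size == 1:
        v = np.repeat(v, dim)
    if v.size != dim:
        raise ValueError("config vector does not match dim")
    return v


def make_gaussian_pair(cfg: GaussianPairConfig):
    """Two seeded Gaussian sample sets (1-D or 2-D)."""
    rng = np.random.default_rng(cfg.seed)
    m0, m1 = _pervec(cfg.mean0, cfg.dim), _pervec(cfg.mean1, cfg.dim)
    s0, s1 = _pervec(cfg.std0, cfg.dim), _pervec(cfg.std1, cfg.dim)
    rho0 = m0 + s0 * rng.standard_normal((cfg.n, cfg.dim))
    rho1 = m1 + s1 * rng.standard_normal((cfg.n, cfg.dim))
    return rho0, rho1


def _crescent(n, center, spread, flip, rng):
    # arc of a circle opening away from the other component
    ang = rng.uniform(-0.45 * np.pi, 0.45 * np.pi, size=n)
    r = 2.5 * spread + spread * 0.3 * rng.standard_normal(n)
    sgn = -1.0 if flip else 1.0
    return np.stack([center[0] + r * np.cos(ang) - 2.5 * spread,
                     center[1] + sgn * np.abs(r * np.sin(ang))], axis=1)


def make_nonconvex_target(cfg: NonconvexConfig):
    """(rho0, rho1): connected source blob, two-component target mixture.

    Component membership is drawn i.i.d. with the configured weights; the
    centre gap of at least three combined spreads keeps the components
    disjoint, so the convex hull of the target contains a near-empty
    region between them.
    """
    rng = np.random.default_rng(cfg.seed)
    rho0 = np.asarray(cfg.center0, float) + cfg.spread0 * rng.standard_normal((cfg.n, 2))
    comp = (rng.random(cfg.n) < cfg.weights[1]).astype(int)
    rho1 = np.empty((cfg.n, 2))
    for c in (0, 1):
        idx = np.flatnonzero(comp == c)
        if cfg.shape == "blobs":
            pts = (np.asarray(cfg.centers[c], float)
                   + cfg.spreads[c] * rng.standard_normal((idx.size, 2)))
        else:
            pts = _crescent(idx.size, cfg.centers[c], cfg.spreads[c], c == 1, rng)
        rho1[idx] = pts
    return rho0, rho1


def make_jump_series(cfg: JumpSeriesConfig) -> IndicatorSeries:
    """A smooth baseline with one injected jump, as an IndicatorSeries."""
    rng = np.random.default_rng(cfg.seed)
    k = np.arange(cfg.n)
    values = cfg.base + cfg.slope * k + cfg.noise_sd * rng.standard_normal(cfg.n)
    values[cfg.jump_index:] += cfg.height
    values = np.maximum(values, 0.0)
    times = (k + 1.0) / cfg.n
    a = np.zeros(cfg.n + 1)
    return IndicatorSeries(times=times, values=values, a_inst=a)
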