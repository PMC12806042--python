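"""Morris–Lecar neuron: simulation, invariant sets, bridge marginals.

The model is the classic two-variable conductance system for membrane
potential v (mV) and potassium gating variable w in [0, 1]:

    C dv/dt = -gCa m_inf(v) (v - VCa) - gK w (v - VK) - gL (v - VL) + I
      dw/dt = phi (w_inf(v) - w) / tau_w(v)

with m_inf(v) = (1 + tanh((v-V1)/V2))/2, w_inf(v) = (1 + tanh((v-V3)/V4))/2
and tau_w(v) = 1/cosh((v-V3)/(2 V4)).  Stochastic runs add sigma_t dW_t to
the v-equation only.  Two printed parameter regimes are provided: Class I
("Hopf", I = 92 uA/cm^2) is bistable between a stable focus and a large
stable limit cycle; Class II ("Homoclinic", I = 37 uA/cm^2) carries a
stable node, a saddle and an upper spiral that sits essentially on the
Hopf point (its eigenvalue real part is about -1e-3 at the printed
parameters, i.e. marginally stable at printed precision), together with a
large stable periodic orbit.

These invariant sets furnish the boundary marginals of the transition-path
problem: rho0 concentrates near the resting state, rho1 on (a sub-arc of)
the oscillatory attractor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import root

from .bridge import DriftSpec, NoiseSchedule, TrajectoryEnsemble

__all__ = [
    "MorrisLecarParams", "CLASS_I", "CLASS_II", "InvariantSetSample",
    "gating", "drift", "ml_drift_spec", "simulate", "find_equilibria",
    "extract_limit_cycle", "make_marginals",
]


@dataclass(frozen=True)
class MorrisLecarParams:
    """Full parameter record for one regime (conductances in mS/cm^2,
    potentials in mV, current in uA/cm^2, capacitance in uF/cm^2)."""

    gCa: float
    gK: float
    gL: float
    VCa: float
    VK: float
    VL: float
    I: float
    C: float
    phi: float
    V1: float
    V2: float
    V3: float
    V4: float
    regime_label: str = "custom"

    def __post_init__(self):
        if min(self.gCa, self.gK, self.gL) <= 0:
            raise ValueError("conductances must be positive")
        if self.C <= 0 or self.phi <= 0:
            raise ValueError("C and phi must be positive")
        if self.V2 == 0 or self.V4 == 0:
            raise ValueError("gating slopes V2, V4 must be nonzero")


CLASS_I = MorrisLecarParams(gCa=4.4, gK=8.0, gL=2.0, VCa=120.0, VK=-84.0,
                            VL=-60.0, I=92.0, C=20.0, phi=0.04,
                            V1=-1.2, V2=18.0, V3=2.0, V4=30.0,
                            regime_label="class_I")

CLASS_II = MorrisLecarParams(gCa=4.0, gK=8.0, gL=2.0, VCa=120.0, VK=-84.0,
                             VL=-60.0, I=37.0, C=20.0, phi=0.23,
                             V1=-1.2, V2=18.0, V3=12.0, V4=17.4,
                             regime_label="class_II")


@dataclass
class InvariantSetSample:
    """A sampled invariant set: an equilibrium or a periodic orbit."""

    kind: str                     # "equilibrium" | "limit_cycle" | "homoclinic_like"
    points: np.ndarray            # (n, 2) time-ordered (v, w)
    period: Optional[float] = None
    stability: Optional[np.ndarray] = None  # Jacobian eigenvalue pair

    @property
    def is_stable(self):
        if self.stability is None:
            return None
        return bool(np.all(self.stability.real < 0))


def gating(v, p: MorrisLecarParams):
    """Steady-state activations and the w time constant at potential v.

    Returns (m_inf, w_inf, tau_w); m_inf and w_inf are half-activated at
    v = V1 and v = V3 respectively, and tau_w peaks at 1 at v = V3.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite membrane potential")
    m_inf = 0.5 * (1.0 + np.tanh((v - p.V1) / p.V2))
    w_inf = 0.5 * (1.0 + np.tanh((v - p.V3) / p.V4))
    tau_w = 1.0 / np.cosh((v - p.V3) / (2.0 * p.V4))
    return m_inf, w_inf, tau_w


def drift(state, p: MorrisLecarParams):
    """Deterministic vector field (dv/dt, dw/dt); batched over rows."""
    s = np.atleast_2d(np.asarray(state, dtype=float))
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite state")
    v, w = s[:, 0], s[:, 1]
    m_inf, w_inf, tau_w = gating(v, p)
    dv = (-p.gCa * m_inf * (v - p.VCa) - p.gK * w * (v - p.VK)
          - p.gL * (v - p.VL) + p.I) / p.C
    dw = p.phi * (w_inf - w) / tau_w
    out = np.stack([dv, dw], axis=1)
    return out[0] if np.asarray(state).ndim == 1 else out


def ml_drift_spec(p: MorrisLecarParams) -> DriftSpec:
    """The Morris–Lecar field packaged as a (time-independent) DriftSpec."""
    return DriftSpec(lambda t, x: drift(x, p), name=f"morris_lecar:{p.regime_label}")


def _clamp_w(s):
    s[:, 1] = np.clip(s[:, 1], 0.0, 1.0)
    return s


def simulate(p: MorrisLecarParams, init, sigma, T, N, n_paths=1, seed=0):
    """Euler–Maruyama ensemble on the uniform grid t_k = k T / N.

    ``init`` is a single state or an (n, 2) sample set (paths draw their
    initial condition from it); ``sigma`` is a scalar or a NoiseSchedule.
    Noise enters the v-equation only; w is clamped to [0, 1] after every
    step.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if N < 1:
        raise ValueError("N must be >= 1")
    sched = sigma if isinstance(sigma, NoiseSchedule) else NoiseSchedule(float(sigma))
    rng = np.random.default_rng(seed)
    init = np.atleast_2d(np.asarray(init, dtype=float))
    if init.shape[0] == 1:
        x = np.repeat(init, n_paths, axis=0)
    else:
        x = init[rng.integers(0, init.shape[0], size=n_paths)]
    x = _clamp_w(x.copy())
    dt = T / N
    out = np.empty((n_paths, N + 1, 2))
    out[:, 0] = x
    for k in range(N):
        tau = k / N
        sig = float(sched.value(tau))
        x = x + dt * drift(x, p)
        if sig > 0:
            x[:, 0] += sig * np.sqrt(dt) * rng.standard_normal(n_paths)
        x = _clamp_w(x)
        out[:, k + 1] = x
    times = np.linspace(0.0, T, N + 1)
    return TrajectoryEnsemble(out, times, direction="forward", seed=seed)


def _jacobian(s, p, h=1e-6):
    J = np.empty((2, 2))
    for j in range(2):
        e = np.zeros(2)
        e[j] = h
        J[:, j] = (drift(s + e, p) - drift(s - e, p)) / (2 * h)
    return J


def find_equilibria(p: MorrisLecarParams, v_range=(-80.0, 60.0),
                    w_range=(0.0, 1.0), n_grid=50, tol=1e-8,
                    field=None) -> list:
    """Multi-start root search for equilibria of the drift field.

    Starts a damped Newton (scipy hybr) from an ``n_grid`` x ``n_grid``
    lattice, keeps roots with ||drift|| < tol, merges duplicates within
    0.5 mV / 0.01 in w, and attaches finite-difference Jacobian
    eigenvalues.  ``field`` overrides the Morris–Lecar drift (used by the
    tests with a linear field).
    """
    f = (lambda s: drift(s, p)) if field is None else field

    def jac(s, h=1e-6):
        J = np.empty((2, 2))
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            J[:, j] = (np.asarray(f(s + e)) - np.asarray(f(s - e))) / (2 * h)
        return J

    found = []
    for v0 in np.linspace(*v_range, n_grid):
        for w0 in np.linspace(*w_range, n_grid):
            sol = root(f, np.array([v0, w0]), tol=1e-12)
            if not sol.success:
                continue
            s = sol.x
            if np.linalg.norm(np.asarray(f(s))) >= tol:
                continue
            if not (v_range[0] - 5 <= s[0] <= v_range[1] + 5 and
                    w_range[0] - 0.05 <= s[1] <= w_range[1] + 0.05):
                continue
            if any(abs(s[0] - q[0]) < 0.5 and abs(s[1] - q[1]) < 0.01 for q in found):
                continue
            found.append(s)
    out = []
    for s in sorted(found, key=lambda q: q[0]):
        eig = np.linalg.eigvals(jac(s))
        out.append(InvariantSetSample(kind="equilibrium",
                                      points=np.atleast_2d(s),
                                      stability=eig))
    return out


def extract_limit_cycle(p: MorrisLecarParams, x0, t_transient=500.0,
                        t_sample=500.0, dt=0.01, closure_tol=1e-2):
    """Deterministic orbit extraction from initial state x0.

    Integrates with the same Euler stepper as :func:`simulate` (sigma = 0),
    discards ``t_transient``, estimates the period from successive upward
    crossings of the time-mean v level and returns one period of samples.
    Raises ``RuntimeError("no oscillation detected")`` when the trajectory
    settles (e.g. when started at a stable equilibrium).
    """
    n_tr = int(round(t_transient / dt))
    n_sm = int(round(t_sample / dt))
    ens = simulate(p, np.asarray(x0, float), 0.0, t_transient + t_sample,
                   n_tr + n_sm, n_paths=1, seed=0)
    path = ens.states[0, n_tr:]
    v = path[:, 0]
    if v.max() - v.min() < 1.0:  # < 1 mV swing: no oscillation
        raise RuntimeError("no oscillation detected")
    level = float(v.mean())
    up = np.flatnonzero((v[:-1] < level) & (v[1:] >= level))
    if up.size < 3:
        raise RuntimeError("no oscillation detected")
    # sub-step crossing times by linear interpolation
    frac = (level - v[up]) / (v[up + 1] - v[up])
    t_cross = (up + frac) * dt
    period = float(np.mean(np.diff(t_cross)))
    i0, i1 = up[-2], up[-1]
    pts = path[i0:i1 + 1]
    gap = np.linalg.norm((pts[-1] - pts[0]) / np.array([100.0, 1.0]))
    if gap > closure_tol:
        raise RuntimeError(f"orbit failed to close (gap {gap:.3g})")
    kind = "limit_cycle" if p.regime_label != "class_II" else "homoclinic_like"
    return InvariantSetSample(kind=kind, points=pts, period=period)


def _stable_node(p):
    eqs = [e for e in find_equilibria(p, n_grid=24) if e.is_stable]
    if not eqs:
        raise RuntimeError("no stable equilibrium found")
    return eqs[0].points[0]  # lowest-v stable equilibrium: the resting state


_CYCLE_SEED_STATE = {"node_to_cycle": (0.0, 0.0), "node_to_homoclinic": (10.0, 0.2)}


def make_marginals(p: MorrisLecarParams, mode="node_to_cycle", n=1000,
                   jitter_sd=0.02, arc_fraction=0.25, seed=0):
    """Boundary marginals for the transition-path problem.

    rho0: n Gaussian-jittered copies of the resting state.  rho1: n points
    resampled uniformly (by normalised arc length) along an arc covering
    ``arc_fraction`` of the extracted periodic orbit, centred on the point
    of maximal v, with the same jitter.  For the jitter and the arc-length
    metric, v is measured in units of 100 mV so that both coordinates are
    order one.
    """
    if mode not in _CYCLE_SEED_STATE:
        raise ValueError(f"unknown mode {mode!r}")
    if not 0 < arc_fraction <= 1:
        raise ValueError("arc_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    eq = _stable_node(p)
    scale = np.array([100.0, 1.0])
    rho0 = eq + jitter_sd * scale * rng.standard_normal((n, 2))
    cyc = extract_limit_cycle(p, _CYCLE_SEED_STATE[mode])
    pts = cyc.points
    # arc-length parameterisation in normalised coordinates
    seg = np.linalg.norm(np.diff(pts / scale, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    start = float(pts[:, 0].argmax())
    s0 = arc[int(start)] - 0.5 * arc_fraction * total
    targets_s = (s0 + arc_fraction * total * rng.random(n)) % total
    rho1 = np.stack([np.interp(targets_s, arc, pts[:, 0]),
                     np.interp(targets_s, arc, pts[:, 1])], axis=1)
    rho1 += jitter_sd * scale * rng.standard_normal((n, 2))
    rho1[:, 1] = np.clip(rho1[:, 1], 0.0, 1.0)
    return rho0, rho1
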