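"""Schrödinger-bridge core: forward/backward SDE propagation and training.

The bridge between two empirical marginals rho0, rho1 relative to the
reference diffusion dX = f dt + sigma_t dW on [0, T] is represented by two
score fields on the internal unit clock tau = t/T:

    forward   dX = (T f + sg(tau) Z(tau, X)) dtau + sg(tau) dW,  X_0 ~ rho0
    backward  dX = (T f - sg(tau) Zhat(tau, X)) dtau + sg(tau) dW,  X_1 ~ rho1

where sg(tau) = sqrt(T) * sigma(tau T) is the unit-clock noise amplitude
(so that the reference process accumulates the same variance sigma^2 T over
the horizon).  Z approximates sg * grad ln(phi) and Zhat approximates
sg * grad ln(phihat), the gradients of the Schrödinger potentials.

Training alternates half-bridge (IPF-style) stages: each stage freezes one
policy, simulates and caches an ensemble from it, and fits the opposite
score field by minimising the time-discretised likelihood loss

    L = E sum_k [ 1/2 ||Z + Zhat||^2 + div_x( sg Zhat - T f ) ](tau_k, X_k) dtau
        + terminal term.

Under frozen-trajectory caching the terminal term is constant in the
trained parameters; information about each marginal enters through the
trajectory initialisations of the alternating stages (this is exactly the
iterative-proportional-fitting view of the problem).  Minimising the
running term over the trained field is an implicit score-matching problem
whose exact minimiser is the time-reversal drift of the frozen policy.
"""

from __future__ import annotations


import json
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.neighbors import KernelDensity

from .nets import Adam, ScoreMLP, ZeroField

__all__ = [
    "NoiseSchedule", "DriftSpec", "ZERO_DRIFT", "TrajectoryEnsemble",
    "BridgeModel", "LossReport", "TrainConfig",
    "propagate_forward", "propagate_backward", "divergence",
    "likelihood_loss", "alternating_train", "train_annealed", "kde_density",
    "marginal_consistency", "save_model", "load_model",
]


# ---------------------------------------------------------------------------
# basic containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSchedule:
    """Noise intensity sigma on the unit clock.

    kind="constant" returns g everywhere; "linear" interpolates g -> g_end;
    "cosine" eases from g to g_end with a half-cosine.
    """

    g: float
    kind: str = "constant"
    g_end: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("constant", "linear", "cosine"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.g < 0:
            raise ValueError("noise intensity must be nonnegative")
        if self.kind != "constant" and self.g_end is None:
            object.__setattr__(self, "g_end", self.g)
        if self.g_end is not None and self.g_end < 0:
            raise ValueError("noise intensity must be nonnegative")

    def value(self, tau):
        tau = np.asarray(tau, dtype=float)
        if self.kind == "constant":
            return np.broadcast_to(float(self.g), tau.shape).copy() if tau.shape else float(self.g)
        w = tau if self.kind == "linear" else 0.5 * (1.0 - np.cos(np.pi * tau))
        return self.g + (self.g_end - self.g) * w


@dataclass(frozen=True)
class DriftSpec:
    """Base drift f(t, x) of the reference SDE (physical time)."""

    f: Callable[[float, np.ndarray], np.ndarray]
    name: str = "custom"
    div: Optional[Callable[[float, np.ndarray], np.ndarray]] = None

    def __call__(self, t, x):
        return np.asarray(self.f(t, np.atleast_2d(np.asarray(x, float))), dtype=float)


def _zero_f(t, x):
    return np.zeros_like(np.atleast_2d(x))


def _zero_div(t, x):
    return np.zeros(np.atleast_2d(x).shape[0])


ZERO_DRIFT = DriftSpec(_zero_f, name="zero", div=_zero_div)


@dataclass
class TrajectoryEnsemble:
    """Monte-Carlo path ensemble on a fixed physical time grid."""

    states: np.ndarray          # (n_paths, N+1, d)
    times: np.ndarray           # (N+1,) physical, strictly increasing
    direction: str = "forward"  # time order of *integration*; states are
                                # always stored in increasing-time order
    seed: Optional[int] = None

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.states.ndim != 3:
            raise ValueError("states must be (n_paths, N+1, dim)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape[1] != self.times.size:
            raise ValueError("states/times length mismatch")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("non-finite states in ensemble")

    @property
    def n_paths(self):
        return self.states.shape[0]

    @property
    def dim(self):
        return self.states.shape[2]


@dataclass
class BridgeModel:
    """A (possibly trained) Schrödinger bridge."""

    drift: DriftSpec
    schedule: NoiseSchedule
    z_fwd: object
    z_bwd: object
    T: float
    N: int
    noise_scale: Optional[np.ndarray] = None  # per-coordinate multiplier

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.noise_scale is not None:
            ns = np.atleast_1d(np.asarray(self.noise_scale, dtype=float))
            if np.any(ns <= 0):
                raise ValueError("noise_scale entries must be positive")
            self.noise_scale = ns

    def sg(self, tau):
        """Unit-clock noise amplitude sqrt(T) * sigma(tau)."""
        return np.sqrt(self.T) * self.schedule.value(tau)

    def ns(self, d):
        """Per-coordinate noise multiplier as a length-d vector."""
        if self.noise_scale is None:
            return np.ones(d)
        if self.noise_scale.size != d:
            raise ValueError("noise_scale dimension mismatch")
        return self.noise_scale

    @property
    def tau_grid(self):
        return np.linspace(0.0, 1.0, self.N + 1)

    @property
    def time_grid(self):
        return self.T * self.tau_grid


@dataclass
class LossReport:
    records: list = dc_field(default_factory=list)  # (stage, direction, iter, loss)

    def append(self, stage, direction, iteration, loss):
        self.records.append((int(stage), str(direction), int(iteration), float(loss)))

    def losses(self, stage=None):
        return np.array([r[3] for r in self.records
                         if stage is None or r[0] == stage])

    @property
    def final_loss(self):
        return self.records[-1][3] if self.records else np.nan


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def _draw_init(samples, n_paths, rng):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.size == 0:
        raise ValueError("empty marginal sample set")
    if not np.all(np.isfinite(samples)):
        raise ValueError("non-finite marginal samples")
    if samples.shape[0] == 1:
        return np.repeat(samples, n_paths, axis=0)
    idx = rng.integers(0, samples.shape[0], size=n_paths)
    return samples[idx]


def propagate_forward(model: BridgeModel, rho0_samples, n_paths, seed=0):
    """Euler–Maruyama sampling of the forward bridge SDE from rho0."""
    rng = np.random.default_rng(seed)
    x = _draw_init(rho0_samples, n_paths, rng)
    d = x.shape[1]
    N, T = model.N, model.T
    dtau = 1.0 / N
    out = np.empty((n_paths, N + 1, d))
    out[:, 0] = x
    taus = model.tau_grid
    ns = model.ns(d)
    for k in range(N):
        tau = taus[k]
        sg = float(model.sg(tau))
        b = T * model.drift(tau * T, x) + sg * ns * model.z_fwd(np.full(x.shape[0], tau), x)
        x = x + b * dtau
        if sg > 0:
            x = x + sg * ns * np.sqrt(dtau) * rng.standard_normal(x.shape)
        out[:, k + 1] = x
    return TrajectoryEnsemble(out, model.time_grid, direction="forward", seed=seed)


def propagate_backward(model: BridgeModel, rho1_samples, n_paths, seed=0):
    """Euler–Maruyama sampling of the backward bridge SDE from rho1.

    Integration runs from tau=1 down to tau=0; the returned states are in
    increasing-time order with ``direction="backward"``.
    """
    rng = np.random.default_rng(seed)
    x = _draw_init(rho1_samples, n_paths, rng)
    d = x.shape[1]
    N, T = model.N, model.T
    dtau = 1.0 / N
    out = np.empty((n_paths, N + 1, d))
    out[:, N] = x
    taus = model.tau_grid
    ns = model.ns(d)
    for k in range(N, 0, -1):
        tau = taus[k]
        sg = float(model.sg(tau))
        b = T * model.drift(tau * T, x) - sg * ns * model.z_bwd(np.full(x.shape[0], tau), x)
        x = x - b * dtau
        if sg > 0:
            x = x + sg * ns * np.sqrt(dtau) * rng.standard_normal(x.shape)
        out[:, k - 1] = x
    return TrajectoryEnsemble(out, model.time_grid, direction="backward", seed=seed)


# ---------------------------------------------------------------------------
# divergence and the likelihood loss
# ---------------------------------------------------------------------------

def divergence(field, t, x, h=1e-5, weights=None):
    """(Optionally weighted) divergence of a vector field at a batch.

    Computes sum_j w_j * d(field_j)/dx_j.  Uses the field's own exact
    ``divergence`` method when available (score networks, linear/constant
    test fields), otherwise central finite differences coordinate by
    coordinate.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if hasattr(field, "divergence"):
        return np.asarray(field.divergence(t, x, weights=weights), dtype=float)
    tb = np.broadcast_to(np.asarray(t, float), (x.shape[0],))
    w = np.ones(x.shape[1]) if weights is None else np.asarray(weights, float)
    scale = np.maximum(np.abs(x).max(axis=0), 1.0)
    out = np.zeros(x.shape[0])
    for j in range(x.shape[1]):
        e = np.zeros(x.shape[1])
        e[j] = h * scale[j]
        fp = np.asarray(field(tb, x + e), dtype=float)
        fm = np.asarray(field(tb, x - e), dtype=float)
        out += w[j] * (fp[:, j] - fm[:, j]) / (2 * e[j])
    return out


def _drift_div(model, tau, x):
    if model.drift.div is not None:
        return np.asarray(model.drift.div(tau * model.T, x), dtype=float)

    def f_at(tb, xb):
        return model.drift(tau * model.T, xb)

    return divergence(f_at, tau, x)


def likelihood_loss(model: BridgeModel, fwd_traj: TrajectoryEnsemble,
                    terminal_log_density=None, terminal_targets=None):
    """Time-discretised negative log-likelihood of the bridge (scalar).

    Running term (left-point rule on the unit clock):
    E sum_k [ 1/2 ||Z + Zhat||^2 + div( sg Zhat - T f ) ] dtau.

    Terminal term: ``-E ln p1(X_1)`` when ``terminal_log_density`` is given,
    or the quadratic cell-target attachment ``+E ||X_1 - y||^2`` when
    ``terminal_targets`` (one target per path) is given.  The printed form
    of the attachment carries a minus sign in front of the expectation; a
    maximised terminal likelihood is a minimised squared distance, so it
    enters the minimised loss with a plus sign here.
    """
    if not np.allclose(fwd_traj.times, model.time_grid):
        raise ValueError("trajectory grid does not match the model grid")
    B, _, d = fwd_traj.states.shape
    taus = model.tau_grid
    dtau = 1.0 / model.N
    total = 0.0
    for k in range(model.N):
        x = fwd_traj.states[:, k]
        tb = np.full(B, taus[k])
        sg = float(model.sg(taus[k]))
        z = np.asarray(model.z_fwd(tb, x), dtype=float)
        zh = np.asarray(model.z_bwd(tb, x), dtype=float)
        quad = 0.5 * np.sum((z + zh) ** 2, axis=1)
        div = (sg * divergence(model.z_bwd, tb, x, weights=model.ns(d))
               - model.T * _drift_div(model, taus[k], x))
        step = float(np.mean(quad + div)) * dtau
        if not np.isfinite(step):
            raise FloatingPointError(f"non-finite likelihood term at time index {k}")
        total += step
    xT = fwd_traj.states[:, -1]
    if terminal_log_density is not None:
        total -= float(np.mean(terminal_log_density(xT)))
    elif terminal_targets is not None:
        y = np.atleast_2d(np.asarray(terminal_targets, dtype=float))
        if y.shape[0] != B:
            raise ValueError("one terminal target per path is required")
        total += float(np.mean(np.sum((xT - y) ** 2, axis=1)))
    if not np.isfinite(total):
        raise FloatingPointError("non-finite likelihood loss (terminal term)")
    return total


# ---------------------------------------------------------------------------
# alternating (IPF-style) likelihood training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    stages: int = 8
    iters: int = 200
    batch_paths: int = 64
    cache_paths: int = 512
    lr: float = 1e-2
    hidden: int = 64
    N: int = 50
    T: float = 1.0


def _kde_log_density(samples, bandwidth=None):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n, d = samples.shape
    if bandwidth is None:
        spread = float(np.mean(samples.std(axis=0))) or 1.0
        bandwidth = max(spread * n ** (-1.0 / (d + 4)), 1e-3)
    kde = KernelDensity(bandwidth=bandwidth).fit(samples)
    return lambda x: kde.score_samples(np.atleast_2d(x))


def alternating_train(config: TrainConfig, rho0_samples, rho1_samples,
                      drift: DriftSpec = None, schedule: NoiseSchedule = None,
                      terminal_mode: str = "density", seed: int = 0,
                      init_fields=None, noise_scale=None):
    """Fit the two score fields by alternating half-bridge stages.

    Even stages freeze the forward policy, cache a forward ensemble and
    train the backward field; odd stages do the mirror image.  Returns the
    trained :class:`BridgeModel` and a :class:`LossReport` of per-iteration
    minibatch losses.

    ``init_fields=(z_fwd, z_bwd)`` warm-starts from previously trained
    score fields (see :func:`train_annealed`).
    """
    rho0 = np.atleast_2d(np.asarray(rho0_samples, dtype=float))
    rho1 = np.atleast_2d(np.asarray(rho1_samples, dtype=float))
    if rho0.size == 0 or rho1.size == 0:
        raise ValueError("both marginals must be nonempty")
    if rho0.shape[1] != rho1.shape[1]:
        raise ValueError("marginal dimensions differ")
    d = rho0.shape[1]
    drift = ZERO_DRIFT if drift is None else drift
    schedule = NoiseSchedule(1.0) if schedule is None else schedule

    both = np.vstack([rho0, rho1])
    x_loc = both.mean(axis=0)
    x_scale = np.maximum(both.std(axis=0), 1e-3)

    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 + 2 * max(config.stages, 1))
    if init_fields is not None:
        z_fwd = ScoreMLP.from_state(init_fields[0].state_dict())
        z_bwd = ScoreMLP.from_state(init_fields[1].state_dict())
    else:
        z_fwd = ScoreMLP(d, hidden=config.hidden, x_loc=x_loc, x_scale=x_scale,
                         seed=int(seeds[0] % (2 ** 31)))
        z_bwd = ScoreMLP(d, hidden=config.hidden, x_loc=x_loc, x_scale=x_scale,
                         seed=int(seeds[1] % (2 ** 31)))
        # Displacement initialisation: start from the constant-speed flow
        # translating the source mean onto the target mean (and back).  The
        # alternating reversal stages largely preserve a flow's transport
        # schedule, so starting at the uniform schedule — the zero-noise
        # optimal one for equal-shape marginals — avoids settling on a
        # kinetically wasteful lazy-start/late-rush schedule.
        sg_mean = float(np.mean(np.sqrt(config.T)
                                * schedule.value(np.linspace(0, 1, config.N))))
        if sg_mean > 0:
            nsv = np.ones(d) if noise_scale is None else np.atleast_1d(
                np.asarray(noise_scale, float))
            disp = rho1.mean(axis=0) - rho0.mean(axis=0)
            z_fwd.params["b2"] = (disp - config.T * np.mean(
                drift(0.0, both), axis=0)) / (sg_mean * nsv)
            z_bwd.params["b2"] = -z_fwd.params["b2"].copy()
    model = BridgeModel(drift, schedule, z_fwd, z_bwd, T=config.T, N=config.N,
                        noise_scale=noise_scale)
    report = LossReport()

    log_p1 = _kde_log_density(rho1) if terminal_mode == "density" else None
    log_p0 = _kde_log_density(rho0) if terminal_mode == "density" else None

    taus = model.tau_grid[:-1]
    dtau = 1.0 / config.N
    sg_grid = np.array([float(model.sg(t)) for t in taus])

    for stage in range(config.stages):
        fwd_stage = stage % 2 == 0  # training the *backward* field this stage
        sim_seed = int(seeds[2 + 2 * stage] % (2 ** 31))
        rng = np.random.default_rng(int(seeds[3 + 2 * stage] % (2 ** 31)))
        if fwd_stage:
            cache = propagate_forward(model, rho0, config.cache_paths, seed=sim_seed)
            trained, frozen = z_bwd, z_fwd
            terminal_logp = log_p1
        else:
            cache = propagate_backward(model, rho1, config.cache_paths, seed=sim_seed)
            trained, frozen = z_fwd, z_bwd
            terminal_logp = log_p0
        states = cache.states  # (n_cache, N+1, d)
        # The terminal term is constant over the stage (the trajectories are
        # frozen), so it is evaluated once on the whole cache and added to
        # every logged iteration loss rather than re-sampled per minibatch.
        term_const = 0.0
        if terminal_logp is not None:
            xend = states[:, -1] if fwd_stage else states[:, 0]
            term_const = -float(np.mean(terminal_logp(xend)))
        opt = Adam(trained.params, lr=config.lr)
        for it in range(config.iters):
            idx = rng.integers(0, states.shape[0], size=config.batch_paths)
            xs = states[idx][:, :-1]                        # (B, N, d)
            B = xs.shape[0]
            flat_x = xs.reshape(B * config.N, d)
            flat_t = np.broadcast_to(taus, (B, config.N)).reshape(-1)
            zt = trained(flat_t, flat_x)
            zf = frozen(flat_t, flat_x)
            ssum = zt + zf
            sg_flat = np.broadcast_to(sg_grid, (B, config.N)).reshape(-1)
            nsd = model.ns(d)
            div_t = trained.divergence(flat_t, flat_x, weights=nsd)
            run = (0.5 * np.sum(ssum ** 2, axis=1) + sg_flat * div_t)
            loss = float(run.sum()) * dtau / B + term_const
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"divergent loss at stage {stage}, iteration {it}")
            grads = trained.loss_grads(
                flat_t, flat_x,
                gy=ssum * (dtau / B),
                gdiv=sg_flat * (dtau / B),
                div_weights=nsd,
            )
            opt.step(grads)
            report.append(stage, "forward" if fwd_stage else "backward", it, loss)
    return model, report


def train_annealed(config: TrainConfig, rho0_samples, rho1_samples, g_levels,
                   drift: DriftSpec = None, terminal_mode: str = "density",
                   seed: int = 0, noise_scale=None):
    """Train a low-noise bridge by annealing through decreasing g levels.

    The alternating scheme mixes slowly from a cold start when the noise is
    small relative to the transport distance (the classic IPF regime
    ~distance^2/g^2).  Annealing trains at the largest g first and
    warm-starts each lower level from the previous solution, rescaling the
    score fields' output layer by g_old/g_new so the initial *drift*
    sg * Z is preserved.  Returns the model at the final (smallest) g and
    the concatenated loss report.
    """
    g_levels = sorted(set(float(g) for g in np.atleast_1d(g_levels)), reverse=True)
    model, report = None, LossReport()
    for li, g in enumerate(g_levels):
        init = None
        if model is not None:
            ratio = g_prev / g
            init = (model.z_fwd, model.z_bwd)
            for net in init:
                net.params["W2"] *= ratio
                net.params["b2"] *= ratio
        model, rep = alternating_train(config, rho0_samples, rho1_samples,
                                       drift=drift, schedule=NoiseSchedule(g),
                                       terminal_mode=terminal_mode,
                                       seed=seed + li, init_fields=init,
                                       noise_scale=noise_scale)
        for r in rep.records:
            report.records.append((r[0] + li * config.stages,) + r[1:])
        g_prev = g
    return model, report


# ---------------------------------------------------------------------------
# density diagnostics
# ---------------------------------------------------------------------------

def kde_density(samples, grid_spec=None, bandwidth=None):
    """Gaussian KDE evaluated on a rectangular grid.

    grid_spec: sequence of (lo, hi, n) per dimension; defaults to the sample
    range extended by three bandwidths, 64 points per axis.  Returns
    (axes, values) where ``values`` has shape (n_1, ..., n_d).
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n, d = samples.shape
    if n < 2:
        raise ValueError("need at least two samples")
    spread = float(np.mean(samples.std(axis=0)))
    if bandwidth is None:
        bandwidth = max(spread * n ** (-1.0 / (d + 4)), 1e-6)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive (degenerate sample set?)")
    if grid_spec is None:
        grid_spec = [(samples[:, j].min() - 3 * bandwidth,
                      samples[:, j].max() + 3 * bandwidth, 64) for j in range(d)]
    axes = [np.linspace(lo, hi, int(m)) for lo, hi, m in grid_spec]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in mesh], axis=1)
    kde = KernelDensity(bandwidth=bandwidth).fit(samples)
    vals = np.exp(kde.score_samples(pts)).reshape([a.size for a in axes])
    return axes, vals


def _l1_on_shared_grid(a, b, bandwidth, grid_n=64):
    both = np.vstack([a, b])
    d = both.shape[1]
    lo = both.min(axis=0) - 3 * bandwidth
    hi = both.max(axis=0) + 3 * bandwidth
    spec = [(lo[j], hi[j], grid_n) for j in range(d)]
    axes, pa = kde_density(a, spec, bandwidth)
    _, pb = kde_density(b, spec, bandwidth)
    cell = np.prod([ax[1] - ax[0] for ax in axes])
    return float(np.sum(np.abs(pa - pb)) * cell)


def marginal_consistency(fwd: TrajectoryEnsemble, bwd: TrajectoryEnsemble,
                         times, bandwidth=None, grid_n=64):
    """L1 distance between forward and backward KDE marginals per time.

    Agreement of the two families of time marginals is the practical
    convergence check of the numerical bridge solution.
    """
    if fwd.times.shape != bwd.times.shape or not np.allclose(fwd.times, bwd.times):
        raise ValueError("ensembles do not share a time grid")
    out = []
    for t in np.atleast_1d(times):
        k = int(np.argmin(np.abs(fwd.times - t)))
        if abs(fwd.times[k] - t) > 1e-9 + 1e-6 * max(1.0, abs(t)):
            raise ValueError(f"time {t} not on the ensemble grid")
        a = fwd.states[:, k]
        b = bwd.states[:, k]
        if bandwidth is None:
            both = np.vstack([a, b])
            n, d = both.shape
            bw = max(float(np.mean(both.std(axis=0))) * n ** (-1.0 / (d + 4)), 1e-6)
        else:
            bw = bandwidth
        out.append(_l1_on_shared_grid(a, b, bw, grid_n))
    return np.array(out)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_model(model: BridgeModel, path, rho0=None, rho1=None):
    """Single-file checkpoint (parameters + config + optional marginals)."""
    if not isinstance(model.z_fwd, ScoreMLP) or not isinstance(model.z_bwd, ScoreMLP):
        raise TypeError("only ScoreMLP-backed models can be checkpointed")
    meta = {
        "T": model.T, "N": model.N,
        "schedule": {"g": model.schedule.g, "kind": model.schedule.kind,
                     "g_end": model.schedule.g_end},
        "drift": model.drift.name,
    }
    if model.noise_scale is not None:
        meta["noise_scale"] = [float(v) for v in model.noise_scale]
    arrays = {"meta": np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)}
    for tag, net in (("fwd", model.z_fwd), ("bwd", model.z_bwd)):
        for k, v in net.state_dict().items():
            arrays[f"{tag}_{k}"] = v
    if rho0 is not None:
        arrays["rho0"] = np.atleast_2d(np.asarray(rho0, float))
    if rho1 is not None:
        arrays["rho1"] = np.atleast_2d(np.asarray(rho1, float))
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path, drift: DriftSpec = None):
    """Inverse of :func:`save_model`; returns (model, rho0, rho1)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        nets = {}
        for tag in ("fwd", "bwd"):
            state = {k.split("_", 1)[1]: data[k] for k in data.files
                     if k.startswith(tag + "_")}
            nets[tag] = ScoreMLP.from_state(state)
        rho0 = data["rho0"] if "rho0" in data.files else None
        rho1 = data["rho1"] if "rho1" in data.files else None
    sched = NoiseSchedule(meta["schedule"]["g"], meta["schedule"]["kind"],
                          meta["schedule"]["g_end"])
    if drift is None:
        if meta["drift"] != "zero":
            raise ValueError(
                f"checkpoint was built with drift {meta['drift']!r}; pass it explicitly")
        drift = ZERO_DRIFT
    model = BridgeModel(drift, sched, nets["fwd"], nets["bwd"],
                        T=meta["T"], N=meta["N"],
                        noise_scale=meta.get("noise_scale"))
    return model, rho0, rho1
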