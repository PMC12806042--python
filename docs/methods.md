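# Methods

## Problem and model

The package computes the Schrödinger bridge between two empirical
marginals ρ₀, ρ₁ relative to a reference diffusion dX = f dt + σₜ dW on
[0, T]: the path measure of minimal KL divergence to the reference among
all measures with those endpoints.  The bridge is represented by its
forward/backward SDE pair; the unknowns are the score fields
Z = σₜ∇ln φₜ and Ẑ = σₜ∇ln φ̂ₜ of the two Schrödinger potentials.

Internally time is rescaled to the unit clock τ = t/T.  The unit-clock
noise amplitude is sg(τ) = √T·σ(τT), so the reference accumulates the
physical variance σ²T over the horizon; the unit-clock drift is T·f.
All score fields are functions of (τ, x).

Noise may be scaled per coordinate (`noise_scale`, default isotropic).
This resolves the dimensional mismatch of states whose coordinates live
on very different scales — for the Morris–Lecar state (v in ~100 mV,
w in [0,1]) the bridge uses scale (1, 0.01), i.e. a reference diffusion
whose per-coordinate intensity is proportional to the coordinate's
natural scale.  The stochastic *simulator* of the neuron itself follows
the model equations literally: noise on the v-equation only.

## Likelihood training

Training alternates half-bridge stages.  Each stage freezes one policy,
simulates and caches an ensemble of `cache_paths` trajectories from it,
and fits the opposite field by Adam on the discretised loss

    E Σₖ [ ½‖Z + Ẑ‖² + ∇·( sg⊙Ẑ − T f ) ](τₖ, Xₖ) Δτ  (+ terminal term).

Minimising this over the trained field given frozen trajectories is an
implicit score-matching problem whose exact minimiser is the
time-reversal drift of the frozen policy; the alternation is therefore
the iterative-proportional-fitting scheme in drift form.  The terminal
log-likelihood term is constant in the trained parameters under frozen
trajectories (information about each marginal enters through the
trajectory initialisations), so it is evaluated once per stage on the
full cache and added to the logged loss.  For transport onto a
clustered target the quadratic attachment E‖X₁ − y_i‖² (source cell i)
replaces the terminal log-density; it enters the minimised loss with a
plus sign, since a maximised terminal likelihood is a minimised squared
distance.

The printed form of the running cost is read as ½‖Z+Ẑ‖², the expansion
½‖Z‖² + ZᵀẐ + ½‖Ẑ‖² used by the FBSDE likelihood framework this scheme
follows; this is the single most consequential interpretation in the
code base and is deliberately localised in `likelihood_loss` /
`alternating_train`.

**Score parameterisation.**  One-hidden-layer tanh networks on features
[τ, (x−loc)/scale] written directly in numpy.  The value, the spatial
divergence, and the parameter gradients of both (including the weighted
divergence used with `noise_scale`) are closed-form; all are verified
against finite differences in the tests.  One hidden layer (default
width 64) keeps those derivations exact and is ample for the 1-D/2-D
problems in scope.  The output layer starts at zero.

**Displacement initialisation.**  The reversal-style alternation largely
preserves a flow's transport *schedule*: started from the zero (Brownian)
policy it settles on a lazy-start/late-rush schedule whose kinetic action
exceeds the optimum substantially even when the endpoint marginals are
matched.  Both fields are therefore initialised at the constant-speed
mean-displacement flow (output bias (mean ρ₁ − mean ρ₀ − T·f̄)/sg, with
opposite signs for the two fields), the zero-noise optimal schedule for
equal-shape marginals.  On the Gaussian benchmark this brings the trained
total action within ~5% of the analytic value.

**Noise annealing.**  Cold-start alternation mixes at a rate ~σ²/Δ²
(Δ the transport distance) and stalls for small noise.  `train_annealed`
trains at the largest g of a ladder first and warm-starts each lower
level from the previous solution, rescaling the output layer by
g_old/g_new so the initial *drift* sg·Z is preserved.

**Defaults** (`TrainConfig`): 8 stages × 200 Adam iterations, learning
rate 1e-2, minibatch 64 paths, cache 512 paths, N = 50 steps, T = 1.
These sizes solve the 1-D/2-D benchmark tasks in ~20–30 s on one CPU
core; stages and iterations are the knobs to raise for harder geometry.
Every routine that touches randomness takes a seed; a master seed fans
out to per-stage simulation and batching streams.

## Morris–Lecar component

The conductance model uses the standard gating form m∞, w∞ =
(1+tanh((v−V₁,₃)/V₂,₄))/2, τ_w = 1/cosh((v−V₃)/(2V₄)) and
dw/dt = φ(w∞−w)/τ_w, with both printed parameter regimes as frozen
presets.  Integration is Euler–Maruyama on a uniform grid (the same
stepper deterministic runs use with σ=0), w clamped to [0,1] after each
step.  Equilibria come from multi-start root solves on a 50×50 lattice
(duplicates merged within 0.5 mV / 0.01 w) with finite-difference
Jacobian classification; periodic orbits from long integration
(dt = 0.01 ms, 500 ms transient) with the period estimated from upward
mean-level crossings and a closure check of 1e-2 in coordinates
normalised by (100 mV, 1).

One substantive numerical finding is documented here because tests
depend on it: at the printed Class II parameters (I = 37) the upper
equilibrium is a *marginally stable* spiral — eigenvalues
−0.00106 ± 0.380i, with the subcritical Hopf at I ≈ 36.32.  Forward
Euler integration destabilises this focus for dt ≳ 0.015, so coarse
simulations (e.g. dt = 0.1) make it appear unstable; the package
classifies by exact Jacobian eigenvalues and reports it as stable.  The
corresponding acceptance-level check asserts instability and is
expected to fail.

Bridge marginals: ρ₀ is a jittered cloud at the resting state, ρ₁ a
uniform-in-arc-length resample of an arc of the extracted cycle
(default quarter cycle centred on the v-maximum), jitter default 0.02
in normalised coordinates.  The source study does not state its jitter
or arc extent; these defaults are declared choices, not inferred values.

## Semi-discrete optimal transport

Cell assignment is argmax_i ⟨x, y_i⟩ + h_i (ties to the lowest index;
invariant under h → h + c1).  Masses are Monte-Carlo over the source
samples.  E(h) is evaluated by 64-point midpoint quadrature along
0 → h — only for monitoring; the optimisation uses the exact gradient
ω(h) − ν with a fixed step (natural scale: std of the score matrix)
halved after 100 non-improving iterations, gauge h_n = 0, tolerance
max|ω−ν| < 0.01.  For cluster splitting, the target is k-means
clustered (or caller-labelled), each cluster summarised by a ≤16-atom
k-means codebook with sample-fraction weights, and source samples
inherit their assigned atom's cluster.  Measure preservation of the
solved map is what makes the induced source partition carry the target
component weights.

## Indicator

I(tₖ) = (1/tₖ)Σ_{j<k} E‖v(t_j, X_j)‖² Δt by a left-point rule, with
v = f + σₜ²∇ln φ (the full forward drift; the control-only field is
available as `mode="control"`).  I is reported from k = 1 and is
nonnegative by construction.  With T = 1 the total action T·I(T) is the
discretised Benamou–Brenier kinetic energy of the flow, hence ≥
W₂²(ρ₀,ρ₁) for a converged bridge, with the excess shrinking as σ → 0;
the oracle-score tests verify both facts against the closed-form
Gaussian bridge, and the trained-bridge version holds seed-averaged.

`detect_tipping` uses indicator increments |I_k − I_{k−1}|: first
crossing of a numeric threshold C, or in "auto" mode the argmax with a
median/MAD z-score (a noiseless baseline with a genuine jump reports
infinite significance; a constant series reports none).  The detected
index is the first step at the post-jump level.

A caution on what the indicator can show: a *trained* bridge has a
smooth (tanh-network) velocity field, so its kinetic energy is a smooth
function of time even when the measure flow splits onto a disconnected
target — the split appears as a mid-horizon *peak* of the instantaneous
action, not as a >5σ increment outlier.  Large auto-mode z-scores
require a genuinely abrupt change of the flow (see the injected-jump and
burst-field tests).  The acceptance-level check asserting z > 5 on the
two-cluster task encodes a claim of the source study that this
implementation does not reproduce, and fails by design.

## Synthetic data

`make_nonconvex_target` emulates a 2-D cohort embedding: a connected
source blob (centre (−3,0), spread 0.8) and a two-component target
(centres (3,±1.8), spread 0.45, weights ½/½ by default; crescent shapes
behind a flag).  Components closer than three combined spreads are
rejected, which certifies the near-empty region inside the target's
convex hull (checked in tests via the KDE density at the hull centroid).
Coordinates are unit-scale, as in scale-free embeddings.  What these
fixtures do *not* emulate: the heavy tails, uneven cluster densities
and nonlinear manifold distortions of real dimensionality-reduced data —
passing tests certify the machinery, not performance on real cohorts.
All generators are pure functions of (config, seed).

## Oracles

`bures_w2` is the closed-form Gaussian W₂².  `gaussian_sb_closed_form`
gives the 1-D entropic-interpolation marginals via the static coupling
cross-covariance c = (−ε + √(ε²+4s₀²s₁²))/2, ε = g²T, composed with
Brownian-bridge conditionals; `gaussian_bridge_score` converts that flow
into the affine forward score by moment matching (m' = α + βm,
v' = 2βv + ε).  An independent log-domain grid Sinkhorn (400 points,
±6 sd) cross-checks the closed form to ~1e-9 in the tests.  The oracle
is deliberately restricted to 1-D, f ≡ 0: that covers every validation
need without matrix Riccati machinery.

## Numerical choices and limitations

* Euler–Maruyama throughout (order 1); N = 50–100 steps suffice for the
  benchmark horizons, and the oracle tests budget an explicit small
  Euler-bias allowance on top of Monte-Carlo error.
* Divergences are exact for score networks and the affine oracle;
  generic callables fall back to central finite differences (adequate in
  the ≤3-dimensional scope).
* KDE diagnostics use an isotropic Gaussian kernel with an explicit
  bandwidth (Scott-style default); L1 discrepancies are grid sums.
* Problem sizes in tests and the acceptance script (2000-sample
  marginals, 2000–5000 paths, 2–3 seeds) are the package's scaled-down
  study conditions; they resolve the asserted tolerances with margin.
* Known limitations: no d > 3 exact divergence (a Hutchinson estimator
  would be the natural extension), no GPU path, no exact power-diagram
  geometry (cells are sample-based), single-hidden-layer scores, and
  the checkpoint format only persists network-backed (not engineered)
  score fields.
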