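"""Action-functional early-warning indicator on two contrasting flows.

The indicator I(t) is the running time-average of the kinetic energy
E||v(t, X_t)||^2 of the bridge's transport velocity.  Compared here on
(a) a smooth unimodal-to-unimodal bridge and (b) a bridge onto a
two-component, non-convex target whose measure flow must split, plus
(c) a constructed series with an injected jump showing what a hard
tipping event looks like to the detector.
"""

import numpy as np

from sbtip import (JumpSeriesConfig, NoiseSchedule, NonconvexConfig,
                   TrainConfig, action_indicator, alternating_train,
                   detect_tipping, make_jump_series, make_nonconvex_target,
                   propagate_forward)

rng = np.random.default_rng(0)
rho0 = -2.0 + np.sqrt(0.1) * rng.standard_normal((1500, 1))
rho1 = 2.0 + np.sqrt(0.1) * rng.standard_normal((1500, 1))

print("--- smooth 1-D bridge ---")
model, _ = alternating_train(TrainConfig(), rho0, rho1,
                             schedule=NoiseSchedule(0.5), seed=0)
ens = propagate_forward(model, rho0, 1500, seed=1)
s = action_indicator(model, ens)
rep = detect_tipping(s, "auto")
print(f"I ranges over [{s.values.min():.2f}, {s.values.max():.2f}]; "
      f"max-increment z-score {rep.zscore:.2f} (no outlying jump)")

print("--- two-cluster (non-convex target) bridge ---")
r0, r1 = make_nonconvex_target(NonconvexConfig(n=1500, seed=0))
model2, _ = alternating_train(TrainConfig(), r0, r1,
                              schedule=NoiseSchedule(0.5), seed=0)
ens2 = propagate_forward(model2, r0, 1500, seed=2)
s2 = action_indicator(model2, ens2)
rep2 = detect_tipping(s2, "auto")
peak = int(np.argmax(s2.a_inst))
print(f"instantaneous action peaks at step {peak}/{model2.N} "
      f"(the splitting phase); z-score of max increment {rep2.zscore:.2f}")

print("--- constructed series with an injected jump ---")
s3 = make_jump_series(JumpSeriesConfig(n=50, jump_index=25, height=4.0,
                                       noise_sd=0.01, seed=3))
rep3 = detect_tipping(s3, "auto")
print(f"tipping detected at step {rep3.index} with z-score {rep3.zscore:.1f}")
print("""
The trained flows are smooth, so their indicator increments carry no
>5-sigma outlier even when the density splits; the splitting instead
shows up as the mid-horizon peak of the instantaneous action.  A genuine
discontinuous change in the measure flow (the injected jump) is flagged
loudly and at the right step.""")
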