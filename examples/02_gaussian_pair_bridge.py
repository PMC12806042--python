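"""Schrödinger bridge between two well-separated 1-D Gaussians.

Trains the forward/backward score pair on samples of N(-2, 0.1) and
N(2, 0.1) with noise g = 0.5 and checks the solution three ways: the
forward flow must land on the target moments, the backward flow on the
source moments, and the two families of time marginals must agree
mid-horizon (the practical convergence certificate of the bridge).
"""

import numpy as np

from sbtip import (NoiseSchedule, TrainConfig, alternating_train,
                   marginal_consistency, propagate_backward,
                   propagate_forward)

rng = np.random.default_rng(0)
rho0 = -2.0 + np.sqrt(0.1) * rng.standard_normal((2000, 1))
rho1 = 2.0 + np.sqrt(0.1) * rng.standard_normal((2000, 1))

model, report = alternating_train(TrainConfig(), rho0, rho1,
                                  schedule=NoiseSchedule(0.5), seed=0)
fwd = propagate_forward(model, rho0, 2000, seed=10)
bwd = propagate_backward(model, rho1, 2000, seed=11)

print(f"forward terminal:  mean {fwd.states[:, -1, 0].mean():+.3f}  "
      f"var {fwd.states[:, -1, 0].var():.3f}   (target +2.000, 0.100)")
print(f"backward terminal: mean {bwd.states[:, 0, 0].mean():+.3f}  "
      f"var {bwd.states[:, 0, 0].var():.3f}   (target -2.000, 0.100)")
l1 = marginal_consistency(fwd, bwd, [0.24, 0.5, 0.76])
for t, d in zip((0.24, 0.5, 0.76), l1):
    print(f"forward/backward L1 discrepancy at t={t}: {d:.3f}")
print(f"final training loss: {report.final_loss:.3f}")
print("""
Small terminal-moment errors show the learned drifts transport each
marginal onto the other; a mid-time L1 well below ~0.3 means the two
SDE representations describe the same evolving density.""")
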