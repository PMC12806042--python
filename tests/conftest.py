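import numpy as np
import pytest

from sbtip import (GaussianSpec, NoiseSchedule, TrainConfig, alternating_train,
                   CLASS_I, CLASS_II)


@pytest.fixture(scope="session")
def gaussian_pair_samples():
    """Seeded samples of the N(-2, 0.1) -> N(2, 0.1) benchmark pair."""
    rng = np.random.default_rng(42)
    rho0 = -2.0 + np.sqrt(0.1) * rng.standard_normal((2000, 1))
    rho1 = 2.0 + np.sqrt(0.1) * rng.standard_normal((2000, 1))
    return rho0, rho1


@pytest.fixture(scope="session")
def gaussian_specs():
    return GaussianSpec([-2.0], [[0.1]]), GaussianSpec([2.0], [[0.1]])


@pytest.fixture(scope="session")
def trained_gaussian_bridge(gaussian_pair_samples):
    """One trained bridge on the benchmark pair (g = 0.5), shared by tests."""
    rho0, rho1 = gaussian_pair_samples
    model, report = alternating_train(TrainConfig(), rho0, rho1,
                                      schedule=NoiseSchedule(0.5), seed=0)
    return model, report


@pytest.fixture(scope="session")
def class_i_equilibrium():
    """Resting state of the Class I regime via an independent Newton solve.

    Hand-rolled damped Newton with finite-difference Jacobian, seeded from
    a coarse lattice; deliberately shares no code with find_equilibria.
    """
    from sbtip import drift

    def newton(s0):
        s = np.array(s0, dtype=float)
        for _ in range(80):
            f = drift(s, CLASS_I)
            if np.linalg.norm(f) < 1e-12:
                break
            J = np.empty((2, 2))
            for j in range(2):
                e = np.zeros(2)
                e[j] = 1e-6
                J[:, j] = (drift(s + e, CLASS_I) - drift(s - e, CLASS_I)) / 2e-6
            try:
                step = np.linalg.solve(J, f)
            except np.linalg.LinAlgError:
                return None
            s = s - np.clip(step, -20, 20)
        return s if np.linalg.norm(drift(s, CLASS_I)) < 1e-10 else None

    roots = []
    for v0 in np.linspace(-70, 40, 12):
        for w0 in np.linspace(0, 1, 6):
            r = newton((v0, w0))
            if r is not None and not any(np.abs(r[0] - q[0]) < 0.5 for q in roots):
                roots.append(r)
    assert roots, "independent Newton found no equilibrium"
    # Class I has a unique equilibrium in the window
    return roots[0]
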