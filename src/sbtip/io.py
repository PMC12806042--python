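"""CSV conventions: marginal samples and trajectory ensembles."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bridge import TrajectoryEnsemble

__all__ = ["save_samples", "load_samples", "save_trajectories", "load_trajectories"]


def save_samples(samples, path, columns=None):
    """Write an (n, d) sample set with columns x1..xd (header required)."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if columns is None:
        columns = [f"x{j + 1}" for j in range(samples.shape[1])]
    pd.DataFrame(samples, columns=list(columns)).to_csv(path, index=False)


def load_samples(path):
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float)


def save_trajectories(ens: TrajectoryEnsemble, path, state_columns=None):
    """Long-format trajectory CSV: path_id, step, t, <state columns>."""
    n, m, d = ens.states.shape
    if state_columns is None:
        state_columns = [f"x{j + 1}" for j in range(d)]
    rec = {
        "path_id": np.repeat(np.arange(n), m),
        "step": np.tile(np.arange(m), n),
        "t": np.tile(ens.times, n),
    }
    flat = ens.states.reshape(n * m, d)
    for j, c in enumerate(state_columns):
        rec[c] = flat[:, j]
    pd.DataFrame(rec).to_csv(path, index=False)


def load_trajectories(path):
    df = pd.read_csv(path)
    n = int(df["path_id"].max()) + 1
    m = int(df["step"].max()) + 1
    state_cols = [c for c in df.columns if c not in ("path_id", "step", "t")]
    df = df.sort_values(["path_id", "step"])
    states = df[state_cols].to_numpy(dtype=float).reshape(n, m, len(state_cols))
    times = df["t"].to_numpy(dtype=float)[:m]
    return TrajectoryEnsemble(states, times)
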