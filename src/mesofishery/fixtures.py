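"""Tiny deterministic fixtures for tests and worked documentation examples.

Everything here is synthetic and generated on demand; nothing is shipped as
data.  The fixtures are hand-checkable: a three-row sample matrix sitting at
the range midpoints and bounds, a five-year baseline trajectory whose first
harvest equals the nominal daily capacity times initial effort, and a small
ensemble table with a planted monotone driver for recovery tests.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import build_space
from .model import simulate
from .params import BioEconParams, GovParams, SimConfig

__all__ = ["midbound_samples", "planted_ensemble", "make_fixtures"]


def midbound_samples() -> pd.DataFrame:
    """Three parameter vectors: range midpoints, lower bounds, upper bounds."""
    space = build_space()
    df = pd.DataFrame([space.midpoint, space.lower, space.upper],
                      columns=space.names,
                      index=pd.Index([0, 1, 2], name="run"))
    return df


def planted_ensemble(n: int = 256, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic sample/outcome pair with one planted driver per outcome.

    ``driven`` is an exact copy of the ``q_day`` column (perfect
    dependence); ``noise`` is independent of every parameter.  Used to check
    that feature scoring recovers planted structure and nothing else.
    """
    space = build_space()
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.uniform(space.lower, space.upper, size=(n, len(space.names))),
        columns=space.names)
    X.index.name = "run"
    y = pd.DataFrame({"driven": X["q_day"].to_numpy(),
                      "noise": rng.normal(size=n)}, index=X.index)
    return X, y


def make_fixtures(out_dir: str | Path) -> list[Path]:
    """Write the fixture files and return their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    samples = midbound_samples()
    p = out / "sample_matrix_midbound.csv"
    samples.to_csv(p)
    written.append(p)

    traj = simulate(BioEconParams(), GovParams(),
                    SimConfig(horizon=5))
    p = out / "trajectory_baseline_5yr.csv"
    traj.to_frame().to_csv(p)
    written.append(p)

    X, y = planted_ensemble()
    p = out / "planted_samples.csv"
    X.to_csv(p)
    written.append(p)
    p = out / "planted_outcomes.csv"
    y.to_csv(p)
    written.append(p)
    return written
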