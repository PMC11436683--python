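"""Uncertainty space and Latin-hypercube experiment design.

This module is the pipeline's data generator: the study has no external
data, its "observations" are parameter vectors drawn uniformly over expert
uncertainty ranges.  Eighteen parameters are sampled (thirteen bio-economic,
five governance); the carbon-injection rate mu, the three pathway fractions
and the C->CO2 conversion are held fixed.  Bounds are generally the baseline
+/- 75% unless the literature constrains them more tightly (e.g. biomass and
carrying capacity are capped at 4.5 Gt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .params import SimConfig

__all__ = [
    "DEFAULT_BOUNDS",
    "UncertaintySpace",
    "SampleMatrix",
    "build_space",
    "lhs_sample",
    "governance_subsets",
    "scenario_overrides",
]

# name -> (lower, upper, units); order fixed for reproducible sampling
DEFAULT_BOUNDS: dict[str, tuple[float, float, str]] = {
    "M0": (1.5, 4.5, "Gt"),
    "K": (1.5, 4.5, "Gt"),
    "r": (0.225, 1.575, "1/yr"),
    "s_r": (25.75, 180.25, "yr"),
    "s_f": (149.75, 1048.25, "yr"),
    "s_m": (212.75, 1489.25, "yr"),
    "c": (18_500.0, 55_500.0, "EUR/day"),
    "q_day": (100.0, 300.0, "t/day"),
    "scc": (38.6, 362.28, "EUR/tCO2"),
    "alpha": (0.1, 1.0, "dimensionless"),
    "gamma": (175.0, 525.0, "EUR/t"),
    "beta": (0.000134, 0.000935, "dimensionless"),
    "X": (1.0, 1.008, "1/yr factor"),
    "Q0": (0.15, 0.45, "1/yr"),
    "FL_effect": (1.0, 2.0, "dimensionless"),
    "pl": (0.1, 0.3, "fraction"),
    "E_effect": (0.2, 0.8, "dimensionless"),
    "el": (0.25, 0.75, "fraction"),
}

#: labels used by :func:`governance_subsets`
HIGH_LOBBY_LOW_CONCERN = "high_lobby_low_concern"
LOW_LOBBY_HIGH_CONCERN = "low_lobby_high_concern"
MIXED = "mixed"


@dataclass
class UncertaintySpace:
    """Ordered box over the sampled parameters."""

    names: list[str]
    lower: np.ndarray
    upper: np.ndarray
    units: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not (len(self.names) == self.lower.size == self.upper.size):
            raise ValueError("names and bounds must align")
        if np.any(self.lower >= self.upper):
            bad = [n for n, lo, up in zip(self.names, self.lower, self.upper)
                   if lo >= up]
            raise ValueError(f"lower >= upper for {bad}")

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lower": self.lower, "upper": self.upper,
                             "units": self.units or ""},
                            index=pd.Index(self.names, name="parameter"))


@dataclass
class SampleMatrix:
    """Latin-hypercube draw: an ``n x d`` table plus its provenance."""

    values: pd.DataFrame
    seed: int
    space: UncertaintySpace

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="run")

    @staticmethod
    def read_csv(path, seed: int = -1,
                 space: Optional[UncertaintySpace] = None) -> "SampleMatrix":
        df = pd.read_csv(path, index_col="run")
        return SampleMatrix(df, seed=seed, space=space or build_space())


def build_space(overrides: Optional[Mapping[str, tuple[float, float]]] = None,
                ) -> UncertaintySpace:
    """Default uncertainty box, with optional per-parameter bound overrides."""
    bounds = dict(DEFAULT_BOUNDS)
    if overrides:
        for name, (lo, up) in overrides.items():
            if name not in bounds:
                raise KeyError(f"unknown parameter {name!r}")
            bounds[name] = (float(lo), float(up), bounds[name][2])
    names = list(bounds)
    return UncertaintySpace(
        names=names,
        lower=np.array([bounds[n][0] for n in names]),
        upper=np.array([bounds[n][1] for n in names]),
        units=[bounds[n][2] for n in names],
    )


def lhs_sample(space: UncertaintySpace, n: int, seed: int) -> SampleMatrix:
    """Stratified-uniform Latin-hypercube draw over the space.

    One stratum per sample and dimension; deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    sampler = qmc.LatinHypercube(d=len(space.names), seed=seed)
    unit = sampler.random(n)
    scaled = qmc.scale(unit, space.lower, space.upper)
    df = pd.DataFrame(scaled, columns=space.names)
    df.index.name = "run"
    return SampleMatrix(values=df, seed=seed, space=space)


def governance_subsets(samples: pd.DataFrame | SampleMatrix,
                       lobby_split: float = 1.5,
                       concern_split: float = 0.5) -> pd.Series:
    """Label each run by its governance quadrant.

    The defaults cut each governance effect at its range midpoint: a run is
    "high lobby / low concern" when the lobby multiplier is at or above 1.5
    AND the concern multiplier is at or above 0.5 (a high multiplier means a
    weak quota reduction, i.e. low concern); the opposite quadrant is "low
    lobby / high concern"; everything else is "mixed".  The three labels
    partition the ensemble.
    """
    df = samples.values if isinstance(samples, SampleMatrix) else samples
    if "FL_effect" not in df or "E_effect" not in df:
        raise KeyError("samples must include FL_effect and E_effect columns")
    fl = df["FL_effect"].to_numpy()
    ee = df["E_effect"].to_numpy()
    labels = np.where((fl >= lobby_split) & (ee >= concern_split),
                      HIGH_LOBBY_LOW_CONCERN,
                      np.where((fl < lobby_split) & (ee < concern_split),
                               LOW_LOBBY_HIGH_CONCERN, MIXED))
    out = pd.Series(labels, index=df.index, name="governance")
    for lab in (HIGH_LOBBY_LOW_CONCERN, LOW_LOBBY_HIGH_CONCERN):
        if not (out == lab).any():
            warnings.warn(f"governance subset {lab!r} is empty", stacklevel=2)
    return out


def scenario_overrides(base_cfg: SimConfig, name: str) -> SimConfig:
    """Named experiment variants of a base configuration.

    ``open`` leaves the config untouched; ``capped20Mt`` limits the yearly
    harvest to 20 million tonnes (the present-day global forage-fish
    capture); ``no_fishing`` disables fishing for the counterfactual.
    """
    if name == "open":
        return base_cfg
    if name == "capped20Mt":
        return base_cfg.replace(harvest_cap=20e6)
    if name == "no_fishing":
        return base_cfg.replace(fishing_enabled=False)
    raise ValueError(f"unknown scenario {name!r}; "
                     "expected one of open, capped20Mt, no_fishing")
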