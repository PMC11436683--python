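"""Parameter containers for the mesopelagic-fishery model.

Three groups of inputs drive a run:

* :class:`BioEconParams` — population, carbon-cycle, and fishery-economics
  constants (biomass pool, logistic growth, catchability, costs, endogenous
  price, social cost of carbon, carbon-injection pathways).
* :class:`GovParams` — quota baseline and the two governance feedbacks
  (industry-lobby uplift and environmental-concern reduction).
* :class:`SimConfig` — horizon, initial effort, optional harvest cap and the
  governance trigger timing.

Defaults are the model's baseline parameterisation; the uncertainty ranges
used for ensemble sampling live in :mod:`mesofishery.design`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

__all__ = ["BioEconParams", "GovParams", "SimConfig"]

_F_SUM_TOL = 1e-9


@dataclass
class BioEconParams:
    """Bio-economic constants for one model run.

    Units: biomass in Gt wet weight, effort in days-at-sea, money in EUR,
    carbon in tonnes C (Gt C at reporting boundaries).
    """

    M0: float = 3.0          # initial mesopelagic biomass, Gt
    K: float = 3.0           # carrying capacity, Gt
    r: float = 0.9           # intrinsic growth rate, 1/yr
    q_day: float = 200.0     # catch per day-at-sea at initial biomass, t/day
    c: float = 37_000.0      # cost of fishing, EUR per day-at-sea
    alpha: float = 0.5       # effort-adjustment factor, dimensionless
    gamma: float = 350.0     # price when harvest = 1 tonne, EUR/t
    beta: float = 0.005345   # price flexibility, dimensionless
    X: float = 1.004         # demand growth factor per year, dimensionless
    scc: float = 162.0       # social cost of carbon, EUR per tonne CO2
    mu: float = 0.77         # carbon injected per year per tonne fish, tC/t/yr
    f_r: float = 0.32        # respiration pathway fraction
    f_f: float = 0.35        # fecal-pellet pathway fraction
    f_m: float = 0.33        # mortality (deadfall) pathway fraction
    s_r: float = 103.0       # sequestration duration, respiration, yr
    s_f: float = 599.0       # sequestration duration, fecal pellets, yr
    s_m: float = 851.0       # sequestration duration, deadfall, yr
    co2_per_c: float = 3.67  # CO2 mass per unit C mass (44/12)

    def __post_init__(self) -> None:
        for fld in fields(self):
            v = getattr(self, fld.name)
            if not v > 0:
                raise ValueError(f"{fld.name} must be strictly positive, got {v!r}")
        if abs(self.f_r + self.f_f + self.f_m - 1.0) > _F_SUM_TOL:
            raise ValueError("pathway fractions f_r + f_f + f_m must sum to 1")
        for name in ("s_r", "s_f", "s_m"):
            if getattr(self, name) <= 1.0:
                raise ValueError(
                    f"{name} must exceed 1 yr (decay fraction 1/s would be >= 100%)"
                )

    def replace(self, **kw) -> "BioEconParams":
        return replace(self, **kw)


@dataclass
class GovParams:
    """Quota baseline and governance-feedback constants."""

    Q0: float = 0.3          # proposed quota rate, fraction of biomass per yr
    FL_effect: float = 1.2   # lobby multiplier on quota when triggered (>= 1)
    pl: float = 0.2          # profit-ratio threshold triggering the lobby
    E_effect: float = 0.8    # environmental-concern multiplier (<= 1)
    el: float = 0.5          # fraction of baseline injection triggering concern

    def __post_init__(self) -> None:
        if not 0 < self.Q0 < 1:
            raise ValueError(f"Q0 must lie in (0, 1), got {self.Q0!r}")
        if self.FL_effect < 1:
            raise ValueError("FL_effect must be >= 1")
        if not 0 < self.E_effect <= 1:
            raise ValueError("E_effect must lie in (0, 1]")
        if not 0 < self.el < 1:
            raise ValueError("el must lie in (0, 1)")
        if not self.pl > 0:
            raise ValueError("pl must be positive")

    def replace(self, **kw) -> "GovParams":
        return replace(self, **kw)


@dataclass
class SimConfig:
    """Run-level configuration shared by all parameter vectors."""

    horizon: int = 50              # yearly steps
    E0: float = 1.0                # initial effort, days-at-sea
    harvest_cap: Optional[float] = None   # absolute yearly ceiling, tonnes
    trigger_grace: int = 5         # years with governance triggers off
    baseline_year: int = 5         # reference year for the concern baseline
    fishing_enabled: bool = True

    def __post_init__(self) -> None:
        if not self.horizon >= self.baseline_year >= 1:
            raise ValueError("require horizon >= baseline_year >= 1")
        if self.E0 < 0:
            raise ValueError("E0 must be nonnegative")
        if self.harvest_cap is not None and self.harvest_cap <= 0:
            raise ValueError("harvest_cap must be positive when set")

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)
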