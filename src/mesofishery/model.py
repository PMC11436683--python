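"""Coupled yearly difference-equation model of a mesopelagic fishery.

The system couples five pieces, stepped on a yearly grid:

* a Gordon-Schaefer surplus-production biomass pool
  ``M[t+1] = M[t] + r M[t] (1 - M[t]/K) - H[t]``;
* harvest proportional to effort and stock, ``H = q E M``, capped by the
  quota, an optional absolute ceiling, and the stock itself;
* open-access effort dynamics, effort rising with profit (expressed in
  day-at-sea equivalents) but frozen whenever the catch is quota-limited;
* an endogenous price ``p = X**t * gamma * H**(-beta)`` falling in supply
  and drifting up with demand;
* three decaying carbon stocks fed by the standing biomass (respiration,
  fecal pellets, deadfall), each ``C_i[t+1] = M mu f_i + C_i (1 - 1/s_i)``.

Governance closes the loop: the yearly quota is ``Q0 * FL * Egov * M`` where
the lobby multiplier ``FL`` kicks in when the profit-to-cost ratio of the
previous year exceeds a threshold, and the concern multiplier ``Egov`` kicks
in when yearly carbon injection falls below a fraction of its early-run
baseline.

All update functions are elementwise over numpy arrays, so a whole
Latin-hypercube ensemble is stepped as one vectorised run.  Internal units
are tonnes, EUR and days-at-sea; biomass and carbon are converted to Gt at
the reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .params import BioEconParams, GovParams, SimConfig

__all__ = [
    "Trajectory",
    "PairedResult",
    "update_biomass",
    "compute_harvest",
    "compute_price",
    "compute_profit",
    "update_effort",
    "update_carbon",
    "compute_quota",
    "simulate",
    "simulate_batch",
    "run_paired",
    "run_paired_batch",
]

GT = 1e9  # tonnes per Gt

# names a sample matrix may override; everything else is held fixed
SAMPLED_BIO = ("M0", "K", "r", "q_day", "c", "alpha", "gamma", "beta", "X",
               "scc", "s_r", "s_f", "s_m")
SAMPLED_GOV = ("Q0", "FL_effect", "pl", "E_effect", "el")
FIXED_BIO = ("mu", "f_r", "f_f", "f_m", "co2_per_c")


# ---------------------------------------------------------------------------
# elementwise state updates


def update_biomass(M, r, K, H):
    """Logistic surplus production less harvest, floored at zero.

    All arguments in consistent biomass units (tonnes internally, but the
    equation is unit-agnostic as long as M, K and H agree).
    """
    M, r, K, H = map(np.asarray, (M, r, K, H))
    if np.any(M < 0) or np.any(K <= 0) or np.any(H < 0) or np.any(r < 0):
        raise ValueError("update_biomass requires M, H, r >= 0 and K > 0")
    return np.maximum(0.0, M + M * r * (1.0 - M / K) - H)


def compute_harvest(E, M, q_coef, quota, cap=None):
    """Yearly harvest in tonnes: ``q_coef * E * M`` subject to ceilings.

    ``q_coef`` is the catchability per day-at-sea per tonne of stock,
    normalised so that one day at sea at the initial biomass catches the
    nominal daily capacity (``q_coef = q_day / M0_tonnes``).  The harvest is
    additionally limited by the quota, an optional absolute cap, and 99% of
    the standing stock (numerical guard against negative biomass).
    """
    E, M = np.asarray(E), np.asarray(M)
    if np.any(E < 0) or np.any(M < 0):
        raise ValueError("effort and biomass must be nonnegative")
    H = q_coef * E * M
    H = np.minimum(H, quota)
    if cap is not None:
        H = np.minimum(H, cap)
    return np.minimum(H, 0.99 * M)


def compute_price(H, t, gamma, beta, X):
    """Endogenous price, EUR/tonne: ``X**t * gamma * H**(-beta)``.

    The demand modifier compounds geometrically over the run.  At ``H = 0``
    the power law is undefined; the price is set to its scale ``X**t*gamma``
    (no trade occurs at zero harvest, so the value is only a record).
    """
    H = np.asarray(H, dtype=float)
    scale = X ** t * gamma
    with np.errstate(divide="ignore"):
        p = scale * np.where(H > 0, H, 1.0) ** (-np.asarray(beta))
    return np.where(H > 0, p, scale)


def compute_profit(p, H, c, E):
    """Fishery profit, EUR/yr: revenue ``p*H`` minus cost ``c*E``."""
    return np.asarray(p) * np.asarray(H) - np.asarray(c) * np.asarray(E)


def update_effort(E, profit, c, alpha, H, quota):
    """Effort adjustment: ``E + alpha * profit / c``, floored at zero.

    Profit is converted to day-at-sea equivalents by the daily cost, keeping
    alpha dimensionless.  When the harvest is quota-limited (H >= quota)
    effort may not increase — positive increments are clipped to zero;
    decreases always pass.
    """
    E = np.asarray(E, dtype=float)
    dE = np.asarray(alpha) * np.asarray(profit) / np.asarray(c)
    dE = np.where(np.asarray(H) >= np.asarray(quota), np.minimum(dE, 0.0), dE)
    return np.maximum(0.0, E + dE)


def update_carbon(M, C_r, C_f, C_m, mu, f_r, f_f, f_m, s_r, s_f, s_m):
    """One-year update of the three sequestered-carbon stocks.

    Each pathway stock gains ``M * mu * f_i`` (injection from the standing
    biomass) and loses the fraction ``1/s_i`` (remineralisation after the
    pathway's expected residence time).  Returns the three pathway stocks
    and their total.
    """
    inj = np.asarray(M) * mu
    C_r = inj * f_r + np.asarray(C_r) * (1.0 - 1.0 / np.asarray(s_r))
    C_f = inj * f_f + np.asarray(C_f) * (1.0 - 1.0 / np.asarray(s_f))
    C_m = inj * f_m + np.asarray(C_m) * (1.0 - 1.0 / np.asarray(s_m))
    return C_r, C_f, C_m, C_r + C_f + C_m


def compute_quota(M, prev_profit, c, prev_E, prev_inject, baseline_inject,
                  Q0, FL_effect, pl, E_effect, el, t, cfg: SimConfig):
    """Yearly quota in tonnes, with lobby and concern multipliers.

    ``quota = Q0 * FL * Egov * M`` where both multipliers are evaluated on
    the *previous* year's state (no simultaneity) and are forced to their
    identity value during the first ``cfg.trigger_grace`` years.  The lobby
    fires when last year's profit-to-cost ratio exceeded ``pl``; the concern
    effect fires when last year's carbon injection fell below ``el`` times
    the baseline-year injection.  Returns ``(quota, lobby_on, concern_on)``.
    """
    M = np.asarray(M, dtype=float)
    if t < cfg.trigger_grace or baseline_inject is None:
        lobby = np.zeros(M.shape, dtype=bool)
        concern = np.zeros(M.shape, dtype=bool)
    else:
        prev_E = np.asarray(prev_E, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(prev_E > 0,
                             np.asarray(prev_profit) / (np.asarray(c) * prev_E),
                             0.0)
        lobby = ratio > np.asarray(pl)
        concern = np.asarray(prev_inject) < np.asarray(el) * np.asarray(baseline_inject)
    FL = np.where(lobby, FL_effect, 1.0)
    Egov = np.where(concern, E_effect, 1.0)
    return Q0 * FL * Egov * M, lobby, concern


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Yearly time series of one run (or a batch of runs stacked on axis 1).

    States (``M``, ``E``, carbon stocks) have ``horizon + 1`` entries; flows
    (harvest, quota, price, profit, trigger flags) have ``horizon``, recorded
    at the year in which they occur.  Biomass and carbon in Gt; harvest and
    quota in tonnes/yr; price EUR/t; profit EUR/yr; effort days-at-sea.
    """

    M: np.ndarray
    E: np.ndarray
    H: np.ndarray
    quota: np.ndarray
    p: np.ndarray
    profit: np.ndarray
    C_r: np.ndarray
    C_f: np.ndarray
    C_m: np.ndarray
    C_total: np.ndarray
    lobby_active: np.ndarray
    concern_active: np.ndarray

    @property
    def horizon(self) -> int:
        return self.H.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Year-indexed table; flow columns are NaN in the terminal year."""
        if self.M.ndim != 1:
            raise ValueError("to_frame applies to single-run trajectories")
        T = self.horizon
        pad = lambda a: np.append(a.astype(float), np.nan)
        return pd.DataFrame(
            {
                "M_Gt": self.M,
                "E_days": self.E,
                "H_t": pad(self.H),
                "quota_t": pad(self.quota),
                "p_eur_per_t": pad(self.p),
                "profit_eur": pad(self.profit),
                "C_r_GtC": self.C_r,
                "C_f_GtC": self.C_f,
                "C_m_GtC": self.C_m,
                "C_total_GtC": self.C_total,
                "lobby_active": pad(self.lobby_active),
                "concern_active": pad(self.concern_active),
            },
            index=pd.RangeIndex(T + 1, name="year"),
        )


@dataclass
class PairedResult:
    """Fished and unfished runs of one parameter vector, monetised.

    ``seq_loss_C`` is the end-of-horizon difference in total sequestered
    carbon (Gt C); ``social_cost_cum`` converts it to EUR via the CO2 mass
    ratio and the social cost of carbon; ``social_cost_final_year`` is the
    last yearly increment of that cumulative cost (EUR/yr).
    """

    fished: Trajectory
    unfished: Trajectory
    seq_loss_C: float | np.ndarray
    social_cost_cum: float | np.ndarray
    social_cost_final_year: float | np.ndarray
    social_cost_series: np.ndarray  # cumulative EUR, per year


# ---------------------------------------------------------------------------
# simulation engine


def _broadcast_params(bio: BioEconParams, gov: GovParams,
                      overrides: Optional[Mapping[str, np.ndarray]] = None,
                      n: int = 1) -> dict:
    """Assemble a name -> array dict of all model constants for a batch."""
    p = {}
    for name in SAMPLED_BIO + FIXED_BIO:
        p[name] = np.full(n, getattr(bio, name), dtype=float)
    for name in SAMPLED_GOV:
        p[name] = np.full(n, getattr(gov, name), dtype=float)
    if overrides:
        for name, col in overrides.items():
            if name not in p:
                raise KeyError(f"unknown parameter {name!r}")
            if name in FIXED_BIO:
                raise ValueError(f"{name} is fixed and may not be sampled")
            arr = np.asarray(col, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"override {name!r} must have shape ({n},)")
            p[name] = arr
    return p


def _simulate(p: dict, cfg: SimConfig) -> Trajectory:
    """Vectorised core loop over a parameter dict of equal-length arrays."""
    n = p["M0"].shape[0]
    T = cfg.horizon
    M0_t = p["M0"] * GT
    K_t = p["K"] * GT
    q_coef = p["q_day"] / M0_t

    M = np.empty((T + 1, n)); E = np.empty((T + 1, n))
    C_r = np.zeros((T + 1, n)); C_f = np.zeros((T + 1, n))
    C_m = np.zeros((T + 1, n)); C_tot = np.zeros((T + 1, n))
    H = np.empty((T, n)); quota = np.empty((T, n))
    price = np.empty((T, n)); profit = np.empty((T, n))
    lobby = np.zeros((T, n), dtype=bool); concern = np.zeros((T, n), dtype=bool)

    M[0] = M0_t
    E[0] = cfg.E0 if cfg.fishing_enabled else 0.0
    baseline_inject = None

    for t in range(T):
        if t == cfg.baseline_year:
            baseline_inject = M[t] * p["mu"]
        prev_profit = profit[t - 1] if t > 0 else np.zeros(n)
        prev_E = E[t - 1] if t > 0 else np.zeros(n)
        prev_inject = M[t - 1] * p["mu"] if t > 0 else M[0] * p["mu"]
        quota[t], lobby[t], concern[t] = compute_quota(
            M[t], prev_profit, p["c"], prev_E, prev_inject, baseline_inject,
            p["Q0"], p["FL_effect"], p["pl"], p["E_effect"], p["el"], t, cfg)
        if cfg.fishing_enabled:
            H[t] = compute_harvest(E[t], M[t], q_coef, quota[t], cfg.harvest_cap)
        else:
            H[t] = 0.0
        price[t] = compute_price(H[t], t, p["gamma"], p["beta"], p["X"])
        profit[t] = compute_profit(price[t], H[t], p["c"], E[t])
        if cfg.fishing_enabled:
            E[t + 1] = update_effort(E[t], profit[t], p["c"], p["alpha"],
                                     H[t], quota[t])
        else:
            E[t + 1] = 0.0
        M[t + 1] = update_biomass(M[t], p["r"], K_t, H[t])
        C_r[t + 1], C_f[t + 1], C_m[t + 1], C_tot[t + 1] = update_carbon(
            M[t], C_r[t], C_f[t], C_m[t], p["mu"],
            p["f_r"], p["f_f"], p["f_m"], p["s_r"], p["s_f"], p["s_m"])

    return Trajectory(M=M / GT, E=E, H=H, quota=quota, p=price, profit=profit,
                      C_r=C_r / GT, C_f=C_f / GT, C_m=C_m / GT,
                      C_total=C_tot / GT, lobby_active=lobby,
                      concern_active=concern)


def _squeeze(traj: Trajectory) -> Trajectory:
    return Trajectory(**{k: getattr(traj, k)[:, 0] for k in traj.__dataclass_fields__})


def simulate(bio: BioEconParams, gov: GovParams, cfg: Optional[SimConfig] = None,
             ) -> Trajectory:
    """Run one parameter vector for ``cfg.horizon`` years.

    Deterministic: a run is a pure function of its parameters (all
    randomness in the pipeline lives in the ensemble sampler).
    """
    cfg = cfg or SimConfig()
    return _squeeze(_simulate(_broadcast_params(bio, gov, n=1), cfg))


def simulate_batch(samples: pd.DataFrame, cfg: Optional[SimConfig] = None,
                   bio: Optional[BioEconParams] = None,
                   gov: Optional[GovParams] = None) -> Trajectory:
    """Run every row of a sample matrix in one vectorised sweep.

    ``samples`` columns override the baseline constants row-wise; missing
    parameters are held at their baseline values, fixed parameters (mu,
    pathway fractions, CO2 conversion) may not appear.  Returns a batch
    Trajectory whose arrays have shape ``(time, n_rows)``.
    """
    cfg = cfg or SimConfig()
    bio = bio or BioEconParams()
    gov = gov or GovParams()
    n = len(samples)
    if n == 0:
        raise ValueError("sample matrix is empty")
    overrides = {c: samples[c].to_numpy() for c in samples.columns}
    return _simulate(_broadcast_params(bio, gov, overrides, n=n), cfg)


def _pair(fished: Trajectory, unfished: Trajectory, scc, co2_per_c) -> PairedResult:
    loss_series = (unfished.C_total - fished.C_total)  # Gt C, per year
    cost_series = loss_series * GT * co2_per_c * scc   # EUR, cumulative
    seq_loss = loss_series[-1]
    cum = cost_series[-1]
    final_year = cost_series[-1] - cost_series[-2]
    return PairedResult(fished=fished, unfished=unfished, seq_loss_C=seq_loss,
                        social_cost_cum=cum, social_cost_final_year=final_year,
                        social_cost_series=cost_series)


def run_paired(bio: BioEconParams, gov: GovParams,
               cfg: Optional[SimConfig] = None) -> PairedResult:
    """Fished run plus no-fishing counterfactual on one parameter vector.

    The counterfactual holds effort at zero; the monetised climate impact is
    the end-of-horizon difference in total sequestered carbon times the CO2
    conversion and the social cost of carbon.
    """
    cfg = cfg or SimConfig()
    fished = simulate(bio, gov, cfg)
    unfished = simulate(bio, gov, cfg.replace(fishing_enabled=False))
    return _pair(fished, unfished, bio.scc, bio.co2_per_c)


def run_paired_batch(samples: pd.DataFrame, cfg: Optional[SimConfig] = None,
                     bio: Optional[BioEconParams] = None,
                     gov: Optional[GovParams] = None) -> PairedResult:
    """Paired fished/unfished counterfactuals for a whole sample matrix."""
    cfg = cfg or SimConfig()
    bio = bio or BioEconParams()
    fished = simulate_batch(samples, cfg, bio, gov)
    unfished = simulate_batch(samples, cfg.replace(fishing_enabled=False), bio, gov)
    scc = samples["scc"].to_numpy() if "scc" in samples else bio.scc
    return _pair(fished, unfished, scc, bio.co2_per_c)
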