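"""Ensemble execution, summary statistics, feature scoring and
worst-case scenario discovery.

Each sampled parameter vector is run twice — with fishing and as a
no-fishing counterfactual — and reduced to a row of scalar outcomes.  On
top of the outcome table the module provides the study's analyses: median /
IQR summaries with optional grouping, extremely-randomised-trees feature
importances that attribute each outcome to the sampled uncertainties, a
quantile filter that flags jointly-bad runs (low catch, low biomass, low
sequestration), and the comparison of governance quadrants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor

from .design import SampleMatrix
from .model import run_paired_batch
from .params import BioEconParams, GovParams, SimConfig

__all__ = [
    "OUTCOME_COLUMNS",
    "WorstCaseSet",
    "run_ensemble",
    "summarize",
    "fraction_where",
    "feature_scores",
    "worst_case",
    "governance_compare",
]

OUTCOME_COLUMNS = (
    "biomass_final_Gt",        # fished end-of-horizon biomass
    "biomass_unfished_Gt",     # counterfactual end-of-horizon biomass
    "catch_final_Gt",          # final-year harvest, Gt/yr
    "catch_median_Gt",         # median yearly harvest over the run
    "catch_total_Gt",          # cumulative harvest over the horizon
    "sequestration_final_GtC",     # fished end-of-horizon carbon stock
    "sequestration_unfished_GtC",  # counterfactual carbon stock
    "social_cost_cum_eur",     # cumulative monetised sequestration loss
    "social_cost_final_year_eur",  # last yearly increment of that loss
    "profit_final_eur",
    "effort_final_days",
)

#: default outcomes scored against the uncertainties
SCORED_OUTCOMES = ("biomass_final_Gt", "catch_final_Gt",
                   "sequestration_final_GtC", "social_cost_cum_eur",
                   "profit_final_eur")


def run_ensemble(samples: SampleMatrix | pd.DataFrame,
                 cfg: Optional[SimConfig] = None,
                 bio: Optional[BioEconParams] = None,
                 gov: Optional[GovParams] = None) -> pd.DataFrame:
    """Paired fished/unfished run per sample row, reduced to scalars.

    The whole matrix is stepped as one vectorised batch, so the result is
    identical however the rows would be chunked.  Any non-finite outcome
    aborts with the offending rows reported.
    """
    df = samples.values if isinstance(samples, SampleMatrix) else samples
    pr = run_paired_batch(df, cfg=cfg, bio=bio, gov=gov)
    f, u = pr.fished, pr.unfished
    out = pd.DataFrame(
        {
            "biomass_final_Gt": f.M[-1],
            "biomass_unfished_Gt": u.M[-1],
            "catch_final_Gt": f.H[-1] / 1e9,
            "catch_median_Gt": np.median(f.H, axis=0) / 1e9,
            "catch_total_Gt": f.H.sum(axis=0) / 1e9,
            "sequestration_final_GtC": f.C_total[-1],
            "sequestration_unfished_GtC": u.C_total[-1],
            "social_cost_cum_eur": np.asarray(pr.social_cost_cum),
            "social_cost_final_year_eur": np.asarray(pr.social_cost_final_year),
            "profit_final_eur": f.profit[-1],
            "effort_final_days": f.E[-1],
        },
        index=df.index,
    )
    bad = ~np.isfinite(out.to_numpy()).all(axis=1)
    if bad.any():
        raise FloatingPointError(
            f"non-finite outcomes for runs {list(out.index[bad][:10])}; "
            f"offending parameter vectors:\n{df.loc[out.index[bad]].head()}")
    return out


def summarize(ensemble: pd.DataFrame, outcome: str,
              labels: Optional[pd.Series] = None) -> pd.DataFrame:
    """Median, quartiles and IQR of one outcome, optionally per group.

    Quartiles use linear interpolation (numpy default), fixed here so that
    reported IQRs are stable across versions.
    """
    if outcome not in ensemble:
        raise KeyError(f"unknown outcome {outcome!r}")

    def _stats(x: pd.Series) -> pd.Series:
        v = x.to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
        return pd.Series({"n": len(v), "median": med, "q1": q1, "q3": q3,
                          "iqr": q3 - q1, "mean": v.mean(), "max": v.max()})

    if labels is None:
        return _stats(ensemble[outcome]).to_frame(outcome).T
    return (ensemble[outcome].groupby(labels.loc[ensemble.index])
            .apply(_stats).unstack())


def fraction_where(ensemble: pd.DataFrame, outcome: str, op: str,
                   threshold: float) -> float:
    """Share of runs whose outcome satisfies the predicate, e.g. profit <= 0."""
    col = ensemble[outcome].to_numpy(dtype=float)
    ops = {"le": np.less_equal, "lt": np.less,
           "ge": np.greater_equal, "gt": np.greater}
    return float(ops[op](col, threshold).mean())


def feature_scores(samples: SampleMatrix | pd.DataFrame,
                   ensemble: pd.DataFrame,
                   outcomes: Sequence[str] = SCORED_OUTCOMES,
                   seed: int = 0, n_estimators: int = 250) -> pd.DataFrame:
    """Extra-trees importance of every sampled parameter for each outcome.

    Fits an extremely-randomised-trees regressor of the outcome on the
    sample matrix and reports normalised impurity importances; each row is
    nonnegative and sums to one.  A constant outcome carries no signal and
    yields uniform scores with a warning.
    """
    X = samples.values if isinstance(samples, SampleMatrix) else samples
    rows = {}
    for i, outcome in enumerate(outcomes):
        y = ensemble[outcome].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            warnings.warn(f"outcome {outcome!r} is constant; "
                          "feature scores set uniform", stacklevel=2)
            rows[outcome] = np.full(X.shape[1], 1.0 / X.shape[1])
            continue
        est = ExtraTreesRegressor(n_estimators=n_estimators,
                                  random_state=(seed + i) % 2**31, n_jobs=1)
        est.fit(X.to_numpy(), y)
        imp = est.feature_importances_
        rows[outcome] = imp / imp.sum()
    return pd.DataFrame(rows, index=X.columns).T


@dataclass
class WorstCaseSet:
    """Runs flagged as jointly bad, with the thresholds that cut them."""

    mask: pd.Series              # True where flagged
    triples: pd.DataFrame        # (biomass, sequestration, catch) of flagged runs
    thresholds: dict[str, float]
    quantile: float
    mode: str                    # "intersection" or "union"

    @property
    def index(self) -> pd.Index:
        return self.mask.index[self.mask]


def worst_case(ensemble: pd.DataFrame, quantile: float = 0.1,
               mode: str = "intersection") -> WorstCaseSet:
    """Flag runs in the lowest tail of catch, biomass and sequestration.

    The default flags runs simultaneously below the ``quantile`` cut of
    cumulative catch, final biomass and end-of-horizon sequestration; the
    relaxed ``union`` mode flags runs bad on any one axis.  An empty
    intersection falls back to the union with a warning.
    """
    if not 0 < quantile < 0.5:
        raise ValueError("quantile must lie in (0, 0.5)")
    if mode not in ("intersection", "union"):
        raise ValueError("mode must be 'intersection' or 'union'")
    cols = {"catch_total_Gt": "catch", "biomass_final_Gt": "biomass",
            "sequestration_final_GtC": "sequestration"}
    cuts = {c: float(np.percentile(ensemble[c].to_numpy(), 100 * quantile,
                                   method="linear")) for c in cols}
    below = pd.DataFrame({c: ensemble[c] <= cuts[c] for c in cols})
    flagged = below.all(axis=1) if mode == "intersection" else below.any(axis=1)
    if mode == "intersection" and not flagged.any():
        warnings.warn("empty worst-case intersection; falling back to union",
                      stacklevel=2)
        mode, flagged = "union", below.any(axis=1)
    triples = ensemble.loc[flagged, list(cols)].rename(columns=cols)
    return WorstCaseSet(mask=flagged, triples=triples, thresholds=cuts,
                        quantile=quantile, mode=mode)


def governance_compare(ensemble: pd.DataFrame, labels: pd.Series,
                       outcomes: Iterable[str] = ("catch_final_Gt",
                                                  "biomass_final_Gt",
                                                  "social_cost_cum_eur"),
                       ) -> dict[str, pd.DataFrame]:
    """Per-quadrant summaries of the governance-sensitive outcomes.

    Group maxima are included but should be read with care: the outcome
    distributions are heavy-tailed and single extreme draws dominate them.
    """
    return {o: summarize(ensemble, o, labels) for o in outcomes}
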