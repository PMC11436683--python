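"""Headline statistics of the full study pipeline.

One call chains the whole analysis — Latin-hypercube draw, paired open and
capped ensembles, governance quadrants, feature scoring, worst-case
discovery — and reduces it to the scalar statistics the study reports.
"""

from __future__ import annotations

from typing import Any, Optional

import numpy as np

from .config import stage_seed
from .design import (HIGH_LOBBY_LOW_CONCERN, LOW_LOBBY_HIGH_CONCERN,
                     build_space, governance_subsets, lhs_sample,
                     scenario_overrides)
from .ensemble import (feature_scores, fraction_where, run_ensemble,
                       summarize, worst_case)
from .params import SimConfig

__all__ = ["headline_report"]


def headline_report(n: int, seed: int, cfg: Optional[SimConfig] = None,
                    with_feature_scores: bool = True,
                    score_rows: Optional[int] = None,
                    worst_case_quantile: float = 0.1) -> dict[str, Any]:
    """Run the study at size ``n`` and return its headline statistics.

    All randomness derives from ``seed`` (split deterministically between
    the sampler and the tree ensembles).  ``score_rows`` optionally caps the
    number of rows fed to the extra-trees scorer, which dominates runtime at
    large ``n``; the simulation statistics always use all ``n`` rows.
    """
    cfg = cfg or SimConfig()
    space = build_space()
    samples = lhs_sample(space, n, stage_seed(seed, "sampling"))
    open_ens = run_ensemble(samples, cfg)
    capped_ens = run_ensemble(samples, scenario_overrides(cfg, "capped20Mt"))
    labels = governance_subsets(samples)

    hi = labels == HIGH_LOBBY_LOW_CONCERN
    lo = labels == LOW_LOBBY_HIGH_CONCERN
    med = lambda col: float(np.median(col.to_numpy()))

    report: dict[str, Any] = {
        "n": n,
        "seed": seed,
        "median_biomass_fished_Gt": med(open_ens.biomass_final_Gt),
        "iqr_biomass_fished_Gt": float(
            summarize(open_ens, "biomass_final_Gt")["iqr"].iloc[0]),
        "median_biomass_unfished_Gt": med(open_ens.biomass_unfished_Gt),
        "median_catch_final_Gt": med(open_ens.catch_final_Gt),
        "median_sequestration_GtC": med(open_ens.sequestration_final_GtC),
        "median_social_cost_cum_trillion_eur": med(
            open_ens.social_cost_cum_eur) / 1e12,
        "median_profit_final_million_eur": med(open_ens.profit_final_eur) / 1e6,
        "fraction_unprofitable": fraction_where(
            open_ens, "profit_final_eur", "le", 0.0),
        "capped_median_catch_Mt": med(capped_ens.catch_final_Gt) * 1e3,
        "capped_mean_catch_Mt": float(
            capped_ens.catch_final_Gt.mean()) * 1e3,
        "capped_median_social_cost_final_year_million_eur": med(
            capped_ens.social_cost_final_year_eur) / 1e6,
        "gov_high_lobby_median_biomass_Gt": med(
            open_ens.biomass_final_Gt[hi]),
        "gov_high_concern_median_biomass_Gt": med(
            open_ens.biomass_final_Gt[lo]),
        "gov_high_lobby_median_catch_Gt": med(open_ens.catch_final_Gt[hi]),
        "gov_high_concern_median_catch_Gt": med(open_ens.catch_final_Gt[lo]),
        "gov_high_lobby_median_social_cost_trillion_eur": med(
            open_ens.social_cost_cum_eur[hi]) / 1e12,
        "gov_high_concern_median_social_cost_trillion_eur": med(
            open_ens.social_cost_cum_eur[lo]) / 1e12,
    }

    wc = worst_case(open_ens, worst_case_quantile)
    report["worst_case_n_flagged"] = int(wc.mask.sum())
    report["worst_case_median_K_Gt"] = float(
        samples.values.loc[wc.index, "K"].median()) if wc.mask.any() else None

    if with_feature_scores:
        rows = min(n, score_rows) if score_rows else n
        fs = feature_scores(samples.values.iloc[:rows],
                            open_ens.iloc[:rows],
                            seed=stage_seed(seed, "trees"))
        report["feature_scores"] = {
            o: fs.loc[o].sort_values(ascending=False).round(4).to_dict()
            for o in fs.index
        }
    return report
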