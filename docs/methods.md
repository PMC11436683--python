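# Methods

## Scope and intent

`mesofishery` is a stylised global model: one biomass pool, one fleet, one
market, yearly steps, no space, no age structure, no food web. Its purpose
is not prediction but exploration — propagating wide parameter uncertainty
through a coherent bioeconomic structure to see which uncertainties drive
which outcomes and which corners of the space produce outcomes worth
avoiding. Every result in the package is an ensemble statistic over that
uncertainty space, not a forecast.

## The coupled model

State: biomass `M` (tonnes internally, Gt at I/O), effort `E` (vessel
days-at-sea), three carbon stocks `C_r, C_f, C_m` (tonnes C). One year is
stepped in a fixed order: (1) quota from last year's triggers, (2) harvest,
(3) price, (4) profit, (5) next year's effort, (6) next year's biomass,
(7) carbon stocks fed by this year's biomass. Flows are recorded in the
year they occur; states have horizon+1 entries.

* **Biomass** — logistic surplus production minus harvest, floored at 0.
  Extinction is absorbing.
* **Harvest** — `q_coef·E·M`, limited by the quota, by an optional absolute
  cap (20 Mt/yr in the capped experiment), and by 99% of the standing stock
  (numerical guard). `q_coef = q_day / M0`: the printed catch-per-day
  (200 t at baseline) is the catch of one day at sea at the *initial*
  biomass, scaling proportionally with the stock thereafter. This
  normalisation reconciles a per-day capacity with a catchability
  coefficient in one constant.
* **Price** — `p = X^t·γ·H^(−β)`. The demand modifier `X` (1.004/yr
  baseline) compounds geometrically: a constant one-off factor of 1.004
  would be economically inert, whereas the multi-decade demand trend it
  represents is not. A config toggle records this choice in every manifest.
  At `H = 0` the price is reported at its scale `X^t·γ`; no trade occurs.
* **Effort** — `ΔE = α·π/c`, profit converted into day-at-sea equivalents
  by the daily cost so that α stays dimensionless on its 0.1–1 range.
  Adding raw currency to days (the naive reading) makes effort jump by tens
  of thousands of days in the first profitable year and then boom-bust to
  zero; converting by `c` preserves the sign structure and the `π = 0`
  fixed point while keeping the adjustment on the fleet's own scale.
  Effort may not increase while the catch is at or above quota; decreases
  always pass; effort floors at 0. Initial effort is 1 day-at-sea — "near
  zero" (a 200 t year-0 catch against a 3 Gt stock) yet enough for
  profit-driven growth to compound.
* **Carbon** — each pathway stock gains `M·μ·f_i` and decays by `1/s_i`
  per year. With constant biomass the stock converges to `M·μ·f_i·s_i`
  (closed form used as a test oracle). Stocks start at zero: reported
  "total sequestration" is the end-of-horizon stock, which at baseline
  (~98 Gt C) is consistent with the ensemble median (~87 Gt C). The
  alternative bookkeeping — undecayed cumulative injection — changes the
  ensemble median social cost by under 5% and is not exposed.
* **Quota** — `Q0·FL·Egov·M_t` in tonnes: the proposed rate `Q0` (0.3/yr
  baseline, an Fmsy-like advisory rate) applies to the current stock.
  The lobby multiplier `FL` (1.2 baseline) fires when last year's
  profit-to-cost ratio `π/(c·E)` exceeded `pl`; zero effort means no lobby.
  The concern multiplier `Egov` (0.8 baseline) fires when last year's
  injection `M·μ` fell below `el` times the year-5 baseline injection.
  Both triggers evaluate the *previous* year (no simultaneity) and are off
  for the first five years while the fishery is still negligible. The
  concern signal uses yearly injection rather than the slowly-decaying
  stocks because the stocks grow monotonically from zero on this horizon
  and a stock-based trigger could never fire.
* **Social cost** — for each parameter vector the model runs twice, with
  fishing and with effort held at zero. The cumulative cost is
  `(C_unfished(T) − C_fished(T))·10⁹·(44/12)·scc` EUR; the final-year cost
  is the last yearly increment of that series. Zero harvest implies zero
  cost by construction.

## The experiment design (what stands in for data)

The study conditions are an 18-parameter uniform box: thirteen bio-economic
parameters (initial biomass and carrying capacity 1.5–4.5 Gt, growth rate
0.225–1.575/yr, three sequestration durations, daily cost, daily capacity,
social cost of carbon 38.6–362.28 €/tCO₂, effort-adjustment α, price level
γ, price flexibility β, demand growth X) and five governance parameters
(quota rate, lobby and concern effect sizes and their thresholds). The
injection rate μ = 0.77, the pathway split (0.32/0.35/0.33) and the C→CO₂
factor 3.67 are held fixed: they rest on metabolic-rate assumptions outside
this model's resolution. Bounds are generally the baseline ±75% except
where the literature constrains them (biomass capped at 4.5 Gt; β's
sampled range sits below its point estimate, and the range governs all
ensemble results). Draws are Latin-hypercube (scipy's sampler), uniform in
each dimension, deterministic given the seed; one global seed is split
deterministically between the sampler and the tree ensembles so a single
integer reproduces the whole pipeline.

What the generator does *not* emulate: parameter correlations (M0 and K
are drawn independently, so a run may start above capacity and relax down),
time-varying drivers, structural alternatives (food-web release,
zooplankton compensation), or observation noise — there are no data to
observe. Passing tests therefore demonstrate internal correctness and
faithful propagation of the stated uncertainty, not realism of any single
trajectory.

## Ensemble analyses

* **Outcomes** per run: final-year biomass, catch, profit and effort;
  median/total catch; end-of-horizon sequestration (fished and unfished);
  cumulative and final-year social cost. Final-year values are used for
  flow outcomes and end-of-horizon stocks for carbon, mirroring how the
  headline statistics are quoted.
* **Summaries** — medians and IQRs with linear-interpolation quartiles
  (fixed for test stability), plus predicate fractions (e.g. share of runs
  unprofitable at year 50).
* **Feature scoring** — ExtraTreesRegressor (250 trees, impurity
  importances, fixed seed, single-threaded for determinism) per outcome;
  rows normalised to sum to 1. Hyperparameters follow the common default
  behaviour of tree-based global sensitivity screening; 5,000–20,000 rows
  are ample for stable rankings.
* **Governance comparison** — the ensemble is partitioned at the
  governance-parameter range midpoints: lobby multiplier ≥ 1.5 and concern
  multiplier ≥ 0.5 (weak quota reduction) is "high lobby / low concern";
  both strictly below is "low lobby / high concern"; the remaining two
  quadrants are "mixed". The cut is a documented assumption, configurable
  in `governance_subsets`; fixed-parameter scenario runs can be built with
  `scenario_overrides` plus explicit `GovParams`.
* **Worst-case discovery** — quantile filtering: runs simultaneously in
  the lowest decile of cumulative catch, final biomass and end
  sequestration (intersection; union as a relaxed mode and as fallback when
  the intersection is empty). This reproduces "filter scenarios with
  overall low scores" as a transparent, desk-scale computation rather than
  a directed optimisation.

## Problem sizes and numerical choices

Ensemble statistics in tests and in `scripts/acceptance.py` use 20,000
paired runs — medians move by well under 1% across seeds at that size —
and tree fitting uses 5,000–20,000 rows. The engine is vectorised across
the ensemble axis; a run is a pure function of its parameter vector, so
outcome tables are bitwise reproducible and chunk-order invariant.
Degenerate inputs are handled explicitly: zero harvest (price limit), zero
effort (no lobby), extinction (absorbing), sequestration durations ≤ 1 yr
(rejected at construction, decay would exceed 100%).

## Known limitations

Single-pool biology with no age structure or species interactions; a
single global market with a reduced-form price; effort as one homogeneous
fleet; carbon pathways linear in biomass with constant residence times.
The quota-governance loop is deliberately minimal (two threshold
multipliers). The ensemble medians for governance-split catch and for the
cumulative social cost are sensitive to how fast effort can build early in
the run — the least constrained structural element of the model — and
should be read as order-of-magnitude indications; the rank orderings
between governance regimes are robust.
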