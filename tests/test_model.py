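"""Unit and property tests for the coupled yearly difference-equation model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mesofishery import (BioEconParams, GovParams, SimConfig, run_paired,
                         simulate, simulate_batch)
from mesofishery.model import (GT, compute_harvest, compute_price,
                               compute_profit, compute_quota, update_biomass,
                               update_carbon, update_effort)

# ---------------------------------------------------------------------------
# biomass


@pytest.mark.parametrize(
    "M, r, K, H, expected",
    [
        (3.0, 0.9, 3.0, 0.0, 3.0),        # at carrying capacity, zero growth
        (0.0, 0.9, 3.0, 0.0, 0.0),        # extinction is absorbing
        (1.5, 0.9, 3.0, 0.1, 2.075),      # 1.5 + 1.5*0.9*0.5 - 0.1
    ],
)
def test_logistic_surplus_production(M, r, K, H, expected):
    assert update_biomass(M, r, K, H) == pytest.approx(expected)


def test_biomass_floored_at_zero_and_rejects_negative_inputs():
    assert update_biomass(0.1, 0.5, 3.0, 5.0) == 0.0
    with pytest.raises(ValueError):
        update_biomass(-1.0, 0.9, 3.0, 0.0)
    with pytest.raises(ValueError):
        update_biomass(1.0, 0.9, -3.0, 0.0)


# ---------------------------------------------------------------------------
# harvest


def test_harvest_cpue_normalisation():
    # one day at sea at the initial biomass catches the daily capacity
    q_coef = 200.0 / (3.0 * GT)
    assert compute_harvest(1.0, 3.0 * GT, q_coef, quota=1e12) == pytest.approx(200.0)
    assert compute_harvest(0.0, 3.0 * GT, q_coef, quota=1e12) == 0.0


def test_harvest_cap_and_stock_guard():
    q_coef = 200.0 / (3.0 * GT)
    huge_E = 1e12
    assert compute_harvest(huge_E, 3.0 * GT, q_coef, quota=1e30,
                           cap=20e6) == pytest.approx(20e6)
    # never more than 99% of the standing stock
    assert compute_harvest(huge_E, 100.0, q_coef, quota=1e30) <= 99.0


# ---------------------------------------------------------------------------
# price and profit


def test_price_examples():
    assert compute_price(1.0, 0, 350.0, 0.9, 1.004) == pytest.approx(350.0)
    assert compute_price(1e6, 0, 350.0, 0.0, 1.004) == pytest.approx(350.0)
    # direct power-law evaluation as the oracle
    assert compute_price(1e6, 0, 350.0, 0.005345, 1.0) == pytest.approx(
        350.0 * 1e6 ** -0.005345)


def test_price_zero_harvest_limit_and_demand_drift():
    assert compute_price(0.0, 3, 350.0, 0.9, 1.004) == pytest.approx(
        1.004 ** 3 * 350.0)
    p0 = compute_price(1e6, 0, 350.0, 5e-4, 1.004)
    p10 = compute_price(1e6, 10, 350.0, 5e-4, 1.004)
    assert p10 == pytest.approx(p0 * 1.004 ** 10)


@pytest.mark.parametrize(
    "p, H, c, E, expected",
    [(350.0, 200.0, 37_000.0, 1.0, 33_000.0),
     (350.0, 0.0, 37_000.0, 0.0, 0.0),
     (350.0, 100.0, 37_000.0, 1.0, -2_000.0)],
)
def test_profit_is_revenue_minus_cost(p, H, c, E, expected):
    assert compute_profit(p, H, c, E) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# effort


def test_effort_rises_with_profit_in_day_equivalents():
    E1 = update_effort(1.0, 33_000.0, 37_000.0, 0.5, H=100.0, quota=200.0)
    assert E1 == pytest.approx(1.0 + 0.5 * 33_000.0 / 37_000.0)


def test_effort_fixed_point_and_quota_freeze():
    assert update_effort(2.0, 0.0, 37_000.0, 0.5, H=0.0, quota=1.0) == 2.0
    # profitable but quota-limited: no increase
    assert update_effort(2.0, 1e6, 37_000.0, 0.5, H=200.0, quota=200.0) == 2.0
    # losses pass through even when quota-limited, and effort floors at 0
    assert update_effort(2.0, -1e3, 37_000.0, 0.5, H=200.0, quota=200.0) < 2.0
    assert update_effort(0.1, -1e9, 37_000.0, 0.5, H=0.0, quota=1.0) == 0.0


# ---------------------------------------------------------------------------
# carbon


def test_carbon_pure_decay_and_injection():
    C_r, _, _, _ = update_carbon(0.0, 10.0, 0.0, 0.0, 0.77,
                                 0.32, 0.35, 0.33, 100.0, 599.0, 851.0)
    assert C_r == pytest.approx(9.9)
    _, C_f, _, tot = update_carbon(3.0, 0.0, 0.0, 0.0, 0.77,
                                   0.32, 0.35, 0.33, 103.0, 599.0, 851.0)
    assert C_f == pytest.approx(3.0 * 0.77 * 0.35)
    assert tot == pytest.approx(3.0 * 0.77)


@pytest.mark.parametrize("f, s", [(0.32, 103.0), (0.35, 30.0), (0.33, 80.0)])
def test_carbon_stock_fixed_point(f, s):
    # holding biomass constant, each stock approaches M*mu*f*s
    M, mu = 3.0, 0.77
    C = 0.0
    for _ in range(int(20 * s)):
        C = M * mu * f + C * (1.0 - 1.0 / s)
    assert C == pytest.approx(M * mu * f * s, rel=0.01)


def test_short_sequestration_duration_is_a_configuration_error():
    with pytest.raises(ValueError):
        BioEconParams(s_r=0.9)
    with pytest.raises(ValueError):
        BioEconParams(f_r=0.5)  # fractions no longer sum to 1


# ---------------------------------------------------------------------------
# quota and governance triggers


def _quota(M_t, prev_profit, prev_E, prev_inject, baseline, gov, t=10,
           cfg=SimConfig()):
    return compute_quota(M_t, prev_profit, 37_000.0, prev_E, prev_inject,
                         baseline, gov.Q0, gov.FL_effect, gov.pl,
                         gov.E_effect, gov.el, t, cfg)


def test_lobby_multiplier_fires_above_profit_threshold():
    gov = GovParams(FL_effect=1.2, pl=0.2)
    M = 3.0 * GT
    # profit ratio 0.25 > pl -> multiplier 1.2
    q, lobby, concern = _quota(M, 0.25 * 37_000.0 * 10.0, 10.0, 100.0, 100.0, gov)
    assert lobby and not concern
    assert q == pytest.approx(gov.Q0 * 1.2 * M)


def test_concern_multiplier_fires_below_sequestration_baseline():
    gov = GovParams(E_effect=0.8, el=0.5)
    M = 3.0 * GT
    q, lobby, concern = _quota(M, 0.0, 10.0, 40.0, 100.0, gov)
    assert concern and not lobby
    assert q == pytest.approx(gov.Q0 * 0.8 * M)


def test_quota_identity_when_triggers_off_and_zero_effort_means_no_lobby():
    gov = GovParams()
    M = 3.0 * GT
    q, lobby, concern = _quota(M, 0.0, 0.0, 100.0, 100.0, gov)
    assert not lobby and not concern
    assert q == pytest.approx(gov.Q0 * M)
    # grace period forces both off regardless of inputs
    q, lobby, concern = _quota(M, 1e12, 1.0, 0.0, 100.0, gov, t=2)
    assert not lobby and not concern


# ---------------------------------------------------------------------------
# full runs


def test_unfished_at_capacity_is_a_fixed_point(baseline):
    bio, gov, cfg = baseline
    traj = simulate(bio, gov, cfg.replace(fishing_enabled=False))
    assert np.allclose(traj.M, bio.K, rtol=1e-12)
    assert np.all(traj.H == 0) and np.all(traj.E == 0)


def test_unfished_below_capacity_converges_monotonically(baseline):
    bio, gov, cfg = baseline
    traj = simulate(bio.replace(M0=1.5), gov, cfg.replace(fishing_enabled=False))
    assert np.all(np.diff(traj.M) >= -1e-12)
    assert traj.M[-1] == pytest.approx(bio.K, rel=1e-9)


def test_baseline_run_respects_all_flow_invariants(baseline):
    bio, gov, cfg = baseline
    traj = simulate(bio, gov, cfg)
    M_t = traj.M[:-1] * GT
    assert np.all(traj.H <= traj.quota + 1e-6)
    assert np.all(traj.H <= 0.99 * M_t + 1e-6)
    assert traj.H[0] == pytest.approx(bio.q_day * cfg.E0)  # year-0 CPUE
    assert np.all(traj.M >= 0) and np.all(traj.E >= 0)
    np.testing.assert_allclose(traj.C_total,
                               traj.C_r + traj.C_f + traj.C_m, rtol=1e-12)


def test_nonnegativity_across_the_sampled_space(samples2k):
    """States stay physical over the full Latin-hypercube ensemble."""
    traj = simulate_batch(samples2k.values)
    for arr in (traj.M, traj.E, traj.H, traj.C_r, traj.C_f, traj.C_m):
        assert np.all(arr >= 0)
    np.testing.assert_allclose(traj.C_total,
                               traj.C_r + traj.C_f + traj.C_m, rtol=1e-12)


def test_batch_equals_single_runs(samples2k):
    sub = samples2k.values.iloc[:5]
    batch = simulate_batch(sub)
    for i in range(len(sub)):
        row = sub.iloc[i]
        bio = BioEconParams(**{k: row[k] for k in
                               ("M0", "K", "r", "q_day", "c", "alpha",
                                "gamma", "beta", "X", "scc",
                                "s_r", "s_f", "s_m")})
        gov = GovParams(**{k: row[k] for k in
                           ("Q0", "FL_effect", "pl", "E_effect", "el")})
        single = simulate(bio, gov)
        np.testing.assert_allclose(single.M, batch.M[:, i], rtol=1e-12)
        np.testing.assert_allclose(single.H, batch.H[:, i], rtol=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(M=st.floats(0.0, 10.0), r=st.floats(0.0, 2.0),
       K=st.floats(0.1, 10.0), H=st.floats(0.0, 5.0))
def test_biomass_update_never_negative(M, r, K, H):
    assert update_biomass(M, r, K, H) >= 0.0


# ---------------------------------------------------------------------------
# paired counterfactual and social cost


def test_social_cost_zero_without_fishing(baseline):
    bio, gov, cfg = baseline
    pr = run_paired(bio, gov, cfg.replace(fishing_enabled=False))
    assert pr.seq_loss_C == pytest.approx(0.0, abs=1e-12)
    assert pr.social_cost_cum == pytest.approx(0.0, abs=1e-3)


def test_social_cost_positive_under_harvest_and_monotone_in_scc(baseline):
    bio, gov, cfg = baseline
    pr = run_paired(bio, gov, cfg)
    assert pr.fished.H.sum() > 0
    assert pr.seq_loss_C > 0
    assert pr.social_cost_cum > 0
    # tonne bookkeeping: cum cost = loss(Gt) * 1e9 * CO2/C * scc
    assert pr.social_cost_cum == pytest.approx(
        pr.seq_loss_C * 1e9 * bio.co2_per_c * bio.scc, rel=1e-12)
    hi = run_paired(bio.replace(scc=2 * bio.scc), gov, cfg)
    assert hi.social_cost_cum >= pr.social_cost_cum


def test_single_year_pulse_carbon_loss_is_harvest_times_mu():
    """Hand-composed two-step check: a harvest pulse of H tonnes at year 0
    lowers year-1 biomass by exactly H, hence year-2 carbon by H*mu."""
    bio = BioEconParams()
    M0 = bio.M0 * GT
    H = 1e8
    M1_f = update_biomass(M0, bio.r, bio.K * GT, H)
    M1_u = update_biomass(M0, bio.r, bio.K * GT, 0.0)
    assert M1_u - M1_f == pytest.approx(H)  # same growth at identical M0
    args = (bio.mu, bio.f_r, bio.f_f, bio.f_m, bio.s_r, bio.s_f, bio.s_m)
    *_, tot1 = update_carbon(M0, 0, 0, 0, *args)       # identical at year 1
    *_, tot2_f = update_carbon(M1_f, *np.zeros(3), *args)
    *_, tot2_u = update_carbon(M1_u, *np.zeros(3), *args)
    assert tot2_u - tot2_f == pytest.approx(H * bio.mu, rel=1e-9)
    cost = (tot2_u - tot2_f) * bio.co2_per_c * bio.scc
    assert cost == pytest.approx(H * bio.mu * 3.67 * bio.scc, rel=1e-9)


def test_sustainable_yield_threshold_brute_force():
    """Constant harvest below rK/4 admits a positive equilibrium; above it
    the stock collapses (surplus-production MSY oracle over a grid)."""
    r, K = 0.8, 2.0
    msy = r * K / 4.0
    for H, survives in [(0.5 * msy, True), (0.9 * msy, True),
                        (1.1 * msy, False), (2.0 * msy, False)]:
        M = K
        for _ in range(3000):
            M = update_biomass(M, r, K, H)
            if M == 0.0:
                break
        assert bool(M > 0) == survives, f"H={H}"
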