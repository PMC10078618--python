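"""Daily stock-and-flow simulator: oracles, conservation and bookkeeping."""

import math

import numpy as np
import pytest

from evpem.core import (
    DAYS_PER_YEAR,
    ForcingSeries,
    ModelConfig,
    annualize,
    calibrate_compare,
    init_state,
    run_treatment,
    simulate,
    step,
)
from evpem.exceptions import ConfigurationError, InvalidInputError
from evpem.response import ResponseCoefficients

OBSERVED_PE_CHANGE = {
    "FW.AMB.SUB": 1.67,
    "BW.AMB.SUB": -0.75,
    "BW.SALT.SUB": -0.58,
    "BW.AMB.EXP": -0.46,
    "BW.SALT.EXP": -1.29,
    "BW.AMB.EXTEXP": -3.73,
    "BW.SALT.EXTEXP": -4.37,
}


def constant_forcing(days, anpp=1.0, bnpp=0.4, f_ch4=0.01, sal=10.0, wl=2.0):
    ones = np.ones(days)
    return ForcingSeries(
        anpp=ones * anpp, bnpp=ones * bnpp, f_ch4=ones * f_ch4,
        sal=ones * sal, wl=ones * wl,
    )


def test_init_state_units():
    config = ModelConfig(h0=1.5, rho_b=0.13)
    state = init_state(config)
    assert state.ms == pytest.approx(1.95e5)
    assert state.pde == pytest.approx(150.0)  # cm of peat
    assert state.pe == config.pe0


def test_init_state_rejects_bad_config():
    with pytest.raises(ConfigurationError):
        ModelConfig(h0=0.0)
    with pytest.raises(ConfigurationError):
        ModelConfig(dt=0.3)
    with pytest.raises(ConfigurationError):
        ModelConfig(alpha=1.0)


def test_single_day_matches_hand_computed_euler_day(coeffs):
    """One submerged day at 10 ppt against explicit hand arithmetic.

    Rates are constant within the day and litter production exceeds
    decomposition, so the eight Euler sub-steps reproduce the single-step
    arithmetic exactly.
    """
    config = ModelConfig(
        h0=1.5, rho_b=0.13, alpha=0.1, f_c=0.43, tr_ag=1.5, tr_bg=0.5,
        ls_ag0=100.0, ls_bg0=50.0, pe0=0.0,
    )
    forcing = constant_forcing(1)
    result = simulate(config, forcing, coeffs)

    # hand oracle, straight from the response-curve coefficients
    k_ag = 5.14e-6 * 100 - 6.14e-5 * 10 + 1.47e-3
    k_bg = 1.02e-6 * 100 - 2.36e-5 * 10 + 8.67e-4
    lp_ag, lp_bg = 1.0 * 1.5, 0.4 * 0.5
    d_ag, d_bg = 100.0 * k_ag, 50.0 * k_bg
    c_ag, c_bg = lp_ag - d_ag, lp_bg - d_bg
    dst = -(0.685 * math.log(10.0) - 1.10)
    net = c_ag + c_bg + dst - 0.01
    pe_change = net / (0.13 * 1e4) / (1.0 - 0.1)
    necb = 1.0 + 0.4 - d_ag - d_bg + dst * 0.43 - 0.01

    day = result.daily.iloc[0]
    assert day["c_ag"] == pytest.approx(c_ag, rel=1e-12)
    assert day["c_bg"] == pytest.approx(c_bg, rel=1e-12)
    assert day["delta_st"] == pytest.approx(dst, rel=1e-12)
    assert day["necb"] == pytest.approx(necb, rel=1e-12)
    assert result.final_state.pe == pytest.approx(pe_change, rel=1e-10)
    assert result.final_state.ms == pytest.approx(1.95e5 + net, rel=1e-12)


def test_step_zero_flows_leave_state_unchanged(coeffs):
    """Zero productivity, empty litter stocks, salinity at the exposed-regime
    zero-loss point: only the water level advances."""
    config = ModelConfig(ls_ag0=0.0, ls_bg0=0.0, pe0=0.0)
    state = init_state(config)
    state.wl = -2.0  # exposed
    sal_zero_loss = math.exp(2.83 / 1.40)
    new, out = step(
        state,
        {"anpp": 0.0, "bnpp": 0.0, "f_ch4": 0.0, "sal": sal_zero_loss, "slr": 0.1},
        coeffs,
        config,
    )
    assert new.ms == state.ms
    assert new.pe == state.pe
    assert new.wl == pytest.approx(state.wl + 0.1)
    assert out.delta_st == pytest.approx(0.0, abs=1e-12)


def test_step_rejects_nonfinite_forcing(coeffs):
    config = ModelConfig()
    state = init_state(config)
    with pytest.raises(InvalidInputError):
        step(state, {"anpp": float("nan"), "bnpp": 0, "f_ch4": 0, "sal": 1, "wl": 0},
             coeffs, config)


def test_mass_conservation_randomized(coeffs):
    """Peat-stock change equals the summed recorded net flows for arbitrary
    forcing, to 1e-9 relative tolerance."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        days = int(rng.integers(5, 60))
        forcing = ForcingSeries(
            anpp=rng.uniform(0, 3, days),
            bnpp=rng.uniform(0, 1.5, days),
            f_ch4=rng.uniform(-0.05, 0.1, days),
            sal=rng.uniform(0.2, 25, days),
            wl=rng.uniform(-12, 8, days),
        )
        config = ModelConfig(
            alpha=float(rng.uniform(0, 0.8)),
            ls_ag0=float(rng.uniform(0, 500)),
            ls_bg0=float(rng.uniform(0, 500)),
        )
        result = simulate(config, forcing, coeffs)
        flows = result.daily
        net = (flows["c_ag"] + flows["c_bg"] + flows["delta_st"] - forcing.f_ch4).sum()
        change = result.final_state.ms - result.ms_initial
        assert change == pytest.approx(net, rel=1e-9, abs=1e-9)


def test_constant_rate_accumulation_closed_form(zero_coeffs):
    """With all response rates zeroed, a year of constant litter transfer
    accumulates exactly 365 times the daily net flow."""
    config = ModelConfig(alpha=0.0, ls_ag0=0.0, ls_bg0=0.0)
    forcing = constant_forcing(DAYS_PER_YEAR, anpp=2.0, bnpp=1.0, f_ch4=0.25)
    result = simulate(config, forcing, zero_coeffs)
    daily_net = 2.0 * config.tr_ag + 1.0 * config.tr_bg - 0.25
    assert result.final_state.ms - result.ms_initial == pytest.approx(
        DAYS_PER_YEAR * daily_net, rel=1e-12
    )
    # with alpha = 0 the elevation change equals the equivalent-depth change
    assert result.final_state.pe == pytest.approx(
        DAYS_PER_YEAR * daily_net / (config.rho_b * 1e4), rel=1e-12
    )


def test_npp_only_elevation_oracle(zero_coeffs):
    """No decomposition, soil term, methane or compaction: PE change is the
    cumulative NPP·TR divided by the areal bulk density."""
    rng = np.random.default_rng(3)
    days = 200
    anpp = rng.uniform(0, 3, days)
    bnpp = rng.uniform(0, 1, days)
    forcing = ForcingSeries(
        anpp=anpp, bnpp=bnpp, f_ch4=np.zeros(days),
        sal=np.full(days, 5.0), wl=np.full(days, 3.0),
    )
    config = ModelConfig(alpha=0.0, ls_ag0=0.0, ls_bg0=0.0)
    result = simulate(config, forcing, zero_coeffs)
    expected = (anpp * config.tr_ag + bnpp * config.tr_bg).sum() / (config.rho_b * 1e4)
    assert result.final_state.pe == pytest.approx(expected, rel=1e-10)


def test_compaction_amplifies_elevation_change(coeffs):
    """Identical forcing with alpha = 0.5 doubles every elevation increment
    relative to alpha = 0."""
    forcing = constant_forcing(30)
    flat = simulate(ModelConfig(alpha=0.0), forcing, coeffs)
    amplified = simulate(ModelConfig(alpha=0.5), forcing, coeffs)
    assert amplified.final_state.pe == pytest.approx(2.0 * flat.final_state.pe, rel=1e-9)


def test_dt_refinement_consistency(coeffs):
    """Halving the sub-step changes the final elevation by < 0.1 %."""
    days = 120
    t = np.arange(days)
    forcing = ForcingSeries(
        anpp=1.0 + 0.5 * np.sin(2 * np.pi * t / 120),
        bnpp=np.full(days, 0.3),
        f_ch4=np.full(days, 0.01),
        sal=np.full(days, 12.0),
        wl=np.full(days, -2.0),
    )
    coarse = simulate(ModelConfig(dt=0.25, ls_ag0=400, ls_bg0=100), forcing, coeffs)
    fine = simulate(ModelConfig(dt=0.125, ls_ag0=400, ls_bg0=100), forcing, coeffs)
    assert fine.final_state.pe == pytest.approx(coarse.final_state.pe, rel=1e-3)


def test_npp_monotonicity_at_realistic_rates(coeffs):
    """More productivity never yields less final peat mass (fitted-rate scale)."""
    days = 90
    base = constant_forcing(days, anpp=0.8, bnpp=0.3)
    more = constant_forcing(days, anpp=1.2, bnpp=0.45)
    config = ModelConfig(ls_ag0=300, ls_bg0=100)
    low = simulate(config, base, coeffs)
    high = simulate(config, more, coeffs)
    assert high.final_state.ms >= low.final_state.ms


def test_ms_floor_sets_terminal_flag(coeffs):
    """A thin peat column driven by persistent losses stops at bedrock."""
    config = ModelConfig(h0=0.0001, ls_ag0=0.0, ls_bg0=0.0)  # 1.3 g m-2 of peat
    forcing = constant_forcing(30, anpp=0.0, bnpp=0.0, f_ch4=0.0, sal=20.0, wl=-10.0)
    result = simulate(config, forcing, coeffs)
    assert result.final_state.exhausted
    assert result.final_state.ms == pytest.approx(0.0, abs=1e-12)
    flows = result.daily
    net = (flows["c_ag"] + flows["c_bg"] + flows["delta_st"]).sum()
    assert result.final_state.ms - result.ms_initial == pytest.approx(net, abs=1e-9)


def test_annualize_bookkeeping(zero_coeffs):
    config = ModelConfig(alpha=0.0, ls_ag0=0.0, ls_bg0=0.0)
    forcing = constant_forcing(2 * DAYS_PER_YEAR, anpp=1.0, bnpp=0.0, f_ch4=0.0)
    result = simulate(config, forcing, zero_coeffs)
    annual = annualize(result)
    assert len(annual) == 2
    per_year = DAYS_PER_YEAR * 1.0 * config.tr_ag / (config.rho_b * 1e4)
    assert annual["pe_change_cm"].to_numpy() == pytest.approx([per_year, per_year])
    assert (annual["wet_days"] == DAYS_PER_YEAR).all()  # wl=2 > pe for both years
    # constant daily NECB sums to 365x
    daily_necb = result.daily["necb"].iloc[0]
    assert annual["necb_gc_m2"].iloc[0] == pytest.approx(DAYS_PER_YEAR * daily_necb)


def test_annualize_needs_a_year(zero_coeffs):
    result = simulate(ModelConfig(), constant_forcing(10), zero_coeffs)
    with pytest.raises(InvalidInputError):
        annualize(result)


def test_calibrate_compare_identity_and_mean_bound():
    metrics = calibrate_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert metrics["nse"] == pytest.approx(1.0)
    assert metrics["mbe"] == pytest.approx(0.0)
    observed = list(OBSERVED_PE_CHANGE.values())
    constant = [0.5] * len(observed)
    assert calibrate_compare(constant, observed)["nse"] <= 0.0


def test_treatment_hindcasts_reproduce_elevation_signs(fixtures, coeffs):
    """One-year hindcasts recover the direction of elevation change for all
    seven treatments: gain in the freshwater marsh, loss in every brackish
    treatment, with the extended-exposure treatments losing the most."""
    simulated = {}
    for rec in fixtures.treatments:
        result = run_treatment(rec, fixtures.rates_for(rec.treatment_id), coeffs)
        simulated[rec.treatment_id] = result.final_state.pe
    assert simulated["FW.AMB.SUB"] > 0
    for tid, pe in simulated.items():
        if tid != "FW.AMB.SUB":
            assert pe < 0, tid
    extexp_worst = min(simulated["BW.AMB.EXTEXP"], simulated["BW.SALT.EXTEXP"])
    others = [pe for tid, pe in simulated.items() if "EXTEXP" not in tid and tid != "FW.AMB.SUB"]
    assert max(simulated["BW.AMB.EXTEXP"], simulated["BW.SALT.EXTEXP"]) < min(others)
    assert extexp_worst == simulated["BW.SALT.EXTEXP"]


def test_forcing_validation():
    with pytest.raises(InvalidInputError):
        ForcingSeries(anpp=[1.0], bnpp=[1.0], f_ch4=[0.0], sal=[1.0])  # no wl/slr
    with pytest.raises(InvalidInputError):
        ForcingSeries(anpp=[1.0, 2.0], bnpp=[1.0], f_ch4=[0.0, 0.0],
                      sal=[1.0, 1.0], wl=[0.0, 0.0])
    with pytest.raises(InvalidInputError) as err:
        ForcingSeries(anpp=[1.0, float("nan")], bnpp=[1.0, 1.0], f_ch4=[0.0, 0.0],
                      sal=[1.0, 1.0], wl=[0.0, 0.0])
    assert "day 1" in str(err.value)
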