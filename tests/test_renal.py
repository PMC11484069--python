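"""Kidney block: hemodynamics, autoregulation, nephron chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import burnsim as bs
from burnsim import renal


@pytest.fixture(scope="module")
def g(human):
    return human[1].values()


def test_renal_pressures_anchor(g):
    p_ra, p_rv = renal.renal_pressures(g["map0_eff"], g["cvp0"], g)
    assert p_ra == pytest.approx(85.0)
    # unit slope with offset -8 at the human anchor: MAP 93 -> 85
    assert g["pra_offset"] == pytest.approx(85.0 - 93.0)
    assert renal.renal_pressures(100.0, 2.0, g)[0] > p_ra


def test_poiseuille_flow(g):
    r = renal.RenalResistances(r_aff=g["r_aff0"], r_eff=g["r_eff0"],
                               r_rv=g["r_rv"])
    assert renal.renal_plasma_flow(50.0, 50.0, r) == 0.0
    j1 = renal.renal_plasma_flow(85.0, 4.0, r)
    r2 = renal.RenalResistances(2 * r.r_aff, 2 * r.r_eff, 2 * r.r_rv)
    assert renal.renal_plasma_flow(85.0, 4.0, r2) == pytest.approx(j1 / 2.0)
    # human nominal: 80 mmHg over 80/37500 resistance -> 625 mL/min
    rr = renal.RenalResistances(80.0 / 37500.0, 0.0, 0.0)
    assert renal.renal_plasma_flow(84.0, 4.0, rr) == pytest.approx(37500.0)


def test_glomerular_pressure(g):
    assert renal.glomerular_pressure(0.0, g["r_eff0"], g["r_rv"], 4.0) == 4.0
    one = renal.glomerular_pressure(1e4, g["r_eff0"], g["r_rv"], 4.0) - 4.0
    two = renal.glomerular_pressure(2e4, g["r_eff0"], g["r_rv"], 4.0) - 4.0
    assert two == pytest.approx(2.0 * one)
    # preset anchor: baseline flow reproduces P_G = 60
    assert renal.glomerular_pressure(g["j_rpf0"], g["r_eff0"], g["r_rv"],
                                     g["prv0"]) == pytest.approx(g["pg0"])


def test_glomerular_oncotic(g):
    gi = dict(g, lam_c=1.0, lam_p=0.25)
    assert renal.glomerular_oncotic(58.0, 18.0, 25.0, gi) == \
        pytest.approx(25.0 + 0.25 * 40.0)
    gi0 = dict(g, lam_p=0.0)
    assert renal.glomerular_oncotic(58.0, 18.0, 25.0, gi0) == \
        pytest.approx(g["lam_c"] * 25.0)
    assert renal.glomerular_oncotic(60.0, 18.0, 25.0, gi) > \
        renal.glomerular_oncotic(55.0, 18.0, 25.0, gi)


def test_gfr_floor_and_dilution_sign(g):
    # filtration equilibrium -> (softplus-smoothed) zero
    assert renal.gfr(43.0, 18.0, 25.0, g["k_fg"], g) < 0.1
    # albumin dilution (lower plasma oncotic) raises GFR at fixed pressures
    lo = renal.glomerular_oncotic(60.0, 18.0, 20.0, g)
    hi = renal.glomerular_oncotic(60.0, 18.0, 25.0, g)
    assert renal.gfr(60.0, 18.0, lo, g["k_fg"], g) > \
        renal.gfr(60.0, 18.0, hi, g["k_fg"], g)


def test_autoregulation_resistances(g):
    assert renal.myogenic_resistance(85.0, g) == 0.0
    assert renal.myogenic_resistance(1e6, g) <= g["amp_mm_rel"] * g["r_aff0"]
    pr = np.linspace(40, 160, 61)
    mm = [renal.myogenic_resistance(p, g) for p in pr]
    assert np.all(np.diff(mm) > 0)
    assert renal.tgf_resistance(g["na_md0"], g) == 0.0
    assert 0.0 < renal.tgf_resistance(2 * g["na_md0"], g) <= \
        g["amp_tgf_rel"] * g["r_aff0"]
    assert renal.efferent_resistance(1.0, g) == pytest.approx(g["r_eff0"])
    assert renal.efferent_resistance(0.5, g) < g["r_eff0"]


def test_proximal_node_band_and_balance(g):
    j, f, r_p = renal.proximal_node(7200.0, 1008.0, 1.0, g)
    assert 0.65 <= r_p <= 0.75
    # equal fractions: outflow concentration equals inflow concentration
    for c_ald in (0.5, 1.0, 2.0, 5.0):
        j2, f2, rp2 = renal.proximal_node(7200.0, 1008.0, c_ald, g)
        assert 0.65 <= rp2 <= 0.75
        assert f2 / j2 == pytest.approx(1008.0 / 7200.0)
    # glomerulotubular balance: fraction (not rate) is controlled
    j3, f3, rp3 = renal.proximal_node(2 * 7200.0, 2 * 1008.0, 1.0, g)
    assert 2 * 7200.0 - j3 == pytest.approx(2.0 * (7200.0 - j))


def test_descending_limb_water_only(g):
    j, f, r_n = renal.descending_limb_node(g["j_pn0"], 300.0, g)
    assert f == 300.0                      # sodium impermeable
    assert r_n == pytest.approx(g["r_n0"])
    # inverse relationship between flow and reabsorption fraction
    _, _, r_hi = renal.descending_limb_node(2.0 * g["j_pn0"], 300.0, g)
    assert r_hi < r_n


def test_ascending_limb_sixty_percent(g):
    for f_nk in (10.0, 120.0, 900.0):
        j, f_ke, p_k = renal.ascending_limb_node(540.0, f_nk, g)
        assert j == 540.0                  # water impermeable
        assert f_ke / f_nk == pytest.approx(0.40)
        assert p_k == 0.60


def test_early_distal_node(g):
    # direct evaluation with a rigged constant fraction of 0.5
    gi = dict(g, p_e_min=0.5, p_e_max=0.5)
    j, f_ec, p_e, na_md = renal.early_distal_node(1000.0, 100.0, gi)
    assert j == 1000.0 and p_e == 0.5
    assert na_md == pytest.approx(0.050)   # 50 mEq/L
    # faster sodium inflow -> lower fraction -> higher MD sodium
    _, _, pe_lo, na_lo = renal.early_distal_node(g["j_pn0"] * 0.25,
                                                 g["f_ke0"], g)
    _, _, pe_hi, na_hi = renal.early_distal_node(g["j_pn0"] * 0.25,
                                                 2.0 * g["f_ke0"], g)
    assert pe_hi < pe_lo and na_hi > na_lo
    with pytest.raises(ArithmeticError):
        renal.early_distal_node(0.0, 10.0, g)


def test_collecting_duct_hormonal_control(g):
    j_ec, f_ec = 540.0, 36.0
    j0, f0, na0, r_c, p_c = renal.collecting_duct_node(j_ec, f_ec, 1.0, 1.0,
                                                       g)
    assert r_c == pytest.approx(g["r_cd0"]) and p_c == pytest.approx(
        g["p_cd0"])
    # ADH retains pure water: UO falls, urine sodium concentrates
    j1, f1, na1, _, _ = renal.collecting_duct_node(j_ec, f_ec, 3.0, 1.0, g)
    assert j1 < j0 and na1 > na0 and f1 == pytest.approx(f0)
    # bounded dose-response: urine never vanishes entirely
    j2, _, _, r_c2, _ = renal.collecting_duct_node(j_ec, f_ec, 1e6, 1.0, g)
    assert j2 > 0 and r_c2 < 1.0


@given(st.floats(100.0, 20000.0), st.floats(0.10, 0.17),
       st.floats(0.3, 3.0), st.floats(0.3, 3.0))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_chain_mass_balance(human, j_gfr, na, c_ald, c_adh):
    """Water and sodium close node-wise and chain-wise to 1e-10 relative."""
    g = human[1].values()
    fl = renal.nephron_chain(j_gfr, na, c_ald, c_adh, g)
    # chain water: GFR = reabsorbed + urine
    water_reab = (j_gfr - fl.j_pn) + (fl.j_pn - fl.j_nk) + (fl.j_nk
                                                            - fl.j_uo)
    assert water_reab + fl.j_uo == pytest.approx(j_gfr, rel=1e-10)
    # chain sodium
    na_reab = (fl.f_gfr - fl.f_pn) + (fl.f_nk - fl.f_ke) + \
        (fl.f_ke - fl.f_ec) + (fl.f_ec - fl.f_uo)
    assert na_reab + fl.f_uo == pytest.approx(fl.f_gfr, rel=1e-10)
    # node contracts
    assert fl.f_nk == fl.f_pn                    # N sodium-impermeable
    assert fl.j_nk == fl.j_pn * (1.0 - fl.r_n)
    assert 0.0 <= fl.r_n <= 1.0 and 0.0 <= fl.p_e <= 1.0
    assert 0.0 < fl.r_c < 1.0 and 0.0 < fl.p_c < 1.0


def test_fractions_bounded_over_pressure_sweep(human_sweep):
    for col in ("r_p", "r_n", "r_c", "p_e", "p_c"):
        s = human_sweep.series(col)
        assert np.all((s >= 0.0) & (s <= 1.0)), col


def test_higher_na_md_lowers_rpf_closed_loop(g):
    """TGF sign: a higher assumed MD sodium constricts the afferent
    arteriole and lowers renal plasma flow."""
    lo = renal._gfr_given_na_md(g["na_md0"], 85.0, 4.0, g["pi_c0"], 1.0, g)
    hi = renal._gfr_given_na_md(1.5 * g["na_md0"], 85.0, 4.0, g["pi_c0"],
                                1.0, g)
    r_lo = renal.renal_plasma_flow(85.0, 4.0, lo[1])
    r_hi = renal.renal_plasma_flow(85.0, 4.0, hi[1])
    assert r_hi < r_lo


def test_angii_preserves_gfr(g):
    """Raising Ang II raises efferent resistance, glomerular pressure and
    GFR in the coupled kidney evaluation."""
    base = renal.renal_steady_flows(93.0, 2.0, g["pi_c0"], g["na_plasma0"],
                                    1.0, 1.0, 1.0, g)
    up = renal.renal_steady_flows(93.0, 2.0, g["pi_c0"], g["na_plasma0"],
                                  1.6, 1.0, 1.0, g)
    assert up.resistances.r_eff > base.resistances.r_eff
    assert up.pressures.p_g > base.pressures.p_g
    assert up.flows.j_gfr > base.flows.j_gfr


def test_perfusion_collapse_reported(g):
    with pytest.raises(ArithmeticError, match="perfusion"):
        renal.renal_steady_flows(10.0, 9.0, g["pi_c0"], g["na_plasma0"],
                                 1.0, 1.0, 1.0, g)
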