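"""Volume kinetics: Starling filtration, lymph, albumin transport, losses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import burnsim as bs
from burnsim import vk


def test_seven_vk_states():
    assert vk.N_VK_STATES == 7
    assert vk.VK_STATE_NAMES == ("v_p", "a_p", "v_bt", "v_it", "a_bt",
                                 "a_it", "na_ecf")


@pytest.mark.parametrize("kf,pc,pt,sigma,pic,pit,expected", [
    (1.0, 10.0, 0.0, 1.0, 25.0, 15.0, 0.0),      # balanced forces
    (0.5, 20.0, -2.0, 0.9, 25.0, 10.0, 4.25),    # direct evaluation
    (2.0, 5.0, 5.0, 0.0, 25.0, 0.0, 0.0),        # sigma=0, equal hydrostatic
])
def test_starling_filtration(kf, pc, pt, sigma, pic, pit, expected):
    assert vk.starling_filtration(kf, pc, pt, sigma, pic, pit) == \
        pytest.approx(expected)


def test_starling_rejects_negative_conductance():
    with pytest.raises(ValueError):
        vk.starling_filtration(-1.0, 10, 0, 1, 25, 15)


@given(st.floats(-30, 30), st.floats(-10, 40), st.floats(0, 1),
       st.floats(0, 40), st.floats(0, 40))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_starling_zero_crossing(pc, pt, sigma, pic, pit):
    """Filtration changes sign exactly where (Pc-Pt) = sigma*(pic-pit)."""
    net = (pc - pt) - sigma * (pic - pit)
    j = vk.starling_filtration(1.7, pc, pt, sigma, pic, pit)
    assert j == pytest.approx(1.7 * net, abs=1e-9)
    assert (j > 0) == (net > 0) or net == 0


def test_lymph_sigmoid_midpoint_and_bounds():
    j = vk.lymphatic_flow(5.0, j_max=100.0, midpoint=5.0, slope=2.0)
    assert j == pytest.approx(50.0)          # (min + max)/2 with min = 0
    assert vk.lymphatic_flow(-1e6, 100.0, 5.0, 2.0) == 0.0
    assert vk.lymphatic_flow(1e6, 100.0, 5.0, 2.0) == 100.0
    # slope maximal at the midpoint (finite differences)
    pts = np.linspace(-10, 20, 301)
    flows = np.array([vk.lymphatic_flow(p, 100.0, 5.0, 2.0) for p in pts])
    slopes = np.diff(flows)
    assert abs(pts[np.argmax(slopes)] - 5.0) < 0.2
    assert np.all(slopes >= 0)


def test_albumin_flux_limits():
    # pure diffusion limit at zero convection
    assert vk.albumin_flux(0.0, 0.04, 0.02, 0.8, ps=2.0) == \
        pytest.approx(0.04)
    # no gradient, no convection
    assert vk.albumin_flux(0.0, 0.03, 0.03, 0.8, ps=2.0) == 0.0
    # convection-dominated asymptote: flux/J -> (1-sigma_a)*C_P
    j = 1e6
    flux = vk.albumin_flux(j, 0.04, 0.02, 0.8, ps=2.0)
    assert flux / j == pytest.approx(0.2 * 0.04, rel=1e-6)


@given(st.floats(-50, 50), st.floats(0.001, 0.08), st.floats(0.001, 0.08),
       st.floats(0, 0.95), st.floats(0.01, 50))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_albumin_flux_continuity_at_zero_convection(j, cp, ct, sa, ps):
    """The Patlak solution is continuous through Pe = 0."""
    f = vk.albumin_flux(j, cp, ct, sa, ps)
    f0 = vk.albumin_flux(1e-9, cp, ct, sa, ps)
    if abs(j) < 1e-9:
        assert f == pytest.approx(f0, abs=1e-9)
    assert math.isfinite(f)


def test_tissue_pressure_curve_anchoring_and_compliance_break(human):
    _, params = human
    g = params.values()
    v0 = g["v_bt0"]
    p0 = vk.tissue_pressure(v0, v0, g["p_tis0"], g["c_tis_lo"],
                            g["c_tis_hi"], g["tis_blend"])
    assert p0 == pytest.approx(g["p_tis0"], abs=1e-9)
    # continuous, monotone, with the configured slope ratio across baseline
    x = np.linspace(0.5, 1.8, 400) * v0
    p = np.array([vk.tissue_pressure(v, v0, g["p_tis0"], g["c_tis_lo"],
                                     g["c_tis_hi"], g["tis_blend"])
                  for v in x])
    assert np.all(np.diff(p) > 0)
    slope_lo = (p[60] - p[0]) / (x[60] - x[0]) * v0
    slope_hi = (p[-1] - p[-60]) / (x[-1] - x[-60]) * v0
    assert slope_lo / slope_hi == pytest.approx(
        g["c_tis_lo"] / g["c_tis_hi"], rel=0.02)


def test_oncotic_pressure_anchor_and_linearity(human):
    _, params = human
    g = params.values()
    pi0 = vk.oncotic_pressure(g["a_p0"], g["v_p0"], g["k_pi"])
    assert pi0 == pytest.approx(g["pi_c0"])
    half = vk.oncotic_pressure(g["a_p0"] / 2.0, g["v_p0"], g["k_pi"])
    assert half == pytest.approx(pi0 / 2.0)


def test_dermal_losses(human):
    profile, params = human
    g = params.values()
    # no burn -> no loss
    assert vk.dermal_loss(g["v_bt0"], 0.0, profile.weight, g, 1.0) == \
        (0.0, 0.0)
    # baseline burnt-tissue volume -> no exudation
    evap, exud = vk.dermal_loss(g["v_bt0"], 0.4, profile.weight, g, 1.0)
    assert exud == 0.0 and evap > 0.0
    # evaporation proportional to burned area
    evap2, _ = vk.dermal_loss(g["v_bt0"], 0.8, profile.weight, g, 1.0)
    assert evap2 == pytest.approx(2.0 * evap)


def test_hematocrit_map():
    assert vk.hematocrit(3000.0, 2000.0) == pytest.approx(0.4)
    assert vk.hematocrit(1500.0, 2000.0) == pytest.approx(2000.0 / 3500.0)
    assert vk.hematocrit(1e12, 2000.0) < 1e-8


def test_plasma_sodium_dilution():
    v = (3000.0, 4000.0, 9000.0)
    na = 0.140 * sum(v)
    assert vk.plasma_sodium(na, *v) == pytest.approx(0.140)
    # pure water gain dilutes 1/1.1; isotonic gain leaves it unchanged
    v_up = tuple(x * 1.1 for x in v)
    assert vk.plasma_sodium(na, *v_up) == pytest.approx(0.140 / 1.1)
    assert vk.plasma_sodium(na * 1.1, *v_up) == pytest.approx(0.140)


def test_sodium_rhs_direct_evaluation(human):
    """LR at 500 mL/h with UO 50 mL/h at urine sodium 100 mEq/L:
    dNa = 500*0.130 - 50*0.100 = 60 mEq/h."""
    profile, params = human
    g = params.values()
    st0 = bs.initialize_state(profile, params)
    fx = vk.FluidFluxes(0, 0, 0, 0, 0, 0, 0, 0)
    d = vk.vk_rhs(st0.v_p, st0.a_p, st0.v_bt, st0.v_it, st0.a_bt, st0.a_it,
                  fx, g, denat_rate=0.0, j_i=500.0, q_i=0.0, j_uo=50.0,
                  f_i=500.0 * 0.130, f_uo=50.0 * 0.100)
    assert d[6] == pytest.approx(60.0)
    # global water balance with no fluxes: dV_total = J_I - J_UO
    assert d[0] + d[2] + d[3] == pytest.approx(450.0)


def test_albumin_conservation_in_rhs(human):
    """With denaturation off and no infusate albumin the albumin
    derivatives sum to zero for any flux state."""
    profile, params = human
    g = params.values()
    st0 = bs.initialize_state(profile, params)
    fx = vk.FluidFluxes(j_c_bt=30.0, j_c_it=80.0, j_l_bt=12.0, j_l_it=55.0,
                        q_bt=0.9, q_it=2.1, j_evap=5.0, j_exud=3.0)
    d = vk.vk_rhs(st0.v_p, st0.a_p, st0.v_bt, st0.v_it, st0.a_bt, st0.a_it,
                  fx, g, denat_rate=0.0, j_i=0.0, q_i=0.0, j_uo=10.0,
                  f_i=0.0, f_uo=1.0)
    assert d[1] + d[4] + d[5] == pytest.approx(0.0, abs=1e-12)
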