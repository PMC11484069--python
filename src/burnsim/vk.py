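"""Three-compartment volume kinetics: water, albumin and sodium exchange
between plasma, burnt tissue and intact tissue.

Water moves by Starling capillary filtration and returns through a sigmoidal
lymphatic; albumin follows the Patlak convection-diffusion solution and rides
back freely with lymph; sodium lives in a single extracellular pool touched
only by infusion and urine (capillary and lymphatic exchange are isotonic).
All functions here are scalar and parameterised by a plain ``dict`` of named
parameter values (see :mod:`burnsim.core`), so they can be called millions of
times inside an ODE right-hand side without container overhead.

Units: volumes mL, flows mL/h, pressures mmHg, albumin g, sodium mEq,
concentrations g/mL and mEq/mL, time hours post-burn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "VK_STATE_NAMES",
    "N_VK_STATES",
    "CompartmentPressures",
    "FluidFluxes",
    "tissue_pressure",
    "capillary_pressure",
    "oncotic_pressure",
    "compartment_pressures",
    "starling_filtration",
    "lymphatic_flow",
    "albumin_flux",
    "dermal_loss",
    "vk_rhs",
    "hematocrit",
    "plasma_sodium",
]

#: The ODE states of the volume-kinetics block, in state-vector order.
VK_STATE_NAMES = ("v_p", "a_p", "v_bt", "v_it", "a_bt", "a_it", "na_ecf")
N_VK_STATES = len(VK_STATE_NAMES)


@dataclass
class CompartmentPressures:
    """Hydrostatic and colloid oncotic pressures of the three compartments."""

    p_c: float   # capillary (intravascular) hydrostatic, mmHg
    p_bt: float  # burnt-tissue hydrostatic, mmHg (includes burn offset)
    p_it: float  # intact-tissue hydrostatic, mmHg
    pi_c: float  # plasma colloid oncotic, mmHg
    pi_bt: float
    pi_it: float


@dataclass
class FluidFluxes:
    """Instantaneous water/albumin/sodium fluxes between compartments."""

    j_c_bt: float  # capillary filtration into burnt tissue, mL/h
    j_c_it: float
    j_l_bt: float  # lymphatic return, mL/h
    j_l_it: float
    q_bt: float    # transcapillary albumin flux, g/h
    q_it: float
    j_evap: float  # dermal evaporation, mL/h
    j_exud: float  # wound exudation, mL/h


def _softplus(x: float, w: float) -> float:
    """Numerically stable w*log(1+exp(x/w))."""
    if w <= 0.0:
        return x if x > 0.0 else 0.0
    z = x / w
    if z > 35.0:
        return x
    if z < -35.0:
        return 0.0
    return w * math.log1p(math.exp(z))


def tissue_pressure(v: float, v0: float, p0: float, c_lo: float, c_hi: float,
                    blend: float) -> float:
    """Interstitial pressure-volume curve.

    Continuous piecewise-linear in relative volume ``x = (v - v0)/v0``:
    slope ``c_lo`` (stiff, strongly negative pressures when dehydrated)
    below baseline and ``c_hi`` (compliant, edema-accommodating) above,
    blended smoothly over a band of width ``blend`` so the ODE right-hand
    side stays continuously differentiable.
    """
    if v <= 0.0 or v0 <= 0.0:
        raise ValueError("tissue volume must be positive")
    x = (v - v0) / v0
    # subtract the blend's value at x=0 so P(v0) = p0 exactly
    return p0 + c_lo * x + (c_hi - c_lo) * (_softplus(x, blend)
                                            - _softplus(0.0, blend))


def capillary_pressure(v_p: float, p: dict) -> float:
    """Capillary hydrostatic pressure, linear in plasma volume."""
    if v_p <= 0.0:
        raise ValueError("plasma volume must be positive")
    return p["p_cap0"] + p["e_cap"] * (v_p - p["v_p0"]) / p["v_p0"]


def oncotic_pressure(albumin: float, volume: float, k_pi: float) -> float:
    """Linear colloid oncotic pressure from albumin concentration."""
    if volume <= 0.0:
        raise ValueError("compartment volume must be positive")
    return k_pi * albumin / volume


def compartment_pressures(v_p: float, a_p: float, v_bt: float, v_it: float,
                          a_bt: float, a_it: float, p: dict,
                          pbt_offset: float = 0.0) -> CompartmentPressures:
    """All six pressures at the current state.

    ``pbt_offset`` is the (non-negative) magnitude of the transient
    burn-induced negative-pressure perturbation applied to the burnt tissue.
    """
    k_pi = p["k_pi"]
    return CompartmentPressures(
        p_c=capillary_pressure(v_p, p),
        p_bt=tissue_pressure(v_bt, p["v_bt0"], p["p_tis0"], p["c_tis_lo"],
                             p["c_tis_hi"], p["tis_blend"]) - pbt_offset,
        p_it=tissue_pressure(v_it, p["v_it0"], p["p_tis0"], p["c_tis_lo"],
                             p["c_tis_hi"], p["tis_blend"]),
        pi_c=oncotic_pressure(a_p, v_p, k_pi),
        pi_bt=oncotic_pressure(a_bt, v_bt, k_pi),
        pi_it=oncotic_pressure(a_it, v_it, k_pi),
    )


def starling_filtration(kf: float, p_c: float, p_t: float, sigma: float,
                        pi_c: float, pi_t: float) -> float:
    """Starling transcapillary filtration kf*[(Pc-Pt) - sigma*(pic-pit)].

    Negative values mean reabsorption into plasma.
    """
    if kf < 0.0:
        raise ValueError("filtration coefficient must be non-negative")
    return kf * ((p_c - p_t) - sigma * (pi_c - pi_t))


def lymphatic_flow(p_t: float, j_max: float, midpoint: float,
                   slope: float) -> float:
    """Sigmoidal lymph flow, bounded in [0, j_max], increasing in tissue P."""
    z = (p_t - midpoint) / slope
    if z > 35.0:
        return j_max
    if z < -35.0:
        return 0.0
    return j_max / (1.0 + math.exp(-z))


def albumin_flux(j_c: float, c_p: float, c_t: float, sigma_a: float,
                 ps: float) -> float:
    """Coupled convection-diffusion albumin flux (Patlak solution), g/h.

    flux = J(1-sa) * (C_p - C_t*exp(-Pe)) / (1 - exp(-Pe)),
    Pe = J(1-sa)/PS.  Limits: pure diffusion PS*(C_p-C_t) as J -> 0 and
    convective wash-through J(1-sa)*C_p for large Pe.
    """
    if c_p < 0.0 or c_t < 0.0:
        raise ValueError("albumin concentrations must be non-negative")
    a = j_c * (1.0 - sigma_a)
    if ps <= 0.0:
        return max(a, 0.0) * c_p + min(a, 0.0) * c_t
    pe = a / ps
    if abs(pe) < 1e-8:
        # symmetric small-Peclet expansion
        return ps * (c_p - c_t) + 0.5 * a * (c_p + c_t)
    if pe > 35.0:
        return a * c_p
    if pe < -35.0:
        return a * c_t
    e = math.exp(-pe)
    return a * (c_p - c_t * e) / (1.0 - e)


def dermal_loss(v_bt: float, tbsa: float, weight: float, p: dict,
                wound_gate: float) -> tuple[float, float]:
    """Dermal water losses (evaporation, exudation), both >= 0, mL/h.

    Evaporation is an empirical constant-rate term proportional to the burned
    area (tbsa*weight); exudation drains the burnt-tissue fluid excess above
    baseline. Both are gated by the wound perturbation signal and therefore
    vanish pre-injury and as the wound heals.
    """
    j_evap = p["k_evap"] * tbsa * weight * wound_gate
    j_exud = p["k_exud"] * max(0.0, v_bt - p["v_bt0"]) * wound_gate
    return j_evap, j_exud


def hematocrit(v_p: float, rcv: float) -> float:
    """HCT = RCV/(RCV + V_P); red-cell volume constant post-injury."""
    if v_p <= 0.0:
        raise ValueError("plasma volume must be positive")
    return rcv / (rcv + v_p)


def plasma_sodium(na_ecf: float, v_p: float, v_bt: float, v_it: float) -> float:
    """Extracellular sodium concentration, mEq/mL (multiply by 1e3 for mEq/L)."""
    v_ecf = v_p + v_bt + v_it
    if v_ecf <= 0.0:
        raise ValueError("extracellular volume must be positive")
    return na_ecf / v_ecf


def vk_fluxes(v_p: float, a_p: float, v_bt: float, v_it: float, a_bt: float,
              a_it: float, p: dict, sig, tbsa: float,
              weight: float) -> tuple[CompartmentPressures, FluidFluxes]:
    """Evaluate all inter-compartment fluxes given perturbation signals."""
    pr = compartment_pressures(v_p, a_p, v_bt, v_it, a_bt, a_it, p,
                               pbt_offset=sig.pbt_offset)
    kf_bt = p["kf_bt0"] * sig.kf_bt_mult
    kf_it = p["kf_it0"] * sig.kf_it_mult
    sigma_bt = p["sigma_bt0"] * sig.sigma_bt_mult
    sigma_it = p["sigma_it0"] * sig.sigma_it_mult
    j_c_bt = starling_filtration(kf_bt, pr.p_c, pr.p_bt, sigma_bt, pr.pi_c,
                                 pr.pi_bt)
    j_c_it = starling_filtration(kf_it, pr.p_c, pr.p_it, sigma_it, pr.pi_c,
                                 pr.pi_it)
    j_l_bt = lymphatic_flow(pr.p_bt + sig.pbt_offset, p["jl_max_bt"],
                            p["lymph_mid_bt"], p["lymph_slope"])
    j_l_it = lymphatic_flow(pr.p_it, p["jl_max_it"], p["lymph_mid_it"],
                            p["lymph_slope"])
    q_bt = albumin_flux(j_c_bt, a_p / v_p, a_bt / v_bt, p["sigma_alb"],
                        p["ps_bt"])
    q_it = albumin_flux(j_c_it, a_p / v_p, a_it / v_it, p["sigma_alb"],
                        p["ps_it"])
    j_evap, j_exud = dermal_loss(v_bt, tbsa, weight, p, sig.wound_gate)
    return pr, FluidFluxes(j_c_bt, j_c_it, j_l_bt, j_l_it, q_bt, q_it,
                           j_evap, j_exud)


def vk_rhs(v_p: float, a_p: float, v_bt: float, v_it: float, a_bt: float,
           a_it: float, fl: FluidFluxes, p: dict, denat_rate: float,
           j_i: float, q_i: float, j_uo: float, f_i: float,
           f_uo: float) -> tuple[float, float, float, float, float, float, float]:
    """Derivatives of the seven volume-kinetics states.

    Water: plasma gains infusion and lymph, loses urine and filtration;
    tissues gain filtration, lose lymph and dermal terms (exudation and
    evaporation are drawn from the burnt tissue). Albumin: Patlak capillary
    flux out of plasma, free lymphatic return at tissue concentration, an
    infusate source, and the heat-denaturation sink in the burnt tissue.
    Sodium: infusion in, urine out - nothing else, since capillary and
    lymphatic water exchange is isotonic.
    """
    c_bt = a_bt / v_bt
    c_it = a_it / v_it
    dv_p = j_i - j_uo - fl.j_c_bt - fl.j_c_it + fl.j_l_bt + fl.j_l_it
    dv_bt = fl.j_c_bt - fl.j_l_bt - fl.j_exud - fl.j_evap
    dv_it = fl.j_c_it - fl.j_l_it
    da_p = q_i - fl.q_bt - fl.q_it + fl.j_l_bt * c_bt + fl.j_l_it * c_it
    da_bt = fl.q_bt - fl.j_l_bt * c_bt - denat_rate * a_bt
    da_it = fl.q_it - fl.j_l_it * c_it
    dna = f_i - f_uo
    return dv_p, da_p, dv_bt, dv_it, da_bt, da_it, dna
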