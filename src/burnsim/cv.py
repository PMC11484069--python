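"""Algebraic circulatory-equilibrium block.

Cardiac output is found where Guyton's venous-return line - driven by mean
systemic pressure (exponential in blood volume) and total peripheral
resistance (sigmoidal in angiotensin II) - intersects a logistic
Frank-Starling cardiac-function curve of CVP. MAP then follows from
CO*TPR*M_MAP + CVP, with M_MAP the net burn vasoactivity multiplier.
The block is purely algebraic and re-solved at every ODE right-hand-side
evaluation (quasi-steady relative to hourly fluid dynamics), warm-started
from the previous solution.

Units: volumes mL, pressures mmHg, CO/VR L/min, TPR mmHg*min/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = ["CVOutputs", "mean_systemic_pressure", "total_peripheral_resistance",
           "venous_return", "cardiac_function_curve", "circulatory_equilibrium",
           "mean_arterial_pressure", "cv_outputs"]


@dataclass
class CVOutputs:
    msp: float   # mean systemic pressure, mmHg
    tpr: float   # total peripheral resistance, mmHg*min/L
    cvp: float   # central venous pressure at equilibrium, mmHg
    co: float    # cardiac output, L/min
    vr: float    # venous return (== co at equilibrium), L/min
    map: float   # mean arterial pressure, mmHg


def mean_systemic_pressure(v_b: float, p: dict) -> float:
    """MSP = MSP0 * exp(k_msp * (V_B - V_B0)/V_B0), increasing in volume."""
    if v_b <= 0.0:
        raise ValueError("blood volume must be positive")
    return p["msp0"] * math.exp(p["k_msp"] * (v_b - p["v_b0"]) / p["v_b0"])


def total_peripheral_resistance(c_angii: float, p: dict) -> float:
    """Sigmoidal TPR(Ang II), bounded in [TPR_min, TPR_max], TPR(1) = TPR0.

    Logistic in log-concentration, so the vasoconstrictor response
    saturates at TPR_max for high Ang II and falls to TPR_min > 0 as the
    hormone vanishes.
    """
    if c_angii <= 0.0:
        raise ValueError("relative Ang II concentration must be positive")
    z = (math.log(c_angii) - p["tpr_mid"]) / p["tpr_slope"]
    if z > 35.0:
        return p["tpr_max"]
    if z < -35.0:
        return p["tpr_min"]
    return p["tpr_min"] + (p["tpr_max"] - p["tpr_min"]) / (1.0 + math.exp(-z))


def venous_return(cvp: float, msp: float, tpr: float, p: dict) -> float:
    """Linear VR(CVP) with slope -1/(kappa_v*TPR); zero at CVP = MSP."""
    return (msp - cvp) / (p["kappa_v"] * tpr)


def cardiac_function_curve(cvp: float, p: dict) -> float:
    """Logistic Frank-Starling CO(CVP) through (CVP0, CO0), plateau CO_max."""
    z = (cvp - p["co_mid"]) / p["co_slope"]
    if z > 35.0:
        return p["co_max"]
    if z < -35.0:
        return 0.0
    return p["co_max"] / (1.0 + math.exp(-z))


def circulatory_equilibrium(msp: float, tpr: float, p: dict,
                            warm: float | None = None) -> tuple[float, float]:
    """Solve the CO-VR intersection; returns (CO, CVP).

    Newton iteration from the warm start (previous step's CVP) with the
    analytic derivative, falling back to bracketed brentq on
    [cvp_floor, msp]. At the returned point |CO - VR| <= 1e-6 L/min.
    """
    floor = p["cvp_floor"]
    if msp <= floor:
        raise ArithmeticError(
            f"circulatory collapse: MSP {msp:.3f} mmHg is below the CVP "
            f"bracket floor {floor:.3f} mmHg")
    r_vr = p["kappa_v"] * tpr

    def f(cvp: float) -> float:
        return cardiac_function_curve(cvp, p) - (msp - cvp) / r_vr

    # Newton with analytic slope of the logistic + line
    cvp = warm if warm is not None and floor < warm < msp else 0.5 * (floor + msp)
    for _ in range(12):
        co = cardiac_function_curve(cvp, p)
        resid = co - (msp - cvp) / r_vr
        if abs(resid) < 1e-9:
            break
        dco = co * (1.0 - co / p["co_max"]) / p["co_slope"]
        step = resid / (dco + 1.0 / r_vr)
        new = cvp - step
        if not (floor <= new <= msp):
            break
        cvp = new
    else:
        pass
    co = cardiac_function_curve(cvp, p)
    if abs(co - (msp - cvp) / r_vr) > 1e-9:
        f_lo, f_hi = f(floor), f(msp)
        if f_lo * f_hi > 0.0:
            raise ArithmeticError(
                "no circulatory equilibrium in bracket: "
                f"f({floor:.2f})={f_lo:.4f}, f({msp:.2f})={f_hi:.4f}")
        cvp = brentq(f, floor, msp, xtol=1e-12, rtol=1e-14)
        co = cardiac_function_curve(cvp, p)
    return co, cvp


def mean_arterial_pressure(co: float, tpr: float, m_map: float,
                           cvp: float) -> float:
    """MAP = CO*TPR*M_MAP + CVP."""
    return co * tpr * m_map + cvp


def cv_outputs(v_b: float, c_angii: float, m_map: float, p: dict,
               warm: float | None = None) -> CVOutputs:
    """Full cardiovascular block: volume and Ang II in, pressures/flows out."""
    msp = mean_systemic_pressure(v_b, p)
    tpr = total_peripheral_resistance(c_angii, p)
    co, cvp = circulatory_equilibrium(msp, tpr, p, warm=warm)
    vr = venous_return(cvp, msp, tpr, p)
    return CVOutputs(msp=msp, tpr=tpr, cvp=cvp, co=co, vr=vr,
                     map=mean_arterial_pressure(co, tpr, m_map, cvp))
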