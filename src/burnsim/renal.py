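"""Kidney model: renal hemodynamics, glomerular filtration with myogenic and
tubuloglomerular-feedback autoregulation, and node-chain reabsorption.

Renal plasma flow obeys Poiseuille's law across the series afferent,
efferent and venous resistances; glomerular pressure is proportional to flow
times downstream resistance; GFR comes from glomerular Starling forces with
a filtration-equilibrium linear estimate of the mean glomerular oncotic
pressure. The filtrate then traverses four tubular nodes:

* P  proximal tubule - water and sodium together, fraction set by
  glomerulotubular balance and aldosterone (baseline 65-75%);
* N  thin descending limb of Henle - water only, inverse-sigmoid in flow
  (the engine of pressure diuresis);
* K  thick ascending limb - sodium only, fixed 60% active fraction;
* E  early distal tubule - sodium only, inverse-sigmoid in sodium inflow;
  its outflow concentration is the macula-densa sodium driving TGF and renin;
* C  collecting duct - water fraction set by ADH, sodium fraction by
  aldosterone; the remainder is urine.

Tubuloglomerular feedback closes an algebraic loop (afferent resistance
depends on macula-densa sodium, which depends on GFR, which depends on
afferent resistance); it is resolved by a monotone one-dimensional
fixed-point solve at every evaluation.

Units: flows mL/h, pressures mmHg, resistances mmHg*h/mL, sodium mEq,
concentrations mEq/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = ["RenalPressures", "RenalResistances", "NephronFlows", "RenalState",
           "renal_pressures", "renal_plasma_flow", "glomerular_pressure",
           "glomerular_oncotic", "gfr", "myogenic_resistance",
           "tgf_resistance", "efferent_resistance", "proximal_node",
           "descending_limb_node", "ascending_limb_node", "early_distal_node",
           "collecting_duct_node", "nephron_chain", "renal_steady_flows"]


@dataclass
class RenalPressures:
    p_ra: float  # renal arterial, mmHg
    p_rv: float  # renal venous, mmHg
    p_g: float   # glomerular capillary, mmHg
    p_b: float   # Bowman's capsule (constant), mmHg
    pi_g: float  # mean glomerular oncotic, mmHg


@dataclass
class RenalResistances:
    r_aff: float  # afferent total = r_aff0 + myogenic + TGF (floored > 0)
    r_eff: float  # efferent, Ang II-modulated
    r_rv: float   # venous, constant


@dataclass
class NephronFlows:
    """Water/sodium flows, reabsorptions and fractions along the chain."""

    j_gfr: float
    f_gfr: float
    j_pn: float
    f_pn: float
    j_nk: float   # == j_ke == j_ec (K and E are water-impermeable)
    f_nk: float
    f_ke: float
    f_ec: float
    j_uo: float
    f_uo: float
    na_md: float  # macula-densa sodium concentration, mEq/mL
    na_uo: float  # urine sodium concentration, mEq/mL
    r_p: float
    r_n: float
    r_c: float
    p_p: float
    p_k: float
    p_e: float
    p_c: float


@dataclass
class RenalState:
    """Everything the kidney block computes at one instant."""

    pressures: RenalPressures
    resistances: RenalResistances
    j_rpf: float
    flows: NephronFlows


def renal_pressures(map_: float, cvp: float, p: dict) -> tuple[float, float]:
    """Linear maps MAP -> renal arterial and CVP -> renal venous pressure."""
    return map_ + p["pra_offset"], cvp + p["prv_offset"]


def myogenic_resistance(p_ra: float, p: dict) -> float:
    """Bounded, increasing myogenic afferent contribution; zero at baseline."""
    return p["amp_mm_rel"] * p["r_aff0"] * math.tanh(
        (p_ra - p["pra0"]) / p["s_mm"])


def tgf_resistance(na_md: float, p: dict) -> float:
    """Bounded, increasing TGF afferent contribution; zero at baseline Na_MD."""
    if na_md <= 0.0:
        raise ValueError("macula densa sodium must be positive")
    return p["amp_tgf_rel"] * p["r_aff0"] * math.tanh(
        (na_md / p["na_md0"] - 1.0) / p["s_tgf"])


def efferent_resistance(c_angii: float, p: dict) -> float:
    """Ang II constricts efferent arterioles; bounded, anchored at baseline."""
    if c_angii <= 0.0:
        raise ValueError("relative Ang II must be positive")
    return p["r_eff0"] * (1.0 + p["a_eff"]
                          * math.tanh(p["g_eff"] * (c_angii - 1.0)))


def renal_plasma_flow(p_ra: float, p_rv: float, r: RenalResistances) -> float:
    """Poiseuille: J_RPF = (P_RA - P_RV) / (R_Aff + R_Eff + R_RV)."""
    total = r.r_aff + r.r_eff + r.r_rv
    if total <= 0.0:
        raise ValueError("total renal resistance must be positive")
    return (p_ra - p_rv) / total


def glomerular_pressure(j_rpf: float, r_eff: float, r_rv: float,
                        p_rv: float) -> float:
    """P_G = J_RPF*(R_Eff + R_RV) + P_RV (downstream pressure drop)."""
    return j_rpf * (r_eff + r_rv) + p_rv


def glomerular_oncotic(p_g: float, p_b: float, pi_c: float, p: dict) -> float:
    """Filtration-equilibrium linear estimate of mean glomerular oncotic P."""
    return p["lam_c"] * pi_c + p["lam_p"] * (p_g - p_b)


def gfr(p_g: float, p_b: float, pi_g: float, k_fg: float, p: dict) -> float:
    """Glomerular Starling filtration, softplus-floored at zero.

    The softplus width (``gfr_floor_w``, mL/h) smooths the no-reverse-
    filtration floor so the coupled ODE right-hand side stays smooth.
    """
    if k_fg <= 0.0:
        raise ValueError("glomerular filtration coefficient must be positive")
    x = k_fg * ((p_g - p_b) - pi_g)
    w = p["gfr_floor_w"]
    z = x / w
    if z > 35.0:
        out = x
    elif z < -35.0:
        out = 0.0
    else:
        out = w * math.log1p(math.exp(z))
    return max(out, 1e-9)


def _dose_response(rel: float, base: float, amp: float, gain: float) -> float:
    """Monotone hormone dose-response around the baseline anchor.

    Logistic in log-concentration: equals ``base`` at rel = 1 and saturates
    at base +/- amp, so fractions stay inside (0, 1) by construction.
    """
    if rel <= 0.0:
        raise ValueError("relative hormone concentration must be positive")
    return base + amp * math.tanh(gain * math.log(rel))


def _inverse_sigmoid(x: float, lo: float, hi: float, mid: float,
                     slope: float) -> float:
    """Decreasing logistic from hi (low x) to lo (high x)."""
    z = (x - mid) / slope
    if z > 35.0:
        return lo
    if z < -35.0:
        return hi
    return lo + (hi - lo) / (1.0 + math.exp(z))


def proximal_node(j_gfr: float, f_gfr: float, c_ald: float,
                  p: dict) -> tuple[float, float, float]:
    """Node P: equal water/sodium fractions (glomerulotubular balance).

    Returns (j_pn, f_pn, r_p). The fraction - not the absolute rate - is
    controlled, so doubling GFR doubles absolute proximal reabsorption.
    """
    if j_gfr < 0.0 or f_gfr < 0.0:
        raise ValueError("node inflows must be non-negative")
    r_p = _dose_response(c_ald, p["r_p0"], p["r_p_amp"], p["g_rp"])
    return j_gfr * (1.0 - r_p), f_gfr * (1.0 - r_p), r_p


def descending_limb_node(j_pn: float, f_pn: float,
                         p: dict) -> tuple[float, float, float]:
    """Node N: passive water reabsorption, inverse sigmoid in water inflow.

    Sodium-impermeable: F_NK = F_PN exactly. Returns (j_nk, f_nk, r_n).
    """
    if j_pn < 0.0 or f_pn < 0.0:
        raise ValueError("node inflows must be non-negative")
    r_n = _inverse_sigmoid(j_pn, p["r_n_min"], p["r_n_max"], p["j_n_mid"],
                           p["s_n_rel"] * p["j_pn0"])
    return j_pn * (1.0 - r_n), f_pn, r_n


def ascending_limb_node(j_nk: float, f_nk: float,
                        p: dict) -> tuple[float, float, float]:
    """Node K: active sodium reabsorption at the fixed fraction p_k (60%).

    Water-impermeable: J_KE = J_NK exactly. Returns (j_ke, f_ke, p_k).
    """
    if j_nk < 0.0 or f_nk < 0.0:
        raise ValueError("node inflows must be non-negative")
    return j_nk, f_nk * (1.0 - p["p_k"]), p["p_k"]


def early_distal_node(j_ke: float, f_ke: float,
                      p: dict) -> tuple[float, float, float, float]:
    """Node E: passive sodium reabsorption, inverse sigmoid in sodium inflow.

    Water-impermeable. Outflow concentration is the macula-densa sodium.
    Returns (j_ec, f_ec, p_e, na_md).
    """
    if j_ke <= 0.0:
        raise ArithmeticError(
            "zero tubular water flow at the early distal node: "
            "macula-densa concentration undefined")
    p_e = _inverse_sigmoid(f_ke, p["p_e_min"], p["p_e_max"], p["f_e_mid"],
                           p["s_e_rel"] * p["f_ke0"])
    f_ec = f_ke * (1.0 - p_e)
    return j_ke, f_ec, p_e, f_ec / j_ke


def collecting_duct_node(j_ec: float, f_ec: float, c_adh: float, c_ald: float,
                         p: dict) -> tuple[float, float, float, float, float]:
    """Node C: hormonal water (ADH) and sodium (aldosterone) reabsorption.

    Returns (j_uo, f_uo, na_uo, r_c, p_c).
    """
    r_c = _dose_response(c_adh, p["r_cd0"], p["amp_rc"], p["g_rc"])
    p_c = _dose_response(c_ald, p["p_cd0"], p["amp_pc"], p["g_pc"])
    j_uo = j_ec * (1.0 - r_c)
    if j_uo <= 0.0:
        raise ArithmeticError("urine flow collapsed to zero at the "
                              "collecting duct")
    f_uo = f_ec * (1.0 - p_c)
    return j_uo, f_uo, f_uo / j_uo, r_c, p_c


def nephron_chain(j_gfr: float, na_plasma: float, c_ald: float, c_adh: float,
                  p: dict) -> NephronFlows:
    """Compose the four nodes; F_GFR = J_GFR * plasma sodium concentration."""
    f_gfr = j_gfr * na_plasma
    j_pn, f_pn, r_p = proximal_node(j_gfr, f_gfr, c_ald, p)
    j_nk, f_nk, r_n = descending_limb_node(j_pn, f_pn, p)
    j_ke, f_ke, p_k = ascending_limb_node(j_nk, f_nk, p)
    j_ec, f_ec, p_e, na_md = early_distal_node(j_ke, f_ke, p)
    j_uo, f_uo, na_uo, r_c, p_c = collecting_duct_node(j_ec, f_ec, c_adh,
                                                       c_ald, p)
    return NephronFlows(j_gfr=j_gfr, f_gfr=f_gfr, j_pn=j_pn, f_pn=f_pn,
                        j_nk=j_nk, f_nk=f_nk, f_ke=f_ke, f_ec=f_ec,
                        j_uo=j_uo, f_uo=f_uo, na_md=na_md, na_uo=na_uo,
                        r_p=r_p, r_n=r_n, r_c=r_c, p_p=r_p, p_k=p_k,
                        p_e=p_e, p_c=p_c)


def _gfr_given_na_md(na_md: float, p_ra: float, p_rv: float, pi_c: float,
                     c_angii: float, p: dict) -> tuple[float, RenalResistances,
                                                       RenalPressures]:
    r_aff = p["r_aff0"] + myogenic_resistance(p_ra, p) + tgf_resistance(na_md, p)
    r_aff = max(r_aff, 0.02 * p["r_aff0"])
    r = RenalResistances(r_aff=r_aff, r_eff=efferent_resistance(c_angii, p),
                         r_rv=p["r_rv"])
    j_rpf = renal_plasma_flow(p_ra, p_rv, r)
    p_g = glomerular_pressure(j_rpf, r.r_eff, r.r_rv, p_rv)
    pi_g = glomerular_oncotic(p_g, p["p_bowman"], pi_c, p)
    j = gfr(p_g, p["p_bowman"], pi_g, p["k_fg"], p)
    return j, r, RenalPressures(p_ra=p_ra, p_rv=p_rv, p_g=p_g,
                                p_b=p["p_bowman"], pi_g=pi_g)


def renal_steady_flows(map_: float, cvp: float, pi_c: float, na_plasma: float,
                       c_angii: float, c_ald: float, c_adh: float, p: dict,
                       warm_na_md: float | None = None) -> RenalState:
    """Evaluate the full kidney block, resolving the TGF algebraic loop.

    The macula-densa sodium that TGF assumes must equal the one the nephron
    chain produces; the composed map is strictly decreasing in the assumed
    value, so the fixed point is unique. A warm-started secant iteration
    handles the common case in two or three chain evaluations, with a
    bracketed brentq fallback.
    """
    p_ra, p_rv = renal_pressures(map_, cvp, p)
    if p_ra <= p_rv:
        raise ArithmeticError(
            f"renal perfusion collapse: P_RA {p_ra:.2f} <= P_RV {p_rv:.2f}")

    def out_given(na_md_in: float) -> tuple[float, float, RenalResistances,
                                            RenalPressures]:
        j, r, pr = _gfr_given_na_md(na_md_in, p_ra, p_rv, pi_c, c_angii, p)
        chain = nephron_chain(j, na_plasma, c_ald, c_adh, p)
        return chain.na_md, j, r, pr

    def g(x: float) -> float:
        return out_given(x)[0] - x

    na0 = p["na_md0"]
    x = warm_na_md if warm_na_md and warm_na_md > 0.0 else na0
    # secant iteration on the fixed-point residual
    x0, f0 = x, g(x)
    x1 = x0 * (1.02 if f0 > 0 else 0.98)
    f1 = g(x1)
    solved = False
    for _ in range(10):
        if abs(f1) < 1e-10 * na0:
            solved = True
            break
        denom = f1 - f0
        if denom == 0.0:
            break
        x2 = x1 - f1 * (x1 - x0) / denom
        if x2 <= 0.0 or x2 > 50.0 * na0:
            break
        x0, f0, x1, f1 = x1, f1, x2, g(x2)
    if not solved and abs(f1) >= 1e-10 * na0:
        lo, hi = 1e-6 * na0, 50.0 * na0
        x1 = brentq(g, lo, hi, xtol=1e-12, rtol=1e-12)
    na_md, j_gfr, r, pr = out_given(x1)
    chain = nephron_chain(j_gfr, na_plasma, c_ald, c_adh, p)
    j_rpf = renal_plasma_flow(pr.p_ra, pr.p_rv, r)
    return RenalState(pressures=pr, resistances=r, j_rpf=j_rpf, flows=chain)
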