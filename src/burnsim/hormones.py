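"""RAAS and ADH dynamics as normalized first-order secretion/clearance ODEs.

Hormone concentrations are dimensionless relative to their pre-injury
baseline (baseline = 1), so secretion gains are identifiable without
absolute assays. Renin secretion falls linearly with fractional macula-densa
sodium; angiotensin II follows renin through a first-order lag (the
secretion delay); aldosterone secretion is exponential in a weighted sum of
plasma-sodium deficit and Ang II excess; ADH secretion is exponential in a
weighted sum of plasma-volume deficit and sodium excess, the osmoreceptor
(sodium) weight being the larger. All secretion rates are floored at zero
and all clearances are first-order, so concentrations stay positive and
the baseline (1,1,1,1) is an exact fixed point.
"""

from __future__ import annotations

import math

__all__ = ["HORMONE_STATE_NAMES", "renin_rhs", "angii_rhs",
           "aldosterone_rhs", "adh_rhs", "hormone_rhs"]

#: hormone block states in state-vector order
HORMONE_STATE_NAMES = ("c_renin", "l_angii", "c_angii", "c_ald", "c_adh")


def renin_rhs(na_md: float, c_renin: float, p: dict) -> float:
    """dC_renin/dt: secretion inverse-linear in fractional MD sodium."""
    if na_md <= 0.0:
        raise ValueError("macula densa sodium must be positive")
    secretion = max(0.0, 1.0 - p["g_renin"]
                    * (na_md - p["na_md0"]) / p["na_md0"])
    return (secretion - c_renin) / p["tau_renin"]


def angii_rhs(c_renin: float, l_angii: float, c_angii: float,
              p: dict) -> tuple[float, float]:
    """(dL/dt, dC_angII/dt): first-order lag of renin, then linear secretion."""
    dl = (c_renin - l_angii) / p["tau_lag"]
    secretion = max(0.0, 1.0 + p["g_angii"] * (l_angii - 1.0))
    dc = (secretion - c_angii) / p["tau_angii"]
    return dl, dc


def aldosterone_rhs(na_plasma: float, c_angii: float, c_ald: float,
                    p: dict) -> float:
    """dC_ald/dt: secretion exponential in weighted Na deficit + Ang II excess."""
    if na_plasma <= 0.0:
        raise ValueError("plasma sodium must be positive")
    dna = (na_plasma - p["na_plasma0"]) / p["na_plasma0"]
    z = -p["w_na_ald"] * dna + p["w_angii_ald"] * (c_angii - 1.0)
    secretion = math.exp(min(z, 35.0))
    return (secretion - c_ald) / p["tau_ald"]


def adh_rhs(v_p: float, na_plasma: float, c_adh: float, p: dict) -> float:
    """dC_adh/dt: baroreceptor (volume) + dominant osmoreceptor (sodium) drive."""
    if v_p <= 0.0 or na_plasma <= 0.0:
        raise ValueError("plasma volume and sodium must be positive")
    dv = (v_p - p["v_p0"]) / p["v_p0"]
    dna = (na_plasma - p["na_plasma0"]) / p["na_plasma0"]
    z = -p["w_v_adh"] * dv + p["w_na_adh"] * dna
    secretion = math.exp(min(z, 35.0))
    return (secretion - c_adh) / p["tau_adh"]


def hormone_rhs(na_md: float, na_plasma: float, v_p: float, c_renin: float,
                l_angii: float, c_angii: float, c_ald: float, c_adh: float,
                p: dict) -> tuple[float, float, float, float, float]:
    """Derivatives of the five hormone states, state-vector order."""
    dr = renin_rhs(na_md, c_renin, p)
    dl, da = angii_rhs(c_renin, l_angii, c_angii, p)
    dald = aldosterone_rhs(na_plasma, c_angii, c_ald, p)
    dadh = adh_rhs(v_p, na_plasma, c_adh, p)
    return dr, dl, da, dald, dadh
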