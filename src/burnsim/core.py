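"""Parameter registry, species presets, steady-state constraint solving and
initial-state construction.

A :class:`ParameterSet` carries every named scalar parameter of the model
with bounds and a class tag: ``subject_invariant`` (literature-nominal,
shared across subjects), ``subject_specific`` (fitted per subject) or
``constraint_derived`` (computed here so the pre-injury model is an exact
steady state). Constraint derivation anchors, among others: red-cell volume
from baseline hematocrit; per-tissue lymph flow equal to baseline Starling
filtration; albumin permeability-surface products from the baseline
transcapillary albumin balance; the CO and TPR curves through the baseline
operating point; glomerular K_f from the 20% filtration fraction; the
collecting-duct water fraction from the 1%-of-RPF urine flow; and
maintenance intake equal to baseline urinary losses.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field, replace

import yaml
from scipy.optimize import brentq

from . import cv as _cv
from . import renal as _renal
from . import vk as _vk
from .perturb import NEUTRAL_SIGNALS

__all__ = ["SubjectProfile", "Parameter", "ParameterSet", "ModelState",
           "BaselineOperatingPoint", "ConstraintError", "load_preset",
           "preset_meta", "derive_constrained_parameters", "initialize_state",
           "baseline_operating_point", "MIN_PER_H"]

SPECIES = ("pig", "sheep", "human")
PARAM_CLASSES = ("subject_invariant", "subject_specific", "constraint_derived")
MIN_PER_H = 60.0  # CO is carried in L/min; flows in mL/h


class ConstraintError(ValueError):
    """A baseline constraint system has no feasible (positive) solution."""


@dataclass(frozen=True)
class SubjectProfile:
    """Subject descriptors that seed every per-subject simulation."""

    species: str
    weight: float               # kg
    tbsa: float                 # burned fraction of body surface, (0, 1)
    hct0: float                 # baseline hematocrit fraction, (0.1, 0.7)
    co0: float | None = None    # baseline cardiac output, L/min (optional)
    map0: float | None = None   # baseline mean arterial pressure, mmHg
    injury_time: float = 0.0    # hours; t = 0 at injury
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if not 0.0 < self.tbsa < 1.0:
            raise ValueError("tbsa must be a fraction in (0, 1)")
        if not 0.1 < self.hct0 < 0.7:
            raise ValueError("baseline hematocrit must be in (0.1, 0.7)")
        if self.weight <= 0.0:
            raise ValueError("weight must be positive")


@dataclass
class Parameter:
    name: str
    value: float
    lower: float
    upper: float
    cls: str
    units: str = "-"
    module: str = ""

    def __post_init__(self) -> None:
        if self.cls not in PARAM_CLASSES:
            raise ValueError(f"unknown parameter class {self.cls!r}")
        if not self.lower <= self.value <= self.upper:
            raise ValueError(
                f"parameter {self.name}: value {self.value} outside bounds "
                f"[{self.lower}, {self.upper}]")


@dataclass
class ParameterSet:
    """Named parameter vector with bounds and class tags."""

    params: dict[str, Parameter] = field(default_factory=dict)
    species: str = ""

    def __getitem__(self, name: str) -> float:
        return self.params[name].value

    def __contains__(self, name: str) -> bool:
        return name in self.params

    def get(self, name: str) -> Parameter:
        return self.params[name]

    def names(self) -> list[str]:
        return list(self.params)

    def values(self) -> dict[str, float]:
        """Plain float dict for the hot numerical kernels."""
        return {k: q.value for k, q in self.params.items()}

    def class_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(PARAM_CLASSES, 0)
        for q in self.params.values():
            counts[q.cls] += 1
        return counts

    def by_class(self, cls: str) -> list[str]:
        return [k for k, q in self.params.items() if q.cls == cls]

    def add(self, name: str, value: float, lower: float | None = None,
            upper: float | None = None, cls: str = "constraint_derived",
            units: str = "-", module: str = "") -> None:
        lo = value if lower is None else lower
        hi = value if upper is None else upper
        self.params[name] = Parameter(name, value, min(lo, value),
                                      max(hi, value), cls, units, module)

    def updated(self, **changes: float) -> "ParameterSet":
        """Copy with value changes (bounds enforced)."""
        out = ParameterSet({k: replace(q) for k, q in self.params.items()},
                           species=self.species)
        for name, value in changes.items():
            q = out.params[name]
            if not q.lower <= value <= q.upper:
                raise ValueError(f"{name}={value} outside bounds "
                                 f"[{q.lower}, {q.upper}]")
            q.value = float(value)
        return out

    def free(self) -> "ParameterSet":
        """Copy without constraint-derived entries."""
        return ParameterSet(
            {k: replace(q) for k, q in self.params.items()
             if q.cls != "constraint_derived"}, species=self.species)

    # -- serialization -----------------------------------------------------
    def to_records(self) -> list[dict]:
        return [{"name": q.name, "value": q.value, "lower": q.lower,
                 "upper": q.upper, "class": q.cls, "units": q.units,
                 "module": q.module} for q in self.params.values()]

    @classmethod
    def from_records(cls, records: list[dict],
                     species: str = "") -> "ParameterSet":
        out = cls(species=species)
        for r in records:
            out.params[r["name"]] = Parameter(
                r["name"], float(r["value"]), float(r["lower"]),
                float(r["upper"]), r["class"], r.get("units", "-"),
                r.get("module", ""))
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"species": self.species,
                            "parameters": self.to_records()}, fh,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_records(doc["parameters"], doc.get("species", ""))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"species": self.species,
                       "parameters": self.to_records()}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            doc = json.load(fh)
        return cls.from_records(doc["parameters"], doc.get("species", ""))


@dataclass
class ModelState:
    """The coupled ODE state (7 volume-kinetics states + hormones + lag)."""

    v_p: float      # plasma water volume, mL
    a_p: float      # plasma albumin content, g
    v_bt: float     # burnt-tissue water volume, mL
    v_it: float     # intact-tissue water volume, mL
    a_bt: float     # burnt-tissue albumin content, g
    a_it: float     # intact-tissue albumin content, g
    na_ecf: float   # extracellular sodium content, mEq
    c_renin: float = 1.0
    l_angii: float = 1.0  # first-order lag state for the Ang II delay
    c_angii: float = 1.0
    c_ald: float = 1.0
    c_adh: float = 1.0

    NAMES = _vk.VK_STATE_NAMES + ("c_renin", "l_angii", "c_angii", "c_ald",
                                  "c_adh")

    def to_vector(self) -> list[float]:
        return [getattr(self, n) for n in self.NAMES]

    @classmethod
    def from_vector(cls, y) -> "ModelState":
        return cls(*map(float, y[: len(cls.NAMES)]))

    def validate(self) -> None:
        for n in self.NAMES:
            if getattr(self, n) <= 0.0:
                raise ValueError(f"state {n} must be strictly positive")


@dataclass
class BaselineOperatingPoint:
    """Steady-state values of every algebraic output pre-injury."""

    msp: float
    tpr: float
    cvp: float
    co: float
    map: float
    p_ra: float
    p_rv: float
    p_g: float
    pi_g: float
    j_rpf: float
    j_gfr: float
    j_uo: float
    f_uo: float
    na_md: float
    na_plasma: float   # mEq/L
    hct: float
    pi_c: float
    filtration_fraction: float
    uo_fraction_of_rpf: float
    fractions: dict[str, float]
    node_concentrations: dict[str, float]  # mEq/L at node outflows


# ---------------------------------------------------------------------------
# presets


import functools


@functools.lru_cache(maxsize=None)
def _load_preset_doc(species: str) -> dict:
    root = importlib.resources.files("burnsim") / "presets"
    doc = yaml.safe_load((root / f"{species}.yaml").read_text())
    if doc.get("inherit"):
        base = yaml.safe_load((root / f"{doc['inherit']}.yaml").read_text())
        merged = dict(base)
        merged.update({k: v for k, v in doc.items()
                       if k not in ("overrides", "inherit")})
        params = {r["name"]: dict(r) for r in base["parameters"]}
        for ov in doc.get("overrides") or []:
            params[ov["name"]].update(ov)
        merged["parameters"] = list(params.values())
        doc = merged
    return doc


def load_preset(species: str) -> ParameterSet:
    """Free (non-derived) parameters of the shipped species preset."""
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    doc = _load_preset_doc(species)
    return ParameterSet.from_records(doc["parameters"], species=species)


def preset_meta(species: str) -> dict:
    """Subject defaults and protocol settings of a species preset."""
    import copy
    doc = _load_preset_doc(species)
    return copy.deepcopy({"subject_defaults": doc["subject_defaults"],
                          "protocol": doc["protocol"]})


def default_profile(species: str, **over) -> SubjectProfile:
    d = preset_meta(species)["subject_defaults"]
    kw = {"species": species, "weight": d["weight"], "tbsa": d["tbsa"],
          "hct0": d["hct0"]}
    kw.update(over)
    return SubjectProfile(**kw)


# ---------------------------------------------------------------------------
# constraint solving


def _solve_ps(j_c: float, c_p: float, c_t: float, sigma_a: float) -> float:
    """Permeability-surface product making capillary albumin influx balance
    the lymphatic return (J_L = J_C at baseline, lymph at tissue conc)."""
    target = j_c * c_t
    lo_flux = j_c * (1.0 - sigma_a) * c_p  # pure-convection lower limit
    if target <= lo_flux:
        raise ConstraintError(
            "albumin balance infeasible: convective influx alone exceeds the "
            "lymphatic return; lower sigma_alb or tissue albumin")

    def f(ps: float) -> float:
        return _vk.albumin_flux(j_c, c_p, c_t, sigma_a, ps) - target

    hi = 1.0
    while f(hi) < 0.0 and hi < 1e9:
        hi *= 4.0
    return brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-12)


def derive_constrained_parameters(profile: SubjectProfile,
                                  free: ParameterSet) -> ParameterSet:
    """Complete a parameter set so the pre-injury model is at steady state.

    Idempotent: constraint-derived entries are recomputed from the free
    parameters and the profile, so calling this on an already-complete set
    returns the same values.
    """
    ps = ParameterSet({k: replace(q) for k, q in free.params.items()
                       if q.cls != "constraint_derived"},
                      species=free.species or profile.species)
    g = ps.values()
    W, tbsa = profile.weight, profile.tbsa

    def add(name, value, units="-", module=""):
        ps.add(name, float(value), units=units, module=module)
        g[name] = float(value)

    # --- volume kinetics baselines ---------------------------------------
    add("v_p0", g["v_p_perkg"] * W, "mL", "volume_kinetics")
    add("v_bt0", g["v_tis_perkg"] * W * tbsa, "mL", "volume_kinetics")
    add("v_it0", g["v_tis_perkg"] * W * (1.0 - tbsa), "mL", "volume_kinetics")
    add("a_p0", g["c_alb_p0"] * g["v_p0"], "g", "volume_kinetics")
    add("a_bt0", g["c_alb_t0"] * g["v_bt0"], "g", "volume_kinetics")
    add("a_it0", g["c_alb_t0"] * g["v_it0"], "g", "volume_kinetics")
    add("k_pi", g["pi_c0"] / g["c_alb_p0"], "mmHg*mL/g", "volume_kinetics")
    add("rcv", g["v_p0"] * profile.hct0 / (1.0 - profile.hct0), "mL",
        "volume_kinetics")
    add("na_ecf0",
        g["na_plasma0"] * (g["v_p0"] + g["v_bt0"] + g["v_it0"]), "mEq",
        "volume_kinetics")

    pi_t0 = g["k_pi"] * g["c_alb_t0"]
    grad = (g["p_cap0"] - g["p_tis0"]) - g["sigma_bt0"] * (g["pi_c0"] - pi_t0)
    if grad <= 0.0:
        raise ConstraintError(
            "baseline Starling gradient non-positive: capillary filtration "
            "cannot balance a positive lymph flow")
    jc_bt0 = g["jc_perkg"] * W * tbsa
    jc_it0 = g["jc_perkg"] * W * (1.0 - tbsa)
    grad_it = (g["p_cap0"] - g["p_tis0"]) - g["sigma_it0"] * (g["pi_c0"] - pi_t0)
    if grad_it <= 0.0:
        raise ConstraintError("baseline Starling gradient non-positive in "
                              "intact tissue")
    add("kf_bt0", jc_bt0 / grad, "mL/h/mmHg", "volume_kinetics")
    add("kf_it0", jc_it0 / grad_it, "mL/h/mmHg", "volume_kinetics")
    mult = g["lymph_max_mult"]
    if mult <= 1.0:
        raise ConstraintError("lymph_max_mult must exceed 1 so the baseline "
                              "lymph flow sits below the sigmoid ceiling")
    mid = g["p_tis0"] + g["lymph_slope"] * math.log(mult - 1.0)
    add("jl_max_bt", mult * jc_bt0, "mL/h", "volume_kinetics")
    add("jl_max_it", mult * jc_it0, "mL/h", "volume_kinetics")
    add("lymph_mid_bt", mid, "mmHg", "volume_kinetics")
    add("lymph_mid_it", mid, "mmHg", "volume_kinetics")
    add("ps_bt", _solve_ps(jc_bt0, g["c_alb_p0"], g["c_alb_t0"],
                           g["sigma_alb"]), "mL/h", "volume_kinetics")
    add("ps_it", _solve_ps(jc_it0, g["c_alb_p0"], g["c_alb_t0"],
                           g["sigma_alb"]), "mL/h", "volume_kinetics")

    # --- cardiovascular anchors ------------------------------------------
    co0 = profile.co0 if profile.co0 else g["co0_perkg"] * W
    map0 = profile.map0 if profile.map0 else g["map0"]
    cvp0, msp0 = g["cvp0"], g["msp0"]
    if not (map0 > msp0 > cvp0):
        raise ConstraintError("pressure ordering MAP0 > MSP0 > CVP0 violated")
    tpr0 = (map0 - cvp0) / co0
    add("co0", co0, "L/min", "cardiovascular")
    add("map0_eff", map0, "mmHg", "cardiovascular")
    add("v_b0", g["v_p0"] + g["rcv"], "mL", "cardiovascular")
    add("tpr0", tpr0, "mmHg*min/L", "cardiovascular")
    add("kappa_v", (msp0 - cvp0) / (co0 * tpr0), "-", "cardiovascular")
    co_max = g["co_max_mult"] * co0
    add("co_max", co_max, "L/min", "cardiovascular")
    add("co_mid", cvp0 + g["co_slope"] * math.log(co_max / co0 - 1.0),
        "mmHg", "cardiovascular")
    tpr_min, tpr_max = g["tpr_min_frac"] * tpr0, g["tpr_max_frac"] * tpr0
    add("tpr_min", tpr_min, "mmHg*min/L", "cardiovascular")
    add("tpr_max", tpr_max, "mmHg*min/L", "cardiovascular")
    frac = (tpr0 - tpr_min) / (tpr_max - tpr_min)
    # midpoint on the log-concentration scale, anchoring TPR(1) = TPR0
    add("tpr_mid", g["tpr_slope"] * math.log(1.0 / frac - 1.0), "-",
        "cardiovascular")

    # --- renal anchors ----------------------------------------------------
    add("pra_offset", g["pra0"] - map0, "mmHg", "renal")
    prv0 = cvp0 + g["prv_offset"]
    add("prv0", prv0, "mmHg", "renal")
    j_rpf0 = g["rpf_perkg"] * W
    add("j_rpf0", j_rpf0, "mL/h", "renal")
    r_tot = (g["pra0"] - prv0) / j_rpf0
    r_effrv = (g["pg0"] - prv0) / j_rpf0
    if r_tot <= r_effrv:
        raise ConstraintError(
            "renal resistance split infeasible: glomerular pressure anchor "
            "requires a negative afferent resistance")
    add("r_rv", g["r_rv_frac"] * r_effrv, "mmHg*h/mL", "renal")
    add("r_eff0", (1.0 - g["r_rv_frac"]) * r_effrv, "mmHg*h/mL", "renal")
    add("r_aff0", r_tot - r_effrv, "mmHg*h/mL", "renal")
    j_gfr0 = g["ff0"] * j_rpf0
    add("j_gfr0", j_gfr0, "mL/h", "renal")
    pi_g0 = g["lam_c"] * g["pi_c0"] + g["lam_p"] * (g["pg0"] - g["p_bowman"])
    net0 = (g["pg0"] - g["p_bowman"]) - pi_g0
    if net0 <= 0.0:
        raise ConstraintError("glomerular Starling balance non-positive at "
                              "baseline: no feasible K_fG")
    add("k_fg", j_gfr0 / net0, "mL/h/mmHg", "renal")

    j_pn0 = j_gfr0 * (1.0 - g["r_p0"])
    add("j_pn0", j_pn0, "mL/h", "renal")
    l0 = (g["r_n0"] - g["r_n_min"]) / (g["r_n_max"] - g["r_n_min"])
    if not 0.0 < l0 < 1.0:
        raise ConstraintError("descending-limb baseline fraction outside its "
                              "sigmoid range")
    add("j_n_mid", j_pn0 + g["s_n_rel"] * j_pn0 * math.log(l0 / (1.0 - l0)),
        "mL/h", "renal")
    f_gfr0 = j_gfr0 * g["na_plasma0"]
    f_ke0 = f_gfr0 * (1.0 - g["r_p0"]) * (1.0 - g["p_k"])
    add("f_ke0", f_ke0, "mEq/h", "renal")
    l0e = (g["p_e0"] - g["p_e_min"]) / (g["p_e_max"] - g["p_e_min"])
    if not 0.0 < l0e < 1.0:
        raise ConstraintError("early-distal baseline fraction outside its "
                              "sigmoid range")
    add("f_e_mid", f_ke0 + g["s_e_rel"] * f_ke0 * math.log(l0e / (1.0 - l0e)),
        "mEq/h", "renal")
    j_nk0 = j_pn0 * (1.0 - g["r_n0"])
    f_ec0 = f_ke0 * (1.0 - g["p_e0"])
    add("na_md0", f_ec0 / j_nk0, "mEq/mL", "hormones")
    j_uo0 = g["uo_rpf0"] * j_rpf0
    if not 0.0 < j_uo0 < j_nk0:
        raise ConstraintError(
            "baseline urine anchor infeasible: collecting-duct inflow "
            f"{j_nk0:.1f} mL/h cannot yield urine {j_uo0:.1f} mL/h")
    add("j_uo0", j_uo0, "mL/h", "renal")
    add("r_cd0", 1.0 - j_uo0 / j_nk0, "-", "renal")
    f_uo0 = f_ec0 * (1.0 - g["p_cd0"])
    add("f_uo0", f_uo0, "mEq/h", "renal")

    # --- maintenance intake balancing baseline urinary losses -------------
    add("maintenance_j", j_uo0, "mL/h", "volume_kinetics")
    add("maintenance_f", f_uo0, "mEq/h", "volume_kinetics")
    return ps


def initialize_state(profile: SubjectProfile,
                     params: ParameterSet) -> ModelState:
    """Pre-injury steady state; compartment sizes scale with weight and TBSA."""
    g = params.values() if isinstance(params, ParameterSet) else params
    for key in ("v_p0", "na_ecf0"):
        if key not in g:
            raise ValueError("parameter set is incomplete: run "
                             "derive_constrained_parameters first")
    return ModelState(v_p=g["v_p0"], a_p=g["a_p0"], v_bt=g["v_bt0"],
                      v_it=g["v_it0"], a_bt=g["a_bt0"], a_it=g["a_it0"],
                      na_ecf=g["na_ecf0"])


def baseline_operating_point(profile: SubjectProfile,
                             params: ParameterSet) -> BaselineOperatingPoint:
    """Evaluate the full algebraic model at the pre-injury steady state.

    Nothing here echoes the anchors: the CV equilibrium and the renal
    TGF fixed point are re-solved from scratch, so the returned ratios are
    genuine model outputs (they match the anchors because the constraint
    solver made the baseline a fixed point).
    """
    g = params.values()
    st = initialize_state(profile, params)
    v_b = st.v_p + g["rcv"]
    cvo = _cv.cv_outputs(v_b, st.c_angii, NEUTRAL_SIGNALS.m_map, g)
    pi_c = _vk.oncotic_pressure(st.a_p, st.v_p, g["k_pi"])
    na_p = _vk.plasma_sodium(st.na_ecf, st.v_p, st.v_bt, st.v_it)
    rs = _renal.renal_steady_flows(cvo.map, cvo.cvp, pi_c, na_p, st.c_angii,
                                   st.c_ald, st.c_adh, g)
    fl = rs.flows
    conc = {
        "B": na_p * 1e3,
        "P": (fl.f_pn / fl.j_pn) * 1e3,
        "N": (fl.f_nk / fl.j_nk) * 1e3,
        "K": (fl.f_ke / fl.j_nk) * 1e3,
        "E": fl.na_md * 1e3,
        "UO": fl.na_uo * 1e3,
    }
    return BaselineOperatingPoint(
        msp=cvo.msp, tpr=cvo.tpr, cvp=cvo.cvp, co=cvo.co, map=cvo.map,
        p_ra=rs.pressures.p_ra, p_rv=rs.pressures.p_rv, p_g=rs.pressures.p_g,
        pi_g=rs.pressures.pi_g, j_rpf=rs.j_rpf, j_gfr=fl.j_gfr,
        j_uo=fl.j_uo, f_uo=fl.f_uo, na_md=fl.na_md, na_plasma=na_p * 1e3,
        hct=_vk.hematocrit(st.v_p, g["rcv"]), pi_c=pi_c,
        filtration_fraction=fl.j_gfr / rs.j_rpf,
        uo_fraction_of_rpf=fl.j_uo / rs.j_rpf,
        fractions={"r_p": fl.r_p, "r_n": fl.r_n, "r_c": fl.r_c,
                   "p_k": fl.p_k, "p_e": fl.p_e, "p_c": fl.p_c},
        node_concentrations=conc)
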