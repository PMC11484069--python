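"""Coupled whole-body simulator and resuscitation protocol controllers.

``model_rhs`` wires the blocks per time step: perturbation signals ->
circulatory equilibrium (blood volume, Ang II, vasoactivity in; CO/CVP/MAP
out) -> kidney (MAP/CVP, plasma oncotic pressure and sodium, hormones in;
urine flow and composition, macula-densa sodium out) -> hormone derivatives
-> volume-kinetics derivatives. Four auxiliary quadrature states accumulate
urine volume, urinary sodium, dermal losses and denatured albumin so the
conservation ledgers close to integrator tolerance.

Integration is stiff-adaptive (LSODA) and proceeds segment-by-segment
between infusion-schedule breakpoints; protocol controllers review hourly
urine output and emit the next hour's rate, producing the realized schedule.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import cv as _cv
from . import renal as _renal
from . import vk as _vk
from .core import ModelState, ParameterSet, SubjectProfile, initialize_state
from .hormones import hormone_rhs
from .perturb import apply_perturbations

__all__ = ["InfusionSchedule", "ResuscitationProtocol", "SimulationResult",
           "model_rhs", "simulate", "run_protocol_controller", "hourly_uo",
           "OUTPUT_COLUMNS"]

log = logging.getLogger("burnsim")

N_STATES = 16  # 7 VK + 5 hormone/lag + 4 quadrature accumulators
STATE_COLUMNS = list(ModelState.NAMES) + ["cum_uo", "cum_fuo", "cum_dermal",
                                          "cum_denat"]
OUTPUT_COLUMNS = ["hct", "na_plasma", "pi_c", "msp", "tpr", "cvp", "co",
                  "map", "p_ra", "j_rpf", "j_gfr", "j_uo", "na_uo", "na_md",
                  "r_aff", "r_eff", "r_p", "r_n", "p_e", "r_c", "p_c",
                  "m_map", "j_infusion"]


@dataclass
class InfusionSchedule:
    """Piecewise-constant hourly IV fluid dose (left-closed intervals).

    ``breakpoints[i]`` starts the interval with ``rates[i]``; the last rate
    holds to the horizon. Composition defaults to Lactated Ringer's
    (Na 130 mEq/L, no albumin).
    """

    breakpoints: list[float] = field(default_factory=lambda: [0.0])
    rates: list[float] = field(default_factory=lambda: [0.0])
    fluid: str = "LR"
    na_conc: float = 0.130   # mEq/mL
    alb_conc: float = 0.0    # g/mL

    def __post_init__(self) -> None:
        if len(self.breakpoints) != len(self.rates):
            raise ValueError("breakpoints and rates must have equal length")
        if any(r < 0 for r in self.rates):
            raise ValueError("infusion rates must be non-negative")
        if any(nxt <= prev for prev, nxt in zip(self.breakpoints[:-1],
                                                self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")

    @classmethod
    def constant(cls, rate: float, start: float = 0.0,
                 **kw) -> "InfusionSchedule":
        if start > 0.0:
            return cls(breakpoints=[0.0, start], rates=[0.0, rate], **kw)
        return cls(breakpoints=[0.0], rates=[rate], **kw)

    def rate_at(self, t: float) -> float:
        if t < self.breakpoints[0]:
            return 0.0
        i = bisect.bisect_right(self.breakpoints, t) - 1
        return self.rates[i]

    def segment_edges(self, t0: float, t1: float) -> list[float]:
        edges = [t0] + [b for b in self.breakpoints if t0 < b < t1] + [t1]
        return edges


@dataclass
class ResuscitationProtocol:
    """Fluid-management policy generating an hourly infusion schedule.

    kinds: ``none`` (no IV fluid), ``fixed_rate`` (deliberate
    over-resuscitation at a constant high rate), ``uo_titrated``
    (urine-output banded multiplicative titration from a weight*TBSA
    Parkland-style initial rate).
    """

    kind: str = "uo_titrated"
    uo_band: tuple[float, float] = (30.0, 50.0)  # band units: see per_kg_band
    per_kg_band: bool = False     # True: band in mL/kg/h
    up_step: float = 1.25
    down_step: float = 0.8
    review_interval: float = 1.0  # hours
    fixed_rate: float = 500.0     # mL/h for kind="fixed_rate"
    max_rate: float = 4000.0
    start_time: float = 0.0       # resuscitation start, hours post-burn

    def __post_init__(self) -> None:
        if self.kind not in ("none", "fixed_rate", "uo_titrated"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.uo_band[0] >= self.uo_band[1]:
            raise ValueError("UO band low must be below high")
        if self.review_interval < 1.0:
            raise ValueError("review interval must be at least 1 h")

    @classmethod
    def paradigm(cls, name: str, species_protocol: dict | None = None,
                 **kw) -> "ResuscitationProtocol":
        """Pig paradigms P1/P2/P3 or a species preset's default policy."""
        name = name.upper()
        sp = species_protocol or {}
        base = dict(uo_band=(sp.get("uo_band_low", 30.0),
                             sp.get("uo_band_high", 50.0)),
                    per_kg_band=sp.get("per_kg_band", False),
                    fixed_rate=sp.get("fixed_rate", 500.0),
                    start_time=sp.get("start_delay_h", 0.0))
        base.update(kw)
        if name == "P1":
            return cls(kind="none", **{k: v for k, v in base.items()
                                       if k not in ("fixed_rate",)})
        if name == "P2":
            return cls(kind="uo_titrated", **base)
        if name == "P3":
            return cls(kind="fixed_rate", **base)
        raise ValueError(f"unknown paradigm {name!r}")

    def initial_rate(self, profile: SubjectProfile) -> float:
        """Parkland-style starting dose: 4 mL/kg per %TBSA over 24 h with
        half given in the first 8 h."""
        if self.kind == "none":
            return 0.0
        if self.kind == "fixed_rate":
            return self.fixed_rate
        total = 4.0 * profile.weight * profile.tbsa * 100.0
        return min(total / 2.0 / 8.0, self.max_rate)

    def band_for(self, profile: SubjectProfile) -> tuple[float, float]:
        lo, hi = self.uo_band
        if self.per_kg_band:
            return lo * profile.weight, hi * profile.weight
        return lo, hi


def run_protocol_controller(protocol: ResuscitationProtocol,
                            profile: SubjectProfile, t: float,
                            current_rate: float,
                            last_hour_uo: float | None) -> float:
    """Next interval's infusion rate at an hourly review point, mL/h."""
    if protocol.kind == "none" or t < protocol.start_time:
        return 0.0
    if protocol.kind == "fixed_rate":
        return protocol.fixed_rate
    if last_hour_uo is None or current_rate <= 0.0:
        # first active review (including after a delayed start): the
        # weight*TBSA formula dose, titrated thereafter
        return protocol.initial_rate(profile)
    lo, hi = protocol.band_for(profile)
    if last_hour_uo < lo:
        rate = current_rate * protocol.up_step
        action = "up"
    elif last_hour_uo > hi:
        rate = current_rate * protocol.down_step
        action = "down"
    else:
        rate, action = current_rate, "hold"
    rate = min(max(rate, 0.0), protocol.max_rate)
    log.info("controller t=%.1f h: UO=%.1f mL/h band=[%.1f, %.1f] -> %s "
             "rate %.1f mL/h", t, last_hour_uo, lo, hi, action, rate)
    return rate


@dataclass
class SimulationResult:
    """Dense predicted trajectories plus the realized infusion schedule."""

    data: pd.DataFrame
    schedule: InfusionSchedule
    profile: SubjectProfile
    params: ParameterSet | None = None

    @property
    def times(self) -> np.ndarray:
        return self.data["time_h"].to_numpy()

    def series(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def at(self, name: str, times) -> np.ndarray:
        """Linear interpolation of an output onto measurement times."""
        return np.interp(np.asarray(times, dtype=float),
                         self.times, self.series(name))


class _SimContext:
    """Mutable per-integration context: flat params, flags, warm starts."""

    __slots__ = ("g", "profile", "schedule", "perturb", "maintenance",
                 "warm_cvp", "warm_na_md")

    def __init__(self, g: dict, profile: SubjectProfile,
                 schedule: InfusionSchedule, perturb: bool,
                 maintenance: bool) -> None:
        self.g = g
        self.profile = profile
        self.schedule = schedule
        self.perturb = perturb
        self.maintenance = maintenance
        self.warm_cvp: float | None = None
        self.warm_na_md: float | None = None


def _algebraic(t: float, y, ctx: _SimContext):
    """Perturbations, CV equilibrium and renal block at one instant."""
    g = ctx.g
    sig = apply_perturbations(t, g, ctx.profile.tbsa, enabled=ctx.perturb)
    v_p = y[0]
    v_b = v_p + g["rcv"]
    # floor hormone states at a tiny positive value: the exact solution is
    # positive but adaptive steps may overshoot during fast decays
    c_angii = max(y[9], 1e-9)
    c_ald = max(y[10], 1e-9)
    c_adh = max(y[11], 1e-9)
    cvo = _cv.cv_outputs(v_b, c_angii, sig.m_map, g, warm=ctx.warm_cvp)
    ctx.warm_cvp = cvo.cvp
    pi_c = _vk.oncotic_pressure(y[1], v_p, g["k_pi"])
    na_p = _vk.plasma_sodium(y[6], v_p, y[2], y[3])
    rs = _renal.renal_steady_flows(cvo.map, cvo.cvp, pi_c, na_p, c_angii,
                                   c_ald, c_adh, g, warm_na_md=ctx.warm_na_md)
    ctx.warm_na_md = rs.flows.na_md
    return sig, cvo, pi_c, na_p, rs


def model_rhs(t: float, y, ctx: _SimContext):
    """Full coupled right-hand side (16 states: 12 model + 4 quadrature)."""
    g = ctx.g
    sig, cvo, pi_c, na_p, rs = _algebraic(t, y, ctx)
    fl = rs.flows
    j_sched = ctx.schedule.rate_at(t)
    j_i = j_sched + (g["maintenance_j"] if ctx.maintenance else 0.0)
    q_i = j_sched * ctx.schedule.alb_conc
    f_i = j_sched * ctx.schedule.na_conc \
        + (g["maintenance_f"] if ctx.maintenance else 0.0)
    _, fx = _vk.vk_fluxes(y[0], y[1], y[2], y[3], y[4], y[5], g, sig,
                          ctx.profile.tbsa, ctx.profile.weight)
    dvk = _vk.vk_rhs(y[0], y[1], y[2], y[3], y[4], y[5], fx, g,
                     sig.denat_rate, j_i, q_i, fl.j_uo, f_i, fl.f_uo)
    dh = hormone_rhs(fl.na_md, na_p, y[0], y[7], y[8], y[9], y[10], y[11], g)
    return [*dvk, *dh, fl.j_uo, fl.f_uo, fx.j_evap + fx.j_exud,
            sig.denat_rate * y[4]]


def _rhs_factory(ctx: _SimContext):
    def rhs(t, y):
        return model_rhs(t, y, ctx)

    return rhs


def _integrate_segments(ctx: _SimContext, y0, t0: float, t1: float,
                        dense_dt: float, rtol: float, atol):
    """LSODA over [t0, t1] with restarts at every schedule breakpoint."""
    rhs = _rhs_factory(ctx)
    ts_all, ys_all = [], []
    y = list(y0)
    for a, b in zip(ctx.schedule.segment_edges(t0, t1)[:-1],
                    ctx.schedule.segment_edges(t0, t1)[1:]):
        n = max(2, int(round((b - a) / dense_dt)) + 1)
        t_eval = np.linspace(a, b, n)
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise ArithmeticError(
                f"integration failed in [{a:.2f}, {b:.2f}] h: {sol.message}; "
                f"last state {sol.y[:, -1] if sol.y.size else y}")
        keep = slice(1, None) if ts_all else slice(None)
        ts_all.append(sol.t[keep])
        ys_all.append(sol.y[:, keep])
        y = sol.y[:, -1].tolist()
    return np.concatenate(ts_all), np.concatenate(ys_all, axis=1), y


def _default_atol(g: dict):
    base = [g["v_p0"], g["a_p0"], g["v_bt0"], g["v_it0"], g["a_bt0"],
            g["a_it0"], g["na_ecf0"], 1.0, 1.0, 1.0, 1.0, 1.0,
            g["j_uo0"], g["f_uo0"], 1.0, 1.0]
    return [1e-8 * max(abs(b), 1.0) for b in base]


def _outputs_frame(ts, ys, ctx: _SimContext) -> pd.DataFrame:
    rows = np.empty((len(ts), len(OUTPUT_COLUMNS)))
    g = ctx.g
    for i, t in enumerate(ts):
        y = ys[:, i]
        sig, cvo, pi_c, na_p, rs = _algebraic(float(t), y, ctx)
        fl = rs.flows
        rows[i] = [
            _vk.hematocrit(y[0], g["rcv"]), na_p * 1e3, pi_c, cvo.msp,
            cvo.tpr, cvo.cvp, cvo.co, cvo.map, rs.pressures.p_ra, rs.j_rpf,
            fl.j_gfr, fl.j_uo, fl.na_uo * 1e3, fl.na_md * 1e3,
            rs.resistances.r_aff, rs.resistances.r_eff, fl.r_p, fl.r_n,
            fl.p_e, fl.r_c, fl.p_c, sig.m_map,
            ctx.schedule.rate_at(float(t)),
        ]
    df = pd.DataFrame(ys.T, columns=STATE_COLUMNS)
    df.insert(0, "time_h", ts)
    return pd.concat([df, pd.DataFrame(rows, columns=OUTPUT_COLUMNS)], axis=1)


def simulate(profile: SubjectProfile, params: ParameterSet | dict,
             schedule: InfusionSchedule | None = None,
             protocol: ResuscitationProtocol | None = None,
             horizon: float = 24.0, perturbations: bool = True,
             maintenance: bool = False, dense_dt: float = 0.1,
             rtol: float = 1e-6, initial_state: ModelState | None = None,
             ) -> SimulationResult:
    """Integrate the coupled model over the resuscitation horizon.

    Exactly one of ``schedule`` / ``protocol`` drives the fluid input; a
    protocol is executed with hourly reviews and its realized schedule is
    returned with the result. ``maintenance=True`` adds the pre-injury
    maintenance intake (used for steady-state hold experiments).
    Deterministic given inputs.
    """
    if (schedule is None) == (protocol is None):
        raise ValueError("provide exactly one of schedule or protocol")
    pset = params if isinstance(params, ParameterSet) else None
    g = params.values() if isinstance(params, ParameterSet) else dict(params)
    if "v_p0" not in g:
        raise ValueError("parameter set incomplete: run "
                         "derive_constrained_parameters first")
    state0 = initial_state or initialize_state(profile, pset or g)
    y0 = state0.to_vector() + [0.0, 0.0, 0.0, 0.0]
    atol = _default_atol(g)

    if protocol is None:
        ctx = _SimContext(g, profile, schedule, perturbations, maintenance)
        ts, ys, _ = _integrate_segments(ctx, y0, 0.0, horizon, dense_dt,
                                        rtol, atol)
        df = _outputs_frame(ts, ys, ctx)
        return SimulationResult(df, schedule, profile, pset)

    # protocol-driven: hourly reviews build the schedule incrementally
    breakpoints, rates = [0.0], [run_protocol_controller(
        protocol, profile, 0.0, 0.0, None)]
    sched = InfusionSchedule(breakpoints=list(breakpoints), rates=list(rates))
    ctx = _SimContext(g, profile, sched, perturbations, maintenance)
    ts_all, ys_all = [], []
    y = y0
    last_cum_uo = 0.0
    t = 0.0
    review = max(1.0, protocol.review_interval)
    while t < horizon - 1e-9:
        t_next = min(t + review, horizon)
        ctx.schedule = sched
        ts, ys, y = _integrate_segments(ctx, y, t, t_next, dense_dt, rtol,
                                        atol)
        keep = slice(1, None) if ts_all else slice(None)
        ts_all.append(ts[keep])
        ys_all.append(ys[:, keep])
        uo_hour = (y[12] - last_cum_uo) / (t_next - t)
        last_cum_uo = y[12]
        t = t_next
        if t < horizon - 1e-9:
            new_rate = run_protocol_controller(protocol, profile, t,
                                               sched.rates[-1], uo_hour)
            if new_rate != sched.rates[-1]:
                breakpoints.append(t)
                rates.append(new_rate)
                sched = InfusionSchedule(breakpoints=list(breakpoints),
                                         rates=list(rates))
    ts = np.concatenate(ts_all)
    ys = np.concatenate(ys_all, axis=1)
    ctx.schedule = sched
    df = _outputs_frame(ts, ys, ctx)
    return SimulationResult(df, sched, profile, pset)


def hourly_uo(result: SimulationResult) -> pd.DataFrame:
    """Hourly urine output (mL/h over each preceding hour) from the
    cumulative urine quadrature state."""
    t = result.times
    cum = result.series("cum_uo")
    hours = np.arange(1.0, math.floor(t[-1] + 1e-9) + 1.0)
    uo = np.interp(hours, t, cum) - np.interp(hours - 1.0, t, cum)
    return pd.DataFrame({"time_h": hours, "uo_mL_per_h": uo})
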