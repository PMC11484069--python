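"""Shared fixtures: solved presets and session-scoped reference simulations."""

import numpy as np
import pytest

import burnsim as bs


@pytest.fixture(scope="session")
def human():
    profile = bs.default_profile("human", weight=70.0)
    params = bs.derive_constrained_parameters(profile,
                                              bs.load_preset("human"))
    return profile, params


@pytest.fixture(scope="session")
def pig():
    profile = bs.default_profile("pig")
    params = bs.derive_constrained_parameters(profile, bs.load_preset("pig"))
    return profile, params


@pytest.fixture(scope="session")
def human_baseline(human):
    profile, params = human
    return bs.baseline_operating_point(profile, params)


@pytest.fixture(scope="session")
def human_sweep(human):
    _, params = human
    return bs.pra_sweep(params)


@pytest.fixture(scope="session")
def pig_paradigm_results(pig):
    """P1/P2/P3 24 h pig simulations under the preset protocols."""
    profile, params = pig
    meta = bs.preset_meta("pig")["protocol"]
    out = {}
    for name in ("P1", "P2", "P3"):
        proto = bs.ResuscitationProtocol.paradigm(name, meta)
        out[name] = bs.simulate(profile, params, protocol=proto,
                                horizon=24.0)
    return out


@pytest.fixture(scope="session")
def hold_result(human):
    """48 h unperturbed hold with maintenance intake."""
    profile, params = human
    return bs.simulate(profile, params, schedule=bs.InfusionSchedule(),
                       horizon=48.0, perturbations=False, maintenance=True)


def total_infused(result) -> float:
    """Analytic infused volume of a piecewise-constant schedule, mL."""
    sched = result.schedule
    t_end = float(result.times[-1])
    edges = list(sched.breakpoints) + [t_end]
    return sum(rate * (edges[i + 1] - edges[i])
               for i, rate in enumerate(sched.rates))


def conservation_errors(result) -> dict:
    """Relative closure of the water/albumin/sodium ledgers."""
    d = result.data
    vol_in = total_infused(result)
    tw = d.v_p + d.v_bt + d.v_it
    water = ((tw.iloc[-1] - tw.iloc[0])
             - (vol_in - d.cum_uo.iloc[-1] - d.cum_dermal.iloc[-1]))
    ta = d.a_p + d.a_bt + d.a_it
    alb_in = vol_in * result.schedule.alb_conc
    albumin = (ta.iloc[-1] - ta.iloc[0]) - (alb_in - d.cum_denat.iloc[-1])
    na_in = vol_in * result.schedule.na_conc
    sodium = ((d.na_ecf.iloc[-1] - d.na_ecf.iloc[0])
              - (na_in - d.cum_fuo.iloc[-1]))
    return {"water": abs(water) / tw.iloc[0],
            "albumin": abs(albumin) / ta.iloc[0],
            "sodium": abs(sodium) / d.na_ecf.iloc[0]}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
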