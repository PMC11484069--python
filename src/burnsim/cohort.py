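"""Synthetic virtual-patient cohorts.

Generates subjects from the species demographic distributions (pig 31.7 +/-
4.2 kg at 40% TBSA; sheep 40 kg at 40%; human 85 +/- 18 kg, 42 +/- 18%
TBSA), draws ground-truth subject-specific parameters uniformly within
configurable sampling ranges, simulates them under a resuscitation
paradigm, and samples the species' measurement schedules (pig: hourly UO
plus HCT/MAP/CO/CVP/Na at hours 0,1,2,3,5,9,12,18,24 over 24 h; sheep:
48 h hourly UO with sparse others; human: hourly UO only) with
multiplicative Gaussian observation noise. Everything is deterministic
given (seed, subject index), so fixtures regenerate byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (ParameterSet, SubjectProfile, default_profile,
                   derive_constrained_parameters, load_preset, preset_meta)
from .fit import MeasurementSet, default_normalization, predict_measurements
from .sim import (InfusionSchedule, ResuscitationProtocol, SimulationResult,
                  simulate)

__all__ = ["CohortSpec", "DEFAULT_NOISE_CV", "DEFAULT_SAMPLING_RANGES",
           "sample_subject", "measurement_schedule", "observe",
           "simulate_subject", "generate_cohort"]

#: per-variable multiplicative observation-noise coefficients of variation
DEFAULT_NOISE_CV = {"uo": 0.10, "hct": 0.02, "co": 0.05, "map": 0.05,
                    "cvp": 0.10, "na": 0.01}

#: plausible inter-individual ranges for the default sampled perturbation
#: parameters (subsets of the registered bounds)
DEFAULT_SAMPLING_RANGES = {
    "amp_kf_bt": (1.0, 6.0),
    "amp_kf_sys": (0.2, 1.5),
    "k_msp": (1.5, 5.0),
    "amp_constrict": (0.05, 0.6),
    "k_evap": (0.5, 3.0),
}

#: pig sparse-variable measurement hours
PIG_SPARSE_HOURS = (0.0, 1.0, 2.0, 3.0, 5.0, 9.0, 12.0, 18.0, 24.0)
SHEEP_SPARSE_HOURS = (0.0, 2.0, 4.0, 8.0, 12.0, 16.0, 24.0, 32.0, 40.0, 48.0)


@dataclass
class CohortSpec:
    """Everything needed to regenerate a cohort deterministically."""

    species: str
    n: int = 10
    seed: int = 0
    paradigms: tuple[str, ...] = ("P2",)   # cycled over subjects
    sampling_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLING_RANGES))
    noise_cv: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_CV))
    horizon: float | None = None   # default: species protocol horizon

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be positive")
        free = load_preset(self.species)
        for name, (lo, hi) in self.sampling_ranges.items():
            q = free.get(name)
            if q.cls != "subject_specific":
                raise ValueError(f"{name} is not subject_specific")
            if lo < q.lower or hi > q.upper or lo >= hi:
                raise ValueError(f"sampling range for {name} must lie "
                                 f"within the registered bounds "
                                 f"[{q.lower}, {q.upper}]")


def sample_subject(spec: CohortSpec,
                   index: int) -> tuple[SubjectProfile, ParameterSet]:
    """Draw one subject and its ground-truth free parameter set."""
    rng = np.random.default_rng([spec.seed, index])
    meta = preset_meta(spec.species)["subject_defaults"]
    w = meta["weight"]
    if meta.get("weight_sd", 0.0) > 0.0:
        for _ in range(100):
            w = rng.normal(meta["weight"], meta["weight_sd"])
            if 0.3 * meta["weight"] < w:
                break
    tbsa = meta["tbsa"]
    if meta.get("tbsa_sd", 0.0) > 0.0:
        for _ in range(100):
            tbsa = rng.normal(meta["tbsa"], meta["tbsa_sd"])
            if 0.05 < tbsa < 0.95:
                break
    profile = SubjectProfile(species=spec.species, weight=float(w),
                             tbsa=float(tbsa), hct0=meta["hct0"],
                             subject_id=f"{spec.species}-{index:03d}")
    free = load_preset(spec.species)
    draws = {name: float(rng.uniform(lo, hi))
             for name, (lo, hi) in sorted(spec.sampling_ranges.items())}
    return profile, free.updated(**draws)


def measurement_schedule(species: str) -> tuple[dict[str, np.ndarray],
                                                set[str]]:
    """Per-variable measurement time grids and default exclusions.

    Pig HCT is generated but excluded from fits by default (the animals'
    contractile spleen autotransfuses, so HCT does not track plasma volume).
    """
    if species == "pig":
        grids = {"uo": np.arange(1.0, 24.0 + 1e-9)}
        for var in ("hct", "co", "map", "cvp", "na"):
            grids[var] = np.array(PIG_SPARSE_HOURS)
        return grids, {"hct"}
    if species == "sheep":
        grids = {"uo": np.arange(1.0, 48.0 + 1e-9)}
        for var in ("hct", "cvp", "map", "co"):
            grids[var] = np.array(SHEEP_SPARSE_HOURS)
        return grids, set()
    if species == "human":
        return {"uo": np.arange(1.0, 24.0 + 1e-9)}, set()
    raise ValueError(f"unknown species {species!r}")


def observe(result: SimulationResult, grids: dict[str, np.ndarray],
            noise_cv: dict[str, float], seed: int,
            normalization: dict[str, float] | None = None) -> MeasurementSet:
    """Sample trajectories on the grids with multiplicative Gaussian noise.

    Instantaneous variables interpolate the dense trajectory; urine output
    is the true hourly collection (from the cumulative urine state). Noisy
    draws are floored at zero. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    probe = MeasurementSet({v: (t, np.zeros_like(t))
                            for v, t in grids.items()})
    clean = predict_measurements(result, probe)
    data = {}
    for var in grids:
        t = np.asarray(grids[var], dtype=float)
        v = clean[var]
        cv = noise_cv.get(var, 0.0)
        if cv > 0.0:
            v = v * (1.0 + cv * rng.standard_normal(len(v)))
        data[var] = (t, np.maximum(v, 0.0))
    return MeasurementSet(data, normalization=normalization or {},
                          subject_id=result.profile.subject_id)


def simulate_subject(spec: CohortSpec, index: int,
                     noiseless: bool = False):
    """sample -> simulate under the paradigm -> observe.

    Returns (profile, truth_free_params, result, measurements). The
    realized infusion schedule (result.schedule) is the known input for
    fitting, mirroring datasets where hourly infusion rates are recorded.
    """
    profile, truth = sample_subject(spec, index)
    params = derive_constrained_parameters(profile, truth)
    meta = preset_meta(spec.species)["protocol"]
    paradigm = spec.paradigms[index % len(spec.paradigms)]
    protocol = ResuscitationProtocol.paradigm(paradigm, meta)
    horizon = spec.horizon or meta["horizon_h"]
    result = simulate(profile, params, protocol=protocol, horizon=horizon)
    grids, excluded = measurement_schedule(spec.species)
    grids = {v: t for v, t in grids.items() if v not in excluded}
    noise = ({v: 0.0 for v in spec.noise_cv} if noiseless
             else spec.noise_cv)
    norm = default_normalization(profile, params, meta)
    meas = observe(result, grids, noise, seed=spec.seed * 100003 + index,
                   normalization={v: norm[v] for v in grids})
    return profile, truth, result, meas


def generate_cohort(spec: CohortSpec, outdir) -> list[str]:
    """Write per-subject profile, truth parameters, infusion and
    measurement files; returns the subject ids."""
    from pathlib import Path

    from . import io as _io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ids = []
    for i in range(spec.n):
        profile, truth, result, meas = simulate_subject(spec, i)
        sub = out / profile.subject_id
        sub.mkdir(exist_ok=True)
        _io.write_profile(sub / "profile.yaml", profile)
        truth.to_yaml(sub / "truth_params.yaml")
        _io.write_schedule(sub / "infusion.csv", result.schedule)
        _io.write_measurements(sub / "measurements.csv", meas)
        ids.append(profile.subject_id)
    return ids
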