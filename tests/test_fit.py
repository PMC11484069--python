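"""Estimation cost, multi-start fitting, sensitivity ranking, metrics."""

import numpy as np
import pytest

import burnsim as bs
from burnsim.fit import (FitConfig, MeasurementSet, bland_altman,
                         cost_function, nmae, pearson_r, uo_range_agreement)


def test_measurement_set_validation():
    with pytest.raises(ValueError, match="unknown"):
        MeasurementSet({"bogus": ([1.0], [2.0])})
    with pytest.raises(ValueError, match="increasing"):
        MeasurementSet({"map": ([2.0, 1.0], [90.0, 91.0])})
    ms = MeasurementSet({"map": ([1.0, 3.0], [90.0, 91.0]),
                         "uo": ([1.0, 2.0, 24.0], [30.0, 40.0, 50.0])})
    assert ms.horizon == 24.0 and ms.n_points() == 5


def test_cost_single_point_example(human):
    """One variable, one point: y_meas 10, y_pred 8, Y 10 -> cost 0.04."""
    res = np.array([(10.0 - 8.0) / 10.0])
    assert res @ res == pytest.approx(0.04)


def test_cost_zero_for_exact_predictions_and_order_invariance(human):
    profile, params = human
    sched = bs.InfusionSchedule.constant(100.0)
    result = bs.simulate(profile, params, schedule=sched, horizon=6.0)
    t = np.array([1.0, 2.0, 4.0, 6.0])
    norm = bs.default_normalization(profile, params)
    from burnsim.fit import predict_measurements
    probe = MeasurementSet({"map": (t, np.zeros_like(t)),
                            "hct": (t, np.zeros_like(t))})
    clean = predict_measurements(result, probe)
    meas = MeasurementSet({"map": (t, clean["map"]),
                           "hct": (t, clean["hct"])},
                          normalization={k: norm[k]
                                         for k in ("map", "hct")})
    free = params.free()
    theta = [free["amp_kf_bt"], free["k_msp"]]
    c = cost_function(theta, ["amp_kf_bt", "k_msp"], profile, free, sched,
                      meas)
    assert c == pytest.approx(0.0, abs=1e-8)
    # measurement ordering (dict insertion order) does not change the cost
    meas2 = MeasurementSet({"hct": (t, clean["hct"]),
                            "map": (t, clean["map"])},
                           normalization={k: norm[k]
                                          for k in ("map", "hct")})
    c2 = cost_function(theta, ["amp_kf_bt", "k_msp"], profile, free, sched,
                       meas2)
    assert c2 == pytest.approx(c, abs=1e-12)


def test_fit_respects_bounds_and_reevaluates(human):
    """A tiny fit returns in-bounds parameters whose cost reproduces
    FitResult.cost on re-evaluation."""
    profile, params = human
    free = params.free()
    sched = bs.InfusionSchedule.constant(150.0)
    truth = free.updated(amp_kf_bt=4.0)
    full = bs.derive_constrained_parameters(profile, truth)
    result = bs.simulate(profile, full, schedule=sched, horizon=6.0)
    t = np.arange(1.0, 6.1)
    from burnsim.fit import predict_measurements
    probe = MeasurementSet({"hct": (t, np.zeros_like(t)),
                            "cvp": (t, np.zeros_like(t))})
    clean = predict_measurements(result, probe)
    norm = bs.default_normalization(profile, full)
    meas = MeasurementSet({"hct": (t, clean["hct"]),
                           "cvp": (t, clean["cvp"])},
                          normalization={k: norm[k]
                                         for k in ("hct", "cvp")})
    cfg = FitConfig(free_names=["amp_kf_bt"], n_starts=3, seed=11,
                    max_nfev=20)
    fr = bs.fit_subject(cfg, profile, sched, meas, params)
    q = free.get("amp_kf_bt")
    assert q.lower <= fr.theta["amp_kf_bt"] <= q.upper
    assert fr.theta["amp_kf_bt"] == pytest.approx(4.0, rel=0.05)
    c = cost_function([fr.theta["amp_kf_bt"]], ["amp_kf_bt"], profile, free,
                      sched, meas)
    assert c == pytest.approx(fr.cost, rel=1e-6, abs=1e-12)
    # search effort is monotone: more starts can only lower the cost
    fr1 = bs.fit_subject(FitConfig(free_names=["amp_kf_bt"], n_starts=1,
                                   seed=11, max_nfev=6),
                         profile, sched, meas, params)
    assert fr.cost <= fr1.cost + 1e-15


def test_fit_rejects_non_subject_specific(human):
    profile, params = human
    meas = MeasurementSet({"map": ([1.0], [90.0])},
                          normalization={"map": 93.0})
    cfg = FitConfig(free_names=["pra0"], n_starts=1)
    with pytest.raises(ValueError, match="subject_specific"):
        bs.fit_subject(cfg, profile, bs.InfusionSchedule(), meas, params)


def test_sensitivity_rank_structural_zero_and_invariance(human):
    """A near-vanishing burnt-tissue compartment makes its perturbation
    amplitude the least sensitive parameter; ranking does not depend on the
    candidate ordering; the human configuration returns a 10-name set."""
    params = bs.load_preset("human")
    profile = bs.SubjectProfile("human", 70.0, 1e-4, 0.40)
    full = bs.derive_constrained_parameters(profile, params)
    sched = bs.InfusionSchedule.constant(100.0)
    result = bs.simulate(profile, full, schedule=sched, horizon=4.0)
    t = np.array([1.0, 2.0, 4.0])
    from burnsim.fit import predict_measurements
    probe = MeasurementSet({"map": (t, np.zeros_like(t)),
                            "hct": (t, np.zeros_like(t))})
    clean = predict_measurements(result, probe)
    norm = bs.default_normalization(profile, full)
    meas = MeasurementSet({"map": (t, clean["map"]),
                           "hct": (t, clean["hct"])},
                          normalization={k: norm[k]
                                         for k in ("map", "hct")})
    pop = [(profile, sched, meas), (profile, sched, meas)]
    cands = ["amp_kf_bt", "amp_kf_sys", "k_msp", "amp_constrict"]
    ranked, kept = bs.sensitivity_rank(pop, cands, params, m=2,
                                       fit_population=False)
    assert ranked[-1][0] == "amp_kf_bt"     # burnt-tissue channel inert
    assert ranked[-1][1] < 0.01 * ranked[0][1]
    ranked2, _ = bs.sensitivity_rank(pop, list(reversed(cands)), params,
                                     m=2, fit_population=False)
    assert [n for n, _ in ranked] == [n for n, _ in ranked2]
    # human-style reduction: 12 candidates down to a free set of 10
    twelve = cands + ["amp_sigma_bt", "amp_sigma_sys", "amp_pbt",
                      "amp_dilate", "k_evap", "k_exud", "g_renin",
                      "w_v_adh"]
    _, kept10 = bs.sensitivity_rank(pop, twelve, params, m=10,
                                    fit_population=False)
    assert len(kept10) == 10


def test_nmae():
    assert nmae([1.0, 2.0], [1.0, 2.0], 10.0) == 0.0
    assert nmae([12.0], [10.0], 10.0) == pytest.approx(20.0)
    with pytest.raises(ValueError):
        nmae([1.0], [1.0], 0.0)


def test_pearson_r():
    assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
    assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
    assert pearson_r([1.0, 1.0], [1.0, 1.0]) == 1.0  # guarded degenerate
    with pytest.raises(ValueError):
        pearson_r([1.0], [1.0])


def test_bland_altman_hand_calculation():
    """diffs = [+1, -1]: bias 0, sample SD = sqrt(2), LoA = 0 +/- 2*1.414."""
    bias, half = bland_altman([11.0, 9.0], [10.0, 10.0])
    assert bias == pytest.approx(0.0)
    assert half == pytest.approx(2.0 * np.sqrt(2.0))
    bias2, half2 = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert bias2 == 0.0 and half2 == 0.0
    with pytest.raises(ValueError):
        bland_altman([1.0], [1.0])


def test_uo_range_agreement_bins():
    # pig bins: <1, 1-1.5, >1.5 mL/h/kg; 1.2 and 1.4 share the middle bin
    assert uo_range_agreement([1.2], [1.4], (1.0, 1.5)) == 100.0
    assert uo_range_agreement([0.8, 1.2, 2.0], [1.1, 1.2, 1.9],
                              (1.0, 1.5)) == pytest.approx(200.0 / 3.0)
    assert uo_range_agreement([0.4], [0.9], (0.5, 1.0)) == 0.0
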