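"""Transient burn-injury perturbation signals.

Each perturbation channel (capillary leak, reflection-coefficient drop,
burnt-tissue negative pressure, protein denaturation, systemic
vasoconstriction/vasodilation, wound gate) follows a normalized
double-exponential time course that is zero pre-injury, peaks at its
subject-specific amplitude, and decays back to baseline - encoding the
"transient and disappearing" character of the post-burn inflammatory
disturbance. Severity is carried by the amplitudes; kinetics by the paired
onset/decay time constants tau1 < tau2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["PerturbationSignals", "perturbation_timecourse",
           "apply_perturbations", "NEUTRAL_SIGNALS"]


@dataclass
class PerturbationSignals:
    """Channel values at a given time, mapped onto model quantities."""

    kf_bt_mult: float = 1.0     # multiplies burnt-tissue filtration coefficient
    kf_it_mult: float = 1.0     # multiplies intact-tissue filtration coefficient
    sigma_bt_mult: float = 1.0  # multiplies burnt-tissue sigma, clipped to [0,1]
    sigma_it_mult: float = 1.0
    pbt_offset: float = 0.0     # burnt-tissue negative-pressure magnitude, mmHg
    denat_rate: float = 0.0     # albumin denaturation rate in burnt tissue, 1/h
    m_map: float = 1.0          # net vasoactivity multiplier on the MAP equation
    wound_gate: float = 0.0     # 0..1 gate for dermal losses


NEUTRAL_SIGNALS = PerturbationSignals()


def perturbation_timecourse(t: float, amplitude: float, tau1: float,
                            tau2: float) -> float:
    """Amplitude-normalized double exponential exp(-t/tau2) - exp(-t/tau1).

    Zero for t < 0; peaks at exactly ``amplitude`` at
    t* = tau1*tau2/(tau2-tau1)*ln(tau2/tau1); decays to zero afterwards.
    """
    if tau1 >= tau2:
        raise ValueError("onset time constant tau1 must be < decay tau2")
    if t <= 0.0 or amplitude == 0.0:
        return 0.0
    t_peak = tau1 * tau2 / (tau2 - tau1) * math.log(tau2 / tau1)
    peak = math.exp(-t_peak / tau2) - math.exp(-t_peak / tau1)
    return amplitude * (math.exp(-t / tau2) - math.exp(-t / tau1)) / peak


def apply_perturbations(t: float, p: dict, tbsa: float,
                        enabled: bool = True) -> PerturbationSignals:
    """Evaluate every channel at time t and map onto model multipliers.

    With ``enabled=False`` (or pre-injury t <= 0) returns neutral signals, so
    the unperturbed model is recovered exactly. The systemic capillary
    channels act on both tissues; the burnt-tissue channels add the larger,
    faster local destruction on top.
    """
    if not enabled or t <= 0.0 or tbsa <= 0.0:
        return NEUTRAL_SIGNALS
    d_kf_bt = perturbation_timecourse(t, p["amp_kf_bt"], p["tau1_cap"],
                                      p["tau2_cap"])
    d_kf_sys = perturbation_timecourse(t, p["amp_kf_sys"], p["tau1_sys"],
                                       p["tau2_sys"])
    d_sig_bt = perturbation_timecourse(t, p["amp_sigma_bt"], p["tau1_cap"],
                                       p["tau2_cap"])
    d_sig_sys = perturbation_timecourse(t, p["amp_sigma_sys"], p["tau1_sys"],
                                        p["tau2_sys"])
    d_pbt = perturbation_timecourse(t, p["amp_pbt"], p["tau1_pbt"],
                                    p["tau2_pbt"])
    d_den = perturbation_timecourse(t, p["amp_denat"], p["tau1_den"],
                                    p["tau2_den"])
    d_vc = perturbation_timecourse(t, p["amp_constrict"], p["tau1_vc"],
                                   p["tau2_vc"])
    d_vd = perturbation_timecourse(t, p["amp_dilate"], p["tau1_vd"],
                                   p["tau2_vd"])
    gate = perturbation_timecourse(t, 1.0, p["tau1_wound"], p["tau2_wound"])
    return PerturbationSignals(
        kf_bt_mult=1.0 + d_kf_bt + d_kf_sys,
        kf_it_mult=1.0 + d_kf_sys,
        sigma_bt_mult=min(1.0, max(0.0, 1.0 - d_sig_bt - d_sig_sys)),
        sigma_it_mult=min(1.0, max(0.0, 1.0 - d_sig_sys)),
        pbt_offset=d_pbt,
        denat_rate=d_den,
        m_map=max(0.1, 1.0 + d_vc - d_vd),
        wound_gate=gate,
    )
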