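"""Parameter-recovery experiments: simulate -> idealize -> summarize loops.

These functions quantify how well the analysis chain recovers known
generator truths (conductance, open probability) under realistic recording
conditions.  They are the basis of the package's reproduction checks and are
useful on their own to gauge estimator bias for new recording settings.

Record lengths follow typical bench practice (30 s per voltage for i/V
fits, 120-300 s single-voltage records for low-open-probability channels);
noise levels are set by signal-to-noise ratio, defined here as the smallest
open-channel amplitude of the experiment divided by the noise sd.
"""

from __future__ import annotations

import numpy as np

from .chanparams import build_relations, fit_conductance
from .gatingsim import (
    AcquisitionConfig,
    GatingModel,
    VoltageProtocol,
    simulate_recording,
    slow_gate_model,
    wildtype_model,
)
from .idealize import DetectorConfig
from .pipeline import idealize_recording

__all__ = [
    "recover_conductance",
    "recover_po",
    "recover_conductance_ratio",
    "l94c_like_model",
    "l94m_like_model",
    "l94r_like_model",
]

#: Printed reference values the recovery experiments are configured with.
WT_G_PS = 174.0
WT_PO_M160 = 0.034
WT_PO_P160 = 0.005
L94C_PO_MAX = 0.4
L94M_PO_M100 = 0.005
L94R_G_FOLD = 4.3


def _seed_children(seed, n: int) -> list[np.random.SeedSequence]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ss.spawn(n)


def l94c_like_model() -> GatingModel:
    """High open probability at negative voltages (max P_O ~ 0.4)."""
    return slow_gate_model(
        "L94C-like", g_true=170.0, p_neg=L94C_PO_MAX, p_pos=0.06, k_close0=20.0
    )


def l94m_like_model() -> GatingModel:
    """Very low, voltage-independent open probability (~0.005 at -100 mV)."""
    return slow_gate_model(
        "L94M-like", g_true=170.0, p_neg=L94M_PO_M100, p_pos=L94M_PO_M100,
        k_close0=50.0,
    )


def l94r_like_model(flicker: bool = True) -> GatingModel:
    """Reduced conductance: WT conductance divided by 4.3."""
    wt = wildtype_model(flicker=flicker)
    from dataclasses import replace

    return replace(wt, genotype_label="L94R-like", g_true=WT_G_PS / L94R_G_FOLD)


def recover_conductance(
    seed=0,
    model: GatingModel | None = None,
    voltages: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0, 100.0),
    duration: float = 30.0,
    n_seeds: int = 10,
    snr: float = 8.0,
    fit_lo: float = 0.0,
    fit_hi: float = 100.0,
) -> list[float]:
    """Fitted conductance (pS) per seed for the full pipeline.

    The noise sd is chosen so that the smallest open-channel amplitude in
    the protocol has the requested signal-to-noise ratio.
    """
    model = model or wildtype_model()
    i_min = min(abs(model.i_true(v)) for v in voltages)
    noise_sd = i_min / snr
    protocol = VoltageProtocol(voltages=voltages, per_voltage_duration=duration)
    acq = AcquisitionConfig(noise_sd=noise_sd, duration=duration)
    detector = DetectorConfig()
    out = []
    for child in _seed_children(seed, n_seeds):
        recording = simulate_recording(model, protocol, acq, child)
        iv, _ = build_relations(idealize_recording(recording, detector))
        out.append(fit_conductance(iv, fit_lo, fit_hi))
    return out


def recover_po(
    seed=0,
    model: GatingModel | None = None,
    voltages: tuple[float, ...] = (-160.0,),
    duration: float = 120.0,
    n_seeds: int = 10,
    snr: float = 10.0,
) -> list[float]:
    """Maximal recovered per-voltage open probability per seed.

    Flicker is disabled: the recovered open probability is then the slow
    gate's conducting fraction, directly comparable with the configured
    stationary value.  With a single voltage this is simply the recovered
    P_O there.
    """
    model = (model or wildtype_model()).without_flicker()
    i_min = min(abs(model.i_true(v)) for v in voltages)
    noise_sd = i_min / snr
    protocol = VoltageProtocol(voltages=voltages, per_voltage_duration=duration)
    acq = AcquisitionConfig(noise_sd=noise_sd, duration=duration)
    detector = DetectorConfig()
    out = []
    for child in _seed_children(seed, n_seeds):
        recording = simulate_recording(model, protocol, acq, child)
        results = idealize_recording(recording, detector)
        out.append(max(po for _, _, po in results))
    return out


def recover_conductance_ratio(
    seed=0,
    n_seeds: int = 10,
    duration: float = 30.0,
    snr: float = 8.0,
) -> list[float]:
    """Per-seed ratio of fitted WT to reduced-conductance-variant conductance."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    wt_ss, mut_ss = ss.spawn(2)
    wt_g = recover_conductance(
        wt_ss, model=wildtype_model(), duration=duration, n_seeds=n_seeds, snr=snr
    )
    mut_g = recover_conductance(
        mut_ss, model=l94r_like_model(), duration=duration, n_seeds=n_seeds, snr=snr
    )
    return [a / b for a, b in zip(wt_g, mut_g)]
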