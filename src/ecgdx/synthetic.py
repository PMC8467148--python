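"""Synthetic 12-lead ECG generator with programmable morphology.

Records are built from template beats (raised-cosine P/QRS/T lobes; the
"M-shaped" bundle-branch morphology is a sum of Gaussians) placed on an RR
grid drawn from a truncated normal and then affinely standardised so the
realised RR mean and standard deviation equal the programmed values exactly
— ground-truth intervals and rhythm statistics are exact by construction,
which is what feature-recovery tests need.  Limb-lead QRS amplitudes are the
projection of a frontal vector onto the hexaxial lead directions, so the
programmed electrical axis is recoverable from leads I and aVF.

Each preset is a parameter bundle whose generated record drives one
diagnostic rule; f-wave frequencies for the flutter/fibrillation presets are
stylised discriminative settings (see docs), not clinical atrial rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .features import FeatureSet
from .io import ECGRecord, LEAD_ORDER

#: Hexaxial limb-lead directions, clockwise-positive degrees from lead I.
LIMB_ANGLES = {"I": 0.0, "II": 60.0, "III": 120.0, "aVR": -150.0, "aVL": -30.0, "aVF": 90.0}
CHEST_LEADS = ("V1", "V2", "V3", "V4", "V5", "V6")
DEFAULT_CHEST_AMPS = {"V1": 0.8, "V2": 1.3, "V3": 1.5, "V4": 1.4, "V5": 1.2, "V6": 1.0}

#: Fraction of a raised-cosine lobe's width between its start and the point
#: where the steepest terminal tangent meets the baseline (tangent method).
_TANGENT_END_FRAC = 0.75 + 1.0 / (2.0 * math.pi)

P_AXIS_DEG = 60.0
P_CHEST_FACTOR = {"V1": 0.4, "V2": 0.25, "V3": 0.25, "V4": 0.25, "V5": 0.25, "V6": 0.25}
PACE_SPIKE_WIDTH_MS = 60.0


@dataclass
class SyntheticParams:
    """Everything the generator needs; intervals in ms, amplitudes in mV."""

    duration_s: float = 10.0
    fs: float = 500.0
    rr_mean_ms: float = 800.0
    rr_std_ms: float = 10.0
    first_beat_s: float = 0.4
    qrs_dur_ms: float = 90.0
    limb_amp_mv: float = 1.0           # frontal QRS vector magnitude
    axis_deg: float = 30.0
    chest_amp_mv: dict = field(default_factory=lambda: dict(DEFAULT_CHEST_AMPS))
    m_shape_leads: tuple[str, ...] = ()
    p_present: bool = True
    p_amp_mv: float = 0.12
    p_dur_ms: float = 100.0
    pr_ms: float = 110.0
    qt_ms: float = 310.0
    t_dur_ms: float = 200.0
    t_frac: float = 0.25               # T amplitude as a fraction of the QRS amplitude
    t_amp_override: dict = field(default_factory=dict)  # lead -> signed mV
    fwave_amp_mv: float = 0.0
    fwave_hz: float = 7.0
    noise_mv: float = 0.008
    drift_mv: float = 0.0
    drift_hz: float = 0.2
    mains_mv: float = 0.0
    mains_hz: float = 50.0
    ectopic_beat_scale: float = 1.0    # QRS scale of the middle beat
    pace_spike_mv: float = 0.0
    seed: int = 0
    intended_class: str = "NSR"

    def validate(self) -> None:
        if not (self.rr_mean_ms > 0 and self.fs > 0 and self.duration_s > 0):
            raise ValueError("rr_mean_ms, fs and duration_s must be positive")
        if not self.qrs_dur_ms < self.rr_mean_ms:
            raise ValueError("qrs_dur_ms must be shorter than rr_mean_ms")
        if self.qt_ms >= self.rr_mean_ms:
            raise ValueError("qt_ms must be shorter than rr_mean_ms")
        if self.p_present and not self.pr_ms < self.rr_mean_ms:
            raise ValueError("pr_ms must be shorter than rr_mean_ms")


def _hann_lobe(n: int) -> np.ndarray:
    """Raised-cosine lobe, zero at both ends, unit peak."""
    if n < 3:
        return np.zeros(n)
    tau = np.arange(n) / (n - 1)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * tau))


def _m_template(n: int) -> np.ndarray:
    """rSR'-like 'M' morphology: two principal positive peaks with a notch,
    a small initial q and a terminal s, tapered to zero at the edges."""
    tau = np.arange(n) / max(n - 1, 1)

    def g(c: float, s: float) -> np.ndarray:
        return np.exp(-((tau - c) ** 2) / (2.0 * s ** 2))

    shape = (-0.18 * g(0.08, 0.035) + 1.0 * g(0.32, 0.085)
             + 0.90 * g(0.68, 0.085) - 0.28 * g(0.95, 0.04))
    taper = np.minimum(1.0, np.minimum(tau, 1.0 - tau) / 0.125)
    return shape * np.sin(0.5 * np.pi * np.clip(taper, 0, 1)) ** 2 / 1.0


def _add(sig: np.ndarray, row: int, start: int, lobe: np.ndarray) -> None:
    """Add a template into a signal row, trimming at record edges."""
    n = sig.shape[1]
    lo = max(0, start)
    hi = min(n, start + lobe.size)
    if hi > lo:
        sig[row, lo:hi] += lobe[lo - start:hi - start]


def _beat_times(p: SyntheticParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(R times in s, RR intervals in ms); realised RR moments equal the
    programmed ones exactly (affine standardisation of truncated draws)."""
    margin_s = p.qrs_dur_ms / 2000.0 + 0.01
    mu = p.rr_mean_ms / 1000.0
    n_int = int(math.floor((p.duration_s - margin_s - p.first_beat_s) / mu))
    if n_int < 0:
        raise ValueError("duration too short for a single beat")
    if n_int == 0:
        return np.array([p.first_beat_s]), np.array([])
    z = np.clip(rng.standard_normal(n_int), -2.5, 2.5)
    if p.rr_std_ms > 0 and n_int >= 2 and np.std(z) > 0:
        rr = p.rr_mean_ms + p.rr_std_ms * (z - z.mean()) / np.std(z)
    else:
        rr = np.full(n_int, p.rr_mean_ms)
    times = p.first_beat_s + np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
    return times, rr


def generate(params: SyntheticParams) -> tuple[ECGRecord, FeatureSet]:
    """Generate a record and the ground-truth feature vector it encodes."""
    p = params
    p.validate()
    rng = np.random.default_rng(p.seed)
    fs = p.fs
    n = int(round(p.duration_s * fs))
    sig = np.zeros((12, n))

    r_times, rr = _beat_times(p, rng)
    d_s = p.qrs_dur_ms / 1000.0
    d_n = max(3, int(round(d_s * fs)))
    qrs_hann = _hann_lobe(d_n)
    qrs_m = _m_template(d_n)

    # per-lead signed QRS amplitudes
    amp = {}
    for lead, ang in LIMB_ANGLES.items():
        amp[lead] = p.limb_amp_mv * math.cos(math.radians(p.axis_deg - ang))
    for lead in CHEST_LEADS:
        amp[lead] = p.chest_amp_mv.get(lead, 1.0)

    # P wave geometry
    p_dur_ms = min(p.p_dur_ms, p.pr_ms - 30.0)
    p_n = max(3, int(round(p_dur_ms / 1000.0 * fs)))
    p_lobe = _hann_lobe(p_n)
    p_amp = {}
    for lead, ang in LIMB_ANGLES.items():
        p_amp[lead] = p.p_amp_mv * math.cos(math.radians(P_AXIS_DEG - ang))
    for lead in CHEST_LEADS:
        p_amp[lead] = p.p_amp_mv * P_CHEST_FACTOR[lead]

    # T wave geometry: lobe placed so its tangent end falls at QRS_on + QT
    t_n = max(3, int(round(p.t_dur_ms / 1000.0 * fs)))
    t_lobe = _hann_lobe(t_n)
    t_start_rel_s = p.qt_ms / 1000.0 - _TANGENT_END_FRAC * p.t_dur_ms / 1000.0
    t_amp = {}
    for lead in LEAD_ORDER:
        if lead in p.t_amp_override:
            t_amp[lead] = p.t_amp_override[lead]
        else:
            t_amp[lead] = p.t_frac * amp[lead]

    spike_n = max(3, int(round(PACE_SPIKE_WIDTH_MS / 1000.0 * fs)))
    spike_lobe = _hann_lobe(spike_n)

    mid_beat = len(r_times) // 2
    for b, r_t in enumerate(r_times):
        on = int(round((r_t - d_s / 2.0) * fs))
        scale = p.ectopic_beat_scale if (b == mid_beat and p.ectopic_beat_scale != 1.0) else 1.0
        for li, lead in enumerate(LEAD_ORDER):
            tmpl = qrs_m if lead in p.m_shape_leads else qrs_hann
            _add(sig, li, on, scale * amp[lead] * tmpl)
            if p.p_present:
                p_start = int(round((r_t - d_s / 2.0 - p.pr_ms / 1000.0) * fs))
                _add(sig, li, p_start, p_amp[lead] * p_lobe)
            t_start = int(round((r_t - d_s / 2.0 + t_start_rel_s) * fs))
            _add(sig, li, t_start, t_amp[lead] * t_lobe)
            if p.pace_spike_mv > 0:
                pace_amp = (p.pace_spike_mv * math.cos(math.radians(p.axis_deg - LIMB_ANGLES[lead]))
                            if lead in LIMB_ANGLES else p.pace_spike_mv)
                _add(sig, li, on, pace_amp * spike_lobe)

    t_axis = np.arange(n) / fs
    if p.fwave_amp_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        sig += p.fwave_amp_mv * np.sin(2 * np.pi * p.fwave_hz * t_axis + phase)
    if p.drift_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        sig += p.drift_mv * np.sin(2 * np.pi * p.drift_hz * t_axis + phase)
    if p.mains_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        sig += p.mains_mv * np.sin(2 * np.pi * p.mains_hz * t_axis + phase)
    if p.noise_mv > 0:
        sig += rng.normal(0.0, p.noise_mv, size=sig.shape)

    rec = ECGRecord(signals=sig, fs=fs, record_id=f"SYN-{p.intended_class}-{p.seed}",
                    meta={"synthetic": True, "intended_class": p.intended_class,
                          "n_beats": len(r_times)})
    return rec, _ground_truth(p, rr, amp)


def _ground_truth(p: SyntheticParams, rr: np.ndarray, amp: dict) -> FeatureSet:
    """Programmed feature values (exact by construction of the templates)."""
    ref_amp = abs(amp["II"])
    n_b = rr.size + 1
    scales = np.ones(n_b)
    if p.ectopic_beat_scale != 1.0:
        scales[n_b // 2] = p.ectopic_beat_scale
    amps = ref_amp * scales
    d = p.qrs_dur_ms
    # Hann value 30 ms after onset, relative change over 30 ms, per lead (mV/ms)
    if p.pace_spike_mv > 0:
        slope = p.pace_spike_mv / 30.0
    else:
        frac = 0.5 * (1 - math.cos(2 * math.pi * min(30.0, d) / d))
        slope = max(abs(a) for a in amp.values()) * frac / 30.0
    mw = {l: (l in p.m_shape_leads) for l in ("V1", "V2", "V3", "V4")}
    t_neg = {}
    for l in ("V1", "V2", "V3"):
        t = p.t_amp_override.get(l, p.t_frac * amp[l])
        t_neg[l] = t < -0.02
    return FeatureSet(
        max_qrs_ampl=float(np.max(amps)), min_qrs_ampl=float(np.min(amps)),
        mean_qrs_ampl=float(np.mean(amps)),
        mean_rr=p.rr_mean_ms if rr.size else None,
        std_rr=p.rr_std_ms if rr.size >= 2 else None,
        positive_p_wave=p.p_present, negative_p_wave=False,
        yes_p_wave=p.p_present, no_p_wave=not p.p_present,
        no_q_wave={"I": True, "V6": True},
        qrs_dur=d,
        pred_r_wave={"I": amp["I"] > 0, "V6": amp["V6"] > 0},
        opp_st_t=(p.t_amp_override.get("V5", p.t_frac * amp["V5"]) * amp["V5"]) < 0,
        mw_shaped_qrs=mw,
        frontal_qrs_angle=p.axis_deg % 360.0,
        slope_ini_qrs=slope,
        t_neg=t_neg,
        pr_interval=p.pr_ms if p.p_present else None,
        qt_int=p.qt_ms,
        max_qrs_ampl_limb=max(abs(amp[l]) for l in ("I", "II", "III")),
    )


# ---------------------------------------------------------------------------
# preset catalogue


def _presets() -> dict[str, SyntheticParams]:
    P = SyntheticParams
    cat = {
        "nsr": P(intended_class="NSR"),
        "stach": P(rr_mean_ms=500, rr_std_ms=5, qt_ms=270, t_dur_ms=140,
                   intended_class="STach"),
        "brady": P(rr_mean_ms=1100, rr_std_ms=8, intended_class="Brady"),
        "sb": P(rr_mean_ms=1200, rr_std_ms=10, intended_class="SB"),
        "pac": P(rr_std_ms=40, duration_s=20, intended_class="PAC"),
        "pvc": P(ectopic_beat_scale=3.0, intended_class="PVC"),
        "sa": P(rr_std_ms=60, intended_class="SA"),
        "afl": P(rr_mean_ms=1000, rr_std_ms=60, fwave_amp_mv=0.10, fwave_hz=8.0,
                 p_present=False, intended_class="AFL"),
        "af": P(rr_mean_ms=1000, rr_std_ms=80, fwave_amp_mv=0.06, fwave_hz=13.0,
                p_present=False, intended_class="AF"),
        "rbbb": P(qrs_dur_ms=130, m_shape_leads=("V1", "V2"), qt_ms=330, t_dur_ms=160,
                  intended_class="RBBB"),
        "irbbb": P(qrs_dur_ms=112, m_shape_leads=("V1",), qt_ms=330, t_dur_ms=160,
                   intended_class="IRBBB"),
        "lbbb": P(qrs_dur_ms=140, qt_ms=340, t_dur_ms=160,
                  t_amp_override={"V5": -0.35, "V6": -0.3, "I": -0.2},
                  intended_class="LBBB"),
        "rad": P(axis_deg=120, intended_class="RAD"),
        "lad": P(axis_deg=300, intended_class="LAD"),
        "lanfb": P(axis_deg=300, intended_class="LAnFB"),
        "lqt": P(qt_ms=420, intended_class="LQT"),
        "lqrsv": P(limb_amp_mv=0.18, intended_class="LQRSV"),
        "iavb": P(pr_ms=220, p_dur_ms=110, p_amp_mv=0.15, intended_class="IAVB"),
        "lpr": P(pr_ms=135, p_amp_mv=0.15, intended_class="LPR"),
        "tinv": P(t_amp_override={"V1": -0.25, "V2": -0.3, "V3": -0.3},
                  intended_class="TInv"),
        "pr": P(p_present=False, axis_deg=300, pace_spike_mv=24.0,
                intended_class="PR"),
    }
    return cat


PRESET_NAMES = tuple(sorted(_presets().keys()))


def preset(name: str, seed: int = 0, **overrides) -> SyntheticParams:
    """Parameter bundle for a named clinical scenario (see :data:`PRESET_NAMES`)."""
    cat = _presets()
    if name not in cat:
        raise KeyError(f"unknown preset {name!r}; known: {', '.join(PRESET_NAMES)}")
    return replace(cat[name], seed=seed, **overrides)
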