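"""Noise suppression, QRS detection and robust median-beat averaging.

The QRS detector follows the spatial-velocity principle: the absolute first
derivative of one or more leads is combined into a nonnegative "velocity"
series that is large over the ventricular depolarisation complex, and peaks
are picked with a combined adaptive/absolute threshold.  Beats are then
aligned on the dominant R (or S) fiducial and combined sample-wise by median
after rejecting beats with non-sustained amplitude or poor template
correlation.

All amplitudes are mV, all thresholds documented in
:class:`PreprocessingConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.signal

from .io import ECGRecord, LEAD_ORDER

logger = logging.getLogger(__name__)


@dataclass
class PreprocessingConfig:
    """Tunable preprocessing parameters (defaults chosen for 500 Hz adult ECG).

    mains_hz / notch_q
        Power-line notch centre frequency (50 or 60 Hz) and quality factor.
    baseline_win1_ms / baseline_win2_ms
        Two-stage moving-median baseline estimator window lengths.  The first
        window (200 ms) rejects the QRS, the second (600 ms) rejects P/T
        waves, so the cascade tracks sub-0.5 Hz wander without touching
        ST-T morphology.
    velocity_lowpass_hz
        Zero-phase low-pass applied to the velocity channel only (the signal
        used for amplitude features is never smoothed).
    threshold_frac / percentile_win_s / velocity_floor_mv_s
        Combined detection threshold: ``max(threshold_frac x rolling 99th
        percentile of velocity over percentile_win_s, velocity_floor_mv_s)``.
        The long window (10 s) with a high percentile keeps the adaptive part
        pinned to QRS velocity: dense fibrillatory waves stay below the top
        percentile, while a single outsized ectopic beat occupies too little
        of the window to drag the threshold above ordinary beats.
    refractory_ms
        Minimum distance between accepted detections.
    refine_win_ms
        Half-width of the raw-signal window searched for the dominant
        deflection when refining a velocity peak to the R/S fiducial.
    amp_reject_frac / corr_reject
        Outlier-beat rules for averaging: reject beats whose fiducial
        amplitude deviates more than ``amp_reject_frac`` from the median R
        amplitude, or whose correlation with the running template falls
        below ``corr_reject``.
    beat_pre_ms / beat_post_ms
        Median-beat window around the fiducial.
    """

    mains_hz: float = 50.0
    notch_q: float = 30.0
    baseline_win1_ms: float = 200.0
    baseline_win2_ms: float = 600.0
    velocity_lowpass_hz: float = 40.0
    threshold_frac: float = 0.4
    percentile_win_s: float = 10.0
    percentile_q: float = 99.0
    velocity_floor_mv_s: float = 10.0
    refractory_ms: float = 200.0
    refine_win_ms: float = 60.0
    amp_reject_frac: float = 0.30
    corr_reject: float = 0.90
    beat_pre_ms: float = 400.0
    beat_post_ms: float = 600.0
    velocity_leads: tuple[str, ...] = ("II", "V1")


DEFAULT_CONFIG = PreprocessingConfig()


@dataclass
class RPeakList:
    """Detected beat fiducials: ascending sample indices and per-peak polarity."""

    indices: np.ndarray
    polarity: np.ndarray
    fs: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.polarity = np.asarray(self.polarity, dtype=int)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class MedianBeat:
    """Per-lead signal-averaged beat with the R fiducial inside the window."""

    beat: np.ndarray            # (12, window) mV
    r_index: int                # fiducial sample within the window
    fs: float
    n_used: int
    n_rejected: int
    lead_names: tuple[str, ...] = LEAD_ORDER
    flags: list[str] = field(default_factory=list)

    def lead(self, name: str) -> np.ndarray:
        return self.beat[self.lead_names.index(name)]

    @property
    def window_samples(self) -> int:
        return self.beat.shape[1]


def _moving_median(x: np.ndarray, size: int) -> np.ndarray:
    size = max(3, size | 1)  # odd
    return scipy.ndimage.median_filter(x, size=(1, size), mode="nearest")


def suppress_noise(rec: ECGRecord, config: PreprocessingConfig = DEFAULT_CONFIG) -> ECGRecord:
    """Suppress mains interference and baseline wander on every lead.

    Mains is removed with a zero-phase IIR notch, wander with a two-stage
    moving-median baseline subtraction.  No low-pass is applied here so that
    QRS/ST-T amplitudes stay intact for the morphological features.  A record
    too short for the notch warm-up is returned baseline-corrected only, with
    a ``degraded_filtering`` flag in ``meta``.
    """
    x = rec.signals
    flags = list(rec.meta.get("quality_flags", []))

    b, a = scipy.signal.iirnotch(config.mains_hz, config.notch_q, fs=rec.fs)
    padlen = 3 * max(len(a), len(b))
    if rec.n_samples > padlen + 1:
        x = scipy.signal.filtfilt(b, a, x, axis=1)
    else:
        flags.append("degraded_filtering")
        logger.warning("%s: record too short for notch filter, skipped", rec.record_id)

    w1 = int(round(config.baseline_win1_ms * rec.fs / 1000.0))
    w2 = int(round(config.baseline_win2_ms * rec.fs / 1000.0))
    baseline = _moving_median(_moving_median(x, w1), w2)
    x = x - baseline

    meta = dict(rec.meta)
    if flags:
        meta["quality_flags"] = flags
    return ECGRecord(signals=x, fs=rec.fs, age=rec.age, sex=rec.sex,
                     dx_codes=list(rec.dx_codes), record_id=rec.record_id, meta=meta)


def spatial_velocity(rec: ECGRecord, leads: tuple[str, ...] | None = None) -> np.ndarray:
    """Spatial velocity: mean over selected leads of |first difference| x fs, in mV/s.

    The first sample is duplicated so the series has the record's length.
    """
    leads = tuple(leads) if leads is not None else DEFAULT_CONFIG.velocity_leads
    if not leads:
        raise ValueError("at least one lead must be selected for spatial velocity")
    rows = np.stack([rec.lead(name) for name in leads])
    v = np.mean(np.abs(np.diff(rows, axis=1)) * rec.fs, axis=0)
    return np.concatenate([[v[0] if v.size else 0.0], v])


def _rolling_percentile(v: np.ndarray, fs: float, win_s: float, q: float) -> np.ndarray:
    """Piecewise rolling percentile (1 s hop, ``win_s`` window), linearly interpolated."""
    hop = max(1, int(round(fs)))
    half = max(1, int(round(win_s * fs / 2)))
    centers = np.arange(0, v.size, hop)
    vals = np.array([np.percentile(v[max(0, c - half):c + half + 1], q) for c in centers])
    return np.interp(np.arange(v.size), centers, vals)


def detect_r_peaks(velocity: np.ndarray, fs: float, rec: ECGRecord | None = None,
                   config: PreprocessingConfig = DEFAULT_CONFIG) -> RPeakList:
    """Pick beat fiducials from a spatial-velocity series.

    Candidate regions exceed both an adaptive threshold (fraction of the
    rolling 99th percentile) and an absolute floor; a refractory interval is
    enforced; when the record is supplied, each velocity peak is refined to
    the extremum of the dominant deflection (root-mean-square across leads)
    within ``refine_win_ms`` of the candidate.
    """
    velocity = np.asarray(velocity, dtype=float)
    if np.any(velocity < 0):
        raise ValueError("velocity series must be nonnegative")
    n = velocity.size
    refractory = max(1, int(round(config.refractory_ms * fs / 1000.0)))

    # smooth the velocity channel only
    nyq = fs / 2.0
    if config.velocity_lowpass_hz < nyq and n > 30:
        b, a = scipy.signal.butter(4, config.velocity_lowpass_hz / nyq)
        v = scipy.signal.filtfilt(b, a, velocity)
        v = np.maximum(v, 0.0)
    else:
        v = velocity

    thr = np.maximum(config.threshold_frac *
                     _rolling_percentile(v, fs, config.percentile_win_s, config.percentile_q),
                     config.velocity_floor_mv_s)
    above = v > thr
    if not np.any(above):
        return RPeakList(np.array([], dtype=int), np.array([], dtype=int), fs,
                         flags=["no_peaks"])

    # contiguous above-threshold regions -> candidate = velocity argmax
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = np.concatenate([[0] if above[0] else [], edges[~above[edges]] + 1]).astype(int)
    stops = np.concatenate([edges[above[edges]] + 1, [n] if above[-1] else []]).astype(int)
    candidates = [s + int(np.argmax(v[s:e])) for s, e in zip(starts, stops)]

    # refractory: keep the larger-velocity candidate of any close pair
    kept: list[int] = []
    for c in candidates:
        if kept and c - kept[-1] < refractory:
            if v[c] > v[kept[-1]]:
                kept[-1] = c
        else:
            kept.append(c)

    # consistency filter: a real beat's velocity peak is commensurate with
    # the others'; edge transients and stray baseline spikes are not
    if len(kept) >= 3:
        pv = v[np.asarray(kept)]
        keep_mask = pv >= 0.4 * np.median(pv)
        kept = [c for c, k in zip(kept, keep_mask) if k]

    polarity = np.ones(len(kept), dtype=int)
    if rec is not None:
        half = int(round(config.refine_win_ms * rec.fs / 1000.0))
        rms = np.sqrt(np.mean(rec.signals ** 2, axis=0))
        refined, pols = [], []
        for c in kept:
            lo, hi = max(0, c - half), min(rec.n_samples, c + half + 1)
            i = lo + int(np.argmax(rms[lo:hi]))
            lead_i = int(np.argmax(np.abs(rec.signals[:, i])))
            refined.append(i)
            pols.append(1 if rec.signals[lead_i, i] >= 0 else -1)
        order = np.argsort(refined)
        ref_sorted = [refined[k] for k in order]
        pol_sorted = [pols[k] for k in order]
        kept, polarity = [], []
        for idx, pol in zip(ref_sorted, pol_sorted):
            if kept and idx - kept[-1] < refractory:
                continue
            kept.append(idx)
            polarity.append(pol)
        polarity = np.asarray(polarity, dtype=int)

    return RPeakList(np.asarray(kept, dtype=int), np.asarray(polarity, dtype=int), fs)


@dataclass(frozen=True)
class RRStats:
    mean_rr_ms: float
    std_rr_ms: float
    heart_rate_bpm: float
    reliable: bool


def rr_statistics(peaks: RPeakList, fs: float | None = None) -> RRStats:
    """Mean/std of successive RR intervals (ms) and heart rate (bpm).

    ``std_rr`` uses population normalisation.  Fewer than 2 peaks leave the
    statistics undefined (raises); fewer than 3 flags them unreliable.
    """
    fs = fs if fs is not None else peaks.fs
    if len(peaks) < 2:
        raise ValueError("RR statistics undefined with fewer than 2 peaks")
    rr = np.diff(peaks.indices) / fs * 1000.0
    mean_rr = float(np.mean(rr))
    std_rr = float(np.std(rr))  # population (ddof=0)
    return RRStats(mean_rr, std_rr, 60000.0 / mean_rr, reliable=len(peaks) >= 3)


def average_beat(rec: ECGRecord, peaks: RPeakList,
                 config: PreprocessingConfig = DEFAULT_CONFIG) -> MedianBeat:
    """Robust median beat aligned on the detected fiducials.

    Beats whose full ``[r - beat_pre_ms, r + beat_post_ms]`` window fits in
    the record are stacked; outliers are rejected when their fiducial
    amplitude deviates more than 30% from the median R amplitude or their
    correlation with the median template drops below 0.9; survivors are
    combined sample-wise by median.  If every beat is rejected, the single
    most template-like beat is returned with an ``all_beats_rejected`` flag.
    """
    if len(peaks) < 1:
        raise ValueError("average_beat requires at least one detected beat")
    pre = int(round(config.beat_pre_ms * rec.fs / 1000.0))
    post = int(round(config.beat_post_ms * rec.fs / 1000.0))
    flags: list[str] = []

    full = [r for r in peaks.indices if r - pre >= 0 and r + post < rec.n_samples]
    if not full:
        # short record: truncate the window around the most central beat
        r = int(peaks.indices[np.argmin(np.abs(peaks.indices - rec.n_samples // 2))])
        lo, hi = max(0, r - pre), min(rec.n_samples, r + post + 1)
        flags.append("truncated_window")
        return MedianBeat(rec.signals[:, lo:hi].copy(), r - lo, rec.fs,
                          n_used=1, n_rejected=0, flags=flags)

    stack = np.stack([rec.signals[:, r - pre:r + post + 1] for r in full])  # (b, 12, w)
    rms_amp = np.sqrt(np.mean(stack[:, :, pre] ** 2, axis=1))  # fiducial amplitude per beat
    med_amp = np.median(rms_amp)

    template = np.median(stack, axis=0).reshape(-1)
    t_center = template - template.mean()
    t_norm = np.linalg.norm(t_center)
    corr = np.ones(len(full))
    if t_norm > 0:
        for b in range(len(full)):
            y = stack[b].reshape(-1)
            y = y - y.mean()
            ny = np.linalg.norm(y)
            corr[b] = float(y @ t_center / (ny * t_norm)) if ny > 0 else 0.0

    amp_ok = np.abs(rms_amp - med_amp) <= config.amp_reject_frac * max(med_amp, 1e-12)
    keep = amp_ok & (corr >= config.corr_reject)
    if not np.any(keep):
        flags.append("all_beats_rejected")
        best = int(np.argmax(corr))
        return MedianBeat(stack[best].copy(), pre, rec.fs, n_used=1,
                          n_rejected=len(full) - 1, flags=flags)

    beat = np.median(stack[keep], axis=0)
    n_used = int(np.sum(keep))
    return MedianBeat(beat, pre, rec.fs, n_used=n_used,
                      n_rejected=len(full) - n_used, flags=flags)
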