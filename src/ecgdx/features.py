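"""Morphological and time-frequency ECG descriptors feeding the rule engine.

Everything the diagnostic rules read is computed here from three inputs: the
noise-suppressed record, the detected fiducials, and the median beat.  The
delineator finds QRS onset/offset by a velocity-threshold crossing outward
from the fiducial on the RMS velocity across leads, and the T end by the
tangent method on the dominant T lead.  Undefined upstream quantities
propagate as ``None`` features, never fabricated numbers; the rule engine
treats ``None`` as "condition false".

Conventions: amplitudes in mV, intervals in ms, the frontal-plane angle in
clockwise-positive hexaxial degrees in [0, 360) with lead I at 0 deg and aVF
at 90 deg (so right-axis deviation is [90, 180] and left-axis deviation
[270, 330], exactly as the rules state them).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np
import scipy.ndimage

from .io import ECGRecord
from .preprocessing import MedianBeat, RPeakList

# delineation / counting constants (unstated upstream; rationale in docs)
VELOCITY_THRESHOLD_FRAC = 0.05   # QRS bounds: fraction of peak RMS velocity
VELOCITY_FLOOR_MV_S = 2.0        # absolute floor for a usable QRS velocity peak
BASELINE_MARGIN = 1.5            # threshold sits this far above the quiet-zone velocity
CLOSING_MS = 12.0                # fills instantaneous velocity notches inside QRS
SUSTAIN_MS = 16.0                # required below-threshold run to accept a bound
DERIV_SMOOTH_MS = 8.0
P_SIGNIFICANCE_MV = 0.02         # 20 uV significant-peak criterion
P_SEARCH_PRE_MS = 400.0
P_SEARCH_STOP_MS = 40.0
Q_WAVE_MIN_MV = 0.025
Q_WAVE_MIN_MS = 10.0
CROSS_SMOOTH_MS = 20.0           # derivative smoothing for the inter-beat count
CROSS_SMOOTH_INSIDE_MS = 10.0    # lighter smoothing inside the QRS (sharp notches)
CROSS_HYSTERESIS_MV_MS = 0.002   # 2 uV/ms on both sides of a counted crossing
OUTSIDE_BLANK_PRE_MS = 20.0      # blanking before QRS onset
OUTSIDE_BLANK_POST_MS = 80.0     # blanking after QRS offset
MW_MIN_SEGMENT_MV = 0.05
MW_PRINCIPAL_FRAC = 0.30
T_SEARCH_MAX_MS = 500.0
T_MIN_AMP_MV = 0.03


@dataclass
class Delineation:
    """Median-beat wave boundaries (sample offsets within the beat window)."""

    qrs_on: int | None = None
    qrs_off: int | None = None
    t_end: int | None = None
    qrs_dur: float | None = None     # ms
    qt_int: float | None = None      # ms
    pr_interval: float | None = None  # ms, filled by detect_p_wave
    flags: list[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.qrs_on is not None and self.qrs_off is not None


@dataclass
class FeatureSet:
    """The complete descriptor vector for one record (one record -> one set).

    Per-lead booleans are stored as small mappings keyed by lead name, so the
    rules can ask e.g. for an M/W-shaped QRS "in any of V1..V4" directly.
    ``None`` marks an undefined quantity.
    """

    max_qrs_ampl: float | None = None
    min_qrs_ampl: float | None = None
    mean_qrs_ampl: float | None = None
    mean_rr: float | None = None
    std_rr: float | None = None
    n_cross_inside_qrs: int | None = None
    n_cross_outside_qrs: int | None = None
    positive_p_wave: bool = False
    negative_p_wave: bool = False
    yes_p_wave: bool = False
    no_p_wave: bool = True
    no_q_wave: Mapping[str, bool] = field(default_factory=dict)   # leads I, V6
    qrs_dur: float | None = None
    pred_r_wave: Mapping[str, bool] = field(default_factory=dict)  # leads I, V6
    opp_st_t: bool | None = None                                   # lead V5
    mw_shaped_qrs: Mapping[str, bool] = field(default_factory=dict)  # V1..V4
    frontal_qrs_angle: float | None = None
    ratio_q_r: float | None = None       # lead I, unsigned phase amplitudes
    ratio_r_s: float | None = None       # max over II, III; +inf when no S
    slope_ini_qrs: float | None = None   # mV/ms over the first 30 ms of QRS
    t_neg: Mapping[str, bool] = field(default_factory=dict)        # V1..V3
    pr_interval: float | None = None
    qt_int: float | None = None
    max_qrs_ampl_limb: float | None = None  # max over I, II, III

    @classmethod
    def neutral(cls, **overrides) -> "FeatureSet":
        """A fully populated, diagnostically silent feature vector.

        Represents an unremarkable sinus beat: regular rhythm at 75 bpm,
        narrow QRS, normal axis, concordant T waves, P present with a short
        PR so none of the interval rules fire.  Useful as the base vector
        for rule worked examples.
        """
        base = cls(
            max_qrs_ampl=1.0, min_qrs_ampl=1.0, mean_qrs_ampl=1.0,
            mean_rr=800.0, std_rr=10.0,
            n_cross_inside_qrs=1, n_cross_outside_qrs=2,
            positive_p_wave=True, negative_p_wave=False,
            yes_p_wave=True, no_p_wave=False,
            no_q_wave={"I": True, "V6": True},
            qrs_dur=90.0,
            pred_r_wave={"I": True, "V6": True},
            opp_st_t=False,
            mw_shaped_qrs={"V1": False, "V2": False, "V3": False, "V4": False},
            frontal_qrs_angle=45.0,
            ratio_q_r=0.0, ratio_r_s=float("inf"),
            slope_ini_qrs=0.03,
            t_neg={"V1": False, "V2": False, "V3": False},
            pr_interval=100.0, qt_int=320.0,
            max_qrs_ampl_limb=1.0,
        )
        for key, value in overrides.items():
            if not hasattr(base, key):
                raise TypeError(f"unknown feature {key!r}")
            setattr(base, key, value)
        return base

    def as_row(self) -> dict:
        """Flat dict (per-lead booleans expanded) for the feature-table writer."""
        row: dict = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, Mapping):
                for lead, b in v.items():
                    row[f"{f.name}_{lead}"] = b
            else:
                row[f.name] = v
        return row


# ---------------------------------------------------------------------------
# helpers


def _smooth_ma(x: np.ndarray, n: int) -> np.ndarray:
    n = max(1, n)
    return scipy.ndimage.uniform_filter1d(x, size=n, mode="nearest")


def _derivative_mv_ms(x: np.ndarray, fs: float, smooth_ms: float = CROSS_SMOOTH_MS) -> np.ndarray:
    d = np.gradient(x) * fs / 1000.0
    return _smooth_ma(d, int(round(smooth_ms * fs / 1000.0)))


def _count_alternations(d: np.ndarray, thr: float) -> int:
    """Sign alternations of a series with hysteresis |d| > thr on both sides."""
    s = np.sign(d)
    s[np.abs(d) <= thr] = 0
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[1:] != s[:-1]))


def _ms(n_ms: float, fs: float) -> int:
    return int(round(n_ms * fs / 1000.0))


# ---------------------------------------------------------------------------
# delineation


def delineate(beat: MedianBeat, fs: float | None = None,
              rr_ms: float | None = None) -> Delineation:
    """QRS onset/offset and T end of a median beat.

    Onset/offset: walk outward from the fiducial on the grey-closed RMS
    velocity across leads until it stays, for at least 16 ms, below a
    threshold set above both 5% of the QRS velocity peak and 1.5x the
    beat's own quiet-zone velocity (so residual fibrillatory waves or noise
    in the median beat cannot hold the search open).  T end: tangent method
    — the steepest tangent of the
    dominant T wave's terminal limb intersected with the baseline.  When the
    mean RR interval is supplied, the T search is capped at 62% of it so the
    following beat's QRS cannot masquerade as a T wave at fast rates.
    """
    fs = fs if fs is not None else beat.fs
    delin = Delineation()
    x = beat.beat
    r = beat.r_index
    n = x.shape[1]

    deriv = np.gradient(x, axis=1) * fs  # mV/s
    rms_v = np.sqrt(np.mean(deriv ** 2, axis=0))
    rms_v = _smooth_ma(rms_v, _ms(DERIV_SMOOTH_MS, fs))
    closed = scipy.ndimage.grey_closing(rms_v, size=max(3, _ms(CLOSING_MS, fs)))

    lo, hi = max(0, r - _ms(80, fs)), min(n, r + _ms(80, fs) + 1)
    peak_v = float(np.max(closed[lo:hi])) if hi > lo else 0.0
    # quiet-zone velocity: the window fringes, away from P/QRS/T activity
    fringe = []
    if r - _ms(250, fs) > _ms(150, fs):
        fringe.append(closed[:_ms(150, fs)])
    if n - r > _ms(500, fs):
        fringe.append(closed[-_ms(50, fs):])
    base = float(np.percentile(np.concatenate(fringe), 95)) if fringe else 0.0
    thr = max(VELOCITY_THRESHOLD_FRAC * peak_v, BASELINE_MARGIN * base,
              VELOCITY_FLOOR_MV_S)
    if peak_v <= 2.0 * thr:
        delin.flags.append("qrs_undefined")
        return delin

    below = closed < thr
    sustain = max(1, _ms(SUSTAIN_MS, fs))

    # onset: leftward from r, first index whose left-neighbourhood stays below
    qrs_on = None
    run = 0
    for i in range(r, -1, -1):
        run = run + 1 if below[i] else 0
        if run >= sustain:
            qrs_on = i + sustain
            break
    if qrs_on is None:
        qrs_on = 0
        delin.flags.append("onset_truncated")

    qrs_off = None
    run = 0
    for i in range(r, n):
        run = run + 1 if below[i] else 0
        if run >= sustain:
            qrs_off = i - sustain
            break
    if qrs_off is None:
        qrs_off = n - 1
        delin.flags.append("offset_truncated")

    delin.qrs_on, delin.qrs_off = int(qrs_on), int(qrs_off)
    delin.qrs_dur = (qrs_off - qrs_on) / fs * 1000.0

    # ---- T end by the tangent method
    t_lo = qrs_off + _ms(40, fs)
    t_hi = min(n, qrs_off + _ms(T_SEARCH_MAX_MS, fs))
    if rr_ms is not None:
        t_hi = min(t_hi, qrs_on + _ms(0.62 * rr_ms, fs))
    if t_hi - t_lo < _ms(60, fs):
        delin.flags.append("t_not_found")
        return delin
    seg = x[:, t_lo:t_hi]
    lead_idx = int(np.argmax(np.max(np.abs(seg), axis=1)))
    y = x[lead_idx]
    t_peak = t_lo + int(np.argmax(np.abs(y[t_lo:t_hi])))
    if abs(y[t_peak]) < T_MIN_AMP_MV:
        delin.flags.append("t_not_found")
        return delin

    dy = _smooth_ma(np.gradient(y), _ms(DERIV_SMOOTH_MS, fs))  # mV/sample
    limb_hi = min(n, t_peak + _ms(250, fs))
    limb = np.arange(t_peak, limb_hi)
    if limb.size < 3:
        delin.flags.append("t_not_found")
        return delin
    # terminal limb moves back toward baseline: slope sign opposite to peak
    sgn = np.sign(y[t_peak])
    cand = limb[np.sign(dy[limb]) == -sgn]
    if cand.size == 0:
        delin.flags.append("t_not_found")
        return delin
    steep = int(cand[np.argmax(np.abs(dy[cand]))])
    slope = dy[steep]
    if slope == 0:
        delin.flags.append("t_not_found")
        return delin
    t_end = steep - y[steep] / slope  # tangent intersects baseline 0
    t_end = int(round(np.clip(t_end, steep, n - 1)))
    delin.t_end = t_end
    delin.qt_int = (t_end - qrs_on) / fs * 1000.0
    return delin


# ---------------------------------------------------------------------------
# P wave


def detect_p_wave(beat: MedianBeat, delin: Delineation, fs: float | None = None,
                  leads: tuple[str, ...] = ("II", "V1"),
                  rr_ms: float | None = None) -> tuple[bool, bool, float | None]:
    """Detect an atrial wave ahead of the QRS and measure the PR interval.

    A P wave is reported when, in ``[QRS_onset - 400 ms, QRS_onset - 40 ms]``,
    a local extremum exceeds the signal 40 ms to each side by at least 20 uV
    on one of the configured leads (II primary, V1 secondary).  The PR
    interval runs from the P onset — the 20 uV departure point left of the
    peak — to the QRS onset.  With an RR hint the window reaches back at
    most 45% of the interval, keeping the preceding beat's T wave out at
    fast rates.

    Returns ``(positive_p, negative_p, pr_interval_ms)``.
    """
    fs = fs if fs is not None else beat.fs
    if delin.qrs_on is None:
        return False, False, None
    reach_ms = P_SEARCH_PRE_MS if rr_ms is None else min(P_SEARCH_PRE_MS, 0.45 * rr_ms)
    w_lo = max(0, delin.qrs_on - _ms(reach_ms, fs))
    w_hi = delin.qrs_on - _ms(P_SEARCH_STOP_MS, fs)
    if w_hi - w_lo < _ms(80, fs):
        return False, False, None  # early-beat truncation

    off40 = _ms(40, fs)
    for lead in leads:
        y = beat.lead(lead)
        baseline = float(np.median(y[w_lo:w_lo + off40])) if w_hi > w_lo + off40 else 0.0
        best = None  # (prominence, index, sign)
        for i in range(w_lo + 1, w_hi - 1):
            left = y[max(w_lo, i - off40)]
            right = y[min(w_hi - 1, i + off40)]
            for sgn in (1, -1):
                drop_l = sgn * (y[i] - left)
                drop_r = sgn * (y[i] - right)
                prom = min(drop_l, drop_r)
                if prom >= P_SIGNIFICANCE_MV and (best is None or prom > best[0]):
                    best = (prom, i, sgn)
        if best is None:
            continue
        _, p_peak, sgn = best
        # onset: 20 uV departure point walking left from the peak
        onset = w_lo
        for i in range(p_peak, w_lo - 1, -1):
            if abs(y[i] - baseline) < P_SIGNIFICANCE_MV:
                onset = i
                break
        pr = (delin.qrs_on - onset) / fs * 1000.0
        return sgn > 0, sgn < 0, pr
    return False, False, None


# ---------------------------------------------------------------------------
# zero crossings of the first derivative


def count_zero_crossings(rec: ECGRecord, peaks: RPeakList, delin: Delineation,
                         beat: MedianBeat, lead: str = "II") -> tuple[int | None, int | None]:
    """Derivative zero-crossing counts inside and outside the QRS.

    Inside: alternations of the smoothed first derivative of the median beat
    within ``[qrs_on, qrs_off]`` (hysteresis 2 uV/ms; 10 ms smoothing so the
    narrow notches of a fragmented QRS survive).  Outside: the same
    count with 20 ms smoothing in each inter-QRS region — ``[qrs_off + 80 ms, next qrs_on -
    20 ms]`` mapped beat-to-beat onto the record — averaged per RR interval
    and rounded.  The blanking keeps the QRS and its immediate ST slope out
    of the atrial-activity count.
    """
    if not delin.defined:
        return None, None
    fs = rec.fs
    thr = CROSS_HYSTERESIS_MV_MS

    d_beat = _derivative_mv_ms(beat.lead(lead), fs, smooth_ms=CROSS_SMOOTH_INSIDE_MS)
    n_inside = _count_alternations(d_beat[delin.qrs_on:delin.qrs_off + 1], thr)

    if len(peaks) < 2:
        return n_inside, None
    d_rec = _derivative_mv_ms(rec.lead(lead), fs)
    off_rel = delin.qrs_off - beat.r_index + _ms(OUTSIDE_BLANK_POST_MS, fs)
    on_rel = delin.qrs_on - beat.r_index - _ms(OUTSIDE_BLANK_PRE_MS, fs)
    counts = []
    for r0, r1 in zip(peaks.indices[:-1], peaks.indices[1:]):
        lo = max(0, r0 + off_rel)
        hi = min(rec.n_samples, r1 + on_rel)
        if hi - lo > 2:
            counts.append(_count_alternations(d_rec[lo:hi], thr))
    if not counts:
        return n_inside, None
    return n_inside, int(round(float(np.mean(counts))))


# ---------------------------------------------------------------------------
# QRS segmentation ("M"/"W" shape)


def _qrs_turning_points(y: np.ndarray, fs: float, on: int, off: int) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear QRS nodes: boundaries plus derivative sign changes,
    pruned until every segment spans at least ``MW_MIN_SEGMENT_MV``."""
    d = _derivative_mv_ms(y, fs, smooth_ms=DERIV_SMOOTH_MS)
    seg = d[on:off + 1]
    s = np.sign(seg)
    interior = [on + i for i in range(1, len(seg)) if s[i] != 0 and s[i - 1] != 0 and s[i] != s[i - 1]]
    nodes = np.array([on] + interior + [off], dtype=int)
    vals = y[nodes]
    # prune small segments: drop the interior node with the least amplitude step
    while len(nodes) > 2:
        steps = np.abs(np.diff(vals))
        k = int(np.argmin(steps))
        if steps[k] >= MW_MIN_SEGMENT_MV:
            break
        drop = k if 0 < k < len(nodes) - 1 else k + 1
        if drop == 0 or drop == len(nodes) - 1:
            break
        nodes = np.delete(nodes, drop)
        vals = y[nodes]
    return nodes, vals


def detect_mw_shape(beat: MedianBeat, delin: Delineation, lead: str,
                    fs: float | None = None) -> bool:
    """True when the QRS segmentation alternates like an 'M' (two principal
    positive peaks with a notch) or a 'W' (mirrored)."""
    fs = fs if fs is not None else beat.fs
    if not delin.defined:
        return False
    y = beat.lead(lead)
    on, off = delin.qrs_on, delin.qrs_off
    nodes, vals = _qrs_turning_points(y, fs, on, off)
    if len(nodes) < 4:
        return False
    scale = float(np.max(np.abs(y[on:off + 1])))
    if scale <= 0:
        return False
    maxima = [vals[i] for i in range(1, len(vals) - 1)
              if vals[i] > vals[i - 1] and vals[i] > vals[i + 1]]
    minima = [vals[i] for i in range(1, len(vals) - 1)
              if vals[i] < vals[i - 1] and vals[i] < vals[i + 1]]
    n_m = sum(1 for v in maxima if v >= MW_PRINCIPAL_FRAC * scale)
    n_w = sum(1 for v in minima if v <= -MW_PRINCIPAL_FRAC * scale)
    return n_m >= 2 or n_w >= 2


# ---------------------------------------------------------------------------
# frontal-plane QRS angle


def frontal_qrs_angle(beat: MedianBeat, delin: Delineation) -> float | None:
    """Direction of the maximal frontal-plane QRS vector, in [0, 360) degrees.

    At the instant of maximal frontal vector magnitude inside the QRS, the
    angle is ``atan2(aVF, I)`` measured clockwise from lead I; invariant to
    uniform limb-lead scaling.
    """
    if not delin.defined:
        return None
    x = beat.lead("I")[delin.qrs_on:delin.qrs_off + 1]
    y = beat.lead("aVF")[delin.qrs_on:delin.qrs_off + 1]
    mag = np.hypot(x, y)
    if mag.size == 0 or np.max(mag) < 1e-9:
        return None
    i = int(np.argmax(mag))
    return float(np.degrees(np.arctan2(y[i], x[i])) % 360.0)


# ---------------------------------------------------------------------------
# remaining descriptors and assembly


def _initial_phase(y: np.ndarray, fs: float, on: int, off: int) -> tuple[float, float]:
    """(signed amplitude, duration ms) of the first deflection after QRS onset."""
    rel = y[on:off + 1] - y[on]
    sgn = 0
    start = 0
    for i, v in enumerate(rel):
        if abs(v) >= Q_WAVE_MIN_MV:
            sgn = 1 if v > 0 else -1
            start = i
            break
    if sgn == 0:
        return 0.0, 0.0
    end = start
    while end < rel.size and sgn * rel[end] > 0:
        end += 1
    amp = float(np.max(sgn * rel[start:end])) * sgn
    return amp, (end - start) / fs * 1000.0


def _phase_amplitudes(y: np.ndarray, on: int, off: int) -> tuple[float, float]:
    """(R amplitude, S amplitude): unsigned positive / negative extremes in the
    QRS; a phase smaller than the wave-existence threshold counts as absent."""
    seg = y[on:off + 1]
    r_amp = float(max(np.max(seg), 0.0))
    s_amp = float(max(-np.min(seg), 0.0))
    return (r_amp if r_amp >= Q_WAVE_MIN_MV else 0.0,
            s_amp if s_amp >= Q_WAVE_MIN_MV else 0.0)


def compute_features(rec: ECGRecord, peaks: RPeakList, beat: MedianBeat,
                     delin: Delineation, amp_lead: str = "II",
                     cross_lead: str = "II") -> FeatureSet:
    """Assemble the full :class:`FeatureSet` for one record.

    QRS amplitudes are peak-to-peak per detected beat on ``amp_lead``;
    zero-crossing counts are taken on ``cross_lead`` outside the QRS and on
    the maximum over V1–V4 inside it (the leads the bundle-branch rule
    inspects); everything else is read off the median beat.
    """
    fs = rec.fs
    fset = FeatureSet()

    rr_hint = None
    if len(peaks) >= 2:
        from .preprocessing import rr_statistics
        stats = rr_statistics(peaks, fs)
        fset.mean_rr, fset.std_rr = stats.mean_rr_ms, stats.std_rr_ms
        rr_hint = stats.mean_rr_ms

    # per-beat QRS peak-to-peak amplitudes on the reference lead
    if delin.defined:
        on_rel = delin.qrs_on - beat.r_index
        off_rel = delin.qrs_off - beat.r_index
        lead_sig = rec.lead(amp_lead)
        amps = []
        for r in peaks.indices:
            lo, hi = max(0, r + on_rel), min(rec.n_samples, r + off_rel + 1)
            if hi - lo > 1:
                amps.append(float(np.ptp(lead_sig[lo:hi])))
        if amps:
            fset.max_qrs_ampl = max(amps)
            fset.min_qrs_ampl = min(amps)
            fset.mean_qrs_ampl = float(np.mean(amps))

    fset.qrs_dur = delin.qrs_dur
    fset.qt_int = delin.qt_int

    pos_p, neg_p, pr = detect_p_wave(beat, delin, fs, rr_ms=rr_hint)
    fset.positive_p_wave, fset.negative_p_wave = pos_p, neg_p
    fset.yes_p_wave = pos_p or neg_p
    fset.no_p_wave = not fset.yes_p_wave
    fset.pr_interval = pr
    delin.pr_interval = pr

    if delin.defined:
        n_in_v = [count_zero_crossings(rec, peaks, delin, beat, lead=l)[0]
                  for l in ("V1", "V2", "V3", "V4")]
        n_in_v = [v for v in n_in_v if v is not None]
        _, n_out = count_zero_crossings(rec, peaks, delin, beat, lead=cross_lead)
        fset.n_cross_inside_qrs = max(n_in_v) if n_in_v else None
        fset.n_cross_outside_qrs = n_out

        on, off = delin.qrs_on, delin.qrs_off

        no_q, pred_r = {}, {}
        for lead in ("I", "V6"):
            y = beat.lead(lead)
            amp, dur = _initial_phase(y, fs, on, off)
            no_q[lead] = not (amp < 0 and dur >= Q_WAVE_MIN_MS)
            seg = y[on:off + 1]
            tot = float(np.sum(np.abs(seg)))
            pred_r[lead] = bool(tot > 0 and np.sum(np.clip(seg, 0, None)) >= 0.95 * tot)
        fset.no_q_wave = no_q
        fset.pred_r_wave = pred_r

        fset.mw_shaped_qrs = {l: detect_mw_shape(beat, delin, l, fs)
                              for l in ("V1", "V2", "V3", "V4")}
        fset.frontal_qrs_angle = frontal_qrs_angle(beat, delin)

        # ST-T displacement opposite the dominant QRS deflection in V5
        if delin.t_end is not None:
            y5 = beat.lead("V5")
            st_lo = off + _ms(40, fs)
            if delin.t_end > st_lo:
                st_mean = float(np.mean(y5[st_lo:delin.t_end + 1]))
                dom = y5[on + int(np.argmax(np.abs(y5[on:off + 1])))]
                fset.opp_st_t = bool(dom * st_mean < 0 and abs(st_mean) > 0.01)
            else:
                fset.opp_st_t = None
        else:
            fset.opp_st_t = None

        yI = beat.lead("I")
        q_amp, q_dur = _initial_phase(yI, fs, on, off)
        r_amp, _ = _phase_amplitudes(yI, on, off)
        q_mag = -q_amp if (q_amp < 0 and q_dur >= Q_WAVE_MIN_MS) else 0.0
        fset.ratio_q_r = q_mag / r_amp if r_amp > 0 else float("inf")

        ratios = []
        for lead in ("II", "III"):
            r_a, s_a = _phase_amplitudes(beat.lead(lead), on, off)
            ratios.append(r_a / s_a if s_a > 0 else float("inf"))
        fset.ratio_r_s = max(ratios)

        n30 = _ms(30, fs)
        if on + n30 < beat.window_samples:
            fset.slope_ini_qrs = float(
                np.max(np.abs(beat.beat[:, on + n30] - beat.beat[:, on])) / 30.0)

        t_neg = {}
        t_hi = delin.t_end if delin.t_end is not None else min(
            beat.window_samples - 1, off + _ms(400, fs))
        t_lo = off + _ms(60, fs)
        for lead in ("V1", "V2", "V3"):
            y = beat.lead(lead)
            if t_hi > t_lo:
                seg = y[t_lo:t_hi + 1]
                peak = seg[int(np.argmax(np.abs(seg)))]
                t_neg[lead] = bool(peak < -P_SIGNIFICANCE_MV)
            else:
                t_neg[lead] = False
        fset.t_neg = t_neg

        fset.max_qrs_ampl_limb = max(
            float(np.ptp(beat.lead(l)[on:off + 1])) for l in ("I", "II", "III"))

    return fset
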