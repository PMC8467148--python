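"""Rule-based multi-label ECG classifier over the 24 scored diagnostic classes.

The engine evaluates a fixed list of if–then rules on a :class:`FeatureSet`,
in a fixed order so that later rules may read earlier outputs (sinus
bradycardia reads bradycardia and normal-rhythm, the incomplete bundle-branch
rule reads the complete one, and the fibrillation rule — evaluated after
flutter — overrides it when its stronger waviness condition holds).
Classification is total: an undefined feature simply makes every condition
that reads it false.

Classes with no rule (NSIVCB, QAb, Tab) always score 0 — deliberate gaps of
the knowledge base, not errors.  Thresholds live in :class:`RuleThresholds`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureSet
from .io import ClassVocabulary

#: Fixed evaluation order; names are the rule names (NSR is the normal-rhythm
#: rule, IAVB the first-degree AV-block rule, TInv the T-inversion rule).
RULE_ORDER = (
    "PAC", "PVC", "STach", "Brady", "SA", "NSR", "SB", "AFL", "AF",
    "LBBB", "RBBB", "IRBBB", "RAD", "LAD", "LAnFB", "PR",
    "LQT", "LQRSV", "IAVB", "LPR", "TInv",
)


@dataclass(frozen=True)
class RuleThresholds:
    """Every numeric constant the rules use, in ms / mV / mV/ms / degrees."""

    pac_band_ms: tuple[float, float] = (35.0, 46.0)
    pac_high_ms: float = 46.0
    pvc_max_factor: float = 2.0
    pvc_min_factor: float = 0.5
    stach_rr_ms: float = 600.0
    brady_rr_ms: float = 1000.0
    afl_cross: int = 9
    af_cross: int = 15
    lbbb_qrs_ms: float = 120.0
    rbbb_qrs_ms: float = 100.0
    rbbb_cross: int = 5
    irbbb_qrs_ms: float = 120.0
    rad_range_deg: tuple[float, float] = (90.0, 180.0)
    lad_range_deg: tuple[float, float] = (270.0, 330.0)
    lanfb_ratio: float = 1.0 / 9.0
    pr_slope_mv_ms: float = 0.7
    lqt_ms: float = 340.0
    lqrsv_mv: float = 0.25
    iavb_pr_ms: float = 130.0
    lpr_pr_ms: float = 110.0


DEFAULT_THRESHOLDS = RuleThresholds()


@dataclass
class DiagnosticScores:
    """Per-class scores in [0, 1] plus the provenance of every fired rule."""

    scores: dict[str, float]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __getitem__(self, abbreviation: str) -> float:
        return self.scores[abbreviation]

    def vector(self, vocab: ClassVocabulary) -> np.ndarray:
        return np.array([self.scores[a] for a in vocab.abbreviations])


def _num(x) -> bool:
    return x is not None and isinstance(x, (int, float)) and math.isfinite(x)


def classify(features: FeatureSet, vocab: ClassVocabulary | None = None,
             thresholds: RuleThresholds = DEFAULT_THRESHOLDS) -> DiagnosticScores:
    """Evaluate all diagnostic rules on a feature vector.

    Pure and total: identical input gives identical scores, undefined
    features never raise, and the flutter/fibrillation pair is mutually
    exclusive by construction.
    """
    vocab = vocab or ClassVocabulary.load()
    t = thresholds
    f = features
    s: dict[str, float] = {a: 0.0 for a in vocab.abbreviations}
    prov: dict[str, list[str]] = {a: [] for a in vocab.abbreviations}

    def fire(abbr: str, value: float, why: str) -> None:
        s[abbr] = value
        prov[abbr].append(why)

    # --- rhythm regularity -------------------------------------------------
    if _num(f.std_rr) and t.pac_band_ms[0] <= f.std_rr <= t.pac_band_ms[1]:
        fire("PAC", 0.7, f"std_RR {f.std_rr:.1f} ms in [{t.pac_band_ms[0]:g}, {t.pac_band_ms[1]:g}]")
    if _num(f.std_rr) and f.std_rr > t.pac_high_ms:
        fire("PAC", 1.0, f"std_RR {f.std_rr:.1f} ms > {t.pac_high_ms:g}")

    if _num(f.max_qrs_ampl) and _num(f.mean_qrs_ampl) and \
            f.max_qrs_ampl > t.pvc_max_factor * f.mean_qrs_ampl:
        fire("PVC", 1.0, f"max_QRS_ampl > {t.pvc_max_factor:g} x mean")
    if _num(f.min_qrs_ampl) and _num(f.mean_qrs_ampl) and \
            f.min_qrs_ampl < t.pvc_min_factor * f.mean_qrs_ampl:
        fire("PVC", 1.0, f"min_QRS_ampl < {t.pvc_min_factor:g} x mean")

    pac, pvc = s["PAC"], s["PVC"]
    if pvc == 0 and pac == 0 and _num(f.mean_rr) and f.mean_rr < t.stach_rr_ms:
        fire("STach", 1.0, f"mean_RR {f.mean_rr:.0f} ms < {t.stach_rr_ms:g}")
    if pvc == 0 and pac == 0 and _num(f.mean_rr) and f.mean_rr > t.brady_rr_ms:
        fire("Brady", 1.0, f"mean_RR {f.mean_rr:.0f} ms > {t.brady_rr_ms:g}")
    if pac == 1 and pvc == 0:
        fire("SA", 1.0, "PAC = 1 and PVC = 0")
    if pac == 0 and pvc == 0:
        fire("NSR", 1.0, "PAC = 0 and PVC = 0")
    if s["Brady"] == 1 and s["NSR"] == 1:
        fire("SB", 1.0, "Brady = 1 and NSR = 1")

    # --- atrial flutter / fibrillation (strict PAC > 0.7, i.e. PAC = 1) ----
    n_out = f.n_cross_outside_qrs
    if pac > 0.7 and _num(n_out) and n_out > t.afl_cross:
        fire("AFL", 1.0, f"PAC > 0.7 and n_cross_outside_QRS {n_out} > {t.afl_cross}")
        s["AF"] = 0.0
    if pac > 0.7 and _num(n_out) and n_out > t.af_cross:
        fire("AF", 1.0, f"PAC > 0.7 and n_cross_outside_QRS {n_out} > {t.af_cross}")
        if s["AFL"] == 1.0:
            prov["AFL"].append("overridden by AF")
        s["AFL"] = 0.0

    # --- conduction --------------------------------------------------------
    if _num(f.qrs_dur) and f.qrs_dur > t.lbbb_qrs_ms and \
            f.no_q_wave.get("I") and f.no_q_wave.get("V6") and \
            (f.pred_r_wave.get("I") or f.pred_r_wave.get("V6")) and f.opp_st_t:
        fire("LBBB", 1.0, f"QRS_dur {f.qrs_dur:.0f} ms, no Q and predominant R in I/V6, "
                          "discordant ST-T in V5")

    if _num(f.qrs_dur) and f.qrs_dur > t.rbbb_qrs_ms and \
            any(f.mw_shaped_qrs.get(l) for l in ("V1", "V2", "V3", "V4")) and \
            _num(f.n_cross_inside_qrs) and f.n_cross_inside_qrs >= t.rbbb_cross:
        fire("RBBB", 1.0, f"QRS_dur {f.qrs_dur:.0f} ms, M/W shape in V1-V4, "
                          f"n_cross_inside_QRS {f.n_cross_inside_qrs} >= {t.rbbb_cross}")
    if s["RBBB"] == 1 and _num(f.qrs_dur) and f.qrs_dur < t.irbbb_qrs_ms:
        fire("IRBBB", 1.0, f"RBBB fired with QRS_dur {f.qrs_dur:.0f} ms < {t.irbbb_qrs_ms:g}")

    # --- axis --------------------------------------------------------------
    ang = f.frontal_qrs_angle
    if _num(ang) and t.rad_range_deg[0] <= ang <= t.rad_range_deg[1]:
        fire("RAD", 1.0, f"frontal angle {ang:.0f} deg in RAD range")
    if _num(ang) and t.lad_range_deg[0] <= ang <= t.lad_range_deg[1]:
        fire("LAD", 1.0, f"frontal angle {ang:.0f} deg in LAD range")

    def _lt(x, bound) -> bool:
        return x is not None and x < bound  # +inf handled: inf < bound is False

    if (s["RAD"] == 1 or s["LAD"] == 1) and \
            (_lt(f.ratio_q_r, t.lanfb_ratio) or _lt(f.ratio_r_s, t.lanfb_ratio)):
        fire("LAnFB", 1.0, "axis deviation with Q/R or R/S ratio < 1/9")

    if f.no_p_wave and (s["RAD"] == 1 or s["LAD"] == 1) and \
            _num(f.slope_ini_qrs) and f.slope_ini_qrs > t.pr_slope_mv_ms:
        fire("PR", 1.0, f"no P, axis deviation, initial QRS slope "
                        f"{f.slope_ini_qrs:.2f} mV/ms > {t.pr_slope_mv_ms:g}")

    # --- intervals, voltage, T waves ---------------------------------------
    if _num(f.qt_int) and f.qt_int > t.lqt_ms:
        fire("LQT", 1.0, f"QT {f.qt_int:.0f} ms > {t.lqt_ms:g}")
    if _num(f.max_qrs_ampl_limb) and f.max_qrs_ampl_limb < t.lqrsv_mv:
        fire("LQRSV", 1.0, f"max limb-lead QRS amplitude {f.max_qrs_ampl_limb:.2f} mV "
                           f"< {t.lqrsv_mv:g}")
    if f.yes_p_wave and _num(f.pr_interval) and f.pr_interval > t.iavb_pr_ms:
        fire("IAVB", 1.0, f"P present, PR {f.pr_interval:.0f} ms > {t.iavb_pr_ms:g}")
    if f.yes_p_wave and _num(f.pr_interval) and f.pr_interval > t.lpr_pr_ms:
        fire("LPR", 1.0, f"P present, PR {f.pr_interval:.0f} ms > {t.lpr_pr_ms:g}")
    if f.t_neg.get("V1") and f.t_neg.get("V2") and f.t_neg.get("V3"):
        fire("TInv", 1.0, "negative T in V1, V2 and V3")

    return DiagnosticScores(scores=s, provenance={k: v for k, v in prov.items() if v})


def binarize(scores: DiagnosticScores, threshold: float = 0.5,
             vocab: ClassVocabulary | None = None) -> np.ndarray:
    """Binary label vector: 1 wherever the class score reaches the threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    vocab = vocab or ClassVocabulary.load()
    return (scores.vector(vocab) >= threshold).astype(int)


def write_challenge_output(path, record_id: str, scores: DiagnosticScores,
                           vocab: ClassVocabulary | None = None,
                           threshold: float = 0.5) -> None:
    """Challenge-style per-record output: class header, binary row, score row."""
    vocab = vocab or ClassVocabulary.load()
    labels = binarize(scores, threshold, vocab)
    vals = scores.vector(vocab)
    lines = [
        f"#{record_id}",
        ",".join(vocab.abbreviations),
        ",".join(str(int(v)) for v in labels),
        ",".join(f"{v:g}" for v in vals),
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
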