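"""End-to-end record analysis: filtering -> QRS detection -> median beat ->
features -> diagnostic scores, in one call."""

from __future__ import annotations

from dataclasses import dataclass

from .features import Delineation, FeatureSet, compute_features, delineate
from .io import ClassVocabulary, ECGRecord
from .preprocessing import (DEFAULT_CONFIG, MedianBeat, PreprocessingConfig,
                            RPeakList, average_beat, detect_r_peaks,
                            spatial_velocity, suppress_noise)
from .rules import DEFAULT_THRESHOLDS, DiagnosticScores, RuleThresholds, classify


@dataclass
class AnalysisResult:
    record: ECGRecord           # noise-suppressed
    peaks: RPeakList
    beat: MedianBeat | None
    delineation: Delineation | None
    features: FeatureSet
    scores: DiagnosticScores


def analyze_record(rec: ECGRecord,
                   config: PreprocessingConfig = DEFAULT_CONFIG,
                   thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
                   vocab: ClassVocabulary | None = None) -> AnalysisResult:
    """Run the full rule-based diagnostic pipeline on one record.

    Degraded inputs degrade gracefully: with no detectable beats the feature
    vector stays largely undefined and the classifier scores every class 0
    except the defaults its rules produce.
    """
    vocab = vocab or ClassVocabulary.load()
    clean = suppress_noise(rec, config)
    velocity = spatial_velocity(clean, config.velocity_leads)
    peaks = detect_r_peaks(velocity, clean.fs, rec=clean, config=config)

    if len(peaks) >= 1:
        beat = average_beat(clean, peaks, config)
        rr_hint = None
        if len(peaks) >= 2:
            from .preprocessing import rr_statistics
            rr_hint = rr_statistics(peaks, clean.fs).mean_rr_ms
        delin = delineate(beat, clean.fs, rr_ms=rr_hint)
        features = compute_features(clean, peaks, beat, delin)
    else:
        beat, delin = None, None
        features = FeatureSet()

    scores = classify(features, vocab, thresholds)
    return AnalysisResult(clean, peaks, beat, delin, features, scores)
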