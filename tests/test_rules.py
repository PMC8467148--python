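"""Diagnostic rule engine: worked examples, invariants, and a brute-force oracle."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgdx import FeatureSet, binarize, classify
from ecgdx.rules import RULE_ORDER


def _oracle(f: FeatureSet) -> dict:
    """Independent literal transcription of the printed rule list.

    Straight-line if/then evaluation with no shared helpers from the
    implementation; every condition re-derived from the printed text.
    """

    def d(x):
        return x is not None and isinstance(x, (int, float)) and math.isfinite(x)

    out = {k: 0.0 for k in
           ["IAVB", "AF", "AFL", "Brady", "RBBB", "IRBBB", "LAnFB", "LAD", "LBBB",
            "LQRSV", "NSIVCB", "PR", "PAC", "PVC", "LQT", "LPR", "QAb", "RAD",
            "SA", "SB", "NSR", "STach", "Tab", "TInv"]}
    if d(f.std_rr) and 35 <= f.std_rr <= 46:
        out["PAC"] = 0.7
    if d(f.std_rr) and f.std_rr > 46:
        out["PAC"] = 1.0
    if d(f.max_qrs_ampl) and d(f.mean_qrs_ampl) and f.max_qrs_ampl > 2 * f.mean_qrs_ampl:
        out["PVC"] = 1.0
    if d(f.min_qrs_ampl) and d(f.mean_qrs_ampl) and f.min_qrs_ampl < 0.5 * f.mean_qrs_ampl:
        out["PVC"] = 1.0
    if out["PVC"] == 0 and out["PAC"] == 0 and d(f.mean_rr) and f.mean_rr < 600:
        out["STach"] = 1.0
    if out["PVC"] == 0 and out["PAC"] == 0 and d(f.mean_rr) and f.mean_rr > 1000:
        out["Brady"] = 1.0
    if out["PAC"] == 1 and out["PVC"] == 0:
        out["SA"] = 1.0
    if out["PAC"] == 0 and out["PVC"] == 0:
        out["NSR"] = 1.0
    if out["Brady"] == 1 and out["NSR"] == 1:
        out["SB"] = 1.0
    if out["PAC"] > 0.7 and d(f.n_cross_outside_qrs) and f.n_cross_outside_qrs > 9:
        out["AFL"], out["AF"] = 1.0, 0.0
    if out["PAC"] > 0.7 and d(f.n_cross_outside_qrs) and f.n_cross_outside_qrs > 15:
        out["AF"], out["AFL"] = 1.0, 0.0
    if d(f.qrs_dur) and f.qrs_dur > 120 and f.no_q_wave.get("I") and f.no_q_wave.get("V6") \
            and (f.pred_r_wave.get("I") or f.pred_r_wave.get("V6")) and f.opp_st_t:
        out["LBBB"] = 1.0
    if d(f.qrs_dur) and f.qrs_dur > 100 \
            and any(f.mw_shaped_qrs.get(l) for l in ("V1", "V2", "V3", "V4")) \
            and d(f.n_cross_inside_qrs) and f.n_cross_inside_qrs >= 5:
        out["RBBB"] = 1.0
    if out["RBBB"] == 1 and d(f.qrs_dur) and f.qrs_dur < 120:
        out["IRBBB"] = 1.0
    if d(f.frontal_qrs_angle) and 90 <= f.frontal_qrs_angle <= 180:
        out["RAD"] = 1.0
    if d(f.frontal_qrs_angle) and 270 <= f.frontal_qrs_angle <= 330:
        out["LAD"] = 1.0
    qr_small = f.ratio_q_r is not None and f.ratio_q_r < 1 / 9
    rs_small = f.ratio_r_s is not None and f.ratio_r_s < 1 / 9
    if (out["RAD"] == 1 or out["LAD"] == 1) and (qr_small or rs_small):
        out["LAnFB"] = 1.0
    if f.no_p_wave and (out["RAD"] == 1 or out["LAD"] == 1) \
            and d(f.slope_ini_qrs) and f.slope_ini_qrs > 0.7:
        out["PR"] = 1.0
    if d(f.qt_int) and f.qt_int > 340:
        out["LQT"] = 1.0
    if d(f.max_qrs_ampl_limb) and f.max_qrs_ampl_limb < 0.25:
        out["LQRSV"] = 1.0
    if f.yes_p_wave and d(f.pr_interval) and f.pr_interval > 130:
        out["IAVB"] = 1.0
    if f.yes_p_wave and d(f.pr_interval) and f.pr_interval > 110:
        out["LPR"] = 1.0
    if f.t_neg.get("V1") and f.t_neg.get("V2") and f.t_neg.get("V3"):
        out["TInv"] = 1.0
    return out


class TestWorkedExamples:
    """The printed rule examples, fed as constructed feature vectors."""

    def test_pac_band_gives_soft_score(self, vocab):
        s = classify(FeatureSet.neutral(std_rr=40.0), vocab)
        assert s["PAC"] == 0.7
        assert s["SA"] == 0.0  # SA needs PAC = 1, not 0.7

    def test_stach_with_normal_rhythm(self, vocab):
        s = classify(FeatureSet.neutral(std_rr=10.0, mean_rr=500.0), vocab)
        assert s["STach"] == 1.0 and s["NSR"] == 1.0

    def test_brady(self, vocab):
        s = classify(FeatureSet.neutral(mean_rr=1100.0), vocab)
        assert s["Brady"] == 1.0 and s["SB"] == 1.0

    def test_neutral_vector_scores_normal_only(self, vocab):
        s = classify(FeatureSet.neutral(), vocab)
        assert s["NSR"] == 1.0
        assert all(v == 0.0 for k, v in s.scores.items() if k != "NSR")

    def test_afl_band(self, vocab):
        s = classify(FeatureSet.neutral(std_rr=60.0, n_cross_outside_qrs=12), vocab)
        assert s["AFL"] == 1.0 and s["AF"] == 0.0 and s["SA"] == 1.0

    def test_af_overrides_afl(self, vocab):
        s = classify(FeatureSet.neutral(std_rr=60.0, n_cross_outside_qrs=20), vocab)
        assert s["AF"] == 1.0 and s["AFL"] == 0.0

    def test_rbbb_and_incomplete_variant(self, vocab):
        base = dict(mw_shaped_qrs={"V1": True, "V2": False, "V3": False, "V4": False},
                    n_cross_inside_qrs=6)
        s = classify(FeatureSet.neutral(qrs_dur=130.0, **base), vocab)
        assert s["RBBB"] == 1.0 and s["IRBBB"] == 0.0
        s = classify(FeatureSet.neutral(qrs_dur=110.0, **base), vocab)
        assert s["RBBB"] == 1.0 and s["IRBBB"] == 1.0

    def test_interval_and_voltage_rules(self, vocab):
        assert classify(FeatureSet.neutral(qt_int=400.0), vocab)["LQT"] == 1.0
        assert classify(FeatureSet.neutral(max_qrs_ampl_limb=0.2), vocab)["LQRSV"] == 1.0
        s = classify(FeatureSet.neutral(pr_interval=150.0), vocab)
        assert s["IAVB"] == 1.0 and s["LPR"] == 1.0

    def test_unruled_classes_always_zero(self, vocab):
        s = classify(FeatureSet.neutral(std_rr=60.0, qt_int=500.0,
                                        n_cross_outside_qrs=30), vocab)
        for cls in ("NSIVCB", "QAb", "Tab"):
            assert s[cls] == 0.0


# coarse grid over every quantity the rules read
_GRID = dict(
    std_rr=[None, 10.0, 40.0, 60.0],
    mean_rr=[500.0, 800.0, 1100.0],
    max_min_mean=[(1.0, 1.0, 1.0), (3.0, 1.0, 1.2), (1.0, 0.4, 1.0)],
    n_cross_outside_qrs=[None, 3, 12, 20],
    qrs_dur=[90.0, 110.0, 130.0],
    mw=[False, True],
    n_cross_inside_qrs=[1, 6],
    frontal_qrs_angle=[None, 45.0, 120.0, 300.0],
    pr_interval=[None, 100.0, 120.0, 150.0],
    qt_int=[320.0, 400.0],
)


def test_brute_force_truth_table_agreement(vocab):
    """classify matches an independently written rule transcription on a
    coarse grid over the ten quantities the rules read (~18k points)."""
    n_checked = 0
    for (std, mrr, (mx, mn, mean), nout, dur, mw, nin, ang, pr, qt) in itertools.product(
            _GRID["std_rr"], _GRID["mean_rr"], _GRID["max_min_mean"],
            _GRID["n_cross_outside_qrs"], _GRID["qrs_dur"], _GRID["mw"],
            _GRID["n_cross_inside_qrs"], _GRID["frontal_qrs_angle"],
            _GRID["pr_interval"], _GRID["qt_int"]):
        f = FeatureSet.neutral(
            std_rr=std, mean_rr=mrr, max_qrs_ampl=mx, min_qrs_ampl=mn,
            mean_qrs_ampl=mean, n_cross_outside_qrs=nout, qrs_dur=dur,
            mw_shaped_qrs={"V1": mw, "V2": False, "V3": False, "V4": False},
            n_cross_inside_qrs=nin, frontal_qrs_angle=ang,
            pr_interval=pr, yes_p_wave=pr is not None, no_p_wave=pr is None,
            qt_int=qt)
        got = classify(f, vocab).scores
        want = _oracle(f)
        assert got == want, f"mismatch at {f}"
        n_checked += 1
    assert n_checked > 10_000


_feature_strategy = st.fixed_dictionaries(dict(
    std_rr=st.one_of(st.none(), st.floats(0, 120)),
    mean_rr=st.floats(300, 1500),
    n_cross_outside_qrs=st.one_of(st.none(), st.integers(0, 40)),
    qt_int=st.floats(200, 600),
    pr_interval=st.one_of(st.none(), st.floats(50, 400)),
    frontal_qrs_angle=st.one_of(st.none(), st.floats(0, 359.99)),
    qrs_dur=st.floats(40, 200),
    max_qrs_ampl_limb=st.floats(0.05, 3.0),
))


@settings(max_examples=300, deadline=None, derandomize=True)
@given(_feature_strategy)
def test_af_afl_mutual_exclusion(params):
    f = FeatureSet.neutral(**params)
    s = classify(f)
    assert not (s["AF"] == 1.0 and s["AFL"] == 1.0)


def test_waviness_monotonicity(vocab):
    """With std_RR > 46, raising the inter-QRS crossing count never moves the
    outcome from fibrillation back to flutter."""
    reached_af = False
    for n in range(0, 41):
        s = classify(FeatureSet.neutral(std_rr=60.0, n_cross_outside_qrs=n), vocab)
        if s["AF"] == 1.0:
            reached_af = True
        if reached_af:
            assert s["AF"] == 1.0 and s["AFL"] == 0.0


def test_classify_pure_function(vocab):
    f = FeatureSet.neutral(std_rr=60.0, n_cross_outside_qrs=12)
    a, b = classify(f, vocab), classify(f, vocab)
    assert a.scores == b.scores and a.provenance == b.provenance


def test_classify_total_on_empty_features(vocab):
    s = classify(FeatureSet(), vocab)  # everything undefined
    assert set(s.scores) == set(vocab.abbreviations)
    # undefined features make conditions false; the PAC=PVC=0 default still
    # satisfies the normal-rhythm conjunction (a knowledge-base quirk kept as printed)
    assert s["NSR"] == 1.0
    assert all(v == 0.0 for k, v in s.scores.items() if k != "NSR")


class TestBinarize:
    def test_threshold_semantics(self, vocab):
        s = classify(FeatureSet.neutral(std_rr=40.0), vocab)
        assert binarize(s, 0.5, vocab)[vocab.index_of("PAC")] == 1
        assert binarize(s, 0.75, vocab)[vocab.index_of("PAC")] == 0

    def test_all_zero_scores(self, vocab):
        s = classify(FeatureSet.neutral(std_rr=40.0), vocab)
        s.scores = {k: 0.0 for k in s.scores}
        assert binarize(s, 0.5, vocab).sum() == 0

    def test_invalid_threshold(self, vocab):
        s = classify(FeatureSet.neutral(), vocab)
        with pytest.raises(ValueError):
            binarize(s, 1.5, vocab)


def test_provenance_records_fired_rules(vocab):
    s = classify(FeatureSet.neutral(std_rr=60.0, n_cross_outside_qrs=20), vocab)
    assert any("std_RR" in w for w in s.provenance["PAC"])
    assert "overridden by AF" in " ".join(s.provenance.get("AFL", []))


def test_rule_order_is_fixed():
    assert RULE_ORDER.index("AFL") < RULE_ORDER.index("AF")
    assert RULE_ORDER.index("RBBB") < RULE_ORDER.index("IRBBB")
    assert RULE_ORDER.index("Brady") < RULE_ORDER.index("SB")
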