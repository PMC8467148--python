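"""Multi-label metrics: printed-formula agreement, ranking oracles, weighted score."""

import itertools

import numpy as np
import pytest

from ecgdx import (RewardMatrix, challenge_score, confusion, f_measure,
                   g_measure, rank_metrics)
from ecgdx.evaluation import ConfusionCounts


def _counts(tp, fp, fn, tn=0):
    return ConfusionCounts(np.array([float(tp)]), np.array([float(fp)]),
                           np.array([float(fn)]), np.array([float(tn)]), ["c"])


class TestConfusion:
    def test_perfect_prediction(self):
        y = np.array([[1, 0], [1, 1], [0, 0], [0, 1]])
        c = confusion(y, y)
        assert np.array_equal(c.tp, [2, 2]) and c.fp.sum() == 0 and c.fn.sum() == 0
        assert np.array_equal(c.tp + c.fp + c.fn + c.tn, [4, 4])

    def test_all_zero_predictions(self):
        y = np.array([[1, 0], [1, 1], [0, 1]])
        c = confusion(y, np.zeros_like(y))
        assert c.tp.sum() == 0 and c.fp.sum() == 0
        assert np.array_equal(c.fn, y.sum(axis=0))

    def test_hand_enumerated_case(self):
        y_true = np.array([[1, 0], [1, 1], [0, 1], [0, 0]])
        y_pred = np.array([[1, 1], [0, 1], [0, 1], [1, 0]])
        c = confusion(y_true, y_pred, ["a", "b"])
        assert (c.tp[0], c.fp[0], c.fn[0], c.tn[0]) == (1, 1, 1, 1)
        assert (c.tp[1], c.fp[1], c.fn[1], c.tn[1]) == (2, 1, 0, 1)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((3, 2)), np.zeros((2, 2)))


class TestPrintedFormulas:
    def test_perfect_class(self):
        for beta in (1.0, 2.0):
            per, _ = f_measure(_counts(1, 0, 0), beta)
            assert per[0] == 1.0
        per, _ = g_measure(_counts(1, 0, 0), 2.0)
        assert per[0] == 1.0

    def test_direct_substitution(self):
        assert f_measure(_counts(1, 1, 1), 1.0)[0][0] == pytest.approx(0.5)
        assert f_measure(_counts(1, 1, 1), 2.0)[0][0] == pytest.approx(0.5)
        # recall-light case ranks lower under F2: F1 = 2/3, F2 = 5/9
        assert f_measure(_counts(1, 0, 1), 1.0)[0][0] == pytest.approx(2 / 3)
        assert f_measure(_counts(1, 0, 1), 2.0)[0][0] == pytest.approx(5 / 9)
        assert g_measure(_counts(2, 1, 1), 2.0)[0][0] == pytest.approx(0.4)
        assert g_measure(_counts(0, 3, 2), 2.0)[0][0] == 0.0

    def test_formula_agreement_on_random_tables(self):
        """F1/F2/G2 equal the printed formulas on 1000 random confusion tables."""
        rng = np.random.default_rng(42)
        tp, fp, fn = (rng.integers(0, 50, size=1000) for _ in range(3))
        tn = rng.integers(0, 50, size=1000)
        counts = ConfusionCounts(tp.astype(float), fp.astype(float), fn.astype(float),
                                 tn.astype(float), [f"c{i}" for i in range(1000)])
        f1, _ = f_measure(counts, 1.0)
        f2, _ = f_measure(counts, 2.0)
        g2, _ = g_measure(counts, 2.0)
        for i in range(1000):
            if tp[i] + fp[i] + fn[i] == 0:
                assert np.isnan(f1[i])
                continue
            assert f1[i] == pytest.approx(2 * tp[i] / (2 * tp[i] + fp[i] + fn[i]), abs=1e-12)
            assert f2[i] == pytest.approx(5 * tp[i] / (5 * tp[i] + fp[i] + 4 * fn[i]), abs=1e-12)
            denom = tp[i] + fp[i] + 2 * fn[i]
            assert g2[i] == pytest.approx(tp[i] / denom if denom else 0.0, abs=1e-12)

    def test_f1_is_harmonic_mean_of_precision_recall(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            tp, fp, fn = rng.integers(1, 30, size=3)
            c = _counts(tp, fp, fn)
            p, r = tp / (tp + fp), tp / (tp + fn)
            assert f_measure(c, 1.0)[0][0] == pytest.approx(2 * p * r / (p + r), abs=1e-12)

    def test_empty_class_excluded_from_macro(self):
        c = ConfusionCounts(np.array([1.0, 0.0]), np.array([0.0, 0.0]),
                            np.array([0.0, 0.0]), np.array([0.0, 5.0]), ["a", "b"])
        per, macro = f_measure(c, 1.0)
        assert np.isnan(per[1]) and macro == 1.0

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            f_measure(_counts(1, 0, 0), 0.0)


def _auroc_bruteforce(y, s):
    """P(score_pos > score_neg) + 0.5 P(tie), by pair enumeration."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def _auprc_bruteforce(y, s):
    """Step-wise precision-recall integration over all score thresholds."""
    order = np.argsort(-s, kind="stable")
    y = y[order]
    tp = fp = 0
    n_pos = int(y.sum())
    area, last_recall = 0.0, 0.0
    for i in range(len(y)):
        if y[i]:
            tp += 1
        else:
            fp += 1
        # threshold boundary: next score differs
        if i + 1 == len(y) or s[order][i + 1] != s[order][i]:
            recall = tp / n_pos
            precision = tp / (tp + fp)
            area += (recall - last_recall) * precision
            last_recall = recall
    return area


class TestRankMetrics:
    def test_perfect_separation(self):
        y = np.array([[1], [1], [0], [0]])
        s = np.array([[0.9], [0.8], [0.2], [0.1]])
        m = rank_metrics(y, s)
        assert m.auroc[0] == 1.0 and m.auprc[0] == 1.0

    def test_uninformative_scores(self):
        y = np.array([[1], [0], [1], [0]])
        s = np.full((4, 1), 0.5)
        assert rank_metrics(y, s).auroc[0] == pytest.approx(0.5)

    def test_against_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            y = rng.integers(0, 2, size=8)
            if y.sum() in (0, 8):
                continue
            s = np.round(rng.random(8), 2)  # rounded to force ties
            m = rank_metrics(y[:, None], s[:, None])
            assert m.auroc[0] == pytest.approx(_auroc_bruteforce(y, s), abs=1e-12)
            assert m.auprc[0] == pytest.approx(_auprc_bruteforce(y, s), abs=1e-9)

    def test_single_class_column_excluded(self):
        y = np.array([[1, 1], [1, 0], [1, 1]])
        s = np.random.default_rng(0).random((3, 2))
        m = rank_metrics(y, s)
        assert np.isnan(m.auroc[0]) and np.isfinite(m.auroc[1])


class TestChallengeScore:
    def _w(self, vocab):
        return RewardMatrix.identity(vocab)

    def test_perfect_prediction_scores_one(self, vocab):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=(30, vocab.n_classes))
        y[:, vocab.index_of("NSR")] |= (y.sum(axis=1) == 0)  # no empty rows
        cs = challenge_score(y, y, self._w(vocab), vocab)
        assert cs.normalized == pytest.approx(1.0)

    def test_always_normal_scores_zero(self, vocab):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, size=(30, vocab.n_classes))
        pred = np.zeros_like(y)
        pred[:, vocab.index_of("NSR")] = 1
        cs = challenge_score(y, pred, self._w(vocab), vocab)
        assert cs.normalized == pytest.approx(0.0)

    def test_toy_case_hand_computed(self, vocab):
        """3 records, identity weights: credit = |intersection| / |union|."""
        n = vocab.n_classes
        y_true = np.zeros((3, n), dtype=int)
        y_pred = np.zeros((3, n), dtype=int)
        ia, ib, ic = vocab.index_of("AF"), vocab.index_of("LBBB"), vocab.index_of("NSR")
        y_true[0, ia] = 1;         y_pred[0, ia] = 1                      # exact: 1
        y_true[1, [ia, ib]] = 1;   y_pred[1, ia] = 1                      # 1/2
        y_true[2, ic] = 1;         y_pred[2, [ic, ib]] = 1                # 1/2
        cs = challenge_score(y_true, y_pred, self._w(vocab), vocab)
        assert cs.raw == pytest.approx(1 + 0.5 + 0.5)
        # perfect = 3 + ... record 1 has two true labels -> 2 * 1/2 each = 1
        assert cs.perfect == pytest.approx(3.0)

    def test_adding_correct_label_never_decreases_raw(self, vocab):
        rng = np.random.default_rng(8)
        w = self._w(vocab)
        for _ in range(20):
            y = rng.integers(0, 2, size=(10, vocab.n_classes))
            pred = (y & rng.integers(0, 2, size=y.shape))
            base = challenge_score(y, pred, w, vocab).raw
            miss = np.argwhere((y == 1) & (pred == 0))
            if miss.size == 0:
                continue
            i, j = miss[rng.integers(len(miss))]
            pred2 = pred.copy()
            pred2[i, j] = 1
            assert challenge_score(y, pred2, w, vocab).raw >= base - 1e-12

    def test_degenerate_normalisation_rejected(self, vocab):
        y = np.zeros((4, vocab.n_classes), dtype=int)
        y[:, vocab.index_of("NSR")] = 1  # truth == inactive baseline
        with pytest.raises(ValueError):
            challenge_score(y, y, self._w(vocab), vocab)


class TestRewardMatrix:
    def test_identity_default(self, vocab):
        w = RewardMatrix.identity(vocab)
        assert np.array_equal(w.weights, np.eye(24))

    def test_csv_roundtrip_with_reordering(self, tmp_path, vocab):
        rng = np.random.default_rng(1)
        w = np.round(rng.random((24, 24)), 3)
        np.fill_diagonal(w, 1.0)
        cols = list(vocab.abbreviations)[::-1]  # scrambled order on disk
        idx = [vocab.abbreviations.index(c) for c in cols]
        lines = ["," + ",".join(cols)]
        for i in idx:
            lines.append(cols[idx.index(i)] + "," + ",".join(f"{w[i, j]:g}" for j in idx))
        # rewrite properly: row label then values in scrambled column order
        lines = ["," + ",".join(cols)]
        for i in idx:
            lines.append(vocab.abbreviations[i] + "," +
                         ",".join(f"{w[i, j]:g}" for j in idx))
        path = tmp_path / "w.csv"
        path.write_text("\n".join(lines))
        loaded = RewardMatrix.from_csv(path, vocab)
        assert np.allclose(loaded.weights, w)

    def test_shape_mismatch_rejected(self, vocab):
        with pytest.raises(ValueError):
            RewardMatrix(np.eye(5), vocab.abbreviations)
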