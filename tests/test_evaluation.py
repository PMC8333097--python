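"""Tests for posterior voting, the metric suite and overlap credit."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sincbird import labels as lb
from sincbird.audio import write_wav
from sincbird.evaluation import (classify_file, compute_metrics,
                                 confusion_proportions, overlap_credit)
from sincbird.training import AudioCache


def brute_force_auc(pos_scores, neg_scores):
    """Exhaustive Mann-Whitney pair count with midrank tie handling."""
    wins = ties = 0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))


class _StubModel:
    """Deterministic posterior emitter for voting-arithmetic tests."""

    def __init__(self, cfg, logp_rows):
        self.cfg = cfg
        self._rows = np.asarray(logp_rows)

    def predict_log_proba(self, frames, batch_size=1024):
        return self._rows[: frames.shape[0]]


@pytest.fixture
def cut_item(tmp_path, rng):
    fs = 16000
    write_wav(tmp_path / "seg.wav", fs, 0.1 * rng.normal(size=480))
    return lb.ListItem(path=str(tmp_path / "seg.wav"), class_index=0,
                       event=lb.SoundEvent("seg", "A_call", 0.0, 0.03, 0)), \
        AudioCache(tmp_path)


class TestClassifyFile:
    def _cfg(self):
        from sincbird.network import NetConfig
        return NetConfig(n_classes=3, fs=16000, n_filt_1=2, len_filt_1=65,
                         conv_layers=[], fc_layers=[8], cw_len_ms=10.0,
                         cw_shift_ms=10.0)

    def test_single_frame_prediction_is_frame_argmax(self, tmp_path, rng):
        fs = 16000
        write_wav(tmp_path / "one.wav", fs, 0.1 * rng.normal(size=160))
        item = lb.ListItem(path=str(tmp_path / "one.wav"), class_index=0,
                           event=lb.SoundEvent("one", "A_call", 0.0, 0.01, 0))
        logp = np.log(np.array([[0.2, 0.7, 0.1]]))
        model = _StubModel(self._cfg(), logp)
        pred, post = classify_file(model, item, AudioCache(tmp_path))
        assert pred == 1
        assert np.allclose(post, [0.2, 0.7, 0.1])

    def test_uniform_posteriors_tie_break_to_class_zero(self, cut_item):
        item, cache = cut_item
        logp = np.full((3, 3), np.log(1 / 3))
        model = _StubModel(self._cfg(), logp)
        pred, post = classify_file(model, item, cache, shift=160)
        assert pred == 0
        assert np.allclose(post, 1 / 3)

    def test_mean_and_argmax_match_hand_computation(self, cut_item):
        item, cache = cut_item
        probs = np.array([[0.6, 0.3, 0.1],
                          [0.1, 0.5, 0.4],
                          [0.1, 0.6, 0.3]])
        model = _StubModel(self._cfg(), np.log(probs))
        pred, post = classify_file(model, item, cache, shift=160)
        assert np.allclose(post, [0.8 / 3, 1.4 / 3, 0.8 / 3])
        assert pred == 1

    def test_log_space_averaging_option_differs(self, cut_item):
        item, cache = cut_item
        probs = np.array([[0.98, 0.01, 0.01],
                          [0.02, 0.49, 0.49],
                          [0.02, 0.49, 0.49]])
        model = _StubModel(self._cfg(), np.log(probs))
        _, post_p = classify_file(model, item, cache, shift=160)
        _, post_g = classify_file(model, item, cache, shift=160,
                                  log_space=True)
        assert post_g[0] != pytest.approx(post_p[0])
        assert post_g.sum() == pytest.approx(1.0)


class TestComputeMetrics:
    def test_perfect_posteriors_all_metrics_one(self):
        y = np.array([0, 1, 2, 1])
        posts = np.eye(3)[y]
        report = compute_metrics(y, y, posts)
        for name in ("accuracy", "roc_auc", "precision", "recall", "f1",
                     "top3", "top5"):
            assert report.metrics[name] == pytest.approx(1.0), name

    def test_auc_matches_exhaustive_pair_count(self):
        """Toy two-class case from first principles: truths (0,0,1,1),
        class-1 scores (0.1, 0.4, 0.35, 0.8)."""
        y = np.array([0, 0, 1, 1])
        s1 = np.array([0.1, 0.4, 0.35, 0.8])
        posts = np.column_stack([1 - s1, s1])
        report = compute_metrics(y, np.array([0, 0, 1, 1]), posts)
        auc1 = brute_force_auc([0.35, 0.8], [0.1, 0.4])
        auc0 = brute_force_auc([0.9, 0.6], [0.65, 0.2])
        expected = (2 * auc0 + 2 * auc1) / 4
        assert report.metrics["roc_auc"] == pytest.approx(expected)

    def test_auc_matches_oracle_on_random_sets(self, rng):
        for _ in range(10):
            n, k = 30, 4
            y = rng.integers(0, k, n)
            if len(np.unique(y)) < 2:
                continue
            posts = rng.dirichlet(np.ones(k), size=n)
            report = compute_metrics(y, posts.argmax(1), posts)
            aucs, weights = [], []
            for c in np.unique(y):
                pos = posts[y == c, c]
                neg = posts[y != c, c]
                aucs.append(brute_force_auc(list(pos), list(neg)))
                weights.append((y == c).sum())
            expected = np.average(aucs, weights=weights)
            assert report.metrics["roc_auc"] == pytest.approx(expected)

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 3, 40)
        posts = rng.dirichlet(np.ones(3), size=40)
        a = compute_metrics(y, posts.argmax(1), posts).metrics["roc_auc"]
        b = compute_metrics(y, posts.argmax(1),
                            np.exp(5 * posts)).metrics["roc_auc"]
        assert a == pytest.approx(b)

    def test_topk_ordering(self, rng):
        """top-1 = accuracy <= top-3 <= top-5 on random prediction sets."""
        from sincbird.evaluation import top_k_accuracy
        for _ in range(20):
            k = int(rng.integers(2, 10))
            y = rng.integers(0, k, 50)
            posts = rng.dirichlet(np.ones(k), size=50)
            pred = posts.argmax(1)
            report = compute_metrics(y, pred, posts)
            top1 = top_k_accuracy(y, posts, 1)
            assert top1 == pytest.approx(report.metrics["accuracy"])
            assert report.metrics["accuracy"] <= report.metrics["top3"] + 1e-12
            assert report.metrics["top3"] <= report.metrics["top5"] + 1e-12

    def test_top5_saturates_with_five_or_fewer_classes(self, rng):
        y = rng.integers(0, 4, 30)
        posts = rng.dirichlet(np.ones(4), size=30)
        report = compute_metrics(y, posts.argmax(1), posts)
        assert report.metrics["top5"] == 1.0

    def test_accuracy_equals_weighted_confusion_diagonal(self, rng):
        y = rng.integers(0, 5, 60)
        pred = rng.integers(0, 5, 60)
        posts = rng.dirichlet(np.ones(5), size=60)
        report = compute_metrics(y, pred, posts)
        counts = np.bincount(y, minlength=5)
        recomputed = np.sum(np.diag(report.confusion) * counts) / 60
        assert report.metrics["accuracy"] == pytest.approx(recomputed)

    def test_absent_class_excluded_with_warning(self):
        y = np.array([0, 0, 1, 1])
        posts = np.column_stack([np.array([0.9, 0.8, 0.2, 0.1]),
                                 np.array([0.05, 0.1, 0.7, 0.8]),
                                 np.array([0.05, 0.1, 0.1, 0.1])])
        with pytest.warns(UserWarning, match="absent"):
            report = compute_metrics(y, y, posts, n_classes=3)
        assert np.isfinite(report.metrics["roc_auc"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([]), np.array([]), np.empty((0, 3)))


class TestConfusionProportions:
    def test_identity_when_all_correct(self):
        y = np.array([0, 1, 2, 2])
        mat, observed = confusion_proportions(y, y, 3)
        assert np.array_equal(mat, np.eye(3))
        assert observed.all()

    def test_single_observed_class(self):
        mat, observed = confusion_proportions(
            np.array([1, 1]), np.array([0, 2]), 3)
        assert mat[1].sum() == pytest.approx(1.0)
        assert list(observed) == [False, True, False]
        assert np.all(mat[[0, 2]] == 0)

    def test_rows_sum_to_one_over_random_toy(self, rng):
        y = rng.integers(0, 7, 50)
        pred = rng.integers(0, 7, 50)
        mat, observed = confusion_proportions(y, pred, 7)
        assert np.allclose(mat[observed].sum(axis=1), 1.0)
        assert mat.sum() == pytest.approx(observed.sum())


class TestOverlapCredit:
    def test_no_overlaps_credited_equals_strict(self):
        res = overlap_credit(["a", "b", "c"], ["a", "c", "c"],
                             [set(), set(), set()])
        assert res.credited_accuracy == res.strict_accuracy

    def test_all_errors_on_overlap_gives_full_credit(self):
        res = overlap_credit(["a", "b"], ["x", "y"], [{"x"}, {"y"}])
        assert res.credited_accuracy == 1.0
        assert res.errors_on_overlap_fraction == 1.0

    def test_hand_counted_toy(self):
        """10 events, 4 with one overlapping species, 2 errors land on the
        overlap tag: credit raises accuracy by exactly 0.2."""
        true = [f"t{i}" for i in range(10)]
        pred = list(true)
        overlaps = [set() for _ in range(10)]
        for i in range(4):
            overlaps[i] = {f"ov{i}"}
        pred[0], pred[1] = "ov0", "ov1"   # 2 errors hitting the overlap
        res = overlap_credit(true, pred, overlaps)
        assert res.strict_accuracy == pytest.approx(0.8)
        assert res.credited_accuracy == pytest.approx(1.0)
        assert res.credited_accuracy - res.strict_accuracy == \
            pytest.approx(0.2)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_credit_bounded_by_overlap_fraction(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        tags = [f"t{i}" for i in range(5)]
        true = [tags[i] for i in rng.integers(0, 5, n)]
        pred = [tags[i] for i in rng.integers(0, 5, n)]
        overlaps = [set(rng.choice(tags, size=rng.integers(0, 3),
                                   replace=False)) - {t}
                    for t in true]
        res = overlap_credit(true, pred, overlaps)
        frac_overlapping = np.mean([bool(o) for o in overlaps])
        assert res.credited_accuracy >= res.strict_accuracy
        assert res.credited_accuracy - res.strict_accuracy <= \
            frac_overlapping + 1e-12
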