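"""Score aggregation, ROC/AUC, bootstrap CI, stratification, confusion."""
import numpy as np
import pytest

from strokect.errors import DataError, ParameterError, StratificationError
from strokect.evalstat import (SubjectRecord, SubjectScore, bootstrap_auc_ci,
                               confusion_at_threshold, lesion_score, roc_auc,
                               stratify_test_set, subject_score)


def _pairwise_auc(scores, labels):
    """Brute-force AUC: P(random positive > random negative), ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestScores:
    def test_lesion_score_is_mean(self):
        assert lesion_score([0.2, 0.4, 0.6]) == pytest.approx(0.4)
        assert lesion_score([1.0] * 70) == 1.0

    def test_lesion_score_empty_rejected(self):
        with pytest.raises(ParameterError):
            lesion_score([])

    def test_subject_score_max_and_empty(self):
        assert subject_score([0.1, 0.9]) == 0.9
        assert subject_score([]) == 0.0

    def test_subject_score_monotone_in_lesions(self, rng):
        scores = list(rng.random(5))
        base = subject_score(scores)
        assert subject_score(scores + [0.0]) >= base
        assert subject_score(scores + [1.0]) >= base

    def test_subject_score_permutation_invariant(self, rng):
        scores = list(rng.random(6))
        assert subject_score(scores) == subject_score(scores[::-1])
        assert SubjectScore("s", scores).score == subject_score(scores)


class TestRocAuc:
    def test_perfect_and_inverted(self):
        labels = [0, 0, 1, 1]
        assert roc_auc([0.1, 0.2, 0.8, 0.9], labels).auc == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], labels).auc == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 20))
        labels = r.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        scores = np.round(r.random(n), 1)  # coarse grid to provoke ties
        assert roc_auc(scores, labels).auc == \
            pytest.approx(_pairwise_auc(scores, labels), abs=1e-9)

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = rng.random(30)
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(3 * scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestBootstrapCI:
    def test_perfect_separation_degenerate_ci(self):
        scores = [0.1, 0.2, 0.8, 0.9] * 5
        labels = [0, 0, 1, 1] * 5
        lo, hi = bootstrap_auc_ci(scores, labels, reps=50, m=10, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_seeded_repeat_identical(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a = bootstrap_auc_ci(scores, labels, reps=100, m=20, seed=7)
        b = bootstrap_auc_ci(scores, labels, reps=100, m=20, seed=7)
        assert a == b
        assert 0.0 <= a[0] <= a[1] <= 1.0

    def test_endpoints_bracket_central_95_percent(self, rng):
        # recompute the percentile positions independently from the same
        # resampling stream
        scores = np.concatenate([rng.normal(0.4, 0.2, 25),
                                 rng.normal(0.6, 0.2, 25)])
        labels = np.array([0] * 25 + [1] * 25)
        reps, m, seed = 200, 30, 3
        lo, hi = bootstrap_auc_ci(scores, labels, reps=reps, m=m, seed=seed)
        r = np.random.default_rng(seed)
        aucs = []
        while len(aucs) < reps:
            idx = r.integers(0, 50, m)
            if len(np.unique(labels[idx])) < 2:
                continue
            aucs.append(_pairwise_auc(scores[idx], labels[idx]))
        aucs = np.sort(aucs)
        assert lo == pytest.approx(aucs[int(np.floor(0.025 * reps))], abs=1e-9)
        assert hi == pytest.approx(aucs[int(np.ceil(0.975 * reps)) - 1], abs=1e-9)

    def test_width_shrinks_with_larger_resamples(self, rng):
        scores = np.concatenate([rng.normal(0.35, 0.15, 200),
                                 rng.normal(0.65, 0.15, 200)])
        labels = np.array([0] * 200 + [1] * 200)
        widths = []
        for m in (20, 160):
            lo, hi = bootstrap_auc_ci(scores, labels, reps=300, m=m, seed=1)
            widths.append(hi - lo)
        assert widths[1] < widths[0]


def _records(spec):
    """spec: list of (scanner, age, label) tuples."""
    return [SubjectRecord(f"s{i}", age, scanner, label)
            for i, (scanner, age, label) in enumerate(spec)]


class TestStratify:
    def test_min_rule_per_stratum(self):
        recs = _records([("A", 50, 1)] * 10 + [("A", 50, 0)] * 4)
        out = stratify_test_set(recs, key="scanner", seed=0)
        assert sum(r.label == 1 for r in out) == 4
        assert sum(r.label == 0 for r in out) == 4

    def test_single_class_stratum_excluded(self):
        recs = _records([("A", 50, 1)] * 3 + [("B", 60, 1)] * 2
                        + [("B", 60, 0)] * 5)
        out = stratify_test_set(recs, key="scanner", seed=0)
        assert all(r.scanner_model == "B" for r in out)
        assert sum(r.label == 1 for r in out) == sum(r.label == 0 for r in out) == 2

    def test_every_stratum_balanced(self, rng):
        spec = [(rng.choice(["A", "B", "C"]), int(rng.integers(20, 90)),
                 int(rng.integers(0, 2))) for _ in range(60)]
        out = stratify_test_set(_records(spec), key="age_decade", seed=5)
        from collections import Counter

        per = Counter((r.age_decade, r.label) for r in out)
        decades = {d for d, _ in per}
        for d in decades:
            assert per[(d, 0)] == per[(d, 1)] > 0

    def test_all_degenerate_rejected(self):
        with pytest.raises(StratificationError):
            stratify_test_set(_records([("A", 50, 1), ("B", 60, 1)]),
                              key="scanner")

    def test_unknown_key_rejected(self):
        with pytest.raises(ParameterError):
            stratify_test_set(_records([("A", 50, 1)]), key="hospital")

    def test_selection_without_replacement(self):
        recs = _records([("A", 50, 1)] * 6 + [("A", 50, 0)] * 6)
        out = stratify_test_set(recs, key="scanner", seed=2)
        ids = [r.subject_id for r in out]
        assert len(ids) == len(set(ids)) == 12


class TestConfusion:
    def test_basic_counts(self):
        c = confusion_at_threshold([0.9, 0.1], [1, 0], t=0.3)
        assert c == {"TP": 1, "FP": 0, "FN": 0, "TN": 1}

    def test_all_below_threshold(self):
        c = confusion_at_threshold([0.1, 0.2, 0.05], [1, 0, 1], t=0.3)
        assert c["TP"] == 0 and c["FP"] == 0
        assert c["FN"] == 2 and c["TN"] == 1

    def test_counts_sum_to_n(self, rng):
        scores = rng.random(25)
        labels = rng.integers(0, 2, 25)
        c = confusion_at_threshold(scores, labels, t=0.3)
        assert c["TP"] + c["FP"] + c["FN"] + c["TN"] == 25

    def test_threshold_is_inclusive(self):
        c = confusion_at_threshold([0.3], [1], t=0.3)
        assert c["TP"] == 1


def test_predictions_csv_round_trip(tmp_path):
    import pandas as pd

    from strokect.evalstat import save_predictions_csv

    path = tmp_path / "pred.csv"
    save_predictions_csv(["a", "b"], [0.7, 0.1], [1, 0], path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["subject_id", "score", "label"]
    assert df["score"].tolist() == [0.7, 0.1]
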