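import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import average_precision_score

from voroperim.evaluation import (
    FoldSplit,
    ap_product_integral,
    average_precision,
    f1_cutoff,
    make_folds,
    run_cv,
)
from voroperim.models import ModelSpec

from helpers import ap_enumeration, f1_scan


class TestAveragePrecision:
    def test_perfect_ranking_scores_one(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_worked_example(self):
        # thresholds: P=1 at R=0.5, then P=2/3 at R=1 -> 0.5*1 + 0.5*2/3
        ap = average_precision([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
        assert ap == pytest.approx(0.8333, abs=1e-4)

    def test_reversed_perfect_ranking_matches_brute_force(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        reversed_scores = [-s for s in scores]
        assert average_precision(reversed_scores, labels) == pytest.approx(
            ap_enumeration(reversed_scores, labels)
        )

    def test_exhaustive_label_arrangements_match_enumeration(self):
        rng = np.random.default_rng(13)
        for n in (2, 4, 6):
            scores = rng.normal(size=n)
            for labels in itertools.product([0, 1], repeat=n):
                if 0 < sum(labels) < n:
                    ours = average_precision(scores, list(labels))
                    assert ours == pytest.approx(ap_enumeration(scores, labels), abs=1e-12)
                    assert ours == pytest.approx(
                        average_precision_score(list(labels), scores), abs=1e-12
                    )

    def test_tied_scores_grouped(self):
        # all scores equal: a single threshold, precision = prevalence
        assert average_precision([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            average_precision([0.1, 0.2], [1, 1])

    @given(
        st.lists(
            st.tuples(st.floats(-5, 5, allow_nan=False), st.integers(0, 1)),
            min_size=3,
            max_size=30,
        )
    )
    def test_invariant_under_monotone_transform(self, pairs):
        # round scores so the float transform cannot collapse distinct values
        scores = np.round([p[0] for p in pairs], 3)
        labels = np.array([p[1] for p in pairs])
        if labels.min() == labels.max():
            return
        base = average_precision(scores, labels)
        transformed = average_precision(np.exp(0.5 * scores) + 3, labels)
        assert transformed == pytest.approx(base, abs=1e-12)


class TestProductIntegralVariant:
    def test_below_or_equal_standard_ap_on_perfect_ranking(self):
        scores, labels = [0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]
        lit = ap_product_integral(scores, labels)
        assert 0 < lit <= 1
        assert lit <= average_precision(scores, labels)

    def test_hand_computed_two_point_case(self):
        # rescaled scores 0 and 1: on (0, 1] prediction set = {positive},
        # PPV = TPR = 1, so the integral is 1
        assert ap_product_integral([0.9, 0.1], [1, 0]) == pytest.approx(1.0)


class TestF1Cutoff:
    def test_separable_case_returns_upper_threshold(self):
        scores = [0.9, 0.9, 0.1, 0.1]
        labels = [1, 1, 0, 0]
        assert f1_cutoff(scores, labels) == 0.9

    def test_objective_equals_half_f1_argmax(self):
        rng = np.random.default_rng(3)
        scores = rng.random(30)
        labels = (rng.random(30) < 0.4).astype(int)
        t = f1_cutoff(scores, labels)
        # maximizing PPV*TPR/(PPV+TPR) is maximizing F1 = 2PR/(P+R)
        best_f1, best_t = -1.0, None
        for cand in sorted(set(scores)):
            pred = scores >= cand
            tp = int(labels[pred].sum())
            p = tp / pred.sum()
            r = tp / labels.sum()
            f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            if f1 > best_f1 + 1e-15:
                best_f1, best_t = f1, cand
        assert t == best_t

    def test_matches_exhaustive_scan_with_mislabeled_point(self):
        scores = [0.95, 0.9, 0.8, 0.4, 0.3, 0.1]
        labels = [1, 0, 1, 1, 0, 0]  # one high-scoring control
        assert f1_cutoff(scores, labels) == f1_scan(scores, labels)


class TestFolds:
    def test_fold_split_rejects_overlap(self):
        with pytest.raises(ValueError):
            FoldSplit(1, frozenset({"a"}), frozenset({"a"}))

    def test_partition_properties(self, small_cohort):
        _, records, _ = small_cohort
        folds = make_folds(records, k=4, seed=3)
        all_subjects = {r.subject_id for r in records}
        seen = []
        for fold in folds:
            assert not fold.train_subjects & fold.test_subjects
            assert fold.train_subjects | fold.test_subjects == all_subjects
            seen.extend(fold.test_subjects)
        assert sorted(seen) == sorted(all_subjects)  # each subject tested once
        sizes = [len(f.test_subjects) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_same_seed_same_folds(self, small_cohort):
        _, records, _ = small_cohort
        a = make_folds(records, k=3, seed=5)
        b = make_folds(records, k=3, seed=5)
        assert [f.test_subjects for f in a] == [f.test_subjects for f in b]

    def test_too_few_subjects_rejected(self, small_cohort):
        _, records, _ = small_cohort
        with pytest.raises(ValueError, match="folds"):
            make_folds(records, k=100, seed=0)


class TestRunCV:
    @pytest.fixture(scope="class")
    def small_report(self, small_cohort, pattern_24_2):
        _, records, _ = small_cohort
        spec = ModelSpec(epochs=3)
        return run_cv(
            records, pattern_24_2, methods=("MD", "sLV", "MD+sLV", "NN", "CNN"),
            k=3, repeats=2, seed=1, model_spec=spec,
        )

    def test_entry_counts_per_method(self, small_report):
        agg = small_report.aggregate()
        for method in ("MD", "sLV", "MD+sLV"):
            assert agg[method]["n"] == 3  # deterministic: one entry per fold
        for method in ("NN", "CNN"):
            assert agg[method]["n"] == 3 * 2  # repeats x folds

    def test_aggregates_recompute_from_entries(self, small_report):
        for method, agg in small_report.aggregate().items():
            aps = small_report.scores(method)
            assert agg["median"] == float(np.median(aps))
            assert agg["std"] == pytest.approx(float(np.std(aps, ddof=1)))

    def test_report_json_round_trips_aggregates(self, small_report, tmp_path):
        import json

        path = tmp_path / "report.json"
        small_report.to_json(path)
        payload = json.loads(path.read_text())
        assert set(payload["methods"]) == {"MD", "sLV", "MD+sLV", "NN", "CNN"}
        for method, block in payload["methods"].items():
            assert block["median"] == small_report.aggregate()[method]["median"]

    def test_unknown_method_rejected(self, small_cohort, pattern_24_2):
        _, records, _ = small_cohort
        with pytest.raises(ValueError, match="unknown"):
            run_cv(records, pattern_24_2, methods=("AUC",), k=3, seed=0)

    def test_all_aps_in_unit_interval(self, small_report):
        for entry in small_report.entries:
            assert 0.0 <= entry["ap"] <= 1.0
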