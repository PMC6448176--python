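import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from problist.evaluation import (
    EvalCounts,
    PatientSummary,
    PrfScores,
    compression_rate,
    estimate_sample_size,
    evaluate_pairwise_clustering,
    evaluate_postcoding,
    f_from_pr,
    prf_from_counts,
    summarize,
)
from problist.postcoding import CodeAssignment


class TestPrf:
    def test_perfect_counts(self):
        scores = prf_from_counts(EvalCounts(tp=3, fp=0, fn=0))
        assert scores == PrfScores(1.0, 1.0, 1.0)

    def test_zero_tp_gives_zero_f(self):
        assert prf_from_counts(EvalCounts(tp=0, fp=5, fn=2)).f_measure == 0.0

    def test_direct_formula(self):
        scores = prf_from_counts(EvalCounts(tp=1, fp=2, fn=1))
        assert scores.precision == pytest.approx(1 / 3)
        assert scores.recall == pytest.approx(1 / 2)
        assert scores.f_measure == pytest.approx(0.4)

    def test_f_equals_harmonic_mean_everywhere(self):
        for precision in (0.0, 0.1, 0.5, 0.91, 1.0):
            for recall in (0.0, 0.2, 0.87, 1.0):
                f = f_from_pr(precision, recall)
                if precision + recall:
                    assert f == pytest.approx(
                        2 * precision * recall / (precision + recall), abs=1e-12
                    )
                else:
                    assert f == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            f_from_pr(1.2, 0.5)


class TestEvaluatePostcoding:
    def test_all_correct(self):
        truth = {f"u{i}": "N17" for i in range(10)}
        assignments = [
            CodeAssignment(f"u{i}", assigned_code="N17", source_item="c", similarity=1.0)
            for i in range(10)
        ]
        counts = evaluate_postcoding(assignments, truth)
        assert (counts.tp, counts.fp, counts.fn) == (10, 0, 0)

    def test_mixed_outcomes(self):
        truth = {f"u{i}": "N17" for i in range(10)}
        assignments = (
            [CodeAssignment(f"u{i}", "N17", "c", 1.0) for i in range(7)]
            + [CodeAssignment(f"u{i}", "E87", "c", 1.0) for i in range(7, 9)]
            + [CodeAssignment("u9")]
        )
        counts = evaluate_postcoding(assignments, truth)
        assert (counts.tp, counts.fp, counts.fn) == (7, 2, 1)

    def test_genuinely_codeless_item_is_tn(self):
        counts = evaluate_postcoding([CodeAssignment("u0")], {"u0": None})
        assert counts.tn == 1 and counts.total == 1

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_matches_item_by_item_recount(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        truth = {}
        assignments = []
        for i in range(n):
            item = f"u{i}"
            truth[item] = None if rng.random() < 0.2 else f"C{rng.integers(3)}"
            if rng.random() < 0.7:
                assignments.append(
                    CodeAssignment(item, f"C{rng.integers(3)}", "src", 0.5)
                )
            else:
                assignments.append(CodeAssignment(item))
        counts = evaluate_postcoding(assignments, truth)
        tp = sum(
            1 for a in assignments
            if a.assigned_code is not None and truth[a.item_id] == a.assigned_code
        )
        fp = sum(
            1 for a in assignments
            if a.assigned_code is not None and truth[a.item_id] != a.assigned_code
        )
        fn = sum(
            1 for a in assignments
            if a.assigned_code is None and truth[a.item_id] is not None
        )
        assert (counts.tp, counts.fp, counts.fn) == (tp, fp, fn)
        assert counts.total == n


class TestPairwiseClustering:
    def test_worked_example(self):
        partition = {"a1": 1, "a2": 1, "b1": 1, "b2": 2}
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        counts = evaluate_pairwise_clustering(partition, labels)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (1, 2, 1, 2)
        assert prf_from_counts(counts).f_measure == pytest.approx(0.4)

    def test_perfect_partition(self):
        partition = {"a1": 1, "a2": 1, "b1": 2, "b2": 2}
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert prf_from_counts(
            evaluate_pairwise_clustering(partition, labels)
        ).f_measure == pytest.approx(1.0)

    def test_all_singletons_zero_recall(self):
        partition = {"a1": 1, "a2": 2}
        labels = {"a1": "A", "a2": "A"}
        scores = prf_from_counts(evaluate_pairwise_clustering(partition, labels))
        assert scores.recall == 0.0 and scores.f_measure == 0.0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_matches_exhaustive_pair_enumeration(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 31))
        items = [f"i{k}" for k in range(n)]
        partition = {i: int(rng.integers(1, 6)) for i in items}
        labels = {i: f"C{rng.integers(4)}" for i in items}
        counts = evaluate_pairwise_clustering(partition, labels)
        tp = fp = fn = tn = 0
        for a, b in itertools.combinations(items, 2):
            same_cluster = partition[a] == partition[b]
            same_code = labels[a] == labels[b]
            tp += same_cluster and same_code
            fp += same_cluster and not same_code
            fn += not same_cluster and same_code
            tn += not same_cluster and not same_code
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (tp, fp, fn, tn)
        assert counts.total == n * (n - 1) // 2


class TestCompressionRate:
    @pytest.mark.parametrize(
        ("items", "topics", "expected"),
        [(302, 60, 0.80), (861, 95, 0.89), (10, 10, 0.0)],
    )
    def test_values(self, items, topics, expected):
        assert round(compression_rate(items, topics), 2) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            compression_rate(10, 11)


def make_summary(pid, items, unique, topics, coded=0.5):
    return PatientSummary(
        patient_id=pid,
        n_items=items,
        n_unique=unique,
        n_topics=topics,
        coded_fraction=coded,
        coded_prf=PrfScores(0.9, 0.8, f_from_pr(0.9, 0.8)),
        clustered_prf=PrfScores(0.7, 0.6, f_from_pr(0.7, 0.6)),
    )


class TestSummarize:
    def test_topic_count_means(self):
        summaries = [
            make_summary(f"P{k}", 1000, 500, t)
            for k, t in enumerate([60, 70, 95, 77, 90])
        ]
        assert summarize(summaries)["mean_topics"] == pytest.approx(78.4)

    def test_single_patient_aggregate_is_that_patient(self):
        summary = make_summary("P1", 302, 184, 60)
        aggregate = summarize([summary])
        assert aggregate["mean_topics"] == 60
        assert aggregate["mean_compression_rate"] == pytest.approx(0.80)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestSampleSize:
    def test_closed_form_values(self):
        assert estimate_sample_size(0.05, 0.05) == 4427
        assert estimate_sample_size(0.1, 0.05) == 1107
        assert estimate_sample_size(0.5, 0.5) == math.ceil(12 * math.log(4))

    def test_monotone_in_epsilon_and_delta(self):
        assert estimate_sample_size(0.04, 0.05) > estimate_sample_size(0.05, 0.05)
        assert estimate_sample_size(0.05, 0.01) > estimate_sample_size(0.05, 0.05)

    @pytest.mark.parametrize(("eps", "delta"), [(0, 0.05), (1.5, 0.05), (0.05, 0)])
    def test_invalid_parameters(self, eps, delta):
        with pytest.raises(ValueError):
            estimate_sample_size(eps, delta)
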