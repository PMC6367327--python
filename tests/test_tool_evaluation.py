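"""Confusion metrics, pairwise agreement, and the all-agree combination scan."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from snvaudit.tool_evaluation import (
    ConfusionTable,
    combine_calls,
    confusion,
    metrics,
    pairwise_agreement,
    scan_combinations,
    summarize_by_size,
)

P, B, M = "pathogenic", "benign", "missing"


class TestConfusion:
    def test_direct_counts(self):
        labels = [P] * 10 + [B] * 90
        calls = [P] * 8 + [B] * 2 + [B] * 85 + [P] * 5
        c = confusion(calls, labels)
        assert (c.tp, c.fn, c.tn, c.fp, c.unclassified) == (8, 2, 85, 5, 0)

    def test_all_missing_goes_to_unclassified(self):
        labels = [P, P, B, B, B]
        c = confusion([M] * 5, labels)
        assert c.unclassified == 5
        assert c.unclassified_pathogenic == 2
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 0, 0)

    def test_all_benign_identity(self):
        c = confusion([B] * 7, [B] * 7)
        assert c.tn == 7 and c.total == 7

    def test_empty_input_gives_zero_table(self):
        c = confusion([], [])
        assert c.total == 0

    def test_counts_conserve(self):
        rng = np.random.default_rng(3)
        labels = [P if b else B for b in rng.integers(0, 2, 50)]
        calls = [(P, B, M)[i] for i in rng.integers(0, 3, 50)]
        assert confusion(calls, labels).total == 50


class TestMetrics:
    def test_arithmetic(self):
        m = metrics(ConfusionTable(tp=8, fp=5, tn=85, fn=2))
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(85 / 90)
        assert m.accuracy == pytest.approx(0.93)

    def test_all_zero_table_undefined(self):
        m = metrics(ConfusionTable())
        assert m.sensitivity is None and m.specificity is None and m.accuracy is None

    def test_no_call_counts_against_sensitivity(self):
        # 3 hits, 1 miss, 1 pathogenic no-call: denominator 5
        m = metrics(ConfusionTable(tp=3, fn=1, unclassified_pathogenic=1))
        assert m.sensitivity == pytest.approx(0.6)


class TestPairwiseAgreement:
    def test_identity_complement_and_partial(self):
        a = [P, B, P, B, P, B, P, B, P, B]
        b = [B if x == P else P for x in a]
        c = a[:7] + [b[i] for i in range(7, 10)]
        mat = pairwise_agreement({"SIFT": a, "CADD": a, "DANN": b, "FATHMM": c})
        assert mat.loc["SIFT", "CADD"] == 1.0
        assert mat.loc["SIFT", "DANN"] == 0.0
        assert mat.loc["SIFT", "FATHMM"] == pytest.approx(0.7)

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(5)
        calls = {
            t: [(P, B, M)[i] for i in rng.integers(0, 3, 30)]
            for t in ("SIFT", "CADD", "DANN")
        }
        mat = pairwise_agreement(calls)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T, equal_nan=True)
        assert all(mat.loc[t, t] == 1.0 for t in calls)

    def test_missing_pairs_excluded_from_denominator(self):
        mat = pairwise_agreement({"SIFT": [P, M, P], "CADD": [P, P, M]})
        assert mat.loc["SIFT", "CADD"] == 1.0  # only the first variant is co-called

    def test_zero_cocalled_pair_reported_missing(self):
        mat = pairwise_agreement({"SIFT": [P, M], "CADD": [M, P]})
        assert np.isnan(mat.loc["SIFT", "CADD"])


class TestCombineCalls:
    def test_singleton_is_the_tool_itself(self):
        calls = {"SIFT": [P, B, M]}
        assert combine_calls(["SIFT"], calls) == [P, B, M]

    def test_disagreement_is_no_call(self):
        calls = {"SIFT": [P], "CADD": [B]}
        assert combine_calls(["SIFT", "CADD"], calls) == [M]

    def test_unanimous_benign(self):
        calls = {"SIFT": [B], "CADD": [B], "DANN": [B]}
        assert combine_calls(["SIFT", "CADD", "DANN"], calls) == [B]

    def test_any_missing_member_is_no_call(self):
        calls = {"SIFT": [P], "CADD": [M]}
        assert combine_calls(["SIFT", "CADD"], calls) == [M]


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(7)
    tools = ("SIFT", "CADD", "DANN")
    n = 20
    labels = [P if b else B for b in rng.integers(0, 2, n)]
    calls = {t: [(P, B, M)[i] for i in rng.integers(0, 3, n)] for t in tools}
    return tools, calls, labels


class TestScanCombinations:

    def test_cardinality_is_two_to_the_k_minus_one(self, toy):
        tools, calls, labels = toy
        assert len(scan_combinations(tools, calls, labels)) == 2 ** 3 - 1

    def test_matches_brute_force_per_subset(self, toy):
        """Vectorized scan equals combine_calls + confusion for all 7 subsets."""
        tools, calls, labels = toy
        results = {r.subset: r.confusion for r in scan_combinations(tools, calls, labels)}
        assert len(results) == 7
        for r in range(1, 4):
            for subset in itertools.combinations(tools, r):
                expected = confusion(combine_calls(subset, calls), labels)
                assert results[frozenset(subset)] == expected

    def test_singleton_equals_single_tool_evaluation(self, toy):
        tools, calls, labels = toy
        results = {r.subset: r for r in scan_combinations(tools, calls, labels)}
        for t in tools:
            assert results[frozenset({t})].confusion == confusion(calls[t], labels)

    def test_combinatorial_guard(self, toy):
        _, calls, labels = toy
        many = [f"T{i}" for i in range(25)]
        calls_many = {t: calls["SIFT"] for t in many}
        with pytest.raises(ValueError, match="refus"):
            scan_combinations(many, calls_many, labels)

    def test_nested_subsets_shrink_the_called_set(self, toy):
        tools, calls, labels = toy
        chain_small = combine_calls(("SIFT",), calls)
        chain_large = combine_calls(("SIFT", "CADD", "DANN"), calls)
        for small, large in zip(chain_small, chain_large):
            if small == M:
                assert large == M  # enlarging never converts no-call into a call


class TestSummarizeBySize:
    def test_hand_computed_means(self):
        labels = [P, P, B, B]
        calls = {"SIFT": [P, P, B, B], "CADD": [P, B, B, P]}
        results = scan_combinations(("SIFT", "CADD"), calls, labels)
        df = summarize_by_size(results).set_index("size")
        # size 1: SIFT perfect (1, 1); CADD (0.5, 0.5)
        assert df.loc[1, "mean_sensitivity"] == pytest.approx(0.75)
        assert df.loc[1, "max_sensitivity"] == pytest.approx(1.0)
        # size 2: unanimity keeps 1 TP of 2 and 1 TN of 2
        assert df.loc[2, "mean_sensitivity"] == pytest.approx(0.5)
        assert df.loc[2, "mean_specificity"] == pytest.approx(0.5)

    def test_identical_tools_are_size_invariant(self):
        labels = [P, B] * 5
        calls = {t: labels for t in ("SIFT", "CADD", "DANN")}
        df = summarize_by_size(scan_combinations(("SIFT", "CADD", "DANN"), calls, labels))
        assert df["mean_sensitivity"].nunique() == 1
        assert df["mean_accuracy"].nunique() == 1


class TestMonotonicity:
    def test_random_nested_chains_on_synthetic_calls(self):
        """All-agree rule along nested subset chains: sensitivity (hits over
        all pathogenic, no-calls penalized) is non-increasing, and the
        false-alarm rate (false positives over all benign) is non-increasing
        — i.e. specificity in the 1 - FPR sense is non-decreasing."""
        rng = np.random.default_rng(13)
        tools = tuple(f"T{i}" for i in range(6))
        n = 80
        labels = [P if b else B for b in rng.integers(0, 2, n)]
        calls = {t: [(P, B, M)[i] for i in rng.integers(0, 3, n)] for t in tools}
        for _ in range(30):
            order = rng.permutation(len(tools))
            sens_prev, fpr_prev = None, None
            for depth in range(1, len(tools) + 1):
                subset = [tools[i] for i in order[:depth]]
                c = confusion(combine_calls(subset, calls), labels)
                m = metrics(c)
                n_benign = c.tn + c.fp + c.unclassified_benign
                fpr = c.fp / n_benign if n_benign else None
                if sens_prev is not None and m.sensitivity is not None:
                    assert m.sensitivity <= sens_prev + 1e-12
                if fpr_prev is not None and fpr is not None:
                    assert fpr <= fpr_prev + 1e-12
                sens_prev = m.sensitivity if m.sensitivity is not None else sens_prev
                fpr_prev = fpr if fpr is not None else fpr_prev
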