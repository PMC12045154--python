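"""Similarity metrics, rank-based Acc Score, confusion matrix, proportions.

Every metric is checked against an independently coded brute-force
evaluation of its formula (plain Python loops, no shared code path).
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dsct.classifier import CellTypeProbabilityMatrix
from dsct.core_data import ExpressionDataset, LabelVocabulary
from dsct.evaluation import (
    ReferenceMap,
    acc_score,
    aggregate_metrics,
    build_reference_map,
    confusion_matrix,
    evaluate_methods,
    metric_cos,
    metric_js,
    metric_kl,
    metric_ppmc,
    metric_ssim,
    proportion_similarity,
)

# ---- independent brute-force oracles -------------------------------------


def brute_cos(p, r):
    num = sum(a * b for a, b in zip(p, r))
    dp = math.sqrt(sum(a * a for a in p))
    dr = math.sqrt(sum(b * b for b in r))
    return num / (dp * dr) if dp * dr > 0 else 0.0


def brute_ppmc(p, r):
    n = len(p)
    mp, mr = sum(p) / n, sum(r) / n
    num = sum((a - mp) * (b - mr) for a, b in zip(p, r))
    dp = math.sqrt(sum((a - mp) ** 2 for a in p))
    dr = math.sqrt(sum((b - mr) ** 2 for b in r))
    return num / (dp * dr) if dp * dr > 0 else 0.0


def brute_ssim(p, r):
    mp_ = max(p)
    mr_ = max(r)
    p = [a / mp_ for a in p] if mp_ > 0 else list(p)
    r = [b / mr_ for b in r] if mr_ > 0 else list(r)
    n = len(p)
    mu_p, mu_r = sum(p) / n, sum(r) / n
    var_p = sum((a - mu_p) ** 2 for a in p) / n
    var_r = sum((b - mu_r) ** 2 for b in r) / n
    cov = sum((a - mu_p) * (b - mu_r) for a, b in zip(p, r)) / n
    C1, C2 = 0.01**2, 0.03**2
    return ((2 * mu_p * mu_r + C1) * (2 * cov + C2)) / (
        (mu_p**2 + mu_r**2 + C1) * (var_p + var_r + C2)
    )


def _simplex(v, eps=1e-12):
    v = [x + eps for x in v]
    s = sum(v)
    return [x / s for x in v]


def brute_kl(p, r):
    ps, rs = _simplex(p), _simplex(r)
    return sum(b * math.log(b / a) for a, b in zip(ps, rs))


def brute_js(p, r):
    ps, rs = _simplex(p), _simplex(r)
    m = [(a + b) / 2 for a, b in zip(ps, rs)]
    return 0.5 * sum(a * math.log(a / c) for a, c in zip(ps, m)) + 0.5 * sum(
        b * math.log(b / c) for b, c in zip(rs, m)
    )


PAIRS = [
    (metric_cos, brute_cos),
    (metric_ppmc, brute_ppmc),
    (metric_ssim, brute_ssim),
    (metric_kl, brute_kl),
    (metric_js, brute_js),
]


@pytest.mark.parametrize("impl,oracle", PAIRS, ids=["COS", "PPMC", "SSIM", "KL", "JS"])
def test_metrics_match_brute_force_on_random_pairs(impl, oracle):
    rng = np.random.default_rng(77)
    for _ in range(200):
        n = rng.integers(2, 40)
        p = rng.random(n)
        r = rng.random(n)
        assert impl(p, r) == pytest.approx(oracle(list(p), list(r)), abs=1e-10)


class TestMetricAnchors:
    def test_cos(self):
        assert metric_cos([1, 2, 2], [1, 2, 2]) == pytest.approx(1.0)
        assert metric_cos([1, 0], [0, 1]) == pytest.approx(0.0)
        assert metric_cos([1, 2, 2], [1, 1, 0]) == pytest.approx(3 / (3 * np.sqrt(2)), abs=1e-10)

    def test_ppmc(self):
        assert metric_ppmc([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert metric_ppmc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        assert metric_ppmc([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5, abs=1e-12)
        with pytest.warns(UserWarning, match="constant"):
            assert metric_ppmc([1, 1], [1, 2]) == 0.0

    def test_ssim(self):
        assert metric_ssim([0.3, 0.7], [0.3, 0.7]) == pytest.approx(1.0)
        assert metric_ssim([0, 0], [0, 0]) == pytest.approx(1.0)  # degenerate
        assert metric_ssim([0, 1], [1, 0]) == pytest.approx(brute_ssim([0, 1], [1, 0]), abs=1e-12)

    def test_kl(self):
        assert metric_kl([0.5, 0.5], [0.5, 0.5]) == pytest.approx(0.0, abs=1e-9)
        expected = 0.5 * math.log(0.5 / 0.25) + 0.5 * math.log(0.5 / 0.75)
        assert metric_kl([0.25, 0.75], [0.5, 0.5]) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.14384, abs=5e-6)
        assert math.isfinite(metric_kl([0.0, 1.0], [0.5, 0.5]))  # eps guard

    def test_js(self):
        assert metric_js([0.2, 0.8], [0.2, 0.8]) == pytest.approx(0.0, abs=1e-9)
        assert metric_js([1, 0], [0, 1]) == pytest.approx(np.log(2), abs=1e-6)


@settings(max_examples=80, derandomize=True, deadline=None)
@given(
    arrays(np.float64, st.integers(2, 15), elements=st.floats(0, 1)),
    arrays(np.float64, st.integers(2, 15), elements=st.floats(0, 1)),
)
def test_metric_ranges_and_symmetry(p, r):
    if len(p) != len(r):
        p, r = p[: min(len(p), len(r))], r[: min(len(p), len(r))]
    assert metric_kl(p, r) >= -1e-12
    js = metric_js(p, r)
    assert -1e-12 <= js <= np.log(2) + 1e-12
    assert js == pytest.approx(metric_js(r, p), abs=1e-12)
    assert -1 - 1e-9 <= metric_ssim(p, r) <= 1 + 1e-9


class TestReferenceMap:
    def test_annotation_one_hot(self):
        ds = ExpressionDataset(np.ones((2, 1)), ["g"], ["a", "b"],
                               labels=["t1", "t2"], layer_tag="normalized")
        rm = build_reference_map(ds, LabelVocabulary(("t1", "t2")))
        np.testing.assert_array_equal(rm.matrix, np.eye(2))
        assert rm.source == "annotation_onehot"

    def test_marker_mode_max_scaling(self):
        ds = ExpressionDataset(np.array([[0.0], [2.0], [4.0]]), ["m1"],
                               ["a", "b", "c"], layer_tag="normalized")
        rm = build_reference_map(ds, LabelVocabulary(("t",)), markers={"t": ["m1"]})
        np.testing.assert_allclose(rm.matrix[:, 0], [0, 0.5, 1.0])

    def test_type_without_markers_errors(self):
        ds = ExpressionDataset(np.ones((1, 1)), ["g"], ["a"], layer_tag="normalized")
        with pytest.raises(ValueError, match="t2"):
            build_reference_map(ds, LabelVocabulary(("t1", "t2")),
                                markers={"t1": ["g"], "t2": ["absent"]})


class TestAggregateMetrics:
    def _pm(self, M, vocab):
        return CellTypeProbabilityMatrix(M, [f"o{i}" for i in range(len(M))], vocab)

    def test_perfect_prediction(self):
        vocab = LabelVocabulary(("a", "b"))
        onehot = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        agg = aggregate_metrics(self._pm(onehot, vocab),
                                ReferenceMap(onehot, "annotation_onehot", vocab))
        assert agg["COS"] == pytest.approx(1.0)
        assert agg["PPMC"] == pytest.approx(1.0)
        assert agg["SSIM"] == pytest.approx(1.0)
        assert agg["KL"] == pytest.approx(0.0, abs=1e-6)
        assert agg["JS"] == pytest.approx(0.0, abs=1e-6)

    def test_half_right_cos_is_half(self):
        vocab = LabelVocabulary(("a", "b"))
        pred = np.array([[1.0, 0.0], [0.0, 1.0]])
        ref = np.array([[1.0, 1.0], [0.0, 0.0]])  # type a perfect, type b orthogonal
        agg = aggregate_metrics(self._pm(pred, vocab),
                                ReferenceMap(ref, "true_proportions", vocab))
        assert agg["COS"] == pytest.approx(0.5)

    def test_shape_mismatch(self):
        vocab = LabelVocabulary(("a", "b"))
        with pytest.raises(ValueError):
            aggregate_metrics(
                self._pm(np.full((2, 2), 0.5), vocab),
                ReferenceMap(np.ones((3, 2)), "true_proportions", vocab),
            )


class TestAccScore:
    def test_dominant_method_scores_one(self):
        table = pd.DataFrame(
            {"COS": [0.9, 0.5, 0.4], "PPMC": [0.8, 0.6, 0.3],
             "SSIM": [0.95, 0.7, 0.5], "KL": [0.01, 0.5, 0.9]},
            index=["A", "B", "C"],
        )
        scores = acc_score(table)
        assert scores["A"] == pytest.approx(1.0)
        assert scores["C"] == pytest.approx(1 / 3)

    def test_identical_methods_tie_at_075(self):
        row = {"COS": 0.5, "PPMC": 0.5, "SSIM": 0.5, "KL": 0.2}
        table = pd.DataFrame([row, row], index=["A", "B"])
        scores = acc_score(table)
        assert scores["A"] == pytest.approx(0.75)
        assert scores["B"] == pytest.approx(0.75)

    def test_invariant_under_monotone_transform(self, rng):
        table = pd.DataFrame(
            rng.random((4, 4)), index=list("ABCD"), columns=["COS", "PPMC", "SSIM", "KL"]
        )
        base = acc_score(table)
        warped = table.copy()
        warped["PPMC"] = np.exp(5 * warped["PPMC"])  # strictly increasing
        pd.testing.assert_series_equal(base, acc_score(warped))

    def test_requirements(self):
        one = pd.DataFrame([{"COS": 1, "PPMC": 1, "SSIM": 1, "KL": 0}], index=["A"])
        with pytest.raises(ValueError, match=">= 2"):
            acc_score(one)
        bad = pd.DataFrame(
            [{"COS": 1, "PPMC": np.nan, "SSIM": 1, "KL": 0}] * 2, index=["A", "B"]
        )
        with pytest.raises(ValueError, match="missing"):
            acc_score(bad)


class TestConfusionMatrix:
    def test_perfect_agreement(self):
        cm, acc = confusion_matrix(["a", "b", "a"], ["a", "b", "a"])
        np.testing.assert_array_equal(cm.to_numpy(), np.eye(2))
        assert acc == 1.0

    def test_constant_prediction_fills_one_column(self):
        cm, _ = confusion_matrix(["c", "c", "c"], ["a", "b", "c"])
        np.testing.assert_array_equal(cm["c"].to_numpy(), [1.0, 1.0, 1.0])

    def test_three_of_four(self):
        cm, acc = confusion_matrix(["a", "a", "b", "b"], ["a", "a", "a", "b"])
        assert acc == 0.75
        assert cm.loc["a", "b"] == pytest.approx(1 / 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_matrix(["a"], ["a", "b"])


class TestProportionSimilarity:
    def _pm(self, M):
        vocab = LabelVocabulary(tuple(f"t{k}" for k in range(M.shape[1])))
        return CellTypeProbabilityMatrix(M, [f"o{i}" for i in range(len(M))], vocab)

    def test_identical_proportions(self):
        pm = self._pm(np.array([[0.7, 0.3], [0.5, 0.5]]))
        ppmc, cos = proportion_similarity(pm, pm.matrix.mean(axis=0))
        assert ppmc == pytest.approx(1.0) and cos == pytest.approx(1.0)

    def test_uniform_vs_uniform_convention(self):
        pm = self._pm(np.full((3, 2), 0.5))
        with pytest.warns(UserWarning, match="constant"):
            ppmc, cos = proportion_similarity(pm, np.array([0.5, 0.5]))
        assert ppmc == 0.0 and cos == pytest.approx(1.0)

    def test_toy_vectors_direct_formula(self):
        pm = self._pm(np.array([[0.7, 0.3]]))
        ppmc, cos = proportion_similarity(pm, np.array([0.6, 0.4]))
        assert cos == pytest.approx(brute_cos([0.7, 0.3], [0.6, 0.4]), abs=1e-12)
        assert ppmc == pytest.approx(brute_ppmc([0.7, 0.3], [0.6, 0.4]), abs=1e-12)

    def test_hard_label_frequencies(self):
        pm = self._pm(np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.6, 0.4]]))
        ppmc, cos = proportion_similarity(pm, np.array([0.75, 0.25]), use_hard_labels=True)
        assert cos == pytest.approx(1.0)  # frequencies are exactly (0.75, 0.25)


def test_evaluate_methods_needs_two():
    vocab = LabelVocabulary(("a", "b"))
    pm = CellTypeProbabilityMatrix(np.array([[1.0, 0.0]]), ["o"], vocab)
    ref = ReferenceMap(np.array([[1.0, 0.0]]), "annotation_onehot", vocab)
    with pytest.raises(ValueError, match=">= 2"):
        evaluate_methods({"only": pm}, ref)
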