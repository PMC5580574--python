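"""AHP weight derivation: eigenvector method and consistency checking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wqassess import (
    JudgmentMatrix,
    check_consistency,
    consistency_ratio,
    matrix_from_scores,
    weights_from_matrix,
)
from wqassess.ahp import AHPError, WeightScheme, WeightSource


def consistent_matrix(names, w):
    """Judgment matrix built from a known weight vector (entry = wi/wj)."""
    w = np.asarray(w, dtype=float)
    return JudgmentMatrix(tuple(names), np.outer(w, 1.0 / w))


class TestMatrixFromScores:
    def test_equal_scores_give_all_ones(self):
        m = matrix_from_scores({"A": 3, "B": 3, "C": 3})
        assert np.allclose(m.entries, 1.0)

    def test_difference_rule(self):
        """Score gap d maps to importance ratio d+1, reciprocal opposite."""
        m = matrix_from_scores({"A": 5, "B": 3})
        assert m.entries[0, 1] == pytest.approx(3.0)
        assert m.entries[1, 0] == pytest.approx(1 / 3)

    def test_symmetric_scores_give_uniform_weights(self):
        m = matrix_from_scores({"A": 4, "B": 4, "C": 4})
        ws = weights_from_matrix(m)
        assert all(w == pytest.approx(1 / 3) for w in ws.weights.values())
        assert ws.consistency_ratio == pytest.approx(0.0, abs=1e-9)

    def test_score_matrices_with_two_levels_are_consistent(self):
        # the additive difference rule is multiplicatively transitive only
        # when at most two distinct scores appear
        m = matrix_from_scores({"A": 5, "B": 2, "C": 2, "D": 5})
        assert consistency_ratio(m) == pytest.approx(0.0, abs=1e-6)

    def test_score_matrices_are_acceptably_consistent(self):
        """With several distinct scores the matrix is near- (not exactly)
        consistent, but always passes the conventional CR < 0.1 rule."""
        m = matrix_from_scores({"A": 1, "B": 2, "C": 4, "D": 5})
        assert 0.0 < consistency_ratio(m) < 0.1
        assert check_consistency(m)

    @pytest.mark.parametrize("scores", [{"A": 0, "B": 3}, {"A": 6, "B": 3}, {"A": 2.5, "B": 3}, {"A": 3}])
    def test_invalid_scores_rejected(self, scores):
        with pytest.raises(AHPError):
            matrix_from_scores(scores)


class TestWeightsFromMatrix:
    def test_uniform_matrix(self):
        m = JudgmentMatrix(("a", "b", "c", "d"), np.ones((4, 4)))
        ws = weights_from_matrix(m)
        assert all(w == pytest.approx(0.25) for w in ws.weights.values())
        assert ws.consistency_ratio == 0.0
        assert ws.source is WeightSource.AHP

    def test_two_by_two_closed_form(self):
        """[[1,3],[1/3,1]] has principal eigenvector (3,1)/4 = (0.75, 0.25)."""
        m = JudgmentMatrix(("A", "B"), np.array([[1, 3], [1 / 3, 1]]))
        ws = weights_from_matrix(m)
        assert ws.weights["A"] == pytest.approx(0.75, abs=1e-9)
        assert ws.weights["B"] == pytest.approx(0.25, abs=1e-9)
        assert ws.consistency_ratio == 0.0

    def test_recovers_generating_weights(self):
        w = (0.5, 0.3, 0.2)
        ws = weights_from_matrix(consistent_matrix("abc", w))
        for name, wi in zip("abc", w):
            assert ws.weights[name] == pytest.approx(wi, abs=1e-10)
        assert ws.consistency_ratio == pytest.approx(0.0, abs=1e-9)

    def test_geometric_mean_agrees_on_consistent_matrices(self):
        m = consistent_matrix("abcd", (0.4, 0.3, 0.2, 0.1))
        we = weights_from_matrix(m, method="eigenvector")
        wg = weights_from_matrix(m, method="geometric_mean")
        for name in "abcd":
            assert we.weights[name] == pytest.approx(wg.weights[name], abs=1e-6)

    def test_agrees_with_dense_eigendecomposition(self):
        """Power iteration matches numpy's full eigendecomposition (oracle)."""
        a = np.array([[1, 2, 9], [0.5, 1, 1], [1 / 9, 1, 1]])
        m = JudgmentMatrix(("x", "y", "z"), a)
        ws = weights_from_matrix(m)
        ev, vec = np.linalg.eig(a)
        k = np.argmax(ev.real)
        expected = vec[:, k].real
        expected /= expected.sum()
        for name, wi in zip(("x", "y", "z"), expected):
            assert ws.weights[name] == pytest.approx(wi, abs=1e-8)


class TestConsistency:
    def test_perturbed_matrix_fails_strict_threshold(self):
        # lambda_max = 3.25667 by dense eigendecomposition, so CR = 0.2213
        a = np.array([[1, 2, 9], [0.5, 1, 1], [1 / 9, 1, 1]])
        m = JudgmentMatrix(("x", "y", "z"), a)
        assert consistency_ratio(m) == pytest.approx(0.22127, abs=1e-4)
        assert not check_consistency(m, threshold=0.01)
        assert not check_consistency(m)  # default 0.1 also fails

    def test_two_by_two_always_consistent(self):
        m = JudgmentMatrix(("A", "B"), np.array([[1, 7], [1 / 7, 1]]))
        assert consistency_ratio(m) == 0.0
        assert check_consistency(m, threshold=1e-6)

    def test_consistent_matrix_passes(self):
        m = consistent_matrix("abc", (0.6, 0.25, 0.15))
        assert check_consistency(m, threshold=0.1)

    def test_threshold_must_be_positive(self):
        m = consistent_matrix("ab", (0.5, 0.5))
        with pytest.raises(AHPError):
            check_consistency(m, threshold=0.0)


class TestMatrixValidation:
    def test_non_reciprocal_rejected(self):
        with pytest.raises(AHPError):
            JudgmentMatrix(("a", "b"), np.array([[1.0, 2.0], [0.6, 1.0]]))

    def test_bad_diagonal_rejected(self):
        with pytest.raises(AHPError):
            JudgmentMatrix(("a", "b"), np.array([[2.0, 1.0], [1.0, 1.0]]))

    def test_nonpositive_rejected(self):
        with pytest.raises(AHPError):
            JudgmentMatrix(("a", "b"), np.array([[1.0, -2.0], [-0.5, 1.0]]))


class TestWeightScheme:
    def test_must_sum_to_one(self):
        with pytest.raises(AHPError):
            WeightScheme({"a": 0.5, "b": 0.4})

    def test_direct_scheme(self, weights):
        assert sum(weights.weights.values()) == pytest.approx(1.0, abs=1e-9)
        assert weights.source is WeightSource.DIRECT


@settings(derandomize=True, max_examples=100)
@given(
    w=st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=3, max_size=8),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_recovery_and_permutation_equivariance(w, seed):
    """Weights recovered from wi/wj matrices to 1e-8, in any indicator order."""
    w = np.asarray(w) / np.sum(w)
    names = [f"i{k}" for k in range(len(w))]
    ws = weights_from_matrix(consistent_matrix(names, w))
    for name, wi in zip(names, w):
        assert ws.weights[name] == pytest.approx(wi, abs=1e-8)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(w))
    ws_p = weights_from_matrix(consistent_matrix([names[i] for i in perm], w[perm]))
    for name in names:
        assert ws_p.weights[name] == pytest.approx(ws.weights[name], abs=1e-8)


@settings(derandomize=True, max_examples=50)
@given(
    factor=st.floats(min_value=0.2, max_value=5.0),
    k=st.integers(min_value=0, max_value=2),
)
def test_diagonal_rescaling_preserves_consistency(factor, k):
    """Scaling row k by f and column k by 1/f is a similarity transform:
    the matrix stays reciprocal and consistent, and the recovered weights
    are the originals with the k-th entry scaled by f (then renormalized)."""
    w = np.array([0.5, 0.3, 0.2])
    a = np.outer(w, 1.0 / w)
    d = np.ones(3)
    d[k] = factor
    b = np.diag(d) @ a @ np.diag(1.0 / d)
    m = JudgmentMatrix(("a", "b", "c"), b)
    assert consistency_ratio(m) == pytest.approx(0.0, abs=1e-8)
    expected = w * d
    expected /= expected.sum()
    ws = weights_from_matrix(m)
    for name, wi in zip(("a", "b", "c"), expected):
        assert ws.weights[name] == pytest.approx(wi, abs=1e-8)
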