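"""Worked values and identities of the training objective and the
evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frn3d.autograd import Tensor
from frn3d.frn import SupportPool
from frn3d.losses import (
    aux_orthogonality_loss,
    aux_orthogonality_loss_t,
    cross_entropy,
    total_loss,
)
from frn3d.metrics import (
    ConfusionCounts,
    confusion_counts,
    evaluate_predictions,
    metrics_from_counts,
    roc_curve,
)


class TestCrossEntropy:
    def test_confident_correct_is_near_zero(self):
        assert cross_entropy([1], [1 - 1e-9]) < 1e-6

    def test_coin_flip_is_ln_two(self):
        np.testing.assert_allclose(cross_entropy([1], [0.5]), np.log(2.0))

    def test_two_sample_worked_value(self):
        # -(1/2)(ln 0.9 + ln 0.9) = 0.10536...
        np.testing.assert_allclose(cross_entropy([1, 0], [0.9, 0.1]),
                                   -np.log(0.9), atol=1e-10)
        np.testing.assert_allclose(cross_entropy([1, 0], [0.9, 0.1]),
                                   0.10536, atol=5e-6)

    def test_clamping_keeps_confident_mistakes_finite(self):
        assert np.isfinite(cross_entropy([1, 0], [0.0, 1.0]))

    def test_minimized_iff_probabilities_match_labels(self, rng):
        y = rng.integers(0, 2, size=20)
        exact = cross_entropy(y, np.clip(y.astype(float), 1e-12, 1 - 1e-12))
        perturbed = cross_entropy(y, np.clip(np.abs(y - 0.1), 1e-12, 1 - 1e-12))
        assert exact < 1e-10 < perturbed

    def test_empty_and_mismatched_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy([], [])
        with pytest.raises(ValueError):
            cross_entropy([1, 0], [0.5])


class TestOrthogonalityLoss:
    def test_orthogonal_rows_give_zero(self):
        assert aux_orthogonality_loss([np.array([[1.0, 0.0]]),
                                       np.array([[0.0, 1.0]])]) == 0.0

    def test_identical_rows_give_two(self):
        # both ordered pairs contribute |<u,u>|^2 = 1
        loss = aux_orthogonality_loss([np.array([[1.0, 0.0]]),
                                       np.array([[1.0, 0.0]])])
        np.testing.assert_allclose(loss, 2.0)

    def test_forty_five_degrees_gives_one(self):
        s2 = np.sqrt(2.0) / 2.0
        loss = aux_orthogonality_loss([np.array([[1.0, 0.0]]),
                                       np.array([[s2, s2]])])
        np.testing.assert_allclose(loss, 1.0)

    def test_row_scale_invariance(self, rng):
        """Unit-sphere projection absorbs any positive row rescaling."""
        a, b = rng.normal(size=(3, 4)), rng.normal(size=(2, 4))
        scales = rng.uniform(0.1, 10.0, size=3)
        l1 = aux_orthogonality_loss([a, b])
        l2 = aux_orthogonality_loss([a * scales[:, None], b])
        assert abs(l1 - l2) < 1e-12

    def test_accepts_support_pools_and_warns_on_zero_rows(self, rng):
        m = rng.normal(size=(4, 3))
        m[2] = 0.0
        pools = [SupportPool(m, 0, 2, 2), SupportPool(rng.normal(size=(4, 3)), 1, 2, 2)]
        with pytest.warns(UserWarning):
            loss = aux_orthogonality_loss(pools)
        assert loss >= 0

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            aux_orthogonality_loss([rng.normal(size=(2, 2))])

    def test_tensor_version_matches_numpy(self, rng):
        a, b = rng.normal(size=(3, 4)), rng.normal(size=(5, 4))
        ref = aux_orthogonality_loss([a, b])
        val = aux_orthogonality_loss_t([Tensor(a), Tensor(b)]).item()
        np.testing.assert_allclose(val, ref, atol=1e-9)


class TestTotalLoss:
    @pytest.mark.parametrize("ce,aux,expected", [
        (1.0, 0.0, 1.0),
        (0.0, 2.0, 0.06),
        (0.5, 1.0, 0.53),
    ])
    def test_weighted_sum(self, ce, aux, expected):
        np.testing.assert_allclose(total_loss(ce, aux), expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            total_loss(np.nan, 0.0)


class TestConfusionCounts:
    def test_all_correct(self):
        c = confusion_counts([1] * 7 + [0] * 7, [1] * 7 + [0] * 7)
        assert (c.tp, c.tn, c.fp, c.fn) == (7, 7, 0, 0)

    def test_counting_example(self):
        c = confusion_counts([1, 1, 1, 1, 0, 0, 0, 0], [1, 1, 1, 0, 1, 0, 0, 0])
        assert (c.tp, c.fn, c.fp, c.tn) == (3, 1, 1, 3)
        assert c.total == 8

    def test_empty_and_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts([], [])
        with pytest.raises(ValueError):
            confusion_counts([0, 2], [0, 1])


class TestMetricsFromCounts:
    def test_worked_example_all_three_quarters(self):
        rep = metrics_from_counts(ConfusionCounts(tp=3, tn=3, fp=1, fn=1))
        assert rep.accuracy == rep.recall == rep.precision == rep.f1 == 0.75

    def test_perfect_counts(self):
        rep = metrics_from_counts(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert rep.accuracy == rep.recall == rep.precision == rep.f1 == 1.0

    def test_degenerate_denominators_warn_and_zero(self):
        with pytest.warns(UserWarning):
            rep = metrics_from_counts(ConfusionCounts(tp=0, tn=4, fp=0, fn=0))
        assert rep.recall == 0.0 and rep.precision == 0.0 and rep.f1 == 0.0
        assert rep.accuracy == 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(tp=st.integers(0, 20), tn=st.integers(0, 20),
           fp=st.integers(0, 20), fn=st.integers(0, 20))
    def test_f1_between_precision_and_recall(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = metrics_from_counts(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        lo, hi = sorted([rep.precision, rep.recall])
        assert lo - 1e-12 <= rep.f1 <= hi + 1e-12
        if rep.precision == rep.recall:
            np.testing.assert_allclose(rep.f1, rep.precision)


class TestRoc:
    def test_perfect_separation(self):
        _, auc = roc_curve([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_reversed_scores(self):
        _, auc = roc_curve([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1])
        assert auc == 0.0

    def test_random_scores_near_half(self, rng):
        n = 2000
        y = rng.integers(0, 2, size=n)
        _, auc = roc_curve(y, rng.random(n))
        # permutation expectation 0.5; SE of AUC ~ sqrt(1/12) / sqrt(n~)
        assert abs(auc - 0.5) < 3 * 0.6 / np.sqrt(n / 4)

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 2, size=50)
        s = rng.random(50)
        _, a1 = roc_curve(y, s)
        _, a2 = roc_curve(y, np.exp(5 * s))
        np.testing.assert_allclose(a1, a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 1, 1], [0.1, 0.5, 0.9])


class TestEvaluatePredictions:
    def test_report_serializes(self, tmp_path):
        rep = evaluate_predictions([0, 1, 0, 1], [0, 1, 1, 1], [0.2, 0.9, 0.6, 0.8])
        text = rep.to_json(tmp_path / "m.json")
        assert (tmp_path / "m.json").exists()
        assert '"accuracy"' in text
        rep.roc_to_tsv(tmp_path / "roc.tsv")
        lines = (tmp_path / "roc.tsv").read_text().strip().splitlines()
        assert lines[0] == "FPR\tTPR"
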