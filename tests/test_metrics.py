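import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vfaug.datasets import DatasetError
from vfaug.metrics import (
    ConfusionMatrix,
    MetricsReport,
    PCAFeatureExtractor,
    aggregate_runs,
    classification_metrics,
    confusion_matrix,
    extract_features,
    fid,
    fid_between,
)


class TestConfusionMatrix:
    def test_hand_enumerable_example(self):
        cm = confusion_matrix(["A", "A", "B"], ["A", "B", "B"], ["A", "B"])
        assert cm.counts.tolist() == [[1, 1], [0, 1]]

    def test_perfect_predictions_are_diagonal(self):
        labels = ["A"] * 3 + ["B"] * 2
        cm = confusion_matrix(labels, labels, ["A", "B"])
        assert np.array_equal(cm.counts, np.diag([3, 2]))

    def test_errors(self):
        with pytest.raises(DatasetError):
            confusion_matrix(["A"], ["A", "B"], ["A", "B"])
        with pytest.raises(DatasetError):
            confusion_matrix(["A"], ["C"], ["A", "B"])

    @given(st.lists(st.tuples(st.sampled_from("ABC"), st.sampled_from("ABC")),
                    min_size=1, max_size=200))
    def test_totals_conserved_and_matches_sklearn(self, pairs):
        from sklearn.metrics import confusion_matrix as sk_cm

        actual = [a for a, _ in pairs]
        predicted = [p for _, p in pairs]
        cm = confusion_matrix(actual, predicted, "ABC")
        assert cm.total == len(pairs)
        assert np.array_equal(
            cm.counts, sk_cm(actual, predicted, labels=list("ABC")))


class TestClassificationMetrics:
    def test_hand_computed_binary_example(self):
        # TP=50, FP=10, FN=5, TN=35 with rows/cols (without, with)
        cm = ConfusionMatrix(np.array([[35, 10], [5, 50]]),
                             ("without_pathology", "with_pathology"))
        rep = classification_metrics(cm, averaging="binary")
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.precision == pytest.approx(50 / 60)
        assert rep.sensitivity == pytest.approx(50 / 55)
        assert rep.specificity == pytest.approx(35 / 45)
        assert rep.f1 == pytest.approx(2 * (50 / 60) * (50 / 55) / (50 / 60 + 50 / 55))

    def test_perfect_classifier_all_ones(self):
        cm = ConfusionMatrix(np.diag([7, 9]), ("without_pathology", "with_pathology"))
        rep = classification_metrics(cm, averaging="binary")
        assert all(v == 1.0 for v in rep.metric_dict().values())

    def test_always_positive_predictor(self):
        cm = ConfusionMatrix(np.array([[0, 20], [0, 30]]),
                             ("without_pathology", "with_pathology"))
        rep = classification_metrics(cm, averaging="binary")
        assert rep.sensitivity == 1.0
        assert rep.specificity == 0.0

    def test_zero_denominator_flagged(self):
        cm = ConfusionMatrix(np.array([[5, 0], [3, 0]]),
                             ("without_pathology", "with_pathology"))
        rep = classification_metrics(cm, averaging="binary")
        assert rep.precision == 0.0
        assert any("precision" in f for f in rep.zero_division_flags)

    def test_all_zero_matrix_rejected(self):
        cm = ConfusionMatrix(np.zeros((2, 2), int), ("a", "b"))
        with pytest.raises(DatasetError):
            classification_metrics(cm)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(1, 50))
    def test_f1_is_harmonic_mean(self, tn, fp, fn, tp):
        cm = ConfusionMatrix(np.array([[tn, fp], [fn, tp]]),
                             ("without_pathology", "with_pathology"))
        rep = classification_metrics(cm, averaging="binary")
        p, r = rep.precision, rep.sensitivity
        expected = 2 * p * r / (p + r) if p + r > 0 else 0.0
        assert rep.f1 == pytest.approx(expected, abs=1e-12)

    def test_accuracy_is_trace_over_total(self):
        rng = np.random.default_rng(0)
        c = rng.integers(0, 20, (4, 4))
        c[0, 0] += 1
        cm = ConfusionMatrix(c, ("a", "b", "c", "d"))
        rep = classification_metrics(cm, averaging="macro")
        assert rep.accuracy == pytest.approx(np.trace(c) / c.sum())

    def test_macro_invariant_to_relabeling(self):
        rng = np.random.default_rng(1)
        c = rng.integers(1, 15, (3, 3))
        cm = ConfusionMatrix(c, ("a", "b", "c"))
        perm = [2, 0, 1]
        cm_p = ConfusionMatrix(c[np.ix_(perm, perm)], ("c", "a", "b"))
        r1 = classification_metrics(cm, averaging="macro")
        r2 = classification_metrics(cm_p, averaging="macro")
        for k, v in r1.metric_dict().items():
            assert v == pytest.approx(r2.metric_dict()[k], abs=1e-12)

    def test_macro_and_weighted_match_sklearn(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(2)
        actual = rng.choice(list("abc"), 200)
        predicted = rng.choice(list("abc"), 200)
        cm = confusion_matrix(actual, predicted, "abc")
        for avg in ("macro", "weighted"):
            rep = classification_metrics(cm, averaging=avg)
            p, r, f, _ = precision_recall_fscore_support(
                actual, predicted, labels=list("abc"), average=avg, zero_division=0)
            assert rep.precision == pytest.approx(p, abs=1e-12)
            assert rep.sensitivity == pytest.approx(r, abs=1e-12)
            assert rep.f1 == pytest.approx(f, abs=1e-12)


class TestFID:
    def test_identical_inputs_give_zero(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 6))
        assert fid(X, X).value == pytest.approx(0.0, abs=1e-6)

    def test_one_dimensional_closed_form(self):
        """Exact sample stats mean 0/var 1 vs mean 1/var 1 give FID = 1."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal(400)
        x = ((x - x.mean()) / x.std(ddof=1))[:, None]
        y = x + 1.0
        assert fid(x, y).value == pytest.approx(1.0, abs=1e-4)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((60, 5))
        B = rng.standard_normal((80, 5)) * 2 + 1
        assert fid(A, B).value == pytest.approx(fid(B, A).value, rel=1e-9)

    def test_diagonal_gaussian_closed_form(self):
        rng = np.random.default_rng(3)
        d = 4
        sd_r = np.array([1.0, 2.0, 0.5, 1.5])
        sd_s = np.array([1.5, 1.0, 1.0, 0.5])
        mu_s = np.array([1.0, -1.0, 0.5, 0.0])
        # construct samples whose sample moments are exactly 0 / diagonal
        base = rng.standard_normal((500, d))
        base = base - base.mean(axis=0)
        L = np.linalg.cholesky(np.cov(base, rowvar=False))
        base = base @ np.linalg.inv(L).T  # sample cov exactly I, mean 0
        X = base * sd_r
        Y = base * sd_s + mu_s
        expected = np.sum(mu_s**2) + np.sum((sd_r - sd_s) ** 2)
        assert fid(X, Y).value == pytest.approx(expected, abs=1e-3)

    def test_trace_term_matches_scipy_sqrtm(self):
        from scipy.linalg import sqrtm

        rng = np.random.default_rng(4)
        A = rng.standard_normal((100, 5))
        B = rng.standard_normal((100, 5)) @ np.diag([1, 2, 1, 0.5, 3])
        res = fid(A, B)
        direct = np.real(np.trace(sqrtm(res.sigma_r @ res.sigma_s)))
        ours = (np.trace(res.sigma_r) + np.trace(res.sigma_s)
                - (res.value - np.sum((res.mu_r - res.mu_s) ** 2))) / 2
        assert ours == pytest.approx(direct, rel=1e-6)

    def test_monotone_under_progressive_corruption(self, pristine_dataset):
        rng = np.random.default_rng(5)
        extractor = PCAFeatureExtractor(6).fit(pristine_dataset)
        ref = extract_features(pristine_dataset, extractor)
        values = []
        for sigma in (0, 20, 60, 120):
            noisy = []
            for im in pristine_dataset:
                px = im.pixels.astype(float) + rng.standard_normal(im.pixels.shape) * sigma
                from vfaug.datasets import LabeledImage

                noisy.append(LabeledImage(
                    pixels=np.clip(px, 0, 255).astype(np.uint8), label=im.label,
                    provenance=im.provenance, id=im.id))
            from vfaug.datasets import ImageDataset

            feats = extract_features(ImageDataset(noisy), extractor)
            values.append(fid(ref, feats).value)
        assert values[0] == pytest.approx(0.0, abs=1e-6)
        assert all(a <= b + 1e-9 for a, b in zip(values, values[1:]))

    def test_input_validation(self):
        with pytest.raises(DatasetError):
            fid(np.zeros((5, 3)), np.zeros((5, 4)))
        with pytest.raises(DatasetError):
            fid(np.zeros((1, 3)), np.zeros((5, 3)))


class TestExtractor:
    def test_deterministic_rows_match_dataset(self, pristine_dataset):
        ex = PCAFeatureExtractor(5).fit(pristine_dataset)
        f1 = extract_features(pristine_dataset, ex)
        f2 = extract_features(pristine_dataset, ex)
        assert f1.shape[0] == len(pristine_dataset)
        assert np.array_equal(f1, f2)

    def test_dataset_vs_itself_fid_zero(self, pristine_dataset):
        res = fid_between(pristine_dataset, pristine_dataset)
        assert res.value == pytest.approx(0.0, abs=1e-6)
        assert res.extractor.startswith("pixel-pca")


class TestAggregate:
    def _report(self, acc):
        return MetricsReport(accuracy=acc, precision=acc, sensitivity=acc,
                             specificity=acc, f1=acc, averaging="binary")

    def test_two_reports_mean_and_sd(self):
        table = aggregate_runs([self._report(0.6), self._report(0.8)])
        assert table.loc["accuracy", "mean"] == pytest.approx(0.7)
        assert table.loc["accuracy", "sd"] == pytest.approx(np.std([0.6, 0.8], ddof=1))
        assert table.loc["accuracy", "n"] == 2

    def test_single_report_sd_zero_n_one(self):
        table = aggregate_runs([self._report(0.5)])
        assert table.loc["f1", "sd"] == 0.0
        assert table.loc["f1", "n"] == 1

    def test_identical_reports_sd_zero(self):
        table = aggregate_runs([self._report(0.4)] * 5)
        assert (table["sd"] == 0).all()
        assert np.allclose(table["mean"], 0.4)
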