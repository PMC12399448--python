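import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vfaug.datasets import ORIGINAL_COUNTS, SYNTHETIC_COUNTS, DatasetError
from vfaug.experiments import (
    ClassifierTrainConfig,
    build_scenario,
    derive_seed,
    evaluate_classifier,
    largest_remainder_allocation,
    run_experiment_grid,
    stratified_split,
    train_classifier,
)

from .conftest import make_flat_dataset


class TestLargestRemainder:
    def test_study_mix10_allocation(self):
        """10% of the study's originals: 40 images, granuloma contributes 0."""
        alloc = largest_remainder_allocation(dict(ORIGINAL_COUNTS), 0.10)
        assert sum(alloc.values()) == 40
        assert alloc["granuloma"] == 0
        assert alloc["without_pathology"] == 16

    @given(st.dictionaries(st.sampled_from("abcdef"), st.integers(0, 60),
                           min_size=1),
           st.floats(0.05, 0.95))
    def test_allocation_bounds(self, counts, fraction):
        alloc = largest_remainder_allocation(counts, fraction)
        for c, n in counts.items():
            assert 0 <= alloc[c] <= n
        assert abs(sum(alloc.values()) - round(fraction * sum(counts.values()))) <= \
            sum(1 for n in counts.values() if n > 0)


class TestStratifiedSplit:
    def test_two_classes_of_five(self):
        ds = make_flat_dataset({"nodule": 5, "cyst": 5}, size=8)
        a, b = stratified_split(ds, 0.8, seed=0)
        assert len(a) == 8 and len(b) == 2
        assert a.distribution().counts["nodule"] == 4
        assert b.distribution().counts["cyst"] == 1

    def test_seed_behaviour(self):
        ds = make_flat_dataset({"nodule": 10, "cyst": 6}, size=8)
        a1, _ = stratified_split(ds, 0.5, seed=1)
        a2, _ = stratified_split(ds, 0.5, seed=1)
        a3, _ = stratified_split(ds, 0.5, seed=2)
        assert a1.ids == a2.ids
        assert len(a3) == len(a1)
        assert a3.ids != a1.ids

    def test_singleton_class_goes_to_train_with_warning(self):
        ds = make_flat_dataset({"nodule": 6, "granuloma": 1}, size=8)
        with pytest.warns(UserWarning):
            a, b = stratified_split(ds, 0.8, seed=0)
        assert "granuloma" in a.labels
        assert "granuloma" not in b.labels

    @given(st.integers(2, 40), st.integers(2, 40), st.floats(0.1, 0.9),
           st.integers(0, 10))
    def test_disjoint_exhaustive_proportional(self, n1, n2, fraction, seed):
        ds = make_flat_dataset({"nodule": n1, "cyst": n2}, size=8)
        a, b = stratified_split(ds, fraction, seed=seed)
        assert len(a) + len(b) == len(ds)
        assert set(a.ids) & set(b.ids) == set()
        for cls, n in (("nodule", n1), ("cyst", n2)):
            na = a.distribution().counts[cls]
            assert abs(na - fraction * n) <= 1

    def test_invalid_fraction(self):
        ds = make_flat_dataset({"nodule": 4}, size=8)
        with pytest.raises(DatasetError):
            stratified_split(ds, 1.5, seed=0)


class TestBuildScenario:
    def test_mix10_exact_arithmetic(self):
        orig = make_flat_dataset({"without_pathology": 50, "nodule": 50}, size=8)
        synth = make_flat_dataset({"without_pathology": 20, "nodule": 20}, size=8,
                                  provenance="synthetic")
        split = build_scenario(orig, synth, "mix10", "binary", seed=0)
        originals_in_train = [im for im in split.train if im.provenance == "original"]
        assert len(originals_in_train) == 10
        assert len(split.test) == 90

    def test_synthetic_only_study_sizes(self):
        orig = make_flat_dataset(dict(ORIGINAL_COUNTS), size=4)
        synth = make_flat_dataset(dict(SYNTHETIC_COUNTS), size=4,
                                  provenance="synthetic")
        split = build_scenario(orig, synth, "synthetic_only", "binary", seed=0)
        assert len(split.train) == 4180
        assert len(split.test) == 404

    def test_mix50_two_per_class_toy(self):
        orig = make_flat_dataset({"nodule": 2, "cyst": 2}, size=8)
        synth = make_flat_dataset({"nodule": 2, "cyst": 2}, size=8,
                                  provenance="synthetic")
        split = build_scenario(orig, synth, "mix50", "multiclass", seed=3)
        train_orig = [im for im in split.train if im.provenance == "original"]
        assert {im.label for im in train_orig} == {"nodule", "cyst"}
        assert len(train_orig) == 2
        assert len(split.test) == 2

    def test_empty_class_contributes_zero_with_warning(self):
        orig = make_flat_dataset({"nodule": 30, "granuloma": 2,
                                  "without_pathology": 10}, size=8)
        synth = make_flat_dataset({"nodule": 5, "granuloma": 5,
                                   "without_pathology": 5}, size=8,
                                  provenance="synthetic")
        with pytest.warns(UserWarning, match="granuloma"):
            split = build_scenario(orig, synth, "mix10", "multiclass", seed=0)
        train_orig = [im for im in split.train
                      if im.provenance == "original" and im.label == "granuloma"]
        assert train_orig == []

    @pytest.mark.parametrize("scenario", ["synthetic_only", "mix10", "mix50",
                                          "original_only_baseline"])
    @pytest.mark.parametrize("task", ["binary", "multiclass"])
    def test_no_leakage_and_count_arithmetic(self, scenario, task):
        orig = make_flat_dataset({"without_pathology": 20, "nodule": 15,
                                  "cyst": 12, "polyp": 9}, size=8)
        synth = make_flat_dataset({"without_pathology": 8, "nodule": 8,
                                   "cyst": 8, "polyp": 8}, size=8,
                                  provenance="synthetic")
        split = build_scenario(orig, synth, scenario, task, seed=5)
        split.check_invariants()  # train/test disjoint, test all-original
        if scenario in ("mix10", "mix50"):
            n_task_orig = len(orig) if task == "binary" else len(orig) - 20
            train_orig = sum(im.provenance == "original" for im in split.train)
            assert train_orig + len(split.test) == n_task_orig

    def test_provenance_validation(self):
        orig = make_flat_dataset({"nodule": 3, "cyst": 3}, size=8)
        bad_synth = make_flat_dataset({"nodule": 2, "cyst": 2}, size=8,
                                      provenance="original", prefix="s")
        with pytest.raises(DatasetError):
            build_scenario(orig, bad_synth, "mix10", "binary", seed=0)


class TestTrainClassifier:
    def _separable_split(self):
        """Two classes with distinct base colors: trivially separable."""
        from vfaug.datasets import ImageDataset, LabeledImage
        from vfaug.experiments import ScenarioSplit

        rng = np.random.default_rng(0)
        images = []
        for i in range(24):
            label = "without_pathology" if i % 2 == 0 else "with_pathology"
            base = 40 if label == "without_pathology" else 200
            px = np.clip(base + rng.normal(0, 10, (16, 16, 3)), 0, 255).astype(np.uint8)
            images.append(LabeledImage(pixels=px, label=label,
                                       provenance="original", id=f"t{i}"))
        ds = ImageDataset(images)
        return ScenarioSplit(scenario="original_only_baseline", task="binary",
                             train=ds, test=ds, seed=0)

    def test_learns_separable_toy(self):
        split = self._separable_split()
        cfg = ClassifierTrainConfig(seed=0, base_channels=4)
        model = train_classifier(split, cfg)
        assert model.history[-1]["accuracy"] >= 0.95

    def test_seed_fixed_history_identical(self):
        split = self._separable_split()
        cfg = ClassifierTrainConfig(seed=3, base_channels=4, epochs=3)
        h1 = train_classifier(split, cfg).history
        h2 = train_classifier(split, cfg).history
        assert h1 == h2

    def test_probabilities_sum_to_one(self):
        split = self._separable_split()
        cfg = ClassifierTrainConfig(seed=0, base_channels=4, epochs=1)
        model = train_classifier(split, cfg)
        rng = np.random.default_rng(1)
        x = rng.uniform(-1, 1, (100, 3, 16, 16))
        proba = model.predict_proba(x)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(proba >= 0)

    def test_single_class_rejected(self):
        from vfaug.experiments import ScenarioSplit

        ds = make_flat_dataset({"nodule": 4}, size=8)
        split = ScenarioSplit(scenario="synthetic_only", task="multiclass",
                              train=ds, test=ds, seed=0)
        with pytest.raises(DatasetError):
            train_classifier(split, ClassifierTrainConfig())

    def test_warm_start_roundtrip(self, tmp_path):
        from vfaug.io import save_checkpoint

        split = self._separable_split()
        cfg = ClassifierTrainConfig(seed=0, base_channels=4, epochs=2)
        model = train_classifier(split, cfg)
        ckpt = tmp_path / "clf.npz"
        save_checkpoint(model, ckpt)
        warm_cfg = ClassifierTrainConfig(seed=1, base_channels=4, epochs=1,
                                         warm_start=str(ckpt))
        warm = train_classifier(split, warm_cfg)
        assert warm.history[-1]["accuracy"] >= model.history[0]["accuracy"]


class TestGrid:
    def test_structural_output_and_aggregation_consistency(self):
        rng_counts = {"without_pathology": 8, "nodule": 8, "cyst": 8}
        orig = make_flat_dataset(rng_counts, size=16)
        synth = make_flat_dataset(rng_counts, size=16, provenance="synthetic")
        cfg = ClassifierTrainConfig(epochs=1, base_channels=4)
        grid = run_experiment_grid(orig, synth, scenarios=("synthetic_only", "mix50"),
                                   tasks=("binary",), repeats=2, seed=0, config=cfg)
        assert set(grid.aggregated) == {("synthetic_only", "binary"),
                                        ("mix50", "binary")}
        for key, agg in grid.aggregated.items():
            accs = [r.accuracy for r in grid.reports[key]]
            assert agg.loc["accuracy", "mean"] == pytest.approx(np.mean(accs))
            assert agg.loc["accuracy", "sd"] == pytest.approx(np.std(accs, ddof=1))
        table = grid.table("binary")
        assert set(table.columns) == {"synthetic_only", "mix50"}

    def test_repeats_below_two_rejected(self):
        orig = make_flat_dataset({"nodule": 4, "cyst": 4}, size=8)
        synth = make_flat_dataset({"nodule": 4, "cyst": 4}, size=8,
                                  provenance="synthetic")
        with pytest.raises(DatasetError):
            run_experiment_grid(orig, synth, repeats=1, seed=0)


def test_derive_seed_stable_and_bounded():
    a = derive_seed(7, "stage", 1)
    assert a == derive_seed(7, "stage", 1)
    assert a != derive_seed(7, "stage", 2)
    assert 0 <= a < 2**31
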