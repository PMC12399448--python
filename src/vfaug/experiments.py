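"""Augmentation scenarios, classifier training and the repeated-experiment grid.

Three training scenarios probe how synthetic images help classification under
class imbalance, for a binary task (without vs with structural pathology) and
a multi-class task (the seven specific pathologies):

* ``synthetic_only``  — train on all synthetic images, test on all originals;
* ``mix10`` / ``mix50`` — train on all synthetic images plus 10% / 50% of the
  originals (allocated per class by largest-remainder rounding), test on the
  remaining originals;
* ``original_only_baseline`` — stratified 80/20 train/validation over the
  originals only (no synthetic data).

Each grid cell is trained and evaluated ``repeats`` times with derived seeds
and summarized as mean +/- sample SD per metric.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import (
    BINARY_LABELS,
    PATHOLOGY_LABELS,
    DatasetError,
    ImageDataset,
    make_binary_labels,
)
from .metrics import MetricsReport, aggregate_runs, classification_metrics, confusion_matrix
from .nn import Adam, AvgPool2, Conv2d, GroupNorm, SiLU, cross_entropy_with_grad, softmax

SCENARIOS = ("synthetic_only", "mix10", "mix50", "original_only_baseline")
TASKS = ("binary", "multiclass")


def derive_seed(base: int, *parts) -> int:
    """Stable sub-stream seed from a base seed and arbitrary tags (< 2^31)."""
    h = hashlib.sha256(":".join(map(str, (base,) + parts)).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def largest_remainder_allocation(counts: dict[str, int], fraction: float) -> dict[str, int]:
    """Per-class integer allocation of ``round(fraction * total)`` items.

    Classes get ``floor(fraction * n_c)`` each; the remaining units go to the
    classes with the largest fractional parts (ties broken by class order).
    """
    labels = list(counts)
    quotas = {c: fraction * counts[c] for c in labels}
    alloc = {c: int(np.floor(quotas[c])) for c in labels}
    target = int(round(fraction * sum(counts.values())))
    remainder = target - sum(alloc.values())
    by_frac = sorted(labels, key=lambda c: (-(quotas[c] - alloc[c]), labels.index(c)))
    for c in by_frac[:max(remainder, 0)]:
        if alloc[c] < counts[c]:
            alloc[c] += 1
    return alloc


def stratified_split(dataset: ImageDataset, fraction: float, seed: int
                     ) -> tuple[ImageDataset, ImageDataset]:
    """Per-class split by largest-remainder rounding; disjoint and exhaustive.

    Part A receives ~``fraction`` of each class (within one image). A class
    with a single image goes entirely to part A with a warning.
    """
    if not 0 < fraction < 1:
        raise DatasetError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for im in dataset:
        by_class.setdefault(im.label, []).append(im.id)
    singletons = [c for c, ids in by_class.items() if len(ids) == 1]
    if singletons:
        warnings.warn(
            f"classes with a single image assigned to the training part: {singletons}",
            stacklevel=2)
    multi = {c: len(ids) for c, ids in by_class.items() if len(ids) > 1}
    alloc = largest_remainder_allocation(multi, fraction) if multi else {}
    a_ids: list[str] = []
    for c, ids in by_class.items():
        ids = sorted(ids)
        rng.shuffle(ids)
        take = len(ids) if c in singletons else alloc.get(c, 0)
        a_ids.extend(ids[:take])
    a_set = set(a_ids)
    part_a = dataset.subset(a_set)
    part_b = dataset.subset([i for i in dataset.ids if i not in a_set])
    return part_a, part_b


@dataclass
class ScenarioSplit:
    """Train/test partition for one augmentation scenario and task."""

    scenario: str
    task: str
    train: ImageDataset
    test: ImageDataset
    seed: int
    warnings: list[str] = field(default_factory=list)

    def check_invariants(self) -> None:
        train_ids = set(self.train.ids)
        test_ids = set(self.test.ids)
        if train_ids & test_ids:
            raise DatasetError("train and test sets overlap")
        if any(im.provenance != "original" for im in self.test):
            raise DatasetError("test set must contain only original images")


def _task_view(dataset: ImageDataset, task: str) -> ImageDataset:
    """Relabel for the binary task; restrict to the 7 pathologies otherwise."""
    if task == "binary":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return make_binary_labels(dataset)
    if task == "multiclass":
        return dataset.filter_labels(PATHOLOGY_LABELS)
    raise DatasetError(f"unknown task {task!r}")


def build_scenario(original: ImageDataset, synthetic: ImageDataset,
                   scenario: str, task: str, seed: int) -> ScenarioSplit:
    """Assemble the train/test partition for one scenario and task."""
    if scenario not in SCENARIOS:
        raise DatasetError(f"unknown scenario {scenario!r}")
    if set(original.ids) & set(synthetic.ids):
        raise DatasetError("original and synthetic datasets share ids")
    if any(im.provenance != "synthetic" for im in synthetic):
        raise DatasetError("synthetic dataset must have provenance=synthetic")
    orig = _task_view(original, task)
    synth = _task_view(synthetic, task)
    warns: list[str] = []

    if scenario == "synthetic_only":
        train, test = synth, orig
    elif scenario in ("mix10", "mix50"):
        p = 0.10 if scenario == "mix10" else 0.50
        counts = {c: orig.labels.count(c) for c in sorted(set(orig.labels))}
        alloc = largest_remainder_allocation(counts, p)
        empty = [c for c, n in alloc.items() if n == 0]
        if empty:
            msg = f"classes contributing 0 originals to the {scenario} train set: {empty}"
            warns.append(msg)
            warnings.warn(msg, stacklevel=2)
        rng = np.random.default_rng(derive_seed(seed, scenario, task))
        take_ids: list[str] = []
        by_class: dict[str, list[str]] = {}
        for im in orig:
            by_class.setdefault(im.label, []).append(im.id)
        for c, ids in by_class.items():
            ids = sorted(ids)
            rng.shuffle(ids)
            take_ids.extend(ids[: alloc.get(c, 0)])
        take = set(take_ids)
        train = synth.concat(orig.subset(take))
        test = orig.subset([i for i in orig.ids if i not in take])
    else:  # original_only_baseline
        train, test = stratified_split(orig, 0.8, derive_seed(seed, scenario, task))

    split = ScenarioSplit(scenario=scenario, task=task, train=train, test=test,
                          seed=seed, warnings=warns)
    split.check_invariants()
    return split


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@dataclass
class ClassifierTrainConfig:
    """Classifier hyperparameters (fixed; no further tuning is performed)."""

    batch_size: int = 16
    learning_rate: float = 1e-4
    epochs: int = 20
    validation_fraction: float = 0.2
    seed: int = 0
    backbone: str = "desk-cnn4"  # also: vgg16, resnet50 (descriptors only)
    warm_start: str | None = None  # path to a saved checkpoint
    base_channels: int = 16

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise DatasetError("validation fraction must be in (0, 1)")
        if min(self.batch_size, self.epochs) < 1 or self.learning_rate <= 0:
            raise DatasetError("hyperparameters must be positive")


#: Descriptors for the paper-scale backbones; not instantiated at desk scale.
BACKBONE_DESCRIPTORS = {
    "desk-cnn4": "4 conv blocks (GN+SiLU+avgpool), global average pool, linear head",
    "vgg16": "16-layer VGG: 13 conv + 3 dense, 3x3 kernels, maxpool stacks",
    "resnet50": "50-layer residual network: bottleneck blocks, stride-2 stages",
}


class SmallCNN:
    """Desk classification backbone: 4 conv blocks on NumPy.

    Each block is conv3x3 -> GroupNorm -> SiLU -> 2x2 average pool; a global
    average pool and a linear head produce class logits. Probabilities come
    from a softmax and sum to 1 by construction.
    """

    def __init__(self, n_classes: int, in_channels: int = 3, base: int = 12,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        chans = [in_channels, base, base * 2, base * 4, base * 4]
        self.blocks = []
        for cin, cout in zip(chans[:-1], chans[1:]):
            self.blocks.append({
                "conv": Conv2d(cin, cout, rng),
                "norm": GroupNorm(cout),
                "act": SiLU(),
                "pool": AvgPool2(),
            })
        from .nn import Dense

        self.head = Dense(chans[-1], n_classes, rng)
        self.n_classes = n_classes
        self.classes: tuple[str, ...] = ()
        self.history: list[dict] = []
        self.config: ClassifierTrainConfig | None = None

    def parameters(self):
        ps = []
        for b in self.blocks:
            ps += b["conv"].params() + b["norm"].params()
        return ps + self.head.params()

    def _forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for b in self.blocks:
            h = b["pool"].forward(b["act"].forward(b["norm"].forward(b["conv"].forward(h))))
        self._pool_shape = h.shape
        feat = h.mean(axis=(2, 3))
        return self.head.forward(feat)

    def _backward(self, g: np.ndarray) -> None:
        gf = self.head.backward(g)
        N, C, H, W = self._pool_shape
        gh = np.broadcast_to(gf[:, :, None, None] / (H * W), self._pool_shape).copy()
        for b in reversed(self.blocks):
            gh = b["conv"].backward(b["norm"].backward(b["act"].backward(b["pool"].backward(gh))))

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        return self._forward(x)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Probability vectors for a (n, 3, S, S) array in [-1, 1]."""
        out = []
        for i in range(0, images.shape[0], 64):
            out.append(softmax(self._forward(images[i : i + 64])))
        return np.concatenate(out, axis=0)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise DatasetError("checkpoint does not match the model architecture")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise DatasetError("checkpoint tensor shape mismatch")
            p.data[...] = a


def _to_input_array(dataset: ImageDataset) -> np.ndarray:
    x = dataset.pixel_array().astype(float) / 127.5 - 1.0
    return np.moveaxis(x, -1, 1)


def train_classifier(split: ScenarioSplit, config: ClassifierTrainConfig) -> SmallCNN:
    """Train the desk CNN on a scenario's train set.

    Images are rescaled to [-1, 1]; optimization is adaptive-moment gradient
    descent on integer-label cross entropy. With a ``warm_start`` checkpoint
    the parameters are loaded before training; otherwise initialization is
    random (the "untrained" condition). Deterministic for a fixed config.
    """
    classes = tuple(sorted(set(split.train.labels)))
    if len(split.train) == 0:
        raise DatasetError("train set is empty")
    if len(classes) < 2:
        raise DatasetError("train set must contain at least 2 classes")
    if split.train.image_size < 16:
        raise DatasetError("the desk backbone needs images of at least 16 px")
    if config.backbone != "desk-cnn4":
        raise DatasetError(
            f"backbone {config.backbone!r} is provided as a descriptor only; "
            "train with 'desk-cnn4' or supply a checkpoint")
    x = _to_input_array(split.train)
    index = {c: i for i, c in enumerate(classes)}
    y = np.array([index[l] for l in split.train.labels])
    model = SmallCNN(n_classes=len(classes), base=config.base_channels,
                     seed=derive_seed(config.seed, "init"))
    model.classes = classes
    model.config = config
    if config.warm_start:
        from .io import load_checkpoint_into

        load_checkpoint_into(model, config.warm_start)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(derive_seed(config.seed, "shuffle"))
    n = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model._forward(x[idx])
            loss, g = cross_entropy_with_grad(logits, y[idx])
            opt.zero_grad()
            model._backward(g)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        model.history.append({
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "accuracy": correct / n,
        })
    return model


def evaluate_classifier(model: SmallCNN, test: ImageDataset,
                        averaging: str | None = None) -> MetricsReport:
    """Evaluate on a held-out set; binary tasks report the with-pathology
    positive class, multi-class tasks report macro one-vs-rest averages."""
    x = _to_input_array(test)
    proba = model.predict_proba(x)
    predicted = [model.classes[i] for i in proba.argmax(axis=1)]
    classes = tuple(sorted(set(model.classes) | set(test.labels)))
    cm = confusion_matrix(test.labels, predicted, classes)
    if averaging is None:
        averaging = "binary" if set(classes) <= set(BINARY_LABELS) else "macro"
    return classification_metrics(cm, averaging=averaging)


# ---------------------------------------------------------------------------
# Default phantom benchmark
# ---------------------------------------------------------------------------

def default_benchmark(seed: int = 0, image_size: int = 32,
                      synthetic_scale: float = 0.4
                      ) -> tuple[ImageDataset, ImageDataset]:
    """The desk-scale phantom benchmark with the study's class imbalance.

    Originals follow the study's original per-class counts (404 images, 157:4
    extreme ratio); the synthetic corpus follows the study's synthetic
    per-class counts scaled down (default 0.4, ~1670 images) and is rendered
    by the phantom generator with disjoint seeds and provenance ``synthetic``.
    It stands in for curated diffusion output: generative samples are smoother
    and less noisy than camera frames, so the synthetic style uses a stronger
    blur and weaker sensor noise, giving a mild train/test domain gap exactly
    where the study has one.
    """
    from .datasets import ClassDistribution
    from .phantom import PhantomStyle, generate_dataset

    original = generate_dataset(ClassDistribution.original_study(),
                                seed=derive_seed(seed, "orig"),
                                image_size=image_size, provenance="original")
    synth_style = PhantomStyle(image_size=image_size, blur_sigma=1.0, noise_sigma=3.0)
    synthetic = generate_dataset(ClassDistribution.synthetic_study().scaled(synthetic_scale),
                                 seed=derive_seed(seed, "synth"),
                                 image_size=image_size, provenance="synthetic",
                                 style=synth_style)
    return original, synthetic


# ---------------------------------------------------------------------------
# Experiment grid
# ---------------------------------------------------------------------------

@dataclass
class GridResult:
    """All per-repeat reports plus aggregated mean +/- SD tables."""

    reports: dict[tuple[str, str], list[MetricsReport]]
    aggregated: dict[tuple[str, str], pd.DataFrame]
    seeds: dict[tuple[str, str], list[int]]
    config: ClassifierTrainConfig

    def table(self, task: str) -> pd.DataFrame:
        """Scenario columns x metric rows of 'mean +/- sd' strings."""
        cols = {}
        for (scenario, t), agg in self.aggregated.items():
            if t != task:
                continue
            cols[scenario] = {
                m: f"{row['mean']:.2f} ± {row['sd']:.2f}"
                for m, row in agg.iterrows()
            }
        return pd.DataFrame(cols)


def run_experiment_grid(original: ImageDataset, synthetic: ImageDataset,
                        scenarios=("synthetic_only", "mix10", "mix50"),
                        tasks=TASKS, repeats: int = 10, seed: int = 0,
                        config: ClassifierTrainConfig | None = None) -> GridResult:
    """Train + evaluate every (scenario, task) cell ``repeats`` times.

    Each repeat uses a derived seed that reshuffles the scenario split and the
    classifier initialization. Aggregation is sample mean and (n-1) SD.
    """
    if repeats < 2:
        raise DatasetError("repeats must be >= 2")
    base_cfg = config or ClassifierTrainConfig()
    reports: dict[tuple[str, str], list[MetricsReport]] = {}
    seeds: dict[tuple[str, str], list[int]] = {}
    for scenario in scenarios:
        for task in tasks:
            cell_reports, cell_seeds = [], []
            for rep in range(repeats):
                rseed = derive_seed(seed, scenario, task, rep)
                split = build_scenario(original, synthetic, scenario, task, rseed)
                cfg = ClassifierTrainConfig(
                    batch_size=base_cfg.batch_size,
                    learning_rate=base_cfg.learning_rate,
                    epochs=base_cfg.epochs,
                    validation_fraction=base_cfg.validation_fraction,
                    seed=rseed, backbone=base_cfg.backbone,
                    warm_start=base_cfg.warm_start,
                    base_channels=base_cfg.base_channels,
                )
                model = train_classifier(split, cfg)
                cell_reports.append(evaluate_classifier(model, split.test))
                cell_seeds.append(rseed)
            reports[(scenario, task)] = cell_reports
            seeds[(scenario, task)] = cell_seeds
    aggregated = {k: aggregate_runs(v) for k, v in reports.items()}
    return GridResult(reports=reports, aggregated=aggregated, seeds=seeds,
                      config=base_cfg)
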