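"""Core in-memory containers for labeled laryngoscopy-style image datasets.

The pipeline operates on square RGB images of the abducted vocal folds, each
carrying one of eight class labels (seven structural pathologies plus a
no-pathology class), a provenance flag (``original`` vs ``synthetic``) and an
optional ground-truth lesion mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

#: Canonical class vocabulary, in the order used throughout the package.
LABELS: tuple[str, ...] = (
    "without_pathology",
    "nodule",
    "cyst",
    "polyp",
    "reinkes_edema",
    "sulcus_vocalis",
    "granuloma",
    "keratosis",
)

#: The seven lesion classes (multi-class task vocabulary).
PATHOLOGY_LABELS: tuple[str, ...] = tuple(l for l in LABELS if l != "without_pathology")

#: Binary task vocabulary.
BINARY_LABELS: tuple[str, str] = ("without_pathology", "with_pathology")

#: Per-class image counts of the study's original dataset (total 404).
ORIGINAL_COUNTS: Mapping[str, int] = {
    "without_pathology": 157,
    "nodule": 71,
    "cyst": 38,
    "polyp": 35,
    "sulcus_vocalis": 33,
    "reinkes_edema": 29,
    "keratosis": 37,
    "granuloma": 4,
}

#: Per-class counts of the curated synthetic dataset (total 4180).
SYNTHETIC_COUNTS: Mapping[str, int] = {
    "without_pathology": 384,
    "nodule": 374,
    "cyst": 538,
    "polyp": 585,
    "sulcus_vocalis": 315,
    "reinkes_edema": 473,
    "keratosis": 970,
    "granuloma": 541,
}

PROVENANCES = ("original", "synthetic")


class DatasetError(ValueError):
    """Raised when inputs violate a dataset contract."""


@dataclass(frozen=True)
class ClassDistribution:
    """Target per-class image counts.

    Missing labels are treated as zero; unknown labels are rejected.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(LABELS)
        if unknown:
            raise DatasetError(f"unknown labels in distribution: {sorted(unknown)}")
        full = {label: int(self.counts.get(label, 0)) for label in LABELS}
        if any(v < 0 for v in full.values()):
            raise DatasetError("class counts must be nonnegative")
        object.__setattr__(self, "counts", full)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def imbalance_ratio(self) -> float:
        """Ratio of the largest to the smallest *nonzero* class count."""
        nonzero = [v for v in self.counts.values() if v > 0]
        if not nonzero:
            return float("nan")
        return max(nonzero) / min(nonzero)

    def scaled(self, factor: float) -> "ClassDistribution":
        """Round-scaled copy (``round(n * factor)``), keeping zeros at zero."""
        return ClassDistribution(
            {k: int(round(v * factor)) for k, v in self.counts.items()}
        )

    @classmethod
    def original_study(cls) -> "ClassDistribution":
        return cls(dict(ORIGINAL_COUNTS))

    @classmethod
    def synthetic_study(cls) -> "ClassDistribution":
        return cls(dict(SYNTHETIC_COUNTS))


@dataclass
class LabeledImage:
    """One square RGB image with label, provenance and optional lesion mask."""

    pixels: np.ndarray  # H x W x 3 uint8
    label: str
    provenance: str
    id: str
    mask: np.ndarray | None = None  # H x W bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise DatasetError(f"pixels must be HxWx3, got shape {px.shape}")
        if px.shape[0] != px.shape[1]:
            raise DatasetError("images must be square (ROI-cropped)")
        if px.dtype != np.uint8:
            raise DatasetError("pixels must be 8-bit (uint8)")
        if self.label not in LABELS and self.label not in BINARY_LABELS:
            raise DatasetError(f"unknown label {self.label!r}")
        if self.provenance not in PROVENANCES:
            raise DatasetError(f"unknown provenance {self.provenance!r}")
        if self.mask is not None:
            m = np.asarray(self.mask)
            if m.shape != px.shape[:2]:
                raise DatasetError("mask shape must match image H x W")
            self.mask = m.astype(bool)
        self.pixels = px

    @property
    def size(self) -> int:
        return int(self.pixels.shape[0])


class ImageDataset:
    """Ordered collection of :class:`LabeledImage` with a manifest view.

    Invariants: unique ids, homogeneous image dimensions.
    """

    def __init__(self, images: Iterable[LabeledImage]):
        self.images: list[LabeledImage] = list(images)
        ids = [im.id for im in self.images]
        if len(set(ids)) != len(ids):
            raise DatasetError("image ids must be unique within a dataset")
        sizes = {im.size for im in self.images}
        if len(sizes) > 1:
            raise DatasetError(f"all images must share dimensions, got sizes {sorted(sizes)}")

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self) -> Iterator[LabeledImage]:
        return iter(self.images)

    def __getitem__(self, i: int) -> LabeledImage:
        return self.images[i]

    @property
    def ids(self) -> list[str]:
        return [im.id for im in self.images]

    @property
    def labels(self) -> list[str]:
        return [im.label for im in self.images]

    @property
    def image_size(self) -> int | None:
        return self.images[0].size if self.images else None

    def distribution(self) -> ClassDistribution:
        counts = {label: 0 for label in LABELS}
        for im in self.images:
            if im.label in counts:
                counts[im.label] += 1
        return ClassDistribution(counts)

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "id": im.id,
                "label": im.label,
                "provenance": im.provenance,
                "path": im.meta.get("path", ""),
                "seed": im.meta.get("seed", ""),
            }
            for im in self.images
        ]
        return pd.DataFrame(rows, columns=["id", "label", "provenance", "path", "seed"])

    def subset(self, ids: Iterable[str]) -> "ImageDataset":
        wanted = set(ids)
        return ImageDataset([im for im in self.images if im.id in wanted])

    def filter_labels(self, labels: Iterable[str]) -> "ImageDataset":
        keep = set(labels)
        return ImageDataset([im for im in self.images if im.label in keep])

    def concat(self, other: "ImageDataset") -> "ImageDataset":
        return ImageDataset(list(self.images) + list(other.images))

    def pixel_array(self) -> np.ndarray:
        """Stacked ``(n, H, W, 3)`` uint8 array."""
        if not self.images:
            raise DatasetError("empty dataset has no pixel array")
        return np.stack([im.pixels for im in self.images])


def make_binary_labels(dataset: ImageDataset) -> ImageDataset:
    """Collapse the 8-class vocabulary to without/with structural pathology.

    Idempotent; counts are conserved. Emits a warning when the result is
    single-class (a degenerate training set).
    """
    out = []
    for im in dataset:
        if im.label in BINARY_LABELS:
            new = im.label
        elif im.label in PATHOLOGY_LABELS:
            new = "with_pathology"
        else:  # pragma: no cover - LabeledImage already validates
            raise DatasetError(f"unknown label {im.label!r}")
        out.append(
            LabeledImage(
                pixels=im.pixels,
                label=new,
                provenance=im.provenance,
                id=im.id,
                mask=im.mask,
                meta=dict(im.meta, source_label=im.meta.get("source_label", im.label)),
            )
        )
    result = ImageDataset(out)
    if len(set(result.labels)) == 1 and len(result) > 0:
        warnings.warn("binary relabeling produced a single-class dataset", stacklevel=2)
    return result
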