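"""Automated curation of synthetic images.

Stands in for the expert review step that discards deformed or unrealistic
generative samples. Two measurable criteria are implemented, mirroring the
stated grounds for rejection: structural implausibility (the wrong number of
fold bands, or no identifiable glottis) and remarkable blurriness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import laplace
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .datasets import ImageDataset, LabeledImage

#: Rec.709 luma weights.
_LUMA = np.array([0.2126, 0.7152, 0.0722])

REJECT_REASONS = ("blurry", "wrong_fold_count", "out_of_range")


@dataclass(frozen=True)
class StructureParams:
    """Conventions of the fold-band detector (tuned on phantoms).

    The threshold is relative to the median luminance of the central crop so
    that it is invariant to global illumination gain and — unlike a fixed
    percentile share — selects nothing when no bright bands are present.
    """

    central_fraction: float = 0.6
    rel_threshold: float = 1.30  # x median luminance of the central crop
    min_eccentricity: float = 0.80
    min_area_fraction: float = 0.04  # of the central crop
    smooth_sigma: float | None = None  # default: image_size / 64, in [0.5, 1.5]


@dataclass(frozen=True)
class CurationThresholds:
    sharpness_min: float = 0.0
    require_two_folds: bool = True
    structure: StructureParams = field(default_factory=StructureParams)


@dataclass
class CurationReport:
    retained: list[str]
    rejected: dict[str, str]  # id -> reason
    thresholds: CurationThresholds

    def to_json(self) -> str:
        return json.dumps(
            {
                "retained": self.retained,
                "rejected": self.rejected,
                "thresholds": {
                    "sharpness_min": self.thresholds.sharpness_min,
                    "require_two_folds": self.thresholds.require_two_folds,
                    "structure": vars(self.thresholds.structure),
                },
            },
            indent=2,
        )


def _luminance(image: LabeledImage) -> np.ndarray:
    return image.pixels.astype(float) @ _LUMA


def sharpness_score(image: LabeledImage) -> float:
    """Variance of the Laplacian of the luminance channel; higher = sharper.

    Invariant to global intensity offsets (the high-pass removes DC).
    """
    return float(np.var(laplace(_luminance(image))))


def structure_score(
    image: LabeledImage, params: StructureParams | None = None
) -> tuple[int, bool]:
    """Count elongated bright bands in the central region.

    The detector thresholds the (lightly smoothed) luminance of the central
    crop relative to its median, labels connected components, and keeps
    components that are large and elongated. A plausible frame shows exactly
    two such bands (the vocal folds).

    Returns ``(fold_band_count, plausible)``.
    """
    params = params or StructureParams()
    lum = _luminance(image)
    S = lum.shape[0]
    m = int(round(S * (1 - params.central_fraction) / 2))
    crop = lum[m : S - m, m : S - m]
    from scipy.ndimage import gaussian_filter

    sigma = params.smooth_sigma
    if sigma is None:
        sigma = float(np.clip(S / 64.0, 0.5, 1.5))
    sm = gaussian_filter(crop, sigma=sigma)
    thr = params.rel_threshold * np.median(sm)
    binary = sm > thr
    labeled = cc_label(binary, connectivity=2)
    min_area = params.min_area_fraction * crop.size
    count = 0
    for prop in regionprops(labeled):
        if prop.area >= min_area and prop.eccentricity >= params.min_eccentricity:
            count += 1
    return count, count == 2


def default_sharpness_threshold(reference: ImageDataset, quantile: float = 0.05) -> float:
    """Sharpness cutoff at a low quantile of scores on a reference (original)
    dataset, so only images blurrier than essentially all originals fail."""
    scores = [sharpness_score(im) for im in reference]
    # "lower" keeps the threshold at an attained score, so a reference image
    # at the quantile itself still passes (>= comparison)
    return float(np.quantile(scores, quantile, method="lower"))


def curate(
    dataset: ImageDataset,
    thresholds: CurationThresholds | None = None,
    overrides: dict[str, bool] | None = None,
) -> tuple[ImageDataset, CurationReport]:
    """Partition a dataset into retained and rejected images.

    An image is retained iff its sharpness is >= the threshold and (when
    required) the structure detector finds exactly two fold bands. A manual
    ``overrides`` map (id -> keep) replicates true expert review and takes
    precedence over the automated criteria. Deterministic; the report
    partitions the input exactly.
    """
    thresholds = thresholds or CurationThresholds()
    overrides = overrides or {}
    retained: list[LabeledImage] = []
    rejected: dict[str, str] = {}
    for im in dataset:
        if im.id in overrides:
            if overrides[im.id]:
                retained.append(im)
            else:
                rejected[im.id] = "out_of_range"
            continue
        if sharpness_score(im) < thresholds.sharpness_min:
            rejected[im.id] = "blurry"
            continue
        if thresholds.require_two_folds:
            _, plausible = structure_score(im, thresholds.structure)
            if not plausible:
                rejected[im.id] = "wrong_fold_count"
                continue
        retained.append(im)
    report = CurationReport(
        retained=[im.id for im in retained], rejected=rejected, thresholds=thresholds
    )
    return ImageDataset(retained), report
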