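"""Evaluation suite: confusion matrices, classification metrics and FID.

Binary metrics treat "with pathology" as the positive class:

    accuracy    = (TP + TN) / (TP + FP + FN + TN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)
    specificity = TN / (TN + FP)

Multi-class reports reduce one-vs-rest per class and average (macro by
default, or weighted by class support). Zero-denominator metrics are 0 and
flagged. The Frechet distance between feature distributions is

    FID = ||mu_r - mu_s||^2 + Tr(Sigma_r + Sigma_s - 2 (Sigma_r Sigma_s)^(1/2))

computed with a symmetrized matrix square root (eigendecomposition of
Sigma_r^(1/2) Sigma_s Sigma_r^(1/2), negative eigenvalues clipped at zero)
and covariances regularized by +1e-6 I.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import DatasetError, ImageDataset


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows = actual class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.classes):
            raise DatasetError("confusion matrix must be KxK matching classes")
        if np.any(c < 0):
            raise DatasetError("confusion matrix entries must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class index k."""
        c = self.counts
        tp = int(c[k, k])
        fp = int(c[:, k].sum() - tp)
        fn = int(c[k, :].sum() - tp)
        tn = int(c.sum() - tp - fp - fn)
        return tp, fp, fn, tn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion_matrix(actual, predicted, classes) -> ConfusionMatrix:
    """Tally actual-vs-predicted label pairs into a ConfusionMatrix."""
    actual = list(actual)
    predicted = list(predicted)
    if len(actual) != len(predicted):
        raise DatasetError("actual and predicted must have equal length")
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for a, p in zip(actual, predicted):
        if a not in index or p not in index:
            raise DatasetError(f"label outside class vocabulary: {a!r}/{p!r}")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    averaging: str  # binary | macro | weighted
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    zero_division_flags: list[str] = field(default_factory=list)
    fid: float | None = None
    confusion: ConfusionMatrix | None = None

    def metric_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
        }

    def to_json(self) -> str:
        out = dict(self.metric_dict(), averaging=self.averaging,
                   per_class=self.per_class, zero_division_flags=self.zero_division_flags)
        if self.fid is not None:
            out["fid"] = self.fid
        if self.confusion is not None:
            out["confusion_matrix"] = self.confusion.counts.tolist()
            out["classes"] = list(self.confusion.classes)
        return json.dumps(out, indent=2)


def _safe_div(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def _ovr_metrics(cm: ConfusionMatrix, k: int, flags: list[str]) -> dict[str, float]:
    tp, fp, fn, tn = cm.one_vs_rest(k)
    cls = cm.classes[k]
    precision = _safe_div(tp, tp + fp, flags, f"precision[{cls}]")
    sensitivity = _safe_div(tp, tp + fn, flags, f"sensitivity[{cls}]")
    specificity = _safe_div(tn, tn + fp, flags, f"specificity[{cls}]")
    f1 = _safe_div(2 * precision * sensitivity, precision + sensitivity,
                   flags, f"f1[{cls}]")
    return {"precision": precision, "sensitivity": sensitivity,
            "specificity": specificity, "f1": f1,
            "support": tp + fn}


def classification_metrics(cm: ConfusionMatrix, averaging: str = "macro",
                           positive_class: str = "with_pathology") -> MetricsReport:
    """Compute the metric suite from a confusion matrix.

    ``binary`` averaging evaluates the positive class directly; ``macro``
    averages one-vs-rest values uniformly over classes; ``weighted`` averages
    them by class support.
    """
    if cm.total == 0:
        raise DatasetError("cannot compute metrics from an all-zero matrix")
    if averaging not in ("binary", "macro", "weighted"):
        raise DatasetError(f"unknown averaging {averaging!r}")
    flags: list[str] = []
    accuracy = float(np.trace(cm.counts)) / cm.total
    per_class = {cm.classes[k]: _ovr_metrics(cm, k, flags)
                 for k in range(len(cm.classes))}

    if averaging == "binary":
        if len(cm.classes) != 2:
            raise DatasetError("binary averaging requires a 2x2 matrix")
        if positive_class not in cm.classes:
            raise DatasetError(f"positive class {positive_class!r} not in classes")
        vals = per_class[positive_class]
    else:
        keys = ("precision", "sensitivity", "specificity", "f1")
        support = np.array([per_class[c]["support"] for c in cm.classes], dtype=float)
        if averaging == "macro":
            wts = np.ones(len(cm.classes)) / len(cm.classes)
        else:
            wts = support / support.sum()
        vals = {k: float(sum(w * per_class[c][k]
                             for w, c in zip(wts, cm.classes)))
                for k in keys}
    return MetricsReport(
        accuracy=accuracy, precision=vals["precision"],
        sensitivity=vals["sensitivity"], specificity=vals["specificity"],
        f1=vals["f1"], averaging=averaging, per_class=per_class,
        zero_division_flags=flags, confusion=cm,
    )


# ---------------------------------------------------------------------------
# Feature extraction and FID
# ---------------------------------------------------------------------------

class PCAFeatureExtractor:
    """Deterministic pixel-PCA feature extractor for FID.

    Fits principal components on a reference dataset's flattened RGB pixels
    and projects any same-sized dataset onto them. A stand-in for the large
    pretrained inception network used at GPU scale; absolute FID values are
    therefore not comparable across extractors.
    """

    def __init__(self, n_components: int = 16):
        self.n_components = n_components
        self._pca = None
        self._size = None

    @property
    def descriptor(self) -> str:
        return f"pixel-pca-{self.n_components}"

    def fit(self, reference: ImageDataset) -> "PCAFeatureExtractor":
        from sklearn.decomposition import PCA

        X = self._flatten(reference)
        k = min(self.n_components, *X.shape)
        self._pca = PCA(n_components=k, svd_solver="full").fit(X)
        self._size = reference.image_size
        return self

    def _flatten(self, dataset: ImageDataset) -> np.ndarray:
        if len(dataset) == 0:
            raise DatasetError("cannot extract features from an empty dataset")
        return dataset.pixel_array().reshape(len(dataset), -1).astype(float) / 255.0

    def transform(self, dataset: ImageDataset) -> np.ndarray:
        if self._pca is None:
            raise DatasetError("extractor must be fitted before use")
        if dataset.image_size != self._size:
            raise DatasetError(
                f"extractor fitted on {self._size} px images, got {dataset.image_size}")
        return self._pca.transform(self._flatten(dataset))


def extract_features(images: ImageDataset, extractor: PCAFeatureExtractor) -> np.ndarray:
    """n x d feature matrix; deterministic given the fitted extractor."""
    return extractor.transform(images)


@dataclass(frozen=True)
class FIDResult:
    value: float
    mu_r: np.ndarray
    mu_s: np.ndarray
    sigma_r: np.ndarray
    sigma_s: np.ndarray
    extractor: str = "precomputed-features"


def _sqrtm_psd(a: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition (eigenvalues clipped)."""
    w, v = np.linalg.eigh((a + a.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T


def fid(real_features: np.ndarray, synth_features: np.ndarray,
        extractor: str = "precomputed-features", eps: float = 1e-6) -> FIDResult:
    """Frechet distance between Gaussian fits of two feature matrices.

    Uses the symmetrized square root Tr((Sr^1/2 Ss Sr^1/2)^1/2); covariances
    are regularized by ``eps * I`` and the result is floored at 0.
    """
    r = np.asarray(real_features, dtype=float)
    s = np.asarray(synth_features, dtype=float)
    if r.ndim != 2 or s.ndim != 2 or r.shape[1] != s.shape[1]:
        raise DatasetError("feature matrices must be 2-D with equal dimension")
    if r.shape[0] < 2 or s.shape[0] < 2:
        raise DatasetError("need at least 2 rows per feature matrix")
    mu_r, mu_s = r.mean(axis=0), s.mean(axis=0)
    d = r.shape[1]
    sig_r = np.cov(r, rowvar=False).reshape(d, d) + eps * np.eye(d)
    sig_s = np.cov(s, rowvar=False).reshape(d, d) + eps * np.eye(d)
    root_r = _sqrtm_psd(sig_r)
    cross = _sqrtm_psd(root_r @ sig_s @ root_r)
    value = float(np.sum((mu_r - mu_s) ** 2)
                  + np.trace(sig_r) + np.trace(sig_s) - 2.0 * np.trace(cross))
    return FIDResult(value=max(value, 0.0), mu_r=mu_r, mu_s=mu_s,
                     sigma_r=sig_r, sigma_s=sig_s, extractor=extractor)


def fid_between(real: ImageDataset, synth: ImageDataset,
                extractor: PCAFeatureExtractor | None = None) -> FIDResult:
    """FID between two image datasets using a pixel-PCA extractor fitted on
    the real set (unless a fitted extractor is supplied)."""
    if extractor is None:
        extractor = PCAFeatureExtractor().fit(real)
    res = fid(extract_features(real, extractor), extract_features(synth, extractor))
    return FIDResult(value=res.value, mu_r=res.mu_r, mu_s=res.mu_s,
                     sigma_r=res.sigma_r, sigma_s=res.sigma_s,
                     extractor=extractor.descriptor)


def aggregate_runs(reports: list[MetricsReport]) -> pd.DataFrame:
    """Per-metric sample mean and (n-1) standard deviation across repeats.

    A single report yields SD 0 by convention (and records n=1).
    """
    if not reports:
        raise DatasetError("need at least one report to aggregate")
    dicts = [r.metric_dict() for r in reports]
    keys = set(dicts[0])
    if any(set(d) != keys for d in dicts):
        raise DatasetError("heterogeneous metric sets cannot be aggregated")
    rows = []
    n = len(reports)
    for key in ("accuracy", "f1", "sensitivity", "specificity", "precision"):
        vals = np.array([d[key] for d in dicts])
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        rows.append({"metric": key, "mean": float(vals.mean()), "sd": sd, "n": n})
    return pd.DataFrame(rows).set_index("metric")
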