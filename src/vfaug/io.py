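"""Dataset, manifest and report I/O.

Datasets live on disk as ``<root>/<label>/<id>.png`` (8-bit RGB), optional
single-channel mask PNGs under ``<root>/masks/``, and a ``manifest.csv`` with
columns ``id,label,provenance,path,seed``. JPEG is accepted on read (for
parity with clinical JPG frames); PNG is always written.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .datasets import LABELS, BINARY_LABELS, DatasetError, ImageDataset, LabeledImage

MANIFEST_COLUMNS = ["id", "label", "provenance", "path", "seed"]


def write_dataset(dataset: ImageDataset, root: str | Path,
                  write_masks: bool = True) -> Path:
    """Write images, masks and the manifest; returns the manifest path."""
    root = Path(root)
    rows = []
    for im in dataset:
        label_dir = root / im.label
        label_dir.mkdir(parents=True, exist_ok=True)
        rel = Path(im.label) / f"{im.id}.png"
        Image.fromarray(im.pixels, mode="RGB").save(root / rel)
        if write_masks and im.mask is not None:
            mask_dir = root / "masks"
            mask_dir.mkdir(exist_ok=True)
            Image.fromarray((im.mask * np.uint8(255)), mode="L").save(
                mask_dir / f"{im.id}.png")
        rows.append({"id": im.id, "label": im.label, "provenance": im.provenance,
                     "path": str(rel), "seed": im.meta.get("seed", "")})
    manifest = root / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_image_dataset(manifest_path: str | Path) -> ImageDataset:
    """Load a dataset from a manifest; validates labels and dimensions.

    All row-level problems (missing file, unknown label, dimension mismatch)
    are collected into one error report instead of failing on the first row.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DatasetError(f"manifest not found: {manifest_path}")
    root = manifest_path.parent
    df = pd.read_csv(manifest_path, dtype={"id": str, "label": str,
                                           "provenance": str, "path": str})
    missing_cols = set(MANIFEST_COLUMNS[:4]) - set(df.columns)
    if missing_cols:
        raise DatasetError(f"manifest lacks columns: {sorted(missing_cols)}")
    errors: list[str] = []
    images: list[LabeledImage] = []
    valid_labels = set(LABELS) | set(BINARY_LABELS)
    for _, row in df.iterrows():
        rid = row["id"]
        if row["label"] not in valid_labels:
            errors.append(f"{rid}: unknown label {row['label']!r}")
            continue
        path = root / row["path"]
        if not path.exists():
            errors.append(f"{rid}: missing file {row['path']}")
            continue
        with Image.open(path) as img:
            px = np.asarray(img.convert("RGB"))
        mask_path = root / "masks" / f"{rid}.png"
        mask = None
        if mask_path.exists():
            with Image.open(mask_path) as m:
                mask = np.asarray(m.convert("L")) > 127
        seed = row.get("seed", "")
        images.append(LabeledImage(
            pixels=px, label=row["label"], provenance=row["provenance"],
            id=rid, mask=mask,
            meta={"path": str(row["path"]), "seed": seed},
        ))
    sizes = {im.size for im in images}
    if len(sizes) > 1:
        errors.append(f"inhomogeneous image dimensions: {sorted(sizes)}")
    if errors:
        raise DatasetError("manifest validation failed:\n  " + "\n  ".join(errors))
    return ImageDataset(images)


def save_checkpoint(model, path: str | Path) -> None:
    """Save a denoiser/classifier as .npz with an embedded metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"format_version": 1, "architecture": getattr(model, "architecture", None)}
    cfg = getattr(model, "config", None)
    if cfg is not None:
        meta["config"] = {k: v for k, v in vars(cfg).items()
                          if isinstance(v, (int, float, str, bool, type(None)))}
    if hasattr(model, "classes"):
        meta["classes"] = list(model.classes)
    arrays = {f"p{i:04d}": p.data for i, p in enumerate(model.parameters())}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint_into(model, path: str | Path) -> dict:
    """Load parameters saved by :func:`save_checkpoint`; returns metadata."""
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        keys = sorted(k for k in z.files if k.startswith("p"))
        params = model.parameters()
        if len(keys) != len(params):
            raise DatasetError("checkpoint does not match model architecture")
        for k, p in zip(keys, params):
            if z[k].shape != p.data.shape:
                raise DatasetError(f"checkpoint tensor {k} shape mismatch")
            p.data[...] = z[k]
    return meta


def write_train_log(model, path: str | Path) -> None:
    """Per-epoch loss log as CSV (epoch, loss[, accuracy])."""
    log = getattr(model, "train_log", None) or getattr(model, "history", [])
    pd.DataFrame(log).to_csv(Path(path), index=False)
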