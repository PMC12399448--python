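"""Procedural phantom laryngoscopy images with ground-truth lesion masks.

Real laryngoscopic frames of the vocal folds cannot be redistributed, so the
pipeline is developed and tested against parametric phantoms that reproduce
the *structure* of such frames: a dark vignette, a textured mucosa field, two
elongated pale fold bands meeting anteriorly around a dark glottal gap, and a
per-class lesion archetype rendered from the standard clinical descriptions
(bilateral symmetric nodules, a unilateral rounded cyst, a reddish polyp,
bilateral Reinke's widening, a dark sulcus groove along a fold edge, a
posterior granuloma, a whitish keratotic patch).

Appearance is parametric, not photorealistic: the phantoms exist to make every
downstream stage (diffusion training, curation, augmentation scenarios,
metrics) testable with known ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .datasets import (
    LABELS,
    ClassDistribution,
    DatasetError,
    ImageDataset,
    LabeledImage,
)

DEGRADE_MODES = ("blur", "remove_folds", "triplicate_fold")

# Base colors (RGB, 8-bit) of the anatomical components.
MUCOSA_RGB = np.array([170.0, 92.0, 88.0])
FOLD_RGB = np.array([230.0, 190.0, 178.0])
GAP_RGB = np.array([35.0, 18.0, 22.0])

LESION_RGB = {
    "nodule": np.array([235.0, 205.0, 200.0]),
    "cyst": np.array([228.0, 195.0, 150.0]),
    "polyp": np.array([200.0, 70.0, 70.0]),
    "reinkes_edema": FOLD_RGB,
    "sulcus_vocalis": np.array([150.0, 80.0, 75.0]),
    "granuloma": np.array([185.0, 100.0, 98.0]),
    "keratosis": np.array([245.0, 242.0, 235.0]),
}


@dataclass(frozen=True)
class PhantomStyle:
    """Geometry/illumination parameters of the phantom renderer.

    Lengths are in canonical units where the image spans [-1, 1] on each axis
    with the anterior commissure toward the top. Nuisance ranges emulate the
    acquisition variation of handheld stroboscopy: in-plane rotation, global
    illumination gain and additive sensor noise.
    """

    image_size: int = 64
    rotation_deg: float = 15.0  # uniform +/- range
    gain_range: float = 0.20  # uniform +/- relative illumination gain
    noise_sigma: float = 4.0  # additive Gaussian noise, 8-bit intensity units
    blur_sigma: float = 0.5  # mild optical blur, px at any size
    fold_width: float = 0.14
    gap_min: float = 0.08
    gap_max: float = 0.14
    anterior_v: float = -0.55
    posterior_v: float = 0.75
    vignette_strength: float = 0.40
    texture_amp: float = 7.0


def _rng_for(label: str, seed: int) -> np.random.Generator:
    """Deterministic per-(label, seed) generator, stable across platforms."""
    digest = hashlib.sha256(f"phantom:{label}:{seed}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _soft(d: np.ndarray, aa: float) -> np.ndarray:
    """Soft indicator of d <= 0 with ~aa-wide anti-aliased edge."""
    return np.clip(0.5 - d / aa, 0.0, 1.0)


def _blend(img: np.ndarray, color: np.ndarray, alpha: np.ndarray) -> None:
    img += alpha[..., None] * (color[None, None, :] - img)


def render_phantom(
    label: str,
    seed: int,
    style: PhantomStyle | None = None,
) -> LabeledImage:
    """Render one phantom frame with its ground-truth lesion mask.

    Deterministic in ``(label, seed, style)``. The lesion mask is empty for
    ``without_pathology`` and marks the lesion pixels otherwise.
    """
    if label not in LABELS:
        raise DatasetError(f"unknown label {label!r}")
    if seed < 0:
        raise DatasetError("seed must be nonnegative")
    style = style or PhantomStyle()
    S = style.image_size
    rng = _rng_for(label, seed)

    # Nuisance and geometry jitter (drawn in fixed order for determinism).
    theta = np.deg2rad(rng.uniform(-style.rotation_deg, style.rotation_deg))
    gain = 1.0 + rng.uniform(-style.gain_range, style.gain_range)
    v0 = style.anterior_v + rng.uniform(-0.05, 0.05)
    v1 = style.posterior_v + rng.uniform(-0.04, 0.04)
    g_max = style.gap_max + rng.uniform(-0.015, 0.015)
    w = style.fold_width + rng.uniform(-0.012, 0.012)
    side = int(rng.integers(0, 2)) * 2 - 1  # unilateral lesion side

    # Canonical coordinates: rotate pixel grid back by theta.
    half = (S - 1) / 2.0
    ys, xs = np.mgrid[0:S, 0:S]
    u_pix = (xs - half) / half
    v_pix = (ys - half) / half
    c, s = np.cos(theta), np.sin(theta)
    u = c * u_pix + s * v_pix
    v = -s * u_pix + c * v_pix
    aa = 2.0 / S  # ~1 px anti-aliasing in canonical units

    # Glottal gap half-width grows from the anterior commissure backwards.
    ramp = np.clip((v - v0) / (v1 - v0), 0.0, 1.0) ** 0.9
    g = style.gap_min + (g_max - style.gap_min) * ramp
    d_v = np.maximum(v0 - v, v - v1)  # signed distance to the v-extent

    au = np.abs(u)
    # Fold bands: g <= |u| <= g + w within the v extent.
    d_fold = np.maximum(np.maximum(g - au, au - (g + w)), d_v)
    fold_alpha = _soft(d_fold, aa)
    # Glottal gap: |u| < g.
    d_gap = np.maximum(au - g, d_v)
    gap_alpha = _soft(d_gap, aa)

    # Mucosa with smooth texture.
    tex = gaussian_filter(rng.standard_normal((S, S)), sigma=max(S / 10.0, 1.5))
    tex = tex / (tex.std() + 1e-12) * style.texture_amp
    img = np.tile(MUCOSA_RGB, (S, S, 1)).astype(float)
    img += tex[..., None]

    _blend(img, FOLD_RGB, fold_alpha)
    _blend(img, GAP_RGB, gap_alpha)

    lesion_alpha = _render_lesion(label, u, v, g, w, v0, v1, side, aa, rng)
    if lesion_alpha is not None:
        _blend(img, LESION_RGB[label], lesion_alpha)
        mask = lesion_alpha > 0.5
    else:
        mask = np.zeros((S, S), dtype=bool)

    # Vignette (pixel frame), illumination gain, optical blur, sensor noise.
    r2 = (u_pix**2 + v_pix**2) / 2.0
    vignette = 1.0 - style.vignette_strength * r2**1.5
    img *= vignette[..., None]
    img *= gain
    if style.blur_sigma > 0:
        img = gaussian_filter(img, sigma=(style.blur_sigma, style.blur_sigma, 0))
    img += rng.standard_normal((S, S, 3)) * style.noise_sigma
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    geometry = {
        "theta": float(theta),
        "v0": float(v0),
        "v1": float(v1),
        "g_max": float(g_max),
        "gap_min": float(style.gap_min),
        "w": float(w),
        "side": side,
        "gain": float(gain),
    }
    return LabeledImage(
        pixels=pixels,
        label=label,
        provenance="original",
        id=f"{label}-{seed:06d}",
        mask=mask,
        meta={"seed": seed, "geometry": geometry, "style": style},
    )


def _render_lesion(
    label: str,
    u: np.ndarray,
    v: np.ndarray,
    g: np.ndarray,
    w: float,
    v0: float,
    v1: float,
    side: int,
    aa: float,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Soft indicator of the lesion region for one archetype, or None."""
    span = v1 - v0

    def disc(cu: float, cv: float, r: float) -> np.ndarray:
        return np.sqrt((u - cu) ** 2 + (v - cv) ** 2) - r

    def gap_at(cv: float) -> float:
        ramp = np.clip((cv - v0) / span, 0.0, 1.0) ** 0.9
        return float(g.min() + (g.max() - g.min()) * ramp)

    if label == "without_pathology":
        return None

    if label == "nodule":
        # Bilateral, symmetric, at the junction of anterior third and
        # posterior two-thirds of the folds.
        cv = v0 + 0.33 * span
        r = 0.07 + rng.uniform(-0.01, 0.01)
        cu = gap_at(cv) + 0.5 * w
        d = np.minimum(disc(cu, cv, r), disc(-cu, cv, r))
        return _soft(d, aa)

    if label == "cyst":
        cv = v0 + 0.5 * span + rng.uniform(-0.05, 0.05)
        r = 0.11 + rng.uniform(-0.015, 0.015)
        cu = side * (gap_at(cv) + 0.5 * w)
        return _soft(disc(cu, cv, r), aa)

    if label == "polyp":
        # Protrudes medially from the fold edge into the glottal gap, so the
        # bright band behind it stays contiguous.
        cv = v0 + 0.45 * span + rng.uniform(-0.05, 0.05)
        r = 0.09 + rng.uniform(-0.012, 0.012)
        cu = side * (gap_at(cv) - 0.02)
        return _soft(disc(cu, cv, r), aa)

    if label == "reinkes_edema":
        # Bilateral polypoid widening: extra band lateral to both folds.
        extra = 0.09 + rng.uniform(-0.012, 0.012)
        bulge = np.sin(np.clip((v - v0) / span, 0, 1) * np.pi)
        au = np.abs(u)
        outer = g + w + extra * bulge
        d = np.maximum(np.maximum((g + w) - au, au - outer), np.maximum(v0 - v, v - v1))
        return _soft(d, aa)

    if label == "sulcus_vocalis":
        # Dark groove notching the medial edge of one fold over its middle
        # portion (a partial-extent sulcus, leaving the band contiguous).
        lo = v0 + 0.30 * span
        hi = v0 + 0.72 * span
        du = u * side - (g + 0.005)
        d = np.maximum(np.maximum(-du, du - 0.050), np.maximum(lo - v, v - hi))
        return _soft(d, aa)

    if label == "granuloma":
        # Posterior unilateral mass near the vocal process.
        cv = v1 - 0.10 * span
        r = 0.105 + rng.uniform(-0.015, 0.015)
        cu = side * (gap_at(cv) + 0.5 * w)
        return _soft(disc(cu, cv, r), aa)

    if label == "keratosis":
        # Whitish patch, elongated along one fold.
        cv = v0 + 0.5 * span
        cu = side * (gap_at(cv) + 0.5 * w)
        du = (u - cu) / (1.1 * w)
        dv = (v - cv) / (0.30 * span)
        return _soft(np.sqrt(du**2 + dv**2) - 1.0, aa / (1.1 * w))

    raise DatasetError(f"unknown label {label!r}")  # pragma: no cover


def generate_dataset(
    distribution: ClassDistribution,
    seed: int = 0,
    image_size: int = 64,
    provenance: str = "original",
    style: PhantomStyle | None = None,
    id_prefix: str = "",
) -> ImageDataset:
    """Generate a phantom dataset with exactly the requested per-class counts.

    Byte-identical for identical arguments. Per-image seeds are derived from
    ``seed`` and the image index so that datasets generated with different
    base seeds are disjoint in appearance.
    """
    style = replace(style or PhantomStyle(), image_size=image_size)
    images: list[LabeledImage] = []
    for label in LABELS:
        n = distribution.counts.get(label, 0)
        for i in range(n):
            im = render_phantom(label, seed=seed * 1_000_003 + i, style=style)
            im.provenance = provenance
            im.id = f"{id_prefix}{provenance[:4]}-{label}-{seed}-{i:05d}"
            images.append(im)
    return ImageDataset(images)


def degrade(image: LabeledImage, mode: str, severity: float) -> LabeledImage:
    """Return a degraded copy emulating failure modes of generative samples.

    ``blur`` low-pass filters with width ``severity`` (px); ``remove_folds``
    replaces the fold bands and glottal gap by mucosa (no folds visible);
    ``triplicate_fold`` inserts a third pale band lateral to one fold. Label
    and id lineage are preserved in metadata.
    """
    if mode not in DEGRADE_MODES:
        raise DatasetError(f"unknown degrade mode {mode!r}")
    if not severity > 0:
        raise DatasetError("severity must be positive")

    S = image.size
    px = image.pixels.astype(float)

    if mode == "blur":
        out = gaussian_filter(px, sigma=(severity, severity, 0))
    else:
        geom = image.meta.get("geometry")
        if geom is None:
            raise DatasetError(
                f"mode {mode!r} requires phantom geometry metadata on the image"
            )
        half = (S - 1) / 2.0
        ys, xs = np.mgrid[0:S, 0:S]
        u_pix = (xs - half) / half
        v_pix = (ys - half) / half
        c, s = np.cos(geom["theta"]), np.sin(geom["theta"])
        u = c * u_pix + s * v_pix
        v = -s * u_pix + c * v_pix
        aa = 2.0 / S
        v0, v1, w = geom["v0"], geom["v1"], geom["w"]
        ramp = np.clip((v - v0) / (v1 - v0), 0.0, 1.0) ** 0.9
        g = geom["gap_min"] + (geom["g_max"] - geom["gap_min"]) * ramp
        d_v = np.maximum(v0 - v, v - v1)
        au = np.abs(u)
        out = px.copy()
        if mode == "remove_folds":
            # Erase everything bright/structured: folds, gap and any lesion.
            region = np.maximum(au - (g + w + 0.1), d_v - 0.05)
            alpha = _soft(region, 4 * aa)
            if image.mask is not None:
                alpha = np.maximum(alpha, image.mask.astype(float))
            rng = np.random.default_rng(int(image.meta.get("seed", 0)) + 91)
            tex = gaussian_filter(rng.standard_normal((S, S)), sigma=max(S / 10.0, 1.5))
            tex = tex / (tex.std() + 1e-12) * 12.0
            fill = np.tile(MUCOSA_RGB * geom.get("gain", 1.0), (S, S, 1)) + tex[..., None]
            out += alpha[..., None] * (fill - out)
        else:  # triplicate_fold
            # opposite side from any unilateral lesion, clear of Reinke bulges
            seam = 0.18
            cu = -geom["side"] * (g + w + seam + 0.5 * w)
            d = np.maximum(np.abs(u - cu) - 0.5 * min(severity, 1.0) * w - 0.25 * w, d_v)
            alpha = _soft(d, aa)
            fold_gain = geom.get("gain", 1.0)
            out += alpha[..., None] * (FOLD_RGB[None, None, :] * fold_gain - out)

    pixels = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    meta = dict(image.meta, degraded_from=image.id, degrade_mode=mode, severity=severity)
    return LabeledImage(
        pixels=pixels,
        label=image.label,
        provenance=image.provenance,
        id=f"{image.id}~{mode}",
        mask=image.mask,
        meta=meta,
    )
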