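import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vfaug.datasets import LABELS, ImageDataset, LabeledImage
from vfaug.phantom import PhantomStyle, render_phantom

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desk_style():
    return PhantomStyle(image_size=64)


@pytest.fixture(scope="session")
def small_style():
    return PhantomStyle(image_size=32)


@pytest.fixture(scope="session")
def one_of_each(desk_style):
    """One 64 px phantom per class, fixed seeds."""
    return {label: render_phantom(label, seed=5, style=desk_style) for label in LABELS}


@pytest.fixture(scope="session")
def pristine_dataset(desk_style):
    """Ten pristine 64 px phantoms across classes."""
    images = []
    for i, label in enumerate(LABELS):
        im = render_phantom(label, seed=100 + i, style=desk_style)
        images.append(im)
    images.append(render_phantom("nodule", seed=200, style=desk_style))
    images.append(render_phantom("cyst", seed=201, style=desk_style))
    return ImageDataset(images)


def make_flat_dataset(counts: dict[str, int], size: int = 16,
                      provenance: str = "original", prefix: str = "") -> ImageDataset:
    """Cheap dataset of flat-colored images (scenario/metrics plumbing tests)."""
    rng = np.random.default_rng(0)
    images = []
    for label, n in counts.items():
        for i in range(n):
            px = np.full((size, size, 3), rng.integers(0, 255), dtype=np.uint8)
            images.append(LabeledImage(
                pixels=px, label=label, provenance=provenance,
                id=f"{prefix}{provenance}-{label}-{i:05d}"))
    return ImageDataset(images)
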