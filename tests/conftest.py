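import numpy as np
import pytest

from vertep import (
    LabelVolume,
    PedicleAnchors,
    PhantomSpec,
    generate_phantom,
)
from vertep.volume import SURROUNDING, TUMOR


@pytest.fixture(scope="session")
def lumbar_phantom():
    """Default lumbar phantom (5 mm central tumor, 1 mm spacing)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def coarse_phantom():
    """Small, fast phantom for optimizer loop tests (2 mm spacing)."""
    spec = PhantomSpec(spacing=2.0, block_size=(90.0, 80.0, 56.0))
    return generate_phantom(spec)


def make_box_volume(shape=(40, 40, 40), spacing=1.0, tumor_radius=6.0):
    """Cube of surrounding tissue with a centered spherical tumor.

    A minimal hand-built volume for coverage and solver tests where the
    vertebra geometry is irrelevant.
    """
    shape = tuple(shape)
    labels = np.full(shape, SURROUNDING, dtype=np.int16)
    center = (np.asarray(shape) - 1) / 2.0 * spacing
    ax = [spacing * np.arange(n) for n in shape]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    labels[r2 <= tumor_radius**2] = TUMOR
    vol = LabelVolume(labels=labels, spacing=(spacing,) * 3, origin=(0.0, 0.0, 0.0))
    return vol, center


@pytest.fixture()
def box_volume():
    return make_box_volume()


def straddle_anchors(center, offset=6.0, depth=30.0):
    """Anchors whose pedicle lines run along +y, straddling ``center`` in x."""
    cx, cy, cz = center
    return PedicleAnchors(
        left_entry=(cx - offset, cy - depth, cz),
        left_direction=(cx - offset, cy - depth + 10.0, cz),
        right_entry=(cx + offset, cy - depth, cz),
        right_direction=(cx + offset, cy - depth + 10.0, cz),
    )
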