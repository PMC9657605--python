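"""Synthetic vertebra + tumor phantoms.

Parametric stand-ins for segmented vertebral models: a rounded vertebral body
(elliptic cylinder with superior/inferior capping) with two pedicle channels,
embedded in a block of surrounding soft tissue, with a spherical tumor stamped
at a named location inside the body.  The phantom also yields the two
operator-style pedicle anchor point pairs (entry point + direction point) that
seed electrode placement.

The default boundary block is 130 x 120 x 75 mm.  Vertebral body sizes are
literature-typical: lumbar ~45 x 35 x 28 mm, thoracic ~35 x 28 x 22 mm
(width x depth x height).  A voxel belongs to a shape iff its *center* lies
inside the analytic shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .volume import BONE, SURROUNDING, TUMOR, LabelVolume

#: full body extents (mm): width (x), depth (y), height (z)
BODY_SIZE_MM = {
    "lumbar": (45.0, 35.0, 28.0),
    "thoracic": (35.0, 28.0, 22.0),
}

TUMOR_LOCATIONS = ("central", "anterior-lateral", "posterior-inferior")

_PEDICLE_RADIUS_MM = 3.5
_PEDICLE_LENGTH_MM = 12.0
_PEDICLE_ANGLE_DEG = 20.0  # transversal convergence angle
_CAP_EXPONENT = 6  # superellipsoid exponent for superior/inferior capping
_TUMOR_OFFSET_FRACTION = 0.4
_TUMOR_CLEARANCE_MM = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of one synthetic vertebra-tumor model."""

    segment: str = "lumbar"
    tumor_location: str = "central"
    tumor_radius: float = 5.0
    spacing: float = 1.0
    block_size: tuple[float, float, float] = (130.0, 120.0, 75.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.segment not in BODY_SIZE_MM:
            raise ValueError(f"unknown segment {self.segment!r}")
        if self.tumor_location not in TUMOR_LOCATIONS:
            raise ValueError(f"unknown tumor location {self.tumor_location!r}")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.tumor_radius <= 0:
            raise ValueError("tumor radius must be positive")
        body = BODY_SIZE_MM[self.segment]
        for bs, bd in zip(self.block_size, body):
            if bs < bd + 20.0:
                raise ValueError(
                    "block_size must exceed the vertebral body by >= 10 mm per side"
                )


@dataclass(frozen=True)
class PedicleAnchors:
    """Operator-selected point pairs per pedicle, world mm.

    ``*_entry`` is the fixed insertion point in the narrowest part of the
    pedicle channel; ``*_direction`` lies inside the vertebral body and encodes
    the pedicle's orientation.
    """

    left_entry: tuple[float, float, float]
    left_direction: tuple[float, float, float]
    right_entry: tuple[float, float, float]
    right_direction: tuple[float, float, float]

    def to_json(self) -> str:
        return json.dumps(
            {
                "left_entry": list(self.left_entry),
                "left_direction": list(self.left_direction),
                "right_entry": list(self.right_entry),
                "right_direction": list(self.right_direction),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PedicleAnchors":
        d = json.loads(text)
        return cls(
            left_entry=tuple(d["left_entry"]),
            left_direction=tuple(d["left_direction"]),
            right_entry=tuple(d["right_entry"]),
            right_direction=tuple(d["right_direction"]),
        )


def _body_membership(spec: PhantomSpec, center: np.ndarray):
    """Return f(points) -> bool array: inside the rounded vertebral body."""
    w, d, h = BODY_SIZE_MM[spec.segment]
    a, b, c = w / 2.0, d / 2.0, h / 2.0

    def inside(pts: np.ndarray) -> np.ndarray:
        rel = np.asarray(pts, dtype=float) - center
        return (
            (rel[..., 0] / a) ** 2
            + (rel[..., 1] / b) ** 2
            + np.abs(rel[..., 2] / c) ** _CAP_EXPONENT
        ) <= 1.0

    return inside


def _tumor_center(spec: PhantomSpec, body_center: np.ndarray) -> np.ndarray:
    """Tumor sphere center for the named location, shrunk to fit the body.

    The nominal offset is 40% of the body half-extent along the location's
    axes; if the sphere would breach the rounded body surface, the offset
    vector is scaled down by bisection until the sphere fits with ~1 mm
    clearance.
    """
    w, d, h = BODY_SIZE_MM[spec.segment]
    half = np.array([w, d, h]) / 2.0
    frac = _TUMOR_OFFSET_FRACTION
    if spec.tumor_location == "central":
        offset = np.zeros(3)
    elif spec.tumor_location == "anterior-lateral":
        offset = np.array([frac * half[0], frac * half[1], 0.0])
    else:  # posterior-inferior
        offset = np.array([0.0, -frac * half[1], -frac * half[2]])

    inside = _body_membership(spec, body_center)
    # sample the sphere surface densely; all samples must fall inside the body
    phi = np.linspace(0.0, np.pi, 24)
    theta = np.linspace(0.0, 2 * np.pi, 48, endpoint=False)
    pp, tt = np.meshgrid(phi, theta, indexing="ij")
    r_eff = spec.tumor_radius + _TUMOR_CLEARANCE_MM
    surf = r_eff * np.stack(
        [np.sin(pp) * np.cos(tt), np.sin(pp) * np.sin(tt), np.cos(pp)], axis=-1
    ).reshape(-1, 3)

    def fits(scale: float) -> bool:
        center = body_center + scale * offset
        return bool(np.all(inside(center + surf)))

    if not fits(0.0):
        raise ValueError(
            f"tumor of radius {spec.tumor_radius} mm does not fit inside the "
            f"{spec.segment} vertebral body even at its centroid"
        )
    if fits(1.0):
        return body_center + offset
    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if fits(mid):
            lo = mid
        else:
            hi = mid
    return body_center + lo * offset


def _pedicle_geometry(spec: PhantomSpec, body_center: np.ndarray):
    """Axis endpoints of the right pedicle channel (left is mirrored).

    Returns (posterior_end, attachment, unit_axis) with the axis pointing
    anteriorly and medially at the transversal convergence angle.
    """
    w, d, _h = BODY_SIZE_MM[spec.segment]
    a, b = w / 2.0, d / 2.0
    theta = np.deg2rad(_PEDICLE_ANGLE_DEG)
    attach = body_center + np.array([0.45 * a, -0.80 * b, 0.0])
    axis = np.array([-np.sin(theta), np.cos(theta), 0.0])
    posterior_end = attach - _PEDICLE_LENGTH_MM * axis
    return posterior_end, attach, axis


def _mirror_x(point: np.ndarray, x_mid: float) -> np.ndarray:
    out = np.array(point, dtype=float)
    out[0] = 2 * x_mid - out[0]
    return out


def generate_phantom(spec: PhantomSpec):
    """Build a synthetic vertebra-tumor label volume.

    Returns
    -------
    volume : LabelVolume
        Labelled grid (surrounding / bone / tumor) covering ``spec.block_size``.
    anchors : PedicleAnchors
        Mirror-symmetric entry and direction points, world mm.
    tumor_com : ndarray, shape (3,)
        Center of mass of the tumor voxels, world mm.
    """
    shape = tuple(int(round(bs / spec.spacing)) for bs in spec.block_size)
    spacing = (spec.spacing,) * 3
    # voxel centers span [s/2, extent - s/2]
    origin = tuple(spec.spacing / 2.0 for _ in range(3))
    axes = [origin[a] + spec.spacing * np.arange(shape[a]) for a in range(3)]
    X = axes[0][:, None, None]
    Y = axes[1][None, :, None]
    Z = axes[2][None, None, :]

    block_center = np.array([bs / 2.0 for bs in spec.block_size])
    body_center = block_center.copy()

    w, d, h = BODY_SIZE_MM[spec.segment]
    a, b, c = w / 2.0, d / 2.0, h / 2.0
    body = (
        ((X - body_center[0]) / a) ** 2
        + ((Y - body_center[1]) / b) ** 2
        + np.abs((Z - body_center[2]) / c) ** _CAP_EXPONENT
    ) <= 1.0

    # pedicle channels: cylinders from the posterior aspect into the body
    p0_r, attach_r, axis_r = _pedicle_geometry(spec, body_center)
    bone = body
    for p0, ax in (
        (p0_r, axis_r),
        (_mirror_x(p0_r, body_center[0]), _mirror_x(axis_r, 0.0)),
    ):
        rel = np.stack(
            np.broadcast_arrays(X - p0[0], Y - p0[1], Z - p0[2]), axis=-1
        )
        t = rel @ ax
        perp2 = np.einsum("...i,...i->...", rel, rel) - t**2
        cyl = (t >= 0) & (t <= _PEDICLE_LENGTH_MM) & (perp2 <= _PEDICLE_RADIUS_MM**2)
        bone = bone | cyl

    tumor_center = _tumor_center(spec, body_center)
    r2 = (
        (X - tumor_center[0]) ** 2
        + (Y - tumor_center[1]) ** 2
        + (Z - tumor_center[2]) ** 2
    )
    tumor = r2 <= spec.tumor_radius**2

    outside = tumor & ~body
    if np.any(outside):
        raise ValueError(
            f"tumor overlaps non-body tissue in {int(np.count_nonzero(outside))} "
            "voxels; tumor must lie fully inside the vertebral body"
        )

    labels = np.full(shape, SURROUNDING, dtype=np.int16)
    labels[bone] = BONE
    labels[tumor] = TUMOR

    volume = LabelVolume(labels=labels, spacing=spacing, origin=origin)

    # anchors: entry just inside the posterior end of the channel, direction
    # point inside the vertebral body along the channel axis
    entry_r = p0_r + 1.5 * axis_r
    direction_r = attach_r + 4.0 * axis_r
    x_mid = body_center[0]
    anchors = PedicleAnchors(
        left_entry=tuple(_mirror_x(entry_r, x_mid)),
        left_direction=tuple(_mirror_x(direction_r, x_mid)),
        right_entry=tuple(entry_r),
        right_direction=tuple(direction_r),
    )

    idx = np.argwhere(labels == TUMOR)
    tumor_com = volume.index_to_world(idx).mean(axis=0)
    return volume, anchors, tumor_com


def default_cohort(
    segment: str = "lumbar",
    radii=(5.0, 7.5, 10.0),
    locations=TUMOR_LOCATIONS,
    spacing: float = 1.0,
    seed: int = 0,
) -> list[PhantomSpec]:
    """The desk-scale evaluation cohort: one body, all location/radius combos."""
    return [
        PhantomSpec(
            segment=segment,
            tumor_location=loc,
            tumor_radius=r,
            spacing=spacing,
            seed=seed,
        )
        for loc in locations
        for r in radii
    ]
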