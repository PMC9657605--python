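"""Needle-electrode geometry.

An electrode is a rigid needle inserted through a pedicle: the *entry* point
is fixed for the whole optimization (transpedicular constraint) while the
*tip* moves.  The electrically exposed segment is the ``exposure_length`` of
needle behind the tip; its far end is the *rear*.  All coordinates are world
mm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


@dataclass(frozen=True)
class Electrode:
    """Entry-constrained needle electrode with an exposed tip segment."""

    entry: tuple[float, float, float]
    tip: tuple[float, float, float]
    radius: float = 0.6  # mm
    exposure_length: float = 20.0  # mm

    def __post_init__(self) -> None:
        object.__setattr__(self, "entry", tuple(float(x) for x in self.entry))
        object.__setattr__(self, "tip", tuple(float(x) for x in self.tip))
        if self.radius <= 0 or self.exposure_length <= 0:
            raise ValueError("radius and exposure_length must be positive")
        depth = np.linalg.norm(np.asarray(self.tip) - np.asarray(self.entry))
        if depth <= self.exposure_length / 2.0:
            raise ValueError(
                f"entry-tip distance {depth:.2f} mm must exceed half the "
                f"exposure length ({self.exposure_length / 2:.1f} mm)"
            )

    @property
    def entry_a(self) -> np.ndarray:
        return np.asarray(self.entry, dtype=float)

    @property
    def tip_a(self) -> np.ndarray:
        return np.asarray(self.tip, dtype=float)

    @property
    def axis_to_entry(self) -> np.ndarray:
        """Unit vector from tip toward entry (withdrawal direction)."""
        return _unit(self.entry_a - self.tip_a)

    @property
    def rear(self) -> np.ndarray:
        """Far end of the exposed segment, world mm."""
        return self.tip_a + self.exposure_length * self.axis_to_entry

    @property
    def midpoint(self) -> np.ndarray:
        """Center of the exposed segment, world mm."""
        return 0.5 * (self.tip_a + self.rear)

    @property
    def insertion_depth(self) -> float:
        return float(np.linalg.norm(self.tip_a - self.entry_a))

    def with_tip(self, new_tip) -> "Electrode":
        """New electrode with the same fixed entry and a moved tip."""
        return replace(self, tip=tuple(float(x) for x in new_tip))


def _closest_points_on_lines(p1, d1, p2, d2):
    """Closest points between lines p1 + s d1 and p2 + t d2."""
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    r = np.asarray(p1, float) - np.asarray(p2, float)
    a = d1 @ d1
    b = d1 @ d2
    c = d2 @ d2
    denom = a * c - b * b
    if denom < 1e-12 * a * c or denom == 0.0:
        # parallel: project each line's base point onto the other direction
        s = 0.0
        t = (r @ d2) / c
    else:
        s = (b * (r @ d2) - c * (r @ d1)) / denom
        t = (a * (r @ d2) - b * (r @ d1)) / denom
    return np.asarray(p1, float) + s * d1, np.asarray(p2, float) + t * d2


def center_of_geometry(e1: Electrode, e2: Electrode) -> np.ndarray:
    """Center of the two-electrode geometry, world mm.

    Cross-connect the needles — the line through tip 1 and rear 2, and the
    line through tip 2 and rear 1 — and take the midpoint of the shortest
    segment between those two lines (their intersection when they cross).
    """
    a0, a1 = e1.tip_a, e2.rear
    b0, b1 = e2.tip_a, e1.rear
    da = a1 - a0
    db = b1 - b0
    if np.linalg.norm(da) < 1e-12 or np.linalg.norm(db) < 1e-12:
        raise ValueError("degenerate electrode pair: coincident tip and rear")
    if np.linalg.norm(e1.tip_a - e2.tip_a) < 1e-9 and np.linalg.norm(e1.rear - e2.rear) < 1e-9:
        raise ValueError("coincident electrodes")
    if np.linalg.norm(np.cross(da, db)) < 1e-12 * np.linalg.norm(da) * np.linalg.norm(db):
        # parallel cross-lines: midpoint of the two segment centers
        return 0.5 * (0.5 * (a0 + a1) + 0.5 * (b0 + b1))
    p, q = _closest_points_on_lines(a0, da, b0, db)
    return 0.5 * (p + q)


def segment_distance(p1, q1, p2, q2, samples: int = 256) -> float:
    """Minimum distance between segments [p1,q1] and [p2,q2] (sampled).

    Dense pairwise sampling; accuracy ~ segment length / samples, ample for
    millimetre-scale clearance rules.
    """
    t = np.linspace(0.0, 1.0, samples)
    a = np.asarray(p1, float) + t[:, None] * (np.asarray(q1, float) - np.asarray(p1, float))
    b = np.asarray(p2, float) + t[:, None] * (np.asarray(q2, float) - np.asarray(p2, float))
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.min()))


def initialize_electrodes(
    anchors, tumor_com, exposure_length: float = 20.0, radius: float = 0.6,
    min_tip_separation: float = 5.0, min_segment_clearance: float | None = None,
) -> tuple[Electrode, Electrode]:
    """Initial electrode pair pulled toward the tumor center of mass.

    Each needle lies on its operator-defined pedicle axis (the line through
    the entry point and the direction point); the tip is advanced along that
    axis so the exposed-segment midpoint sits at the axis point nearest the
    tumor center of mass.  The two needles thus straddle the tumor on their
    own pedicle lines.  If the tips end up closer than ``min_tip_separation``
    or the exposed segments closer than ``min_segment_clearance`` (default:
    two radii plus 1 mm, enough to keep rasterized masks disjoint at 1 mm
    spacing), both tips are retracted toward their entries in 1 mm steps
    until separated.
    """
    com = np.asarray(tumor_com, dtype=float)
    if min_segment_clearance is None:
        min_segment_clearance = 2.0 * radius + 1.0
    tips = []
    units = []
    for entry, direction in (
        (anchors.left_entry, anchors.left_direction),
        (anchors.right_entry, anchors.right_direction),
    ):
        entry = np.asarray(entry, dtype=float)
        if np.linalg.norm(com - entry) < 1e-9:
            raise ValueError("entry point coincides with tumor center of mass")
        u = _unit(np.asarray(direction, dtype=float) - entry)
        midpoint = entry + ((com - entry) @ u) * u
        tips.append(midpoint + (exposure_length / 2.0) * u)
        units.append(u)

    def _metrics(tips_now) -> tuple[float, float]:
        rears = [
            tips_now[i] + exposure_length * _unit(
                np.asarray((anchors.left_entry, anchors.right_entry)[i], float)
                - tips_now[i]
            )
            for i in range(2)
        ]
        sep = float(np.linalg.norm(tips_now[0] - tips_now[1]))
        clear = segment_distance(tips_now[0], rears[0], tips_now[1], rears[1])
        return sep, clear

    sep, clear = _metrics(tips)
    for _ in range(200):
        if sep >= min_tip_separation and clear >= min_segment_clearance:
            break
        candidate = [tips[0] - 1.0 * units[0], tips[1] - 1.0 * units[1]]
        new_sep, new_clear = _metrics(candidate)
        if abs(new_sep - sep) < 1e-9 and abs(new_clear - clear) < 1e-9:
            # exact stall: parallel axes, retraction changes nothing; accept
            # if the needles at least clear each other physically
            if clear >= 2.0 * radius:
                break
            raise ValueError(
                "could not separate initialized electrodes: pedicle axes run "
                f"within {clear:.2f} mm of each other"
            )
        tips = candidate
        sep, clear = new_sep, new_clear
    else:
        raise ValueError("could not separate initialized electrodes")
    e1 = Electrode(entry=anchors.left_entry, tip=tuple(tips[0]),
                   radius=radius, exposure_length=exposure_length)
    e2 = Electrode(entry=anchors.right_entry, tip=tuple(tips[1]),
                   radius=radius, exposure_length=exposure_length)
    return e1, e2


def insertion_parameters(electrode: Electrode, volume) -> dict[str, float]:
    """Surgical insertion parameters for one electrode.

    Angles follow the convention used for transpedicular screw placement:
    the *transversal* angle is the needle axis projected onto the axial (xy)
    plane measured against the anteroposterior (y) axis; the *sagittal* angle
    is the projection onto the sagittal (yz) plane against the same axis.
    The sagittal plane is the volume's x midline.
    """
    v = electrode.tip_a - electrode.entry_a
    transversal = float(np.degrees(np.arctan2(v[0], v[1])))
    sagittal = float(np.degrees(np.arctan2(v[2], v[1])))
    x_mid = volume.origin[0] + (volume.shape[0] - 1) * volume.spacing[0] / 2.0
    return {
        "transversal_angle_deg": transversal,
        "sagittal_angle_deg": sagittal,
        "entry_distance_from_sagittal_plane_mm": float(abs(electrode.entry[0] - x_mid)),
        "insertion_depth_mm": electrode.insertion_depth,
    }
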