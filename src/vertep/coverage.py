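"""Clinical-target-volume weighting, coverage metrics and undertreated islands.

The gross tumor volume (GTV) must be covered by at least the electroporation
threshold field (default 400 V/cm).  The clinical target volume (CTV) adds a
safety margin (default 5 mm) around the GTV in which the requirement is
relaxed: a distance-based weighting map assigns weight 1 on the GTV, falling
linearly to ``edge_weight`` (default 0) at the outer CTV edge, and a CTV
voxel counts as covered when its field reaches *weight x threshold* — the
"soft coverage" criterion.  Undertreated CTV voxels are grouped into
26-connected "islands" whose weighted masses and centers of mass drive the
electrode-position forces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage

from .solver import FieldSolution
from .volume import TUMOR, LabelVolume


@dataclass
class WeightMap:
    """CTV weighting map on the label grid."""

    weights: np.ndarray  # in [0, 1]
    margin: float  # mm
    edge_weight: float  # weight at the outer CTV edge


@dataclass
class Island:
    """One 26-connected undertreated component of the CTV."""

    voxels: np.ndarray  # (k, 3) voxel indices
    mass: float  # weighted voxel count, scaled to 1 mm voxels
    com: np.ndarray  # weighted center of mass, world mm


@dataclass
class CoverageReport:
    """Coverage summary for one field solution."""

    gtv_coverage: float  # fraction of GTV voxels at/above threshold
    ctv_soft_coverage: float  # weight-fraction of CTV covered softly
    undertreated_mass: float  # summed weight over uncovered CTV voxels
    threshold: float  # V/cm


def build_weight_map(
    volume: LabelVolume, margin: float = 5.0, edge_weight: float = 0.0
) -> WeightMap:
    """Distance-based CTV weighting map.

    The distance of each voxel to the GTV is the Euclidean distance transform
    (in mm, voxel-center metric) of the non-tumor region.  Weights are 1 on
    the GTV, ``1 - (1 - edge_weight) * d / margin`` within the margin, and 0
    beyond it.  A higher ``edge_weight`` (e.g. 0.5 for metastatic tumors)
    enforces a residual field requirement at the outer CTV edge.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    gtv = volume.mask(TUMOR)
    if not np.any(gtv):
        raise ValueError("volume contains no tumor voxels")
    d = scipy.ndimage.distance_transform_edt(~gtv, sampling=volume.spacing)
    w = 1.0 - (1.0 - edge_weight) * d / margin
    w[d > margin] = 0.0
    w[gtv] = 1.0
    np.clip(w, 0.0, 1.0, out=w)
    return WeightMap(weights=w, margin=float(margin), edge_weight=float(edge_weight))


def _check_grids(field: FieldSolution, wmap: WeightMap, volume: LabelVolume) -> None:
    if field.field_magnitude.shape != volume.shape or wmap.weights.shape != volume.shape:
        raise ValueError("field, weight map and volume grids do not match")


def _mass_scale(volume: LabelVolume) -> float:
    """Island mass is a weighted voxel count normalized to 1 mm voxels."""
    return volume.voxel_volume_mm3 / 1.0


def _tissue_mask(field: FieldSolution, volume: LabelVolume) -> np.ndarray:
    """Voxels holding tissue (everything outside the needle masks)."""
    if field.electrode_mask is None:
        return np.ones(volume.shape, dtype=bool)
    return ~field.electrode_mask


def soft_coverage(
    field: FieldSolution,
    wmap: WeightMap,
    volume: LabelVolume,
    threshold: float = 400.0,
) -> CoverageReport:
    """GTV coverage and CTV soft coverage of a field solution.

    A CTV voxel with weight w is covered iff E >= w * threshold; soft
    coverage is the covered weight fraction.  GTV coverage applies the full
    threshold to every tumor voxel.  Voxels occupied by the needles
    themselves hold metal, not tissue, and are excluded from both tallies.
    """
    _check_grids(field, wmap, volume)
    E = field.field_magnitude
    w = wmap.weights
    tissue = _tissue_mask(field, volume)
    ctv = (w > 0) & tissue
    covered = ctv & (E >= w * threshold)
    total_w = float(w[ctv].sum())
    cov_w = float(w[covered].sum())
    gtv = volume.mask(TUMOR) & tissue
    n_gtv = np.count_nonzero(gtv)
    gtv_cov = (
        float(np.count_nonzero(E[gtv] >= threshold)) / float(n_gtv)
        if n_gtv
        else 0.0
    )
    scale = _mass_scale(volume)
    return CoverageReport(
        gtv_coverage=gtv_cov,
        ctv_soft_coverage=cov_w / total_w if total_w > 0 else 0.0,
        undertreated_mass=(total_w - cov_w) * scale,
        threshold=float(threshold),
    )


#: 26-connectivity structuring element
_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


def find_islands(
    field: FieldSolution,
    wmap: WeightMap,
    volume: LabelVolume,
    threshold: float = 400.0,
    discard_fraction: float = 0.1,
) -> list[Island]:
    """Undertreated islands of the CTV, largest first.

    Undertreated voxels (weight-scaled threshold not reached) are grouped by
    26-connectivity; islands whose weighted mass falls below
    ``discard_fraction`` of the largest island's mass are discarded.  Island
    centers of mass are weighted by the CTV map, so they lean toward the GTV.
    """
    _check_grids(field, wmap, volume)
    E = field.field_magnitude
    w = wmap.weights
    under = (w > 0) & _tissue_mask(field, volume) & (E < w * threshold)
    if not np.any(under):
        return []
    lab, n = scipy.ndimage.label(under, structure=_STRUCTURE_26)
    scale = _mass_scale(volume)
    masses = scipy.ndimage.sum_labels(w, lab, index=np.arange(1, n + 1)) * scale
    keep = masses >= discard_fraction * masses.max()
    islands: list[Island] = []
    for comp_id in np.flatnonzero(keep) + 1:
        idx = np.argwhere(lab == comp_id)
        wv = w[idx[:, 0], idx[:, 1], idx[:, 2]]
        coords = volume.index_to_world(idx)
        com = (coords * wv[:, None]).sum(axis=0) / wv.sum()
        islands.append(Island(voxels=idx, mass=float(masses[comp_id - 1]), com=com))
    islands.sort(key=lambda i: i.mass, reverse=True)
    return islands
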