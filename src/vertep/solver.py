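"""Stationary electric-field computation on the voxel grid.

Solves the nonlinear Laplace problem

    div( sigma(|grad V|) grad V ) = 0

with Dirichlet conditions on the two rasterized electrode masks (applied
voltage on the active needle, 0 V on the return needle) and zero-flux
(insulating) conditions on the outer domain boundary.  The discretization is
a cell-centered finite-volume scheme on the label grid with harmonic-mean
face conductivities; the field dependence of the conductivity is resolved by
Picard (fixed-point) iteration.

The linear systems are solved matrix-free by preconditioned conjugate
gradients.  The preconditioner is the constant-coefficient Neumann Laplacian
inverted exactly in the DCT-II basis (a spectral Poisson solve), which keeps
the iteration count essentially independent of grid size; the solution from
the previous Picard step / previous optimizer iteration warm-starts CG.

Units: potentials in V, spacing supplied in mm, assembly in SI (m), field
magnitudes reported in V/cm (1 V/mm = 10 V/cm, applied centrally here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.ndimage

from .conductivity import TISSUE_LAWS, ConductivityLaw, sigma_of_E
from .electrodes import Electrode
from .volume import LabelVolume

logger = logging.getLogger(__name__)

MM_PER_CM = 10.0  # 1 V/mm = 10 V/cm


@dataclass
class SolverConfig:
    """Numerical settings for the nonlinear field solve."""

    picard_tol: float = 1e-3  # max relative sigma change between iterations
    picard_max_iter: int = 50
    linear_solver_tol: float = 1e-6  # relative residual for CG
    linear_max_iter: int = 5000
    use_preconditioner: bool = True
    spacing_override: float | None = None  # solve on a resampled grid (mm)
    damping_threshold: float = 0.2  # geometric sigma damping above this change


@dataclass
class FieldSolution:
    """Potential and field grids for one solve."""

    potential: np.ndarray  # V, full grid
    field_magnitude: np.ndarray  # V/cm
    applied_voltage: float  # V
    current: float  # A, total through the active electrode
    current_return: float  # A, total through the return electrode (negative)
    picard_iterations: int
    converged: bool
    picard_residuals: list[float] = field(default_factory=list)
    sigma: np.ndarray | None = None  # S/m at convergence
    electrode_mask: np.ndarray | None = None  # voxels occupied by either needle
    face_conductance: list | None = None  # per-axis face conductances, S


class ElectrodeGeometryError(ValueError):
    """Raised when electrode rasterization is geometrically invalid."""


def rasterize_electrodes(
    electrodes: tuple[Electrode, Electrode], volume: LabelVolume
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel masks of the two exposed electrode segments.

    A voxel belongs to an electrode iff its center lies within the electrode
    radius of the exposed segment [tip, rear]; the nearest voxel to each of a
    dense set of axis samples is added as well, so the mask is a connected
    line of voxels even when the radius is below half the voxel diagonal.

    Raises
    ------
    ElectrodeGeometryError
        If an exposed segment leaves the grid or the two masks touch
        (short-circuit geometry).
    """
    from .electrodes import segment_distance

    e1, e2 = electrodes
    clearance = e1.radius + e2.radius
    if segment_distance(e1.tip_a, e1.rear, e2.tip_a, e2.rear) < clearance:
        raise ElectrodeGeometryError("electrodes in contact")
    masks = [_rasterize_segment(e, volume) for e in electrodes]
    active, ret = masks
    if np.any(active & ret):
        raise ElectrodeGeometryError("electrodes in contact")
    return active, ret


def _rasterize_segment(e: Electrode, volume: LabelVolume) -> np.ndarray:
    p0 = e.tip_a
    p1 = e.rear
    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    shape = np.asarray(volume.shape)

    step = float(min(volume.spacing)) / 4.0
    n_samples = max(int(np.ceil(np.linalg.norm(p1 - p0) / step)) + 1, 2)
    ts = np.linspace(0.0, 1.0, n_samples)
    samples = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]

    rel = (samples - origin) / spacing
    if np.any(rel < -0.5) or np.any(rel > shape - 0.5):
        raise ElectrodeGeometryError(
            "exposed electrode segment extends outside the volume"
        )

    mask = np.zeros(volume.shape, dtype=bool)

    # radius test on a bounding subgrid
    pad = e.radius + float(max(volume.spacing))
    lo = np.maximum(np.floor((np.minimum(p0, p1) - pad - origin) / spacing), 0).astype(int)
    hi = np.minimum(
        np.ceil((np.maximum(p0, p1) + pad - origin) / spacing) + 1, shape
    ).astype(int)
    ax = [origin[a] + spacing[a] * np.arange(lo[a], hi[a]) for a in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    d = pts - p0
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    t = np.clip(np.einsum("...i,i->...", d, seg) / seg_len2, 0.0, 1.0)
    closest = p0 + t[..., None] * seg
    dist2 = np.sum((pts - closest) ** 2, axis=-1)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = dist2 <= e.radius**2

    # snap nearest voxel per axis sample to guarantee connectivity
    snap = np.clip(np.rint(rel).astype(int), 0, shape - 1)
    mask[snap[:, 0], snap[:, 1], snap[:, 2]] = True
    return mask


class _FVSystem:
    """Matrix-free 7-point finite-volume operator with Dirichlet holes.

    ``surface_distance`` optionally gives, per voxel, the distance (mm) from
    the voxel center to the true electrode surface.  Faces between an
    electrode voxel and tissue then use that distance instead of the full
    cell spacing (an embedded-boundary correction): the needle is an
    equipotential, so the Dirichlet value holds on its physical surface, and
    anchoring the flux there removes the O(h) effective-radius error of the
    staircase mask.
    """

    def __init__(
        self,
        sigma: np.ndarray,
        dirichlet: np.ndarray,
        spacing_mm,
        surface_distance: np.ndarray | None = None,
    ) -> None:
        self.dirichlet = dirichlet
        h = np.asarray(spacing_mm, dtype=float) * 1e-3  # m
        self.g = []
        for a in range(3):
            s0 = _axis_slice(a, slice(None, -1))
            s1 = _axis_slice(a, slice(1, None))
            harm = 2.0 * sigma[s0] * sigma[s1] / (sigma[s0] + sigma[s1])
            area = h[(a + 1) % 3] * h[(a + 2) % 3]
            g = harm * area / h[a]
            if surface_distance is not None:
                d0 = dirichlet[s0]
                d1 = dirichlet[s1]
                ha = h[a] * 1e3  # mm
                # face with Dirichlet on the low side: flux anchored at the
                # surface, over the tissue voxel's distance to it
                for dmask, tissue_sl in ((d0 & ~d1, s1), (d1 & ~d0, s0)):
                    if np.any(dmask):
                        dist = np.clip(
                            surface_distance[tissue_sl][dmask], 0.1 * ha, 1.5 * ha
                        )
                        g[dmask] = sigma[tissue_sl][dmask] * area / (dist * 1e-3)
            self.g.append(g)

    def apply_full(self, u: np.ndarray) -> np.ndarray:
        """A u on the full grid (no Dirichlet masking)."""
        out = np.zeros_like(u)
        for a in range(3):
            s0 = _axis_slice(a, slice(None, -1))
            s1 = _axis_slice(a, slice(1, None))
            f = self.g[a] * (u[s1] - u[s0])
            out[s0] -= f
            out[s1] += f
        return out

    def apply(self, u: np.ndarray) -> np.ndarray:
        """A restricted to unknowns: input/output zeroed on Dirichlet voxels."""
        v = u.copy()
        v[self.dirichlet] = 0.0
        out = self.apply_full(v)
        out[self.dirichlet] = 0.0
        return out


def _axis_slice(axis: int, sl: slice):
    out = [slice(None)] * 3
    out[axis] = sl
    return tuple(out)


class _DCTPreconditioner:
    """Spectral inverse of a constant-coefficient Neumann Laplacian.

    The 7-point Neumann Laplacian on a box is diagonalized by the DCT-II in
    each axis; using a representative conductivity it serves as a grid-size
    robust preconditioner for the heterogeneous system.  Dirichlet entries
    are projected out before and after the solve.
    """

    def __init__(self, sigma: np.ndarray, dirichlet: np.ndarray, spacing_mm) -> None:
        self.dirichlet = dirichlet
        h = np.asarray(spacing_mm, dtype=float) * 1e-3
        free = ~dirichlet
        sigma_ref = float(np.exp(np.mean(np.log(sigma[free]))))
        lam = []
        for a, n in enumerate(sigma.shape):
            area = h[(a + 1) % 3] * h[(a + 2) % 3]
            g = sigma_ref * area / h[a]
            k = np.arange(n)
            lam.append(2.0 * g * (1.0 - np.cos(np.pi * k / n)))
        L = (
            lam[0][:, None, None]
            + lam[1][None, :, None]
            + lam[2][None, None, :]
        )
        # zero mode: pin to the smallest nonzero eigenvalue (the true system
        # is nonsingular thanks to the Dirichlet voxels)
        L[0, 0, 0] = min(lam[a][1] for a in range(3) if len(lam[a]) > 1)
        # single precision: the preconditioner only needs to approximate the
        # inverse, and float32 transforms are substantially cheaper
        self._L = L.astype(np.float32)

    def apply(self, r: np.ndarray) -> np.ndarray:
        v = r.astype(np.float32)
        v[self.dirichlet] = 0.0
        z = scipy.fft.idctn(
            scipy.fft.dctn(v, type=2, norm="ortho", workers=1) / self._L,
            type=2,
            norm="ortho",
            workers=1,
        )
        z[self.dirichlet] = 0.0
        return z.astype(np.float64)


def _pcg(system, b, x0, precond, tol, max_iter):
    """Preconditioned CG on full-grid arrays (zeros on Dirichlet voxels)."""
    x = x0.copy()
    x[system.dirichlet] = 0.0
    r = b - system.apply(x)
    bnorm = float(np.linalg.norm(b))
    if bnorm == 0.0:
        return np.zeros_like(b), 0
    z = precond(r) if precond is not None else r
    p = z.copy()
    rz = float(np.vdot(r, z).real)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        q = system.apply(p)
        pq = float(np.vdot(p, q).real)
        if pq <= 0:
            logger.warning("CG breakdown (non-positive curvature); stopping")
            break
        alpha = rz / pq
        x += alpha * p
        r -= alpha * q
        if np.linalg.norm(r) <= tol * bnorm:
            break
        z = precond(r) if precond is not None else r
        rz_new = float(np.vdot(r, z).real)
        p = z + (rz_new / rz) * p
        rz = rz_new
    else:
        raise RuntimeError(
            f"linear solve failed to reach tolerance {tol} in {max_iter} iterations"
        )
    return x, n_iter


def _sigma_from_field(labels: np.ndarray, E: np.ndarray, laws) -> np.ndarray:
    sigma = np.empty(labels.shape, dtype=float)
    for label, law in laws.items():
        m = labels == label
        if np.any(m):
            sigma[m] = sigma_of_E(E[m], law)
    return sigma


def field_magnitude_from_potential(V: np.ndarray, spacing_mm) -> np.ndarray:
    """|grad V| in V/cm by central differences (one-sided at the boundary)."""
    grads = np.gradient(V, *[float(s) for s in spacing_mm])  # V/mm
    return np.sqrt(sum(g * g for g in grads)) * MM_PER_CM


def solve_field(
    volume: LabelVolume,
    electrodes: tuple[Electrode, Electrode] | None = None,
    applied_voltage: float = 0.0,
    laws: dict[int, ConductivityLaw] | None = None,
    config: SolverConfig | None = None,
    *,
    active_mask: np.ndarray | None = None,
    return_mask: np.ndarray | None = None,
    surface_distance: np.ndarray | None = None,
    warm_start: FieldSolution | None = None,
) -> FieldSolution:
    """Solve the nonlinear stationary field problem.

    Either ``electrodes`` (rasterized here) or explicit ``active_mask`` /
    ``return_mask`` Dirichlet masks must be given; the mask form is the test
    hook for analytic benchmark geometries (parallel plates, concentric
    spheres).  With explicit masks, ``surface_distance`` may supply each
    voxel center's distance (mm) to the true Dirichlet surface to enable the
    embedded-boundary coupling (applied automatically for rasterized
    needles).

    Returns a :class:`FieldSolution`; if the Picard iteration does not reach
    its tolerance within the iteration budget the solution is still returned
    with ``converged=False`` and a warning logged.
    """
    if applied_voltage < 0:
        raise ValueError("applied_voltage must be non-negative")
    laws = dict(TISSUE_LAWS) if laws is None else laws
    config = config or SolverConfig()

    if config.spacing_override is not None and electrodes is not None:
        return _solve_resampled(volume, electrodes, applied_voltage, laws, config)

    if active_mask is None or return_mask is None:
        if electrodes is None:
            raise ValueError("either electrodes or explicit masks are required")
        active_mask, return_mask = rasterize_electrodes(electrodes, volume)
        surface_distance = _electrode_surface_distance(electrodes, volume)

    dirichlet = active_mask | return_mask
    Vd = np.zeros(volume.shape, dtype=float)
    Vd[active_mask] = float(applied_voltage)

    labels = volume.labels
    spacing = volume.spacing

    if warm_start is not None and warm_start.sigma is not None and (
        warm_start.sigma.shape == labels.shape
    ):
        sigma = warm_start.sigma.copy()
        scale = (
            applied_voltage / warm_start.applied_voltage
            if warm_start.applied_voltage > 0
            else 0.0
        )
        u = warm_start.potential * scale - Vd
        u[dirichlet] = 0.0
    else:
        sigma = _sigma_from_field(labels, np.zeros(labels.shape), laws)
        u = np.zeros(volume.shape, dtype=float)

    residuals: list[float] = []
    converged = False
    n_picard = 0
    V = Vd.copy()
    rel = 1.0
    system = None
    for n_picard in range(1, config.picard_max_iter + 1):
        system = _FVSystem(sigma, dirichlet, spacing, surface_distance)
        b = -system.apply_full(Vd)
        b[dirichlet] = 0.0
        precond = (
            _DCTPreconditioner(sigma, dirichlet, spacing).apply
            if config.use_preconditioner
            else None
        )
        # inexact Picard: solve only as tightly as the current nonlinear
        # error warrants, then polish at full tolerance once converged
        tol = min(1e-4, max(0.02 * rel, config.linear_solver_tol))
        u, _ = _pcg(system, b, u, precond, tol, config.linear_max_iter)
        V = Vd + u
        E = field_magnitude_from_potential(V, spacing)
        sigma_new = _sigma_from_field(labels, E, laws)
        prev_rel = residuals[-1] if residuals else np.inf
        rel = float(np.max(np.abs(sigma_new - sigma) / sigma_new))
        residuals.append(rel)
        if (
            rel > config.damping_threshold
            or rel > 0.6 * prev_rel
            or rel < 10.0 * config.picard_tol
        ):
            # geometric under-relaxation through the initial transient,
            # whenever the undamped map stalls or oscillates between
            # conductivity states, and through the convergence tail (where
            # single transition-zone voxels flip under undamped updates)
            sigma = np.sqrt(sigma * sigma_new)
        else:
            sigma = sigma_new
        if rel < config.picard_tol:
            converged = True
            u, _ = _pcg(
                system, b, u, precond, config.linear_solver_tol, config.linear_max_iter
            )
            V = Vd + u
            break
    if not converged:
        logger.warning(
            "Picard iteration did not converge in %d iterations (last change %.3g)",
            config.picard_max_iter,
            residuals[-1] if residuals else float("nan"),
        )

    E = field_magnitude_from_potential(V, spacing)
    sol = FieldSolution(
        potential=V,
        field_magnitude=E,
        applied_voltage=float(applied_voltage),
        current=0.0,
        current_return=0.0,
        picard_iterations=n_picard,
        converged=converged,
        picard_residuals=residuals,
        sigma=sigma,
        electrode_mask=dirichlet,
        face_conductance=system.g if system is not None else None,
    )
    sol.current = compute_current(sol, active_mask, dirichlet, volume)
    sol.current_return = compute_current(sol, return_mask, dirichlet, volume)
    return sol


def _electrode_surface_distance(electrodes, volume: LabelVolume) -> np.ndarray:
    """Per-voxel distance (mm) from the voxel center to the nearest needle
    surface, evaluated on bounding subgrids around each exposed segment."""
    out = np.full(volume.shape, np.inf)
    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    shape = np.asarray(volume.shape)
    for e in electrodes:
        p0, p1 = e.tip_a, e.rear
        pad = e.radius + 3.0 * float(max(volume.spacing))
        lo = np.maximum(
            np.floor((np.minimum(p0, p1) - pad - origin) / spacing), 0
        ).astype(int)
        hi = np.minimum(
            np.ceil((np.maximum(p0, p1) + pad - origin) / spacing) + 1, shape
        ).astype(int)
        ax = [origin[a] + spacing[a] * np.arange(lo[a], hi[a]) for a in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)
        seg = p1 - p0
        t = np.clip(
            np.einsum("...i,i->...", pts - p0, seg) / float(seg @ seg), 0.0, 1.0
        )
        closest = p0 + t[..., None] * seg
        dist = np.sqrt(np.sum((pts - closest) ** 2, axis=-1)) - e.radius
        sub = out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        np.minimum(sub, dist, out=sub)
    return out


def compute_current(
    solution: FieldSolution,
    electrode_mask: np.ndarray,
    all_electrode_mask: np.ndarray,
    volume: LabelVolume,
) -> float:
    """Total current (A) leaving an electrode mask into the tissue.

    Sums, over every grid face between an electrode voxel and a non-electrode
    voxel, the flux sigma_face * (V_elec - V_neighbor) / h * A_face in SI
    units, using the same face conductances as the field solve when they are
    available.  Positive for a source electrode, negative for a sink.
    """
    if solution.sigma is None:
        raise ValueError("solution carries no conductivity grid")
    V = solution.potential
    sigma = solution.sigma
    h = np.asarray(volume.spacing, dtype=float) * 1e-3
    total = 0.0
    tissue = ~all_electrode_mask
    for a in range(3):
        s0 = _axis_slice(a, slice(None, -1))
        s1 = _axis_slice(a, slice(1, None))
        if solution.face_conductance is not None:
            g = solution.face_conductance[a]
        else:
            harm = 2.0 * sigma[s0] * sigma[s1] / (sigma[s0] + sigma[s1])
            g = harm * h[(a + 1) % 3] * h[(a + 2) % 3] / h[a]
        fwd = electrode_mask[s0] & tissue[s1]
        total += float(np.sum(g[fwd] * (V[s0][fwd] - V[s1][fwd])))
        bwd = electrode_mask[s1] & tissue[s0]
        total += float(np.sum(g[bwd] * (V[s1][bwd] - V[s0][bwd])))
    return total


def _solve_resampled(volume, electrodes, applied_voltage, laws, config):
    """Solve on a coarser nearest-neighbour resampling of the label grid."""
    target = float(config.spacing_override)
    zoom = [s / target for s in volume.spacing]
    coarse_labels = scipy.ndimage.zoom(volume.labels, zoom, order=0)
    origin = tuple(
        o - s / 2.0 + target / 2.0 for o, s in zip(volume.origin, volume.spacing)
    )
    coarse = LabelVolume(
        labels=coarse_labels,
        spacing=(target,) * 3,
        origin=origin,
        legend=dict(volume.legend),
    )
    sub = SolverConfig(
        picard_tol=config.picard_tol,
        picard_max_iter=config.picard_max_iter,
        linear_solver_tol=config.linear_solver_tol,
        linear_max_iter=config.linear_max_iter,
        use_preconditioner=config.use_preconditioner,
        spacing_override=None,
    )
    return solve_field(coarse, electrodes, applied_voltage, laws, sub)
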