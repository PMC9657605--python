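"""Force-based electrode-position and voltage optimization.

Two needle electrodes enter through the pedicles (fixed entry points) and are
iteratively repositioned by three "forces", evaluated per iteration from the
computed field distribution:

* ``F_geo`` — attraction of the electrode-geometry center toward the tumor
  center of mass;
* island forces — gravitation-like attraction of each electrode's tip and
  rear toward the weighted centers of mass of undertreated CTV islands,
  ``F_i = m_i / ||d_i||^2 * unit(d_i)`` (mass = weighted voxel count,
  distances in mm, clamped below at 1 mm);
* ``F_dd`` — inverse-distance repulsion between the tips, preventing
  short-circuit geometries.

The final force on each electrode is the weighted sum (weights w1..w4,
defaults 1.3 / 0.1 / 0.02 / 5); it is applied at the tip as a displacement
clipped to ``max_step`` mm, with the axis re-derived through the fixed entry
point.  The pulse amplitude follows a voltage-to-distance rule (1000 V/cm
times the exposed-midpoint distance, rounded to 100 V, clamped to the
500-3000 V generator range).  If a reposition lowers soft coverage, the move
is reverted and the voltage (and the working voltage-to-distance ratio) is
raised by 10% instead.  The loop stops on full soft coverage, a coverage
change below 0.1 percentage points, the iteration cap, the voltage cap, or
the 45 A current limit; a final ramp then raises the voltage in 100 V steps
while coverage is incomplete.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .conductivity import TISSUE_LAWS, ConductivityLaw
from .coverage import Island, build_weight_map, find_islands, soft_coverage
from .electrodes import Electrode, center_of_geometry, initialize_electrodes
from .phantom import PedicleAnchors
from .solver import (
    ElectrodeGeometryError,
    FieldSolution,
    SolverConfig,
    solve_field,
)
from .volume import LabelVolume

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class OptimizerConfig:
    """Optimization parameters with pulse-generator constraints."""

    w1: float = 1.3  # tumor-center attraction
    w2: float = 0.1  # island attraction at the tip
    w3: float = 0.02  # island attraction at the rear
    w4: float = 5.0  # tip-tip repulsion
    voltage_to_distance: float = 1000.0  # V/cm
    voltage_step: float = 100.0  # V
    voltage_min: float = 500.0  # V
    voltage_max: float = 3000.0  # V
    current_limit: float = 45.0  # A
    max_iterations: int = 50
    coverage_tolerance: float = 0.1  # percentage points
    threshold: float = 400.0  # V/cm
    margin: float = 5.0  # mm
    edge_weight: float = 0.0
    discard_fraction: float = 0.1
    max_step: float = 10.0  # mm displacement per iteration
    revert_boost_fraction: float = 0.10
    error_displacement: float = 0.5  # mm
    exposure_length: float = 20.0  # mm
    electrode_radius: float = 0.6  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3, self.w4) < 0:
            raise ValueError("force weights must be non-negative")
        if self.voltage_min > self.voltage_max:
            raise ValueError("voltage_min must not exceed voltage_max")
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")


@dataclass
class ForceSet:
    """Force components of one iteration."""

    f_geo: np.ndarray
    f_tip_sum_1: np.ndarray
    f_rear_sum_1: np.ndarray
    f_tip_sum_2: np.ndarray
    f_rear_sum_2: np.ndarray
    f_dd: np.ndarray  # acts at tip 2; negated at tip 1
    f_ele1: np.ndarray
    f_ele2: np.ndarray


@dataclass
class TreatmentPlan:
    """Final plan: electrode coordinates, voltage, coverage and provenance."""

    electrodes: tuple[Electrode, Electrode]
    applied_voltage: float
    current: float
    gtv_coverage: float
    ctv_soft_coverage: float
    iterations: int
    termination_reason: str
    history: list[dict] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        e1, e2 = self.electrodes
        return {
            "electrodes": [
                {"entry": list(e1.entry), "tip": list(e1.tip)},
                {"entry": list(e2.entry), "tip": list(e2.tip)},
            ],
            "applied_voltage_V": self.applied_voltage,
            "current_A": self.current,
            "gtv_coverage": self.gtv_coverage,
            "ctv_soft_coverage": self.ctv_soft_coverage,
            "iterations": self.iterations,
            "termination_reason": self.termination_reason,
            "history": self.history,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def force_geo(e1: Electrode, e2: Electrode, tumor_com) -> np.ndarray:
    """Vector from the electrode-geometry center to the tumor center of mass."""
    return np.asarray(tumor_com, dtype=float) - center_of_geometry(e1, e2)


def island_forces(
    electrode: Electrode, islands: list[Island], min_distance: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Summed island attractions at the electrode tip and rear.

    Each island pulls with magnitude mass / distance^2 along the unit vector
    toward its center of mass; distances (mm) are clamped below at
    ``min_distance`` to bound the force near coincidence.
    """
    tip_sum = np.zeros(3)
    rear_sum = np.zeros(3)
    for pt, acc in ((electrode.tip_a, tip_sum), (electrode.rear, rear_sum)):
        for isl in islands:
            d = isl.com - pt
            dist = np.linalg.norm(d)
            if dist < _EPS:
                continue
            acc += (isl.mass / max(dist, min_distance) ** 2) * (d / dist)
    return tip_sum, rear_sum


def repulsive_force(e1: Electrode, e2: Electrode) -> np.ndarray:
    """Inverse-distance tip-tip repulsion; acts at tip 2, negated at tip 1."""
    dd = e2.tip_a - e1.tip_a
    dist = np.linalg.norm(dd)
    if dist < _EPS:
        raise ValueError("degenerate electrode pair: coincident tips")
    return (1.0 / dist) * (dd / dist)


def total_forces(
    f_geo,
    tip1,
    rear1,
    tip2,
    rear2,
    f_dd,
    config: OptimizerConfig,
) -> ForceSet:
    """Weighted force sums acting on the two electrodes."""
    f_geo = np.asarray(f_geo, float)
    f_dd = np.asarray(f_dd, float)
    f1 = config.w1 * f_geo + config.w2 * np.asarray(tip1) + config.w3 * np.asarray(rear1) - config.w4 * f_dd
    f2 = config.w1 * f_geo + config.w2 * np.asarray(tip2) + config.w3 * np.asarray(rear2) + config.w4 * f_dd
    if not (np.all(np.isfinite(f1)) and np.all(np.isfinite(f2))):
        raise ValueError("non-finite electrode force")
    return ForceSet(
        f_geo=f_geo,
        f_tip_sum_1=np.asarray(tip1, float),
        f_rear_sum_1=np.asarray(rear1, float),
        f_tip_sum_2=np.asarray(tip2, float),
        f_rear_sum_2=np.asarray(rear2, float),
        f_dd=f_dd,
        f_ele1=f1,
        f_ele2=f2,
    )


def apply_force(electrode: Electrode, force, config: OptimizerConfig) -> Electrode:
    """Move the tip by the force (mm), clipped to ``max_step``; entry fixed.

    The needle axis is re-derived through the fixed entry point, so the
    transpedicular constraint holds by construction.
    """
    force = np.asarray(force, dtype=float)
    if not np.all(np.isfinite(force)):
        raise ValueError("non-finite force")
    norm = np.linalg.norm(force)
    disp = force if norm <= config.max_step else force * (config.max_step / norm)
    new_tip = electrode.tip_a + disp
    if np.linalg.norm(new_tip - electrode.entry_a) < _EPS:
        raise ValueError("electrode tip would coincide with its entry point")
    return electrode.with_tip(new_tip)


def _round_to_step(value: float, step: float) -> float:
    return float(np.round(value / step) * step)


def voltage_from_geometry(
    e1: Electrode, e2: Electrode, ratio: float, config: OptimizerConfig
) -> float:
    """Voltage-to-distance rule: ratio (V/cm) x exposed-midpoint distance.

    Rounded to the generator's voltage step and clamped to its range; at the
    initialized positions both midpoints sit on the tumor center of mass, so
    a (near-)zero distance is legitimate and clamps to ``voltage_min``.
    """
    dist_cm = float(np.linalg.norm(e1.midpoint - e2.midpoint)) / 10.0
    U = _round_to_step(ratio * dist_cm, config.voltage_step)
    return float(np.clip(U, config.voltage_min, config.voltage_max))


def optimize(
    volume: LabelVolume,
    anchors: PedicleAnchors,
    tumor_com=None,
    laws: dict[int, ConductivityLaw] | None = None,
    config: OptimizerConfig | None = None,
    solver_config: SolverConfig | None = None,
) -> TreatmentPlan:
    """Run the full electrode-position and voltage optimization.

    ``tumor_com`` defaults to the weighted center of the volume's tumor
    voxels.  Deterministic for fixed inputs and ``config.seed`` (the seed
    feeds only the random recovery displacement after geometry errors).
    """
    laws = dict(TISSUE_LAWS) if laws is None else laws
    config = config or OptimizerConfig()
    solver_config = solver_config or SolverConfig()
    rng = np.random.default_rng(config.seed)
    log: list[str] = []
    history: list[dict] = []

    if tumor_com is None:
        idx = np.argwhere(volume.labels == 2)
        if idx.size == 0:
            raise ValueError("volume contains no tumor voxels")
        tumor_com = volume.index_to_world(idx).mean(axis=0)
    tumor_com = np.asarray(tumor_com, dtype=float)

    wmap = build_weight_map(volume, margin=config.margin, edge_weight=config.edge_weight)
    e1, e2 = initialize_electrodes(
        anchors, tumor_com, exposure_length=config.exposure_length,
        radius=config.electrode_radius,
    )
    ratio = config.voltage_to_distance
    U = voltage_from_geometry(e1, e2, ratio, config)
    log.append(f"initialized electrodes toward tumor CoM {np.round(tumor_com, 2).tolist()}")
    log.append(f"initial voltage {U:.0f} V (ratio {ratio:.0f} V/cm)")

    prev_cov: float | None = None
    prev_pair: tuple[Electrode, Electrode] | None = None
    prev_U: float | None = None
    sol: FieldSolution | None = None
    last_report = None
    termination = None
    it = 0
    cov_tol = config.coverage_tolerance / 100.0  # pp -> fraction

    while it < config.max_iterations and termination is None:
        it += 1
        solved = _solve_with_retry(
            volume, (e1, e2), U, laws, solver_config, rng, config, log, warm=sol
        )
        if solved is None:
            termination = "geometry_error"
            it -= 1
            break
        sol, (e1, e2) = solved
        report = soft_coverage(sol, wmap, volume, config.threshold)
        last_report = report
        entry = {
            "iteration": it,
            "voltage_V": U,
            "current_A": sol.current,
            "current_balance": abs(sol.current + sol.current_return)
            / max(abs(sol.current), 1e-30),
            "gtv_coverage": report.gtv_coverage,
            "ctv_soft_coverage": report.ctv_soft_coverage,
            "tips": [list(e1.tip), list(e2.tip)],
            "event": "accepted",
        }
        log.append(
            f"iteration {it}: U={U:.0f} V, I={sol.current:.2f} A, "
            f"GTV {100 * report.gtv_coverage:.1f}%, soft CTV "
            f"{100 * report.ctv_soft_coverage:.1f}%"
        )

        if report.ctv_soft_coverage >= 1.0 - _EPS:
            history.append(entry)
            termination = "full_coverage"
            break
        if sol.current > config.current_limit:
            history.append(entry)
            log.append(f"current limit exceeded ({sol.current:.1f} A)")
            termination = "max_current"
            break
        if prev_cov is not None and report.ctv_soft_coverage < prev_cov - _EPS:
            # revert the move, raise the voltage instead and keep the working
            # voltage-to-distance ratio at the raised value
            entry["event"] = "reverted"
            history.append(entry)
            e1, e2 = prev_pair  # type: ignore[misc]
            # boost relative to the amplitude of the reverted-to iteration
            base_U = max(U, prev_U if prev_U is not None else U)
            new_U = float(np.clip(
                _round_to_step(base_U * (1.0 + config.revert_boost_fraction), config.voltage_step),
                config.voltage_min,
                config.voltage_max,
            ))
            if new_U <= base_U + _EPS:
                log.append("coverage decreased at the voltage cap; terminating")
                termination = "max_voltage"
                break
            U = new_U
            dist_cm = float(np.linalg.norm(e1.midpoint - e2.midpoint)) / 10.0
            ratio = max(ratio, U / dist_cm)
            log.append(
                f"coverage decreased: reverted positions, voltage raised to "
                f"{U:.0f} V, ratio {ratio:.0f} V/cm"
            )
            continue
        history.append(entry)
        if prev_cov is not None and report.ctv_soft_coverage - prev_cov < cov_tol:
            termination = "tolerance"
            break
        prev_cov = report.ctv_soft_coverage
        prev_pair = (e1, e2)
        prev_U = U

        islands = find_islands(sol, wmap, volume, config.threshold, config.discard_fraction)
        f_geo = force_geo(e1, e2, tumor_com)
        t1, r1 = island_forces(e1, islands)
        t2, r2 = island_forces(e2, islands)
        f_dd = repulsive_force(e1, e2)
        forces = total_forces(f_geo, t1, r1, t2, r2, f_dd, config)
        try:
            e1 = apply_force(e1, forces.f_ele1, config)
            e2 = apply_force(e2, forces.f_ele2, config)
        except ValueError as exc:
            log.append(f"force application failed: {exc}")
            termination = "geometry_error"
            break
        U = voltage_from_geometry(e1, e2, ratio, config)

    if termination is None:
        termination = "max_iterations"

    # final ramp: raise the voltage in generator steps until full coverage
    if (
        last_report is not None
        and sol is not None
        and termination != "max_current"
        and last_report.ctv_soft_coverage < 1.0 - _EPS
    ):
        while U < config.voltage_max - _EPS:
            U_next = min(U + config.voltage_step, config.voltage_max)
            try:
                sol_next = solve_field(
                    volume, (e1, e2), U_next, laws, solver_config, warm_start=sol
                )
            except (ElectrodeGeometryError, RuntimeError) as exc:
                log.append(f"voltage ramp solve failed: {exc}")
                break
            report = soft_coverage(sol_next, wmap, volume, config.threshold)
            if sol_next.current > config.current_limit:
                log.append(
                    f"ramp to {U_next:.0f} V exceeds the current limit; keeping {U:.0f} V"
                )
                break
            sol, U, last_report = sol_next, U_next, report
            history.append({
                "iteration": it,
                "voltage_V": U,
                "current_A": sol.current,
                "current_balance": abs(sol.current + sol.current_return)
                / max(abs(sol.current), 1e-30),
                "gtv_coverage": report.gtv_coverage,
                "ctv_soft_coverage": report.ctv_soft_coverage,
                "tips": [list(e1.tip), list(e2.tip)],
                "event": "ramp",
            })
            log.append(
                f"voltage ramp: U={U:.0f} V, soft CTV "
                f"{100 * report.ctv_soft_coverage:.1f}%"
            )
            if report.ctv_soft_coverage >= 1.0 - _EPS:
                break

    log.append(f"terminated after {it} iterations: {termination}")
    return TreatmentPlan(
        electrodes=(e1, e2),
        applied_voltage=U,
        current=sol.current if sol is not None else 0.0,
        gtv_coverage=last_report.gtv_coverage if last_report is not None else 0.0,
        ctv_soft_coverage=last_report.ctv_soft_coverage if last_report is not None else 0.0,
        iterations=it,
        termination_reason=termination,
        history=history,
        log=log,
    )


def _solve_with_retry(volume, pair, U, laws, solver_config, rng, config, log, warm):
    """Solve the field, retrying once after a geometry error.

    On a rasterization/geometry failure both tips are displaced by
    ``error_displacement`` mm in independent uniformly random directions and
    the solve is retried once; a second failure returns None.
    """
    e1, e2 = pair
    for attempt in range(2):
        try:
            sol = solve_field(
                volume, (e1, e2), U, laws, solver_config, warm_start=warm
            )
            return sol, (e1, e2)
        except (ElectrodeGeometryError, ValueError) as exc:
            log.append(f"geometry error: {exc}")
            if attempt == 1:
                log.append("geometry error persists; terminating")
                return None
            moved = []
            for e in (e1, e2):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                try:
                    moved.append(e.with_tip(e.tip_a + config.error_displacement * v))
                except ValueError:
                    moved.append(e)
            e1, e2 = moved
            log.append(
                f"displaced tips by {config.error_displacement} mm in random directions"
            )
    return None
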