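"""Force arithmetic and the optimization loop."""

import dataclasses

import numpy as np
import pytest

from vertep import (
    Electrode,
    Island,
    OptimizerConfig,
    apply_force,
    force_geo,
    island_forces,
    optimize,
    repulsive_force,
    total_forces,
    voltage_from_geometry,
)
from vertep.volume import SURROUNDING, TUMOR, LabelVolume

from conftest import make_box_volume, straddle_anchors

CFG = OptimizerConfig()


def _island(mass, com):
    return Island(voxels=np.zeros((1, 3), dtype=int), mass=mass, com=np.asarray(com, float))


class TestForces:
    def test_force_geo_is_vector_to_tumor_com(self):
        e1 = Electrode(entry=(-5.0, -20.0, 0.0), tip=(-5.0, 0.0, 0.0))
        e2 = Electrode(entry=(5.0, -20.0, 0.0), tip=(5.0, 0.0, 0.0))
        # geometry center at (0, -10, 0)
        f = force_geo(e1, e2, (5.0, -10.0, 0.0))
        assert np.allclose(f, (5.0, 0.0, 0.0))
        assert np.allclose(force_geo(e1, e2, (0.0, -10.0, 0.0)), 0.0)

    def test_force_geo_translation_invariant(self):
        t = np.array([3.1, -2.7, 8.4])
        e1 = Electrode(entry=(-5.0, -20.0, 0.0), tip=(-5.0, 0.0, 0.0))
        e2 = Electrode(entry=(5.0, -20.0, 0.0), tip=(5.0, 0.0, 0.0))
        e1t = Electrode(entry=tuple(e1.entry_a + t), tip=tuple(e1.tip_a + t))
        e2t = Electrode(entry=tuple(e2.entry_a + t), tip=tuple(e2.tip_a + t))
        com = np.array([4.0, -7.0, 2.0])
        assert np.allclose(force_geo(e1, e2, com), force_geo(e1t, e2t, com + t))

    def test_island_force_inverse_square(self):
        e = Electrode(entry=(0.0, -30.0, 0.0), tip=(0.0, 0.0, 0.0))
        tip_sum, rear_sum = island_forces(e, [_island(100.0, (0.0, 10.0, 0.0))])
        assert np.allclose(tip_sum, (0.0, 1.0, 0.0))  # 100 / 10^2
        # rear at (0, -20, 0): distance 30
        assert np.allclose(rear_sum, (0.0, 100.0 / 900.0, 0.0))

    def test_island_force_symmetric_pair_cancels_at_tip(self):
        e = Electrode(entry=(0.0, -30.0, 0.0), tip=(0.0, 0.0, 0.0))
        islands = [_island(50.0, (10.0, 0.0, 0.0)), _island(50.0, (-10.0, 0.0, 0.0))]
        tip_sum, _ = island_forces(e, islands)
        assert np.allclose(tip_sum, 0.0, atol=1e-12)

    def test_island_distance_clamped_at_one_mm(self):
        e = Electrode(entry=(0.0, -30.0, 0.0), tip=(0.0, 0.0, 0.0))
        tip_sum, _ = island_forces(e, [_island(1.0, (0.0, 0.2, 0.0))])
        assert np.linalg.norm(tip_sum) == pytest.approx(1.0)  # 1 / max(0.2,1)^2

    def test_no_islands_zero_force(self):
        e = Electrode(entry=(0.0, -30.0, 0.0), tip=(0.0, 0.0, 0.0))
        tip_sum, rear_sum = island_forces(e, [])
        assert np.allclose(tip_sum, 0.0) and np.allclose(rear_sum, 0.0)

    def test_repulsion_inverse_distance_and_antisymmetric(self):
        e1 = Electrode(entry=(0.0, -30.0, 0.0), tip=(0.0, 0.0, 0.0))
        e2 = Electrode(entry=(10.0, -30.0, 0.0), tip=(10.0, 0.0, 0.0))
        f = repulsive_force(e1, e2)
        assert np.allclose(f, (0.1, 0.0, 0.0))
        assert np.allclose(repulsive_force(e2, e1), -f)

    def test_repulsion_unit_at_one_mm(self):
        e1 = Electrode(entry=(0.0, -30.0, 0.0), tip=(0.0, 0.0, 0.0))
        e2 = Electrode(entry=(1.0, -30.0, 0.0), tip=(1.0, 0.0, 0.0))
        assert np.linalg.norm(repulsive_force(e1, e2)) == pytest.approx(1.0)

    def test_total_forces_weighted_sum_and_signs(self):
        z = np.zeros(3)
        fs = total_forces((1.0, 0.0, 0.0), z, z, z, z, z, CFG)
        assert np.allclose(fs.f_ele1, (1.3, 0.0, 0.0))
        assert np.allclose(fs.f_ele2, (1.3, 0.0, 0.0))
        fs = total_forces(z, z, z, z, z, (0.1, 0.0, 0.0), CFG)
        assert np.allclose(fs.f_ele1, (-0.5, 0.0, 0.0))
        assert np.allclose(fs.f_ele2, (0.5, 0.0, 0.0))
        fs = total_forces(z, z, z, z, z, z, CFG)
        assert np.allclose(fs.f_ele1, 0.0) and np.allclose(fs.f_ele2, 0.0)


class TestApplyForce:
    def test_zero_force_identity(self):
        e = Electrode(entry=(0.0, -30.0, 0.0), tip=(0.0, 0.0, 0.0))
        assert apply_force(e, (0.0, 0.0, 0.0), CFG) == e

    def test_displacement_clipped_to_max_step(self):
        e = Electrode(entry=(0.0, -30.0, 0.0), tip=(0.0, 0.0, 0.0))
        cfg = dataclasses.replace(CFG, max_step=3.0)
        moved = apply_force(e, (10.0, 0.0, 0.0), cfg)
        assert np.allclose(moved.tip, (3.0, 0.0, 0.0))
        moved = apply_force(e, (8.0, 6.0, 0.0), CFG)  # norm 10 = default cap
        assert np.allclose(moved.tip, (8.0, 6.0, 0.0))

    def test_subcritical_force_applied_in_full(self):
        e = Electrode(entry=(0.0, -30.0, 0.0), tip=(0.0, 0.0, 0.0))
        moved = apply_force(e, (1.0, -2.0, 0.5), CFG)
        assert np.allclose(moved.tip, (1.0, -2.0, 0.5))

    def test_entry_stays_on_axis(self):
        e = Electrode(entry=(2.0, -30.0, 1.0), tip=(0.0, 0.0, 0.0))
        moved = apply_force(e, (2.5, 1.0, -0.7), CFG)
        assert moved.entry == e.entry
        # entry lies on the line through tip with direction tip->entry
        axis = moved.axis_to_entry
        rel = moved.entry_a - moved.tip_a
        assert np.linalg.norm(np.cross(rel, axis)) < 1e-9


class TestVoltageFromGeometry:
    def _pair(self, separation):
        e1 = Electrode(entry=(0.0, -30.0, 0.0), tip=(0.0, 0.0, 0.0))
        e2 = Electrode(entry=(separation, -30.0, 0.0), tip=(separation, 0.0, 0.0))
        return e1, e2

    def test_exact_multiple_passes_through(self):
        assert voltage_from_geometry(*self._pair(20.0), 1000.0, CFG) == 2000.0

    def test_rounding_to_generator_step(self):
        assert voltage_from_geometry(*self._pair(23.4), 1000.0, CFG) == 2300.0

    def test_clamped_to_generator_range(self):
        assert voltage_from_geometry(*self._pair(32.0), 1000.0, CFG) == 3000.0
        assert voltage_from_geometry(*self._pair(2.0), 1000.0, CFG) == 500.0


class TestOptimizeLoop:
    """End-to-end runs on small 2 mm phantoms (fast, same physics)."""

    @pytest.fixture(scope="class")
    def coarse_plan(self, coarse_phantom):
        vol, anchors, com = coarse_phantom
        plan = optimize(vol, anchors, com)
        return plan

    def test_terminates_with_full_coverage(self, coarse_plan):
        assert coarse_plan.termination_reason in {
            "full_coverage", "tolerance", "max_voltage"
        }
        assert coarse_plan.gtv_coverage == 1.0
        assert coarse_plan.ctv_soft_coverage == 1.0

    def test_entry_points_never_move(self, coarse_plan, coarse_phantom):
        _, anchors, _ = coarse_phantom
        e1, e2 = coarse_plan.electrodes
        assert e1.entry == tuple(anchors.left_entry)
        assert e2.entry == tuple(anchors.right_entry)

    def test_voltage_is_generator_compatible(self, coarse_plan):
        U = coarse_plan.applied_voltage
        assert 500.0 <= U <= 3000.0
        assert U % 100.0 == 0.0
        for h in coarse_plan.history:
            assert 500.0 <= h["voltage_V"] <= 3000.0
            assert h["voltage_V"] % 100.0 == 0.0

    def test_accepted_coverage_non_decreasing(self, coarse_plan):
        accepted = [
            h["ctv_soft_coverage"]
            for h in coarse_plan.history
            if h["event"] == "accepted"
        ]
        assert np.all(np.diff(accepted) >= -1e-12)

    def test_iteration_budget_respected(self, coarse_plan):
        assert coarse_plan.iterations <= CFG.max_iterations
        n_ramp = sum(1 for h in coarse_plan.history if h["event"] == "ramp")
        assert n_ramp <= (3000 - 500) / 100

    def test_deterministic_rerun(self, coarse_phantom, coarse_plan):
        vol, anchors, com = coarse_phantom
        again = optimize(vol, anchors, com)
        assert again.to_json() == coarse_plan.to_json()
        assert again.log == coarse_plan.log

    def test_oversized_tumor_saturates_voltage(self):
        """A tumor too large for two needles ends at the 3000 V cap."""
        vol, center = make_box_volume(shape=(50, 50, 50), spacing=2.0,
                                      tumor_radius=16.0)
        anchors = straddle_anchors(center, offset=10.0, depth=44.0)
        plan = optimize(vol, anchors, center)
        assert plan.applied_voltage == 3000.0
        assert plan.ctv_soft_coverage < 1.0
        assert plan.termination_reason in {"max_voltage", "tolerance", "max_iterations"}

    def test_tumor_shift_moves_converged_tips_same_direction(self):
        """Parameter recovery: lateral tumor shift drags the tips laterally.

        The tumor is large enough that the initial placement undertreats it,
        forcing iterations; the island and geometry forces must then pull the
        needles toward the displaced target.  (The optimizer is fully
        deterministic for fixed inputs, so a single run per shift is a valid
        sign test.)
        """
        shift = 6.0
        tips = []
        for dx in (0.0, shift):
            vol, center = make_box_volume(shape=(36, 36, 36), spacing=2.0,
                                          tumor_radius=9.0)
            labels = np.full(vol.shape, SURROUNDING, dtype=np.int16)
            ax = [2.0 * np.arange(n) for n in vol.shape]
            X, Y, Z = np.meshgrid(*ax, indexing="ij")
            com = center + np.array([dx, 0.0, 0.0])
            r2 = (X - com[0]) ** 2 + (Y - com[1]) ** 2 + (Z - com[2]) ** 2
            labels[r2 <= 81.0] = TUMOR
            vol2 = LabelVolume(labels=labels, spacing=vol.spacing, origin=vol.origin)
            anchors = straddle_anchors(center, offset=8.0, depth=34.0)
            plan = optimize(vol2, anchors, com)
            e1, e2 = plan.electrodes
            tips.append(0.5 * (e1.tip_a + e2.tip_a))
        assert tips[1][0] - tips[0][0] > 0.0

    def test_missing_tumor_rejected(self):
        labels = np.zeros((10, 10, 10), dtype=np.int16)
        vol = LabelVolume(labels=labels, spacing=(2.0, 2.0, 2.0))
        anchors = straddle_anchors((10.0, 10.0, 10.0), offset=4.0, depth=9.0)
        with pytest.raises(ValueError, match="no tumor"):
            optimize(vol, anchors)
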