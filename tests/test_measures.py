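"""Radiographic angle measures, contact statistics, curve invariants."""

import math

import numpy as np
import pytest

import footmech as fm
from footmech.measures import (
    AngleSet,
    ContactStats,
    LoadDisplacementCurve,
    MeasurementError,
    contact_statistics,
    correction_angles,
    deformity_angles,
    raw_angles,
    total_contact_force,
)


def _base_positions():
    """Minimal landmark set for angle measurement, axes aligned (zero pose)."""
    return {
        "tibia_shaft_distal": np.array([0.0, 0.0, 100.0]),
        "tibia_shaft_proximal": np.array([0.0, 0.0, 400.0]),
        "talus_posterior": np.array([0.0, 0.0, 50.0]),
        "talus_head_center": np.array([50.0, 0.0, 40.0]),
        "met1_base": np.array([60.0, 0.0, 38.0]),
        "met1_head": np.array([160.0, 0.0, 18.0]),
        "calcaneal_axis_inferior": np.array([-20.0, 0.0, 0.0]),
        "calcaneal_axis_superior": np.array([-20.0, 0.0, 40.0]),
    }


def _rot_y(deg):
    a = math.radians(deg)
    return np.array([[math.cos(a), 0, math.sin(a)], [0, 1, 0], [-math.sin(a), 0, math.cos(a)]])


def _rot_x(deg):
    a = math.radians(deg)
    return np.array([[1, 0, 0], [0, math.cos(a), -math.sin(a)], [0, math.sin(a), math.cos(a)]])


class TestRawAngles:
    def test_collinear_axes_measure_zero(self):
        pos = _base_positions()
        # make the metatarsal axis exactly parallel to the talar axis
        d = pos["talus_head_center"] - pos["talus_posterior"]
        pos["met1_head"] = pos["met1_base"] + 2.0 * d
        a = raw_angles(pos)
        assert a.meary_lateral == pytest.approx(0.0, abs=1e-9)
        assert a.meary_ap == pytest.approx(0.0, abs=1e-9)
        assert a.hindfoot_valgus == pytest.approx(0.0, abs=1e-9)

    def test_constructed_sagittal_rotation_measures_exactly(self):
        """Rotating the metatarsal axis 10 deg dorsally in the sagittal
        plane (the arch-collapse direction) raises the lateral Meary angle
        by exactly 10 deg."""
        pos = _base_positions()
        d = pos["talus_head_center"] - pos["talus_posterior"]
        pos["met1_head"] = pos["met1_base"] + 2.0 * d
        base = raw_angles(pos)
        pos["met1_head"] = pos["met1_base"] + 2.0 * (_rot_y(-10.0) @ d)
        rotated = raw_angles(pos)
        assert rotated.meary_lateral - base.meary_lateral == pytest.approx(10.0, abs=1e-6)

    def test_constructed_coronal_tilt_measures_exactly(self):
        """Tilting the calcaneal axis 5 deg into eversion (its top deviating
        medially, the valgus-deformity direction) reads exactly +5 deg with
        the tibial axis vertical."""
        pos = _base_positions()
        base = raw_angles(pos)
        v = pos["calcaneal_axis_superior"] - pos["calcaneal_axis_inferior"]
        pos["calcaneal_axis_superior"] = pos["calcaneal_axis_inferior"] + _rot_x(-5.0) @ v
        tilted = raw_angles(pos)
        assert tilted.hindfoot_valgus - base.hindfoot_valgus == pytest.approx(5.0, abs=1e-6)

    def test_invariant_under_global_rigid_transform(self):
        rng = np.random.default_rng(5)
        pos = _base_positions()
        base = raw_angles(pos)
        for _ in range(10):
            phi = rng.normal(0, 0.5, 3)
            from footmech.solver import rotation_matrix

            R = rotation_matrix(phi)
            t = rng.normal(0, 50.0, 3)
            moved = {k: R @ v + t for k, v in pos.items()}
            a = raw_angles(moved)
            assert a.meary_lateral == pytest.approx(base.meary_lateral, abs=1e-6)
            assert a.meary_ap == pytest.approx(base.meary_ap, abs=1e-6)
            assert a.hindfoot_valgus == pytest.approx(base.hindfoot_valgus, abs=1e-6)

    def test_missing_landmark_named_in_error(self):
        pos = _base_positions()
        del pos["talus_posterior"]
        with pytest.raises(MeasurementError, match="talus_posterior"):
            raw_angles(pos)


class TestDeformityAndCorrection:
    def test_self_reference_is_zero(self, intact_result):
        d = deformity_angles(intact_result, intact_result)
        assert d.as_tuple() == (0.0, 0.0, 0.0)

    def test_antisymmetry(self, intact_result, flatfoot_result):
        d1 = deformity_angles(flatfoot_result, intact_result)
        d2 = deformity_angles(intact_result, flatfoot_result)
        assert d1.meary_lateral == pytest.approx(-d2.meary_lateral, abs=1e-12)
        assert d1.hindfoot_valgus == pytest.approx(-d2.hindfoot_valgus, abs=1e-12)

    def test_flatfoot_deformity_positive_in_all_three(self, intact_result, flatfoot_result):
        """Attenuation produces dorsiflexion, abduction and valgus deformity."""
        d = deformity_angles(flatfoot_result, intact_result)
        assert d.meary_lateral > 0
        assert d.meary_ap > 0
        assert d.hindfoot_valgus > 0

    def test_correction_of_flatfoot_by_itself_is_zero(self, intact_result, flatfoot_result):
        c = correction_angles(flatfoot_result, flatfoot_result, intact_result)
        assert c.as_tuple() == (0.0, 0.0, 0.0)

    def test_geometry_mismatch_rejected(self, intact_result):
        other = fm.build_intact_model(
            fm.generate_foot_geometry(fm.GeometryParams(random_seed=9, perturbation_sd=0.5))
        )
        res_other = other.with_load(0.0).fit(
            settings=fm.SolverSettings(ramp_steps=1, max_iterations=1, residual_tol=1e9)
        )
        with pytest.raises(MeasurementError):
            deformity_angles(res_other, intact_result)


class TestContactStatistics:
    def test_uniform_field_hand_oracle(self, intact_result):
        """Constructed pressure fields reproduce the area-weighted mean."""
        res = intact_result
        # overwrite one patch with a constructed field
        import copy

        res2 = copy.copy(res)
        res2.contact_pressures = dict(res.contact_pressures)
        patch = next(
            p.patch for p in res.model.contact_pairs if p.patch.joint == "talonavicular"
        )
        uniform = np.full(len(patch.areas), 2.0)
        res2.contact_pressures[patch.name] = uniform
        for p in res.model.contact_pairs:
            if p.patch.joint == "talonavicular" and p.patch.name != patch.name:
                res2.contact_pressures[p.patch.name] = np.zeros(len(p.patch.areas))
        st = contact_statistics(res2, "talonavicular")
        assert st.mean_pressure == pytest.approx(2.0)
        assert st.peak_pressure == pytest.approx(2.0)
        assert st.area == pytest.approx(patch.total_area)

    def test_two_point_hand_arithmetic(self):
        """1 MPa on 10 mm^2 plus 3 MPa on 10 mm^2: mean 2, peak 3, area 20."""
        p = np.array([1.0, 3.0])
        a = np.array([10.0, 10.0])
        mean = float((p * a).sum() / a.sum())
        st = ContactStats(mean_pressure=mean, peak_pressure=float(p.max()), area=float(a.sum()))
        assert st.mean_pressure == pytest.approx(2.0)
        assert st.peak_pressure == pytest.approx(3.0)
        assert st.area == pytest.approx(20.0)

    def test_separated_joint_reports_zeros(self, intact_result):
        import copy

        res2 = copy.copy(intact_result)
        res2.contact_pressures = {
            k: np.zeros_like(v) for k, v in intact_result.contact_pressures.items()
        }
        st = contact_statistics(res2, "calcaneocuboid")
        assert (st.mean_pressure, st.peak_pressure, st.area) == (0.0, 0.0, 0.0)

    def test_unknown_joint_rejected(self, intact_result):
        with pytest.raises(MeasurementError, match="unknown joint"):
            contact_statistics(intact_result, "knee")

    def test_loaded_joints_carry_pressure(self, intact_result):
        for joint in ("tibiotalar", "subtalar", "talonavicular", "ground"):
            st = contact_statistics(intact_result, joint)
            assert st.peak_pressure >= st.mean_pressure >= 0.0
            assert total_contact_force(intact_result, joint) > 0.0

    def test_ground_reaction_matches_axial_load(self, intact_result):
        """Vertical equilibrium: the ground carries the full axial load."""
        f = total_contact_force(intact_result, "ground")
        assert f == pytest.approx(680.0, rel=0.01)


class TestCurveInvariants:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(MeasurementError):
            LoadDisplacementCurve((0.0, 100.0), (0.0,))

    def test_decreasing_drop_rejected(self):
        with pytest.raises(MeasurementError):
            LoadDisplacementCurve((0.0, 100.0, 200.0), (0.0, 2.0, 1.0))

    def test_incremental_compliance(self):
        c = LoadDisplacementCurve((0.0, 100.0, 200.0), (0.0, 2.0, 3.0))
        assert np.allclose(c.incremental_compliance(), [0.02, 0.01])
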