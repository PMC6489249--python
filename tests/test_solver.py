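"""Statics solver: closed-form toy systems, gradient oracle, solve contract."""

import numpy as np
import pytest

import footmech as fm
from footmech import constitutive as law
from footmech.assembly import (
    ContactPair,
    FootModel,
    FoundationLaw,
    LineElement,
    LoadCase,
    RoutePoint,
    Segment,
)
from footmech.geometry import ContactPatchDef, FootGeometry, GeometryParams, Surface
from footmech.solver import (
    SolverSettings,
    build_pose,
    energy_and_gradient,
    potential_energy,
    residual_norm,
    rotation_matrix,
    left_jacobian,
    segment_loads,
    solve_equilibrium,
)


def _empty_geometry():
    return FootGeometry(
        params=GeometryParams(),
        landmarks={},
        segments={},
        ligament_sites={},
        contact_patches=(),
        ground_plane=(np.zeros(3), np.array([0.0, 0.0, 1.0])),
    )


def _toy_block_on_spring(k=100.0, load=500.0, slack=100.0):
    """A block hanging below a fixed anchor on a vertical linear spring."""
    segments = {
        "anchor": Segment("anchor", np.array([0.0, 0.0, slack]), (False,) * 6),
        "block": Segment("block", np.zeros(3), (False, False, True, False, False, False)),
    }
    spec = law.LigamentSpec("spring", law.LinearLawParams(k), in_situ_strain=0.0)
    el = LineElement(
        "spring",
        "ligament",
        spec,
        (RoutePoint("anchor", np.zeros(3)), RoutePoint("block", np.zeros(3))),
        slack_length=slack,
    )
    return FootModel(
        geometry=_empty_geometry(),
        segments=segments,
        elements=(el,),
        contact_pairs=(),
        load_case=LoadCase(axial_load=load, segment="block"),
        scenario="intact",
    )


def _toy_block_on_foundation(k_f=5.0, area=100.0, load=400.0):
    """A block resting on a rigid ground through a linear foundation."""
    segments = {
        "block": Segment("block", np.array([0.0, 0.0, 10.0]),
                         (False, False, True, False, False, False)),
    }
    patch = ContactPatchDef(
        joint="ground",
        name="pad",
        point_segment="block",
        surface_segment="ground",
        surface=Surface("plane", np.zeros(3), np.array([0.0, 0.0, 1.0])),
        points=np.array([[0.0, 0.0, 0.0]]),
        areas=np.array([area]),
        normals=np.array([[0.0, 0.0, 1.0]]),
        foundation="ground",
    )
    pair = ContactPair(
        "ground", patch, FoundationLaw("linear", stiffness=k_f, reg=1e-9)
    )
    return FootModel(
        geometry=_empty_geometry(),
        segments=segments,
        elements=(),
        contact_pairs=(pair,),
        load_case=LoadCase(axial_load=load, segment="block"),
        scenario="intact",
    )


class TestRotations:
    def test_rotation_matrix_orthonormal(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            phi = rng.normal(0, 1, 3)
            R = rotation_matrix(phi)
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_left_jacobian_matches_finite_difference(self):
        """Jl maps d(phi) to the spatial rotation increment."""
        rng = np.random.default_rng(2)
        h = 1e-7
        for _ in range(10):
            phi = rng.normal(0, 0.8, 3)
            J = left_jacobian(phi)
            for k in range(3):
                dphi = np.zeros(3)
                dphi[k] = h
                dR = rotation_matrix(phi + dphi) @ rotation_matrix(phi).T
                omega = np.array([dR[2, 1] - dR[1, 2], dR[0, 2] - dR[2, 0],
                                  dR[1, 0] - dR[0, 1]]) / 2.0
                assert np.allclose(omega / h, J[:, k], atol=1e-5)


class TestToyOracles:
    def test_block_on_spring_closed_form(self):
        """Vertical spring k=100 N/mm under 500 N stretches exactly 5 mm."""
        model = _toy_block_on_spring(k=100.0, load=500.0)
        res = solve_equilibrium(model)
        assert res.converged
        drop = -res.pose[0]
        assert drop == pytest.approx(5.0, rel=1e-6)
        assert res.element_forces["spring"] == pytest.approx(500.0, rel=1e-6)

    def test_block_on_foundation_closed_form(self):
        """Penetration solves k_f * A * delta = load."""
        k_f, area, load = 5.0, 100.0, 400.0
        model = _toy_block_on_foundation(k_f, area, load)
        res = solve_equilibrium(model)
        assert res.converged
        penetration = -res.pose[0]
        assert penetration == pytest.approx(load / (k_f * area), rel=1e-6)

    def test_spring_energy_quadratic(self):
        """A linear element stretched 1 mm at k=100 stores 50 N mm."""
        model = _toy_block_on_spring(k=100.0, load=0.0)
        x = np.array([-1.0])  # block down 1 mm stretches the spring 1 mm
        assert potential_energy(model, x) == pytest.approx(50.0, rel=1e-12)

    def test_unloaded_zero_strain_energy_is_zero(self):
        model = _toy_block_on_spring(k=100.0, load=0.0)
        assert potential_energy(model, np.zeros(1)) == pytest.approx(0.0, abs=1e-12)


class TestGradient:
    def test_analytic_gradient_matches_central_differences(self, intact_model):
        """>= 20 random poses; relative error < 1e-5 against the FD oracle."""
        rng = np.random.default_rng(2024)
        x0 = build_pose(intact_model)
        h = 1e-6
        checked = 0
        while checked < 20:
            x = x0 + rng.normal(0.0, 0.3, x0.shape)
            V, g = energy_and_gradient(intact_model, x)
            g_fd = np.empty_like(g)
            for k in range(len(x)):
                xp = x.copy()
                xp[k] += h
                xm = x.copy()
                xm[k] -= h
                g_fd[k] = (potential_energy(intact_model, xp)
                           - potential_energy(intact_model, xm)) / (2 * h)
            err = np.linalg.norm(g - g_fd) / max(1.0, np.linalg.norm(g))
            assert err < 1e-5
            checked += 1


class TestSolveContract:
    def test_intact_foot_converges_and_is_deterministic(self, intact_result, intact_model):
        assert intact_result.converged
        assert intact_result.residual_norm <= 1e-3
        # bit-identical repeat from the same warm start
        again = solve_equilibrium(intact_model.with_load(680.0), start=intact_result.pose)
        assert np.array_equal(again.pose, intact_result.pose)

    def test_energy_history_non_increasing(self, intact_result):
        e = intact_result.energy_history
        assert len(e) >= 2
        assert np.all(np.diff(e) <= 1e-9 * np.maximum(1.0, np.abs(e[:-1])))

    def test_force_and_torque_balance_independent_of_optimizer(self, intact_result):
        """Net force (N) and torque (N mm / 100 mm) on every free segment
        vanish at convergence, assembled from the physical loads."""
        model = intact_result.model
        loads = segment_loads(model, intact_result.pose)
        for seg in model.segments.values():
            f, tau = loads[seg.name]
            for k in range(3):
                if seg.free_dofs[k]:
                    assert abs(f[k]) <= 1e-3
                if seg.free_dofs[3 + k]:
                    assert abs(tau[k]) / 100.0 <= 1e-3

    def test_element_forces_nonnegative(self, intact_result):
        assert all(f >= 0.0 for f in intact_result.element_forces.values())

    def test_contact_pressures_nonnegative_and_normal(self, intact_result):
        details = intact_result.contact_details()
        for name, d in details.items():
            assert np.all(d["pressure"] >= 0.0)
            # frictionless: force vectors parallel to the outward directions
            f = d["force"]
            n = d["direction"]
            tangential = f - (np.sum(f * n, axis=1))[:, None] * n
            assert np.allclose(tangential, 0.0, atol=1e-12)

    def test_nonconvergence_reports_diagnostics(self, intact_model):
        starved = SolverSettings(max_iterations=1, ramp_steps=1, residual_tol=1e-12)
        res = solve_equilibrium(intact_model.with_load(680.0), settings=starved)
        assert not res.converged
        assert res.message
        assert res.residual_norm > 0
        assert len(res.residual_history) >= 1

    def test_rejects_bad_start_shape(self, intact_model):
        with pytest.raises(ValueError):
            solve_equilibrium(intact_model, start=np.zeros(3))

    def test_summary_mentions_scenario_and_convergence(self, intact_result):
        text = intact_result.summary()
        assert "intact" in text
        assert "converged" in text
        assert "talonavicular" in text


class TestJitterRobustness:
    def test_assembly_and_solve_succeed_across_jittered_geometries(self):
        """Smoke property: with 0.5 mm landmark jitter the intact model
        assembles and reaches a loaded equilibrium for ten seeds (engineering
        smoke tolerance 0.05 N, bounded iteration budget)."""
        settings = SolverSettings(residual_tol=0.05, max_iterations=80)
        for seed in range(1, 11):
            params = fm.GeometryParams(random_seed=seed, perturbation_sd=0.5)
            geometry = fm.generate_foot_geometry(params)
            model = fm.build_intact_model(geometry).with_load(680.0)
            res = model.fit(settings=settings)
            assert res.converged, f"seed {seed}: residual {res.residual_norm:.3e}"
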