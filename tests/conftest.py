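"""Shared fixtures.

Equilibrium solves are the expensive operations, so the standard study
(default geometry, 680 N: intact, flatfoot, four reconstructions) is solved
once per session and shared.
"""

import numpy as np
import pytest

import footmech as fm
from footmech.config import ScenarioConfig
from footmech.pipeline import ScenarioResult, run_scenario_study


@pytest.fixture(scope="session")
def default_geometry():
    return fm.generate_foot_geometry()


@pytest.fixture(scope="session")
def intact_model(default_geometry):
    return fm.build_intact_model(default_geometry)


@pytest.fixture(scope="session")
def study_results():
    """name -> ScenarioResult for flatfoot and the four reconstructions.

    All share one geometry; the intact and flatfoot solves are reused.
    """
    results: dict[str, ScenarioResult] = {}
    base = run_scenario_study(ScenarioConfig())  # flatfoot, no reconstruction
    results["flatfoot"] = base
    for method in ("ISLR", "ASLR", "CSILR", "CSPLR"):
        cfg = ScenarioConfig(reconstruction=method)
        from footmech.assembly import add_reconstruction, apply_flatfoot, build_intact_model

        intact_model = build_intact_model(
            base.geometry, options=cfg.model_options()
        ).with_load(cfg.load)
        model_r = add_reconstruction(
            apply_flatfoot(intact_model, factor=cfg.attenuation_factor),
            method,
            reference_positions=base.intact.landmark_positions(),
        )
        recon = model_r.fit(start=base.flatfoot.pose, settings=cfg.solver_settings())
        results[method] = ScenarioResult(
            config=cfg,
            geometry=base.geometry,
            intact=base.intact,
            flatfoot=base.flatfoot,
            reconstructed=recon,
        )
    return results


@pytest.fixture(scope="session")
def validation_curve(intact_model):
    """Axial-load sweep 0..600 N on the intact default model."""
    from footmech.measures import load_displacement_protocol

    return load_displacement_protocol(intact_model)


@pytest.fixture(scope="session")
def attenuation_sweep(study_results):
    """Deformity angles over attenuation factors 1.0, 0.9, ..., 0.5 on the
    default model, warm-started along the disease-progression path."""
    from footmech.assembly import apply_flatfoot, build_intact_model
    from footmech.measures import AngleSet, deformity_angles
    from footmech.solver import SolverSettings

    base = study_results["flatfoot"]
    intact = base.intact
    intact_model = base.intact.model
    factors = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)
    angles = [AngleSet(0.0, 0.0, 0.0)]
    pose = intact.pose
    for f in factors[1:]:
        model_f = apply_flatfoot(
            fm.build_intact_model(base.geometry, options=base.config.model_options()).with_load(
                base.config.load
            ),
            factor=f,
        )
        res = model_f.fit(start=pose, settings=base.config.solver_settings())
        assert res.converged, f"attenuation {f} did not converge: {res.message}"
        pose = res.pose
        angles.append(deformity_angles(res, intact))
    return factors, angles


@pytest.fixture(scope="session")
def seed_studies():
    """Per-seed convergence flags and correction angles for all four
    reconstructions across jittered geometry seeds (1 mm landmark jitter).

    Uses a bounded iteration budget so non-convergent cases fail fast; the
    tests assert on the recorded outcomes.
    """
    from footmech.assembly import add_reconstruction, apply_flatfoot, build_intact_model
    from footmech.config import GeometryConfig
    from footmech.pipeline import solve_flatfoot_from_intact
    from footmech.measures import correction_angles
    from footmech.solver import SolverSettings

    settings = SolverSettings(max_iterations=80)
    out = {}
    for seed in (1, 2, 3, 4, 5):
        cfg = ScenarioConfig(geometry=GeometryConfig(random_seed=seed, perturbation_sd=1.0))
        geometry = fm.generate_foot_geometry(cfg.geometry_params())
        intact_model = fm.build_intact_model(geometry, options=cfg.model_options()).with_load(
            cfg.load
        )
        intact = intact_model.fit(settings=settings)
        flat = solve_flatfoot_from_intact(intact_model, intact, settings=settings)
        entry = {
            "intact_converged": intact.converged,
            "flatfoot_converged": flat.converged,
            "converged": {},
            "corr": {},
        }
        for method in ("ISLR", "ASLR", "CSILR", "CSPLR"):
            model_r = add_reconstruction(
                apply_flatfoot(intact_model, factor=cfg.attenuation_factor),
                method,
                reference_positions=intact.landmark_positions(),
            )
            recon = model_r.fit(start=flat.pose, settings=settings)
            entry["converged"][method] = recon.converged
            entry["corr"][method] = correction_angles(flat, recon, intact)
        out[seed] = entry
    return out


@pytest.fixture(scope="session")
def intact_result(study_results):
    return study_results["flatfoot"].intact


@pytest.fixture(scope="session")
def flatfoot_result(study_results):
    return study_results["flatfoot"].flatfoot
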