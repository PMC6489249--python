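"""End-to-end scenario pipeline: geometry -> model -> solve -> measures -> files.

Every scenario run solves the intact model on the same geometry first (the
intact condition defines angle zero), then the flatfoot and, if requested,
the reconstructed condition.  The flatfoot solve is warm-started from the
intact equilibrium through a short attenuation continuation (the disease
progression path), which keeps the solver on the physical branch; the
reconstructed solve is warm-started from the flatfoot equilibrium.
"""

from __future__ import annotations

import csv
import json
import pathlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np  # noqa: F401

from . import measures
from .assembly import FootModel, add_reconstruction, apply_flatfoot, build_intact_model
from .config import ScenarioConfig
from .geometry import FootGeometry, generate_foot_geometry
from .measures import AngleSet, ContactStats, LoadDisplacementCurve
from .solver import EquilibriumResult, SolverSettings

__all__ = ["ScenarioResult", "run_scenario_study", "run_scenario", "run_validation_curve",
           "ATTENUATION_CONTINUATION"]

#: Intermediate attenuation factors used to walk from the intact model to a
#: strongly attenuated flatfoot model at constant load.
ATTENUATION_CONTINUATION: tuple[float, ...] = (0.85, 0.7, 0.6)


@dataclass
class ScenarioResult:
    """Solved conditions of one scenario plus derived measures."""

    config: ScenarioConfig
    geometry: FootGeometry
    intact: EquilibriumResult
    flatfoot: EquilibriumResult | None = None
    reconstructed: EquilibriumResult | None = None

    @property
    def final(self) -> EquilibriumResult:
        return self.reconstructed or self.flatfoot or self.intact

    def deformity(self) -> AngleSet:
        return measures.deformity_angles(self.final, self.intact)

    def correction(self) -> AngleSet | None:
        if self.reconstructed is None or self.flatfoot is None:
            return None
        return measures.correction_angles(self.flatfoot, self.reconstructed, self.intact)

    # -- reporting ----------------------------------------------------------

    def report_rows(self) -> list[dict]:
        rows = []
        for name, res in (
            ("intact", self.intact),
            ("flatfoot", self.flatfoot),
            (self.config.reconstruction, self.reconstructed),
        ):
            if res is None or name == "none":
                continue
            angles = measures.deformity_angles(res, self.intact)
            tn = measures.contact_statistics(res, "talonavicular")
            cc = measures.contact_statistics(res, "calcaneocuboid")
            row = {
                "scenario": name,
                "meary_lateral_deg": round(angles.meary_lateral, 1),
                "meary_ap_deg": round(angles.meary_ap, 1),
                "hindfoot_valgus_deg": round(angles.hindfoot_valgus, 1),
                "talonavicular_mean_mpa": round(tn.mean_pressure, 3),
                "talonavicular_peak_mpa": round(tn.peak_pressure, 3),
                "talonavicular_area_mm2": round(tn.area, 1),
                "calcaneocuboid_mean_mpa": round(cc.mean_pressure, 3),
                "calcaneocuboid_peak_mpa": round(cc.peak_pressure, 3),
                "calcaneocuboid_area_mm2": round(cc.area, 1),
                "converged": res.converged,
                "residual_N": f"{res.residual_norm:.3e}",
            }
            corr = self.correction()
            if corr is not None and name == self.config.reconstruction:
                row["correction_ap_deg"] = round(corr.meary_ap, 1)
                row["correction_lateral_deg"] = round(corr.meary_lateral, 1)
                row["correction_valgus_deg"] = round(corr.hindfoot_valgus, 1)
            rows.append(row)
        return rows

    def to_json_dict(self) -> dict:
        out = {"config": self.config.model_dump(), "conditions": {}}
        for name, res in (
            ("intact", self.intact),
            ("flatfoot", self.flatfoot),
            ("reconstructed", self.reconstructed),
        ):
            if res is None:
                continue
            angles = measures.deformity_angles(res, self.intact)
            out["conditions"][name] = {
                "converged": res.converged,
                "residual_N": res.residual_norm,
                "energy_Nmm": res.energy,
                "deformity_deg": {
                    "meary_lateral": angles.meary_lateral,
                    "meary_ap": angles.meary_ap,
                    "hindfoot_valgus": angles.hindfoot_valgus,
                },
                "element_forces_N": res.element_forces,
            }
        corr = self.correction()
        if corr is not None:
            out["correction_deg"] = {
                "meary_lateral": corr.meary_lateral,
                "meary_ap": corr.meary_ap,
                "hindfoot_valgus": corr.hindfoot_valgus,
            }
        return out


def solve_flatfoot_from_intact(
    intact_model: FootModel,
    intact_result: EquilibriumResult,
    factor: float = 0.5,
    settings: SolverSettings | None = None,
    continuation: Sequence[float] = ATTENUATION_CONTINUATION,
) -> EquilibriumResult:
    """Solve the attenuated model, warm-started along the attenuation path."""
    pose = intact_result.pose
    result = intact_result
    steps = [f for f in continuation if f > factor] + [factor]
    for f in steps:
        model_f = apply_flatfoot(intact_model, factor=f)
        result = model_f.fit(start=pose, settings=settings)
        pose = result.pose
    return result


#: Graft-modulus continuation fractions: the reconstruction is brought to
#: full stiffness in warm-started steps (tensioning progression), keeping
#: the solve on the physical branch.
GRAFT_CONTINUATION: tuple[float, ...] = (0.1, 0.3, 1.0)


def solve_reconstruction_from_flatfoot(
    intact_model: FootModel,
    intact_result: EquilibriumResult,
    flatfoot_result: EquilibriumResult,
    method,
    factor: float = 0.5,
    settings: SolverSettings | None = None,
    continuation: Sequence[float] = GRAFT_CONTINUATION,
) -> EquilibriumResult:
    """Solve the reconstructed condition, ramping the graft modulus.

    Graft slack lengths are referenced to the intact loaded equilibrium;
    the elastic modulus is scaled up in warm-started increments from the
    flatfoot pose so the stiff graft does not throw the iterate off the
    physical equilibrium branch.
    """
    from .constitutive import GraftParams

    refs = intact_result.landmark_positions()
    flat_model = apply_flatfoot(intact_model, factor=factor)
    pose = flatfoot_result.pose
    result = flatfoot_result
    base = GraftParams()
    for frac in continuation:
        graft = GraftParams(elastic_modulus=base.elastic_modulus * frac, area=base.area)
        model_r = add_reconstruction(flat_model, method, graft=graft, reference_positions=refs)
        result = model_r.fit(start=pose, settings=settings)
        pose = result.pose
    return result


def run_scenario_study(config: ScenarioConfig) -> ScenarioResult:
    """Generate geometry, build and solve every condition the scenario needs."""
    geometry = generate_foot_geometry(config.geometry_params())
    options = config.model_options()
    settings = config.solver_settings()

    intact_model = build_intact_model(geometry, options=options)
    intact_model = intact_model.with_load(config.load)
    intact = intact_model.fit(settings=settings)

    result = ScenarioResult(config=config, geometry=geometry, intact=intact)
    if config.condition == "intact":
        return result

    flat = solve_flatfoot_from_intact(
        intact_model, intact, factor=config.attenuation_factor, settings=settings
    )
    result.flatfoot = flat

    if config.reconstruction != "none":
        result.reconstructed = solve_reconstruction_from_flatfoot(
            intact_model,
            intact,
            flat,
            config.reconstruction,
            factor=config.attenuation_factor,
            settings=settings,
        )
    return result


def _write_csv(path: pathlib.Path, rows: list[dict]) -> None:
    keys: list[str] = []
    for row in rows:
        for k in row:
            if k not in keys:
                keys.append(k)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(rows)


def _write_convergence_log(path: pathlib.Path, result: EquilibriumResult) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "energy_Nmm", "residual_N"])
        n = max(len(result.energy_history), len(result.residual_history))
        for i in range(n):
            e = f"{result.energy_history[i]:.10g}" if i < len(result.energy_history) else ""
            r = f"{result.residual_history[i]:.10g}" if i < len(result.residual_history) else ""
            writer.writerow([i, e, r])


def run_scenario(config: ScenarioConfig) -> tuple[ScenarioResult, list[pathlib.Path]]:
    """Run a scenario and write report.csv, report.json and convergence logs.

    Returns the ScenarioResult and the written paths.  Callers should treat
    a non-converged final condition as a failure (the CLI exits nonzero).
    """
    result = run_scenario_study(config)
    outdir = pathlib.Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    report_csv = outdir / "report.csv"
    _write_csv(report_csv, result.report_rows())
    paths.append(report_csv)

    report_json = outdir / "report.json"
    with open(report_json, "w") as fh:
        json.dump(result.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths.append(report_json)

    log = outdir / "convergence.csv"
    _write_convergence_log(log, result.final)
    paths.append(log)
    return result, paths


def run_validation_curve(
    config: ScenarioConfig, loads: Sequence[float] = measures.VALIDATION_LOADS
) -> tuple[LoadDisplacementCurve, pathlib.Path]:
    """Axial-loading navicular-drop protocol on the intact model; writes CSV."""
    geometry = generate_foot_geometry(config.geometry_params())
    model = build_intact_model(geometry, options=config.model_options())
    curve = measures.load_displacement_protocol(
        model, loads=loads, settings=config.solver_settings()
    )
    outdir = pathlib.Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "validation_curve.csv"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["load_N", "navicular_drop_mm"])
        for w, d in zip(curve.loads, curve.navicular_drop):
            writer.writerow([f"{w:.10g}", f"{d:.10g}"])
    return curve, path
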