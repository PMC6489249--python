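"""Outcome measures: radiographic angles, navicular load-displacement, and
joint contact statistics.

Angles replicate the clinical radiographic views with deterministic landmark
surrogates.  A measurement frame is built from the current pose (vertical
axis from the tibial shaft, anterior axis from the first metatarsal), so all
angle measures are exactly invariant to rigid transforms of the whole pose:

* lateral Meary's angle — talar long axis vs first-metatarsal axis in the
  sagittal projection (positive = talonavicular dorsiflexion deformity,
  i.e. arch collapse);
* AP Meary's angle — the same axes in the transverse projection (positive =
  talonavicular abduction deformity);
* hindfoot (tibiocalcaneal) valgus — tibial vs calcaneal axes in the
  coronal projection (positive = valgus).

All deformity angles are reported relative to the solved intact condition,
which defines zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .assembly import FootModel
from .solver import EquilibriumResult, SolverSettings

__all__ = [
    "AngleSet",
    "ContactStats",
    "LoadDisplacementCurve",
    "MeasurementError",
    "ProtocolError",
    "raw_angles",
    "deformity_angles",
    "correction_angles",
    "load_displacement_protocol",
    "contact_statistics",
    "total_contact_force",
    "VALIDATION_LOADS",
]

#: Axial loads (N) of the validation protocol: 0 to 600 N in 100-N steps.
VALIDATION_LOADS: tuple[float, ...] = (0.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0)


class MeasurementError(ValueError):
    """A measure could not be computed (missing landmark, joint, mismatch)."""


class ProtocolError(RuntimeError):
    """A multi-solve protocol failed part-way; carries partial results."""

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class AngleSet:
    """Radiographic angle triple in degrees (deformity-positive signs)."""

    meary_lateral: float
    meary_ap: float
    hindfoot_valgus: float

    def __sub__(self, other: "AngleSet") -> "AngleSet":
        return AngleSet(
            self.meary_lateral - other.meary_lateral,
            self.meary_ap - other.meary_ap,
            self.hindfoot_valgus - other.hindfoot_valgus,
        )

    def __neg__(self) -> "AngleSet":
        return AngleSet(-self.meary_lateral, -self.meary_ap, -self.hindfoot_valgus)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.meary_lateral, self.meary_ap, self.hindfoot_valgus)


@dataclass(frozen=True)
class ContactStats:
    """Area-weighted contact pressure statistics over a joint (MPa, mm^2)."""

    mean_pressure: float
    peak_pressure: float
    area: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_pressure <= self.peak_pressure + 1e-12):
            raise MeasurementError("contact stats require 0 <= mean <= peak")
        if self.area < 0:
            raise MeasurementError("contact area must be >= 0")


@dataclass(frozen=True)
class LoadDisplacementCurve:
    """Vertical navicular-tuberosity drop (mm) versus axial load (N)."""

    loads: tuple[float, ...]
    navicular_drop: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.loads) != len(self.navicular_drop):
            raise MeasurementError("loads and drops must have equal length")
        drops = np.asarray(self.navicular_drop)
        if np.any(np.diff(drops) < -1e-6):
            raise MeasurementError("navicular drop must be non-decreasing with load")

    def incremental_compliance(self) -> np.ndarray:
        """Drop increment per load increment (mm/N) between steps."""
        loads = np.asarray(self.loads)
        drops = np.asarray(self.navicular_drop)
        return np.diff(drops) / np.diff(loads)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"load_N": self.loads, "navicular_drop_mm": self.navicular_drop})


_ANGLE_LANDMARKS = (
    "talus_head_center",
    "talus_posterior",
    "met1_base",
    "met1_head",
    "tibia_shaft_proximal",
    "tibia_shaft_distal",
    "calcaneal_axis_superior",
    "calcaneal_axis_inferior",
)


def _positions(pose) -> Mapping[str, np.ndarray]:
    if isinstance(pose, EquilibriumResult):
        return pose.landmark_positions()
    if isinstance(pose, Mapping):
        return pose
    raise MeasurementError(f"cannot extract landmark positions from {type(pose).__name__}")


def raw_angles(pose) -> AngleSet:
    """Radiographic angles of a pose (an EquilibriumResult or a mapping of
    landmark name to world position)."""
    pos = _positions(pose)
    for name in _ANGLE_LANDMARKS:
        if name not in pos:
            raise MeasurementError(f"missing landmark {name!r} for angle measurement")

    ez = np.asarray(pos["tibia_shaft_proximal"]) - np.asarray(pos["tibia_shaft_distal"])
    ez = ez / np.linalg.norm(ez)
    a = np.asarray(pos["met1_head"]) - np.asarray(pos["met1_base"])
    ex = a - (a @ ez) * ez
    nex = np.linalg.norm(ex)
    if nex < 1e-9:
        raise MeasurementError("degenerate measurement frame: metatarsal axis parallel to tibia")
    ex = ex / nex
    ey = np.cross(ez, ex)

    def comp(v):
        return float(v @ ex), float(v @ ey), float(v @ ez)

    v_tal = comp(np.asarray(pos["talus_head_center"]) - np.asarray(pos["talus_posterior"]))
    v_met = comp(a)
    u_tib = comp(ez)
    u_cal = comp(
        np.asarray(pos["calcaneal_axis_superior"]) - np.asarray(pos["calcaneal_axis_inferior"])
    )

    sag = lambda v: math.degrees(math.atan2(-v[2], v[0]))  # plantar declination +
    trans = lambda v: math.degrees(math.atan2(-v[1], v[0]))  # lateral deviation +
    cor = lambda v: math.degrees(math.atan2(v[1], v[2]))  # medial tilt of up-axis +

    return AngleSet(
        meary_lateral=sag(v_tal) - sag(v_met),
        meary_ap=trans(v_met) - trans(v_tal),
        hindfoot_valgus=cor(u_cal) - cor(u_tib),
    )


def _check_same_geometry(a, b) -> None:
    if isinstance(a, EquilibriumResult) and isinstance(b, EquilibriumResult):
        ga, gb = a.model.geometry, b.model.geometry
        if ga is gb:
            return
        if ga.params != gb.params:
            raise MeasurementError("poses were measured on different geometries")
        for name, lm in ga.landmarks.items():
            if name not in gb.landmarks or not np.array_equal(
                lm.position, gb.landmarks[name].position
            ):
                raise MeasurementError("poses were measured on different geometries")


def deformity_angles(result, intact_reference) -> AngleSet:
    """Angles of ``result`` relative to the intact condition (which is zero)."""
    _check_same_geometry(result, intact_reference)
    return raw_angles(result) - raw_angles(intact_reference)


def correction_angles(flatfoot_result, recon_result, intact_reference) -> AngleSet:
    """Correction achieved by a reconstruction: flatfoot deformity minus
    residual deformity after the procedure (positive = toward intact)."""
    _check_same_geometry(flatfoot_result, recon_result)
    _check_same_geometry(flatfoot_result, intact_reference)
    return deformity_angles(flatfoot_result, intact_reference) - deformity_angles(
        recon_result, intact_reference
    )


def load_displacement_protocol(
    model: FootModel,
    loads: Sequence[float] = VALIDATION_LOADS,
    settings: SolverSettings | None = None,
) -> LoadDisplacementCurve:
    """Quasi-static axial loading sweep measuring vertical navicular drop.

    One equilibrium solve per load (warm-started from the previous step);
    the drop is the vertical displacement of the navicular tuberosity
    relative to the first (reference) load step.  A non-converged solve
    raises ProtocolError carrying the partial curve.
    """
    from dataclasses import replace as _replace

    loads = tuple(float(w) for w in loads)
    if len(loads) < 1:
        raise MeasurementError("protocol needs at least one load")
    base = settings or SolverSettings()
    drops: list[float] = []
    z_ref = None
    pose = None
    for w in loads:
        # near zero load several contacts and ties sit exactly at their
        # activation boundaries (a nonsmooth equilibrium); chasing the
        # full-load tolerance there is numerically meaningless
        step = base if w >= 50.0 else _replace(base, residual_tol=max(base.residual_tol, 0.05))
        result = model.with_load(w).fit(start=pose, settings=step)
        if not result.converged:
            raise ProtocolError(
                f"equilibrium failed at load {w:.0f} N "
                f"(residual {result.residual_norm:.3e} N)",
                partial=LoadDisplacementCurve(loads[: len(drops)], tuple(drops)),
            )
        pose = result.pose
        z = float(result.landmark_positions()["navicular_tuberosity"][2])
        if z_ref is None:
            z_ref = z
        drops.append(z_ref - z)
    return LoadDisplacementCurve(loads, tuple(drops))


def _joint_patches(result: EquilibriumResult, joint: str):
    pairs = [p for p in result.model.contact_pairs if p.patch.joint == joint]
    if not pairs:
        known = sorted({p.patch.joint for p in result.model.contact_pairs})
        raise MeasurementError(f"unknown joint {joint!r}; model has {known}")
    return pairs


def contact_statistics(result: EquilibriumResult, joint: str) -> ContactStats:
    """Contact area, area-weighted mean pressure and peak pressure of a joint.

    Only patch points in contact (pressure > 0) contribute; a fully
    separated joint reports (0, 0, 0).
    """
    pressures = []
    areas = []
    for pair in _joint_patches(result, joint):
        p = result.contact_pressures[pair.patch.name]
        a = pair.patch.areas
        mask = p > 0
        pressures.append(p[mask])
        areas.append(a[mask])
    p = np.concatenate(pressures) if pressures else np.array([])
    a = np.concatenate(areas) if areas else np.array([])
    if p.size == 0:
        return ContactStats(0.0, 0.0, 0.0)
    area = float(a.sum())
    return ContactStats(
        mean_pressure=float((p * a).sum() / area),
        peak_pressure=float(p.max()),
        area=area,
    )


def total_contact_force(result: EquilibriumResult, joint: str) -> float:
    """Total normal contact force (N) transmitted across a joint."""
    total = 0.0
    for pair in _joint_patches(result, joint):
        p = result.contact_pressures[pair.patch.name]
        total += float((p * pair.patch.areas).sum())
    return total
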