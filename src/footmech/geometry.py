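"""Parametric synthetic foot geometry.

No subject scan underlies this package, so the skeleton is a canonical
landmark template of an adult right foot: named 3-D landmarks grouped into
six rigid segments (tibia+fibula, talus, calcaneus, navicular, cuboid,
forefoot = cuneiforms+metatarsals+phalanges), ligament attachment sites for
every ligament in the packaged property tables, articular contact patches
for the tibiotalar, subtalar, talonavicular, calcaneocuboid and midfoot
joints, plantar ground-contact pads, and the graft tunnel landmarks used by
the four spring-ligament reconstruction routings.

Frame convention (the template's own choice): +X anterior, +Y medial (right
foot), +Z up; the ground plane is Z = 0; all positions in mm.

The template is deliberately aligned: the talar long axis and the first
metatarsal axis share one direction, and the tibial and calcaneal coronal
axes are parallel, so the lateral/AP Meary angles and hindfoot valgus all
measure zero in the neutral build pose.  Deformity is therefore read as a
change from this reference, mirroring the convention that the intact
condition defines zero.

Coordinates are order-of-magnitude anatomical, not subject-specific.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Landmark",
    "GeometryParams",
    "SegmentDef",
    "Surface",
    "ContactPatchDef",
    "FootGeometry",
    "ReconstructionMethod",
    "generate_foot_geometry",
    "graft_route",
    "GeometryError",
]

#: Template reference dimensions (mm) that GeometryParams rescale.
TEMPLATE_FOOT_LENGTH = 250.0
TEMPLATE_ARCH_HEIGHT = 45.0

#: Shared direction of the talar long axis and first-metatarsal axis in the
#: template (anterior, slightly medial, plantar-declined), before scaling.
_ARCH_AXIS = np.array([95.0, 3.0, -28.0])
_ARCH_AXIS = _ARCH_AXIS / np.linalg.norm(_ARCH_AXIS)


class GeometryError(ValueError):
    """Invalid geometry parameters or an incomplete geometry."""


class ReconstructionMethod(str, enum.Enum):
    """The four simulated spring-ligament graft routings."""

    ISLR = "ISLR"  # inferior spring ligament reconstruction
    ASLR = "ASLR"  # anatomic spring ligament reconstruction
    CSILR = "CSILR"  # combined superomedial/inferior (navicular-to-tibia limb)
    CSPLR = "CSPLR"  # combined superomedial/plantar


@dataclass(frozen=True)
class Landmark:
    name: str
    position: np.ndarray  # (3,) mm, global frame
    segment: str

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise GeometryError(f"landmark {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the synthetic foot generator.

    foot_length and arch_height rescale the template anteroposteriorly /
    vertically; ``scale`` is an additional global similarity factor.
    ``hindfoot_alignment`` pre-tilts the calcaneus in the coronal plane
    (degrees, positive = valgus).  ``perturbation_sd`` adds seeded Gaussian
    jitter to every landmark for robustness studies.
    """

    foot_length: float = TEMPLATE_FOOT_LENGTH
    arch_height: float = TEMPLATE_ARCH_HEIGHT
    hindfoot_alignment: float = 0.0
    scale: float = 1.0
    random_seed: int = 0
    perturbation_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.foot_length > 0:
            raise GeometryError(f"foot_length must be > 0, got {self.foot_length}")
        if self.arch_height < 0:
            raise GeometryError(f"arch_height must be >= 0, got {self.arch_height}")
        if not self.scale > 0:
            raise GeometryError(f"scale must be > 0, got {self.scale}")
        if self.perturbation_sd < 0:
            raise GeometryError(f"perturbation_sd must be >= 0, got {self.perturbation_sd}")

    @property
    def global_scale(self) -> float:
        return self.scale * self.foot_length / TEMPLATE_FOOT_LENGTH


@dataclass(frozen=True)
class SegmentDef:
    """A rigid group of bones with a body frame anchored at ``origin``."""

    name: str
    bones: tuple[str, ...]
    origin: np.ndarray  # (3,) build-pose frame origin, mm


@dataclass(frozen=True)
class Surface:
    """Articular support surface fixed to a segment (plane, sphere or cylinder).

    For a plane, ``point``/``normal`` define it (normal points from the
    surface toward the mating patch points).  For a sphere/cylinder,
    ``point`` is the center/axis point, ``normal`` the cylinder axis
    direction, and ``radius`` the radius; patch points contact the convex
    surface from outside.
    """

    kind: str  # "plane" | "sphere" | "cylinder"
    point: np.ndarray
    normal: np.ndarray
    radius: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("plane", "sphere", "cylinder"):
            raise GeometryError(f"unknown surface kind {self.kind!r}")
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        object.__setattr__(self, "normal", n / nn if nn > 0 else n)


@dataclass(frozen=True)
class ContactPatchDef:
    """A frictionless elastic-foundation contact patch.

    ``points`` (build pose, on the surface) ride on ``point_segment``;
    the supporting ``surface`` is fixed to ``surface_segment`` ("ground"
    denotes the fixed world plane).  ``areas`` are per-point tributary
    areas in mm^2; ``normals`` are outward surface normals at build.
    """

    joint: str
    name: str
    point_segment: str
    surface_segment: str
    surface: Surface
    points: np.ndarray  # (n, 3)
    areas: np.ndarray  # (n,)
    normals: np.ndarray  # (n, 3)
    foundation: str = "cartilage"  # "cartilage" | "ground"

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        areas = np.asarray(self.areas, dtype=float)
        normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
        if pts.shape[0] != areas.shape[0] or pts.shape != normals.shape:
            raise GeometryError(f"patch {self.name}: inconsistent point/area/normal shapes")
        if np.any(areas <= 0):
            raise GeometryError(f"patch {self.name}: tributary areas must be positive")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "areas", areas)
        object.__setattr__(self, "normals", normals)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


@dataclass(frozen=True)
class FootGeometry:
    """The assembled synthetic geometry consumed by the model builder."""

    params: GeometryParams
    landmarks: dict[str, Landmark]
    segments: dict[str, SegmentDef]
    ligament_sites: dict[str, tuple[str, ...]]  # name -> ordered landmark names
    contact_patches: tuple[ContactPatchDef, ...]
    ground_plane: tuple[np.ndarray, np.ndarray]  # (point, unit normal)

    def position(self, name: str) -> np.ndarray:
        try:
            return self.landmarks[name].position
        except KeyError:
            raise GeometryError(f"missing landmark {name!r}") from None

    def segment_of(self, name: str) -> str:
        return self.landmarks[name].segment

    def landmark_positions(self) -> dict[str, np.ndarray]:
        return {k: v.position for k, v in self.landmarks.items()}

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "params": {
                "foot_length": self.params.foot_length,
                "arch_height": self.params.arch_height,
                "hindfoot_alignment": self.params.hindfoot_alignment,
                "scale": self.params.scale,
                "random_seed": self.params.random_seed,
                "perturbation_sd": self.params.perturbation_sd,
            },
            "landmarks": {
                k: {"position": v.position.tolist(), "segment": v.segment}
                for k, v in sorted(self.landmarks.items())
            },
            "segments": {
                k: {"bones": list(v.bones), "origin": v.origin.tolist()}
                for k, v in sorted(self.segments.items())
            },
            "ligament_sites": {k: list(v) for k, v in sorted(self.ligament_sites.items())},
            "contact_patches": [
                {
                    "joint": p.joint,
                    "name": p.name,
                    "point_segment": p.point_segment,
                    "surface_segment": p.surface_segment,
                    "surface": {
                        "kind": p.surface.kind,
                        "point": p.surface.point.tolist(),
                        "normal": p.surface.normal.tolist(),
                        "radius": p.surface.radius,
                    },
                    "points": p.points.tolist(),
                    "areas": p.areas.tolist(),
                    "normals": p.normals.tolist(),
                    "foundation": p.foundation,
                }
                for p in self.contact_patches
            ],
            "ground_plane": {
                "point": self.ground_plane[0].tolist(),
                "normal": self.ground_plane[1].tolist(),
            },
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "FootGeometry":
        params = GeometryParams(**d["params"])
        landmarks = {
            k: Landmark(k, np.asarray(v["position"]), v["segment"])
            for k, v in d["landmarks"].items()
        }
        segments = {
            k: SegmentDef(k, tuple(v["bones"]), np.asarray(v["origin"]))
            for k, v in d["segments"].items()
        }
        sites = {k: tuple(v) for k, v in d["ligament_sites"].items()}
        patches = tuple(
            ContactPatchDef(
                joint=p["joint"],
                name=p["name"],
                point_segment=p["point_segment"],
                surface_segment=p["surface_segment"],
                surface=Surface(
                    p["surface"]["kind"],
                    np.asarray(p["surface"]["point"]),
                    np.asarray(p["surface"]["normal"]),
                    p["surface"]["radius"],
                ),
                points=np.asarray(p["points"]),
                areas=np.asarray(p["areas"]),
                normals=np.asarray(p["normals"]),
                foundation=p["foundation"],
            )
            for p in d["contact_patches"]
        )
        gp = (np.asarray(d["ground_plane"]["point"]), np.asarray(d["ground_plane"]["normal"]))
        return cls(params, landmarks, segments, sites, patches, gp)

    @classmethod
    def from_json(cls, text_or_path) -> "FootGeometry":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# canonical template
# ---------------------------------------------------------------------------

_SEGMENT_BONES: dict[str, tuple[str, ...]] = {
    "tibia": ("tibia", "fibula"),
    "talus": ("talus",),
    "calcaneus": ("calcaneus",),
    "navicular": ("navicular",),
    "cuboid": ("cuboid",),
    "forefoot": (
        "medial_cuneiform",
        "intermediate_cuneiform",
        "lateral_cuneiform",
        "metatarsal_1",
        "metatarsal_2",
        "metatarsal_3",
        "metatarsal_4",
        "metatarsal_5",
    )
    + tuple(f"phalanx_{i}" for i in range(1, 15)),
}


def _template_landmarks() -> dict[str, tuple[str, np.ndarray]]:
    """name -> (segment, template position)."""
    A = _ARCH_AXIS
    talus_posterior = np.array([40.0, 10.0, 59.0])
    talus_head_center = talus_posterior + 52.0 * A
    met1_base = np.array([126.0, 14.0, 34.0])
    met1_head = met1_base + 88.0 * A

    t: dict[str, tuple[str, Sequence[float]]] = {
        # --- tibia + fibula (one rigid segment) ---
        "tibia_shaft_proximal": ("tibia", (55, 8, 400)),
        "tibia_shaft_distal": ("tibia", (55, 8, 120)),
        "tibia_plafond_center": ("tibia", (55, 5, 76)),
        "medial_malleolus": ("tibia", (52, 30, 60)),
        "medial_malleolus_anterior": ("tibia", (62, 28, 64)),
        "medial_malleolus_tip": ("tibia", (52, 28, 48)),
        "lateral_malleolus": ("tibia", (50, -34, 52)),
        "tibia_anterior_distal": ("tibia", (66, -10, 80)),
        "fibula_anterior_distal": ("tibia", (62, -28, 76)),
        "tibia_posterior_distal": ("tibia", (42, -10, 80)),
        "fibula_posterior_distal": ("tibia", (40, -28, 76)),
        "tibia_graft_attachment": ("tibia", (58, 26, 88)),
        "achilles_origin": ("tibia", (25, -2, 300)),
        "tibialis_posterior_origin": ("tibia", (42, 14, 240)),
        "tibialis_anterior_origin": ("tibia", (70, 2, 240)),
        "peroneus_longus_origin": ("tibia", (48, -26, 240)),
        "peroneus_brevis_origin": ("tibia", (46, -28, 170)),
        "flexor_hallucis_longus_origin": ("tibia", (40, -8, 220)),
        "flexor_digitorum_longus_origin": ("tibia", (40, 12, 220)),
        # --- talus ---
        "talus_posterior": ("talus", talus_posterior),
        "talus_head_center": ("talus", talus_head_center),
        "talus_trochlea_center": ("talus", (54, 4, 50)),
        "talus_neck_lateral": ("talus", (72, -6, 55)),
        "talus_neck_medial": ("talus", (74, 18, 53)),
        "talus_neck_dorsal": ("talus", (76, 10, 58)),
        "talus_neck_inferior": ("talus", (76, 6, 43)),
        "talus_posterior_medial": ("talus", (42, 16, 52)),
        "talus_posterior_lateral": ("talus", (38, -10, 54)),
        "talus_posterior_inferior": ("talus", (40, 0, 48)),
        "talus_sinus": ("talus", (66, 0, 48)),
        "talus_medial_surface": ("talus", (52, 18, 50)),
        "talus_lateral_process": ("talus", (54, -18, 46)),
        "talus_posterior_facet_center": ("talus", (50, -4, 40)),
        "talus_middle_facet_center": ("talus", (74, 18, 40)),
        "talus_fhl_groove": ("talus", (38, 2, 50)),
        # --- calcaneus ---
        "calcaneus_posterior_tuberosity": ("calcaneus", (8, -2, 30)),
        "calcaneal_axis_superior": ("calcaneus", (9, -2, 46)),
        "calcaneal_axis_inferior": ("calcaneus", (9, -2, 4)),
        "calcaneus_achilles_insertion": ("calcaneus", (5, -2, 44)),
        "heel_pad_center": ("calcaneus", (14, -2, 0)),
        "sustentaculum_tali": ("calcaneus", (74, 24, 42)),
        "sustentaculum_fhl_groove": ("calcaneus", (72, 22, 36)),
        "calcaneus_lateral_cfl": ("calcaneus", (44, -26, 34)),
        "calcaneus_sinus": ("calcaneus", (64, -2, 41)),
        "calcaneus_anterior_dorsal": ("calcaneus", (78, 0, 38)),
        "calcaneus_posterior_talar": ("calcaneus", (34, 0, 42)),
        "calcaneus_medial_surface": ("calcaneus", (50, 20, 38)),
        "calcaneus_lateral_surface": ("calcaneus", (52, -22, 38)),
        "calcaneus_anterior_process": ("calcaneus", (84, -14, 34)),
        "calcaneus_cc_center": ("calcaneus", (80, -14, 30)),
        "calcaneus_cc_dorsal": ("calcaneus", (84, -10, 36)),
        "calcaneus_cc_plantar": ("calcaneus", (74, -8, 16)),
        "calcaneus_icn_origin": ("calcaneus", (76, 8, 32)),
        "calcaneus_plantar_anterior": ("calcaneus", (68, -2, 14)),
        "calcaneus_medial_tubercle": ("calcaneus", (20, 0, 8)),
        "long_plantar_origin": ("calcaneus", (30, -4, 10)),
        "calcaneus_islr_attachment": ("calcaneus", (76, 8, 26)),
        "anterior_calcaneal_hole_medial": ("calcaneus", (66, 12, 26)),
        "anterior_calcaneal_hole_lateral": ("calcaneus", (66, -16, 26)),
        "posterior_calcaneal_hole_medial": ("calcaneus", (58, 22, 40)),
        "posterior_calcaneal_hole_lateral": ("calcaneus", (52, -16, 34)),
        # --- navicular ---
        "navicular_center": ("navicular", (110, 12, 44)),
        "navicular_tuberosity": ("navicular", (106, 30, 30)),
        "navicular_dorsal": ("navicular", (108, 12, 54)),
        "navicular_plantar": ("navicular", (108, 8, 32)),
        "navicular_smcn_insertion": ("navicular", (102, 22, 40)),
        "navicular_icn_insertion": ("navicular", (104, 4, 32)),
        "navicular_cn_dorsal": ("navicular", (106, -2, 46)),
        "navicular_cn_plantar": ("navicular", (104, 0, 32)),
        "navicular_cn_lateral": ("navicular", (106, -4, 38)),
        "navicular_nc_center": ("navicular", (116, 12, 41)),
        "navicular_hole_dorsal": ("navicular", (108, 16, 50)),
        "navicular_hole_plantar": ("navicular", (108, 16, 32)),
        # --- cuboid ---
        "cuboid_center": ("cuboid", (102, -16, 28)),
        "cuboid_dorsal": ("cuboid", (104, -10, 40)),
        "cuboid_plantar": ("cuboid", (102, -14, 14)),
        "cuboid_medial": ("cuboid", (104, -8, 32)),
        "cuboid_cc_dorsal": ("cuboid", (100, -12, 34)),
        "cuboid_groove": ("cuboid", (100, -18, 10)),
        "short_plantar_insertion": ("cuboid", (96, -12, 14)),
        "cuboid_cm_center": ("cuboid", (112, -16, 26)),
        # --- forefoot (cuneiforms + metatarsals + phalanges) ---
        "met1_base": ("forefoot", met1_base),
        "met1_head": ("forefoot", met1_head),
        "met_pad_center": ("forefoot", (200, -2, 0)),
        "hallux_pad": ("forefoot", (238, 17, 0)),
        "fascia_insertion": ("forefoot", (204, 10, 5)),
        "long_plantar_insertion": ("forefoot", (128, -10, 15)),
        "tibialis_anterior_insertion": ("forefoot", (130, 20, 36)),
        "peroneus_longus_distal_attachment": ("forefoot", (128, 16, 14)),
        "peroneus_brevis_insertion": ("forefoot", (138, -30, 22)),
        "flexor_hallucis_longus_insertion": ("forefoot", (232, 17, 4)),
        "flexor_digitorum_longus_insertion": ("forefoot", (228, -4, 4)),
    }
    return {k: (seg, np.asarray(pos, dtype=float)) for k, (seg, pos) in t.items()}


#: Ordered attachment landmark names for every ligament in the packaged
#: tables plus the plantar fascia and long/short plantar ligaments.
LIGAMENT_SITES: dict[str, tuple[str, ...]] = {
    # tibial/fibular table
    "anterior_talofibular": ("lateral_malleolus", "talus_neck_lateral"),
    "anterior_tibiofibular": ("tibia_anterior_distal", "fibula_anterior_distal"),
    "anterior_tibiotalar": ("medial_malleolus_anterior", "talus_neck_medial"),
    "calcaneofibular": ("lateral_malleolus", "calcaneus_lateral_cfl"),
    "posterior_talofibular": ("lateral_malleolus", "talus_posterior_lateral"),
    "posterior_tibiofibular": ("tibia_posterior_distal", "fibula_posterior_distal"),
    "posterior_tibiotalar": ("medial_malleolus", "talus_posterior_medial"),
    "tibiocalcaneal": ("medial_malleolus", "sustentaculum_tali"),
    "tibionavicular": ("medial_malleolus_anterior", "navicular_dorsal"),
    # midfoot table
    "anterior_talocalcaneal": ("talus_neck_inferior", "calcaneus_anterior_dorsal"),
    "posterior_talocalcaneal": ("talus_posterior_inferior", "calcaneus_posterior_talar"),
    "lateral_talocalcaneal": ("talus_lateral_process", "calcaneus_lateral_surface"),
    "medial_talocalcaneal": ("talus_medial_surface", "calcaneus_medial_surface"),
    "interosseous_talocalcaneal": ("talus_sinus", "calcaneus_sinus"),
    "dorsal_talonavicular": ("talus_neck_dorsal", "navicular_dorsal"),
    "interosseous_calcaneocuboid": ("calcaneus_cc_dorsal", "cuboid_cc_dorsal"),
    "plantar_calcaneocuboid": ("calcaneus_cc_plantar", "cuboid_plantar"),
    "inferior_calcaneonavicular": ("calcaneus_icn_origin", "navicular_icn_insertion"),
    "superomedial_calcaneonavicular": ("sustentaculum_tali", "navicular_smcn_insertion"),
    "dorsal_cuboideonavicular": ("cuboid_dorsal", "navicular_cn_dorsal"),
    "plantar_cuboideonavicular": ("cuboid_plantar", "navicular_cn_plantar"),
    "interosseous_cuboideonavicular": ("cuboid_medial", "navicular_cn_lateral"),
    # plantar table
    "plantar_fascia": ("calcaneus_medial_tubercle", "fascia_insertion"),
    "long_plantar": ("long_plantar_origin", "cuboid_plantar", "long_plantar_insertion"),
    "short_plantar": ("calcaneus_plantar_anterior", "short_plantar_insertion"),
}

#: Graft routings, as ordered limbs of landmark names.
GRAFT_ROUTES: dict[ReconstructionMethod, tuple[tuple[str, ...], ...]] = {
    ReconstructionMethod.ISLR: (("navicular_hole_plantar", "calcaneus_islr_attachment"),),
    ReconstructionMethod.ASLR: (
        ("anterior_calcaneal_hole_medial", "navicular_hole_plantar"),
        ("navicular_hole_dorsal", "posterior_calcaneal_hole_medial"),
    ),
    ReconstructionMethod.CSILR: (
        ("navicular_hole_plantar", "calcaneus_islr_attachment"),
        ("navicular_hole_dorsal", "tibia_graft_attachment"),
    ),
    ReconstructionMethod.CSPLR: (
        (
            "peroneus_longus_distal_attachment",
            "anterior_calcaneal_hole_medial",
            "anterior_calcaneal_hole_lateral",
            "posterior_calcaneal_hole_lateral",
            "posterior_calcaneal_hole_medial",
            "navicular_hole_dorsal",
            "navicular_hole_plantar",
        ),
    ),
}


def _orthonormal_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = axis / np.linalg.norm(axis)
    helper = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2


def _sphere_patch(center, radius, axis, polar_deg, n_ring, area_each):
    """Socket points on a sphere around ``axis``: one polar point plus rings."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    e1, e2 = _orthonormal_basis(a)
    pts, normals = [np.asarray(center) + radius * a], [a.copy()]
    for polar in polar_deg:
        sp, cp = math.sin(math.radians(polar)), math.cos(math.radians(polar))
        for k in range(n_ring):
            phi = 2.0 * math.pi * k / n_ring
            d = cp * a + sp * (math.cos(phi) * e1 + math.sin(phi) * e2)
            pts.append(np.asarray(center) + radius * d)
            normals.append(d)
    pts = np.array(pts)
    normals = np.array(normals)
    areas = np.full(len(pts), area_each)
    return pts, areas, normals


def generate_foot_geometry(params: GeometryParams | None = None) -> FootGeometry:
    """Generate the parametric synthetic foot geometry.

    Deterministic for fixed params (jitter is drawn from
    ``numpy.random.default_rng(random_seed)``).  All contact patch points are
    constructed exactly on their supporting surfaces, so every articulation
    starts in touching, zero-pressure contact at build.
    """
    if params is None:
        params = GeometryParams()

    template = _template_landmarks()
    names = list(template.keys())
    pos = np.array([template[n][1] for n in names])
    segs = [template[n][0] for n in names]

    # vertical arch rescale (linear in z: preserves axis collinearity)
    pos[:, 2] *= params.arch_height / TEMPLATE_ARCH_HEIGHT

    # coronal pre-tilt of the calcaneus about an anterior axis through the
    # posterior subtalar facet center (positive = valgus for a right foot)
    if params.hindfoot_alignment != 0.0:
        ang = math.radians(params.hindfoot_alignment)
        pivot = pos[names.index("talus_posterior_facet_center")].copy()
        c, s = math.cos(ang), math.sin(ang)
        rot = np.array([[1, 0, 0], [0, c, s], [0, -s, c]])  # about +x, valgus>0
        for i, seg in enumerate(segs):
            if seg == "calcaneus":
                pos[i] = pivot + rot @ (pos[i] - pivot)

    # seeded jitter, then global similarity scale
    if params.perturbation_sd > 0.0:
        rng = np.random.default_rng(params.random_seed)
        pos = pos + rng.normal(0.0, params.perturbation_sd, size=pos.shape)
    s = params.global_scale
    pos = pos * s

    landmarks = {n: Landmark(n, p, seg) for n, p, seg in zip(names, pos, segs)}
    get = lambda n: landmarks[n].position  # noqa: E731

    segments = {}
    for seg_name, bones in _SEGMENT_BONES.items():
        pts = np.array([lm.position for lm in landmarks.values() if lm.segment == seg_name])
        segments[seg_name] = SegmentDef(seg_name, bones, pts.mean(axis=0))

    patches: list[ContactPatchDef] = []

    # tibiotalar: talar trochlea cylinder (axis mediolateral), plafond points on tibia
    troch = get("talus_trochlea_center")
    r_tt = 18.0 * s
    pts, areas, normals = [], [], []
    # deep mortise arc: anterior/posterior plafond walls resist AP sliding
    for alpha in (-35.0, -17.5, 0.0, 17.5, 35.0):
        for dy in (-12.0 * s, 0.0, 12.0 * s):
            d = np.array([math.sin(math.radians(alpha)), 0.0, math.cos(math.radians(alpha))])
            pts.append(troch + np.array([0.0, dy, 0.0]) + r_tt * d)
            normals.append(d)
            areas.append(60.0 * s * s)
    patches.append(
        ContactPatchDef(
            joint="tibiotalar",
            name="tibiotalar",
            point_segment="tibia",
            surface_segment="talus",
            surface=Surface("cylinder", troch, np.array([0.0, 1.0, 0.0]), r_tt),
            points=np.array(pts),
            areas=np.array(areas),
            normals=np.array(normals),
        )
    )

    # subtalar posterior facet: the calcaneal facet is convex (cylindrical)
    # and the talar counterpart concave, which locks sliding transverse to
    # the facet; the cylinder axis follows the oblique subtalar joint axis
    # (inclined ~42 deg, deviated ~16 deg medially), so inversion/eversion
    # is the frictionless free motion and is governed by the ligaments —
    # the deltoid and spring complex in particular
    cpost = get("talus_posterior_facet_center")
    down = np.array([0.0, 0.0, -1.0])
    r_st = 10.0 * s
    st_axis_point = cpost - np.array([0.0, 0.0, r_st])
    pts, areas, normals = [], [], []
    # modest axial (mediolateral) lever: the facet resists inversion and
    # eversion only weakly through contact, leaving the hindfoot coronal
    # balance to the ligaments (deltoid, calcaneofibular, interosseous)
    for alpha in (-25.0, 0.0, 25.0):
        for dy in (-3.5 * s, 3.5 * s):
            d = np.array([math.sin(math.radians(alpha)), 0.0, math.cos(math.radians(alpha))])
            pts.append(st_axis_point + np.array([0.0, dy, 0.0]) + r_st * d)
            normals.append(d)
            areas.append(60.0 * s * s)
    patches.append(
        ContactPatchDef(
            joint="subtalar",
            name="subtalar_posterior_facet",
            point_segment="talus",
            surface_segment="calcaneus",
            surface=Surface("cylinder", st_axis_point, np.array([0.0, 1.0, 0.0]), r_st),
            points=np.array(pts),
            areas=np.array(areas),
            normals=np.array(normals),
        )
    )

    # subtalar middle facet (sustentaculum shelf): plane on talus, points on calcaneus
    cmid = get("talus_middle_facet_center")
    offs = np.array([[-5, -3, 0], [5, 3, 0]], float) * s
    patches.append(
        ContactPatchDef(
            joint="subtalar",
            name="subtalar_middle_facet",
            point_segment="calcaneus",
            surface_segment="talus",
            surface=Surface("plane", cmid, down),
            points=cmid + offs,
            areas=np.full(2, 60.0 * s * s),
            normals=np.tile(down, (2, 1)),
        )
    )

    # sinus tarsi stop: the talar lateral process sits ~1.5 mm above the
    # calcaneal sinus floor; the gap closes as the hindfoot collapses into
    # plantarflexion/eversion, bounding severe deformity (the impingement
    # seen in late-stage flatfoot)
    sinus_floor = 0.5 * (get("talus_sinus") + get("calcaneus_sinus"))
    up_z = np.array([0.0, 0.0, 1.0])
    clearance = 1.5 * s
    stop_pts = np.array(
        [
            sinus_floor + np.array([-4.0 * s, -3.0 * s, clearance]),
            sinus_floor + np.array([4.0 * s, 1.0 * s, clearance]),
        ]
    )
    patches.append(
        ContactPatchDef(
            joint="subtalar",
            name="sinus_tarsi_stop",
            point_segment="talus",
            surface_segment="calcaneus",
            surface=Surface("plane", sinus_floor, up_z),
            points=stop_pts,
            areas=np.full(2, 50.0 * s * s),
            normals=np.tile(up_z, (2, 1)),
        )
    )

    # talonavicular: talar head sphere, socket points on navicular
    head = get("talus_head_center")
    r_tn = 16.0 * s
    # the socket axis is tilted dorsally: the navicular cups the head from
    # the front and above, while inferior support is left to the
    # sustentaculum facet and the spring-ligament hammock (so attenuating
    # the spring complex shifts head load medially onto the calcaneus)
    pts, areas, normals = _sphere_patch(head, r_tn, _ARCH_AXIS, (25.0, 45.0), 5, 50.0 * s * s)
    patches.append(
        ContactPatchDef(
            joint="talonavicular",
            name="talonavicular",
            point_segment="navicular",
            surface_segment="talus",
            surface=Surface("sphere", head, _ARCH_AXIS, r_tn),
            points=pts,
            areas=areas,
            normals=normals,
        )
    )

    # talonavicular, second center: the head is ovoid, not spherical — the
    # inferomedial hammock region gets its own smaller sphere so relative
    # spin of the socket engages contact (congruence stabilizes rotation)
    off = np.array([0.0, 0.9, -0.3])
    off = off - (off @ _ARCH_AXIS) * _ARCH_AXIS
    off /= np.linalg.norm(off)
    head2 = head + 8.0 * s * off
    r_tn2 = 10.0 * s
    pts, areas, normals = _sphere_patch(head2, r_tn2, _ARCH_AXIS + 0.4 * off, (30.0,), 3, 40.0 * s * s)
    patches.append(
        ContactPatchDef(
            joint="talonavicular",
            name="talonavicular_inferomedial",
            point_segment="navicular",
            surface_segment="talus",
            surface=Surface("sphere", head2, _ARCH_AXIS, r_tn2),
            points=pts,
            areas=areas,
            normals=normals,
        )
    )

    # talonavicular dorsal rim stop: the navicular's dorsal rim abuts the
    # talar neck when the midfoot rotates dorsally around the head (~2 mm
    # clearance at build), bounding talonavicular sag the way the dorsal
    # neck impingement does in severe collapse
    neck_center = head - 12.0 * s * _ARCH_AXIS + np.array([0.0, 0.0, 2.0 * s])
    rim = get("navicular_dorsal")
    rim2 = get("navicular_cn_dorsal")
    r_neck = float(np.linalg.norm(rim - neck_center)) - 2.0 * s
    stop_pts = np.array([rim, rim2])
    stop_normals = np.array(
        [(p - neck_center) / np.linalg.norm(p - neck_center) for p in stop_pts]
    )
    patches.append(
        ContactPatchDef(
            joint="talonavicular",
            name="talonavicular_dorsal_stop",
            point_segment="navicular",
            surface_segment="talus",
            surface=Surface("sphere", neck_center, _ARCH_AXIS, r_neck),
            points=stop_pts,
            areas=np.full(2, 50.0 * s * s),
            normals=stop_normals,
        )
    )


    # calcaneocuboid: sphere on calcaneus, socket points on cuboid
    cc = get("calcaneus_cc_center")
    toward_cuboid = get("cuboid_center") - cc
    r_cc = 12.0 * s
    pts, areas, normals = _sphere_patch(cc, r_cc, toward_cuboid, (30.0,), 4, 55.0 * s * s)
    patches.append(
        ContactPatchDef(
            joint="calcaneocuboid",
            name="calcaneocuboid",
            point_segment="cuboid",
            surface_segment="calcaneus",
            surface=Surface("sphere", cc, toward_cuboid, r_cc),
            points=pts,
            areas=areas,
            normals=normals,
        )
    )

    # calcaneocuboid, second (medial) center: the saddle facet is modeled as
    # two horizontally offset spheres; their common axis is then transverse,
    # so the saddle locks abduction/adduction (yaw) of the lateral column
    # while leaving sagittal rocking to the plantar ligaments
    axis_cc = toward_cuboid / np.linalg.norm(toward_cuboid)
    off2 = np.array([0.0, 1.0, 0.0])
    off2 = off2 - (off2 @ axis_cc) * axis_cc
    off2 /= np.linalg.norm(off2)
    cc2 = cc + 6.0 * s * off2
    r_cc2 = 8.0 * s
    pts, areas, normals = _sphere_patch(cc2, r_cc2, axis_cc + 0.4 * off2, (30.0,), 3, 35.0 * s * s)
    patches.append(
        ContactPatchDef(
            joint="calcaneocuboid",
            name="calcaneocuboid_dorsal",
            point_segment="cuboid",
            surface_segment="calcaneus",
            surface=Surface("sphere", cc2, axis_cc, r_cc2),
            points=pts,
            areas=areas,
            normals=normals,
        )
    )

    # naviculocuneiform: near-planar facet on the distal navicular face,
    # tilted plantarward (the keystone facet faces anteroinferiorly, so
    # joint compression carries part of the vertical arch load; planar
    # contact also resists forefoot/navicular tilting — the talonavicular
    # ball alone would leave the navicular free to spin)
    nc = get("navicular_nc_center")
    # normal along the medial strut line (facet -> first metatarsal pad), so
    # joint compression flows down the metatarsal shaft without a couple
    met1_pad = get("met_pad_center") + np.array([5.0, 18.0, 0.0]) * s
    n_nc = met1_pad - nc
    n_nc = n_nc / np.linalg.norm(n_nc)
    e1, e2 = _orthonormal_basis(n_nc)
    offs = [9.0 * s * e1 + 9.0 * s * e2, 9.0 * s * e1 - 9.0 * s * e2,
            -9.0 * s * e1 + 9.0 * s * e2, -9.0 * s * e1 - 9.0 * s * e2]
    pts = [nc + o for o in offs]
    # dorsal edge abutment: points sitting 1 mm off the facet at its dorsal
    # rim engage when the midfoot sags (dorsiflexes), bounding the sag the
    # way the dorsal joint margins and capsule do
    e_dorsal = np.array([0.0, 0.0, 1.0]) - n_nc[2] * n_nc
    e_dorsal /= np.linalg.norm(e_dorsal)
    for dy in (-4.0 * s, 4.0 * s):
        pts.append(nc + 13.0 * s * e_dorsal + dy * np.cross(n_nc, e_dorsal) + 1.0 * s * n_nc)
    pts = np.array(pts)
    patches.append(
        ContactPatchDef(
            joint="naviculocuneiform",
            name="naviculocuneiform",
            point_segment="forefoot",
            surface_segment="navicular",
            surface=Surface("plane", nc, n_nc),
            points=pts,
            areas=np.full(6, 60.0 * s * s),
            normals=np.tile(n_nc, (6, 1)),
        )
    )
    # mortise socket of the same joint: the cuneiform bases are recessed
    # onto the navicular, locking in-plane (transverse) sliding
    r_ncs = 10.0 * s
    pts, areas, normals = _sphere_patch(
        nc - 2.0 * s * n_nc, r_ncs, n_nc, (30.0, 60.0), 6, 18.0 * s * s
    )
    patches.append(
        ContactPatchDef(
            joint="naviculocuneiform",
            name="naviculocuneiform_socket",
            point_segment="forefoot",
            surface_segment="navicular",
            surface=Surface("sphere", nc - 2.0 * s * n_nc, n_nc, r_ncs),
            points=pts,
            areas=areas,
            normals=normals,
        )
    )

    # cuboid-metatarsal: near-planar facet on the distal cuboid face,
    # slightly plantar-tilted like the naviculocuneiform facet
    cm = get("cuboid_cm_center")
    # lateral strut line: facet -> fifth metatarsal pad
    met5_pad = get("met_pad_center") + np.array([-10.0, -26.0, 0.0]) * s
    nx = met5_pad - cm
    nx = nx / np.linalg.norm(nx)
    e1, e2 = _orthonormal_basis(nx)
    offs = [8.0 * s * e1 + 8.0 * s * e2, 8.0 * s * e1 - 8.0 * s * e2,
            -8.0 * s * e1 + 8.0 * s * e2, -8.0 * s * e1 - 8.0 * s * e2]
    pts = [cm + o for o in offs]
    e_dorsal = np.array([0.0, 0.0, 1.0]) - nx[2] * nx
    e_dorsal /= np.linalg.norm(e_dorsal)
    for dy in (-4.0 * s, 4.0 * s):
        pts.append(cm + 12.0 * s * e_dorsal + dy * np.cross(nx, e_dorsal) + 1.0 * s * nx)
    pts = np.array(pts)
    patches.append(
        ContactPatchDef(
            joint="cuboid_metatarsal",
            name="cuboid_metatarsal",
            point_segment="forefoot",
            surface_segment="cuboid",
            surface=Surface("plane", cm, nx),
            points=pts,
            areas=np.full(6, 45.0 * s * s),
            normals=np.tile(nx, (6, 1)),
        )
    )
    # mortise socket of the lateral tarsometatarsal joints
    r_cms = 9.0 * s
    pts, areas, normals = _sphere_patch(
        cm - 2.0 * s * nx, r_cms, nx, (30.0, 60.0), 6, 15.0 * s * s
    )
    patches.append(
        ContactPatchDef(
            joint="cuboid_metatarsal",
            name="cuboid_metatarsal_socket",
            point_segment="forefoot",
            surface_segment="cuboid",
            surface=Surface("sphere", cm - 2.0 * s * nx, nx, r_cms),
            points=pts,
            areas=areas,
            normals=normals,
        )
    )

    # cubonavicular facet: the navicular and cuboid articulate directly;
    # this small planar contact gives the transverse midfoot its torsional
    # integrity (without it the midfoot has a twist-buckling mode)
    nav_c = get("navicular_center")
    cub_c = get("cuboid_center")
    n_cn = nav_c - cub_c
    n_cn = n_cn / np.linalg.norm(n_cn)
    c_cn = 0.5 * (get("navicular_cn_lateral") + get("cuboid_medial"))
    e1, e2 = _orthonormal_basis(n_cn)
    offs = [5.0 * s * e1, -2.5 * s * e1 + 4.3 * s * e2, -2.5 * s * e1 - 4.3 * s * e2]
    pts = np.array([c_cn + o for o in offs])
    patches.append(
        ContactPatchDef(
            joint="cubonavicular",
            name="cubonavicular",
            point_segment="navicular",
            surface_segment="cuboid",
            surface=Surface("plane", c_cn, n_cn),
            points=pts,
            areas=np.full(3, 40.0 * s * s),
            normals=np.tile(n_cn, (3, 1)),
        )
    )

    # plantar ground pads (heel on calcaneus; metatarsal heads + hallux on forefoot)
    up = np.array([0.0, 0.0, 1.0])
    ground_origin = np.zeros(3)
    heel = get("heel_pad_center")
    heel_pts = heel + np.array([[-6, -8, 0], [-6, 8, 0], [8, -8, 0], [8, 8, 0]], float) * s
    heel_pts[:, 2] = heel[2]
    patches.append(
        ContactPatchDef(
            joint="ground",
            name="ground_heel",
            point_segment="calcaneus",
            surface_segment="ground",
            surface=Surface("plane", ground_origin, up),
            points=heel_pts,
            areas=np.full(4, 180.0 * s * s),
            normals=np.tile(up, (4, 1)),
            foundation="ground",
        )
    )
    mp = get("met_pad_center")
    fore_pts = np.array(
        [
            mp + np.array([5.0, 18.0, 0.0]) * s,  # first metatarsal head
            mp + np.array([0.0, -4.0, 0.0]) * s,  # central metatarsals
            mp + np.array([-10.0, -26.0, 0.0]) * s,  # fifth metatarsal head
            get("hallux_pad"),
        ]
    )
    patches.append(
        ContactPatchDef(
            joint="ground",
            name="ground_forefoot",
            point_segment="forefoot",
            surface_segment="ground",
            surface=Surface("plane", ground_origin, up),
            points=fore_pts,
            areas=np.array([200.0, 170.0, 170.0, 120.0]) * s * s,
            normals=np.tile(up, (4, 1)),
            foundation="ground",
        )
    )

    geometry = FootGeometry(
        params=params,
        landmarks=landmarks,
        segments=segments,
        ligament_sites=dict(LIGAMENT_SITES),
        contact_patches=tuple(patches),
        ground_plane=(ground_origin, up),
    )
    validate_geometry(geometry)
    return geometry


_REQUIRED_GRAFT_LANDMARKS = (
    "navicular_hole_dorsal",
    "navicular_hole_plantar",
    "anterior_calcaneal_hole_medial",
    "anterior_calcaneal_hole_lateral",
    "posterior_calcaneal_hole_medial",
    "posterior_calcaneal_hole_lateral",
    "tibia_graft_attachment",
    "peroneus_longus_distal_attachment",
)


def validate_geometry(geometry: FootGeometry) -> None:
    """Check the FootGeometry invariants; raise GeometryError on violation."""
    for name, site in geometry.ligament_sites.items():
        for lm in site:
            if lm not in geometry.landmarks:
                raise GeometryError(f"ligament {name}: attachment landmark {lm!r} missing")
    for lm in _REQUIRED_GRAFT_LANDMARKS:
        if lm not in geometry.landmarks:
            raise GeometryError(f"graft landmark {lm!r} missing")
    for patch in geometry.contact_patches:
        if np.any(patch.areas <= 0):
            raise GeometryError(f"patch {patch.name}: nonpositive tributary area")
        if patch.point_segment not in geometry.segments:
            raise GeometryError(f"patch {patch.name}: unknown segment {patch.point_segment}")
        if patch.surface_segment != "ground" and patch.surface_segment not in geometry.segments:
            raise GeometryError(f"patch {patch.name}: unknown segment {patch.surface_segment}")


def graft_route(
    geometry: FootGeometry, method: ReconstructionMethod | str
) -> tuple[tuple[Landmark, ...], ...]:
    """Ordered graft routing for ``method`` as one or two limbs of landmarks."""
    try:
        method = ReconstructionMethod(method)
    except ValueError:
        valid = ", ".join(m.value for m in ReconstructionMethod)
        raise GeometryError(f"unknown reconstruction method {method!r}; expected one of {valid}")
    limbs = []
    for limb in GRAFT_ROUTES[method]:
        limbs.append(tuple(geometry.landmarks[name] for name in limb))
    return tuple(limbs)


def graft_route_lengths(
    geometry: FootGeometry,
    method: ReconstructionMethod | str,
    positions: Mapping[str, np.ndarray] | None = None,
) -> tuple[float, ...]:
    """Routed polyline length of each graft limb, using ``positions`` (a
    landmark-name -> world-position mapping, e.g. from a solved pose) or the
    build-pose landmark positions."""
    if positions is None:
        positions = geometry.landmark_positions()
    lengths = []
    for limb in graft_route(geometry, method):
        pts = [np.asarray(positions[lm.name]) for lm in limb]
        lengths.append(float(sum(np.linalg.norm(b - a) for a, b in zip(pts[:-1], pts[1:]))))
    return tuple(lengths)


def export_segment_hulls(geometry: FootGeometry, directory) -> list[str]:
    """Write one PLY convex hull per segment for visualization (needs trimesh)."""
    import pathlib

    import trimesh

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for seg in geometry.segments:
        pts = np.array([lm.position for lm in geometry.landmarks.values() if lm.segment == seg])
        for patch in geometry.contact_patches:
            if patch.point_segment == seg:
                pts = np.vstack([pts, patch.points])
        if len(pts) < 4:
            continue
        hull = trimesh.points.PointCloud(pts).convex_hull
        path = directory / f"{seg}.ply"
        hull.export(path)
        written.append(str(path))
    return written
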