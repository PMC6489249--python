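"""Mechanical system assembly: rigid segments, tension-only line elements,
frictionless elastic-foundation contact, load case and scenario surgery.

The intact model carries one line element per ligament in the packaged
property tables (plus the plantar fascia and the long and short plantar
ligaments) with slack lengths calibrated so every ligament sits at its
in-situ strain in the neutral build pose, constant-force muscle elements,
and compression-only contact pairs at the articulations and the ground.

Scenario transforms:

* ``apply_flatfoot`` halves (by default) the force scale of the spring
  ligament complex (superomedial + inferior calcaneonavicular), the four
  tibial-origin deltoid bands, the long/short plantar ligaments and the
  plantar fascia — and nothing else;
* ``add_reconstruction`` routes a peroneus longus tendon graft (37 mm^2,
  E = 2769 MPa, tension-only linear) along one of the four reconstruction
  paths, removing the peroneus longus muscle element (graft donor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import constitutive as law
from .geometry import (
    ContactPatchDef,
    FootGeometry,
    GeometryError,
    ReconstructionMethod,
    graft_route,
)

__all__ = [
    "Segment",
    "RoutePoint",
    "LineElement",
    "MuscleSpec",
    "ContactPair",
    "LoadCase",
    "ModelOptions",
    "FootModel",
    "AssemblyError",
    "ScenarioStateError",
    "build_intact_model",
    "apply_flatfoot",
    "add_reconstruction",
    "winkler_foundation_stiffness",
    "FLATFOOT_ATTENUATED_STRUCTURES",
    "DEFAULT_MUSCLE_FRACTIONS",
    "STANDING_MUSCLE_FRACTIONS",
]


class AssemblyError(ValueError):
    """Model assembly failed (missing site, bad configuration)."""


class ScenarioStateError(RuntimeError):
    """A scenario transform was applied to a model in the wrong state."""


#: Structures attenuated to induce flatfoot: spring ligament complex, the
#: four modeled tibial-origin deltoid bands, long/short plantar ligaments
#: and plantar fascia.
FLATFOOT_ATTENUATED_STRUCTURES = frozenset(
    {
        "superomedial_calcaneonavicular",
        "inferior_calcaneonavicular",
        "anterior_tibiotalar",
        "posterior_tibiotalar",
        "tibiocalcaneal",
        "tibionavicular",
        "long_plantar",
        "short_plantar",
        "plantar_fascia",
    }
)

#: Default constant muscle forces as fractions of the axial load.  The
#: default study condition is the passive structure (zero activation): with
#: the tibia riding a vertical loading rig, no tendon force is required for
#: balance, and open-loop constant tendon forces measurably distort the
#: coronal (valgus) response of the reduced model at mild ligament
#: attenuation.  The muscle elements are always assembled (routes intact)
#: so activation can be turned on per scenario.
DEFAULT_MUSCLE_FRACTIONS: dict[str, float] = {
    "achilles": 0.0,
    "tibialis_posterior": 0.0,
    "tibialis_anterior": 0.0,
    "peroneus_longus": 0.0,
    "peroneus_brevis": 0.0,
    "flexor_hallucis_longus": 0.0,
    "flexor_digitorum_longus": 0.0,
}

#: Documented non-zero activation table for relaxed standing (fractions of
#: the axial load; order-of-magnitude from standing EMG/force estimates).
#: Used as a sensitivity condition, not as the default study condition.
STANDING_MUSCLE_FRACTIONS: dict[str, float] = {
    "achilles": 0.125,
    "tibialis_posterior": 0.025,
    "tibialis_anterior": 0.01,
    "peroneus_longus": 0.0175,
    "peroneus_brevis": 0.01,
    "flexor_hallucis_longus": 0.0125,
    "flexor_digitorum_longus": 0.0075,
}

#: Muscle routing as ordered landmark names (via points are frictionless).
MUSCLE_ROUTES: dict[str, tuple[str, ...]] = {
    "achilles": ("achilles_origin", "calcaneus_achilles_insertion"),
    "tibialis_posterior": (
        "tibialis_posterior_origin",
        "medial_malleolus_tip",
        "navicular_tuberosity",
    ),
    "tibialis_anterior": ("tibialis_anterior_origin", "tibialis_anterior_insertion"),
    "peroneus_longus": (
        "peroneus_longus_origin",
        "lateral_malleolus",
        "cuboid_groove",
        "peroneus_longus_distal_attachment",
    ),
    "peroneus_brevis": ("peroneus_brevis_origin", "lateral_malleolus", "peroneus_brevis_insertion"),
    "flexor_hallucis_longus": (
        "flexor_hallucis_longus_origin",
        "talus_fhl_groove",
        "sustentaculum_fhl_groove",
        "flexor_hallucis_longus_insertion",
    ),
    "flexor_digitorum_longus": (
        "flexor_digitorum_longus_origin",
        "medial_malleolus_tip",
        "flexor_digitorum_longus_insertion",
    ),
}


def winkler_foundation_stiffness(
    elastic_modulus: float = 10.0, poisson: float = 0.45, thickness: float = 2.0
) -> float:
    """Elastic-foundation (Winkler) stiffness in MPa/mm for a confined
    cartilage layer: ``E (1-nu) / ((1+nu)(1-2nu) t)``.

    ``thickness`` is the total compliant layer (both facing cartilage
    surfaces in series; default 1 mm per side).
    """
    if thickness <= 0:
        raise AssemblyError("cartilage thickness must be > 0")
    return elastic_modulus * (1 - poisson) / ((1 + poisson) * (1 - 2 * poisson) * thickness)


@dataclass(frozen=True)
class Segment:
    """A rigid bony segment; ``free_dofs`` masks (tx, ty, tz, rx, ry, rz)."""

    name: str
    origin: np.ndarray  # build-pose rotation center, mm
    free_dofs: tuple[bool, bool, bool, bool, bool, bool]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    @property
    def fixed(self) -> bool:
        return not any(self.free_dofs)


@dataclass(frozen=True)
class RoutePoint:
    """A route point bound to a segment; ``local`` is relative to the
    segment's build-pose origin (build rotation is the identity)."""

    segment: str
    local: np.ndarray
    landmark: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "local", np.asarray(self.local, dtype=float))


@dataclass(frozen=True)
class MuscleSpec:
    """Constant tendon force (N) along a routed polyline.

    ``fraction_of_load`` records the force as a fraction of the axial load
    so that load sweeps rescale muscle activation proportionally.
    """

    name: str
    constant_force: float
    fraction_of_load: float = 0.0

    def __post_init__(self) -> None:
        if self.constant_force < 0:
            raise AssemblyError(f"muscle {self.name}: constant_force must be >= 0")


#: Slack-activation smoothing zone (mm of elongation) applied to the
#: tension-only elements of assembled models: the same fixed penalty
#: regularization used at contact activation, keeping the total energy C2
#: where an element crosses its slack point.  Standalone elements default
#: to the exact (unregularized) laws.
ELEMENT_SLACK_REG_MM = 0.01


@dataclass(frozen=True)
class LineElement:
    """A tension-only routed element (ligament, graft limb, or muscle).

    ``slack_reg`` smooths the slack/taut transition over a small elongation
    zone (see ELEMENT_SLACK_REG_MM); with the default 0 the element follows
    the exact tension law.
    """

    name: str
    kind: str  # "ligament" | "graft" | "muscle"
    spec: object  # LigamentSpec | GraftParams | MuscleSpec
    route: tuple[RoutePoint, ...]
    slack_length: float = 0.0  # mm; build length for muscles
    slack_reg: float = 0.0  # mm, elongation smoothing zone

    def __post_init__(self) -> None:
        if len(self.route) < 2:
            raise AssemblyError(f"element {self.name}: route needs >= 2 points")
        if self.kind != "muscle" and self.slack_length <= 0:
            raise AssemblyError(f"element {self.name}: slack_length must be > 0")

    @property
    def segments_spanned(self) -> tuple[str, ...]:
        seen = []
        for rp in self.route:
            if rp.segment not in seen:
                seen.append(rp.segment)
        return tuple(seen)

    @property
    def inert(self) -> bool:
        """True when all route points share one segment (constant length)."""
        return len(self.segments_spanned) < 2

    def _smoothed_elongation(self, dl: float) -> tuple[float, float]:
        r = self.slack_reg
        if r <= 0.0 or dl >= r:
            return (dl - 0.5 * r if dl >= r else dl), 1.0
        return dl * dl / (2.0 * r), dl / r

    def tension(self, length: float) -> float:
        """Axial tension (N) at routed ``length`` (mm); tension-only."""
        if self.kind == "muscle":
            return self.spec.constant_force
        dl = length - self.slack_length
        if dl <= 0.0:
            return 0.0
        s, sp = self._smoothed_elongation(dl)
        if self.kind == "graft":
            return law.graft_axial_stiffness(self.spec) * s * sp
        eff = self.spec.effective_law
        if isinstance(eff, law.ExpLawParams):
            return law.exp_tension_force(s / self.slack_length, eff) * sp
        return law.linear_tension_force(s, eff) * sp

    def strain_energy(self, length: float) -> float:
        """Stored energy (N mm): exact integral of the tension law.

        Muscles contribute the work potential ``F * (L - L_build)`` of their
        constant force.
        """
        if self.kind == "muscle":
            return self.spec.constant_force * (length - self.slack_length)
        dl = length - self.slack_length
        if dl <= 0:
            return 0.0
        s, _ = self._smoothed_elongation(dl)
        if self.kind == "graft":
            return 0.5 * law.graft_axial_stiffness(self.spec) * s * s
        eff = self.spec.effective_law
        if isinstance(eff, law.ExpLawParams):
            eps = s / self.slack_length
            return self.slack_length * eff.a * (math.expm1(eff.b * eps) / eff.b - eps)
        return 0.5 * eff.k * s * s


@dataclass(frozen=True)
class FoundationLaw:
    """Compression-only pressure-penetration law of a contact foundation.

    ``linear``: p = k * delta (cartilage Winkler reduction).
    ``exponential``: p = p0 * (exp(delta/d0) - 1) (strain-stiffening plantar
    soft tissue).

    Contact activation is regularized over a fixed small transition zone
    ``reg`` (mm): the raw penetration is mapped through the C1 ramp
    ``s(d) = d^2/(2 reg)`` for ``d < reg`` and ``d - reg/2`` beyond, and the
    base law is evaluated at ``s``.  This keeps the contact energy C2 at
    activation (penalty regularization of the nonsmooth unilateral contact);
    for any working penetration ``reg`` is a negligible offset.
    """

    kind: str  # "linear" | "exponential"
    stiffness: float = 0.0  # MPa/mm (linear)
    p0: float = 0.0  # MPa (exponential)
    d0: float = 1.0  # mm (exponential)
    reg: float = 0.02  # mm, activation smoothing zone

    def _s(self, delta: float) -> tuple[float, float]:
        if delta >= self.reg:
            return delta - 0.5 * self.reg, 1.0
        return delta * delta / (2.0 * self.reg), delta / self.reg

    def pressure(self, delta: float) -> float:
        if delta <= 0:
            return 0.0
        s, sp = self._s(delta)
        if self.kind == "linear":
            return self.stiffness * s * sp
        return self.p0 * math.expm1(s / self.d0) * sp

    def energy_density(self, delta: float) -> float:
        """Integral of pressure over penetration (N/mm^2 * mm = N/mm)."""
        if delta <= 0:
            return 0.0
        s, _ = self._s(delta)
        if self.kind == "linear":
            return 0.5 * self.stiffness * s * s
        return self.p0 * (self.d0 * math.expm1(s / self.d0) - s)


@dataclass(frozen=True)
class ContactPair:
    """Frictionless compression-only contact between a patch and a surface."""

    kind: str  # "joint" | "ground"
    patch: ContactPatchDef
    foundation: FoundationLaw
    friction_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.friction_coefficient != 0.0:
            raise AssemblyError("contact is frictionless: friction_coefficient must be 0")


@dataclass(frozen=True)
class LoadCase:
    """Vertical axial load (N) applied through the tibia/fibula segment."""

    axial_load: float = 680.0
    segment: str = "tibia"
    direction: tuple[float, float, float] = (0.0, 0.0, -1.0)

    def __post_init__(self) -> None:
        if self.axial_load < 0:
            raise AssemblyError("axial_load must be >= 0")


@dataclass(frozen=True)
class ModelOptions:
    """Assembly options with documented defaults.

    ``muscle_fractions`` maps muscle name to constant force as a fraction of
    the axial load; pass an empty mapping for a muscle-free model.
    ``cartilage_thickness`` is per facing side (mm); the two sides combine in
    series into the Winkler foundation.
    """

    in_situ_strain: float = 0.04
    linear_in_situ_strain: float = 0.0
    cartilage_modulus: float = 10.0  # MPa
    cartilage_poisson: float = 0.45
    cartilage_thickness: float = 1.0  # mm per side
    ground_p0: float = 0.06  # MPa
    ground_d0: float = 1.2  # mm
    muscle_fractions: Mapping[str, float] | None = None
    graft_pretension_strain: float = 0.0
    harvest_peroneus_longus: bool = True

    def resolved_muscle_fractions(self) -> dict[str, float]:
        if self.muscle_fractions is None:
            return dict(DEFAULT_MUSCLE_FRACTIONS)
        return dict(self.muscle_fractions)


@dataclass
class FootModel:
    """The assembled quasi-static mechanical model.

    This is the package's model object: build it from a ``FootGeometry``
    via :func:`build_intact_model`, transform it with
    :func:`apply_flatfoot` / :func:`add_reconstruction`, then call
    :meth:`fit` to obtain an :class:`footmech.solver.EquilibriumResult`.
    """

    geometry: FootGeometry
    segments: dict[str, Segment]
    elements: tuple[LineElement, ...]
    contact_pairs: tuple[ContactPair, ...]
    load_case: LoadCase
    scenario: str = "intact"
    options: ModelOptions = field(default_factory=ModelOptions)

    def __post_init__(self) -> None:
        for el in self.elements:
            for rp in el.route:
                if rp.segment not in self.segments:
                    raise AssemblyError(
                        f"element {el.name}: route segment {rp.segment!r} not in model"
                    )

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_geometry(
        cls, geometry: FootGeometry | None = None, options: ModelOptions | None = None
    ) -> "FootModel":
        """Convenience constructor: intact model on (default) geometry."""
        from .geometry import generate_foot_geometry

        if geometry is None:
            geometry = generate_foot_geometry()
        return build_intact_model(geometry, options=options)

    # -- queries -------------------------------------------------------------

    def element(self, name: str) -> LineElement:
        for el in self.elements:
            if el.name == name:
                return el
        raise KeyError(name)

    def element_names(self) -> list[str]:
        return [el.name for el in self.elements]

    def free_segments(self) -> list[Segment]:
        return [s for s in self.segments.values() if not s.fixed]

    def build_length(self, element: LineElement) -> float:
        pts = [self.segments[rp.segment].origin + rp.local for rp in element.route]
        return float(sum(np.linalg.norm(b - a) for a, b in zip(pts[:-1], pts[1:])))

    def with_load(self, axial_load: float, scale_muscles: bool = True) -> "FootModel":
        """Copy of the model at a different axial load.

        By default muscle forces rescale proportionally with the load
        (activation tracks body-weight fraction), so the zero-load model is
        force-free apart from ligament pretension.
        """
        new_elements = self.elements
        if scale_muscles:
            updated = []
            for el in self.elements:
                if el.kind == "muscle":
                    spec = el.spec
                    updated.append(
                        replace(
                            el,
                            spec=MuscleSpec(
                                spec.name,
                                spec.fraction_of_load * axial_load,
                                spec.fraction_of_load,
                            ),
                        )
                    )
                else:
                    updated.append(el)
            new_elements = tuple(updated)
        return replace(
            self,
            elements=new_elements,
            load_case=replace(self.load_case, axial_load=axial_load),
        )

    # -- solving --------------------------------------------------------------

    def fit(self, start=None, settings=None):
        """Solve for static equilibrium; returns an EquilibriumResult."""
        from .solver import solve_equilibrium

        return solve_equilibrium(self, start=start, settings=settings)

    solve = fit

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        def spec_dict(el: LineElement) -> dict:
            s = el.spec
            if isinstance(s, law.LigamentSpec):
                lw = s.law
                d = {"type": "ligament", "name": s.name, "in_situ_strain": s.in_situ_strain,
                     "attenuation_factor": s.attenuation_factor}
                if isinstance(lw, law.ExpLawParams):
                    d.update(law_kind="exp", a=lw.a, b=lw.b)
                else:
                    d.update(law_kind="linear", k=lw.k)
                return d
            if isinstance(s, law.GraftParams):
                return {"type": "graft", "elastic_modulus": s.elastic_modulus,
                        "area": s.area, "slack_length": s.slack_length}
            return {"type": "muscle", "name": s.name, "constant_force": s.constant_force}

        return {
            "scenario": self.scenario,
            "load_case": {"axial_load": self.load_case.axial_load,
                          "segment": self.load_case.segment},
            "segments": {
                k: {"origin": v.origin.tolist(), "free_dofs": list(v.free_dofs)}
                for k, v in sorted(self.segments.items())
            },
            "elements": [
                {
                    "name": el.name,
                    "kind": el.kind,
                    "slack_length": el.slack_length,
                    "spec": spec_dict(el),
                    "route": [
                        {"segment": rp.segment, "local": rp.local.tolist(),
                         "landmark": rp.landmark}
                        for rp in el.route
                    ],
                }
                for el in self.elements
            ],
            "contact_pairs": [
                {
                    "kind": cp.kind,
                    "patch": cp.patch.name,
                    "joint": cp.patch.joint,
                    "friction_coefficient": cp.friction_coefficient,
                    "foundation": {
                        "kind": cp.foundation.kind,
                        "stiffness": cp.foundation.stiffness,
                        "p0": cp.foundation.p0,
                        "d0": cp.foundation.d0,
                    },
                }
                for cp in self.contact_pairs
            ],
        }


# ---------------------------------------------------------------------------
# assembly operations
# ---------------------------------------------------------------------------

_FREE = (True,) * 6
#: The tibia/fibula segment rides a vertical loading rig: free to translate
#: along z only; the ground is the fixed body.
_TIBIA_DOFS = (False, False, True, False, False, False)


def _route_from_landmarks(model_segments, geometry, names: Sequence[str]) -> tuple[RoutePoint, ...]:
    pts = []
    for nm in names:
        lm = geometry.landmarks.get(nm)
        if lm is None:
            raise AssemblyError(f"attachment landmark {nm!r} missing from geometry")
        seg = model_segments[lm.segment]
        pts.append(RoutePoint(lm.segment, lm.position - seg.origin, nm))
    return tuple(pts)


def build_intact_model(
    geometry: FootGeometry,
    specs: Mapping[str, law.LigamentSpec] | None = None,
    options: ModelOptions | None = None,
    load_case: LoadCase | None = None,
) -> FootModel:
    """Assemble the intact foot model from geometry and the property tables.

    One tension-only element per table ligament (plus fascia and long/short
    plantar ligaments) with slack lengths calibrated to the in-situ strain at
    build pose; constant-force muscle elements; frictionless compression-only
    contact at every articular patch and the ground pads.
    """
    options = options or ModelOptions()
    load_case = load_case or LoadCase()
    if specs is None:
        specs = law.build_ligament_specs(
            in_situ_strain=options.in_situ_strain,
            linear_in_situ_strain=options.linear_in_situ_strain,
        )

    segments = {
        name: Segment(name, sd.origin, _TIBIA_DOFS if name == "tibia" else _FREE)
        for name, sd in geometry.segments.items()
    }

    elements: list[LineElement] = []
    for name, site in geometry.ligament_sites.items():
        if name not in specs:
            raise AssemblyError(f"no constitutive spec for ligament {name!r}")
        spec = specs[name]
        route = _route_from_landmarks(segments, geometry, site)
        pts = [geometry.position(nm) for nm in site]
        build_len = float(sum(np.linalg.norm(b - a) for a, b in zip(pts[:-1], pts[1:])))
        slack = law.slack_length_from_build(build_len, spec.in_situ_strain)
        elements.append(
            LineElement(name, "ligament", spec, route, slack, slack_reg=ELEMENT_SLACK_REG_MM)
        )

    fractions = options.resolved_muscle_fractions()
    for mname, frac in fractions.items():
        if mname not in MUSCLE_ROUTES:
            raise AssemblyError(f"unknown muscle {mname!r}")
        route = _route_from_landmarks(segments, geometry, MUSCLE_ROUTES[mname])
        pts = [geometry.position(nm) for nm in MUSCLE_ROUTES[mname]]
        build_len = float(sum(np.linalg.norm(b - a) for a, b in zip(pts[:-1], pts[1:])))
        spec = MuscleSpec(mname, frac * load_case.axial_load, frac)
        elements.append(LineElement(f"muscle_{mname}", "muscle", spec, route, build_len))

    k_cart = winkler_foundation_stiffness(
        options.cartilage_modulus, options.cartilage_poisson, 2.0 * options.cartilage_thickness
    )
    contact_pairs = []
    for patch in geometry.contact_patches:
        if patch.foundation == "ground":
            foundation = FoundationLaw("exponential", p0=options.ground_p0, d0=options.ground_d0)
            kind = "ground"
        else:
            foundation = FoundationLaw("linear", stiffness=k_cart)
            kind = "joint"
        contact_pairs.append(ContactPair(kind, patch, foundation))

    return FootModel(
        geometry=geometry,
        segments=segments,
        elements=tuple(elements),
        contact_pairs=tuple(contact_pairs),
        load_case=load_case,
        scenario="intact",
        options=options,
    )


def apply_flatfoot(model: FootModel, factor: float = 0.5) -> FootModel:
    """Attenuate the flatfoot structure set by ``factor``; tag ``flatfoot``.

    Exactly the spring ligament complex, the four deltoid bands, the
    long/short plantar ligaments and the plantar fascia are touched.
    """
    if model.scenario != "intact":
        raise ScenarioStateError(
            f"flatfoot induction requires an intact model, got {model.scenario!r}"
        )
    if not (0.0 < factor <= 1.0):
        raise law.ParameterError(f"attenuation factor must be in (0, 1], got {factor}")
    new_elements = []
    for el in model.elements:
        if el.kind == "ligament" and el.name in FLATFOOT_ATTENUATED_STRUCTURES:
            new_elements.append(replace(el, spec=law.attenuate(el.spec, factor)))
        else:
            new_elements.append(el)
    return replace(model, elements=tuple(new_elements), scenario="flatfoot")


def add_reconstruction(
    model: FootModel,
    method: ReconstructionMethod | str,
    graft: law.GraftParams | None = None,
    reference_positions: Mapping[str, np.ndarray] | None = None,
) -> FootModel:
    """Append the graft element(s) of ``method`` to a flatfoot model.

    The graft is fixed (tied) wherever it enters a bone tunnel, so each
    limb is split into its bone-to-bone spans and every span acts as an
    independent tension-only linear-elastic segment of stiffness
    ``E*A/L_slack`` (spans running inside a single bone are inert and
    dropped).  Span slack lengths come from the landmark positions in
    ``reference_positions`` divided by ``(1 + graft_pretension_strain)``;
    the reference defaults to the build pose (graft fixed with the foot
    fully reduced).  The scenario pipeline passes the landmark positions of
    the *intact loaded* equilibrium instead, modeling a graft tensioned to
    restore the normal weight-bearing relationships.  The peroneus longus
    muscle element is removed (graft donor) unless
    ``options.harvest_peroneus_longus`` is False.
    """
    if model.scenario != "flatfoot":
        raise ScenarioStateError(
            f"reconstruction requires a flatfoot model, got {model.scenario!r}"
        )
    method = ReconstructionMethod(method)
    limbs = graft_route(model.geometry, method)

    elements = list(model.elements)
    if model.options.harvest_peroneus_longus:
        elements = [el for el in elements if el.name != "muscle_peroneus_longus"]

    if reference_positions is None:
        reference_positions = model.geometry.landmark_positions()

    base = graft or law.GraftParams()
    for i, limb in enumerate(limbs, start=1):
        spans = [
            (a.name, b.name)
            for a, b in zip(limb[:-1], limb[1:])
            if a.segment != b.segment
        ]
        for j, (a, b) in enumerate(spans, start=1):
            route = _route_from_landmarks(model.segments, model.geometry, (a, b))
            ref_len = float(
                np.linalg.norm(
                    np.asarray(reference_positions[b]) - np.asarray(reference_positions[a])
                )
            )
            slack = ref_len / (1.0 + model.options.graft_pretension_strain)
            params = law.GraftParams(base.elastic_modulus, base.area, slack)
            suffix = f"_limb{i}" if len(limbs) > 1 else ""
            if len(spans) > 1:
                suffix += f"_span{j}"
            elements.append(
                LineElement(
                    f"graft_{method.value}{suffix}",
                    "graft",
                    params,
                    route,
                    slack,
                    slack_reg=ELEMENT_SLACK_REG_MM,
                )
            )

    return replace(model, elements=tuple(elements), scenario=f"flatfoot+{method.value}")
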