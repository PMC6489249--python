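"""Material laws and property tables for the ligamentous foot model.

Two families of tension-only line-element laws are used:

* an exponential force-strain law ``T(eps) = a * (exp(b*eps) - 1)`` for the
  tibial/fibular ligaments and, after cross-sectional-area scaling, for the
  hindfoot/midfoot ligaments;
* a linear force-elongation law ``T = k * dL`` for the tibionavicular
  ligament, the plantar fascia and the long/short plantar ligaments.

Both laws clamp to zero force in compression (slack) and are continuous at
zero strain.  The hindfoot/midfoot ligaments inherit the anterior
talofibular (ATFL) exponential parameters with the force scale ``a``
multiplied by the ratio of the ligament's cross-sectional area to the ATFL
reference area of 62.85 mm^2; the exponent ``b`` is unchanged, so force at a
fixed strain is proportional to area.

Slack lengths are calibrated from the neutral build pose through an in-situ
strain (default 4%): ``L_slack = L_build / (1 + eps_insitu)``.

The three property tables ship as CSV files under ``footmech/data`` and are
validated against embedded SHA-256 checksums at load time.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Union

import pandas as pd

__all__ = [
    "ATFL_REFERENCE_AREA_MM2",
    "ExpLawParams",
    "LinearLawParams",
    "AreaScaledSpec",
    "GraftParams",
    "LigamentSpec",
    "exp_tension_force",
    "linear_tension_force",
    "area_ratio",
    "atfl_scaled_params",
    "slack_length_from_build",
    "graft_axial_stiffness",
    "attenuate",
    "load_tibial_table",
    "load_midfoot_table",
    "load_plantar_table",
    "build_ligament_specs",
    "check_tables",
    "TableCheckRow",
]

#: Cross-sectional area of the anterior talofibular ligament (mm^2), the
#: reference for area-ratio scaling of hindfoot/midfoot ligament stiffness.
ATFL_REFERENCE_AREA_MM2 = 62.85

#: ATFL exponential parameters: force scale a (N) and strain exponent b (-).
ATFL_A_N = 7.18
ATFL_B = 12.50

#: Ligament whose recomputed area ratio differs from the printed table value
#: at 3 decimals (printed 2.560, computed 161.00/62.85 = 2.562).  Forces are
#: derived from the area; the printed value is kept in the data file.
RATIO_EXCEPTION_LIGAMENT = "superomedial_calcaneonavicular"

_DATA_CHECKSUMS = {
    "tibial_ligaments.csv": "a268fb1964681530510746f430bee94824930b8343ab95539646377f85f81145",
    "midfoot_ligaments.csv": "547f162bfb4393cf4f642c987baaf47badbc3625273db25a687033db4d88b610",
    "plantar_structures.csv": "4379b80791f429bd785e8ea1805963066ff77ca5f7b07ab36c6692a36c8da3aa",
}


class ParameterError(ValueError):
    """A constitutive parameter violates its validity domain."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpLawParams:
    """Exponential tension law ``T(eps) = a*(exp(b*eps)-1)``; a in N, b unitless."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a >= 0.0 and math.isfinite(self.a)):
            raise ParameterError(f"force scale a must be >= 0 and finite, got {self.a}")
        if not (self.b > 0.0 and math.isfinite(self.b)):
            raise ParameterError(f"strain exponent b must be > 0 and finite, got {self.b}")


@dataclass(frozen=True)
class LinearLawParams:
    """Linear tension law ``T = k * elongation``; k in N/mm."""

    k: float

    def __post_init__(self) -> None:
        if not (self.k >= 0.0 and math.isfinite(self.k)):
            raise ParameterError(f"stiffness k must be >= 0 and finite, got {self.k}")


@dataclass(frozen=True)
class AreaScaledSpec:
    """Cross-sectional area and its ratio to the ATFL reference area."""

    area: float
    reference_area: float = ATFL_REFERENCE_AREA_MM2
    ratio: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.reference_area <= 0.0:
            raise ParameterError("reference_area must be > 0")
        expected = self.area / self.reference_area
        if self.ratio == 0.0:
            object.__setattr__(self, "ratio", expected)
        elif abs(self.ratio - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ParameterError(
                f"ratio {self.ratio} inconsistent with area/reference_area {expected}"
            )


@dataclass(frozen=True)
class GraftParams:
    """Peroneus longus tendon graft: linear elastic, tension-only in use.

    Defaults are the graft constants used throughout: cross-section 37 mm^2
    and elastic modulus 2769 MPa.  ``slack_length`` is set when the graft is
    routed (build-pose routed length, i.e. zero pretension, by default).
    """

    elastic_modulus: float = 2769.0
    area: float = 37.0
    slack_length: float = 1.0

    def __post_init__(self) -> None:
        for name in ("elastic_modulus", "area", "slack_length"):
            v = getattr(self, name)
            if not (v > 0.0 and math.isfinite(v)):
                raise ParameterError(f"graft {name} must be > 0 and finite, got {v}")


LawParams = Union[ExpLawParams, LinearLawParams]


@dataclass(frozen=True)
class LigamentSpec:
    """A named ligament: law, in-situ strain and attenuation state."""

    name: str
    law: LawParams
    in_situ_strain: float = 0.04
    attenuation_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.in_situ_strain < 0.0:
            raise ParameterError(f"{self.name}: in_situ_strain must be >= 0")
        if not (0.0 < self.attenuation_factor <= 1.0):
            raise ParameterError(f"{self.name}: attenuation_factor must be in (0, 1]")

    @property
    def effective_law(self) -> LawParams:
        """Law with the attenuation factor folded into the force scale."""
        f = self.attenuation_factor
        if isinstance(self.law, ExpLawParams):
            return ExpLawParams(self.law.a * f, self.law.b)
        return LinearLawParams(self.law.k * f)


# ---------------------------------------------------------------------------
# force laws
# ---------------------------------------------------------------------------


def _check_finite(x: float, what: str) -> float:
    x = float(x)
    if not math.isfinite(x):
        raise ValueError(f"{what} must be finite, got {x}")
    return x


def exp_tension_force(strain: float, params: ExpLawParams) -> float:
    """Tension (N) of the exponential law at engineering ``strain``; 0 in slack."""
    strain = _check_finite(strain, "strain")
    if strain <= 0.0:
        return 0.0
    return params.a * math.expm1(params.b * strain)


def linear_tension_force(elongation: float, params: LinearLawParams) -> float:
    """Tension (N) of the linear law at ``elongation`` (mm); 0 in slack."""
    elongation = _check_finite(elongation, "elongation")
    if elongation <= 0.0:
        return 0.0
    return params.k * elongation


def area_ratio(area: float, reference_area: float = ATFL_REFERENCE_AREA_MM2) -> float:
    """Cross-sectional area ratio relative to the ATFL reference area."""
    if reference_area <= 0.0:
        raise ParameterError("reference_area must be > 0")
    return area / reference_area


def atfl_scaled_params(area: float, reference_area: float = ATFL_REFERENCE_AREA_MM2) -> ExpLawParams:
    """ATFL exponential parameters with force scale ``a`` scaled by area ratio.

    Only ``a`` is scaled, so the tension at any fixed strain is proportional
    to the cross-sectional area.
    """
    if area <= 0.0:
        raise ParameterError("area must be > 0")
    return ExpLawParams(ATFL_A_N * area_ratio(area, reference_area), ATFL_B)


def slack_length_from_build(build_length: float, in_situ_strain: float) -> float:
    """Slack length such that the element carries ``in_situ_strain`` at build pose."""
    if build_length <= 0.0:
        raise ParameterError("build_length must be > 0")
    if in_situ_strain <= -1.0:
        raise ParameterError("in_situ_strain must be > -1")
    return build_length / (1.0 + in_situ_strain)


def graft_axial_stiffness(params: GraftParams) -> float:
    """Axial stiffness E*A/L_slack (N/mm) of a graft limb."""
    return params.elastic_modulus * params.area / params.slack_length


def attenuate(spec: LigamentSpec, factor: float) -> LigamentSpec:
    """Scale the force scale (``a`` or ``k``) of ``spec`` by ``factor`` in (0, 1].

    Composition multiplies: ``attenuate(f1) o attenuate(f2) == attenuate(f1*f2)``.
    """
    if not (0.0 < factor <= 1.0):
        raise ParameterError(f"attenuation factor must be in (0, 1], got {factor}")
    return replace(spec, attenuation_factor=spec.attenuation_factor * factor)


# ---------------------------------------------------------------------------
# packaged tables
# ---------------------------------------------------------------------------


def _read_table(filename: str) -> pd.DataFrame:
    ref = resources.files("footmech.data").joinpath(filename)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = _DATA_CHECKSUMS[filename]
    if digest != expected:
        raise RuntimeError(
            f"packaged table {filename} is corrupted (sha256 {digest} != {expected})"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_tibial_table() -> pd.DataFrame:
    """Tibial/fibular ligament table: exponential (a, b) rows plus the linear
    tibionavicular row (columns ``ligament, a_N, b, k_N_per_mm``)."""
    return _read_table("tibial_ligaments.csv")


def load_midfoot_table() -> pd.DataFrame:
    """Calcaneal/talar/midfoot ligament areas and printed area ratios."""
    return _read_table("midfoot_ligaments.csv")


def load_plantar_table() -> pd.DataFrame:
    """Plantar fascia and long/short plantar ligament linear stiffnesses."""
    return _read_table("plantar_structures.csv")


def build_ligament_specs(
    in_situ_strain: float = 0.04, linear_in_situ_strain: float = 0.0
) -> dict[str, LigamentSpec]:
    """All ligament specs from the packaged tables, keyed by ligament name.

    The single long/short plantar table row expands into separate
    ``long_plantar`` and ``short_plantar`` elements sharing its stiffness.
    Midfoot rows derive their exponential law from the ligament area, not the
    printed (rounded) ratio.

    ``in_situ_strain`` applies to the exponential-law ligaments, whose toe
    region keeps the resulting pretension at a few newtons.  Linear-law
    elements (tibionavicular, plantar fascia, long/short plantar ligaments)
    default to a much smaller 0.2% assembly strain: their stiffnesses are
    of order 10^2 N/mm over long spans, so a blanket 4% strain would
    preload the arch with a non-physiological ~1.5 kN, while 0.2% leaves a
    modest resting tie tension (~80 N in the fascia) that keeps the midfoot
    facets seated.  Both defaults are overridable.
    """
    specs: dict[str, LigamentSpec] = {}
    tib = load_tibial_table()
    for row in tib.itertuples(index=False):
        if pd.isna(row.a_N):
            law: LawParams = LinearLawParams(float(row.k_N_per_mm))
            eps = linear_in_situ_strain
        else:
            law = ExpLawParams(float(row.a_N), float(row.b))
            eps = in_situ_strain
        specs[row.ligament] = LigamentSpec(row.ligament, law, eps)
    for row in load_midfoot_table().itertuples(index=False):
        law = atfl_scaled_params(float(row.area_mm2))
        specs[row.ligament] = LigamentSpec(row.ligament, law, in_situ_strain)
    plantar = load_plantar_table().set_index("structure")["k_N_per_mm"]
    specs["plantar_fascia"] = LigamentSpec(
        "plantar_fascia",
        LinearLawParams(float(plantar["plantar_fascia"])),
        linear_in_situ_strain,
    )
    k_lsp = float(plantar["long_short_plantar_ligament"])
    for name in ("long_plantar", "short_plantar"):
        specs[name] = LigamentSpec(name, LinearLawParams(k_lsp), linear_in_situ_strain)
    return specs


@dataclass(frozen=True)
class TableCheckRow:
    """Outcome of recomputing one midfoot-table area ratio."""

    ligament: str
    area_mm2: float
    printed_ratio: float
    computed_ratio: float
    matches_3dp: bool
    documented_exception: bool


def check_tables(reference_area: float = ATFL_REFERENCE_AREA_MM2) -> list[TableCheckRow]:
    """Recompute every midfoot area ratio and compare to the printed column at 3 dp.

    All rows agree except the superomedial calcaneonavicular ligament, whose
    printed 2.560 differs from the recomputed 2.562; that row is flagged as
    the documented exception rather than a failure.
    """
    rows = []
    for row in load_midfoot_table().itertuples(index=False):
        computed = area_ratio(float(row.area_mm2), reference_area)
        matches = round(computed, 3) == round(float(row.area_ratio), 3)
        rows.append(
            TableCheckRow(
                ligament=row.ligament,
                area_mm2=float(row.area_mm2),
                printed_ratio=float(row.area_ratio),
                computed_ratio=computed,
                matches_3dp=matches,
                documented_exception=(not matches) and row.ligament == RATIO_EXCEPTION_LIGAMENT,
            )
        )
    return rows
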