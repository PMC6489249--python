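"""Model assembly: element counts, calibration, scenario transforms."""

import numpy as np
import pytest

import footmech as fm
from footmech import constitutive as law
from footmech.assembly import (
    FLATFOOT_ATTENUATED_STRUCTURES,
    DEFAULT_MUSCLE_FRACTIONS,
    STANDING_MUSCLE_FRACTIONS,
    ModelOptions,
    ScenarioStateError,
    add_reconstruction,
    apply_flatfoot,
    build_intact_model,
    winkler_foundation_stiffness,
)


class TestBuildIntact:
    def test_element_count_is_tables_plus_plantar_plus_muscles(self, intact_model):
        # 9 tibial + 13 midfoot + fascia + long/short plantar + 7 muscles
        ligaments = [e for e in intact_model.elements if e.kind == "ligament"]
        muscles = [e for e in intact_model.elements if e.kind == "muscle"]
        assert len(ligaments) == 25
        assert len(muscles) == 7
        assert len(intact_model.elements) == 32

    def test_build_pose_strain_equals_in_situ_strain(self, intact_model):
        for el in intact_model.elements:
            if el.kind != "ligament":
                continue
            L = intact_model.build_length(el)
            strain = (L - el.slack_length) / el.slack_length
            assert strain == pytest.approx(el.spec.in_situ_strain, abs=1e-12), el.name

    def test_zero_pretension_build_pose_is_exact_equilibrium(self, default_geometry):
        """With all in-situ strains zero, no muscles and no load, the build
        pose balances exactly (every element at slack, every contact
        touching at zero pressure)."""
        from footmech import constitutive as law
        from footmech.assembly import LoadCase
        from footmech.solver import build_pose, residual_norm

        specs = law.build_ligament_specs(in_situ_strain=0.0, linear_in_situ_strain=0.0)
        model = build_intact_model(
            default_geometry,
            specs=specs,
            options=ModelOptions(muscle_fractions={}),
            load_case=LoadCase(axial_load=0.0),
        )
        assert residual_norm(model, build_pose(model)) <= 1e-9

    def test_all_contacts_frictionless(self, intact_model):
        assert all(cp.friction_coefficient == 0.0 for cp in intact_model.contact_pairs)

    def test_tibiofibular_ligaments_are_intra_segment_and_inert(self, intact_model):
        for name in ("anterior_tibiofibular", "posterior_tibiofibular"):
            el = intact_model.element(name)
            assert el.inert
            assert el.segments_spanned == ("tibia",)

    def test_tibia_rides_vertical_rig(self, intact_model):
        tibia = intact_model.segments["tibia"]
        assert tibia.free_dofs == (False, False, True, False, False, False)
        free = {s.name for s in intact_model.free_segments()}
        assert free == {"tibia", "talus", "calcaneus", "navicular", "cuboid", "forefoot"}

    def test_cartilage_foundation_is_winkler_reduction(self, intact_model):
        k = winkler_foundation_stiffness(10.0, 0.45, 2.0)
        assert k == pytest.approx(10.0 * 0.55 / (1.45 * 0.1 * 2.0), rel=1e-12)
        joint_pairs = [cp for cp in intact_model.contact_pairs if cp.kind == "joint"]
        assert joint_pairs
        for cp in joint_pairs:
            assert cp.foundation.stiffness == pytest.approx(k)

    def test_default_muscles_are_passive(self, intact_model):
        assert all(v == 0.0 for v in DEFAULT_MUSCLE_FRACTIONS.values())
        for el in intact_model.elements:
            if el.kind == "muscle":
                assert el.spec.constant_force == 0.0
        assert all(v > 0 for v in STANDING_MUSCLE_FRACTIONS.values())

    def test_with_load_rescales_muscles(self, default_geometry):
        m = build_intact_model(
            default_geometry,
            options=ModelOptions(muscle_fractions=STANDING_MUSCLE_FRACTIONS),
        )
        achilles = m.element("muscle_achilles")
        assert achilles.spec.constant_force == pytest.approx(0.125 * 680.0)
        m2 = m.with_load(340.0)
        assert m2.element("muscle_achilles").spec.constant_force == pytest.approx(42.5)


class TestFlatfoot:
    def test_attenuates_exactly_the_named_set(self, default_geometry):
        m = build_intact_model(default_geometry)
        flat = apply_flatfoot(m, factor=0.5)
        before = {e["name"]: e for e in m.to_dict()["elements"]}
        after = {e["name"]: e for e in flat.to_dict()["elements"]}
        changed = {n for n in before if before[n] != after[n]}
        assert changed == set(FLATFOOT_ATTENUATED_STRUCTURES)

    def test_plantar_fascia_halved(self, default_geometry):
        flat = apply_flatfoot(build_intact_model(default_geometry), factor=0.5)
        assert flat.element("plantar_fascia").spec.effective_law.k == pytest.approx(101.65)
        # untouched example
        atfl = flat.element("anterior_talofibular").spec.effective_law
        assert (atfl.a, atfl.b) == (pytest.approx(7.18), pytest.approx(12.50))

    def test_reapplication_is_a_state_error(self, default_geometry):
        flat = apply_flatfoot(build_intact_model(default_geometry))
        with pytest.raises(ScenarioStateError):
            apply_flatfoot(flat)

    def test_factor_one_is_identity(self, default_geometry):
        m = build_intact_model(default_geometry)
        flat = apply_flatfoot(m, factor=1.0)
        for el, el2 in zip(m.elements, flat.elements):
            if el.kind == "ligament":
                assert el2.spec.attenuation_factor == el.spec.attenuation_factor

    def test_invalid_factor_rejected(self, default_geometry):
        m = build_intact_model(default_geometry)
        with pytest.raises(law.ParameterError):
            apply_flatfoot(m, factor=0.0)


class TestReconstruction:
    @pytest.fixture()
    def flat(self, default_geometry):
        return apply_flatfoot(build_intact_model(default_geometry))

    def test_requires_flatfoot_state(self, default_geometry):
        with pytest.raises(ScenarioStateError):
            add_reconstruction(build_intact_model(default_geometry), "ISLR")

    def test_islr_adds_one_graft_nav_to_calc(self, flat):
        recon = add_reconstruction(flat, "ISLR")
        grafts = [e for e in recon.elements if e.kind == "graft"]
        assert len(grafts) == 1
        assert set(grafts[0].segments_spanned) == {"navicular", "calcaneus"}
        assert recon.scenario == "flatfoot+ISLR"

    def test_aslr_adds_two_limbs(self, flat):
        grafts = [e for e in add_reconstruction(flat, "ASLR").elements if e.kind == "graft"]
        assert len(grafts) == 2

    def test_csplr_spans_tied_at_tunnels(self, flat):
        """The continuous route splits into bone-to-bone spans (graft tied at
        each tunnel); intra-bone passes are inert and dropped."""
        grafts = [e for e in add_reconstruction(flat, "CSPLR").elements if e.kind == "graft"]
        assert len(grafts) == 2
        spanned = [set(g.segments_spanned) for g in grafts]
        assert {"forefoot", "calcaneus"} in spanned  # plantar tie span
        assert {"calcaneus", "navicular"} in spanned  # superomedial span

    def test_graft_taut_at_reference_positions(self, flat):
        recon = add_reconstruction(flat, "ISLR")
        (graft,) = [e for e in recon.elements if e.kind == "graft"]
        assert recon.build_length(graft) == pytest.approx(graft.slack_length, rel=1e-12)
        assert graft.spec.elastic_modulus == 2769.0
        assert graft.spec.area == 37.0

    def test_peroneus_longus_harvested(self, flat):
        recon = add_reconstruction(flat, "CSILR")
        assert "muscle_peroneus_longus" not in recon.element_names()
        # toggleable
        keep = ModelOptions(harvest_peroneus_longus=False)
        from dataclasses import replace

        flat2 = replace(flat, options=keep)
        recon2 = add_reconstruction(flat2, "CSILR")
        assert "muscle_peroneus_longus" in recon2.element_names()

    def test_removing_graft_restores_flatfoot_model(self, flat):
        recon = add_reconstruction(flat, "ASLR")
        stripped = [e for e in recon.elements if e.kind != "graft"]
        flat_names = [e for e in flat.elements if e.name != "muscle_peroneus_longus"]
        assert [e.name for e in stripped] == [e.name for e in flat_names]
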