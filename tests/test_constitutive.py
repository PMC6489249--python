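"""Constitutive laws and property tables against independent hand oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from footmech import constitutive as law


TABLE1_PARAMS = [
    ("anterior_talofibular", 7.18, 12.50),
    ("anterior_tibiofibular", 5.52, 22.63),
    ("anterior_tibiotalar", 2.06, 20.11),
    ("calcaneofibular", 0.20, 49.63),
    ("posterior_talofibular", 0.14, 44.35),
    ("posterior_tibiofibular", 6.87, 20.07),
    ("posterior_tibiotalar", 1.34, 28.65),
    ("tibiocalcaneal", 0.51, 45.99),
]


class TestExponentialLaw:
    @pytest.mark.parametrize(
        "strain,a,b,expected",
        [
            (0.0, 7.18, 12.50, 0.0),
            (-0.05, 7.18, 12.50, 0.0),  # tension-only clamp
            # hand arithmetic: 7.18 * (e^1.25 - 1)
            (0.10, 7.18, 12.50, 7.18 * (math.e**1.25 - 1.0)),
        ],
    )
    def test_printed_examples(self, strain, a, b, expected):
        got = law.exp_tension_force(strain, law.ExpLawParams(a, b))
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_matches_hand_oracle_over_table_ranges(self):
        """Random (strain, params) draws agree with direct a*(e^(b*eps)-1)."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            name, a, b = TABLE1_PARAMS[rng.integers(len(TABLE1_PARAMS))]
            eps = float(rng.uniform(-0.05, 0.15))
            oracle = a * (math.exp(b * eps) - 1.0) if eps > 0 else 0.0
            got = law.exp_tension_force(eps, law.ExpLawParams(a, b))
            assert got == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        idx=st.integers(0, len(TABLE1_PARAMS) - 1),
        eps1=st.floats(1e-6, 0.2),
        scale=st.floats(1.01, 3.0),
    )
    def test_strictly_increasing_in_tension(self, idx, eps1, scale):
        _, a, b = TABLE1_PARAMS[idx]
        p = law.ExpLawParams(a, b)
        assert law.exp_tension_force(eps1 * scale, p) > law.exp_tension_force(eps1, p)

    def test_continuity_at_zero(self):
        for _, a, b in TABLE1_PARAMS:
            p = law.ExpLawParams(a, b)
            assert law.exp_tension_force(1e-12, p) == pytest.approx(0.0, abs=1e-9)
            assert law.exp_tension_force(0.0, p) == 0.0
            assert law.exp_tension_force(-1e-12, p) == 0.0

    def test_rejects_nonfinite_strain(self):
        with pytest.raises(ValueError):
            law.exp_tension_force(float("nan"), law.ExpLawParams(7.18, 12.5))


class TestLinearLaw:
    @pytest.mark.parametrize(
        "dl,k,expected",
        [(0.0, 203.3, 0.0), (1.0, 203.3, 203.3), (-2.0, 39.1, 0.0)],
    )
    def test_examples(self, dl, k, expected):
        assert law.linear_tension_force(dl, law.LinearLawParams(k)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_hand_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = float(rng.uniform(10.0, 300.0))
            dl = float(rng.uniform(-2.0, 5.0))
            oracle = k * dl if dl > 0 else 0.0
            got = law.linear_tension_force(dl, law.LinearLawParams(k))
            assert got == pytest.approx(oracle, rel=1e-12, abs=1e-12)


class TestAreaScaling:
    @pytest.mark.parametrize(
        "area,expected_3dp",
        [(14.4, 0.229), (62.85, 1.000), (98.70, 1.570)],
    )
    def test_area_ratio_printed_values(self, area, expected_3dp):
        assert round(law.area_ratio(area), 3) == pytest.approx(expected_3dp)

    def test_scaled_params(self):
        p = law.atfl_scaled_params(62.85)
        assert (p.a, p.b) == (pytest.approx(7.18), pytest.approx(12.50))
        p = law.atfl_scaled_params(14.4)
        assert p.a == pytest.approx(7.18 * 14.4 / 62.85, rel=1e-12)
        assert p.b == 12.50

    def test_force_proportional_to_area(self):
        """Doubling the cross-section doubles the force at any fixed strain."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            area = float(rng.uniform(5.0, 170.0))
            eps = float(rng.uniform(0.01, 0.15))
            f1 = law.exp_tension_force(eps, law.atfl_scaled_params(area))
            f2 = law.exp_tension_force(eps, law.atfl_scaled_params(2 * area))
            assert f2 == pytest.approx(2 * f1, rel=1e-9)

    def test_rejects_bad_inputs(self):
        with pytest.raises(law.ParameterError):
            law.area_ratio(10.0, reference_area=0.0)
        with pytest.raises(law.ParameterError):
            law.atfl_scaled_params(-1.0)


class TestSlackLength:
    def test_algebraic_identities(self):
        assert law.slack_length_from_build(104.0, 0.04) == pytest.approx(100.0)
        assert law.slack_length_from_build(50.0, 0.0) == pytest.approx(50.0)

    def test_round_trip(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            L = float(rng.uniform(5.0, 300.0))
            eps = float(rng.uniform(0.0, 0.1))
            slack = law.slack_length_from_build(L, eps)
            assert (L - slack) / slack == pytest.approx(eps, abs=1e-12)


class TestGraft:
    def test_axial_stiffness_hand_values(self):
        k = law.graft_axial_stiffness(law.GraftParams(2769.0, 37.0, 102.453))
        assert k == pytest.approx(2769.0 * 37.0 / 102.453, rel=1e-12)
        assert k == pytest.approx(1000.0, rel=1e-4)
        k50 = law.graft_axial_stiffness(law.GraftParams(2769.0, 37.0, 50.0))
        assert k50 == pytest.approx(2049.06, rel=1e-4)

    def test_doubling_length_halves_stiffness(self):
        k1 = law.graft_axial_stiffness(law.GraftParams(slack_length=40.0))
        k2 = law.graft_axial_stiffness(law.GraftParams(slack_length=80.0))
        assert k1 == pytest.approx(2 * k2, rel=1e-12)

    def test_default_constants(self):
        g = law.GraftParams()
        assert (g.elastic_modulus, g.area) == (2769.0, 37.0)


class TestAttenuate:
    def make_spec(self, linear=False):
        lw = law.LinearLawParams(203.3) if linear else law.ExpLawParams(7.18, 12.5)
        return law.LigamentSpec("x", lw)

    def test_halves_linear_stiffness(self):
        spec = law.attenuate(self.make_spec(linear=True), 0.5)
        assert spec.effective_law.k == pytest.approx(101.65)

    def test_identity(self):
        spec = self.make_spec()
        assert law.attenuate(spec, 1.0).effective_law.a == pytest.approx(7.18)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(f1=st.floats(0.1, 1.0), f2=st.floats(0.1, 1.0))
    def test_composition_multiplies(self, f1, f2):
        spec = self.make_spec()
        ab = law.attenuate(law.attenuate(spec, f1), f2)
        direct = law.attenuate(spec, f1 * f2)
        assert ab.effective_law.a == pytest.approx(direct.effective_law.a, rel=1e-12)

    def test_exponent_unchanged_and_force_scales(self):
        """Halving the force scale halves the force at every strain."""
        spec = self.make_spec()
        half = law.attenuate(spec, 0.5)
        assert half.effective_law.b == spec.effective_law.b
        for eps in (0.01, 0.05, 0.12):
            f_full = law.exp_tension_force(eps, spec.effective_law)
            f_half = law.exp_tension_force(eps, half.effective_law)
            assert f_half == pytest.approx(0.5 * f_full, rel=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(law.ParameterError):
            law.attenuate(self.make_spec(), 0.0)
        with pytest.raises(law.ParameterError):
            law.attenuate(self.make_spec(), 1.5)


class TestTables:
    def test_tibial_table_row_count_and_values(self):
        t = law.load_tibial_table()
        assert len(t) == 9
        atfl = t[t.ligament == "anterior_talofibular"].iloc[0]
        assert (atfl.a_N, atfl.b) == (7.18, 12.50)
        tn = t[t.ligament == "tibionavicular"].iloc[0]
        assert tn.k_N_per_mm == 39.1

    def test_midfoot_table_has_13_rows(self):
        assert len(law.load_midfoot_table()) == 13

    def test_check_tables_all_pass_except_documented_exception(self):
        rows = law.check_tables()
        assert len(rows) == 13
        mismatches = [r for r in rows if not r.matches_3dp]
        assert len(mismatches) == 1
        (smcn,) = mismatches
        assert smcn.ligament == "superomedial_calcaneonavicular"
        assert smcn.documented_exception
        assert smcn.printed_ratio == pytest.approx(2.560)
        assert round(smcn.computed_ratio, 3) == pytest.approx(2.562)

    def test_reference_area_override_identity(self):
        default = law.check_tables()
        override = law.check_tables(reference_area=62.85)
        assert [r.computed_ratio for r in default] == [r.computed_ratio for r in override]

    def test_specs_cover_tables_plus_plantar_structures(self):
        specs = law.build_ligament_specs()
        # 9 tibial + 13 midfoot + fascia + long + short plantar
        assert len(specs) == 25
        assert specs["plantar_fascia"].effective_law.k == pytest.approx(203.3)
        assert specs["long_plantar"].effective_law.k == pytest.approx(75.9)
        assert specs["short_plantar"].effective_law.k == pytest.approx(75.9)
        smcn = specs["superomedial_calcaneonavicular"].effective_law
        assert smcn.a == pytest.approx(7.18 * 161.0 / 62.85, rel=1e-12)
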