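"""Profile I/O, display rounding, fixtures and report round-trips."""

import json

import pytest
import yaml

from nanowaste.report import (
    FixtureSpec,
    ProfileValidationError,
    assess,
    bundle_from_dict,
    format_interval,
    format_value,
    generate_fixtures,
    load_profile,
    packaged_profile,
    render_report,
    report_from_dict,
    round_sig,
    truncate_int,
)
from nanowaste.quantification import enm_mass_in_nanowaste, eol_nanowaste_mass


MINIMAL = {
    "product_id": "mini",
    "enm_type": "Ag",
    "assessment_year": 2011,
    "x_production": {"value": 1000, "unit": "Mg/year"},
    "retention_time_years": 1,
    "F_pen": 0.5,
    "F_eol": 0.5,
    "C_NM": {"value": 100, "unit": "mg/kg"},
    "F_NM": 1.0,
}


class TestLoadProfile:
    def test_packaged_textile_parameters(self, textile_bundle):
        p = textile_bundle.profile
        assert p.market_penetration.low == 0.001
        assert p.eol_fraction.low == 0.9
        assert p.enm_concentration.unit == "mg/kg"
        assert (p.enm_concentration.low, p.enm_concentration.high) == (100, 240)
        assert p.enm_eol_fraction.high == 0.99
        assert textile_bundle.x_production.low == pytest.approx(26.3e6)
        assert p.market_penetration.sources  # provenance carried through

    def test_fraction_out_of_bounds_names_field(self):
        bad = dict(MINIMAL, F_pen=1.2)
        with pytest.raises(ProfileValidationError, match="market_penetration"):
            bundle_from_dict(bad)

    def test_empty_file_is_a_parse_error(self, tmp_path):
        f = tmp_path / "empty.yaml"
        f.write_text("")
        with pytest.raises(ProfileValidationError, match="empty"):
            load_profile(f)

    def test_missing_field_reported_with_path(self):
        bad = {k: v for k, v in MINIMAL.items() if k != "C_NM"}
        with pytest.raises(ProfileValidationError, match="C_NM"):
            bundle_from_dict(bad)

    def test_bad_treatment_shares_reported(self):
        bad = dict(MINIMAL, treatment_shares={"RC": 0.5})
        with pytest.raises(ProfileValidationError, match="treatment_shares"):
            bundle_from_dict(bad)


class TestRounding:
    @pytest.mark.parametrize(
        "value,sigfigs,expected",
        [
            (23_670, 3, "23.7 × 10^3"),
            (0.7811, 2, "0.78"),
            (5.623992, 2, "5.6"),
            (715.476, 3, "715"),
            (1430.952, 3, "1430"),
            (26.264e6, 3, "26.3 × 10^6"),
            (0.467115, 2, "0.47"),
            (1.22925, 3, "1.23"),
            (0, 3, "0"),
        ],
    )
    def test_display_forms(self, value, sigfigs, expected):
        assert format_value(value, sigfigs) == expected

    def test_truncate_mode_versus_rounding(self):
        # the flagged truncate-to-integer mode for legacy table cells
        assert format_value(313.5, truncate=True) == "313"
        assert format_value(313.5, 3) == "314"
        assert truncate_int(313.5) == 313

    def test_round_sig_half_away_from_zero(self):
        assert round_sig(0.785, 2) == pytest.approx(0.79)
        assert round_sig(23_670, 3) == 23_700

    def test_interval_formatting(self):
        from nanowaste.units import interval

        assert format_interval(interval([0.781110, 5.623992], "Mg/year"), 2) == (
            "0.78-5.6 Mg/year"
        )


class TestFixtures:
    def test_seeded_determinism_byte_identical(self):
        a = generate_fixtures(FixtureSpec(n_profiles=10, seed=42))
        b = generate_fixtures(FixtureSpec(n_profiles=10, seed=42))
        assert yaml.safe_dump_all(a, sort_keys=True) == yaml.safe_dump_all(
            b, sort_keys=True
        )

    def test_different_seeds_differ(self):
        a = generate_fixtures(FixtureSpec(n_profiles=5, seed=1))
        b = generate_fixtures(FixtureSpec(n_profiles=5, seed=2))
        assert a != b

    def test_generated_profiles_pass_validation(self):
        for d in generate_fixtures(FixtureSpec(n_profiles=25, seed=7)):
            bundle = bundle_from_dict(d)  # must not raise
            assert 0 <= bundle.profile.market_penetration.high <= 1

    def test_generated_profiles_respect_mass_bound_end_to_end(self):
        """NM never exceeds X times the peak concentration fraction."""
        for d in generate_fixtures(FixtureSpec(n_profiles=25, seed=13)):
            bundle = bundle_from_dict(d)
            p = bundle.profile
            X = eol_nanowaste_mass(p, bundle.x_production)
            NM = enm_mass_in_nanowaste(p, X)
            peak = p.enm_concentration.as_fraction().high
            assert NM.high <= X.high * peak * (1 + 1e-12)


class TestReportRoundTrip:
    def test_serialise_load_rerender_idempotent(self, textile_bundle):
        report = assess(textile_bundle)
        d1 = report.to_dict()
        blob = json.dumps(d1, sort_keys=True)
        rebuilt = report_from_dict(json.loads(blob))
        d2 = rebuilt.to_dict()
        assert d1 == d2
        assert render_report(rebuilt) == render_report(report)

    def test_full_precision_retained_alongside_display(self, textile_bundle):
        d = assess(textile_bundle).to_dict()
        assert d["enm_mass"]["low"] == pytest.approx(0.781110)
        assert d["eol_mass_display"] == "23.7 × 10^3 Mg/year"


class TestAssessPipeline:
    def test_textile_report_contents(self, textile_bundle):
        report = assess(textile_bundle)
        text = render_report(report)
        assert "23.7 × 10^3 Mg/year" in text
        assert "MEDIUM" in text
        assert report.allocation  # 5 % RC / 95 % IN split present

    def test_racquet_flue_gas_cleaning_suppresses_air(self, racquet_bundle):
        report = assess(racquet_bundle)
        from nanowaste.fate import Compartment, RouteQualifier, TreatmentTechnology

        route = report.routes[TreatmentTechnology.IN]
        assert route.qualifiers[Compartment.AIR] is RouteQualifier.NEGLIGIBLE

    def test_sunscreen_landfill_water_primary(self, sunscreen_bundle):
        report = assess(sunscreen_bundle)
        from nanowaste.fate import Compartment, RouteQualifier, TreatmentTechnology

        route = report.routes[TreatmentTechnology.LF]
        assert route.qualifiers[Compartment.WATER] is RouteQualifier.PRIMARY
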