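"""Step-1 quantification: production helpers, Eq.-style mass chains, by-products."""

import pytest
from hypothesis import given, settings, strategies as st

from nanowaste.quantification import (
    ByproductRate,
    NanoproductProfile,
    ProductionRecord,
    backcast_production,
    byproduct_mass,
    enm_mass_in_nanowaste,
    enm_used_in_manufacture,
    eol_nanowaste_mass,
    market_units_to_mass,
    packaged_byproduct_rates,
    quantify,
)
from nanowaste.report import round_sig
from nanowaste.units import Quantity, interval, interval_product, propagate_mc


def mass_record(mass, year, growth=0.0, pid="p"):
    return ProductionRecord(
        product_id=pid,
        reference_year=year,
        production_mass=interval(mass, "Mg/year"),
        annual_growth=growth,
    )


class TestBackcastProduction:
    def test_polyester_one_year_growth(self):
        # 24.5e6 Mg in 2004 at 7.2 %/year -> 26.264e6, printed as 26.3e6
        out = backcast_production(mass_record(24.5e6, 2004, 0.072), 2005)
        assert out.low == pytest.approx(26.264e6)
        assert round_sig(out.low, 3) == pytest.approx(26.3e6)

    def test_reference_year_is_identity(self):
        rec = mass_record(1234.5, 2010, 0.3)
        out = backcast_production(rec, 2010)
        assert out.low == out.high == 1234.5

    def test_two_year_compounding(self):
        out = backcast_production(mass_record(24.5e6, 2004, 0.072), 2006)
        assert out.low == pytest.approx(24.5e6 * 1.072**2)

    def test_negative_exponent_backcasts(self):
        out = backcast_production(mass_record(26.264e6, 2005, 0.072), 2004)
        assert out.low == pytest.approx(24.5e6)

    def test_market_units_record_redirected(self):
        rec = ProductionRecord(
            product_id="u",
            reference_year=2008,
            market_units=interval(1e6, "units/year"),
            unit_mass=Quantity(200, "g"),
        )
        with pytest.raises(ValueError, match="market_units_to_mass"):
            backcast_production(rec, 2010)


class TestMarketUnitsToMass:
    def test_suncare_market(self):
        rec = ProductionRecord(
            product_id="sunscreen",
            reference_year=2008,
            market_units=interval(547e6, "units/year"),
            unit_mass=Quantity(200, "g"),
            sector_fraction=0.654,
        )
        out = market_units_to_mass(rec)
        assert out.unit == "Mg/year"
        assert out.low == pytest.approx(71547.6)
        assert round_sig(out.low, 3) == pytest.approx(71.5e3)

    def test_zero_units(self):
        rec = ProductionRecord(
            product_id="z",
            reference_year=2000,
            market_units=interval(0, "units/year"),
            unit_mass=Quantity(200, "g"),
        )
        assert market_units_to_mass(rec).high == 0.0

    def test_unit_bookkeeping_kg(self):
        rec = ProductionRecord(
            product_id="kg",
            reference_year=2000,
            market_units=interval(1e6, "units/year"),
            unit_mass=Quantity(1, "kg"),
        )
        assert market_units_to_mass(rec).low == pytest.approx(1000.0)

    def test_missing_unit_mass(self):
        rec = ProductionRecord(
            product_id="m",
            reference_year=2000,
            market_units=interval(1e6, "units/year"),
        )
        with pytest.raises(ValueError, match="unit_mass"):
            market_units_to_mass(rec)

    def test_exactly_one_basis_enforced(self):
        with pytest.raises(ValueError, match="exactly one"):
            ProductionRecord(
                product_id="both",
                reference_year=2000,
                production_mass=interval(1, "Mg/year"),
                market_units=interval(1, "units/year"),
            )


def make_profile(f_pen, f_eol, c_nm, c_unit, f_nm, pid="p"):
    return NanoproductProfile(
        product_id=pid,
        enm_type="Ag",
        retention_time_years=6,
        market_penetration=interval(f_pen),
        eol_fraction=interval(f_eol),
        enm_concentration=interval(c_nm, c_unit),
        enm_eol_fraction=interval(f_nm),
    )


TEXTILE = make_profile(0.001, 0.9, [100, 240], "mg/kg", [0.33, 0.99])
SUNSCREEN = make_profile(0.1, [0.1, 0.2], [2, 10], "percent", 1.0)
RACQUET = make_profile([0.2, 0.5], [0.95, 1.0], 1.49, "g/kg", 1.0)


class TestNanowasteMass:
    def test_textile(self):
        X = eol_nanowaste_mass(TEXTILE, interval(26.3e6, "Mg/year"))
        assert X.low == pytest.approx(23_670.0)

    def test_sunscreen(self):
        X = eol_nanowaste_mass(SUNSCREEN, interval(71.5e3, "Mg/year"))
        assert X.low == pytest.approx(715.0)
        assert X.high == pytest.approx(1430.0)

    def test_racquet(self):
        X = eol_nanowaste_mass(RACQUET, interval(1650, "Mg/year"))
        assert (X.low, X.high) == (pytest.approx(313.5), pytest.approx(825.0))

    def test_zero_penetration_absorbs(self):
        p = make_profile(0.0, [0.5, 1.0], 100, "mg/kg", 1.0)
        X = eol_nanowaste_mass(p, interval([1e3, 1e6], "Mg/year"))
        assert X.low == X.high == 0.0

    def test_fraction_above_one_rejected(self):
        with pytest.raises(ValueError, match="market_penetration"):
            make_profile(1.2, 0.9, 100, "mg/kg", 1.0)


class TestEnmMass:
    def test_textile(self):
        NM = enm_mass_in_nanowaste(TEXTILE, interval(23_670, "Mg/year"))
        assert NM.low == pytest.approx(0.781110)
        assert NM.high == pytest.approx(5.623992)
        assert round_sig(NM.low, 2) == pytest.approx(0.78)
        assert round_sig(NM.high, 2) == pytest.approx(5.6)

    def test_sunscreen(self):
        NM = enm_mass_in_nanowaste(SUNSCREEN, interval([715, 1430], "Mg/year"))
        assert NM.low == pytest.approx(14.3)
        assert NM.high == pytest.approx(143.0)

    def test_racquet(self):
        NM = enm_mass_in_nanowaste(RACQUET, interval([313.5, 825], "Mg/year"))
        assert NM.low == pytest.approx(0.467115)
        assert NM.high == pytest.approx(1.22925)

    def test_zero_concentration(self):
        p = make_profile(0.5, 0.5, 0.0, "mg/kg", 1.0)
        NM = enm_mass_in_nanowaste(p, interval([10, 20], "Mg/year"))
        assert NM.high == 0.0


class TestManufactureUse:
    def test_nanosilver_in_textiles(self):
        out = enm_used_in_manufacture(
            interval(26.3e3, "Mg"), interval([100, 238.5], "g/Mg")
        )
        assert round_sig(out.low, 2) == pytest.approx(2.6)
        assert round_sig(out.high, 2) == pytest.approx(6.3)

    def test_zero_production(self):
        out = enm_used_in_manufacture(interval(0, "Mg"), interval(100, "g/Mg"))
        assert out.high == 0.0

    def test_hand_multiplication(self):
        out = enm_used_in_manufacture(interval(1e4, "Mg"), interval(50, "g/Mg"))
        assert out.low == pytest.approx(0.5)


class TestByproducts:
    def test_hipco_soot(self):
        rate = ByproductRate("SWCNT", "Carbon soot", interval(1250, "g/g"))
        out = byproduct_mass(rate, Quantity(1, "kg"))
        assert out.unit == "kg"
        assert out.low == pytest.approx(1250.0)

    def test_fullerene_soot_range(self):
        rate = ByproductRate("Fullerene", "Carbon soot", interval([7.22, 25.6], "g/g"))
        out = byproduct_mass(rate, Quantity(10, "kg"))
        assert (out.low, out.high) == (pytest.approx(72.2), pytest.approx(256.0))

    def test_zero_production(self):
        rate = ByproductRate("Ag", "Ag+ in H2O solution", interval(0.43, "g/g"))
        assert byproduct_mass(rate, Quantity(0, "kg")).high == 0.0

    def test_solvent_volume_rate(self):
        rate = ByproductRate("Au", "Thiol solvent", interval(15, "L/g"))
        out = byproduct_mass(rate, Quantity(2, "g"))
        assert out.unit == "L"
        assert out.low == pytest.approx(30.0)

    def test_incompatible_rate_unit_rejected(self):
        with pytest.raises(ValueError, match="rate unit"):
            ByproductRate("Ag", "bad", interval(1, "Mg"))

    def test_packaged_table_loads(self):
        rates = packaged_byproduct_rates()
        assert len(rates) == 15
        hipco = [r for r in rates if "HiPco" in r.process_note and r.rate.low == 1250]
        assert len(hipco) == 1 and hipco[0].enm_type == "SWCNT"
        assert all(r.rate.low >= 0 for r in rates)


@settings(derandomize=True, max_examples=150)
@given(
    x=st.floats(0, 1e8),
    f_pen=st.floats(0, 1.0),
    f_eol=st.floats(0, 1.0),
    bump=st.floats(0, 0.5),
)
def test_nanowaste_mass_monotone_in_every_factor(x, f_pen, f_eol, bump):
    base = eol_nanowaste_mass(
        make_profile(f_pen, f_eol, 100, "mg/kg", 1.0), interval(x, "Mg/year")
    )
    more_pen = eol_nanowaste_mass(
        make_profile(min(f_pen + bump, 1.0), f_eol, 100, "mg/kg", 1.0),
        interval(x, "Mg/year"),
    )
    more_prod = eol_nanowaste_mass(
        make_profile(f_pen, f_eol, 100, "mg/kg", 1.0),
        interval(x * (1 + bump), "Mg/year"),
    )
    assert more_pen.high >= base.high and more_pen.low >= base.low
    assert more_prod.high >= base.high and more_prod.low >= base.low


@settings(derandomize=True, max_examples=100)
@given(
    x_hi=st.floats(1.0, 1e6),
    c_hi=st.floats(1.0, 1e5),
    f_hi=st.floats(0.01, 1.0),
)
def test_enm_mass_bounded_by_peak_concentration(x_hi, c_hi, f_hi):
    """NM never exceeds the nanowaste mass times the peak concentration."""
    p = make_profile(1.0, 1.0, [c_hi / 2, c_hi], "mg/kg", [f_hi / 2, f_hi])
    X = interval([x_hi / 2, x_hi], "Mg/year")
    NM = enm_mass_in_nanowaste(p, X)
    assert NM.high <= X.high * (c_hi * 1e-6) * (1 + 1e-12)


def test_end_to_end_envelope_matches_mc_extrema():
    """Monte-Carlo extrema stay inside the analytic envelope and converge
    toward its endpoints as the sample size grows."""
    chain = [
        interval([20e6, 30e6], "Mg/year"),
        interval([0.001, 0.002]),
        interval([0.8, 0.9]),
        interval([100, 240], "mg/kg"),
        interval([0.33, 0.99]),
    ]
    env = interval_product(chain)
    small = propagate_mc(chain, n=1_000, seed=3)
    large = propagate_mc(chain, n=200_000, seed=3)
    for s in (small, large):
        assert env.low <= s.min <= s.max <= env.high
    # wider coverage of the envelope at larger n
    assert large.min <= small.min and large.max >= small.max
    assert (large.max - large.min) > 0.5 * (env.high - env.low)


def test_quantify_records_trace(textile_bundle):
    res = quantify(
        textile_bundle.profile, textile_bundle.x_production, 2011
    )
    assert [s.operation for s in res.trace] == [
        "eol_nanowaste_mass",
        "enm_mass_in_nanowaste",
    ]
    assert res.trace[0].output == res.eol_mass
    assert res.enm_mass.low == pytest.approx(0.781110)
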