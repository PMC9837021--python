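"""Composition pipeline: mass normalization, crystallinity, volume
fractions, densities, lumen porosity, and scenario construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibermech.composition import (
    CW_PHASES,
    MASS_PHASES,
    FiberRecord,
    Triple,
    build_scenarios,
    cellwall_density,
    cellwall_volume_fractions,
    crystallinity_mass,
    lumen_porosity,
    normalize_masses,
    random_fiber_record,
    rve_fractions,
)


class TestNormalizeMasses:
    def test_deficit_goes_to_nanopores(self):
        # banana-type record: raw sum 98 -> 2 % unassigned extractives
        raw = dict(zip(MASS_PHASES, (71, 10, 8, 4, 5, 0)))
        m = normalize_masses(raw)
        assert m["npor"] == pytest.approx(2.0)
        assert m["totcel"] == pytest.approx(71.0)
        assert sum(m.values()) == pytest.approx(100.0)

    def test_excess_scaled_proportionally(self):
        # alfa-type record: raw sum 125 -> everything scaled by 0.8
        raw = dict(zip(MASS_PHASES, (45, 39, 39, 0, 0, 2)))
        m = normalize_masses(raw)
        assert m["totcel"] == pytest.approx(36.0)
        assert m["hemcel"] == pytest.approx(31.2)
        assert sum(m.values()) == pytest.approx(100.0)

    def test_already_normalized_unchanged(self):
        raw = dict(zip(MASS_PHASES, (60, 20, 10, 5, 3, 2)))
        assert normalize_masses(raw) == pytest.approx(raw)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_masses({"totcel": -1.0})

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 80), min_size=6, max_size=6))
    def test_always_sums_to_100(self, vals):
        m = normalize_masses(dict(zip(MASS_PHASES, vals)))
        assert sum(m.values()) == pytest.approx(100.0)
        assert all(v >= 0 for v in m.values())


class TestCrystallinity:
    def test_limits(self, props):
        assert crystallinity_mass(0.0, props) == 0.0
        assert crystallinity_mass(1.0, props) == pytest.approx(1.0)

    def test_banana_value(self, props):
        # direct evaluation with rho_amcel = 1.50, rho_NF = 1.59
        assert crystallinity_mass(0.45, props) == pytest.approx(0.4645, abs=2e-4)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.01, 0.99))
    def test_mass_index_exceeds_volume_index(self, xi):
        # amorphous cellulose is lighter than the crystal
        assert crystallinity_mass(xi) >= xi

    def test_out_of_range_rejected(self, props):
        with pytest.raises(ValueError):
            crystallinity_mass(1.2, props)


class TestVolumeFractions:
    def test_banana_average_row(self, props):
        m = normalize_masses(dict(zip(MASS_PHASES, (71, 10, 8, 4, 5, 0))))
        f = cellwall_volume_fractions(m, crystallinity_mass(0.45, props), props)
        expected = dict(zip(CW_PHASES, (0.31, 0.38, 0.10, 0.10, 0.04, 0.03, 0.03)))
        for p, v in expected.items():
            assert f[p] == pytest.approx(v, abs=0.01), p  # printed-integer slack
        assert sum(f.values()) == pytest.approx(1.0)

    def test_jute_average_row(self, props):
        m = normalize_masses(dict(zip(MASS_PHASES, (58, 18, 18, 0, 0, 0))))
        f = cellwall_volume_fractions(m, crystallinity_mass(0.71, props), props)
        assert f["NF"] == pytest.approx(0.37, abs=0.01)
        assert f["lig"] == pytest.approx(0.20, abs=0.01)

    def test_single_phase(self, props):
        m = normalize_masses({"totcel": 100.0})
        f = cellwall_volume_fractions(m, 1.0, props)
        assert f["NF"] == pytest.approx(1.0)


class TestRVEFractions:
    def test_banana_groups(self, props):
        m = normalize_masses(dict(zip(MASS_PHASES, (71, 10, 8, 4, 5, 0))))
        f = cellwall_volume_fractions(m, crystallinity_mass(0.45, props), props)
        r = rve_fractions(f)
        assert r.f_pn_cw == pytest.approx(0.30, abs=0.01)
        assert r.f_pn["hemcel"] == pytest.approx(10 / 30, abs=0.02)
        assert sum(r.f_pn.values()) == pytest.approx(1.0)
        assert r.f_cel["NF"] + r.f_cel["amcel"] == pytest.approx(1.0)

    def test_flax_microfibril_share(self, db, props):
        s = build_scenarios(db["Flax"], props)["avg"]
        assert s.rve.f_MF_cw == pytest.approx(0.69, abs=0.01)

    def test_degenerate_rejected(self):
        f = {p: 0.0 for p in CW_PHASES}
        f["NF"] = 1.0
        with pytest.raises(ValueError):
            rve_fractions(f)


class TestDensityPorosity:
    def test_cellwall_densities(self, db, props):
        assert build_scenarios(db["Banana"], props)["avg"].rho_cw == pytest.approx(1.51, abs=0.005)
        assert build_scenarios(db["Flax"], props)["avg"].rho_cw == pytest.approx(1.48, abs=0.005)

    def test_pure_crystal_density(self, props):
        f = {p: 0.0 for p in CW_PHASES}
        f["NF"] = 1.0
        assert cellwall_density(f, props) == pytest.approx(1.59)

    def test_lumen_values(self):
        assert lumen_porosity(1.38, 1.48) == pytest.approx(0.068, abs=0.001)
        assert lumen_porosity(1.4, 1.4) == 0.0
        assert lumen_porosity(1.35, 1.42) == pytest.approx(0.05, abs=0.003)

    def test_lumen_clamped(self):
        # fiber denser than its cell wall (rounding artifacts): no negative pore space
        assert lumen_porosity(1.65, 1.43) == 0.0


class TestScenarios:
    def test_density_fallback_pm10pct(self, props):
        rec = _record(rho=Triple(None, 0.89, None))
        b = build_scenarios(rec, props)
        assert b["min"].rho_fib == pytest.approx(0.801)
        assert b["max"].rho_fib == pytest.approx(0.979)

    def test_mfa_fallback_pm3deg(self, props):
        rec = _record(mfa=Triple(None, 10.0, None))
        b = build_scenarios(rec, props)
        assert b["max"].theta == 7.0  # small angle -> stiff scenario
        assert b["min"].theta == 13.0

    def test_reported_extreme_beats_5pp_rule(self, db, props):
        # kenaf: reported max cellulose 81 exceeds avg + 5
        b = build_scenarios(db["Kenaf"], props)
        f_max = b["max"].f_cw
        m_avg = normalize_masses({p: db["Kenaf"].masses[p].avg for p in MASS_PHASES})
        assert m_avg["totcel"] + 5.0 < 81.0
        # the max scenario cellulose volume corresponds to mass 81
        assert f_max["NF"] + f_max["amcel"] > b["avg"].f_cw["NF"] + b["avg"].f_cw["amcel"]

    def test_five_point_rule_when_no_extreme(self, props):
        rec = _record()  # no reported extremes at all
        b = build_scenarios(rec, props)
        mf = {s: b[s].f_cw["NF"] + b[s].f_cw["amcel"] for s in ("min", "avg", "max")}
        assert mf["min"] < mf["avg"] < mf["max"]

    def test_fraction_groups_sum_to_one(self, db, props):
        for name in ("Flax", "Coir", "Rice"):
            for s in build_scenarios(db[name], props).values():
                assert sum(s.f_cw.values()) == pytest.approx(1.0, abs=1e-12)
                assert sum(s.rve.f_pn.values()) == pytest.approx(1.0, abs=1e-12)
                assert sum(s.rve.f_cel.values()) == pytest.approx(1.0, abs=1e-12)
                assert 0.0 <= s.f_lum < 1.0

    def test_scenario_lumen_uses_average_cellwall_density(self, db, props):
        b = build_scenarios(db["Flax"], props)
        assert b["min"].rho_cw == b["avg"].rho_cw == b["max"].rho_cw


class TestDatabase:
    def test_all_26_fibers_load(self, db):
        assert len(db) == 26
        types = {rec.type for rec in db.values()}
        assert types == {"bast", "grass", "leaf", "fruit/seed", "straw"}

    def test_provenance_flags(self, db):
        assert "mfa" in db["Alfa"].assumed
        assert {"mfa", "xi", "rho"} <= db["Barley"].assumed
        assert not db["Flax"].assumed

    def test_invalid_record_rejected(self):
        with pytest.raises(ValueError):
            _record(mfa=Triple(None, 120.0, None))


class TestRandomRecords:
    def test_generated_records_run_through_pipeline(self, rng, props):
        for i in range(10):
            rec = random_fiber_record(rng, name=f"syn{i}")
            b = build_scenarios(rec, props)
            for s in b.values():
                assert sum(s.f_cw.values()) == pytest.approx(1.0, abs=1e-12)
                assert 0.0 <= s.f_lum < 1.0
                assert 0.0 <= s.theta <= 90.0
            # favorable scenario has at least as much cellulose, as small an
            # angle and as little lumen as the unfavorable one
            assert b["max"].theta <= b["min"].theta
            assert b["max"].f_lum <= b["min"].f_lum


def _record(mfa=Triple(9.0, 10.0, 12.0), rho=Triple(1.2, 1.3, 1.4)):
    masses = {p: Triple(None, v, None) for p, v in
              zip(MASS_PHASES, (60.0, 20.0, 12.0, 2.0, 1.0, 0.0))}
    return FiberRecord(
        name="test", type="bast", masses=masses,
        xi_V=Triple(None, 60.0, None), mfa=mfa, rho_fib=rho,
    )
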