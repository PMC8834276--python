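import math

import pytest

from etcc.carrying_capacity import (
    RoundingPolicy,
    annualize,
    compute_site,
    correction_factor,
    correction_set_from_climate,
    effective_carrying_capacity,
    facility_management,
    ideal_management_capacity,
    physical_carrying_capacity,
    real_carrying_capacity,
    rotation_factor,
)
from etcc.datasets import JAJRUD, LAR, TANGEH_VASHI, TEHRAN_CF7_PERCENT, TEHRAN_RCC_DAILY
from etcc.errors import (
    ConfigurationError,
    DomainError,
    RecordValidationError,
    UsageError,
)
from etcc.site_model import ClimateRecord, LimitingVariable, RecreationZone, SiteProfile


class TestRotationFactor:
    @pytest.mark.parametrize("avail, visit, expected", [
        (8, 8, 1.0),
        (12, 3, 4.0),
        (24, 24, 1.0),
    ])
    def test_examples(self, avail, visit, expected):
        assert rotation_factor(avail, visit) == expected

    @pytest.mark.parametrize("avail, visit", [(0, 8), (8, 0), (-1, 8)])
    def test_non_positive_arguments(self, avail, visit):
        with pytest.raises(DomainError):
            rotation_factor(avail, visit)


class TestPhysicalCarryingCapacity:
    @pytest.mark.parametrize("area, space, rf, expected", [
        (4_430_300, 2500, 1, 1772),
        (88_500, 1500, 1, 59),
        (2500, 2500, 1, 1),
        (2_858_000, 2500, 1, 1143),  # 1143.2 floors to 1143
        (34_700, 2500, 1, 13),       # 13.88 floors to 13
    ])
    def test_examples(self, area, space, rf, expected):
        assert physical_carrying_capacity(area, space, rf) == expected

    def test_rotation_factor_scales(self):
        assert physical_carrying_capacity(2500, 2500, 4) == 4

    def test_half_up_policy(self):
        policy = RoundingPolicy(pcc_daily="half_up")
        assert physical_carrying_capacity(2_858_000, 2500, 1, policy) == 1143
        assert physical_carrying_capacity(34_700, 2500, 1, policy) == 14

    def test_zero_area(self):
        assert physical_carrying_capacity(0, 2500, 1) == 0

    @pytest.mark.parametrize("area, space, rf", [(-1, 2500, 1), (100, 0, 1), (100, 2500, 0)])
    def test_domain_errors(self, area, space, rf):
        with pytest.raises(DomainError):
            physical_carrying_capacity(area, space, rf)


class TestAnnualize:
    @pytest.mark.parametrize("daily, days, expected", [
        (1143, 365, 417_195),
        (13, 155, 2_015),
        (1772, 109, 193_148),
        (5, 0, 0),
    ])
    def test_examples(self, daily, days, expected):
        assert annualize(daily, days) == expected

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            annualize(-1, 100)
        with pytest.raises(DomainError):
            annualize(1, 400)


class TestCorrectionFactor:
    @pytest.mark.parametrize("m, expected", [(57, 16), (116, 32), (0, 0), (144, 39)])
    def test_day_examples(self, m, expected):
        var = LimitingVariable("Cf5", m, "days", 365)
        assert correction_factor(var).percent == expected

    def test_carries_sources(self):
        cf = correction_factor(LimitingVariable("Cf5", 57, "days", 365))
        assert (cf.code, cf.source_m, cf.source_mt) == ("Cf5", 57, 365)

    def test_total_override(self):
        var = LimitingVariable("Cf1", 10, "days", 365)
        assert correction_factor(var, total=100).percent == 10

    def test_missing_denominator(self):
        with pytest.raises(DomainError):
            correction_factor(LimitingVariable("Cf7", 2717, "hours", None))

    def test_decimals(self):
        var = LimitingVariable("Cf5", 57, "days", 365)
        assert correction_factor(var, percent_decimals=1).percent == 15.6


class TestCorrectionSetFromClimate:
    def _record(self, site, magnitudes, units=None):
        codes = [f"Cf{i + 1}" for i in range(len(magnitudes))]
        units = units or ["days"] * len(magnitudes)
        return ClimateRecord(site, "st", 1000.0, "35", "52", tuple(
            LimitingVariable(c, m, u) for c, m, u in zip(codes, magnitudes, units)))

    def test_lar_with_cf7_override(self, tehran_by_site):
        record = tehran_by_site["climate"][LAR]
        cfs = correction_set_from_climate(
            record, percent_overrides=TEHRAN_CF7_PERCENT[LAR])
        assert [cf.percent for cf in cfs] == [3, 1, 1, 3, 16, 1, 21, 12]

    def test_all_zero_magnitudes(self):
        record = self._record("x", [0, 0, 0])
        assert [cf.percent for cf in correction_set_from_climate(record)] == [0, 0, 0]

    def test_tangeh_vashi_day_variables(self):
        # day-based magnitudes only (no hour variable), default Mt = 365
        record = self._record("tv", [15, 2, 4, 11, 144, 3, 24])
        cfs = correction_set_from_climate(record)
        assert [cf.percent for cf in cfs] == [4, 1, 1, 3, 39, 1, 7]

    def test_hour_variable_without_config_raises_with_code(self):
        record = self._record("x", [10, 2717], units=["days", "hours"])
        with pytest.raises(ConfigurationError, match="Cf2"):
            correction_set_from_climate(record)

    def test_hour_variable_with_mt_default(self):
        record = self._record("x", [10, 2190], units=["days", "hours"])
        cfs = correction_set_from_climate(record, mt_defaults={"Cf2": 8760})
        assert cfs[1].percent == 25

    def test_input_order_preserved(self, tehran_by_site):
        record = tehran_by_site["climate"][JAJRUD]
        cfs = correction_set_from_climate(
            record, percent_overrides=TEHRAN_CF7_PERCENT[JAJRUD])
        assert [cf.code for cf in cfs] == [f"Cf{i}" for i in range(1, 9)]


class TestRealCarryingCapacity:
    def test_single_half_reduction(self):
        assert real_carrying_capacity(100, [50]) == 50

    def test_lar_et1_multiplicative(self):
        # frozen from the sequential one-factor-at-a-time oracle:
        # 1772 * .97 * .99 * .99 * .97 * .84 * .99 * .79 * .88 = 944.717
        assert real_carrying_capacity(1772, [3, 1, 1, 3, 16, 1, 21, 12]) == 944

    def test_empty_factor_list_is_identity(self):
        assert real_carrying_capacity(123, []) == 123

    def test_subtractive_literal(self):
        assert real_carrying_capacity(100, [10, 20], mode="subtractive") == 70

    def test_subtractive_floors_at_zero(self):
        assert real_carrying_capacity(10, [20, 20], mode="subtractive") == 0

    def test_unknown_mode(self):
        with pytest.raises(UsageError):
            real_carrying_capacity(100, [10], mode="bogus")

    def test_percent_out_of_range(self):
        with pytest.raises(DomainError):
            real_carrying_capacity(100, [101])

    def test_exact_matches_sequential_oracle(self):
        percents = [3, 1, 1, 3, 16, 1, 21, 12]
        seq = 1772.0
        for pct in percents:
            seq *= (100 - pct) / 100
        exact = real_carrying_capacity(1772, percents, exact=True)
        assert math.isclose(exact, seq, rel_tol=1e-12)


class TestIdealManagementCapacity:
    @pytest.mark.parametrize("area, per, expected", [
        (35_765, 1000, 36),
        (74_811, 1000, 75),
        (1000, 1000, 1),
        (3650, 1000, 4),  # half-up; the published 5 for this site is not derivable
        (100, 1000, 1),   # minimum one guardian
    ])
    def test_examples(self, area, per, expected):
        assert ideal_management_capacity(area, per) == expected

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            ideal_management_capacity(0, 1000)
        with pytest.raises(DomainError):
            ideal_management_capacity(1000, 0)


class TestFacilityManagement:
    @pytest.mark.parametrize("imc, emc, expected", [
        (36, 14, 61),
        (75, 28, 63),
        (5, 4, 20),
        (10, 10, 0),
        (10, 0, 100),
    ])
    def test_examples(self, imc, emc, expected):
        assert facility_management(imc, emc) == expected

    def test_emc_above_imc(self):
        with pytest.raises(DomainError):
            facility_management(5, 6)

    def test_zero_imc(self):
        with pytest.raises(DomainError):
            facility_management(0, 0)


class TestEffectiveCarryingCapacity:
    @pytest.mark.parametrize("rcc, fm, expected", [
        (4, 63, 2),    # 1.48 -> ceiling 2
        (6, 63, 3),    # 2.22 -> ceiling 3
        (2, 61, 1),    # 0.78 -> ceiling 1
        (2, 63, 1),    # 0.74 -> ceiling 1
        (1, 20, 1),    # 0.80 -> ceiling 1
        (100, 0, 100),
    ])
    def test_examples(self, rcc, fm, expected):
        assert effective_carrying_capacity(rcc, fm) == expected

    def test_floor_policy(self):
        policy = RoundingPolicy(ecc_daily="floor")
        assert effective_carrying_capacity(3, 20, policy) == 2  # 2.4 floors to 2

    def test_fm_out_of_range(self):
        with pytest.raises(DomainError):
            effective_carrying_capacity(10, 101)
        with pytest.raises(DomainError):
            effective_carrying_capacity(10, -1)


class TestComputeSite:
    def test_jajrud_injected_ecc_annuals(self, tehran_by_site):
        results = compute_site(
            tehran_by_site["sites"][JAJRUD],
            tehran_by_site["zones"],
            tehran_by_site["climate"][JAJRUD],
            tehran_by_site["management"][JAJRUD],
            cf_percent_overrides=TEHRAN_CF7_PERCENT[JAJRUD],
            rcc_injection=TEHRAN_RCC_DAILY,
        )
        ecc = {(r.use_type, r.class_label): r.ecc_annual for r in results}
        assert ecc[("extensive", 1)] == 730
        assert ecc[("extensive", 2)] == 1095
        assert ecc[("intensive", 2)] == 365

    def test_zero_area_zones(self):
        profile = SiteProfile("z", 10.0, 1, 1, 100, 8.0, 8.0)
        zone = RecreationZone("z", "extensive", 1, 0.0, 2500.0)
        climate = ClimateRecord("z", "st", 0.0, "0", "0",
                                (LimitingVariable("Cf1", 10, "days", 365),))
        from etcc.site_model import ManagementCapacity
        mgmt = ManagementCapacity("z", imc=2, emc=1)
        (res,) = compute_site(profile, [zone], climate, mgmt)
        assert res.pcc_daily == res.rcc_daily == res.ecc_daily == 0
        assert res.pcc_annual == 0

    def test_no_limits_no_deficit_degenerate_equality(self):
        profile = SiteProfile("z", 10.0, 1, 1, 100, 8.0, 8.0)
        zone = RecreationZone("z", "extensive", 1, 25_000.0, 2500.0)
        climate = ClimateRecord("z", "st", 0.0, "0", "0",
                                (LimitingVariable("Cf1", 0, "days", 365),))
        from etcc.site_model import ManagementCapacity
        mgmt = ManagementCapacity("z", imc=2, emc=2)
        (res,) = compute_site(profile, [zone], climate, mgmt)
        assert res.pcc_exact == res.rcc_exact == res.ecc_exact
        assert res.pcc_daily == res.rcc_daily == res.ecc_daily == 10

    def test_missing_climate_strict(self, tehran_by_site):
        with pytest.raises(ConfigurationError):
            compute_site(tehran_by_site["sites"][LAR], tehran_by_site["zones"],
                         None, tehran_by_site["management"][LAR])

    def test_missing_management_non_strict_leaves_ecc_unset(self, tehran_by_site):
        results = compute_site(
            tehran_by_site["sites"][TANGEH_VASHI],
            tehran_by_site["zones"],
            tehran_by_site["climate"][TANGEH_VASHI],
            None,
            cf_percent_overrides=TEHRAN_CF7_PERCENT[TANGEH_VASHI],
            strict=False,
        )
        assert results and all(r.ecc_daily is None for r in results)
        assert all(r.rcc_daily is not None for r in results)

    def test_wrong_site_climate_record(self, tehran_by_site):
        with pytest.raises(ConfigurationError):
            compute_site(tehran_by_site["sites"][LAR], tehran_by_site["zones"],
                         tehran_by_site["climate"][JAJRUD],
                         tehran_by_site["management"][LAR])

    def test_annual_consistency_and_ordering(self, tehran_results):
        for res in tehran_results.values():
            assert res.pcc_annual == res.pcc_daily * res.operating_days
            assert res.rcc_annual == res.rcc_daily * res.operating_days
            assert res.ecc_annual == res.ecc_daily * res.operating_days
            assert res.pcc_daily >= res.rcc_daily >= res.ecc_daily

    def test_result_ordering_invariant_enforced(self):
        from etcc.carrying_capacity import CapacityResult
        with pytest.raises(RecordValidationError):
            CapacityResult(site_name="x", use_type="extensive", class_label=1,
                           operating_days=100, rf=1.0, pcc_exact=5.0,
                           pcc_daily=5, pcc_annual=500,
                           rcc_exact=9.0, rcc_daily=9, rcc_annual=900)
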