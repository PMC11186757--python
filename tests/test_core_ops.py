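"""Unit tests for the primitive accounting operations."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbudget import DataError, DomainError
from pbudget.core import (
    annualize,
    canopy_production,
    hedley_group,
    leaching_flux,
    mean_residence_time,
    microbial_p,
    p_use_efficiencies,
    plant_demand,
    plant_pool,
    plant_uptake,
    profile_scale,
    resorption_fraction,
    soil_pool,
)

finite = st.floats(min_value=0.01, max_value=1e4, allow_nan=False)


class TestPlantPool:
    @pytest.mark.parametrize(
        "conc, biomass, expected",
        [(0.5, 460.0, 0.23), (0.0, 1234.0, 0.0), (1.0, 1000.0, 1.0)],
    )
    def test_concentration_by_biomass(self, conc, biomass, expected):
        assert plant_pool(conc, biomass) == pytest.approx(expected)

    def test_rejects_negative_inputs(self):
        with pytest.raises(DomainError):
            plant_pool(-0.1, 100.0)


class TestSoilPool:
    def test_unit_arithmetic(self):
        assert soil_pool(100.0, 1.5, (0, 10)) == pytest.approx(15.0)

    @given(conc=finite, bd=st.floats(0.5, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_additive_over_contiguous_layers(self, conc, bd):
        split = (
            soil_pool(conc, bd, (0, 10))
            + soil_pool(conc, bd, (10, 30))
            + soil_pool(conc, bd, (30, 60))
        )
        assert split == pytest.approx(soil_pool(conc, bd, (0, 60)), rel=1e-12)

    def test_rejects_inverted_layer(self):
        with pytest.raises(DomainError):
            soil_pool(10.0, 1.5, (30, 10))


class TestMicrobialP:
    def test_fumigation_difference_over_kep(self):
        assert microbial_p(3.0, 1.8, 0.4) == pytest.approx(3.0)

    def test_null_difference(self):
        assert microbial_p(2.0, 2.0, 0.4) == 0.0

    def test_negative_difference_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert microbial_p(1.5, 2.0, 0.4) == 0.0

    def test_rejects_nonpositive_kep(self):
        with pytest.raises(DomainError):
            microbial_p(3.0, 1.8, 0.0)


class TestHedleyGroup:
    FRACTIONS = {
        "exchangeable_pi": 2.0,
        "exchangeable_po": 1.0,
        "moderately_labile_po": 3.0,
    }

    def test_residual_by_difference(self):
        groups = hedley_group(self.FRACTIONS, total_p=10.0)
        assert groups.residual == pytest.approx(4.0)
        assert not groups.flagged

    def test_closure_gives_zero_residual(self):
        groups = hedley_group(self.FRACTIONS, total_p=6.0)
        assert groups.residual == 0.0
        assert not groups.flagged

    def test_overshoot_floored_and_flagged(self):
        groups = hedley_group(self.FRACTIONS, total_p=5.0)
        assert groups.residual == 0.0
        assert groups.flagged

    def test_rejects_negative_total(self):
        with pytest.raises(DomainError):
            hedley_group(self.FRACTIONS, total_p=-1.0)


class TestAnnualize:
    @staticmethod
    def month_intervals(year, months, value):
        out = []
        for m in months:
            start = dt.date(year, m, 1)
            end = dt.date(year + 1, 1, 1) if m == 12 else dt.date(year, m + 1, 1)
            out.append((start, end, value))
        return out

    def test_complete_year_sums(self):
        result = annualize(self.month_intervals(2013, range(1, 13), 0.02))
        assert result.value == pytest.approx(0.24)
        assert result.coverage == pytest.approx(1.0)

    def test_incomplete_coverage_scaled(self):
        # 6 months covering 181 days; the sum is rescaled to a full year
        intervals = self.month_intervals(2013, range(1, 7), 0.02)
        result = annualize(intervals)
        assert result.value == pytest.approx(0.12 * 365 / 181)
        assert result.coverage == pytest.approx(181 / 365)

    def test_leap_year_normalized(self):
        result = annualize(self.month_intervals(2016, range(1, 13), 1.0))
        assert result.value == pytest.approx(12 * 365 / 366)

    def test_rejects_overlapping_intervals(self):
        intervals = [
            (dt.date(2013, 1, 1), dt.date(2013, 3, 1), 1.0),
            (dt.date(2013, 2, 1), dt.date(2013, 4, 1), 1.0),
        ]
        with pytest.raises(DataError):
            annualize(intervals)


class TestVegetationFluxRules:
    def test_canopy_production_adds_herbivory(self):
        assert canopy_production(0.24, 0.04) == pytest.approx(0.28)
        assert canopy_production(0.24, 0.0) == pytest.approx(0.24)

    @pytest.mark.parametrize(
        "green, senesced, expected",
        [(1.0, 0.45, 0.55), (1.0, 1.0, 0.0), (1.0, 0.0, 1.0)],
    )
    def test_resorption_fraction(self, green, senesced, expected):
        assert resorption_fraction(green, senesced).fraction == pytest.approx(expected)

    def test_resorption_fraction_clamped_when_senesced_exceeds_green(self):
        result = resorption_fraction(1.0, 1.2)
        assert result.fraction == 0.0
        assert result.flagged

    def test_resorption_fraction_rejects_zero_green(self):
        with pytest.raises(DomainError):
            resorption_fraction(0.0, 0.1)

    def test_demand_is_exact_sum(self):
        assert plant_demand({"a": 0.1, "b": 0.2}) == pytest.approx(0.3)
        assert plant_demand({"only": 0.42}) == pytest.approx(0.42)
        with pytest.raises(DataError):
            plant_demand({})

    def test_uptake_by_difference(self):
        assert plant_uptake(0.71, 0.32) == pytest.approx(0.39)
        assert plant_uptake(0.5, 0.0) == pytest.approx(0.5)
        assert plant_uptake(0.5, 0.5) == 0.0

    def test_negative_uptake_warned_but_retained(self):
        with pytest.warns(UserWarning):
            assert plant_uptake(0.3, 0.4) == pytest.approx(-0.1)


class TestProfileScale:
    def test_proportional_scaling(self):
        assert profile_scale(0.5, (1.0, 0.6, 0.2)) == pytest.approx([0.5, 0.3, 0.1])

    def test_uniform_profile_copies_surface(self):
        assert profile_scale(2.0, (3.0, 3.0, 3.0)) == pytest.approx([2.0, 2.0, 2.0])

    def test_rejects_zero_surface_weight(self):
        with pytest.raises(DomainError):
            profile_scale(1.0, (0.0, 1.0))


class TestLeaching:
    @pytest.mark.parametrize(
        "conc, expected", [(0.01, 7.3e-5), (0.0, 0.0), (1.0, 7.3e-3)]
    )
    def test_drainage_conversion(self, conc, expected):
        assert leaching_flux(conc, 20.0) == pytest.approx(expected)


class TestDerivedIndicators:
    PRINTED_POOLS = {
        "canopy": 0.23, "sapwood": 0.36, "fine_root": 0.24, "understorey": 0.23,
    }

    def test_mrt_from_component_pools(self):
        assert mean_residence_time(self.PRINTED_POOLS, 0.39) == pytest.approx(
            2.7179, abs=1e-3
        )

    def test_mrt_scaling(self):
        base = mean_residence_time(self.PRINTED_POOLS, 0.39)
        assert mean_residence_time(self.PRINTED_POOLS, 0.78) == pytest.approx(base / 2)
        pools = {k: 1.0 / 4 for k in self.PRINTED_POOLS}
        assert mean_residence_time(pools, 1.0) == pytest.approx(1.0)

    def test_mrt_undefined_for_zero_uptake(self):
        with pytest.raises(DomainError):
            mean_residence_time(self.PRINTED_POOLS, 0.0)

    def test_pue_ratios_and_linearity(self):
        pue = p_use_efficiencies(1500.0, 380.0, 507.0, 0.28, 0.28, 0.39)
        assert pue.pue_gpp_overstorey == pytest.approx(1500.0 / 0.28)
        assert pue.pue_growth == pytest.approx(1300.0)
        doubled = p_use_efficiencies(3000.0, 760.0, 1014.0, 0.28, 0.28, 0.39)
        assert doubled.pue_gpp_overstorey == pytest.approx(2 * pue.pue_gpp_overstorey)
        assert doubled.pue_growth == pytest.approx(2 * pue.pue_growth)

    def test_pue_rejects_zero_denominators(self):
        with pytest.raises(DomainError):
            p_use_efficiencies(1500.0, 380.0, 507.0, 0.0, 0.28, 0.39)
        with pytest.raises(DomainError):
            p_use_efficiencies(1500.0, 380.0, 507.0, 0.28, 0.28, 0.0)
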