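"""The attributable-fraction chain: components, variances, composition."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hivaaf import (
    ConfigurationError,
    FractionEstimate,
    InputValidationError,
    ProportionEstimate,
    RatioEstimate,
    adherence_af,
    alcohol_nonadherence_af,
    combine_aaf,
    compute_all,
    compute_stratum,
    levin_af,
    overall_treated_risk,
    product_variance,
    treated_death_share,
    untreated_risk,
)

Pfix = ProportionEstimate.fixed
Rfix = RatioEstimate.fixed


class TestAdherenceAf:
    def test_no_exposure_and_null_risk(self):
        assert adherence_af(Pfix(0.0), Rfix(2.0)).value == 0.0
        assert adherence_af(Pfix(0.4), Rfix(1.0)).value == 0.0

    def test_bundled_point_estimate(self):
        # denominator 1 + 0.401·(3.13-1) = 1.85413; value 0.85413/1.85413
        af = adherence_af(Pfix(0.401), Rfix(3.13))
        assert 1 + 0.401 * (3.13 - 1) == pytest.approx(1.85413)
        assert af.value == pytest.approx(0.85413 / 1.85413, rel=1e-12)
        assert round(af.value, 4) == 0.4607

    def test_variance_formula(self):
        p = ProportionEstimate.from_interval(0.401, 0.369, 0.433)
        rr = RatioEstimate.from_interval(3.13, 1.95, 5.05)
        af = adherence_af(p, rr)
        denom = 1 + p.value * (rr.value - 1)
        expected = (
            product_variance(p.value, p.variance, rr.value, rr.variance) / denom**4
        )
        assert af.variance == pytest.approx(expected, rel=1e-12)

    @given(p=st.floats(0.0, 1.0), rr=st.floats(0.05, 10.0))
    def test_equals_unsimplified_form(self, p, rr):
        # (P_adher + P_na·RR − 1)/(P_adher + P_na·RR) with P_adher = 1 − P_na
        padher = 1.0 - p
        denom = padher + p * rr
        expected = (denom - 1.0) / denom
        assert adherence_af(Pfix(p), Rfix(rr)).value == pytest.approx(
            expected, rel=1e-10, abs=1e-12
        )

    @given(
        p1=st.floats(0.05, 0.45),
        p2=st.floats(0.5, 0.95),
        rr=st.floats(1.05, 8.0),
    )
    def test_strictly_increasing_in_prevalence_and_risk(self, p1, p2, rr):
        assert (
            adherence_af(Pfix(p1), Rfix(rr)).value
            < adherence_af(Pfix(p2), Rfix(rr)).value
        )
        assert (
            adherence_af(Pfix(p1), Rfix(rr)).value
            < adherence_af(Pfix(p1), Rfix(rr + 1.0)).value
        )


class TestAlcoholNonadherenceAf:
    def test_all_drinkers(self):
        af = alcohol_nonadherence_af(Pfix(1.0), Rfix(1.82))
        assert af.value == pytest.approx(0.82 / 1.82, rel=1e-12)

    def test_east_young_men(self):
        af = alcohol_nonadherence_af(Pfix(0.246), Rfix(1.82))
        expected = 0.246 * 0.82 / (1 + 0.246 * 0.82)
        assert af.value == pytest.approx(expected, rel=1e-12)
        assert round(af.value, 4) == 0.1679

    def test_abstainer_population_variance_through_prevalence_only(self):
        p = ProportionEstimate(0.0, 0.0, 0.0, variance=1e-4)
        rr = RatioEstimate.from_interval(1.82, 1.63, 2.04)
        af = alcohol_nonadherence_af(p, rr)
        assert af.value == 0.0
        # at P=0 the denominator is 1, so Var[AF] reduces to Var[P·RR]
        assert af.variance == pytest.approx(
            product_variance(0.0, 1e-4, 1.82, rr.variance), rel=1e-12
        )


class TestTreatedDeathShare:
    def test_full_coverage(self):
        assert treated_death_share(Pfix(1.0), Rfix(5.0)).value == pytest.approx(1.0)

    def test_unit_hazard_ratio(self):
        assert treated_death_share(Pfix(0.37), Rfix(1.0)).value == pytest.approx(0.37)

    def test_east_coverage(self):
        pdt = treated_death_share(Pfix(0.1424), Rfix(2.63))
        expected = 0.1424 / (0.1424 + 2.63 * (1 - 0.1424))
        assert pdt.value == pytest.approx(expected, rel=1e-12)
        assert round(pdt.value, 4) == 0.0594

    def test_variance_partials(self):
        pt = ProportionEstimate.from_interval(0.1424, 0.1207, 0.1641)
        hr = RatioEstimate.from_interval(2.63, 1.92, 3.57)
        pdt = treated_death_share(pt, hr)
        denom = (pt.value + hr.value * (1 - pt.value)) ** 2
        d_pt = hr.value / denom
        d_hr = pt.value * (1 - pt.value) / denom
        assert pdt.variance == pytest.approx(
            d_pt**2 * pt.variance + d_hr**2 * hr.variance, rel=1e-12
        )

    def test_zero_coverage_returns_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            pdt = treated_death_share(Pfix(0.0), Rfix(2.63))
        assert pdt.value == 0.0
        assert any("coverage is 0" in m for m in caplog.messages)

    @given(
        pt=st.floats(0.02, 0.98),
        hr1=st.floats(1.0, 5.0),
        delta=st.floats(0.1, 3.0),
    )
    def test_strictly_decreasing_in_hazard_ratio(self, pt, hr1, delta):
        a = treated_death_share(Pfix(pt), Rfix(hr1)).value
        b = treated_death_share(Pfix(pt), Rfix(hr1 + delta)).value
        assert b < a


class TestRiskScale:
    def test_treated_population_mixture(self):
        assert f"{overall_treated_risk(0.401, 3.13):.2f}" == "1.85"
        assert overall_treated_risk(0.0, 3.13) == pytest.approx(1.0)
        assert overall_treated_risk(1.0, 3.13) == pytest.approx(3.13)

    def test_untreated_population(self):
        assert f"{untreated_risk(0.401, 3.13, 2.63):.2f}" == "4.88"
        assert untreated_risk(0.0, 9.9, 1.0) == pytest.approx(1.0)
        assert untreated_risk(0.0, 9.9, 2.5) == pytest.approx(2.5)

    def test_domain_errors(self):
        with pytest.raises(InputValidationError):
            overall_treated_risk(1.2, 3.13)
        with pytest.raises(InputValidationError):
            untreated_risk(0.4, 3.13, -1.0)


class TestCombineAaf:
    def _frac(self, value, variance=0.0):
        return FractionEstimate.from_variance(value, variance)

    def test_absorbing_zero_and_identity(self):
        zero = combine_aaf(self._frac(0.0), self._frac(0.5), self._frac(0.5))
        assert zero.value == 0.0 and zero.variance == 0.0
        one = combine_aaf(self._frac(1.0), self._frac(1.0), self._frac(1.0))
        assert one.value == 1.0

    def test_triple_product_point_estimate(self):
        aaf = combine_aaf(
            self._frac(0.4607), self._frac(0.1679), self._frac(0.0594)
        )
        assert aaf.value == pytest.approx(0.4607 * 0.1679 * 0.0594, rel=1e-12)

    def test_wald_interval_untruncated(self):
        est = combine_aaf(
            self._frac(0.01, 1e-4), self._frac(1.0), self._frac(1.0)
        )
        assert est.ci_lower < 0.0  # small fraction, large variance: crosses 0
        assert est.ci_lower == pytest.approx(
            est.value - 1.959964 * math.sqrt(est.variance)
        )


class TestComputeStratum:
    def test_east_young_men_full_chain(self, east_record, bundled_params):
        res = compute_stratum(east_record, "men", "15-34", bundled_params)
        assert res.aaf.value == pytest.approx(0.00459, abs=5e-5)
        assert res.aaf.value == pytest.approx(
            res.adaf.value * res.naaaf.value * res.pdt.value, rel=1e-12
        )

    def test_adaf_and_pdt_shared_within_region(self, east_record, bundled_params):
        a = compute_stratum(east_record, "men", "15-34", bundled_params)
        b = compute_stratum(east_record, "women", "55+", bundled_params)
        assert a.adaf == b.adaf
        assert a.pdt == b.pdt
        assert a.naaaf != b.naaaf

    def test_zero_drinking_prevalence_gives_zero_aaf(self, bundled_params):
        from hivaaf import RegionRecord

        rec = RegionRecord(
            region="dry",
            coverage=Pfix(0.2),
            drinkers={("men", "all"): Pfix(0.0), ("women", "all"): Pfix(0.0)},
        )
        res = compute_stratum(rec, "men", "all", bundled_params)
        assert res.aaf.value == 0.0

    def test_missing_cell_is_a_validation_error(self, east_record, bundled_params):
        with pytest.raises(InputValidationError, match="80\\+"):
            compute_stratum(east_record, "men", "80+", bundled_params)

    def test_aaf_bounded_by_components(self, bundled_records, bundled_params):
        for res in compute_all(bundled_records, bundled_params):
            assert res.aaf.value <= min(
                res.adaf.value, res.naaaf.value, res.pdt.value
            )

    def test_unknown_region_filter_rejected(self, bundled_records, bundled_params):
        with pytest.raises(ConfigurationError, match="Atlantis"):
            compute_all(bundled_records, bundled_params, regions=["Atlantis"])

    def test_zero_input_variances_collapse_intervals(self, east_record):
        from hivaaf import RiskParameterSet

        params = RiskParameterSet(
            p_na=Pfix(0.401),
            rr_drink=Rfix(1.82),
            rr_na=Rfix(3.13),
            hr_nontreat=Rfix(2.63),
        )
        rec_fixed = type(east_record)(
            region=east_record.region,
            coverage=Pfix(east_record.coverage.value),
            drinkers=east_record.drinkers,
        )
        res = compute_stratum(rec_fixed, "men", "15-34", params)
        for comp in (res.adaf, res.naaaf, res.pdt, res.aaf):
            assert comp.variance == 0.0
            assert comp.ci_lower == comp.value == comp.ci_upper


@given(p=st.floats(0.0, 1.0), rr=st.floats(1.0, 10.0))
def test_levin_af_in_unit_interval(p, rr):
    af = levin_af(p, rr)
    assert 0.0 <= af < 1.0
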