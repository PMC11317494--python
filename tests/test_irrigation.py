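"""Irrigation suitability indices and the class-interpolated IWQI."""

import math

import pytest

from hydrochem.errors import ConfigError, ValidationError
from hydrochem.irrigation import (
    DEFAULT_IWQI_CLASS_TABLE,
    DEFAULT_IWQI_WEIGHTS,
    classify_irrigation,
    irrigation_indices,
    irrigation_table,
    iwqi_rating,
    iwqi_score,
    IrrigationIndices,
)
from hydrochem.samples import DEFAULT_EQUIVALENT_WEIGHTS as EW, WaterSample, to_meq


def sample_from_meq(ec=None, **meq):
    conc = {ion: v * EW[ion] for ion, v in meq.items()}
    return WaterSample(site_id="X", ph=7.5, ec=ec, conc=conc)


class TestClassicalIndices:
    def test_site_mean_values(self, s1_balance):
        idx = irrigation_indices(s1_balance)
        assert idx.sar == pytest.approx(0.506, abs=0.002)
        assert idx.na_pct == pytest.approx(16.3, abs=0.1)
        assert idx.ssp == pytest.approx(15.1, abs=0.1)
        assert idx.ps == pytest.approx(1.08, abs=0.01)
        assert idx.rsc == pytest.approx(-0.54, abs=0.01)

    def test_no_alkali_water_scores_zero(self):
        idx = irrigation_indices(to_meq(sample_from_meq(Ca=2.0, HCO3=2.0)))
        assert idx.sar == 0.0 and idx.na_pct == 0.0 and idx.ssp == 0.0

    def test_sar_undefined_without_divalents(self):
        idx = irrigation_indices(to_meq(sample_from_meq(Na=3.0, Cl=3.0)))
        assert idx.sar is None
        assert idx.class_labels["SAR"] == "undefined"

    def test_literal_sar_variant_is_100x(self, s1_balance):
        plain = irrigation_indices(s1_balance).sar
        literal = irrigation_indices(s1_balance, sar_times_100=True).sar
        assert literal == pytest.approx(100.0 * plain)

    @pytest.mark.parametrize("lam", [0.25, 4.0])
    def test_scaling_laws_of_sodicity_indices(self, s1_balance, lam):
        """Na% and SSP are scale-free; SAR scales as sqrt(lambda)."""
        scaled = to_meq(
            sample_from_meq(**{i: lam * s1_balance.meq[i] for i in ("Ca", "Mg", "Na", "K")})
        )
        base = to_meq(sample_from_meq(**{i: s1_balance.meq[i] for i in ("Ca", "Mg", "Na", "K")}))
        i0, i1 = irrigation_indices(base), irrigation_indices(scaled)
        assert i1.na_pct == pytest.approx(i0.na_pct, rel=1e-9)
        assert i1.ssp == pytest.approx(i0.ssp, rel=1e-9)
        assert i1.sar == pytest.approx(math.sqrt(lam) * i0.sar, rel=1e-9)

    def test_ssp_never_exceeds_na_pct(self, balances):
        for bal in balances:
            idx = irrigation_indices(bal)
            assert idx.ssp <= idx.na_pct


class TestClassification:
    def test_salinity_bands(self):
        mk = lambda ps: IrrigationIndices(sar=1, na_pct=10, ssp=10, ps=ps, rsc=0)
        assert classify_irrigation(mk(1.08))["PS"] == "excellent-to-good"
        assert classify_irrigation(mk(4.0))["PS"] == "good-to-injurious"
        assert classify_irrigation(mk(6.0))["PS"] == "injurious-to-unsatisfactory"

    def test_rsc_bands_with_exclusive_lower_edge(self):
        mk = lambda rsc: IrrigationIndices(sar=1, na_pct=10, ssp=10, ps=1, rsc=rsc)
        assert classify_irrigation(mk(1.0))["RSC"] == "acceptable"
        assert classify_irrigation(mk(1.25))["RSC"] == "doubtful"  # boundary falls up
        assert classify_irrigation(mk(3.0))["RSC"] == "inappropriate"

    def test_sodicity_bands(self):
        mk = lambda sar: IrrigationIndices(sar=sar, na_pct=10, ssp=10, ps=1, rsc=0)
        assert classify_irrigation(mk(5))["SAR"] == "excellent"
        assert classify_irrigation(mk(12))["SAR"] == "good"
        assert classify_irrigation(mk(30))["SAR"] == "unsuitable"


class TestIwqiRating:
    def test_interpolation_inside_a_class(self):
        # EC in the best class: qi = 100 - (464-200)*15/550
        assert iwqi_rating("EC", 464.0) == pytest.approx(92.8, abs=0.01)

    def test_class_lower_bound_gives_q_max(self):
        for param, rows in DEFAULT_IWQI_CLASS_TABLE.items():
            for row in rows:
                assert iwqi_rating(param, row.x_inf) == pytest.approx(row.q_max)

    def test_mid_class_sar(self):
        assert iwqi_rating("SAR", 7.0) == pytest.approx(60 - 25 / 6, abs=0.01)

    def test_below_range_uses_zero_origin(self):
        # Na < 2 meq/L: the 0-35 class with x_inf = 0, x_amp = 2
        assert iwqi_rating("Na", 0.7203) == pytest.approx(35 - 0.7203 * 35 / 2, abs=1e-6)

    def test_above_range_is_zero(self):
        assert iwqi_rating("EC", 3000.0) == 0.0
        assert iwqi_rating("EC", 5000.0) == 0.0

    def test_continuity_at_internal_class_edges(self):
        # the scheme is continuous between adjacent defined classes; the drop
        # to the out-of-range class at the very top of the scale is a genuine
        # discontinuity of the published table and is not asserted
        for param, rows in DEFAULT_IWQI_CLASS_TABLE.items():
            starts = {r.x_inf for r in rows}
            for row in rows:
                edge = row.x_inf + row.x_amp
                if edge not in starts:
                    continue
                below = iwqi_rating(param, edge - 1e-9 * max(edge, 1))
                at = iwqi_rating(param, edge)
                assert abs(below - at) < 0.01

    def test_bounded_everywhere(self):
        for param in DEFAULT_IWQI_CLASS_TABLE:
            for v in (0.0, 0.5, 1.0, 2.7, 5.0, 9.9, 200.0, 4000.0):
                assert 0.0 <= iwqi_rating(param, v) <= 100.0

    def test_negative_value_rejected(self):
        with pytest.raises(ValidationError):
            iwqi_rating("EC", -1.0)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ConfigError):
            iwqi_rating("pH", 7.0)


class TestIwqiScore:
    def test_site_mean_is_high_restriction(self, s1, s1_balance):
        r = iwqi_score(s1, s1_balance)
        assert 45 <= r.score <= 50
        assert r.restriction_class == "high"

    def test_top_class_lower_bounds_score_100(self):
        s = sample_from_meq(ec=200.0, Na=2.0, Cl=1.0, HCO3=1.0, Ca=2.0)
        bal = to_meq(s)  # SAR = 2/sqrt(1) = 2, the top-class lower bound
        r = iwqi_score(s, bal)
        assert all(q == pytest.approx(100.0) for q in r.qi.values())
        assert r.score == pytest.approx(100.0)
        assert r.restriction_class == "none"

    def test_uniform_weights_average_the_ratings(self, s1, s1_balance):
        w = {p: 0.2 for p in DEFAULT_IWQI_WEIGHTS}
        r = iwqi_score(s1, s1_balance, weights=w)
        assert r.score == pytest.approx(sum(r.qi.values()) / 5.0)

    def test_bad_weights_rejected(self, s1, s1_balance):
        with pytest.raises(ConfigError):
            iwqi_score(s1, s1_balance, weights={p: 0.3 for p in DEFAULT_IWQI_WEIGHTS})


def test_fixture_sites_inside_reported_ranges(site_means, balances):
    """Every site's classical indices fall inside the campaign-wide ranges."""
    frame = irrigation_table(site_means, balances)
    assert frame["sar"].between(0.37, 0.68).all()
    assert frame["na_pct"].between(13.7, 18.7).all()
    assert frame["ssp"].between(12.5, 17.5).all()
    assert frame["ps"].between(0.73, 1.6).all()
    assert frame["rsc"].between(-1.27, 0.58).all()
    assert (frame["ps"] < 3.0).all()          # 100% excellent-to-good salinity
    assert (frame["rsc"] < 1.25).all()        # 100% acceptable residual carbonate
    assert frame["na_pct"].mean() == pytest.approx(16.11, rel=0.01)
    assert frame["ssp"].mean() == pytest.approx(14.88, rel=0.01)
    assert 0.49 <= frame["sar"].mean() <= 0.50
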