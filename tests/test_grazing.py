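"""Gut-pigment power fit, gut passage time, grazing, and egestion models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from salpflux.demography import day_night_average
from salpflux.grazing import (
    GPT_MIN_OAL,
    Q10Config,
    egestion_gpig,
    egestion_iversen,
    fit_gut_pigment_power,
    gut_passage_time,
    iversen_pellet_carbon,
    iversen_pellet_rate,
    population_grazing,
)
from tests.test_demography import make_tow


def records(lengths, gpig):
    return pd.DataFrame({"length_oal": lengths, "gpig": gpig})


class TestPigmentFit:
    def test_exact_points_recover_power_law(self):
        lengths = np.array([5.0, 10.0, 20.0])
        fit = fit_gut_pigment_power(records(lengths, 0.01 * lengths**2))
        assert fit.a == pytest.approx(0.01)
        assert fit.b == pytest.approx(2.0)

    def test_two_distinct_lengths_fall_back_to_mean(self, caplog):
        with caplog.at_level("WARNING"):
            fit = fit_gut_pigment_power(records([5.0, 10.0], [1.0, 3.0]))
        assert fit.is_fallback
        assert fit.fallback_mean == pytest.approx(2.0)
        assert "falling back" in caplog.text

    def test_duplicated_point_leaves_exact_fit_unchanged(self):
        lengths = np.array([5.0, 10.0, 20.0, 20.0])
        fit = fit_gut_pigment_power(records(lengths, 0.01 * lengths**2))
        assert fit.a == pytest.approx(0.01)
        assert fit.b == pytest.approx(2.0)

    def test_all_zero_gpig_is_an_error(self):
        with pytest.raises(ValueError, match="gpig > 0"):
            fit_gut_pigment_power(records([5.0, 10.0, 20.0], [0.0, 0.0, 0.0]))


class TestGutPassageTime:
    def test_printed_value_at_20mm(self):
        # 2.607·ln(20) − 2.6 = 5.21 h at the reference temperature
        assert gut_passage_time(20.0, 10.0) == pytest.approx(5.21, abs=0.005)

    def test_ln_e_identity(self):
        assert gut_passage_time(np.e, 10.0) == pytest.approx(0.007, abs=1e-9)

    def test_q10_halves_gpt_ten_degrees_warmer(self):
        cfg = Q10Config(q10=2.0, t_ref=10.0)
        assert gut_passage_time(20.0, 20.0, cfg) == pytest.approx(
            gut_passage_time(20.0, 10.0, cfg) / 2
        )

    def test_below_validity_bound_raises(self):
        with pytest.raises(ValueError, match="OAL"):
            gut_passage_time(2.0, 10.0)

    @given(st.floats(3.0, 130.0), st.floats(3.0, 130.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_increasing_in_length(self, l1, l2):
        lo, hi = sorted([l1, l2])
        assert gut_passage_time(lo, 10.0) <= gut_passage_time(hi, 10.0)

    @given(st.floats(0.0, 20.0), st.floats(0.0, 20.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_decreasing_in_temperature(self, t1, t2):
        lo, hi = sorted([t1, t2])
        cfg = Q10Config(q10=2.0, t_ref=10.0)
        assert gut_passage_time(20.0, hi, cfg) <= gut_passage_time(20.0, lo, cfg)


class TestPopulationGrazing:
    def fit_const(self):
        # exact fit through three points of a·L^b
        lengths = np.array([10.0, 20.0, 40.0])
        return fit_gut_pigment_power(records(lengths, 2.0 * lengths**1.5))

    def test_zero_abundance_zero_grazing(self):
        pop = day_night_average([make_tow(np.array([]))], temperature=10.0)
        out = population_grazing(pop, self.fit_const(), temp=10.0)
        assert out.total_pigment == 0.0
        assert out.total_carbon == 0.0

    def test_day_night_hour_weighting_sums_to_24(self):
        day = make_tow([20.0], volume=200.0)
        night = make_tow([20.0], volume=200.0, is_night=True)
        pop = day_night_average([day, night], temperature=10.0)
        fit = self.fit_const()
        out = population_grazing(pop, fit, temp=10.0)
        mid = 18.5  # midpoint of bin [16, 21)
        rate = fit.predict(mid) / gut_passage_time(mid, 10.0)
        expected_ng = 24.0 * 1.0 * rate  # (14+10) h × 1 ind m⁻²
        assert out.total_pigment == pytest.approx(expected_ng * 1e-6)

    def test_doubling_abundance_doubles_grazing(self):
        one = day_night_average([make_tow([20.0], volume=200.0)], temperature=10)
        two = day_night_average(
            [make_tow([20.0, 20.0], volume=200.0)], temperature=10
        )
        fit = self.fit_const()
        g1 = population_grazing(one, fit, temp=10.0).total_pigment
        g2 = population_grazing(two, fit, temp=10.0).total_pigment
        assert g2 == pytest.approx(2 * g1)

    def test_missing_temperature_is_an_error(self):
        pop = day_night_average([make_tow([20.0])], temperature=float("nan"))
        with pytest.raises(ValueError, match="temperature"):
            population_grazing(pop, self.fit_const(), temp=float("nan"))

    def test_carbon_units_scale_with_c_to_chl(self):
        pop = day_night_average([make_tow([20.0])], temperature=10.0)
        fit = self.fit_const()
        a = population_grazing(pop, fit, temp=10.0, c_to_chl=50.0)
        b = population_grazing(pop, fit, temp=10.0, c_to_chl=100.0)
        assert b.total_carbon == pytest.approx(2 * a.total_carbon)
        assert b.total_pigment == pytest.approx(a.total_pigment)


class TestEgestion:
    def test_egestion_efficiency_fraction(self):
        assert egestion_gpig(100.0) == pytest.approx(36.0)
        assert egestion_gpig(0.0) == 0.0
        assert egestion_gpig(57.0, ee=1.0) == pytest.approx(57.0)

    def test_egestion_never_exceeds_grazing(self):
        for gr in (0.0, 10.0, 1234.5):
            assert egestion_gpig(gr) <= gr

    def test_iversen_printed_values_at_50mm(self):
        assert iversen_pellet_rate(50.0, 0.0) == pytest.approx(0.1867, abs=5e-4)
        assert iversen_pellet_carbon(50.0) == pytest.approx(178.3, abs=0.1)

    def test_iversen_small_size_limits(self):
        # exponent → 0 as size → 0⁺, and 1^2.0665 = 1
        assert iversen_pellet_rate(1e-9, 0.0) == pytest.approx(0.5388, rel=1e-6)
        assert iversen_pellet_carbon(1.0) == pytest.approx(0.055)

    def test_iversen_nonpositive_size_rejected(self):
        with pytest.raises(ValueError, match="size"):
            iversen_pellet_rate(0.0, 0.0)
        with pytest.raises(ValueError, match="size"):
            iversen_pellet_carbon(-1.0)

    def test_iversen_population_matches_hand_sum(self):
        day = make_tow([48.0], volume=200.0)
        night = make_tow([48.0], volume=200.0, is_night=True)
        pop = day_night_average([day, night], temperature=10.0)
        cfg = Q10Config(q10=2.0, t_ref=0.0)
        out = egestion_iversen(pop, temp=10.0, q10cfg=cfg)
        mid = 48.5  # bin [46, 51)
        per_h = (
            0.5388 * np.exp(-0.0212 * mid) * 2.0  # Q10 factor at 10 °C
            * 0.055 * mid**2.0665
        )
        assert out["blastozooid"] == pytest.approx(24.0 * per_h * 1e-3)
        assert out["oozooid"] == 0.0

    def test_iversen_linear_in_abundance(self):
        one = day_night_average([make_tow([48.0], volume=200.0)], temperature=10)
        three = day_night_average(
            [make_tow([48.0] * 3, volume=200.0)], temperature=10
        )
        e1 = egestion_iversen(one, temp=10.0)["blastozooid"]
        e3 = egestion_iversen(three, temp=10.0)["blastozooid"]
        assert e3 == pytest.approx(3 * e1)
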