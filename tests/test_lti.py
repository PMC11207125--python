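"""Transfer-function container, Routh arrays, step simulation and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rfacontrol as rc
from rfacontrol.lti import InfiniteDCGainError, UnsettledError, StepSeries


class TestRationalTF:
    def test_rejects_zero_leading_denominator(self):
        with pytest.raises(ValueError):
            rc.RationalTF([1.0], [0.0, 1.0])

    def test_discrete_requires_sample_period(self):
        with pytest.raises(ValueError):
            rc.RationalTF([1.0], [1.0, -0.5], domain="z")

    def test_zinv_round_trip(self):
        tf = rc.RationalTF.from_zinv([0, 1.0, 0.5], [1.0, -0.3], dt=1.0)
        num, den = tf.to_zinv()
        assert num[0] == 0.0 and num[1] == 1.0 and num[2] == 0.5
        assert den[0] == 1.0 and den[1] == -0.3


class TestCanonicalPlants:
    def test_continuous_variants_differ_only_in_denominator_precision(self):
        printed = rc.canonical_plant("as_printed")
        refined = rc.canonical_plant("routh_refined")
        assert printed.den[1] == 2.12
        assert refined.den[1] == 2.1186
        np.testing.assert_allclose(printed.num, refined.num)
        assert printed.num_degree == 8 and printed.den_degree == 9
        assert printed.is_strictly_proper

    def test_dc_gain_near_1_61(self):
        for variant in ("as_printed", "routh_refined"):
            assert rc.dc_gain(rc.canonical_plant(variant)) == pytest.approx(
                1.610, rel=0.01
            )

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            rc.canonical_plant("nonsense")

    def test_discrete_plant_structure(self):
        tf = rc.canonical_discrete_plant()
        num, den = tf.to_zinv()
        assert den[1] == -2.42
        assert np.count_nonzero(num) == 6  # b1..b6
        assert tf.dt == 1.0
        # no pure integrator: den(z=1) = sum of coefficients is nonzero
        assert abs(np.sum(den)) > 1e-12


class TestDCGain:
    def test_first_order(self):
        assert rc.dc_gain(rc.RationalTF([2.0], [1.0, 1.0])) == 2.0

    def test_integrator_signals_infinite_gain(self):
        with pytest.raises(InfiniteDCGainError):
            rc.dc_gain(rc.RationalTF([1.0], [1.0, 0.0]))

    def test_discrete_gain_at_z_equal_1(self):
        tf = rc.RationalTF([0.5], [1.0, -0.5], domain="z", dt=1.0)
        assert rc.dc_gain(tf) == pytest.approx(1.0)


class TestStepResponse:
    def test_first_order_matches_analytic(self):
        resp = rc.step_response(rc.RationalTF([1.0], [1.0, 1.0]), horizon=5.0)
        expected = 1.0 - np.exp(-resp.t)
        np.testing.assert_allclose(resp.y, expected, rtol=1e-6, atol=1e-12)
        assert resp.y[1000] == pytest.approx(0.632121, abs=1e-6)

    def test_second_order_matches_analytic(self):
        wn, z = 2.0, 0.5
        resp = rc.step_response(
            rc.RationalTF([wn**2], [1.0, 2 * z * wn, wn**2]), horizon=10.0
        )
        wd = wn * np.sqrt(1 - z**2)
        t = resp.t
        expected = 1 - np.exp(-z * wn * t) * (
            np.cos(wd * t) + z / np.sqrt(1 - z**2) * np.sin(wd * t)
        )
        np.testing.assert_allclose(resp.y, expected, rtol=1e-6, atol=1e-9)

    def test_improper_rejected(self):
        with pytest.raises(ValueError):
            rc.step_response(rc.RationalTF([1.0, 0.0, 0.0], [1.0, 1.0]), 1.0)

    def test_plant_terminal_value_reaches_dc_gain(self, plant):
        resp = rc.step_response(plant, horizon=120.0, dt=1e-2)
        assert resp.y[-1] == pytest.approx(rc.dc_gain(plant), rel=1e-3)

    def test_stable_strictly_proper_settles_to_dc_gain(self, rng):
        # random stable systems built from random left-half-plane poles
        for _ in range(10):
            n = rng.integers(2, 5)
            poles = -rng.uniform(0.3, 3.0, size=n) + 1j * rng.uniform(-2, 2, size=n)
            poles = np.concatenate([poles, np.conj(poles)])
            den = np.real(np.poly(poles))
            tf = rc.RationalTF([den[-1]], den)
            resp = rc.step_response(tf, horizon=40.0, dt=5e-3)
            m = rc.step_metrics(resp, final_value=rc.dc_gain(tf))
            assert m.final_value == pytest.approx(resp.y[-1], rel=5e-3)


class TestStepMetrics:
    def test_first_order_classics(self):
        resp = rc.step_response(rc.RationalTF([1.0], [1.0, 1.0]), horizon=10.0)
        m = rc.step_metrics(resp, final_value=1.0)
        assert m.overshoot_pct == 0.0
        assert m.rise_time == pytest.approx(np.log(9), rel=1e-4)
        assert m.settling_time == pytest.approx(-np.log(0.02), rel=1e-3)

    def test_underdamped_overshoot_matches_closed_form(self):
        wn, z = 2.0, 0.5
        tf = rc.RationalTF([wn**2], [1.0, 2 * z * wn, wn**2])
        m = rc.step_metrics(rc.step_response(tf, horizon=20.0), final_value=1.0)
        expected = 100 * np.exp(-z * np.pi / np.sqrt(1 - z**2))
        assert m.overshoot_pct == pytest.approx(expected, rel=1e-4)
        assert m.rise_time <= m.peak_time

    def test_open_loop_plant_metrics(self, plant):
        resp = rc.step_response(plant, horizon=20.0)
        m = rc.step_metrics(resp, final_value=rc.dc_gain(plant))
        assert m.peak_amplitude == pytest.approx(33.6, rel=0.01)
        assert m.settling_time == pytest.approx(15.2, rel=0.01)
        assert m.rise_time == pytest.approx(0.038, rel=0.05)

    def test_unsettled_horizon_raises(self, plant):
        resp = rc.step_response(plant, horizon=5.0)
        with pytest.raises(UnsettledError):
            rc.step_metrics(resp, final_value=rc.dc_gain(plant))


class TestRouth:
    def test_stable_quadratic(self):
        rt = rc.routh_table([1.0, 2.0, 1.0])
        assert rt.first_column == [1.0, 2.0, 1.0]
        assert rt.stable and rt.sign_changes == 0

    def test_one_right_half_plane_root(self):
        rt = rc.routh_table([1.0, 1.0, -2.0])  # roots {1, -2}
        assert rt.first_column == [1.0, 1.0, -2.0]
        assert rt.sign_changes == 1 and not rt.stable

    def test_open_loop_plant_table(self, plant):
        rt = rc.routh_table(plant.den)
        assert len(rt.rows) == 10
        assert rt.first_column[2] == pytest.approx(5.5608, abs=1e-3)
        assert rt.stable
        assert all(v > 0 for v in rt.first_column)

    def test_zero_first_column_element_epsilon(self):
        # s^4 + s^3 + 2s^2 + 2s + 3: the s^2 pivot vanishes
        rt = rc.routh_table([1.0, 1.0, 2.0, 2.0, 3.0])
        assert rt.epsilon_rows
        assert not rt.stable
        assert rt.sign_changes == 2  # two RHP roots, by the epsilon limit

    def test_all_zero_row_auxiliary_polynomial(self):
        # (s^2+1)(s+1) = s^3 + s^2 + s + 1: s^1 row vanishes
        rt = rc.routh_table([1.0, 1.0, 1.0, 1.0])
        assert rt.auxiliary_rows
        assert rt.sign_changes == 0
        assert not rt.stable  # imaginary-axis pair is not asymptotically stable

    def test_all_zero_polynomial_rejected(self):
        with pytest.raises(ValueError):
            rc.routh_table([0.0, 0.0])

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-5, max_value=5).filter(lambda v: abs(v) > 1e-3),
            min_size=3,
            max_size=7,
        )
    )
    def test_sign_changes_count_right_half_plane_roots(self, coeffs):
        roots = np.roots(coeffs)
        if np.any(np.abs(roots.real) < 1e-6):  # skip near-imaginary-axis ties
            return
        rt = rc.routh_table(coeffs)
        assert rt.sign_changes == int(np.sum(roots.real > 0))

    def test_sign_changes_match_eigenvalue_oracle_bulk(self, rng):
        hits = 0
        for _ in range(500):
            deg = rng.integers(2, 7)
            c = rng.uniform(-3, 3, size=deg + 1)
            if abs(c[0]) < 1e-3:
                c[0] = 1.0
            roots = np.roots(c)
            if np.any(np.abs(roots.real) < 1e-9):
                continue
            rt = rc.routh_table(c)
            assert rt.sign_changes == int(np.sum(roots.real > 0))
            hits += 1
        assert hits > 400  # the degenerate skip is rare


class TestPolesZeros:
    def test_factorable(self):
        pz = rc.poles_zeros(rc.RationalTF([1.0, 1.0], [1.0, 3.0, 2.0]))
        np.testing.assert_allclose(sorted(pz.zeros.real), [-1.0])
        np.testing.assert_allclose(sorted(pz.poles.real), [-2.0, -1.0])

    def test_open_loop_dominant_pair(self, plant):
        pz = rc.poles_zeros(plant)
        target = -0.3521 + 3.1406j
        assert min(abs(pz.poles - target)) < 5e-3
        # conjugate symmetry
        for p in pz.poles:
            if abs(p.imag) > 1e-9:
                assert min(abs(pz.poles - np.conj(p))) < 1e-9

    def test_round_trip_through_roots(self, rng):
        for _ in range(20):
            re = rng.uniform(-2, 2, size=2)
            im = rng.uniform(0.1, 2, size=1)
            roots = np.concatenate([re, [re[0] + 1j * im[0], re[0] - 1j * im[0]]])
            den = np.real(np.poly(roots))
            pz = rc.poles_zeros(rc.RationalTF([1.0], den))
            # multiset comparison: each constructed root has a computed match
            assert len(pz.poles) == len(roots)
            for r in roots:
                assert min(abs(pz.poles - r)) < 1e-8


class TestDomainConversion:
    def test_zoh_single_pole(self):
        zd = rc.RationalTF([0.0951626], [1.0, -0.904837], domain="z", dt=0.1)
        cont = rc.d2c_convert(zd, method="zoh")
        pole = rc.poles_zeros(cont).poles[0]
        assert pole.real == pytest.approx(-1.0, rel=1e-4)

    def test_tustin_is_involution(self):
        tf = rc.RationalTF([1.0], [1.0, 1.0])
        back = rc.d2c_convert(rc.c2d_convert(tf, 0.1, "tustin"), "tustin")
        np.testing.assert_allclose(back.num, [1.0], atol=1e-8)
        np.testing.assert_allclose(back.den, [1.0, 1.0], atol=1e-8)

    def test_zoh_round_trip_second_order(self, rng):
        for _ in range(5):
            wn = rng.uniform(0.5, 3.0)
            z = rng.uniform(0.3, 0.95)
            tf = rc.RationalTF([wn**2], [1.0, 2 * z * wn, wn**2])
            back = rc.d2c_convert(rc.c2d_convert(tf, 0.05, "zoh"), "zoh")
            np.testing.assert_allclose(back.den, tf.den, rtol=1e-6, atol=1e-8)
            np.testing.assert_allclose(
                back.num[-1], tf.num[-1], rtol=1e-6
            )

    def test_zoh_rejects_pole_at_origin(self):
        zd = rc.RationalTF([1.0], [1.0, 0.0], domain="z", dt=1.0)
        with pytest.raises(ValueError):
            rc.d2c_convert(zd, method="zoh")


class TestRefineFromRouth:
    def test_degree_two_interleave(self):
        out = rc.refine_plant_from_routh([[1.0, 3.0], [2.0]], degree=2)
        np.testing.assert_allclose(out, [1.0, 2.0, 3.0])

    def test_open_loop_rows_recover_refined_denominator(self, plant):
        rows = [
            [1.0, 15.7632, 55.2829, 49.1387, 7.2780],
            [2.1186, 21.6147, 46.7952, 24.4473, 0.5032],
        ]
        np.testing.assert_allclose(
            rc.refine_plant_from_routh(rows, degree=9), plant.den
        )

    def test_closed_loop_rows_give_degree_ten_characteristic(self):
        rows = [
            [17.08, 1276.1, 10389.0, 15563.0, 5874.3, 8.12],
            [233.14, 4412.4, 15301.0, 11168.0, 592.91],
        ]
        out = rc.refine_plant_from_routh(rows, degree=10)
        np.testing.assert_allclose(
            out,
            [17.08, 233.14, 1276.1, 4412.4, 10389.0, 15301.0, 15563.0,
             11168.0, 5874.3, 592.91, 8.12],
        )

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(ValueError):
            rc.refine_plant_from_routh([[1.0, 2.0], [1.0, 2.0, 3.0]], degree=3)


def test_step_series_requires_matching_shapes():
    with pytest.raises(ValueError):
        StepSeries(np.arange(3.0), np.arange(4.0))
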