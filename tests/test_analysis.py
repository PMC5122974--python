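import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize

from encortex import analysis
from encortex.analysis import (circular_variance, correlate, fit_naka_rushton,
                               fit_von_mises, lhi_2d, lhi_from_sites, lhi_1d,
                               mean_si, naka_rushton, nli_from_curve,
                               nonlinearity_index, suppression_index,
                               von_mises)
from encortex.mapsynth import OrientationMap, Track, generate_map
from encortex.stimuli import BATTERY_CONTRASTS, BATTERY_ORIENTATIONS


class TestNakaRushtonFit:
    def test_noiseless_round_trip(self):
        c = np.asarray(BATTERY_CONTRASTS)
        r = naka_rushton(c, 1.0, 0.25, 2.0)
        fit = fit_naka_rushton(c, r)
        assert fit.r_max_param == pytest.approx(1.0, abs=1e-4)
        assert fit.c50_param == pytest.approx(0.25, abs=1e-4)
        assert fit.n_param == pytest.approx(2.0, abs=1e-4)
        assert fit.well_fit

    def test_effective_semi_saturation_identity(self):
        c = np.asarray(BATTERY_CONTRASTS)
        for c50, n in [(0.1, 1.0), (0.25, 2.0), (0.4, 3.5), (0.7, 0.8)]:
            fit = fit_naka_rushton(c, naka_rushton(c, 2.0, c50, n))
            # definitional: f(semi_saturation) = f(1)/2
            assert fit(fit.semi_saturation) == pytest.approx(
                fit.max_response / 2, rel=1e-6)

    def test_semi_saturation_matches_bisection_oracle(self):
        r_max, c50, n = 1.0, 0.25, 2.0
        target = naka_rushton(1.0, r_max, c50, n) / 2

        def g(c):
            return naka_rushton(c, r_max, c50, n) - target
        oracle = optimize.brentq(g, 1e-9, 1.0, xtol=1e-12)
        fit = fit_naka_rushton(np.asarray(BATTERY_CONTRASTS),
                               naka_rushton(np.asarray(BATTERY_CONTRASTS),
                                            r_max, c50, n))
        assert fit.semi_saturation == pytest.approx(oracle, abs=1e-6)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_naka_rushton([0.1, 0.2, 0.3], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_naka_rushton([0.1, 0.2, 0.5, 1.0], [1, 2, np.nan, 3])


class TestVonMisesFit:
    def test_noiseless_round_trip(self):
        th = np.arange(0, 180, 22.5)
        r = von_mises(th, 0.1, 1.0, 3.0, 45.0)
        fit = fit_von_mises(th, r)
        assert fit.preferred_orientation == pytest.approx(45.0, abs=1e-3)
        assert fit.kappa == pytest.approx(3.0, abs=1e-3)
        assert fit.well_fit

    def test_hwhh_is_half_height_above_baseline(self):
        th = np.arange(0, 180, 11.25)
        fit = fit_von_mises(th, von_mises(th, 0.2, 0.8, 2.0, 30.0))
        half = fit.baseline + fit.amplitude / 2
        assert fit(fit.preferred_orientation + fit.hwhh) == pytest.approx(
            half, rel=1e-6)

    def test_flat_responses_flagged(self):
        fit = fit_von_mises(np.arange(0, 180, 22.5), np.full(8, 2.0))
        assert fit.flat
        assert fit.circular_variance == 1.0
        assert np.isnan(fit.hwhh)

    def test_circular_variance_range(self):
        th = np.arange(0, 180, 22.5)
        sharp = circular_variance(th, von_mises(th, 0.0, 1.0, 20.0, 10.0))
        broad = circular_variance(th, von_mises(th, 0.5, 0.2, 0.5, 10.0))
        assert 0 <= sharp < broad <= 1


class TestSuppressionIndex:
    def test_boundary_cases(self):
        assert suppression_index(1.0, 1.0) == 0.0
        assert suppression_index(0.0, 1.0) == 1.0
        assert suppression_index(2.0, 1.0) == -1.0   # facilitation is negative

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            suppression_index(1.0, 0.0)

    @given(r_plaid=st.floats(0, 10), a=st.floats(0.01, 10))
    def test_affine_in_plaid_response(self, r_plaid, a):
        si = suppression_index(r_plaid, 2.0)
        si_scaled = suppression_index(a * r_plaid, 2.0)
        assert si_scaled == pytest.approx(1 - a * (1 - si), abs=1e-9)

    def test_mean_si_boundary_cases(self):
        assert mean_si(np.full(8, 2.0), 2.0) == 0.0
        assert mean_si(np.zeros(8), 2.0) == 1.0
        # dropping the preferred+preferred pair only uses the other 7
        vals = np.array([2.0] + [0.0] * 7)
        assert mean_si(vals, 2.0, include_preferred_pair=False) == 1.0


class TestLHI:
    def test_homogeneous_neighbourhood_scores_one(self):
        assert lhi_from_sites([-300, -200, -100, 100, 200, 300],
                              [45] * 6) == pytest.approx(1.0)

    def test_orthogonal_equidistant_pair_cancels(self):
        assert lhi_from_sites([100, -100], [0.0, 90.0]) == pytest.approx(0.0,
                                                                         abs=1e-12)

    def test_mixed_neighbourhood_matches_vector_sum_oracle(self):
        d = np.array([-200, -100, 100, 200])
        om = np.array([90.0, 0.0, 0.0, 90.0])
        w = np.exp(-d.astype(float) ** 2 / (2 * 180.0 ** 2))
        oracle = abs(np.sum(w * np.exp(2j * np.deg2rad(om)))) / w.sum()
        w100, w200 = np.exp(-100 ** 2 / (2 * 180.0 ** 2)), np.exp(-200 ** 2 / (2 * 180.0 ** 2))
        assert oracle == pytest.approx((w100 - w200) / (w100 + w200))
        assert lhi_from_sites(d, om) == pytest.approx(oracle)

    @given(st.lists(st.floats(0, 179.999), min_size=4, max_size=10),
           st.floats(0, 179.9))
    def test_bounds_and_rotation_invariance(self, oris, rot):
        d = 100.0 * (np.arange(len(oris)) + 1)
        val = lhi_from_sites(d, oris)
        assert -1e-9 <= val <= 1 + 1e-9
        rotated = [(o + rot) % 180 for o in oris]
        assert lhi_from_sites(d, rotated) == pytest.approx(val, abs=1e-9)

    def test_unity_only_for_coincident_orientations(self):
        close = lhi_from_sites([100, 200], [10.0, 10.0])
        apart = lhi_from_sites([100, 200], [10.0, 40.0])
        assert close == pytest.approx(1.0)
        assert apart < 1.0 - 1e-3

    def test_flank_requirement(self):
        pos = np.column_stack([np.arange(7) * 100.0, np.zeros(7)])
        track = Track(pos, np.full(7, 20.0))
        assert lhi_1d(track, 3) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            lhi_1d(track, 1)

    def test_2d_constant_map_is_unity(self):
        omap = OrientationMap(np.full((80, 80), 60.0), 20.0, 1000.0)
        assert lhi_2d(omap, (800.0, 800.0)) == pytest.approx(1.0)

    def test_2d_low_at_pinwheels_high_in_domains(self, small_map):
        l2 = analysis.lhi_2d_map(small_map)
        pos, _ = small_map.pinwheel_centers()
        px = small_map.pixel_pitch_um
        margin = 3 * 180.0
        interior = [(x, y) for x, y in pos
                    if margin < x < small_map.extent_um[0] - margin
                    and margin < y < small_map.extent_um[1] - margin]
        pw_vals = [lhi_2d(small_map, p) for p in interior[:50]]
        assert np.median(pw_vals) < 0.3
        assert min(pw_vals) < 0.3          # pinwheel class present
        assert l2.max() > 0.7              # iso-domain class present
        assert np.median(pw_vals) < np.median(l2)

    def test_2d_edge_rejected(self, small_map):
        with pytest.raises(ValueError):
            lhi_2d(small_map, (100.0, 100.0))


class TestNonlinearityIndex:
    def test_linear_curve_scores_zero(self):
        def chord(c):
            return 0.5 + (np.asarray(c) - 0.3) * 0.5 / 0.7
        assert nli_from_curve(chord, 0.3, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_maximal_saturation_scores_plus_one(self):
        assert nli_from_curve(lambda c: np.ones_like(np.asarray(c, float)),
                              0.3, 1.0) == pytest.approx(1.0)

    def test_maximal_expansion_scores_minus_one(self):
        assert nli_from_curve(lambda c: np.full_like(np.asarray(c, float), 0.5),
                              0.3, 1.0) == pytest.approx(-1.0)

    def test_bounded_and_monotone_in_exponent(self):
        # hold the effective semi-saturation at 0.3 while the exponent grows
        vals = []
        for n in (1.0, 1.5, 2.0, 3.0, 4.0, 6.0):
            c50 = optimize.brentq(
                lambda c50: c50 * (1 + 2 * c50 ** n) ** (-1 / n) - 0.3,
                0.3, 1e6)
            nli = nli_from_curve(lambda c: naka_rushton(c, 1.0, c50, n),
                                 0.3, naka_rushton(1.0, 1.0, c50, n))
            assert -1.0 - 1e-9 <= nli <= 1.0 + 1e-9
            vals.append(nli)
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_degenerate_chord_flagged(self):
        with pytest.raises(ValueError):
            nli_from_curve(lambda c: c, 1.0, 1.0)


class TestCorrelate:
    def test_perfect_line(self):
        x = np.linspace(0, 1, 20)
        res = correlate(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_independent_samples_uncorrelated(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(1000), rng.standard_normal(1000)
        assert abs(correlate(x, y).r) < 0.1

    def test_constant_input_flagged(self):
        res = correlate(np.ones(20), np.arange(20.0))
        assert np.isnan(res.r)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 2, 3], [3, 2, 1])


class TestLHIComparison:
    def test_constant_map_degenerates_at_unity(self):
        omap = OrientationMap(np.full((150, 150), 12.0), 20.0, 1000.0)
        cmp_ = analysis.lhi_compare(omap, n_points=20, seed=0)
        assert np.allclose(cmp_.lhi2d, 1.0, atol=1e-9)
        assert np.allclose(cmp_.lhi1d_mean, 1.0, atol=1e-9)
        assert np.isnan(cmp_.spearman)     # degenerate scatter is flagged

    def test_monotone_relation_on_synthetic_map(self, small_map):
        cmp_ = analysis.lhi_compare(small_map, n_points=150, seed=1)
        assert cmp_.spearman > 0.8
        assert 0.0 <= cmp_.frac_excess_gt <= 1.0
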