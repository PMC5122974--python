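import numpy as np
import pytest
from scipy import ndimage

from encortex.pathway import (BROAD_GEOMETRY, NARROW_GEOMETRY, DoGParams,
                              FeedforwardUnit, PhotoreceptorParams,
                              PushPullGeometry, SpikingParams, dog_kernel,
                              photoreceptor, pushpull_input, spiking,
                              thalamic_response)
from encortex.stimuli import GratingSpec, PixelGrid, make_grating

GRID = PixelGrid()


class TestPhotoreceptor:
    def test_zero_input_gives_zero(self):
        assert np.all(photoreceptor(np.zeros((8, 8))) == 0.0)

    @pytest.mark.parametrize("exponent", [0.5, 1.0, 2.0, 10.0])
    def test_semi_saturation_point(self, exponent):
        p = PhotoreceptorParams(L50=0.5, exponent=exponent)
        out = photoreceptor(np.full((4, 4), 0.5), p)
        assert np.allclose(out, 0.5)

    def test_monotone_and_bounded(self):
        s = np.linspace(0, 1, 101)
        out = photoreceptor(s)
        assert np.all(np.diff(out) >= 0)
        assert out.min() >= 0 and out.max() < 1

    def test_subadditive_for_compressive_exponent(self):
        # saturating transfer: P(a+b) <= P(a) + P(b) for a concave unit
        p = PhotoreceptorParams(L50=0.5, exponent=1.0)
        a, b = np.full((3, 3), 0.3), np.full((3, 3), 0.6)
        assert np.all(photoreceptor(a + b, p)
                      <= photoreceptor(a, p) + photoreceptor(b, p) + 1e-12)


class TestDoG:
    def test_kernel_is_balanced(self):
        k = dog_kernel(DoGParams(), GRID)
        assert abs(k.sum()) < 1e-6

    def test_polarity(self):
        on = dog_kernel(DoGParams(polarity="on"), GRID)
        off = dog_kernel(DoGParams(polarity="off"), GRID)
        c = on.shape[0] // 2
        assert on[c, c] > 0 and off[c, c] < 0
        assert np.array_equal(off, -on)

    def test_center_surround_sigma_ratio(self):
        p = DoGParams(sigma_surround=0.9)
        assert abs(p.sigma_center - 0.3) < 1e-12

    def test_underresolved_kernel_rejected(self):
        with pytest.raises(ValueError):
            dog_kernel(DoGParams(sigma_surround=0.3), GRID)


class TestThalamus:
    def test_uniform_field_evokes_nothing(self):
        maps = thalamic_response(np.full((64, 64), 0.7), DoGParams(), GRID)
        assert np.abs(maps.t_on).max() < 1e-9
        assert np.abs(maps.t_off).max() < 1e-9

    def test_bar_response_matches_direct_convolution(self):
        # independent oracle: scipy.ndimage.convolve with reflect boundary
        grid = PixelGrid(32, 32, 0.1)
        img = np.full((32, 32), 0.4)
        img[:, 14:18] = 0.9   # bright vertical bar
        p = photoreceptor(img)
        kernel = dog_kernel(DoGParams(), grid)
        expected = ndimage.convolve(p, kernel, mode="mirror")
        maps = thalamic_response(p, DoGParams(), grid)
        assert np.allclose(maps.t_on, expected, atol=1e-8)
        assert maps.t_on[16, 15] > 0                      # ON drive at the bar
        assert np.maximum(maps.t_off, 0)[16, 10] > 0      # OFF drive in a flank

    def test_off_channel_is_contrast_inverse(self):
        img = make_grating(GratingSpec(0.0, 0.8), GRID)
        maps = thalamic_response(img.values, DoGParams(), GRID)
        # linearity: convolving the negated modulation flips the sign
        inv = thalamic_response(1.0 - img.values, DoGParams(), GRID)
        assert np.allclose(maps.t_off, inv.t_on, atol=1e-8)


class TestPushPull:
    def test_blank_stimulus_silent(self):
        unit = FeedforwardUnit()
        assert unit.t_tot(np.full((64, 64), 0.5)) == pytest.approx(0.0, abs=1e-9)

    def test_optimal_phase_maximal_among_battery_phases(self):
        unit = FeedforwardUnit()
        responses = {ph: unit.t_tot(make_grating(GratingSpec(0, 1.0, ph), GRID))
                     for ph in (0, np.pi / 2, np.pi, 3 * np.pi / 2)}
        assert max(responses, key=responses.get) == np.pi

    def test_tuning_narrows_with_more_subunits(self):
        # half-width proxy: orientation where the phase-max response halves
        widths = []
        for n in (2, 4, 6, 8):
            unit = FeedforwardUnit(PushPullGeometry(n_subunits=n))
            oris = np.arange(0, 92.5, 7.5)
            resp = np.array([
                max(unit.t_tot(make_grating(GratingSpec(o, 1.0, ph), GRID))
                    for ph in (0, np.pi / 2, np.pi, 3 * np.pi / 2))
                for o in oris])
            half = resp[0] / 2
            widths.append(oris[np.argmax(resp < half)])
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_tuning_symmetric_about_preferred(self):
        unit = FeedforwardUnit()
        for d in (10.0, 25.0, 50.0):
            plus = unit.response([GratingSpec(d, 1.0)])
            minus = unit.response([GratingSpec(-d, 1.0)])
            assert plus == pytest.approx(minus, rel=1e-6)

    def test_column_outside_grid_rejected(self):
        tiny = PixelGrid(16, 16, 0.1)
        unit = FeedforwardUnit(PushPullGeometry(n_subunits=16), grid=tiny)
        with pytest.raises(ValueError):
            unit.t_tot(np.full((16, 16), 0.6))


class TestSpiking:
    def test_rectified_power_law(self):
        assert spiking(0.0) == 0.0
        assert spiking(-3.0) == 0.0
        assert spiking(2.0) == pytest.approx(4.0 * spiking(1.0))

    def test_gain_scales_linearly(self):
        assert spiking(1.5, SpikingParams(gain=3.0)) == pytest.approx(
            3.0 * spiking(1.5, SpikingParams(gain=1.0)))


class TestFeedforwardSuppression:
    def test_orthogonal_plaid_suppresses_preferred_component(self):
        """The pre-cortical mechanism: photoreceptor saturation makes the
        response to a 0.5+0.5 orthogonal plaid smaller than to the
        preferred grating alone at 0.5 contrast."""
        unit = FeedforwardUnit()
        r_pref = unit.response([GratingSpec(0.0, 0.5)])
        r_plaid = np.mean([
            unit.response([GratingSpec(0.0, 0.5, 0.0), GratingSpec(90.0, 0.5, p2)])
            for p2 in (0, np.pi / 2, np.pi, 3 * np.pi / 2)])
        assert r_plaid < r_pref

    def test_preferred_orientation_by_stimulus_rotation(self):
        a = FeedforwardUnit(preferred_orientation=0.0)
        b = FeedforwardUnit(preferred_orientation=60.0)
        assert a.response([GratingSpec(15.0, 1.0)]) == pytest.approx(
            b.response([GratingSpec(75.0, 1.0)]), rel=1e-9)

    def test_broad_unit_is_broader(self):
        oris = np.arange(0, 91, 7.5)
        narrow = FeedforwardUnit(NARROW_GEOMETRY)
        broad = FeedforwardUnit(BROAD_GEOMETRY)
        tn = np.array([narrow.response([GratingSpec(o, 1.0)]) for o in oris])
        tb = np.array([broad.response([GratingSpec(o, 1.0)]) for o in oris])
        # broad normalized tuning dominates the narrow one away from peak
        assert np.all(tb / tb[0] >= tn / tn[0] - 1e-9)
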