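import numpy as np
import pytest
from hypothesis import given, strategies as st

from encortex.stimuli import (BATTERY_ORIENTATIONS, GratingSpec, PixelGrid,
                              equal_plaid_components, make_battery,
                              make_grating, make_plaid)

GRID = PixelGrid()


class TestGrating:
    def test_zero_contrast_is_uniform_midgrey(self):
        img = make_grating(GratingSpec(45.0, 0.0), GRID)
        assert np.all(img.values == 0.5)

    def test_full_contrast_spans_unit_range(self):
        img = make_grating(GratingSpec(0.0, 1.0), GRID)
        # discrete sampling: extrema within half a pixel-phase step of 0 and 1
        assert img.values.min() < 0.02
        assert img.values.max() > 0.98
        assert abs(img.values.mean() - 0.5) < 1e-3

    def test_rotation_by_90_exchanges_axes(self):
        a = make_grating(GratingSpec(0.0, 0.8, 0.7), GRID)
        b = make_grating(GratingSpec(90.0, 0.8, 0.7), GRID)
        assert np.allclose(a.values, b.values.T, atol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            GratingSpec(0.0, 1.5)
        with pytest.raises(ValueError):
            make_grating(GratingSpec(0.0, 0.5, spatial_frequency=5.0), GRID)

    @given(orientation=st.floats(0, 360), contrast=st.floats(0, 1),
           phase=st.floats(0, 2 * np.pi))
    def test_values_always_in_unit_interval(self, orientation, contrast, phase):
        img = make_grating(GratingSpec(orientation, contrast, phase), GRID)
        assert img.values.min() >= 0.0 and img.values.max() <= 1.0


class TestPlaid:
    def test_single_component_equals_grating(self):
        spec = GratingSpec(30.0, 0.6, 1.0)
        assert np.array_equal(make_plaid([spec], GRID).values,
                              make_grating(spec, GRID).values)

    def test_identical_halves_superpose_to_full_grating(self):
        s = GratingSpec(22.5, 0.5, 0.3)
        plaid = make_plaid([s, s], GRID)
        full = make_grating(GratingSpec(22.5, 1.0, 0.3), GRID)
        assert np.allclose(plaid.values, full.values, atol=1e-12)

    def test_orthogonal_pair_bounded_and_balanced(self):
        plaid = make_plaid([GratingSpec(0.0, 0.5), GratingSpec(90.0, 0.5)], GRID)
        assert plaid.values.min() >= 0 and plaid.values.max() <= 1
        assert abs(plaid.values.mean() - 0.5) < 1e-3

    def test_overrange_total_contrast_rejected_unless_clipping(self):
        comps = [GratingSpec(0.0, 0.5), GratingSpec(90.0, 0.75)]
        with pytest.raises(ValueError):
            make_plaid(comps, GRID)
        img = make_plaid(comps, GRID, allow_clipping=True)
        assert img.values.min() >= 0 and img.values.max() <= 1

    def test_equal_plaid_contrast_split(self):
        for n in (1, 2, 4, 8):
            comps = equal_plaid_components(n, 1.0)
            assert len(comps) == n
            assert all(abs(c.contrast - 1 / n) < 1e-12 for c in comps)
            oris = sorted(c.orientation for c in comps)
            assert np.allclose(oris, np.arange(n) * 180.0 / n)


class TestBattery:
    def test_grating_battery_contents(self):
        batt = make_battery("grating_battery", GRID)
        assert len(batt) == 224
        oris = {m[0].orientation for m in batt.metadata}
        assert oris == set(BATTERY_ORIENTATIONS)

    def test_pair_plaid_battery_composition(self):
        batt = make_battery("pair_plaid_battery", GRID)
        # 36 unordered orientation pairs x 16 phase combinations
        assert len(batt) == 36 * 16
        assert all(len(m) == 2 and all(c.contrast == 0.5 for c in m)
                   for m in batt.metadata)

    def test_complexity_series_contrasts(self):
        batt = make_battery("complexity_series", GRID)
        counts = sorted({len(m) for m in batt.metadata})
        assert counts == [1, 2, 4, 8]
        for m in batt.metadata:
            assert abs(sum(c.contrast for c in m) - 1.0) < 1e-12

    def test_octotropic_spans_orientation_space(self):
        batt = make_battery("octotropic", GRID)
        for m in batt.metadata:
            assert len(m) == 8
            assert np.allclose(sorted(c.orientation for c in m),
                               np.arange(8) * 22.5)

    def test_unknown_battery_rejected(self):
        with pytest.raises(ValueError):
            make_battery("nonsense", GRID)

    def test_phase_averaged_battery_mean_is_midgrey(self):
        batt = make_battery("grating_battery", GRID)
        mean = np.mean([img.values for img in batt.images])
        assert abs(mean - 0.5) < 1e-3
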