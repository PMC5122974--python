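import numpy as np
import pytest
from hypothesis import given, strategies as st

from encortex.cortex import (CircuitSite, CorticalModel, ENParams, ModelNeuron,
                             UnorientedCellParams, dn_response, en_response,
                             extrastriate_pool, iso_site, neighbor_weights,
                             pinwheel_site, simulate_population,
                             surround_excitation, unoriented_response)
from encortex.mapsynth import generate_map
from encortex.stimuli import GratingSpec


class TestNeighborWeights:
    def test_weights_sum_to_one(self):
        w = neighbor_weights([-300, -200, -100, 100, 200, 300])
        assert abs(w.weights.sum() - 1.0) < 1e-9

    def test_equidistant_neighbours_weighted_equally(self):
        w = neighbor_weights([150, -150, 150, -150])
        assert np.allclose(w.weights, 0.25)

    def test_gaussian_distance_ratio(self):
        w = neighbor_weights([100, 200])
        expected = np.exp((200 ** 2 - 100 ** 2) / (2 * 180.0 ** 2))
        assert w.weights[0] / w.weights[1] == pytest.approx(expected, rel=1e-12)

    def test_self_and_empty_rejected(self):
        with pytest.raises(ValueError):
            neighbor_weights([0, 100])
        with pytest.raises(ValueError):
            neighbor_weights([2000.0])


class TestCircuitStages:
    def test_excitation_identity_when_neighbours_at_unity(self):
        w = neighbor_weights([100, 200, 300])
        assert surround_excitation(0.7, [1.0, 1.0, 1.0], w) == pytest.approx(0.7)
        assert surround_excitation(0.7, [0.0, 0.0, 0.0], w) == 0.0

    def test_en_response_limits(self):
        p = ENParams(r_max=1.0, beta0=0.01, beta1=1.0, beta2=1.0)
        assert en_response(0.0, 5.0, p) == 0.0
        assert en_response(1e9, 1.0, p) == pytest.approx(1.0, rel=1e-6)
        # direct arithmetic on the stated defaults
        assert en_response(1.0, 1.0, p) == pytest.approx(1.0 / 2.01)

    def test_dn_response_saturates_at_unity(self):
        w = neighbor_weights([100, 200])
        c = 50.0
        assert dn_response(c, [c, c], w, beta0=0.01) == pytest.approx(1.0, rel=1e-3)

    def test_unoriented_cell_blank_and_compression(self, cortical_model):
        up = cortical_model.unoriented_params
        assert unoriented_response(0.0, up) == 0.0
        unit = cortical_model.unit("narrow", 0.0)
        p25 = unit.unoriented_drive([GratingSpec(0.0, 0.25)])
        p100 = unit.unoriented_drive([GratingSpec(0.0, 1.0)])
        c25 = unoriented_response(p25, up)
        c100 = unoriented_response(p100, up)
        assert c25 >= 0.8 * c100     # severely compressed response function

    def test_unoriented_cell_is_orientation_blind(self, cortical_model):
        unit = cortical_model.unit("narrow", 0.0)
        drives = [unit.unoriented_drive([GratingSpec(th, 1.0)])
                  for th in (0.0, 30.0, 90.0, 120.0)]
        assert max(drives) / min(drives) < 1.02


class TestReferenceSites:
    def test_site_constructors(self):
        iso = iso_site(40.0)
        assert all(abs((o - 40.0 + 90) % 180 - 90) <= 10.0
                   for o in iso.neighbor_orientations)
        pin = pinwheel_site(0.0)
        spread = sorted(pin.neighbor_orientations)
        assert max(spread) - min(spread) > 120.0    # spans the 180 deg range

    def test_en_sharpening_mechanism(self, cortical_model):
        """Co-tuned excitation boosts the preferred response more than the
        orthogonal-flank response."""
        cm = cortical_model
        site = iso_site(0.0, "narrow")
        c_p, n_p, _ = cm._drives(site, (GratingSpec(0.0, 1.0),), False)
        c_o, n_o, _ = cm._drives(site, (GratingSpec(45.0, 1.0),), False)
        assert (c_p * n_p) / (c_o * n_o) > c_p / c_o

    def test_unknown_model_rejected(self, cortical_model):
        with pytest.raises(ValueError):
            cortical_model.site_response(iso_site(), [GratingSpec(0, 1.0)],
                                         model="xx")


@pytest.fixture(scope="module")
def tiny_map():
    return generate_map(shape=(64, 64), wavelength_um=400,
                        pixel_pitch_um=20, seed=3)


class TestSimulatePopulation:

    def test_ff_ignores_positions(self, tiny_map, cortical_model):
        stimuli = [[GratingSpec(0.0, 1.0)], [GratingSpec(90.0, 1.0)]]
        a = ModelNeuron((640.0, 640.0), 10.0, "narrow")
        b = ModelNeuron((400.0, 500.0), 10.0, "narrow")
        ra = simulate_population(tiny_map, [a], stimuli, "ff", cortical_model)
        rb = simulate_population(tiny_map, [b], stimuli, "ff", cortical_model)
        assert np.allclose(ra.response.values, rb.response.values)

    def test_zero_stimulus_gives_zero_table(self, tiny_map, cortical_model):
        stimuli = [[GratingSpec(0.0, 0.0)]]
        n = ModelNeuron((640.0, 640.0), 0.0, "narrow")
        out = simulate_population(tiny_map, [n], stimuli, "en", cortical_model)
        assert np.allclose(out.response.values, 0.0, atol=1e-12)

    def test_en_depends_on_map_neighbourhood(self, tiny_map, cortical_model):
        stimuli = [[GratingSpec(0.0, 1.0)]]
        a = ModelNeuron((640.0, 640.0), 0.0, "narrow")
        b = ModelNeuron((420.0, 480.0), 0.0, "narrow")
        ra = simulate_population(tiny_map, [a], stimuli, "en", cortical_model)
        rb = simulate_population(tiny_map, [b], stimuli, "en", cortical_model)
        assert not np.allclose(ra.response.values, rb.response.values)


class TestDirectionalCircuitEffects:
    """The map-position-dependent effects of one uniform parameter set."""

    def test_en_iso_vs_pinwheel_differ(self, model_comparison_report):
        m = model_comparison_report["metrics"]
        assert m["iso_en"]["hwhh"] != pytest.approx(m["pin_en"]["hwhh"], rel=0.05)

    def test_dn_broadens_iso_tuning(self, model_comparison_report):
        m = model_comparison_report["metrics"]
        assert m["iso_dn"]["hwhh"] > m["iso_ff"]["hwhh"]

    def test_dn_leaves_pinwheel_tuning_near_intact(self, model_comparison_report):
        m = model_comparison_report["metrics"]
        assert m["pin_dn"]["hwhh"] <= 1.05 * m["pin_ff"]["hwhh"]

    def test_en_pin_complex_plaids_exceed_ff(self, model_comparison_report):
        m = model_comparison_report["metrics"]
        en = np.asarray(m["pin_en"]["complexity_norm"])
        ff = np.asarray(m["pin_ff"]["complexity_norm"])
        assert np.all(en[2:] > ff[2:])     # 4- and 8-grating plaids

    def test_octotropic_favours_pinwheel(self, model_comparison_report):
        m = model_comparison_report["metrics"]
        assert m["pin_en"]["octo_norm"] > m["iso_en"]["octo_norm"]


class TestExtrastriatePool:
    def test_blank_image_gives_zero_map(self, cortical_model):
        blank = np.full((96, 96), 0.5)
        out = extrastriate_pool(blank, cortical_model, "iso")
        assert np.abs(out).max() < 1e-9
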