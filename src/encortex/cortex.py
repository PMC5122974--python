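"""Intra-cortical circuit: surround excitation and normalization on a map.

Every model neuron receives the feedforward drive C computed by
:mod:`encortex.pathway` and interacts with a local cortical neighbourhood of
orientation-tuned neighbours whose preferred orientations are dictated by
the neuron's position in the orientation map.  Three output models are
available, all using one global parameter set at every cortical site:

``ff``  the feedforward response C itself (no lateral terms);
``en``  excitation-normalization: C is multiplied by the Gaussian-weighted
        sum of neighbour responses (C_E = C * sum_j w_j C_j) and then
        self-normalized by a hyperbolic function whose semi-saturation term
        is the output C_U of an un-oriented inhibitory cell with a severely
        compressed contrast response,
        C_EN = r_max * C_E / (beta1 * C_E + beta2 * C_U + beta0);
``dn``  divisive normalization by the same weighted neighbour pool,
        C_N = C / (sum_j w_j C_j + beta0).

Regional differences between iso-orientation domains and pinwheel centres
arise solely from the neighbourhood orientation composition, never from
regional parameter changes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .pathway import (BROAD_GEOMETRY, NARROW_GEOMETRY, DoGParams,
                      FeedforwardUnit, PhotoreceptorParams, PushPullGeometry,
                      SpikingParams, ThalamicMaps)
from .stimuli import (BATTERY_CONTRASTS, BATTERY_ORIENTATIONS, BATTERY_PHASES,
                      GratingSpec, LuminanceImage, PixelGrid,
                      equal_plaid_components)

__all__ = [
    "NeighborhoodWeights",
    "ENParams",
    "UnorientedCellParams",
    "ModelNeuron",
    "CircuitSite",
    "iso_site",
    "pinwheel_site",
    "neighbor_weights",
    "surround_excitation",
    "unoriented_response",
    "en_response",
    "dn_response",
    "CorticalModel",
    "simulate_population",
    "extrastriate_pool",
    "orientation_response_maps",
]

#: Cortical interaction length scale in micrometres (same sigma as the LHI).
SIGMA_CORTEX_UM = 180.0

#: Electrode-like neighbourhood: three neighbours on each side, 100 um apart.
NEIGHBOR_DISTANCES_UM = (-300.0, -200.0, -100.0, 100.0, 200.0, 300.0)


@dataclass(frozen=True)
class NeighborhoodWeights:
    """Gaussian distance weights over a cortical neighbourhood, summing to 1."""

    weights: np.ndarray
    distances: np.ndarray
    sigma: float = SIGMA_CORTEX_UM

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def neighbor_weights(distances: Sequence[float],
                     sigma: float = SIGMA_CORTEX_UM) -> NeighborhoodWeights:
    """Normalised Gaussian weights for neighbours at the given distances (um).

    The reference neuron itself is excluded (a zero distance is rejected);
    at least one neighbour must lie within 3 sigma.
    """
    d = np.abs(np.asarray(distances, float))
    if d.size == 0 or np.any(d == 0):
        raise ValueError("neighbour distances must be non-zero (self excluded)")
    if not np.any(d <= 3 * sigma):
        raise ValueError("no neighbour within 3 sigma of the reference")
    w = np.exp(-d ** 2 / (2 * sigma ** 2))
    return NeighborhoodWeights(w / w.sum(), d, sigma)


def surround_excitation(C: float | np.ndarray, neighbor_responses: Sequence[float],
                        weights: NeighborhoodWeights) -> float | np.ndarray:
    """Multiplicative surround excitation, C_E = C * sum_j w_j C_j."""
    pooled = float(np.dot(weights.weights, np.asarray(neighbor_responses, float)))
    return C * pooled


@dataclass(frozen=True)
class UnorientedCellParams:
    """Un-oriented inhibitory cell with a severely compressed response.

    The cell pools the rectified ON+OFF thalamic drive over space (an
    orientation-untuned quantity) and passes it through a hyperbolic
    function whose semi-saturation sits far below the full-contrast drive,
    so its output is nearly flat across the upper contrast range.
    """

    gain: float = 1.0
    semi_saturation: float = 0.01

    def __post_init__(self) -> None:
        if self.semi_saturation <= 0:
            raise ValueError("semi_saturation must be positive")


def unoriented_response(maps_or_drive: ThalamicMaps | float,
                        params: UnorientedCellParams) -> float:
    """C_U = gain * p / (p + s50) with p the pooled rectified thalamic drive."""
    if isinstance(maps_or_drive, ThalamicMaps):
        p = float(maps_or_drive.rectified_sum().mean())
    else:
        p = float(maps_or_drive)
    return params.gain * p / (p + params.semi_saturation)


@dataclass(frozen=True)
class ENParams:
    """Excitation-normalization parameters (global across the cortex)."""

    r_max: float = 2.0
    beta0: float = 0.01
    beta1: float = 1.0
    beta2: float = 1.0

    def __post_init__(self) -> None:
        if self.beta0 <= 0:
            raise ValueError("beta0 must be positive")


def en_response(C_E: float | np.ndarray, C_U: float | np.ndarray,
                params: ENParams | None = None) -> float | np.ndarray:
    """C_EN = r_max * C_E / (beta1 * C_E + beta2 * C_U + beta0)."""
    p = params or ENParams()
    return p.r_max * C_E / (p.beta1 * C_E + p.beta2 * C_U + p.beta0)


def dn_response(C: float | np.ndarray, neighbor_responses: Sequence[float],
                weights: NeighborhoodWeights, beta0: float = 0.01
                ) -> float | np.ndarray:
    """C_N = C / (sum_j w_j C_j + beta0)."""
    pooled = float(np.dot(weights.weights, np.asarray(neighbor_responses, float)))
    return C / (pooled + beta0)


@dataclass(frozen=True)
class ModelNeuron:
    """A neuron embedded in the cortical map."""

    position_um: tuple[float, float]
    preferred_orientation: float
    tuning_class: Literal["narrow", "broad"] = "narrow"

    @property
    def geometry(self) -> PushPullGeometry:
        return NARROW_GEOMETRY if self.tuning_class == "narrow" else BROAD_GEOMETRY


@dataclass(frozen=True)
class CircuitSite:
    """A model neuron plus the lateral neighbourhood it interacts with.

    Neighbour preferred orientations are absolute (degrees in [0, 180));
    distances are cortical micrometres from the reference neuron.
    """

    preferred_orientation: float
    tuning_class: Literal["narrow", "broad"]
    neighbor_orientations: tuple[float, ...]
    neighbor_distances_um: tuple[float, ...] = NEIGHBOR_DISTANCES_UM
    label: str = ""

    def weights(self, sigma: float = SIGMA_CORTEX_UM) -> NeighborhoodWeights:
        return neighbor_weights(self.neighbor_distances_um, sigma)


#: Orientation jitter of an iso-orientation neighbourhood (within +-10 deg).
_ISO_OFFSETS = (-9.0, -6.0, -3.0, 3.0, 6.0, 9.0)
#: Orientation offsets of a pinwheel neighbourhood (spanning 180 deg).
#: Ordered to match NEIGHBOR_DISTANCES_UM: the offset magnitude shrinks with
#: distance, so the nearest neighbours are the most dissimilar (near
#: orthogonal), as in polar-plot examples of electrode tracks crossing a
#: pinwheel centre.
_PINWHEEL_OFFSETS = (-22.5, -45.0, -90.0, 90.0, 45.0, 22.5)


def iso_site(preferred_orientation: float = 0.0,
             tuning_class: Literal["narrow", "broad"] = "narrow") -> CircuitSite:
    """Reference iso-orientation-domain site: co-tuned neighbourhood."""
    return CircuitSite(
        preferred_orientation % 180.0, tuning_class,
        tuple((preferred_orientation + o) % 180.0 for o in _ISO_OFFSETS),
        label="iso")


def pinwheel_site(preferred_orientation: float = 0.0,
                  tuning_class: Literal["narrow", "broad"] = "broad") -> CircuitSite:
    """Reference pinwheel-centre site: neighbourhood spans all orientations."""
    return CircuitSite(
        preferred_orientation % 180.0, tuning_class,
        tuple((preferred_orientation + o) % 180.0 for o in _PINWHEEL_OFFSETS),
        label="pinwheel")


def _phase_combinations(components: Sequence[GratingSpec],
                        per_component: bool) -> list[tuple[GratingSpec, ...]]:
    """Phase variants of a stimulus: either a common phase offset applied to
    all components (flashed plaid series) or the full cartesian product of
    component phases (pair-plaid battery)."""
    if per_component and len(components) <= 2:
        combos = itertools.product(BATTERY_PHASES, repeat=len(components))
        return [tuple(GratingSpec(c.orientation, c.contrast, ph, c.spatial_frequency)
                      for c, ph in zip(components, phs))
                for phs in combos]
    return [tuple(GratingSpec(c.orientation, c.contrast, c.phase + dph,
                              c.spatial_frequency) for c in components)
            for dph in BATTERY_PHASES]


class CorticalModel:
    """Calibrated model instance shared by every site of a simulation.

    The only free scale in the feedforward pathway is the spiking gain A;
    it is set once so that the phase-averaged response of a narrowly tuned
    unit to its preferred full-contrast grating equals 1.  The un-oriented
    cell's semi-saturation is set to 5 % of the pooled thalamic drive at
    full contrast (making its response nearly flat above ~10 % contrast) and
    its gain so that beta2*C_U at full contrast matches beta1*C_E of an
    iso-domain reference neuron at its preferred full-contrast grating --
    the regime in which the normalization visibly bends the iso-domain
    contrast-response curve.  All parameters are global: identical at every
    cortical site.
    """

    def __init__(self,
                 grid: PixelGrid | None = None,
                 photoreceptor_params: PhotoreceptorParams | None = None,
                 dog_params: DoGParams | None = None,
                 spiking_exponent: float = 2.0,
                 en_params: ENParams | None = None,
                 sigma_cortex: float = SIGMA_CORTEX_UM,
                 spatial_frequency: float = 0.5,
                 cu_level: float = 1.5):
        self.grid = grid or PixelGrid()
        self.photoreceptor_params = photoreceptor_params or PhotoreceptorParams()
        self.dog_params = dog_params or DoGParams()
        self.en_params = en_params or ENParams()
        self.sigma_cortex = sigma_cortex
        self.spatial_frequency = spatial_frequency
        self._units: dict[tuple[str, float], FeedforwardUnit] = {}

        # calibrate the spiking gain on the narrow reference unit
        probe = FeedforwardUnit(NARROW_GEOMETRY, 0.0, self.grid,
                                self.photoreceptor_params, self.dog_params,
                                SpikingParams(1.0, spiking_exponent))
        pref = (GratingSpec(0.0, 1.0, 0.0, spatial_frequency),)
        raw = probe.response(pref)
        self.spiking_params = SpikingParams(1.0 / raw, spiking_exponent)

        # calibrate the un-oriented cell against the iso reference circuit:
        # beta2*C_U at full contrast sits a factor cu_level above beta1*C_E,
        # deep enough that normalization bends the iso contrast-response
        # curve without drowning the excitation pool's orientation signal
        p_full = probe.unoriented_drive(pref)
        s50 = 0.05 * p_full
        c, pooled, _ = self._drives(iso_site(0.0, "narrow"), pref, False)
        c_e_full = c * pooled
        gain = (cu_level * self.en_params.beta1 * c_e_full / self.en_params.beta2
                / (p_full / (p_full + s50)))
        self.unoriented_params = UnorientedCellParams(gain=gain, semi_saturation=s50)

    # -- units -------------------------------------------------------------

    def unit(self, tuning_class: str, preferred_orientation: float) -> FeedforwardUnit:
        key = (tuning_class, round(preferred_orientation % 180.0, 6))
        if key not in self._units:
            geom = NARROW_GEOMETRY if tuning_class == "narrow" else BROAD_GEOMETRY
            self._units[key] = FeedforwardUnit(
                geom, preferred_orientation, self.grid,
                self.photoreceptor_params, self.dog_params,
                getattr(self, "spiking_params", SpikingParams()))
        return self._units[key]

    # -- per-stimulus drives ------------------------------------------------

    def _drives(self, site: CircuitSite, components: tuple[GratingSpec, ...],
                per_component_phases: bool,
                allow_clipping: bool = False) -> tuple[float, float, float]:
        """Phase-averaged (C, pooled neighbour rate, pooled thalamic drive).

        The lateral circuit couples mean rates: every response entering the
        cortical interaction is first averaged over the stimulus phase set,
        exactly like the measured response magnitudes it models.  Coupling
        raw per-phase responses instead would make the lateral terms depend
        on accidental phase alignment between differently tuned neighbours.
        """
        variants = _phase_combinations(components, per_component_phases)
        unit = self.unit(site.tuning_class, site.preferred_orientation)
        nb_units = [self.unit(site.tuning_class, o) for o in site.neighbor_orientations]
        w = site.weights(self.sigma_cortex).weights
        c = np.mean([unit.response_to_components(v, allow_clipping)
                     for v in variants])
        cj = [np.mean([nu.response_to_components(v, allow_clipping)
                       for v in variants]) for nu in nb_units]
        p = np.mean([unit.unoriented_drive(v, phases=(0.0,),
                                           allow_clipping=allow_clipping)
                     for v in variants])
        return float(c), float(np.dot(w, cj)), float(p)

    def site_response(self, site: CircuitSite,
                      components: Sequence[GratingSpec],
                      model: Literal["ff", "en", "dn"] = "en",
                      per_component_phases: bool = False,
                      allow_clipping: bool = False) -> float:
        """Phase-averaged response of a circuit site under one model."""
        if model not in ("ff", "en", "dn"):
            raise ValueError(f"unknown model {model!r}")
        comps = tuple(components)
        c, pooled, p_drive = self._drives(site, comps, per_component_phases,
                                          allow_clipping)
        if model == "ff":
            return c
        if model == "dn":
            return c / (pooled + self.en_params.beta0)
        c_u = unoriented_response(p_drive, self.unoriented_params)
        return float(en_response(c * pooled, c_u, self.en_params))

    # -- convenience curves --------------------------------------------------

    def tuning_curve(self, site: CircuitSite, model: str = "en",
                     orientations: Sequence[float] | None = None,
                     contrast: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        oris = np.asarray(orientations if orientations is not None
                          else BATTERY_ORIENTATIONS, float)
        resp = np.array([
            self.site_response(site, (GratingSpec(o, contrast, 0.0,
                                                  self.spatial_frequency),), model)
            for o in oris])
        return oris, resp

    def contrast_curve(self, site: CircuitSite, model: str = "en",
                       orientation: float | None = None,
                       contrasts: Sequence[float] = BATTERY_CONTRASTS
                       ) -> tuple[np.ndarray, np.ndarray]:
        ori = site.preferred_orientation if orientation is None else orientation
        cons = np.asarray(contrasts, float)
        resp = np.array([
            self.site_response(site, (GratingSpec(ori, c, 0.0,
                                                  self.spatial_frequency),), model)
            for c in cons])
        return cons, resp

    def complexity_curve(self, site: CircuitSite, model: str = "en",
                         counts: Sequence[int] = (1, 2, 4, 8)) -> np.ndarray:
        """Responses to plaids of n equally spaced orientations (total
        contrast 1.0, preferred component included)."""
        return np.array([
            self.site_response(
                site, equal_plaid_components(
                    n, 1.0, site.preferred_orientation, 0.0, self.spatial_frequency),
                model)
            for n in counts])

    def pair_plaid_responses(self, site: CircuitSite, model: str = "en",
                             pref_orientation: float | None = None) -> np.ndarray:
        """Responses to the 8 plaids pairing the preferred battery
        orientation with each battery orientation (0.5 + 0.5 contrast,
        averaged over the 16 phase combinations)."""
        p = (site.preferred_orientation if pref_orientation is None
             else pref_orientation)
        out = []
        for o2 in BATTERY_ORIENTATIONS:
            comps = (GratingSpec(p, 0.5, 0.0, self.spatial_frequency),
                     GratingSpec(o2, 0.5, 0.0, self.spatial_frequency))
            out.append(self.site_response(site, comps, model,
                                          per_component_phases=True))
        return np.array(out)

    def octotropic_response(self, site: CircuitSite, model: str = "en") -> float:
        comps = equal_plaid_components(8, 1.0, 0.0, 0.0, self.spatial_frequency)
        return self.site_response(site, comps, model)


# ---------------------------------------------------------------------------
# population simulation (generic, position-based)
# ---------------------------------------------------------------------------

def simulate_population(omap, neurons: Sequence[ModelNeuron],
                        stimuli: Sequence[Sequence[GratingSpec]],
                        model: Literal["ff", "en", "dn"] = "en",
                        cortical_model: CorticalModel | None = None,
                        track_angle_deg: float = 0.0) -> pd.DataFrame:
    """Run every neuron through every stimulus under one model.

    ``omap`` is an :class:`encortex.mapsynth.OrientationMap` supplying each
    neuron's lateral neighbourhood (six sites at 100-300 um along a track of
    direction ``track_angle_deg`` through the neuron's position); it is
    ignored by the lateral-free ``ff`` model.  One :class:`CorticalModel`
    (a single global parameter set) serves every neuron.

    Returns a table with columns (neuron_id, site_class, stimulus_id, model,
    response).
    """
    if model not in ("ff", "en", "dn"):
        raise ValueError(f"unknown model {model!r}")
    cm = cortical_model or CorticalModel()
    rows = []
    for nid, neuron in enumerate(neurons):
        if model == "ff":
            site = CircuitSite(neuron.preferred_orientation, neuron.tuning_class,
                               (neuron.preferred_orientation,) * 6, label="ff")
        else:
            nb_ori = omap.track_orientations(neuron.position_um, track_angle_deg,
                                             NEIGHBOR_DISTANCES_UM)
            site = CircuitSite(neuron.preferred_orientation, neuron.tuning_class,
                               tuple(nb_ori))
        for sid, comps in enumerate(stimuli):
            r = cm.site_response(site, comps, model)
            rows.append((nid, site.label or neuron.tuning_class, sid, model, r))
    return pd.DataFrame(rows, columns=["neuron_id", "site_class", "stimulus_id",
                                       "model", "response"])


# ---------------------------------------------------------------------------
# extra-striate pooling over image positions
# ---------------------------------------------------------------------------

def _column_kernel(geom: PushPullGeometry, grid: PixelGrid, x_offset: float
                   ) -> np.ndarray:
    """Sparse kernel placing the subunit column relative to the RF centre."""
    dpp = grid.degrees_per_pixel
    ys = (np.arange(geom.n_subunits) - (geom.n_subunits - 1) / 2) * geom.rf_spacing
    ry = int(np.ceil(np.max(np.abs(ys)) / dpp)) if geom.n_subunits > 1 else 0
    rx = int(np.ceil(abs(x_offset) / dpp)) + 1
    k = np.zeros((2 * ry + 3, 2 * rx + 3))
    cy, cx = ry + 1, rx + 1
    for y in ys:
        fy, fx = y / dpp + cy, x_offset / dpp + cx
        iy, ix = int(np.floor(fy)), int(np.floor(fx))
        dy, dx = fy - iy, fx - ix
        k[iy, ix] += (1 - dy) * (1 - dx)
        k[iy + 1, ix] += dy * (1 - dx)
        k[iy, ix + 1] += (1 - dy) * dx
        k[iy + 1, ix + 1] += dy * dx
    return k


def orientation_response_maps(image: LuminanceImage | np.ndarray,
                              cm: CorticalModel,
                              tuning_class: str = "narrow",
                              n_orientations: int = 8
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Feedforward response maps C(theta; x, y) for receptive fields centred
    at every image position, for ``n_orientations`` equally spaced
    orientation preferences.

    Returns ``(stack, pooled_drive)``: stack has shape (n_orientations, H,
    W); pooled_drive is the rectified thalamic drive map feeding the
    un-oriented cell.
    """
    arr = image.values if isinstance(image, LuminanceImage) else np.asarray(image, float)
    grid = cm.grid if arr.shape == (cm.grid.height, cm.grid.width) else PixelGrid(
        arr.shape[1], arr.shape[0], cm.grid.degrees_per_pixel)
    unit = FeedforwardUnit(
        NARROW_GEOMETRY if tuning_class == "narrow" else BROAD_GEOMETRY,
        0.0, grid, cm.photoreceptor_params, cm.dog_params, cm.spiking_params)
    geom = unit.geometry
    k_on = _column_kernel(geom, grid, -geom.column_offset / 2)[::-1, ::-1]
    k_off = _column_kernel(geom, grid, geom.column_offset / 2)[::-1, ::-1]
    angles = np.arange(n_orientations) * 180.0 / n_orientations
    stack = np.empty((n_orientations, arr.shape[0], arr.shape[1]))
    drive = np.zeros(arr.shape)
    for i, th in enumerate(angles):
        rot = arr if th == 0 else np.clip(
            ndimage.rotate(arr, -th, reshape=False, order=1, mode="nearest"), 0, 1)
        maps = unit.thalamic_maps(rot)
        t_map = (signal.fftconvolve(np.maximum(maps.t_on, 0), k_on, "same")
                 + signal.fftconvolve(np.maximum(maps.t_off, 0), k_off, "same"))
        c_map = cm.spiking_params.gain * np.maximum(t_map, 0) ** cm.spiking_params.exponent
        rs = maps.rectified_sum()
        if th != 0:
            c_map = np.maximum(ndimage.rotate(c_map, th, reshape=False, order=1,
                                              mode="nearest"), 0)
            rs = np.maximum(ndimage.rotate(rs, th, reshape=False, order=1,
                                           mode="nearest"), 0)
        stack[i] = c_map
        drive += rs / n_orientations
    return stack, drive


def extrastriate_pool(image: LuminanceImage | np.ndarray,
                      cm: CorticalModel,
                      pool: Literal["iso", "pinwheel"] = "iso",
                      tuning_class: str = "narrow",
                      sigma_pool_deg: float = 0.8,
                      stack_drive: tuple[np.ndarray, np.ndarray] | None = None
                      ) -> np.ndarray:
    """Heat map of a simulated extra-striate cell pooling eight model
    neurons with equally spaced orientation preferences.

    In an iso-orientation domain each pooled neuron's cortical
    neighbourhood shares its own preference, so its lateral pool is the
    same-orientation response in a small spatial surround; at a pinwheel
    centre the neighbourhood spans all orientations, so the lateral pool is
    the orientation-averaged response in that surround.  Both pools pass
    through the identical excitation-normalization stage and the eight
    normalized responses are summed at every image position.
    """
    if pool not in ("iso", "pinwheel"):
        raise ValueError(f"unknown pool {pool!r}")
    stack, drive = (stack_drive if stack_drive is not None
                    else orientation_response_maps(image, cm, tuning_class))
    sig_px = sigma_pool_deg / cm.grid.degrees_per_pixel

    def blur(a: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(a, sig_px, mode="nearest")

    p_map = blur(drive)
    up = cm.unoriented_params
    c_u_map = up.gain * p_map / (p_map + up.semi_saturation)
    mean_map = blur(stack.mean(axis=0))
    out = np.zeros_like(drive)
    for i in range(stack.shape[0]):
        lateral = blur(stack[i]) if pool == "iso" else mean_map
        c_e = stack[i] * lateral
        out += en_response(c_e, c_u_map, cm.en_params)
    return out
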