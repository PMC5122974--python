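"""Feedforward visual pathway: photoreceptor, thalamus, push-pull cortex.

The stimulus image is compressed pointwise by a saturating photoreceptor
nonlinearity, convolved with balanced ON/OFF difference-of-Gaussians (DoG)
thalamic receptive fields, summed along a pair of push-pull subunit columns
(ON inputs along one vertical column, OFF inputs along a displaced column,
each half-wave rectified) and finally passed through an expansive power-law
spiking nonlinearity.  The pathway unit as built prefers gratings of
orientation 0 (modulation along x); responses at other preferred
orientations are obtained by rotating the stimulus, not the receptive field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, signal

from .stimuli import GratingSpec, LuminanceImage, PixelGrid, make_plaid

__all__ = [
    "PhotoreceptorParams",
    "DoGParams",
    "ThalamicMaps",
    "PushPullGeometry",
    "SpikingParams",
    "photoreceptor",
    "dog_kernel",
    "thalamic_response",
    "pushpull_input",
    "spiking",
    "FeedforwardUnit",
    "NARROW_GEOMETRY",
    "BROAD_GEOMETRY",
]


@dataclass(frozen=True)
class PhotoreceptorParams:
    """Pointwise saturating (Naka-Rushton) luminance compression.

    ``L50`` is the semi-saturation luminance on the same [0, 1] scale as the
    stimulus.  The default is a steep sigmoid centred on the mid-grey
    operating point (exponent 10), i.e. a high incremental gain in a narrow
    band around the adapted luminance: both the brightening and the
    darkening excursions of a grating are then compressed already at modest
    contrasts, which is what transmits an early-saturating contrast response
    (and with it cross-orientation suppression) to the thalamus.  A purely
    hyperbolic unit (exponent 1) is steepest at zero luminance, so the dark
    stripes of a grating would be expanded rather than compressed and the
    feedforward suppression would reverse into facilitation.
    """

    L50: float = 0.5
    exponent: float = 10.0

    def __post_init__(self) -> None:
        if self.L50 <= 0:
            raise ValueError("L50 must be positive")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")


def photoreceptor(image: LuminanceImage | np.ndarray,
                  params: PhotoreceptorParams | None = None) -> np.ndarray:
    """P = S^e / (S^e + L50^e), applied pixelwise."""
    params = params or PhotoreceptorParams()
    s = image.values if isinstance(image, LuminanceImage) else np.asarray(image, float)
    if s.min() < 0:
        raise ValueError("luminance must be non-negative")
    se = s ** params.exponent
    return se / (se + params.L50 ** params.exponent)


@dataclass(frozen=True)
class DoGParams:
    """Difference-of-Gaussians thalamic receptive field.

    The centre s.d. is fixed at one third of the surround s.d.  Both
    Gaussians are normalised to unit volume so that the kernel integrates to
    zero and a uniform field evokes exactly no response.
    """

    sigma_surround: float = 0.9
    polarity: str = "on"

    def __post_init__(self) -> None:
        if self.sigma_surround <= 0:
            raise ValueError("sigma_surround must be positive")
        if self.polarity not in ("on", "off"):
            raise ValueError("polarity must be 'on' or 'off'")

    @property
    def sigma_center(self) -> float:
        return self.sigma_surround / 3.0


def dog_kernel(params: DoGParams, grid: PixelGrid) -> np.ndarray:
    """Discrete DoG kernel on the grid's pixel pitch; sums to zero."""
    dpp = grid.degrees_per_pixel
    if params.sigma_center / dpp < 3.0 - 1e-9:
        raise ValueError(
            f"DoG centre sigma {params.sigma_center} deg is under-resolved at "
            f"{dpp} deg/px (need >= 3 px per sigma)")
    r = int(np.ceil(3 * params.sigma_surround / dpp))
    ax = np.arange(-r, r + 1) * dpp
    xx, yy = np.meshgrid(ax, ax)
    rho2 = xx ** 2 + yy ** 2

    def unit_gauss(sig: float) -> np.ndarray:
        g = np.exp(-rho2 / (2 * sig ** 2))
        return g / g.sum()

    kernel = unit_gauss(params.sigma_center) - unit_gauss(params.sigma_surround)
    return kernel if params.polarity == "on" else -kernel


@dataclass(frozen=True)
class ThalamicMaps:
    """ON- and OFF-channel thalamic response fields on the stimulus grid."""

    t_on: np.ndarray
    t_off: np.ndarray
    grid: PixelGrid

    def rectified_sum(self) -> np.ndarray:
        return np.maximum(self.t_on, 0.0) + np.maximum(self.t_off, 0.0)


def _convolve_reflect(field_arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size convolution with reflective boundary handling."""
    r = kernel.shape[0] // 2
    padded = np.pad(field_arr, r, mode="reflect")
    return signal.fftconvolve(padded, kernel, mode="valid")


def thalamic_response(p_field: np.ndarray, params: DoGParams,
                      grid: PixelGrid) -> ThalamicMaps:
    """Convolve the photoreceptor output with ON and OFF DoG fields.

    No rectification is applied here; the push-pull stage rectifies each
    sampled subunit input.
    """
    if not np.all(np.isfinite(p_field)):
        raise ValueError("photoreceptor field contains non-finite values")
    on = dog_kernel(DoGParams(params.sigma_surround, "on"), grid)
    t_on = _convolve_reflect(p_field, on)
    return ThalamicMaps(t_on=t_on, t_off=-t_on, grid=grid)


@dataclass(frozen=True)
class PushPullGeometry:
    """Arrangement of thalamic subunits feeding one cortical simple cell.

    ``n_subunits`` ON-centre inputs are sampled along a vertical column at
    ``x1 = -column_offset/2`` and the same number of OFF-centre inputs along
    a column at ``x2 = +column_offset/2``; the offset defaults to half a
    period of the default 0.5 cyc/deg grating, making the two columns
    phase-opponent.  Longer columns (more subunits) give narrower orientation
    tuning.
    """

    n_subunits: int = 8
    rf_spacing: float = 0.3
    column_offset: float = 1.0
    pull_gain: float = 0.8

    def __post_init__(self) -> None:
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")
        if self.column_offset <= 0:
            raise ValueError("column_offset must be positive")
        if not 0.0 <= self.pull_gain <= 1.0:
            raise ValueError("pull_gain must be in [0, 1]")

    @property
    def column_length(self) -> float:
        return (self.n_subunits - 1) * self.rf_spacing

    def subunit_points(self, rf_center: tuple[float, float] = (0.0, 0.0)
                       ) -> tuple[np.ndarray, np.ndarray]:
        """(ON points, OFF points) as arrays of (x, y) in degrees."""
        cx, cy = rf_center
        ys = cy + (np.arange(self.n_subunits) - (self.n_subunits - 1) / 2) * self.rf_spacing
        on = np.column_stack([np.full_like(ys, cx - self.column_offset / 2), ys])
        off = np.column_stack([np.full_like(ys, cx + self.column_offset / 2), ys])
        return on, off


#: Narrowly tuned unit: 8 subunits give an elongated receptive field.
NARROW_GEOMETRY = PushPullGeometry(n_subunits=8)
#: Broadly tuned unit: 2 subunits give a short receptive field.
BROAD_GEOMETRY = PushPullGeometry(n_subunits=2)


def _sample(field_arr: np.ndarray, points_deg: np.ndarray, grid: PixelGrid) -> np.ndarray:
    """Bilinear samples of a grid field at (x, y) positions in degrees."""
    dpp = grid.degrees_per_pixel
    cols = points_deg[:, 0] / dpp + (grid.width - 1) / 2
    rows = points_deg[:, 1] / dpp + (grid.height - 1) / 2
    if (cols.min() < 0 or rows.min() < 0 or cols.max() > grid.width - 1
            or rows.max() > grid.height - 1):
        raise ValueError("push-pull column extends outside the stimulus grid")
    return ndimage.map_coordinates(field_arr, np.vstack([rows, cols]), order=1)


def pushpull_input(maps: ThalamicMaps, geom: PushPullGeometry,
                   rf_center: tuple[float, float] = (0.0, 0.0)) -> float:
    """Push-pull combination of rectified thalamic inputs over two columns.

    In each subregion the rectified input of one polarity excites and the
    rectified input of the opposite polarity inhibits (the pull): the ON
    column contributes ``[t_on]+ - pull_gain * [t_off]+`` at each subunit
    and the OFF column ``[t_off]+ - pull_gain * [t_on]+``.  With a perfect
    pull (gain 1) each antagonistic pair recombines into the signed thalamic
    drive and the receptive field ignores patterns that only modulate along
    the columns (e.g. orthogonal gratings).  The default pull gain of 0.8
    leaves a small excess of excitation, so non-preferred patterns
    contribute a weak rectified drive -- which is what lets plaid components
    of similar low contrast sum rather than suppress.  The total may be
    negative; the spiking stage rectifies it.
    """
    on_pts, off_pts = geom.subunit_points(rf_center)
    g = geom.pull_gain
    on_col_on = _sample(maps.t_on, on_pts, maps.grid)
    on_col_off = _sample(maps.t_off, on_pts, maps.grid)
    off_col_on = _sample(maps.t_on, off_pts, maps.grid)
    off_col_off = _sample(maps.t_off, off_pts, maps.grid)
    push = np.maximum(on_col_on, 0) - g * np.maximum(on_col_off, 0)
    pull = np.maximum(off_col_off, 0) - g * np.maximum(off_col_on, 0)
    return float(push.sum() + pull.sum())


@dataclass(frozen=True)
class SpikingParams:
    """Expansive power-law spiking nonlinearity, C = A * max(T, 0)^m."""

    gain: float = 1.0
    exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")


def spiking(t_tot: float | np.ndarray, params: SpikingParams | None = None
            ) -> float | np.ndarray:
    params = params or SpikingParams()
    return params.gain * np.maximum(t_tot, 0.0) ** params.exponent


class FeedforwardUnit:
    """A model simple cell: photoreceptor -> DoG -> push-pull -> spiking.

    The unit's preferred orientation is implemented by rotating the stimulus
    into the unit's frame (component specifications are rotated analytically;
    raw images are rotated by resampling) rather than by rotating the
    receptive field.
    """

    def __init__(self,
                 geometry: PushPullGeometry = NARROW_GEOMETRY,
                 preferred_orientation: float = 0.0,
                 grid: PixelGrid | None = None,
                 photoreceptor_params: PhotoreceptorParams | None = None,
                 dog_params: DoGParams | None = None,
                 spiking_params: SpikingParams | None = None):
        self.grid = grid or PixelGrid()
        self.geometry = geometry
        self.preferred_orientation = float(preferred_orientation) % 180.0
        self.photoreceptor_params = photoreceptor_params or PhotoreceptorParams()
        self.dog_params = dog_params or DoGParams()
        self.spiking_params = spiking_params or SpikingParams()
        self._kernel = dog_kernel(
            DoGParams(self.dog_params.sigma_surround, "on"), self.grid)

    # -- raw pipeline ------------------------------------------------------

    def thalamic_maps(self, image: LuminanceImage | np.ndarray) -> ThalamicMaps:
        p = photoreceptor(image, self.photoreceptor_params)
        t_on = _convolve_reflect(p, self._kernel)
        return ThalamicMaps(t_on=t_on, t_off=-t_on, grid=self.grid)

    def t_tot(self, image: LuminanceImage | np.ndarray) -> float:
        return pushpull_input(self.thalamic_maps(image), self.geometry)

    # -- stimulus-level responses -----------------------------------------

    def response_to_components(self, components: Sequence[GratingSpec],
                               allow_clipping: bool = False) -> float:
        """Spiking response to a plaid given by component specs."""
        rotated = [c.rotated(self.preferred_orientation) for c in components]
        image = make_plaid(rotated, self.grid, allow_clipping=allow_clipping)
        return float(spiking(self.t_tot(image), self.spiking_params))

    def response(self, components: Sequence[GratingSpec],
                 phases: Iterable[float] | None = None,
                 allow_clipping: bool = False) -> float:
        """Phase-averaged response: every component is flashed at each phase
        offset in ``phases`` (added to the component's own phase) and the
        spiking responses are averaged, mirroring the flashed-stimulus
        protocol."""
        from .stimuli import BATTERY_PHASES
        phases = BATTERY_PHASES if phases is None else tuple(phases)
        vals = []
        for dph in phases:
            shifted = [GratingSpec(c.orientation, c.contrast, c.phase + dph,
                                   c.spatial_frequency) for c in components]
            vals.append(self.response_to_components(shifted, allow_clipping))
        return float(np.mean(vals))

    def response_to_image(self, image: LuminanceImage | np.ndarray) -> float:
        """Response to an arbitrary image (rotated into the unit's frame)."""
        arr = image.values if isinstance(image, LuminanceImage) else np.asarray(image, float)
        if self.preferred_orientation != 0.0:
            arr = ndimage.rotate(arr, -self.preferred_orientation, reshape=False,
                                 order=1, mode="nearest")
            arr = np.clip(arr, 0.0, 1.0)
        return float(spiking(self.t_tot(arr), self.spiking_params))

    @property
    def _pool_mask(self) -> np.ndarray:
        """Centred isotropic Gaussian pooling window (weights sum to 1);
        the taper keeps the pooled drive orientation-blind on a square
        grid, where a hard-edged window would pick up partial grating
        periods differently at different orientations."""
        if not hasattr(self, "_pool_mask_cache"):
            x, y = self.grid.coords()
            sigma = 0.25 * min(self.grid.extent_deg)
            w = np.exp(-(x ** 2 + y ** 2) / (2 * sigma ** 2))
            self._pool_mask_cache = w / w.sum()
        return self._pool_mask_cache

    def unoriented_drive(self, components: Sequence[GratingSpec],
                         phases: Iterable[float] | None = None,
                         allow_clipping: bool = False) -> float:
        """Mean rectified thalamic drive over a circular pool, phase
        averaged.

        This is the drive pooled by un-oriented inhibitory cells; it does not
        depend on the unit's preferred orientation or geometry.
        """
        from .stimuli import BATTERY_PHASES
        phases = BATTERY_PHASES if phases is None else tuple(phases)
        vals = []
        for dph in phases:
            shifted = [GratingSpec(c.orientation, c.contrast, c.phase + dph,
                                   c.spatial_frequency) for c in components]
            image = make_plaid(shifted, self.grid, allow_clipping=allow_clipping)
            rs = self.thalamic_maps(image).rectified_sum()
            vals.append(float((rs * self._pool_mask).sum()))
        return float(np.mean(vals))
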