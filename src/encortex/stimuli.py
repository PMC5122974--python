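"""Sinusoidal grating and plaid stimuli.

All stimuli are static luminance images on a square pixel grid calibrated in
visual degrees.  A grating is parameterised by orientation (degrees, with the
convention that orientation 0 modulates luminance along the x axis), Michelson
contrast, spatial phase and spatial frequency.  Plaids are sums of gratings
around the mid-grey level; the *total contrast* of a plaid is defined as the
sum of its component contrasts, so that luminance stays inside [0, 1].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GratingSpec",
    "PixelGrid",
    "LuminanceImage",
    "StimulusSet",
    "make_grating",
    "make_plaid",
    "make_battery",
    "BATTERY_ORIENTATIONS",
    "BATTERY_PHASES",
    "BATTERY_CONTRASTS",
]

#: The eight stimulus orientations of the standard battery (degrees).
BATTERY_ORIENTATIONS = tuple(np.arange(8) * 22.5)

#: The four spatial phases at which each stimulus is flashed (radians).
BATTERY_PHASES = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)

#: The seven Michelson contrasts of the contrast series.
BATTERY_CONTRASTS = (1 / 64, 1 / 32, 1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0)


@dataclass(frozen=True)
class GratingSpec:
    """One sinusoidal grating component.

    Parameters
    ----------
    orientation : float
        Orientation in degrees; reduced modulo 180.  Orientation 0 modulates
        along x (vertical stripes), orientation 90 along y.
    contrast : float
        Michelson contrast in [0, 1].
    phase : float
        Spatial phase in radians, reduced modulo 2*pi.
    spatial_frequency : float
        Cycles per degree.
    """

    orientation: float
    contrast: float
    phase: float = 0.0
    spatial_frequency: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError(f"contrast must be in [0, 1], got {self.contrast}")
        if self.spatial_frequency <= 0:
            raise ValueError("spatial_frequency must be positive")
        object.__setattr__(self, "orientation", float(self.orientation) % 180.0)
        object.__setattr__(self, "phase", float(self.phase) % (2 * np.pi))

    def rotated(self, angle: float) -> "GratingSpec":
        """The same grating seen in a frame rotated by ``angle`` degrees."""
        return replace(self, orientation=(self.orientation - angle) % 180.0)


@dataclass(frozen=True)
class PixelGrid:
    """Square pixel raster calibrated in visual degrees."""

    width: int = 64
    height: int = 64
    degrees_per_pixel: float = 0.1

    def __post_init__(self) -> None:
        if self.degrees_per_pixel <= 0:
            raise ValueError("degrees_per_pixel must be positive")
        if self.width < 2 or self.height < 2:
            raise ValueError("degenerate grid")

    @property
    def extent_deg(self) -> tuple[float, float]:
        return (self.width * self.degrees_per_pixel,
                self.height * self.degrees_per_pixel)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) meshgrids in degrees, origin at the grid centre."""
        x = (np.arange(self.width) - (self.width - 1) / 2) * self.degrees_per_pixel
        y = (np.arange(self.height) - (self.height - 1) / 2) * self.degrees_per_pixel
        return np.meshgrid(x, y)

    def check_resolvable(self, spatial_frequency: float) -> None:
        """Reject spatial frequencies that alias or do not fit the grid."""
        period_px = 1.0 / (spatial_frequency * self.degrees_per_pixel)
        if period_px < 4.0:
            raise ValueError(
                f"spatial frequency {spatial_frequency} cyc/deg gives a period of "
                f"{period_px:.2f} px (< 4 px) and would alias on this grid")
        if min(self.width, self.height) * self.degrees_per_pixel * spatial_frequency < 2.0:
            raise ValueError("grid holds fewer than 2 cycles of the grating")


@dataclass(frozen=True)
class LuminanceImage:
    """Pixel grid of luminance values in [0, 1]."""

    values: np.ndarray
    grid: PixelGrid

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.height, self.grid.width):
            raise ValueError("image shape does not match grid")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("luminance values outside [0, 1]")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))


@dataclass
class StimulusSet:
    """Ordered collection of stimuli plus their component specifications."""

    images: list[LuminanceImage]
    metadata: list[tuple[GratingSpec, ...]]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.metadata):
            raise ValueError("metadata length must equal image count")
        if not self.labels:
            self.labels = [f"stim_{i:04d}" for i in range(len(self.images))]

    def __len__(self) -> int:
        return len(self.images)


def _component_field(spec: GratingSpec, grid: PixelGrid) -> np.ndarray:
    x, y = grid.coords()
    th = np.deg2rad(spec.orientation)
    arg = 2 * np.pi * spec.spatial_frequency * (x * np.cos(th) + y * np.sin(th))
    return 0.5 * spec.contrast * np.sin(arg + spec.phase)


def make_grating(spec: GratingSpec, grid: PixelGrid | None = None) -> LuminanceImage:
    """Render a single sinusoidal grating around mid-grey."""
    grid = grid or PixelGrid()
    grid.check_resolvable(spec.spatial_frequency)
    return LuminanceImage(0.5 + _component_field(spec, grid), grid)


def make_plaid(components: list[GratingSpec] | tuple[GratingSpec, ...],
               grid: PixelGrid | None = None,
               allow_clipping: bool = False) -> LuminanceImage:
    """Superimpose grating components around mid-grey.

    The sum of component contrasts (the plaid's total contrast) must not
    exceed 1, which keeps every pixel inside [0, 1] analytically.  Passing
    ``allow_clipping=True`` permits over-range superpositions (e.g. a 25 %
    mask plus a 100 % test grating) whose luminance is clipped to [0, 1],
    as a display would.
    """
    grid = grid or PixelGrid()
    components = list(components)
    if not components:
        raise ValueError("plaid needs at least one component")
    total = sum(c.contrast for c in components)
    if total > 1.0 + 1e-9 and not allow_clipping:
        raise ValueError(f"total contrast {total:.3f} exceeds 1 and would clip")
    for c in components:
        grid.check_resolvable(c.spatial_frequency)
    values = 0.5 + sum(_component_field(c, grid) for c in components)
    return LuminanceImage(np.clip(values, 0.0, 1.0), grid)


def equal_plaid_components(n: int, total_contrast: float = 1.0,
                           base_orientation: float = 0.0, phase: float = 0.0,
                           spatial_frequency: float = 0.5) -> tuple[GratingSpec, ...]:
    """``n`` gratings equally spaced over [0, 180) at total contrast ``total``.

    The component at ``base_orientation`` is always included, so the series
    1, 2, 4, 8 components always contains the base (preferred) grating while
    its contrast drops as 1/n.  Component phases are staggered uniformly
    around the phase circle (``phase + 2*pi*k/n``): components equally
    spaced in orientation are also equally spaced in phase, which avoids the
    accidental coherent superposition of all components at one point that a
    common phase would produce.
    """
    step = 180.0 / n
    return tuple(
        GratingSpec(orientation=base_orientation + k * step,
                    contrast=total_contrast / n,
                    phase=phase + 2 * np.pi * k / n,
                    spatial_frequency=spatial_frequency)
        for k in range(n))


def make_battery(name: str, grid: PixelGrid | None = None,
                 spatial_frequency: float = 0.5) -> StimulusSet:
    """Build one of the named stimulus batteries.

    ``grating_battery``
        8 orientations x 4 phases x 7 contrasts = 224 single gratings.
    ``pair_plaid_battery``
        all unordered orientation pairs (including equal pairs) of 50 %
        contrast gratings, at all 4 x 4 phase combinations.
    ``complexity_series``
        plaids of 1, 2, 4 and 8 equally spaced orientations at total
        contrast 1.0, flashed at the 4 phases.
    ``octotropic``
        8 gratings equally spaced in orientation summed at total contrast
        1.0, flashed at the 4 phases.
    """
    grid = grid or PixelGrid()
    sf = spatial_frequency
    images: list[LuminanceImage] = []
    meta: list[tuple[GratingSpec, ...]] = []
    labels: list[str] = []

    if name == "grating_battery":
        for ori in BATTERY_ORIENTATIONS:
            for con in BATTERY_CONTRASTS:
                for ph in BATTERY_PHASES:
                    spec = GratingSpec(ori, con, ph, sf)
                    images.append(make_grating(spec, grid))
                    meta.append((spec,))
                    labels.append(f"grating_o{ori:g}_c{con:g}_p{ph:.2f}")
    elif name == "pair_plaid_battery":
        pairs = itertools.combinations_with_replacement(BATTERY_ORIENTATIONS, 2)
        for o1, o2 in pairs:
            for p1 in BATTERY_PHASES:
                for p2 in BATTERY_PHASES:
                    comps = (GratingSpec(o1, 0.5, p1, sf),
                             GratingSpec(o2, 0.5, p2, sf))
                    images.append(make_plaid(comps, grid))
                    meta.append(comps)
                    labels.append(f"plaid_o{o1:g}+{o2:g}_p{p1:.2f}+{p2:.2f}")
    elif name == "complexity_series":
        for n in (1, 2, 4, 8):
            for ph in BATTERY_PHASES:
                comps = equal_plaid_components(n, 1.0, 0.0, ph, sf)
                images.append(make_plaid(comps, grid))
                meta.append(comps)
                labels.append(f"complexity_n{n}_p{ph:.2f}")
    elif name == "octotropic":
        for ph in BATTERY_PHASES:
            comps = equal_plaid_components(8, 1.0, 0.0, ph, sf)
            images.append(make_plaid(comps, grid))
            meta.append(comps)
            labels.append(f"octotropic_p{ph:.2f}")
    else:
        raise ValueError(f"unknown battery {name!r}")

    return StimulusSet(images, meta, labels)
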