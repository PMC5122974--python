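"""Synthetic orientation-preference maps, electrode tracks and recordings.

The map generator band-pass filters complex Gaussian noise around a single
spatial frequency (the inverse map wavelength); half the argument of the
filtered field is an orientation preference in [0, 180).  Such fields
reproduce the characteristic layout of optical-imaging maps: smooth
iso-orientation domains of roughly one wavelength, interleaved with
phase singularities (pinwheel centres) where the orientation cycles through
180 degrees around a point.

Electrode tracks sample the map along straight lines at 100 um spacing,
matching a 32-channel linear probe inserted tangentially.  Synthetic
recordings draw Poisson spike counts around Naka-Rushton x Von Mises mean
responses, the statistical structure the analysis battery assumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stimuli import BATTERY_CONTRASTS, BATTERY_ORIENTATIONS

__all__ = [
    "OrientationMap",
    "Track",
    "SiteTruth",
    "SyntheticRecording",
    "generate_map",
    "sample_track",
    "synth_recording",
    "site_snr",
    "site_filter",
    "lhi_computable_sites",
]


@dataclass(frozen=True)
class OrientationMap:
    """Field of preferred orientations on a micrometre-calibrated grid."""

    orientations: np.ndarray  # degrees in [0, 180), shape (H, W)
    pixel_pitch_um: float
    wavelength_um: float
    seed: int | None = None

    def __post_init__(self) -> None:
        o = np.asarray(self.orientations, float)
        if o.ndim != 2 or min(o.shape) < 4:
            raise ValueError("degenerate map shape")
        if o.min() < 0 or o.max() >= 180.0:
            raise ValueError("orientations must lie in [0, 180)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.orientations.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        h, w = self.shape
        return (w * self.pixel_pitch_um, h * self.pixel_pitch_um)

    def doubled_field(self) -> np.ndarray:
        """Complex unit field exp(2i * orientation)."""
        return np.exp(2j * np.deg2rad(self.orientations))

    def orientation_at(self, positions_um: np.ndarray) -> np.ndarray:
        """Orientations at continuous (x, y) positions, in degrees.

        Interpolation happens on the doubled-angle complex field (bilinear
        on real and imaginary parts, then half the argument), which respects
        the circular topology: sites straddling 179 and 1 degrees
        interpolate near 0, never near 90.
        """
        pos = np.atleast_2d(np.asarray(positions_um, float))
        cols = pos[:, 0] / self.pixel_pitch_um
        rows = pos[:, 1] / self.pixel_pitch_um
        h, w = self.shape
        if (cols.min() < 0 or rows.min() < 0
                or cols.max() > w - 1 or rows.max() > h - 1):
            raise ValueError("position outside the map")
        c0 = np.clip(np.floor(cols).astype(int), 0, w - 2)
        r0 = np.clip(np.floor(rows).astype(int), 0, h - 2)
        fc, fr = cols - c0, rows - r0
        z = self.doubled_field()
        zi = (z[r0, c0] * (1 - fr) * (1 - fc) + z[r0 + 1, c0] * fr * (1 - fc)
              + z[r0, c0 + 1] * (1 - fr) * fc + z[r0 + 1, c0 + 1] * fr * fc)
        return np.rad2deg(np.angle(zi)) / 2.0 % 180.0

    def track_orientations(self, center_um: tuple[float, float],
                           angle_deg: float,
                           distances_um: Sequence[float]) -> np.ndarray:
        """Orientations at signed distances along a line through a point."""
        cx, cy = center_um
        th = np.deg2rad(angle_deg)
        d = np.asarray(distances_um, float)
        pts = np.column_stack([cx + d * np.cos(th), cy + d * np.sin(th)])
        return self.orientation_at(pts)

    def pinwheel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Phase singularities located by the winding number of the doubled
        angle around each pixel plaquette.

        Returns (positions_um with shape (n, 2), charges of +-1/2).
        """
        phi = 2 * np.deg2rad(self.orientations)
        d1 = _wrap(phi[:-1, 1:] - phi[:-1, :-1])
        d2 = _wrap(phi[1:, 1:] - phi[:-1, 1:])
        d3 = _wrap(phi[1:, :-1] - phi[1:, 1:])
        d4 = _wrap(phi[:-1, :-1] - phi[1:, :-1])
        winding = (d1 + d2 + d3 + d4) / (2 * np.pi)
        rows, cols = np.nonzero(np.abs(winding) > 0.5)
        pos = np.column_stack([(cols + 0.5) * self.pixel_pitch_um,
                               (rows + 0.5) * self.pixel_pitch_um])
        return pos, winding[rows, cols] / 2.0


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def generate_map(shape: tuple[int, int] = (512, 512),
                 wavelength_um: float = 1000.0,
                 pixel_pitch_um: float = 20.0,
                 seed: int | None = 0,
                 bandwidth_frac: float = 0.25) -> OrientationMap:
    """Band-pass filtered complex Gaussian noise orientation map.

    The annular Gaussian filter is centred on spatial frequency
    1/wavelength with s.d. ``bandwidth_frac`` times that frequency.
    """
    h, w = shape
    if h < 8 or w < 8:
        raise ValueError("degenerate map shape")
    if wavelength_um < 4 * pixel_pitch_um:
        raise ValueError("wavelength must be at least 4 pixels")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h, d=pixel_pitch_um)
    fx = np.fft.fftfreq(w, d=pixel_pitch_um)
    fr = np.sqrt(fx[None, :] ** 2 + fy[:, None] ** 2)
    f0 = 1.0 / wavelength_um
    filt = np.exp(-((fr - f0) ** 2) / (2 * (bandwidth_frac * f0) ** 2))
    z = np.fft.ifft2(np.fft.fft2(noise) * filt)
    orientations = np.rad2deg(np.angle(z)) / 2.0 % 180.0
    return OrientationMap(orientations, pixel_pitch_um, wavelength_um, seed)


@dataclass(frozen=True)
class Track:
    """Linear electrode track: up to 32 sites at exactly 100 um spacing."""

    positions_um: np.ndarray       # (n, 2)
    orientations: np.ndarray       # degrees, read off the map
    spacing_um: float = 100.0

    def __post_init__(self) -> None:
        n = len(self.positions_um)
        if n < 2 or n > 32:
            raise ValueError("track must have 2..32 sites")
        d = np.linalg.norm(np.diff(self.positions_um, axis=0), axis=1)
        if not np.allclose(d, self.spacing_um, atol=1e-6):
            raise ValueError("sites must be exactly evenly spaced")

    @property
    def n_sites(self) -> int:
        return len(self.positions_um)

    def distances_from(self, site_index: int) -> np.ndarray:
        """Signed distances (um) of every site from a reference site."""
        return (np.arange(self.n_sites) - site_index) * self.spacing_um


def sample_track(omap: OrientationMap, start_um: tuple[float, float],
                 angle_deg: float, n_sites: int = 32,
                 spacing_um: float = 100.0) -> Track:
    """Read site orientations along a straight line on the map."""
    th = np.deg2rad(angle_deg)
    d = np.arange(n_sites) * spacing_um
    pts = np.column_stack([start_um[0] + d * np.cos(th),
                           start_um[1] + d * np.sin(th)])
    orientations = omap.orientation_at(pts)   # raises if the track leaves the map
    return Track(pts, orientations, spacing_um)


@dataclass(frozen=True)
class SiteTruth:
    """Ground-truth response parameters of one synthetic recording site.

    Mean response to a grating of contrast c at orientation theta:
    ``r_max * c^n/(c^n + c50^n) * exp(kappa*(cos 2(theta - pref) - 1))
    + baseline``, in spike counts per presentation.
    """

    r_max: float = 30.0
    c50: float = 0.25
    n: float = 2.0
    preferred_orientation: float = 0.0
    kappa: float = 2.0
    baseline: float = 0.0

    def mean_response(self, orientation_deg: np.ndarray | float,
                      contrast: np.ndarray | float) -> np.ndarray:
        c = np.asarray(contrast, float)
        th = np.asarray(orientation_deg, float)
        cr = c ** self.n / (c ** self.n + self.c50 ** self.n)
        vm = np.exp(self.kappa
                    * (np.cos(2 * np.deg2rad(th - self.preferred_orientation)) - 1))
        return self.r_max * cr * vm + self.baseline


@dataclass
class SyntheticRecording:
    """Poisson spike-count table for a set of sites and a grating battery.

    ``counts`` has shape (n_sites, n_orientations, n_contrasts, n_trials);
    ``means`` holds the noiseless mean structure on the same stimulus grid.
    """

    truths: list[SiteTruth]
    counts: np.ndarray
    means: np.ndarray
    orientations: np.ndarray
    contrasts: np.ndarray
    n_trials: int
    seed: int | None

    @property
    def n_sites(self) -> int:
        return len(self.truths)

    def responses(self, noiseless: bool = False) -> np.ndarray:
        """Trial-averaged response magnitudes (sites, oris, contrasts)."""
        return self.means if noiseless else self.counts.mean(axis=3)

    def to_frame(self) -> pd.DataFrame:
        sites, oris, cons = np.meshgrid(np.arange(self.n_sites),
                                        self.orientations, self.contrasts,
                                        indexing="ij")
        return pd.DataFrame({
            "site": sites.ravel(), "orientation": oris.ravel(),
            "contrast": cons.ravel(),
            "mean_count": self.counts.mean(axis=3).ravel(),
            "true_mean": self.means.ravel(),
        })


def synth_recording(truths: Sequence[SiteTruth],
                    orientations: Sequence[float] = BATTERY_ORIENTATIONS,
                    contrasts: Sequence[float] = BATTERY_CONTRASTS,
                    n_trials: int = 20,
                    seed: int | None = 0) -> SyntheticRecording:
    """Sample Poisson spike counts around the sites' mean structure."""
    oris = np.asarray(orientations, float)
    cons = np.asarray(contrasts, float)
    means = np.stack([t.mean_response(oris[:, None], cons[None, :])
                      for t in truths])
    rng = np.random.default_rng(seed)
    counts = rng.poisson(means[..., None].repeat(n_trials, axis=3))
    return SyntheticRecording(list(truths), counts, means, oris, cons,
                              n_trials, seed)


def site_snr(recording: SyntheticRecording) -> np.ndarray:
    """Signal-to-noise ratio per site: mean response at the preferred
    orientation and full contrast, divided by the across-trial s.d. at the
    least preferred orientation and lowest contrast (infinite when that
    s.d. is zero)."""
    mean_resp = recording.counts.mean(axis=3)       # (sites, oris, cons)
    full = int(np.argmax(recording.contrasts))
    low = int(np.argmin(recording.contrasts))
    pref = np.argmax(mean_resp[:, :, full], axis=1)
    worst = np.argmin(mean_resp[:, :, full], axis=1)
    idx = np.arange(recording.n_sites)
    signal = mean_resp[idx, pref, full]
    noise = recording.counts[idx, worst, low, :].std(axis=1)
    return np.where(noise > 0, signal / np.maximum(noise, 1e-300), np.inf)


def site_filter(recording: SyntheticRecording,
                snr_threshold: float = 5.0) -> np.ndarray:
    """Boolean mask of sites whose SNR exceeds the threshold."""
    if recording.n_trials < 2:
        raise ValueError("need at least 2 trials per stimulus")
    return site_snr(recording) > snr_threshold


def lhi_computable_sites(passed: Sequence[bool], min_flank: int = 3) -> np.ndarray:
    """Indices of sites with at least ``min_flank`` immediately flanking
    passing sites on each side.

    On a fully passing 32-site track this retains the interior sites with
    indices 3..28 (0-based), i.e. the 4th through 29th electrodes.
    """
    ok = np.asarray(passed, bool)
    idx = []
    for i in range(len(ok)):
        if not ok[i]:
            continue
        left = ok[:i][::-1]
        right = ok[i + 1:]
        if (left[:min_flank].sum() >= min_flank
                and right[:min_flank].sum() >= min_flank):
            idx.append(i)
    return np.array(idx, dtype=int)
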