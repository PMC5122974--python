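"""Measurement battery: contrast-response and tuning fits, suppression,
local homogeneity and nonlinearity indices, and correlation summaries.

Conventions follow multi-electrode cortical physiology practice: the
contrast response is a Naka-Rushton hyperbolic ratio whose *effective*
maximum is the fitted value at 100 % contrast and whose *effective*
semi-saturation contrast is where the fit reaches half that value; the
orientation tuning is a Von Mises curve over doubled angles with an
explicit baseline; the Local Homogeneity Index (LHI) is the Gaussian
weighted resultant length of doubled preferred orientations around a site,
normalised so that a perfectly homogeneous neighbourhood scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .mapsynth import OrientationMap, Track

__all__ = [
    "CRFit",
    "TuningFit",
    "IndexRecord",
    "CorrelationResult",
    "fit_naka_rushton",
    "fit_von_mises",
    "suppression_index",
    "mean_si",
    "lhi_from_sites",
    "lhi_1d",
    "lhi_2d",
    "lhi_2d_map",
    "lhi_compare",
    "LHIComparison",
    "naka_rushton",
    "von_mises",
    "nonlinearity_index",
    "nli_from_curve",
    "circular_variance",
    "correlate",
]

SIGMA_LHI_UM = 180.0


# ---------------------------------------------------------------------------
# contrast response
# ---------------------------------------------------------------------------

def naka_rushton(c: np.ndarray | float, r_max: float, c50: float,
                 n: float) -> np.ndarray | float:
    """Hyperbolic-ratio contrast response, R_max * c^n / (c^n + c50^n)."""
    cn = np.asarray(c, float) ** n
    return r_max * cn / (cn + c50 ** n)


@dataclass(frozen=True)
class CRFit:
    """Fitted contrast-response descriptor."""

    r_max_param: float
    c50_param: float
    n_param: float
    max_response: float        # fitted value at 100 % contrast
    semi_saturation: float     # contrast where the fit is half of that
    fit_quality: float         # Pearson r between fit and data
    well_fit: bool             # fit_quality >= 0.95

    def __call__(self, c: np.ndarray | float) -> np.ndarray | float:
        return naka_rushton(c, self.r_max_param, self.c50_param, self.n_param)


def _effective_semi_saturation(c50: float, n: float) -> float:
    # solve f(c) = f(1)/2 analytically: c^n = c50^n / (1 + 2 c50^n)
    return float(c50 * (1.0 + 2.0 * c50 ** n) ** (-1.0 / n))


def fit_naka_rushton(contrasts, responses,
                     n_bounds: tuple[float, float] = (0.5, 6.0),
                     n_starts: int = 5) -> CRFit:
    """Bounded least-squares Naka-Rushton fit with multiple starts.

    The optimiser is restarted from ``n_starts`` log-spaced c50 guesses
    (the hyperbolic ratio has local minima at extreme exponents) and the
    best solution by residual norm is kept.
    """
    c = np.asarray(contrasts, float)
    r = np.asarray(responses, float)
    if c.size < 4 or np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct contrasts")
    if not np.all(np.isfinite(r)) or np.any(r < 0):
        raise ValueError("responses must be finite and non-negative")

    scale = max(r.max(), 1e-12)
    lo = [1e-6 * scale, 1e-3, n_bounds[0]]
    hi = [10.0 * scale, 10.0, n_bounds[1]]
    best, best_cost = None, np.inf
    for c50_0 in np.geomspace(0.03, 0.8, n_starts):
        try:
            popt, _ = optimize.curve_fit(
                naka_rushton, c, r, p0=[scale, c50_0, 2.0],
                bounds=(lo, hi), maxfev=20000)
        except RuntimeError:
            continue
        cost = float(np.sum((naka_rushton(c, *popt) - r) ** 2))
        if cost < best_cost:
            best, best_cost = popt, cost
    if best is None:
        # optimiser failure is flagged, not silently dropped
        return CRFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False)
    r_max, c50, n = map(float, best)
    fit_vals = naka_rushton(c, r_max, c50, n)
    quality = _safe_pearson(fit_vals, r)
    return CRFit(r_max, c50, n,
                 max_response=float(naka_rushton(1.0, r_max, c50, n)),
                 semi_saturation=_effective_semi_saturation(c50, n),
                 fit_quality=quality, well_fit=bool(quality >= 0.95))


# ---------------------------------------------------------------------------
# orientation tuning
# ---------------------------------------------------------------------------

def von_mises(theta_deg: np.ndarray | float, baseline: float, amplitude: float,
              kappa: float, pref_deg: float) -> np.ndarray | float:
    """Orientation tuning curve b + a * exp(kappa*(cos 2(theta-pref) - 1))."""
    d = np.deg2rad(np.asarray(theta_deg, float) - pref_deg)
    return baseline + amplitude * np.exp(kappa * (np.cos(2 * d) - 1.0))


def _hwhh_from_kappa(kappa: float) -> float:
    """Half width at half height (deg) of the Von Mises above its baseline."""
    arg = 1.0 - np.log(2.0) / kappa
    if arg <= -1.0:
        return 90.0   # curve never falls to half height: flat-flagged width
    return float(np.degrees(np.arccos(arg)) / 2.0)


def circular_variance(orientations_deg, responses) -> float:
    """1 - |sum R * exp(2i theta)| / sum R over the measured orientations."""
    th = np.deg2rad(np.asarray(orientations_deg, float))
    r = np.asarray(responses, float)
    total = r.sum()
    if total <= 0:
        return 1.0
    return float(1.0 - np.abs(np.sum(r * np.exp(2j * th))) / total)


@dataclass(frozen=True)
class TuningFit:
    """Fitted orientation-tuning descriptor."""

    preferred_orientation: float
    hwhh: float
    kappa: float
    baseline: float
    amplitude: float
    circular_variance: float
    fit_quality: float
    well_fit: bool          # fit_quality >= 0.7
    flat: bool = False

    def __call__(self, theta_deg) -> np.ndarray | float:
        return von_mises(theta_deg, self.baseline, self.amplitude,
                         self.kappa, self.preferred_orientation)


def fit_von_mises(orientations, responses,
                  kappa_bounds: tuple[float, float] = (0.05, 60.0)) -> TuningFit:
    """Fit a baseline-plus-Von-Mises tuning curve to grating responses."""
    th = np.asarray(orientations, float)
    r = np.asarray(responses, float)
    if th.size < 6:
        raise ValueError("need at least 6 orientations")
    if not np.all(np.isfinite(r)):
        raise ValueError("responses must be finite")
    cv = circular_variance(th, r)
    spread = r.max() - r.min()
    if spread <= 1e-12 * max(r.max(), 1.0):
        # all-equal responses: flat tuning, undefined width
        return TuningFit(np.nan, np.nan, np.nan, float(r.mean()), 0.0,
                         1.0, 0.0, False, flat=True)

    pref0 = float(th[np.argmax(r)])
    scale = max(spread, 1e-12)
    lo = [0.0, 1e-6 * scale, kappa_bounds[0], pref0 - 90.0]
    hi = [max(r.max(), 1e-12), 10.0 * scale, kappa_bounds[1], pref0 + 90.0]
    best, best_cost = None, np.inf
    for k0 in (0.5, 2.0, 8.0):
        try:
            popt, _ = optimize.curve_fit(
                von_mises, th, r, p0=[max(r.min(), 1e-9 * scale), scale, k0, pref0],
                bounds=(lo, hi), maxfev=20000)
        except RuntimeError:
            continue
        cost = float(np.sum((von_mises(th, *popt) - r) ** 2))
        if cost < best_cost:
            best, best_cost = popt, cost
    if best is None:
        return TuningFit(np.nan, np.nan, np.nan, np.nan, np.nan, cv, np.nan,
                         False, flat=False)
    b, a, kappa, pref = map(float, best)
    quality = _safe_pearson(von_mises(th, b, a, kappa, pref), r)
    return TuningFit(pref % 180.0, _hwhh_from_kappa(kappa), kappa, b, a,
                     cv, quality, bool(quality >= 0.7))


# ---------------------------------------------------------------------------
# suppression indices
# ---------------------------------------------------------------------------

def suppression_index(r_plaid: float, r_pref_half_contrast: float) -> float:
    """SI = 1 - R(plaid) / R(preferred grating at 0.5 contrast).

    Negative values mark facilitation (the plaid beats the preferred
    component alone).
    """
    if r_pref_half_contrast <= 0:
        raise ValueError("undefined SI: zero response to the preferred "
                         "component (site should be excluded)")
    return float(1.0 - r_plaid / r_pref_half_contrast)


def mean_si(plaid_responses, r_pref_half_contrast: float,
            include_preferred_pair: bool = True) -> float:
    """Mean SI over the plaids containing the preferred orientation.

    ``plaid_responses`` is ordered by the paired battery orientation; the
    first entry is the preferred+preferred pair, dropped when
    ``include_preferred_pair`` is False.
    """
    r = np.asarray(plaid_responses, float)
    if not include_preferred_pair:
        r = r[1:]
    return float(np.mean([suppression_index(x, r_pref_half_contrast) for x in r]))


# ---------------------------------------------------------------------------
# local homogeneity index
# ---------------------------------------------------------------------------

def lhi_from_sites(distances_um, orientations_deg,
                   sigma_um: float = SIGMA_LHI_UM) -> float:
    """Gaussian-weighted resultant of doubled orientations.

    ``LHI = k * |sum_j w_j exp(2i Omega_j)|`` with
    ``w_j = exp(-d_j^2 / 2 sigma^2)`` and ``k`` the inverse of the
    theoretical maximum (the sum of the weights), so LHI is 1 exactly when
    every neighbour shares one orientation.
    """
    d = np.asarray(distances_um, float)
    om = np.deg2rad(np.asarray(orientations_deg, float))
    if d.size == 0:
        raise ValueError("no neighbouring sites")
    w = np.exp(-d ** 2 / (2 * sigma_um ** 2))
    return float(np.abs(np.sum(w * np.exp(2j * om))) / w.sum())


def lhi_1d(track: Track, site_index: int, sigma_um: float = SIGMA_LHI_UM,
           min_flank: int = 3) -> float:
    """One-dimensional LHI of a site on an electrode track.

    All other track sites contribute (self excluded); at least
    ``min_flank`` sites are required on each side.
    """
    n = track.n_sites
    if site_index < min_flank or site_index > n - 1 - min_flank:
        raise ValueError(
            f"need at least {min_flank} sites on each side of the reference")
    d = track.distances_from(site_index)
    mask = np.arange(n) != site_index
    return lhi_from_sites(d[mask], track.orientations[mask], sigma_um)


def lhi_2d(omap: OrientationMap, point_um: tuple[float, float],
           sigma_um: float = SIGMA_LHI_UM) -> float:
    """Two-dimensional LHI over all map pixels within 3 sigma of a point."""
    px = omap.pixel_pitch_um
    x, y = point_um
    r_px = int(np.ceil(3 * sigma_um / px))
    ci, ri = x / px, y / px
    h, w = omap.shape
    if (ci < r_px or ri < r_px or ci > w - 1 - r_px or ri > h - 1 - r_px):
        raise ValueError("point closer than 3 sigma to the map edge")
    c0, r0 = int(round(ci)), int(round(ri))
    cols = np.arange(c0 - r_px, c0 + r_px + 1)
    rows = np.arange(r0 - r_px, r0 + r_px + 1)
    dx = cols * px - x
    dy = rows * px - y
    d2 = dx[None, :] ** 2 + dy[:, None] ** 2
    wgt = np.exp(-d2 / (2 * sigma_um ** 2)) * (d2 <= (3 * sigma_um) ** 2)
    z = np.exp(2j * np.deg2rad(omap.orientations[np.ix_(rows, cols)]))
    return float(np.abs(np.sum(wgt * z)) / wgt.sum())


def lhi_2d_map(omap: OrientationMap, sigma_um: float = SIGMA_LHI_UM) -> np.ndarray:
    """LHI at every map pixel (FFT convolution; edges use partial windows)."""
    from scipy import signal as _signal
    px = omap.pixel_pitch_um
    r_px = int(np.ceil(3 * sigma_um / px))
    ax = np.arange(-r_px, r_px + 1) * px
    d2 = ax[None, :] ** 2 + ax[:, None] ** 2
    kern = np.exp(-d2 / (2 * sigma_um ** 2)) * (d2 <= (3 * sigma_um) ** 2)
    z = omap.doubled_field()
    num = np.abs(_signal.fftconvolve(z, kern, mode="same"))
    den = _signal.fftconvolve(np.ones(omap.shape), kern, mode="same")
    return np.clip(num / den, 0.0, 1.0)


@dataclass
class LHIComparison:
    """Paired 2D and 8-angle-mean 1D LHI samples plus summary fits."""

    lhi2d: np.ndarray
    lhi1d_mean: np.ndarray
    quad_coeffs: np.ndarray     # polynomial fit lhi1d ~ quad(lhi2d)
    quad_r2: float
    spearman: float
    max_excess: float           # max over points of (1D - 2D)
    frac_excess_gt: float       # fraction of points with (1D - 2D) > 0.2


def lhi_compare(omap: OrientationMap, n_points: int = 500, n_angles: int = 8,
                seed: int | None = 0, sigma_um: float = SIGMA_LHI_UM,
                min_flank: int = 7, spacing_um: float = 100.0,
                excess_threshold: float = 0.2) -> LHIComparison:
    """Compare 2D LHI with the mean 1D LHI of radial penetrations.

    For each randomly chosen interior point, ``n_angles`` equally spaced
    simulated tracks (2*min_flank+1 sites at the electrode spacing,
    spanning the probe's reach well beyond the Gaussian window) are
    read off the map and their 1D LHIs averaged; the scatter against the
    2D LHI is summarised by a quadratic fit, its R^2, the Spearman
    correlation and the worst-case 1D overestimate.
    """
    rng = np.random.default_rng(seed)
    margin = 3 * sigma_um + min_flank * spacing_um + 2 * omap.pixel_pitch_um
    ext_x, ext_y = omap.extent_um
    if ext_x <= 2 * margin or ext_y <= 2 * margin:
        raise ValueError("map too small for the requested comparison")
    xs = rng.uniform(margin, ext_x - margin, n_points)
    ys = rng.uniform(margin, ext_y - margin, n_points)
    angles = np.arange(n_angles) * 180.0 / n_angles
    offsets = (np.arange(2 * min_flank + 1) - min_flank) * spacing_um
    nonself = offsets != 0
    v2d = np.empty(n_points)
    v1d = np.empty(n_points)
    for i, (x, y) in enumerate(zip(xs, ys)):
        v2d[i] = lhi_2d(omap, (x, y), sigma_um)
        vals = []
        for a in angles:
            om = omap.track_orientations((x, y), a, offsets[nonself])
            vals.append(lhi_from_sites(offsets[nonself], om, sigma_um))
        v1d[i] = np.mean(vals)
    if np.ptp(v2d) < 1e-12:            # degenerate scatter (constant map)
        coeffs = np.array([0.0, 0.0, float(v1d.mean())])
        r2, rho = np.nan, np.nan
    else:
        coeffs = np.polyfit(v2d, v1d, 2)
        fitted = np.polyval(coeffs, v2d)
        ss_res = np.sum((v1d - fitted) ** 2)
        ss_tot = np.sum((v1d - v1d.mean()) ** 2)
        r2 = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else np.nan
        rho = float(stats.spearmanr(v2d, v1d).statistic)
    excess = v1d - v2d
    return LHIComparison(v2d, v1d, coeffs, r2, rho,
                         float(excess.max()),
                         float(np.mean(excess > excess_threshold)))


# ---------------------------------------------------------------------------
# nonlinearity index
# ---------------------------------------------------------------------------

def nli_from_curve(curve, semi_saturation: float, max_response: float,
                   n_samples: int = 1001) -> float:
    """Chord-and-area nonlinearity index of a contrast-response curve.

    The chord joins the half-maximum point ``(c_s, M/2)`` to the
    full-contrast point ``(1, M)``.  The signed area between the curve and
    the chord on that interval (positive above) is divided by the area
    between the chord and the maximal-saturation path (a vertical rise to M
    at c_s, then flat), i.e. the triangle of area ``(1 - c_s) * M / 4``.
    The index is +1 for maximal saturation, 0 for a linear rise and -1 for
    maximal expansion.
    """
    cs, M = float(semi_saturation), float(max_response)
    if not 0.0 < cs < 1.0 - 1e-9:
        raise ValueError("degenerate chord: semi-saturation must be in (0, 1)")
    if M <= 0:
        raise ValueError("max_response must be positive")
    c = np.linspace(cs, 1.0, n_samples)
    chord = M / 2.0 + (c - cs) * (M / 2.0) / (1.0 - cs)
    area = np.trapezoid(np.asarray(curve(c), float) - chord, c)
    return float(area / ((1.0 - cs) * M / 4.0))


def nonlinearity_index(fit: CRFit, n_samples: int = 1001) -> float:
    """Nonlinearity index of a fitted contrast-response curve."""
    if not np.isfinite(fit.semi_saturation) or fit.semi_saturation >= 1.0 - 1e-9:
        return np.nan   # degenerate triangle, flagged as undefined
    return nli_from_curve(fit, fit.semi_saturation, fit.max_response, n_samples)


# ---------------------------------------------------------------------------
# correlation summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


@dataclass(frozen=True)
class IndexRecord:
    """Per-site indices entering the correlation analyses."""

    lhi: float
    hwhh: float
    si_orthogonal: float
    mean_si: float
    semi_saturation: float
    nli: float
    octo_norm: float


def correlate(index_a, index_b, min_n: int = 10) -> CorrelationResult:
    """Pearson correlation with two-sided p and least-squares line."""
    x = np.asarray(index_a, float)
    y = np.asarray(index_b, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} paired sites")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, x.size)
    lr = stats.linregress(x, y)
    return CorrelationResult(float(lr.rvalue), float(lr.pvalue),
                             float(lr.slope), float(lr.intercept), x.size)


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(stats.pearsonr(a, b).statistic)
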