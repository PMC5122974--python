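"""Reproducible experiment runners binding stimuli, models, maps, analysis.

Each runner consumes an :class:`ExperimentConfig`, is deterministic given
the config (seeds included), and returns a machine-parseable report (plain
dict) carrying the config hash.  When an output directory is configured the
report is written as JSON along with CSV tables.

The population runner evaluates thousands of (neuron, stimulus) pairs; to
keep this tractable the feedforward pathway is tabulated once per tuning
class on a fine grid of stimulus-relative orientations and interpolated
(the pathway response depends only on the stimulus rotated into a unit's
preferred frame).  Interpolation accuracy is tested against direct
evaluation in the test suite.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import analysis
from .cortex import (NEIGHBOR_DISTANCES_UM, CorticalModel, CircuitSite,
                     en_response, extrastriate_pool, iso_site,
                     neighbor_weights, orientation_response_maps,
                     pinwheel_site, unoriented_response)
from .mapsynth import OrientationMap, generate_map
from .pathway import (BROAD_GEOMETRY, NARROW_GEOMETRY, pushpull_input, spiking)
from .stimuli import (BATTERY_CONTRASTS, BATTERY_ORIENTATIONS, BATTERY_PHASES,
                      GratingSpec, LuminanceImage, PixelGrid,
                      equal_plaid_components, make_grating, make_plaid)

__all__ = [
    "ExperimentConfig",
    "ResponseTables",
    "run_model_comparison",
    "run_busse",
    "run_lhi_validation",
    "run_image_demo",
    "run_full_population",
    "two_bar_image",
    "rosette_image",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Serializable configuration of one experiment run."""

    seed: int = 0
    out_dir: str | None = None
    # synthetic map
    map_shape: tuple[int, int] = (512, 512)
    map_wavelength_um: float = 1000.0
    map_pixel_pitch_um: float = 20.0
    # population
    n_per_stratum: int = 40
    lhi_strata: tuple[float, ...] = (0.0, 1 / 3, 2 / 3, 1.0)
    class_lhi_threshold: float = 0.5
    # LHI validation
    n_lhi_points: int = 500
    n_lhi_angles: int = 8
    # reference-site probing
    tuning_orientations_deg: float = 11.25
    strict: bool = False     # raise on property-suite failure

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        d = json.loads(text)
        for k in ("map_shape", "lhi_strata"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_report(report: dict, config: ExperimentConfig, name: str,
                  frames: dict[str, pd.DataFrame] | None = None) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{name}_report.json").write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True))
    for key, frame in (frames or {}).items():
        frame.to_csv(out / f"{name}_{key}.csv", index=False)


def _check(report: dict, config: ExperimentConfig, name: str) -> None:
    failures = [k for k, v in report["properties"].items() if not v]
    report["failures"] = failures
    report["passed"] = not failures
    if failures and config.strict:
        raise RuntimeError(f"{name}: failing properties: {failures}")


# ---------------------------------------------------------------------------
# reference-site model comparison (tuning, contrast, complexity)
# ---------------------------------------------------------------------------

def _site_battery(cm: CorticalModel, site: CircuitSite,
                  tuning_step: float) -> dict:
    """All drives for one reference site; responses under ff/en/dn."""
    out: dict = {}
    oris = np.arange(0.0, 180.0, tuning_step)
    sf = cm.spatial_frequency

    def all_models(components, per_component=False, clip=False):
        c, pooled, p = cm._drives(site, tuple(components), per_component, clip)
        c_u = unoriented_response(p, cm.unoriented_params)
        return {
            "ff": c,
            "en": float(en_response(c * pooled, c_u, cm.en_params)),
            "dn": c / (pooled + cm.en_params.beta0),
        }

    out["tuning_oris"] = oris
    out["tuning"] = {m: np.empty(oris.size) for m in ("ff", "en", "dn")}
    for i, o in enumerate(oris):
        r = all_models([GratingSpec(o, 1.0, 0.0, sf)])
        for m in r:
            out["tuning"][m][i] = r[m]

    cons = np.asarray(BATTERY_CONTRASTS)
    out["contrasts"] = cons
    out["contrast"] = {m: np.empty(cons.size) for m in ("ff", "en", "dn")}
    for i, cval in enumerate(cons):
        r = all_models([GratingSpec(site.preferred_orientation, cval, 0.0, sf)])
        for m in r:
            out["contrast"][m][i] = r[m]

    pref = site.preferred_orientation
    r_half = all_models([GratingSpec(pref, 0.5, 0.0, sf)])
    plaid = all_models((GratingSpec(pref, 0.5, 0.0, sf),
                        GratingSpec(pref + 90.0, 0.5, 0.0, sf)),
                       per_component=True)
    out["si"] = {m: analysis.suppression_index(plaid[m], r_half[m])
                 for m in ("ff", "en", "dn")}

    counts = (1, 2, 4, 8)
    out["complexity_counts"] = np.asarray(counts)
    out["complexity"] = {m: np.empty(len(counts)) for m in ("ff", "en", "dn")}
    for i, n in enumerate(counts):
        r = all_models(equal_plaid_components(n, 1.0, pref, 0.0, sf))
        for m in r:
            out["complexity"][m][i] = r[m]

    octo = all_models(equal_plaid_components(8, 1.0, 0.0, 0.0, sf))
    peak = {m: out["tuning"][m].max() for m in ("ff", "en", "dn")}
    out["octo_norm"] = {m: octo[m] / peak[m] for m in ("ff", "en", "dn")}
    return out


def _hwhh_and_nli(battery: dict, model: str) -> tuple[float, float]:
    tun = analysis.fit_von_mises(battery["tuning_oris"], battery["tuning"][model])
    cr = analysis.fit_naka_rushton(battery["contrasts"],
                                   battery["contrast"][model])
    return tun.hwhh, analysis.nonlinearity_index(cr)


def run_model_comparison(config: ExperimentConfig,
                         cm: CorticalModel | None = None) -> dict:
    """Reference iso-domain and pinwheel sites under FF, EN and DN.

    Emits orientation tuning, contrast response and complexity-series
    tables plus the derived HWHH / NLI / SI quantities, and evaluates the
    direction properties that distinguish the models.
    """
    cm = cm or CorticalModel()
    step = config.tuning_orientations_deg
    iso = _site_battery(cm, iso_site(0.0, "narrow"), step)
    pin = _site_battery(cm, pinwheel_site(0.0, "broad"), step)

    metrics: dict = {}
    for name, bat in (("iso", iso), ("pin", pin)):
        for model in ("ff", "en", "dn"):
            hwhh, nli = _hwhh_and_nli(bat, model)
            cr_fit = analysis.fit_naka_rushton(bat["contrasts"],
                                               bat["contrast"][model])
            metrics[f"{name}_{model}"] = {
                "hwhh": hwhh, "nli": nli, "si": bat["si"][model],
                "semi_saturation": cr_fit.semi_saturation,
                "octo_norm": bat["octo_norm"][model],
                "complexity_norm": (bat["complexity"][model]
                                    / bat["complexity"][model][0]).tolist(),
            }

    m = metrics
    comp_en_pin = np.asarray(m["pin_en"]["complexity_norm"])
    comp_ff_pin = np.asarray(m["pin_ff"]["complexity_norm"])
    comp_en_iso = np.asarray(m["iso_en"]["complexity_norm"])
    properties = {
        "en_iso_sharpening": m["iso_en"]["hwhh"] < m["iso_ff"]["hwhh"],
        "en_pin_broadening": m["pin_en"]["hwhh"] > m["pin_ff"]["hwhh"],
        "en_saturation_ordering": m["iso_en"]["nli"] > m["pin_en"]["nli"],
        "en_suppression_chain": (m["iso_en"]["si"] > m["iso_ff"]["si"]
                                 > m["pin_en"]["si"]),
        "en_iso_complexity_decreasing": bool(np.all(np.diff(comp_en_iso) < 0)),
        "en_pin_complex_enhancement": bool(np.all(comp_en_pin[2:] > comp_ff_pin[2:])),
        "octotropic_ordering": (m["pin_en"]["octo_norm"]
                                > m["iso_en"]["octo_norm"]),
        "dn_iso_broadening": m["iso_dn"]["hwhh"] > m["iso_ff"]["hwhh"],
        "dn_pin_near_intact": m["pin_dn"]["hwhh"] <= 1.05 * m["pin_ff"]["hwhh"],
        "dn_saturation_ordering": m["iso_dn"]["nli"] > m["pin_dn"]["nli"],
    }
    report = {"experiment": "model_comparison", "config_hash": config.config_hash,
              "metrics": metrics, "properties": properties}
    _check(report, config, "model_comparison")

    frames = {}
    for name, bat in (("iso", iso), ("pin", pin)):
        frames[f"tuning_{name}"] = pd.DataFrame(
            {"orientation": bat["tuning_oris"], **bat["tuning"]})
        frames[f"contrast_{name}"] = pd.DataFrame(
            {"contrast": bat["contrasts"], **bat["contrast"]})
        frames[f"complexity_{name}"] = pd.DataFrame(
            {"n_components": bat["complexity_counts"], **bat["complexity"]})
    _write_report(report, config, "model_comparison", frames)
    return report


# ---------------------------------------------------------------------------
# Busse-style contrast-combination sweep
# ---------------------------------------------------------------------------

def run_busse(config: ExperimentConfig, cm: CorticalModel | None = None,
              mask_contrast: float = 0.25,
              test_contrasts: Sequence[float] = (0.0,) + BATTERY_CONTRASTS
              ) -> dict:
    """Plaids with the preferred component fixed at 25 % contrast while the
    orthogonal (test) component's contrast varies.

    All responses are normalized to the model output for the preferred
    grating at 25 % contrast, the scale on which the summation and
    winner-take-all diagnostics are evaluated (the test-alone response of
    an orientation-selective unit is near zero, so ratios to it are
    ill-posed).
    """
    cm = cm or CorticalModel()
    sf = cm.spatial_frequency
    sites = {"iso_narrow": iso_site(0.0, "narrow"),
             "pin_broad": pinwheel_site(0.0, "broad")}
    curves: dict = {}
    diagnostics: dict = {}
    rows = []
    for sname, site in sites.items():
        pref = site.preferred_orientation
        for model in ("ff", "en"):
            ref = cm.site_response(site, [GratingSpec(pref, mask_contrast, 0.0, sf)],
                                   model)
            plaids, tests, singles = [], [], []
            for tc in test_contrasts:
                comps = [GratingSpec(pref, mask_contrast, 0.0, sf)]
                if tc > 0:
                    comps.append(GratingSpec(pref + 90.0, tc, 0.0, sf))
                plaids.append(cm.site_response(site, comps, model,
                                               per_component_phases=True,
                                               allow_clipping=True) / ref)
                tests.append((cm.site_response(
                    site, [GratingSpec(pref + 90.0, tc, 0.0, sf)], model)
                    if tc > 0 else 0.0) / ref)
                singles.append(cm.site_response(
                    site, [GratingSpec(pref, tc, 0.0, sf)], model)
                    / ref if tc > 0 else 0.0)
            key = f"{sname}_{model}"
            curves[key] = {"test_contrast": list(test_contrasts),
                           "plaid": plaids, "test_alone": tests,
                           "pref_alone": singles}
            i25 = list(test_contrasts).index(mask_contrast)
            i100 = int(np.argmax(test_contrasts))
            diagnostics[key] = {
                "summation_at_equal_25": plaids[i25] > max(1.0, tests[i25]),
                "plaid_over_mask_at_25": plaids[i25],
                "wta_gap_at_100": abs(plaids[i100] - tests[i100]),
                "winner_take_all_within_10pct": abs(plaids[i100] - tests[i100]) < 0.1,
            }
            for tc, pl, te in zip(test_contrasts, plaids, tests):
                rows.append((sname, model, tc, pl, te))
    report = {"experiment": "busse", "config_hash": config.config_hash,
              "mask_contrast": mask_contrast, "curves": curves,
              "diagnostics": diagnostics,
              "properties": {
                  "en_iso_winner_take_all":
                      diagnostics["iso_narrow_en"]["winner_take_all_within_10pct"],
                  "en_completes_wta": (
                      diagnostics["iso_narrow_en"]["wta_gap_at_100"]
                      < diagnostics["iso_narrow_ff"]["wta_gap_at_100"]),
                  "summation_at_equal_25":
                      diagnostics["iso_narrow_en"]["summation_at_equal_25"],
              }}
    _check(report, config, "busse")
    frame = pd.DataFrame(rows, columns=["site", "model", "test_contrast",
                                        "plaid_norm", "test_alone_norm"])
    _write_report(report, config, "busse", {"curves": frame})
    return report


# ---------------------------------------------------------------------------
# LHI validation
# ---------------------------------------------------------------------------

def run_lhi_validation(config: ExperimentConfig,
                       omap: OrientationMap | None = None) -> dict:
    """1D-vs-2D LHI comparison on a synthetic map (scatter + quadratic fit)."""
    omap = omap or generate_map(config.map_shape, config.map_wavelength_um,
                                config.map_pixel_pitch_um, config.seed)
    cmp_ = analysis.lhi_compare(omap, config.n_lhi_points,
                                config.n_lhi_angles, seed=config.seed + 1)
    report = {
        "experiment": "lhi_validation", "config_hash": config.config_hash,
        "n_points": config.n_lhi_points,
        "spearman": cmp_.spearman,
        "quad_coeffs": cmp_.quad_coeffs.tolist(),
        "quad_r2": cmp_.quad_r2,
        "max_excess_1d_minus_2d": cmp_.max_excess,
        "frac_excess_gt_0.2": cmp_.frac_excess_gt,
        "properties": {"spearman_above_0.8": cmp_.spearman > 0.8},
    }
    _check(report, config, "lhi_validation")
    frame = pd.DataFrame({"lhi2d": cmp_.lhi2d, "lhi1d_mean": cmp_.lhi1d_mean})
    _write_report(report, config, "lhi_validation", {"scatter": frame})
    return report


# ---------------------------------------------------------------------------
# image demo (contours vs patterns)
# ---------------------------------------------------------------------------

def _draw_bar(values: np.ndarray, grid: PixelGrid, center_deg, angle_deg,
              length_deg, width_deg, level) -> None:
    x, y = grid.coords()
    th = np.deg2rad(angle_deg)
    u = (x - center_deg[0]) * np.cos(th) + (y - center_deg[1]) * np.sin(th)
    v = -(x - center_deg[0]) * np.sin(th) + (y - center_deg[1]) * np.cos(th)
    values[(np.abs(u) <= length_deg / 2) & (np.abs(v) <= width_deg / 2)] = level


def two_bar_image(grid: PixelGrid | None = None) -> LuminanceImage:
    """Two isolated bright bars (contours) on a mid-grey ground."""
    grid = grid or PixelGrid(96, 96, 0.1)
    v = np.full((grid.height, grid.width), 0.5)
    ex, _ = grid.extent_deg
    _draw_bar(v, grid, (-ex / 5, 0.0), 90.0, ex * 0.55, 0.25, 1.0)
    _draw_bar(v, grid, (ex / 5, 0.0), 60.0, ex * 0.55, 0.25, 1.0)
    return LuminanceImage(v, grid)


def rosette_image(grid: PixelGrid | None = None,
                  n_petals: int = 8) -> LuminanceImage:
    """Rosette: short bars at all orientations radiating from one centre."""
    grid = grid or PixelGrid(96, 96, 0.1)
    v = np.full((grid.height, grid.width), 0.5)
    for k in range(n_petals):
        _draw_bar(v, grid, (0.0, 0.0), k * 180.0 / n_petals, 1.4, 0.25, 1.0)
    return LuminanceImage(v, grid)


def run_image_demo(config: ExperimentConfig, cm: CorticalModel | None = None,
                   images: dict[str, LuminanceImage] | None = None) -> dict:
    """Process contour and pattern images through iso- and pinwheel-pooling
    extra-striate cells.

    The iso pool sums eight narrowly tuned neurons whose neighbourhoods
    share their preference; the pinwheel pool sums eight broadly tuned
    neurons normalised by the orientation-averaged neighbourhood.  Each
    pool's heat maps are expressed relative to that pool's peak response to
    a full-contrast preferred grating, so the two pools are compared on
    their own response scales.
    """
    cm = cm or CorticalModel()
    grid = PixelGrid(96, 96, cm.grid.degrees_per_pixel)
    if images is None:
        images = {"two_bars": two_bar_image(grid), "rosette": rosette_image(grid)}
    grating_img = make_grating(
        GratingSpec(0.0, 1.0, 0.0, cm.spatial_frequency), grid)

    pools = {"iso": "narrow", "pinwheel": "broad"}
    refs, maps = {}, {}
    for pool, cls in pools.items():
        sd = orientation_response_maps(grating_img, cm, cls)
        refs[pool] = float(extrastriate_pool(grating_img, cm, pool, cls,
                                             stack_drive=sd).max())
        maps[pool] = {}
        for name, img in images.items():
            sd = orientation_response_maps(img, cm, cls)
            maps[pool][name] = extrastriate_pool(img, cm, pool, cls,
                                                 stack_drive=sd) / refs[pool]

    bar_peak = {p: float(maps[p]["two_bars"].max()) for p in pools}
    ros_int = {p: float(maps[p]["rosette"].mean()) for p in pools}
    # each pool's pattern preference: integrated rosette response relative to
    # its own peak contour response
    pattern_pref = {p: ros_int[p] / bar_peak[p] for p in pools}
    report = {
        "experiment": "image_demo", "config_hash": config.config_hash,
        "bar_peak": bar_peak, "rosette_integral": ros_int,
        "pattern_preference": pattern_pref,
        "bar_peak_ratio_iso_over_pin": bar_peak["iso"] / bar_peak["pinwheel"],
        "rosette_ratio_pin_over_iso": ros_int["pinwheel"] / ros_int["iso"],
        "properties": {
            "iso_pool_prefers_bars": bar_peak["iso"] > bar_peak["pinwheel"],
            "pin_pool_relative_pattern_preference":
                pattern_pref["pinwheel"] > pattern_pref["iso"],
        },
    }
    _check(report, config, "image_demo")
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pool in pools:
            for name in images:
                np.savetxt(out / f"image_demo_{pool}_{name}.csv",
                           maps[pool][name], delimiter=",")
    _write_report(report, config, "image_demo")
    report["maps"] = maps
    return report


# ---------------------------------------------------------------------------
# response tables (fast population pathway)
# ---------------------------------------------------------------------------

class ResponseTables:
    """Phase-averaged feedforward responses tabulated over stimulus-relative
    orientation, per tuning class, with periodic linear interpolation.

    Tables cover the grating battery (orientation x contrast), the
    0.5+0.5-contrast pair plaids (orientation x separation, averaged over
    the 16 phase combinations) and the octotropic plaid, plus the pooled
    thalamic drive of the un-oriented cell for each stimulus.
    """

    GRATING_STEP = 2.5
    PLAID_STEP = 5.0

    def __init__(self, cm: CorticalModel):
        self.cm = cm
        sf = cm.spatial_frequency
        unit = cm.unit("narrow", 0.0)   # supplies thalamic maps for both classes
        sp = cm.spiking_params

        def eval_image(image):
            maps = unit.thalamic_maps(image)
            tn = pushpull_input(maps, NARROW_GEOMETRY)
            tb = pushpull_input(maps, BROAD_GEOMETRY)
            return (float(spiking(tn, sp)), float(spiking(tb, sp)),
                    float(maps.rectified_sum().mean()))

        def eval_components(components):
            """Mean over the 4 common phase offsets."""
            vals = np.zeros(3)
            for dph in BATTERY_PHASES:
                shifted = [GratingSpec(c.orientation, c.contrast, c.phase + dph,
                                       c.spatial_frequency) for c in components]
                vals += eval_image(make_plaid(shifted, cm.grid))
            return vals / len(BATTERY_PHASES)

        # gratings: delta x contrast
        self.g_deltas = np.arange(0.0, 180.0, self.GRATING_STEP)
        nC = len(BATTERY_CONTRASTS)
        self.grating = {"narrow": np.empty((self.g_deltas.size, nC)),
                        "broad": np.empty((self.g_deltas.size, nC))}
        self.cu_grating = np.empty(nC)
        for j, con in enumerate(BATTERY_CONTRASTS):
            for i, d in enumerate(self.g_deltas):
                n, b, p = eval_components([GratingSpec(d, con, 0.0, sf)])
                self.grating["narrow"][i, j] = n
                self.grating["broad"][i, j] = b
                if i == 0:
                    self.cu_grating[j] = p

        # pair plaids: delta1 x separation (16 phase combinations)
        self.p_deltas = np.arange(0.0, 180.0, self.PLAID_STEP)
        seps = np.asarray(BATTERY_ORIENTATIONS)
        self.p_seps = seps
        self.plaid = {"narrow": np.empty((self.p_deltas.size, seps.size)),
                      "broad": np.empty((self.p_deltas.size, seps.size))}
        self.cu_plaid = np.empty(seps.size)
        for j, sep in enumerate(seps):
            for i, d in enumerate(self.p_deltas):
                vals = np.zeros(3)
                for p1 in BATTERY_PHASES:
                    for p2 in BATTERY_PHASES:
                        img = make_plaid([GratingSpec(d, 0.5, p1, sf),
                                          GratingSpec(d + sep, 0.5, p2, sf)],
                                         cm.grid)
                        vals += eval_image(img)
                vals /= 16.0
                self.plaid["narrow"][i, j] = vals[0]
                self.plaid["broad"][i, j] = vals[1]
                if i == 0:
                    self.cu_plaid[j] = vals[2]

        # octotropic plaid: base-orientation offset
        self.o_deltas = np.arange(0.0, 180.0, self.GRATING_STEP)
        self.octo = {"narrow": np.empty(self.o_deltas.size),
                     "broad": np.empty(self.o_deltas.size)}
        for i, d in enumerate(self.o_deltas):
            n, b, p = eval_components(
                equal_plaid_components(8, 1.0, d, 0.0, sf))
            self.octo["narrow"][i] = n
            self.octo["broad"][i] = b
            if i == 0:
                self.cu_octo = p

    @staticmethod
    def _interp_periodic(deltas: np.ndarray, values: np.ndarray,
                         x: np.ndarray | float) -> np.ndarray | float:
        xq = np.asarray(x, float) % 180.0
        ext_d = np.append(deltas, 180.0)
        ext_v = np.append(values, values[:1])
        out = np.interp(xq, ext_d, ext_v)
        return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out

    def grating_response(self, cls: str, delta, contrast_idx: int):
        return self._interp_periodic(self.g_deltas,
                                     self.grating[cls][:, contrast_idx], delta)

    def plaid_response(self, cls: str, delta1, sep_idx: int):
        return self._interp_periodic(self.p_deltas,
                                     self.plaid[cls][:, sep_idx], delta1)

    def octo_response(self, cls: str, delta):
        return self._interp_periodic(self.o_deltas, self.octo[cls], delta)


# ---------------------------------------------------------------------------
# end-to-end population
# ---------------------------------------------------------------------------

def _en_from_tables(tables: ResponseTables, cls: str, c_site, c_neighbors,
                    weights, cu_drive: float) -> float:
    cm = tables.cm
    pooled = float(np.dot(weights, c_neighbors))
    c_u = unoriented_response(cu_drive, cm.unoriented_params)
    return float(en_response(c_site * pooled, c_u, cm.en_params))


def run_full_population(config: ExperimentConfig,
                        cm: CorticalModel | None = None,
                        tables: ResponseTables | None = None) -> dict:
    """Simulate an EN-model population across a synthetic orientation map
    and reproduce the correlation structure between map topography and
    response properties.

    Neurons are placed at map locations stratified by 2D LHI (guaranteeing
    dynamic range), assigned the narrow tuning class in homogeneous
    surroundings and the broad class near pinwheels, and probed with the
    grating battery, the preferred-orientation pair plaids and the
    octotropic plaid.  Per-site fits yield HWHH, semi-saturation, NLI and
    suppression indices; the report carries the six correlation signs.
    """
    cm = cm or CorticalModel()
    tables = tables or ResponseTables(cm)
    rng = np.random.default_rng(config.seed)
    omap = generate_map(config.map_shape, config.map_wavelength_um,
                        config.map_pixel_pitch_um, config.seed)
    l2 = analysis.lhi_2d_map(omap)

    px = omap.pixel_pitch_um
    margin_px = int(np.ceil((3 * analysis.SIGMA_LHI_UM + 400.0) / px))
    h, w = omap.shape
    interior = np.zeros((h, w), bool)
    interior[margin_px:h - margin_px, margin_px:w - margin_px] = True

    # stratified site selection over 2D LHI
    edges = np.asarray(config.lhi_strata)
    chosen: list[tuple[int, int]] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = interior & (l2 >= lo) & (l2 < hi if hi < 1 else l2 <= hi)
        rr, cc = np.nonzero(mask)
        if rr.size == 0:
            continue
        take = min(config.n_per_stratum, rr.size)
        sel = rng.choice(rr.size, size=take, replace=False)
        chosen.extend(zip(rr[sel], cc[sel]))

    dists = np.asarray(NEIGHBOR_DISTANCES_UM)
    wts = neighbor_weights(dists, cm.sigma_cortex).weights
    batt_oris = np.asarray(BATTERY_ORIENTATIONS)
    full_c = len(BATTERY_CONTRASTS) - 1

    records = []
    for r, c in chosen:
        pos = (c * px, r * px)
        pref = float(omap.orientations[r, c])
        cls = "narrow" if l2[r, c] >= config.class_lhi_threshold else "broad"
        angle = float(rng.uniform(0.0, 180.0))
        nb_ori = omap.track_orientations(pos, angle, dists)
        lhi1 = analysis.lhi_from_sites(dists, nb_ori)

        # orientation tuning at full contrast
        tuning = np.empty(batt_oris.size)
        for i, o in enumerate(batt_oris):
            c_site = tables.grating_response(cls, o - pref, full_c)
            c_nb = [tables.grating_response(cls, o - t, full_c) for t in nb_ori]
            tuning[i] = _en_from_tables(tables, cls, c_site, c_nb, wts,
                                        tables.cu_grating[full_c])
        tun_fit = analysis.fit_von_mises(batt_oris, tuning)
        pref_batt_idx = int(np.argmax(tuning))
        pref_batt = float(batt_oris[pref_batt_idx])

        # contrast response at the preferred battery orientation
        cr = np.empty(len(BATTERY_CONTRASTS))
        for j in range(len(BATTERY_CONTRASTS)):
            c_site = tables.grating_response(cls, pref_batt - pref, j)
            c_nb = [tables.grating_response(cls, pref_batt - t, j) for t in nb_ori]
            cr[j] = _en_from_tables(tables, cls, c_site, c_nb, wts,
                                    tables.cu_grating[j])
        cr_fit = analysis.fit_naka_rushton(np.asarray(BATTERY_CONTRASTS), cr)
        nli = analysis.nonlinearity_index(cr_fit) if cr_fit.well_fit else np.nan

        # pair plaids containing the preferred battery orientation
        plaid_resp = np.empty(batt_oris.size)
        for j in range(batt_oris.size):
            d1 = pref_batt - pref
            c_site = tables.plaid_response(cls, d1, j)
            c_nb = [tables.plaid_response(cls, pref_batt - t, j) for t in nb_ori]
            plaid_resp[j] = _en_from_tables(tables, cls, c_site, c_nb, wts,
                                            tables.cu_plaid[j])
        # reorder so entry k pairs the preferred with orientation pref+k*22.5
        half_idx = len(BATTERY_CONTRASTS) - 2   # contrast 0.5 in the battery
        c_site = tables.grating_response(cls, pref_batt - pref, half_idx)
        c_nb = [tables.grating_response(cls, pref_batt - t, half_idx)
                for t in nb_ori]
        r_half = _en_from_tables(tables, cls, c_site, c_nb, wts,
                                 tables.cu_grating[half_idx])
        orth_j = batt_oris.size // 2    # separation 90 deg
        si_orth = analysis.suppression_index(plaid_resp[orth_j], r_half)
        msi = analysis.mean_si(plaid_resp, r_half)

        # octotropic plaid, normalized to the unit's maximum grating response
        c_site = tables.octo_response(cls, -pref)
        c_nb = [tables.octo_response(cls, -t) for t in nb_ori]
        octo = _en_from_tables(tables, cls, c_site, c_nb, wts, tables.cu_octo)
        octo_norm = octo / tuning.max()

        records.append({
            "row": r, "col": c, "class": cls, "pref": pref,
            "lhi_1d": lhi1, "lhi_2d": float(l2[r, c]),
            "hwhh": tun_fit.hwhh if tun_fit.well_fit else np.nan,
            "circular_variance": tun_fit.circular_variance,
            "semi_saturation": (cr_fit.semi_saturation if cr_fit.well_fit
                                else np.nan),
            "nli": nli, "si_orthogonal": si_orth, "mean_si": msi,
            "octo_norm": octo_norm,
            "cr_quality": cr_fit.fit_quality, "vm_quality": tun_fit.fit_quality,
        })

    frame = pd.DataFrame.from_records(records)
    corr = {}
    pairs = {
        "lhi_vs_hwhh": ("lhi_1d", "hwhh"),
        "lhi_vs_si": ("lhi_1d", "si_orthogonal"),
        "lhi_vs_mean_si": ("lhi_1d", "mean_si"),
        "lhi_vs_semi_saturation": ("lhi_1d", "semi_saturation"),
        "lhi_vs_nli": ("lhi_1d", "nli"),
        "lhi_vs_octo": ("lhi_1d", "octo_norm"),
        "hwhh_vs_mean_si": ("hwhh", "mean_si"),
        "hwhh_vs_octo": ("hwhh", "octo_norm"),
    }
    from scipy import stats as _stats
    for name, (a, b) in pairs.items():
        res = analysis.correlate(frame[a], frame[b])
        ok = np.isfinite(frame[a]) & np.isfinite(frame[b])
        rho = float(_stats.spearmanr(frame[a][ok], frame[b][ok]).statistic)
        corr[name] = {"pearson_r": res.r, "p": res.p, "spearman": rho,
                      "n": res.n}

    properties = {
        "lhi_vs_hwhh_negative": corr["lhi_vs_hwhh"]["pearson_r"] < 0,
        "lhi_vs_si_positive": corr["lhi_vs_si"]["pearson_r"] > 0,
        "lhi_vs_semi_saturation_negative":
            corr["lhi_vs_semi_saturation"]["pearson_r"] < 0,
        "lhi_vs_nli_positive": corr["lhi_vs_nli"]["pearson_r"] > 0,
        "lhi_vs_octo_negative": corr["lhi_vs_octo"]["pearson_r"] < 0,
        "hwhh_vs_mean_si_negative": corr["hwhh_vs_mean_si"]["pearson_r"] < 0,
        "octo_spearman_lhi_negative": corr["lhi_vs_octo"]["spearman"] < 0,
        "octo_spearman_inv_width_negative":
            corr["hwhh_vs_octo"]["spearman"] > 0,   # wider tuning, larger octo
    }
    report = {"experiment": "full_population", "config_hash": config.config_hash,
              "n_sites": int(len(frame)), "correlations": corr,
              "properties": properties}
    _check(report, config, "full_population")
    _write_report(report, config, "full_population", {"sites": frame})
    report["sites"] = frame
    return report
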