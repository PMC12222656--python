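"""Synthetic radiographs, growth series, and environmental series with known truth.

Massive corals lay down one low-density (boreal winter) plus one high-density
(boreal summer) band per year.  This module renders that banded structure
into synthetic slab radiographs through a known linear luminance-density
map, with a multiplicative beam-intensity gradient and additive grayscale
noise, and generates the matching annual growth series (AR(1) anomalies,
linear trends, step shifts) and environmental forcing series (seasonal SST
with a warming trend, seasonal precipitation, river discharge, a logistic
population curve).  Every generator is deterministic for a fixed seed, and
every rendered scene returns its ground truth so the downstream densitometry,
banding, chronology, and regime-detection stages can be tested without any
external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .densitometry import CalibrationCurve, CoreImage, WedgeStandard

__all__ = [
    "GrowthTruth",
    "SceneSpec",
    "default_true_curve",
    "gen_growth_series",
    "gen_env_monthly",
    "gen_population_annual",
    "gen_core_image",
    "gen_wedge_image",
    "gen_background_plate",
    "gen_calibration_scene",
    "CalibrationScene",
]


@dataclass
class GrowthTruth:
    """Ground-truth annual growth for one synthetic core.

    ``extensions`` (cm yr-1) and ``densities`` (g cm-3) are per-year values;
    the per-year calcification truth is their product.  ``shift_years`` are
    the calendar years at which injected step changes begin.
    """

    first_year: int
    extensions: np.ndarray
    densities: np.ndarray
    shift_years: list = field(default_factory=list)
    ar1_coef: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.extensions = np.asarray(self.extensions, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.extensions.shape != self.densities.shape:
            raise ValueError("extensions and densities must have equal length")
        if np.any(self.extensions <= 0):
            raise ValueError("extensions must be positive")
        if np.any(self.densities <= 0):
            raise ValueError("densities must be positive")
        if not -1 < self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in (-1, 1)")
        last = self.first_year + len(self.extensions) - 1
        for y in self.shift_years:
            if not self.first_year <= y <= last:
                raise ValueError(f"shift year {y} outside record span "
                                 f"{self.first_year}-{last}")

    @property
    def n_years(self) -> int:
        return len(self.extensions)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.n_years)

    @property
    def calcification(self) -> np.ndarray:
        return self.extensions * self.densities

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "extension_cm": self.extensions,
                             "density_g_cm3": self.densities,
                             "calcification_g_cm2": self.calcification})


@dataclass
class SceneSpec:
    """Imaging parameters for rendering a synthetic radiograph."""

    pixel_size: float = 0.005          # cm per pixel (50 um)
    slab_thickness: float = 0.6        # cm, slabs milled to even 6 mm
    beam_gradient_amp: float = 0.0     # multiplicative vignetting amplitude
    grayscale_noise_sd: float = 0.0    # additive noise, grayscale units
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.slab_thickness <= 0:
            raise ValueError("slab_thickness must be positive")
        if not 0 <= self.beam_gradient_amp < 1:
            raise ValueError("beam_gradient_amp must lie in [0, 1)")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def default_true_curve(bit_depth: int = 16) -> CalibrationCurve:
    """The generating luminance->density map used by the synthetic scenes.

    Denser material attenuates more, so luminance decreases with density.
    The 16-bit default puts air near 62000 counts and maps the full count
    range onto densities 0 to ~3.2 g cm-3 (slope -5.2e-5 g cm-3 per count),
    so coral (~2.0) and the aragonite standard (2.93) both render in range;
    the 8-bit variant scales the same geometry into 0-255.
    """
    if bit_depth == 16:
        slope = -5.2e-5
        air = 62000.0
    elif bit_depth == 8:
        slope = -1.31e-2
        air = 245.0
    else:
        raise ValueError("bit_depth must be 8 or 16")
    return CalibrationCurve(slope=slope, intercept=-slope * air,
                            density_range=(0.0, 3.0))


# ---------------------------------------------------------------------------
# growth and environmental series
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, coef: float, marginal_sd: float) -> np.ndarray:
    """AR(1) anomaly series with the given stationary (marginal) SD."""
    if marginal_sd == 0:
        return np.zeros(n)
    innov_sd = marginal_sd * math.sqrt(1.0 - coef**2)
    out = np.empty(n)
    out[0] = rng.normal(0.0, marginal_sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        out[t] = coef * out[t - 1] + eps[t - 1]
    return out


def gen_growth_series(n_years: int, base_extension: float, base_density: float,
                      trend_extension: float = 0.0, shifts=(),
                      ar1_coef: float = 0.0, noise_sd: float = 0.0,
                      seed: int | None = None, first_year: int = 1951,
                      trend_density: float = 0.0,
                      density_noise_sd: float | None = None,
                      min_extension: float = 0.02,
                      min_density: float = 0.2) -> GrowthTruth:
    """Generate an annual growth series with trend, step shifts, and AR(1) noise.

    Parameters
    ----------
    n_years
        Record length (>= 2).
    base_extension, base_density
        Long-term levels in cm yr-1 and g cm-3 (0.45 cm yr-1 and ~2.0 g cm-3
        are typical for slow-growing massive Caribbean corals).
    trend_extension, trend_density
        Linear drift per year added to the respective series.
    shifts
        Iterable of ``(year_index, delta)`` step changes applied to the
        extension series; ``year_index`` is 1-based within the record, and the
        step persists from that year onward.
    ar1_coef, noise_sd
        Lag-1 autocorrelation and *marginal* SD of the additive anomaly.
        The anomaly is additive (not multiplicative) so positivity is
        enforced by a floor, not by the noise model.
    density_noise_sd
        Marginal SD for the density anomaly; defaults to ``noise_sd / 2``.
    """
    if n_years < 2:
        raise ValueError("n_years must be >= 2")
    if base_extension <= 0:
        raise ValueError("base_extension must be positive")
    if base_density <= 0:
        raise ValueError("base_density must be positive")
    if not -1 < ar1_coef < 1:
        raise ValueError("ar1_coef must lie in (-1, 1)")

    rng = np.random.default_rng(seed)
    t = np.arange(n_years, dtype=float)

    ext = base_extension + trend_extension * t
    shift_years = []
    for pos, delta in shifts:
        pos = int(pos)
        if not 1 <= pos <= n_years:
            raise ValueError(f"shift index {pos} outside 1..{n_years}")
        ext[pos - 1:] += delta
        shift_years.append(first_year + pos - 1)
    ext = ext + _ar1(rng, n_years, ar1_coef, noise_sd)

    dsd = noise_sd / 2.0 if density_noise_sd is None else density_noise_sd
    dens = base_density + trend_density * t + _ar1(rng, n_years, ar1_coef, dsd)

    return GrowthTruth(first_year=first_year,
                       extensions=np.maximum(ext, min_extension),
                       densities=np.maximum(dens, min_density),
                       shift_years=shift_years, ar1_coef=ar1_coef,
                       noise_sd=noise_sd)


_ENV_KINDS = {"sst", "precipitation", "discharge"}


def gen_env_monthly(kind: str, start_year: int, end_year: int, mean_level: float,
                    seasonal_amp: float = 0.0, linear_trend: float = 0.0,
                    noise_sd: float = 0.0, seed: int | None = None,
                    peak_month: int = 9) -> pd.Series:
    """Generate a monthly environmental series (12 values per calendar year).

    ``value(y, m) = mean + amp * cos(2*pi*(m - peak_month)/12)
    + trend * (y - start + (m - 0.5)/12) + noise``.  Precipitation and
    discharge are clipped at zero (no negative rainfall or flow).  The index
    is a month-start DatetimeIndex.
    """
    if kind not in _ENV_KINDS:
        raise ValueError(f"unknown kind {kind!r}; expected one of {sorted(_ENV_KINDS)}")
    if end_year < start_year:
        raise ValueError("end_year must be >= start_year")
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, end_year + 1)
    months = np.arange(1, 13)
    yy, mm = np.meshgrid(years, months, indexing="ij")
    frac = yy - start_year + (mm - 0.5) / 12.0
    values = (mean_level
              + seasonal_amp * np.cos(2 * np.pi * (mm - peak_month) / 12.0)
              + linear_trend * frac)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = values.ravel()
    if kind in ("precipitation", "discharge"):
        values = np.maximum(values, 0.0)
    index = pd.date_range(start=f"{start_year}-01-01", periods=values.size, freq="MS")
    return pd.Series(values, index=index, name=kind)


def gen_population_annual(start_year: int, end_year: int, carrying_capacity: float,
                          growth_rate: float = 0.08, midpoint_year: int = 1975,
                          initial_fraction: float | None = None,
                          noise_sd: float = 0.0, seed: int | None = None) -> pd.Series:
    """Logistic human-population curve, one value per calendar year.

    ``P(y) = K / (1 + exp(-r * (y - midpoint)))`` plus optional Gaussian
    noise, floored at zero.  ``initial_fraction`` is accepted for symmetry
    with other generators but the midpoint parameterization is primary.
    """
    if end_year < start_year:
        raise ValueError("end_year must be >= start_year")
    if carrying_capacity <= 0:
        raise ValueError("carrying_capacity must be positive")
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, end_year + 1)
    pop = carrying_capacity / (1.0 + np.exp(-growth_rate * (years - midpoint_year)))
    if noise_sd > 0:
        pop = pop + rng.normal(0.0, noise_sd, size=pop.size)
    return pd.Series(np.maximum(pop, 0.0), index=years, name="population")


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def _gradient_field(shape: tuple[int, int], amp: float) -> np.ndarray:
    """Radial vignetting gain in [1 - amp, 1], brightest at field center."""
    h, w = shape
    if amp == 0:
        return np.ones(shape)
    y = np.linspace(-1.0, 1.0, h)[:, None] if h > 1 else np.zeros((1, 1))
    x = np.linspace(-1.0, 1.0, w)[None, :] if w > 1 else np.zeros((1, 1))
    rho2 = (y**2 + x**2) / 2.0
    return 1.0 - amp * rho2


def _finalize(lum: np.ndarray, scene: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Apply gradient, noise, clipping, and quantization to clean luminance."""
    lum = lum * _gradient_field(lum.shape, scene.beam_gradient_amp)
    if scene.grayscale_noise_sd > 0:
        lum = lum + rng.normal(0.0, scene.grayscale_noise_sd, size=lum.shape)
    hi = 2**scene.bit_depth - 1
    return np.clip(np.rint(lum), 0, hi)


def band_layout(truth: GrowthTruth, pixel_size: float,
                ld_fraction: float = 0.45,
                density_contrast: float = 0.4) -> pd.DataFrame:
    """Per-band ground truth for rendering: positions (px) and densities.

    Each year is split into one low-density band (``ld_fraction`` of the
    annual extension, formed Dec-May) followed by one high-density band
    (formed Jun-Nov).  Band densities are placed symmetrically about the
    annual mean so that the length-weighted couplet mean equals the annual
    density truth exactly, with total LD-to-HD contrast ``density_contrast``.

    Columns: band_index, band_type (LD/HD), year, start_px, end_px,
    true_density.  Bands are ordered oldest to youngest.
    """
    if not 0 < ld_fraction < 1:
        raise ValueError("ld_fraction must lie in (0, 1)")
    rows = []
    pos = 0.0
    for i, (year, ext, dens) in enumerate(zip(truth.years, truth.extensions,
                                              truth.densities)):
        len_ld = ext * ld_fraction
        len_hd = ext - len_ld
        # weighted mean of (d_ld, d_hd) with weights (len_ld, len_hd) == dens
        d_ld = dens - density_contrast * (len_hd / ext)
        d_hd = dens + density_contrast * (len_ld / ext)
        if d_ld <= 0:
            raise ValueError(f"density contrast too large: LD density <= 0 in year {year}")
        for btype, blen, bdens in (("LD", len_ld, d_ld), ("HD", len_hd, d_hd)):
            px = blen / pixel_size
            if px < 2:
                raise ValueError(
                    f"{btype} band in year {year} is {px:.2f} px at "
                    f"pixel_size={pixel_size}; bands must be >= 2 px to be resolvable"
                )
            rows.append({"band_index": len(rows), "band_type": btype, "year": year,
                         "start_px": pos, "end_px": pos + px, "true_density": bdens})
            pos += px
    return pd.DataFrame(rows)


def gen_core_image(truth: GrowthTruth, curve: CalibrationCurve, scene: SceneSpec,
                   width_px: int = 48, ld_fraction: float = 0.45,
                   density_contrast: float = 0.4,
                   rotation_deg: float = 0.0) -> tuple[CoreImage, pd.DataFrame]:
    """Render a banded coral-slab radiograph and return its band ground truth.

    Density along the growth axis is piecewise-constant per band; pixel
    luminance is the inverse calibration applied to the local density,
    multiplied by the beam-gradient field, plus grayscale noise, clipped and
    quantized to the bit depth.  By default the growth axis is the image's
    vertical (row) axis so bands are horizontal; ``rotation_deg`` tilts the
    growth axis by that angle toward the column axis for transect-geometry
    tests.  Band boundaries are returned at exact (fractional) pixel
    positions along the growth axis.
    """
    layout = band_layout(truth, scene.pixel_size, ld_fraction, density_contrast)
    edges = np.concatenate([[0.0], layout["end_px"].to_numpy()])
    band_density = layout["true_density"].to_numpy()
    total_px = edges[-1]

    theta = math.radians(rotation_deg)
    if abs(rotation_deg) < 1e-12:
        # anti-aliased rendering: pixel r (center at r, extent [r-0.5, r+0.5])
        # carries the mean density over its extent, so band edges land at
        # their exact fractional positions in pixel-center coordinates
        height = int(math.ceil(total_px))
        cum = np.concatenate([[0.0], np.cumsum(band_density * np.diff(edges))])

        def integral(u):
            u = np.clip(u, 0.0, total_px)  # clamp: flat continuation at ends
            base = np.interp(u, edges, cum)
            return base

        r = np.arange(height, dtype=float)
        lo = np.maximum(r - 0.5, 0.0)
        hi = np.minimum(r + 0.5, total_px)
        mean_density = (integral(hi) - integral(lo)) / np.maximum(hi - lo, 1e-12)
        density_img = np.repeat(mean_density[:, None], width_px, axis=1)
    else:
        height = int(math.ceil(total_px * math.cos(theta) + width_px * abs(math.sin(theta)))) + 1
        rr, cc = np.meshgrid(np.arange(height, dtype=float),
                             np.arange(width_px, dtype=float), indexing="ij")
        u = rr * math.cos(theta) + cc * math.sin(theta)
        idx = np.clip(np.searchsorted(edges, u, side="right") - 1, 0,
                      band_density.size - 1)
        density_img = band_density[idx]

    rng = np.random.default_rng(scene.seed)
    lum = curve.luminance(density_img)
    pixels = _finalize(lum, scene, rng)
    meta = {"synthetic": True, "n_years": truth.n_years,
            "first_year": int(truth.first_year), "rotation_deg": rotation_deg,
            "slab_thickness_cm": scene.slab_thickness}
    return CoreImage(pixels, bit_depth=scene.bit_depth,
                     pixel_size=scene.pixel_size, metadata=meta), layout


def gen_wedge_image(curve: CalibrationCurve, wedge_spec: WedgeStandard,
                    scene: SceneSpec, width_px: int = 32,
                    air_margin_px: int = 40) -> CoreImage:
    """Render the calibration wedge (thin end at column 0) plus an air margin.

    Equivalent density increases linearly along the wedge axis (columns), so
    clean luminance varies monotonically along a wedge transect.  The
    ``air_margin_px`` rightmost columns contain background only (density 0)
    and serve as the air-anchor region.
    """
    # pixel-center convention: the thin end (zero thickness) sits at the
    # center of column 0, so column c carries rho(c * pixel_size)
    n_wedge = int(round(wedge_spec.length / scene.pixel_size))
    cols = np.arange(n_wedge) * scene.pixel_size
    rho = np.concatenate([wedge_spec.equivalent_density(cols),
                          np.zeros(air_margin_px)])
    lum = curve.luminance(rho)[None, :].repeat(width_px, axis=0)
    rng = np.random.default_rng(scene.seed)
    pixels = _finalize(lum, scene, rng)
    meta = {"synthetic": True, "object": "wedge",
            "wedge_length_cm": wedge_spec.length,
            "wedge_density_g_cm3": wedge_spec.material_density,
            "air_margin_px": air_margin_px}
    return CoreImage(pixels, bit_depth=scene.bit_depth,
                     pixel_size=scene.pixel_size, metadata=meta)


def gen_background_plate(scene: SceneSpec, shape: tuple[int, int],
                         base_luminance: float | None = None) -> CoreImage:
    """Blank aluminium-plate exposure carrying only the beam gradient + noise."""
    if base_luminance is None:
        base_luminance = 0.85 * (2**scene.bit_depth - 1)
    rng = np.random.default_rng(scene.seed)
    lum = np.full(shape, float(base_luminance))
    pixels = _finalize(lum, scene, rng)
    return CoreImage(pixels, bit_depth=scene.bit_depth,
                     pixel_size=scene.pixel_size,
                     metadata={"synthetic": True, "object": "plate"})


@dataclass
class CalibrationScene:
    """A complete synthetic densitometry calibration setup."""

    wedge_image: CoreImage
    transect: list                       # polyline along the wedge, thin end first
    transect_start_offset_cm: float      # distance from the zero-thickness tip
    air_region: tuple                    # (x0, y0, x1, y1) over background
    standard_image: CoreImage            # uniform aragonite validation slab
    standard_density: float              # g cm-3
    true_curve: CalibrationCurve
    wedge_spec: WedgeStandard


def gen_calibration_scene(seed: int = 1, noise_sd: float = 1.0,
                          pixel_size: float = 0.01,
                          standard_density: float = 2.93,
                          bit_depth: int = 16) -> CalibrationScene:
    """Wedge + air + aragonite-standard scene from one known linear map.

    This is the canonical self-check of the densitometry chain: fit the
    calibration from the wedge transect and air anchor, then predict the
    density of the rendered aragonite standard (2.93 g cm-3 by default).
    """
    curve = default_true_curve(bit_depth)
    wedge_spec = WedgeStandard()
    scene = SceneSpec(pixel_size=pixel_size, grayscale_noise_sd=noise_sd,
                      bit_depth=bit_depth, seed=seed)
    wedge_img = gen_wedge_image(curve, wedge_spec, scene, width_px=32,
                                air_margin_px=40)
    n_wedge = int(round(wedge_spec.length / pixel_size))
    h, w = wedge_img.shape
    transect = [(2.0, h / 2.0), (n_wedge - 3.0, h / 2.0)]
    air_region = (n_wedge + 5, 2, w - 3, h - 3)

    rng_std = np.random.default_rng(seed + 1)
    std_lum = np.full((64, 64), float(curve.luminance(standard_density)))
    if noise_sd > 0:
        std_lum = std_lum + rng_std.normal(0.0, noise_sd, size=std_lum.shape)
    std_pixels = np.clip(np.rint(std_lum), 0, 2**bit_depth - 1)
    standard = CoreImage(std_pixels, bit_depth=bit_depth, pixel_size=pixel_size,
                         metadata={"synthetic": True, "object": "aragonite_standard",
                                   "true_density": standard_density})
    return CalibrationScene(wedge_image=wedge_img, transect=transect,
                            transect_start_offset_cm=transect[0][0] * pixel_size,
                            air_region=air_region, standard_image=standard,
                            standard_density=standard_density, true_curve=curve,
                            wedge_spec=wedge_spec)
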