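"""X-ray densitometry: luminance-to-density calibration and transect profiles.

Coral slabs of even thickness are X-rayed together with an aluminium
calibration wedge and blank aluminium plates.  Grayscale luminance in the
radiograph varies (approximately linearly, at fixed slab thickness and
exposure) with the areal mass the beam traverses, so a wedge of known
material density and linearly increasing thickness provides a set of
(luminance, equivalent-density) pairs from which a linear calibration
``density = slope * luminance + intercept`` is fitted.  Air gives the
zero-density anchor; a slab of pure aragonite of known density serves as an
independent validation standard.

Blank-plate exposures are used for flat-field correction: beam-intensity
variation across the field of view is multiplicative in exposure, so the
image is divided by the normalized plate.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "CoreImage",
    "WedgeStandard",
    "CalibrationCurve",
    "DensityProfile",
    "ValidationReport",
    "flat_field_correct",
    "fit_wedge_calibration",
    "validate_calibration",
    "extract_transect",
]


@dataclass
class CoreImage:
    """A calibrated 2-D grayscale radiograph.

    Parameters
    ----------
    pixels
        2-D array of grayscale values in ``[0, 2**bit_depth - 1]``.
    bit_depth
        Bits per pixel of the acquisition (8 or 16 for the supported formats).
    pixel_size
        Physical size of one pixel in cm.
    metadata
        Free-form slab metadata (core id, site, depth in m, collection date,
        slab thickness in cm, exposure settings).
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size: float = 0.005
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        hi = 2**self.bit_depth - 1
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > hi):
            raise ValueError(
                f"pixel values outside [0, {hi}] for bit_depth={self.bit_depth}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    # ------------------------------------------------------------------ I/O
    def to_file(self, path) -> None:
        """Write as 16-bit grayscale TIFF (default) or 8-bit PNG by suffix."""
        path = str(path)
        arr = np.asarray(np.rint(self.pixels), dtype=np.uint16 if self.bit_depth > 8 else np.uint8)
        if path.lower().endswith((".tif", ".tiff")):
            import tifffile

            tifffile.imwrite(path, arr)
        elif path.lower().endswith(".png"):
            from PIL import Image

            Image.fromarray(arr).save(path)
        else:
            raise ValueError(f"unsupported image format: {path}")

    @classmethod
    def from_file(cls, path, pixel_size: float, metadata: dict | None = None) -> "CoreImage":
        path = str(path)
        if path.lower().endswith((".tif", ".tiff")):
            import tifffile

            arr = tifffile.imread(path)
        else:
            from PIL import Image

            arr = np.asarray(Image.open(path))
        if arr.ndim == 3:  # collapse trivially replicated channels
            arr = arr[..., 0]
        bit_depth = 16 if arr.dtype.itemsize > 1 else 8
        return cls(arr.astype(float), bit_depth=bit_depth, pixel_size=pixel_size,
                   metadata=metadata or {})


@dataclass
class WedgeStandard:
    """Aluminium calibration wedge of known density and linear taper.

    Defaults follow a 9.9 cm wedge with a 0.138 degree slope milled from
    aluminium (2.71 g cm-3), imaged next to coral slabs of 0.6 cm thickness.
    The wedge's local thickness ``t(s) = s * tan(slope)`` at distance ``s``
    from the thin end is converted to the density a coral slab of reference
    thickness would need to present the same areal mass:

        rho_eq(s) = material_density * t(s) / slab_thickness_ref
    """

    length: float = 9.9                 # cm
    slope_angle: float = 0.138          # degrees
    material_density: float = 2.71      # g cm-3
    slab_thickness_ref: float = 0.6     # cm

    def __post_init__(self) -> None:
        for name in ("length", "slope_angle", "material_density", "slab_thickness_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def equivalent_density(self, s) -> np.ndarray:
        """Slab-equivalent density (g cm-3) at distance ``s`` (cm) from the thin end."""
        s = np.asarray(s, dtype=float)
        thickness = s * math.tan(math.radians(self.slope_angle))
        return self.material_density * thickness / self.slab_thickness_ref

    @property
    def max_equivalent_density(self) -> float:
        return float(self.equivalent_density(self.length))


@dataclass
class CalibrationCurve:
    """Linear luminance -> bulk density map: ``density = slope * L + intercept``."""

    slope: float                        # g cm-3 per grayscale unit
    intercept: float                    # g cm-3
    fit_r2: float = 1.0
    n_points: int = 2
    density_range: tuple[float, float] = (0.0, 3.0)
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")

    def density(self, luminance) -> np.ndarray:
        """Map luminance to bulk density (g cm-3)."""
        return self.slope * np.asarray(luminance, dtype=float) + self.intercept

    # alias so a curve can be used like a function
    __call__ = density

    def luminance(self, density) -> np.ndarray:
        """Inverse map: luminance at which the curve predicts ``density``."""
        return (np.asarray(density, dtype=float) - self.intercept) / self.slope

    @classmethod
    def from_points(cls, luminances, densities, weights=None) -> "CalibrationCurve":
        """Weighted least-squares line through (luminance, density) pairs."""
        L = np.asarray(luminances, dtype=float)
        d = np.asarray(densities, dtype=float)
        if L.size < 2:
            raise ValueError("need at least 2 calibration points")
        w = np.ones_like(L) if weights is None else np.asarray(weights, dtype=float)
        sw = np.sqrt(w)
        A = np.column_stack([L * sw, sw])
        coef, *_ = np.linalg.lstsq(A, d * sw, rcond=None)
        slope, intercept = float(coef[0]), float(coef[1])
        pred = slope * L + intercept
        dbar = np.average(d, weights=w)
        ss_res = float(np.sum(w * (d - pred) ** 2))
        ss_tot = float(np.sum(w * (d - dbar) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        return cls(slope=slope, intercept=intercept, fit_r2=r2, n_points=int(L.size),
                   density_range=(float(d.min()), float(d.max())))

    # ------------------------------------------------------------------ I/O
    def to_json(self, path, provenance: dict | None = None) -> None:
        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "fit_r2": self.fit_r2,
            "n_points": self.n_points,
            "density_range": list(self.density_range),
            "warnings": list(self.warnings),
            "provenance": provenance or {},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(slope=payload["slope"], intercept=payload["intercept"],
                   fit_r2=payload.get("fit_r2", 1.0), n_points=payload.get("n_points", 2),
                   density_range=tuple(payload.get("density_range", (0.0, 3.0))),
                   warnings=payload.get("warnings", []))


@dataclass
class DensityProfile:
    """Bulk density sampled along a transect perpendicular to growth bands."""

    positions: np.ndarray               # cm along transect, strictly increasing
    densities: np.ndarray               # g cm-3
    polyline: list = field(default_factory=list)   # pixel-coordinate vertices
    averaging_width: int = 1            # pixels across the transect

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.positions.shape != self.densities.shape:
            raise ValueError("positions and densities must have the same length")
        if self.positions.size >= 2 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.densities)):
            raise ValueError("densities must be finite")

    def __len__(self) -> int:
        return self.positions.size

    @property
    def length(self) -> float:
        """Transect length in cm."""
        return float(self.positions[-1] - self.positions[0]) if len(self) else 0.0

    @property
    def step(self) -> float:
        """Median sampling step in cm."""
        return float(np.median(np.diff(self.positions)))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"position_cm": self.positions,
                      "density_g_cm3": self.densities}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DensityProfile":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["position_cm"].to_numpy(), df["density_g_cm3"].to_numpy())


@dataclass
class ValidationReport:
    predicted_density: float
    expected_density: float
    residual: float
    tolerance: float
    passed: bool


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def flat_field_correct(image: CoreImage, plate: CoreImage,
                       smooth_sigma: float = 3.0) -> CoreImage:
    """Remove multiplicative beam-intensity variation using a blank-plate exposure.

    The plate records the spatial pattern of the beam; dividing by the plate
    normalized to its own mean removes the pattern while preserving the
    image's overall luminance scale.  The plate is Gaussian-smoothed first so
    plate shot noise is not imprinted on the corrected image.

    Raises ``ValueError`` on shape/bit-depth mismatch or if the smoothed
    plate contains zeros (increase ``smooth_sigma`` or re-expose the plate).
    """
    if image.shape != plate.shape:
        raise ValueError(f"image shape {image.shape} != plate shape {plate.shape}")
    if image.bit_depth != plate.bit_depth:
        raise ValueError("image and plate bit depths differ")
    p = np.asarray(plate.pixels, dtype=float)
    if smooth_sigma > 0:
        p = ndimage.gaussian_filter(p, smooth_sigma, mode="nearest")
    if np.any(p <= 0):
        raise ValueError(
            "plate contains non-positive pixels after smoothing; "
            "increase smooth_sigma or use a cleaner plate exposure"
        )
    gain = p / p.mean()
    corrected = np.asarray(image.pixels, dtype=float) / gain
    corrected = np.clip(corrected, 0, image.max_value)
    return CoreImage(corrected, bit_depth=image.bit_depth, pixel_size=image.pixel_size,
                     metadata={**image.metadata, "flat_field_corrected": True})


def _sample_luminance(image: CoreImage, polyline, width: int,
                      step_px: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Luminance along a polyline, width-averaged perpendicular to it.

    Sub-pixel sampling by bilinear interpolation at ``step_px`` steps;
    returns (arclength positions in px, mean luminance).  Pixel coordinates
    are ``(x, y)`` = (column, row), 0-based at pixel centers.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("averaging width must be an odd positive pixel count")
    verts = np.asarray(polyline, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 2 or verts.shape[1] != 2:
        raise ValueError("polyline must be a list of >= 2 (x, y) vertices")

    xs, ys, arcs = [], [], []
    total = 0.0
    for (x0, y0), (x1, y1) in zip(verts[:-1], verts[1:]):
        seg_len = math.hypot(x1 - x0, y1 - y0)
        if seg_len == 0:
            continue
        n = max(2, int(round(seg_len / step_px)) + 1)
        t = np.linspace(0.0, 1.0, n)
        if total > 0:  # avoid duplicating the shared vertex
            t = t[1:]
        sx = x0 + t * (x1 - x0)
        sy = y0 + t * (y1 - y0)
        xs.append(sx)
        ys.append(sy)
        arcs.append(total + t * seg_len)
        total += seg_len
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    arc = np.concatenate(arcs)

    # perpendicular unit vector per sample (from local tangent)
    dx = np.gradient(x)
    dy = np.gradient(y)
    norm = np.hypot(dx, dy)
    norm[norm == 0] = 1.0
    px, py = -dy / norm, dx / norm

    half = (width - 1) // 2
    offsets = np.arange(-half, half + 1)
    sample_x = x[None, :] + offsets[:, None] * px[None, :]
    sample_y = y[None, :] + offsets[:, None] * py[None, :]

    h, w = image.shape
    if (sample_x.min() < -0.5 or sample_x.max() > w - 0.5
            or sample_y.min() < -0.5 or sample_y.max() > h - 0.5):
        raise ValueError("transect (including averaging width) exits the image")

    # map_coordinates expects (row, col) order
    vals = ndimage.map_coordinates(np.asarray(image.pixels, dtype=float),
                                   [sample_y, sample_x], order=1, mode="nearest")
    return arc, vals.mean(axis=0)


def fit_wedge_calibration(wedge_image: CoreImage, wedge_spec: WedgeStandard,
                          transect, air_region, width: int = 11,
                          step_px: float = 0.25,
                          air_anchor_weight: float | None = None,
                          start_offset_cm: float = 0.0,
                          monotonic_tolerance: float = 0.05) -> CalibrationCurve:
    """Fit the linear luminance->density calibration from a wedge radiograph.

    ``transect`` is a polyline (pixel coordinates) running along the wedge
    *starting at the thin end*, so that distance along the transect maps to
    wedge thickness and hence to slab-equivalent density; if the transect
    starts ``start_offset_cm`` past the zero-thickness tip, say so, or the
    wedge line and the air anchor disagree and tilt the fit.  ``air_region``
    is a rectangle ``(x0, y0, x1, y1)`` over background (no object); its
    mean luminance anchors the zero-density end of the line with weight
    ``n_samples / 10`` unless overridden.
    """
    arc_px, lum = _sample_luminance(wedge_image, transect, width, step_px)
    if lum.size < 10:
        raise ValueError(f"only {lum.size} usable wedge samples (need >= 10)")
    rho = wedge_spec.equivalent_density(arc_px * wedge_image.pixel_size
                                        + start_offset_cm)

    x0, y0, x1, y1 = (int(round(v)) for v in air_region)
    air_patch = np.asarray(wedge_image.pixels, dtype=float)[min(y0, y1):max(y0, y1) + 1,
                                                            min(x0, x1):max(x0, x1) + 1]
    if air_patch.size == 0:
        raise ValueError("air_region is empty")
    air_lum = float(air_patch.mean())

    # luminance should change monotonically with wedge thickness; flag otherwise
    sm = ndimage.uniform_filter1d(lum, size=max(3, lum.size // 50))
    steps = np.diff(sm)
    dominant = np.sign(np.median(steps)) or 1.0
    frac_against = float(np.mean(steps * dominant < 0))
    curve_warnings = []
    if frac_against > monotonic_tolerance:
        msg = (f"wedge luminance not monotonic: {frac_against:.1%} of steps "
               "run against the dominant direction")
        curve_warnings.append(msg)
        warnings.warn(msg, stacklevel=2)

    w_anchor = lum.size / 10.0 if air_anchor_weight is None else float(air_anchor_weight)
    L = np.append(lum, air_lum)
    d = np.append(rho, 0.0)
    w = np.append(np.ones_like(lum), w_anchor)
    curve = CalibrationCurve.from_points(L, d, weights=w)
    curve.warnings = curve_warnings
    curve.density_range = (0.0, float(rho.max()))
    return curve


def validate_calibration(curve: CalibrationCurve, standard_luminance: float,
                         expected_density: float,
                         tolerance: float = 0.05) -> ValidationReport:
    """Check the calibration against a standard of known density.

    The canonical standards are air (expected density 0) and a slab of pure
    aragonite of known density (2.93 g cm-3 for a *Tridacna maxima* shell
    slab of coral-equivalent thickness).
    """
    predicted = float(curve.density(standard_luminance))
    residual = predicted - expected_density
    return ValidationReport(predicted_density=predicted,
                            expected_density=float(expected_density),
                            residual=residual, tolerance=float(tolerance),
                            passed=abs(residual) <= tolerance)


def extract_transect(image: CoreImage, polyline, width: int,
                     curve: CalibrationCurve, step_px: float = 0.25) -> DensityProfile:
    """Sample a density profile along a transect drawn perpendicular to bands.

    Luminance is sampled at 0.25-pixel steps by bilinear interpolation,
    averaged across ``width`` pixels perpendicular to the transect, and
    converted to density through the calibration curve.  Positions are cm of
    arclength from the transect start.
    """
    arc_px, lum = _sample_luminance(image, polyline, width, step_px)
    return DensityProfile(positions=arc_px * image.pixel_size,
                          densities=curve.density(lum),
                          polyline=[tuple(map(float, v)) for v in polyline],
                          averaging_width=width)
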