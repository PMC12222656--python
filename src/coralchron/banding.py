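"""Growth-band delineation and annual growth metrics.

A density profile across a massive coral shows alternating low-density
(winter) and high-density (summer) bands; one LD+HD couplet is one year of
growth.  This module locates band boundaries on a profile, stitches the
boundary lists of overlapping transects into one per-core sequence, and
converts couplets into annual linear extension (cm yr-1), skeletal density
(g cm-3), and calcification (g cm-2 yr-1 = extension x density).

Band boundaries can also be supplied manually as CSV (band_index,
band_type, start_cm, end_cm[, mean_density]) since operator delineation is
the traditional workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .densitometry import DensityProfile

__all__ = [
    "BandBoundaryList",
    "AnnualGrowthRecord",
    "detect_band_boundaries",
    "stitch_transects",
    "compute_annual_metrics",
    "annual_metrics_from_bands",
]


@dataclass
class BandBoundaryList:
    """Alternating LD/HD band intervals along a transect.

    ``boundaries`` (cm, strictly increasing) delimit the bands;
    ``band_types`` labels the interval between consecutive boundaries, so
    ``len(band_types) == len(boundaries) - 1`` and labels strictly
    alternate.  ``provenance`` records whether the list was detected
    automatically or entered manually.
    """

    boundaries: np.ndarray
    band_types: list
    provenance: str = "detected"
    diagnostics: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.band_types = list(self.band_types)
        n = self.boundaries.size
        if n and len(self.band_types) != n - 1:
            raise ValueError("band_types must have one entry per interval "
                             "(len(boundaries) - 1)")
        if n >= 2 and not np.all(np.diff(self.boundaries) > 0):
            raise ValueError("boundaries must be strictly increasing")
        for a, b in zip(self.band_types[:-1], self.band_types[1:]):
            if a == b:
                raise ValueError("band types must strictly alternate")
        for t in self.band_types:
            if t not in ("LD", "HD"):
                raise ValueError(f"unknown band type {t!r}")

    @property
    def n_bands(self) -> int:
        return len(self.band_types)

    @property
    def band_lengths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    @property
    def is_empty(self) -> bool:
        return self.n_bands == 0

    def couplets(self) -> list[tuple[int, int]]:
        """Indices of complete (LD, HD) band pairs, oldest first.

        Position increases toward recent growth: within a year the LD band
        (Dec-May) precedes the HD band (Jun-Nov), so couplets are
        consecutive (LD, HD) pairs.  Pairing proceeds backward from the
        young end so any unpaired leftover band sits at the old end.
        """
        pairs = []
        i = len(self.band_types) - 1
        while i >= 1:
            if self.band_types[i] == "HD" and self.band_types[i - 1] == "LD":
                pairs.append((i - 1, i))
                i -= 2
            else:
                i -= 1
        pairs.sort()
        return pairs

    @property
    def n_couplets(self) -> int:
        return len(self.couplets())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "band_index": np.arange(self.n_bands),
            "band_type": self.band_types,
            "start_cm": self.boundaries[:-1],
            "end_cm": self.boundaries[1:],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "manual") -> "BandBoundaryList":
        df = df.sort_values("start_cm").reset_index(drop=True)
        starts = df["start_cm"].to_numpy(dtype=float)
        ends = df["end_cm"].to_numpy(dtype=float)
        if not np.allclose(starts[1:], ends[:-1]):
            raise ValueError("bands must be contiguous (start == previous end)")
        boundaries = np.concatenate([starts, ends[-1:]])
        return cls(boundaries, list(df["band_type"]), provenance=provenance)

    @classmethod
    def from_csv(cls, path) -> "BandBoundaryList":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class AnnualGrowthRecord:
    """Annual growth metrics for one core.

    A record spanning ``first_year``-``last_year`` carries exactly
    ``last_year - first_year`` annual increments labeled
    ``first_year + 1 .. last_year`` (each couplet is labeled by the calendar
    year of its HD band).  ``calcification = extension * density`` holds
    exactly for every year.
    """

    core_id: str
    years: np.ndarray
    extension: np.ndarray              # cm yr-1
    density: np.ndarray                # g cm-3
    site: str = ""
    depth: float = float("nan")        # m

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.extension = np.asarray(self.extension, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if not (self.years.size == self.extension.size == self.density.size):
            raise ValueError("years, extension, density must have equal length")
        if self.years.size == 0:
            raise ValueError("record is empty")
        if not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be contiguous")
        if np.any(self.extension <= 0) or np.any(self.density <= 0):
            raise ValueError("extension and density must be positive")

    @property
    def calcification(self) -> np.ndarray:
        return self.extension * self.density

    @property
    def first_year(self) -> int:
        """Start of the spanned period (the year before the first increment)."""
        return int(self.years[0]) - 1

    @property
    def last_year(self) -> int:
        return int(self.years[-1])

    @property
    def n_years(self) -> int:
        """Number of annual increments; equals last_year - first_year."""
        return self.years.size

    def series(self, parameter: str) -> pd.Series:
        data = {"extension": self.extension, "density": self.density,
                "calcification": self.calcification}[parameter]
        return pd.Series(data, index=pd.Index(self.years, name="year"),
                         name=f"{self.core_id}:{parameter}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"core_id": self.core_id, "year": self.years,
                             "extension_cm": self.extension,
                             "density_g_cm3": self.density,
                             "calcification_g_cm2": self.calcification})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, core_id: str | None = None) -> "AnnualGrowthRecord":
        df = pd.read_csv(path)
        cid = core_id or (str(df["core_id"].iloc[0]) if "core_id" in df else "core")
        return cls(core_id=cid, years=df["year"].to_numpy(),
                   extension=df["extension_cm"].to_numpy(),
                   density=df["density_g_cm3"].to_numpy())


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_band_boundaries(profile: DensityProfile, smoothing_window: float = 0.05,
                           min_band_width: float = 0.05,
                           min_prominence: float = 0.02) -> BandBoundaryList:
    """Locate LD/HD band boundaries on a density profile.

    The profile is smoothed with a moving average of ``smoothing_window``
    cm; HD band centers are local maxima and LD centers local minima of the
    smoothed profile (peak spacing at least ``min_band_width``).  Between
    each adjacent extremum pair the boundary is placed where the smoothed
    profile crosses the midpoint of the two extremum values — for
    plateau-like bands this half-amplitude crossing sits on the true
    transition independent of the two bands' widths.  Bands narrower than
    ``min_band_width`` are merged into their neighbors.  The outermost
    boundaries are the profile ends (those outer bands may be partial).

    A profile with no density alternation yields an empty result carrying a
    diagnostic, not an exception.
    """
    if len(profile) < 20:
        raise ValueError("profile must have >= 20 samples")
    if smoothing_window >= profile.length / 4:
        raise ValueError("smoothing_window must be < profile length / 4")

    pos = profile.positions
    step = profile.step
    win = max(1, int(round(smoothing_window / step)))
    win += 1 - win % 2  # odd window keeps the filter symmetric (no phase shift)
    sm = ndimage.uniform_filter1d(profile.densities, size=win, mode="nearest")

    spread = float(np.percentile(sm, 95) - np.percentile(sm, 5))
    prom = max(min_prominence, 0.2 * spread)
    dist = max(1, int(round(min_band_width / step)))
    # pad below the minimum (for peaks) / above the maximum (for troughs) so
    # plateaus touching the profile ends still present a flank to the peak
    # finder and their prominence is set by the interior flank alone
    lo_pad = float(sm.min()) - max(spread, prom)
    hi_pad = float(sm.max()) + max(spread, prom)
    peaks, _ = signal.find_peaks(np.concatenate([[lo_pad], sm, [lo_pad]]),
                                 prominence=prom, distance=dist)
    troughs, _ = signal.find_peaks(-np.concatenate([[hi_pad], sm, [hi_pad]]),
                                   prominence=prom, distance=dist)
    peaks = np.clip(peaks - 1, 0, sm.size - 1)
    troughs = np.clip(troughs - 1, 0, sm.size - 1)

    if peaks.size == 0 or troughs.size == 0:
        return BandBoundaryList(np.array([]), [], provenance="detected",
                                diagnostics=["no banding detected: profile lacks "
                                             "alternating density extrema"])

    # merge extrema, enforce alternation (keep the more extreme of duplicates;
    # ties broken toward the earlier/older position)
    ext = sorted([(int(i), "H") for i in peaks] + [(int(i), "L") for i in troughs])
    cleaned: list[tuple[int, str]] = []
    for idx, kind in ext:
        if cleaned and cleaned[-1][1] == kind:
            prev_idx = cleaned[-1][0]
            better = (sm[idx] > sm[prev_idx]) if kind == "H" else (sm[idx] < sm[prev_idx])
            if better:
                cleaned[-1] = (idx, kind)
        else:
            cleaned.append((idx, kind))

    # merge bands narrower than min_band_width: drop extremum pairs too close
    changed = True
    while changed and len(cleaned) >= 2:
        changed = False
        for k in range(len(cleaned) - 1):
            if pos[cleaned[k + 1][0]] - pos[cleaned[k][0]] < min_band_width:
                del cleaned[k:k + 2]  # removing both restores alternation
                changed = True
                break

    if len(cleaned) < 2:
        return BandBoundaryList(np.array([]), [], provenance="detected",
                                diagnostics=["no banding detected: fewer than two "
                                             "alternating extrema after merging"])

    # boundary = half-amplitude crossing between adjacent extrema
    inner = []
    for (i0, _k0), (i1, _k1) in zip(cleaned[:-1], cleaned[1:]):
        level = 0.5 * (sm[i0] + sm[i1])
        seg = sm[i0:i1 + 1] - level
        sign_change = np.nonzero(np.diff(np.signbit(seg)))[0]
        if sign_change.size == 0:
            continue
        j = i0 + sign_change[0]
        frac = seg[j - i0] / (seg[j - i0] - seg[j + 1 - i0])
        inner.append(pos[j] + frac * (pos[j + 1] - pos[j]))

    boundaries = np.concatenate([[pos[0]], inner, [pos[-1]]])
    boundaries = np.unique(boundaries)
    types = []
    first_kind = cleaned[0][1]
    t = "HD" if first_kind == "H" else "LD"
    for _ in range(boundaries.size - 1):
        types.append(t)
        t = "LD" if t == "HD" else "HD"
    result = BandBoundaryList(boundaries, types, provenance="detected")
    if result.n_couplets == 0:
        result.diagnostics.append("no complete LD+HD couplet found")
    return result


# ---------------------------------------------------------------------------
# stitching
# ---------------------------------------------------------------------------

def stitch_transects(segments: list[BandBoundaryList], overlaps: list[int],
                     couplet_densities: list | None = None,
                     density_tolerance: float = 0.05) -> BandBoundaryList:
    """Merge overlapping transect boundary lists into one per-core sequence.

    ``overlaps[k]`` declares how many complete LD+HD couplets are shared
    between segment ``k`` (its youngest/last couplets) and segment ``k+1``
    (its oldest/first couplets); at least one full couplet of overlap is
    required so no incomplete band is carried across a transect join.
    Within an overlap, band lengths from the earlier (already accepted)
    segment win.  If ``couplet_densities`` (one array of per-couplet mean
    densities per segment) are given, overlapping couplets whose densities
    disagree by more than ``density_tolerance`` (relative) are recorded as
    warnings; the earlier segment still wins.
    """
    if not segments:
        raise ValueError("no segments to stitch")
    if len(overlaps) != len(segments) - 1:
        raise ValueError("need exactly one overlap count per consecutive segment pair")
    for seg in segments:
        if seg.n_couplets < 1:
            raise ValueError("every segment must contain >= 1 complete couplet")

    warnings_list: list[str] = []
    # accumulate (type, length) bands; start with the whole first segment
    types = list(segments[0].band_types)
    lengths = list(segments[0].band_lengths)

    for k, (seg, m) in enumerate(zip(segments[1:], overlaps), start=1):
        m = int(m)
        if m < 1:
            raise ValueError(
                f"overlap between segments {k-1} and {k} is {m} couplets; "
                "at least one complete LD+HD couplet is required to avoid "
                "incomplete bands at the join"
            )
        prev_couplets = segments[k - 1].couplets()
        new_couplets = seg.couplets()
        if m > len(prev_couplets) or m > len(new_couplets):
            raise ValueError(f"declared overlap of {m} couplets exceeds the "
                             f"couplets available in segments {k-1}/{k}")
        if couplet_densities is not None:
            prev_d = np.asarray(couplet_densities[k - 1], dtype=float)[-m:]
            new_d = np.asarray(couplet_densities[k], dtype=float)[:m]
            rel = np.abs(new_d - prev_d) / prev_d
            for j, r in enumerate(rel):
                if r > density_tolerance:
                    warnings_list.append(
                        f"overlap couplet {j} between segments {k-1} and {k}: "
                        f"densities disagree by {r:.1%} (> {density_tolerance:.0%}); "
                        "keeping the earlier segment"
                    )
        # append the non-overlapped part of the new segment: everything after
        # its m-th couplet's HD band
        skip_to = new_couplets[m - 1][1] + 1
        seg_lengths = seg.band_lengths
        for i in range(skip_to, seg.n_bands):
            if types and types[-1] == seg.band_types[i]:
                raise ValueError(f"stitch between segments {k-1} and {k} breaks "
                                 "LD/HD alternation")
            types.append(seg.band_types[i])
            lengths.append(seg_lengths[i])

    boundaries = np.concatenate([[segments[0].boundaries[0]],
                                 segments[0].boundaries[0] + np.cumsum(lengths)])
    return BandBoundaryList(boundaries, types, provenance="stitched",
                            warnings=warnings_list)


# ---------------------------------------------------------------------------
# annual metrics
# ---------------------------------------------------------------------------

def compute_annual_metrics(profile: DensityProfile, bands: BandBoundaryList,
                           last_complete_year: int, core_id: str = "core",
                           exclude_outermost: bool = False,
                           density_mode: str = "length_weighted",
                           site: str = "", depth: float = float("nan")) -> AnnualGrowthRecord:
    """Annual extension, density, and calcification from banded profile data.

    Per couplet: extension = LD length + HD length; density is the
    length-weighted mean of profile samples across the couplet (default) or
    the unweighted mean of the two band means (``density_mode='band_mean'``);
    calcification is their product.  Couplets are labeled backward from
    ``last_complete_year`` (the year of the youngest complete HD band);
    ``exclude_outermost`` additionally drops the youngest couplet when the
    outermost band may still be forming.
    """
    if density_mode not in ("length_weighted", "band_mean"):
        raise ValueError("density_mode must be 'length_weighted' or 'band_mean'")
    pairs = bands.couplets()
    if not pairs:
        raise ValueError("no complete LD+HD couplet in the boundary list")
    if exclude_outermost:
        pairs = pairs[:-1]
        if not pairs:
            raise ValueError("no couplet left after excluding the outermost")

    extensions, densities = [], []
    for lo, hi in pairs:
        start, mid, end = (bands.boundaries[lo], bands.boundaries[lo + 1],
                           bands.boundaries[hi + 1])
        extensions.append(end - start)
        sel = (profile.positions >= start) & (profile.positions < end)
        if not np.any(sel):
            raise ValueError(f"couplet [{start:.3f}, {end:.3f}) cm has no "
                             "usable profile samples")
        if density_mode == "length_weighted":
            densities.append(float(profile.densities[sel].mean()))
        else:
            sel_ld = sel & (profile.positions < mid)
            sel_hd = sel & (profile.positions >= mid)
            if not (np.any(sel_ld) and np.any(sel_hd)):
                raise ValueError("a band in couplet has no usable profile samples")
            densities.append(0.5 * (float(profile.densities[sel_ld].mean())
                                    + float(profile.densities[sel_hd].mean())))

    n = len(pairs)
    years = np.arange(last_complete_year - n + 1, last_complete_year + 1)
    return AnnualGrowthRecord(core_id=core_id, years=years,
                              extension=np.array(extensions),
                              density=np.array(densities),
                              site=site, depth=depth)


def annual_metrics_from_bands(bands_table: pd.DataFrame, last_complete_year: int,
                              core_id: str = "core",
                              exclude_outermost: bool = False,
                              site: str = "", depth: float = float("nan")) -> AnnualGrowthRecord:
    """Annual metrics from a manually measured band table (no image needed).

    ``bands_table`` columns: band_type (LD/HD), start_cm, end_cm,
    mean_density.  Bands must alternate and be contiguous; couplet density
    is the length-weighted mean of the two band densities.
    """
    bands = BandBoundaryList.from_frame(bands_table)
    dens = bands_table.sort_values("start_cm")["mean_density"].to_numpy(dtype=float)
    pairs = bands.couplets()
    if not pairs:
        raise ValueError("no complete LD+HD couplet in the band table")
    if exclude_outermost:
        pairs = pairs[:-1]
        if not pairs:
            raise ValueError("no couplet left after excluding the outermost")
    lengths = bands.band_lengths
    extensions, densities = [], []
    for lo, hi in pairs:
        ext = lengths[lo] + lengths[hi]
        extensions.append(ext)
        densities.append((lengths[lo] * dens[lo] + lengths[hi] * dens[hi]) / ext)
    n = len(pairs)
    years = np.arange(last_complete_year - n + 1, last_complete_year + 1)
    return AnnualGrowthRecord(core_id=core_id, years=years,
                              extension=np.array(extensions),
                              density=np.array(densities),
                              site=site, depth=depth)
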