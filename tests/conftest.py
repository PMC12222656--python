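import numpy as np
import pytest

from coralchron import banding, densitometry, synthgen


@pytest.fixture(scope="session")
def true_curve():
    return synthgen.default_true_curve(16)


@pytest.fixture
def synthetic_core(true_curve):
    """Factory: rendered 30-year core + its ground truth, keyed by seed/noise."""

    def _make(seed=3, noise_sd=1.0, n_years=30, gradient=0.0, pixel_size=0.005):
        truth = synthgen.gen_growth_series(n_years, 0.45, 2.0, ar1_coef=0.3,
                                           noise_sd=0.03, seed=seed)
        scene = synthgen.SceneSpec(pixel_size=pixel_size,
                                   grayscale_noise_sd=noise_sd,
                                   beam_gradient_amp=gradient, seed=seed)
        image, layout = synthgen.gen_core_image(truth, true_curve, scene)
        return truth, scene, image, layout

    return _make


@pytest.fixture
def center_profile(true_curve):
    """Extract the center-column density profile of a rendered core."""

    def _extract(image, width=11):
        h, w = image.shape
        line = [(w / 2.0, 0.0), (w / 2.0, h - 1.0)]
        return densitometry.extract_transect(image, line, width, true_curve)

    return _extract


def square_wave_profile(band_cm=0.2, n_couplets=8, lo=1.8, hi=2.2, step=0.002):
    """Noiseless alternating LD/HD profile with known transitions."""
    total = 2 * n_couplets * band_cm
    pos = np.arange(int(round(total / step))) * step + step / 2
    band_idx = np.floor(pos / band_cm).astype(int)
    dens = np.where(band_idx % 2 == 0, lo, hi)
    return densitometry.DensityProfile(pos, dens)


def couplet_profile(lengths_densities, step=0.00125):
    """Profile from [(length_cm, density), ...] segments, sampled at centers."""
    edges = np.concatenate([[0.0], np.cumsum([l for l, _ in lengths_densities])])
    pos = np.arange(int(round(edges[-1] / step))) * step + step / 2
    dens = np.empty_like(pos)
    for (length, d), a, b in zip(lengths_densities, edges[:-1], edges[1:]):
        dens[(pos >= a) & (pos < b)] = d
    return densitometry.DensityProfile(pos, dens), edges


def bands_from_edges(edges, first_type="LD"):
    types = []
    t = first_type
    for _ in range(len(edges) - 1):
        types.append(t)
        t = "HD" if t == "LD" else "LD"
    return banding.BandBoundaryList(np.asarray(edges), types)
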