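"""Published summary statistics for the Martinique *Siderastrea siderea* cores.

Twelve cores from four reef sites in southern Martinique (Caye d'Olbian,
Corps de Garde, Jardin Tropical, Pointe Borgnese), with their spanned
period, number of annual increments, and long-term mean (+/- SD) linear
extension rate (cm yr-1), skeletal density (g cm-3), and calcification rate
(g cm-2 yr-1).  These published summaries parameterize the bundled
synthetic demo and serve as arithmetic cross-checks (the calcification mean
is the product of the extension and density means; the increment count
equals last_year - first_year).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["MARTINIQUE_CORES", "normalization_assignment"]

_ROWS = [
    # core_id, site, depth_m, first_year, last_year, n_years,
    # ext_mean, ext_sd, dens_mean, dens_sd, calc_mean, calc_sd
    ("CO01", "Caye d'Olbian", 9.3, 1940, 2020, 80, 0.36, 0.10, 2.12, 0.12, 0.76, 0.21),
    ("CO02", "Caye d'Olbian", 9.6, 1962, 2020, 58, 0.42, 0.01, 2.12, 0.13, 0.89, 0.21),
    ("CO03", "Caye d'Olbian", 13.2, 1989, 2020, 31, 0.39, 0.08, 1.98, 0.08, 0.77, 0.14),
    ("CG01", "Corps de Garde", 7.3, 1954, 2020, 66, 0.44, 0.01, 1.92, 0.07, 0.85, 0.17),
    ("CG02", "Corps de Garde", 7.3, 1950, 2020, 70, 0.33, 0.06, 2.05, 0.09, 0.67, 0.13),
    ("CG03", "Corps de Garde", 6.9, 1917, 2020, 103, 0.53, 0.14, 1.57, 0.05, 0.84, 0.22),
    ("JT01", "Jardin Tropical", 7.3, 1948, 2020, 72, 0.40, 0.09, 1.95, 0.11, 0.78, 0.19),
    ("JT02", "Jardin Tropical", 7.6, 1912, 2020, 108, 0.43, 0.17, 1.90, 0.11, 0.83, 0.33),
    ("PB01", "Pointe Borgnese", 9.0, 1993, 2020, 27, 0.45, 0.01, 1.87, 0.06, 0.84, 0.22),
    ("PB02", "Pointe Borgnese", 9.5, 1997, 2020, 23, 0.40, 0.11, 2.05, 0.08, 0.81, 0.23),
    ("PB03", "Pointe Borgnese", 4.4, 1993, 2020, 27, 0.42, 0.11, 2.26, 0.14, 0.96, 0.28),
    ("PB04", "Pointe Borgnese", 4.5, 2006, 2020, 14, 0.39, 0.15, 2.04, 0.16, 0.81, 0.33),
]

MARTINIQUE_CORES = pd.DataFrame(
    _ROWS,
    columns=["core_id", "site", "depth_m", "first_year", "last_year", "n_years",
             "extension_mean", "extension_sd", "density_mean", "density_sd",
             "calcification_mean", "calcification_sd"],
).set_index("core_id")

# Normalization design used in the study: seven long cores are referenced to
# 1954-2020, the five shorter ones to 1993-2020; PB02 and PB04 are too short
# even for the short period and are excluded from the group means (but remain
# in the master chronologies).
REFERENCE_PERIODS = {"long": (1954, 2020), "short": (1993, 2020)}
LONG_PERIOD_CORES = ["CO01", "CO02", "CG01", "CG02", "CG03", "JT01", "JT02"]
SHORT_PERIOD_CORES = ["PB01", "PB02", "PB03", "PB04", "CO03"]
EXCLUDED_FROM_GROUP_MEAN = ["PB02", "PB04"]


def normalization_assignment() -> dict:
    """core_id -> reference-period name, per the study design."""
    out = {c: "long" for c in LONG_PERIOD_CORES}
    out.update({c: "short" for c in SHORT_PERIOD_CORES})
    return out
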