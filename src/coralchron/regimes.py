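"""Sequential t-test analysis of regime shifts (STARS).

Detects statistically significant step changes in the mean of an annual
series without specifying candidate years in advance.  The method fixes a
cut-off length ``l`` (the shortest regime worth detecting) and a two-tailed
significance level, computes the critical mean difference

    diff = t_crit(alpha, df = 2l - 2) * sqrt(2 * sigma_l^2 / l)

with ``sigma_l^2`` the variance pooled (averaged) over all consecutive
windows of length ``l``, and then scans the series sequentially: a value
leaving the current regime mean by more than ``diff`` is a candidate shift,
confirmed or rejected by the regime-shift index (RSI) — the cumulative
exceedance beyond the ``mean +/- diff`` threshold over up to ``l`` values
from the candidate on, normalized by ``l * sigma_l``.  A negative running
sum rejects the candidate (it is absorbed into the current regime);
survival confirms the shift at the candidate year.

Growth series are log-transformed (natural log) before detection by
convention, since growth-rate variability is closer to multiplicative.
This implementation fixes every constant of the sequential algorithm
(degrees of freedom, pooled variance, RSI normalization) so results are
reproducible from the definition alone; no outlier weighting or red-noise
prewhitening is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StarsParams", "RegimeShiftResult", "stars_detect", "rsi"]


@dataclass
class StarsParams:
    """Tuning constants for STARS detection."""

    cutoff_length: int = 10          # years; shortest admissible regime
    significance: float = 0.05       # two-tailed probability
    log_transform: bool = False      # natural log before detection

    def __post_init__(self) -> None:
        if self.cutoff_length < 2:
            raise ValueError("cutoff_length must be >= 2")
        if not 0 < self.significance < 1:
            raise ValueError("significance must lie in (0, 1)")


@dataclass
class RegimeShiftResult:
    """Detected shifts, regime means (analysis units), and the RSI trace."""

    shift_years: list
    tentative_shift_years: list      # candidates surviving to the series end with
                                     # fewer than cutoff confirming values
    regime_starts: list              # first year of each regime (incl. series start)
    regime_means: list               # in analysis units (log units when log-transformed)
    rsi_series: pd.Series            # RSI per year (nonzero only at candidates)
    diff_threshold: float
    sigma_l: float
    params: StarsParams
    log_transform: bool = False

    def __post_init__(self) -> None:
        if list(self.shift_years) != sorted(self.shift_years):
            raise ValueError("shift_years must be strictly increasing")

    @property
    def regime_means_natural(self) -> list:
        """Regime means back-transformed to the original units."""
        if self.log_transform:
            return [float(np.exp(m)) for m in self.regime_means]
        return [float(m) for m in self.regime_means]

    def regime_table(self) -> pd.DataFrame:
        starts = list(self.regime_starts)
        ends = starts[1:] + [int(self.rsi_series.index[-1]) + 1]
        return pd.DataFrame({"start_year": starts,
                             "end_year": [e - 1 for e in ends],
                             "mean": self.regime_means,
                             "mean_natural": self.regime_means_natural})

    def to_json(self, path) -> None:
        payload = {
            "params": {"cutoff_length": self.params.cutoff_length,
                       "significance": self.params.significance,
                       "log_transform": self.params.log_transform},
            "diff_threshold": self.diff_threshold,
            "sigma_l": self.sigma_l,
            "shift_years": [int(y) for y in self.shift_years],
            "tentative_shift_years": [int(y) for y in self.tentative_shift_years],
            "regimes": self.regime_table().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _rsi_scan(x: np.ndarray, start: int, level: float, direction: float,
              cutoff: int, sigma_l: float) -> float:
    """Cumulative normalized exceedance from ``start`` over up to ``cutoff`` values.

    Stops at the first negative running sum (rejection); otherwise returns
    the final (positive or zero) sum, normalized by ``cutoff * sigma_l``.
    """
    csum = 0.0
    for j in range(start, min(start + cutoff, x.size)):
        csum += direction * (x[j] - level)
        if csum < 0:
            break
    return csum / (cutoff * sigma_l)


def rsi(series, candidate_index: int, current_mean: float,
        params: StarsParams, sigma_l: float | None = None) -> float:
    """Regime-shift index for a candidate shift at ``candidate_index``.

    The shift direction is taken from the side of ``current_mean`` on which
    the candidate value lies; the exceedance is measured beyond
    ``current_mean +/- diff``.  Positive RSI supports the shift; a zero or
    negative value rejects it.
    """
    x = np.asarray(series, dtype=float)
    if not 0 <= candidate_index < x.size:
        raise ValueError("candidate_index outside series")
    l = params.cutoff_length
    if sigma_l is None:
        sigma_l = float(np.sqrt(_pooled_window_variance(x, l)))
    tcrit = stats.t.ppf(1 - params.significance / 2, df=2 * l - 2)
    diff = tcrit * np.sqrt(2 * sigma_l**2 / l)
    direction = 1.0 if x[candidate_index] >= current_mean else -1.0
    level = current_mean + direction * diff
    return _rsi_scan(x, candidate_index, level, direction, l, sigma_l)


def _pooled_window_variance(x: np.ndarray, l: int) -> float:
    """Average sample variance over all consecutive windows of length ``l``."""
    if x.size < l:
        raise ValueError("series shorter than cutoff length")
    windows = np.lib.stride_tricks.sliding_window_view(x, l)
    return float(windows.var(axis=1, ddof=1).mean())


def stars_detect(series: pd.Series, params: StarsParams | None = None) -> RegimeShiftResult:
    """Run sequential regime-shift detection on a year-indexed annual series.

    Requires at least ``2 * cutoff_length`` values; with
    ``params.log_transform`` all values must be positive (the offending year
    is named otherwise).  Returns the confirmed shift years, per-regime
    means in analysis units, and the RSI value recorded at every candidate
    year (positive at confirmed shifts).
    """
    params = params or StarsParams()
    if not isinstance(series, pd.Series):
        series = pd.Series(np.asarray(series, dtype=float))
    series = series.dropna()
    years = series.index.to_numpy()
    x = series.to_numpy(dtype=float)
    l = params.cutoff_length
    if x.size < 2 * l:
        raise ValueError(f"series has {x.size} values; need >= {2 * l} "
                         f"(twice the cutoff length)")
    if params.log_transform:
        bad = np.nonzero(x <= 0)[0]
        if bad.size:
            raise ValueError(f"non-positive value in year {years[bad[0]]}; "
                             "cannot log-transform")
        x = np.log(x)

    var_l = _pooled_window_variance(x, l)
    sigma_l = float(np.sqrt(var_l))
    if sigma_l == 0:
        # constant series: no variability, no shifts
        rsi_series = pd.Series(np.zeros(x.size), index=years, name="rsi")
        return RegimeShiftResult(shift_years=[], tentative_shift_years=[],
                                 regime_starts=[int(years[0])],
                                 regime_means=[float(x.mean())],
                                 rsi_series=rsi_series, diff_threshold=0.0,
                                 sigma_l=0.0, params=params,
                                 log_transform=params.log_transform)

    tcrit = stats.t.ppf(1 - params.significance / 2, df=2 * l - 2)
    diff = float(tcrit * np.sqrt(2 * var_l / l))

    rsi_values = np.zeros(x.size)
    shifts: list[int] = []
    tentative: list[int] = []
    regime_start = 0
    mu = float(x[:l].mean())

    i = l
    while i < x.size:
        dev = x[i] - mu
        if abs(dev) > diff:
            direction = 1.0 if dev > 0 else -1.0
            level = mu + direction * diff
            r = _rsi_scan(x, i, level, direction, l, sigma_l)
            rsi_values[i] = r
            if r > 0 and i + l <= x.size:
                shifts.append(i)
                regime_start = i
                mu = float(x[i:i + l].mean())
            else:
                # rejected -- or surviving but with fewer than cutoff
                # confirming values left (tentative, not confirmed)
                if r > 0:
                    tentative.append(i)
                mu = float(x[regime_start:i + 1].mean())
        else:
            mu = float(x[regime_start:i + 1].mean())
        i += 1

    regime_edges = [0] + shifts + [x.size]
    regime_starts = [int(years[j]) for j in regime_edges[:-1]]
    regime_means = [float(x[a:b].mean())
                    for a, b in zip(regime_edges[:-1], regime_edges[1:])]
    return RegimeShiftResult(
        shift_years=[int(years[j]) for j in shifts],
        tentative_shift_years=[int(years[j]) for j in tentative],
        regime_starts=regime_starts, regime_means=regime_means,
        rsi_series=pd.Series(rsi_values, index=years, name="rsi"),
        diff_threshold=diff, sigma_l=sigma_l, params=params,
        log_transform=params.log_transform,
    )
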