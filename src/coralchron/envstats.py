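"""Environmental series preparation and growth-vs-environment statistics.

Monthly series (SST, precipitation, river discharge) are annualized as
calendar-year means, with the within-year extrema of the monthly means
(SSTmin / SSTmax) tracked separately because thermal-stress responses key
on the warmest month rather than the annual mean.  Station records of
different lengths are merged by a linear rescaling fitted over their
overlap, with a Monte-Carlo (residual resampling) envelope quantifying the
rescaling uncertainty.  Associations between (log-transformed) annual
growth parameters and environmental series are assessed with Pearson
correlations and linear/polynomial least-squares fits, on the full span and
on split sub-periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "EnvSeries",
    "AnnualClimate",
    "RegressionResult",
    "RescaleResult",
    "annualize",
    "annual_climate",
    "rescale_series",
    "pearson",
    "fit_trend",
    "growth_env_analysis",
]


@dataclass
class EnvSeries:
    """A monthly or annual environmental series with units and provenance."""

    data: pd.Series                   # DatetimeIndex (monthly) or int years (annual)
    units: str
    kind: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("units must be non-empty")
        if not self.data.index.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if self.data.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing (duplicates found)")

    @classmethod
    def from_csv(cls, path, units: str, kind: str = "", source: str = "") -> "EnvSeries":
        """Read tidy CSV: (date, value) for monthly or (year, value) for annual."""
        df = pd.read_csv(path)
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        if "date" in cols:
            s = pd.Series(df["value"].to_numpy(),
                          index=pd.DatetimeIndex(pd.to_datetime(df["date"])))
        elif "year" in cols:
            s = pd.Series(df["value"].to_numpy(),
                          index=pd.Index(df["year"].astype(int), name="year"))
        else:
            raise ValueError("CSV must have a 'date' or 'year' column plus 'value'")
        return cls(data=s, units=units, kind=kind, source=source)


@dataclass
class AnnualClimate:
    """Annual mean plus within-year extrema of monthly means (e.g. SSTmin/max)."""

    table: pd.DataFrame               # index: year; columns: mean, min, max

    def __post_init__(self) -> None:
        t = self.table
        if not {"mean", "min", "max"} <= set(t.columns):
            raise ValueError("table must have 'mean', 'min', 'max' columns")
        ok = (t["min"] <= t["mean"] + 1e-12) & (t["mean"] <= t["max"] + 1e-12)
        if not ok.all():
            raise ValueError("min <= mean <= max violated")

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


@dataclass
class RegressionResult:
    """Outcome of a Pearson correlation or least-squares trend fit."""

    kind: str                          # 'pearson' | 'linear' | 'poly2' | 'poly3'
    r2: float
    p: float
    n: int
    r: float = float("nan")            # Pearson only
    coefficients: list = field(default_factory=list)  # highest degree first
    valid: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.valid:
            if self.n < 3:
                raise ValueError("n must be >= 3")
            if not -1 - 1e-12 <= self.r <= 1 + 1e-12 and not np.isnan(self.r):
                raise ValueError("r outside [-1, 1]")
            if not -1e-12 <= self.r2 <= 1 + 1e-12:
                raise ValueError("r2 outside [0, 1]")


@dataclass
class RescaleResult:
    """Linear cross-station rescaling with a Monte-Carlo uncertainty envelope."""

    intercept: float
    slope: float
    rescaled: pd.Series                # pre-overlap reference months mapped to target scale
    combined: pd.Series                # rescaled pre-overlap + original target
    envelope: pd.DataFrame             # columns lo, hi (2.5/97.5 percentiles) per rescaled month
    n_overlap: int
    r2: float


# ---------------------------------------------------------------------------
# annualization
# ---------------------------------------------------------------------------

def _monthly(series) -> pd.Series:
    s = series.data if isinstance(series, EnvSeries) else series
    if not isinstance(s.index, pd.DatetimeIndex):
        raise ValueError("expected a monthly series with a DatetimeIndex")
    return s


def annualize(monthly, statistic: str = "mean",
              max_missing_months: int = 2) -> pd.Series:
    """Calendar-year aggregation of a monthly series.

    ``statistic`` is one of mean/min/max/sum; min and max are the extrema of
    the monthly means within the year.  Years missing more than
    ``max_missing_months`` months are dropped (and reported via the returned
    series' ``attrs['dropped_years']``).
    """
    if statistic not in ("mean", "min", "max", "sum"):
        raise ValueError("statistic must be one of mean|min|max|sum")
    s = _monthly(monthly).dropna()
    if s.empty:
        raise ValueError("no data to annualize")
    grouped = s.groupby(s.index.year)
    counts = grouped.count()
    keep = counts[counts >= 12 - max_missing_months].index
    dropped = sorted(set(counts.index) - set(keep))
    out = getattr(grouped, statistic)().loc[keep]
    out.index.name = "year"
    out.attrs["dropped_years"] = dropped
    if out.empty:
        raise ValueError("all years dropped: too many missing months")
    return out


def annual_climate(monthly, max_missing_months: int = 2) -> AnnualClimate:
    """Annual mean/min/max table (SSTmin and SSTmax for a temperature series)."""
    table = pd.DataFrame({
        "mean": annualize(monthly, "mean", max_missing_months),
        "min": annualize(monthly, "min", max_missing_months),
        "max": annualize(monthly, "max", max_missing_months),
    })
    return AnnualClimate(table)


# ---------------------------------------------------------------------------
# cross-station rescaling
# ---------------------------------------------------------------------------

def rescale_series(target, reference, overlap: tuple[int, int],
                   n_mc: int = 500, seed: int | None = None) -> RescaleResult:
    """Extend ``target`` backward using ``reference`` via a linear rescaling.

    An OLS fit ``target = a + b * reference`` over the overlap years maps
    reference months preceding the target record onto the target's scale.
    Uncertainty: ``n_mc`` residual-bootstrap replicates (residuals resampled
    with replacement, the line refitted, the mapping reapplied) give a
    per-month 95% envelope (2.5/97.5 percentiles of the replicate
    predictions).  Deterministic for a fixed seed.
    """
    t = _monthly(target).dropna()
    ref = _monthly(reference).dropna()
    y0, y1 = overlap
    in_overlap = (t.index.year >= y0) & (t.index.year <= y1)
    joined = pd.concat([t[in_overlap].rename("t"),
                        ref[(ref.index.year >= y0) & (ref.index.year <= y1)].rename("r")],
                       axis=1, join="inner").dropna()
    if len(joined) < 24:
        raise ValueError(f"overlap {y0}-{y1} has {len(joined)} paired months; "
                         "need >= 24")
    X = sm.add_constant(joined["r"].to_numpy())
    fit = sm.OLS(joined["t"].to_numpy(), X).fit()
    a, b = float(fit.params[0]), float(fit.params[1])
    resid = fit.resid

    pre = ref[ref.index < t.index.min()]
    mapped = a + b * pre

    rng = np.random.default_rng(seed)
    preds = np.empty((n_mc, len(pre)))
    yhat = fit.fittedvalues
    for k in range(n_mc):
        boot_y = yhat + rng.choice(resid, size=resid.size, replace=True)
        coef, *_ = np.linalg.lstsq(X, boot_y, rcond=None)
        preds[k] = coef[0] + coef[1] * pre.to_numpy()
    lo, hi = np.percentile(preds, [2.5, 97.5], axis=0)
    envelope = pd.DataFrame({"lo": lo, "hi": hi}, index=pre.index)

    combined = pd.concat([mapped, t]).sort_index()
    return RescaleResult(intercept=a, slope=b, rescaled=mapped, combined=combined,
                         envelope=envelope, n_overlap=len(joined),
                         r2=float(fit.rsquared))


# ---------------------------------------------------------------------------
# correlation and trend fitting
# ---------------------------------------------------------------------------

def _align(x, y) -> pd.DataFrame:
    xs = x if isinstance(x, pd.Series) else pd.Series(np.asarray(x, dtype=float))
    ys = y if isinstance(y, pd.Series) else pd.Series(np.asarray(y, dtype=float))
    return pd.concat([xs.rename("x"), ys.rename("y")], axis=1, join="inner").dropna()


def pearson(x, y) -> RegressionResult:
    """Sample Pearson correlation with a two-sided t-test p-value (df = n - 2).

    Series inputs are inner-joined on their (year) index first.  Zero
    variance in either variable yields a flagged-invalid result rather than
    NaN propagation.
    """
    df = _align(x, y)
    n = len(df)
    if n < 3:
        raise ValueError(f"only {n} paired values after alignment; need >= 3")
    if df["x"].std(ddof=0) == 0 or df["y"].std(ddof=0) == 0:
        return RegressionResult(kind="pearson", r2=0.0, p=float("nan"), n=n,
                                valid=False, note="zero variance: correlation undefined")
    r, p = stats.pearsonr(df["x"], df["y"])
    return RegressionResult(kind="pearson", r=float(r), r2=float(r) ** 2,
                            p=float(p), n=n)


def fit_trend(x, y, degree: int = 1, log_y: bool = False) -> RegressionResult:
    """Least-squares polynomial fit of y on x with r^2 and overall-F p-value.

    ``log_y`` applies the natural log to y first (growth parameters are
    conventionally log-transformed).  Coefficients are returned highest
    degree first.  Requires ``n >= degree + 2``; a rank-deficient design
    (e.g. constant x) is rejected.
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2, or 3")
    df = _align(x, y)
    n = len(df)
    if n < degree + 2:
        raise ValueError(f"n={n} too small for degree {degree} (need >= {degree + 2})")
    yv = df["y"].to_numpy(dtype=float)
    if log_y:
        if np.any(yv <= 0):
            raise ValueError("log_y requires strictly positive y values")
        yv = np.log(yv)
    xv = df["x"].to_numpy(dtype=float)
    X = np.vander(xv, degree + 1)  # columns x^degree .. 1
    if np.linalg.matrix_rank(X) < degree + 1:
        raise ValueError("rank-deficient design (is x constant?)")
    fit = sm.OLS(yv, X).fit()
    p = float(fit.f_pvalue)
    if np.isnan(p) and fit.rsquared > 1 - 1e-12:
        p = 0.0  # perfect fit: zero residual variance
    return RegressionResult(kind="linear" if degree == 1 else f"poly{degree}",
                            r2=float(fit.rsquared), p=p, n=n,
                            coefficients=[float(c) for c in fit.params])


def growth_env_analysis(masters: dict, env_annuals: dict,
                        periods: list[tuple[int, int]] | None = None,
                        log_growth: bool = True, degrees=(1, 2),
                        min_overlap: int = 5, lag: int = 0,
                        adjust_p: bool = False) -> pd.DataFrame:
    """Cross every growth parameter with every environmental series.

    ``masters`` maps parameter name to a year-indexed ``pd.Series`` (or an
    object with a ``.series`` attribute, e.g. ``MasterChronology``);
    ``env_annuals`` maps variable name to a year-indexed annual series.
    For each (parameter, variable) pair, a Pearson correlation (on the
    log-transformed growth values when ``log_growth``) and polynomial trend
    fits of the requested degrees are computed over the full common span
    and over each sub-period (inclusive endpoints).  Pairs with fewer than
    ``min_overlap`` common years are marked insufficient.  ``lag`` shifts
    the environmental series forward by that many years before alignment
    (default 0: same-year comparison).  p-values are unadjusted by default;
    ``adjust_p`` adds a Benjamini-Hochberg FDR-adjusted column ``p_adj``
    across all computed tests.

    Returns a tidy table: growth, env, period, model, r, r2, p, n, note.
    """
    rows = []
    period_list: list[tuple[str, tuple[int, int] | None]] = [("full", None)]
    for a, b in (periods or []):
        period_list.append((f"{a}-{b}", (int(a), int(b))))

    for gname, gobj in masters.items():
        g = gobj.series if hasattr(gobj, "series") else gobj
        g = g.dropna()
        if log_growth:
            if np.any(g <= 0):
                raise ValueError(f"growth parameter {gname!r} has non-positive "
                                 "values; cannot log-transform")
            g = np.log(g)
        for ename, eobj in env_annuals.items():
            e = eobj.data if isinstance(eobj, EnvSeries) else eobj
            e = e.dropna()
            if lag:
                e = e.copy()
                e.index = e.index + lag
            for plabel, prange in period_list:
                gg, ee = g, e
                if prange is not None:
                    a, b = prange
                    gg = g.loc[(g.index >= a) & (g.index <= b)]
                    ee = e.loc[(e.index >= a) & (e.index <= b)]
                common = gg.index.intersection(ee.index)
                base = {"growth": gname, "env": ename, "period": plabel,
                        "n": len(common)}
                if len(common) < min_overlap:
                    rows.append({**base, "model": "none", "r": np.nan,
                                 "r2": np.nan, "p": np.nan,
                                 "note": "insufficient overlap"})
                    continue
                pr = pearson(ee.loc[common], gg.loc[common])
                rows.append({**base, "model": "pearson", "r": pr.r, "r2": pr.r2,
                             "p": pr.p, "note": pr.note})
                for deg in degrees:
                    if len(common) < deg + 2:
                        continue
                    ft = fit_trend(ee.loc[common], gg.loc[common], degree=deg)
                    rows.append({**base, "model": ft.kind, "r": np.nan,
                                 "r2": ft.r2, "p": ft.p, "note": ""})
    table = pd.DataFrame(rows, columns=["growth", "env", "period", "model",
                                        "r", "r2", "p", "n", "note"])
    if adjust_p:
        from statsmodels.stats.multitest import multipletests

        table["p_adj"] = np.nan
        mask = table["p"].notna()
        if mask.any():
            table.loc[mask, "p_adj"] = multipletests(
                table.loc[mask, "p"], method="fdr_bh")[1]
    return table
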