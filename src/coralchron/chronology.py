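"""Multi-core normalization and master chronologies.

Cores of different lengths and mean growth levels are combined by an
additive normalization: each core's mean over a common reference period is
subtracted from its annual values, then the group mean of those
reference-period means is added back, preserving the original units while
removing between-core level offsets (including depth-related ones).  Short
cores that do not reach their group's reference period can be excluded from
the group mean while still entering the master chronology.

The master chronology is the per-year mean across normalized cores, with
the standard error of the per-core values (sample SD / sqrt(n)) and the
per-year replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "NormalizationScheme",
    "MasterChronology",
    "normalize_records",
    "build_master",
    "decadal_means",
]


@dataclass
class NormalizationScheme:
    """Reference periods and core assignment for additive normalization.

    ``reference_periods`` maps a period name to an inclusive (start, end)
    year range; ``assignment`` maps every core id to exactly one period
    name.  Cores in ``excluded_from_group_mean`` do not contribute to their
    period's group mean (their own mean is taken over their full span
    because they do not cover the reference period), but they are still
    normalized and included in the master chronology.
    """

    reference_periods: dict
    assignment: dict
    excluded_from_group_mean: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reference_periods = {
            name: (int(a), int(b)) for name, (a, b) in self.reference_periods.items()
        }
        for core, name in self.assignment.items():
            if name not in self.reference_periods:
                raise ValueError(f"core {core!r} assigned to unknown period {name!r}")
        for core in self.excluded_from_group_mean:
            if core not in self.assignment:
                raise ValueError(f"excluded core {core!r} has no period assignment")

    @classmethod
    def auto(cls, records: dict, reference_periods: dict,
             excluded: list | None = None) -> "NormalizationScheme":
        """Assign each core to the longest reference period it fully covers.

        Cores covering no period are assigned to the shortest period and
        must be listed in ``excluded`` (they cannot contribute a
        reference-period mean).
        """
        periods = sorted(reference_periods.items(), key=lambda kv: kv[1][1] - kv[1][0],
                         reverse=True)
        shortest = min(reference_periods, key=lambda k: reference_periods[k][1]
                       - reference_periods[k][0])
        excluded = list(excluded or [])
        assignment = {}
        for core, series in records.items():
            years = series.dropna().index
            chosen = None
            for name, (a, b) in periods:
                if years.min() <= a and years.max() >= b:
                    chosen = name
                    break
            if chosen is None:
                chosen = shortest
                if core not in excluded:
                    excluded.append(core)
            assignment[core] = chosen
        return cls(reference_periods=dict(reference_periods), assignment=assignment,
                   excluded_from_group_mean=excluded)

    def to_yaml(self, path) -> None:
        payload = {
            "reference_periods": {k: list(v) for k, v in self.reference_periods.items()},
            "assignment": dict(self.assignment),
            "excluded_from_group_mean": list(self.excluded_from_group_mean),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "NormalizationScheme":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(reference_periods={k: tuple(v) for k, v in
                                      payload["reference_periods"].items()},
                   assignment=payload["assignment"],
                   excluded_from_group_mean=payload.get("excluded_from_group_mean", []))


@dataclass
class MasterChronology:
    """Per-year mean +/- SE across normalized cores for one growth parameter."""

    years: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_cores: np.ndarray
    parameter: str = "extension"

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.mean = np.asarray(self.mean, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.n_cores = np.asarray(self.n_cores, dtype=int)
        if not (self.years.size == self.mean.size == self.se.size == self.n_cores.size):
            raise ValueError("years, mean, se, n_cores must have equal length")
        if np.any(self.n_cores[np.isfinite(self.mean)] < 1):
            raise ValueError("mean defined for a year with no contributing cores")

    @property
    def series(self) -> pd.Series:
        return pd.Series(self.mean, index=pd.Index(self.years, name="year"),
                         name=self.parameter)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "mean": self.mean,
                             "se": self.se, "n_cores": self.n_cores})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, parameter: str = "extension") -> "MasterChronology":
        df = pd.read_csv(path)
        return cls(df["year"].to_numpy(), df["mean"].to_numpy(),
                   df["se"].to_numpy(), df["n_cores"].to_numpy(), parameter=parameter)

    def plot(self, ax=None, **kwargs):
        """Line-plus-SE-envelope plot in the style of multi-core chronology figures."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        ax.plot(self.years, self.mean, color="black", lw=1.5, **kwargs)
        lo = self.mean - np.nan_to_num(self.se)
        hi = self.mean + np.nan_to_num(self.se)
        ax.fill_between(self.years, lo, hi, color="gray", alpha=0.4, lw=0)
        ax.set_xlabel("year")
        ax.set_ylabel(self.parameter)
        return ax


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def normalize_records(records: dict, scheme: NormalizationScheme) -> dict:
    """Additively normalize per-core annual series to common reference periods.

    ``normalized[core][year] = raw[core][year] - own_mean + group_mean``,
    where ``own_mean`` is the core's mean over its assigned reference period
    (full-span mean for excluded cores) and ``group_mean`` is the mean of
    the reference-period means over non-excluded cores assigned to that
    period.  Being an additive shift, year-to-year anomalies within a core
    are untouched.
    """
    own_means = {}
    for core, series in records.items():
        if core not in scheme.assignment:
            raise ValueError(f"core {core!r} has no period assignment")
        a, b = scheme.reference_periods[scheme.assignment[core]]
        if core in scheme.excluded_from_group_mean:
            own_means[core] = float(series.dropna().mean())
        else:
            sub = series.dropna().loc[(series.dropna().index >= a)
                                      & (series.dropna().index <= b)]
            if sub.empty:
                raise ValueError(
                    f"core {core!r} does not overlap its reference period "
                    f"{a}-{b} and is not listed as excluded"
                )
            own_means[core] = float(sub.mean())

    group_means = {}
    for name in scheme.reference_periods:
        members = [c for c, p in scheme.assignment.items()
                   if p == name and c not in scheme.excluded_from_group_mean]
        if members:
            group_means[name] = float(np.mean([own_means[c] for c in members]))
    # a period with only excluded cores falls back to the overall group mean
    overall = float(np.mean([m for m in group_means.values()])) if group_means else 0.0

    out = {}
    for core, series in records.items():
        gm = group_means.get(scheme.assignment[core], overall)
        out[core] = series - own_means[core] + gm
    return out


def build_master(normalized: dict, parameter: str = "extension") -> MasterChronology:
    """Per-year mean, SE (sample SD / sqrt(n)), and replication across cores."""
    if not normalized:
        raise ValueError("no records given")
    df = pd.DataFrame(normalized).sort_index()
    mean = df.mean(axis=1, skipna=True)
    n = df.notna().sum(axis=1)
    sd = df.std(axis=1, ddof=1, skipna=True)
    se = sd / np.sqrt(n)
    se[n < 2] = np.nan
    return MasterChronology(years=df.index.to_numpy(), mean=mean.to_numpy(),
                            se=se.to_numpy(), n_cores=n.to_numpy(),
                            parameter=parameter)


def decadal_means(master: MasterChronology) -> pd.Series:
    """Decadal averages of the master chronology.

    Decades are half-open ``[y, y+10)`` windows anchored at the first year
    divisible by 10 within the span, labeled ``"y-y+10"``; each mean uses
    the years available in that window.
    """
    years = master.years
    first, last = int(years.min()), int(years.max())
    anchor = first if first % 10 == 0 else (first // 10 + 1) * 10
    if anchor + 10 - 1 > last and anchor > first:
        raise ValueError("master must span at least one full decade")
    s = master.series
    out = {}
    y = anchor
    while y <= last:
        window = s.loc[(s.index >= y) & (s.index < y + 10)].dropna()
        if len(window):
            out[f"{y}-{y + 10}"] = float(window.mean())
        y += 10
    return pd.Series(out, name=f"{master.parameter}_decadal_mean")
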