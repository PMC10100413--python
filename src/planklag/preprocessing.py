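"""Standardization of raw plankton records and series transforms.

Raw long-format records (date, taxon, guild, density) are turned into a
monthly :class:`~planklag.containers.DensityPanel` in three steps:
zero-fill of unrecorded taxa on sampled dates, monthly averaging, and
removal of taxa whose monthly series is almost entirely zero.  Metric
series derived from the panel are then made stationary for the lag
analyses by ordinary-least-squares detrending, additive removal of the
mean monthly seasonal cycle, and z-scaling.

Two conventions matter and are fixed here:

* zeros are imputed only for taxa unrecorded on dates when sampling
  happened; calendar months with no sampling at all stay missing;
* the seasonal cycle is estimated on the *detrended* residuals
  (detrend → deseasonalize → scale), and the 12 monthly means are
  centred to sum to zero before subtraction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GUILDS, DensityPanel, MetricSeries

RECORD_COLUMNS = ("date", "taxon", "guild", "density")


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError("no records supplied")
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing required columns: {missing}")
    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    rec["density"] = rec["density"].astype(float)
    if (rec["density"] < 0).any():
        line = int(rec.index[rec["density"] < 0][0])
        raise ValueError(f"negative density at record index {line}")
    bad = set(rec["guild"].unique()) - set(GUILDS)
    if bad:
        raise ValueError(f"unknown guild values: {sorted(bad)}")
    return rec


def fill_unrecorded_with_zero(records: pd.DataFrame) -> pd.DataFrame:
    """Add zero-density records for every (sampling date × taxon) pair absent
    from the input.  Existing records are untouched.  Idempotent."""
    rec = _check_records(records)
    guild_of = dict(zip(rec["taxon"], rec["guild"]))
    dates = rec["date"].unique()
    taxa = list(guild_of)
    full = pd.MultiIndex.from_product([dates, taxa], names=["date", "taxon"])
    have = pd.MultiIndex.from_frame(rec[["date", "taxon"]])
    absent = full.difference(have)
    if len(absent) == 0:
        return rec.reset_index(drop=True)
    fill = pd.DataFrame(
        {
            "date": absent.get_level_values("date"),
            "taxon": absent.get_level_values("taxon"),
        }
    )
    fill["guild"] = fill["taxon"].map(guild_of)
    fill["density"] = 0.0
    out = pd.concat([rec[list(RECORD_COLUMNS)], fill[list(RECORD_COLUMNS)]], ignore_index=True)
    return out.sort_values(["date", "taxon"], kind="stable").reset_index(drop=True)


def monthly_mean(records: pd.DataFrame) -> DensityPanel:
    """Average zero-filled records to mean density per calendar month.

    Months inside the span with no sampling at all are marked missing
    (NaN), not zero."""
    rec = _check_records(records)
    rec["month"] = rec["date"].dt.to_period("M")
    wide = rec.pivot_table(index="month", columns="taxon", values="density", aggfunc="mean")
    wide = wide.sort_index()
    guilds = dict(zip(rec["taxon"], rec["guild"]))
    return DensityPanel(wide, guilds)


def filter_sparse_taxa(panel: DensityPanel, max_zero_fraction: float = 0.99) -> DensityPanel:
    """Drop taxa whose monthly series is more than ``max_zero_fraction``
    zeros (strict inequality; fraction over non-missing months)."""
    keep = []
    for taxon in panel.taxa:
        col = panel.data[taxon].dropna()
        if len(col) == 0:
            continue
        frac = float((col == 0).sum()) / len(col)
        if frac <= max_zero_fraction:
            keep.append(taxon)
    if not keep:
        raise ValueError("all taxa removed by the sparsity filter; panel unusable")
    return panel.subset(keep)


def linear_detrend(series: MetricSeries) -> MetricSeries:
    """Residuals of an OLS line on the integer month index.

    Missing values stay missing and do not enter the fit."""
    y = series.to_numpy()
    ok = np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError(f"series {series.name!r}: need >= 3 non-missing values to detrend")
    t = np.arange(len(y), dtype=float)
    slope, intercept = np.polyfit(t[ok], y[ok], 1)
    resid = y - (slope * t + intercept)
    return series.with_values(resid, detrended=True)


def deseasonalize(series: MetricSeries) -> MetricSeries:
    """Subtract the mean monthly seasonal cycle, centred to sum to zero.

    Expects detrended input (the seasonal means are estimated on the
    detrend residuals).  Raises if any calendar month is entirely
    missing."""
    if not series.detrended:
        raise ValueError(f"series {series.name!r}: detrend before deseasonalizing")
    if len(series) < 24:
        raise ValueError(f"series {series.name!r}: need >= 24 months to estimate seasonality")
    y = series.values
    month_of_year = y.index.month
    means = np.full(13, np.nan)  # 1-based
    for m in range(1, 13):
        vals = y[month_of_year == m].dropna()
        if len(vals) == 0:
            raise ValueError(f"series {series.name!r}: calendar month {m} entirely missing")
        means[m] = vals.mean()
    means[1:] -= np.nanmean(means[1:])  # centre the 12 means to sum to zero
    out = y.to_numpy() - means[month_of_year]
    return series.with_values(out, deseasonalized=True)


def zscale(series: MetricSeries) -> MetricSeries:
    """Scale to zero mean, unit variance (sample sd, n−1 denominator)."""
    y = series.to_numpy()
    ok = np.isfinite(y)
    vals = y[ok]
    if len(np.unique(vals)) < 2:
        raise ValueError(f"series {series.name!r}: need >= 2 distinct values to scale")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError(f"series {series.name!r}: zero variance")
    return series.with_values((y - vals.mean()) / sd, scaled=True)


def standardize(series: MetricSeries) -> MetricSeries:
    """The full stationarity pipeline: detrend → deseasonalize → z-scale."""
    return zscale(deseasonalize(linear_detrend(series)))


def interpolate_gaps(series: MetricSeries, limit: int | None = None) -> MetricSeries:
    """Linearly interpolate internal missing values, flagging the filled
    entries.  Only consumers that need a gap-free grid (delay embedding)
    should use this; leading/trailing gaps are left missing."""
    y = series.values
    filled = y.interpolate(method="linear", limit=limit, limit_area="inside")
    mask = y.isna() & filled.notna()
    prev = series.interpolated if series.interpolated is not None else np.zeros(len(y), bool)
    return series.with_values(filled, interpolated=(prev | mask.to_numpy()))
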