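"""Core in-memory containers shared by every pipeline stage.

Two objects travel through the whole analysis:

``DensityPanel``
    A month × taxon matrix of mean plankton densities (individuals/ml)
    with a guild label (``"phyto"`` or ``"zoo"``) per taxon.  The time
    index is a consecutive monthly :class:`pandas.PeriodIndex`; months
    with no sampling at all hold ``NaN`` (missing), never zero.

``MetricSeries``
    One named monthly scalar series (a system-state metric or a
    functional-diversity metric) together with flags recording which
    transforms (detrend / deseasonalize / z-scale) have been applied and
    a mask of values that were filled by interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GUILDS = ("phyto", "zoo")


@dataclass(frozen=True)
class MetricSeries:
    """A named monthly scalar series with transform provenance flags."""

    name: str
    values: pd.Series  # float values on a monthly PeriodIndex
    detrended: bool = False
    deseasonalized: bool = False
    scaled: bool = False
    interpolated: np.ndarray | None = None  # bool mask aligned with values

    def __post_init__(self) -> None:
        vals = self.values
        if not isinstance(vals, pd.Series):
            raise TypeError("MetricSeries.values must be a pandas Series")
        if not isinstance(vals.index, pd.PeriodIndex) or vals.index.freqstr not in ("M", "ME"):
            raise ValueError(f"series {self.name!r}: index must be a monthly PeriodIndex")
        if not vals.index.is_monotonic_increasing or vals.index.has_duplicates:
            raise ValueError(f"series {self.name!r}: month index must be strictly increasing")
        vals = vals.astype(float)
        object.__setattr__(self, "values", vals)
        if self.interpolated is not None and len(self.interpolated) != len(vals):
            raise ValueError(f"series {self.name!r}: interpolation mask length mismatch")

    # -- convenience -------------------------------------------------
    def __len__(self) -> int:
        return len(self.values)

    @property
    def index(self) -> pd.PeriodIndex:
        return self.values.index

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def with_values(self, new: np.ndarray | pd.Series, **flag_updates) -> "MetricSeries":
        """Copy with replaced values (same index) and updated flags."""
        if isinstance(new, pd.Series):
            series = new
        else:
            series = pd.Series(np.asarray(new, dtype=float), index=self.values.index)
        return replace(self, values=series, **flag_updates)


@dataclass
class DensityPanel:
    """Month × taxon matrix of mean densities plus a taxon → guild map."""

    data: pd.DataFrame  # index: monthly PeriodIndex; columns: taxa
    guilds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.PeriodIndex) or idx.freqstr not in ("M", "ME"):
            raise ValueError("panel index must be a monthly PeriodIndex")
        if idx.has_duplicates or not idx.is_monotonic_increasing:
            raise ValueError("panel month index must be strictly increasing and unique")
        # enforce a consecutive grid: absent months become missing rows
        if len(idx) > 1:
            full = pd.period_range(idx[0], idx[-1], freq="M")
            if not idx.equals(full):
                self.data = self.data.reindex(full)
        self.data = self.data.astype(float)
        with np.errstate(invalid="ignore"):
            if (self.data.to_numpy() < 0).any():
                raise ValueError("panel densities must be non-negative")
        missing = [t for t in self.data.columns if t not in self.guilds]
        if missing:
            raise ValueError(f"taxa without a guild label: {missing[:5]}")
        bad = {g for g in self.guilds.values()} - set(GUILDS)
        if bad:
            raise ValueError(f"unknown guilds: {sorted(bad)}")

    # -- convenience -------------------------------------------------
    @property
    def months(self) -> pd.PeriodIndex:
        return self.data.index

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    def guild_taxa(self, guild: str) -> list[str]:
        if guild not in GUILDS:
            raise ValueError(f"unknown guild {guild!r}; expected one of {GUILDS}")
        return [t for t in self.data.columns if self.guilds[t] == guild]

    def subset(self, taxa: list[str]) -> "DensityPanel":
        return DensityPanel(self.data[taxa].copy(), {t: self.guilds[t] for t in taxa})

    def to_wide_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "month", self.data.index.astype(str))
        out.to_csv(path, index=False)
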