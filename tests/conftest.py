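import numpy as np
import pandas as pd
import pytest

from planklag.containers import DensityPanel, MetricSeries


def make_panel(values: np.ndarray, guilds: list[str] | None = None, start="2000-01") -> DensityPanel:
    """Wrap a month × taxon array into a DensityPanel."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    if guilds is None:
        guilds = ["phyto"] * (k - 1) + ["zoo"] if k > 1 else ["phyto"]
    taxa = [f"t{j}" for j in range(k)]
    months = pd.period_range(start, periods=n, freq="M")
    return DensityPanel(
        pd.DataFrame(values, index=months, columns=taxa),
        dict(zip(taxa, guilds)),
    )


def make_series(values, name="x", start="2000-01", **flags) -> MetricSeries:
    values = np.asarray(values, dtype=float)
    months = pd.period_range(start, periods=len(values), freq="M")
    return MetricSeries(name, pd.Series(values, index=months), **flags)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
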