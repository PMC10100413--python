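"""Five whole-system state series computed from a density panel.

* **Community** — scores on the first principal component of the
  correlation-matrix PCA across taxa (a one-dimensional summary of
  community composition).
* **Density** — natural log of the summed density of all taxa.
* **FI** — Fisher information of the multivariate trajectory inside a
  sliding window: months are grouped into discrete "system states" and
  the information in the state-occupancy distribution is scored;
  decreasing FI indicates decreasing order/stability.
* **MVI** — log of the square root of the dominant eigenvalue of the
  windowed taxon covariance matrix (a multivariate variability index).
* **Z_P ratio** — log ratio of total zooplankton to total phytoplankton
  density (the predator–prey balance).

Log transforms of quantities that can be zero in sparse panels use
log(x + ε) with ε = half the smallest positive observed value of that
quantity (ε = 0 when no zeros occur).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DensityPanel, MetricSeries


@dataclass
class StateMetricSet:
    community: MetricSeries
    density: MetricSeries
    fi: MetricSeries
    mvi: MetricSeries
    zp_ratio: MetricSeries

    def as_dict(self) -> dict[str, MetricSeries]:
        return {
            "community": self.community,
            "density": self.density,
            "fi": self.fi,
            "mvi": self.mvi,
            "zp_ratio": self.zp_ratio,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: v.values for k, v in self.as_dict().items()})


def _log_with_offset(x: np.ndarray) -> np.ndarray:
    """log(x + ε), ε = half the smallest positive value when zeros occur."""
    x = np.asarray(x, dtype=float)
    finite = x[np.isfinite(x)]
    eps = 0.0
    if (finite == 0).any():
        positive = finite[finite > 0]
        if len(positive) == 0:
            raise ValueError("all values zero; log transform undefined")
        eps = 0.5 * positive.min()
    with np.errstate(divide="ignore"):
        out = np.log(x + eps)
    return out


def community_pc1(panel: DensityPanel) -> MetricSeries:
    """PC1 scores of the correlation-matrix PCA across taxa.

    Each taxon series is centred and scaled before the decomposition so
    high-density taxa do not dominate.  The score sign is fixed so the
    loading-weighted mean density correlates non-negatively with the
    scores.  Months with any missing taxon are excluded from the fit
    and carry a missing score."""
    X = panel.data.to_numpy()
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("community_pc1 needs >= 2 taxa and >= 3 months")
    ok = np.isfinite(X).all(axis=1)
    Xc = X[ok]
    sd = Xc.std(axis=0, ddof=1)
    if (sd == 0).all():
        raise ValueError("degenerate panel: all taxa constant")
    keep = sd > 0
    Z = (Xc[:, keep] - Xc[:, keep].mean(axis=0)) / sd[keep]
    # PCA via SVD of the scaled matrix
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[0]
    scores = Z @ loadings
    weighted_mean_density = Xc[:, keep] @ loadings
    c = np.corrcoef(scores, weighted_mean_density)[0, 1]
    if np.isfinite(c) and c < 0:
        scores = -scores
    out = np.full(X.shape[0], np.nan)
    out[ok] = scores
    return MetricSeries("community", pd.Series(out, index=panel.months))


def total_density(panel: DensityPanel) -> MetricSeries:
    """Natural log of the per-month sum of all taxa (both guilds)."""
    total = panel.data.sum(axis=1, min_count=1).to_numpy()
    return MetricSeries("density", pd.Series(_log_with_offset(total), index=panel.months))


def trophic_ratio(panel: DensityPanel) -> MetricSeries:
    """log(Σ zooplankton / Σ phytoplankton) per month."""
    zoo = panel.guild_taxa("zoo")
    phy = panel.guild_taxa("phyto")
    if not zoo or not phy:
        raise ValueError("trophic_ratio needs both guilds in the panel")
    zs = panel.data[zoo].sum(axis=1, min_count=1).to_numpy()
    ps = panel.data[phy].sum(axis=1, min_count=1).to_numpy()
    vals = _log_with_offset(zs) - _log_with_offset(ps)
    return MetricSeries("zp_ratio", pd.Series(vals, index=panel.months))


def fisher_information_window(
    window: np.ndarray, bin_tolerance: float = 2.0, scales: np.ndarray | None = None
) -> float:
    """FI of one gap-free window (months × taxa).

    Months are grouped into discrete system states by first occurrence:
    a month joins the earliest state whose founding month it matches in
    *every* taxon, where two values match when they differ by no more
    than ``bin_tolerance`` × that taxon's measurement scale.  The scale
    plays the role of a fixed per-variable state size; it defaults to
    the sd of the taxon's values in the window, but the sliding-window
    driver passes the full-series sd so the state size does not vary
    from window to window.  A constant taxon has scale 0 and must match
    exactly.  With p_s the occupancy fraction of state s in
    first-occurrence order and q_s = √p_s, FI = 4·Σ (q_s − q_{s+1})²
    including the boundary terms q_0 = q_{m+1} = 0.

    One occupied state gives FI = 8; m equally occupied states give
    8/m, so FI → 0 as states proliferate."""
    W = np.asarray(window, dtype=float)
    if not np.isfinite(W).all():
        return np.nan
    n = W.shape[0]
    if scales is None:
        scales = W.std(axis=0, ddof=1) if n > 1 else np.zeros(W.shape[1])
    tol = bin_tolerance * np.asarray(scales, dtype=float)
    founders: list[np.ndarray] = []
    counts: list[int] = []
    for i in range(n):
        row = W[i]
        for s, f in enumerate(founders):
            if np.all(np.abs(row - f) <= tol):
                counts[s] += 1
                break
        else:
            founders.append(row)
            counts.append(1)
    p = np.asarray(counts, dtype=float) / n
    q = np.sqrt(p)
    q_ext = np.concatenate([[0.0], q, [0.0]])
    return float(4.0 * np.sum(np.diff(q_ext) ** 2))


def fisher_information(
    panel: DensityPanel,
    window_months: int = 48,
    step: int = 1,
    bin_tolerance: float = 2.0,
) -> MetricSeries:
    """Sliding-window Fisher information, assigned to each window's
    final month.  Windows containing missing values yield NaN.  The
    per-taxon state size is ``bin_tolerance`` × the taxon's full-series
    sd, held fixed across windows."""
    if window_months < 8:
        raise ValueError("window_months: must be >= 8")
    X = panel.data.to_numpy()
    T = X.shape[0]
    if window_months > T:
        raise ValueError(f"window ({window_months}) longer than series ({T})")
    scales = np.array(
        [np.nanstd(X[:, j], ddof=1) if np.isfinite(X[:, j]).sum() > 1 else 0.0
         for j in range(X.shape[1])]
    )
    out = np.full(T, np.nan)
    for end in range(window_months - 1, T, step):
        out[end] = fisher_information_window(
            X[end - window_months + 1 : end + 1], bin_tolerance, scales
        )
    return MetricSeries("fi", pd.Series(out, index=panel.months))


def mvi(panel: DensityPanel, window_months: int = 12) -> MetricSeries:
    """log √(dominant eigenvalue) of the windowed taxon covariance
    matrix, assigned to the window's final month.  Windows with missing
    values yield NaN.  The covariance may be singular (more taxa than
    months); the dominant eigenvalue is still defined."""
    if window_months < 2:
        raise ValueError("window_months: must be >= 2")
    X = panel.data.to_numpy()
    T = X.shape[0]
    if window_months > T:
        raise ValueError(f"window ({window_months}) longer than series ({T})")
    out = np.full(T, np.nan)
    for end in range(window_months - 1, T):
        W = X[end - window_months + 1 : end + 1]
        if not np.isfinite(W).all():
            continue
        C = np.cov(W, rowvar=False, ddof=1)
        C = np.atleast_2d(C)
        lam = float(np.linalg.eigvalsh(C)[-1])
        if lam <= 0:
            continue  # degenerate window: no defined variability index
        out[end] = 0.5 * np.log(lam)  # log sqrt(lam)
    return MetricSeries("mvi", pd.Series(out, index=panel.months))


def compute_state_metrics(
    panel: DensityPanel,
    fi_window: int = 48,
    fi_step: int = 1,
    fi_bin_tolerance: float = 2.0,
    mvi_window: int = 12,
) -> StateMetricSet:
    return StateMetricSet(
        community=community_pc1(panel),
        density=total_density(panel),
        fi=fisher_information(panel, fi_window, fi_step, fi_bin_tolerance),
        mvi=mvi(panel, mvi_window),
        zp_ratio=trophic_ratio(panel),
    )
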