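"""Red-noise (AR(1)) surrogate ensembles.

The null model for both the cross-correlation and the cross-mapping
significance tests: pseudorandom series that share the observed series'
mean, variance and lag-1 autocorrelation but none of its deterministic
structure.  Each surrogate follows

    x_1 = w_1,    x_{t+1} = r·x_t + (1 − r²)^{1/2}·w_{t+1}

with w i.i.d. Gaussian matched to the observed mean and variance and r
the AR(1) coefficient fitted to the observed (detrended,
deseasonalized) series.  The (1 − r²)^{1/2} innovation scale makes the
surrogate variance equal the observed variance; an ``as_printed``
variant with (1 + r²)^{1/2} is provided for comparison but inflates the
variance and is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .containers import MetricSeries


@dataclass
class SurrogateEnsemble:
    matrix: np.ndarray  # n × T
    r: float
    noise_mean: float
    noise_sd: float
    seed: int

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def T(self) -> int:
        return self.matrix.shape[1]


def estimate_ar1(series: MetricSeries | np.ndarray, method: str = "mle") -> float:
    """Lag-1 autocorrelation coefficient of a series.

    ``method="mle"`` fits an ARIMA(1,0,0) model by maximum likelihood;
    ``method="yw"`` uses the Yule-Walker moment estimate (faster, used
    only where many fits are needed).  Raises when the fitted process is
    non-stationary (|r| >= 1)."""
    x = series.to_numpy() if isinstance(series, MetricSeries) else np.asarray(series, float)
    x = x[np.isfinite(x)]
    if len(x) < 20:
        raise ValueError("estimate_ar1 needs >= 20 non-missing points")
    if method == "mle":
        import warnings

        from statsmodels.tsa.arima.model import ARIMA

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ARIMA(x, order=(1, 0, 0), trend="c").fit()
        r = float(fit.arparams[0])
    elif method == "yw":
        xc = x - x.mean()
        denom = float(xc @ xc)
        if denom == 0:
            raise ValueError("constant series: AR(1) coefficient undefined")
        r = float(xc[1:] @ xc[:-1]) / denom
    else:
        raise ValueError(f"unknown method {method!r}")
    if not -1 < r < 1:
        raise ValueError(
            f"non-stationary AR(1) fit (r={r:.3f}); detrend/deseasonalize the series first"
        )
    return r


def red_noise_surrogates(
    series: MetricSeries | np.ndarray,
    n: int = 10_000,
    seed: int = 0,
    r: float | None = None,
    as_printed: bool = False,
) -> SurrogateEnsemble:
    """Generate ``n`` red-noise surrogates matched to the observed
    series.  ``r`` may be passed to skip refitting.  Deterministic for
    a fixed seed."""
    if n <= 0:
        raise ValueError("n: must be positive")
    x = series.to_numpy() if isinstance(series, MetricSeries) else np.asarray(series, float)
    obs = x[np.isfinite(x)]
    T = len(x)
    if T < 24:
        raise ValueError("red_noise_surrogates needs series length >= 24")
    if r is None:
        r = estimate_ar1(obs)
    mean, sd = float(obs.mean()), float(obs.std(ddof=1))
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    w = rng.normal(mean, sd, size=(n, T))
    scale = np.sqrt(1.0 + r * r) if as_printed else np.sqrt(1.0 - r * r)
    # recursion x_t = r x_{t-1} + scale·w_t (t >= 2), x_1 = w_1, via an IIR filter
    e = w * scale
    e[:, 0] = w[:, 0]
    matrix = lfilter([1.0], [1.0, -r], e, axis=1)
    return SurrogateEnsemble(matrix=matrix, r=r, noise_mean=mean, noise_sd=sd, seed=seed)
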