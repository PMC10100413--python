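"""Synthetic inputs for every pipeline stage.

Real long-term lake plankton panels are monthly, strongly seasonal,
serially correlated, zero-inflated, and occasionally punctuated by
regime shifts.  The community generator emulates exactly those features
on the log scale: per-taxon log-density = trend + 12-month sinusoid +
AR(1) noise, exponentiated (so densities are non-negative by
construction), with zeros injected afterwards by Bernoulli masking and
an optional step change in mean log-density for a designated subset of
taxa.

Two further generators provide ground truth for the inference stages: a
pair of coupled logistic maps with known (uni/bi-directional) causal
structure for convergent cross mapping, and a red-noise/lagged-copy
pair for lag-recovery checks.

All generators expand one integer seed into independent per-stream
child seeds, so adding a call does not perturb other streams, and a
fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DensityPanel

# ---------------------------------------------------------------------------
# trait-table schema
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitBlock:
    """One trait: a fuzzy block (affinities over categories), a
    categorical trait, or a numeric trait, with a Gower weight."""

    name: str
    kind: str  # "fuzzy" | "categorical" | "numeric"
    categories: tuple[str, ...] = ()
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("fuzzy", "categorical", "numeric"):
            raise ValueError(f"trait block {self.name!r}: unknown kind {self.kind!r}")
        if self.kind in ("fuzzy", "categorical") and len(self.categories) < 2:
            raise ValueError(f"trait block {self.name!r}: needs >= 2 categories")
        if self.weight < 0:
            raise ValueError(f"trait block {self.name!r}: negative weight")

    @property
    def columns(self) -> list[str]:
        if self.kind == "numeric":
            return [self.name]
        return [f"{self.name}.{c}" for c in self.categories]


#: Phytoplankton traits: resource acquisition, reproduction and
#: predator-defence axes (size classes fuzzy-coded; * = fuzzy block).
PHYTO_TRAITS: tuple[TraitBlock, ...] = (
    TraitBlock("cell_length_um", "fuzzy", ("<=10", ">10-25", ">25-100", ">100")),
    TraitBlock(
        "sa_vol_ratio", "fuzzy", ("<0.5", ">0.5-1.0", ">1.0-5.0", ">5.0-10.0", ">10.0")
    ),
    TraitBlock("organic_carbon_ratio", "numeric"),
    TraitBlock("trophy", "categorical", ("autotrophic", "mixotrophic")),
    TraitBlock("nitrogen_fixing", "categorical", ("yes", "no")),
    TraitBlock("filamentous", "categorical", ("yes", "no")),
    TraitBlock("mobility", "categorical", ("none", "flagellated", "rapheated")),
    TraitBlock("colonial", "categorical", ("colonial", "not_colonial")),
    TraitBlock("siliceous", "categorical", ("yes", "no")),
)

#: Zooplankton traits (trait data are scarcer; body size fuzzy-coded).
ZOO_TRAITS: tuple[TraitBlock, ...] = (
    TraitBlock("body_length_mm", "fuzzy", ("<=0.3", ">0.3-0.9", ">0.9-1.5", ">1.5")),
    TraitBlock(
        "trophic_group",
        "categorical",
        ("herbivore", "omnivore", "carnivore", "omnicarnivore", "omniherbivore"),
    ),
    TraitBlock(
        "feeding_mode",
        "categorical",
        (
            "bosmina_filtration",
            "chydorus_filtration",
            "daphnia_filtration",
            "microfagous",
            "raptorial",
            "sida_filtration",
            "suspension",
        ),
    ),
    TraitBlock(
        "reproductive_mechanism",
        "categorical",
        ("sexual", "asexual", "cyclic_parthenogenesis"),
    ),
)

GUILD_TRAITS = {"phyto": PHYTO_TRAITS, "zoo": ZOO_TRAITS}


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class CommunitySimConfig:
    """Lake-like community panel.  Defaults mirror the observed study
    systems: 33 years of monthly data, a modest phytoplankton guild and
    a small zooplankton guild, seasonal cycles and red noise."""

    n_phyto: int = 18
    n_zoo: int = 6
    n_months: int = 396
    season_amplitude: float = 0.8  # log-density units, per-taxon scale drawn around this
    ar_coefficient: float = 0.6
    noise_sd: float = 0.5
    regime_shift_month: int | None = None
    regime_shift_magnitude: float = 0.0
    zero_inflation: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_months < 24:
            raise ValueError("n_months: must be >= 24")
        if self.n_phyto < 2:
            raise ValueError("n_phyto: must be >= 2")
        if self.n_zoo < 2:
            raise ValueError("n_zoo: must be >= 2")
        if not -1 < self.ar_coefficient < 1:
            raise ValueError("ar_coefficient: must lie in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd: must be >= 0")
        if self.season_amplitude < 0:
            raise ValueError("season_amplitude: must be >= 0")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation: must lie in [0, 1)")
        if self.regime_shift_month is not None and not (
            0 < self.regime_shift_month < self.n_months
        ):
            raise ValueError("regime_shift_month: must be inside the series")


@dataclass
class CoupledLogisticConfig:
    """Two coupled logistic maps; the standard benchmark system for
    cross-mapping causality.  ``beta_xy`` is the effect of y on x and
    ``beta_yx`` the effect of x on y (zero = no influence)."""

    r_x: float = 3.8
    r_y: float = 3.5
    beta_xy: float = 0.02
    beta_yx: float = 0.1
    n_steps: int = 1000
    burn_in: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.n_steps < 10:
            raise ValueError("n_steps: must be >= 10")
        if self.burn_in < 0:
            raise ValueError("burn_in: must be >= 0")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def _ar1_noise(rng: np.random.Generator, n: int, r: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    w = rng.normal(0.0, 1.0, n)
    x = np.empty(n)
    x[0] = w[0]
    s = np.sqrt(1.0 - r * r)
    for t in range(1, n):
        x[t] = r * x[t - 1] + s * w[t]
    return sd * x


def simulate_community(
    config: CommunitySimConfig,
) -> tuple[DensityPanel, dict[str, pd.DataFrame]]:
    """Generate a monthly density panel plus per-guild trait tables.

    Returns ``(panel, {"phyto": traits, "zoo": traits})``.  When a
    regime shift is configured, the first half of each guild's taxa
    shifts its mean log-density by ``regime_shift_magnitude`` from
    ``regime_shift_month`` onward.
    """
    config.validate()
    n_taxa = config.n_phyto + config.n_zoo
    rng_struct, rng_noise, rng_zero, rng_tr_p, rng_tr_z = _child_rngs(config.seed, 5)

    taxa = [f"phy_{i:03d}" for i in range(config.n_phyto)] + [
        f"zoo_{i:03d}" for i in range(config.n_zoo)
    ]
    guilds = {t: ("phyto" if t.startswith("phy") else "zoo") for t in taxa}

    months = pd.period_range("1985-01", periods=config.n_months, freq="M")
    t = np.arange(config.n_months, dtype=float)

    base_log = rng_struct.normal(1.5, 0.8, n_taxa)  # mean log-density per taxon
    trend = rng_struct.normal(0.0, 0.2, n_taxa) / max(config.n_months, 1)
    amp = config.season_amplitude * rng_struct.uniform(0.5, 1.5, n_taxa)
    phase = rng_struct.uniform(0.0, 2 * np.pi, n_taxa)

    log_density = np.empty((config.n_months, n_taxa))
    for j in range(n_taxa):
        seasonal = amp[j] * np.sin(2 * np.pi * t / 12.0 + phase[j])
        noise = _ar1_noise(rng_noise, config.n_months, config.ar_coefficient, config.noise_sd)
        log_density[:, j] = base_log[j] + trend[j] * t + seasonal + noise

    shifted: list[str] = []
    if config.regime_shift_month is not None and config.regime_shift_magnitude != 0.0:
        # first half of each guild responds to the shift
        idx = list(range(config.n_phyto // 2)) + [
            config.n_phyto + i for i in range(config.n_zoo // 2)
        ]
        shifted = [taxa[j] for j in idx]
        log_density[config.regime_shift_month :, idx] += config.regime_shift_magnitude

    density = np.exp(log_density)
    if config.zero_inflation > 0:
        mask = rng_zero.random(density.shape) < config.zero_inflation
        density[mask] = 0.0

    panel = DensityPanel(pd.DataFrame(density, index=months, columns=taxa), guilds)
    panel.shifted_taxa = shifted  # type: ignore[attr-defined]

    traits = {
        "phyto": _trait_table(taxa[: config.n_phyto], "phyto", rng_tr_p),
        "zoo": _trait_table(taxa[config.n_phyto :], "zoo", rng_tr_z),
    }
    return panel, traits


def _trait_table(taxa: list[str], guild: str, rng: np.random.Generator) -> pd.DataFrame:
    rows: dict[str, np.ndarray | list] = {}
    blocks = GUILD_TRAITS[guild]
    n = len(taxa)
    for block in blocks:
        if block.kind == "fuzzy":
            # sparse Dirichlet: most taxa have affinity concentrated in 1-2 classes
            aff = rng.dirichlet(np.full(len(block.categories), 0.5), size=n)
            for k, col in enumerate(block.columns):
                rows[col] = aff[:, k]
        elif block.kind == "categorical":
            rows[block.name] = rng.choice(block.categories, size=n).tolist()
        else:
            rows[block.name] = np.round(rng.lognormal(-1.0, 0.5, n), 4)
    df = pd.DataFrame(rows, index=pd.Index(taxa, name="taxon"))
    return df


def generate_trait_table(n_taxa: int, guild: str, seed: int = 0) -> pd.DataFrame:
    """Stand-alone trait table for ``n_taxa`` taxa of one guild."""
    if guild not in GUILD_TRAITS:
        raise ValueError(f"unknown guild {guild!r}; expected 'phyto' or 'zoo'")
    if n_taxa < 2:
        raise ValueError("n_taxa: must be >= 2")
    (rng,) = _child_rngs(seed, 1)
    prefix = "phy" if guild == "phyto" else "zoo"
    taxa = [f"{prefix}_{i:03d}" for i in range(n_taxa)]
    return _trait_table(taxa, guild, rng)


def simulate_coupled_logistic(config: CoupledLogisticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the coupled logistic pair

    ``x(t+1) = x(t)·(r_x − r_x·x(t) − beta_xy·y(t))``
    ``y(t+1) = y(t)·(r_y − r_y·y(t) − beta_yx·x(t))``

    discarding the first ``burn_in`` steps.  Raises if a trajectory
    leaves (0, 1), naming the offending step."""
    config.validate()
    (rng,) = _child_rngs(config.seed, 1)
    total = config.n_steps + config.burn_in
    x = np.empty(total)
    y = np.empty(total)
    x[0], y[0] = rng.uniform(0.2, 0.8, 2)
    for t in range(total - 1):
        x[t + 1] = x[t] * (config.r_x - config.r_x * x[t] - config.beta_xy * y[t])
        y[t + 1] = y[t] * (config.r_y - config.r_y * y[t] - config.beta_yx * x[t])
        if not (0.0 < x[t + 1] < 1.0 and 0.0 < y[t + 1] < 1.0):
            raise ValueError(f"coupled logistic diverged outside (0,1) at step {t + 1}")
    return x[config.burn_in :], y[config.burn_in :]


def simulate_lagged_pair(
    k: int, noise_sd: float, n: int, seed: int = 0, ar_coefficient: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    """A red-noise base series and a partner that repeats it ``k`` steps
    later: ``partner(t) = base(t − k) + white noise``.  Both are returned
    aligned on a common index of length ``n``.

    The cross-correlation of (base, partner) therefore peaks at lag
    ``+k`` under the convention statistic(j) = corr(base_t, partner_{t+j}).
    """
    if abs(k) >= n / 4:
        raise ValueError(f"|k|={abs(k)} too large for n={n} (need |k| < n/4)")
    if noise_sd < 0:
        raise ValueError("noise_sd: must be >= 0")
    rng_base, rng_noise = _child_rngs(seed, 2)
    pad = abs(k)
    base_full = _ar1_noise(rng_base, n + 2 * pad, ar_coefficient, 1.0)
    base = base_full[pad : pad + n]
    partner = base_full[pad - k : pad - k + n].copy()
    if noise_sd > 0:
        partner += rng_noise.normal(0.0, noise_sd, n)
    return base, partner
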