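"""End-to-end orchestration: simulate/ingest → preprocess → state
metrics → functional diversity → lagged cross-correlation → lagged CCM
→ report bundle, behind one YAML-serializable config with a single seed.

Every stage is also callable on its own (the CLI exposes them as
subcommands over persisted intermediates); ``run_full_analysis`` wires
them together in memory and writes the result tables:

* ``state_metrics.csv`` / ``fd_metrics.csv`` — raw monthly series;
* ``associations.tsv`` — one row per FD × state pair (30 with the
  default two guilds × three FD × five state metrics);
* ``ccm.tsv`` — one row per pair per direction (60);
* ``classifications.tsv`` — paired-lag causality labels (30);
* ``manifest.json`` — seed, config hash, package versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ccm import classify_pair, ccm_skill, convergence_test, lagged_ccm, select_E
from .containers import DensityPanel, MetricSeries
from .functional_diversity import (
    FuzzyTraitMatrix,
    embed_trait_space,
    fd_series,
    gower_dissimilarity,
)
from .lagged_association import classify
from .preprocessing import (
    fill_unrecorded_with_zero,
    filter_sparse_taxa,
    interpolate_gaps,
    monthly_mean,
    standardize,
)
from .state_metrics import compute_state_metrics
from .surrogates import red_noise_surrogates
from .synthetic_data import GUILD_TRAITS, CommunitySimConfig, simulate_community

log = logging.getLogger(__name__)

FD_METRICS = ("fric", "fdis", "feve")
STATE_METRICS = ("community", "density", "fi", "mvi", "zp_ratio")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PreprocessingConfig:
    max_zero_fraction: float = 0.99
    interpolation_limit: int | None = None


@dataclass
class StateConfig:
    fi_window: int = 48
    fi_step: int = 1
    fi_bin_tolerance: float = 2.0
    mvi_window: int = 12


@dataclass
class FDConfig:
    max_dim: int = 10
    cailliez_correction: bool = True


@dataclass
class AssociationConfig:
    max_lag: int = 60
    n_surrogates: int = 10_000
    quantiles: tuple[float, float] = (0.025, 0.975)
    strongest_mode: str = "max"


@dataclass
class CCMConfig:
    E_min: int = 1
    E_max: int = 10
    max_tp: int = 60
    n_surrogates: int = 10_000
    library_samples: int = 100
    library_grid_points: int = 8
    synchrony_band: int = 12
    surrogate_mode: str = "predictor"
    as_printed_surrogates: bool = False
    tau: int = 1


@dataclass
class AnalysisConfig:
    seed: int = 0
    simulation: CommunitySimConfig = field(default_factory=CommunitySimConfig)
    density_csv: str | None = None  # when set, read instead of simulating
    trait_csvs: dict[str, str] = field(default_factory=dict)  # guild -> path
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    state: StateConfig = field(default_factory=StateConfig)
    fd: FDConfig = field(default_factory=FDConfig)
    association: AssociationConfig = field(default_factory=AssociationConfig)
    ccm: CCMConfig = field(default_factory=CCMConfig)

    # -- YAML round-trip ---------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["association"]["quantiles"] = list(self.association.quantiles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        sub = {
            "simulation": CommunitySimConfig,
            "preprocessing": PreprocessingConfig,
            "state": StateConfig,
            "fd": FDConfig,
            "association": AssociationConfig,
            "ccm": CCMConfig,
        }
        kwargs = {}
        for key, klass in sub.items():
            if key in d:
                kwargs[key] = klass(**d.pop(key))
        if "association" in kwargs:
            q = kwargs["association"].quantiles
            kwargs["association"].quantiles = (float(q[0]), float(q[1]))
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def smoke_config(seed: int = 0) -> AnalysisConfig:
    """A fast profile for continuous testing: 200 surrogates, lags ±24,
    a reduced library grid, and a smaller simulated community.  The
    paper-faithful profile (10,000 surrogates, lags ±60) is the
    documented default of :class:`AnalysisConfig`."""
    cfg = AnalysisConfig(seed=seed)
    cfg.simulation = CommunitySimConfig(n_phyto=12, n_zoo=5, n_months=240, seed=seed)
    cfg.association.max_lag = 24
    cfg.association.n_surrogates = 200
    cfg.ccm.max_tp = 24
    cfg.ccm.n_surrogates = 200
    cfg.ccm.library_samples = 20
    cfg.ccm.library_grid_points = 4
    cfg.ccm.E_max = 6
    cfg.fd.max_dim = 6
    return cfg


# ---------------------------------------------------------------------------
# CSV ingestion
# ---------------------------------------------------------------------------


def read_density_csv(path) -> pd.DataFrame:
    """Strictly parse a long-format density CSV (date, taxon, guild,
    density), reporting the offending line on failure."""
    df = pd.read_csv(path, dtype=str)
    required = ["date", "taxon", "guild", "density"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            pd.Timestamp(row.date)
        except (ValueError, TypeError):
            raise ValueError(f"{path}:{i}: unparseable date {row.date!r}") from None
        try:
            dens = float(row.density)
        except (ValueError, TypeError):
            raise ValueError(f"{path}:{i}: unparseable density {row.density!r}") from None
        if dens < 0:
            raise ValueError(f"{path}:{i}: negative density {dens}")
        if row.guild not in ("phyto", "zoo"):
            raise ValueError(f"{path}:{i}: unknown guild {row.guild!r}")
    df["density"] = df["density"].astype(float)
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_density_csv(panel: DensityPanel, path) -> None:
    """Emit the long-format CSV the pipeline reads (synthetic data
    round-trips through the public entry points)."""
    rows = []
    for month in panel.months:
        date = month.to_timestamp().date().isoformat()
        for taxon in panel.taxa:
            v = panel.data.at[month, taxon]
            if np.isfinite(v):
                rows.append((date, taxon, panel.guilds[taxon], v))
    pd.DataFrame(rows, columns=["date", "taxon", "guild", "density"]).to_csv(path, index=False)


def series_frame(series: dict[str, MetricSeries]) -> pd.DataFrame:
    out = pd.DataFrame({k: v.values for k, v in series.items()})
    out.insert(0, "month", out.index.astype(str))
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# stage functions
# ---------------------------------------------------------------------------


def build_panel(config: AnalysisConfig) -> tuple[DensityPanel, dict[str, pd.DataFrame]]:
    """Simulate a community (or ingest CSVs) and apply the sparsity
    filter."""
    if config.density_csv:
        records = read_density_csv(config.density_csv)
        records = fill_unrecorded_with_zero(records)
        panel = monthly_mean(records)
        traits = {
            guild: pd.read_csv(path, index_col="taxon")
            for guild, path in config.trait_csvs.items()
        }
    else:
        panel, traits = simulate_community(config.simulation)
    panel = filter_sparse_taxa(panel, config.preprocessing.max_zero_fraction)
    traits = {g: t.loc[[x for x in t.index if x in set(panel.taxa)]] for g, t in traits.items()}
    return panel, traits


def compute_fd(
    panel: DensityPanel, traits: dict[str, pd.DataFrame], fd_cfg: FDConfig
) -> dict[str, MetricSeries]:
    """Six FD series: three metrics × two guilds."""
    out: dict[str, MetricSeries] = {}
    for guild in ("phyto", "zoo"):
        matrix = FuzzyTraitMatrix.from_table(traits[guild], GUILD_TRAITS[guild])
        D = gower_dissimilarity(matrix)
        space = embed_trait_space(D, fd_cfg.max_dim, fd_cfg.cailliez_correction)
        fds = fd_series(panel, space, guild)
        for metric, series in fds.as_dict().items():
            out[f"{guild}_{metric}"] = series
    return out


def _standardized(series: MetricSeries, interp_limit: int | None) -> MetricSeries:
    return standardize(interpolate_gaps(series, interp_limit))


def _child_seeds(seed: int, n: int) -> np.ndarray:
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    return rng.integers(0, 2**31 - 1, size=n)


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------


def run_full_analysis(config: AnalysisConfig, out_dir) -> dict:
    """Run every stage and write the report bundle to ``out_dir``.

    Returns a dict with the in-memory tables.  On a stage failure the
    outputs written so far are retained and the manifest records the
    failure point."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "planklag_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "stages_completed": [],
        "failed_stage": None,
    }
    bundle: dict = {}
    stage = "simulate"
    try:
        panel, traits = build_panel(config)
        bundle["panel"] = panel
        panel.to_wide_csv(out / "panel.csv")
        manifest["stages_completed"].append(stage)

        stage = "state_metrics"
        states = compute_state_metrics(
            panel,
            fi_window=config.state.fi_window,
            fi_step=config.state.fi_step,
            fi_bin_tolerance=config.state.fi_bin_tolerance,
            mvi_window=config.state.mvi_window,
        ).as_dict()
        series_frame(states).to_csv(out / "state_metrics.csv", index=False)
        bundle["state"] = states
        manifest["stages_completed"].append(stage)

        stage = "functional_diversity"
        fd = compute_fd(panel, traits, config.fd)
        series_frame(fd).to_csv(out / "fd_metrics.csv", index=False)
        bundle["fd"] = fd
        manifest["stages_completed"].append(stage)

        stage = "standardize"
        interp = config.preprocessing.interpolation_limit
        std_state = {k: _standardized(v, interp) for k, v in states.items()}
        std_fd = {k: _standardized(v, interp) for k, v in fd.items()}
        manifest["stages_completed"].append(stage)

        stage = "associations"
        bundle["associations"] = associations_table(std_fd, std_state, config)
        bundle["associations"].to_csv(out / "associations.tsv", sep="\t", index=False)
        manifest["stages_completed"].append(stage)

        stage = "ccm"
        ccm_table, class_table, pair_details = ccm_tables(std_fd, std_state, config)
        ccm_table.to_csv(out / "ccm.tsv", sep="\t", index=False)
        class_table.to_csv(out / "classifications.tsv", sep="\t", index=False)
        (out / "ccm_pairs.json").write_text(json.dumps(pair_details, indent=1, sort_keys=True))
        bundle["ccm"] = ccm_table
        bundle["classifications"] = class_table
        manifest["stages_completed"].append(stage)
    except Exception as exc:  # record the failure point, keep partials
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle


def associations_table(
    std_fd: dict[str, MetricSeries],
    std_state: dict[str, MetricSeries],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """One row per FD × state pair: lag-0 and strongest-lag correlation
    calls against the red-noise null."""
    acfg = config.association
    pairs = [(f, s) for f in sorted(std_fd) for s in STATE_METRICS]
    seeds = _child_seeds(config.seed, len(pairs))
    rows = []
    for (fd_name, st_name), seed in zip(pairs, seeds):
        x = std_fd[fd_name]
        ens = red_noise_surrogates(x, n=acfg.n_surrogates, seed=int(seed))
        profile = classify(
            x,
            std_state[st_name],
            ens,
            max_lag=acfg.max_lag,
            quantiles=acfg.quantiles,
            strongest_mode=acfg.strongest_mode,
        )
        guild, metric = fd_name.split("_", 1)
        rows.append(
            {"guild": guild, "fd_metric": metric, "state_metric": st_name, **profile.as_row()}
        )
    return pd.DataFrame(rows)


def ccm_tables(
    std_fd: dict[str, MetricSeries],
    std_state: dict[str, MetricSeries],
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Lagged CCM in both directions for every FD × state pair, plus the
    paired-lag classification table and per-pair JSON details."""
    ccfg = config.ccm
    E_range = range(ccfg.E_min, ccfg.E_max + 1)
    # E per series, selected once on the standardized (detrended) form
    E_of: dict[str, int] = {}
    for name, series in {**std_fd, **std_state}.items():
        E_of[name] = select_E(series, E_range, tau=ccfg.tau)
    pairs = [(f, s) for f in sorted(std_fd) for s in STATE_METRICS]
    seeds = _child_seeds(config.seed + 1, 2 * len(pairs))
    rows, class_rows = [], []
    details: dict = {}
    for i, (fd_name, st_name) in enumerate(pairs):
        guild, metric = fd_name.split("_", 1)
        profiles = {}
        for j, (pred_name, tgt_name, dir_label) in enumerate(
            [
                (fd_name, st_name, "fd_xmap_state"),
                (st_name, fd_name, "state_xmap_fd"),
            ]
        ):
            E = E_of[pred_name]
            prof = lagged_ccm(
                {**std_fd, **std_state}[pred_name],
                {**std_fd, **std_state}[tgt_name],
                E=E,
                max_tp=ccfg.max_tp,
                tau=ccfg.tau,
                n_surrogates=ccfg.n_surrogates,
                seed=int(seeds[2 * i + j]),
                direction=dir_label,
                surrogate_mode=ccfg.surrogate_mode,
            )
            # convergence at the optimal offset
            res = ccm_skill(
                {**std_fd, **std_state}[pred_name],
                {**std_fd, **std_state}[tgt_name],
                E=E,
                tp=prof.optimal_tp,
                n_samples=ccfg.library_samples,
                library_sizes=None,
                seed=int(seeds[2 * i + j]),
                tau=ccfg.tau,
                direction=dir_label,
            )
            convergent = convergence_test(res)
            profiles[dir_label] = prof
            rows.append(
                {
                    "guild": guild,
                    "fd_metric": metric,
                    "state_metric": st_name,
                    "direction": dir_label,
                    "gloss": (
                        f"{pred_name} manifold predicts {tgt_name} "
                        f"(tests {tgt_name} -> {pred_name} causation)"
                    ),
                    "E": E,
                    "optimal_tp": prof.optimal_tp,
                    "skill_at_optimal": prof.skill_at_optimal,
                    "null_q95": prof.null_q95,
                    "significant": prof.significant,
                    "convergent": convergent,
                }
            )
            details[f"{fd_name}|{st_name}|{dir_label}"] = {
                "E": E,
                "tps": prof.tps.tolist(),
                "skills": [None if not np.isfinite(s) else round(float(s), 6) for s in prof.skills],
                "optimal_tp": prof.optimal_tp,
                "null_q95": prof.null_q95,
                "significant": prof.significant,
                "library_sizes": res.library_sizes.tolist(),
                "library_skills": [round(float(s), 6) for s in res.skills],
                "convergent": convergent,
            }
        summary = classify_pair(
            profiles["fd_xmap_state"], profiles["state_xmap_fd"], ccfg.synchrony_band
        )
        class_rows.append(
            {
                "guild": guild,
                "fd_metric": metric,
                "state_metric": st_name,
                "forward_tp": profiles["fd_xmap_state"].optimal_tp,
                "reverse_tp": profiles["state_xmap_fd"].optimal_tp,
                "classification": summary.classification,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(class_rows), details
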