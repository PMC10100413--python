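"""Trait-based functional diversity from fuzzy-coded trait tables.

The chain is: species-level trait records → fuzzy-coded taxon × trait
matrix (affinities per category, so a genus-level taxon carries the
plasticity of its member species) → Gower dissimilarity over mixed
trait blocks → principal-coordinates embedding into a Euclidean trait
space of at most ``max_dim`` axes → three per-month community metrics:

* **FRic** — convex-hull volume of the present taxa, normalized by the
  hull of all taxa in the same space (∈ [0, 1]);
* **FDis** — abundance-weighted mean distance to the abundance-weighted
  centroid;
* **FEve** — evenness of abundance along the minimum spanning tree of
  the present taxa (∈ [0, 1]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .containers import DensityPanel, MetricSeries
from .synthetic_data import TraitBlock

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fuzzy-coded trait matrix
# ---------------------------------------------------------------------------


@dataclass
class FuzzyTraitMatrix:
    """Taxon × trait matrix with every fuzzy/categorical block expressed
    as affinity columns (rows summing to 1 per block) and numeric traits
    as single columns."""

    data: pd.DataFrame  # index: taxa; columns per block
    blocks: tuple[TraitBlock, ...]
    excluded: list[str] = field(default_factory=list)  # taxa dropped for lack of data

    def __post_init__(self) -> None:
        for block in self.blocks:
            if block.kind == "numeric":
                if block.name not in self.data.columns:
                    raise ValueError(f"numeric trait {block.name!r} missing from table")
                continue
            cols = block.columns
            missing = [c for c in cols if c not in self.data.columns]
            if missing:
                raise ValueError(f"block {block.name!r} missing columns {missing}")
            aff = self.data[cols].to_numpy(dtype=float)
            rowsum = np.nansum(aff, axis=1)
            has_data = ~np.isnan(aff).all(axis=1)
            if np.any(np.abs(rowsum[has_data] - 1.0) > 1e-9):
                raise ValueError(f"block {block.name!r}: affinity rows must sum to 1")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @classmethod
    def from_table(cls, table: pd.DataFrame, blocks: tuple[TraitBlock, ...]) -> "FuzzyTraitMatrix":
        """Build from a taxon-level table where each block is either
        already affinity columns (``block.category``) or a single label
        column (converted to one-hot affinities)."""
        cols: dict[str, np.ndarray] = {}
        for block in blocks:
            if block.kind == "numeric":
                cols[block.name] = table[block.name].to_numpy(dtype=float)
            elif set(block.columns) <= set(table.columns):
                for c in block.columns:
                    cols[c] = table[c].to_numpy(dtype=float)
            elif block.name in table.columns:
                labels = table[block.name]
                for cat, c in zip(block.categories, block.columns):
                    cols[c] = (labels == cat).astype(float).to_numpy()
            else:
                raise ValueError(f"block {block.name!r} not found in trait table")
        return cls(pd.DataFrame(cols, index=table.index), blocks)


def fuzzy_code(
    species_records: pd.DataFrame,
    blocks: tuple[TraitBlock, ...],
    taxon_col: str = "taxon",
) -> FuzzyTraitMatrix:
    """Aggregate species-level trait records to taxon-level affinities.

    For a fuzzy or categorical block given as a label column, a taxon's
    affinity to each category is the fraction of its member species
    assigned to that category; blocks already given as affinity columns
    are averaged over species and re-normalized.  Numeric traits are
    averaged.  Taxa with no usable trait data are listed on the result's
    ``excluded`` attribute and dropped (a warning is logged)."""
    if taxon_col not in species_records.columns:
        raise ValueError(f"species records need a {taxon_col!r} column")
    grouped = species_records.groupby(taxon_col, sort=True)
    taxa, rows, excluded = [], [], []
    for taxon, grp in grouped:
        row: dict[str, float] = {}
        any_data = False
        for block in blocks:
            if block.kind == "numeric":
                if block.name in grp.columns:
                    v = grp[block.name].astype(float).mean()
                    row[block.name] = v
                    any_data = any_data or np.isfinite(v)
                else:
                    row[block.name] = np.nan
                continue
            if set(block.columns) <= set(grp.columns):
                aff = grp[list(block.columns)].to_numpy(dtype=float)
                mean = np.nanmean(aff, axis=0)
                total = np.nansum(mean)
                if total > 0:
                    mean = mean / total
                    any_data = True
                else:
                    mean = np.full(len(block.columns), np.nan)
            elif block.name in grp.columns:
                labels = grp[block.name].dropna()
                if len(labels):
                    counts = labels.value_counts()
                    mean = np.array(
                        [counts.get(cat, 0) / len(labels) for cat in block.categories]
                    )
                    any_data = True
                else:
                    mean = np.full(len(block.categories), np.nan)
            else:
                mean = np.full(len(block.categories), np.nan)
            for c, v in zip(block.columns, mean):
                row[c] = v
        if any_data:
            taxa.append(taxon)
            rows.append(row)
        else:
            excluded.append(taxon)
    if excluded:
        log.warning("fuzzy_code: excluded taxa with no trait data: %s", excluded)
    if not taxa:
        raise ValueError("no taxon has any trait data")
    df = pd.DataFrame(rows, index=pd.Index(taxa, name="taxon"))
    return FuzzyTraitMatrix(df, blocks, excluded=excluded)


# ---------------------------------------------------------------------------
# Gower dissimilarity
# ---------------------------------------------------------------------------


def gower_dissimilarity(traits: FuzzyTraitMatrix) -> pd.DataFrame:
    """Weighted Gower dissimilarity over mixed trait blocks, in [0, 1].

    Numeric block: |xi − xj| / range.  Fuzzy/categorical block: half the
    Manhattan distance between affinity vectors.  The overall value is
    the weighted mean over blocks where both taxa have data; a pair with
    no shared block raises."""
    n = len(traits.data)
    if n < 2:
        raise ValueError("gower_dissimilarity needs >= 2 taxa")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for block in traits.blocks:
        if block.kind == "numeric":
            x = traits.data[block.name].to_numpy(dtype=float)
            ok = np.isfinite(x)
            rng = np.nanmax(x) - np.nanmin(x) if ok.any() else 0.0
            if rng > 0:
                d = np.abs(x[:, None] - x[None, :]) / rng
            else:
                d = np.zeros((n, n))
            valid = ok[:, None] & ok[None, :]
        else:
            aff = traits.data[block.columns].to_numpy(dtype=float)
            ok = np.isfinite(aff).all(axis=1)
            d = 0.5 * np.abs(aff[:, None, :] - aff[None, :, :]).sum(axis=2)
            valid = ok[:, None] & ok[None, :]
        d = np.where(valid, d, 0.0)
        num += block.weight * d
        den += block.weight * valid
    if (den == 0).any():
        i, j = np.argwhere(den == 0)[0]
        raise ValueError(
            f"taxa {traits.taxa[i]!r} and {traits.taxa[j]!r} share no trait block"
        )
    D = num / den
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    return pd.DataFrame(D, index=traits.data.index, columns=traits.data.index)


# ---------------------------------------------------------------------------
# trait space (principal coordinates)
# ---------------------------------------------------------------------------


@dataclass
class TraitSpace:
    """Euclidean embedding of a dissimilarity matrix (PCoA axes,
    variance-ordered)."""

    coordinates: pd.DataFrame  # taxa × m
    eigenvalues: np.ndarray
    cailliez_constant: float = 0.0

    @property
    def taxa(self) -> list[str]:
        return list(self.coordinates.index)

    @property
    def m(self) -> int:
        return self.coordinates.shape[1]

    def points(self, taxa: list[str], n_dims: int | None = None) -> np.ndarray:
        pts = self.coordinates.loc[taxa].to_numpy()
        return pts if n_dims is None else pts[:, :n_dims]


def _double_centre(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * J @ (D**2) @ J


def _cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant making D + c (off-diagonal) Euclidean
    (Cailliez 1983): the largest real eigenvalue of a 2n × 2n block
    matrix built from the double-centred forms of D² and D."""
    n = D.shape[0]
    delta1 = _double_centre(D)
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    delta2 = -0.5 * J @ D @ J
    upper = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    lower = np.hstack([-np.eye(n), -4.0 * delta2])
    eig = np.linalg.eigvals(np.vstack([upper, lower]))
    real = eig[np.abs(eig.imag) < 1e-8].real
    return float(max(real.max(), 0.0))


def embed_trait_space(
    dissimilarity: pd.DataFrame, max_dim: int = 10, correct_negative: bool = True
) -> TraitSpace:
    """Principal-coordinates analysis with an additive (Cailliez)
    correction for negative eigenvalues.  Retains
    m = min(max_dim, n_taxa − 1, number of positive eigenvalues) axes."""
    D = dissimilarity.to_numpy(dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("embed_trait_space needs >= 3 taxa")
    if not np.allclose(D, D.T, atol=1e-12) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("dissimilarity must be symmetric with zero diagonal")
    c = 0.0
    lam, vec = np.linalg.eigh(_double_centre(D))
    tol = 1e-8 * max(abs(lam[0]), abs(lam[-1]), 1.0)
    if correct_negative and lam[0] < -tol:
        c = _cailliez_constant(D)
        Dc = D + c
        np.fill_diagonal(Dc, 0.0)
        lam, vec = np.linalg.eigh(_double_centre(Dc))
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    positive = lam > tol
    m = int(min(max_dim, n - 1, positive.sum()))
    if m < 1:
        raise ValueError("no positive eigenvalues; dissimilarity carries no structure")
    coords = vec[:, :m] * np.sqrt(lam[:m])
    return TraitSpace(
        pd.DataFrame(coords, index=dissimilarity.index,
                     columns=[f"pcoa_{i + 1}" for i in range(m)]),
        eigenvalues=lam,
        cailliez_constant=c,
    )


# ---------------------------------------------------------------------------
# the three FD metrics
# ---------------------------------------------------------------------------


def _hull_volume(points: np.ndarray) -> float:
    """Convex-hull volume; an interval length in 1-D.  NaN when the
    point set is degenerate for its dimension."""
    d = points.shape[1]
    if d == 1:
        return float(points.max() - points.min())
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return np.nan


def fric(space: TraitSpace, present: list[str]) -> float:
    """Functional richness: hull volume of the present taxa divided by
    the hull volume of all taxa, both in m_eff = min(m, S − 1)
    dimensions (the leading PCoA axes).  NaN when fewer than m_eff + 1
    taxa are present or the point set is degenerate."""
    S = len(present)
    m_eff = min(space.m, S - 1)
    if m_eff < 1 or S < m_eff + 1:
        return np.nan
    vol = _hull_volume(space.points(present, m_eff))
    total = _hull_volume(space.points(space.taxa, m_eff))
    if not np.isfinite(vol) or not np.isfinite(total) or total == 0:
        return np.nan
    return vol / total


def fdis(space: TraitSpace, abundances: dict[str, float] | pd.Series) -> float:
    """Functional dispersion: abundance-weighted mean distance to the
    abundance-weighted centroid.  Zero for a single present taxon."""
    w = pd.Series(abundances, dtype=float)
    w = w[w > 0]
    if w.sum() <= 0:
        raise ValueError("fdis needs positive total abundance")
    pts = space.points(list(w.index))
    weights = w.to_numpy() / w.sum()
    centroid = weights @ pts
    dist = np.linalg.norm(pts - centroid, axis=1)
    return float(weights @ dist)


def feve(space: TraitSpace, abundances: dict[str, float] | pd.Series) -> float:
    """Functional evenness: regularity of abundance along the minimum
    spanning tree of the present taxa.

    Branch l joining taxa i, j gets EW_l = dist(i,j)/(w_i + w_j);
    PEW_l = EW_l / Σ EW; FEve = (Σ min(PEW_l, 1/(S−1)) − 1/(S−1)) /
    (1 − 1/(S−1)).  NaN for fewer than 3 present taxa."""
    w = pd.Series(abundances, dtype=float)
    w = w[w > 0]
    S = len(w)
    if S < 3:
        return np.nan
    pts = space.points(list(w.index))
    D = squareform(pdist(pts))
    mst = minimum_spanning_tree(D).tocoo()
    wv = w.to_numpy()
    ew = mst.data / (wv[mst.row] + wv[mst.col])
    if ew.sum() == 0:
        return np.nan
    pew = ew / ew.sum()
    thresh = 1.0 / (S - 1)
    return float((np.minimum(pew, thresh).sum() - thresh) / (1.0 - thresh))


# ---------------------------------------------------------------------------
# monthly FD series
# ---------------------------------------------------------------------------


@dataclass
class FDSeries:
    fric: MetricSeries
    fdis: MetricSeries
    feve: MetricSeries

    def as_dict(self) -> dict[str, MetricSeries]:
        return {"fric": self.fric, "fdis": self.fdis, "feve": self.feve}


def fd_series(panel: DensityPanel, space: TraitSpace, guild: str) -> FDSeries:
    """Monthly FRic/FDis/FEve for one guild.  A taxon is present in a
    month when its density is strictly positive; densities serve as
    abundance weights.  Months failing a metric's preconditions carry
    missing values."""
    taxa = [t for t in panel.guild_taxa(guild) if t in set(space.taxa)]
    missing = set(panel.guild_taxa(guild)) - set(taxa)
    if missing:
        raise ValueError(f"panel taxa absent from trait space: {sorted(missing)[:5]}")
    sub = panel.data[taxa]
    T = len(panel.months)
    out = {k: np.full(T, np.nan) for k in ("fric", "fdis", "feve")}
    for i in range(T):
        row = sub.iloc[i]
        if row.isna().any():
            continue
        present = row[row > 0]
        if len(present) == 0:
            continue
        if len(present) >= 2:
            out["fric"][i] = fric(space, list(present.index))
        out["fdis"][i] = fdis(space, present) if len(present) >= 1 else np.nan
        if len(present) == 1:
            out["fdis"][i] = 0.0
        out["feve"][i] = feve(space, present)
    idx = panel.months
    return FDSeries(
        fric=MetricSeries(f"{guild}_fric", pd.Series(out["fric"], index=idx)),
        fdis=MetricSeries(f"{guild}_fdis", pd.Series(out["fdis"], index=idx)),
        feve=MetricSeries(f"{guild}_feve", pd.Series(out["feve"], index=idx)),
    )
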