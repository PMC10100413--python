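"""Empirical dynamic modelling: simplex projection and convergent
cross mapping (CCM) with lagged prediction offsets.

CCM tests whether variable B causally forces variable A by asking how
well A's delay-embedded manifold predicts B ("A xmap B"): if B drives
A, B's history is written into A's dynamics and the cross-map skill
(Pearson ρ between cross-mapped predictions and observations) rises —
converges — as the library of delay vectors grows.  A signed prediction
offset tp shifts the predicted value of B relative to the library
vectors; scanning tp over ±max_lag months locates the lead-lag
structure of the causal signal, and paired forward/reverse scans
classify which variable leads.

Neighbor search uses the E+1 nearest delay vectors with exponential
weights exp(−d/d_min), a Theiler exclusion window of
max(tau·E, |tp|) around the prediction target to prevent
serial-correlation leakage, and uniform weights over tied sets when
d_min = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .containers import MetricSeries
from .surrogates import estimate_ar1, red_noise_surrogates


def _as_array(series) -> np.ndarray:
    if isinstance(series, MetricSeries):
        return series.to_numpy()
    return np.asarray(series, dtype=float)


# ---------------------------------------------------------------------------
# delay embedding
# ---------------------------------------------------------------------------


@dataclass
class Embedding:
    """Delay vectors (x_t, x_{t−tau}, …, x_{t−(E−1)tau}) for every time
    t with no missing component."""

    E: int
    tau: int
    vectors: np.ndarray  # n_valid × E
    times: np.ndarray  # time index of each vector (its most recent component)
    T: int  # length of the source series


def delay_embed(series, E: int, tau: int = 1) -> Embedding:
    x = _as_array(series)
    if E < 1:
        raise ValueError("E: must be >= 1")
    if tau < 1:
        raise ValueError("tau: must be >= 1")
    T = len(x)
    start = (E - 1) * tau
    if T - start < E + 2:
        raise ValueError(f"series too short for E={E}, tau={tau} (usable vectors < E+2)")
    times = np.arange(start, T)
    M = np.column_stack([x[times - i * tau] for i in range(E)])
    ok = np.isfinite(M).all(axis=1)
    if ok.sum() < E + 2:
        raise ValueError(f"fewer than E+2 gap-free delay vectors (E={E})")
    return Embedding(E=E, tau=tau, vectors=M[ok], times=times[ok], T=T)


# ---------------------------------------------------------------------------
# nearest-neighbor simplex prediction
# ---------------------------------------------------------------------------


def _simplex_predict(dist: np.ndarray, lib_targets: np.ndarray, k: int) -> np.ndarray:
    """Weighted nearest-neighbor prediction for each row of a (queries ×
    library) distance matrix.  Inadmissible entries must be +inf.  Rows
    with fewer than k admissible neighbors predict NaN."""
    n_q = dist.shape[0]
    k = min(k, dist.shape[1])
    idx = np.argpartition(dist, k - 1, axis=1)[:, :k]
    rows = np.arange(n_q)[:, None]
    d = dist[rows, idx]
    pred = np.full(n_q, np.nan)
    usable = np.isfinite(d).all(axis=1)
    if not usable.any():
        return pred
    du = d[usable]
    dmin = du.min(axis=1, keepdims=True)
    with np.errstate(over="ignore"):
        w = np.where(dmin > 0, np.exp(-du / np.where(dmin > 0, dmin, 1.0)), (du == 0).astype(float))
    # d_min = 0: uniform over the tied (zero-distance) set
    wsum = w.sum(axis=1, keepdims=True)
    w = w / wsum
    pred[usable] = (w * lib_targets[idx[usable]]).sum(axis=1)
    return pred


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return np.nan
    a, b = a[ok] - a[ok].mean(), b[ok] - b[ok].mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float(a @ b / denom)


def default_theiler(E: int, tau: int, tp: int) -> int:
    return max(tau * E, abs(tp))


def simplex_skill(series, E: int, tp: int = 1, tau: int = 1, theiler: int | None = None) -> float:
    """Leave-one-out simplex forecast skill of a series tp steps ahead.

    Each delay vector is predicted from its E+1 nearest neighbors
    outside the Theiler window; skill is the Pearson ρ between the
    predictions and the observed values."""
    x = _as_array(series)
    emb = delay_embed(x, E, tau)
    if theiler is None:
        theiler = default_theiler(E, tau, tp)
    tgt_time = emb.times + tp
    valid = (tgt_time >= 0) & (tgt_time < emb.T)
    valid[valid] &= np.isfinite(x[tgt_time[valid]])
    if valid.sum() < E + 2:
        raise ValueError("too few vectors with a valid forecast target")
    V = emb.vectors[valid]
    t = emb.times[valid]
    targets = x[t + tp]
    if np.nanstd(targets) == 0:
        raise ValueError("constant series: forecast skill undefined")
    dist = cdist(V, V)
    excl = np.abs(t[:, None] - t[None, :]) <= theiler
    dist[excl] = np.inf
    pred = _simplex_predict(dist, targets, E + 1)
    return _pearson(pred, targets)


def select_E(series, E_range=range(1, 11), tau: int = 1, tp: int = 1) -> int:
    """Embedding dimension maximizing simplex skill at tp (ties →
    smallest E)."""
    best_E, best_skill = None, -np.inf
    for E in E_range:
        try:
            s = simplex_skill(series, E, tp=tp, tau=tau)
        except ValueError:
            continue
        if np.isfinite(s) and s > best_skill + 1e-12:
            best_E, best_skill = E, s
    if best_E is None:
        raise ValueError("no embedding dimension yields a defined forecast skill")
    return best_E


# ---------------------------------------------------------------------------
# convergent cross mapping
# ---------------------------------------------------------------------------


@dataclass
class CCMResult:
    """Cross-map skill of direction ``A xmap B`` (A's manifold predicts
    B, testing B's causal influence on A)."""

    direction: str
    E: int
    tau: int
    tp: int
    library_sizes: np.ndarray
    skills: np.ndarray  # mean skill per library size
    sample_skills: dict[int, np.ndarray] = field(default_factory=dict)
    convergent: bool | None = None
    significant: bool | None = None
    optimal_tp: int | None = None
    null_q95: float | None = None

    @property
    def skill(self) -> float:
        """Skill at the largest library."""
        return float(self.skills[-1])


def _geometric_sizes(lo: int, hi: int, n: int) -> np.ndarray:
    sizes = np.unique(np.round(np.geomspace(lo, hi, n)).astype(int))
    return sizes[(sizes >= lo) & (sizes <= hi)]


def ccm_skill(
    predictor,
    target,
    E: int,
    tp: int = 0,
    library_sizes: np.ndarray | list[int] | None = None,
    n_samples: int = 100,
    seed: int = 0,
    tau: int = 1,
    theiler: int | None = None,
    direction: str = "A xmap B",
) -> CCMResult:
    """Cross-map skill of ``predictor xmap target`` over a grid of
    library sizes.

    For each library size L, ``n_samples`` random subsets of the
    predictor's delay vectors form the library; the target series is
    predicted at offset tp via simplex weights and skill is the mean
    Pearson ρ across samples.  At the maximum L the full library is
    used once (sampling without replacement of everything)."""
    A, B = _as_array(predictor), _as_array(target)
    if len(A) != len(B):
        raise ValueError("predictor and target must share length")
    emb = delay_embed(A, E, tau)
    if theiler is None:
        theiler = default_theiler(E, tau, tp)
    tgt_time = emb.times + tp
    valid = (tgt_time >= 0) & (tgt_time < emb.T)
    valid[valid] &= np.isfinite(B[tgt_time[valid]])
    V = emb.vectors[valid]
    t = emb.times[valid]
    targets = B[t + tp]
    N = len(V)
    if N < E + 2:
        raise ValueError("too few usable delay vectors for cross mapping")
    if library_sizes is None:
        library_sizes = _geometric_sizes(E + 2, N, 8)
    sizes = np.asarray(sorted(int(s) for s in library_sizes))
    sizes = sizes[sizes <= N]
    usable = sizes[sizes >= E + 2]
    if len(usable) < len(sizes):
        import logging

        logging.getLogger(__name__).warning(
            "skipping library sizes below E+2=%d", E + 2
        )
    sizes = usable
    dist = cdist(V, V)
    excl = np.abs(t[:, None] - t[None, :]) <= theiler
    dist_full = dist.copy()
    dist_full[excl] = np.inf
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    k = E + 1
    skills = np.empty(len(sizes))
    sample_skills: dict[int, np.ndarray] = {}
    for si, L in enumerate(sizes):
        if L >= N:
            s = _pearson(_simplex_predict(dist_full, targets, k), targets)
            sample_skills[int(L)] = np.array([s])
            skills[si] = s
            continue
        vals = np.empty(n_samples)
        for rep in range(n_samples):
            lib = rng.choice(N, size=L, replace=False)
            dsub = dist_full[:, lib]
            pred = _simplex_predict(dsub, targets[lib], k)
            vals[rep] = _pearson(pred, targets)
        sample_skills[int(L)] = vals
        skills[si] = np.nanmean(vals)
    return CCMResult(
        direction=direction,
        E=E,
        tau=tau,
        tp=tp,
        library_sizes=sizes,
        skills=skills,
        sample_skills=sample_skills,
    )


def convergence_test(result: CCMResult, margin: float = 0.05) -> bool:
    """Convergence check: skill at the largest library must exceed the
    95th percentile of the sampled skills at the smallest library, by at
    least ``margin``."""
    if len(result.library_sizes) < 2:
        raise ValueError("convergence_test needs >= 2 library sizes")
    lo = int(result.library_sizes[0])
    lo_samples = result.sample_skills[lo]
    if len(lo_samples) < 20:
        raise ValueError("convergence_test needs >= 20 samples at the smallest library")
    q95 = float(np.nanquantile(lo_samples, 0.95))
    top = result.skill
    flag = bool(np.isfinite(top) and top > q95 and (top - q95) >= margin)
    result.convergent = flag
    return flag


# ---------------------------------------------------------------------------
# lagged CCM
# ---------------------------------------------------------------------------


@dataclass
class LaggedCCMProfile:
    direction: str
    E: int
    tps: np.ndarray
    skills: np.ndarray  # full-library skill per tp
    optimal_tp: int
    skill_at_optimal: float
    null_q95: float | None
    significant: bool | None
    null_skills: np.ndarray | None = None


def _full_library_skill(
    A: np.ndarray, B: np.ndarray, E: int, tau: int, tp: int, theiler: int | None = None
) -> float:
    emb = delay_embed(A, E, tau)
    if theiler is None:
        theiler = default_theiler(E, tau, tp)
    tgt_time = emb.times + tp
    valid = (tgt_time >= 0) & (tgt_time < emb.T)
    valid[valid] &= np.isfinite(B[tgt_time[valid]])
    if valid.sum() < E + 2:
        return np.nan
    V = emb.vectors[valid]
    t = emb.times[valid]
    targets = B[t + tp]
    dist = cdist(V, V)
    dist[np.abs(t[:, None] - t[None, :]) <= theiler] = np.inf
    return _pearson(_simplex_predict(dist, targets, E + 1), targets)


def lagged_ccm(
    predictor,
    target,
    E: int,
    max_tp: int = 60,
    tau: int = 1,
    n_surrogates: int = 1000,
    seed: int = 0,
    direction: str = "A xmap B",
    surrogate_mode: str = "predictor",  # "predictor" | "both"
    ar1_method: str = "mle",
    tie_tolerance: float = 1e-4,
) -> LaggedCCMProfile:
    """Full-library cross-map skill for every prediction offset
    tp ∈ [−max_tp, +max_tp]; the optimal tp is the argmax, with offsets
    whose skills are within ``tie_tolerance`` of the maximum treated as
    tied and resolved toward the smallest |tp| (skill estimates are
    noisy; parsimony prefers the shortest delay among indistinguishable
    ones).  Significance compares the observed skill at the optimal tp
    with the 95th percentile of skills obtained when red-noise
    surrogates replace the predictor (and, optionally, the target
    too)."""
    A, B = _as_array(predictor), _as_array(target)
    tps = np.arange(-max_tp, max_tp + 1)
    skills = np.array([_full_library_skill(A, B, E, tau, int(tp)) for tp in tps])
    if not np.isfinite(skills).any():
        raise ValueError("no prediction offset yields a defined skill")
    finite = np.where(np.isfinite(skills), skills, -np.inf)
    near = finite >= finite.max() - tie_tolerance
    candidates = np.flatnonzero(near)
    ibest = int(candidates[np.lexsort((tps[candidates], np.abs(tps[candidates])))[0]])
    opt_tp = int(tps[ibest])
    opt_skill = float(skills[ibest])
    null_q95 = None
    significant = None
    null_skills = None
    if n_surrogates > 0:
        r_a = estimate_ar1(A[np.isfinite(A)], method=ar1_method)
        ens_a = red_noise_surrogates(A, n=n_surrogates, seed=seed, r=r_a).matrix
        if surrogate_mode == "both":
            r_b = estimate_ar1(B[np.isfinite(B)], method=ar1_method)
            ens_b = red_noise_surrogates(B, n=n_surrogates, seed=seed + 1, r=r_b).matrix
        elif surrogate_mode != "predictor":
            raise ValueError(f"unknown surrogate_mode {surrogate_mode!r}")
        null_skills = np.empty(n_surrogates)
        for i in range(n_surrogates):
            sa = ens_a[i]
            sb = B if surrogate_mode == "predictor" else ens_b[i]
            null_skills[i] = _full_library_skill(sa, sb, E, tau, opt_tp)
        null_q95 = float(np.nanquantile(null_skills, 0.95))
        significant = bool(opt_skill > null_q95)
    return LaggedCCMProfile(
        direction=direction,
        E=E,
        tps=tps,
        skills=skills,
        optimal_tp=opt_tp,
        skill_at_optimal=opt_skill,
        null_q95=null_q95,
        significant=significant,
        null_skills=null_skills,
    )


# ---------------------------------------------------------------------------
# paired-lag direction classification
# ---------------------------------------------------------------------------

CLASSIFICATIONS = ("synchronous", "fd_leads", "state_leads", "bidirectional_equal", "none")


@dataclass
class CausalPairSummary:
    forward: LaggedCCMProfile  # FD xmap state
    reverse: LaggedCCMProfile  # state xmap FD
    classification: str


def classify_pair(
    forward: LaggedCCMProfile, reverse: LaggedCCMProfile, synchrony_band: int = 12
) -> CausalPairSummary:
    """Paired-lag causality-direction classification.

    Precedence: (1) significance gate — if neither mapping beats its
    null the pair is "none"; (2) crossing test — optimal lags of
    opposite sign mean the pairing line crosses the zero-lag line and
    one side leads (forward negative / reverse positive → FD leads,
    the mirror image → state leads); (3) synchrony band — both optimal
    lags within ±synchrony_band months → "synchronous"; (4) equal lags
    on both sides outside the band → "bidirectional_equal"; anything
    else → "none"."""
    f_tp, r_tp = forward.optimal_tp, reverse.optimal_tp
    f_sig = bool(forward.significant) if forward.significant is not None else True
    r_sig = bool(reverse.significant) if reverse.significant is not None else True
    if not (f_sig or r_sig):
        label = "none"
    elif f_tp < 0 < r_tp:
        label = "fd_leads"
    elif r_tp < 0 < f_tp:
        label = "state_leads"
    elif abs(f_tp) <= synchrony_band and abs(r_tp) <= synchrony_band:
        label = "synchronous"
    elif f_tp == r_tp:
        label = "bidirectional_equal"
    else:
        label = "none"
    return CausalPairSummary(forward=forward, reverse=reverse, classification=label)
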