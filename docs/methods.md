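# Methods

This note records the models, conventions, numerical choices and known
limitations behind `planklag`. It is written for a reader who wants to
know exactly what each number means, which defaults matter, and what a
passing test suite does and does not demonstrate about real lake data.

## 1. Data model and standardization

The unit of analysis is a monthly density panel: a month × taxon matrix
of mean plankton densities (individuals/ml) with a guild label
(`phyto`/`zoo`) per taxon, on a strictly consecutive monthly index.
Raw inputs are long-format records `(date, taxon, guild, density)`.

Conventions, fixed once:

* **Zero-fill.** If sampling happened on a date but a known taxon was
  not recorded, its density on that date is zero. Calendar months with
  *no sampling at all* are missing (NaN), never zero. Zero-filling is
  idempotent.
* **Monthly mean.** Cell values are arithmetic means over the sampling
  dates inside each calendar month; imputed zeros enter the mean.
* **Sparsity filter.** A taxon is dropped when strictly more than 99%
  of its non-missing monthly values are zero (keeping rare species is
  deliberate; series that are almost entirely zero break the
  downstream ordination and embedding steps). Exactly 99% is retained.
* **Stationarity transforms**, applied in this order to every metric
  series before any lag analysis: OLS **detrend** on the integer month
  index → **deseasonalize** (subtract each calendar month's mean of
  the detrended values, the 12 means centred to sum to zero) →
  **z-scale** (sample sd, n−1 denominator; {0,2} → ±0.7071).
  Detrending and deseasonalizing are each idempotent to 1e-8.
* **Gaps.** Missing values propagate through the transforms. Only the
  delay-embedding consumer requires a gap-free grid; internal gaps are
  linearly interpolated there and the filled points are flagged.
  Leading/trailing gaps are never invented.

## 2. State metrics

Five monthly series summarize system state. Log transforms of
quantities that can be zero use log(x + ε) with ε = half the smallest
positive observed value of that quantity (ε = 0 when no zeros occur);
this keeps sparse synthetic panels finite without distorting months
away from zero.

* **Community** — scores on the first principal component of the
  *correlation*-matrix PCA across taxa (each taxon series centred and
  scaled first, so abundant taxa do not dominate). The score sign is
  fixed so the loading-weighted mean density correlates non-negatively
  with the scores; sign is irrelevant to every downstream significance
  call (|r| and cross-map skill are sign-free). Computed on scaled
  densities; whether raw, log or scaled densities are used upstream is
  a declared choice, flagged here.
* **Density** — natural log of the per-month sum over all taxa.
* **Z_P ratio** — log(Σ zoo / Σ phyto) per month.
* **MVI** — for each sliding window (default 12 months) the covariance
  matrix of the taxon series is formed and log √(largest eigenvalue)
  is assigned to the window's final month. A single full-series
  covariance would give one number, not a series; the window length is
  a knob. Windows containing missing values yield NaN. The covariance
  may be singular (more taxa than months); the dominant eigenvalue is
  still defined.
* **FI (Fisher information)** — within each sliding window (default 48
  months, step 1) the multivariate monthly observations are grouped
  into discrete *system states*: scanning months in order, a month
  joins the earliest state whose founding month it matches in every
  taxon, two values matching when they differ by at most
  `bin_tolerance` × the taxon's measurement scale. With p_s the
  occupancy fraction of state s in first-occurrence order and
  q_s = √p_s, FI = 4·Σ (q_s − q_{s+1})² with boundary terms
  q_0 = q_{m+1} = 0, assigned to the window's final month. One state
  gives FI = 8; m equally occupied states give 8/m → 0.

  **State-size choice.** The measurement scale is the taxon's
  *full-series* standard deviation, held fixed across windows
  (multiplier default 2; both are knobs). A scale recomputed per
  window — whether from successive differences or within-window
  spread — makes the state size depend on how ordered the window is,
  which inverts the intended behavior: shuffling a series inflates a
  difference-based scale and merges genuinely distinct regimes into
  one state. A fixed per-variable state size is also what the binned
  construction assumes (it plays the role of measurement uncertainty).
  With this choice an ordered regime scores higher FI than the same
  panel with shuffled months in 100/100 simulation replicates.
  Matching is `<=`, so an exactly constant panel (scale 0) forms one
  state and yields FI = 8 exactly.

## 3. Functional diversity

* **Fuzzy coding.** Taxa are often resolved to genus/family while
  traits are species-level. A taxon's affinity to each category of a
  fuzzy or categorical trait block is the fraction of its member
  species in that category (rows sum to 1 per block); numeric traits
  are averaged. Single-species taxa become one-hot. Taxa with no
  usable trait data are excluded *and listed*, never silently dropped.
* **Gower dissimilarity** over mixed blocks: numeric → |xᵢ − xⱼ|/range
  (0 if the trait has zero range); fuzzy/categorical → half the
  Manhattan distance between affinity vectors (∈ [0,1]); overall value
  = weighted mean over blocks where both taxa have data. Blocks are
  equally weighted by default (weights are a knob). Output is
  symmetric, zero-diagonal, in [0,1], and matches a per-pair loop
  implementation to 1e-12.
* **Trait space.** Principal coordinates (classical MDS) of the Gower
  matrix. Negative eigenvalues (Gower is generally non-Euclidean) are
  handled by the additive Cailliez correction — the smallest constant
  c added to off-diagonal dissimilarities that makes them Euclidean,
  obtained as the largest eigenvalue of the standard 2n × 2n companion
  problem — chosen because it is deterministic; a knob disables it.
  m = min(max_dim, n_taxa − 1, #positive eigenvalues) axes are kept,
  max_dim = 10 by default: convex-hull estimation in higher dimensions
  is numerically fragile, which is the reason the dimension is capped.
  Euclidean inputs round-trip exactly (c = 0, distances reproduced to
  1e-8).
* **FRic** — hull volume of the present taxa divided by the hull of
  *all* taxa in the same space, so FRic ∈ [0,1] and is comparable
  across months (the normalization is this package's explicit choice).
  Dimension fallback: both hulls are computed in
  m_eff = min(m, S_present − 1) leading axes, because a month with S
  taxa cannot support an m ≥ S dimensional hull (zooplankton guilds
  can have as few as 4 taxa); m_eff = 1 degrades to an interval-length
  ratio. Degenerate (coplanar) point sets yield a flagged missing
  value, not zero.
* **FDis** — weighted centroid c = Σ wⱼxⱼ/Σ wⱼ; FDis = Σ wⱼ‖xⱼ − c‖ /
  Σ wⱼ. Zero for a single present taxon. Invariant to rigid motions of
  the space and to uniform weight scaling.
* **FEve** — minimum spanning tree over present taxa; branch l joining
  i,j has EW_l = dist(i,j)/(wᵢ + wⱼ), PEW_l = EW_l/Σ EW,
  FEve = (Σ min(PEW_l, 1/(S−1)) − 1/(S−1)) / (1 − 1/(S−1)) ∈ [0,1];
  missing for S < 3.
* **Monthly series.** A taxon is present when its density is strictly
  positive (no relative-abundance cutoff — rare species are kept on
  purpose); raw densities serve as weights (FDis/FEve are
  scale-invariant, so raw vs relative abundance only matters through
  presence, which it does not change). Months failing a metric's
  preconditions carry missing values.

## 4. Red-noise surrogates

The null model throughout is an AR(1) ("red noise") process matched to
the observed series:

    x₁ = w₁,   x_{t+1} = r·x_t + (1 − r²)^{1/2}·w_{t+1}

with w i.i.d. Gaussian with the observed mean and variance, and r the
AR(1) coefficient fitted by ARIMA(1,0,0) maximum likelihood on the
detrended, deseasonalized series (a Yule-Walker option exists for
bulk fitting). The (1 − r²)^{1/2} innovation scale is what makes the
surrogate variance equal the observed variance (the stationary form);
an `as_printed` variant with (1 + r²)^{1/2} is provided for comparison
but inflates the variance by (1 + r²)/(1 − r²) and is not the default.
Non-stationary fits (|r| ≥ 1) are rejected with advice to detrend.

Fidelity at r = 0.7, T = 396: the ensemble-mean lag-1 autocorrelation
is within ±0.03 of r. The per-surrogate sample variance is unbiased
but disperses with relative sd √(2(1+r²)/((1−r²)T)) ≈ 0.12 — an
unavoidable property of stationary AR(1) sample variances — so a
[0.8, 1.25] band around the observed variance captures ≈93% of
surrogates, not more, at these settings.

## 5. Lagged cross-correlation

For series x (an FD metric) and y (a state metric), both standardized,
the statistic at signed lag j ∈ [−max_lag, +max_lag] (default ±60) is
the Pearson correlation of x_t with y_{t+j} over the pairwise-complete
overlap (missing below 10 points). **Sign convention:** a peak at
*positive* j means x's values reappear in y j months later — x leads;
a peak at negative j means y leads. The profile is antisymmetric under
argument exchange: ccf(x,y)(j) = ccf(y,x)(−j).

Two significance calls against an ensemble (default 10,000) of
red-noise surrogates substituted for x:

* **Lag 0** — the observed r outside the per-lag 2.5%/97.5% empirical
  quantiles. Calibration: on independent red-noise pairs the
  rejection rate is ≈5% (500 replicates × 1000 surrogates → 0.056).
* **Strongest lag** — the observed max |r| over all lags against the
  95th percentile of the null distribution of per-surrogate *maxima*.
  Testing the maximum against per-lag bands would be biased by
  selection over the 121 lags; the maxima distribution controls this,
  and is by construction never laxer than any single-lag threshold
  (asserted at run time). A per-lag alternative mode exists.

## 6. Lagged convergent cross mapping

* **Embedding.** Delay vectors (x_t, x_{t−τ}, …, x_{t−(E−1)τ}), τ = 1
  month (knob). E is chosen per series, once, on the standardized
  series, as the argmax of leave-one-out simplex forecast skill at
  tp = 1 over E = 1…10 (ties to the smallest E), and reused across all
  prediction offsets.
* **Simplex prediction.** E+1 nearest neighbors with weights
  exp(−d/d_min); when d_min = 0 the weights fall back to uniform over
  the tied set. A Theiler exclusion window of max(τ·E, |tp|) around
  the prediction target removes serially correlated neighbors.
* **Cross mapping.** "A xmap B": B is predicted from A's delay
  manifold; success means B's history is encoded in A's dynamics, i.e.
  B causally influences A. Every output row carries a plain-language
  gloss because this inversion is a standing source of confusion.
  Library sizes grow on a geometric grid from E+2 to the maximum (8
  points, 100 random subsets per size by default; the full library is
  used once at the top). **Convergence**: skill at the largest library
  must exceed the 95th percentile of sampled skills at the smallest
  library by ≥ 0.05.
* **Lag scan.** Full-library skill at every offset tp ∈ ±60. The
  optimal tp is the argmax, with skills within 1e-4 of the maximum
  treated as tied and resolved toward the smallest |tp|: skill
  estimates are noisy, and for any offset whose prediction target
  falls *inside* the delay vector the skill is near-identical, forming
  a plateau that extends E−1 steps below the true lag (an argmax
  without the tie rule is biased by ≈ −(E−1)/2). The lag-recovery
  fixtures use E = 1 — the true Markov order of their AR(1) base
  series — where the peak is sharp; recovery there is exact to ±1
  month for injected lags up to ±24 at noise sd 0.25, n = 480.
* **Significance.** Observed skill at the optimal tp against the 95th
  percentile of skills when red-noise surrogates replace the predictor
  (substituting both series is a knob).
* **Paired-lag classification.** With `forward` = FD xmap state and
  `reverse` = state xmap FD, precedence is: (1) significance gate — if
  neither direction beats its null: *none*; (2) crossing — optimal
  lags of strictly opposite sign mean the pairing line crosses the
  zero-lag line: forward < 0 < reverse → *FD-leads*, reverse < 0 <
  forward → *state-leads*; (3) synchrony band — both |tp| ≤ 12 months
  → *synchronous*; (4) equal lags outside the band →
  *bidirectional-equal*; (5) anything else (significant, non-crossing,
  unequal, outside the band) has no meaningful lead–lag label and maps
  to *none*.

## 7. Synthetic data: what it emulates, and what it does not

Per-taxon log-density = base level + small linear trend + 12-month
sinusoid (amplitude drawn per taxon around `season_amplitude`) + AR(1)
noise (coefficient `ar_coefficient`, marginal sd `noise_sd`);
exponentiation guarantees non-negativity; zeros are then injected by
Bernoulli masking at rate `zero_inflation` (real records contain true
zeros); an optional regime shift adds `regime_shift_magnitude` to the
mean log-density of the first half of each guild's taxa from
`regime_shift_month` on. Defaults — 18 phytoplankton and 6 zooplankton
taxa, 396 months (33 years), ar = 0.6, noise sd = 0.5, season
amplitude 0.8, 5% zeros — sit inside the ranges long-term lake
monitoring series actually span. One global seed expands into
independent child streams per generator, so adding a call never
perturbs other streams, and fixed seeds give bit-identical output.

The generator does **not** emulate: trophic coupling between guilds
(guild series are independent), observation-effort changes, taxonomic
reassignments mid-series, non-sinusoidal or drifting phenology, or
trait–abundance covariation (trait tables are drawn independently of
dynamics). Passing tests therefore demonstrate that the *estimators
and tests* behave correctly on data with realistic marginal structure
(seasonality, autocorrelation, zero inflation, regime shifts, known
causal direction); they do not validate ecological conclusions about
any real lake.

Ground-truth fixtures: the coupled logistic pair
x(t+1) = x(t)(r_x − r_x·x(t) − β_xy·y(t)),
y(t+1) = y(t)(r_y − r_y·y(t) − β_yx·x(t)) (burn-in discarded;
divergence outside (0,1) is an error naming the step) provides known
unidirectional/bidirectional causality; the lagged pair
(base red noise, partner(t) = base(t−k) + white noise) provides known
lead-lag structure.

## 8. Problem sizes and profiles

The default profile is the analysis-faithful one: 10,000 surrogates,
lags ±60, E ≤ 10, 100 library subsamples. The shipped *smoke* profile
(`smoke_config()`) — 200 surrogates, lags ±24, 20 library subsamples,
a 4-point library grid, E ≤ 6, a 240-month 17-taxon community — is the
package's fast-iteration profile; it exercises every code path and
completes a full run in well under a minute, and is what the
combinatorics/determinism checks use. Simulation-based checks size
their replicate counts to the quantity being estimated (e.g. 500
replicates × 1000 surrogates for the type-I rate; 50 seeds for
direction recovery; 100 for the FI order comparison).

## 9. Known limitations

* FI is reported only where a window is gap-free; its value depends on
  the declared state-size convention (§2), and comparisons should keep
  that convention fixed.
* FRic in months with few taxa uses the m_eff fallback and is not
  strictly comparable to full-dimension months; such months are
  identifiable from the taxon counts.
* The CCM lag scan inherits the plateau ambiguity of delay-coordinate
  targets (§6); optimal lags from large-E embeddings carry a known
  downward bias of up to E−1 months, mitigated but not eliminated by
  the tie rule.
* Surrogate significance substitutes the predictor only (by default);
  with strong shared seasonality imperfectly removed, this null can be
  liberal.
* `estimate_ar1` fits AR(1) by MLE; series with strong remaining
  structure (e.g. un-removed trends) are rejected rather than
  silently accommodated.
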