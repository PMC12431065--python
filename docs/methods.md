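# Methods

This note documents the models, the parameter choices, the synthetic data
the package is validated on, and the numerical decisions — in enough detail
that a user can judge what the tests do and do not demonstrate.

## State-space model and Kalman imputation

Each pixel's index series is a structural time series: a local linear trend
(level L_t, slope β_t), a dummy-variable seasonal block of period s whose
s consecutive values sum to zero in expectation, and white observation
noise. The state vector `[L, β, S_t, …, S_{t−s+2}]` has dimension s+1; the
observation reads L_t + S_t. All four disturbance parameters are standard
deviations and are squared when the covariances are built (an
`as_variance` flag flips the interpretation).

Parameter defaults, per series:

| parameter | default | units | rationale |
|---|---|---|---|
| θ₁ (level) | 0.07·x̄/3 | index | empirical NDVI process level for 15-day composites, rescaled to a 5-day step; x̄ = mean of valid values (RMS optional) |
| θ₂ (slope) | θ₁/5 | index | slope is a derivative of the level; a fifth of the level scale |
| θ₃ (seasonal) | 0.0011 | index | fixed operational constant |
| θ₄ (observation) | 0.0104 | index | propagated from the ±1.5% radiometric accuracy of the L2A product; the printed propagation formula is ambiguous, so the constant is used directly and `recompute_theta4` implements one reading, ε/√2·(1 − mean(y²)), clearly labelled as such |
| s (period) | 73 | steps | one year at a 5-day cadence |

Filtering handles missing dates as prediction-only steps; imputation uses
the full-series RTS smoother (offline conditioning), not filter-only
output — the smoother uses observations on both sides of a gap and is the
right estimator when the whole archive is available at once.
Initialisation is diffuse: level at the first valid observation, everything
else zero, prior covariance 100·I (index²). The smoother forgets this
prior quickly wherever data exist; pixels whose seasonal cycle positions
are never observed honestly retain large posterior variance, which the
fusion stage then uses to down-weight the KF there. A pixel with fewer
than two valid dates is flagged degenerate and carried with the prior mean
and maximal variance.

The 95% band is `estimate ± 1.96·√(P_k + θ₄²)`: the posterior variance of
a *new observation* at that date, not just of the latent signal. On data
simulated from the model itself with ~60% block missingness this band
covers ≈95% of held-out observations (the acceptance script measures
~95.6% over 50,600 masked dates), i.e. slightly conservative, consistent
with the diffuse prior's extra width early in each series.

Correctness is established two independent ways: brute-force
joint-Gaussian conditioning (assemble the exact joint covariance of all
states and observations, condition on the observed subset; agreement to
1e−8 on 50 random small instances) and the fixed-parameter structural
model of statsmodels (agreement to 1e−7).

The per-pixel *reliability* is the time mean of P_k — small values mean
the filter was certain throughout, large values flag pixels whose dynamics
the model could not pin down.

## Weighted-correlation clustering

Similarity between a candidate and the reference series is the Pearson
correlation over jointly valid dates multiplied by the completeness ratio
L_i/L_r (the weighting down-ranks sparse candidates even when their
overlap correlates perfectly; an overlap-count multiplier is available as
an alternative reading). The greedy pass repeatedly selects the most
complete unassigned pixel as reference (ties broken by smallest row-major
id, for reproducibility) and absorbs every unassigned pixel whose weighted
correlation strictly exceeds the threshold (default 0.75, "exceeds" read
as strict). Pairs with fewer than 10 jointly valid dates, or zero variance
on the overlap, are treated as below any threshold; pixels with fewer than
10 valid dates stay unassigned (label −1). Clusters smaller than 5 pixels
are kept but flagged; their members skip LSTM training and fall back to
KF-only fusion.

Because the reference is always the most complete pixel still available,
L_i ≤ L_r within a pass and the weighted coefficient never exceeds 1 where
it matters.

## Clustered LSTM imputation

One sequence-to-one network per (non-small) cluster: a single LSTM layer
of 32 units with a linear head, input window 12 steps (60 days — long
enough to span a phenological transition, short enough for ~420-step
series), trained on the cluster's most complete pixel with its gaps
bridged by linear interpolation. Min-max scaling to [0, 1] is fitted on
the reference's training portion only and reused for every member — this
prevents validation leakage and keeps members on a common scale. Windows
are never shuffled; the validation split is the chronological tail (20% of
targets), so no training pair sees information later than its target.
Optimisation is Adam (learning rate 0.005) on an MSE loss, batches of 32
in chronological order, at most 128 epochs with early stopping after 5
epochs without validation improvement and best-weight restoration. The
implementation is plain NumPy (forward pass + full backpropagation through
time, verified against finite differences); a fixed seed makes training
exactly reproducible.

Prediction walks forward through each member's series building the input
window per date from, in priority order: the scaled observation, the
model's own earlier prediction for that date, the linear-interpolation
fallback. Dates inside the first window, which a next-step model cannot
reach, carry the fallback value and flag. Every date thus receives an
estimate and a provenance flag (observed / recycled / fallback).

σ_LSTM per pixel is the population standard deviation of
(prediction − observation) over the pixel's valid dates at model-reachable
dates (t ≥ window). Pixels with fewer than 10 residual pairs pool the
cluster's residuals instead. Members of small or untrained clusters carry
σ_LSTM = +∞, which drives their LSTM fusion weight to exactly zero.

## Inverse-variance fusion

Weights use the time-varying KF posterior variance P_k against the
per-pixel scalar σ²_LSTM, so one uncertainty source per model feeds both
the weights and the combined variance. Degenerate cases are defined
explicitly: both variances zero → equal weights; one zero → full weight to
the certain model; an infinite variance → zero weight, with its
(zero-weight × infinite-variance) term contributing nothing to the
combined variance.

The error covariance Cov(e_KF, e_LSTM) is not prescribed anywhere
upstream; the package estimates it per pixel as the sample covariance of
the two models' in-sample residuals at valid dates, shrunk to zero below
10 pairs. Because P_k is a model variance rather than the sample variance
of those same residuals, the raw estimate can exceed the Cauchy–Schwarz
bound √(P_k·σ²_LSTM); at assembly it is clipped to that bound (the
`combined_variance` primitive itself raises on violation). With
independent, correctly calibrated errors the fusion attains the
closed-form posterior variance (1/v₁ + 1/v₂)⁻¹ — an algebraic identity
exercised in the tests — and its MSE is no worse than the better member's.

The final cube preserves every observation; fused estimates at observed
dates are still stored for evaluation. Bands are Gaussian at 95%.

## Evaluation

All error metrics compare reconstructions against observations at valid
dates only. MAPE (in %) excludes dates with |y| < 0.01 — near-zero
observations (open water) make the ratio explode without any real error —
while MAE and RMSE use every valid date. The four-class map
cross-tabulates per-pixel MAE against reliability at thresholds 0.012 and
0.000125, "low" meaning strictly below; a value exactly at a threshold
counts as high. In-sample evaluation at valid dates matches the
operational procedure but flatters the smoother, which interpolates
through the scored dates; the package therefore also provides a hold-out
mode (hide a fraction of valid dates before fitting, score only there),
and the headline ensemble-dominance test uses it.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical regime the method assumes: a
5-day, 422-step series per pixel built from a slow trend plus an annual
sinusoid; spatially contiguous cluster zones (nearest-centre regions of
random centres) with distinct seasonal phase/amplitude/trend per cluster;
stationary AR(1) per-pixel deviations (coefficient 0.7, sd 0.03) standing
in for within-cluster heterogeneity; observation noise at the radiometric
scale (0.0104). Cloud missingness mirrors the fact that weather systems
are far larger than a 20 km tile: most dates are grid-scale clear or
overcast, a stratified 15% minority are partially covered by random disk
blobs (per-pixel survival 0.5), and one date is forced fully missing. This
yields ~38% valid dates per pixel, temporally block-wise gaps (mean
missing-run length ≈ 2.7 steps), and tight per-pixel valid-count
dispersion (sd ≈ 4 at T = 422) — the regime in which a completeness-ratio
weighting with a strict threshold is meaningful.

Not emulated: radiative-transfer effects, sensor view-angle artefacts,
land-cover maps, abrupt disturbances (fire, hail, flood), or
non-stationary cloud climatology. Passing tests therefore demonstrate the
method's internal consistency and its behaviour under its own assumptions,
not performance on any particular real archive.

Default generator sizes (20×20 grid, T = 422, s = 73) match the cadence
and series length of an operational Sentinel-2 stack while keeping a
single-CPU end-to-end run to ~2 minutes; unit tests use smaller cubes with
proportionally shorter periods (e.g. s = 24, T = 120 — five full cycles)
so the seasonal block stays identifiable.

## Numerical notes and known limitations

- The transition matrix is applied through its sparsity pattern (O(m²) per
  step rather than O(m³)); covariances are re-symmetrised each step. The
  smoother gain solves against the one-step-ahead covariance directly.
- With s + 1 ≈ 74 states, a pixel needs valid observations spread over the
  annual cycle to pin the seasonal block; short cubes whose period nearly
  equals their length leave it underdetermined, and the posterior variance
  reports exactly that. Choose `season` to match the true cycle length of
  the data.
- The predicted signal variance is guaranteed non-decreasing through a gap
  only after the diffuse seasonal prior has been resolved (roughly one
  full cycle of data); before that, rotation of unequal per-state
  variances through the observation equation can make it wobble.
- Early stopping with patience 5 on short series (few batches per epoch)
  can stop the LSTM before convergence; this is the configured operational
  behaviour, and the fusion compensates by weighting with the measured
  residual scale.
- The clustering is quadratic in the number of clusters × pixels in the
  worst case (every pixel a singleton) and makes no spatial-contiguity
  claim; singleton clusters along heterogeneous boundaries are expected
  and handled by the KF fallback.
- MAPE is reported for completeness but is dominated by near-zero
  observations even with the floor; prefer MAE/RMSE for comparisons.
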