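# Methods

This note records the statistical model behind `mtscompare`, the concrete
definitions chosen where a statistic admits several, and what the
synthetic benchmark does and does not establish.

## Data model and quality control

A dataset is N participants × R channels × T timepoints with a sampling
interval TR (seconds) and a metadata table (binary diagnosis, age in
years, sex coded 0 = male / 1 = female, site, optional motion summary).
Channel order is fixed by the input manifest and propagates to every
design matrix, so coefficient vectors are comparable across runs.

Framewise displacement follows the Power convention: the sum of absolute
backward differences of the three translations (mm) plus the three
rotations (radians) converted to arc length on a 50 mm sphere; the first
frame is 0 by definition. The rotation radius and the radians convention
are stated here because the FD literature leaves both implicit. Quality
control first removes participants whose every channel is constant zero
(max |x| < 1e−12, a tolerance that ignores float noise), then those with
mean FD above the threshold (default 0.55 mm, a deliberately lenient
motion criterion). Participants with neither a mean-FD value nor motion
traces are retained with a logged warning rather than silently dropped.
QC is idempotent and refuses to produce a dataset missing an entire
diagnosis class.

## Univariate features

Mean and SD are computed on the raw signal; the other 23 features on the
z-scored signal (sample SD, ddof = 1), so they measure the shape of the
dynamics rather than the units of the recording. Choices that the
one-line feature glosses leave open:

- **ACF**: biased (1/T) estimator via FFT, lags up to T/2.
  `ACF_timescale` is the first lag below 1/e; `ACF_first_min` the first
  lag after which the ACF turns upward; `periodicity` the first local ACF
  maximum at lag ≥ 2 with positive value (0 if none);
  `whiten_timescale` the change in the 1/e timescale after first
  differencing.
- **Spectra**: Welch with Hann window, segment length min(T, 64), 50%
  overlap, one-sided, frequencies in Hz via TR. `fALFF` uses the absolute
  0.01–0.08 Hz band; `low_freq_power` the lowest 20% of the frequency
  axis; `centroid_freq` the power-weighted mean frequency. fALFF is
  scale-invariant, so computing it on the z-scored series is harmless.
- **Scaling**: ~20 log-spaced window sizes in [5, T/4], fit over the
  lower half (the low-scale regime). DFA uses order-1 detrending of the
  cumulative profile. The rescaled-range exponent uses the Anis–Lloyd
  bias-corrected form, 0.5 + slope of log(R/S) − log E[R/S] under iid
  noise: raw R/S is inflated at small windows and a naive low-scale slope
  overshoots 0.5 for white noise by ~0.1, which would defeat the point of
  a Hurst-type statistic.
- **Symbolic/information**: terciles are equiprobable (marginal
  quantiles); entropies in nats. `AMI2` is the plug-in mutual information
  of a 5×5 histogram at lag 2; `AMI_timescale` the first local minimum of
  the Gaussian automutual information −½ln(1 − ρ(k)²);
  `transition_variance` the summed column variances (population) of the
  row-normalized 3×3 symbol transition matrix.
- **Distribution/shape**: histogram modes use 5 or 10 equal-width bins of
  the z-scored values; outlier timing averages the normalized time index
  of the most extreme 5% of samples; `high_fluctuation` counts z-score
  increments exceeding 0.04; `trev` is ⟨d³⟩/⟨d²⟩^{3/2} over increments;
  `embedding_dist` compares the histogram (20 bins) of successive
  distances in the 2-d lag-1 embedding against a fitted exponential
  density by mean absolute deviation; `forecast_error` is the residual SD
  of a 3-point rolling-mean forecast; stretch features count the longest
  run of strictly decreasing steps and of above-mean samples.

Undefined cells (constant series, failed fits) are stored as NaN and
imputed only inside the evaluation harness, never silently zeroed.
Exact numerical parity with any published feature library is not a goal;
where definitions coincide the features agree with their closed-form
limits (white-noise DFA ≈ 0.5, AR(1) timescales, sinusoid periodicity,
uniform-symbol entropy = ln 9, …), which is what the tests pin down.

## Pairwise statistics

All SPIs are computed on z-scored series (Pearson correlation then equals
the empirical covariance). Directed SPIs — transfer entropy, directed
information, additive noise model, spectral Granger causality, the two
phase-slope indices and cointegration — are stored on all R(R−1) ordered
pairs; the rest on the R(R−1)/2 unique pairs. The phase slope index is
antisymmetric rather than merely direction-dependent.

Estimator choices:

- **DTW** is the unconstrained dynamic program with |xᵢ − yⱼ| local cost;
  the barycenter statistic is the maximum of the DTW-barycenter-average
  (10 iterations from the elementwise mean).
- **Spectral statistics** share the Welch settings above. Coherence is
  the band-mean magnitude of the complex coherency; PSI is
  Im Σ_f C*(f)C(f+δf) over the full band, its time–frequency variant the
  mean over 4 equal time windows; PLI is |⟨sign sin Δφ⟩| and the power
  envelope correlation the Pearson correlation of analytic-signal
  amplitudes, both over the full band without pre-filtering.
- **Information-theoretic statistics** use Gaussian (linear) estimators
  with history 1 and delay 1, which admit exact oracles: TE(x→y) is half
  the log residual-variance ratio of nested autoregressions (identical to
  the Granger ln-variance ratio over 2); DI adds the instantaneous
  Gaussian mutual information of the bivariate innovations; Φ* is the
  mismatched-decoding form for Gaussians — full predictive information
  minus the decoding information of the disconnected (per-part) model,
  maximized over a scalar decoding temperature β ∈ [0, 10] by bounded
  scalar optimization. Φ* is reported un-normalized.
- **Causal statistics**: the additive-noise-model score is the distance
  correlation between the putative cause and the residuals of an RBF
  kernel-ridge regression (median-heuristic bandwidth, α = 0.01); spectral
  Granger causality is the parametric Geweke measure from a VAR fit
  (order by BIC, capped at 10), averaged over 128 frequencies on [0, π) —
  the parametric route was chosen over nonparametric spectral
  factorization because the Geweke identity against time-domain Granger
  causality gives an exact correctness check; cointegration is the ADF
  statistic of the residuals of the OLS regression of y on x
  (Engle–Granger second step).

Per-pair failures yield NaN and are logged; a pathological pair never
aborts a tensor.

## Evaluation harness

Per training fold, in order: median imputation (training statistics
only), robust sigmoid normalization fitted on the training rows, linear
SVM (C = 1, hinge loss, inverse-frequency class weights), prediction on
the untouched test fold, balanced accuracy. The sigmoid scale constant
IQR/1.349 is the normal-consistent SD estimate; a zero-IQR column falls
back to a mean/SD sigmoid and a constant column maps to 0.5. Transformed
test values are *not* clipped to [0, 1]: clipping would destroy
monotonicity exactly where outliers live. Folds come from stratified
10-fold CV repeated 10 times with a fixed seed, so every model compared
under a scheme sees the same 100 test folds. In-sample (resubstitution)
balanced accuracy on the training fold is what fold-wise selection ranks.

A caution the tests make explicit: on a single modest-sized null dataset
the 100 fold accuracies are strongly correlated, so a model's CV mean can
sit far from 50% by chance; only the average over independent datasets —
or the permutation null below — is centered at chance.

## Inference

The permutation null re-runs the identical harness under label shuffles
(default 1000; the scheme seed, and hence the fold-generation procedure,
is shared with the observed run). The null is summarized by its sample
mean and SD and the one-sided p-value read from the Gaussian upper tail,
which resolves p-values far beyond the 1/(n_perm+1) floor of a raw count.
Families (regions, features, SPIs) are corrected with Benjamini–Hochberg;
the family size can be stated explicitly when only a subset of p-values
is supplied. Paired comparisons over shared folds use the corrected
resampled t-test with n₂/n₁ the realized mean test/train ratio (1/9 for
10-fold) and df = k·r − 1; the variance inflation makes it strictly more
conservative than the naive paired t. Similarity between items is the
absolute Spearman correlation of their values concatenated across
channels and participants.

## Selection and PCA

Fold-wise selection never touches test rows or labels. For the coupling
families, whose training accuracy saturates at 100% in full dimension,
each SPI is ranked by training accuracy in the subspace of its first 10
principal components — PCA fitted per training fold on
sigmoid-normalized rows, the leakage-free reading of the procedure — and
the winner is re-scored on the fold in its full space. Training-accuracy
ties within 1e−12 are averaged over the tied units' test accuracies.
`pca_reduce` itself performs centering-only PCA: normalizing inside it
would turn low-rank inputs full-rank through the sigmoid nonlinearity,
so normalization is the caller's explicit step.

## Synthetic benchmark

The generator simulates VAR(1) dynamics x_t = A x_{t−1} + ε with
diagonal Gaussian innovations, a 200-sample burn-in, and defaults of
T = 150 samples at TR = 2 s — the scale of a typical single-session
resting-state acquisition. Group effects add a delta to a region's
self-coupling, innovation SD, mean, or a pair's (symmetric) coupling;
stability (spectral radius < 1) is enforced for both groups. The
stationary covariance solves the discrete Lyapunov equation
Σ = AΣAᵀ + Q, giving exact targets for recovery tests. Demographics are
drawn from simple distributions (age ~ N(30, 8²) clipped to [18, 65],
sex Bernoulli(½)); optional motion traces are random walks sized to give
realistic FD magnitudes.

What passing the synthetic suite shows: the harness is calibrated (null
center at 50%), the representations detect the effects they are built to
detect, and selection finds planted units. What it does not show:
linear-Gaussian VAR(1) has no hemodynamic response, no scanner noise or
site structure, no nonstationarity and no nonlinear coupling, so
performance on real recordings — where those ingredients matter — is not
implied. Problem sizes in the tests (N = 60–100, R = 8, 100–200
permutations) were chosen as the smallest at which the planted effects
are comfortably detectable; the acceptance script uses the same scale.

## Known limitations

- Information-theoretic SPIs are linear-Gaussian; they will miss purely
  nonlinear dependence that the ANM or DTW statistics may catch.
- The Gaussian tail approximation assumes the null is adequately
  normal; the raw null samples are retained so this can be checked.
- The corrected resampled t-test is approximate (fold dependence is
  modeled only through the variance inflation term).
- The fc_combo concatenation leaves the coupling and univariate blocks
  on their original scales until per-fold normalization; no block
  weighting is applied.
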