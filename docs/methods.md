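# Methods

This note records the models implemented, the defaults and why, the
numerical choices made where the method family leaves room, and what
the synthetic-data experiments do and do not establish.

## Synchronization likelihood

For each channel the record is delay-embedded
(X_i = (x_i, x_{i+L}, …, x_{i+(m−1)L})). Around every anchor *i* the
critical distance ε_{k,i} is the empirical p_ref-quantile
(linear-interpolation quantile, inclusive comparison `d ≤ ε`) of
Euclidean distances to the window times `w1 < |i − j| < w2`; the inner
exclusion `w1` suppresses autocorrelation (Theiler window), the outer
limit `w2` plays the role of a sliding-window length. SL between two
channels is the joint recurrence count over the window divided by
p_ref × window size, clipped to [0, 1]. The inclusive comparison makes
identical channels score exactly 1 wherever the quantile cut retains
`p_ref·N` points; independent channels score p_ref in expectation
(verified by simulation against toy parameters).

Only anchors with a *full* two-sided window are estimated, so every
time point has identical estimator variance; the first 2^15 valid
slices feed the dynamic analysis by default. Parameters derive from the
band: `L = floor(fs/3hf)`, `m = round(3hf/lf) + 1`, `w1 = 2L(m−1)`,
`w2 = w1 + ceil(n_rec/2p_ref) − 1` with n_rec = 100 recurrences; at
250 Hz and 0.5–4 Hz this yields (25, 20, 960, 1959), and p_ref
defaults to 0.05. PLI discounts numerically-zero phase lags (|Im C|
at the rounding level of |C| counts as sign 0); PLI/WPLI windows
default to `w2 − w1 + 1` samples to match SL's temporal support.

## Cost thresholding and graph measures

At cost K, `round_half_away(K·N(N−1)/2)` strongest edges keep their
weights (60 of 171 at K = 0.35, N = 19); ties at the cut break by
(weight desc, node-pair lexicographic) for determinism. D is retained
weight over maximum possible weight; C is the Onnela geometric-mean
clustering normalized by the global maximum weight (nodes of binary
degree < 2 contribute 0); E uses edge lengths 1/w with disconnected
pairs contributing 0. The all-slice fast paths (partial sort for D,
argpartition for C) are tested against the per-slice reference; the
top-K *sum* is tie-order independent, and tie sets at the cut have
measure zero for continuous weights.

## Excursions from median

Median crossings partition a series into maximal runs of constant
nonzero sign of x − median; each run contributes duration^a ×
(max |x − median|)^b with a = 0.9, b = 1. Samples exactly at the median
terminate a run and belong to none — the method family does not pin
this down; the choice here is deterministic and brute-force tested.
The sum is unnormalized by length, which matters when comparing records
of different durations.

## Focus-based multifractal analysis (SSC)

The noise-like series is cumulatively summed (after mean-centering)
into a walk; per scale s ∈ {2^3 … 2^13} (upper limit N/4) the walk is
cut into non-overlapping windows, each bridge-detrended (line through
its endpoints removed) before taking its standard deviation (ddof = 1;
both the detrending and the ddof are exposed as toggles). S(q, s) is
the q-power mean of these dispersions, evaluated in log space so
|q| = 15 stays finite, with the geometric-mean limit at q = 0. Windows
with σ = 0 (locally constant input — thresholded-network series and
shuffled cascades genuinely produce them) carry no fluctuation
information and are excluded from the power means; a scale losing *all*
windows raises an error.

All moments share one point at s = N (the focus), so H(q) and ln F are
estimated by one joint least-squares fit of
`ln S(q, s) ≈ ln F + H(q)(ln s − ln N)`, solved in closed form. This
anchoring is what keeps H(q) monotone in practice; a residual
non-monotone h(q) is flagged and warned about, not silently repaired,
and a spectrum whose maximum sits on the q-grid boundary raises an
error. τ(q) = qH(q) − 1 is differentiated by central differences
(one-sided at the ends); D(h) = qh − τ. FWHM interpolates the half-max
crossing linearly on each limb and truncates (with a flag) at the
limb's extreme h when the spectrum never descends to half maximum —
spectrum mass is never extrapolated.

Recovery on exact fGn (circulant embedding, so the target H is exact):
mean |h_max − H| ≤ 0.05 for H ∈ {0.3, 0.5, 0.8} at n = 2^15 over 20
seeds, with a small positive bias (≈ +0.01…+0.02) typical of
walk-domain estimators at this length.

## Modified permutation entropy

Lag-spaced windows of length 7 (lag 3) map to dense ranks by ascending
value with *exact* floating ties sharing a rank — thresholded-network
series repeat values legitimately, which is the reason for the
modified scheme; no epsilon rounding is applied. Entropy is base-2
Shannon over the empirical pattern distribution, unnormalized
(ceiling log2(7!) = 12.299 bits for continuous i.i.d. input; the
finite-sample shortfall at 2^15 samples is ≈ 0.11 bits).

## Surrogate framework

Four steps, 40 surrogates each, decision by mean ± 2σ of the surrogate
index (≈ 0.05 per-step confidence; verified ≤ 15% rejection on
null-true inputs at reduced length):

1. *Spectrum*: power-law surrogates are synthesized with
   complex-Gaussian spectral coefficients scaled by f^(slope/2) —
   Rayleigh amplitudes, so the null carries the same estimation noise
   as a genuine Gaussian 1/f process. The index is the fit misfit
   ln(1 − R²); R² itself piles up against 1 for steep spectra, which
   degenerates a ±2σ band. Pass: the original's misfit does not exceed
   μ + 2σ.
2. *Shuffling*: pass needs both FWHM and |spectral slope| above the
   shuffle band (shuffling reduces any series to white noise).
3. *Phase randomization*: FWHM above the band of amplitude-preserving
   phase-randomized surrogates (linear correlations preserved exactly,
   by construction of the rFFT; the mean sits in the untouched zero
   bin).
4. *Monofractal*: FWHM above the band of spectral-synthesis Gaussian
   surrogates with the slope fitted from the original.

Spectral slopes come from a Welch periodogram (8 segments, 50 %
overlap) collapsed to one point per octave by geometric means before
the log–log regression; linear-frequency fitting would let the dense
high-frequency bins dominate and punish benign high-end curvature. The
zero bin and top octave are excluded.

Calibration: binomial cascades (p = 0.3, 2^15 points) pass all four
steps in 18/20 seeded runs; fGn (H = 0.7) fails the monofractal step
20/20 while passing the spectrum step 20/20.

## Group statistics and classification

Per cost, groups compare by a two-sample t-test when both pass
Shapiro–Wilk and Levene at α = 0.05, else Mann–Whitney U; the BH-FDR
family is the 8 cost-wise p-values within one (index, measure) panel.
Cost effects use Friedman with W = χ²/(n(k−1)); all-constant panels
return (0, 1, 0) rather than erroring. Cost is collapsed by the
trapezoidal AUC of per-cost index values (dynamics first, AUC second —
summing before the multifractal step would distort it).

The classifier is a scikit-learn random forest under stratified
leave-one-pair-out CV: the i-th fold (by sorted subject id) holds out
one subject per class. Per-fold PPV/NPV (and SEN/SPE when undefined)
are excluded from means rather than zero-filled — with two-subject
holdouts a fold may predict no positives at all. Gini importances are
per-fold normalized (sum 1) and summed over folds. The default grid is
trees ∈ {100, 250, 500, 1000} × max features ∈ {1, √p, 5, all}; grid
search reuses the reporting folds (non-nested), an acknowledged
optimism source appropriate only for feature exploration at this
cohort size. Label-permutation significance repeats the full CV on 100
relabeled copies and flags metrics above μ + 2σ.

## Synthetic data: what it does and does not show

The generators cover the statistical structure the pipeline is
sensitive to: exact long-range dependence (circulant-embedding fGn —
the covariance is the closed-form fGn autocovariance, so recovery tests
have a true H), genuine multifractality with closed-form singularity
support (random binomial cascades, returned as bin-mass increments),
band-limited cross-channel coupling (mixed filtered sources plus
independent noise), null dynamic networks (i.i.d. Normal(0.3, 3·10⁻⁴)
edges), and planted two-group mean shifts. They do *not* emulate
volume conduction, nonstationary artifacts, 1/f-plus-oscillation EEG
spectra, or realistic inter-subject variability — passing tests
establish estimator correctness and pipeline calibration, not clinical
validity on real recordings.

The random-network control (100 networks, 19 nodes, 2^15 time points,
K = 0.35) is the package's headline self-contained experiment: the
strength series yields mean h_max ≈ 0.513, FWHM ≈ 0.239, mPE ≈ 12.185
bits (seed 1), i.e. white-noise scaling, pure finite-size spectrum
width, and near-ceiling entropy. The clustering series matches closely;
the efficiency series matches on h_max and mPE but shows a wider
finite-size FWHM (≈ 0.30) — its marginal is more discrete and
heavy-tailed because small weight changes reconfigure shortest paths —
a known limitation of treating the three measures as interchangeable.

## Problem sizes used by the test suite

Full-length (2^15) series are used wherever a quantitative value is
asserted; the end-to-end pipeline test runs a reduced configuration
(toy embedding window, 256 time points, 3 costs, 50 trees) chosen to
exercise every stage rather than to estimate anything precisely.
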