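# dfcomplexity

Dynamic functional connectivity (DFC) and its temporal complexity, for
multichannel electrophysiology. The package estimates time-resolved
synchronization-likelihood networks from band-limited recordings,
thresholds them at fixed connection cost, and characterizes the
resulting network-measure time series by multifractal and
information-theoretic indices — with group statistics, surrogate
testing and random-forest classification on top, and synthetic
generators for every input so the whole pipeline is testable without
any recordings.

## What it computes

**Connectivity.** The synchronization likelihood (SL) between channels
*k* and *l* at time *i* counts shared recurrences of delay-embedded
state vectors inside a window `w1 < |i − j| < w2`, normalized so that
independent signals give SL = p_ref and identical signals give SL = 1.
Embedding parameters follow from the band: for 250 Hz delta-band EEG
(0.5–4 Hz), `m = 25, L = 20, w1 = 960, w2 = 1959`. PLI and WPLI
(Hilbert-phase based) are included for validation.

**Graphs.** Each time point's matrix keeps only the strongest fraction
*K* of edges (cost thresholding, K = 0.15 … 0.50); global strength D,
Onnela weighted clustering C and weighted efficiency E then form
network-measure time series (NMTS).

**Complexity.** Each NMTS is summarized by seven indices: the static
(time-averaged) value, mean, variance, excursions-from-median
(Σ duration^0.9 · amplitude), the focus-based multifractal peak
position h_max and spectrum width FWHM, and the tie-tolerant modified
permutation entropy (order 7, lag 3, bits). The multifractal analysis
fits the scaling function

    S(q, s) = { (1/N_s) Σ_v σ(v, s)^q }^(1/q)

jointly over all moments q = −15…15 through the common focus at the
full-record scale, then Legendre-transforms H(q) into the singularity
spectrum. A four-step surrogate framework (power-law fit, shuffling,
phase randomization, strictly monofractal surrogates; 40 surrogates and
a μ±2σ rule per step) separates true multifractality from finite-size
background.

**Statistics and classification.** Cost-wise two-group tests
(t / Mann–Whitney behind a Shapiro–Wilk + Levene gate) with
Benjamini–Hochberg FDR, Friedman + Kendall-W cost-effect tests,
trapezoidal cost-AUC collapse into 21 features, and a random forest
evaluated by stratified leave-one-pair-out cross-validation with Gini
importances and label-permutation significance.

## Worked example

The package's fully self-contained control experiment: dynamic networks
whose edges fluctuate independently (19 nodes, 2^15 time points, edge
weights i.i.d. Normal(0.3, 3·10⁻⁴), thresholded at K = 0.35) carry no
temporal structure, so their strength series must look like white noise
to the complexity measures:

```
$ python analysis/01_random_network_control.py --n-networks 10 --seed 0
10 networks, measures ['D'] -> results/random_network_control.csv
  D: h_max = 0.510 +/- 0.021  FWHM = 0.238 +/- 0.007  mPE = 12.184 +/- 0.004
```

h_max ≈ 0.5 is the white-noise Hurst exponent; FWHM ≈ 0.24 is pure
finite-size multifractal background (a cascade with p = 0.3 gives ≈
0.96 at the same length); and mPE ≈ 12.18 bits sits just below the
log2(7!) = 12.299 ceiling, the shortfall being finite-sample bias.
Departures from these values in real recordings indicate genuine
temporal structuring of brain connectivity.

The other drivers under `analysis/` validate estimator recovery on
exact fractional Gaussian noise and binomial cascades
(`02_estimator_validation.py`), calibrate the surrogate framework on
positive and negative controls (`03_surrogate_framework.py`), and run
the full pipeline end-to-end on a synthetic two-group cohort
(`04_synthetic_cohort.py`).

## Command-line interface

`dfcomplexity` exposes subcommands `simulate`, `preprocess`, `connect`,
`graph`, `dynamics`, `surrogate`, `stats`, `classify` and `run` (full
pipeline from a YAML config plus a cohort manifest); stages compose via
CSV/JSON files. See `dfcomplexity --help`.
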