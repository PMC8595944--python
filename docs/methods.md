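# Methods

This note documents the models, parameter choices and numerical decisions
behind `somnospec`, in the spirit of the methods documentation of mature
scientific packages.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pre-processing

Four stages, in order:

1. **Common-average re-reference.** The instantaneous mean over the eight
   channels is subtracted from every channel.  The operation is idempotent
   and commutes with linear filtering (both are checked as properties).
2. **Filtering.** A linear-phase FIR band-pass (0.1–70 Hz) and a band-stop
   notch (60 ± 2 Hz), both designed with a Hamming window, are combined and
   applied as a zero-phase convolution with the kernel's autocorrelation
   (equivalent to forward–backward filtering).  Tap counts follow the
   Hamming rule `N ≈ 3.3·fs/Δf` with a 0.6 Hz transition.  Zero phase keeps
   the epoch grid aligned; the double application squares the (already
   tiny) pass-band ripple and doubles stop-band attenuation, so the
   contracts are ≥ 40 dB at 60 Hz and ±1 dB over 1–50 Hz.
3. **Epoch-adaptive artifact rejection.** The recording is cut into
   non-overlapping epochs (default 30 s, anchored at sample 0; a partial
   trailing epoch is discarded).  Per channel, an epoch is flagged when its
   peak absolute amplitude exceeds `k_amp` (default 5) times the median
   per-epoch peak, or its mean power exceeds `k_pow` (default 10) times the
   median per-epoch power; an epoch is rejected if any channel flags it.
   The median-multiplier scheme is this package's explicit stand-in for
   epoch-adaptive thresholding: it adapts to each recording, is invariant
   to a common rescaling of all channels, and its two parameters are
   exposed in the configuration.  Rejection produces a mask; the signal is
   never modified.
4. **Edge trimming.** The first and last `trim_minutes` (default 5 for
   whole-night data; short demo runs use less) are additionally rejected,
   to drop the awake periods at lights-off/lights-on.  A trim exceeding
   half the recording is an error.

## Spectral features

The Blackman–Tukey estimate with a rectangular lag window spanning the full
30-s epoch is computed by the autocorrelation route: the biased linear
autocorrelation over all lags |k| ≤ N−1 is folded onto the N-point
frequency grid and Fourier transformed.  With this lag window the estimate
coincides with the epoch periodogram — an identity the test suite exploits
by checking the implementation against an independent DFT periodogram to
1e-8 relative error.  Epoch PSDs are averaged per channel over all kept
epochs, then normalized to unit sum over the analysis range [0.1, 70) Hz
(grid resolution `fs/6000 = 1/30 Hz`), giving PSDn.

Band conventions:

- Bins are assigned half-open, `[f1, f2)`, so the seven tiling bands
  (δ₁, δ₂, θ, α, β₁, β₂, γ) partition the analysis range exactly and their
  relative powers sum to 1.  σ (10–16 Hz, the spindle band) intentionally
  overlaps α and β₁.
- **Relative power** is the within-band PSDn sum; on a flat spectrum it
  reduces to a bin-count ratio (δ₂: 60/2097 ≈ 0.0286).
- **Spectral entropy** renormalizes PSDn within the band before applying
  Shannon's formula with the 1/log N normalization.  Renormalization is the
  reading that actually attains the stated [0, 1] range per band; without
  it the within-band values would not sum to one and the maximum would
  depend on the band's share of total power.  The logarithm base cancels
  against 1/log N; natural log is used, and `0·log 0` is taken as 0.
  A band with zero mass is an error (entropy undefined) rather than a
  silent 0.

Group-level spectra average PSDn over channels per subject, then take the
per-frequency median and quartiles within each severity group; the
slow-oscillation peak is the argmax of the median curve inside a search
band (0.2–1.0 Hz in the pipeline), flagged when it lands on the band edge.

## Synthetic data

The generator reproduces the *statistical* structure the analysis consumes,
not sleep physiology.

**EEG.** Per channel, independent band-limited Gaussian processes are
generated by forward–backward order-4 Butterworth band-pass filtering of
1/f^slope-colored white noise (default slope 1), each rescaled to an exact
per-band share of the background power; the default shares
(δ₁ .35, δ₂ .20, θ .15, α .10, β₁ .08, β₂ .07, γ .05) describe a
delta-dominated, monotonically thinning sleep spectrum.  Filtering then
rescaling gives exact power control without spectral-leakage assumptions;
filter roll-off exchanges a small amount of power symmetrically across
adjacent band edges, which is why planted-fraction recovery is asserted at
±0.03.  An optional narrowband peak (a fixed-frequency sinusoid with a
random phase) carries a configurable fraction of total power — the
slow-oscillation regime plants 0.75 / 0.417 / 0.267 Hz for
controls / mild / moderate-severe with relative amplitudes 0.08 / 0.10 /
0.13, so frequency decreases and amplitude increases with severity.  The
peak amplitudes were chosen so the peak bin clearly exceeds the 1/f floor
inside the 0.2–1.0 Hz search band after periodogram splitting of an
off-grid line across two bins.  Artifacts are raised-cosine bursts of
0.5–2 s, Poisson-placed, with amplitude a multiple (default 8×) of the
signal RMS (30 µV), shared across channels like movement artifacts.
Everything is bit-reproducible under a fixed seed.

**Cohort.** Cross-variable dependence is induced by a Gaussian copula:
requested Spearman targets are converted to Pearson inputs with
`ρ_P = 2 sin(π ρ_S / 6)` (so targets survive any monotone marginal
transform), the correlation matrix is validated as symmetric/unit-diagonal/
positive-semidefinite, and normal scores are mapped through per-group
marginals.  Marginals are location–scale normal or lognormal distributions
parameterized by median and quartiles; the defaults reproduce the
reference cohort's group-wise summaries (group sizes 176/98/20, 57% male,
ages 5–9).  AHI marginals are truncated to the severity intervals
(≤ 1 / (1, 5) / ≥ 5 events/h), so group labels always respect the cutoffs.
Each subject also receives an EEG synthesis spec: band fractions
interpolate between control-like and severe-like regimes with the
subject's latent severity (group index plus within-group AHI percentile),
and the slow-oscillation parameters follow the subject's group.

The latent-correlation magnitudes of the `REALISTIC_CORRELATION` preset
(severity indices co-vary at 0.35–0.6, oxygenation opposes them, cognitive
scores co-vary at 0.3–0.55 and weakly oppose severity) are free
parameters: no generative description of the real cohort exists beyond its
marginal summaries, so these values are a documented choice, not an
estimate.

What the generator does *not* emulate — hypnogram architecture, spindle
trains, REM cycling, nonstationarity across the night, volume-conduction
correlations between channels — bounds what passing tests show: they
demonstrate that the pipeline recovers planted spectral and rank-
correlation structure, not that it characterizes real sleep physiology.

## Correlation networks

Partial Spearman correlation ranks all variables with midranks (sex enters
as a 0/1 indicator, age in years, both ranked alongside the data), removes
covariate effects from the ranked variables by least squares, and
correlates the residuals — equivalent to the recursive partial-correlation
formula on the Spearman matrix, which serves as the test oracle.  Fewer
than 4 complete observations is an error; a variable constant after
ranking yields an *undefined* (NaN) correlation, deliberately distinct
from an error.

The bootstrap draws `n_subsample = 20` subjects with replacement per run
(`n_boot = 1000` runs), residualizes within the run, and aggregates
per-entry medians and 2.5/97.5 percentiles over the runs in which the
entry was defined; undefined runs (a variable constant within a draw,
plausible at n = 20) are excluded rather than imputed, and per-entry valid
counts are reported, with entries undefined in more than half the runs
flagged.  Subjects are canonically ordered by id before drawing, so
results are invariant to input row order.  The bootstrap median
concentrates on the *group sample* correlation: its spread under the null
scales with the group size, not the resample size, which is why null
calibration and recovery properties are stated for full-size groups
(n = 176) resampled at 20.

Thresholding is inclusive (|ρ| ≥ 0.30); signed weights are preserved for
display, while modularity and the centrality distances use |ρ| (and
1/|ρ|).  Modularity is maximized on the thresholded graph by
Clauset–Newman–Moore greedy agglomeration followed by Kernighan–Lin-style
refinement (single-node moves and community merges; on graphs of ≤ 30
nodes also pair swaps, and on ≤ 12 nodes additional seeded random
restarts, where the quadratic move set is affordable).  An empty edge set
yields singleton modules with Q defined as 0.  Centralities: strength is
the incident |ρ| sum; closeness and betweenness use 1/|ρ| shortest-path
distances; fully disconnected nodes get 0 by convention.  The
Fruchterman–Reingold layout (500 iterations, |ρ| as attraction weight) is
seeded and deterministic; per-(measure, group) seeds are derived from the
master seed through `SeedSequence` with fixed keys, so adding a group does
not perturb the others.

## Reporting

Continuous variables are summarized as median (Q1, Q3) per severity group
and compared pairwise with two-sided Mann–Whitney U tests — the exact null
distribution for tie-free pooled samples of ≤ 25, a tie-corrected normal
approximation otherwise (the exact branch is verified against full
enumeration for all suite cases with n₁ + n₂ ≤ 12).  Sex uses Fisher's
exact test.  Raw p < 0.05 flags are reported by default, matching common
practice for cohort description tables; Benjamini–Hochberg adjustment is
available behind a flag and can only remove flags, never add them.

## Problem sizes and determinism

The test suite validates at desk scale by choice: planted-fraction
recovery uses one hour of 2-channel EEG; slow-oscillation recovery uses
10 subjects per group at 600 s; bootstrap recovery uses 20 independent
cohorts of a 176-subject group; the end-to-end determinism check runs the
full pipeline twice on 30 subjects with 10-minute recordings (trim
1 min/side, since a 5-min trim would consume a 10-min recording) and
compares file checksums.  Whole-night durations are a configuration
choice, not a code path change.  All randomness flows from explicit seeds;
reruns with the same configuration produce byte-identical cohort, feature
and matrix files.

## Known limitations

- The artifact-rejection statistic is a principled stand-in; it is not a
  re-implementation of any published epoch-adaptive method's internals.
- Modularity on large dense graphs uses greedy + single-move refinement
  only; optimality is guaranteed only against the small-graph oracle.
- The EDF writer quantizes to 16 bits (relative error ~1e-4 of channel
  range), adequate for spectral work but not a lossless archive format.
- Negative correlations contribute to modularity through their absolute
  weight; signed-modularity variants are out of scope.
- Welch/multitaper estimators, sleep staging and REM/NREM-resolved
  spectra are deliberately out of scope.
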