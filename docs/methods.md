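# Methods

This note documents the models, estimators and numerical choices behind
`circaflux`, the parameters that matter, what the synthetic generators do
and do not emulate, and the known limitations.

## Signal model for luminescence traces

A clock-reporter trace is modeled as a damped sinusoid on a drifting
baseline:

    y(t) = c + b t + A exp(-t / tau) sin(2 pi t / T + 2 pi t0 / T) + e(t)

with period `T` (hours, ~24), acrophase offset `t0` (hours), amplitude `A`
(a.u.), damping time `tau` (hours; infinite = self-sustained), linear
drift `b` and i.i.d. Gaussian noise `e`. The synthetic generator
(`synthdata.gen_trace`) draws from exactly this model, seeded, and its
noise-free limit is used as closed-form truth throughout the tests.
Default sampling is one frame per 30 min over 6 days.

## Baseline subtraction

`detrend_running` subtracts a centered running average of width `w`
(default 24 h). The window uses trapezoid weights — half weight on the two
endpoint samples, so the window spans exactly `w` hours. This choice is
load-bearing: a symmetric window removes any linear trend exactly at
interior points, and a closed trapezoid over a whole number of periods of
a sinusoid is exactly zero, so a 24 h window passes 24 h *and* 12 h
oscillations through untouched while removing drift. Edges fall back to
the shrinking (renormalized) version of the same window; the first and
last half-window of a detrended trace is therefore distorted, and
downstream consumers either flag it (phase analysis) or should exclude it
(peak matching near record ends).

## Damped-sine period estimation

`fit_damped_sine` fits `A exp(-t/tau) sin(2 pi t/T + phi) + c` by
trust-region least squares. Numerical choices:

- the damping enters as a rate `1/tau >= 0`, so an undamped fit sits on a
  finite boundary instead of at infinity;
- the period is initialized from up to three periodogram peaks inside the
  period bounds (default 16-32 h) and the best of the multi-starts is
  kept, which prevents locking onto harmonics;
- periodogram peaks must be genuine local maxima carrying at least 5 % of
  the dominant peak's power; sidelobe leakage of an out-of-band
  oscillation therefore cannot seed a fit, and a record with no in-band
  peak returns a *flagged* failure result rather than raising;
- amplitude and phase starts come from the linear projection of the data
  onto the sine/cosine pair at the initial period; the damping start from
  the ratio of first- and second-half standard deviations.

On noise-free traces the fit recovers all four parameters to better than
1e-4 relative error; at amplitude-to-noise 10 over 6 days the mean period
error across 200 traces is a few hundredths of an hour (both checked in
the acceptance suite).

## Peaks and phase shifts

`detect_peaks` finds local maxima separated by at least 12 h (default),
requires a prominence of at least 5 % of the trace range (so noise bumps
near troughs are not counted), and refines each peak time by quadratic
interpolation of the three samples around the maximum; interpolation can
be disabled to reproduce sampling-resolution (30 min) peak times.
`peak_phase_shift` pairs peaks of two conditions by *mutual* nearest
neighbor within half a period and reports the signed mean difference;
mutual matching makes the statistic exactly antisymmetric under argument
swap. Peaks inside the detrending edge margin should be excluded before
matching (the acceptance checks do).

## Hilbert phase, instantaneous period, Kuramoto synchrony

The instantaneous phase is the argument of the analytic signal of a
detrended trace. The FFT-based Hilbert transform assumes a circular
record, and a record holding a non-integer number of cycles leaks a slow
phase wobble across the whole series; mirror padding does not remove it.
`analytic_phase` therefore pads each trace with a *periodic continuation*
at the trace's own dominant period (from a zero-padded periodogram) and
rounds the total padded length to a whole number of periods, which makes
the wrap seamless: the residual period error is zero for
grid-commensurate periods and below ~0.15 h otherwise. Traces whose mean
exceeds 0.1 of their SD are flagged as likely not detrended. The first and
last 12 h (configurable) are flagged as unreliable edge.

`instantaneous_period` is `2 pi /` (OLS slope of the continuous phase over
a centered window, default 12 h); non-positive slopes yield missing
values.

`kuramoto_K` computes `r(t) = |mean_j exp(i phi_j(t))|` and averages it
over the requested interval (default start 0.5 d, skipping the
synchronization transient). Time-averaging `r(t)` was chosen over pooling
phases across time because pooling conflates common frequency drift with
desynchrony; the alternative remains a one-line change and the choice is
stated here explicitly.

## Circular acrophase summaries

Acrophases (hours mod 24) are mapped to angles `2 pi h / 24`; the summary
reports the circular mean, the directional-statistics circular SD
`sqrt(-2 ln Rbar)` converted to hours, and the arithmetic mean amplitude.
Peak times default to quadratically interpolated values; sampling-grid
resolution is available by disabling interpolation in `detect_peaks`.

## Imaging

`remove_cosmic_rays` is a selective median filter: a pixel is replaced by
its `(2r+1)^2` neighborhood median only if it exceeds that median by more
than a threshold (defaults radius 2 px, threshold 50, bright-only — the
common Remove Outliers defaults). `rescale_contrast` uses one global
min/max for the whole stack so relative temporal dynamics survive, and it
is *off* the quantitative path by default: per-frame equalization would
destroy the amplitude information the fits need. ROI grids are
non-overlapping squares (8/16/32 px) anchored at the chamber mask's
bounding box; trailing partial ROIs are dropped so all ROIs have equal
area; coordinates are 0-based, row-major, with half-open bounds. Traces
are plain per-ROI arithmetic means per frame.

## JTK_cycle

For each candidate period (default: 24 h only) and each lag on a grid
(default resolution: half the sampling interval, i.e. 2 h lags for 4 h
sampling), the reference is the rank vector of
`cos(2 pi (t - lag) / period)` at the sample timepoints; replicates share
their timepoint's value, so references carry ties. The test statistic

    S = sum over pairs of sign-concordance of data with the reference

uses only pairs with distinct reference ranks; `tau = S / M` with `M` the
number of such pairs (the maximum attainable |S|). Under the null the
data are exchangeable, and the distribution of the concordant-pair count
depends only on the reference's tie-group sizes: its generating function
factors into sequential Gaussian binomials, which are convolved exactly in
integer arithmetic (the classic iterative-convolution construction of the
Jonckheere-Terpstra null). Exact p-values are two-sided
(`P(|S'| >= |S|)`); beyond 50 samples a normal approximation with
continuity correction takes over. The per-gene best (period, lag)
maximizes |tau| (ties prefer positive tau, then the earlier lag), and the
p-value is Bonferroni-adjusted by the number of hypotheses scanned.

Choices worth stating:

- **Single 24 h period by default.** One sampled cycle at six timepoints
  cannot discriminate nearby periods; scanning 20-28 h would only inflate
  the Bonferroni factor. The scan list is configurable for longer designs.
- **Replicates as repeated measurements**, not averaged: averaging would
  invalidate the exact null's exchangeability argument.
- **Amplitude** is half the Hodges-Lehmann (median of pairwise
  differences) estimate of peak-to-trough, with peak/trough groups being
  the samples within a quarter period of the best-lag cosine's peak and
  trough; it is read on the cpm scale, so the selection rule
  "amplitude > 10" means 10 cpm.
- **Degenerate genes** (all values tied) get p = 1 and amplitude 0; tau is
  undefined and reported as NaN.
- **Day/night binning** uses lag mod 24 with [0, 12) as day; the boundary
  value 12 counts as night.

Flat-gene simulations confirm the adjusted p-values are conservative
(empirical CDF below the diagonal) and the false-positive fraction of the
full selection rule at nominal 0.01 stays below 0.015; a noiseless cosine
at the 6 x 4 design is detected at adjusted p ~ 2.5e-9 with its lag
recovered on the 2 h grid (acceptance suite).

## Differential mean profiles

`deg_anova` compares replicate-averaged temporal profiles (one value per
timepoint) across conditions: one-way ANOVA (P < 0.01) followed by Tukey
HSD (P < 0.05) to assign specific contrasts. The profile-level test
deliberately ignores within-timepoint replicate variance — it asks whether
the *mean temporal profile* differs, matching the selection rule the
transcriptome summaries use.

## Synthetic data: what it emulates, what it does not

The generators emulate: damped ~24 h oscillations with drift and Gaussian
noise at 30-min sampling; ROI-tiled image stacks with Poisson-placed
single-pixel spikes (cosmic-ray stand-ins) and optional Gaussian pixel
noise; two-phase feeding-fasting protocols (H/L media, orders HL/LH/HH/LL,
configurable cycle period and duty) followed by free running, with a
first-order-uptake metabolite concentration `dC/dt = -kC` reset to the
incoming medium's concentration at each change (the uptake rate `k`, in
1/h, is a free parameter — the concentration model itself is a
package-level choice, stated here, since only its qualitative shape is
constrained); and gene expression as negative-binomial counts
(`var = mu + d mu^2`) around `baseline (1 + a cos(2 pi (t - lag)/T))`,
six 4 h timepoints, four replicates, with mean counts on the cpm scale
(implicit constant library size).

Not emulated: mechanistic clock dynamics or entrainment (waveform-level
truth only), batch effects or library-size variation between replicates,
spatial correlation of image noise, cell movement or drift, and partial
ROI occupancy. Tests passing on these generators therefore validate the
*estimators* against their stated models; they do not certify behavior
under real-data pathologies such as batch structure or optical drift.

The image-pipeline checks model a *synchronized* culture: ROI acrophases
share a common mean with 0.5 h spatial jitter, as in an entrained
chamber. This is also the regime in which a selective median filter is
well-posed on block-tiled synthetic frames — with ROI phases scattered
uniformly, neighboring blocks can differ by more than the outlier
threshold and the filter would clip block borders, an artifact of the
piecewise-constant synthetic geometry rather than of the filter.

## Problem sizes and defaults

Acceptance-level checks run at: 200 traces for SNR-10 period recovery
(6 d, 30-min sampling, amplitude/noise = 10, truth 23.7 h); 2,000 flat
negative-binomial genes for the false-positive rate; a 4 x 4 grid of
8 px ROIs (32 x 32 px frames, 289 frames) with ~280 injected spikes for
the pipeline identity; 48-200-member ensembles for the Kuramoto
identities; and full permutation enumeration up to n = 8 for the JTK
null. These sizes are the package's standard validation settings and keep
the whole suite in the tens of seconds.

## Known limitations

- The exact JTK null assumes tie-free data; heavily tied counts make the
  exact p conservative (ties only shrink |S|).
- The periodic-extension Hilbert padding keys on the dominant periodogram
  peak; records whose dominant spectral peak is not the oscillation of
  interest (e.g. dominated by residual drift) should be detrended first —
  the `not_detrended` flag exists for exactly this case.
- The damped-sine model assumes a single oscillatory component; bimodal
  or strongly non-sinusoidal waveforms bias `A` and `phi` though `T` is
  generally robust.
- `deg_anova` treats the six timepoint means as independent observations;
  temporal autocorrelation within a profile is ignored, as in the
  profile-mean selection rule it implements.
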