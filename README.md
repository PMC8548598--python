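# circaflux

Circadian analysis of bioluminescence recordings and rhythmic
transcriptomes: image-to-trace extraction, detrending, period / phase /
synchrony estimation, and JTK_cycle-based rhythmic-gene detection —
exercised end to end on synthetic data with known ground truth.

## Who this is for

Labs recording clock-reporter dynamics (e.g. Per2::Luc fibroblasts imaged
every 30 min under feeding-fasting-like media cycles) and profiling the
entrained transcriptome (samples every 4 h over 24 h with replicates) need
the same analysis chain again and again: turn a TIFF time-lapse into
per-ROI luminescence traces, subtract the baseline, estimate the period,
acrophase and population synchrony, and then ask which genes cycle and
with what phase. `circaflux` packages that chain as tested, seeded,
reusable functions, together with generators that emulate each data type so
every stage can be validated against exact truth without any external
download.

## Models and statistics

- **Damped-sine period fit** — detrended luminescence is modeled as
  `y(t) = A e^(-t/tau) sin(2 pi t / T + phi) + c`, fitted by trust-region
  least squares with the period initialized from periodogram peaks inside
  configurable bounds (default 16-32 h).
- **Baseline subtraction** — centered running average of width `w`
  (default 24 h, the approximate expected period) with trapezoid endpoint
  weights, which annihilates linear drift exactly and passes any
  oscillation whose period divides `w` untouched.
- **Hilbert phase and Kuramoto synchrony** — the instantaneous phase is
  the argument of the analytic signal of each detrended trace (with a
  periodic edge extension suppressing end distortion); unwrapping gives a
  continuous phase whose local slope is the instantaneous frequency.
  Synchrony of an ROI ensemble is the Kuramoto order parameter
  `K = <| mean_j exp(i phi_j(t)) |>_t`, 1 for complete synchrony and 0 for
  an incoherent population.
- **Circular acrophase statistics** — circular mean and
  `sqrt(-2 ln Rbar)` circular SD on the 24 h circle, plus mean amplitude,
  for polar acrophase summaries.
- **JTK_cycle** — for each candidate (period, lag) a cosine reference is
  ranked at the sample timepoints; the Jonckheere-Terpstra/Kendall
  statistic `S` counts sign-concordant pairs; its *exact* permutation null
  (computed by Gaussian-binomial convolution over the reference's tie
  structure) yields an exact two-sided p-value, Bonferroni-adjusted over
  the scanned hypotheses. Rhythmic genes are selected by adjusted
  `P < 0.01` and amplitude `> 10` (cpm scale, robust Hodges-Lehmann
  peak-to-trough estimate), then summarized by day/night phase fractions,
  phase-ordered `[-1, 1]`-scaled heatmap matrices and Venn overlaps.
  Differential mean profiles between conditions use one-way ANOVA
  (`P < 0.01`) followed by Tukey HSD (`P < 0.05`).
- **Synthetic truth** — seeded generators for damped ~24 h traces with
  drift and noise, ROI-tiled image stacks with cosmic-ray-like spikes
  (truth coordinates returned), feeding-fasting protocol schedules with a
  first-order-uptake metabolite model, and rhythmic-vs-flat
  negative-binomial expression matrices.

## Worked example

```python
import numpy as np
from circaflux import (TraceTruth, TraceSet, default_grid, gen_trace,
                       detrend_window24, fit_damped_sine, analytic_phase,
                       unwrap_phase, kuramoto_K, ExprTruth, gen_expr_matrix,
                       jtk_scan, select_rhythmic, phase_day_night)

t = default_grid(144.0, 0.5)           # 6 days sampled every 30 min
cols = [gen_trace(TraceTruth(period_h=23.7, phase0_h=6.0, amplitude=100.0,
                             damping_tau_h=96.0, baseline_offset=500.0,
                             noise_sd=10.0, seed=s), t).values[:, 0]
        for s in range(8)]             # 8 synchronized ROIs
ts = TraceSet(t, np.column_stack(cols), [f"roi{i}" for i in range(8)])
det = detrend_window24(ts)
fit = fit_damped_sine(det.time_h, det.values[:, 0])
print(f"period = {fit.period_h:.2f} h, damping tau = {fit.damping_tau_h:.0f} h, "
      f"amplitude = {fit.amplitude:.1f} a.u.")
K = kuramoto_K(unwrap_phase(analytic_phase(det))).K
print(f"Kuramoto K over [12 h, end] = {K:.3f}")

data = gen_expr_matrix(ExprTruth(n_genes=500, frac_rhythmic=0.2,
                                 rel_amplitude=0.5, baseline_cpm=100.0,
                                 dispersion=0.05, seed=0))
res = jtk_scan(data.counts, data.annot)
sel = select_rhythmic(res, p_max=0.01, amp_min=10.0)
dn = phase_day_night(res.loc[sel, "lag_h"].to_numpy())
print(f"rhythmic genes: {len(sel)}/500 (true: {int(data.truth.is_rhythmic.sum())})")
print(f"day-phase fraction: {dn.day_fraction:.2f}")
```

Output:

```
period = 23.57 h, damping tau = 86 h, amplitude = 106.1 a.u.
Kuramoto K over [12 h, end] = 0.966
rhythmic genes: 101/500 (true: 100)
day-phase fraction: 0.44
```

The fitted period lands within 0.15 h of the generating 23.7 h truth at
this noise level; `K` close to 1 reflects the shared phase of the 8 ROIs;
the JTK selection recovers 101 of the 100 truly rhythmic genes (one false
positive) and, with lags drawn uniformly, about half of them peak in the
0-12 h "day" half.

A full configuration-driven run (image stacks → traces → rhythms →
synchrony → JTK, one output directory with a checksummed manifest):

```sh
circaflux all --config src/circaflux/data/demo.yaml
```

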