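# Demo run: three metabolic conditions (feeding-fasting HL, fasting-feeding
# LH, constant feeding HH), small ROI grid and gene panel so the full
# pipeline finishes in well under five minutes.
seed: 7
outdir: demo_out
conditions: [HL, LH, HH]
simulate:
  n_rows: 3
  n_cols: 3
  roi_size_px: 8
  duration_h: 120.0
  dt_h: 0.5
  period_h: 24.0
  damping_tau_h: 72.0
  amplitude: 100.0
  baseline_offset: 500.0
  trend_slope: -0.5
  noise_sd: 5.0
  pixel_noise_sd: 2.0
  spike_rate: 0.3
  spike_amp: 500.0
  phase_offsets_h: {HL: 0.0, LH: 8.0, HH: 0.0}
  phase_jitter_h: 0.5
  expr:
    n_genes: 120
    frac_rhythmic: 0.3
    rel_amplitude: 0.5
    baseline_cpm: 100.0
    dispersion: 0.05
imaging:
  cosmic_radius_px: 2
  cosmic_threshold: 50.0
rhythms:
  detrend_window_h: 24.0
  period_bounds_h: [16.0, 32.0]
  min_separation_h: 12.0
sync:
  t0_h: 12.0
  step_h: 12.0
jtk:
  periods_h: [24.0]
  p_max: 0.01
  amp_min: 10.0
  min_cpm: 1.0
  min_samples: 3
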