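# Example run configuration: two-odor comparison study on two MSS channels.
#
# Two sources share dominant base components (humidity at 100, two base VOCs
# at 10, arbitrary concentration units) and differ only in one low-level
# flavor component each — the regime where interfering gases dominate the
# raw sensor response and the rDC protocol pays off.
sources:
  sample_a:
    humidity: 100.0
    base_voc_1: 10.0
    base_voc_2: 10.0
    flavor_a: 1.0
  sample_b:
    humidity: 100.0
    base_voc_1: 10.0
    base_voc_2: 10.0
    flavor_b: 1.0

# Per-component first-order sorption parameters of each receptor film:
# partition coefficient K (dimensionless), time constant tau_s (s), and
# responsivity g (fractional resistance change per sorbed unit; negative so
# sorption drives the output positive under the -1 V bridge bias).
films:
  PPPO:
    humidity:   {partition: 1.0, tau_s: 2.0,  responsivity: -6.0e-7}
    base_voc_1: {partition: 2.0, tau_s: 0.5,  responsivity: -4.0e-7}
    base_voc_2: {partition: 1.5, tau_s: 8.0,  responsivity: -3.0e-7}
    flavor_a:   {partition: 5.0, tau_s: 1.0,  responsivity: -2.0e-6}
    flavor_b:   {partition: 2.0, tau_s: 0.6,  responsivity: -8.0e-7}
  PS:
    humidity:   {partition: 0.5, tau_s: 4.0,  responsivity: -4.0e-7}
    base_voc_1: {partition: 1.0, tau_s: 20.0, responsivity: -6.0e-7}
    base_voc_2: {partition: 1.0, tau_s: 1.5,  responsivity: -2.0e-7}
    flavor_a:   {partition: 3.0, tau_s: 2.0,  responsivity: -1.0e-6}
    flavor_b:   {partition: 6.0, tau_s: 0.8,  responsivity: -3.0e-6}

bridge:
  voltage_v: -1.0            # Wheatstone bridge bias VB

protocol:
  mode: rdc                  # 'rdc' or 'normal'
  samples: [sample_a, sample_b]
  interval_s: 5.0            # alternating injection interval
  total_duration_s: 120.0
  sampling_rate_hz: 100.0
  flow_rate_ml_min: 30.0     # metadata only

noise:
  gaussian_sigma_uv: 2.0
  drift_slope_uv_per_s: 0.05
  undulation: null           # e.g. {amplitude_uv: 0.5, frequency_hz: 0.7}

analysis:
  window_start_s: 55.0       # steady-state analysis window (Sample-1 aligned)
  window_end_s: 115.0
  cycle_duration_s: 10.0
  n_repetitions: 6
  fit_window_s: [9.0, 10.0]  # straight-line fit range for the noise estimate

replicates: 6
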