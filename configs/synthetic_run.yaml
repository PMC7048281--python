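# Packaged synthetic end-to-end fixture: 2 compartments x 3 time points x 3
# replicates at 5e4 reads/sample, with a time-increasing postprandial effect
# planted on the canonical variants of 8 miRNAs in the calf-EV group.
seed: 1

simulate:
  n_mirnas: 20
  groups: [colostrum_EV, calf_EV]
  time_points: ["0h", "1h", "6h"]
  replicates: 3
  depth: 50000
  dispersion: 0.1
  error_rate: 0.001
  contaminant_fraction: 0.10
  short_fraction: 0.02
  no_adapter_fraction: 0.02
  planted:
    group: calf_EV
    n_features: 8
    log2fc_by_time:
      "1h": 1.5
      "6h": 2.5

enumeration:
  max_trim: 6
  max_add: 3
  min_len: 16

thresholds:
  alpha: 0.05
  min_abs_lfc: 1.0
  min_base_mean: 50

diffexp:
  min_total_count: 10

profiling:
  top_k: 500
  n_top_abundant: 100
  reference_group: colostrum_EV
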