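# Default pipeline configuration: every stage parameter at its
# documented default.  Pass to `fnirsgait run-all --config`.
seed: 1
target_fs: 60.0

# direct motion-artifact correction
stdv_threshold: 65.0
amplitude_threshold: 0.05
t_motion: 0.5
t_mask: 1.0
wavelet_iqr: 0.8

# confound regression
k_components: 8
use_short_channels: true
use_motion: true
lowpass_pre_hz: 0.5

# final band filtering / scaling
hp_hz: 0.01
hp_order: 2
lp_hz: 0.1
lp_order: 6

# events
merge_tolerance_s: 2.0
refractory_s: 10.0
clearance_s: 10.0

# hierarchical models
chains: 4
draws: 600
warmup: 300
fit_models: true

cohort:
  n_pd: 3
  n_hc: 3
  pd_speed_ms: 0.95
  hc_speed_ms: 1.09
  protocol:
    n_runs: 4
    run_length_s: 390.0
    initial_stand_s: 60.0
    walk_leg_s: 20.0
    stop_duration_s: 30.0
    freeze_median_s: 3.8
  truth:
    systemic_rank: 8
    systemic_scale_uM: 1.5
    hbr_ratio: -0.3333333333333333
    freeze_surge_uM: 0.0
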