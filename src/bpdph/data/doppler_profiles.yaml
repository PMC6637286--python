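# Pulmonary-artery Doppler timing profiles (per experimental group).
#
# Only the TPV/RVET ratios are reported by group (0.32 air vehicle,
# 0.27 hyperoxia vehicle, 0.31 hyperoxia IL-1Ra); absolute timings use a
# right-ventricular ejection time of 50 ms, typical for an anaesthetised
# mouse, and scale TPV to reproduce the ratios.
default_sample_rate_hz: 1000
default_shape: triangle
profiles:
  air_vehicle:
    tpv_ms: 16.0
    rvet_ms: 50.0
    peak_velocity: 0.9
    heart_period_ms: 120.0
  hyperoxia_vehicle:
    tpv_ms: 13.5
    rvet_ms: 50.0
    peak_velocity: 0.9
    heart_period_ms: 120.0
  hyperoxia_il1ra:
    tpv_ms: 15.5
    rvet_ms: 50.0
    peak_velocity: 0.9
    heart_period_ms: 120.0
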