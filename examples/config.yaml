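# Run configuration template.
#
# Sampling and mounting -------------------------------------------------------
# Nominal sample rate of the device; CSV timestamps must agree within 1%.
sample_rate_hz: 25
# Map device axes (x, y, z; prefix '-' to flip sign) onto anatomical roles.
# The longitudinal axis must read +1 g during quiet standing.
axis_roles:
  longitudinal: x
  anterior_posterior: y
  medio_lateral: z

# Classifier parameters -------------------------------------------------------
# variant: "hfital" (posture-first tree, anterior-posterior counts) or
#          "moxal" (activity-first tree, tri-axial counts).
variant: hfital
# Data-segmentation window size, seconds.
ws_seconds: 4
# Amount-of-physical-activity threshold, counts per second.
pa_th_cps: 4.3
# Sensor-orientation threshold, g (cos of the thigh-to-gravity angle).
so_th_g: 0.8

# Activity-counts definition --------------------------------------------------
# Band-pass isolating the dynamic acceleration before rectification.
counts_filter:
  low_hz: 0.25
  high_hz: 11
  order: 4

# Reporting -------------------------------------------------------------------
# Cohort aggregation of the optimization objective: median or mean.
aggregate: median
# Manual alignment offset (s) applied if inputs are not pre-synchronized.
offset_s: 0.0
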