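# Example pipeline configuration.
#
# The `porcine18` preset pins the study-design analysis constants:
# 5 ms activation-delay threshold for the core zone, 10 ms early-prolongation
# threshold, snapshots at 0/1/2.5/5/10 min, 460 ms categorical QTc cutoff.
# Anything set explicitly below overrides the preset.

preset: porcine18

generator:
  n_animals: 18
  n_leads: 48            # within the 32-64 plate range
  grid_shape: [6, 8]
  fs_egm: 4000.0         # epicardial sampling rate, Hz
  fs_ecg: 1028.0         # surface-ECG sampling rate, Hz
  rr_mean: 534.0         # ms, between-animal lognormal
  rr_sd: 97.0
  noise_sd: 0.02         # additive waveform noise, mV
  st_shift_mv: 0.2       # core-zone ST elevation during occlusion
  # biphasic border-zone ARI course: early prolongation, later shortening (ms)
  border_ari_delta_profile: {0: 0.0, 1: 24.0, 2.5: 24.0, 5: -10.0, 10: -30.0}
  seed: 0

zone_mode: abs           # "abs" (>5 ms) or "rel" (>20% of baseline AT)
assoc_mode: pooled       # or per_animal_max
period: [1.0, 10.0]      # phase 1A analysis window, minutes
write_signals: false     # set true to export per-record signal CSVs
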