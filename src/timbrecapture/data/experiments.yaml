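# Default configurations for the five additional-singleton experiments.
# All timing constants in ms, spectral centroids (SC) in Hz, modulation depths
# dimensionless in [0, 1], levels in dB SPL (metadata only).
#
# jnd units: 5% relative SC change per brightness jnd, 0.10 absolute depth per
# roughness jnd.  The nominal fundamental is chosen so that the reference
# spectral slope alpha = 3 yields SC = 512 Hz (f0 is resolved at load time).

shared:
  n_harmonics: 20
  reference_alpha: 3.0
  reference_sc_hz: 512.0      # fixes the nominal f0 via SC inversion
  f0_jitter_width_hz: 20.0    # total width of the uniform per-trial f0 jitter
  distractor_duration_ms: 170.0
  target_short_ms: 120.0
  target_long_ms: 220.0
  ramp_ms: 5.0
  ioi_ms: 230.0
  timeout_ms: 3000.0
  am_freq_hz: 50.0
  sc_jnd_fraction: 0.05
  depth_jnd_per_unit: 0.10
  distractor_level_db: 80.0

experiments:
  exp1:
    n_blocks: 6
    block_size: 60
    singleton_fraction: 0.5
    distractor_sc_hz: 512.0
    singletons:
      literal:
        # SC as printed; the brightness deviation in jnd is its additive
        # 5%-ladder equivalent, (822/512 - 1) / 0.05.
        - {sc_hz: 822.0, am_depth: 0.0, jnd_brightness: 12.109375, jnd_roughness: 0.0, level_db: 74.0}
  exp2:
    n_blocks: 8
    block_size: 80
    singleton_fraction: 0.8
    distractor_sc_hz: 512.0
    singletons:
      brightness_ladder: {base: 512.0, jnd_fraction: 0.05, multipliers: [1, 2, 5, 10], mode: additive}
      levels_db: [79.5, 79.0, 77.5, 75.0]
  exp3:
    n_blocks: 8
    block_size: 80
    singleton_fraction: 0.8
    distractor_sc_hz: 512.0
    singletons:
      roughness_ladder: {base: 0.0, jnd_fraction: 0.10, multipliers: [1, 2, 5, 10], mode: additive}
      levels_db: [80.0, 80.0, 80.0, 80.0]
  exp4:
    n_blocks: 8
    block_size: 80
    singleton_fraction: 0.8
    distractor_sc_hz: 631.0
    singletons:
      # Printed SC values kept verbatim; deviations recorded as +/-2 and +/-4
      # jnd (only 696 Hz matches a compound 5% rule exactly).
      literal:
        - {sc_hz: 512.0, am_depth: 0.0, jnd_brightness: -4.0, jnd_roughness: 0.0, level_db: 80.0}
        - {sc_hz: 569.0, am_depth: 0.0, jnd_brightness: -2.0, jnd_roughness: 0.0, level_db: 79.0}
        - {sc_hz: 696.0, am_depth: 0.0, jnd_brightness: 2.0, jnd_roughness: 0.0, level_db: 77.0}
        - {sc_hz: 768.0, am_depth: 0.0, jnd_brightness: 4.0, jnd_roughness: 0.0, level_db: 75.0}
  exp5:
    n_blocks: 8
    block_size: 80
    singleton_fraction: 0.8
    distractor_sc_hz: 512.0
    singletons:
      cross:
        brightness: {base: 512.0, jnd_fraction: 0.05, multipliers: [2, 5], mode: compound}
        roughness: {base: 0.0, jnd_fraction: 0.10, multipliers: [2, 5], mode: additive}
      levels_db_by_brightness: {2: 79.0, 5: 77.5}
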