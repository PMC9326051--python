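# Example configuration for the gatedspect CLI.
#
# Sections mirror the library dataclasses; every key is optional and falls
# back to the documented default.  `phantom` maps to PhantomConfig,
# `detector` to DetectorModel (see docs/methods.md for units and meaning).

phantom:
  grid_dims: [90, 60, 55]    # desk grid; [180, 120, 110] with 2.2 for full
  voxel_size: 4.4            # mm
  cardiac_period: 1.0        # s
  resp_period: 5.0           # s
  ed_to_es: 0.325            # s, contraction duration
  diaphragm_amp: 20.0        # mm (15.0 for the reduced-motion case)
  ap_expansion: 12.0         # mm growth of the AP body extent at peak inhale
  wall_mode: uniform         # or non-uniform (thinned angular sector)

detector:
  n_bins: [64, 64]           # detector bins at 4.4 mm
  radius_of_rotation: 320.0  # mm
  intrinsic_fwhm: 2.5        # mm
  dew_k: 0.5                 # DEW scatter multiplier
  scatter_fraction: 0.3
  sensitivity_scale: 33.4    # counts per (mCi/ml * mm * s)
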