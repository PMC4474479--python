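# Default run configuration: the assay's standard operating point.
# Kinetics/effect constants are the simulator calibration that puts the
# detected read-out at ~13 foci/nucleus (6 Gy, 2 h) and ~5 (6 Gy, 24 h)
# with the control fold changes of the validated assay.

kinetics:
  amplitude_per_gy: 23.7     # foci / Gy (linear induction coefficient)
  saturation_dose: 6.0       # Gy; induction plateaus above this
  fast_fraction: 0.75        # fraction resolved in the fast (NHEJ-like) phase
  tau_fast: 0.6              # h
  tau_slow: 21.1             # h
  baseline_mean: 0.2         # foci per unirradiated nucleus

render:
  pixel_size: 0.3667         # um/px (3 px == 1.1 um)
  image_shape: [672, 672]
  psf_sigma: 0.15            # um
  nucleus_area_mean: 180.0   # um^2
  nucleus_count_range: [60, 80]
  focus_width_mean_2h: 0.62  # um FWHM
  focus_width_mean_24h: 0.75
  focus_amplitude_mean: 350.0
  background_level: 150.0
  noise_sd: 12.0
  dispersion: 0.3            # excess-Fano factor of per-cell focus counts
  seed: 0
  subthreshold_fraction_2h: 0.15
  subthreshold_fraction_24h: 0.0
  subthreshold_width: 0.3

segmentation:
  smoothing_sigma: 1.0       # um
  min_nucleus_area: 40.0     # um^2
  max_nucleus_area: 400.0
  split_touching: true
  exclude_border: true

detection:
  intensity_threshold: 50.0  # gray levels above local background
  min_width: 3.0             # px equivalent-circular diameter
  max_width: 19.0
  pixel_size: 0.3667
  background_radius: 10      # px

criteria:
  suppression_cutoff: 0.5
  persistence_cutoff: 1.5
  toxicity_cutoff: 0.5
  sub_threshold_flag_level: 2.0

effects:
  CGK733: {formation_scale: 0.48}
  etoposide_6.25uM: {slow_resolution_scale: 0.36}
  etoposide_25uM: {formation_scale: 1.10, slow_resolution_scale: 0.33}
  topotecan: {width_scale: 0.3}
  toxic_reference: {survival_fraction: 0.4}

seed: 0
fields_per_well: 4
simulate: true
write_images: false
out_dir: fociscreen_out
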