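# Default desk-scale configuration of the full five-study replication.
# Any section may be overridden; omitted keys fall back to these values.

spectrum:
  kvp: 120.0            # tube voltage (80, 100 or 120)
  filtration_mm_al: 2.5 # aluminium-equivalent inherent filtration

protocol:
  n_views: 400          # projections over 360 degrees (physical protocol: 2400)
  n_detectors: 256      # elements across the 168-mm field of view
  n0: 1.0e5             # unattenuated counts per ray above 30 keV, per slice
  slice_averaging: 8    # emulates averaging eight 0.25-mm slices
  fov_cm: 16.8
  noise: true           # false replaces Poisson draws by expected counts

design:
  source: generated     # generated | analytic | table1_fixture
  target_hu: 280.0      # CT-angiography attenuation level of every mixture tube

roi:
  radius_fraction: 0.6  # ROI radius as a fraction of the tube radius

smoothing:
  sigma_px: 2.0         # Gaussian post-smoothing of material images
  truncate_sigmas: 2.0

reconstruction:
  filter: hann          # hann | ramp

studies:
  - id: AuGd_mix
    thresholds_kev: [30, 51, 78, 83, 98]
  - id: IGd_mix
    thresholds_kev: [30, 51, 64, 72, 85]
  - id: Au_only
    thresholds_kev: [30, 53, 78, 83, 98]
  - id: Gd_only
    thresholds_kev: [30, 51, 64, 72, 85]
  - id: I_only
    thresholds_kev: [30, 51, 64, 72, 85]
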