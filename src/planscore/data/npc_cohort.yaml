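# Default study conditions: a paired cohort of 20 nasopharyngeal-carcinoma
# patients, each re-planned with five fluence-map beamlet widths
# (2/4/6/8/10 mm -> groups BL02..BL10).  Cell means and SDs are the
# published group summaries of that cohort; the synthetic sampler draws
# plan-level values around them.  "Dmax" rows are the near-maximum dose
# reported as D2%.

study:
  groups: [BL02, BL04, BL06, BL08, BL10]
  beamlet_width_mm: {BL02: 2, BL04: 4, BL06: 6, BL08: 8, BL10: 10}
  n_patients: 20
  patient_effect_sd: 0.0   # cell SDs are totals; raise (<= smallest cell SD) for paired draws
  seed: 0

# prescription dose (Gy) per target volume
prescriptions: {PTVnx: 70.0, PTVnd: 66.0, PTV1: 64.0, PTV2: 56.0}

# mean/sd aligned with study.groups order
metrics:
  - {structure: PTVnx, metric: CI, category: ptv, direction: higher_better,
     mean: [0.62, 0.62, 0.62, 0.61, 0.59], sd: [0.05, 0.04, 0.04, 0.05, 0.05]}
  - {structure: PTVnd, metric: CI, category: ptv, direction: higher_better,
     mean: [0.14, 0.15, 0.15, 0.14, 0.14], sd: [0.07, 0.08, 0.08, 0.07, 0.07]}
  - {structure: PTV1, metric: CI, category: ptv, direction: higher_better,
     mean: [0.47, 0.48, 0.48, 0.47, 0.47], sd: [0.08, 0.08, 0.08, 0.07, 0.08]}
  - {structure: PTV2, metric: CI, category: ptv, direction: higher_better,
     mean: [0.76, 0.77, 0.77, 0.75, 0.76], sd: [0.05, 0.05, 0.05, 0.05, 0.05]}
  - {structure: PTVnx, metric: HI, category: ptv, direction: lower_better,
     mean: [0.07, 0.07, 0.07, 0.08, 0.08], sd: [0.02, 0.02, 0.02, 0.02, 0.02]}
  - {structure: PTVnd, metric: HI, category: ptv, direction: lower_better,
     mean: [0.07, 0.07, 0.08, 0.08, 0.09], sd: [0.01, 0.01, 0.01, 0.01, 0.01]}
  - {structure: PTV1, metric: HI, category: ptv, direction: lower_better,
     mean: [0.15, 0.14, 0.15, 0.16, 0.15], sd: [0.02, 0.01, 0.01, 0.02, 0.03]}
  - {structure: PTV2, metric: HI, category: ptv, direction: lower_better,
     mean: [0.27, 0.27, 0.28, 0.29, 0.29], sd: [0.02, 0.02, 0.02, 0.02, 0.03]}
  - {structure: PTVnx, metric: TC, category: ptv, direction: higher_better,
     mean: [98.04, 98.16, 97.92, 97.60, 97.50], sd: [1.20, 1.10, 1.16, 1.09, 1.10]}
  - {structure: PTVnd, metric: TC, category: ptv, direction: higher_better,
     mean: [98.25, 98.31, 97.82, 97.49, 96.96], sd: [1.16, 1.23, 0.90, 0.86, 0.93]}
  - {structure: PTV1, metric: TC, category: ptv, direction: higher_better,
     mean: [98.23, 98.30, 98.00, 97.84, 97.59], sd: [0.84, 0.80, 0.71, 0.61, 0.61]}
  - {structure: PTV2, metric: TC, category: ptv, direction: higher_better,
     mean: [98.01, 98.15, 97.76, 97.40, 97.16], sd: [1.05, 1.01, 0.92, 0.75, 0.42]}
  - {structure: PTVnx, metric: D2, category: ptv, direction: lower_better,
     mean: [74.56, 74.55, 74.72, 75.05, 75.15], sd: [0.33, 0.27, 0.32, 0.54, 0.58]}
  - {structure: PTVnd, metric: D2, category: ptv, direction: lower_better,
     mean: [70.96, 71.01, 71.00, 71.01, 71.09], sd: [0.30, 0.28, 0.26, 0.22, 0.20]}
  - {structure: PTV1, metric: D2, category: ptv, direction: lower_better,
     mean: [74.26, 74.27, 74.40, 74.70, 74.59], sd: [0.34, 0.30, 0.35, 0.56, 1.05]}
  - {structure: PTV2, metric: D2, category: ptv, direction: lower_better,
     mean: [73.48, 73.49, 73.56, 73.79, 73.89], sd: [0.43, 0.40, 0.44, 0.57, 0.64]}
  - {structure: Temporal lobes, metric: Dmax, category: oar, direction: lower_better,
     mean: [72.39, 71.91, 72.28, 73.03, 73.03], sd: [3.63, 4.03, 3.84, 4.03, 4.03]}
  - {structure: Mandibular joints, metric: Dmax, category: oar, direction: lower_better,
     mean: [66.29, 66.27, 66.03, 67.29, 66.56], sd: [5.30, 5.56, 5.89, 5.68, 5.18]}
  - {structure: Mandibles, metric: Dmax, category: oar, direction: lower_better,
     mean: [68.02, 68.06, 67.74, 67.40, 67.77], sd: [3.97, 4.13, 4.38, 3.70, 3.95]}
  - {structure: Spinal cord, metric: Dmax, category: oar, direction: lower_better,
     mean: [42.87, 43.18, 42.89, 43.07, 43.49], sd: [1.33, 3.06, 1.71, 1.33, 1.23]}
  - {structure: Optic nerves, metric: Dmax, category: oar, direction: lower_better,
     mean: [40.25, 41.35, 42.48, 44.77, 43.28], sd: [16.24, 16.34, 15.50, 14.38, 13.75]}
  - {structure: Optic chiasm, metric: Dmax, category: oar, direction: lower_better,
     mean: [38.03, 39.06, 41.96, 43.08, 40.61], sd: [17.16, 17.30, 14.46, 14.81, 13.38]}
  - {structure: Brainstem, metric: Dmax, category: oar, direction: lower_better,
     mean: [49.18, 49.10, 49.19, 49.50, 50.90], sd: [2.25, 2.22, 2.48, 2.51, 4.65]}
  - {structure: Parotids, metric: V30, category: oar, direction: lower_better,
     mean: [49.01, 48.51, 48.86, 51.30, 53.53], sd: [6.73, 5.54, 6.17, 7.68, 10.11]}
  - {structure: Pituitary, metric: Dmax, category: oar, direction: lower_better,
     mean: [55.16, 52.88, 55.97, 55.68, 55.26], sd: [11.25, 11.54, 8.60, 9.73, 9.53]}
  - {structure: Lens, metric: Dmax, category: oar, direction: lower_better,
     mean: [7.53, 7.27, 7.24, 7.28, 7.31], sd: [2.33, 2.19, 2.14, 2.16, 2.24]}
  - {structure: Eyes, metric: Dmean, category: oar, direction: lower_better,
     mean: [7.61, 7.52, 7.78, 7.88, 7.98], sd: [2.39, 2.37, 2.28, 2.32, 2.29]}

# per-group segment composition: plan total MU (mean/sd), share of <5 MU
# segments, and segment counts chosen so mixture-mean * n_segments matches
# the group total (rescaling stays near 1, preserving the small-MU share)
segments:
  total_mu_mean: {BL02: 739.80, BL04: 843.03, BL06: 776.97, BL08: 728.17, BL10: 701.71}
  total_mu_sd: {BL02: 43.74, BL04: 52.62, BL06: 30.51, BL08: 42.41, BL10: 30.67}
  small_fraction: {BL02: 0.3235, BL04: 0.1570, BL06: 0.2410, BL08: 0.3275, BL10: 0.3950}
  n_segments: {BL02: 60, BL04: 57, BL06: 57, BL08: 59, BL10: 62}
  low_mu_range: [1.0, 4.5]
  high_mu_range: [6.0, 28.0]
  small_threshold: 5.0

# upper-bound OAR dose constraints; the parotid V30 bound is shipped as
# published but is almost certainly a typo for <= 50 (see docs/methods.md)
constraints:
  - {structure: Lens, metric: Dmax, bound: 8, units: Gy}
  - {structure: Eyes, metric: Dmean, bound: 5, units: Gy}
  - {structure: Parotids, metric: V30, bound: 5, units: "%"}
  - {structure: Mandibular joints, metric: Dmax, bound: 70, units: Gy}
  - {structure: Pituitary, metric: Dmax, bound: 60, units: Gy}
  - {structure: Mandibles, metric: Dmax, bound: 70, units: Gy}
  - {structure: Brainstem, metric: Dmax, bound: 54, units: Gy}
  - {structure: Spinal cord, metric: Dmax, bound: 45, units: Gy}
  - {structure: Optic nerves, metric: Dmax, bound: 54, units: Gy}
  - {structure: Optic chiasm, metric: Dmax, bound: 54, units: Gy}
  - {structure: Temporal lobes, metric: Dmax, bound: 65, units: Gy}

# desk-scale voxel phantom: spherical target with an abutting OAR; the
# Gaussian blur sigma is mapped 1:1 (mm) from the group's beamlet width
phantom:
  grid_shape: [48, 48, 48]
  spacing_mm: [2.0, 2.0, 2.0]
  target_center: [24, 24, 24]
  target_radius_mm: 30.0
  oars:
    - {name: Brainstem, center: [24, 24, 42], radius_mm: 6.0}
    - {name: Spinal cord, center: [24, 45, 24], radius_mm: 4.0}
  prescription_dose_gy: 70.0
  base_dose_gy: 5.0
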