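"""Beamlet-width surrogate on the voxel phantom.

Builds the spherical-target phantom at increasing penumbra blur widths
(the stand-in for fluence-map coarseness) and prints target coverage at
the 95% isodose, the homogeneity index, the conformity index and the mean
dose spilled into the abutting organ at risk.  Coarser fluence (more
blur) should erode coverage/conformity and raise the spill.
"""

from planscore import (
    build_phantom,
    conformity_index,
    coverage_volumes,
    datasets,
    dose_statistics,
    homogeneity_index,
    target_coverage,
)

config = datasets.load_study_config()
rx = datasets.phantom_spec(config).prescription_dose

print("sigma_mm    TC(%)     HI      CI   OAR_mean(Gy)")
for sigma in (0, 1, 2, 4, 6, 8, 10):
    grid, masks = build_phantom(datasets.phantom_spec(config, blur_sigma=sigma))
    target, oar = masks[0], masks[1]
    vols = coverage_volumes(grid, target, 0.95 * rx)
    stats = dose_statistics(grid, target)
    print(
        f"{sigma:8.0f} {target_coverage(vols):8.2f} {homogeneity_index(stats):7.3f}"
        f" {conformity_index(vols):7.3f} {grid.dose[oar.voxels].mean():10.2f}"
    )

print("\nTC and CI fall, HI and OAR spill rise, as the penumbra widens.")
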