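"""Shared helpers importable from hypothesis test modules."""

import numpy as np

from planscore import DoseGrid, StructureMask


def survival_quantile(doses, x):
    """Brute-force Dx oracle: the largest sample value received by at
    least x% of the voxels, found by scanning every candidate value."""
    doses = np.asarray(doses, dtype=float)
    qualifying = [v for v in np.unique(doses) if 100.0 * np.mean(doses >= v) >= x]
    return max(qualifying)


def grid_from_dose_list(doses, spacing=(1.0, 1.0, 1.0)):
    arr = np.asarray(doses, dtype=float).reshape(1, 1, -1)
    grid = DoseGrid(dose=arr, spacing=spacing)
    mask = StructureMask(name="L", role="oar", voxels=np.ones_like(arr, dtype=bool))
    return grid, mask
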