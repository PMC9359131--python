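"""Cumulative dose–volume histograms and plan-quality indices.

A cumulative DVH condenses the 3-D absorbed-dose distribution inside a
structure into the percentage of the structure volume receiving at least
each dose level.  From it follow the point metrics used in plan reports
(D2%, D50%, D98%, Dmean, VxGy) and the target indices:

* target coverage  TC  = 100 * TV_PI / TV
* homogeneity index HI = (D2% - D98%) / D50%   (ICRU-83 difference form;
  smaller is more uniform)
* conformity index  CI = TV_PI**2 / (TV * V_PI), in [0, 1]; 1 is perfect

where TV is the target volume, TV_PI the target volume enclosed by the
prescription isodose and V_PI the total prescription-isodose volume.

Conventions (declared, since reporting systems differ): Dx% is the largest
dose received by at least x% of the volume, linearly interpolated on the
cumulative curve; voxel volume is the product of the grid spacings (binary
masks, no partial-volume weighting); the near-maximum dose reported as
"Dmax" in clinical tables is D2%, with the true voxel maximum also exposed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, ValidationError

DEFAULT_BIN_WIDTH = 0.05  # Gy

__all__ = [
    "DoseGrid",
    "StructureMask",
    "DVHCurve",
    "DoseStatistics",
    "PlanVolumes",
    "compute_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "dose_statistics",
    "coverage_volumes",
    "target_coverage",
    "homogeneity_index",
    "conformity_index",
    "extract_plan_metrics",
]


@dataclass(frozen=True)
class DoseGrid:
    """3-D absorbed dose (Gy per voxel) on a regular lattice.

    Parameters
    ----------
    dose : ndarray, shape (nx, ny, nz)
        Absorbed dose in Gy; all values must be >= 0.
    spacing : 3-tuple of float
        Voxel spacing in mm along each axis; all > 0.
    origin : 3-tuple of float
        Position of voxel (0, 0, 0) in mm.  Informational only.
    """

    dose: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        dose = np.asarray(self.dose, dtype=float)
        if dose.ndim != 3:
            raise ValidationError(f"dose array must be 3-D, got ndim={dose.ndim}")
        if np.any(dose < 0):
            raise ValidationError("dose values must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "dose", dose)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm**3 (spacings are mm)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class StructureMask:
    """Binary voxel mask for one anatomical structure, aligned to a DoseGrid."""

    name: str
    role: str  # "target" | "oar"
    voxels: np.ndarray

    def __post_init__(self):
        if self.role not in ("target", "oar"):
            raise ValidationError(f"role must be 'target' or 'oar', got {self.role!r}")
        voxels = np.asarray(self.voxels, dtype=bool)
        if voxels.ndim != 3:
            raise ValidationError("mask must be 3-D")
        if not voxels.any():
            raise ValidationError(f"structure {self.name!r} has no voxels set")
        object.__setattr__(self, "voxels", voxels)

    def volume_cc(self, grid: DoseGrid) -> float:
        self._check_aligned(grid)
        return int(self.voxels.sum()) * grid.voxel_volume_cc

    def _check_aligned(self, grid: DoseGrid) -> None:
        if self.voxels.shape != grid.dose.shape:
            raise AlignmentError(
                f"mask {self.name!r} shape {self.voxels.shape} does not match "
                f"grid shape {grid.dose.shape}"
            )


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH: % of structure volume receiving >= each bin-edge dose."""

    structure: str
    bin_edges: np.ndarray  # Gy, ascending
    cum_volume: np.ndarray  # %, non-increasing, 100 -> 0

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        vol = np.asarray(self.cum_volume, dtype=float)
        if edges.shape != vol.shape or edges.ndim != 1 or edges.size < 2:
            raise ValidationError("bin_edges and cum_volume must be equal-length 1-D arrays")
        if np.any(np.diff(edges) <= 0):
            raise ValidationError("bin_edges must be strictly ascending")
        if np.any(np.diff(vol) > 1e-12):
            raise ValidationError("cum_volume must be non-increasing")
        if np.any(vol < -1e-12) or np.any(vol > 100 + 1e-9):
            raise ValidationError("cum_volume must lie in [0, 100]")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "cum_volume", vol)

    def dose_at_volume(self, x: float) -> float:
        return dose_at_volume(self, x)

    def volume_at_dose(self, d: float) -> float:
        return volume_at_dose(self, d)


@dataclass(frozen=True)
class DoseStatistics:
    """Point dose metrics for one structure.

    ``dmax_report`` is the near-maximum D2% that clinical tables report as
    Dmax; ``dmax_true`` is the actual hottest-voxel dose.
    """

    d2: float
    d98: float
    d50: float
    dmean: float
    dmax_true: float

    def __post_init__(self):
        if not (self.d2 + 1e-9 >= self.d50 >= self.d98 - 1e-9 >= -1e-9):
            raise ValidationError(
                f"quantile ordering violated: d2={self.d2}, d50={self.d50}, d98={self.d98}"
            )

    @property
    def dmax_report(self) -> float:
        return self.d2


@dataclass(frozen=True)
class PlanVolumes:
    """Volumes entering TC and CI: target (TV), covered target (TV_PI),
    prescription-isodose volume (V_PI), all in cm**3."""

    tv: float
    tv_pi: float
    v_pi: float

    def __post_init__(self):
        if self.tv <= 0:
            raise ValidationError("target volume must be positive")
        if not (0 <= self.tv_pi <= min(self.tv, self.v_pi) + 1e-9):
            raise ValidationError(
                f"require 0 <= tv_pi <= min(tv, v_pi); got tv={self.tv}, "
                f"tv_pi={self.tv_pi}, v_pi={self.v_pi}"
            )


def compute_dvh(
    grid: DoseGrid, mask: StructureMask, bin_width: float = DEFAULT_BIN_WIDTH
) -> DVHCurve:
    """Cumulative DVH of ``mask`` on ``grid``.

    cum_volume[i] = 100 * #{masked voxels with dose >= bin_edges[i]} / #masked,
    with edges 0, bin_width, ... spanning past the masked maximum so the
    curve starts at 100% and ends at 0%.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    mask._check_aligned(grid)
    doses = np.sort(grid.dose[mask.voxels])
    n = doses.size
    dmax = float(doses[-1])
    n_edges = int(np.floor(dmax / bin_width + 1e-9)) + 2
    edges = np.arange(n_edges, dtype=float) * bin_width
    # voxels with dose >= edge, via one searchsorted over the sorted doses
    cum = 100.0 * (n - np.searchsorted(doses, edges, side="left")) / n
    return DVHCurve(structure=mask.name, bin_edges=edges, cum_volume=cum)


def dose_at_volume(dvh: DVHCurve, x: float) -> float:
    """Dx%: largest dose received by at least ``x`` percent of the volume.

    Returns the largest histogram edge whose cumulative volume still
    reaches ``x`` (the empirical inverse of the survival curve).  This is
    exact whenever the underlying doses sit on bin edges — in particular a
    uniform structure has Dx equal to its dose for every x — and is within
    one bin width of the sorted-voxel percentile otherwise.
    """
    if not (0 < x <= 100):
        raise ValidationError(f"x must be in (0, 100], got {x}")
    cum = dvh.cum_volume
    qualifying = np.nonzero(cum >= x)[0]
    if qualifying.size == 0:  # cannot happen for a well-formed curve (first = 100)
        raise ValidationError("malformed DVH curve: no edge reaches the requested volume")
    return float(dvh.bin_edges[int(qualifying[-1])])


def volume_at_dose(dvh: DVHCurve, d: float) -> float:
    """Vd: % of the structure volume receiving at least ``d`` Gy (interpolated)."""
    if d < 0:
        raise ValidationError("dose must be non-negative")
    return float(np.interp(d, dvh.bin_edges, dvh.cum_volume))


def dose_statistics(
    grid: DoseGrid, mask: StructureMask, bin_width: float = DEFAULT_BIN_WIDTH
) -> DoseStatistics:
    """D2/D50/D98 from the structure DVH, plus the exact mean and maximum."""
    dvh = compute_dvh(grid, mask, bin_width=bin_width)
    doses = grid.dose[mask.voxels]
    return DoseStatistics(
        d2=dose_at_volume(dvh, 2.0),
        d98=dose_at_volume(dvh, 98.0),
        d50=dose_at_volume(dvh, 50.0),
        dmean=float(doses.mean()),
        dmax_true=float(doses.max()),
    )


def coverage_volumes(
    grid: DoseGrid, target: StructureMask, prescription: float
) -> PlanVolumes:
    """TV, TV_PI and V_PI (cm**3) at the given prescription isodose (Gy)."""
    if prescription <= 0:
        raise ValidationError("prescription dose must be positive")
    target._check_aligned(grid)
    vv = grid.voxel_volume_cc
    covered = grid.dose >= prescription
    return PlanVolumes(
        tv=int(target.voxels.sum()) * vv,
        tv_pi=int((target.voxels & covered).sum()) * vv,
        v_pi=int(covered.sum()) * vv,
    )


def target_coverage(v: PlanVolumes) -> float:
    """TC (%) = 100 * TV_PI / TV."""
    return 100.0 * v.tv_pi / v.tv


def homogeneity_index(s: DoseStatistics) -> float:
    """HI = (D2% - D98%) / D50%; 0 for perfectly uniform target dose."""
    if s.d50 <= 0:
        raise ValidationError("D50% must be positive to compute HI")
    return (s.d2 - s.d98) / s.d50


def conformity_index(v: PlanVolumes) -> float:
    """CI = TV_PI**2 / (TV * V_PI) in [0, 1]; 1 means the prescription
    isodose coincides with the target."""
    if v.v_pi == 0:
        warnings.warn(
            "no voxel reaches the prescription dose; conformity index set to 0",
            stacklevel=2,
        )
        return 0.0
    return v.tv_pi**2 / (v.tv * v.v_pi)


_VX_RE = re.compile(r"^V(\d+(?:\.\d+)?)$")


def extract_plan_metrics(
    grid: DoseGrid,
    structures: Sequence[StructureMask],
    prescriptions: Mapping[str, float],
    metric_config: Mapping[str, Sequence[str]],
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> pd.DataFrame:
    """Evaluate configured metrics per structure; one row per (structure, metric).

    Recognised metric names: ``TC``, ``HI``, ``CI`` (targets; require a
    prescription dose for the structure), ``D2``, ``D50``, ``D98``,
    ``Dmean``, ``Dmax`` (reported as D2%), and ``V<dose>`` such as ``V30``.
    Returns a DataFrame with columns structure, metric, value.
    """
    by_name = {s.name: s for s in structures}
    rows = []
    for struct_name, metrics in metric_config.items():
        if struct_name not in by_name:
            raise ConfigurationError(f"structure {struct_name!r} not provided")
        mask = by_name[struct_name]
        stats = dose_statistics(grid, mask, bin_width=bin_width)
        dvh = compute_dvh(grid, mask, bin_width=bin_width)
        volumes = None
        if any(m in ("TC", "CI") for m in metrics):
            if struct_name not in prescriptions:
                raise ConfigurationError(
                    f"metric TC/CI for {struct_name!r} needs a prescription dose"
                )
            volumes = coverage_volumes(grid, mask, prescriptions[struct_name])
        for metric in metrics:
            if metric == "TC":
                value = target_coverage(volumes)
            elif metric == "CI":
                value = conformity_index(volumes)
            elif metric == "HI":
                value = homogeneity_index(stats)
            elif metric == "D2":
                value = stats.d2
            elif metric == "D50":
                value = stats.d50
            elif metric == "D98":
                value = stats.d98
            elif metric == "Dmean":
                value = stats.dmean
            elif metric == "Dmax":
                value = stats.dmax_report
            elif (m := _VX_RE.match(metric)) is not None:
                value = volume_at_dose(dvh, float(m.group(1)))
            else:
                raise ConfigurationError(f"unknown metric name {metric!r}")
            rows.append({"structure": struct_name, "metric": metric, "value": float(value)})
    return pd.DataFrame(rows, columns=["structure", "metric", "value"])
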