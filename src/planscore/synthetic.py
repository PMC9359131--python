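"""Synthetic study inputs: voxel phantoms, metric cohorts, segment MU lists.

No raw treatment plans are publicly deposited for the beamlet-width cohort
this package analyses, so the generators here emulate its three kinds of
input at desk scale:

* ``build_phantom`` — a spherical-target dose phantom whose penumbra is an
  isotropic Gaussian blur.  The blur width sigma stands in for the beamlet
  width: a coarser fluence map smears dose across the target edge exactly
  the way a wider penumbra does, which reproduces the qualitative study
  finding (finer fluence -> better coverage/conformity, lower spill into an
  abutting organ at risk) with a single parameter.
* ``sample_metric_cohort`` — per-plan dosimetric metrics drawn cell-wise as
  Normal(mean, sd) around configured group x structure x metric cells, with
  an optional shared per-patient offset giving the paired structure of a
  cohort in which the same patients are re-planned once per group.
* ``sample_segments`` — per-plan segment monitor units from a two-component
  uniform mixture (a low-MU and a high-MU component), rescaled to a plan
  total, emulating the small-segment composition of dynamic IMRT plans.

The per-patient offset uses a variance carve-out: offset ~ N(0, pe) and
residual sd = sqrt(sd**2 - pe**2), so the configured cell sd is the *total*
between-plan sd regardless of pairing strength, and the cross-group
correlation of a cell is pe**2/sd**2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

import pandas as pd

from .dvh import DoseGrid, StructureMask
from .errors import ConfigurationError, GeometryError, ValidationError

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "SegmentSpec",
    "SegmentRecord",
    "build_phantom",
    "sample_metric_cohort",
    "sample_segments",
    "sample_cohort_segments",
    "metric_bounds",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and dose parameters of the spherical-target phantom.

    ``blur_sigma`` (mm) is the penumbra width and the phantom's only knob
    linking fluence-map coarseness to dose spill; 0 gives a perfect step.
    Centers are voxel coordinates, radii are mm.
    """

    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    target_center: tuple[float, float, float]
    target_radius: float
    oar_specs: Sequence[tuple[str, tuple[float, float, float], float]] = ()
    prescription_dose: float = 70.0
    blur_sigma: float = 0.0
    base_dose: float = 5.0

    def __post_init__(self):
        if any(int(n) < 2 for n in self.grid_shape):
            raise ValidationError("grid_shape axes must each be >= 2 voxels")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive on every axis")
        if self.target_radius <= 0 or any(r <= 0 for _, _, r in self.oar_specs):
            raise ValidationError("structure radii must be positive")
        if self.blur_sigma < 0:
            raise ValidationError("blur_sigma must be >= 0")
        if self.prescription_dose <= 0:
            raise ValidationError("prescription_dose must be positive")
        if self.base_dose < 0:
            raise ValidationError("base_dose must be >= 0")
        self._check_inside("target", self.target_center, self.target_radius)
        for name, center, radius in self.oar_specs:
            self._check_inside(name, center, radius)

    def _check_inside(self, name, center, radius):
        for ax in range(3):
            lo_mm = center[ax] * self.spacing[ax] - radius
            hi_mm = center[ax] * self.spacing[ax] + radius
            if lo_mm < 0 or hi_mm > (self.grid_shape[ax] - 1) * self.spacing[ax]:
                raise GeometryError(
                    f"structure {name!r} (center {center}, radius {radius} mm) "
                    f"extends outside the grid along axis {ax}"
                )


def _sphere_mask(spec: PhantomSpec, center, radius_mm) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing)]
    cx, cy, cz = (c * s for c, s in zip(center, spec.spacing))
    dx2 = (axes[0] - cx) ** 2
    dy2 = (axes[1] - cy) ** 2
    dz2 = (axes[2] - cz) ** 2
    r2 = dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
    return r2 <= radius_mm**2


def build_phantom(spec: PhantomSpec) -> tuple[DoseGrid, list[StructureMask]]:
    """Deterministic step-dose phantom blurred by an isotropic Gaussian.

    Dose equals ``prescription_dose`` inside the target sphere and
    ``base_dose`` outside, then (for blur_sigma > 0) is convolved with a
    Gaussian of width ``blur_sigma`` mm.  Returns the dose grid and the
    masks for the target ("PTV") and each configured OAR.
    """
    target = _sphere_mask(spec, spec.target_center, spec.target_radius)
    if not target.any():
        raise GeometryError("target sphere contains no voxel center")
    dose = np.full(spec.grid_shape, float(spec.base_dose))
    dose[target] = spec.prescription_dose
    if spec.blur_sigma > 0:
        sigma_vox = [spec.blur_sigma / s for s in spec.spacing]
        dose = gaussian_filter(dose, sigma=sigma_vox, mode="nearest")
    grid = DoseGrid(dose=dose, spacing=spec.spacing)
    masks = [StructureMask(name="PTV", role="target", voxels=target)]
    for name, center, radius in spec.oar_specs:
        voxels = _sphere_mask(spec, center, radius)
        if not voxels.any():
            raise GeometryError(f"OAR {name!r} sphere contains no voxel center")
        masks.append(StructureMask(name=name, role="oar", voxels=voxels))
    return grid, masks


@dataclass(frozen=True)
class CohortSpec:
    """Cell-wise Normal cohort: (group, structure, metric) -> (mean, sd).

    ``patient_effect_sd`` (same units as the cell values) is the sd of a
    per-patient offset shared by all of that patient's plans for a given
    (structure, metric); it is carved out of each cell sd, so it must not
    exceed the smallest configured sd.
    """

    group_labels: Sequence[str]
    n_patients: int
    metric_params: Mapping[tuple[str, str, str], tuple[float, float]]
    patient_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.group_labels) < 1:
            raise ValidationError("at least one group label required")
        if self.n_patients < 2:
            raise ValidationError("n_patients must be >= 2")
        if self.patient_effect_sd < 0:
            raise ValidationError("patient_effect_sd must be >= 0")
        cells = set()
        for (g, s, m), (mean, sd) in self.metric_params.items():
            if sd < 0:
                raise ValidationError(f"sd must be >= 0 for cell {(g, s, m)}")
            cells.add((s, m))
        for g in self.group_labels:
            for s, m in cells:
                if (g, s, m) not in self.metric_params:
                    raise ConfigurationError(
                        f"metric_params cell missing for group {g!r}, "
                        f"structure {s!r}, metric {m!r}"
                    )

    @property
    def cells(self) -> list[tuple[str, str]]:
        seen: dict[tuple[str, str], None] = {}
        for (_, s, m) in self.metric_params:
            seen.setdefault((s, m))
        return list(seen)


def metric_bounds(metric: str) -> tuple[float, float]:
    """Physical bounds for a metric value, inferred from its name.

    Percent metrics (TC, Vx) live in [0, 100], CI in [0, 1]; every other
    dosimetric quantity is simply non-negative.
    """
    if metric == "TC" or metric.startswith("V"):
        return (0.0, 100.0)
    if metric == "CI":
        return (0.0, 1.0)
    return (0.0, np.inf)


def _truncated_draw(rng, mean, offsets, resid_sd, lo, hi, max_rounds=100):
    vals = mean + offsets + rng.normal(0.0, resid_sd, offsets.size)
    for _ in range(max_rounds):
        bad = (vals < lo) | (vals > hi)
        if not bad.any():
            return vals
        vals[bad] = mean + offsets[bad] + rng.normal(0.0, resid_sd, int(bad.sum()))
    return np.clip(vals, lo, hi)


def sample_metric_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a paired metric cohort as a long-format table.

    Returns a DataFrame with columns plan_id, group, structure, metric,
    value; plan_id is "P{nn}-{group}" so the patient identity is shared
    across groups.  Values are truncated to the metric's physical bounds by
    resampling (clipping only as a last resort), which leaves the cell
    means essentially unchanged for cells well inside their bounds.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    pe = spec.patient_effect_sd
    patients = [f"P{i + 1:02d}" for i in range(spec.n_patients)]
    rows = []
    for structure, metric in spec.cells:
        lo, hi = metric_bounds(metric)
        offsets = rng.normal(0.0, pe, spec.n_patients) if pe > 0 else np.zeros(spec.n_patients)
        for group in spec.group_labels:
            mean, sd = spec.metric_params[(group, structure, metric)]
            resid_sd = float(np.sqrt(max(sd**2 - pe**2, 0.0)))
            vals = _truncated_draw(rng, mean, offsets, resid_sd, lo, hi)
            for pid, v in zip(patients, vals):
                rows.append(
                    {
                        "plan_id": f"{pid}-{group}",
                        "group": group,
                        "structure": structure,
                        "metric": metric,
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows, columns=["plan_id", "group", "structure", "metric", "value"])


@dataclass(frozen=True)
class SegmentSpec:
    """Two-component uniform MU mixture for one plan's segments."""

    n_segments: int
    total_mu: float
    small_weight: float
    low_mu_range: tuple[float, float] = (1.0, 4.5)
    high_mu_range: tuple[float, float] = (6.0, 28.0)
    small_threshold: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_segments < 1:
            raise ValidationError("n_segments must be >= 1")
        if self.total_mu <= 0:
            raise ValidationError("total_mu must be positive")
        if not (0.0 <= self.small_weight <= 1.0):
            raise ValidationError("small_weight must be in [0, 1]")
        for rng_ in (self.low_mu_range, self.high_mu_range):
            if not (0 < rng_[0] <= rng_[1]):
                raise ValidationError(f"MU range must be positive and ordered, got {rng_}")
        if self.low_mu_range[1] >= self.small_threshold:
            raise ValidationError(
                "low_mu_range must lie entirely below the small-segment threshold"
            )


@dataclass(frozen=True)
class SegmentRecord:
    """One deliverable segment of one beam of one plan."""

    plan_id: str
    beam: str
    segment_index: int
    mu: float

    def __post_init__(self):
        if self.mu < 0:
            raise ValidationError("segment MU must be >= 0")


def sample_segments(
    spec: SegmentSpec, plan_id: str = "plan", n_beams: int = 9
) -> list[SegmentRecord]:
    """Draw one plan's segment MU list; the MUs are rescaled so their sum
    equals ``spec.total_mu`` exactly.  Segments are dealt round-robin over
    ``n_beams`` beams.  Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    small = rng.random(spec.n_segments) < spec.small_weight
    mu = np.where(
        small,
        rng.uniform(*spec.low_mu_range, spec.n_segments),
        rng.uniform(*spec.high_mu_range, spec.n_segments),
    )
    mu *= spec.total_mu / mu.sum()
    return [
        SegmentRecord(
            plan_id=plan_id,
            beam=f"B{(i % n_beams) + 1}",
            segment_index=i + 1,
            mu=float(m),
        )
        for i, m in enumerate(mu)
    ]


def sample_cohort_segments(
    group_params: Mapping[str, Mapping[str, float]],
    n_patients: int,
    seed: int = 0,
    low_mu_range: tuple[float, float] = (1.0, 4.5),
    high_mu_range: tuple[float, float] = (6.0, 28.0),
) -> pd.DataFrame:
    """Segment lists for every (patient, group) plan of a cohort.

    ``group_params[group]`` must provide ``total_mu_mean``, ``total_mu_sd``,
    ``small_fraction`` and ``n_segments``.  Each plan's total MU is drawn
    Normal around the group mean (truncated positive); the small-segment
    mixture weight is the group fraction, so the per-plan small-segment
    share fluctuates binomially as real cohorts do.  Returns the canonical
    segments table (plan_id, beam, segment, mu).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, params in group_params.items():
        for i in range(n_patients):
            total = -1.0
            while total <= 0:
                total = rng.normal(params["total_mu_mean"], params["total_mu_sd"])
            spec = SegmentSpec(
                n_segments=int(params["n_segments"]),
                total_mu=float(total),
                small_weight=float(params["small_fraction"]),
                low_mu_range=low_mu_range,
                high_mu_range=high_mu_range,
                seed=int(rng.integers(2**31 - 1)),
            )
            for rec in sample_segments(spec, plan_id=f"P{i + 1:02d}-{group}"):
                rows.append(
                    {
                        "plan_id": rec.plan_id,
                        "beam": rec.beam,
                        "segment": rec.segment_index,
                        "mu": rec.mu,
                    }
                )
    return pd.DataFrame(rows, columns=["plan_id", "beam", "segment", "mu"])
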