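"""Loaders for the shipped study-defaults configuration.

``data/npc_cohort.yaml`` carries the default study conditions — the
published group-level means and SDs of the five-beamlet-width NPC cohort,
its OAR dose constraints, per-group segment-MU composition and the
desk-scale phantom geometry.  The helpers here turn that file (or a
user-supplied one with the same layout) into the package's domain objects.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError
from .scoring import ConstraintTable, MetricSpec
from .synthetic import CohortSpec, PhantomSpec

__all__ = [
    "load_study_config",
    "default_groups",
    "cohort_spec",
    "mean_metric_table",
    "metric_specs",
    "constraint_table",
    "phantom_spec",
    "segment_group_params",
]


def load_study_config(path: str | Path | None = None) -> dict:
    """Parse a study-config YAML; ``None`` loads the packaged defaults."""
    if path is None:
        text = resources.files("planscore.data").joinpath("npc_cohort.yaml").read_text()
    else:
        text = Path(path).read_text()
    config = yaml.safe_load(text)
    for key in ("study", "metrics"):
        if key not in config:
            raise ConfigurationError(f"study config lacks required section {key!r}")
    return config


def default_groups(config: dict | None = None) -> list[str]:
    config = config or load_study_config()
    return list(config["study"]["groups"])


def cohort_spec(
    config: dict | None = None,
    n_patients: int | None = None,
    patient_effect_sd: float | None = None,
    seed: int | None = None,
) -> CohortSpec:
    """CohortSpec built from a study config, with optional overrides."""
    config = config or load_study_config()
    study = config["study"]
    groups = list(study["groups"])
    params = {}
    for row in config["metrics"]:
        for g, mean, sd in zip(groups, row["mean"], row["sd"]):
            params[(g, row["structure"], row["metric"])] = (float(mean), float(sd))
    return CohortSpec(
        group_labels=groups,
        n_patients=int(n_patients if n_patients is not None else study["n_patients"]),
        metric_params=params,
        patient_effect_sd=float(
            patient_effect_sd if patient_effect_sd is not None else study["patient_effect_sd"]
        ),
        seed=int(seed if seed is not None else study.get("seed", 0)),
    )


def mean_metric_table(config: dict | None = None, category: str | None = None) -> pd.DataFrame:
    """The configured cell means as a long-format metric table, one plan
    per group (plan_id = group label).  This is the group-mean table the
    scoring stage consumes directly."""
    config = config or load_study_config()
    groups = default_groups(config)
    rows = []
    for row in config["metrics"]:
        if category is not None and row["category"] != category:
            continue
        for g, mean in zip(groups, row["mean"]):
            rows.append(
                {
                    "plan_id": g,
                    "group": g,
                    "structure": row["structure"],
                    "metric": row["metric"],
                    "value": float(mean),
                }
            )
    return pd.DataFrame(rows, columns=["plan_id", "group", "structure", "metric", "value"])


def metric_specs(config: dict | None = None, category: str | None = None) -> list[MetricSpec]:
    """Scored-item specifications (structure, metric, category, direction,
    unit weight) from a study config."""
    config = config or load_study_config()
    return [
        MetricSpec(
            structure=row["structure"],
            metric=row["metric"],
            category=row["category"],
            direction=row["direction"],
            weight=float(row.get("weight", 1.0)),
        )
        for row in config["metrics"]
        if category is None or row["category"] == category
    ]


def constraint_table(config: dict | None = None) -> ConstraintTable:
    config = config or load_study_config()
    if "constraints" not in config:
        raise ConfigurationError("study config has no constraints section")
    return ConstraintTable(rows=pd.DataFrame(config["constraints"]))


def phantom_spec(config: dict | None = None, blur_sigma: float = 0.0) -> PhantomSpec:
    """PhantomSpec from the config's phantom block at a given blur width."""
    config = config or load_study_config()
    ph = config.get("phantom")
    if ph is None:
        raise ConfigurationError("study config has no phantom section")
    return PhantomSpec(
        grid_shape=tuple(ph["grid_shape"]),
        spacing=tuple(ph["spacing_mm"]),
        target_center=tuple(ph["target_center"]),
        target_radius=float(ph["target_radius_mm"]),
        oar_specs=[
            (o["name"], tuple(o["center"]), float(o["radius_mm"])) for o in ph.get("oars", [])
        ],
        prescription_dose=float(ph["prescription_dose_gy"]),
        blur_sigma=float(blur_sigma),
        base_dose=float(ph["base_dose_gy"]),
    )


def segment_group_params(config: dict | None = None) -> dict[str, dict[str, float]]:
    """Per-group segment-sampler parameters keyed by group label."""
    config = config or load_study_config()
    seg = config.get("segments")
    if seg is None:
        raise ConfigurationError("study config has no segments section")
    return {
        g: {
            "total_mu_mean": float(seg["total_mu_mean"][g]),
            "total_mu_sd": float(seg["total_mu_sd"][g]),
            "small_fraction": float(seg["small_fraction"][g]),
            "n_segments": int(seg["n_segments"][g]),
        }
        for g in default_groups(config)
    }
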