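"""End-to-end orchestration: inputs -> metrics -> score -> efficiency -> stats.

``run_pipeline`` executes the full analysis either on synthetic study
inputs (phantom DVHs, sampled cohort, sampled segments) or on user CSVs,
writing every intermediate table plus a JSON summary naming the winning
(lowest overall score) group.  Runs are deterministic given the seed; any
stage failure removes the partial outputs and is re-raised with the stage
name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import datasets, io
from .dvh import (
    compute_dvh,
    conformity_index,
    coverage_volumes,
    dose_statistics,
    homogeneity_index,
    target_coverage,
)
from .efficiency import compare_cohort, efficiency_table, split_plan_id
from .errors import PipelineError, ValidationError
from .scoring import breakdowns_to_frame, evaluate_constraints, score_cohort
from .synthetic import build_phantom, sample_cohort_segments, sample_metric_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

# target coverage in the phantom sweep is read at the clinical 95% isodose
COVERAGE_ISODOSE_FRACTION = 0.95


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``mode`` is "synthetic" (generate the cohort; ``seed`` required) or
    "from_files" (``metrics_path`` required, ``segments_path`` optional).
    ``study_config`` points to a study YAML; ``None`` uses the packaged
    defaults.
    """

    mode: str
    out_dir: str | Path
    seed: int | None = None
    study_config: str | Path | None = None
    metrics_path: str | Path | None = None
    segments_path: str | Path | None = None
    paired: bool = True
    rounding: int = 3

    def __post_init__(self):
        if self.mode not in ("synthetic", "from_files"):
            raise ValidationError(f"mode must be 'synthetic' or 'from_files', got {self.mode!r}")
        if self.mode == "synthetic" and self.seed is None:
            raise ValidationError("synthetic mode requires a seed")
        if self.mode == "from_files" and self.metrics_path is None:
            raise ValidationError("from_files mode requires metrics_path")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls(**raw)


@dataclass
class PipelineResult:
    summary: dict
    outputs: dict[str, Path]


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study = datasets.load_study_config(config.study_config)
    outputs: dict[str, Path] = {}
    timings: dict[str, float] = {}
    summary: dict = {
        "mode": config.mode,
        "seed": config.seed,
        "config_hash": _config_hash(config),
    }
    logger.info("pipeline start: mode=%s seed=%s hash=%s", config.mode, config.seed,
                summary["config_hash"])

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    for p in outputs.values():
                        p.unlink(missing_ok=True)
                    raise PipelineError(name, str(exc)) from exc
                timings[name] = round(time.perf_counter() - self.t0, 4)
                return False

        return _Stage()

    if config.mode == "synthetic":
        with stage("phantom"):
            widths = study["study"].get("beamlet_width_mm", {})
            phantom_rows = []
            curves = []
            for group in datasets.default_groups(study):
                sigma = float(widths.get(group, 0.0))
                grid, masks = build_phantom(datasets.phantom_spec(study, blur_sigma=sigma))
                target = masks[0]
                level = COVERAGE_ISODOSE_FRACTION * datasets.phantom_spec(study).prescription_dose
                vols = coverage_volumes(grid, target, level)
                stats = dose_statistics(grid, target)
                row = {
                    "group": group,
                    "blur_sigma_mm": sigma,
                    "TC": target_coverage(vols),
                    "HI": homogeneity_index(stats),
                    "CI": conformity_index(vols),
                }
                for mask in masks[1:]:
                    row[f"{mask.name} Dmean"] = float(grid.dose[mask.voxels].mean())
                phantom_rows.append(row)
                for mask in masks:
                    c = compute_dvh(grid, mask)
                    curves.append(
                        type(c)(
                            structure=f"{group}:{mask.name}",
                            bin_edges=c.bin_edges,
                            cum_volume=c.cum_volume,
                        )
                    )
            outputs["phantom_indices"] = out_dir / "phantom_indices.csv"
            pd.DataFrame(phantom_rows).to_csv(outputs["phantom_indices"], index=False)
            outputs["dvh"] = out_dir / "dvh_curves.csv"
            io.write_dvh_curves(curves, outputs["dvh"])

        with stage("cohort"):
            spec = datasets.cohort_spec(study, seed=config.seed)
            metrics = sample_metric_cohort(spec)
            outputs["metrics"] = out_dir / "metrics.csv"
            io.write_metric_table(metrics, outputs["metrics"])

        with stage("segments"):
            segments = sample_cohort_segments(
                datasets.segment_group_params(study),
                n_patients=spec.n_patients,
                seed=(config.seed + 1) % (2**31 - 1),
            )
            outputs["segments"] = out_dir / "segments.csv"
            io.write_segments(segments, outputs["segments"])
    else:
        with stage("ingest"):
            metrics = io.read_metric_table(config.metrics_path)
            segments = (
                io.read_segments(config.segments_path)
                if config.segments_path is not None
                else None
            )

    with stage("score"):
        specs = datasets.metric_specs(study)
        # only score items every group reports
        available = set(zip(metrics["structure"], metrics["metric"]))
        specs = [s for s in specs if (s.structure, s.metric) in available]
        breakdowns = score_cohort(metrics, specs)
        frame = breakdowns_to_frame(breakdowns)
        frame["score_display"] = frame["score"].round(config.rounding)
        outputs["scores"] = out_dir / "scores.csv"
        frame.to_csv(outputs["scores"], index=False)
        per_group = {
            b.group: {
                "ptv_subtotal": b.ptv_subtotal,
                "oar_subtotal": b.oar_subtotal,
                "overall": b.overall,
                "ptv_subtotal_display": round(b.ptv_subtotal, config.rounding),
                "oar_subtotal_display": round(b.oar_subtotal, config.rounding),
                "overall_display": round(b.overall, config.rounding),
            }
            for b in breakdowns
        }
        best = min(per_group.values(), key=lambda v: v["overall"])["overall"]
        winners = sorted(g for g, v in per_group.items() if v["overall"] == best)
        summary["scores"] = per_group
        summary["winner"] = winners[0] if len(winners) == 1 else None
        summary["winners"] = winners  # >1 entry means a tie
        reference_group = winners[0]

    with stage("constraints"):
        group_means = (
            metrics.groupby(["group", "structure", "metric"], sort=False)["value"]
            .mean()
            .reset_index()
            .rename(columns={"group": "plan_id"})
            .assign(group=lambda d: d["plan_id"])
        )
        report = evaluate_constraints(group_means, datasets.constraint_table(study))
        outputs["constraints"] = out_dir / "constraints.csv"
        report.rows.to_csv(outputs["constraints"], index=False)
        summary["constraints"] = {
            str(r["plan_id"]): bool(r["plan_pass"])
            for _, r in report.plan_summary.iterrows()
        }

    if segments is not None:
        with stage("efficiency"):
            eff = efficiency_table(segments)
            outputs["efficiency"] = out_dir / "efficiency.csv"
            eff.to_csv(outputs["efficiency"], index=False)
            summary["efficiency"] = {
                g: {
                    "total_mu_mean": float(sub["total_mu"].mean()),
                    "total_mu_sd": float(sub["total_mu"].std(ddof=1)),
                    "small_segment_pct_mean": float(sub["small_segment_pct"].mean()),
                }
                for g, sub in eff.groupby("group", sort=False)
            }

    with stage("statistics"):
        per_plan = metrics.copy()

        def patient_of(pid):
            try:
                return split_plan_id(pid)[0]
            except ValidationError:
                return None  # group-summary table: no patient identity

        patients = per_plan["plan_id"].map(patient_of)
        comparable = patients.notna().all() and patients.nunique() > 1
        if comparable and len(set(per_plan["group"])) > 1:
            comparisons = compare_cohort(
                per_plan, reference_group=reference_group, paired=config.paired
            )
            if segments is not None:
                eff_long = efficiency_table(segments).melt(
                    id_vars=["plan_id", "patient", "group"],
                    value_vars=["total_mu", "small_segment_pct"],
                    var_name="metric",
                    value_name="value",
                )
                eff_long["structure"] = "plan"
                comparisons = pd.concat(
                    [
                        comparisons,
                        compare_cohort(
                            eff_long, reference_group=reference_group, paired=config.paired
                        ),
                    ],
                    ignore_index=True,
                )
            outputs["comparisons"] = out_dir / "comparisons.csv"
            comparisons.to_csv(outputs["comparisons"], index=False)
            summary["n_significant"] = int(comparisons["significant"].sum())
            summary["n_comparisons"] = int(len(comparisons))

    summary["timings_s"] = timings
    outputs["summary"] = out_dir / "summary.json"
    outputs["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline done: winner=%s", summary.get("winner"))
    return PipelineResult(summary=summary, outputs=outputs)
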