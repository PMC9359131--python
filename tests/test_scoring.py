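"""Relative-deviation quality scoring and constraint checking."""

import numpy as np
import pandas as pd
import pytest

from planscore import (
    ConstraintTable,
    MetricSpec,
    aggregate_score,
    datasets,
    evaluate_constraints,
    item_score,
    score_cohort,
    select_reference,
)
from planscore.errors import ScoringError, ScoringUndefinedError, ValidationError

GROUPS = ["BL02", "BL04", "BL06", "BL08", "BL10"]


class TestSelectReference:
    def test_cohort_minimum_for_lower_better(self):
        # group-mean near-max brainstem doses of the five-beamlet cohort
        values = dict(zip(GROUPS, [49.18, 49.10, 49.19, 49.50, 50.90]))
        c, refs = select_reference(values, "lower_better")
        assert c == 49.10
        assert refs == ("BL04",)

    def test_cohort_maximum_for_higher_better(self):
        values = dict(zip(GROUPS, [98.25, 98.31, 97.82, 97.49, 96.96]))
        c, refs = select_reference(values, "higher_better")
        assert c == 98.31
        assert refs == ("BL04",)

    def test_ties_record_all_reference_groups(self):
        c, refs = select_reference({"A": 5.0, "B": 5.0, "C": 7.0}, "lower_better")
        assert c == 5.0
        assert set(refs) == {"A", "B"}
        assert item_score(5.0, c) == 0.0

    def test_single_group_rejected(self):
        with pytest.raises(ScoringError):
            select_reference({"A": 1.0}, "lower_better")


class TestItemScore:
    def test_worked_brainstem_example(self):
        # 50.90 Gy vs the cohort-best 49.10 Gy scores 0.037 at unit weight
        assert round(item_score(50.90, 49.10, 1.0), 3) == 0.037

    def test_reference_group_scores_zero(self):
        assert item_score(49.10, 49.10, 1.0) == 0.0

    def test_weighting(self):
        assert item_score(60.0, 50.0, 0.5) == pytest.approx(0.100)

    def test_scale_invariance(self):
        base = item_score(55.0, 50.0, 1.0)
        for a in (0.01, 2.0, 1000.0):
            assert item_score(55.0 * a, 50.0 * a, 1.0) == pytest.approx(base, rel=1e-12)

    def test_zero_reference_undefined(self):
        with pytest.raises(ScoringUndefinedError):
            item_score(1.0, 0.0, 1.0)


class TestAggregateScore:
    def test_published_component_sum(self):
        assert aggregate_score([0.111, 0.125]) == pytest.approx(0.236)

    def test_empty_sum_is_zero(self):
        assert aggregate_score([]) == 0.0

    def test_negative_item_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_score([0.1, -0.2])


class TestScoreCohort:
    def test_oar_subtotal_of_reference_group(self, study_config):
        """The 11 published OAR group means yield a 0.079 subtotal for the
        best (4 mm) group: it holds some but not all per-item minima."""
        table = datasets.mean_metric_table(study_config, category="oar")
        specs = datasets.metric_specs(study_config, category="oar")
        assert len(specs) == 11
        by_group = {b.group: b for b in score_cohort(table, specs)}
        assert round(by_group["BL04"].oar_subtotal, 3) == 0.079

    def test_other_groups_near_published_subtotals(self, study_config):
        # published subtotals carry 2-d.p. input rounding; allow +-0.003
        table = datasets.mean_metric_table(study_config, category="oar")
        specs = datasets.metric_specs(study_config, category="oar")
        by_group = {b.group: b.oar_subtotal for b in score_cohort(table, specs)}
        published = {"BL02": 0.125, "BL06": 0.270, "BL08": 0.457, "BL10": 0.441}
        for g, expected in published.items():
            assert abs(by_group[g] - expected) <= 0.003

    def test_group_attaining_every_reference_scores_zero(self):
        rows = []
        for g, offset in [("A", 0.0), ("B", 1.0), ("C", 2.0)]:
            for metric, base in [("Dmax", 50.0), ("Dmean", 10.0)]:
                rows.append({"plan_id": g, "group": g, "structure": "S",
                             "metric": metric, "value": base + offset})
        specs = [
            MetricSpec("S", "Dmax", "oar", "lower_better"),
            MetricSpec("S", "Dmean", "oar", "lower_better"),
        ]
        by_group = {b.group: b for b in score_cohort(pd.DataFrame(rows), specs)}
        assert by_group["A"].overall == 0.0
        assert by_group["B"].overall > 0.0

    def test_matches_hand_transcription_on_random_cohort(self, rng):
        groups = ["G1", "G2", "G3"]
        specs = [
            MetricSpec("S1", "Dmax", "oar", "lower_better", weight=1.0),
            MetricSpec("S2", "Dmean", "oar", "lower_better", weight=2.0),
            MetricSpec("PTV", "TC", "ptv", "higher_better", weight=1.0),
            MetricSpec("PTV", "HI", "ptv", "lower_better", weight=0.5),
        ]
        rows = []
        values = {}
        for spec in specs:
            for g in groups:
                v = float(rng.uniform(1.0, 100.0))
                values[(g, spec.structure, spec.metric)] = v
                rows.append({"plan_id": g, "group": g, "structure": spec.structure,
                             "metric": spec.metric, "value": v})
        by_group = {b.group: b for b in score_cohort(pd.DataFrame(rows), specs)}
        for g in groups:
            expected = 0.0
            for spec in specs:
                cohort = [values[(h, spec.structure, spec.metric)] for h in groups]
                c = min(cohort) if spec.direction == "lower_better" else max(cohort)
                expected += abs(
                    (values[(g, spec.structure, spec.metric)] - c) / c * spec.weight
                )
            assert by_group[g].overall == pytest.approx(expected, rel=1e-12)
            assert by_group[g].overall == pytest.approx(
                by_group[g].ptv_subtotal + by_group[g].oar_subtotal, rel=1e-12
            )

    def test_every_item_has_a_zero_scoring_group(self, rng):
        rows = []
        for g in GROUPS:
            for metric in ("Dmax", "Dmean", "V30"):
                rows.append({"plan_id": g, "group": g, "structure": "S",
                             "metric": metric, "value": float(rng.uniform(10, 90))})
        specs = [MetricSpec("S", m, "oar", "lower_better") for m in ("Dmax", "Dmean", "V30")]
        breakdowns = score_cohort(pd.DataFrame(rows), specs)
        n_items = len(specs)
        for j in range(n_items):
            assert min(b.items[j].s for b in breakdowns) == 0.0

    def test_plan_level_table_scores_group_means(self, rng):
        # two plans per group; the scored M is the group mean
        rows = []
        for g, (v1, v2) in {"A": (10.0, 14.0), "B": (11.0, 11.0)}.items():
            for pid, v in [("P01", v1), ("P02", v2)]:
                rows.append({"plan_id": f"{pid}-{g}", "group": g, "structure": "S",
                             "metric": "Dmax", "value": v})
        specs = [MetricSpec("S", "Dmax", "oar", "lower_better")]
        by_group = {b.group: b for b in score_cohort(pd.DataFrame(rows), specs)}
        assert by_group["B"].items[0].m == pytest.approx(11.0)
        assert by_group["B"].overall == 0.0  # mean 11 < mean 12
        assert by_group["A"].overall == pytest.approx(1.0 / 11.0)

    def test_missing_cell_reported_by_name(self):
        rows = pd.DataFrame(
            [{"plan_id": g, "group": g, "structure": "S", "metric": "Dmax", "value": 1.0}
             for g in ("A", "B")]
        )
        with pytest.raises(ScoringError, match="Dmean"):
            score_cohort(rows, [MetricSpec("S", "Dmean", "oar", "lower_better")])


class TestConstraints:
    def make_table(self, values):
        return pd.DataFrame(
            [{"plan_id": "plan", "group": "G", "structure": s, "metric": m, "value": v}
             for (s, m), v in values.items()]
        )

    def test_pass_fail_and_boundary(self, study_config):
        constraints = datasets.constraint_table(study_config)
        values = {
            ("Brainstem", "Dmax"): 49.10,       # below 54 -> pass
            ("Spinal cord", "Dmax"): 46.0,      # above 45 -> fail
            ("Lens", "Dmax"): 8.0,              # exactly at bound -> pass
        }
        report = evaluate_constraints(self.make_table(values), constraints)
        status = report.rows.set_index(["structure", "metric"])["status"]
        assert status[("Brainstem", "Dmax")] == "pass"
        assert status[("Spinal cord", "Dmax")] == "fail"
        assert status[("Lens", "Dmax")] == "pass"

    def test_missing_metric_blocks_plan_pass(self):
        constraints = ConstraintTable(
            rows=pd.DataFrame(
                [{"structure": "Brainstem", "metric": "Dmax", "bound": 54.0, "units": "Gy"},
                 {"structure": "Lens", "metric": "Dmax", "bound": 8.0, "units": "Gy"}]
            )
        )
        report = evaluate_constraints(
            self.make_table({("Brainstem", "Dmax"): 40.0}), constraints
        )
        assert (report.rows["status"] == "unevaluated").sum() == 1
        assert not report.plan_summary["plan_pass"].iloc[0]

    def test_all_within_bounds_passes_plan(self):
        constraints = ConstraintTable(
            rows=pd.DataFrame(
                [{"structure": "Brainstem", "metric": "Dmax", "bound": 54.0, "units": "Gy"}]
            )
        )
        report = evaluate_constraints(
            self.make_table({("Brainstem", "Dmax"): 40.0}), constraints
        )
        assert report.plan_summary["plan_pass"].iloc[0]
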