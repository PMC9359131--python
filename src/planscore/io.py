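"""CSV readers and writers for the package's tabular interchange formats.

All tables are plain CSV with fixed headers:

* metric table:  ``plan_id,group,structure,metric,value``
* segments:      ``plan_id,beam,segment,mu``
* DVH curves:    ``structure,dose_gy,cum_volume_pct`` (edges ascending,
  one curve per structure)
* constraints:   ``structure,metric,bound,units``
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dvh import DVHCurve
from .errors import ValidationError
from .scoring import ConstraintTable

METRIC_COLUMNS = ["plan_id", "group", "structure", "metric", "value"]
SEGMENT_COLUMNS = ["plan_id", "beam", "segment", "mu"]
DVH_COLUMNS = ["structure", "dose_gy", "cum_volume_pct"]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} is missing columns {missing}")


def read_metric_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, METRIC_COLUMNS, f"metric table {path}")
    return df[METRIC_COLUMNS]


def write_metric_table(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, METRIC_COLUMNS, "metric table")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[METRIC_COLUMNS].to_csv(path, index=False)


def read_segments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SEGMENT_COLUMNS, f"segments table {path}")
    return df[SEGMENT_COLUMNS]


def write_segments(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, SEGMENT_COLUMNS, "segments table")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[SEGMENT_COLUMNS].to_csv(path, index=False)


def write_dvh_curves(curves: Sequence[DVHCurve], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "structure": c.structure,
                "dose_gy": c.bin_edges,
                "cum_volume_pct": c.cum_volume,
            }
        )
        for c in curves
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_dvh_curves(path: str | Path) -> list[DVHCurve]:
    df = pd.read_csv(path)
    _require_columns(df, DVH_COLUMNS, f"DVH table {path}")
    curves = []
    for structure, sub in df.groupby("structure", sort=False):
        curves.append(
            DVHCurve(
                structure=str(structure),
                bin_edges=sub["dose_gy"].to_numpy(dtype=float),
                cum_volume=sub["cum_volume_pct"].to_numpy(dtype=float),
            )
        )
    return curves


def read_constraints(path: str | Path) -> ConstraintTable:
    df = pd.read_csv(path)
    return ConstraintTable(rows=df)


def write_constraints(table: ConstraintTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.rows.to_csv(path, index=False)
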