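"""Readers and writers for the pipeline's tabular formats.

Input is the canonical long-format table (CSV or TSV with header, delimiter
auto-detected): one row per protein x molecule x concentration with a real
log2FC outcome.  Rows whose outcome is missing or non-numeric are dropped
and counted — imputation is out of scope.  Outputs are plain TSV: ranked
cause tables, per-rank sweep maps, and the rank-frequency summary.  Cells
without an identified cause carry the literal token ``None``.  Probabilities
are exact integer ratios internally and serialized at 12 significant digits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .causal_core import CausalTable, SchemaError, VariableSchema
from .cause_search import CauseResult
from .sweep import NONE_TOKEN, FrequencyTable, SweepGrid

CAUSE_COLUMNS = (
    "rank",
    "variable",
    "value",
    "p_actual",
    "p_counterfactual",
    "conditional_probability",
    "n_support",
    "verdict",
)


class EmptyTableError(ValueError):
    """No usable rows remain after validation."""


@dataclass(frozen=True)
class TableReadReport:
    """Bookkeeping for one table read."""

    n_rows_read: int
    n_rows_accepted: int
    n_rows_rejected: int
    rejected_reasons: dict[str, int]
    domains_summary: dict[str, int]


def _fmt(x: Any) -> str:
    """12-significant-digit numeric serialization; None -> 'NA'."""
    if x is None:
        return "NA"
    return format(float(x), ".12g")


def read_corona_table(
    path: str | Path,
    schema: VariableSchema = VariableSchema(),
    column_map: Mapping[str, str] | None = None,
) -> tuple[CausalTable, TableReadReport]:
    """Read and validate a long-format corona table.

    ``column_map`` renames input columns to the schema's names (for files
    whose headers differ from the canonical ones).  Extra columns are
    ignored; rows with missing or non-numeric outcome are dropped and
    tallied in the report.  Row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in schema.all_vars if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    df = df[list(schema.all_vars)]
    raw = df[schema.outcome_var]
    numeric = pd.to_numeric(raw, errors="coerce")
    finite = np.isfinite(numeric.to_numpy(dtype=float))

    reasons: dict[str, int] = {}
    n_missing = int(raw.isna().sum())
    n_nonnum = int((raw.notna() & numeric.isna()).sum())
    n_nonfinite = int((numeric.notna() & ~finite).sum())
    if n_missing:
        reasons["missing_outcome"] = n_missing
    if n_nonnum:
        reasons["non_numeric_outcome"] = n_nonnum
    if n_nonfinite:
        reasons["non_finite_outcome"] = n_nonfinite

    accepted = df.loc[finite].copy()
    accepted[schema.outcome_var] = numeric.loc[finite].astype(float)
    if accepted.empty:
        raise EmptyTableError(f"{path.name}: no rows with a usable outcome")
    table = CausalTable(schema, accepted)
    report = TableReadReport(
        n_rows_read=len(df),
        n_rows_accepted=len(accepted),
        n_rows_rejected=len(df) - len(accepted),
        rejected_reasons=reasons,
        domains_summary={v: len(d) for v, d in table.domains.items()},
    )
    return table, report


def write_cause_results(
    results: Sequence[CauseResult], path: str | Path
) -> Path:
    """Write ranked cause results as TSV (deterministic row order)."""
    path = Path(path)
    lines = ["\t".join(CAUSE_COLUMNS)]
    for r in results:
        lines.append(
            "\t".join(
                (
                    str(r.rank) if r.rank is not None else "NA",
                    str(r.assignment.variable),
                    str(r.assignment.value),
                    _fmt(r.p_actual),
                    _fmt(r.p_counterfactual),
                    _fmt(r.conditional_probability),
                    str(r.n_actual),
                    "cause" if r.is_cause else "non-cause",
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_sweep_outputs(
    grid: SweepGrid,
    freq: FrequencyTable,
    out_dir: str | Path,
    json_mirror: bool = False,
) -> list[Path]:
    """Write per-rank sweep maps and the rank-frequency table.

    Emits ``cause_map_rank<r>.tsv`` (long format: theta_abundant,
    theta_rest, cause_value, probability; ``None``/``NA`` for cause-free
    slots) for each rank 1..k, plus ``cause_frequencies.tsv`` with raw cell
    counts and percentages per rank.  With ``json_mirror`` a single
    machine-readable ``sweep.json`` is written alongside.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for r in range(1, grid.k + 1):
        lines = ["\t".join(("theta_abundant", "theta_rest", "cause_value", "probability"))]
        for i, ta in enumerate(grid.theta_abundant_axis):
            for j, tr in enumerate(grid.theta_rest_axis):
                v = grid.rank_value(i, j, r)
                prob = None if v is None else grid.cells[i][j][r - 1][1]
                lines.append(
                    "\t".join(
                        (
                            _fmt(ta),
                            _fmt(tr),
                            NONE_TOKEN if v is None else str(v),
                            _fmt(prob),
                        )
                    )
                )
        p = out_dir / f"cause_map_rank{r}.tsv"
        p.write_text("\n".join(lines) + "\n")
        written.append(p)

    freq_path = out_dir / "cause_frequencies.tsv"
    freq.to_dataframe().to_csv(
        freq_path, sep="\t", index=False, float_format="%.12g"
    )
    written.append(freq_path)

    if json_mirror:
        payload = {
            "theta_abundant_axis": [float(x) for x in grid.theta_abundant_axis],
            "theta_rest_axis": [float(x) for x in grid.theta_rest_axis],
            "k": grid.k,
            "mode": grid.mode,
            "cells": [
                [
                    [
                        {"cause_value": str(v), "probability": float(p)}
                        for v, p in cell
                    ]
                    for cell in row
                ]
                for row in grid.cells
            ],
            "frequencies": {
                str(r): {v: c for v, c in freq.counts[r].items()}
                for r in freq.counts
            },
            "total_cells": freq.total_cells,
        }
        jp = out_dir / "sweep.json"
        jp.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(jp)
    return written
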