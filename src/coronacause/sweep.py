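"""Threshold sweep: ranked actual causes over a 2-D grid of effect thresholds.

One effect predicate fixes a single pair of log2FC thresholds
(θ_abundant for highly abundant proteins, θ_rest for everything else).
Because the identified causes depend on where those thresholds sit, the
sweep re-runs the cause search over a grid of pairs: θ_abundant ranges from
the minimum observed log2FC up to the 0.1 pivot, θ_rest from the pivot up to
the maximum observed log2FC.  Each grid cell records the top-k causes (or a
``None`` marker when no candidate satisfies AC1 ∧ PC2 there), and the
frequency summary reports, per rank, the percentage of cells each molecule
occupies — the robustness of a causal attribution to the choice of effect
thresholds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .causal_core import (
    CausalTable,
    EffectPredicate,
    Orientation,
    THRESHOLD_PIVOT,
    load_abundant_fixture,
)
from .cause_search import ContingencyIndex, find_causes_from_mask

#: Literal token marking a grid cell (or rank slot) with no identified cause.
NONE_TOKEN = "None"

#: Default grid resolution: 20 depletion-side x 21 enrichment-side steps
#: (420 cells).
DEFAULT_STEPS = (20, 21)


class DegenerateRangeError(ValueError):
    """The observed log2FC range does not straddle the threshold pivot."""


def build_grid(
    table: CausalTable,
    n_abundant_steps: int = DEFAULT_STEPS[0],
    n_rest_steps: int = DEFAULT_STEPS[1],
    pivot: float = THRESHOLD_PIVOT,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear threshold axes over [min log2FC, pivot] and [pivot, max log2FC].

    Both endpoints are included on each axis.
    """
    if n_abundant_steps < 2 or n_rest_steps < 2:
        raise ValueError("step counts must be >= 2")
    y = table.outcome()
    lo, hi = float(y.min()), float(y.max())
    if lo >= pivot or hi <= pivot:
        raise DegenerateRangeError(
            f"observed log2FC range [{lo}, {hi}] must straddle the pivot {pivot}"
        )
    return (
        np.linspace(lo, pivot, n_abundant_steps),
        np.linspace(pivot, hi, n_rest_steps),
    )


@dataclass(frozen=True)
class SweepGrid:
    """Ranked causes per (θ_abundant, θ_rest) threshold pair.

    ``cells[i][j]`` corresponds to ``(theta_abundant_axis[i],
    theta_rest_axis[j])`` and holds up to ``k`` ``(cause value, conditional
    probability)`` pairs in rank order; an empty tuple marks a None cell.
    """

    theta_abundant_axis: np.ndarray
    theta_rest_axis: np.ndarray
    cells: tuple[tuple[tuple[tuple[Any, Fraction], ...], ...], ...]
    k: int
    mode: str

    @property
    def n_cells(self) -> int:
        return len(self.theta_abundant_axis) * len(self.theta_rest_axis)

    def cell(self, i: int, j: int) -> tuple[tuple[Any, Fraction], ...]:
        return self.cells[i][j]

    def rank_value(self, i: int, j: int, rank: int) -> Any | None:
        """Cause value at 1-based ``rank`` in cell (i, j), or None."""
        cell = self.cells[i][j]
        return cell[rank - 1][0] if rank <= len(cell) else None


def run_sweep(
    table: CausalTable,
    axes: tuple[np.ndarray, np.ndarray] | None = None,
    *,
    k: int = 3,
    mode: str = "standardized",
    orientation: Orientation = Orientation.DEPLETION_ENRICHMENT,
    abundant_ids: frozenset[str] | None = None,
    variables: Sequence[str] | None = None,
    n_abundant_steps: int = DEFAULT_STEPS[0],
    n_rest_steps: int = DEFAULT_STEPS[1],
) -> SweepGrid:
    """Run the cause search at every threshold pair of the grid.

    Cells are mutually independent (pure function of the table and the
    cell's predicate), so the result does not depend on evaluation order and
    repeated runs are identical.
    """
    if axes is None:
        axes = build_grid(table, n_abundant_steps, n_rest_steps)
    theta_a, theta_r = (np.asarray(a, dtype=float) for a in axes)
    for ax in (theta_a, theta_r):
        if len(ax) < 1 or np.any(np.diff(ax) <= 0):
            raise ValueError("threshold axes must be strictly increasing")
    if abundant_ids is None:
        abundant_ids = load_abundant_fixture()
    if variables is None:
        variables = table.schema.candidate_vars
    indexes = {v: ContingencyIndex(table, v) for v in variables}

    template = EffectPredicate(
        abundant_ids=abundant_ids, orientation=orientation
    )
    rows = []
    for ta in theta_a:
        row = []
        for tr in theta_r:
            pred = EffectPredicate(
                theta_abundant=float(ta),
                theta_rest=float(tr),
                abundant_ids=template.abundant_ids,
                orientation=template.orientation,
                protein_var=template.protein_var,
            )
            phi = pred.mask(table)
            results = find_causes_from_mask(indexes, phi, k=k, mode=mode)
            top = tuple(
                (r.assignment.value, r.conditional_probability)
                for r in results
                if r.is_cause and r.rank is not None
            )
            row.append(top)
        rows.append(tuple(row))
    return SweepGrid(theta_a, theta_r, tuple(rows), k=k, mode=mode)


@dataclass(frozen=True)
class FrequencyTable:
    """Per-rank cell counts and percentages for each cause value.

    ``counts[r]`` maps each cause value (plus the ``None`` token for
    cause-free slots) to the number of grid cells where it holds rank ``r``;
    per rank, the counts sum exactly to ``total_cells``.
    """

    counts: dict[int, dict[str, int]]
    total_cells: int

    def percent(self, rank: int, value: Any) -> float:
        return 100.0 * self.counts[rank].get(str(value), 0) / self.total_cells

    def values(self) -> list[str]:
        """All cause values observed at any rank, None token last."""
        seen = {v for c in self.counts.values() for v in c}
        ordered = sorted(seen - {NONE_TOKEN})
        if NONE_TOKEN in seen:
            ordered.append(NONE_TOKEN)
        return ordered

    def to_dataframe(self) -> pd.DataFrame:
        """Long summary: one row per cause value, count/percent per rank."""
        rows = []
        for value in self.values():
            row: dict[str, Any] = {"cause_value": value}
            for r in sorted(self.counts):
                row[f"rank{r}_count"] = self.counts[r].get(value, 0)
                row[f"rank{r}_percent"] = self.percent(r, value)
            rows.append(row)
        return pd.DataFrame(rows)


def frequency_table(grid: SweepGrid) -> FrequencyTable:
    """Tally, per rank, how many cells attribute that rank to each value."""
    counts: dict[int, dict[str, int]] = {}
    for r in range(1, grid.k + 1):
        tally: Counter[str] = Counter()
        for i in range(len(grid.theta_abundant_axis)):
            for j in range(len(grid.theta_rest_axis)):
                v = grid.rank_value(i, j, r)
                tally[NONE_TOKEN if v is None else str(v)] += 1
        counts[r] = dict(tally)
    return FrequencyTable(counts=counts, total_cells=grid.n_cells)


def top3_membership_rate(grid: SweepGrid, value: Any) -> float:
    """Percent of cells where ``value`` appears at any rank 1..k."""
    hits = sum(
        1
        for i in range(len(grid.theta_abundant_axis))
        for j in range(len(grid.theta_rest_axis))
        if any(v == value for v, _ in grid.cells[i][j])
    )
    return 100.0 * hits / grid.n_cells
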